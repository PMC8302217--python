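"""End-to-end orchestration of the analysis stages on one config.

Runs, in order: simulation (or loading of user inputs), architecture
classification, BBH orthology, evolutionary reconstruction and
reconciliation, conservation ages and tables, differential expression,
enrichment, PTM comparison and locus synteny.  Stage outputs are written
under a run directory together with a manifest (seed, parameters,
package version); deterministic stages are bit-reproducible and
stochastic stages reproduce under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .species import default_ladder
from . import synthetic_data as sd
from . import gene_architecture as ga
from . import orthology as orth
from . import evolution as evo
from . import conservation as cons
from . import expression as expr
from . import enrichment as enr
from . import ptm_mip as ptm
from . import synteny as syn

log = logging.getLogger("igpipe.pipeline")

STAGES = ("architecture", "orthology", "evolution", "conservation",
          "expression", "enrichment", "ptm", "synteny")


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


@dataclass
class PipelineConfig:
    outdir: str = "igpipe_run"
    seed: int = 0
    simulation: sd.SimulationConfig = field(default_factory=sd.SimulationConfig)
    min_identity: float = 50.0
    alpha: float = 0.05
    de_min_count: int = 5
    de_min_samples: int = 4
    age_mode: str = "strict"
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        sim = sd.SimulationConfig(**raw.pop("simulation", {}))
        cfg = cls(simulation=sim, **raw)
        return cfg

    def enabled(self, stage: str) -> bool:
        return bool(self.stages.get(stage, True))


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - reported with stage name
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all enabled stages on simulated data; returns the report bundle."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ladder = default_ladder()
    report: dict = {}

    log.info("simulating inputs (seed=%d)", config.seed)
    bundle = sd.simulate_bundle(config.simulation, outdir / "inputs",
                                seed=config.seed)
    species_of = orth.read_species_map(bundle["species_map"])

    arch_calls: list[ga.ArchitectureCall] = []
    if config.enabled("architecture"):
        arch_calls = _run_architecture(bundle, ladder, outdir, report)
    arch_map = ga.architecture_map(arch_calls)

    graph = None
    groups: list[set] = []
    if config.enabled("orthology"):
        graph, groups = _run_orthology(bundle, species_of, config, outdir,
                                       report)

    if config.enabled("evolution") and graph is not None:
        _run_evolution(graph, groups, species_of, ladder, outdir, report)

    profiles: list[cons.PresenceProfile] = []
    if config.enabled("conservation") and graph is not None:
        profiles = _run_conservation(graph, arch_map, config, outdir, report)

    calls: list[expr.DECall] = []
    if config.enabled("expression"):
        calls = _run_expression(bundle, config, outdir, report)

    if config.enabled("enrichment"):
        _run_enrichment(arch_map, config, outdir, report)

    if config.enabled("ptm"):
        _run_ptm(config, outdir, report)

    if config.enabled("synteny"):
        _run_synteny(bundle, groups, species_of, outdir, report)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "min_identity": config.min_identity,
            "alpha": config.alpha,
            "age_mode": config.age_mode,
            "simulation": dataclasses.asdict(config.simulation),
        },
        "stages": {s: config.enabled(s) for s in STAGES},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    (outdir / "report.json").write_text(json.dumps(report, indent=1, default=str))
    return report


@_stage("architecture")
def _run_architecture(bundle, ladder, outdir, report):
    calls = []
    census = {}
    for sp in ladder.leaves:
        sp_calls, rep = ga.classify_annotation(bundle[f"gtf_{sp}"], sp)
        calls.extend(sp_calls)
        census[sp] = rep
        ga.write_calls(sp_calls, sp, outdir / f"architecture.{sp}", rep)
    report["architecture"] = census
    return calls


@_stage("orthology")
def _run_orthology(bundle, species_of, config, outdir, report):
    records = orth.read_similarity(bundle["similarity"])
    result = orth.infer_orthology(records, species_of, config.min_identity)
    orth.write_orthogroups(result.orthogroups, species_of,
                           outdir / "orthogroups.tsv")
    pd.DataFrame(result.edges, columns=["gene_a", "gene_b"]).to_csv(
        outdir / "orthology_edges.tsv", sep="\t", index=False)
    report["orthology"] = {
        "edges": len(result.edges),
        "orthogroups": len(result.orthogroups),
    }
    return result.graph, result.orthogroups


@_stage("evolution")
def _run_evolution(graph, groups, species_of, ladder, outdir, report):
    histories = evo.reconstruct_all(graph, groups, species_of, ladder)
    summary = evo.summarize_histories(histories, ladder)
    summary.to_csv(outdir / "evolution_summary.tsv", sep="\t", index=False)
    with open(outdir / "gene_trees.nwk", "w") as fh:
        for h in histories:
            fh.write(evo.event_newick(h.tree) + "\n")
    report["evolution"] = {
        "families": len(histories),
        "duplications": int(sum(h.reconciliation.duplication_count
                                for h in histories)),
        "losses": int(sum(h.reconciliation.loss_count for h in histories)),
        "edited_families": int(sum(1 for h in histories if h.edits)),
    }
    return histories


@_stage("conservation")
def _run_conservation(graph, arch_map, config, outdir, report):
    profiles = cons.profiles_from_graph(graph, arch_map)
    table = cons.architecture_table(profiles)
    fractions = cons.conservation_fractions(table)
    fractions.to_csv(outdir / "conservation_table.tsv", sep="\t", index=False)
    ages = cons.age_table(profiles, config.age_mode)
    ages.to_csv(outdir / "ages.tsv", sep="\t", index=False)
    report["conservation"] = {
        "profiles": len(profiles),
        "pooled_pct_IG": fractions.attrs.get("pooled_pct_IG"),
        "ages": ages["age"].value_counts().to_dict(),
    }
    return profiles


@_stage("expression")
def _run_expression(bundle, config, outdir, report):
    matrix = pd.read_csv(bundle["counts"], sep="\t", index_col=0)
    design_df = pd.read_csv(bundle["design"], sep="\t")
    design = dict(zip(design_df["sample"], design_df["condition"]))
    calls, tally = expr.run_de(
        matrix, design, alpha=config.alpha,
        min_count=config.de_min_count, min_samples=config.de_min_samples)
    pd.DataFrame(
        [(c.gene, c.log2fc, c.pvalue, c.klass) for c in calls],
        columns=["gene", "log2fc", "p", "class"],
    ).to_csv(outdir / "de_calls.tsv", sep="\t", index=False)
    (outdir / "de_tally.json").write_text(json.dumps(tally, indent=1))
    report["expression"] = tally
    return calls


@_stage("enrichment")
def _run_enrichment(arch_map, config, outdir, report):
    # toy term map over the classified genes: one term per architecture
    # class plus shuffled decoy terms, so the stage exercises a real
    # study-vs-background contrast on simulated data
    rng = np.random.default_rng(config.seed + 17)
    genes = sorted(g for g, a in arch_map.items() if a in ("IG", "MEG"))
    if not genes:
        report["enrichment"] = {"terms": 0}
        return []
    terms: dict[str, set] = {}
    for g in genes:
        terms[g] = set()
        if arch_map[g] == "IG" and rng.random() < 0.6:
            terms[g].add("DOMAIN:single_exon_signature")
        if rng.random() < 0.3:
            terms[g].add("DOMAIN:common_fold")
    study = [g for g in genes if arch_map[g] == "IG"]
    results = enr.hypergeom_enrich(study, genes, terms)
    enr.enrichment_frame(results).to_csv(
        outdir / "enrichment.tsv", sep="\t", index=False)
    report["enrichment"] = {
        "terms": len(results),
        "significant": sum(1 for r in results
                           if r.pvalue <= config.alpha and r.qvalue <= 0.10),
    }
    return results


@_stage("ptm")
def _run_ptm(config, outdir, report):
    props = {
        "Acetylation": (0.30, 0.10),
        "Phosphorylation": (0.35, 0.60),
        "Succinylation": (0.20, 0.20),
        "Myristoylation": (0.0, 0.05),
    }
    table = sd.emit_ptm_table(props, n_ig=400, n_meg=400,
                              seed=config.seed + 23)
    comps, summary = ptm.classify_all_ptms(table, 400, 400, config.alpha)
    ptm.comparison_frame(comps).to_csv(outdir / "ptm_comparison.tsv",
                                       sep="\t", index=False)
    report["ptm"] = summary
    return comps


@_stage("synteny")
def _run_synteny(bundle, groups, species_of, outdir, report):
    og_of = {g: f"OG{i:05d}" for i, grp in enumerate(groups)
             for g in grp}
    loci = {}
    for sp in ("mouse", "rat"):
        genes = ga.read_annotation(bundle[f"gtf_{sp}"], sp)
        nuclear = [g for g in genes if g.chrom == "chr1"]
        end = max((g.end for g in nuclear), default=1)
        loci[sp] = syn.extract_locus(nuclear, sp, "chr1", 1, end, og_of)
    rep = syn.pairwise_synteny(loci["mouse"], loci["rat"])
    syn.report_frame(rep).to_csv(outdir / "synteny.tsv", sep="\t",
                                 index=False)
    syn.locus_svg(loci["mouse"], loci["rat"], outdir / "synteny.svg")
    report["synteny"] = {
        "matches": len(rep.matches),
        "losses": len(rep.losses),
        "novel": len(rep.novel),
        "expansions": len(rep.expansions),
        "inversions": rep.inversions,
    }
    return rep
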