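"""Synthetic inputs with known ground truth for every pipeline stage.

Gene families are generated by a birth--death process along the fixed
species ladder: each lineage entering a species-tree branch experiences
duplications and losses as Poisson events at the configured per-branch
rates, placed uniformly on the branch.  The resulting event tree (nodes
labeled speciation / duplication / loss / leaf) yields, per family,

* the extant genes of each species,
* the true orthology relation -- two extant genes are orthologs iff their
  last common ancestor in the event tree is a speciation node (this
  relation is always a cograph),
* a true gene architecture (IG or MEG) evolved along the tree with a
  per-edge switch probability.

From these histories the emitters write the concrete files the pipeline
consumes: per-species GTF annotations (with optional decoy records that
exercise the exclusion filters), BLAST-tabular similarity tables
consistent with the true orthology, a negative-binomial count matrix with
planted differentially-expressed genes, and PTM tables with planted
proportion differences.  All emitters are deterministic under a fixed
seed.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .species import SpeciesLadder, default_ladder

# ---------------------------------------------------------------------------
# configuration


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults are the study conditions.

    Duplication/loss rates are expected events per species-tree branch
    (branch lengths are 1).  The count matrix follows a 4-vs-4 two-stage
    design.
    """

    n_families: int = 500
    duplication_rate: float = 0.3
    loss_rate: float = 0.2
    ig_prob: float = 0.3
    switch_prob: float = 0.1
    similarity_noise: float = 0.0
    decoy_fraction: float = 0.0
    # count-matrix parameters
    n_genes: int = 2000
    reps_per_condition: int = 4
    nb_dispersion: float = 0.1
    de_fraction: float = 0.1
    ne_fraction: float = 0.25
    log2_effect: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duplication_rate < 0 or self.loss_rate < 0:
            raise ValueError("rates must be >= 0")
        if not math.isfinite(self.duplication_rate + self.loss_rate):
            raise ValueError("rates must be finite")
        for name in ("ig_prob", "switch_prob", "de_fraction", "ne_fraction",
                     "decoy_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.similarity_noise < 0.5:
            raise ValueError("similarity_noise must be in [0, 0.5)")
        if self.reps_per_condition < 2:
            raise ValueError("need >= 2 replicates per condition")


# ---------------------------------------------------------------------------
# event trees

SPECIATION = "speciation"
DUPLICATION = "duplication"
LOSS = "loss"
LEAF = "leaf"


@dataclass
class EventNode:
    """Node of a gene-family event tree.

    ``species`` is the species-tree node at which the event happens: the
    ladder node for a speciation, the *target* species node of the branch
    carrying a duplication or loss, and the species for an extant leaf.
    """

    kind: str
    species: str
    children: list["EventNode"] = field(default_factory=list)
    gene_id: str | None = None
    architecture: str | None = None

    def walk(self) -> Iterable["EventNode"]:
        yield self
        for c in self.children:
            yield from c.walk()

    def extant_leaves(self) -> list["EventNode"]:
        return [n for n in self.walk() if n.kind == LEAF]


@dataclass
class TrueHistory:
    """Simulator output for one gene family, with ground truth."""

    family_id: str
    root: EventNode
    ladder: SpeciesLadder
    extant: list[tuple[str, str]]          # (gene id, species)
    architectures: dict[str, str]          # gene id -> IG | MEG
    ortholog_pairs: set[frozenset]         # unordered gene-id pairs
    duplication_events: list[str]          # species branch per raw event
    loss_events: list[str]
    speciation_count: int
    duplication_rate: float
    loss_rate: float
    seed: int

    @property
    def species_of(self) -> dict[str, str]:
        return dict(self.extant)

    def event_census(self) -> dict[str, int]:
        """Counts of node kinds in the emitted tree (bookkeeping check)."""
        out = {SPECIATION: 0, DUPLICATION: 0, LOSS: 0, LEAF: 0}
        for n in self.root.walk():
            out[n.kind] += 1
        return out


def simulate_gene_family(
    ladder: SpeciesLadder,
    config: SimulationConfig,
    seed: int,
    family_id: str = "fam0",
) -> TrueHistory:
    """Run the birth--death process for one family; reproducible per seed."""
    rng = np.random.default_rng(seed)
    dup_rate, loss_rate = config.duplication_rate, config.loss_rate
    counter = itertools.count(1)
    per_species: dict[str, int] = {}
    dup_events: list[str] = []
    loss_events: list[str] = []

    def flip(arch: str) -> str:
        if rng.random() < config.switch_prob:
            return "MEG" if arch == "IG" else "IG"
        return arch

    def at_node(sp: str, arch: str) -> EventNode:
        if not ladder.children[sp]:
            per_species[sp] = per_species.get(sp, 0) + 1
            gid = f"{family_id}_{sp}_g{per_species[sp]}"
            return EventNode(LEAF, sp, gene_id=gid, architecture=arch)
        kids = [on_branch(c, arch) for c in ladder.children[sp]]
        return EventNode(SPECIATION, sp, children=kids)

    def on_branch(sp: str, arch: str, remaining: float = 1.0) -> EventNode:
        # one architecture flip chance per event-tree edge
        arch = flip(arch)
        t_dup = rng.exponential(1.0 / dup_rate) if dup_rate > 0 else math.inf
        t_loss = rng.exponential(1.0 / loss_rate) if loss_rate > 0 else math.inf
        t = min(t_dup, t_loss)
        if t >= remaining:
            return at_node(sp, arch)
        if t_loss <= t_dup:
            loss_events.append(sp)
            return EventNode(LOSS, sp)
        dup_events.append(sp)
        left = on_branch(sp, arch, remaining - t_dup)
        right = on_branch(sp, arch, remaining - t_dup)
        return EventNode(DUPLICATION, sp, children=[left, right])

    root_arch = "IG" if rng.random() < config.ig_prob else "MEG"
    root = at_node(ladder.root, root_arch)

    extant = [(n.gene_id, n.species) for n in root.extant_leaves()]
    architectures = {n.gene_id: n.architecture for n in root.extant_leaves()}

    pairs: set[frozenset] = set()

    def gather(node: EventNode) -> list[str]:
        if node.kind == LEAF:
            return [node.gene_id]  # type: ignore[list-item]
        if node.kind == LOSS:
            return []
        lists = [gather(c) for c in node.children]
        if node.kind == SPECIATION:
            for a_list, b_list in itertools.combinations(lists, 2):
                for a in a_list:
                    for b in b_list:
                        pairs.add(frozenset((a, b)))
        return [g for lst in lists for g in lst]

    gather(root)
    n_spec = sum(1 for n in root.walk() if n.kind == SPECIATION)
    return TrueHistory(
        family_id=family_id,
        root=root,
        ladder=ladder,
        extant=extant,
        architectures=architectures,
        ortholog_pairs=pairs,
        duplication_events=dup_events,
        loss_events=loss_events,
        speciation_count=n_spec,
        duplication_rate=dup_rate,
        loss_rate=loss_rate,
        seed=seed,
    )


def simulate_families(
    ladder: SpeciesLadder, config: SimulationConfig, seed: int | None = None
) -> list[TrueHistory]:
    """Simulate ``config.n_families`` families with per-family child seeds."""
    base = config.seed if seed is None else seed
    ss = np.random.SeedSequence(base)
    seeds = ss.generate_state(config.n_families)
    return [
        simulate_gene_family(ladder, config, int(s) % (2**31 - 1),
                             family_id=f"fam{i:05d}")
        for i, s in enumerate(seeds)
    ]


# ---------------------------------------------------------------------------
# observable (recoverable) event totals


@dataclass
class ObservableCounts:
    duplications: int
    losses: int
    dups_per_branch: dict[str, int]
    losses_per_branch: dict[str, int]


def _restrict(node: EventNode, keep: set[str]) -> EventNode | None:
    """Topological restriction of the tree to the leaves in ``keep``.

    Unary nodes collapse; adjacent duplication nodes are flattened into
    one multifurcation (two duplications with no surviving speciation
    between them are indistinguishable from, and counted like, one
    multi-copy duplication burst).
    """
    if node.kind == LEAF:
        return node if node.gene_id in keep else None
    if node.kind == LOSS:
        return None
    kids = [r for r in (_restrict(c, keep) for c in node.children)
            if r is not None]
    if not kids:
        return None
    if len(kids) == 1:
        return kids[0]
    if node.kind == DUPLICATION:
        flat: list[EventNode] = []
        for k in kids:
            if k.kind == DUPLICATION:
                flat.extend(k.children)
            else:
                flat.append(k)
        kids = flat
    return EventNode(node.kind, node.species, children=kids)


def observable_event_counts(history: TrueHistory) -> ObservableCounts:
    """Duplication/loss totals recoverable from cross-species orthology.

    Events leave no trace in the orthology relation when every witness is
    gone: a fully-lost clade collapses to a single loss on its topmost
    branch; a duplication whose other copy left no extant descendants is
    invisible; paralog clades with no cross-species ortholog are
    disconnected from the orthology graph and unobservable.  Counting is
    therefore done per connected component of the true orthology relation
    on the pruned true event tree, by a direct recursion on the true labels
    (independent of the graph-based inference path this ground truth is
    used to test).
    """
    import networkx as nx

    ladder = history.ladder
    g = nx.Graph()
    for pair in history.ortholog_pairs:
        a, b = tuple(pair)
        g.add_edge(a, b)
    dups = 0
    dpb: dict[str, int] = {}
    lpb: dict[str, int] = {}
    losses = 0

    def mu(node: EventNode) -> str:
        return ladder.lca([leaf.species for leaf in node.extant_leaves()])

    def charge_losses(top: str, bottom: str, include_top: bool) -> None:
        nonlocal losses
        path = ladder.path_down(top, bottom)
        passed = path[:-1] if include_top else path[1:-1]
        for node in passed:
            taken = path[path.index(node) + 1]
            for off in ladder.off_path_children(node, taken):
                losses += 1
                lpb[off] = lpb.get(off, 0) + 1

    def count(node: EventNode) -> None:
        nonlocal dups
        if node.kind == LEAF:
            return
        img = mu(node)
        if node.kind == DUPLICATION:
            dups += len(node.children) - 1
            dpb[img] = dpb.get(img, 0) + len(node.children) - 1
            share_crossings(img, node.children)
        else:  # speciation
            for c in node.children:
                side = ladder.side_of(img, mu(c))
                charge_losses(side, mu(c), include_top=True)
                count(c)

    def share_crossings(anchor: str, copies: list[EventNode]) -> None:
        # copies of one duplication burst descend independently, but
        # copies confined to the same side of the anchor node coalesce at
        # a lower duplication and cross species nodes only once
        rest: dict[str, list[EventNode]] = {}
        for c in copies:
            m = mu(c)
            if m == anchor:
                count(c)
            else:
                rest.setdefault(ladder.side_of(anchor, m), []).append(c)
        for grp in rest.values():
            sub = ladder.lca([mu(c) for c in grp])
            charge_losses(anchor, sub, include_top=True)
            if len(grp) == 1:
                count(grp[0])
            else:
                share_crossings(sub, grp)

    for comp in nx.connected_components(g):
        sub = _restrict(history.root, set(comp))
        if sub is None or sub.kind == LEAF:
            continue
        count(sub)
    return ObservableCounts(dups, losses, dpb, lpb)


# ---------------------------------------------------------------------------
# annotation emission (GTF)

_DECOY_KINDS = ("mitochondrial", "non_coding", "multi_transcript",
                "utr_intron", "incomplete")

_GENE_SPAN = 900
_GENE_GAP = 1100


def _gtf_line(chrom, feature, start, end, strand, attrs) -> str:
    attr = " ".join(f'{k} "{v}";' for k, v in attrs)
    frame = "0" if feature == "CDS" else "."
    return f"{chrom}\tsim\t{feature}\t{start}\t{end}\t.\t{strand}\t{frame}\t{attr}\n"


def _emit_gene(lines, chrom, gid, start, arch, strand="+") -> None:
    """Write one protein-coding gene with the requested architecture."""
    tid = f"{gid}.t1"
    gene_attrs = [("gene_id", gid), ("gene_biotype", "protein_coding")]
    tx_attrs = gene_attrs[:1] + [("transcript_id", tid),
                                 ("gene_biotype", "protein_coding")]
    end = start + _GENE_SPAN - 1
    lines.append(_gtf_line(chrom, "gene", start, end, strand, gene_attrs))
    lines.append(_gtf_line(chrom, "transcript", start, end, strand, tx_attrs))
    if arch == "IG":
        lines.append(_gtf_line(chrom, "exon", start, end, strand, tx_attrs))
        lines.append(_gtf_line(chrom, "CDS", start + 100, start + 799,
                               strand, tx_attrs))
    else:  # MEG: two coding exons separated by an intron
        lines.append(_gtf_line(chrom, "exon", start, start + 199, strand,
                               tx_attrs))
        lines.append(_gtf_line(chrom, "exon", start + 400, end, strand,
                               tx_attrs))
        lines.append(_gtf_line(chrom, "CDS", start + 100, start + 199,
                               strand, tx_attrs))
        lines.append(_gtf_line(chrom, "CDS", start + 400, start + 700,
                               strand, tx_attrs))


def _emit_decoy(lines, kind, idx, start) -> dict:
    gid = f"decoy_{kind}_{idx}"
    tid = f"{gid}.t1"
    end = start + _GENE_SPAN - 1
    if kind == "mitochondrial":
        attrs_g = [("gene_id", gid), ("gene_biotype", "protein_coding")]
        attrs_t = [("gene_id", gid), ("transcript_id", tid),
                   ("gene_biotype", "protein_coding")]
        lines.append(_gtf_line("MT", "gene", start, end, "+", attrs_g))
        lines.append(_gtf_line("MT", "transcript", start, end, "+", attrs_t))
        lines.append(_gtf_line("MT", "exon", start, end, "+", attrs_t))
        lines.append(_gtf_line("MT", "CDS", start + 10, end - 10, "+", attrs_t))
        expect = ("EXCLUDED", "mitochondrial")
    elif kind == "non_coding":
        attrs_g = [("gene_id", gid), ("gene_biotype", "lncRNA")]
        attrs_t = [("gene_id", gid), ("transcript_id", tid),
                   ("gene_biotype", "lncRNA")]
        lines.append(_gtf_line("chr1", "gene", start, end, "+", attrs_g))
        lines.append(_gtf_line("chr1", "transcript", start, end, "+", attrs_t))
        lines.append(_gtf_line("chr1", "exon", start, end, "+", attrs_t))
        expect = ("EXCLUDED", "non_coding")
    elif kind == "incomplete":
        attrs_g = [("gene_id", gid), ("gene_biotype", "protein_coding")]
        attrs_t = [("gene_id", gid), ("transcript_id", tid),
                   ("gene_biotype", "protein_coding")]
        lines.append(_gtf_line("chr1", "gene", start, end, "+", attrs_g))
        lines.append(_gtf_line("chr1", "transcript", start, end, "+", attrs_t))
        lines.append(_gtf_line("chr1", "exon", start, end, "+", attrs_t))
        expect = ("EXCLUDED", "incomplete_annotation")
    elif kind == "multi_transcript":
        attrs_g = [("gene_id", gid), ("gene_biotype", "protein_coding")]
        lines.append(_gtf_line("chr1", "gene", start, end, "+", attrs_g))
        for j in (1, 2):
            t = f"{gid}.t{j}"
            attrs_t = [("gene_id", gid), ("transcript_id", t),
                       ("gene_biotype", "protein_coding")]
            lines.append(_gtf_line("chr1", "transcript", start, end, "+",
                                   attrs_t))
            lines.append(_gtf_line("chr1", "exon", start, end, "+", attrs_t))
            lines.append(_gtf_line("chr1", "CDS", start + 100, start + 799,
                                   "+", attrs_t))
        expect = ("MEG", "multi_transcript")
    elif kind == "utr_intron":
        # uiSEG: one coding exon plus a separate 5' UTR exon
        attrs_g = [("gene_id", gid), ("gene_biotype", "protein_coding")]
        attrs_t = [("gene_id", gid), ("transcript_id", tid),
                   ("gene_biotype", "protein_coding")]
        lines.append(_gtf_line("chr1", "gene", start, end, "+", attrs_g))
        lines.append(_gtf_line("chr1", "transcript", start, end, "+", attrs_t))
        lines.append(_gtf_line("chr1", "exon", start, start + 99, "+", attrs_t))
        lines.append(_gtf_line("chr1", "exon", start + 300, end, "+", attrs_t))
        lines.append(_gtf_line("chr1", "CDS", start + 350, start + 800, "+",
                               attrs_t))
        expect = ("MEG", "utr_intron")
    else:  # pragma: no cover
        raise ValueError(kind)
    return {"gene_id": gid, "expected_class": expect[0],
            "expected_reason": expect[1]}


def emit_annotations(
    histories: Sequence[TrueHistory],
    config: SimulationConfig,
    seed: int,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write one GTF per species; returns species -> path.

    Each extant gene becomes a protein-coding gene record whose exon/CDS
    geometry encodes its true architecture.  ``config.decoy_fraction``
    plants additional records (mitochondrial contig, non-coding biotype,
    multi-transcript, uiSEG, missing CDS) for the exclusion filters; their
    expected calls are recorded in ``<species>.decoys.json``.
    """
    if not histories:
        raise ValueError("histories must be non-empty")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ladder = histories[0].ladder
    rng = np.random.default_rng(seed)
    paths: dict[str, Path] = {}
    for species in ladder.leaves:
        genes = [
            (gid, h.architectures[gid])
            for h in histories
            for gid, sp in h.extant
            if sp == species
        ]
        lines: list[str] = []
        pos = 1000
        for gid, arch in genes:
            _emit_gene(lines, "chr1", gid, pos, arch)
            pos += _GENE_GAP
        n_decoys = int(round(config.decoy_fraction * len(genes)))
        decoys = []
        for i in range(n_decoys):
            kind = _DECOY_KINDS[int(rng.integers(len(_DECOY_KINDS)))]
            decoys.append(_emit_decoy(lines, kind, i, pos))
            pos += _GENE_GAP
        path = outdir / f"{species}.gtf"
        path.write_text("".join(lines))
        (outdir / f"{species}.decoys.json").write_text(
            json.dumps(decoys, indent=1))
        paths[species] = path
    return paths


# ---------------------------------------------------------------------------
# similarity emission

SIMILARITY_COLUMNS = ("qseqid", "sseqid", "pident", "length", "bitscore")


def emit_similarity(
    history: TrueHistory, noise: float = 0.0, seed: int = 0
) -> pd.DataFrame:
    """BLAST-tabular records consistent with the family's true orthology.

    All true-ortholog pairs of the family share one identity draw above
    the 50% threshold (so reciprocal-best-hit search with co-best ties
    recovers one-to-many orthology exactly); cross-species non-ortholog
    pairs get identities well below it.  Within-species pairs emit no
    record.  ``noise`` adds per-record Gaussian jitter (sd = 40*noise
    identity points) that erodes both the threshold margin and the tie
    structure.
    """
    if not 0.0 <= noise < 0.5:
        raise ValueError("noise must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    species = history.species_of
    ortho_identity = float(rng.uniform(70.0, 90.0))
    rows: list[tuple] = []
    genes = [g for g, _ in history.extant]
    aln_len = 200
    for a, b in itertools.combinations(genes, 2):
        if species[a] == species[b]:
            continue
        if frozenset((a, b)) in history.ortholog_pairs:
            base = ortho_identity
        else:
            base = float(rng.uniform(10.0, 35.0))
        for q, s in ((a, b), (b, a)):
            ident = base + (rng.normal(0.0, 40.0 * noise) if noise > 0 else 0.0)
            ident = float(min(100.0, max(1.0, ident)))
            rows.append((q, s, round(ident, 3), aln_len,
                         round(ident * 2.0, 3)))
    return pd.DataFrame(rows, columns=SIMILARITY_COLUMNS)


def emit_similarity_table(
    histories: Sequence[TrueHistory],
    noise: float = 0.0,
    seed: int = 0,
    path: str | Path | None = None,
) -> pd.DataFrame:
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(len(histories))
    frames = [
        f for f in (
            emit_similarity(h, noise, int(s) % (2**31 - 1))
            for h, s in zip(histories, seeds)
        ) if not f.empty
    ]
    df = (pd.concat(frames, ignore_index=True) if frames
          else pd.DataFrame(columns=SIMILARITY_COLUMNS))
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df


# ---------------------------------------------------------------------------
# count matrix


def emit_counts(
    config: SimulationConfig, seed: int
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Integer gene x (2*reps) count matrix plus truth labels UP/DN/NC/NE.

    Expressed genes draw negative-binomial counts (mean lognormal around
    100, dispersion ``nb_dispersion``); planted UP/DN genes shift the
    stage-B mean by ``2**log2_effect``; NE genes are capped below the
    expression floor (every count <= 4).
    """
    rng = np.random.default_rng(seed)
    n, reps = config.n_genes, config.reps_per_condition
    genes = [f"g{i:05d}" for i in range(n)]
    samples = [f"A{j+1}" for j in range(reps)] + [f"B{j+1}" for j in range(reps)]
    n_ne = int(round(config.ne_fraction * n))
    n_expressed = n - n_ne
    n_de = int(round(config.de_fraction * n_expressed))
    n_up = n_de // 2
    n_dn = n_de - n_up

    labels: dict[str, str] = {}
    counts = np.zeros((n, 2 * reps), dtype=np.int64)
    order = rng.permutation(n)
    ne_idx = order[:n_ne]
    up_idx = order[n_ne:n_ne + n_up]
    dn_idx = order[n_ne + n_up:n_ne + n_up + n_dn]
    nc_idx = order[n_ne + n_de:]

    counts[ne_idx] = np.minimum(rng.poisson(0.5, size=(len(ne_idx), 2 * reps)), 4)
    for idx in ne_idx:
        labels[genes[idx]] = "NE"

    expressed = np.concatenate([up_idx, dn_idx, nc_idx])
    base_mean = rng.lognormal(mean=np.log(100.0), sigma=1.0,
                              size=len(expressed))
    base_mean = np.maximum(base_mean, 10.0)
    fold = np.ones(len(expressed))
    fold[: len(up_idx)] = 2.0 ** config.log2_effect
    fold[len(up_idx): len(up_idx) + len(dn_idx)] = 2.0 ** (-config.log2_effect)

    def nb(mean: np.ndarray, size: tuple) -> np.ndarray:
        if config.nb_dispersion <= 0:
            return rng.poisson(mean[:, None], size=size)
        r = 1.0 / config.nb_dispersion
        p = r / (r + mean)
        return rng.negative_binomial(r, p[:, None], size=size)

    counts[expressed, :reps] = nb(base_mean, (len(expressed), reps))
    counts[expressed, reps:] = nb(base_mean * fold, (len(expressed), reps))
    for pos, idx in enumerate(expressed):
        if pos < len(up_idx):
            labels[genes[idx]] = "UP"
        elif pos < len(up_idx) + len(dn_idx):
            labels[genes[idx]] = "DN"
        else:
            labels[genes[idx]] = "NC"
    df = pd.DataFrame(counts, index=pd.Index(genes, name="gene"),
                      columns=samples)
    return df, labels


# ---------------------------------------------------------------------------
# PTM table


def emit_ptm_table(
    proportions: dict[str, tuple[float, float]],
    n_ig: int,
    n_meg: int,
    seed: int,
) -> pd.DataFrame:
    """Long-format PTM records: one row per (protein, modification).

    ``proportions[ptm] = (p_ig, p_meg)`` are per-protein Bernoulli rates.
    A PTM with proportion 0 in a class appears on no protein of the class.
    """
    if n_ig <= 0 or n_meg <= 0:
        raise ValueError("n_ig and n_meg must be positive")
    for ptm, (p_ig, p_meg) in proportions.items():
        if not (0.0 <= p_ig <= 1.0 and 0.0 <= p_meg <= 1.0):
            raise ValueError(f"proportions for {ptm!r} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rows: list[tuple[str, str, str]] = []
    for ptm, (p_ig, p_meg) in sorted(proportions.items()):
        for i in range(n_ig):
            if rng.random() < p_ig:
                rows.append((f"ig_{i:05d}", ptm, "IG"))
        for i in range(n_meg):
            if rng.random() < p_meg:
                rows.append((f"meg_{i:05d}", ptm, "MEG"))
    return pd.DataFrame(rows, columns=["protein_id", "ptm_type", "class"])


# ---------------------------------------------------------------------------
# bundle writer (used by the CLI and the pipeline)


def write_truth(histories: Sequence[TrueHistory], path: str | Path) -> None:
    payload = []
    for h in histories:
        obs = observable_event_counts(h)
        payload.append({
            "family_id": h.family_id,
            "extant": h.extant,
            "architectures": h.architectures,
            "ortholog_pairs": sorted(sorted(p) for p in h.ortholog_pairs),
            "raw_duplications": len(h.duplication_events),
            "raw_losses": len(h.loss_events),
            "observable_duplications": obs.duplications,
            "observable_losses": obs.losses,
        })
    Path(path).write_text(json.dumps(payload, indent=1))


def write_species_map(
    histories: Sequence[TrueHistory], path: str | Path
) -> pd.DataFrame:
    rows = [(g, sp) for h in histories for g, sp in h.extant]
    df = pd.DataFrame(rows, columns=["gene_id", "species"])
    df.to_csv(path, sep="\t", index=False)
    return df


def simulate_bundle(
    config: SimulationConfig, outdir: str | Path, seed: int | None = None
) -> dict[str, Path]:
    """Simulate and write every input the pipeline consumes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    base = config.seed if seed is None else seed
    ladder = default_ladder()
    histories = simulate_families(ladder, config, base)
    paths = emit_annotations(histories, config, base + 1, outdir / "annotations")
    sim_path = outdir / "similarity.tsv"
    emit_similarity_table(histories, config.similarity_noise, base + 2, sim_path)
    map_path = outdir / "species_map.tsv"
    write_species_map(histories, map_path)
    counts, labels = emit_counts(config, base + 3)
    counts_path = outdir / "counts.tsv"
    counts.to_csv(counts_path, sep="\t")
    design = pd.DataFrame({
        "sample": counts.columns,
        "condition": ["A"] * config.reps_per_condition
                     + ["B"] * config.reps_per_condition,
    })
    design_path = outdir / "design.tsv"
    design.to_csv(design_path, sep="\t", index=False)
    (outdir / "de_truth.json").write_text(json.dumps(labels, indent=1))
    truth_path = outdir / "truth.json"
    write_truth(histories, truth_path)
    ladder_path = outdir / "ladder.nwk"
    ladder_path.write_text(ladder.to_newick() + "\n")
    manifest = {
        "config": dataclasses.asdict(config), "seed": base,
        "n_families": len(histories),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    out = {"similarity": sim_path, "species_map": map_path,
           "counts": counts_path, "design": design_path,
           "truth": truth_path, "ladder": ladder_path}
    out.update({f"gtf_{sp}": p for sp, p in paths.items()})
    return out
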