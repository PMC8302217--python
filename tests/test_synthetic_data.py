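import itertools
import json

import networkx as nx
import numpy as np
import pytest

from igpipe.species import default_ladder
from igpipe.synthetic_data import (
    LEAF, LOSS, DUPLICATION, SPECIATION,
    SimulationConfig, simulate_gene_family, simulate_families,
    observable_event_counts, emit_annotations, emit_similarity,
    emit_similarity_table, emit_counts, emit_ptm_table,
)
from igpipe import gene_architecture as ga
from igpipe import orthology as orth

from conftest import true_orthology_graph


def has_induced_p4(graph):
    """Exhaustive induced-P4 search (independent of the package's cotree)."""
    for quad in itertools.combinations(graph.nodes, 4):
        sub = graph.subgraph(quad)
        degs = sorted(d for _, d in sub.degree())
        if sub.number_of_edges() == 3 and degs == [1, 1, 2, 2]:
            return True
    return False


class TestSimulateGeneFamily:
    def test_no_events_gives_one_gene_per_species(self, ladder):
        cfg = SimulationConfig(duplication_rate=0.0, loss_rate=0.0)
        h = simulate_gene_family(ladder, cfg, 3)
        assert len(h.extant) == 7
        assert {sp for _, sp in h.extant} == set(ladder.leaves)
        assert len(h.ortholog_pairs) == 21
        # event tree congruent to the ladder: speciations at every
        # internal ladder node, nothing else
        kinds = h.event_census()
        assert kinds[SPECIATION] == 6 and kinds[DUPLICATION] == 0
        assert kinds[LOSS] == 0 and kinds[LEAF] == 7

    def test_no_events_orthology_is_complete_and_p4_free(self, ladder):
        cfg = SimulationConfig(duplication_rate=0.0, loss_rate=0.0)
        h = simulate_gene_family(ladder, cfg, 4)
        g = true_orthology_graph(h)
        assert g.number_of_edges() == 21  # K7
        assert not has_induced_p4(g)

    def test_leaf_count_matches_naive_recount(self, ladder):
        cfg = SimulationConfig(duplication_rate=0.5, loss_rate=0.3)
        for seed in range(10):
            h = simulate_gene_family(ladder, cfg, seed)

            def recount(node):  # independent recursive traversal
                if node.kind == LEAF:
                    return 1
                return sum(recount(c) for c in node.children)

            assert recount(h.root) == len(h.extant)

    def test_orthology_is_always_a_cograph(self, small_batch):
        checked = 0
        for h in small_batch:
            if len(h.extant) <= 25:
                assert not has_induced_p4(true_orthology_graph(h))
                checked += 1
        assert checked > 10

    def test_no_same_species_ortholog_pairs(self, small_batch):
        for h in small_batch:
            sp = h.species_of
            for pair in h.ortholog_pairs:
                a, b = tuple(pair)
                assert sp[a] != sp[b]

    def test_event_census_bookkeeping(self, small_batch):
        for h in small_batch:
            census = h.event_census()
            assert census[DUPLICATION] == len(h.duplication_events)
            assert census[LOSS] == len(h.loss_events)
            assert census[SPECIATION] == h.speciation_count
            assert census[LEAF] == len(h.extant)

    def test_same_seed_reproduces(self, ladder):
        cfg = SimulationConfig()
        a = simulate_gene_family(ladder, cfg, 99)
        b = simulate_gene_family(ladder, cfg, 99)
        assert a.extant == b.extant
        assert a.ortholog_pairs == b.ortholog_pairs
        assert a.architectures == b.architectures

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(duplication_rate=-1)
        with pytest.raises(ValueError):
            SimulationConfig(ig_prob=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(similarity_noise=0.7)
        with pytest.raises(ValueError):
            SimulationConfig(reps_per_condition=1)


class TestEmitAnnotations:
    def test_round_trip_recovers_planted_architecture(
            self, ladder, small_batch, tmp_path):
        cfg = SimulationConfig(decoy_fraction=0.0)
        paths = emit_annotations(small_batch, cfg, 5, tmp_path)
        truth = {g: a for h in small_batch for g, a in h.architectures.items()}
        seen = 0
        for sp, path in paths.items():
            genes = ga.read_annotation(path, sp)
            for gene in genes:
                call = ga.classify_gene(gene)
                assert call.klass == truth[gene.gene_id], gene.gene_id
                seen += 1
        assert seen == sum(len(h.extant) for h in small_batch)

    def test_decoys_hit_the_planted_filters(self, ladder, small_batch,
                                            tmp_path):
        cfg = SimulationConfig(decoy_fraction=0.2)
        paths = emit_annotations(small_batch, cfg, 6, tmp_path)
        n_decoys = 0
        for sp, path in paths.items():
            decoys = json.loads(
                (tmp_path / f"{sp}.decoys.json").read_text())
            calls = {c.gene_id: c
                     for c in (ga.classify_gene(g)
                               for g in ga.read_annotation(path, sp))}
            for d in decoys:
                call = calls[d["gene_id"]]
                assert call.klass == d["expected_class"]
                assert call.reason == d["expected_reason"]
                n_decoys += 1
        assert n_decoys > 0

    def test_empty_histories_rejected(self):
        with pytest.raises(ValueError):
            emit_annotations([], SimulationConfig(), 0, "/tmp/none")


class TestEmitSimilarity:
    def test_noise_free_bbh_round_trip(self, small_batch):
        df = emit_similarity_table(small_batch, 0.0, 17)
        species_of = {g: sp for h in small_batch for g, sp in h.extant}
        recs = [orth.SimilarityRecord(r.qseqid, r.sseqid, r.pident,
                                      r.length, r.bitscore)
                for r in df.itertuples(index=False)]
        edges = set(orth.best_bidirectional_hits(recs, species_of))
        truth = {tuple(sorted(p))
                 for h in small_batch for p in h.ortholog_pairs}
        assert edges == truth

    def test_no_same_species_records_and_percent_scale(self, small_batch):
        h = max(small_batch, key=lambda h: len(h.extant))
        df = emit_similarity(h, 0.2, 3)
        sp = h.species_of
        assert all(sp[q] != sp[s]
                   for q, s in zip(df.qseqid, df.sseqid))
        assert ((df.pident > 0) & (df.pident <= 100)).all()

    def test_noise_bound_enforced(self, small_batch):
        with pytest.raises(ValueError):
            emit_similarity(small_batch[0], 0.5, 1)


class TestEmitCounts:
    def test_all_low_genes_are_ne_and_determinism(self):
        cfg = SimulationConfig(n_genes=300, ne_fraction=0.3)
        m1, lab1 = emit_counts(cfg, 8)
        m2, lab2 = emit_counts(cfg, 8)
        assert m1.equals(m2) and lab1 == lab2
        ne = [g for g, l in lab1.items() if l == "NE"]
        assert len(ne) == 90
        assert (m1.loc[ne] <= 4).all().all()  # below the 5-count floor

    def test_null_config_type_one_error(self):
        cfg = SimulationConfig(n_genes=2000, de_fraction=0.0,
                               ne_fraction=0.0, log2_effect=0.0)
        matrix, labels = emit_counts(cfg, 11)
        assert set(labels.values()) == {"NC"}
        from igpipe import expression as expr
        design = {c: ("A" if c.startswith("A") else "B")
                  for c in matrix.columns}
        _, tally = expr.run_de(matrix, design)
        rate = (tally["counts"]["UP"] + tally["counts"]["DN"]) / 2000
        se = (0.05 * 0.95 / 2000) ** 0.5
        assert abs(rate - 0.05) <= 3 * se


class TestEmitPtmTable:
    def test_zero_proportion_class_absent(self):
        df = emit_ptm_table({"ac": (0.0, 0.1)}, 200, 200, 4)
        assert (df["class"] == "MEG").all()
        assert df["ptm_type"].eq("ac").all()

    def test_degenerate_totals_rejected(self):
        with pytest.raises(ValueError):
            emit_ptm_table({"ac": (0.1, 0.1)}, 0, 10, 1)
        with pytest.raises(ValueError):
            emit_ptm_table({"ac": (1.2, 0.1)}, 10, 10, 1)


class TestObservableCounts:
    def test_no_event_family_has_zero_observable_events(self, ladder):
        cfg = SimulationConfig(duplication_rate=0.0, loss_rate=0.0)
        h = simulate_gene_family(ladder, cfg, 2)
        obs = observable_event_counts(h)
        assert obs.duplications == 0 and obs.losses == 0

    def test_observable_never_exceeds_raw(self, small_batch):
        for h in small_batch:
            obs = observable_event_counts(h)
            assert obs.duplications <= len(h.duplication_events)
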