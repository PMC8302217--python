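import math

import numpy as np
import pandas as pd
import pytest

from igpipe.expression import (
    class_tally, classify_de, cpm_normalize, de_test, expression_floor,
    run_de, strong_subset, tally,
)
from igpipe.synthetic_data import SimulationConfig, emit_counts

SAMPLES = [f"{c}{i}" for c in "AB" for i in range(1, 5)]
DESIGN = {s: s[0] for s in SAMPLES}


def matrix(rows, genes=None):
    genes = genes or [f"g{i}" for i in range(len(rows))]
    return pd.DataFrame(rows, index=genes, columns=SAMPLES)


class TestCpm:
    def test_definition(self):
        m = matrix([[10] * 8])
        cpm = cpm_normalize(m, {s: 1e6 for s in SAMPLES})
        assert (cpm.iloc[0] == 10).all()

    def test_all_zero_gene_stays_zero(self):
        m = matrix([[5] * 8, [0] * 8])
        assert (cpm_normalize(m).iloc[1] == 0).all()

    def test_scale_invariance_of_a_doubled_sample(self):
        rng = np.random.default_rng(0)
        m = matrix(rng.integers(1, 100, size=(20, 8)))
        doubled = m.copy()
        doubled["A1"] = doubled["A1"] * 2
        assert np.allclose(cpm_normalize(m)["A1"],
                           cpm_normalize(doubled)["A1"])

    def test_zero_library_rejected(self):
        m = matrix([[0] * 8])
        with pytest.raises(ValueError):
            cpm_normalize(m)


class TestExpressionFloor:
    @pytest.mark.parametrize(
        "n_high, is_ne", [(8, False), (4, False), (3, True), (0, True)])
    def test_boundary_on_high_count_samples(self, n_high, is_ne):
        row = [5] * n_high + [0] * (8 - n_high)
        ne = expression_floor(matrix([row]))
        assert (("g0" in ne) == is_ne)

    def test_all_zero_gene_is_ne(self):
        assert "g0" in expression_floor(matrix([[0] * 8]))

    def test_thresholds_configurable(self):
        row = [3] * 8
        assert "g0" in expression_floor(matrix([row]), min_count=5)
        assert "g0" not in expression_floor(matrix([row]), min_count=3)

    def test_bad_thresholds_rejected(self):
        with pytest.raises(ValueError):
            expression_floor(matrix([[1] * 8]), min_count=0)


class TestDeTest:
    def test_identical_condition_means_give_zero_log2fc(self):
        m = matrix([[50] * 8])
        res = de_test(m, DESIGN)
        assert res.loc["g0", "log2fc"] == 0.0

    def test_label_swap_negates_log2fc_and_swaps_calls(self):
        cfg = SimulationConfig(n_genes=400, de_fraction=0.2,
                               ne_fraction=0.0)
        m, _ = emit_counts(cfg, 21)
        res = de_test(m, DESIGN)
        swapped = de_test(m, {s: ("B" if c == "A" else "A")
                              for s, c in DESIGN.items()})
        assert np.allclose(res["log2fc"], -swapped["log2fc"])
        calls = tally(classify_de(res, set()))
        anti = tally(classify_de(swapped, set()))
        assert calls["counts"]["UP"] == anti["counts"]["DN"]
        assert calls["counts"]["DN"] == anti["counts"]["UP"]

    def test_exact_method_flags_pooled_shift(self):
        m = matrix([[100, 110, 90, 100, 400, 410, 390, 400],
                    [100, 110, 90, 100, 100, 110, 90, 100]])
        res = de_test(m, DESIGN, method="exact")
        assert res.loc["g0", "pvalue"] < 0.05

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            de_test(matrix([[1] * 8]), DESIGN, method="bayes")

    def test_too_few_replicates_rejected(self):
        m = pd.DataFrame([[1, 2]], index=["g"], columns=["A1", "B1"])
        with pytest.raises(ValueError):
            de_test(m, {"A1": "A", "B1": "B"})


class TestClassifyDe:
    @pytest.mark.parametrize(
        "p, lfc, expect",
        [(0.01, 1.2, "UP"), (0.30, 3.0, "NC"), (0.01, -1.2, "DN"),
         (0.05, 0.8, "UP"), (0.051, 0.8, "NC")],
    )
    def test_rules(self, p, lfc, expect):
        res = pd.DataFrame({"log2fc": [lfc], "pvalue": [p]}, index=["g"])
        assert classify_de(res, set())[0].klass == expect

    def test_ne_overrides_everything(self):
        res = pd.DataFrame({"log2fc": [5.0], "pvalue": [1e-9]}, index=["g"])
        call = classify_de(res, {"g"})[0]
        assert call.klass == "NE" and math.isnan(call.log2fc)

    def test_tally_conserves_gene_count(self):
        cfg = SimulationConfig(n_genes=500)
        m, _ = emit_counts(cfg, 30)
        calls, t = run_de(m, DESIGN)
        assert t["total"] == 500
        assert sum(t["counts"].values()) == 500

    def test_tally_percentages_recompute(self):
        t = class_tally({"UP": 37, "DN": 9, "NC": 387, "NE": 653})
        total = 37 + 9 + 387 + 653
        assert t["percent"]["UP"] == round(100 * 37 / total, 2)
        assert abs(sum(t["percent"].values()) - 100) < 0.05


class TestPlantedRecovery:
    def test_fourfold_genes_recovered_with_high_power(self):
        cfg = SimulationConfig(n_genes=1000, de_fraction=0.1,
                               ne_fraction=0.0, log2_effect=2.0,
                               nb_dispersion=0.05)
        m, labels = emit_counts(cfg, 13)
        calls, _ = run_de(m, DESIGN)
        by_gene = {c.gene: c for c in calls}
        planted = [g for g, l in labels.items() if l in ("UP", "DN")]
        hit = sum(by_gene[g].klass == labels[g] for g in planted)
        assert hit / len(planted) >= 0.95
        # planted UP genes sit near the programmed effect size
        ups = [by_gene[g].log2fc for g, l in labels.items() if l == "UP"]
        assert np.median(np.abs(np.array(ups) - 2.0)) <= 0.5

    def test_strong_subset_threshold(self):
        calls = classify_de(
            pd.DataFrame({"log2fc": [2.5, 1.0, -2.2], "pvalue": [0.01] * 3},
                         index=["a", "b", "c"]), set())
        assert strong_subset(calls, 2.0) == {"a", "c"}
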