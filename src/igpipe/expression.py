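"""CPM normalization and UP/DN/NC/NE expression classification.

Counts from a two-stage design (embryonic stages E9.5 = condition A and
E10.5 = condition B, four replicates each) are normalized to counts per
million.  A gene is *not expressed* (NE) unless at least ``min_samples``
of its samples reach ``min_count`` reads (defaults 4 of 8 and 5).  For the
remaining genes a per-gene test yields a p-value and a log2 fold change
(B vs A, pseudo-count 0.5); genes are then classed UP (p <= alpha,
positive log2FC), DN (p <= alpha, negative) or NC (no change).

The differential-expression engine is pluggable: the default is a Welch
t-test on log2-CPM; a pooled-count exact binomial test is available.  The
classification rules, not the test, are the fixed part of the procedure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

PSEUDOCOUNT = 0.5
CLASSES = ("UP", "DN", "NC", "NE")


@dataclass(frozen=True)
class DECall:
    gene: str
    log2fc: float      # NaN for NE genes
    pvalue: float      # NaN for NE genes
    klass: str


def _split_design(
    matrix: pd.DataFrame, design: Mapping[str, str]
) -> tuple[list[str], list[str]]:
    a = [s for s in matrix.columns if design[s] == "A"]
    b = [s for s in matrix.columns if design[s] == "B"]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 replicates per condition")
    return a, b


def cpm_normalize(
    matrix: pd.DataFrame, library_sizes: Mapping[str, float] | None = None
) -> pd.DataFrame:
    """counts / library size * 1e6; library size defaults to the column sum."""
    sizes = pd.Series(
        library_sizes if library_sizes is not None
        else matrix.sum(axis=0), dtype=float
    )[matrix.columns]
    if (sizes <= 0).any():
        bad = sizes.index[sizes <= 0].tolist()
        raise ValueError(f"zero library size for samples {bad}")
    return matrix / sizes * 1e6


def expression_floor(
    matrix: pd.DataFrame, min_count: int = 5, min_samples: int = 4
) -> set[str]:
    """Genes below the expression floor (NE set).

    A gene is expressed iff at least ``min_samples`` samples have count
    >= ``min_count``; everything else is NE.
    """
    if min_count <= 0 or min_samples <= 0:
        raise ValueError("thresholds must be positive")
    ok = (matrix >= min_count).sum(axis=1) >= min_samples
    return set(matrix.index[~ok])


def de_test(
    matrix: pd.DataFrame,
    design: Mapping[str, str],
    method: str = "logcpm_t",
) -> pd.DataFrame:
    """Per-gene (log2FC, p-value); log2FC = log2((mean CPM_B + c)/(mean CPM_A + c)).

    ``logcpm_t``: Welch t-test on log2(CPM + c) between conditions.
    ``exact``: binomial test on pooled condition counts against the
    library-size proportion.
    """
    a_cols, b_cols = _split_design(matrix, design)
    cpm = cpm_normalize(matrix)
    mean_a = cpm[a_cols].mean(axis=1)
    mean_b = cpm[b_cols].mean(axis=1)
    log2fc = np.log2((mean_b + PSEUDOCOUNT) / (mean_a + PSEUDOCOUNT))

    if method == "logcpm_t":
        la = np.log2(cpm[a_cols] + PSEUDOCOUNT)
        lb = np.log2(cpm[b_cols] + PSEUDOCOUNT)
        import warnings as _w
        with _w.catch_warnings():
            # constant rows trigger a precision-loss RuntimeWarning; they
            # are mapped to p = 1 below
            _w.simplefilter("ignore", RuntimeWarning)
            t, p = stats.ttest_ind(lb, la, axis=1, equal_var=False)
        p = np.where(np.isnan(p), 1.0, p)  # zero variance both sides
    elif method == "exact":
        lib_a = float(matrix[a_cols].to_numpy().sum())
        lib_b = float(matrix[b_cols].to_numpy().sum())
        p0 = lib_b / (lib_a + lib_b)
        sum_a = matrix[a_cols].sum(axis=1).to_numpy()
        sum_b = matrix[b_cols].sum(axis=1).to_numpy()
        p = np.array([
            stats.binomtest(int(kb), int(ka + kb), p0).pvalue
            if ka + kb > 0 else 1.0
            for ka, kb in zip(sum_a, sum_b)
        ])
    else:
        raise ValueError(f"unknown method {method!r}")
    return pd.DataFrame(
        {"log2fc": log2fc, "pvalue": p}, index=matrix.index
    )


def classify_de(
    results: pd.DataFrame,
    ne_set: Iterable[str],
    alpha: float = 0.05,
) -> list[DECall]:
    """NE overrides; else UP/DN by p <= alpha and log2FC sign; else NC."""
    ne = set(ne_set)
    calls = []
    for gene, row in results.iterrows():
        if gene in ne:
            calls.append(DECall(gene, math.nan, math.nan, "NE"))
        elif row["pvalue"] <= alpha and row["log2fc"] > 0:
            calls.append(DECall(gene, row["log2fc"], row["pvalue"], "UP"))
        elif row["pvalue"] <= alpha and row["log2fc"] < 0:
            calls.append(DECall(gene, row["log2fc"], row["pvalue"], "DN"))
        else:
            calls.append(DECall(gene, row["log2fc"], row["pvalue"], "NC"))
    return calls


def class_tally(counts: Mapping[str, int]) -> dict:
    """Counts and percentages per class; denominator = sum of class counts."""
    total = sum(counts.get(k, 0) for k in CLASSES)
    pct = {
        k: (round(100.0 * counts.get(k, 0) / total, 2) if total else 0.0)
        for k in CLASSES
    }
    return {"counts": {k: counts.get(k, 0) for k in CLASSES},
            "total": total, "percent": pct}


def tally(calls: Sequence[DECall]) -> dict:
    counts: dict[str, int] = {}
    for c in calls:
        counts[c.klass] = counts.get(c.klass, 0) + 1
    return class_tally(counts)


def run_de(
    matrix: pd.DataFrame,
    design: Mapping[str, str],
    alpha: float = 0.05,
    min_count: int = 5,
    min_samples: int = 4,
    method: str = "logcpm_t",
) -> tuple[list[DECall], dict]:
    """Floor -> test -> classify -> tally, on the full count matrix."""
    ne = expression_floor(matrix, min_count, min_samples)
    results = de_test(matrix, design, method)
    calls = classify_de(results, ne, alpha)
    return calls, tally(calls)


def strong_subset(calls: Sequence[DECall], min_abs_log2fc: float = 2.0
                  ) -> set[str]:
    """Strongly changed genes (|log2FC| >= threshold and UP/DN)."""
    return {
        c.gene for c in calls
        if c.klass in ("UP", "DN") and abs(c.log2fc) >= min_abs_log2fc
    }
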