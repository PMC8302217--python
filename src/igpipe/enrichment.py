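"""Hypergeometric over-representation analysis with BH correction.

Given a study gene set, a background universe and a flat gene -> terms
map, each term is tested for over-representation by the upper-tail
hypergeometric probability P(X >= k) of drawing k term-bearing genes in a
study of size n from a background of N genes of which K carry the term.
Benjamini-Hochberg q-values are attached.  Terms absent from the
background are skipped; under-representation (lower tail) is available
behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

TermMap = Mapping[str, set]


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    k: int      # study genes with term
    K: int      # background genes with term
    n: int      # study size
    N: int      # background size
    pvalue: float
    qvalue: float


def hypergeom_pvalue(k: int, N: int, K: int, n: int,
                     tail: str = "upper") -> float:
    """P(X >= k) (or <= k) for X ~ Hypergeometric(N, K, n)."""
    if tail == "upper":
        return float(stats.hypergeom.sf(k - 1, N, K, n))
    if tail == "lower":
        return float(stats.hypergeom.cdf(k, N, K, n))
    raise ValueError("tail must be 'upper' or 'lower'")


def adjust_bh(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, in input order, capped at 1."""
    if len(pvalues) == 0:
        return []
    _, q, _, _ = multipletests(pvalues, method="fdr_bh")
    return [float(v) for v in q]


def hypergeom_enrich(
    study: Iterable[str],
    background: Iterable[str],
    terms: TermMap,
    tail: str = "upper",
) -> list[EnrichmentResult]:
    """Per-term enrichment of the study set, sorted by p-value.

    ``study`` must be a subset of ``background``; genes without terms are
    allowed and simply contribute to N.
    """
    study_set = set(study)
    bg = set(background)
    if not bg:
        raise ValueError("background is empty")
    if not study_set <= bg:
        extra = sorted(study_set - bg)[:5]
        raise ValueError(f"study genes not in background: {extra}")
    n, N = len(study_set), len(bg)
    term_bg: dict[str, int] = {}
    term_study: dict[str, int] = {}
    for gene in bg:
        for term in terms.get(gene, ()):
            term_bg[term] = term_bg.get(term, 0) + 1
            if gene in study_set:
                term_study[term] = term_study.get(term, 0) + 1
    rows = []
    for term in sorted(term_bg):
        K = term_bg[term]
        k = term_study.get(term, 0)
        rows.append((term, k, K, hypergeom_pvalue(k, N, K, n, tail)))
    qvals = adjust_bh([p for *_, p in rows])
    results = [
        EnrichmentResult(term, k, K, n, N, p, q)
        for (term, k, K, p), q in zip(rows, qvals)
    ]
    return sorted(results, key=lambda r: (r.pvalue, r.term))


def enrichment_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.term, r.k, r.K, r.n, r.N, r.pvalue, r.qvalue) for r in results],
        columns=["term", "k", "K", "n", "N", "p", "q"],
    )


def read_term_map(path: str | Path) -> dict[str, set]:
    """TSV (gene_id, term_id) -> gene -> set of terms."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, set] = {}
    for gene, term in zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)):
        out.setdefault(gene, set()).add(term)
    return out


def calibration_false_positive_rate(
    background: Sequence[str],
    terms: TermMap,
    study_size: int,
    alpha: float = 0.05,
    n_draws: int = 10_000,
    seed: int = 0,
) -> float:
    """Fraction of (draw, term) tests with p <= alpha for random study sets.

    Vectorized permutation check of the test's calibration: for the
    discrete hypergeometric this fraction is at most alpha.
    """
    rng = np.random.default_rng(seed)
    bg = sorted(set(background))
    N = len(bg)
    term_names = sorted({t for g in bg for t in terms.get(g, ())})
    member = np.zeros((len(term_names), N), dtype=bool)
    index = {t: i for i, t in enumerate(term_names)}
    for j, gene in enumerate(bg):
        for t in terms.get(gene, ()):
            member[index[t], j] = True
    K = member.sum(axis=1)
    hits = 0
    total = 0
    for _ in range(n_draws):
        pick = rng.choice(N, size=study_size, replace=False)
        k = member[:, pick].sum(axis=1)
        p = stats.hypergeom.sf(k - 1, N, K, study_size)
        hits += int((p <= alpha).sum())
        total += len(term_names)
    return hits / total
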