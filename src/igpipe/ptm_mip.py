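"""PTM prevalence comparison (IG vs MEG proteins) and a microprotein screen.

Each post-translational modification type is compared between the IG and
MEG protein populations with a pooled two-proportion Z-test (two-sided
normal p-value).  Classes: a PTM present in exactly one population is
``unique-IG`` / ``unique-MEG`` (decided before any test); otherwise
``similar`` when p >= alpha, and ``IG-enriched`` / ``MEG-enriched`` when
p < alpha, named after the population with the higher relative
percentage.  No multiple-testing correction is applied across PTM types
(per-type alpha = 0.05).

The microprotein screen encodes the three textual criteria of candidate
miPs -- short single-domain proteins that can heterodimerize with a
larger multi-domain partner sharing the domain -- with explicit default
thresholds (length <= 250 aa; partner >= 400 aa with >= 2 domains).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from statsmodels.stats.proportion import proportions_ztest

PTM_CLASSES = ("similar", "IG-enriched", "MEG-enriched",
               "unique-IG", "unique-MEG")


@dataclass(frozen=True)
class PTMComparison:
    ptm: str
    k_ig: int
    n_ig: int
    k_meg: int
    n_meg: int
    z: float
    pvalue: float
    klass: str


def compare_ptm(
    ptm: str,
    k_ig: int,
    n_ig: int,
    k_meg: int,
    n_meg: int,
    alpha: float = 0.05,
) -> PTMComparison:
    """Pooled two-proportion Z-test for one PTM type.

    z = (p1 - p2) / sqrt(p(1-p)(1/n1 + 1/n2)) with p the pooled
    proportion; p-value two-sided normal.
    """
    if n_ig <= 0 or n_meg <= 0:
        raise ValueError("population totals must be positive")
    if not (0 <= k_ig <= n_ig and 0 <= k_meg <= n_meg):
        raise ValueError("counts must satisfy 0 <= k <= n")
    if k_ig == 0 and k_meg > 0:
        return PTMComparison(ptm, k_ig, n_ig, k_meg, n_meg,
                             math.nan, math.nan, "unique-MEG")
    if k_meg == 0 and k_ig > 0:
        return PTMComparison(ptm, k_ig, n_ig, k_meg, n_meg,
                             math.nan, math.nan, "unique-IG")
    if k_ig == 0 and k_meg == 0:
        return PTMComparison(ptm, 0, n_ig, 0, n_meg, 0.0, 1.0, "similar")
    p_ig, p_meg = k_ig / n_ig, k_meg / n_meg
    if p_ig == p_meg:
        z, p = 0.0, 1.0
    else:
        z, p = proportions_ztest([k_ig, k_meg], [n_ig, n_meg],
                                 alternative="two-sided")
        z, p = float(z), float(p)
    if p >= alpha:
        klass = "similar"
    else:
        klass = "IG-enriched" if p_ig > p_meg else "MEG-enriched"
    return PTMComparison(ptm, k_ig, n_ig, k_meg, n_meg, z, p, klass)


def classify_all_ptms(
    table: pd.DataFrame,
    n_ig: int,
    n_meg: int,
    alpha: float = 0.05,
) -> tuple[list[PTMComparison], dict[str, int]]:
    """Compare every PTM type of a long table (protein_id, ptm_type, class).

    ``class`` is the population (IG|MEG) of each modified protein; totals
    of the two populations are supplied separately since unmodified
    proteins carry no row.
    """
    if table.empty:
        return [], {}
    comps = []
    for ptm, grp in table.groupby("ptm_type", sort=True):
        k_ig = grp.loc[grp["class"] == "IG", "protein_id"].nunique()
        k_meg = grp.loc[grp["class"] == "MEG", "protein_id"].nunique()
        comps.append(compare_ptm(str(ptm), k_ig, n_ig, k_meg, n_meg, alpha))
    summary: dict[str, int] = {}
    for c in comps:
        summary[c.klass] = summary.get(c.klass, 0) + 1
    assert sum(summary.values()) == len(comps)
    return comps, summary


def comparison_frame(comps: Sequence[PTMComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.ptm, c.k_ig, c.n_ig, c.k_meg, c.n_meg, c.z, c.pvalue, c.klass)
         for c in comps],
        columns=["ptm_type", "k_ig", "n_ig", "k_meg", "n_meg",
                 "z", "p", "class"],
    )


# ---------------------------------------------------------------------------
# microprotein screen


@dataclass(frozen=True)
class MiPCandidate:
    protein_id: str
    length: int
    domain: str
    partner_id: str
    partner_length: int


def screen_microproteins(
    proteins: Sequence[tuple[str, int, Sequence[str]]],
    max_length: int = 250,
    partner_min_length: int = 400,
) -> list[MiPCandidate]:
    """Candidates: short single-domain proteins with a large multi-domain
    partner sharing the domain.

    ``proteins`` rows are (id, length in aa, domain list).  The recorded
    partner is the longest qualifying one (ties broken by id).
    """
    for pid, length, _ in proteins:
        if length <= 0:
            raise ValueError(f"non-positive length for {pid!r}")
    by_domain: dict[str, list[tuple[str, int]]] = {}
    for pid, length, domains in proteins:
        if len(domains) >= 2 and length >= partner_min_length:
            for dom in set(domains):
                by_domain.setdefault(dom, []).append((pid, length))
    out = []
    for pid, length, domains in proteins:
        if length > max_length or len(set(domains)) != 1 or not domains:
            continue
        dom = next(iter(set(domains)))
        partners = [p for p in by_domain.get(dom, []) if p[0] != pid]
        if not partners:
            continue
        partner = max(partners, key=lambda p: (p[1], p[0]))
        out.append(MiPCandidate(pid, length, dom, partner[0], partner[1]))
    return out


def read_protein_table(path) -> list[tuple[str, int, list[str]]]:
    """TSV (id, length, semicolon-joined domains) -> screen input rows."""
    df = pd.read_csv(path, sep="\t")
    rows = []
    for r in df.itertuples(index=False):
        domains = [d for d in str(r[2]).split(";") if d and d != "nan"]
        rows.append((str(r[0]), int(r[1]), domains))
    return rows
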