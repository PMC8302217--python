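"""Conservation age of mouse genes and architecture-conservation tables.

The age of a mouse gene is the clade label recording how broadly its
orthologs are conserved on the species ladder.  Two rules are shipped:

* ``strict`` (default): the age is the largest clade whose *every*
  non-mouse species carries an ortholog, walking the cumulative ladder
  rat -> Muridae; +human,chimp -> Eutheria; +opossum -> Theria;
  +chick -> Tetrapoda; +zebrafish -> Vertebrata.
* ``deepest``: the age is the clade of the ladder-LCA of mouse plus every
  species with any ortholog (span-based; tolerant of gappy profiles).

A gene with no orthologs anywhere is mouse-specific under both rules.

The architecture table mirrors the per-genome summary layout (columns
IGs / MEGs / Others / Total): for each non-mouse species, mouse genes
with at least one ortholog there are tallied by the majority architecture
of those orthologs (ties count as Other).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .species import SpeciesLadder, default_ladder

NON_MOUSE = ("rat", "human", "chimp", "opossum", "chick", "zebrafish")

#: cumulative-ladder requirements, youngest to oldest
AGE_LADDER: tuple[tuple[str, frozenset[str]], ...] = (
    ("Muridae", frozenset({"rat"})),
    ("Eutheria", frozenset({"rat", "human", "chimp"})),
    ("Theria", frozenset({"rat", "human", "chimp", "opossum"})),
    ("Tetrapoda", frozenset({"rat", "human", "chimp", "opossum", "chick"})),
    ("Vertebrata", frozenset(NON_MOUSE)),
)

MOUSE_SPECIFIC = "mouse-specific"
AGE_ORDER = (MOUSE_SPECIFIC,) + tuple(name for name, _ in AGE_LADDER)


@dataclass
class PresenceProfile:
    """Per-species orthologs of one mouse gene, with their architecture."""

    mouse_gene: str
    orthologs: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    # species -> [(ortholog gene id, architecture IG|MEG|Other)]

    def species_with_orthologs(self) -> set[str]:
        return {sp for sp, lst in self.orthologs.items() if lst}


@dataclass(frozen=True)
class AgeCall:
    mouse_gene: str
    age: str
    mode: str


def assign_age(
    profile: PresenceProfile,
    mode: str = "strict",
    ladder: SpeciesLadder | None = None,
) -> AgeCall:
    if mode not in ("strict", "deepest"):
        raise ValueError("mode must be 'strict' or 'deepest'")
    present = profile.species_with_orthologs()
    if not present:
        return AgeCall(profile.mouse_gene, MOUSE_SPECIFIC, mode)
    if mode == "strict":
        age = MOUSE_SPECIFIC
        for name, required in AGE_LADDER:
            if required <= present:
                age = name
            else:
                break
        return AgeCall(profile.mouse_gene, age, mode)
    ladder = ladder or default_ladder()
    clade = ladder.lca(["mouse", *present])
    # the LCA of mouse with any non-mouse set lies on the mouse->root path
    name = "Eutheria" if clade == "Primates" else clade
    return AgeCall(profile.mouse_gene, name, mode)


def age_rank(age: str) -> int:
    return AGE_ORDER.index(age)


def profiles_from_graph(
    graph: nx.Graph,
    architecture_of: Mapping[str, str],
    focal_species: str = "mouse",
) -> list[PresenceProfile]:
    """One profile per focal-species gene, from its BBH neighbors."""
    profiles = []
    for gene, data in sorted(graph.nodes(data=True)):
        if data.get("species") != focal_species:
            continue
        prof = PresenceProfile(gene, {sp: [] for sp in NON_MOUSE})
        for nb in sorted(graph.neighbors(gene)):
            sp = graph.nodes[nb].get("species")
            if sp == focal_species or sp is None:
                continue
            arch = architecture_of.get(nb, "Other")
            if arch not in ("IG", "MEG"):
                arch = "Other"
            prof.orthologs.setdefault(sp, []).append((nb, arch))
        profiles.append(prof)
    return profiles


def _majority_class(orthos: Sequence[tuple[str, str]]) -> str:
    counts = Counter(arch for _, arch in orthos)
    n_ig, n_meg = counts.get("IG", 0), counts.get("MEG", 0)
    if n_ig > n_meg:
        return "IGs"
    if n_meg > n_ig:
        return "MEGs"
    return "Others"


def architecture_table(profiles: Iterable[PresenceProfile]) -> pd.DataFrame:
    """Per-species counts of ortholog-bearing genes by majority architecture."""
    rows = {sp: Counter() for sp in NON_MOUSE}
    for prof in profiles:
        for sp, orthos in prof.orthologs.items():
            if not orthos or sp not in rows:
                continue
            rows[sp][_majority_class(orthos)] += 1
    table = pd.DataFrame(
        [
            {
                "Genome": sp,
                "IGs": rows[sp].get("IGs", 0),
                "MEGs": rows[sp].get("MEGs", 0),
                "Others": rows[sp].get("Others", 0),
            }
            for sp in NON_MOUSE
        ]
    )
    table["Total"] = table[["IGs", "MEGs", "Others"]].sum(axis=1)
    return table


def conservation_fractions(table: pd.DataFrame) -> pd.DataFrame:
    """Row and pooled percentages of the first class (IGs column).

    Reports both nearest-integer and 2-decimal percentages; zero-total
    rows are skipped with a notice column.
    """
    out = table.copy()
    pct, pct_int, note = [], [], []
    for _, row in table.iterrows():
        if row["Total"] == 0:
            pct.append(float("nan"))
            pct_int.append(pd.NA)
            note.append("zero total; skipped")
            continue
        p = 100.0 * row["IGs"] / row["Total"]
        pct.append(round(p, 2))
        pct_int.append(int(round(p)))
        note.append("")
    out["pct_IG"] = pct
    out["pct_IG_int"] = pd.array(pct_int, dtype="Int64")
    out["note"] = note
    total = table["Total"].sum()
    pooled = 100.0 * table["IGs"].sum() / total if total else float("nan")
    out.attrs["pooled_pct_IG"] = round(pooled, 2) if total else float("nan")
    out.attrs["pooled_pct_IG_int"] = int(round(pooled)) if total else None
    return out


def age_table(
    profiles: Iterable[PresenceProfile], mode: str = "strict"
) -> pd.DataFrame:
    calls = [assign_age(p, mode) for p in profiles]
    df = pd.DataFrame(
        [(c.mouse_gene, c.age, c.mode) for c in calls],
        columns=["gene_id", "age", "mode"],
    )
    return df
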