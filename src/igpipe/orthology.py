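"""Best-bidirectional-hit orthology graphs and orthogroups.

Follows the ProteinOrtho procedure: from pairwise similarity records
(BLAST tabular dialect), the best hit of a gene in each *target species*
is found; a cross-species pair is an orthology edge when each gene is
among the other's best hits and both directions reach the identity
threshold (50% by default, boundary inclusive).  Co-best ties are all
kept, so a gene may be linked to several in-paralogs of one species.

Best hits are determined over all records and the identity threshold is
applied afterwards to the two best directions; this keeps the edge set
monotone (raising the threshold never adds an edge).

Orthogroups default to connected components of the orthology graph; an
optional density-based splitter removes a minimum edge cut from loosely
connected components.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import networkx as nx
import pandas as pd


class SimilarityRecord(NamedTuple):
    query: str
    subject: str
    identity: float      # percent, (0, 100]
    length: int
    score: float


def read_similarity(path: str | Path) -> list[SimilarityRecord]:
    """Read a BLAST-tabular similarity TSV (qseqid sseqid pident length bitscore)."""
    df = pd.read_csv(path, sep="\t")
    required = {"qseqid", "sseqid", "pident", "bitscore"}
    if not required <= set(df.columns):
        # headerless classic BLAST outfmt 6 style: take first five columns
        df = pd.read_csv(
            path, sep="\t", header=None,
            names=["qseqid", "sseqid", "pident", "length", "bitscore"],
            usecols=range(5),
        )
    return [
        SimilarityRecord(str(r.qseqid), str(r.sseqid), float(r.pident),
                         int(getattr(r, "length", 0)), float(r.bitscore))
        for r in df.itertuples(index=False)
    ]


def read_species_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["gene_id"].astype(str), df["species"].astype(str)))


def best_bidirectional_hits(
    records: Sequence[SimilarityRecord],
    species_of: Mapping[str, str],
    min_identity: float = 50.0,
) -> list[tuple[str, str]]:
    """Accepted BBH edges, sorted, each as an ordered (min, max) pair.

    A record whose query or subject lacks a species assignment, or that
    links two genes of one species, is ignored.  Best hits per (query,
    target species) are ranked by (score, identity); exact ties are all
    kept as co-best.
    """
    if not 0.0 < min_identity <= 100.0:
        raise ValueError("min_identity must be in (0, 100]")
    # (query, subject) -> strongest record for that ordered pair
    strongest: dict[tuple[str, str], tuple[float, float]] = {}
    for rec in records:
        if rec.query == rec.subject:
            continue
        sp_q = species_of.get(rec.query)
        sp_s = species_of.get(rec.subject)
        if sp_q is None or sp_s is None or sp_q == sp_s:
            continue
        key = (rec.score, rec.identity)
        prev = strongest.get((rec.query, rec.subject))
        if prev is None or key > prev:
            strongest[(rec.query, rec.subject)] = key

    # best hit set per (query, target species)
    best: dict[tuple[str, str], tuple[tuple[float, float], set[str]]] = {}
    for (q, s), key in strongest.items():
        slot = (q, species_of[s])
        cur = best.get(slot)
        if cur is None or key > cur[0]:
            best[slot] = (key, {s})
        elif key == cur[0]:
            cur[1].add(s)

    edges: set[tuple[str, str]] = set()
    for (q, s), (score, ident) in strongest.items():
        if q >= s:
            continue
        back = strongest.get((s, q))
        if back is None:
            continue
        if ident < min_identity or back[1] < min_identity:
            continue
        if s in best[(q, species_of[s])][1] and q in best[(s, species_of[q])][1]:
            edges.add((q, s))
    return sorted(edges)


class SameSpeciesEdgeError(ValueError):
    """An orthology edge between two genes of one species was requested."""


def build_orthology_graph(
    edges: Iterable[tuple[str, str]],
    species_of: Mapping[str, str],
) -> nx.Graph:
    """Undirected orthology graph; isolated genes are retained as nodes."""
    g = nx.Graph()
    for gene, sp in species_of.items():
        g.add_node(gene, species=sp)
    for a, b in edges:
        if a == b:
            raise SameSpeciesEdgeError(f"self loop on {a!r}")
        if a not in species_of or b not in species_of:
            raise KeyError(f"edge ({a!r}, {b!r}) has an unmapped gene")
        if species_of[a] == species_of[b]:
            raise SameSpeciesEdgeError(
                f"edge ({a!r}, {b!r}) joins two {species_of[a]} genes")
        g.add_edge(a, b)
    return g


def _density(g: nx.Graph, nodes: set[str]) -> float:
    n = len(nodes)
    if n < 2:
        return 1.0
    m = g.subgraph(nodes).number_of_edges()
    return 2.0 * m / (n * (n - 1))


def cluster_orthogroups(
    graph: nx.Graph,
    split_low_density: bool = False,
    density_threshold: float = 0.3,
    _depth: int = 10,
) -> list[set[str]]:
    """Partition the non-isolated genes into orthogroups.

    Default: connected components.  With ``split_low_density``, components
    whose edge density is below the threshold are recursively split along
    a minimum edge cut.
    """
    groups: list[set[str]] = []
    for comp in nx.connected_components(graph):
        comp = set(comp)
        if len(comp) < 2:
            continue  # isolated gene: no orthology evidence
        if (split_low_density and _depth > 0
                and _density(graph, comp) < density_threshold):
            sub = graph.subgraph(comp).copy()
            cut = nx.minimum_edge_cut(sub)
            sub.remove_edges_from(cut)
            groups.extend(
                cluster_orthogroups(sub, split_low_density,
                                    density_threshold, _depth - 1))
        else:
            groups.append(comp)
    return sorted(groups, key=lambda s: sorted(s)[0])


@dataclass
class OrthologyResult:
    graph: nx.Graph
    edges: list[tuple[str, str]]
    orthogroups: list[set[str]]


def infer_orthology(
    records: Sequence[SimilarityRecord],
    species_of: Mapping[str, str],
    min_identity: float = 50.0,
    split_low_density: bool = False,
) -> OrthologyResult:
    edges = best_bidirectional_hits(records, species_of, min_identity)
    graph = build_orthology_graph(edges, species_of)
    groups = cluster_orthogroups(graph, split_low_density)
    return OrthologyResult(graph, edges, groups)


def write_orthogroups(groups: Sequence[set[str]],
                      species_of: Mapping[str, str],
                      path: str | Path) -> pd.DataFrame:
    rows = [
        (f"OG{i:05d}", gene, species_of.get(gene, ""))
        for i, grp in enumerate(groups)
        for gene in sorted(grp)
    ]
    df = pd.DataFrame(rows, columns=["group_id", "gene_id", "species"])
    df.to_csv(path, sep="\t", index=False)
    return df
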