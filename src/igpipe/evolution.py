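"""Gene-family history reconstruction from orthology graphs.

A valid orthology relation is a *cograph* (no induced path on four
vertices).  Its modular decomposition is a cotree of series/parallel
nodes which, read as a gene tree, carries the evolutionary events
directly: series nodes (joins) are speciations, parallel nodes (unions)
are duplications.  The event-labeled gene tree is then reconciled with
the species ladder by LCA mapping, which places each duplication on a
species-tree branch and reads off gene losses as the species-tree edges a
gene lineage skips.

Noisy similarity data can yield non-cographs; a greedy editing heuristic
(resolve induced P4s by the single-edge change that leaves the fewest P4s,
preferring removals, never adding same-species edges) repairs the graph
and reports the edit set.

Cotrees are kept in canonical form (adjacent like-labeled nodes merged),
so speciation nodes may be multifurcating; reconciliation resolves such
nodes against the ladder topology and counts a duplication node with k
children as k-1 duplication events.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .species import SpeciesLadder

SERIES = "series"
PARALLEL = "parallel"
SPECIATION = "speciation"
DUPLICATION = "duplication"


class PrimeModuleError(ValueError):
    """The graph is not a cograph; run :func:`cograph_edit` first."""


@dataclass
class CoNode:
    """Cotree / event-tree node; leaves carry a gene id."""

    kind: str                      # series|parallel|speciation|duplication|leaf
    children: list["CoNode"] = field(default_factory=list)
    gene: str | None = None
    species: str | None = None
    inconsistent: bool = False

    def walk(self) -> Iterable["CoNode"]:
        yield self
        for c in self.children:
            yield from c.walk()

    def leaves(self) -> list["CoNode"]:
        return [n for n in self.walk() if n.kind == "leaf"]

    def leaf_genes(self) -> list[str]:
        return [n.gene for n in self.leaves()]  # type: ignore[misc]


# ---------------------------------------------------------------------------
# cograph recognition / modular decomposition

def modular_decomposition(graph: nx.Graph) -> CoNode:
    """Canonical cotree of a cograph (series/parallel internal nodes).

    Recursion: a disconnected graph is the parallel composition of its
    components; a graph with disconnected complement is the series
    composition of the co-components; anything else contains a prime
    module and raises :class:`PrimeModuleError`.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph has no cotree")

    def build(nodes: frozenset) -> CoNode:
        if len(nodes) == 1:
            (v,) = nodes
            return CoNode("leaf", gene=v)
        sub = graph.subgraph(nodes)
        comps = [frozenset(c) for c in nx.connected_components(sub)]
        if len(comps) > 1:
            kids = [build(c) for c in comps]
            return _merge(CoNode(PARALLEL, children=kids))
        co = nx.complement(sub)
        co_comps = [frozenset(c) for c in nx.connected_components(co)]
        if len(co_comps) > 1:
            kids = [build(c) for c in co_comps]
            return _merge(CoNode(SERIES, children=kids))
        raise PrimeModuleError(
            f"prime module on {len(nodes)} vertices; graph is not a cograph")

    def _merge(node: CoNode) -> CoNode:
        # canonical form: fold children with the same composition label
        kids: list[CoNode] = []
        for c in node.children:
            if c.kind == node.kind:
                kids.extend(c.children)
            else:
                kids.append(c)
        node.children = kids
        return node

    return build(frozenset(graph.nodes))


def is_cograph(graph: nx.Graph) -> bool:
    """True iff the graph has no induced P4 (= admits a cotree)."""
    if graph.number_of_nodes() == 0:
        return True
    try:
        modular_decomposition(graph)
        return True
    except PrimeModuleError:
        return False


def cotree_to_graph(root: CoNode) -> nx.Graph:
    """Adjacency encoded by a cotree: edge iff the LCA is a series node."""
    g = nx.Graph()
    for leaf in root.leaves():
        g.add_node(leaf.gene)

    def walk(node: CoNode) -> list[str]:
        if node.kind == "leaf":
            return [node.gene]  # type: ignore[list-item]
        groups = [walk(c) for c in node.children]
        if node.kind in (SERIES, SPECIATION):
            for ga, gb in itertools.combinations(groups, 2):
                for a in ga:
                    for b in gb:
                        g.add_edge(a, b)
        return [x for grp in groups for x in grp]

    walk(root)
    return g


# ---------------------------------------------------------------------------
# P4 search and greedy cograph editing

def induced_p4s(graph: nx.Graph) -> list[tuple]:
    """All induced 4-vertex paths, each as its ordered vertex tuple."""
    out = []
    for quad in itertools.combinations(sorted(graph.nodes), 4):
        sub = graph.subgraph(quad)
        if sub.number_of_edges() != 3:
            continue
        degs = sorted(d for _, d in sub.degree())
        if degs != [1, 1, 2, 2]:
            continue
        ends = [v for v, d in sub.degree() if d == 1]
        path = nx.shortest_path(sub, ends[0], ends[1])
        if len(path) == 4:
            out.append(tuple(path))
    return out


def cograph_edit(
    graph: nx.Graph,
    species_of: Mapping[str, str] | None = None,
) -> tuple[nx.Graph, list[tuple[str, str, str]]]:
    """Greedy repair to a cograph; returns (edited graph, edit list).

    Each step toggles the single pair (among vertices participating in
    induced P4s) that leaves the fewest P4s; ties prefer edge removal over
    addition, then lexicographic order.  Edges between genes of the same
    species are never added.  Edits are reported as (op, u, v) with op in
    {"remove", "add"}.
    """
    g = graph.copy()
    edits: list[tuple[str, str, str]] = []
    guard = max(4, g.number_of_nodes() ** 2)
    while guard > 0:
        guard -= 1
        p4s = induced_p4s(g)
        if not p4s:
            break
        candidates: set[tuple[str, str]] = set()
        for path in p4s:
            for u, v in itertools.combinations(path, 2):
                candidates.add(tuple(sorted((u, v))))
        best_key = None
        best_move = None
        for u, v in sorted(candidates):
            removing = g.has_edge(u, v)
            if not removing and species_of is not None and \
                    species_of.get(u) == species_of.get(v):
                continue
            if removing:
                g.remove_edge(u, v)
            else:
                g.add_edge(u, v)
            remaining = len(induced_p4s(g))
            if removing:
                g.add_edge(u, v)
            else:
                g.remove_edge(u, v)
            key = (remaining, 0 if removing else 1, u, v)
            if best_key is None or key < best_key:
                best_key = key
                best_move = (u, v, removing)
        if best_move is None:  # only forbidden additions available
            u, v = sorted(p4s[0][1:3])
            best_move = (u, v, True)
        u, v, removing = best_move
        if removing:
            g.remove_edge(u, v)
            edits.append(("remove", u, v))
        else:
            g.add_edge(u, v)
            edits.append(("add", u, v))
    return g, edits


# ---------------------------------------------------------------------------
# event labeling

@dataclass
class EventTree:
    root: CoNode
    species_of: dict[str, str]
    inconsistent_nodes: int = 0


def label_events(
    cotree: CoNode, species_of: Mapping[str, str]
) -> EventTree:
    """Turn a cotree into an event tree: series->speciation, parallel->duplication.

    A speciation node whose child subtrees share a species is biologically
    impossible (two same-species genes would be orthologs); such nodes are
    flagged ``inconsistent`` rather than silently relabeled.
    """
    n_bad = 0

    def convert(node: CoNode) -> CoNode:
        nonlocal n_bad
        if node.kind == "leaf":
            sp = species_of.get(node.gene or "")
            if sp is None:
                raise KeyError(f"gene {node.gene!r} has no species")
            return CoNode("leaf", gene=node.gene, species=sp)
        kids = [convert(c) for c in node.children]
        kind = SPECIATION if node.kind in (SERIES, SPECIATION) else DUPLICATION
        out = CoNode(kind, children=kids)
        if kind == SPECIATION:
            sets = [frozenset(l.species for l in c.leaves()) for c in kids]
            for sa, sb in itertools.combinations(sets, 2):
                if sa & sb:
                    out.inconsistent = True
                    n_bad += 1
                    break
        return out

    root = convert(cotree)
    return EventTree(root, dict(species_of), n_bad)


# ---------------------------------------------------------------------------
# reconciliation

@dataclass
class Reconciliation:
    """LCA embedding of an event tree into the species ladder."""

    image: dict[int, str]                 # id(node) -> ladder node
    duplication_count: int
    loss_count: int
    speciation_count: int
    dups_per_branch: Counter
    losses_per_branch: Counter
    root_image: str

    @property
    def total_events(self) -> int:
        return self.duplication_count + self.loss_count


def reconcile(tree: EventTree, ladder: SpeciesLadder) -> Reconciliation:
    """Most-parsimonious (LCA) reconciliation with loss inference.

    Each node maps to the ladder LCA of its descendant species.  A
    duplication with k children counts k-1 duplication events on the
    branch above its image.  Losses: a lineage descending from species
    node X to species node Y passes every intermediate ladder node, and
    each passage where the sibling branch has no representative is one
    loss.  Multifurcating speciation nodes are resolved against the ladder
    topology (children grouped by the side of the image node that contains
    them) rather than binarized.
    """
    for leaf in tree.root.leaves():
        if leaf.species not in ladder:
            raise KeyError(f"species {leaf.species!r} not in ladder")

    image: dict[int, str] = {}

    def assign(node: CoNode) -> str:
        if node.kind == "leaf":
            image[id(node)] = node.species  # type: ignore[assignment]
            return node.species  # type: ignore[return-value]
        img = ladder.lca([assign(c) for c in node.children])
        image[id(node)] = img
        return img

    assign(tree.root)

    dup_count = 0
    loss_count = 0
    spec_count = 0
    dpb: Counter = Counter()
    lpb: Counter = Counter()

    def charge(top: str, bottom: str, include_top: bool) -> None:
        nonlocal loss_count
        path = ladder.path_down(top, bottom)
        passed = path[:-1] if include_top else path[1:-1]
        for i, node in enumerate(path[:-1]):
            if node not in passed:
                continue
            taken = path[i + 1]
            for off in ladder.off_path_children(node, taken):
                loss_count += 1
                lpb[off] += 1

    def descend(node: CoNode) -> None:
        nonlocal dup_count, spec_count
        if node.kind == "leaf":
            return
        img = image[id(node)]
        if node.kind == DUPLICATION:
            dup_count += len(node.children) - 1
            dpb[img] += len(node.children) - 1
            resolve_dup(img, list(node.children))
        else:
            spec_count += 1
            resolve(img, list(node.children))

    def resolve_dup(m_node: str, members: list[CoNode]) -> None:
        # Children of one duplication multifurcation are mutually
        # non-orthologous, so two of them may share a passage through a
        # species node only by coalescing at a lower duplication -- which
        # the canonical cotree allows anywhere.  The cheapest embedding
        # therefore sends one lineage per occupied side of m_node, losing
        # the sides it skips; members mapping to m_node itself sit at the
        # coalescence point and cost nothing.
        at_node = [m for m in members if image[id(m)] == m_node]
        below = [m for m in members if image[id(m)] != m_node]
        for m in at_node:
            descend(m)
        groups: dict[str, list[CoNode]] = {}
        for m in below:
            side = ladder.side_of(m_node, image[id(m)])
            groups.setdefault(side, []).append(m)
        for side in ladder.children[m_node]:
            grp = groups.get(side, [])
            if not grp:
                continue
            sub_lca = ladder.lca([image[id(m)] for m in grp])
            charge(m_node, sub_lca, include_top=True)
            if len(grp) == 1:
                descend(grp[0])
            else:
                resolve_dup(sub_lca, grp)

    def resolve(s_node: str, members: list[CoNode]) -> None:
        at_node = [m for m in members if image[id(m)] == s_node]
        below = [m for m in members if image[id(m)] != s_node]
        for m in at_node:
            # image equal to the resolution point: lineage sits at s_node
            # (inconsistent/noisy input); no losses chargeable
            descend(m)
        groups: dict[str, list[CoNode]] = {}
        for m in below:
            side = ladder.side_of(s_node, image[id(m)])
            groups.setdefault(side, []).append(m)
        for side in ladder.children[s_node]:
            grp = groups.get(side, [])
            if not grp:
                continue  # side lost or covered by at_node members
            sub_lca = ladder.lca([image[id(m)] for m in grp])
            charge(side, sub_lca, include_top=True)
            if len(grp) == 1:
                descend(grp[0])
            else:
                resolve(sub_lca, grp)

    descend(tree.root)
    return Reconciliation(
        image=image,
        duplication_count=dup_count,
        loss_count=loss_count,
        speciation_count=spec_count,
        dups_per_branch=dpb,
        losses_per_branch=lpb,
        root_image=image[id(tree.root)],
    )


def _check_ancestor_preserving(tree: EventTree, rec: Reconciliation,
                               ladder: SpeciesLadder) -> bool:
    for node in tree.root.walk():
        for c in node.children:
            if not ladder.is_ancestor(rec.image[id(node)], rec.image[id(c)]):
                return False
    return True


# ---------------------------------------------------------------------------
# whole-orthogroup driver and summaries

@dataclass
class FamilyHistory:
    orthogroup: set[str]
    edits: list[tuple[str, str, str]]
    tree: EventTree
    reconciliation: Reconciliation


def reconstruct_family(
    graph: nx.Graph,
    genes: set[str],
    species_of: Mapping[str, str],
    ladder: SpeciesLadder,
) -> FamilyHistory:
    """graph restriction -> (edit) -> cotree -> events -> reconciliation."""
    sub = graph.subgraph(genes).copy()
    edited, edits = cograph_edit(sub, species_of)
    cotree = modular_decomposition(edited)
    tree = label_events(cotree, species_of)
    rec = reconcile(tree, ladder)
    assert _check_ancestor_preserving(tree, rec, ladder)
    return FamilyHistory(set(genes), edits, tree, rec)


def reconstruct_all(
    graph: nx.Graph,
    orthogroups: Sequence[set[str]],
    species_of: Mapping[str, str],
    ladder: SpeciesLadder,
) -> list[FamilyHistory]:
    return [
        reconstruct_family(graph, grp, species_of, ladder)
        for grp in orthogroups
    ]


def summarize_histories(
    histories: Sequence[FamilyHistory], ladder: SpeciesLadder
) -> "pd.DataFrame":
    """Per-clade totals of gains (duplications), losses and root presence."""
    import pandas as pd

    dups: Counter = Counter()
    losses: Counter = Counter()
    roots: Counter = Counter()
    for h in histories:
        dups.update(h.reconciliation.dups_per_branch)
        losses.update(h.reconciliation.losses_per_branch)
        roots[h.reconciliation.root_image] += 1
    rows = []
    for node in sorted(ladder.parent, key=ladder.depth):
        rows.append({
            "clade": node,
            "gains": dups.get(node, 0),
            "losses": losses.get(node, 0),
            "family_roots": roots.get(node, 0),
        })
    return pd.DataFrame(rows)


def event_newick(tree: EventTree) -> str:
    """Newick with event labels in comments, e.g. ``(a,b)[&&event=speciation]``."""

    def render(node: CoNode) -> str:
        if node.kind == "leaf":
            return f"{node.gene}"
        inner = ",".join(render(c) for c in node.children)
        return f"({inner})[&&event={node.kind}]"

    return render(tree.root) + ";"
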