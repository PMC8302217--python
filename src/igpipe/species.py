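"""The fixed seven-taxon vertebrate species ladder.

The comparative analyses in this package are anchored on the mouse genome
and six reference vertebrates spanning three classes.  The rooted binary
species tree

    (((((mouse,rat)Muridae,(human,chimp)Primates)Eutheria,opossum)Theria,
       chick)Tetrapoda,zebrafish)Vertebrata

doubles as the "age ladder": a mouse gene conserved out to zebrafish is
assigned the age *Vertebrata*, one conserved only in rat the age *Muridae*,
and so on.  ``Primates`` is an implementation label for the human+chimp
cherry; the five clade names Muridae/Eutheria/Theria/Tetrapoda/Vertebrata
are the age groups used throughout.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import dendropy

LEAVES: tuple[str, ...] = (
    "mouse", "rat", "human", "chimp", "opossum", "chick", "zebrafish",
)
INTERNAL: tuple[str, ...] = (
    "Muridae", "Primates", "Eutheria", "Theria", "Tetrapoda", "Vertebrata",
)

#: Parent map of the fixed topology; the root has parent ``None``.
_PARENT: dict[str, str | None] = {
    "mouse": "Muridae",
    "rat": "Muridae",
    "human": "Primates",
    "chimp": "Primates",
    "Muridae": "Eutheria",
    "Primates": "Eutheria",
    "Eutheria": "Theria",
    "opossum": "Theria",
    "Theria": "Tetrapoda",
    "chick": "Tetrapoda",
    "Tetrapoda": "Vertebrata",
    "zebrafish": "Vertebrata",
    "Vertebrata": None,
}

NEWICK = (
    "(((((mouse,rat)Muridae,(human,chimp)Primates)Eutheria,opossum)Theria,"
    "chick)Tetrapoda,zebrafish)Vertebrata;"
)


class SpeciesLadder:
    """Rooted binary species tree with named internal nodes.

    Provides the tree queries the reconciliation and age-assignment code
    needs: LCA, ancestor tests, root-ward paths and subtree leaf sets.
    """

    def __init__(self, parent: dict[str, str | None] | None = None):
        self.parent = dict(parent or _PARENT)
        roots = [n for n, p in self.parent.items() if p is None]
        if len(roots) != 1:
            raise ValueError("ladder must have exactly one root")
        self.root = roots[0]
        self.children: dict[str, list[str]] = {n: [] for n in self.parent}
        for node, par in self.parent.items():
            if par is not None:
                self.children[par].append(node)
        self.leaves = tuple(n for n in self.parent if not self.children[n])
        self.internal = tuple(n for n in self.parent if self.children[n])
        self._depth: dict[str, int] = {}
        for node in self.parent:
            d, cur = 0, node
            while self.parent[cur] is not None:
                cur = self.parent[cur]  # type: ignore[assignment]
                d += 1
            self._depth[node] = d
        self._subtree: dict[str, frozenset[str]] = {}
        for node in self.parent:
            self._subtree[node] = frozenset(self._collect_leaves(node))

    def _collect_leaves(self, node: str) -> list[str]:
        if not self.children[node]:
            return [node]
        out: list[str] = []
        for c in self.children[node]:
            out.extend(self._collect_leaves(c))
        return out

    # -- queries -----------------------------------------------------------

    def __contains__(self, name: str) -> bool:
        return name in self.parent

    def depth(self, node: str) -> int:
        return self._depth[node]

    def subtree_leaves(self, node: str) -> frozenset[str]:
        return self._subtree[node]

    def path_to_root(self, node: str) -> list[str]:
        """Nodes from ``node`` (inclusive) up to the root (inclusive)."""
        out = [node]
        while self.parent[out[-1]] is not None:
            out.append(self.parent[out[-1]])  # type: ignore[arg-type]
        return out

    def is_ancestor(self, anc: str, node: str) -> bool:
        """True if ``anc`` is an ancestor of or equal to ``node``."""
        return anc in self.path_to_root(node)

    def lca(self, nodes: Iterable[str]) -> str:
        nodes = list(nodes)
        if not nodes:
            raise ValueError("lca of empty node set")
        common = set(self.path_to_root(nodes[0]))
        for n in nodes[1:]:
            common &= set(self.path_to_root(n))
        return max(common, key=lambda n: self._depth[n])

    def path_down(self, top: str, bottom: str) -> list[str]:
        """Nodes from ``top`` down to ``bottom``, both inclusive.

        ``top`` must be an ancestor of or equal to ``bottom``.
        """
        up = self.path_to_root(bottom)
        if top not in up:
            raise ValueError(f"{top!r} is not an ancestor of {bottom!r}")
        return list(reversed(up[: up.index(top) + 1]))

    def distance(self, anc: str, node: str) -> int:
        """Number of edges from ancestor ``anc`` down to ``node``."""
        return len(self.path_down(anc, node)) - 1

    def side_of(self, node: str, descendant: str) -> str:
        """The child of ``node`` whose subtree contains ``descendant``."""
        for c in self.children[node]:
            if self.is_ancestor(c, descendant):
                return c
        raise ValueError(f"{descendant!r} not below {node!r}")

    def off_path_children(self, node: str, taken: str) -> list[str]:
        return [c for c in self.children[node] if c != taken]

    # -- IO ----------------------------------------------------------------

    def to_newick(self) -> str:
        def render(node: str) -> str:
            if not self.children[node]:
                return node
            inner = ",".join(render(c) for c in self.children[node])
            return f"({inner}){node}"

        return render(self.root) + ";"

    @classmethod
    def default(cls) -> "SpeciesLadder":
        return cls()

    @classmethod
    def from_newick(cls, source: str) -> "SpeciesLadder":
        """Build a ladder from a Newick string or file path.

        Internal node labels are required (they are the clade names used
        by the age assignment).
        """
        import os

        if os.path.exists(source):
            tree = dendropy.Tree.get(path=source, schema="newick")
        else:
            tree = dendropy.Tree.get(data=source, schema="newick")
        parent: dict[str, str | None] = {}

        def name_of(nd: dendropy.Node) -> str:
            if nd.taxon is not None and nd.taxon.label:
                return nd.taxon.label.replace(" ", "_")
            if nd.label:
                return nd.label
            raise ValueError("every node in the species tree must be named")

        def walk(nd: dendropy.Node, par: str | None) -> None:
            name = name_of(nd)
            if name in parent:
                raise ValueError(f"duplicate node name {name!r}")
            parent[name] = par
            for ch in nd.child_nodes():
                walk(ch, name)

        walk(tree.seed_node, None)
        return cls(parent)


def default_ladder() -> SpeciesLadder:
    """The fixed 7-leaf ladder used across the package."""
    return SpeciesLadder()
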