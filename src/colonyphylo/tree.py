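"""Rooted clade trees over colony labels.

A minimal rooted-tree container used throughout the package: tips are
colony identifiers, every node owns the branch *above* it (so the root's
branch is the stem leading into the tree), and each node's clade — the
frozenset of tip labels below it — is the primary handle for mutation
assignment and expansion calls. Newick import/export goes through
dendropy.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = ["CladeTree"]


class CladeTree:
    """Rooted tree with labelled tips and per-node branch lengths.

    Nodes are integer ids in preorder (root = 0). ``parent[i]`` is the
    parent id (-1 for the root); ``clade[i]`` is the frozenset of tip
    labels below node ``i``; ``length[i]`` is the length of the branch
    above node ``i`` (the root's entry is the stem).
    """

    def __init__(
        self,
        parent: Sequence[int],
        labels: Sequence[str | None],
        length: Sequence[float] | None = None,
    ):
        self.parent = np.asarray(parent, dtype=int)
        self.n_nodes = len(self.parent)
        self.labels = list(labels)
        self.children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i in range(1, self.n_nodes):
            self.children[self.parent[i]].append(i)
        if length is None:
            length = np.zeros(self.n_nodes)
        self.length = np.asarray(length, dtype=float)
        self.clade: list[frozenset[str]] = [frozenset()] * self.n_nodes
        for i in reversed(range(self.n_nodes)):  # preorder => children after parents
            if not self.children[i]:
                if self.labels[i] is None:
                    raise ValueError(f"tip node {i} has no label")
                self.clade[i] = frozenset([self.labels[i]])
            else:
                self.clade[i] = frozenset().union(*(self.clade[c] for c in self.children[i]))
        self.tips = sorted(self.clade[0])

    # -- construction ---------------------------------------------------

    @classmethod
    def from_laminar(cls, tips: Iterable[str], clades: Iterable[frozenset]) -> "CladeTree":
        """Build a tree from a laminar family of clades over ``tips``.

        ``clades`` may include or omit the full tip set and singletons;
        both are added automatically. Raises ``ValueError`` if the family
        is not laminar (two clades overlap without nesting).
        """
        tips = sorted(set(tips))
        full = frozenset(tips)
        fam = {full} | {frozenset([t]) for t in tips}
        for c in clades:
            c = frozenset(c)
            if not c or not c <= full:
                raise ValueError("clade not a subset of the tip set")
            fam.add(c)
        sets = sorted(fam, key=lambda s: (-len(s), tuple(sorted(s))))
        for a in sets:
            for b in sets:
                if a & b and not (a <= b or b <= a):
                    raise ValueError(f"clades {sorted(a)} and {sorted(b)} conflict")
        # parent of each set = smallest strict superset
        parent_set: dict[frozenset, frozenset | None] = {full: None}
        for s in sets:
            if s is full or s == full:
                continue
            best = None
            for t in sets:
                if s < t and (best is None or len(t) < len(best)):
                    best = t
            parent_set[s] = best
        # preorder ids
        kids: dict[frozenset, list[frozenset]] = {s: [] for s in sets}
        for s, p in parent_set.items():
            if p is not None:
                kids[p].append(s)
        for p in kids:
            kids[p].sort(key=lambda s: (-len(s), tuple(sorted(s))))
        order: list[frozenset] = []
        stack = [full]
        while stack:
            s = stack.pop()
            order.append(s)
            stack.extend(reversed(kids[s]))
        idx = {s: i for i, s in enumerate(order)}
        parent = [idx[parent_set[s]] if parent_set[s] is not None else -1 for s in order]
        labels = [next(iter(s)) if len(s) == 1 else None for s in order]
        return cls(parent, labels)

    @classmethod
    def from_newick(cls, newick: str) -> "CladeTree":
        dt = dendropy.Tree.get(data=newick, schema="newick", suppress_internal_node_taxa=True)
        nodes = list(dt.preorder_node_iter())
        idx = {id(n): i for i, n in enumerate(nodes)}
        parent = [-1] + [idx[id(n.parent_node)] for n in nodes[1:]]
        labels = [n.taxon.label if n.taxon is not None else None for n in nodes]
        length = [n.edge.length if n.edge.length is not None else 0.0 for n in nodes]
        return cls(parent, labels, length)

    def to_newick(self, lengths: Sequence[float] | None = None) -> str:
        """Newick string; ``lengths`` overrides per-node branch lengths."""
        L = self.length if lengths is None else np.asarray(lengths, dtype=float)
        taxa = dendropy.TaxonNamespace(self.tips)
        dt = dendropy.Tree(taxon_namespace=taxa)
        dnodes = [None] * self.n_nodes
        dnodes[0] = dt.seed_node
        for i in range(1, self.n_nodes):
            ch = dendropy.Node()
            dnodes[self.parent[i]].add_child(ch)
            dnodes[i] = ch
        for i in range(self.n_nodes):
            dnodes[i].edge.length = float(L[i])
            if self.labels[i] is not None:
                dnodes[i].taxon = taxa.get_taxon(self.labels[i])
        return dt.as_string(schema="newick", suppress_rooting=True).strip()

    # -- queries ---------------------------------------------------------

    def is_tip(self, i: int) -> bool:
        return not self.children[i]

    @property
    def tip_ids(self) -> list[int]:
        return [i for i in range(self.n_nodes) if not self.children[i]]

    @property
    def internal_ids(self) -> list[int]:
        return [i for i in range(self.n_nodes) if self.children[i]]

    def node_of_clade(self, tipset: Iterable[str]) -> int | None:
        s = frozenset(tipset)
        for i in range(self.n_nodes):
            if self.clade[i] == s:
                return i
        return None

    def mrca(self, tipset: Iterable[str]) -> int:
        """Most recent common ancestor node of a set of tip labels."""
        s = frozenset(tipset)
        if not s <= frozenset(self.tips):
            raise ValueError("tip set contains unknown labels")
        best = 0
        for i in range(self.n_nodes):
            if s <= self.clade[i] and len(self.clade[i]) < len(self.clade[best]):
                best = i
        return best

    def node_heights(self, lengths: Sequence[float] | None = None) -> np.ndarray:
        """Cumulative branch length from the origin of the stem to each node."""
        L = self.length if lengths is None else np.asarray(lengths, dtype=float)
        h = np.zeros(self.n_nodes)
        for i in range(self.n_nodes):
            p = self.parent[i]
            h[i] = L[i] + (h[p] if p >= 0 else 0.0)
        return h

    def clade_set(self, min_size: int = 2, exclude_root: bool = True) -> set[frozenset]:
        """Set of clades (tip-label frozensets), for topology comparison."""
        out = set()
        for i in range(self.n_nodes):
            if exclude_root and i == 0:
                continue
            if len(self.clade[i]) >= min_size:
                out.add(self.clade[i])
        return out

    def __repr__(self) -> str:  # pragma: no cover
        return f"CladeTree(n_tips={len(self.tips)}, n_nodes={self.n_nodes})"
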