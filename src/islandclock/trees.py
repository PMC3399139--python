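"""Rooted binary time-trees.

The container is deliberately array-based: tips occupy indices
``0 .. n_taxa-1`` (in the order taxa first appear), internal nodes
``n_taxa .. 2*n_taxa-2``, and every node except the root has a parent
pointer.  Node ages are in Ma with tips fixed at 0; ages may be absent
(``None``) on a bare topology until a dating run or simulation assigns them.
"""

from __future__ import annotations

from typing import Optional, Sequence

import dendropy
import numpy as np


class TreeStructureError(ValueError):
    """Raised for unrooted, polytomous, or otherwise malformed trees."""


class AgeConstraintError(ValueError):
    """Raised when node ages violate the parent-older-than-child ordering."""


class RootedTimeTree:
    """Rooted binary tree over named tips with optional node ages (Ma)."""

    __slots__ = ("taxon_labels", "parent", "children", "ages", "_postorder", "_tipsets")

    def __init__(
        self,
        taxon_labels: Sequence[str],
        parent: np.ndarray,
        children: Sequence[tuple[int, ...]],
        ages: Optional[np.ndarray] = None,
    ):
        self.taxon_labels = list(taxon_labels)
        self.parent = np.asarray(parent, dtype=np.int64)
        self.children = [tuple(c) for c in children]
        self.ages = None if ages is None else np.asarray(ages, dtype=float)
        self._postorder = None
        self._tipsets = None
        self._validate_structure()
        if self.ages is not None:
            self.validate_ages()

    # ---------------------------------------------------------------- basics
    @property
    def n_taxa(self) -> int:
        return len(self.taxon_labels)

    @property
    def n_nodes(self) -> int:
        return len(self.children)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    def is_tip(self, node: int) -> bool:
        return node < self.n_taxa

    @property
    def internal_nodes(self) -> list[int]:
        return [i for i in range(self.n_taxa, self.n_nodes)]

    def _validate_structure(self) -> None:
        n = self.n_taxa
        if n < 2:
            raise TreeStructureError("a rooted tree needs at least two tips")
        if len(set(self.taxon_labels)) != n:
            raise TreeStructureError("duplicate taxon labels")
        if self.n_nodes != 2 * n - 1:
            raise TreeStructureError(
                f"a binary tree on {n} tips must have {2 * n - 1} nodes, "
                f"got {self.n_nodes}"
            )
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise TreeStructureError("tree must have exactly one root")
        for i, kids in enumerate(self.children):
            if i < n:
                if kids:
                    raise TreeStructureError(f"tip {self.taxon_labels[i]!r} has children")
            elif len(kids) != 2:
                raise TreeStructureError(
                    f"internal node {self.node_label(i)!r} has {len(kids)} children "
                    "(binary rooted tree required)"
                )

    def validate_ages(self) -> None:
        if self.ages is None:
            raise AgeConstraintError("tree has no ages")
        if np.any(self.ages[: self.n_taxa] != 0.0):
            raise AgeConstraintError("all tip ages must equal 0")
        for i in self.internal_nodes:
            for c in self.children[i]:
                if not self.ages[i] > self.ages[c]:
                    raise AgeConstraintError(
                        f"node {self.node_label(i)!r} (age {self.ages[i]:g}) is not "
                        f"older than its child {self.node_label(c)!r} "
                        f"(age {self.ages[c]:g})"
                    )

    # ------------------------------------------------------------ traversals
    @property
    def postorder(self) -> list[int]:
        """Node indices, every child before its parent."""
        if self._postorder is None:
            order, stack = [], [self.root]
            while stack:
                node = stack.pop()
                order.append(node)
                stack.extend(self.children[node])
            self._postorder = order[::-1]
        return self._postorder

    def tipset(self, node: int) -> frozenset[int]:
        """Indices of tips descending from ``node`` (a tip descends from itself)."""
        if self._tipsets is None:
            sets: list[frozenset[int]] = [frozenset()] * self.n_nodes
            for nd in self.postorder:
                if self.is_tip(nd):
                    sets[nd] = frozenset([nd])
                else:
                    s: frozenset[int] = frozenset()
                    for c in self.children[nd]:
                        s |= sets[c]
                    sets[nd] = s
            self._tipsets = sets
        return self._tipsets[node]

    def clade_labels(self, node: int) -> tuple[str, ...]:
        return tuple(sorted(self.taxon_labels[t] for t in self.tipset(node)))

    def node_label(self, node: int) -> str:
        if self.is_tip(node):
            return self.taxon_labels[node]
        return "mrca(" + ",".join(self.clade_labels(node)) + ")"

    def mrca(self, taxon_a: str, taxon_b: str) -> int:
        """Most recent common ancestor of two distinct tips.

        Calibrations attach to internal nodes, so ``taxon_a == taxon_b``
        (the MRCA would be the tip itself) is rejected.
        """
        try:
            ia = self.taxon_labels.index(taxon_a)
            ib = self.taxon_labels.index(taxon_b)
        except ValueError as exc:
            raise KeyError(f"taxon not in tree: {exc}") from None
        if ia == ib:
            raise ValueError(
                f"MRCA of {taxon_a!r} with itself is the tip; calibrated nodes "
                "must be internal"
            )
        anc = set()
        node = ia
        while node >= 0:
            anc.add(node)
            node = int(self.parent[node])
        node = ib
        while node not in anc:
            node = int(self.parent[node])
        return node

    def branch_duration(self, node: int) -> float:
        """Time span (Ma) of the branch subtending ``node``."""
        if self.ages is None:
            raise AgeConstraintError("tree has no ages")
        p = int(self.parent[node])
        if p < 0:
            raise ValueError("root has no subtending branch")
        return float(self.ages[p] - self.ages[node])

    def copy(self) -> "RootedTimeTree":
        return RootedTimeTree(
            self.taxon_labels,
            self.parent.copy(),
            list(self.children),
            None if self.ages is None else self.ages.copy(),
        )

    def with_ages(self, ages: np.ndarray) -> "RootedTimeTree":
        return RootedTimeTree(self.taxon_labels, self.parent.copy(), list(self.children), ages)

    # ----------------------------------------------------------------- I/O
    @classmethod
    def from_newick(cls, newick: str, ages_from_lengths: bool = False) -> "RootedTimeTree":
        """Parse a rooted binary newick string.

        With ``ages_from_lengths`` the branch lengths are interpreted as time
        durations (the tree must then be ultrametric) and node ages are
        reconstructed with tips at 0.
        """
        dtree = dendropy.Tree.get(
            data=newick, schema="newick", rooting="force-rooted",
            suppress_internal_node_taxa=True,
        )
        dnodes = list(dtree.preorder_node_iter())
        for nd in dnodes:
            nc = len(nd.child_nodes())
            if nc not in (0, 2):
                tips = sorted(
                    lf.taxon.label for lf in nd.leaf_iter() if lf.taxon is not None
                )
                raise TreeStructureError(
                    f"node subtending {{{','.join(tips)}}} has {nc} children; "
                    "a rooted binary tree is required (resolve polytomies / root the tree)"
                )
        leaves = [nd for nd in dnodes if nd.is_leaf()]
        labels = []
        for lf in leaves:
            if lf.taxon is None or not lf.taxon.label:
                raise TreeStructureError("every tip must be named")
            labels.append(lf.taxon.label)
        n = len(labels)
        index = {id(nd): i for i, nd in enumerate(leaves)}
        internals = [nd for nd in dnodes if not nd.is_leaf()]
        # number internals so children always precede parents (reverse preorder)
        for j, nd in enumerate(reversed(internals)):
            index[id(nd)] = n + j
        parent = np.full(2 * n - 1, -1, dtype=np.int64)
        children: list[tuple[int, ...]] = [()] * (2 * n - 1)
        for nd in dnodes:
            i = index[id(nd)]
            kids = tuple(index[id(c)] for c in nd.child_nodes())
            children[i] = kids
            for c in nd.child_nodes():
                parent[index[id(c)]] = i
        ages = None
        if ages_from_lengths:
            depth = {id(dtree.seed_node): 0.0}
            for nd in dnodes[1:]:
                el = nd.edge.length if nd.edge.length is not None else 0.0
                depth[id(nd)] = depth[id(nd.parent_node)] + float(el)
            tip_depths = [depth[id(lf)] for lf in leaves]
            height = max(tip_depths)
            if height > 0 and (height - min(tip_depths)) / height > 1e-6:
                raise AgeConstraintError(
                    "branch lengths are not ultrametric; cannot reconstruct node ages"
                )
            ages = np.zeros(2 * n - 1)
            for nd in internals:
                ages[index[id(nd)]] = height - depth[id(nd)]
            ages[:n] = 0.0
        return cls(labels, parent, children, ages)

    def to_newick(self, lengths: str = "auto") -> str:
        """Serialize to newick.

        ``lengths='auto'`` writes time durations when ages are present and a
        bare topology otherwise; ``'none'`` always writes bare topology.
        """
        write_lengths = lengths == "auto" and self.ages is not None

        def fmt(node: int) -> str:
            if self.is_tip(node):
                s = _quote(self.taxon_labels[node])
            else:
                s = "(" + ",".join(fmt(c) for c in self.children[node]) + ")"
            p = int(self.parent[node])
            if write_lengths and p >= 0:
                s += f":{self.ages[p] - self.ages[node]:.10g}"
            return s

        return fmt(self.root) + ";"


def _quote(label: str) -> str:
    if any(ch in label for ch in " ,():;[]'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def canonical_topology(tree: RootedTimeTree) -> tuple:
    """Order-insensitive topology fingerprint (nested sorted tip tuples)."""

    def rec(node: int):
        if tree.is_tip(node):
            return tree.taxon_labels[node]
        return tuple(sorted((rec(c) for c in tree.children[node]), key=str))

    return rec(tree.root)
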