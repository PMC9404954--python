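"""Chronogram handling: rooted ultrametric trees with branch lengths in Ma.

Thin wrapper over :mod:`dendropy` adding validation (non-negative branch
lengths, unique tip labels, ultrametricity to a relative tolerance),
taxon grafting at a fixed split age, and the Brownian-motion tip
covariance matrix. Internal nodes are addressed by the set of tip labels
whose MRCA they are — node numbers of particular software traversals are
not portable.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import dendropy
import numpy as np

from .errors import FormatError

ULTRAMETRIC_RTOL = 1e-6


def _node_id(tips: frozenset) -> str:
    joined = "|".join(sorted(tips))
    return "n" + hashlib.sha1(joined.encode()).hexdigest()[:8]


@dataclass
class NodeInfo:
    """An internal node addressed by its MRCA tip set."""

    node_id: str
    tips: frozenset
    age: float  # Ma before present (tree depth minus root distance)
    root_distance: float


class Chronogram:
    """A rooted time tree with unique tip labels."""

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        self._validate()

    # -- construction ----------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "Chronogram":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except dendropy.utility.error.DataParseError as exc:
            # dendropy rejects duplicate tip labels (and other malformations)
            # during tokenizing; surface them under this package's hierarchy
            if "Duplicate" in str(exc) or "duplicate" in str(exc):
                raise FormatError(f"duplicate tip labels: {exc}") from exc
            raise FormatError(str(exc)) from exc
        return cls(tree)

    @classmethod
    def from_file(cls, path) -> "Chronogram":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True,
                                   unquoted_underscores=True).strip()

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    def copy(self) -> "Chronogram":
        return Chronogram.from_newick(self.to_newick())

    # -- validation ------------------------------------------------------
    def _validate(self) -> None:
        labels = [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            dup = sorted({x for x in labels if labels.count(x) > 1})
            raise FormatError(f"duplicate tip labels: {dup}")
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise FormatError(f"negative branch length {edge.length}")
        self._index()
        depths = np.array([self._rd[leaf] for leaf in self.tree.leaf_node_iter()])
        self.depth = float(depths.max()) if depths.size else 0.0
        spread = float(depths.max() - depths.min()) if depths.size else 0.0
        self.is_ultrametric = spread <= ULTRAMETRIC_RTOL * max(self.depth, 1e-300)

    def _index(self) -> None:
        """Cache root distances and leaf sets per node."""
        self._rd: dict = {}
        self._leafset: dict = {}
        self._parent: dict = {}
        for node in self.tree.preorder_node_iter():
            parent = node.parent_node
            self._parent[node] = parent
            edge = node.edge.length or 0.0
            self._rd[node] = (self._rd[parent] + edge) if parent else 0.0
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                self._leafset[node] = frozenset([node.taxon.label])
            else:
                self._leafset[node] = frozenset().union(
                    *(self._leafset[c] for c in node.child_nodes()))

    # -- queries ---------------------------------------------------------
    @property
    def tip_labels(self) -> list[str]:
        return sorted(self._leafset[self.tree.seed_node])

    def __len__(self) -> int:
        return len(self._leafset[self.tree.seed_node])

    def node_age(self, node) -> float:
        return self.depth - self._rd[node]

    def mrca(self, labels) -> dendropy.Node:
        want = frozenset(labels)
        missing = want - self._leafset[self.tree.seed_node]
        if missing:
            raise KeyError(f"tips not in tree: {sorted(missing)}")
        node = next(leaf for leaf in self.tree.leaf_node_iter()
                    if leaf.taxon.label in want)
        while not want <= self._leafset[node]:
            node = self._parent[node]
        return node

    def internal_nodes(self) -> list[NodeInfo]:
        out = []
        for node in self.tree.preorder_node_iter():
            if node.is_leaf():
                continue
            tips = self._leafset[node]
            out.append(NodeInfo(
                node_id=_node_id(tips), tips=tips,
                age=self.node_age(node), root_distance=self._rd[node]))
        return out

    # -- editing ---------------------------------------------------------
    def graft(self, new_tip: str, sister_tip: str, split_age: float) -> "Chronogram":
        """Attach ``new_tip`` as sister to ``sister_tip`` at ``split_age`` Ma.

        The new divergence sits on the sister's terminal branch, so both
        daughter branches have length ``split_age`` and ultrametricity is
        preserved. Fails when the split age is not inside the terminal
        branch or when the label already exists.
        """
        if split_age <= 0:
            raise ValueError("split_age must be positive")
        if new_tip in self._leafset[self.tree.seed_node]:
            raise ValueError(f"tip {new_tip!r} already in tree")
        out = self.copy()
        sister = next((leaf for leaf in out.tree.leaf_node_iter()
                       if leaf.taxon.label == sister_tip), None)
        if sister is None:
            raise KeyError(f"sister tip {sister_tip!r} not in tree")
        terminal = sister.edge.length or 0.0
        if split_age >= terminal:
            raise ValueError(
                f"split_age {split_age} not below the parent node at {terminal} Ma")
        parent = sister.parent_node
        parent.remove_child(sister)
        joint = parent.new_child(edge_length=terminal - split_age)
        sister.edge.length = split_age
        joint.add_child(sister)
        taxon = dendropy.Taxon(label=new_tip)
        out.tree.taxon_namespace.add_taxon(taxon)
        joint.new_child(taxon=taxon, edge_length=split_age)
        return Chronogram.from_newick(out.to_newick())

    def drop_tip(self, label: str) -> "Chronogram":
        if label not in self._leafset[self.tree.seed_node]:
            raise KeyError(f"tip {label!r} not in tree")
        out = self.copy()
        out.tree.prune_taxa_with_labels([label])
        return Chronogram.from_newick(out.tree.as_string(schema="newick"))

    # -- Brownian machinery ----------------------------------------------
    def bm_covariance(self) -> tuple[list[str], np.ndarray]:
        """Tip covariance under unit-rate BM: shared root-to-MRCA path lengths.

        Entry (i, j) is the root distance of the MRCA of tips i and j; the
        diagonal is each tip's root-to-tip depth. Tips follow sorted label
        order. The matrix is positive semidefinite for any valid tree.
        """
        labels = self.tip_labels
        idx = {lab: i for i, lab in enumerate(labels)}
        n = len(labels)
        V = np.zeros((n, n))
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                i = idx[node.taxon.label]
                V[i, i] = self._rd[node]
                continue
            children = node.child_nodes()
            sets = [sorted(idx[t] for t in self._leafset[c]) for c in children]
            rd = self._rd[node]
            for a in range(len(sets)):
                for b in range(a + 1, len(sets)):
                    for i in sets[a]:
                        V[i, sets[b]] = rd
                        for j in sets[b]:
                            V[j, i] = rd
        return labels, V

    def tip_distances(self) -> tuple[list[str], np.ndarray]:
        """Patristic distances between tips."""
        labels, V = self.bm_covariance()
        depths = np.diag(V)
        return labels, depths[:, None] + depths[None, :] - 2.0 * V

    def node_tip_distances(self) -> tuple[list[NodeInfo], list[str], np.ndarray]:
        """Patristic distance from every internal node to every tip."""
        labels = self.tip_labels
        idx = {lab: i for i, lab in enumerate(labels)}
        tip_rd = {lab: self._rd[leaf] for leaf in self.tree.leaf_node_iter()
                  for lab in [leaf.taxon.label]}
        nodes = []
        rows = []
        for node in self.tree.preorder_node_iter():
            if node.is_leaf():
                continue
            tips = self._leafset[node]
            info = NodeInfo(_node_id(tips), tips, self.node_age(node),
                            self._rd[node])
            row = np.empty(len(labels))
            for lab in labels:
                anc = node
                while lab not in self._leafset[anc]:
                    anc = self._parent[anc]
                row[idx[lab]] = (self._rd[node] + tip_rd[lab]
                                 - 2.0 * self._rd[anc])
            nodes.append(info)
            rows.append(row)
        return nodes, labels, np.array(rows)


def read_chronogram(path_or_newick) -> Chronogram:
    """Read a newick chronogram from a path or a literal newick string."""
    text = str(path_or_newick)
    if text.lstrip().startswith("("):
        return Chronogram.from_newick(text)
    return Chronogram.from_file(path_or_newick)
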