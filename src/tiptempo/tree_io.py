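"""Reading, validation and indexing of dated phylogenies.

Trees are stored as flat integer-indexed structures (parent array, child
lists, branch lengths in Ma) because every downstream computation — pruning
likelihoods, stochastic maps, root-to-tip path extraction — iterates over
nodes far more often than it touches the Newick text.  Parsing and writing
are delegated to :mod:`dendropy`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "PhyloTree",
    "TreeSet",
    "TreeValidationError",
    "read_trees",
    "write_trees",
    "lineage_nodes",
]


class TreeValidationError(ValueError):
    """Raised when a tree or tree set violates the dated-tree contract."""


@dataclass
class PhyloTree:
    """A rooted, dated phylogeny with stable integer node ids.

    Node ids are assigned in preorder, so the root is always node 0.
    Polytomies are allowed; branch lengths are in millions of years and
    must be finite and non-negative.  Node ages (Ma before present) are
    derived by setting the root age to the maximum root-to-tip path
    length, so on an ultrametric tree every tip has age 0.
    """

    parent: np.ndarray          # int array, -1 at the root
    children: list[list[int]]
    branch_length: np.ndarray   # float array, 0.0 at the root (unused)
    tip_label: dict[int, str]
    root: int = 0
    _tip_index: dict[str, int] = field(default_factory=dict, repr=False)
    _age: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.branch_length = np.asarray(self.branch_length, dtype=float)
        self._validate()
        self._tip_index = {lab: nid for nid, lab in self.tip_label.items()}

    # -- construction -------------------------------------------------

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "PhyloTree":
        tree = tree.clone(depth=1)
        if tree.seed_node is None:
            raise TreeValidationError("empty tree")
        nodes = list(tree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        parent = np.full(n, -1, dtype=np.int64)
        blen = np.zeros(n, dtype=float)
        children: list[list[int]] = [[] for _ in range(n)]
        tip_label: dict[int, str] = {}
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                p = index[id(nd.parent_node)]
                parent[i] = p
                children[p].append(i)
                blen[i] = 0.0 if nd.edge.length is None else float(nd.edge.length)
            if nd.is_leaf():
                if nd.taxon is None or nd.taxon.label is None:
                    raise TreeValidationError(f"unlabeled tip at node {i}")
                tip_label[i] = nd.taxon.label
        return cls(parent=parent, children=children, branch_length=blen,
                   tip_label=tip_label)

    # -- validation ----------------------------------------------------

    def _validate(self) -> None:
        n = self.n_nodes
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1 or roots[0] != self.root:
            raise TreeValidationError(
                f"expected exactly one root at node {self.root}, found {roots}")
        if not np.all(np.isfinite(self.branch_length)):
            raise TreeValidationError("non-finite branch length")
        if np.any(self.branch_length < 0):
            raise TreeValidationError("negative branch length")
        # preorder ids: parents precede children, which also rules out cycles
        if not np.all(self.parent[1:] < np.arange(1, n)):
            raise TreeValidationError("node ids are not in preorder")
        labels = list(self.tip_label.values())
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise TreeValidationError(f"duplicate tip labels: {dupes}")
        for nid, kids in enumerate(self.children):
            if not kids and nid not in self.tip_label:
                raise TreeValidationError(f"leaf node {nid} has no tip label")

    # -- basic queries -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_tips(self) -> int:
        return len(self.tip_label)

    @property
    def tip_labels(self) -> list[str]:
        return sorted(self.tip_label.values())

    @property
    def tips(self) -> list[int]:
        return sorted(self.tip_label)

    def tip_id(self, label: str) -> int:
        try:
            return self._tip_index[label]
        except KeyError:
            raise KeyError(f"unknown tip label: {label!r}") from None

    def preorder(self) -> np.ndarray:
        return np.arange(self.n_nodes)

    def postorder(self) -> np.ndarray:
        return np.arange(self.n_nodes - 1, -1, -1)

    # -- derived quantities --------------------------------------------

    def depths(self) -> np.ndarray:
        """Distance of every node from the root (Ma)."""
        d = np.zeros(self.n_nodes)
        for v in range(1, self.n_nodes):
            d[v] = d[self.parent[v]] + self.branch_length[v]
        return d

    @property
    def ages(self) -> np.ndarray:
        """Node ages in Ma before present (root age = max root-to-tip depth)."""
        if self._age is None:
            d = self.depths()
            self._age = d.max() - d
        return self._age

    @property
    def root_age(self) -> float:
        return float(self.ages[self.root])

    @property
    def total_length(self) -> float:
        return float(self.branch_length[1:].sum()) if self.n_nodes > 1 else 0.0

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        tip_ages = self.ages[self.tips]
        scale = max(self.root_age, 1.0)
        return bool(np.ptp(tip_ages) <= rel_tol * scale)

    # -- output --------------------------------------------------------

    def to_dendropy(self, taxon_namespace: dendropy.TaxonNamespace | None = None
                    ) -> dendropy.Tree:
        tns = taxon_namespace or dendropy.TaxonNamespace()
        tree = dendropy.Tree(taxon_namespace=tns)
        dnodes = {self.root: tree.seed_node}
        for v in range(self.n_nodes):
            if v == self.root:
                continue
            nd = dendropy.Node()
            nd.edge.length = float(self.branch_length[v])
            dnodes[self.parent[v]].add_child(nd)
            dnodes[v] = nd
        for nid, lab in self.tip_label.items():
            dnodes[nid].taxon = tns.require_taxon(label=lab)
        return tree

    def to_newick(self) -> str:
        return self.to_dendropy().as_string(
            schema="newick", suppress_rooting=True).strip()


@dataclass
class TreeSet:
    """An ordered list of trees over the same tip-label set.

    The list order is the phylogeny index axis of the estimate cube, so
    it must be stable across reads.
    """

    trees: list[PhyloTree]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.trees:
            raise TreeValidationError("empty tree set")
        ref = set(self.trees[0].tip_labels)
        for i, t in enumerate(self.trees[1:], start=1):
            cur = set(t.tip_labels)
            if cur != ref:
                diff = sorted(ref.symmetric_difference(cur))
                raise TreeValidationError(
                    f"tree {i} tip set differs from tree 0; "
                    f"symmetric difference: {diff}")

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def __getitem__(self, i: int) -> PhyloTree:
        return self.trees[i]

    @property
    def tip_labels(self) -> list[str]:
        return self.trees[0].tip_labels


def read_trees(path: str, format: str = "newick") -> TreeSet:
    """Read a set of dated trees from Newick or NEXUS text.

    All trees must share an identical tip-label set; mismatches raise
    :class:`TreeValidationError` naming the offending labels.  Branch
    lengths are preserved at full precision.  A warning is emitted for
    non-ultrametric trees (tolerated: imputed tips may break
    ultrametricity).
    """
    if format not in ("newick", "nexus"):
        raise ValueError(f"unsupported tree format: {format!r}")
    try:
        tl = dendropy.TreeList.get(path=path, schema=format,
                                   preserve_underscores=True)
    except Exception as exc:  # dendropy raises many distinct error classes
        raise TreeValidationError(f"failed to parse {path!r} as {format}: {exc}")
    if len(tl) == 0:
        raise TreeValidationError(f"no trees found in {path!r}")
    trees = [PhyloTree.from_dendropy(t) for t in tl]
    ts = TreeSet(trees=trees, provenance=str(path))
    for i, t in enumerate(trees):
        if not t.is_ultrametric():
            warnings.warn(f"tree {i} in {path!r} is not ultrametric; "
                          "node ages use root age = max root-to-tip depth")
            break
    return ts


def write_trees(tree_set: TreeSet, path: str) -> None:
    """Write a tree set as one Newick string per line (UTF-8)."""
    with open(path, "w", encoding="utf-8") as fh:
        for t in tree_set:
            fh.write(t.to_newick() + "\n")


def lineage_nodes(tree: PhyloTree, tip: str) -> list[int]:
    """Ordered node ids along the root-to-tip path for species ``tip``.

    The first element is the root, the last the tip node; consecutive
    elements are parent-child pairs.
    """
    v = tree.tip_id(tip)
    path = [v]
    while tree.parent[v] >= 0:
        v = int(tree.parent[v])
        path.append(v)
    path.reverse()
    return path
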