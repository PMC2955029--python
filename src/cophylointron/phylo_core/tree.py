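"""Tree container and tree-level utilities.

Trees are stored rooted; unrooted trees carry a trifurcating root.  Newick
serialisation goes through dendropy so all the usual dialects parse.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Optional

import dendropy
import numpy as np


class TreeError(ValueError):
    pass


class Node:
    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label: Optional[str] = None,
                 length: Optional[float] = None) -> None:
        self.label = label
        self.length = length
        self.children: list["Node"] = []
        self.parent: Optional["Node"] = None

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.label!r}, {self.length!r}, {len(self.children)} ch)"


class PhyloTree:
    """A rooted (or trifurcating-root unrooted) phylogenetic tree."""

    def __init__(self, root: Node) -> None:
        self.root = root
        labels = [l for l in self.leaf_labels() if l is not None]
        if len(set(labels)) != len(labels):
            raise TreeError("duplicate leaf labels")

    # -- traversal ---------------------------------------------------------
    def postorder(self) -> Iterator[Node]:
        stack, out = [self.root], []
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        return iter(reversed(out))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(reversed(n.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def n_leaves(self) -> int:
        return len(self.leaves())

    # -- construction / io -------------------------------------------------
    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        depth = 0
        for i, ch in enumerate(text):
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
                if depth < 0:
                    raise TreeError(f"unbalanced ')' at character offset {i}")
        if depth != 0:
            raise TreeError(f"unbalanced '(' ({depth} unclosed) in newick string")
        try:
            dt = dendropy.Tree.get(data=text, schema="newick",
                                   preserve_underscores=True)
        except Exception as exc:
            raise TreeError(f"cannot parse newick: {exc}") from exc
        return cls(_from_dendropy(dt.seed_node))

    @classmethod
    def read(cls, path: str | Path) -> "PhyloTree":
        return cls.from_newick(Path(path).read_text())

    def to_newick(self, precision: int = 10) -> str:
        def fmt(n: Node) -> str:
            if n.is_leaf:
                s = n.label or ""
            else:
                s = "(" + ",".join(fmt(c) for c in n.children) + ")"
                if n.label:
                    s += str(n.label)
            if n.length is not None:
                s += f":{n.length:.{precision}g}"
            return s

        return fmt(self.root) + ";"

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")

    def copy(self) -> "PhyloTree":
        def clone(n: Node) -> Node:
            m = Node(n.label, n.length)
            for c in n.children:
                m.add(clone(c))
            return m

        return PhyloTree(clone(self.root))

    def to_dendropy(self, taxon_namespace=None) -> dendropy.Tree:
        return dendropy.Tree.get(data=self.to_newick(), schema="newick",
                                 preserve_underscores=True,
                                 taxon_namespace=taxon_namespace)

    # -- manipulation ------------------------------------------------------
    def unroot(self) -> "PhyloTree":
        """Collapse a bifurcating root into a trifurcation, in place."""
        r = self.root
        while len(r.children) == 2 and not all(c.is_leaf for c in r.children):
            a, b = r.children
            keep, merge = (a, b) if not b.is_leaf else (b, a)
            # absorb `merge`'s branch into its grandchildren is wrong; instead
            # splice the non-leaf child's children up into the root
            child = keep if not keep.is_leaf else merge
            other = merge if child is keep else keep
            r.children = [other] + child.children
            for g in child.children:
                g.parent = r
            if other.length is not None and child.length is not None:
                other.length += child.length
            break
        return self

    def suppress_unifurcations(self) -> "PhyloTree":
        """Remove degree-2 internal nodes, summing branch lengths, in place."""
        changed = True
        while changed:
            changed = False
            for n in list(self.postorder()):
                if n.is_leaf or len(n.children) != 1:
                    continue
                child = n.children[0]
                if n.parent is None:
                    self.root = child
                    child.parent = None
                    child.length = None
                else:
                    if child.length is not None and n.length is not None:
                        child.length += n.length
                    idx = n.parent.children.index(n)
                    n.parent.children[idx] = child
                    child.parent = n.parent
                changed = True
        return self

    def relabel(self, mapping: dict[str, str]) -> "PhyloTree":
        for n in self.leaves():
            if n.label in mapping:
                n.label = mapping[n.label]
        return self

    def restrict(self, taxa: set[str]) -> "PhyloTree":
        """Return a copy restricted to ``taxa``, unifurcations suppressed."""
        t = self.copy()
        for n in list(t.postorder()):
            if n.is_leaf and n.label not in taxa and n.parent is not None:
                n.parent.children.remove(n)
        # drop empty internals
        changed = True
        while changed:
            changed = False
            for n in list(t.postorder()):
                if not n.is_leaf and not n.children and n.parent is not None:
                    n.parent.children.remove(n)
                    changed = True
        t.suppress_unifurcations()
        return t


def _from_dendropy(dn) -> Node:
    label = None
    if dn.taxon is not None:
        label = dn.taxon.label
    elif dn.label:
        label = dn.label
    node = Node(label, dn.edge.length)
    for c in dn.child_nodes():
        node.add(_from_dendropy(c))
    return node


# ---------------------------------------------------------------------------
# distance matrices
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Symmetric labelled distance matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("label/matrix size mismatch")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("distance matrix is not symmetric")
        np.fill_diagonal(self.values, 0.0)

    @property
    def n(self) -> int:
        return len(self.labels)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def reorder(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)])


def patristic(tree: PhyloTree) -> DistanceMatrix:
    """Path-length (sum of branch lengths) distances between all leaf pairs."""
    leaves = tree.leaves()
    labels = [n.label for n in leaves]
    index = {id(n): i for i, n in enumerate(leaves)}
    n = len(leaves)
    D = np.zeros((n, n))
    below: dict[int, list[tuple[int, float]]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = [(index[id(node)], 0.0)]
            continue
        lists = []
        for c in node.children:
            if c.length is None:
                raise TreeError(f"missing branch length above {c.label or 'internal node'}")
            lists.append([(i, d + c.length) for i, d in below[id(c)]])
        for a in range(len(lists)):
            for b in range(a + 1, len(lists)):
                for i, di in lists[a]:
                    for j, dj in lists[b]:
                        D[i, j] = D[j, i] = di + dj
        below[id(node)] = [pair for lst in lists for pair in lst]
    return DistanceMatrix(labels, D)


def robinson_foulds(a: PhyloTree, b: PhyloTree) -> int:
    """Unweighted Robinson-Foulds distance, via dendropy."""
    tns = dendropy.TaxonNamespace()
    da = a.to_dendropy(tns)
    db = b.to_dendropy(tns)
    da.encode_bipartitions()
    db.encode_bipartitions()
    return int(dendropy.calculate.treecompare.symmetric_difference(da, db))
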