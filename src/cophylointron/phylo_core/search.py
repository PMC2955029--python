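"""Heuristic maximum-likelihood tree search.

Hill climbing from a neighbor-joining start, alternating NNI (optionally SPR)
move rounds with full branch-length/model re-optimisation until no move
improves the log-likelihood.  Deterministic: candidate moves are generated in
a fixed traversal order and ties keep the incumbent, so an alignment with no
signal returns the NJ starting tree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional, Sequence

from ..formats_io import MultipleAlignment
from .distance import jc_distance_matrix, nj_tree
from .likelihood import TreeLikelihood
from .model import SubstModel
from .tree import Node, PhyloTree

_EPS = 1e-6
_DEFAULT_BL = 0.1


@dataclass
class SearchResult:
    tree: PhyloTree
    model: SubstModel
    lnl: float


def nni_neighbors(tree: PhyloTree) -> Iterator[PhyloTree]:
    """All trees one nearest-neighbor interchange away (2 per internal edge)."""
    nodes = list(tree.postorder())
    for vi, v in enumerate(nodes):
        if v.is_leaf or v.parent is None or len(v.children) != 2:
            continue
        for k in (0, 1):
            t2 = tree.copy()
            nodes2 = list(t2.postorder())
            v2 = nodes2[vi]
            u2 = v2.parent
            s2 = next(c for c in u2.children if c is not v2)
            a2 = v2.children[k]
            ui = u2.children.index(s2)
            ai = v2.children.index(a2)
            u2.children[ui], v2.children[ai] = a2, s2
            a2.parent, s2.parent = u2, v2
            yield t2


def spr_neighbors(tree: PhyloTree) -> Iterator[PhyloTree]:
    """Subtree prune-and-regraft neighbours (regraft onto every distant edge)."""
    nodes = list(tree.postorder())
    n_nodes = len(nodes)
    for vi in range(n_nodes):
        v = nodes[vi]
        if v.parent is None or v.parent.parent is None and len(v.parent.children) <= 2:
            continue
        forbidden = {id(v), id(v.parent)}
        sub_ids = {id(x) for x in _subtree(v)}
        for ei in range(n_nodes):
            e = nodes[ei]
            if e.parent is None or id(e) in sub_ids or id(e) in forbidden:
                continue
            if e.parent is v.parent and len(v.parent.children) == 2:
                continue  # regraft onto sibling edge recreates the same topology
            t2 = tree.copy()
            nodes2 = list(t2.postorder())
            v2, e2 = nodes2[vi], nodes2[ei]
            p2 = v2.parent
            p2.children.remove(v2)
            # split the target edge with a new attachment node
            attach = Node(length=(e2.length or _DEFAULT_BL) / 2.0)
            gp = e2.parent
            gp.children[gp.children.index(e2)] = attach
            attach.parent = gp
            e2.length = (e2.length or _DEFAULT_BL) / 2.0
            attach.add(e2)
            attach.add(v2)
            t2.suppress_unifurcations()
            if t2.root is p2 and len(p2.children) == 1:
                t2.root = p2.children[0]
                t2.root.parent = None
            yield t2


def _subtree(v: Node) -> Iterator[Node]:
    stack = [v]
    while stack:
        n = stack.pop()
        yield n
        stack.extend(n.children)


def ml_search(aln: MultipleAlignment, model: SubstModel,
              moves: Sequence[str] = ("nni",), seed: int = 0,
              start_tree: Optional[PhyloTree] = None,
              optimize_model_params: bool = True,
              effort: str = "full") -> SearchResult:
    """NJ-start hill climb; ``moves=()`` optimises the NJ tree only.

    ``seed`` is accepted for interface stability; the search itself is
    deterministic (fixed traversal order, ties keep the incumbent).
    ``effort="quick"`` uses looser optimisation tolerances throughout (used
    inside bootstrap null replicates).
    """
    if aln.n_taxa < 3:
        raise ValueError("tree search needs at least 3 taxa")
    free = ("branches", "model") if optimize_model_params else ("branches",)
    tree = (start_tree or nj_tree(jc_distance_matrix(aln))).copy()
    tl = TreeLikelihood(tree, aln, model)
    best_lnl = tl.optimize(free=free, effort=effort)
    best_tree, best_model = tree, tl.model
    if aln.n_taxa < 4:
        return SearchResult(best_tree, best_model, best_lnl)
    generators = {"nni": nni_neighbors, "spr": spr_neighbors}
    active = [generators[m] for m in moves]
    while active:
        cand_best = None
        cand_lnl = best_lnl
        for gen in active:
            for cand in gen(best_tree):
                ctl = TreeLikelihood(cand, aln, best_model)
                lnl = ctl.optimize_branch_lengths(max_rounds=1, xatol=1e-3,
                                                  brent_maxiter=25)
                if lnl > cand_lnl + _EPS:
                    cand_lnl, cand_best = lnl, cand
        if cand_best is None:
            break
        tl = TreeLikelihood(cand_best, aln, best_model)
        best_lnl = tl.optimize(free=free, effort=effort)
        best_tree, best_model = cand_best, tl.model
    return SearchResult(best_tree, best_model, best_lnl)


def enumerate_topologies(labels: Sequence[str],
                         branch_length: float = _DEFAULT_BL) -> list[PhyloTree]:
    """All unrooted binary topologies on ``labels`` by sequential addition.

    1, 1, 3, 15, 105 ... trees for 3, 4, 5, 6 ... labels; usable as the
    exhaustive oracle for small searches.
    """
    labels = list(labels)
    if len(labels) < 3:
        raise ValueError("need at least 3 labels")
    base = PhyloTree(Node())
    for lab in labels[:3]:
        base.root.add(Node(lab, branch_length))
    trees = [base]
    for lab in labels[3:]:
        nxt: list[PhyloTree] = []
        for t in trees:
            nodes = list(t.postorder())
            for ni, node in enumerate(nodes):
                if node.parent is None:
                    continue
                t2 = t.copy()
                n2 = list(t2.postorder())[ni]
                p2 = n2.parent
                mid = Node(length=branch_length)
                p2.children[p2.children.index(n2)] = mid
                mid.parent = p2
                mid.add(n2)
                mid.add(Node(lab, branch_length))
                nxt.append(t2)
        trees = nxt
    return trees
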