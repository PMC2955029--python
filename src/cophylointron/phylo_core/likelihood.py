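"""Felsenstein pruning likelihood with discrete-gamma + invariant rate classes.

Sites are compressed to unique column patterns.  Ambiguity codes and gaps
contribute partial likelihood 1 over their compatible states (missing data).
Branch lengths are optimised by bounded Brent line search per branch (the
likelihood as a function of one branch is evaluated cheaply from cached
conditionals on both sides of that branch), model parameters by L-BFGS-B on a
log/logit-transformed vector, alternating until the log-likelihood
improvement falls below tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from ..formats_io import AMBIGUITY, MultipleAlignment
from .model import SubstModel
from .tree import Node, PhyloTree, TreeError

_STATES = "ACGT"
_MIN_BL = 1e-8
_MAX_BL = 20.0

_LUT = np.ones((256, 4))
for _c, _compat in AMBIGUITY.items():
    _LUT[ord(_c)] = [1.0 if s in _compat else 0.0 for s in _STATES]

#: optimisation effort presets: (ascent tol, branch rounds, brent xatol,
#: brent maxiter, max ascent rounds)
EFFORT = {
    "full": (1e-4, 2, 1e-6, 60, 20),
    "quick": (0.05, 1, 1e-3, 20, 2),
}


@dataclass
class SitewiseLikelihoods:
    """Per-column log-likelihoods; ``total`` is their sum."""

    values: np.ndarray

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def __len__(self) -> int:
        return len(self.values)


class TreeLikelihood:
    """Likelihood machinery bound to one (tree, alignment, model) triple.

    The tree is referenced, not copied: branch-length optimisation writes the
    fitted lengths back onto the tree's nodes.
    """

    def __init__(self, tree: PhyloTree, aln: MultipleAlignment,
                 model: SubstModel) -> None:
        tree_taxa = set(tree.leaf_labels())
        aln_taxa = set(aln.ids)
        if tree_taxa != aln_taxa:
            missing = sorted(tree_taxa ^ aln_taxa)
            raise ValueError(f"taxon sets differ between tree and alignment: {missing}")
        self.tree = tree
        codes = np.frombuffer("".join(r.seq for r in aln.records).encode(),
                              dtype=np.uint8).reshape(aln.n_taxa, aln.n_cols)
        _, first_idx, inverse = np.unique(codes.T, axis=0, return_index=True,
                                          return_inverse=True)
        self._pattern_of_col = inverse
        self._counts = np.bincount(inverse, minlength=len(first_idx)).astype(float)
        # (taxa, 4, n_pat): leaf conditionals
        self._leaf = np.ascontiguousarray(
            _LUT[codes[:, first_idx]].transpose(0, 2, 1))
        self._row_of = {t: i for i, t in enumerate(aln.ids)}
        self.n_cols = aln.n_cols
        self.n_pat = len(first_idx)
        self._index_tree()
        self._set_model(model)

    # -- bookkeeping -------------------------------------------------------
    def _index_tree(self) -> None:
        self._post = list(self.tree.postorder())
        for n in self._post:
            if n is not self.tree.root and (n.length is None
                                            or not np.isfinite(n.length)):
                raise TreeError("branch length missing or non-finite")
        self._P: dict[int, np.ndarray] = {}
        self._down: dict[int, np.ndarray] = {}

    def _set_model(self, model: SubstModel) -> None:
        self.model = model
        lam, self._U, self._Uinv = model.eigen()
        self._rates, self._weights = model.category_rates()
        self._ncat = len(self._rates)
        self._rl = np.outer(self._rates, lam)     # (ncat, 4)
        self._P.clear()

    def _pmat(self, t: float) -> np.ndarray:
        e = np.exp(self._rl * max(t, 0.0))        # (ncat, 4)
        return np.einsum("ij,cj,jk->cik", self._U, e, self._Uinv)

    def _branch_P(self, node: Node) -> np.ndarray:
        key = id(node)
        if key not in self._P:
            self._P[key] = self._pmat(node.length)
        return self._P[key]

    # -- pruning -----------------------------------------------------------
    def _compute_down(self) -> None:
        """Post-order conditional likelihoods below every node."""
        ncat = self._ncat
        for node in self._post:
            if node.is_leaf:
                leaf = self._leaf[self._row_of[node.label]]   # (4, npat)
                self._down[id(node)] = np.broadcast_to(
                    leaf[None], (ncat, 4, self.n_pat))
                continue
            prod = None
            for c in node.children:
                term = self._branch_P(c) @ self._down[id(c)]
                prod = term if prod is None else prod * term
            self._down[id(node)] = prod

    def _pattern_lnl(self) -> np.ndarray:
        self._compute_down()
        root = self._down[id(self.tree.root)]
        site = np.einsum("c,x,cxp->p", self._weights, self.model.freqs, root)
        return np.log(np.maximum(site, 1e-300))

    def site_log_likelihoods(self) -> SitewiseLikelihoods:
        return SitewiseLikelihoods(self._pattern_lnl()[self._pattern_of_col])

    def log_likelihood(self) -> float:
        return float(self._pattern_lnl() @ self._counts)

    # -- single-branch machinery -------------------------------------------
    def _edge_context(self, node: Node) -> tuple[np.ndarray, np.ndarray]:
        """(H, down) for the branch above ``node``.

        ``H[c, x, p]`` is the likelihood of everything outside node's subtree
        given state ``x`` at node's parent (stationary frequencies folded in):
        the full-tree likelihood is ``sum_cxy w_c H[c,x,p] P[c,x,y] down[c,y,p]``.
        """
        path = []
        a = node
        while a.parent is not None:
            path.append(a)
            a = a.parent
        path.reverse()  # root-side first; path[-1] is `node`
        G = np.broadcast_to(self.model.freqs[None, :, None],
                            (self._ncat, 4, self.n_pat))
        for step in path:
            u = step.parent
            for sib in u.children:
                if sib is not step:
                    G = G * (self._branch_P(sib) @ self._down[id(sib)])
            if step is not node:
                # move G from u down across step's branch
                G = np.einsum("cxp,cxy->cyp", G, self._branch_P(step))
        return G, self._down[id(node)]

    def _optimize_one_branch(self, node: Node, xatol: float,
                             maxiter: int) -> float:
        H, down = self._edge_context(node)
        w = self._weights

        def neg_lnl(t: float) -> float:
            P = self._pmat(t)
            tmp = P.transpose(0, 2, 1) @ H          # (ncat, 4, npat)
            site = np.einsum("c,cyp->p", w, tmp * down)
            return -float(np.log(np.maximum(site, 1e-300)) @ self._counts)

        res = minimize_scalar(neg_lnl, bounds=(_MIN_BL, _MAX_BL),
                              method="bounded",
                              options={"xatol": xatol, "maxiter": maxiter})
        node.length = float(res.x)
        self._P.pop(id(node), None)
        return -float(res.fun)

    def optimize_branch_lengths(self, max_rounds: int = 5, tol: float = 1e-4,
                                xatol: float = 1e-6,
                                brent_maxiter: int = 60) -> float:
        best = self.log_likelihood()
        branches = [n for n in self._post if n.parent is not None]
        lnl = best
        for _ in range(max_rounds):
            for node in branches:
                self._compute_down()
                lnl = self._optimize_one_branch(node, xatol, brent_maxiter)
            if lnl - best < tol:
                best = max(lnl, best)
                break
            best = lnl
        return best

    # -- model optimisation ------------------------------------------------
    def optimize_model(self, with_freqs: bool = True) -> float:
        v0 = self.model.to_vector(with_freqs)
        if v0.size == 0:
            return self.log_likelihood()

        def neg_lnl(v: np.ndarray) -> float:
            try:
                self._set_model(self.model.from_vector(v, with_freqs))
            except (ValueError, FloatingPointError):
                return 1e12
            return -float(self._pattern_lnl() @ self._counts)

        f0 = neg_lnl(v0)
        res = minimize(neg_lnl, v0, method="L-BFGS-B",
                       options={"maxiter": 60, "ftol": 1e-8})
        best = res.x if res.fun <= f0 else v0  # keep the better of the two
        self._set_model(self.model.from_vector(best, with_freqs))
        return self.log_likelihood()

    def optimize(self, free: tuple[str, ...] = ("branches", "model"),
                 effort: str = "full") -> float:
        """Coordinate ascent over branch lengths and model parameters."""
        tol, rounds, xatol, brent_maxiter, max_ascent = EFFORT[effort]
        lnl = self.log_likelihood()
        if not np.isfinite(lnl):
            raise ValueError("non-finite log-likelihood at starting point")
        has_model = "model" in free and self.model.to_vector().size > 0
        if "branches" in free and not has_model:
            return self.optimize_branch_lengths(
                max_rounds=3 * rounds, tol=tol, xatol=xatol,
                brent_maxiter=brent_maxiter)
        for _ in range(max_ascent):
            prev = lnl
            if "branches" in free:
                lnl = self.optimize_branch_lengths(
                    max_rounds=rounds, tol=tol, xatol=xatol,
                    brent_maxiter=brent_maxiter)
            if has_model:
                lnl = self.optimize_model()
            if lnl - prev < tol:
                break
        return lnl


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------

def log_likelihood(tree: PhyloTree, aln: MultipleAlignment,
                   model: SubstModel) -> SitewiseLikelihoods:
    """Site-wise log-likelihoods of ``aln`` on ``tree`` under ``model``."""
    return TreeLikelihood(tree, aln, model).site_log_likelihoods()


def optimize(tree: PhyloTree, aln: MultipleAlignment, model: SubstModel,
             free: tuple[str, ...] = ("branches", "model"),
             effort: str = "full") -> tuple[PhyloTree, SubstModel, float]:
    """Optimise branch lengths and/or model parameters in place; returns lnL."""
    tl = TreeLikelihood(tree, aln, model)
    lnl = tl.optimize(free=free, effort=effort)
    return tree, tl.model, lnl
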