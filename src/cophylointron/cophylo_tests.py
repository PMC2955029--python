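"""Topological-congruence tests between two data partitions.

Two complementary tests of whether a host gene (cox1) and its resident
intron share one evolutionary history:

* reciprocal AU (approximately unbiased) tests — for each dataset, compare
  the site log-likelihoods of its own ML topology against the other
  dataset's ML topology via the multiscale RELL bootstrap;
* the non-parametric Huelsenbeck–Bull likelihood-ratio test — compare the
  one-tree model (both partitions share a topology, each with its own model
  and branch lengths) against the two-tree model, d = 2(lnL0 − lnL1), with a
  null distribution built by bootstrapping columns of each partition,
  concatenating, and randomising which columns of the concatenation belong
  to which partition — a homogeneity null under which the one-tree model
  holds by construction.

Under the sign convention d = 2(lnL0 − lnL1) the statistic is ≤ 0 (the
two-tree model nests the one-tree model); strongly negative d means the
partitions prefer different trees.  The p-value is the plain proportion of
null replicates with a smaller (more negative) d than observed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm

from .formats_io import MultipleAlignment, SequenceRecord
from .phylo_core import (PhyloTree, SubstModel, TreeLikelihood,
                         bootstrap_columns, ml_search)

_AU_SCALES = np.arange(0.5, 1.45, 0.1)  # 0.5 ... 1.4, ten scales


# ---------------------------------------------------------------------------
# AU test
# ---------------------------------------------------------------------------

@dataclass
class AuResult:
    """AU p-values per candidate topology on one dataset."""

    p_values: list[float]
    bp_values: np.ndarray       # (n_topologies, n_scales) RELL win frequencies
    scales: np.ndarray
    n_replicates: int
    site_lnl: np.ndarray        # (n_topologies, n_sites)

    def best(self) -> int:
        return int(np.argmax(self.site_lnl.sum(axis=1)))


def au_test(candidate_topologies: Sequence[PhyloTree], aln: MultipleAlignment,
            model: SubstModel, n_replicates: int = 10_000,
            seed: int = 0) -> AuResult:
    """Multiscale RELL AU test of candidate topologies on one alignment.

    Branch lengths and model parameters are re-optimised per topology; the
    per-site log-likelihood vectors are then resampled at ten scale factors
    (0.5 to 1.4), the win frequency of each topology is recorded per scale,
    and the AU p-value comes from the signed-distance/curvature fit of
    Shimodaira's multiscale bootstrap.
    """
    if len(candidate_topologies) < 2:
        raise ValueError("need at least 2 candidate topologies")
    rng = np.random.default_rng(seed)
    site_lnl = []
    for top in candidate_topologies:
        tl = TreeLikelihood(top.copy(), aln, model)
        tl.optimize(free=("branches", "model"))
        site_lnl.append(tl.site_log_likelihoods().values)
    L = np.vstack(site_lnl)                      # (T, n)
    T, n = L.shape
    if np.allclose(L.max(axis=0) - L.min(axis=0), 0.0, atol=1e-12):
        import warnings
        warnings.warn("identical site likelihood vectors; AU p = 1 for all")
        return AuResult([1.0] * T, np.ones((T, len(_AU_SCALES))),
                        _AU_SCALES.copy(), n_replicates, L)
    bp = np.zeros((T, len(_AU_SCALES)))
    for si, r in enumerate(_AU_SCALES):
        m = max(1, int(round(r * n)))
        counts = rng.multinomial(m, np.full(n, 1.0 / n), size=n_replicates)
        sums = counts @ L.T                      # (B, T)
        winners = np.argmax(sums, axis=1)
        bp[:, si] = np.bincount(winners, minlength=T) / n_replicates
    p_values = [
        _au_pvalue(bp[t], _AU_SCALES, n_replicates) for t in range(T)
    ]
    return AuResult(p_values, bp, _AU_SCALES.copy(), n_replicates, L)


def _au_pvalue(bp: np.ndarray, scales: np.ndarray, B: int) -> float:
    """Weighted-least-squares fit of z(r) = d sqrt(r) + c / sqrt(r).

    Only scales with interior win frequencies (0 < bp < 1) inform the fit;
    a topology that never (always) wins at every scale is beyond the
    bootstrap's resolution and gets p = 0 (p = 1).
    """
    eps = 1.0 / (2.0 * B)
    interior = (bp > eps) & (bp < 1.0 - eps)
    if interior.sum() < 2:
        return 0.0 if bp.mean() < 0.5 else 1.0
    bp_i = bp[interior]
    z = norm.isf(bp_i)               # Phi^-1(1 - bp)
    sq = np.sqrt(scales[interior])
    X = np.column_stack([sq, 1.0 / sq])
    # binomial variance of bp propagated through the normal quantile
    var = bp_i * (1.0 - bp_i) / (B * norm.pdf(z) ** 2)
    w = np.sqrt(1.0 / np.maximum(var, 1e-12))
    beta, *_ = np.linalg.lstsq(X * w[:, None], z * w, rcond=None)
    d_hat, c_hat = beta
    return float(np.clip(norm.sf(d_hat - c_hat), 0.0, 1.0))


def reciprocal_au(aln_a: MultipleAlignment, aln_b: MultipleAlignment,
                  model_a: SubstModel, model_b: SubstModel,
                  n_replicates: int = 10_000, seed: int = 0,
                  search_moves: Sequence[str] = ("nni",)
                  ) -> dict[str, AuResult]:
    """ML topology per partition, then each dataset tests both topologies.

    Returns ``{"A": AuResult, "B": AuResult}`` where each result's topology
    order is [own ML topology, other partition's ML topology].
    """
    res_a = ml_search(aln_a, model_a, moves=search_moves)
    res_b = ml_search(aln_b, model_b, moves=search_moves)
    out_a = au_test([res_a.tree, res_b.tree], aln_a, model_a,
                    n_replicates, seed)
    out_b = au_test([res_b.tree, res_a.tree], aln_b, model_b,
                    n_replicates, seed + 1)
    return {"A": out_a, "B": out_b}


# ---------------------------------------------------------------------------
# one-tree / two-tree likelihoods
# ---------------------------------------------------------------------------

def _check_taxa(aln_a: MultipleAlignment, aln_b: MultipleAlignment) -> None:
    if set(aln_a.ids) != set(aln_b.ids):
        diff = sorted(set(aln_a.ids) ^ set(aln_b.ids))
        raise ValueError(f"partitions have different taxon sets: {diff}")


def one_tree_lnL(aln_a: MultipleAlignment, aln_b: MultipleAlignment,
                 model_a: SubstModel, model_b: SubstModel,
                 search_moves: Sequence[str] = ("nni",),
                 effort: str = "full") -> tuple[float, PhyloTree]:
    """Shared-topology log-likelihood.

    The ML topology is estimated on the concatenation; each partition's
    branch lengths and model are then optimised independently on that fixed
    topology; lnL0 is the sum.
    """
    _check_taxa(aln_a, aln_b)
    concat = aln_a.concat(aln_b.subset(aln_a.ids))
    shared = ml_search(concat, SubstModel(family=model_a.family,
                                          alpha=model_a.alpha,
                                          p_inv=model_a.p_inv),
                       moves=search_moves, effort=effort).tree
    lnl = 0.0
    for aln, model in ((aln_a, model_a), (aln_b, model_b)):
        tl = TreeLikelihood(shared.copy(), aln, model)
        lnl += tl.optimize(free=("branches", "model"), effort=effort)
    return lnl, shared


def two_tree_lnL(aln_a: MultipleAlignment, aln_b: MultipleAlignment,
                 model_a: SubstModel, model_b: SubstModel,
                 search_moves: Sequence[str] = ("nni",),
                 effort: str = "full") -> tuple[float, PhyloTree, PhyloTree]:
    """Independent-topology log-likelihood: a free search per partition."""
    _check_taxa(aln_a, aln_b)
    res_a = ml_search(aln_a, model_a, moves=search_moves, effort=effort)
    res_b = ml_search(aln_b, model_b, moves=search_moves, effort=effort)
    return res_a.lnl + res_b.lnl, res_a.tree, res_b.tree


# ---------------------------------------------------------------------------
# Huelsenbeck-Bull LRT with bootstrap/randomisation null
# ---------------------------------------------------------------------------

@dataclass
class LrtResult:
    lnl0: float
    lnl1: float
    d: float                      # 2 (lnL0 - lnL1), <= 0 up to tolerance
    null_d: np.ndarray
    p: float
    n_replicates: int
    tree_shared: Optional[PhyloTree] = None
    tree_a: Optional[PhyloTree] = None
    tree_b: Optional[PhyloTree] = None


def _observed_d(aln_a, aln_b, model_a, model_b, search_moves, effort="full"):
    lnl0, shared = one_tree_lnL(aln_a, aln_b, model_a, model_b, search_moves,
                                effort)
    lnl1, ta, tb = two_tree_lnL(aln_a, aln_b, model_a, model_b, search_moves,
                                effort)
    return lnl0, lnl1, 2.0 * (lnl0 - lnl1), shared, ta, tb


def hb_lrt(aln_a: MultipleAlignment, aln_b: MultipleAlignment,
           model: SubstModel | tuple[SubstModel, SubstModel],
           replicates: int = 500, seed: int = 0,
           search_moves: Sequence[str] = ("nni",),
           null_search_moves: Sequence[str] = (),
           null_mode: str = "site-shuffle") -> LrtResult:
    """Non-parametric LRT of one-tree vs two-tree models.

    Each null replicate bootstraps the columns of each partition
    independently, concatenates them, and randomises which columns belong to
    which partition (``site-shuffle``): both pseudo-partitions then draw from
    one common signal mixture, so the one-tree hypothesis holds in the null
    by construction and a strongly negative observed d is evidence of real
    conflict.  ``pair-shuffle`` instead permutes which partition-B row
    carries each taxon label; it destroys the association entirely
    (an independence null) and is provided for comparison only.  p is the
    plain proportion of null d values below the observed d, with no
    continuity correction.

    Null-replicate searches default to the reduced NJ-only search
    (``null_search_moves=()``) for tractability; the observed statistic uses
    the full configured search.
    """
    if replicates < 1:
        raise ValueError("need at least one replicate")
    if isinstance(model, tuple):
        model_a, model_b = model
    else:
        model_a = model_b = model
    rng = np.random.default_rng(seed)
    lnl0, lnl1, d, shared, ta, tb = _observed_d(
        aln_a, aln_b, model_a, model_b, search_moves)
    null_d = np.empty(replicates)
    ids = list(aln_a.ids)
    for rep in range(replicates):
        ba = bootstrap_columns(aln_a, rng)
        bb = bootstrap_columns(aln_b.subset(ids), rng)
        if null_mode == "pair-shuffle":
            perm = rng.permutation(len(ids))
            bb = MultipleAlignment([
                SequenceRecord(ids[i], bb.records[j].seq)
                for i, j in enumerate(perm)
            ])
        elif null_mode == "site-shuffle":
            concat = ba.concat(bb)
            cols = rng.permutation(concat.n_cols)
            ca, cb = cols[:ba.n_cols], cols[ba.n_cols:]
            rows_a, rows_b = [], []
            for r in concat.records:
                s = np.array(list(r.seq))
                rows_a.append(SequenceRecord(r.id, "".join(s[ca])))
                rows_b.append(SequenceRecord(r.id, "".join(s[cb])))
            ba, bb = MultipleAlignment(rows_a), MultipleAlignment(rows_b)
        else:
            raise ValueError(f"unknown null_mode {null_mode!r}")
        _, _, d_rep, *_ = _observed_d(ba, bb, model_a, model_b,
                                      null_search_moves, effort="quick")
        null_d[rep] = d_rep
    p = float(np.count_nonzero(null_d < d) / replicates)
    return LrtResult(lnl0, lnl1, d, null_d, p, replicates,
                     tree_shared=shared, tree_a=ta, tree_b=tb)
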