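"""Pairwise distances from alignments and neighbor joining.

NJ is the Saitou & Nei (1987) agglomeration with the Studier & Keppler Q
criterion; negative branch-length estimates are clamped to zero.  It serves
as the deterministic starting tree for the heuristic likelihood search.
"""

from __future__ import annotations

import numpy as np

from ..formats_io import MultipleAlignment
from .tree import DistanceMatrix, Node, PhyloTree

_NUC = {"A": 0, "C": 1, "G": 2, "T": 3}


def p_distance_matrix(aln: MultipleAlignment) -> DistanceMatrix:
    """Proportion of differing sites over pairwise unambiguous positions."""
    codes = np.array([[_NUC.get(c, -1) for c in r.seq] for r in aln.records])
    n = aln.n_taxa
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (codes[i] >= 0) & (codes[j] >= 0)
            m = ok.sum()
            D[i, j] = D[j, i] = (codes[i][ok] != codes[j][ok]).mean() if m else 0.0
    return DistanceMatrix(aln.ids, D)


def jc_distance_matrix(aln: MultipleAlignment, max_d: float = 5.0) -> DistanceMatrix:
    """Jukes-Cantor corrected distances; saturated pairs capped at ``max_d``."""
    P = p_distance_matrix(aln)
    arg = 1.0 - 4.0 * P.values / 3.0
    with np.errstate(invalid="ignore", divide="ignore"):
        D = np.where(arg > 0, -0.75 * np.log(np.maximum(arg, 1e-12)), max_d)
    D = np.minimum(D, max_d)
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(aln.ids, D)


def nj_tree(d: DistanceMatrix) -> PhyloTree:
    """Neighbor-joining tree; unrooted (trifurcating root) for n >= 3."""
    n = d.n
    if n < 3:
        raise ValueError(f"neighbor joining needs >= 3 taxa, got {n}")
    D = d.values.astype(float).copy()
    nodes: list[Node] = [Node(label) for label in d.labels]
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i_loc, j_loc = np.unravel_index(np.argmin(Q), Q.shape)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        i, j = active[i_loc], active[j_loc]
        dij = sub[i_loc, j_loc]
        li = 0.5 * dij + (r[i_loc] - r[j_loc]) / (2.0 * (m - 2))
        lj = dij - li
        parent = Node()
        ni, nj = nodes[i], nodes[j]
        ni.length, nj.length = max(li, 0.0), max(lj, 0.0)
        parent.add(ni)
        parent.add(nj)
        # distances from the new node to the remaining taxa
        new_row = 0.5 * (D[i, :] + D[j, :] - dij)
        D = np.vstack([D, new_row])
        D = np.hstack([D, np.append(new_row, 0.0)[:, None]])
        nodes.append(parent)
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]
    # join the final three on a trifurcating root (three-point formulas)
    a, b, c = active
    dab, dac, dbc = D[a, b], D[a, c], D[b, c]
    root = Node()
    for idx, bl in ((a, 0.5 * (dab + dac - dbc)),
                    (b, 0.5 * (dab + dbc - dac)),
                    (c, 0.5 * (dac + dbc - dab))):
        nodes[idx].length = max(bl, 0.0)
        root.add(nodes[idx])
    return PhyloTree(root)
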