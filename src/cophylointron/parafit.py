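"""ParaFit co-speciation test on principal coordinates of patristic distances.

The global statistic is the sum of squared entries of the fourth-corner
matrix D = B' A C, where B and C are the principal-coordinate embeddings of
the host and parasite patristic distance matrices (rows = taxa, columns =
axes scaled by the square root of their eigenvalues) and A is the binary
host × parasite association matrix.  Significance comes from permuting, for
each parasite independently, which host it is attached to (permutation of
each column of A).  The per-link statistic (ParaFitLink1) is the drop in the
global statistic when that link is removed, tested with the same permutation
scheme; within a replicate the global and reduced association matrices share
one permutation.

PCoA uses Gower double-centering of −d²/2.  When negative eigenvalues arise
(non-Euclidean distances) the Lingoes correction adds 2c (c = |λ_min|) to
all squared off-diagonal distances and re-decomposes; a Cailliez option is
provided but untuned.  Patristic distances are used raw by default, matching
DistPCoA-style usage; ``sqrt=True`` embeds their square roots, which are
always Euclidean for a tree metric.

The null hypothesis is random host–parasite association, so — unlike the AU
and likelihood-ratio tests — a *small* p supports co-speciation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .phylo_core.tree import DistanceMatrix

_EPS = 1e-8


# ---------------------------------------------------------------------------
# principal coordinates
# ---------------------------------------------------------------------------

@dataclass
class PcoaResult:
    """Principal coordinates: points × axes, eigenvalues, applied correction."""

    coordinates: np.ndarray
    eigenvalues: np.ndarray
    correction_constant: float
    labels: list[str] = field(default_factory=list)


def _gower(d2: np.ndarray) -> np.ndarray:
    n = d2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return J @ (-0.5 * d2) @ J


def _decompose(G: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    vals, vecs = np.linalg.eigh((G + G.T) / 2.0)
    order = np.argsort(vals)[::-1]
    return vals[order], vecs[:, order]


def pcoa(d: DistanceMatrix, correction: str = "lingoes") -> PcoaResult:
    """Principal-coordinates embedding of a distance matrix.

    Axes with eigenvalue <= 1e-8 * λ_max are dropped; negative-eigenvalue
    axes are never retained.  ``correction`` is "none", "lingoes" or
    "cailliez"; a correction is applied only when a meaningful negative
    eigenvalue is present.
    """
    D = d.values
    vals, vecs = _decompose(_gower(D ** 2))
    c = 0.0
    tol = _EPS * max(abs(vals[0]), 1.0)
    if vals[-1] < -tol and correction != "none":
        if correction == "lingoes":
            c = float(-vals[-1])
            D2 = D ** 2 + 2.0 * c
        elif correction == "cailliez":
            c = _cailliez_constant(D)
            D2 = (D + c) ** 2
        else:
            raise ValueError(f"unknown correction {correction!r}")
        np.fill_diagonal(D2, 0.0)
        vals, vecs = _decompose(_gower(D2))
    keep = vals > _EPS * max(abs(vals[0]), 1.0)
    coords = vecs[:, keep] * np.sqrt(vals[keep])
    return PcoaResult(coords, vals, c, list(d.labels))


def _cailliez_constant(D: np.ndarray) -> float:
    n = D.shape[0]
    d1 = _gower(D ** 2)
    d2 = _gower(D)
    upper = np.hstack([np.zeros((n, n)), 2.0 * d1])
    lower = np.hstack([-np.eye(n), -4.0 * d2])
    sp = np.vstack([upper, lower])
    return float(np.max(np.real(np.linalg.eigvals(sp))))


# ---------------------------------------------------------------------------
# association matrix
# ---------------------------------------------------------------------------

@dataclass
class AssociationMatrix:
    """Binary hosts × parasites matrix; every parasite linked to >= 1 host."""

    hosts: list[str]
    parasites: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.hosts), len(self.parasites)):
            raise ValueError("association matrix shape mismatch")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("association entries must be 0/1")

    @classmethod
    def from_links(cls, links: Sequence[tuple[str, str]],
                   hosts: Optional[Sequence[str]] = None,
                   parasites: Optional[Sequence[str]] = None
                   ) -> "AssociationMatrix":
        hosts = list(hosts) if hosts is not None else sorted({h for h, _ in links})
        parasites = (list(parasites) if parasites is not None
                     else sorted({p for _, p in links}))
        A = np.zeros((len(hosts), len(parasites)), dtype=int)
        for h, p in links:
            A[hosts.index(h), parasites.index(p)] = 1
        return cls(hosts, parasites, A)

    @property
    def links(self) -> list[tuple[int, int]]:
        """(host index, parasite index) of every 1 entry, column-major order."""
        cols, rows = np.nonzero(self.values.T)
        return list(zip(rows.tolist(), cols.tolist()))


# ---------------------------------------------------------------------------
# the test
# ---------------------------------------------------------------------------

@dataclass
class ParafitResult:
    global_stat: float
    global_p: float
    link_stats: list[float]
    link_ps: list[float]
    links: list[tuple[str, str]]
    n_permutations: int
    seed: int
    correction_constants: tuple[float, float] = (0.0, 0.0)


def _fourth_corner(B: np.ndarray, A: np.ndarray, C: np.ndarray) -> float:
    D = B.T @ A @ C
    return float(np.sum(D * D))


def parafit_global(host_pcoa: PcoaResult, parasite_pcoa: PcoaResult,
                   A: AssociationMatrix, n_perm: int = 999,
                   seed: int = 0, test_links: bool = False) -> ParafitResult:
    """Global (and optionally per-link) ParaFit permutation test.

    p-values use the (1 + exceedances) / (1 + n_perm) estimator.  Within one
    permutation replicate, the same permuted association is used for the
    global statistic and for every link's reduced statistic, mirroring the
    reference permutation scheme.
    """
    B = host_pcoa.coordinates
    C = parasite_pcoa.coordinates
    Am = A.values.astype(float)
    if B.shape[0] != Am.shape[0] or C.shape[0] != Am.shape[1]:
        raise ValueError(
            f"dimension mismatch: hosts {B.shape[0]} x parasites {C.shape[0]} "
            f"vs association {Am.shape}")
    rng = np.random.default_rng(seed)
    observed = _fourth_corner(B, Am, C)
    link_idx = A.links
    obs_link = []
    if test_links:
        for hi, pi in link_idx:
            Ak = Am.copy()
            Ak[hi, pi] = 0.0
            obs_link.append(observed - _fourth_corner(B, Ak, C))
    n_ge_global = 1
    n_ge_link = [1] * len(obs_link)
    n_hosts = Am.shape[0]
    for _ in range(n_perm):
        perms = [rng.permutation(n_hosts) for _ in range(Am.shape[1])]
        P = np.column_stack([Am[perms[j], j] for j in range(Am.shape[1])])
        g = _fourth_corner(B, P, C)
        if g >= observed - 1e-12:
            n_ge_global += 1
        if not test_links:
            continue
        for k, (hi, pi) in enumerate(link_idx):
            # reduced association under the same replicate's permutations
            reduced = Am[:, pi].copy()
            reduced[hi] = 0.0
            Pk = P.copy()
            Pk[:, pi] = reduced[perms[pi]]
            stat_k = g - _fourth_corner(B, Pk, C)
            if stat_k >= obs_link[k] - 1e-12:
                n_ge_link[k] += 1
    global_p = n_ge_global / (n_perm + 1)
    link_ps = [n / (n_perm + 1) for n in n_ge_link]
    named_links = [(A.hosts[hi], A.parasites[pi]) for hi, pi in link_idx]
    return ParafitResult(observed, global_p, obs_link, link_ps, named_links,
                         n_perm, seed if isinstance(seed, int) else -1,
                         (host_pcoa.correction_constant,
                          parasite_pcoa.correction_constant))


def parafit_link1(host_pcoa: PcoaResult, parasite_pcoa: PcoaResult,
                  A: AssociationMatrix, link: tuple[str, str],
                  n_perm: int = 999, seed: int = 0) -> tuple[float, float]:
    """ParaFitLink1 statistic and permutation p for one host–parasite link."""
    if link not in [(A.hosts[h], A.parasites[p]) for h, p in A.links]:
        raise ValueError(f"link {link} absent from association matrix")
    res = parafit_global(host_pcoa, parasite_pcoa, A, n_perm=n_perm,
                         seed=seed, test_links=True)
    k = res.links.index(link)
    return res.link_stats[k], res.link_ps[k]


def parafit_test(host_patristic: DistanceMatrix,
                 parasite_patristic: DistanceMatrix,
                 links: Sequence[tuple[str, str]], n_perm: int = 999,
                 seed: int = 0, correction: str = "lingoes",
                 sqrt_distances: bool = False,
                 drop_taxa: Sequence[str] = ()) -> ParafitResult:
    """Patristic distances + links -> full ParaFit analysis.

    ``drop_taxa`` removes hosts (and their links) before testing — the
    one-flag sensitivity re-run used to ask whether a few strong links drive
    the global signal.
    """
    links = [(h, p) for h, p in links if h not in set(drop_taxa)]
    if not links:
        raise ValueError("no links left after dropping taxa")
    hosts = [l for l in host_patristic.labels
             if l in {h for h, _ in links}]
    parasites = [l for l in parasite_patristic.labels
                 if l in {p for _, p in links}]
    hd = host_patristic.reorder(hosts)
    pd_ = parasite_patristic.reorder(parasites)
    if sqrt_distances:
        hd = DistanceMatrix(hd.labels, np.sqrt(hd.values))
        pd_ = DistanceMatrix(pd_.labels, np.sqrt(pd_.values))
    hp = pcoa(hd, correction)
    pp = pcoa(pd_, correction)
    A = AssociationMatrix.from_links(links, hosts, parasites)
    return parafit_global(hp, pp, A, n_perm=n_perm, seed=seed,
                          test_links=True)
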