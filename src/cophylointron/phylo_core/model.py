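"""Reversible nucleotide substitution models: JC, K80, HKY, TrN, GTR, +Γ, +I.

The rate matrix is scaled so the expected substitution rate is one per unit
branch length, including the invariant-site class (gamma-category rates are
divided by ``1 - p_inv``), so branch lengths are in expected substitutions per
site throughout.

Among-site rate variation uses ``n_cat`` equal-probability discrete gamma
classes.  Class rates default to the category medians; ``gamma_method="mean"``
switches to category means for cross-checks against engines that use them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

FAMILIES = ("JC", "K80", "HKY", "TrN", "GTR")
# exchangeability order: AC, AG, AT, CG, CT, GT (states A C G T)
_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


@dataclass
class SubstModel:
    family: str = "GTR"
    rates: np.ndarray = field(default_factory=lambda: np.ones(6))
    freqs: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    alpha: Optional[float] = None
    p_inv: float = 0.0
    n_cat: int = 4
    gamma_method: str = "median"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")
        self.rates = np.asarray(self.rates, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.family in ("JC", "K80"):
            self.freqs = np.full(4, 0.25)
        self.freqs = self.freqs / self.freqs.sum()
        if not (0.0 <= self.p_inv < 1.0):
            raise ValueError("p_inv must be in [0, 1)")
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError("gamma shape alpha must be > 0")
        self._enforce_family()

    # -- family constraints -------------------------------------------------
    def _enforce_family(self) -> None:
        r = self.rates
        if self.family == "JC":
            self.rates = np.ones(6)
        elif self.family == "K80" or self.family == "HKY":
            kappa = (r[1] + r[4]) / 2.0
            self.rates = np.array([1.0, kappa, 1.0, 1.0, kappa, 1.0])
        elif self.family == "TrN":
            self.rates = np.array([1.0, r[1], 1.0, 1.0, r[4], 1.0])
        # GTR: free, normalised so GT = 1
        if self.family == "GTR" and self.rates[5] > 0:
            self.rates = self.rates / self.rates[5]

    # -- rate matrix ---------------------------------------------------------
    def q_matrix(self) -> np.ndarray:
        """GTR-form rate matrix, scaled to mean rate 1 (before +I scaling)."""
        Q = np.zeros((4, 4))
        for k, (i, j) in enumerate(_PAIRS):
            Q[i, j] = self.rates[k] * self.freqs[j]
            Q[j, i] = self.rates[k] * self.freqs[i]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -np.dot(self.freqs, np.diag(Q))
        return Q / mu

    def eigen(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Eigen-decomposition of Q via the symmetrising similarity transform.

        Returns ``(lam, U, Uinv)`` with ``P(t) = U @ diag(exp(lam t)) @ Uinv``.
        """
        Q = self.q_matrix()
        sp = np.sqrt(self.freqs)
        B = (Q * sp[:, None]) / sp[None, :]   # diag(sp) Q diag(1/sp), symmetric
        lam, V = np.linalg.eigh((B + B.T) / 2.0)
        U = V / sp[:, None]
        Uinv = V.T * sp[None, :]
        return lam, U, Uinv

    # -- rate classes --------------------------------------------------------
    def category_rates(self) -> tuple[np.ndarray, np.ndarray]:
        """Rates and weights of all classes, invariant class (rate 0) first.

        The non-zero rates are rescaled so the overall mean rate is exactly 1.
        """
        if self.alpha is None:
            g_rates = np.array([1.0])
        elif self.gamma_method == "median":
            k = self.n_cat
            g_rates = gamma_dist.ppf((2 * np.arange(k) + 1) / (2 * k),
                                     a=self.alpha, scale=1.0 / self.alpha)
            g_rates = g_rates / g_rates.mean()
        elif self.gamma_method == "mean":
            k = self.n_cat
            edges = gamma_dist.ppf(np.arange(k + 1) / k, a=self.alpha,
                                   scale=1.0 / self.alpha)
            # mean of each slice of a mean-1 gamma: k * (I(a+1, b_hi) - I(a+1, b_lo))
            inc = gammainc(self.alpha + 1, edges * self.alpha)
            g_rates = k * np.diff(inc)
        else:
            raise ValueError(f"unknown gamma_method {self.gamma_method!r}")
        if self.p_inv > 0:
            w = np.concatenate([[self.p_inv],
                                np.full(len(g_rates), (1 - self.p_inv) / len(g_rates))])
            r = np.concatenate([[0.0], g_rates / (1 - self.p_inv)])
        else:
            w = np.full(len(g_rates), 1.0 / len(g_rates))
            r = g_rates
        return r, w

    def transition_matrices(self, t: float) -> np.ndarray:
        """P(t r_c) for every rate class; shape (n_classes, 4, 4)."""
        lam, U, Uinv = self.eigen()
        r, _ = self.category_rates()
        return np.einsum("ij,cj,jk->cik", U, np.exp(np.outer(r, lam) * t), Uinv)

    # -- free-parameter vectorisation (for numerical optimisation) -----------
    def free_param_names(self, with_freqs: bool = True) -> list[str]:
        names: list[str] = []
        if self.family in ("K80", "HKY"):
            names.append("kappa")
        elif self.family == "TrN":
            names += ["kappa_ag", "kappa_ct"]
        elif self.family == "GTR":
            names += ["r_ac", "r_ag", "r_at", "r_cg", "r_ct"]
        if with_freqs and self.family in ("HKY", "TrN", "GTR"):
            names += ["f_a", "f_c", "f_g"]
        if self.alpha is not None:
            names.append("alpha")
        if self.p_inv > 0 or self._fit_pinv:
            names.append("p_inv")
        return names

    _fit_pinv: bool = False

    def to_vector(self, with_freqs: bool = True) -> np.ndarray:
        v: list[float] = []
        if self.family in ("K80", "HKY"):
            v.append(np.log(self.rates[1]))
        elif self.family == "TrN":
            v += [np.log(self.rates[1]), np.log(self.rates[4])]
        elif self.family == "GTR":
            v += list(np.log(self.rates[:5]))
        if with_freqs and self.family in ("HKY", "TrN", "GTR"):
            v += list(np.log(self.freqs[:3] / self.freqs[3]))
        if self.alpha is not None:
            v.append(np.log(self.alpha))
        if self.p_inv > 0 or self._fit_pinv:
            p = min(max(self.p_inv, 1e-6), 0.95)
            v.append(np.log(p / (1 - p)))
        return np.array(v)

    def from_vector(self, v: np.ndarray, with_freqs: bool = True) -> "SubstModel":
        v = list(v)
        m = replace(self)
        rates = np.ones(6)
        if self.family in ("K80", "HKY"):
            k = np.exp(v.pop(0))
            rates = np.array([1, k, 1, 1, k, 1])
        elif self.family == "TrN":
            k1, k2 = np.exp(v.pop(0)), np.exp(v.pop(0))
            rates = np.array([1, k1, 1, 1, k2, 1])
        elif self.family == "GTR":
            rates = np.concatenate([np.exp([v.pop(0) for _ in range(5)]), [1.0]])
        m.rates = rates
        if with_freqs and self.family in ("HKY", "TrN", "GTR"):
            x = np.exp([v.pop(0) for _ in range(3)])
            m.freqs = np.concatenate([x, [1.0]])
            m.freqs = m.freqs / m.freqs.sum()
        if self.alpha is not None:
            m.alpha = float(np.exp(v.pop(0)))
        if self.p_inv > 0 or self._fit_pinv:
            z = v.pop(0)
            m.p_inv = float(1.0 / (1.0 + np.exp(-z)) * 0.95)
        m._enforce_family()
        return m

    @classmethod
    def from_string(cls, spec: str, **kw) -> "SubstModel":
        """Parse names like ``"GTR+G+I"``, ``"TrN+G"``, ``"JC"``, ``"HKY"``."""
        parts = spec.replace("Γ", "G").split("+")
        fam = parts[0].upper()
        fam = {"TRN": "TrN", "JC69": "JC"}.get(fam, fam)
        if fam not in FAMILIES:
            raise ValueError(f"unknown model {spec!r}")
        alpha = 1.0 if any(p.upper() == "G" for p in parts[1:]) else None
        p_inv = 0.1 if any(p.upper() == "I" for p in parts[1:]) else 0.0
        m = cls(family=fam, alpha=alpha, p_inv=p_inv, **kw)
        if p_inv > 0:
            m._fit_pinv = True
        return m

    def name(self) -> str:
        s = self.family
        if self.alpha is not None:
            s += "+G"
        if self.p_inv > 0:
            s += "+I"
        return s
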