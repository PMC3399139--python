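"""GTR + discrete-gamma substitution model.

The general time-reversible rate matrix is parameterized by six
exchangeabilities (AC, AG, AT, CG, CT, GT with GT fixed to 1) and four
stationary base frequencies, normalized so the mean substitution rate is 1 —
branch lengths are then expected substitutions per site.  Among-site rate
variation uses Yang's discrete-gamma approximation with equal-probability
categories represented by their conditional means (6 categories by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as _gamma_dist

STATE_ORDER = "ACGT"
EXCHANGEABILITY_ORDER = ("AC", "AG", "AT", "CG", "CT", "GT")


@dataclass
class SubstitutionModel:
    exchangeabilities: np.ndarray = field(
        default_factory=lambda: np.ones(6)
    )  # AC, AG, AT, CG, CT, GT; GT == 1
    base_freqs: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    gamma_shape: float = 1.0
    n_categories: int = 6

    def __post_init__(self):
        self.exchangeabilities = np.asarray(self.exchangeabilities, dtype=float)
        self.base_freqs = np.asarray(self.base_freqs, dtype=float)
        if self.exchangeabilities.shape != (6,) or np.any(self.exchangeabilities <= 0):
            raise ValueError("six positive exchangeabilities required")
        if abs(self.exchangeabilities[5] - 1.0) > 1e-12:
            raise ValueError("GT exchangeability is the reference and must equal 1")
        if self.base_freqs.shape != (4,) or np.any(self.base_freqs <= 0):
            raise ValueError("four positive base frequencies required")
        if abs(self.base_freqs.sum() - 1.0) > 1e-8:
            raise ValueError("base frequencies must sum to 1")
        if self.gamma_shape <= 0:
            raise ValueError("gamma shape must be positive")
        if self.n_categories < 1:
            raise ValueError("need at least one rate category")

    # ------------------------------------------------------------ rate matrix
    def rate_matrix(self) -> np.ndarray:
        """Reversible Q with rows summing to 0 and mean rate normalized to 1."""
        s = np.zeros((4, 4))
        pairs = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))
        for r, (i, j) in zip(self.exchangeabilities, pairs):
            s[i, j] = s[j, i] = r
        q = s * self.base_freqs[np.newaxis, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -(self.base_freqs * np.diag(q)).sum()
        return q / mu

    def eigensystem(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Eigendecomposition of Q exploiting reversibility.

        Returns ``(w, left, right)`` such that
        ``P(t) = left @ diag(exp(w t)) @ right`` with real ``w``.
        """
        q = self.rate_matrix()
        sq = np.sqrt(self.base_freqs)
        sym = q * (sq[:, None] / sq[None, :])
        w, v = np.linalg.eigh(0.5 * (sym + sym.T))
        left = v / sq[:, None]
        right = v.T * sq[None, :]
        return w, left, right

    def category_rates(self) -> np.ndarray:
        """Conditional-mean rates of the equal-probability gamma categories."""
        return discrete_gamma_rates(self.gamma_shape, self.n_categories)


def discrete_gamma_rates(shape: float, n_categories: int) -> np.ndarray:
    """Mean rate of each of K equal-probability slices of a mean-1 gamma.

    For X ~ Gamma(shape=a, scale=1/a) the mean over the slice between
    quantiles q_{i} and q_{i+1} is K * [I(a+1, a q_{i+1}) - I(a+1, a q_i)],
    with I the regularized lower incomplete gamma function.
    """
    k = n_categories
    if k == 1:
        return np.ones(1)
    a = shape
    probs = np.arange(1, k) / k
    cuts = _gamma_dist.ppf(probs, a, scale=1.0 / a)
    edges = np.concatenate([[0.0], cuts, [np.inf]])
    upper = gammainc(a + 1.0, np.where(np.isinf(edges[1:]), 1e308, a * edges[1:]))
    lower = gammainc(a + 1.0, a * edges[:-1])
    rates = k * (upper - lower)
    # guard against tiny numerical drift: the slice means must average to 1
    return rates / rates.mean()


def transition_matrices(model: SubstitutionModel, lengths: np.ndarray) -> np.ndarray:
    """P(t) = exp(Q t) for a vector of branch lengths, shape (len(t), 4, 4)."""
    lengths = np.asarray(lengths, dtype=float)
    if np.any(lengths < 0):
        raise ValueError("branch lengths must be nonnegative")
    w, left, right = model.eigensystem()
    ew = np.exp(np.multiply.outer(lengths, w))  # (T, 4)
    p = np.einsum("ij,tj,jk->tik", left, ew, right)
    np.clip(p, 0.0, None, out=p)
    return p / p.sum(axis=-1, keepdims=True)


def gtr_transition_matrix(model: SubstitutionModel, branch_length: float) -> np.ndarray:
    """Single transition matrix P = exp(Q t); rows sum to 1."""
    if branch_length < 0:
        raise ValueError("branch length must be nonnegative")
    return transition_matrices(model, np.array([branch_length]))[0]
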