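"""Canonical correlation between two genes' site blocks and the pair weight.

Given correlation blocks S_PP (m x m), S_QQ (n x n) and S_PQ (m x n) built
from shrinkage-weighted site correlations, the canonical correlations
``xi_1 >= ... >= xi_k`` (k = min(m, n)) are the square roots of the
eigenvalues of ``S_PP^+ S_PQ S_QQ^+ S_QP`` (pseudo-inverses, so exactly
collinear blocks such as relative-usage profiles are handled).

Each coefficient is tested sequentially with a Bartlett-style chi-squared
statistic: for coefficient c,

    chi2_c = -(g - (m + n)/2) * sum_{i=c..k} ln(1 - xi_i^2),
    df_c   = (m - c + 1)(n - c + 1),

where ``g`` is the number of observations the correlations were estimated
over (the number of experiments).  Coefficient c counts as significant only
if tests 1..c all reject; testing stops at the first acceptance.

The scalar gene-pair weight averages the significant coefficients with
weights ``-ln P_c``:

    w = sum_c xi_c * L_c / sum_c L_c,   L_c = -ln P_c if P_c <= alpha else 0,

over the significant leading run; w = 0 when nothing is significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datamodel import ValidationError

__all__ = [
    "BlockCorrelation",
    "GenePairCCA",
    "canonical_correlations",
    "significance_sequence",
    "pair_weight",
    "gene_pair_cca",
]

#: eigenvalues are kept strictly below 1 so log(1 - xi^2) stays finite
EIG_CLIP = 1e-12
#: p-value floor applied before taking the logarithm in the weight
P_FLOOR = 1e-300
#: relative tolerance of the Moore-Penrose pseudo-inverse
PINV_RTOL = 1e-10


@dataclass
class BlockCorrelation:
    """Joint site-correlation matrix of a gene pair, in blocks."""

    pp: np.ndarray  # m x m
    qq: np.ndarray  # n x n
    pq: np.ndarray  # m x n

    def __post_init__(self):
        self.pp = np.asarray(self.pp, dtype=float)
        self.qq = np.asarray(self.qq, dtype=float)
        self.pq = np.asarray(self.pq, dtype=float)
        m, n = self.pq.shape
        if self.pp.shape != (m, m) or self.qq.shape != (n, n):
            raise ValidationError("inconsistent block shapes")
        for name, b in (("pp", self.pp), ("qq", self.qq), ("pq", self.pq)):
            if not np.all(np.isfinite(b)):
                raise ValidationError(f"non-finite entries in block {name}")

    @property
    def qp(self) -> np.ndarray:
        return self.pq.T

    @property
    def shape(self) -> tuple[int, int]:
        return self.pq.shape


@dataclass
class GenePairCCA:
    """Canonical correlations, sequential tests and the weight of one pair."""

    xi: np.ndarray            # descending, length min(m, n)
    statistics: np.ndarray    # chi-squared statistic per coefficient
    dof: np.ndarray           # degrees of freedom per coefficient
    pvalues: np.ndarray
    n_significant: int
    weight: float
    g: int                    # effective sample size used in the test


def canonical_correlations(block: BlockCorrelation) -> np.ndarray:
    """Canonical correlations of a block-correlation matrix, descending."""
    m, n = block.shape
    k = min(m, n)
    ipp = np.linalg.pinv(block.pp, rcond=PINV_RTOL, hermitian=True)
    iqq = np.linalg.pinv(block.qq, rcond=PINV_RTOL, hermitian=True)
    P = ipp @ block.pq @ iqq @ block.qp
    ev = np.linalg.eigvals(P)
    ev = np.real(ev)
    ev = np.clip(ev, 0.0, 1.0 - EIG_CLIP)
    ev = np.sort(ev)[::-1][:k]
    return np.sqrt(ev)


def significance_sequence(
    xi, m: int, n: int, g: int, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Sequential Bartlett tests of the canonical correlations.

    Returns ``(statistics, dof, pvalues, n_significant)`` where
    ``n_significant`` is the length of the leading run of rejections at
    level ``alpha``.
    """
    xi = np.asarray(xi, dtype=float)
    k = len(xi)
    if g <= (m + n) / 2:
        raise ValidationError(
            f"effective sample size g={g} must exceed (m+n)/2={(m + n) / 2}"
        )
    if np.any(xi < 0) or np.any(xi >= 1):
        raise ValidationError("canonical correlations must lie in [0, 1)")
    factor = g - 0.5 * (m + n)
    logs = np.log1p(-(xi**2))
    stats_ = np.array([-factor * logs[c:].sum() for c in range(k)])
    dof = np.array([(m - c) * (n - c) for c in range(k)], dtype=int)
    pvals = stats.chi2.sf(stats_, dof)
    n_sig = 0
    for c in range(k):
        if pvals[c] <= alpha:
            n_sig += 1
        else:
            break
    return stats_, dof, pvals, n_sig


def pair_weight(
    xi, pvalues, n_significant: int, alpha: float = 0.05
) -> float:
    """p-value-weighted average of the significant canonical correlations."""
    xi = np.asarray(xi, dtype=float)
    pvalues = np.asarray(pvalues, dtype=float)
    if n_significant == 0:
        return 0.0
    L = np.zeros(len(xi))
    run = slice(0, n_significant)
    p = np.maximum(pvalues[run], P_FLOOR)
    L[run] = np.where(p <= alpha, -np.log(p), 0.0)
    total = L.sum()
    if total == 0.0:
        return 0.0
    return float(np.sum(xi * L) / total)


def gene_pair_cca(
    block: BlockCorrelation, g: int, alpha: float = 0.05
) -> GenePairCCA:
    """Full per-pair computation: correlations, tests, and the weight."""
    m, n = block.shape
    xi = canonical_correlations(block)
    stats_, dof, pvals, n_sig = significance_sequence(xi, m, n, g, alpha)
    w = pair_weight(xi, pvals, n_sig, alpha)
    return GenePairCCA(
        xi=xi,
        statistics=stats_,
        dof=dof,
        pvalues=pvals,
        n_significant=n_sig,
        weight=w,
        g=g,
    )
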