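"""Shrinkage estimation of replicate measurement error, per poly(A) site.

For one site measured across ``T`` experiments with ``R(t)`` replicates, the
per-experiment error variance ``K2[t]`` (unbiased replicate variance) is a
high-variance estimate when ``R(t)`` is small; the pooled variance
``K2_bar = sum_t (R(t)-1)/(R-T) * K2[t]`` is low-variance but biased.  A
James–Stein-style shrinkage factor ``rho*`` in [0, 1], estimated from a
quadratic loss, blends the two:

    W*[t] = (1 - rho*) * K2[t] + rho* * K2_bar

The shrinkage error ``psi[t] = sqrt(W*[t] / R(t))`` estimates the standard
error of the experiment mean; its inverse square weights the experiment
means into a precision-weighted site mean, and deviations from that mean,
standardized by ``psi``, feed the shrinkage-weighted correlation between
sites.

With no replication anywhere (all ``R(t) = 1``) shrinkage is undefined; the
profile then degrades gracefully to ``psi = 1`` so the correlation becomes
the plain sample correlation over experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import ExperimentDesign, ValidationError

__all__ = ["ShrinkageProfile", "shrinkage_stats", "shrinkage_correlation"]

#: relative floor applied to psi so the precision weights stay finite
PSI_FLOOR_SCALE = 1e-6


@dataclass
class ShrinkageProfile:
    """Per-site shrinkage statistics over one experimental design.

    Arrays are indexed by experiment, in design order.
    """

    design: ExperimentDesign
    means: np.ndarray          # experiment means of the replicates
    variances: np.ndarray      # K2[t], unbiased replicate variance (0 if R(t)=1)
    var_of_var: np.ndarray     # var(K2[t]) under the quadratic-loss estimate
    pooled_variance: float     # K2_bar, df-weighted pooled variance
    rho_raw: float             # shrinkage factor before clipping
    rho: float                 # clipped factor in [0, 1]
    balanced: np.ndarray       # W*[t]
    psi: np.ndarray            # shrinkage error, floored
    weighted_mean: float       # precision-weighted site mean (1/psi^2 weights)
    unreplicated: bool

    @property
    def standardized(self) -> np.ndarray:
        """(means - weighted_mean) / psi, the vector correlated across sites."""
        return (self.means - self.weighted_mean) / self.psi


def shrinkage_stats(values, design: ExperimentDesign) -> ShrinkageProfile:
    """Compute the shrinkage profile of one site.

    Parameters
    ----------
    values
        Measurements of the site, one per design sample, in design order.
    design
        The experiment/replicate layout (``T >= 2``).
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (design.n_samples,):
        raise ValidationError(
            f"expected {design.n_samples} values, got shape {values.shape}"
        )
    T = design.n_experiments
    R = design.n_samples
    reps = design.replicates_of

    means = np.empty(T)
    K2 = np.zeros(T)
    vK2 = np.zeros(T)
    for t, exp in enumerate(design.experiments):
        cols = design.columns_of(exp)
        x = values[cols]
        rt = len(x)
        means[t] = x.mean()
        if rt > 1:
            K2[t] = x.var(ddof=1)
            dev2 = (x - means[t]) ** 2
            vK2[t] = rt / (rt - 1) ** 3 * np.sum((dev2 - K2[t]) ** 2)

    if R - T == 0:
        # no replication anywhere: shrinkage undefined, fall back to psi = 1
        psi = np.ones(T)
        wmean = float(means.mean())
        return ShrinkageProfile(
            design=design,
            means=means,
            variances=K2,
            var_of_var=vK2,
            pooled_variance=0.0,
            rho_raw=1.0,
            rho=1.0,
            balanced=np.zeros(T),
            psi=psi,
            weighted_mean=wmean,
            unreplicated=True,
        )

    df = np.array([reps[e] - 1 for e in design.experiments], dtype=float)
    pooled = float(np.sum(df / (R - T) * K2))

    denom = float(np.sum((K2 - pooled) ** 2))
    if denom == 0.0:
        # all experiment variances equal the pooled value: full shrinkage is
        # the continuous limit and loses nothing
        rho_raw = rho = 1.0
    else:
        rho_raw = float(np.sum((1.0 - df / (R - T)) * vK2) / denom)
        rho = min(1.0, max(0.0, rho_raw))

    W = (1.0 - rho) * K2 + rho * pooled
    Rt = np.array([reps[e] for e in design.experiments], dtype=float)
    psi = np.sqrt(W / Rt)
    floor = PSI_FLOOR_SCALE * max(1.0, float(np.max(np.abs(means))))
    psi = np.maximum(psi, floor)

    w = 1.0 / psi**2
    wmean = float(np.sum(means * w) / np.sum(w))
    return ShrinkageProfile(
        design=design,
        means=means,
        variances=K2,
        var_of_var=vK2,
        pooled_variance=pooled,
        rho_raw=rho_raw,
        rho=rho,
        balanced=W,
        psi=psi,
        weighted_mean=wmean,
        unreplicated=False,
    )


def _sd_weighted_mean(values, design: ExperimentDesign) -> float:
    # reference only: experiment means weighted by inverse replicate variance
    # (the precursor of the shrinkage-weighted mean; breaks down at K2 = 0)
    prof = shrinkage_stats(values, design)
    w = 1.0 / prof.variances
    return float(np.sum(prof.means * w) / np.sum(w))


def shrinkage_correlation(
    profile_m: ShrinkageProfile, profile_n: ShrinkageProfile
) -> float:
    """Shrinkage-weighted correlation between two sites' experiment means.

    Each site's experiment means are centred at its precision-weighted mean
    and standardized by its shrinkage error; the correlation is the cosine of
    the two standardized vectors, clipped to [-1, 1].  Returns 0 when either
    site is flat (all standardized deviations 0).
    """
    if profile_m.design != profile_n.design:
        raise ValidationError("profiles come from different designs")
    u = profile_m.standardized
    v = profile_n.standardized
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        return 0.0
    lam = float(np.dot(u, v) / (nu * nv))
    return float(np.clip(lam, -1.0, 1.0))
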