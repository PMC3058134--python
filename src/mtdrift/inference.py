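"""Fitting the drift (Kimura) model to heteroplasmy cohorts.

The estimator is the method of moments used for germline-bottleneck studies:
the mean mutation level ``p0`` estimates the founder heteroplasmy, and the
normalized variance ``V / (p0 (1 - p0))`` estimates ``1 - b``, since the
Kimura distribution's variance is ``p (1-p) (1-b)``.  From the fitted
``(p0, b)`` the derived quantities of interest follow: the probability of an
offspring fixing on wild-type or mutant, and the probability of exceeding a
clinically motivated mutant-load threshold (60% by default).

Sampling uncertainty is quantified by a parametric Monte Carlo: draw many
simulated cohorts of the observed size from the fitted distribution, refit
each, and take percentile intervals of every statistic.  Goodness of fit uses
a Kolmogorov-Smirnov statistic against the fitted mixed distribution with a
Monte-Carlo p-value; each null replicate is refitted before its KS distance
is computed, which keeps the p-value calibrated despite estimated parameters
(a parametric bootstrap with estimation).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .kimura import (
    KimuraParams,
    KimuraSampler,
    _cdf_many,
    _masses_arrays,
    kimura_cdf,
    kimura_masses,
    kimura_tail,
)

__all__ = [
    "FitError",
    "KimuraFit",
    "GofResult",
    "fit_moments",
    "fit_from_summary",
    "mc_confidence_intervals",
    "ks_test_mc",
]

DEFAULT_TAIL_THRESHOLD = 0.6
_CI_STATS = ("p0", "V", "normalized_variance", "b", "f0", "f1", "tail_prob")


class FitError(ValueError):
    """The cohort cannot be described by a proper drift distribution."""


@dataclass(frozen=True)
class KimuraFit:
    """Moment fit of the drift model plus derived statistics.

    ``b = 1 - normalized_variance`` exactly; fixation and tail probabilities
    are evaluated at the point estimates, and ``ci`` (when populated by
    :func:`mc_confidence_intervals`) holds 95% percentile intervals per
    statistic.
    """

    n: int
    p0: float
    V: float
    normalized_variance: float
    b: float
    f0: float
    f1: float
    tail_threshold: float
    tail_prob: float
    ci: dict | None = None
    ci_reps: int | None = None
    ci_failed: int | None = None
    seed: int | None = None

    @property
    def params(self) -> KimuraParams:
        return KimuraParams(p=self.p0, b=self.b)

    def to_report(self) -> dict:
        """Report dict with both fraction and percent representations."""

        def both(v):
            return {"fraction": v, "percent": 100.0 * v}

        rep = {
            "n": self.n,
            "p0": both(self.p0),
            "V": self.V,
            "normalized_variance": self.normalized_variance,
            "b": self.b,
            "f0": both(self.f0),
            "f1": both(self.f1),
            "tail_threshold": both(self.tail_threshold),
            "tail_prob": both(self.tail_prob),
        }
        if self.ci is not None:
            rep["ci95"] = {k: list(v) for k, v in self.ci.items()}
            rep["ci_reps"] = self.ci_reps
            rep["ci_failed_refits"] = self.ci_failed
            rep["seed"] = self.seed
        return rep


@dataclass(frozen=True)
class GofResult:
    """KS distance against the fitted distribution and its Monte-Carlo p-value."""

    D: float
    p_value: float
    reps: int
    seed: int
    n: int
    fit: KimuraFit


def fit_from_summary(p0: float, V: float, n: int, tail_threshold: float = DEFAULT_TAIL_THRESHOLD) -> KimuraFit:
    """Fit from printed summary statistics (mean, variance, sample size).

    Fails when the normalized variance reaches 1 (data more dispersed than
    complete fixation allows) or 0 (no spread at all).
    """
    p0, V = float(p0), float(V)
    if not (0.0 < p0 < 1.0):
        raise FitError(f"mean mutation level must be in (0, 1), got {p0!r}")
    if V <= 0.0:
        raise FitError(f"variance must be positive, got {V!r} (all-identical input?)")
    nv = V / (p0 * (1.0 - p0))
    if nv >= 1.0:
        raise FitError(
            f"normalized variance {nv:.4g} >= 1: more dispersed than complete "
            "fixation; no drift distribution fits"
        )
    b = 1.0 - nv
    params = KimuraParams(p=p0, b=b)
    m = kimura_masses(params)
    return KimuraFit(
        n=int(n),
        p0=p0,
        V=V,
        normalized_variance=nv,
        b=b,
        f0=m.f0,
        f1=m.f1,
        tail_threshold=float(tail_threshold),
        tail_prob=kimura_tail(tail_threshold, params),
    )


def fit_moments(
    loads,
    tail_threshold: float = DEFAULT_TAIL_THRESHOLD,
    exclude_zeros: bool = False,
) -> KimuraFit:
    """Moment fit to raw heteroplasmy fractions.

    Measurements reported as exactly 0 (below the detection threshold) are
    genuine candidate fixations under drift and enter the fit by default;
    ``exclude_zeros=True`` is a sensitivity switch.
    """
    loads = np.asarray(loads, dtype=float)
    if exclude_zeros:
        loads = loads[loads > 0.0]
    if loads.ndim != 1 or len(loads) < 3:
        raise FitError("need at least 3 measurements")
    if np.any((loads < 0.0) | (loads > 1.0)):
        raise FitError("heteroplasmy fractions must lie in [0, 1]")
    if np.unique(loads).size < 2:
        raise FitError("all measurements identical: variance 0 puts b on the boundary")
    p0 = float(loads.mean())
    V = float(loads.var(ddof=1))
    if not (0.0 < p0 < 1.0):
        raise FitError(f"sample mean {p0:.4g} on the boundary of (0, 1)")
    return fit_from_summary(p0, V, len(loads), tail_threshold)


def _refit_replicates(samples: np.ndarray, tail_threshold: float):
    """Vectorized moment refits of replicate cohorts (rows of ``samples``).

    Returns a dict of per-replicate statistic arrays and a validity mask;
    replicates whose refit fails (boundary mean, nv outside (0, 1), or series
    non-convergence) are flagged.
    """
    p0 = samples.mean(axis=1)
    V = samples.var(axis=1, ddof=1)
    valid = (p0 > 0.0) & (p0 < 1.0) & (V > 0.0)
    nv = np.full_like(p0, np.nan)
    nv[valid] = V[valid] / (p0[valid] * (1.0 - p0[valid]))
    valid &= (nv > 0.0) & (nv < 1.0)
    b = 1.0 - nv
    f0 = np.full_like(p0, np.nan)
    f1 = np.full_like(p0, np.nan)
    tail = np.full_like(p0, np.nan)
    if valid.any():
        idx = np.nonzero(valid)[0]
        cdf_thr, f0_v, f1_v, conv = _cdf_many(
            p0[idx], b[idx], np.full((len(idx), 1), tail_threshold)
        )
        f0[idx], f1[idx] = f0_v, f1_v
        tail[idx] = 1.0 - cdf_thr[:, 0]
        valid[idx] &= conv
    return {
        "p0": p0,
        "V": V,
        "normalized_variance": nv,
        "b": b,
        "f0": f0,
        "f1": f1,
        "tail_prob": tail,
    }, valid


def mc_confidence_intervals(fit: KimuraFit, reps: int = 10000, seed: int = 3243) -> KimuraFit:
    """Populate 95% percentile intervals by parametric Monte Carlo.

    Draws ``reps`` cohorts of size ``fit.n`` from the fitted distribution,
    refits each, and takes the 2.5th/97.5th percentiles of every statistic.
    Replicates whose refit fails are recorded and excluded; more than 50%
    failures is an error.
    """
    if reps < 2:
        raise ValueError("reps must be >= 2")
    rng = np.random.default_rng(seed)
    sampler = KimuraSampler(fit.params)
    samples = sampler.draw(rng, (reps, fit.n))
    stats, valid = _refit_replicates(samples, fit.tail_threshold)
    n_failed = int(reps - valid.sum())
    if n_failed > reps / 2:
        raise FitError(
            f"{n_failed}/{reps} Monte-Carlo refits failed; the fit is too close "
            "to a boundary for percentile intervals"
        )
    ci = {
        k: tuple(np.percentile(stats[k][valid], [2.5, 97.5])) for k in _CI_STATS
    }
    return replace(fit, ci=ci, ci_reps=reps, ci_failed=n_failed, seed=seed)


def _ks_statistic_exact(loads: np.ndarray, fit: KimuraFit) -> float:
    """Sup distance between the empirical CDF and the fitted mixed CDF.

    Tie-aware; evaluated at the data points plus 0 and 1 so the atoms are
    honoured, approaching each evaluation point from both sides.
    """
    n = len(loads)
    vals, counts = np.unique(np.concatenate([loads, [0.0, 1.0]]), return_counts=True)
    # remove the sentinel copies of 0 and 1 from the counts
    counts = counts.astype(float)
    counts[vals == 0.0] -= 1
    counts[vals == 1.0] -= 1
    ecdf = np.cumsum(counts) / n
    ecdf_left = ecdf - counts / n
    F = kimura_cdf(vals, fit.params)
    F_left = F.copy()
    F_left[vals == 0.0] -= fit.f0
    F_left[vals == 1.0] -= fit.f1
    return float(
        np.max(np.maximum(np.abs(ecdf - F), np.abs(ecdf_left - F_left)))
    )


def _ks_statistics_batch(samples: np.ndarray, stats: dict, valid: np.ndarray) -> np.ndarray:
    """KS distances of replicate rows against their own refitted distributions."""
    reps, n = samples.shape
    out = np.full(reps, np.nan)
    idx = np.nonzero(valid)[0]
    if idx.size == 0:
        return out
    x = np.sort(samples[idx], axis=1)
    F, f0, f1, conv = _cdf_many(stats["p0"][idx], stats["b"][idx], x)
    # interior points are almost surely distinct; the tied blocks at the atoms
    # 0 and 1 are handled by their block-extreme candidates C0 and C1 below
    at_atom = (x == 0.0) | (x == 1.0)
    j = np.arange(1, n + 1) / n
    A = np.where(at_atom, 0.0, np.abs(j - F))
    B = np.where(at_atom, 0.0, np.abs(j - 1.0 / n - F))
    k0 = (x == 0.0).sum(axis=1) / n
    k1 = (x == 1.0).sum(axis=1) / n
    C0 = np.abs(k0 - f0)
    C1 = np.abs((1.0 - k1) - (1.0 - f1))
    D = np.maximum(np.maximum(A, B).max(axis=1), np.maximum(C0, C1))
    out[idx] = np.where(conv, D, np.nan)
    return out


def ks_test_mc(loads, reps: int = 2000, seed: int = 3243, exclude_zeros: bool = False) -> GofResult:
    """Monte-Carlo KS goodness-of-fit test of the drift null.

    ``D`` is the sup distance between the empirical CDF and the fitted Kimura
    CDF; the p-value is ``(1 + #{D* >= D}) / (reps_valid + 1)`` over null
    replicates that are drawn from the fitted distribution and refitted before
    their distance is computed.
    """
    loads = np.asarray(loads, dtype=float)
    fit = fit_moments(loads, exclude_zeros=exclude_zeros)
    if exclude_zeros:
        loads = loads[loads > 0.0]
    D = _ks_statistic_exact(loads, fit)
    rng = np.random.default_rng(seed)
    sampler = KimuraSampler(fit.params)
    samples = sampler.draw(rng, (reps, fit.n))
    stats, valid = _refit_replicates(samples, fit.tail_threshold)
    D_star = _ks_statistics_batch(samples, stats, valid)
    ok = ~np.isnan(D_star)
    n_valid = int(ok.sum())
    if n_valid < reps / 2:
        raise FitError(f"only {n_valid}/{reps} null replicates could be refitted")
    p_value = (1.0 + float((D_star[ok] >= D).sum())) / (n_valid + 1.0)
    return GofResult(D=D, p_value=p_value, reps=n_valid, seed=seed, n=fit.n, fit=fit)
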