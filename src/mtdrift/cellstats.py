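"""Descriptive statistics for single-cell pools and replicate measurements.

Covers the dispersion side of a segregation study: per-pool summaries of
single-cell mutant loads, the regression of per-pool SD on per-pool mean
(drift predicts dispersion growing with mean load below 50%), the one-way
random-effects intraclass correlation for replicate measurements within an
embryo, and the transmission rate under a detection threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "PoolSummary",
    "RegressionResult",
    "ICCResult",
    "TransmissionRate",
    "summarize_pools",
    "pooled_mean",
    "mean_sd_regression",
    "icc_oneway",
    "transmission_rate",
]


@dataclass(frozen=True)
class PoolSummary:
    pool_id: str
    tissue: str
    n_cells: int
    mean_load: float
    sd_load: float | None  # None for singleton pools (flagged, excluded from regression)
    min_load: float
    max_load: float


@dataclass(frozen=True)
class RegressionResult:
    """OLS of per-pool SD on per-pool mean, with Pearson r and its two-sided p."""

    r: float
    slope: float
    slope_se: float
    intercept: float
    n_pools: int
    p_value: float


@dataclass(frozen=True)
class ICCResult:
    """One-way random-effects intraclass correlation (unbalanced allowed)."""

    icc: float
    n_groups: int
    replicates_per_group: tuple[int, ...]
    ms_between: float
    ms_within: float


@dataclass(frozen=True)
class TransmissionRate:
    carriers: int
    total: int
    rate: float
    ci95: tuple[float, float]


def _as_groups(data) -> dict:
    """Normalize grouped input: mapping id -> loads, or iterable of (id, loads)."""
    if isinstance(data, Mapping):
        return {str(k): np.asarray(v, dtype=float) for k, v in data.items()}
    return {str(k): np.asarray(v, dtype=float) for k, v in data}


def summarize_pools(pools, tissue: str = "") -> list[PoolSummary]:
    """Per-pool mean, SD (n-1), min and max of single-cell loads.

    ``pools`` maps pool id to its cell loads (fractions).  Empty pools are an
    error; singleton pools get ``sd_load=None`` and are excluded from the
    mean-SD regression downstream.
    """
    groups = _as_groups(pools)
    out = []
    for pid, loads in groups.items():
        if loads.size == 0:
            raise ValueError(f"pool {pid!r} is empty")
        if np.any((loads < 0.0) | (loads > 1.0)):
            raise ValueError(f"pool {pid!r} has loads outside [0, 1]")
        sd = float(loads.std(ddof=1)) if loads.size >= 2 else None
        if sd is None:
            warnings.warn(f"pool {pid!r} has a single cell; SD undefined", stacklevel=2)
        out.append(
            PoolSummary(
                pool_id=pid,
                tissue=tissue,
                n_cells=int(loads.size),
                mean_load=float(loads.mean()),
                sd_load=sd,
                min_load=float(loads.min()),
                max_load=float(loads.max()),
            )
        )
    return out


def pooled_mean(pools) -> float:
    """Cell-weighted grand mean across pools (comparable to a whole-sample load)."""
    groups = _as_groups(pools)
    all_loads = np.concatenate(list(groups.values()))
    return float(all_loads.mean())


def mean_sd_regression(pools: Sequence[PoolSummary], weighted: bool = False) -> RegressionResult:
    """OLS of per-pool SD on per-pool mean, plus Pearson correlation.

    Unweighted by default (pools count equally regardless of cell number); the
    weighted option uses cell counts as weights.  Requires at least 3 pools
    with a defined SD.
    """
    usable = [s for s in pools if s.sd_load is not None]
    if len(usable) < 3:
        raise ValueError(f"need at least 3 pools with >= 2 cells, got {len(usable)}")
    x = np.array([s.mean_load for s in usable])
    y = np.array([s.sd_load for s in usable])
    if np.unique(x).size < 2:
        raise ValueError("all pool means identical; slope undefined")
    if weighted:
        w = np.array([s.n_cells for s in usable], dtype=float)
        W = np.diag(w)
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
        resid = y - X @ beta
        dof = len(x) - 2
        s2 = float(resid @ W @ resid) / dof
        cov = s2 * np.linalg.inv(X.T @ W @ X)
        slope, intercept, slope_se = beta[1], beta[0], float(np.sqrt(cov[1, 1]))
        r, p = sps.pearsonr(x, y)
    else:
        res = sps.linregress(x, y)
        slope, intercept, slope_se = res.slope, res.intercept, res.stderr
        r, p = res.rvalue, res.pvalue
    return RegressionResult(
        r=float(r),
        slope=float(slope),
        slope_se=float(slope_se),
        intercept=float(intercept),
        n_pools=len(usable),
        p_value=float(p),
    )


def icc_oneway(groups) -> ICCResult:
    """One-way random-effects ICC for replicate loads within groups.

    ``ICC = (MSB - MSW) / (MSB + (k0 - 1) MSW)`` with the standard unbalanced
    correction ``k0 = (sum k_i - sum k_i^2 / sum k_i) / (g - 1)``.  Groups with
    a single replicate are dropped with a warning.
    """
    gdict = _as_groups(groups)
    kept, dropped = {}, []
    for gid, vals in gdict.items():
        if vals.size >= 2:
            kept[gid] = vals
        else:
            dropped.append(gid)
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} group(s) with a single replicate: {dropped}",
            stacklevel=2,
        )
    g = len(kept)
    if g < 2:
        raise ValueError("need at least 2 groups with >= 2 replicates")
    ks = np.array([v.size for v in kept.values()], dtype=float)
    N = ks.sum()
    grand = np.concatenate(list(kept.values())).mean()
    means = np.array([v.mean() for v in kept.values()])
    ssb = float((ks * (means - grand) ** 2).sum())
    ssw = float(sum(((v - v.mean()) ** 2).sum() for v in kept.values()))
    msb = ssb / (g - 1)
    msw = ssw / (N - g)
    k0 = (N - (ks**2).sum() / N) / (g - 1)
    if msw == 0.0:
        icc = 1.0
    else:
        icc = (msb - msw) / (msb + (k0 - 1.0) * msw)
    return ICCResult(
        icc=float(icc),
        n_groups=g,
        replicates_per_group=tuple(int(k) for k in ks),
        ms_between=msb,
        ms_within=msw,
    )


def transmission_rate(loads, detection_threshold: float = 0.02) -> TransmissionRate:
    """Fraction of offspring with a detectable mutant load.

    A load exactly at the detection threshold counts as detected.  The 95%
    interval is the exact (Clopper-Pearson) binomial CI.
    """
    loads = np.asarray(loads, dtype=float)
    if loads.size < 1:
        raise ValueError("need at least one offspring")
    carriers = int((loads >= detection_threshold).sum())
    total = int(loads.size)
    ci = sps.binomtest(carriers, total).proportion_ci(confidence_level=0.95, method="exact")
    return TransmissionRate(
        carriers=carriers,
        total=total,
        rate=carriers / total,
        ci95=(float(ci.low), float(ci.high)),
    )
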