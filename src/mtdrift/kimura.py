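"""Kimura distribution of heteroplasmy under pure random genetic drift.

The distribution of an allele (here: mutant mtDNA) frequency after an episode
of pure drift from an initial frequency ``p`` is Kimura's solution of the
drift diffusion equation.  It is a mixture of

* a point mass ``f0`` at 0 (fixation on wild-type, i.e. loss of the mutant),
* a point mass ``f1`` at 1 (fixation on the mutant), and
* a continuous density ``phi`` on (0, 1),

all indexed by a single drift parameter ``b`` in (0, 1): ``b -> 1`` means no
drift (the distribution degenerates to a spike at ``p``), ``b -> 0`` complete
fixation (mass ``1-p`` at 0 and ``p`` at 1).  Under a Wright-Fisher bottleneck
of ``N`` segregating units over ``g`` generations, ``b = (1 - 1/N)**g``.  The
variance is ``p (1-p) (1-b)`` for every ``b``.

The series (eigenfunction expansion of the diffusion) is

    f0     = q + sum_{i>=1} (2i+1) p q (-1)^i F_i(q) b^{i(i+1)/2}
    f1     = p + sum_{i>=1} (2i+1) p q (-1)^i F_i(p) b^{i(i+1)/2}
    phi(x) = sum_{i>=1} i(i+1)(2i+1) p q F_i(p) F_i(x) b^{i(i+1)/2}

with ``q = 1 - p`` and ``F_i(x) = 2F1(1-i, i+2; 2; x)``, a terminating
hypergeometric polynomial of degree ``i-1``.  Everything here is evaluated by
stable forward recurrences in the term index: ``F_i(x)`` equals
``2 P'_i(1-2x) / (i (i+1))`` with ``P_i`` the Legendre polynomial, and both
``P_i`` and ``P'_i`` obey three-term recurrences.  The termwise antiderivative
``int_0^x F_i = (1 - P_i(1-2x)) / (i (i+1))`` gives a closed-form CDF, so no
quadrature is needed anywhere in this module.

All heteroplasmy values are fractions in [0, 1]; percent only at I/O
boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "KimuraParams",
    "KimuraMasses",
    "KimuraConvergenceError",
    "kimura_masses",
    "kimura_pdf",
    "kimura_cdf",
    "kimura_tail",
    "kimura_moments",
    "kimura_sample",
    "KimuraSampler",
]

#: series terms are added until (2i+1) i (i+1) b^{i(i+1)/2} < _SERIES_TOL,
#: a bound on every remaining increment of every series evaluated here
_SERIES_TOL = 1e-13
_MAX_TERMS = 500
#: truncation round-off below this magnitude is clipped to zero in the density
_NEG_CLIP = 1e-10
_DEFAULT_GRID = 4097


class KimuraConvergenceError(RuntimeError):
    """Raised when the eigenfunction series does not converge within the term cap."""

    def __init__(self, p, b, tol=_SERIES_TOL, max_terms=_MAX_TERMS):
        super().__init__(
            f"Kimura series did not reach increment tolerance {tol:g} within "
            f"{max_terms} terms for p={p!r}, b={b!r}; b this close to 1 is outside "
            f"the supported range (b <= ~0.999)"
        )


@dataclass(frozen=True)
class KimuraParams:
    """Initial heteroplasmy ``p`` and drift (bottleneck) parameter ``b``.

    Both must lie strictly inside (0, 1).  ``b -> 1`` is the no-drift limit,
    ``b -> 0`` complete fixation.
    """

    p: float
    b: float

    def __post_init__(self):
        p, b = float(self.p), float(self.b)
        if not (0.0 < p < 1.0):
            raise ValueError(f"initial heteroplasmy p must be in (0, 1), got {self.p!r}")
        if not (0.0 < b < 1.0):
            raise ValueError(f"drift parameter b must be in (0, 1), got {self.b!r}")
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "b", b)


@dataclass(frozen=True)
class KimuraMasses:
    """Fixation probabilities and the remaining continuous mass."""

    f0: float
    f1: float

    @property
    def continuous_mass(self) -> float:
        return 1.0 - self.f0 - self.f1


def _legendre_steps(z, max_terms):
    """Yield ``(i, P_i(z), P'_i(z))`` for i = 1, 2, ... by forward recurrence.

    ``z`` may be a scalar or array; the recurrence is elementwise.
    """
    z = np.asarray(z, dtype=float)
    P_prev = np.ones_like(z)   # P_0
    P_cur = z.copy()           # P_1
    Pd_prev = np.zeros_like(z)  # P'_0
    Pd_cur = np.ones_like(z)   # P'_1
    i = 1
    while i <= max_terms:
        yield i, P_cur, Pd_cur
        # (i+1) P_{i+1} = (2i+1) z P_i - i P_{i-1};  P'_{i+1} = P'_{i-1} + (2i+1) P_i
        P_next = ((2 * i + 1) * z * P_cur - i * P_prev) / (i + 1)
        Pd_next = Pd_prev + (2 * i + 1) * P_cur
        P_prev, P_cur = P_cur, P_next
        Pd_prev, Pd_cur = Pd_cur, Pd_next
        i += 1


def _term_weights(b, max_terms=_MAX_TERMS, tol=_SERIES_TOL):
    """``b^{i(i+1)/2}`` for i = 1..imax, truncated where the term bound falls below tol."""
    i = np.arange(1, max_terms + 1, dtype=float)
    with np.errstate(over="ignore"):
        w = b ** (i * (i + 1) / 2.0)
    bound = (2 * i + 1) * i * (i + 1) * w
    below = np.nonzero(bound < tol)[0]
    if below.size == 0:
        return None  # not converged within the cap
    imax = below[0] + 1
    return w[:imax]


def kimura_masses(params: KimuraParams) -> KimuraMasses:
    """Point masses at 0 (loss of the mutant) and 1 (fixation of the mutant)."""
    p, b = params.p, params.b
    q = 1.0 - p
    w = _term_weights(b)
    if w is None:
        raise KimuraConvergenceError(p, b)
    f0, f1 = q, p
    # F_i at argument q for loss, at p for fixation; z = 1-2x
    gen_q = _legendre_steps(2.0 * p - 1.0, len(w))
    gen_p = _legendre_steps(1.0 - 2.0 * p, len(w))
    for (i, _, Pd_q), (_, _, Pd_p) in zip(gen_q, gen_p):
        c = (2 * i + 1) * p * q * (-1) ** i * 2.0 / (i * (i + 1)) * w[i - 1]
        f0 += c * Pd_q
        f1 += c * Pd_p
    f0 = float(min(max(f0, 0.0), 1.0))
    f1 = float(min(max(f1, 0.0), 1.0))
    return KimuraMasses(f0=f0, f1=f1)


def _masses_arrays(p, b, max_terms=_MAX_TERMS, tol=_SERIES_TOL):
    """Vectorized fixation masses for arrays of (p, b).

    Returns ``(f0, f1, converged)``; elements whose series hits the term cap are
    flagged rather than raising, so Monte-Carlo refits can drop them.
    """
    p = np.asarray(p, dtype=float)
    b = np.asarray(b, dtype=float)
    q = 1.0 - p
    f0 = q.copy()
    f1 = p.copy()
    converged = np.zeros(p.shape, dtype=bool)
    gen_q = _legendre_steps(2.0 * p - 1.0, max_terms)
    gen_p = _legendre_steps(1.0 - 2.0 * p, max_terms)
    w = b.copy()  # b^{i(i+1)/2} at i=1
    for (i, _, Pd_q), (_, _, Pd_p) in zip(gen_q, gen_p):
        c = (2 * i + 1) * p * q * (-1) ** i * 2.0 / (i * (i + 1)) * w
        f0 += c * Pd_q
        f1 += c * Pd_p
        converged |= (2 * i + 1) * i * (i + 1) * w < tol
        if converged.all():
            break
        w = w * b ** (i + 1)  # b^{T_{i+1}} = b^{T_i} * b^{i+1}
    return np.clip(f0, 0.0, 1.0), np.clip(f1, 0.0, 1.0), converged


def kimura_pdf(x, params: KimuraParams):
    """Continuous density ``phi(x)`` on (0, 1).

    The point masses at 0 and 1 are queried via :func:`kimura_masses`; ``x``
    outside the open interval raises a domain error.
    """
    p, b = params.p, params.b
    x_arr = np.atleast_1d(np.asarray(x, dtype=float))
    if np.any((x_arr <= 0.0) | (x_arr >= 1.0)):
        raise ValueError("kimura_pdf is defined on the open interval (0, 1)")
    w = _term_weights(b)
    if w is None:
        raise KimuraConvergenceError(p, b)
    q = 1.0 - p
    phi = np.zeros_like(x_arr)
    gen_p = _legendre_steps(1.0 - 2.0 * p, len(w))
    gen_x = _legendre_steps(1.0 - 2.0 * x_arr, len(w))
    for (i, _, Pd_p), (_, _, Pd_x) in zip(gen_p, gen_x):
        phi += 4.0 * (2 * i + 1) * p * q / (i * (i + 1)) * Pd_p * Pd_x * w[i - 1]
    if np.any(phi < -_NEG_CLIP):
        worst = float(phi.min())
        raise RuntimeError(
            f"Kimura density evaluated to {worst:g} < -{_NEG_CLIP:g}; "
            "this indicates a bug, not truncation round-off"
        )
    phi = np.clip(phi, 0.0, None)
    return phi if np.ndim(x) else float(phi[0])


def _cdf_continuous(x_arr, p, b, w):
    """``int_0^x phi`` termwise in closed form (no quadrature)."""
    q = 1.0 - p
    out = np.zeros_like(x_arr)
    gen_p = _legendre_steps(1.0 - 2.0 * p, len(w))
    gen_x = _legendre_steps(1.0 - 2.0 * x_arr, len(w))
    for (i, _, Pd_p), (_, P_x, _) in zip(gen_p, gen_x):
        out += 2.0 * (2 * i + 1) * p * q / (i * (i + 1)) * Pd_p * (1.0 - P_x) * w[i - 1]
    return out


def kimura_cdf(x, params: KimuraParams):
    """Right-continuous CDF on [0, 1]: ``cdf(0) = f0``, ``cdf(1) = 1``."""
    p, b = params.p, params.b
    x_arr = np.atleast_1d(np.asarray(x, dtype=float))
    if np.any((x_arr < 0.0) | (x_arr > 1.0)):
        raise ValueError("kimura_cdf is defined on [0, 1]")
    w = _term_weights(b)
    if w is None:
        raise KimuraConvergenceError(p, b)
    m = kimura_masses(params)
    out = m.f0 + _cdf_continuous(x_arr, p, b, w)
    out[x_arr >= 1.0] += m.f1
    out = np.clip(out, 0.0, 1.0)
    return out if np.ndim(x) else float(out[0])


def _cdf_many(p, b, x, max_terms=_MAX_TERMS, tol=_SERIES_TOL):
    """CDF at points ``x[r, :]`` of the distribution with parameters ``(p[r], b[r])``.

    One recurrence pass shared across replicates; used by the Monte-Carlo
    goodness-of-fit machinery.  Returns ``(cdf, f0, f1, converged)``.
    """
    p = np.asarray(p, dtype=float)[:, None]
    b = np.asarray(b, dtype=float)[:, None]
    x = np.asarray(x, dtype=float)
    q = 1.0 - p
    f0, f1, converged = _masses_arrays(p[:, 0], b[:, 0], max_terms, tol)
    out = np.broadcast_to(f0[:, None], x.shape).copy()
    w = b.copy()
    gen_p = _legendre_steps(1.0 - 2.0 * p, max_terms)
    gen_x = _legendre_steps(1.0 - 2.0 * x, max_terms)
    done_bound = np.zeros(p.shape, dtype=bool)
    for (i, _, Pd_p), (_, P_x, _) in zip(gen_p, gen_x):
        out += 2.0 * (2 * i + 1) * p * q / (i * (i + 1)) * Pd_p * (1.0 - P_x) * w
        done_bound |= (2 * i + 1) * i * (i + 1) * w < tol
        if done_bound.all():
            break
        w = w * b ** (i + 1)
    out[x >= 1.0] += np.broadcast_to(f1[:, None], x.shape)[x >= 1.0]
    return np.clip(out, 0.0, 1.0), f0, f1, converged


def kimura_tail(threshold, params: KimuraParams) -> float:
    """``P(x > threshold)`` — e.g. the probability of exceeding a 60% mutant load."""
    thr = float(threshold)
    if not (0.0 <= thr <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    return 1.0 - kimura_cdf(thr, params)


def kimura_moments(params: KimuraParams):
    """Closed-form ``(mean, variance)``: drift is unbiased, variance = p(1-p)(1-b)."""
    p, b = params.p, params.b
    return p, p * (1.0 - p) * (1.0 - b)


class KimuraSampler:
    """Inverse-CDF sampler with a precomputed grid.

    The continuous part is inverted by linear interpolation on ``grid_size``
    equally spaced points; draws falling into the CDF's flat segments below
    ``f0`` or above ``1 - f1`` land exactly on the atoms 0 and 1.
    """

    def __init__(self, params: KimuraParams, grid_size: int = _DEFAULT_GRID):
        if grid_size < 2:
            raise ValueError("grid_size must be at least 2")
        self.params = params
        w = _term_weights(params.b)
        if w is None:
            raise KimuraConvergenceError(params.p, params.b)
        self.masses = kimura_masses(params)
        self._grid = np.linspace(0.0, 1.0, grid_size)
        # continuous CDF only: its value at 1 is 1 - f1, so u > 1 - f1 maps to the atom at 1
        self._cdf = self.masses.f0 + _cdf_continuous(self._grid, params.p, params.b, w)
        self._cdf = np.maximum.accumulate(np.clip(self._cdf, 0.0, 1.0))

    def draw(self, rng: np.random.Generator, size) -> np.ndarray:
        u = rng.uniform(size=size)
        return np.interp(u, self._cdf, self._grid)


def kimura_sample(params: KimuraParams, n: int, seed, grid_size: int = _DEFAULT_GRID):
    """``n`` i.i.d. heteroplasmy draws; reproducible under ``seed``.

    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return KimuraSampler(params, grid_size).draw(rng, n)
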