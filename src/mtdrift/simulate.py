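"""Synthetic heteroplasmy data: Wright-Fisher drift, single-cell sampling, assay noise.

This module plays two roles.  It is the package's synthetic-data generator,
emulating the kind of material an mtDNA segregation study collects (an embryo
cohort from a carrier, replicate blastomere measurements, single-cell pools),
and it is the independent oracle against which the Kimura machinery is
cross-validated: a Wright-Fisher bottleneck of ``N`` segregating units run for
``g`` generations produces heteroplasmy distributed, in the large-``N``
diffusion regime, as Kimura's distribution with ``b = (1 - 1/N)**g``.

The measurement model is deliberately simple: additive Gaussian replicate
noise (the assay's reported replicate SD is below 1.7%), truncation to [0, 1],
and censoring of values below the detection threshold (2% by default) to
exactly 0, mirroring how a diagnostic lab reports "no detectable mutation".
PCR chemistry is not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "DriftSimConfig",
    "SyntheticCohort",
    "simulate_offspring",
    "simulate_single_cells",
    "simulate_blastomere_replicates",
]

#: mnemonic default seed (m.3243A>G)
DEFAULT_SEED = 3243

#: default within-embryo replicate SD; calibrated so that a drift cohort with
#: between-embryo SD ~0.25 yields a one-way ICC of ~0.994 and a maximal
#: inter-blastomere difference of ~6 percentage points over a 35-embryo cohort
DEFAULT_WITHIN_SD = 0.018


@dataclass(frozen=True)
class DriftSimConfig:
    """Wright-Fisher bottleneck plus assay-noise settings.

    ``N`` segregating units are binomially resampled for ``g`` generations from
    founder heteroplasmy ``p``; the implied Kimura drift parameter
    ``b = (1 - 1/N)**g`` is reported with every simulated cohort.
    """

    p: float
    N: int = 25
    g: int = 8
    n_offspring: int = 35
    copies_per_cell: int = 150
    noise_sd: float = 0.017
    detection_threshold: float = 0.02
    seed: int = DEFAULT_SEED

    def __post_init__(self):
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"founder heteroplasmy p must be in [0, 1], got {self.p!r}")
        if self.N < 2:
            raise ValueError(f"need at least 2 segregating units, got N={self.N!r}")
        if self.g < 0:
            raise ValueError("generations g must be >= 0")
        if self.n_offspring < 1:
            raise ValueError("n_offspring must be >= 1")
        if self.copies_per_cell < 1:
            raise ValueError("copies_per_cell must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0.0 <= self.detection_threshold < 1.0):
            raise ValueError("detection_threshold must be in [0, 1)")

    @property
    def b(self) -> float:
        """Implied Kimura drift parameter ``(1 - 1/N)**g``."""
        return (1.0 - 1.0 / self.N) ** self.g


@dataclass
class SyntheticCohort:
    """True and measured heteroplasmy per offspring, plus optional replicates."""

    true_loads: np.ndarray
    measured_loads: np.ndarray
    config: DriftSimConfig
    b: float
    replicates: np.ndarray | None = None  # shape (n_offspring, k)
    seed: int = field(default=DEFAULT_SEED)

    def __post_init__(self):
        self.true_loads = np.asarray(self.true_loads, dtype=float)
        self.measured_loads = np.asarray(self.measured_loads, dtype=float)
        if self.true_loads.shape != self.measured_loads.shape:
            raise ValueError("true_loads and measured_loads must have equal length")

    @property
    def n_offspring(self) -> int:
        return len(self.true_loads)


def _measure(true_loads, noise_sd, detection_threshold, rng):
    """Apply the assay model: Gaussian noise, clamp to [0,1], censor below threshold."""
    noisy = true_loads + rng.normal(0.0, noise_sd, size=np.shape(true_loads))
    noisy = np.clip(noisy, 0.0, 1.0)
    noisy[noisy < detection_threshold] = 0.0
    return noisy


def wright_fisher(p, N, g, n, rng):
    """Final allele frequencies of ``n`` independent WF lineages (N units, g generations)."""
    freq = np.full(n, float(p))
    for _ in range(g):
        freq = rng.binomial(N, freq) / N
    return freq


def simulate_offspring(config: DriftSimConfig) -> SyntheticCohort:
    """Draw an offspring cohort by binomial resampling of ``N`` units over ``g`` generations.

    True loads are the post-drift frequencies; measured loads add assay noise
    and detection-threshold censoring.  Reproducible under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    true = wright_fisher(config.p, config.N, config.g, config.n_offspring, rng)
    measured = _measure(true, config.noise_sd, config.detection_threshold, rng)
    return SyntheticCohort(
        true_loads=true,
        measured_loads=measured,
        config=config,
        b=config.b,
        seed=config.seed,
    )


def simulate_single_cells(p, copies_per_cell, n_cells, noise_sd=0.017, seed=DEFAULT_SEED):
    """Single-cell mutant loads within one pool.

    Each cell carries ``Binomial(copies_per_cell, p) / copies_per_cell`` mutant
    molecules (the binomial partition of mtDNA copies at cell division), plus
    measurement noise, clamped to [0, 1].
    """
    if copies_per_cell < 1:
        raise ValueError("copies_per_cell must be >= 1")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    loads = rng.binomial(int(copies_per_cell), float(p), size=n_cells) / copies_per_cell
    loads = loads + rng.normal(0.0, noise_sd, size=n_cells)
    return np.clip(loads, 0.0, 1.0)


def simulate_blastomere_replicates(
    cohort: SyntheticCohort,
    k: int = 2,
    within_sd: float = DEFAULT_WITHIN_SD,
    seed: int | None = None,
) -> SyntheticCohort:
    """Attach ``k`` replicate (blastomere-style) measurements per offspring.

    Replicates scatter around each offspring's true load with SD ``within_sd``
    (intra-embryo agreement); they are clamped to [0, 1] but not censored, as
    replicate pairs are only taken on embryos already scored.  With the default
    ``within_sd`` a drift cohort with between-embryo SD around 0.23-0.25 yields
    a one-way ICC of about 0.994.
    """
    if k < 2:
        raise ValueError("need k >= 2 replicates")
    if within_sd < 0:
        raise ValueError("within_sd must be >= 0")
    use_seed = cohort.seed + 1 if seed is None else seed
    rng = np.random.default_rng(use_seed)
    reps = cohort.true_loads[:, None] + rng.normal(
        0.0, within_sd, size=(cohort.n_offspring, k)
    )
    return replace(cohort, replicates=np.clip(reps, 0.0, 1.0))
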