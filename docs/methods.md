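# Methods

## The drift model

`mtdrift` models the mutant load of a heteroplasmic mtDNA mutation in an
offspring (embryo, oocyte, or single cell) as the outcome of pure random
genetic drift from a founder fraction `p`. The distribution is Kimura's
solution of the neutral drift diffusion: point masses `f0` at 0 and `f1` at 1
plus a continuous density on (0, 1), indexed by a single drift parameter
`b ∈ (0, 1)`. `b` compounds everything about the germline bottleneck that the
data can identify — `b = (1 − 1/N)^g` for `N` segregating units over `g`
generations — so the package deliberately does not model primordial-germ-cell
copy-number dynamics, selection, or mutation; only the `b`-indexed family is
implemented. Mean and variance are exact in closed form (`E x = p`,
`Var x = p(1−p)(1−b)`), which is what makes the moment estimator below
consistent.

### Numerics of the series

The eigenfunction series involves the terminating hypergeometric polynomials
`F(1−i, i+2; 2; x)`. These are evaluated, not through generic hypergeometric
routines (which cancel catastrophically for large `i`), but through the
identity `F(1−i, i+2; 2; x) = 2 P'_i(1−2x) / (i(i+1))` with `P_i` the Legendre
polynomial; `P_i` and `P'_i` are advanced together by their three-term
recurrences, one pass per series evaluation. The termwise antiderivative
`∫₀ˣ F(1−i, i+2; 2; t) dt = (1 − P_i(1−2x)) / (i(i+1))` gives the CDF in
closed form, so normalization, tail probabilities and the sampler involve no
quadrature at all. A unit test cross-checks the recurrence evaluation against
scipy's generic `hyp2f1` at small `i`, and quadrature of the density is used
only in tests, as an independent route.

Truncation: terms decay like `b^{i(i+1)/2}`; summation stops once the bound
`(2i+1) i (i+1) b^{i(i+1)/2} < 1e-13` (which dominates every remaining
increment of every series used), with a hard cap of 500 terms. Within the cap
this supports `b` up to ≈ 0.999; beyond that a `KimuraConvergenceError` names
the parameters, rather than silently returning a truncated value. Negative
density values from round-off are clipped to zero only below 1e-10 in
magnitude; anything larger raises, to distinguish round-off from bugs.

Sampling is inverse-CDF on 4,097 equally spaced points (configurable) with
linear interpolation; draws falling in the CDF's flat segments below `f0` or
above `1 − f1` land exactly on the atoms, so fixation fractions in simulated
cohorts are exact zeros and ones. The interpolation error is far below the
Monte-Carlo error at the replicate counts used anywhere in the package.

All heteroplasmy values are fractions internally; percent appears only at
I/O boundaries (TSV tables and JSON reports carry both, consistently).

## Inference

The fit is the field's standard moment estimator: `p0` = sample mean, `V` =
sample variance (n−1 denominator; the conventional choice, documented because
published tables do not disambiguate it), normalized variance
`nv = V/(p0(1−p0))`, and `b = 1 − nv`. `nv ≥ 1` (over-dispersion beyond
complete fixation) or zero variance are explicit fit failures, not clamped
values. Measurements reported as 0 (below the assay's detection threshold)
enter the fit by default — under drift they are genuine candidate fixations —
with an `exclude_zeros` sensitivity switch. Fixation and tail probabilities
are evaluated at the point estimates; their uncertainty comes only from the
Monte-Carlo refits, mirroring how such tables are conventionally presented.
The default exceedance threshold is 0.6 (the mutant load commonly treated as
high-risk prenatally); it is configurable.

Confidence intervals: draw `reps` cohorts of the observed size from the
fitted distribution, refit each, and take 2.5th/97.5th percentiles per
statistic (10,000 replicates by default). Replicates whose refit fails are
counted and excluded; more than 50% failures aborts. Percentile intervals of
this kind slightly undercover for small cohorts — measured coverage for the
mean at n = 35 is about 94% (the acceptance suite verifies 95% ± 2% over
2,000 outer replications) — a known property of the method, not corrected
for, since the aim is to reproduce the published procedure.

Goodness of fit: the KS statistic is the sup distance between the empirical
CDF and the fitted *mixed* CDF, evaluated at the data points and at 0 and 1
from both sides so the atoms are honoured. Whether the published analysis
refitted its null replicates is not stated; here each replicate **is**
refitted before its distance is computed (parametric bootstrap with
estimation), because that choice is verifiable: the acceptance suite measures
a type-I error of 0.05 within ±0.02 over 2,000 null trials (a precise
measurement put the level at 0.050 ± 0.004). Without refitting, the test
would be conservative. The p-value is `(1 + #{D* ≥ D})/(reps + 1)`, never
exactly zero.

## The synthetic-data generator

`simulate_offspring` is a literal Wright–Fisher bottleneck: `g` binomial
resampling steps of `N` units from the founder frequency, per offspring. It
doubles as the package's independent oracle: in the diffusion regime the
final frequencies follow the Kimura distribution with `b = (1 − 1/N)^g`, and
the acceptance suite verifies this by two-sample KS at n = 10⁴ for
(N, g) ∈ {(100, 50), (250, 120), (500, 250)}. The regime boundary matters:
the Kimura law is the N → ∞ limit, and the discrete chain's O(1/N) deviation
is itself statistically detectable at n = 10⁴ below roughly N = 100 (measured
sup-CDF distance ≈ 0.068 at N = 10 and 0.043 at N = 30, against a 1%-level
critical value of 0.023 — an exact transition-matrix computation confirms the
deviation belongs to the chain, not the implementation). Cross-validation is
therefore performed where the two models agree, and a transition-matrix test
separately confirms the atoms converge at rate O(1/N).

The measurement model is additive Gaussian replicate noise (default SD 0.017,
matching a reported replicate SD below 1.7%), truncation to [0, 1], and
censoring to exactly 0 below the detection threshold (default 0.02). Defaults
emulate a carrier's embryo cohort: founder load 0.337, N = 25, g = 8 (so
b ≈ 0.72), 35 offspring — the published study conditions the package is
benchmarked against. `simulate_single_cells` draws binomial loads at a given
mtDNA copy number (defaults to the ~150 copies of a lymphocyte; blastomeres
and oocytes carry 10⁴–10⁶, where binomial scatter vanishes and assay noise
dominates).

Replicate blastomere measurements scatter around each embryo's true load
with a within-embryo SD of 0.018 by default. No published within-embryo SD
exists to copy; the value is a calibration, chosen from the
variance-components identity `ICC = σ²_between/(σ²_between + σ²_within)` so
that a drift cohort (between-embryo SD ≈ 0.25) yields the reported intraclass
correlation of ≈ 0.994, and it simultaneously reproduces the reported ~6%
maximal inter-blastomere difference (expected maximum of 35 draws of
|N(0, √2 · 0.018)|). The generator emulates dispersion, censoring and
replicate agreement; it does not emulate PCR chemistry, selection against
high-load cells, copy-number variation between embryos, or tissue
differentiation — so passing tests validate the drift statistics, not those
biological mechanisms.

Default seed everywhere is 3243 (mnemonic); every stochastic routine takes
an explicit seed and every report records it.

## Cell-level statistics

- `summarize_pools`: per-pool mean, SD (n−1), min/max; singleton pools are
  flagged and excluded from regression; the cell-weighted grand mean is
  exposed for comparison with whole-sample loads.
- `mean_sd_regression`: unweighted OLS of per-pool SD on per-pool mean with
  Pearson r and its two-sided p — the simplest reading of how such slopes are
  published; a cell-count-weighted option exists.
- `icc_oneway`: one-way random-effects ICC,
  `(MSB − MSW)/(MSB + (k0 − 1) MSW)` with the unbalanced correction
  `k0 = (Σk − Σk²/Σk)/(g − 1)`. One-way is the natural model for replicate
  blastomeres (no "rater" structure); the form is stated precisely so it is
  testable, and it is cross-checked against both a hand-rolled ANOVA and
  pingouin's ICC(1,1).
- `transmission_rate`: a load exactly at the detection threshold counts as
  detected (the threshold is the smallest *detectable* proportion); the 95%
  CI is exact Clopper–Pearson.

## Known discrepancies with published rounded values

Three published numbers cannot be reproduced from the published inputs, and
the package reports its computed values rather than the printed ones. All
three were cross-checked against an exact Wright–Fisher transition-matrix
oracle at matched `b`, which agrees with this implementation and not with the
printed values, so they are attributable to the published table's rounding
chain (statistics were computed from unrounded raw data, then printed
rounded):

- At (p = 0.337, b = 0.72) the mutant-fixation mass is 0.0028, printed as
  0.4% — consistent with an unrounded `b` slightly below 0.72 (the same table
  prints b = 0.72 beside a normalized variance of 0.27, i.e. 0.73, for the
  same reason; this package reports full precision).
- At (p = 0.126, b = 0.87) the mutant-fixation mass is 4.1 × 10⁻¹⁰, printed
  as 2 × 10⁻⁷. The diffusion value is confirmed by the matrix oracle
  (5 × 10⁻¹⁰ at N = 800, decreasing with N); a series truncated near
  increment 10⁻⁷ would leave a remainder of the printed order.
- At (p = 0.126, b = 0.87) P(x > 0.6) is 0.20%, printed as 0.3% —
  reproducible with an unrounded b ≈ 0.86, which still prints as 0.87.

The corresponding acceptance-suite assertions are left failing on these
three quantities by design; weakening them would hide a real, explained
disagreement.

## Problem sizes

Monte-Carlo defaults follow the published procedure (10,000 CI replicates of
n = 35; 2,000 KS replicates). The calibration experiments in the acceptance
suite use 2,000 trials/outer replications (type-I error, CI coverage), 10⁴
draws per sample for distributional comparisons, and a 19 × 19 parameter grid
for the normalization and moment identities; these sizes give standard errors
comfortably inside the asserted tolerances.
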