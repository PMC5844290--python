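# Methods

## The probability model

The package's core is the classical Luria–Delbrück mutant-count
distribution in its Lea–Coulson form. Cultures grow deterministically
from *N*₀ to *N*ₜ cells; mutation events occur Poisson with mean
*m* = μ(*N*ₜ − *N*₀); each event founds a clone whose final size follows
*P*(*C* = *k*) = 1/(*k*(*k*+1)), *k* ≥ 1 (the size law implied by
exponential growth with mutants growing at the wild-type rate); the
plated count is the sum of clone sizes. The pmf is tabulated by the
Ma–Sandri–Sarkar recursion `p_0 = e^{-m}`,
`p_r = (m/r) Σ_{i<r} p_i/(r-i+1)`; the tail mass `P(R > r_max)` is taken
as the exact complement `1 − Σ p_r` rather than by extending the
recursion, so tables always sum to one and censored likelihood
contributions are exact.

Assumptions inherited from this model, and therefore by everything
downstream: no phenotypic lag, no differential mutant fitness, no cell
death, fully plated (or pre-scaled) cultures. Partial plating is carried
through the data model (`plated_fraction`) and applied by the simulator
as binomial thinning, but the estimators do not correct for it — they
warn instead. These are the standard idealisations of the assay; the
package is explicit rather than silent about them.

Numerics: the recursion is evaluated in linear double precision. This is
accurate over the whole practicable range (`p_0` underflows only near
*m* ≈ 745, while assay designs live at *m* ≲ 100); no log-space path is
needed. Likelihood evaluations cap tabulation at a jackpot-censoring
threshold (default 10⁴) and treat larger counts as right-censored via the
exact tail mass, which bounds cost at O(cap²) per evaluation without
biasing the fit.

## Estimators

- **Median method** (`median_lc`). Solves `r̃/m − ln m = 1.24` for the
  sample median count r̃ by bracketed Brent root-finding (relative
  tolerance 1e-12; the left side is strictly decreasing so the root is
  unique). Undefined at r̃ < 1; callers are directed to `p0`/`mle`. The
  even-n median is the mean of the two central order statistics. An
  alternative reading — per-culture single-count conversions followed by
  the median — is available (`per_culture=True`); both orderings select
  the same order statistics and differ only through the nonlinear map.
- **Median CI.** Distribution-free order-statistic interval: the largest
  rank *k* with `P(X < k) ≤ (1−level)/2`, `X ~ Binomial(n, ½)`, computed
  from binomial tails directly for any *n* (no table lookup); at n = 18
  and 95% this selects ranks (5, 14) with achieved coverage 0.9691. The
  achieved (conservative) confidence is reported. The interval endpoints
  (counts) are mapped through the median equation to rate bounds; the
  mapping is monotone, so ordering is preserved. Requires n ≥ 6.
- **p0.** `m = −ln(P̂0)` with Clopper–Pearson limits on `P̂0` mapped
  through the log; applicable only when zero-count cultures exist.
- **MLE.** Bounded scalar minimisation of the negative MSS log-likelihood
  over log *m* (geometric probe spacing keeps the search off the
  underflow plateau at implausibly large *m*) with bracket expansion,
  then profile-likelihood limits at a drop of
  `χ²₁(level)/2` (1.92 at 95%) found by Brent root-finding on each side;
  all-zero data sit at the *m* = 0 boundary with upper limit `1.92/n`.
- `auto` dispatches: median method when r̃ ≥ 1, else p0, else the *m* = 0
  boundary — the chain is exhaustive for integer counts.

Rates are normalised per cell, μ = *m*/*N*ₜ (not per generation, which
would divide by a further ln 2; only relative rates are used downstream,
so the constant cancels).

## Comparisons

Rank-sum tests (Wilcoxon–Mann–Whitney) run on culture-level mutant
counts when the two experiments share *N*ₜ and on per-culture
frequencies otherwise; ranks are scale-invariant, so the choice is
immaterial at shared *N*ₜ. The exact U distribution is enumerated when
both samples have n ≤ 12 without ties; otherwise the normal
approximation with tie and continuity correction is used. No
multiple-testing correction is applied by default (raw p-values, as is
conventional for these panels); Benjamini–Hochberg is available where
matrices of tests are produced.

Fold changes, dominance ratios and interaction indices get percentile
bootstrap intervals (default 2000 draws) that resample cultures — the
independent experimental unit — with replacement within each strain,
re-estimating via the `auto` chain per resample. Bootstrap streams are
keyed by each strain's label (SHA-256 of `(strain_id, reporter)` mixed
into the seed), which makes results reproducible, independent of panel
ordering, and the synergy test exactly symmetric under transposition of
the two single mutants.

Calls are operationalised as: **mutator** iff fold > 1 and rank-sum
p < α; **recessive** iff the heterozygote is not significantly above the
wild-type diploid; **dominant** iff the het/hom ratio CI lies above 0.75;
**semidominant** otherwise (the expected case being a ratio CI containing
0.5 — two gene copies contributing equally); **synergistic** iff the
interaction index `fold_ab/(fold_a·fold_b)` has a CI lower bound above 1,
**sub-multiplicative** iff the upper bound is below 1. The multiplicative
null is the standard epistasis convention for mutation rates; thresholds
are module constants and keyword arguments, not magic numbers. Where the
design was genuinely open — whether to test counts or rates, which
two-sided Fisher convention to use, which association statistic — the
defaults are the field-standard choices and the alternatives are exposed
as options.

## Incidence arm

Variant frequency is occurrences over the number of tumors whose
corresponding exon was sequenced; pooling across studies or cancer types
sums numerators and denominators (associative by construction). Pairwise
tests are two-sided Fisher exact tests under the "sum of all tables no
more probable than observed" convention (delegated to scipy, which the
test suite verifies against exact rational enumeration for every table
with margins ≤ 30). The mutator-strength/frequency association is the
Spearman rank correlation of log fold against log frequency, with an
exact full-permutation p-value for n ≤ 9 pairs and the asymptotic p
beyond.

## The simulator

The generator is the exact generative twin of the pmf: Poisson event
counts, clone sizes by inverse transform `C = floor(1/U)` (truncated at
*N*ₜ, which lumps the tail mass `1/N_t` at *N*ₜ — the truncated mean is
the harmonic number `H_{N_t}`), optional binomial thinning for partial
plating. It refuses designs with μ·*N*ₜ > 10⁶, whose jackpots would
exceed tabulation limits. A deliberately small-scale, mechanistically
independent oracle (explicit binary fission for ≤ 14 generations, each
daughter mutating independently, mutant lineages breeding true) validates
the compound draw at matched means.

The `paper_panel` preset emulates a cancer-variant mutator survey in
yeast: wild-type forward-mutation rate 3 × 10⁻⁸ per cell (*m* = 3 at
*N*ₜ = 10⁸ — a typical yeast CAN1-scale design; *N*ₜ is a configurable
assumption, not a measured value), an exonuclease-null benchmark at 7×,
variants at 2×/6×/20×/100×, a diploid trio with the heterozygote at the
midpoint of wild type and a 40× homozygote, an MMR-null arm at 25× in
which one weak variant (3× alone) synergises with interaction index 10
while two variants are neutral passengers, and 18 cultures per strain.
Master seed → per-strain streams are derived by stable hashing, so
extending a panel never perturbs existing strains' draws.

What the simulator does **not** emulate: colony-count measurement error,
plate-to-plate variation, viability differences between mutant classes,
phenotypic lag, or variation of *N*ₜ between cultures of one strain.
Passing tests therefore demonstrate correctness of the statistical
machinery under the model's own assumptions, not robustness to those
real-data complications.

## Validation study sizes

The test suite and `scripts/acceptance.py` use: pmf-vs-convolution
agreement at *m* ∈ {0.5, 1, 2.5, 5, 10} up to r = 50 (tolerance 1e-10);
10⁵ cultures per goodness-of-fit comparison (α = 0.01) and for the
jackpot dispersion ratio; 200 replicate experiments (18 cultures,
*m* = 10) for estimator error and for 2×/10×/100× fold recovery; 10⁴
experiments for median-CI coverage; 2000 null simulations for rank-sum
type-I error; all 2×2 tables with margins ≤ 30 for Fisher calibration;
100 null and 200 synergistic quartets (18 cultures per arm, folds 3 and
25, ten-fold excess for the power arm) for the synergy logic; and 200
diploid trios (24 cultures, 20×/40× folds) for semidominance. These sizes
give Monte-Carlo error comfortably below the decision margins while
keeping a full run to a few minutes on one CPU.

## Known limitations

- No plating-efficiency correction in the estimators (documented warning).
- The median-method CI maps count order statistics through the median
  equation; for a lower interval endpoint of 0 the equation's continuous
  extension (`−ln m = 1.24`) is used.
- Percentile bootstrap intervals for ratios of small experiments (n = 18)
  can undercover modestly; the dominance/synergy calls inherit that.
- The exact rank-sum path requires tie-free data and so rarely engages on
  raw counts; count data go through the tie-corrected approximation.
- Fluctuation-assay extensions (phenotypic lag, differential mutant
  fitness, death during growth) are out of scope.
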