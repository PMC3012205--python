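# Methods

## Model and assumptions

The package analyses a two-way classification of families: schizotypal
vs. non-schizotypal, and (within schizotypal families) high- vs.
low-fitness, with prior probability `p_low` of the low-fitness class.
The analytic model rests on three assumptions:

1. diagnosable psychotic conditions are negligibly rare outside
   schizotypal families;
2. genetic fitness is symmetrically distributed across families, so the
   default prior is `p_low = 0.5` (other priors are supported as an
   explicit generalization of the symmetric model; all headline numbers
   assume 0.5);
3. the per-member diagnosis probability is `r` times higher in
   low-fitness than in high-fitness schizotypal families, `r ≥ 1`.

All fertilities are *relative*: mean offspring count divided by the
population mean offspring count, so the population reference is 1.
The model is parameterized by `(r, d, W, p_low)` with class means derived
as `W_H = W + p_low·d`, `W_L = W − (1 − p_low)·d`. This
parameterization, rather than `(W_H, W_L)`, is canonical because the
headline quantities (bias, flip window) are expressed directly in `W`
and `d`; the class means are exposed read-only. Construction rejects
`r < 1`, `d < 0`, priors outside (0, 1) and any combination with
`W_L < 0` (a negative fertility is meaningless).

The fertility difference `d` deliberately subsumes the fertility cost of
the disorder itself: patients are *included* in family fertility means,
both analytically and in the estimators. `r = 1` is representable so the
degenerate no-signal case can be exercised; strict positivity of the
bias is claimed only for `r > 1, d > 0`.

## Key quantities and numerical choices

- Posterior class probability of a patient's family:
  `P(L|D) = r·p_low/(r·p_low + 1 − p_low)`. The baseline diagnosis
  probability cancels; tests verify this against exhaustive four-cell
  joint-table enumeration at several baselines.
- Underestimation bias: implemented in the factored form
  `d·p_low·(1 − p_low)·(r − 1)/(r·p_low + 1 − p_low)`, algebraically
  equal to `d·(P(L|D) − p_low)`. The factored form is exactly zero at
  `r = 1` or `d = 0` in floating point, which the mixture form
  `P(H|D)·W_H + P(L|D)·W_L` is not; the estimated fertility is therefore
  computed as `W − bias`, making the consistency identity
  `Ŵ = W − bias` exact, and the posterior-weighted mixture serves as the
  independent cross-check (asserted to 1e−12 in tests).
- Regime labels use a neutrality band of half-width `tol = 0.01`
  relative-fertility units around 1, because exact neutrality is
  measure-zero under floating point. `flip_condition` takes the same
  tolerance (default 0 for the exact window `1 ≤ W < 1 + bias`); sweeps
  pass one tolerance to both paths so label-based and threshold-based
  flags agree cell by cell.

## Synthetic populations

`simulate_population` draws independent families: schizotypal with
probability `prop_schizotypal`; schizotypal families low-fitness with
probability `p_low`; each member diagnosed independently
(`p_diag_high`, `r·p_diag_high`, or `p_diag_nonschizotypal`); offspring
counts Poisson with mean `base_mean_offspring` times the class relative
fertility. Defaults, with rationale:

- `family_size = 5`, fixed: the algebra treats members exchangeably, and
  a fixed size keeps the proband-weighting relations transparent.
  Random family sizes are a possible extension, not implemented.
- `p_diag_high = 0.01`: order of lifetime prevalence. The closed forms
  are invariant to it; it only needs to be small enough that multiple
  diagnoses per family are rare.
- `p_diag_nonschizotypal = 0`: diagnosable conditions negligibly rare
  outside schizotypal families (assumption 1); validated to be strictly
  below `p_diag_high` when nonzero.
- `prop_schizotypal = 0.2`: "schizotypal" denotes the upper tail of a
  descriptive family-level classification; a 20% tail is a realistic
  operationalization and the closed forms do not depend on it.
- `base_mean_offspring = 2.0`: replacement-level fertility; only the
  scaling from relative fertility to counts.
- Poisson offspring: the model constrains only class *means*, so a
  mean-parameterized minimal-assumption count law is used. It is
  swappable in principle (any law with the right class means leaves the
  estimands unchanged).
- Diagnosis and fertility are independent *within* class:
  all fertility effects route through class membership, since `d`
  already includes the fertility cost of diagnosis. An optional
  `diagnosed_fertility_factor` multiplies diagnosed members' expected
  offspring for sensitivity analyses; it defaults to 1 (off).

What the generator does **not** emulate: pedigree structure beyond flat
families, assortative mating, genotypes or allele dynamics, variable
family sizes, within-family correlation of fitness beyond the shared
class, or the extra-pair-conception pathway (noted qualitatively in the
literature but with no computation defined). Passing tests therefore
demonstrate internal consistency of the closed forms under the model's
own assumptions, not unbiasedness of real family studies.

## Estimation

- Proband-wise ascertainment (default): every diagnosed individual is a
  proband, so a family enters the sample once per diagnosed member. This
  is the exact-information version of drawing patients uniformly and is
  the conditioning under which the empirical low-fitness fraction
  converges to `P(L|D)`; an `n_probands` option resamples patients
  uniformly with replacement instead. Family-wise ascertainment (any
  family with ≥ 1 patient, once) is provided for comparison but diverges
  from the posterior when families can hold multiple patients.
- Both estimands are ratio estimators with the whole-population mean
  offspring in the denominator. When `W ≠ 1` the realized population
  mean is `m = prop_schizotypal·W + (1 − prop_schizotypal)` rather than
  1, so the estimators converge to `W/m` and `Ŵ/m`; the Monte-Carlo
  comparison divides the analytic references by `m` (at the headline
  setting `W = 1`, `m = 1`).
- Standard errors: nonparametric bootstrap (default 500 resamples) over
  families — families, not individuals, are the independent units. For
  the ascertained estimate, numerator draws and population denominator
  are resampled independently.
- Monte-Carlo validation (`compare_analytic_mc`) runs
  simulate → ascertain → estimate over independent replicates with
  child seeds derived from one master seed via `numpy` `SeedSequence`,
  and brackets each analytic value with a normal-theory CI of the
  replicate mean (supported levels 0.90/0.95/0.99; z-quantiles are
  hard-coded to avoid a scipy dependency).

## Problem sizes

The validation experiment reported by the test suite uses 200 replicates
of 10,000 families (≈ 10⁷ simulated individuals in total), which places
the 99% CI half-widths near 0.002–0.007 relative-fertility units —
narrow enough to detect any systematic error in the closed forms while
running in a few seconds. Property-based suites use 200 randomized
parameter draws per property, derandomized for reproducibility.

## Known limitations

- The model quantifies the *direction* and closed-form *size* of the
  bias under its own assumptions; it provides no correction estimator
  for real study data (none exists in this framework).
- The flat-family simplification ignores how real studies weight
  different relative classes (parents, siblings, offspring).
- Binary fitness classes are a coarse stand-in for a continuous fitness
  distribution; `r` and `d` absorb everything about its shape.
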