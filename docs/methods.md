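# Methods

## Model

The CBMN dose-response is modelled as a linear-quadratic yield curve

    y(D) = c + αD + βD²,

where *y* is the expected number of micronuclei per binucleated cell at
absorbed dose *D* (Gy), *c* ≥ 0 the spontaneous MN frequency, *α* ≥ 0 the
single-track (linear) and *β* ≥ 0 the two-track (quadratic) radiation
response. Per-cell MN counts are treated as Poisson; real pooled CBMN data
are mildly overdispersed (dispersion index up to ~1.12 at background), and
that overdispersion is deliberately ignored in fitting, as is conventional
in cytogenetic biodosimetry.

## Calibration fitting

With N_i scored cells and M_i total MN at dose D_i, the aggregated Poisson
log-likelihood

    L(c, α, β) = Σ_i [ M_i ln λ_i − N_i λ_i ],   λ_i = c + αD_i + βD_i²,

is maximised over the non-negative orthant with L-BFGS-B, started from the
unweighted least-squares solution on the observed yields M_i/N_i clipped to
≥ 10⁻⁶. Aggregated counts are sufficient for (c, α, β) under the Poisson
model, so per-cell histograms and per-dose totals give identical fits.
Tolerances (ftol 10⁻¹⁵, gtol 10⁻¹⁰) sit far below the precision of any
reported coefficient. The coefficient covariance is the inverse observed
Fisher information I_jk = Σ_i N_i x_ij x_ik / λ_i with x_i = (1, D_i, D_i²);
its diagonal gives the standard errors. At least three distinct doses are
required; all-zero MN totals are rejected as degenerate.

The packaged pooled fully-automated table is fitted to
c = 0.0179, α = 0.0235, β = 0.0081 — within one published standard error of
the reference equation. The fitted standard errors are smaller than the
published ones, which is expected: the published fit weighted per-donor
curves whose between-donor spread exceeds pure Poisson error, while this
fit sees only the pooled counts. Coefficient agreement, not SE agreement,
is therefore the reproduction criterion.

## Dose estimation

The point dose inverts the curve at the observed yield y = M/N:
D = (−α + √(α² + 4β(y − c))) / (2β) for β > 0, (y − c)/α for β = 0;
yields at or below background map to 0 Gy (negative doses are physically
meaningless).

The 95% limits merge the two error sources by the curve-crossing
construction:

1. exact (Garwood) Poisson limits on M — lower ½χ²₀.₀₂₅(2M) (0 when M = 0),
   upper ½χ²₀.₉₇₅(2M+2) — divided by N give yield limits (y_L, y_U); a
   normal approximation is available behind `poisson_method="approx"`;
2. the curve band y(D) ± 1.96·√(x'Σx), x = (1, D, D²), from the fitted
   covariance Σ;
3. the lower dose limit is the smallest D where the *upper* band reaches
   y_L (0 if the band at D = 0 already exceeds it); the upper limit is
   where the *lower* band reaches y_U. Crossings are bracketed by Brent's
   method on [0, D_max] to 10⁻⁹ Gy.

D_max defaults to 10 Gy; a limit beyond it raises an error rather than
extrapolating silently, and any point estimate above the curve's maximum
calibrated dose carries an `extrapolated` flag. Triage uses the point
estimate only, with the cutoff dose itself classed low (the clinical
category is "at most 1.5 Gy").

## Scoring errors

All three automated-scoring error rates are percentages of the total scored
BN cells at a dose point: false-positive BN (auto-selected cells a human
rejects), false-positive MN (auto-counted MN rejected on inspection) and
false-negative MN (MN found only on complete re-scoring). Corrections
operate on totals: semi-automated mode removes the false positives, manual
mode additionally restores the false negatives. Because no record exists of
*which* cells gained or lost MN, the histogram adjustment is a deterministic
convention — MN removals demote cells from the lowest occupied positive
class first, additions promote from the lowest occupied class first, and
rejected BN cells are taken from the 0-MN class (over 97% of cells are
class 0 at every dose, so this is the overwhelmingly likely case). Any
total-preserving rule is admissible; a deterministic one is testable.

The dose-dependent error model interpolates the per-dose rate grid
piecewise-linearly with constant extrapolation beyond the ends. The printed
rates are sparse and non-monotone below 1 Gy, so fitting a smooth trend
would impose structure the data do not support.

Because the published false-positive MN range (0.72–1.50%) excludes the
0 Gy row (0.67%) while other summaries include it, `summarize_error_table`
reports ranges both with and without the unirradiated point.

## Synthetic data

The generator's defaults emulate the reference study design: nine doses
(0–4 Gy), ~18,000 cells per dose, manual-mode generating coefficients,
Poisson per-cell counts. Options:

* **overdispersion** — a gamma-mixed Poisson (negative binomial) with shape
  λ/(DI−1), hitting a target dispersion index (default 1.1, within the
  1.03–1.12 band of real data) at the generating mean;
* **donor heterogeneity** — per-donor multipliers on the background *c*
  (e.g. 1.4 for female donors, reflecting the reported higher spontaneous
  MN frequency in women), with cells split evenly across donors and pooled;
* **scoring corruption** — binomial draws against the error model's rates
  at each dose: missed MN are removed from randomly chosen MN-bearing cells
  (capped at the MN present; the cap is recorded, not raised), spurious MN
  are added to randomly chosen cells, spurious BN cells join the 0-MN class
  carrying no MN. Each corruption returns the inspection record that
  exactly undoes it, making the correction round trip testable by
  construction;
* **blind samples** — coded observations at configured doses with a truth
  key.

All randomness flows from one integer seed through a single
`numpy.random.Generator`; identical configurations give identical outputs.

What the simulator does *not* model: image-level artefacts (corruption acts
on aggregate rates, not cell images), donor variance components beyond the
baseline multiplier, age/smoking covariates, and partial-body or protracted
exposures. Passing tests on synthetic data therefore demonstrate the
statistical machinery — not the imaging pipeline — and say nothing about
scorer-specific biases beyond the three tabulated rates.

## Numerical and design choices

* Sample variance in the dispersion index uses the n−1 denominator (the
  convention of the standard biodosimetry manuals; at n ≥ 16,000 the
  alternative is indistinguishable at printed precision).
* The u statistic is exposed for diagnostics but gates nothing: the
  reference workflow reports dispersion indices only.
* Dose-point containers allow a single dose (useful for I/O and summaries);
  identifiability (≥ 3 distinct doses) is enforced where it matters, at fit
  time.
* CI boundary doses count as covered in dose-accuracy reports (inclusive
  reading of "falling within the interval"); a strict mode is available.
* Delivered doses exactly at the triage cutoff count as the low class, and
  true 0 Gy samples are excluded from triage contingency tables (they have
  no defined class on the delivered axis) but included in dose-accuracy
  summaries.

## Problem sizes in the stochastic tests

Coverage of the merged-error CI is checked over 500 seeded replicates at a
true dose of 2 Gy, refitting the calibration curve per replicate from
aggregate Poisson counts at the reference scale and drawing 2,000-cell
samples (aggregate draws are distributionally identical to per-cell draws
for fitting and keep the loop fast). Parameter recovery runs 100 full
simulated studies at the reference scale. The corruption-bias check (median
fitted β lower on corrupted than clean data) uses 20 seeds at 6,000 cells
per dose — the direction of the bias is scale-free, so the smaller size
only widens the replicate spread.

## Known limitations

* The merged-error CI follows the documented curve-crossing method; the
  reference software's exact iteration is not public, so agreement is
  validated against brute-force grid oracles rather than against that
  implementation.
* Overdispersion is simulated but never fitted (no negative-binomial
  likelihood); fitted SEs are mildly anticonservative on overdispersed
  data.
* No partial-body exposure, protracted-dose (G-function) or Bayesian
  estimation.
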