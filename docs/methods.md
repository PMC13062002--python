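# Methods

## The statistical problem

Two-sample Mendelian randomisation (MR) estimates the causal effect θ of an
exposure X on a disease outcome Y using genetic variants as instrumental
variables, from summary statistics alone. For each variant j, one study
supplies the variant–exposure association β̂_Xj (SE σ_Xj) and an independent
study supplies the variant–outcome association β̂_Yj (SE σ_Yj), both as
per-allele effects: ln(OR) for binary traits, standardised coefficients for
quantitative ones. If variant j affects Y only through X (the exclusion
restriction), then β_Yj = θ·β_Xj and each Wald ratio θ_j = β_Yj/β_Xj is a
valid estimate of θ.

The motivating application is keratoconus, a progressive ectatic corneal
disease, as the case-control outcome, with metabolic (serum glucose) and
inflammatory/atopic traits (atopy, asthma, eosinophil count, rheumatoid
arthritis, inflammatory bowel disease) as exposures. The package carries
the published log-odds estimates for those analyses as reference inputs
(`mrkit.reference`), and everything else runs on synthetic data of the same
shape.

## Harmonisation

Both effect estimates must refer to the same effect allele. Variants are
matched by identifier (first occurrence wins; duplicates are logged).
Outcome records with swapped allele labels have β negated and eaf → 1−eaf;
opposite-strand records are reverse-complemented first and logged as strand
flips. Palindromic pairs (A/T, G/C) cannot be strand-resolved from labels;
policies:

* `drop_all` — remove every palindrome;
* `drop_ambiguous` (default) — drop when either study's eaf is within
  ±0.08 of 0.5 (inclusive; i.e. eaf ∈ [0.42, 0.58]), otherwise align so the
  minor-allele side agrees;
* `infer_by_frequency` — always align by minor-allele side (eaf exactly
  0.5 remains undecidable and is dropped).

The default window ±0.08 is the conservative field convention. Every
variant present in both inputs is either kept or dropped with a reason
code, so retained + dropped = overlap, and harmonising an already aligned
pair is a no-op. Allele frequencies are metadata for alignment only; no
coordinate arithmetic is performed.

## Instrument selection and strength

Per-variant variance explained is approximated as R² = 2·MAF(1−MAF)·β² and
strength as F = R²(N−1)/(1−R²). The same R² formula is applied to the
binary outcome's log-odds β (observed scale); a liability-scale conversion
is deliberately out of scope. Selection applies, in order:

1. genome-wide significance of the exposure association, p < 5×10⁻⁸
   (strict inequality; threshold configurable);
2. a Steiger-style directionality filter: keep only variants with
   R²_exposure strictly greater than R²_outcome (ties rejected).

The exposure-side MAF of the harmonised record is used for both R² values
so the comparison differs only through the effect sizes. Aggregate
strength uses a Cragg–Donald-style form, F_overall =
((N−K−1)/K)·R²_tot/(1−R²_tot) with R²_tot = Σ R²_j (independence of
instruments assumed — LD pruning is an upstream responsibility); because
aggregation conventions vary across the literature, per-SNP minimum and
mean F are reported alongside. F < 10 raises a weak-instrument flag but
never excludes a variant: strength is a diagnostic here, not a filter.

**Selection bias of the Steiger filter.** Because the filter compares
*observed* effects, it preferentially removes variants whose outcome effect
is large by chance. The induced bias is negligible while |θ|·|γ| ≪ |γ|
relative to the outcome SE, but becomes visible in simulation when |θ|
approaches 1 on the scale where exposure effects γ ≈ 0.08 and outcome SEs
≈ 0.015: at θ ≈ −0.84 roughly a quarter of valid instruments are rejected
and the IVW estimate attenuates by ~0.1. The pipeline therefore exposes
`apply_steiger` as a switch, and the calibration studies that validate the
estimators run on unfiltered instruments.

## Estimators

With ratios θ_j and weights w_j = 1/se(θ_j)² = β_Xj²/σ_Yj²:

* **IVW**: θ̂ = Σw_jθ_j / Σw_j; fixed-effect SE (Σw_j)^{−1/2}; identical to
  the weighted regression of β_Y on β_X through the origin with weights
  1/σ_Y². Heterogeneity is Cochran's Q = Σw_j(θ_j − θ̂)² on J−1 df.
* **MR-Egger**: weighted regression of β_Y on β_X with an unconstrained
  intercept, weights 1/σ_Y². Instruments are first oriented so every
  β_X ≥ 0 (negating both betas where needed) because the fit is not
  invariant to allele recoding. The intercept estimates average
  directional pleiotropy; its two-sided normal z-test is the pleiotropy
  diagnostic.
* **Simple median**: the unweighted median of the θ_j (mean of the central
  two for even J). Its SE is a parametric bootstrap (default 10 000
  resamples, seeded): each resample redraws every β_X and β_Y from
  N(observed, SE²) and recomputes the median ratio; the SE is the SD of
  those medians.

SEs default to a multiplicative random-effects model, inflating the
fixed-effect SE by max(1, sqrt(Q/df)) (df = J−1 for IVW, J−2 for Egger);
point estimates are identical under either model. The Wald-ratio SE uses
the first-order delta method σ_Y/|β_X| — the convention that makes IVW the
standard precision-weighted estimator — with an exposure-noise-aware
second-order option (`wald_ratio_exposure_aware`) available. P-values use
the normal reference (not t), matching summary-data MR practice; they are
floored at 10⁻³⁰⁰ to stay positive. Odds ratios are exp(θ̂) with CI
exp(θ̂ ± z·SE), z = Φ⁻¹((1+c)/2) = 1.959964 at 95%.

Numerical notes: IVW and the median are computed directly from their
defining formulas; the Egger fit is delegated to a weighted least-squares
routine, with its residual-scale convention undone for the fixed model and
floored at 1 for the random model. Degenerate designs (constant exposure
effects) and insufficient instrument counts (<2 for IVW, <3 otherwise)
raise typed errors.

## Synthetic data generator

The generator emulates the two-sample design: maf_j ~ U(0.05, 0.5)
(instruments are common variants), γ_j ~ N(gamma_mean, gamma_sd),
pleiotropy α_j = 0 / N(0, α_sd) / N(α_mean, α_sd) for none / balanced /
directional modes (γ and α independent, so InSIDE holds; balanced enforces
α_mean = 0), true outcome effect θγ_j + α_j. Sampling SEs use the standard
approximations se_X = (2·maf(1−maf)·N_X)^{−1/2} and se_Y =
(2·maf(1−maf)·N_Y·φ(1−φ))^{−1/2} for a case fraction φ (default 0.5);
observed effects are normal around their truths, so doubling N halves the
variance exactly. Allele labels are assigned per variant with configurable
palindromic (default 20%) and label-swapped (default 25%) fractions to
exercise harmonisation; frequencies are shared between the cohorts without
sampling noise. Defaults N_X = 200 000, N_Y = 50 000, J = 50, γ ~ N(0, 0.03)
describe a well-powered biobank-scale exposure paired with a large
case-control outcome study.

What the generator does **not** model: LD between instruments, winner's
curse from in-sample instrument discovery, frequency estimation noise,
liability-scale effects, sample overlap between studies, or
population-structure confounding. Passing tests therefore demonstrate
correctness of the estimators and plumbing under the stated model, not
robustness to those real-data complications.

`evaluate` replicates a scenario (replicate r reseeds with seed + r) and
tabulates mean bias, empirical SE, mean estimated SE, RMSE, CI coverage and
the Egger intercept rejection rate, each with Monte-Carlo SEs.

### Reference calibration conditions

`strong_instrument_scenario` freezes the conditions used by the calibration
studies and acceptance checks: J = 50, γ ~ N(0.08, 0.02), N_X = 200 000,
giving mean per-SNP F ≈ 500. At this strength the first-order
weak-instrument attenuation of IVW (≈ −θ/F) is below the Monte-Carlo error
of a 1000-replicate study, so bias checks measure implementation
correctness rather than the known delta-method approximation. Calibration
runs use bootstrap size 200 (100 where only the Egger intercept is read)
and 1000–2000 replicates; these sizes put the whole calibration suite in
the tens of seconds on one CPU while keeping Monte-Carlo SEs ≈ 0.001 on
bias and ≈ 0.005–0.007 on coverage and test size.

Measured behaviour worth knowing (all reproduced by
`analysis/04_calibration_study.py` and the test suite):

* IVW and simple-median bias are within 3 Monte-Carlo SEs of zero at
  θ ∈ {−0.722, 0, 0.263, 0.610}; IVW coverage ≈ 0.95.
* MR-Egger shows finite-sample regression dilution of order −(1 −
  I²_GX)·θ ≈ −0.03·θ under these conditions (I²_GX =
  σ_γ²/(σ_γ² + se_X²) ≈ 0.97) — a known property of Egger regression when
  instrument effects are measured with noise, not an implementation issue;
  its random-effects CIs still cover at ≈ 0.95.
* The Egger intercept test holds size ≈ 0.045 under the sharp
  no-pleiotropy null with the default random-effects model (exactly 0.050
  fixed-effect). Under *balanced* pleiotropy the multiplicative inflation
  convention is mildly anti-conservative (measured ≈ 0.067 at α = 0.05)
  because additive pleiotropy variance is not proportional to 1/w_j; this
  is the standard convention's behaviour and is documented rather than
  patched.

## Pipeline and reporting

`run_analysis` runs each configured exposure against the one outcome:
read → harmonise → significance filter → Steiger filter → diagnostics →
IVW + Egger + median → odds-ratio transform. An exposure left with fewer
than three instruments is marked "insufficient instruments" and the run
continues. The Bonferroni threshold is α/m with m the number of IVW tests
actually performed (the published twelve-test design gives 0.05/12 =
0.0042); exposures with IVW p below it are listed as significant.
Non-independence of exposures makes this conservative — no
correlation-adjusted alternative is attempted.

Reports render rows Simple median / IVW / MR-Egger / (intercept) with
estimates at 4 decimals and p-values in scientific notation below 0.001,
the formatting of published MR tables; TSV and JSON renderings carry
field-identical rows. Output contains no timestamps, and the bootstrap
seed lives in the config, so identical configurations produce byte-identical
reports. Exit status is nonzero only for configuration/I/O errors, never
for null results.

## Known limitations

* Only the three published estimator families are implemented — no
  weighted median, mode-based estimators, MR-PRESSO, multivariable MR, or
  Steiger directionality p-values.
* The published headline effects themselves cannot be recomputed without
  the per-instrument source data; the package reproduces the published
  OR/CI/p values from their reported (ln(OR), SE) pairs and validates the
  estimators on simulation instead. One published table cell (glucose,
  UK Biobank, IVW p-value) is internally inconsistent at the last printed
  digit between that source's own table (3.34E-04) and text (3.32E-04);
  recomputation gives 3.349E-04, and checks allow one unit in the last
  printed digit.
* Variant matching is by identifier only; no positional matching,
  liftover, LD-proxy lookup, or reference-panel work.
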