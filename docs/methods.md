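# Methods

## Model and assumptions

For SNP *j*, the two-sample summary-data model is

    γ̂_j ~ N(γ_j, σ_Xj²)        (exposure GWAS)
    Γ̂_j ~ N(β γ_j + α_j, σ_Yj²) (outcome GWAS, independent sample)

with β the causal effect on the log-odds (or standardized) scale and α_j a
direct ("horizontally pleiotropic") effect. All estimators assume the two
samples do not overlap, so sampling errors of γ̂ and Γ̂ are independent, and
that instruments are mutually independent after LD clumping. Standard errors
σ_Xj, σ_Yj are treated as known.

Validity of each estimator under pleiotropy:

- **IVW** requires α_j = 0 for every instrument (or balanced α with InSIDE and
  a random-effects reading).
- **MR-Egger** allows directional pleiotropy provided α_j is independent of
  γ_j (InSIDE); its intercept estimates E[α].
- **Weighted median** requires ≥ 50% of the inverse-variance weight to come
  from valid instruments.
- **Maximum likelihood / MR-RAPS** assume α_j = 0 (simple) or
  α_j ~ N(0, τ²) (RAPS with overdispersion); both honour the exposure-side
  measurement error that biases IVW toward the null with weak instruments.

## Numerical choices

- **Wald ratio SE** is first-order, σ_Yj/|γ̂_j|: exposure uncertainty is
  deliberately ignored in the weights so that Cochran's Q has its usual
  reference distribution; the estimators that model σ_X (ML, RAPS) handle it
  in the likelihood instead.
- **IVW random effects** are multiplicative with the scale floored at 1:
  SE = (Σw)^(-1/2) · max(1, √(Q/(k−1))). Heterogeneity can widen but never
  narrow the interval. With Q < k−1 (the common case on well-behaved panels)
  fixed- and random-effects results coincide.
- **Egger** re-orients every SNP so γ̂_j > 0 before fitting (the fit is not
  flip-invariant otherwise) and floors the residual SD at 1 when scaling
  parameter uncertainty; p-values use t with k−2 df. A singular design (no
  spread in γ̂) raises an estimation error rather than returning meaningless
  coefficients.
- **Weighted median** interpolates the ordered ratios at standardized
  cumulative weight p_j = (S_j − w_j/2)/S_k = 0.5; the SE is the SD over
  parametric-bootstrap redraws of (γ̂, Γ̂) (default 1000, caller-seeded).
- **Maximum likelihood** profiles the k nuisance γ_j out analytically,
  leaving −2ℓ(β) = Σ (Γ̂_j − βγ̂_j)²/(σ_Yj² + β²σ_Xj²); the 1-D optimization
  is initialized at the IVW estimate and the SE comes from the numerical
  curvature at the optimum.
- **MR-RAPS** solves the exact derivative of that profile log-likelihood,
  ψ(β) = Σ r_j (γ̂_j(σ_Yj²+τ²) + βσ_Xj²Γ̂_j)/v_j² = 0 with
  r_j = Γ̂_j − βγ̂_j, v_j = σ_Yj² + β²σ_Xj² + τ². This score has mean zero at
  the true β under measurement error — the property that defines the method —
  whereas the naive weighted score Σ γ̂_j r_j / v_j does not (it collapses to
  IVW whenever σ_X ∝ σ_Y). Overdispersion τ² ≥ 0 is estimated from the moment
  condition E[r²] = v by alternating root-finds; SEs are sandwich-form. The
  Huber/Tukey robust-loss variants are not implemented.
- **MR-PRESSO** simulates the RSS null by redrawing both γ* and Γ* and
  recomputing the leave-one-out IVW fits on each replicate; p-values use the
  (1+count)/(n_sim+1) estimator so they are never exactly 0. Outlier p-values
  are Bonferroni-adjusted across instruments. The distortion test is not
  implemented.
- **Steiger** sums z-based per-SNP r² = z²/(z²+n−2) per trait and compares
  the implied correlation magnitudes with Fisher's z for two independent
  samples. An exact tie reports direction = false with p = 1 (reachable on
  degenerate synthetic input) rather than erroring.
- **I² truncation**: I² = max(0, (Q−df)/Q), so any Q ≤ df reports exactly 0.
- **Clumping** is greedy on ascending p-value with lexicographic snp_id
  tie-break, making the instrument set independent of input row order; there
  is no distance window (r² only), and a SNP absent from the LD matrix is
  treated as independent with a warning.
- **Bonferroni thresholds** are kept at full precision internally and printed
  at 4 decimals (0.05/3 → 0.0167, 0.05/52 → 0.0010).

## Harmonization rules

Matching is by variant id only. Outcome records with swapped allele labels
are sign-flipped (frequency reflected); non-palindromic mismatches are retried
after base complementation (strand flip); anything still irreconcilable is
dropped with reason `allele_mismatch`, never silently kept. Palindromic SNPs
(A/T, G/C) with exposure effect-allele frequency strictly inside the window
(default 0.01–0.30) — or with missing frequency — are dropped: their strand
cannot be resolved. The window is applied to the effect-allele frequency as
given; whether such windows should refer to effect- or minor-allele frequency
is genuinely ambiguous in the field, and the window is a config parameter
(common practice also uses windows symmetric about 0.5, e.g. 0.42–0.58).
Palindromic SNPs kept outside the window are additionally oriented by which
side of 0.5 the two frequencies fall on. Variants below the MAF floor
(default 0.01) in either study are dropped. Every exposure SNP ends up either
retained or in the drop log with exactly one machine-readable reason. Proxy
lookup is a user-supplied id→id mapping (the user asserts r² > 0.8); no remote
LD queries are performed.

## Synthetic-data generator

`SyntheticTruth` defaults describe a well-powered two-sample design:
k = 50 instruments, n_x = n_y = 20 000, MAF ~ U(0.05, 0.5) with
σ = (2·n·maf·(1−maf))^(-1/2) on the standardized scale, and true exposure
effects γ_j ~ |N(0, 0.25²)| resampled until the per-SNP F = (γ_j/σ_Xj)²
clears the floor (default 10). Effects are half-normal because the effect
allele is coded as the exposure-increasing allele, the convention of GWAS
instrument lists; this is also what makes a *directional* pleiotropy model
actually directional after Egger's canonical orientation. The implied
per-allele effects (median |γ| ≈ 0.17 log-odds) and F statistics match strong
genome-wide-significant loci for common immune-mediated disease. Instrument
strength matters for the Monte-Carlo studies: the ratio-based estimators carry
a regression-dilution bias governed by 1 − I²_GX = σ_X²/(var(γ)+σ_X²), and
the default was chosen so that this bias sits well below the Monte-Carlo
resolution of the 400-replicate recovery study (1 − I²_GX ≈ 0.006 at these
settings). Weak-instrument scenarios are exercised explicitly by lowering
`gamma_sd`/`f_floor` rather than by weakening the default.

Pleiotropy models: `none`, `balanced` (α ~ N(0, τ²)), `directional`
(α ~ N(μ, τ²)), `outlier` (chosen indices and magnitudes; 0.12 ≈ 10 outcome
SEs at the default sample sizes). Binary-trait interpretation (log-odds)
affects labels only — the mechanics are identical on the standardized scale.

What the generator does **not** emulate: LD between instruments (the LD
matrix used by clumping is constructed separately and independently of the
effect draws), case-control ascertainment, sample overlap between the two
GWAS, allele-frequency differences between studies, winner's-curse selection
of instruments, and indels/multi-allelic variants. Passing calibration and
recovery suites therefore demonstrate correctness of the estimators under the
stated two-sample model, not robustness to those real-data complications.

## Study sizes used by the reproduction script

Exact-arithmetic checks run on 3–82-SNP constructed panels. The Monte-Carlo
studies use 400 replicates for null calibration (IVW, Cochran Q, PRESSO
global, the latter with 1000 simulations per replicate) and for recovery
(bias and CI coverage of all five estimators), 500 replicates for
Egger-intercept recovery under μ = 0.02, 100 for PRESSO outlier detection and
200 for Steiger direction recovery — sizes at which a 5% rate is estimated
with ~1% binomial SE and the whole script completes in seconds.

## Known limitations

- Real GWAS inputs with per-SNP sample sizes are reduced to mean n for the
  Steiger test.
- The confounder screen tests marginal association of each instrument with a
  single third trait; it is not multivariable MR.
- MR-PRESSO's distortion test, mode-based estimators, CAUSE-style mixture
  models, radial MR and colocalization are out of scope.
- The pipeline requires rsID overlap (optionally via a proxy map); there is
  no chromosome/position reconciliation or liftover.
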