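# Methods

## Model and assumptions

All quantities live on the log-odds (or standardized-trait) scale.  A
genetic instrument *j* is assumed to satisfy the three instrumental-
variable conditions: relevance (a real association with the exposure),
independence (no association with confounders of the exposure–outcome
relation) and exclusion restriction (no effect on the outcome except
through the exposure).  Under these, the per-SNP Wald ratio
Γ̂ⱼ/γ̂ⱼ estimates the causal effect, and the estimators differ in how
they behave when exclusion restriction fails (horizontal pleiotropy):

- **IVW** assumes all instruments valid.  Fixed-effect SE is
  1/√(Σ γ̂ⱼ²/σ_Γⱼ²); the random-effects SE multiplies this by
  √max(1, Q/(J−1)), so it never falls below the fixed-effect SE.
- **MR-Egger** allows directional pleiotropy that is independent of
  instrument strength (InSIDE).  Instruments are re-oriented so all
  γ̂ⱼ ≥ 0 before the weighted regression with intercept — without a
  fixed orientation the intercept is not identified.  SEs are scaled by
  √(Q/(J−2)) with no floor, exactly as in a standard weighted
  least-squares fit, which makes the intercept t-test exactly
  calibrated under the null; inference uses t with J−2 df.
- **Weighted median** interpolates the Wald ratio at cumulative weight
  0.5 (running sum minus half the current weight), weights γ̂ⱼ²/σ_Γⱼ²
  (first-order; second-order weights are not offered).
- **Weighted mode** maximizes a weighted Gaussian kernel density over
  the ratios.  Bandwidth is a user-scaled modified Silverman rule,
  0.9·min(sd, IQR/1.34)·J^(−1/5); a spread measure that is zero up to
  rounding is ignored so numerically tied ratios cannot collapse the
  kernel, and the density is additionally evaluated at the ratios
  themselves so narrow kernels are never missed between grid points.
- Median and mode SEs come from a parametric bootstrap that perturbs
  the per-SNP betas with their SEs (default 1000 draws, seed required).
  Outcome-side noise is drawn antithetically — each draw paired with
  its negation — which reduces Monte-Carlo variance and makes the SE
  exactly invariant under sign flips of the study.

**MR-PRESSO.**  The global statistic is the weighted sum of squared
leave-one-out residuals wⱼ(Γ̂ⱼ − β̂₍₋ⱼ₎γ̂ⱼ)²; its null distribution is
built from parametric simulations of (γ̂*, Γ̂*) around the fitted
no-pleiotropy model with the observed SEs (default 1000 simulations).
Per-SNP outlier p-values are empirical exceedance probabilities,
Bonferroni-scaled across the instruments tested.  The outlier test is
applied **iteratively** — flagged SNPs are removed and the test is
repeated on the remainder until nothing new is flagged — because a
single pass suffers masking: one gross outlier drags the leave-one-out
slope toward a second one, and in simulations with three planted
outliers a single pass recovers all three in barely half of studies
while the iterated test recovers essentially all.  The global p-value
always refers to the first, full-set pass, so iteration changes which
SNPs are removed, not the heterogeneity evidence.  A distortion test
(shift in estimate relative to re-sampled inliers) is available but
off by default.

**Mediation.**  Indirect = β_EM·β_MO (product of coefficients) with a
first-order delta-method SE and no covariance term — the two legs come
from non-overlapping two-sample estimates.  Direct = total − indirect
(difference method), so the decomposition is additive by construction.
When `use_mvmr_direct=True` (default) the mediator→outcome coefficient
comes from a multivariable IVW of the outcome on exposure and mediator
effects jointly (no intercept, weights 1/σ_Γ², residual-scaled SEs at
J−2 df); this keeps both identities — indirect equals the product of
the two steps, and total equals direct plus indirect — while using the
exposure-adjusted mediator effect.  The proportion mediated is
indirect/total on the log-odds scale, withheld and flagged
*non-causal* when total and indirect oppose in sign, and flagged
unstable when |total| < 2·SE(total) (the ratio's delta-method SE is
unreliable near a null total effect).  In an MVMR design with an
identically-zero mediator column the fit reduces exactly to the
univariable IVW of the other column.

## Instrument selection

Stages run in a fixed order — significance filter, optional
user-supplied exclusion list, greedy LD pruning, outcome-association
exclusion, harmonization, F ≥ 10 screen — and the audit trail records
exactly one disposition per candidate SNP.  Greedy pruning keeps the
most significant remaining SNP and discards everything at r² ≥ r²max
against the kept set (ties on p-value break lexicographically on
snp_id), which makes the kept set maximal.  LD is always an explicit
input matrix; the package never consults a reference panel.  Note that
with the default thresholds the F screen is vacuous: p < 5×10⁻⁸
already implies F = (β/σ)² > 29.7, so the screen only binds when the
significance threshold is relaxed below genome-wide level.

Harmonization drops palindromic (A/T, C/G) SNPs unconditionally — no
allele-frequency-based strand inference — and handles swapped and
strand-complemented allele encodings for the rest; missing effect-allele
frequency is tolerated for non-palindromic SNPs.

## Synthetic data generator

The generator emulates the statistical structure of two-sample (and
three-table mediation) GWAS summary data directly at the summary
level; there are no individual-level genotypes.  Per SNP the true
instrument effect has magnitude uniform on [0.5, 1.5]×`instrument_sd`
(default 0.1) with random sign — bounded away from zero so Wald ratios
stay well conditioned — and observed effects add independent Gaussian
noise at the configured SEs (defaults: 0.01 exposure, 0.02 outcome,
0.01 mediator, roughly the precision of biobank-scale GWAS for common
variants).  The causal chain is exposure→mediator→outcome with
β_total = β_direct + β_EM·β_MO enforced exactly; defaults
β_total = 0.2, β_EM = 0.3, β_MO = 1/3 put half the effect through the
mediator.  Directional pleiotropy α ~ N(μ_α, τ²) is assigned to a
configurable fraction of instruments, drawn independently of
instrument strength (InSIDE holds by construction) and **relative to
the exposure-increasing allele**: with a fully random orientation the
mean pleiotropic effect is unidentifiable, since the re-orientation
every estimator applies would average it to zero.  Deliberately weak
instruments use |γ| = √3·σ_γ so the expected F-statistic is 4.
Mediator-specific instruments (no exposure path, default spread 0.15)
supply the mediator→outcome leg; without them that leg would estimate
β_total/β_EM rather than β_MO, because every shared instrument affects
the outcome through both paths.  LD is exchangeable block-diagonal —
one r² per block — which is enough to exercise greedy pruning.

Not emulated: allele-frequency spectra coupled to effect sizes,
case-control ascertainment, genomic coordinates, or sample overlap
between studies.  Passing calibration on these data shows the
estimators behave as their theory predicts under the stated generative
assumptions; it does not certify behaviour under real-data pathologies
such as sample overlap or winner's curse.

Reproducibility: a master seed spawns per-replicate seeds through
NumPy's `SeedSequence`, so calibration runs are deterministic and
order-independent; identical configurations yield bit-identical
tables.

## Calibration study design

The Monte-Carlo checks in `tests/test_acceptance.py` and
`scripts/acceptance.py` use 100–1000 replicates per block with J = 30
to 100 instruments per study — sizes at which every block completes in
seconds while Monte-Carlo error stays well inside the asserted bands.
Null calibration and parameter recovery run at the default noise
levels.  Two checks are consistency properties and are evaluated in a
precise-summary-statistics regime (SEs 0.001–0.005): the weighted
median's robustness to 40% invalid instruments — its contamination
bias scales with the Wald-ratio noise (≈ 0.12 at the default SEs,
≈ 0.01 in the precise regime) and only vanishes asymptotically — and
planted-outlier detection, where a fixed ratio displacement of +1.0
must be large relative to each SNP's outcome SE to be detectable at
all.  The Egger-intercept recovery check likewise uses a small
exposure-side SE because measurement error in γ̂ leaks a fraction of
the slope into the intercept (the NOME condition of the Egger model).

## Numerical choices and degenerate inputs

- P-values are two-sided normal everywhere except Egger (t, J−2 df),
  clipped into (0, 1]; confidence intervals are normal-theory (t for
  Egger).
- Wald ratios are undefined at γ̂ = 0 and raise; bootstrap draws that
  land exactly on zero are nudged by the smallest positive float.
- Exactly collinear MVMR designs (condition number > 10¹²) raise a
  collinearity error rather than returning unstable coefficients.
- Duplicated snp_ids within one table are a hard error; silently
  keeping the first row would make results depend on row order.
- Odds ratios are exp-transformed from log-odds only at reporting
  time.

## Known limitations

- No proxy-SNP substitution, no reference-panel LD computation, no
  remote lookups of secondary phenotypes (an explicit exclusion list
  stands in for confounder screening).
- Multiple-testing correction across outcomes is off by default by
  design; a Benjamini–Hochberg column is available behind a flag.
- The MR-PRESSO distortion test is a simplified re-sampling version
  and is reported only on request.
- The weighted-mode bandwidth multiplier and median/mode bootstrap size
  are exposed because no single default suits every instrument set.
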