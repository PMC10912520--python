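# mrkit

Two-sample Mendelian randomization (MR) with two-step mediation
analysis, operating entirely on GWAS summary statistics.

MR uses genetic variants as instrumental variables to estimate the
causal effect of an exposure (for example atrial fibrillation) on an
outcome (for example a digestive-system cancer) from two independent
GWAS: per SNP *j*, an exposure association γ̂ⱼ (SE σ_γⱼ) and an outcome
association Γ̂ⱼ (SE σ_Γⱼ).  Each valid instrument gives a Wald ratio
β̂ⱼ = Γ̂ⱼ/γ̂ⱼ; the package pools them and probes the instrument
assumptions:

- **IVW** — inverse-variance-weighted pooling, β̂ = Σwⱼβ̂ⱼ / Σwⱼ with
  wⱼ = γ̂ⱼ²/σ_Γⱼ²; the random-effects variant inflates the SE by
  √max(1, Q/(J−1)) under heterogeneity (Cochran's Q).
- **MR-Egger** — the same weighted regression with a free intercept;
  the intercept estimates average directional pleiotropy and its t-test
  is the pleiotropy diagnostic.
- **Weighted median** — consistent when more than half the weight lies
  on valid instruments.
- **Weighted mode** — the mode of the smoothed weighted Wald-ratio
  density; consistent when the largest group of concordant instruments
  is valid.
- **MR-PRESSO** — a simulation-based residual-sum-of-squares global
  pleiotropy test with per-SNP outlier identification and removal.
- **Two-step mediation MR** — with a mediator M, the indirect
  (mediator-borne) effect is the product β_EM·β_MO of the
  exposure→mediator and mediator→outcome MR estimates; the direct
  effect is total − indirect, and the proportion mediated is
  indirect/total on the log-odds scale (flagged *non-causal* when the
  two oppose in sign).  The mediator→outcome step can come from a
  univariable fit on mediator instruments or from a multivariable IVW
  that adjusts for the exposure.

Instrument selection follows the standard filters, each recorded in a
per-SNP audit trail: genome-wide significance (p < 5×10⁻⁸), greedy LD
pruning (R² < 0.1 against a user-supplied LD matrix), exclusion of SNPs
associated with the outcome (p < 5×10⁻⁸), harmonization to a shared
effect allele (palindromic A/T and C/G SNPs removed), and a per-SNP
instrument-strength screen F = (β/σ)² ≥ 10.

Because real biobank-scale inputs are large and access-controlled, the
package ships a synthetic summary-statistics generator with known
ground truth (true causal effect, pleiotropy distribution, mediation
split), so every stage is testable at desk scale.  See
`docs/methods.md` for the generative model and its limitations.

## Worked example

```python
import numpy as np
from mrkit import HarmonizedStudy, ivw, cochran_q

study = HarmonizedStudy(
    snps=["rs1", "rs2"], effect_allele=["A", "A"], other_allele=["G", "C"],
    exposure_beta=np.array([0.10, 0.10]), exposure_se=np.array([0.01, 0.01]),
    outcome_beta=np.array([0.02, 0.03]), outcome_se=np.array([0.005, 0.01]),
)
res = ivw(study, random_effects=False)
print(f"beta = {res.beta:.4f}, se = {res.se:.5f}, OR = {res.odds_ratio:.3f}")
q, df, p = cochran_q(study, "ivw")
print(f"Q = {q:.3f} (df={df}), p = {p:.3f}")
```

prints

```
beta = 0.2200, se = 0.04472, OR = 1.246
Q = 0.800 (df=1), p = 0.371
```

The two SNPs have Wald ratios 0.2 and 0.3 with inverse-variance weights
400 and 100, so the pooled log-OR is (400·0.2 + 100·0.3)/500 = 0.22
with SE 1/√500, i.e. an odds ratio of 1.25 per unit exposure; Q = 0.8
on 1 degree of freedom shows no detectable heterogeneity.

The same analysis from the shell, on simulated tables:

```sh
mrkit simulate --n-snps 50 --seed 5 --out sim/
mrkit select --exposure sim/exposure.tsv --outcome sim/outcome.tsv --out sel/
mrkit mr --harmonized sel/instruments.tsv --out mr.tsv
mrkit diagnose --harmonized sel/instruments.tsv --out diag/
mrkit mediate --exposure sim/exposure.tsv --outcome sim/outcome.tsv \
      --mediator HF=sim/mediator.tsv --out med/
```

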