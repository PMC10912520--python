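"""Causal-effect estimators for two-sample Mendelian randomization.

All estimators consume a :class:`~mrkit.summary_io.HarmonizedStudy` with
per-SNP exposure effects ``gamma_j`` (SE ``s_gx_j``) and outcome effects
``Gamma_j`` (SE ``s_gy_j``) and return a causal log-odds-ratio estimate.

Methods
-------
- Wald ratio: ``Gamma_j / gamma_j`` per SNP, first-order delta SE.
- IVW: inverse-variance-weighted pooling of Wald ratios, equivalently a
  weighted regression of outcome on exposure betas through the origin
  with weights ``1/s_gy^2``.  The random-effects variant inflates the SE
  multiplicatively by ``sqrt(max(1, Q/(J-1)))`` under heterogeneity.
- MR-Egger: the same regression with a free intercept; the intercept
  estimates average directional pleiotropy.
- Weighted median: consistent when >50% of the weight lies on valid
  instruments; SE by seeded parametric bootstrap.
- Weighted mode: the mode of the smoothed weighted Wald-ratio density;
  consistent when the largest group of instruments sharing one ratio is
  valid.

ORs are obtained by exponentiating at reporting time only; everything
internal stays on the log-odds scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .summary_io import HarmonizedStudy

METHOD_LABELS = ("wald", "ivw_fe", "ivw_re", "egger", "weighted_median", "weighted_mode")

DEFAULT_N_BOOT = 1000


class EstimatorError(ValueError):
    """Estimator preconditions violated (too few or degenerate instruments)."""


@dataclass
class MRResult:
    """Output of one MR estimator on one instrument set."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.se > 0):
            raise EstimatorError(f"standard error must be positive, got {self.se}")
        if not (self.ci_low <= self.beta <= self.ci_high):
            raise EstimatorError("confidence interval must bracket the estimate")

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    @property
    def or_ci(self) -> tuple[float, float]:
        return float(np.exp(self.ci_low)), float(np.exp(self.ci_high))


def _normal_result(method: str, beta: float, se: float, n_snp: int, extras: dict | None = None) -> MRResult:
    z = stats.norm.ppf(0.975)
    pval = float(min(1.0, max(np.nextafter(0, 1), 2.0 * stats.norm.sf(abs(beta) / se))))
    return MRResult(
        method=method,
        beta=float(beta),
        se=float(se),
        ci_low=float(beta - z * se),
        ci_high=float(beta + z * se),
        pval=pval,
        n_snp=n_snp,
        extras=extras or {},
    )


def wald_ratio(gx: float, se_gx: float, gy: float, se_gy: float) -> MRResult:
    """Single-SNP causal estimate ``gy/gx`` with first-order delta SE ``se_gy/|gx|``."""
    if gx == 0:
        raise EstimatorError("Wald ratio undefined for a zero SNP-exposure effect")
    if se_gx <= 0 or se_gy <= 0:
        raise EstimatorError("standard errors must be positive")
    beta = gy / gx
    se = se_gy / abs(gx)
    return _normal_result("wald", beta, se, 1)


def _ivw_core(gx: np.ndarray, gy: np.ndarray, se_gy: np.ndarray) -> tuple[float, float, float]:
    """Fixed-effect IVW slope, SE and Cochran's Q.

    Weighted least squares of gy on gx through the origin with weights
    1/se_gy**2; identical to inverse-variance pooling of Wald ratios
    with weights gx**2/se_gy**2.
    """
    w = 1.0 / se_gy**2
    sxx = float(np.sum(w * gx * gx))
    if sxx <= 0:
        raise EstimatorError("all SNP-exposure effects are zero; IVW undefined")
    beta = float(np.sum(w * gx * gy)) / sxx
    se_fixed = sxx ** -0.5
    q = float(np.sum(w * (gy - beta * gx) ** 2))
    return beta, se_fixed, q


def ivw(study: HarmonizedStudy, random_effects: bool = True) -> MRResult:
    """Inverse-variance-weighted estimate.

    The fixed-effect SE is ``1/sqrt(sum w_j gamma_j^2)``; the
    (multiplicative) random-effects SE scales it by
    ``sqrt(max(1, Q/(J-1)))`` so it can never fall below the
    fixed-effect SE.  With one SNP, both reduce exactly to the Wald
    ratio.
    """
    j = study.n_snp
    beta, se_fixed, q = _ivw_core(study.exposure_beta, study.outcome_beta, study.outcome_se)
    scale = 1.0
    if random_effects and j >= 2:
        scale = max(1.0, q / (j - 1)) ** 0.5
    se = se_fixed * scale
    method = "ivw_re" if random_effects else "ivw_fe"
    extras = {"q": q, "q_df": max(j - 1, 0), "re_scale": scale, "se_fixed": se_fixed}
    return _normal_result(method, beta, se, j, extras)


def _orient(study: HarmonizedStudy) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Flip per-SNP signs so every exposure beta is non-negative.

    The Wald ratios, IVW weights and the Egger fit after orientation are
    invariant to the original allele coding, which makes the intercept
    interpretable and the bootstrap exactly sign-equivariant.
    """
    s = np.where(study.exposure_beta < 0, -1.0, 1.0)
    return s * study.exposure_beta, s * study.outcome_beta, study.exposure_se.copy(), study.outcome_se.copy()


def _egger_core(gx: np.ndarray, gy: np.ndarray, se_gy: np.ndarray) -> dict:
    """Weighted least squares of gy on gx with intercept, weights 1/se_gy**2."""
    w = 1.0 / se_gy**2
    sw = w.sum()
    xbar = float(np.sum(w * gx)) / sw
    ybar = float(np.sum(w * gy)) / sw
    sxx = float(np.sum(w * (gx - xbar) ** 2))
    if sxx <= 0:
        raise EstimatorError("SNP-exposure effects have no spread; Egger slope undefined")
    slope = float(np.sum(w * (gx - xbar) * (gy - ybar))) / sxx
    intercept = ybar - slope * xbar
    resid = gy - intercept - slope * gx
    q = float(np.sum(w * resid**2))
    var_slope = 1.0 / sxx
    var_intercept = 1.0 / sw + xbar**2 / sxx
    return {
        "slope": slope,
        "intercept": intercept,
        "se_slope": var_slope**0.5,
        "se_intercept": var_intercept**0.5,
        "q": q,
    }


def mr_egger(study: HarmonizedStudy) -> MRResult:
    """MR-Egger regression: slope = causal estimate, intercept = average
    directional pleiotropy.

    SNPs are re-oriented so all exposure betas are non-negative.  Both
    SEs receive the multiplicative heterogeneity scaling
    ``sqrt(Q/(J-2))`` of a standard weighted least-squares fit (no floor
    at 1, so the intercept test is exactly t-calibrated under the null);
    p-values and CIs use the t distribution with J-2 degrees of freedom.
    """
    j = study.n_snp
    if j < 3:
        raise EstimatorError(f"MR-Egger requires at least 3 instruments, got {j}")
    gx, gy, _, se_gy = _orient(study)
    fit = _egger_core(gx, gy, se_gy)
    df = j - 2
    # tiny lower bound keeps SEs positive on exactly collinear data
    scale = max(np.finfo(float).tiny ** 0.5, fit["q"] / df) ** 0.5
    se_slope = fit["se_slope"] * scale
    se_int = fit["se_intercept"] * scale
    tcrit = stats.t.ppf(0.975, df)
    p_slope = float(min(1.0, 2.0 * stats.t.sf(abs(fit["slope"]) / se_slope, df)))
    p_int = float(min(1.0, 2.0 * stats.t.sf(abs(fit["intercept"]) / se_int, df)))
    return MRResult(
        method="egger",
        beta=fit["slope"],
        se=se_slope,
        ci_low=fit["slope"] - tcrit * se_slope,
        ci_high=fit["slope"] + tcrit * se_slope,
        pval=max(np.nextafter(0, 1), p_slope),
        n_snp=j,
        extras={
            "intercept": fit["intercept"],
            "intercept_se": se_int,
            "intercept_p": max(np.nextafter(0, 1), p_int),
            "q": fit["q"],
            "q_df": df,
            "re_scale": scale,
        },
    )


def _wald_ratios_and_weights(gx, gy, se_gy) -> tuple[np.ndarray, np.ndarray]:
    if np.any(gx == 0):
        raise EstimatorError("Wald ratio undefined for a zero SNP-exposure effect")
    ratios = gy / gx
    weights = gx**2 / se_gy**2
    return ratios, weights / weights.sum()


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order]
    cum = np.cumsum(w) - 0.5 * w
    if 0.5 <= cum[0]:
        return float(r[0])
    if 0.5 >= cum[-1]:
        return float(r[-1])
    return float(np.interp(0.5, cum, r))


def _silverman_bandwidth(ratios: np.ndarray) -> float:
    # modified Silverman rule: 0.9 min(sd, IQR/1.34) J^(-1/5); a spread
    # measure that is zero up to rounding (e.g. the IQR of numerically
    # tied ratios) is ignored rather than allowed to collapse the kernel
    j = len(ratios)
    sd = float(np.std(ratios, ddof=1)) if j > 1 else 0.0
    q75, q25 = np.percentile(ratios, [75, 25])
    iqr = float(q75 - q25)
    tol = 1e-9 * max(sd, float(np.max(np.abs(ratios)), ), 1e-300)
    candidates = [c for c in (sd, iqr / 1.34) if c > tol]
    if not candidates:
        return 0.0
    return 0.9 * min(candidates) * j ** (-0.2)


def _weighted_mode_point(ratios: np.ndarray, weights: np.ndarray, bandwidth_factor: float) -> float:
    h = bandwidth_factor * _silverman_bandwidth(ratios)
    if h <= 0:  # all ratios (effectively) identical
        return float(ratios[np.argmax(weights)])
    lo, hi = ratios.min() - 3 * h, ratios.max() + 3 * h
    # evaluate at the ratios themselves too, so narrow kernels are never
    # missed between grid points
    grid = np.concatenate([np.linspace(lo, hi, 1024), ratios])
    dens = (weights[:, None] * stats.norm.pdf((grid[None, :] - ratios[:, None]) / h)).sum(axis=0)
    return float(grid[np.argmax(dens)])


def _bootstrap_se(
    point_fn,
    gx: np.ndarray,
    gy: np.ndarray,
    se_gx: np.ndarray,
    se_gy: np.ndarray,
    n_boot: int,
    seed: int,
) -> float:
    """Parametric bootstrap: perturb per-SNP betas with their SEs.

    Outcome-side noise is drawn antithetically (each draw paired with
    its negation), which reduces Monte-Carlo variance and makes the SE
    exactly invariant to negating all outcome effects.  ``n_boot`` is
    rounded up to the next even number.
    """
    rng = np.random.default_rng(seed)
    m = (n_boot + 1) // 2
    zx_half = rng.standard_normal((m, len(gx)))
    zy_half = rng.standard_normal((m, len(gx)))
    zx = np.vstack([zx_half, zx_half])
    zy = np.vstack([zy_half, -zy_half])
    est = np.empty(2 * m)
    for b in range(2 * m):
        bx = gx + se_gx * zx[b]
        by = gy + se_gy * zy[b]
        bx = np.where(bx == 0, np.finfo(float).tiny, bx)
        ratios = by / bx
        weights = bx**2 / se_gy**2
        est[b] = point_fn(ratios, weights / weights.sum())
    se = float(np.std(est, ddof=1))
    if se <= 0:
        se = np.finfo(float).tiny ** 0.5
    return se


def weighted_median(
    study: HarmonizedStudy,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 42,
) -> MRResult:
    """Weighted-median estimator over inverse-variance-weighted Wald ratios.

    The estimate interpolates the ratio at cumulative weight 0.5
    (running weight sum minus half the current weight); the SE comes
    from a seeded parametric bootstrap.
    """
    j = study.n_snp
    if j < 3:
        raise EstimatorError(f"weighted median requires at least 3 instruments, got {j}")
    gx, gy, se_gx, se_gy = _orient(study)
    ratios, weights = _wald_ratios_and_weights(gx, gy, se_gy)
    beta = _weighted_median_point(ratios, weights)
    se = _bootstrap_se(_weighted_median_point, gx, gy, se_gx, se_gy, n_boot, seed)
    return _normal_result("weighted_median", beta, se, j, {"n_boot": n_boot, "seed": seed})


def weighted_mode(
    study: HarmonizedStudy,
    bandwidth_factor: float = 1.0,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 42,
) -> MRResult:
    """Mode-based estimator: argmax of the weighted Gaussian-kernel
    density over Wald ratios (bandwidth = ``bandwidth_factor`` times the
    modified Silverman rule)."""
    j = study.n_snp
    if j < 3:
        raise EstimatorError(f"weighted mode requires at least 3 instruments, got {j}")
    if bandwidth_factor <= 0:
        raise EstimatorError("bandwidth_factor must be positive")
    gx, gy, se_gx, se_gy = _orient(study)
    ratios, weights = _wald_ratios_and_weights(gx, gy, se_gy)

    def point(r, w):
        return _weighted_mode_point(r, w, bandwidth_factor)

    beta = point(ratios, weights)
    se = _bootstrap_se(point, gx, gy, se_gx, se_gy, n_boot, seed)
    return _normal_result(
        "weighted_mode", beta, se, j,
        {"n_boot": n_boot, "seed": seed, "bandwidth_factor": bandwidth_factor},
    )


def run_all_estimators(
    study: HarmonizedStudy,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 42,
) -> list[MRResult]:
    """IVW (random effects), MR-Egger, weighted median and weighted mode
    on one study, in that order."""
    return [
        ivw(study, random_effects=True),
        mr_egger(study),
        weighted_median(study, n_boot=n_boot, seed=seed),
        weighted_mode(study, n_boot=n_boot, seed=seed),
    ]
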