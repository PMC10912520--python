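"""Heterogeneity, pleiotropy and influence diagnostics.

Covers Cochran's Q for the IVW and Egger fits, a simulation-based
residual-sum-of-squares global pleiotropy test with per-SNP outlier
identification and removal (MR-PRESSO), leave-one-out re-estimation,
per-SNP Wald ratios and the Egger intercept test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .mr_estimators import (
    EstimatorError,
    MRResult,
    _egger_core,
    _ivw_core,
    _orient,
    ivw,
    mr_egger,
    wald_ratio,
)
from .summary_io import HarmonizedStudy


def cochran_q(study: HarmonizedStudy, method: str = "ivw") -> tuple[float, int, float]:
    """Cochran's Q heterogeneity statistic around the IVW or Egger fit.

    Q = sum_j w_j (Gamma_j - fitted_j)^2 with w_j = 1/se_Gamma_j^2
    (identically, gamma_j^2/se_Gamma_j^2 on the Wald-ratio scale);
    df = J-1 for IVW, J-2 for Egger; p from the upper chi-square tail.
    """
    j = study.n_snp
    if method == "ivw":
        if j < 2:
            raise EstimatorError("Cochran's Q (IVW) requires at least 2 instruments")
        _, _, q = _ivw_core(study.exposure_beta, study.outcome_beta, study.outcome_se)
        df = j - 1
    elif method == "egger":
        if j < 3:
            raise EstimatorError("Cochran's Q (Egger) requires at least 3 instruments")
        gx, gy, _, se_gy = _orient(study)
        q = _egger_core(gx, gy, se_gy)["q"]
        df = j - 2
    else:
        raise ValueError(f"unknown method {method!r}; expected 'ivw' or 'egger'")
    p = float(stats.chi2.sf(q, df))
    return float(q), df, p


def egger_intercept_test(study: HarmonizedStudy) -> tuple[float, float, float]:
    """(intercept, SE, two-sided p) from the MR-Egger regression — the
    average-directional-pleiotropy test."""
    res = mr_egger(study)
    return res.extras["intercept"], res.extras["intercept_se"], res.extras["intercept_p"]


def single_snp(study: HarmonizedStudy) -> list[tuple[str, MRResult]]:
    """Per-SNP Wald-ratio estimates, order-stable with the input."""
    return [
        (snp, wald_ratio(gx, sx, gy, sy))
        for snp, gx, sx, gy, sy in zip(
            study.snps, study.exposure_beta, study.exposure_se,
            study.outcome_beta, study.outcome_se,
        )
    ]


def leave_one_out(study: HarmonizedStudy) -> list[tuple[str, MRResult]]:
    """Random-effects IVW re-estimated with each SNP excluded in turn."""
    j = study.n_snp
    if j < 2:
        raise EstimatorError("leave-one-out requires at least 2 instruments")
    keep = np.ones(j, dtype=bool)
    results = []
    for i, snp in enumerate(study.snps):
        keep[i] = False
        results.append((snp, ivw(study.subset(keep), random_effects=True)))
        keep[i] = True
    return results


# ---------------------------------------------------------------------------
# MR-PRESSO

@dataclass
class PressoResult:
    """Global pleiotropy test with per-SNP outlier removal."""

    global_rss_observed: float
    global_p: float
    outlier_p: dict[str, float]
    outliers: set[str]
    corrected: MRResult
    uncorrected: MRResult
    distortion_p: float | None = None
    n_sim: int = 0
    extras: dict = field(default_factory=dict)


def _loo_betas(gx: np.ndarray, gy: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out fixed-effect IVW slopes in O(J) via running sums."""
    s_xy = np.sum(w * gx * gy)
    s_xx = np.sum(w * gx * gx)
    return (s_xy - w * gx * gy) / (s_xx - w * gx * gx)


def _loo_betas_matrix(gx: np.ndarray, gy: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Row-wise leave-one-out IVW slopes for a (n_sim, J) batch."""
    s_xy = np.sum(w * gx * gy, axis=1, keepdims=True)
    s_xx = np.sum(w * gx * gx, axis=1, keepdims=True)
    return (s_xy - w * gx * gy) / (s_xx - w * gx * gx)


def mr_presso(
    study: HarmonizedStudy,
    n_sim: int = 1000,
    outlier_threshold: float = 0.05,
    seed: int = 42,
    distortion: bool = False,
) -> PressoResult:
    """Residual-sum-of-squares global pleiotropy test with outlier removal.

    The observed statistic sums, over SNPs, the weighted squared
    leave-one-out residual ``w_j (Gamma_j - beta_(-j) gamma_j)^2``.  Its
    null distribution is built from ``n_sim`` parametric simulations of
    ``(gamma*, Gamma*)`` around the fitted no-pleiotropy model with the
    observed SEs.  Per-SNP outlier p-values are the empirical exceedance
    probabilities of each SNP's residual contribution, Bonferroni-scaled
    across the instruments tested; SNPs below ``outlier_threshold`` are
    removed and the test repeated on the remainder until no further SNP
    is flagged (iterating guards against masking, where one extreme
    outlier drags the fitted slope towards a second one).  The global
    p-value always refers to the first, full-set pass.  The corrected
    estimate is the random-effects IVW on the outlier-free subset.
    """
    j = study.n_snp
    if j < 4:
        raise EstimatorError("MR-PRESSO requires more instruments (at least 4)")
    if n_sim < 100:
        raise EstimatorError("MR-PRESSO needs n_sim >= 100 for a usable null distribution")

    rng = np.random.default_rng(seed)
    keep = np.ones(j, dtype=bool)
    outlier_p: dict[str, float] = {}
    rss_obs = None
    global_p = None
    rss_first: np.ndarray | None = None
    while True:
        idx = np.flatnonzero(keep)
        gx = study.exposure_beta[idx]
        gy = study.outcome_beta[idx]
        se_gx = study.exposure_se[idx]
        se_gy = study.outcome_se[idx]
        w = 1.0 / se_gy**2
        jj = len(idx)

        beta_loo = _loo_betas(gx, gy, w)
        rss_j = w * (gy - beta_loo * gx) ** 2
        gx_sim = gx + se_gx * rng.standard_normal((n_sim, jj))
        gy_sim = beta_loo * gx + se_gy * rng.standard_normal((n_sim, jj))
        beta_loo_sim = _loo_betas_matrix(gx_sim, gy_sim, w)
        rss_sim = w * (gy_sim - beta_loo_sim * gx_sim) ** 2
        p_raw = (1 + np.sum(rss_sim >= rss_j, axis=0)) / (n_sim + 1)
        p_adj = np.minimum(1.0, p_raw * jj)

        if rss_obs is None:  # first, full-set pass defines the global test
            rss_obs = float(np.sum(rss_j))
            global_p = float((1 + np.sum(rss_sim.sum(axis=1) >= rss_obs)) / (n_sim + 1))
            rss_first = rss_j
        for pos, p in zip(idx, p_adj):
            outlier_p[study.snps[pos]] = float(p)

        newly = p_adj < outlier_threshold
        if not np.any(newly) or jj - int(np.sum(newly)) < 2:
            break
        keep[idx[newly]] = False

    out_mask = ~keep
    outliers = {snp for snp, flag in zip(study.snps, out_mask) if flag}

    uncorrected = ivw(study, random_effects=True)
    if outliers and np.sum(~out_mask) >= 1:
        corrected = ivw(study.subset(~out_mask), random_effects=True)
    else:
        corrected = uncorrected

    distortion_p = None
    if distortion and outliers and np.sum(~out_mask) >= 2:
        distortion_p = _distortion_test(study, out_mask, rng, n_sim)

    return PressoResult(
        global_rss_observed=rss_obs,
        global_p=global_p,
        outlier_p=outlier_p,
        outliers=outliers,
        corrected=corrected,
        uncorrected=uncorrected,
        distortion_p=distortion_p,
        n_sim=n_sim,
        extras={"rss_per_snp": dict(zip(study.snps, map(float, rss_first)))},
    )


def _distortion_test(
    study: HarmonizedStudy,
    out_mask: np.ndarray,
    rng: np.random.Generator,
    n_sim: int,
) -> float:
    """Is the shift in the causal estimate after outlier removal larger
    than expected from re-sampling inlier SNPs into the outlier slots?"""
    beta_all = ivw(study, random_effects=False).beta
    inlier = study.subset(~out_mask)
    beta_corrected = ivw(inlier, random_effects=False).beta
    if beta_corrected == 0:
        return 1.0
    d_obs = abs((beta_all - beta_corrected) / beta_corrected)
    n_out = int(np.sum(out_mask))
    n_in = inlier.n_snp
    d_sim = np.empty(n_sim)
    w_in = 1.0 / inlier.outcome_se**2
    s_xy_in = np.sum(w_in * inlier.exposure_beta * inlier.outcome_beta)
    s_xx_in = np.sum(w_in * inlier.exposure_beta**2)
    for b in range(n_sim):
        pick = rng.integers(0, n_in, size=n_out)
        s_xy = s_xy_in + np.sum(w_in[pick] * inlier.exposure_beta[pick] * inlier.outcome_beta[pick])
        s_xx = s_xx_in + np.sum(w_in[pick] * inlier.exposure_beta[pick] ** 2)
        d_sim[b] = abs((s_xy / s_xx - beta_corrected) / beta_corrected)
    return float((1 + np.sum(d_sim >= d_obs)) / (n_sim + 1))
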