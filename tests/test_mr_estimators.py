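"""Causal estimators: closed forms, oracle equivalence and invariances."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from mrkit import (
    EstimatorError,
    ivw,
    mr_egger,
    wald_ratio,
    weighted_median,
    weighted_mode,
)

from conftest import make_study, random_study


# ---------------------------------------------------------------------------
# Wald ratio

@pytest.mark.parametrize(
    "gx,gy,se_gy,beta,se",
    [
        (0.1, 0.02, 0.005, 0.2, 0.05),
        (0.1, 0.0, 0.005, 0.0, 0.05),
        (-0.1, 0.02, 0.005, -0.2, 0.05),
    ],
)
def test_wald_ratio_closed_form(gx, gy, se_gy, beta, se):
    res = wald_ratio(gx, 0.01, gy, se_gy)
    assert res.beta == pytest.approx(beta)
    assert res.se == pytest.approx(se)


def test_wald_ratio_zero_exposure_effect_rejected():
    with pytest.raises(EstimatorError):
        wald_ratio(0.0, 0.01, 0.02, 0.005)


# ---------------------------------------------------------------------------
# IVW

def test_ivw_two_snp_worked_example(two_snp_study):
    """Weights 400 and 100 pool ratios 0.2 and 0.3 into 0.22; Q = 0.8
    is below J-1 so the random-effects SE equals the fixed one."""
    fe = ivw(two_snp_study, random_effects=False)
    assert fe.beta == pytest.approx(0.22, abs=1e-12)
    assert fe.se == pytest.approx(1 / np.sqrt(500), abs=1e-12)
    assert fe.extras["q"] == pytest.approx(0.8, abs=1e-12)
    re = ivw(two_snp_study, random_effects=True)
    assert re.se == fe.se
    assert re.beta == fe.beta


def test_ivw_single_snp_equals_wald(rng):
    study = random_study(rng, j=1)
    res = ivw(study)
    wald = wald_ratio(study.exposure_beta[0], study.exposure_se[0],
                      study.outcome_beta[0], study.outcome_se[0])
    assert res.beta == pytest.approx(wald.beta, abs=1e-15)
    assert res.se == pytest.approx(wald.se, abs=1e-15)


def test_ivw_duplicating_snps_halves_fixed_variance(rng):
    study = random_study(rng, j=8)
    doubled = make_study(
        np.tile(study.exposure_beta, 2), np.tile(study.exposure_se, 2),
        np.tile(study.outcome_beta, 2), np.tile(study.outcome_se, 2),
    )
    v1 = ivw(study, random_effects=False).se ** 2
    v2 = ivw(doubled, random_effects=False).se ** 2
    assert v2 == pytest.approx(v1 / 2, rel=1e-12)


def test_ivw_matches_statsmodels_wls(rng):
    """Independent oracle: WLS through the origin with weights 1/se²."""
    for _ in range(20):
        study = random_study(rng)
        fit = sm.WLS(study.outcome_beta, study.exposure_beta,
                     weights=1.0 / study.outcome_se**2).fit()
        res = ivw(study, random_effects=False)
        assert res.beta == pytest.approx(fit.params[0], abs=1e-10)


def test_ivw_random_effects_se_never_below_fixed(rng):
    for _ in range(30):
        study = random_study(rng)
        assert ivw(study, True).se >= ivw(study, False).se - 1e-15


# ---------------------------------------------------------------------------
# MR-Egger

def test_egger_exact_linear_data():
    gx = np.array([0.05, 0.1, 0.15, 0.2])
    study = make_study(gx, [0.01] * 4, 0.5 * gx, [0.01] * 4)
    res = mr_egger(study)
    assert res.beta == pytest.approx(0.5, abs=1e-12)
    assert res.extras["intercept"] == pytest.approx(0.0, abs=1e-12)


def test_egger_exact_affine_data():
    gx = np.array([0.05, 0.1, 0.15, 0.2])
    study = make_study(gx, [0.01] * 4, 0.5 * gx + 0.02, [0.01] * 4)
    res = mr_egger(study)
    assert res.beta == pytest.approx(0.5, abs=1e-12)
    assert res.extras["intercept"] == pytest.approx(0.02, abs=1e-12)


def test_egger_matches_statsmodels_wls_with_intercept(rng):
    from mrkit.mr_estimators import _egger_core, _orient

    for _ in range(20):
        study = random_study(rng, j=int(rng.integers(3, 20)))
        gx, gy, _, se_gy = _orient(study)
        fit = sm.WLS(gy, sm.add_constant(gx), weights=1.0 / se_gy**2).fit()
        core = _egger_core(gx, gy, se_gy)
        assert core["intercept"] == pytest.approx(fit.params[0], abs=1e-10)
        assert core["slope"] == pytest.approx(fit.params[1], abs=1e-10)


def test_egger_equals_ivw_on_exact_no_pleiotropy_data():
    gx = np.array([0.05, 0.1, 0.15, 0.25])
    study = make_study(gx, [0.01] * 4, 0.4 * gx, [0.01] * 4)
    assert mr_egger(study).beta == pytest.approx(ivw(study).beta, abs=1e-10)
    assert mr_egger(study).extras["intercept"] == pytest.approx(0.0, abs=1e-12)


def test_egger_requires_three_instruments(two_snp_study):
    with pytest.raises(EstimatorError, match="3"):
        mr_egger(two_snp_study)


# ---------------------------------------------------------------------------
# weighted median / mode

def test_weighted_median_symmetric_equal_weights():
    study = make_study([0.1, 0.1, 0.1], [0.01] * 3, [0.01, 0.02, 0.03], [0.01] * 3)
    assert weighted_median(study, n_boot=50, seed=1).beta == pytest.approx(0.2)


def test_weighted_median_seeded_determinism(rng):
    study = random_study(rng, j=10)
    a = weighted_median(study, n_boot=200, seed=7)
    b = weighted_median(study, n_boot=200, seed=7)
    assert (a.beta, a.se) == (b.beta, b.se)
    c = weighted_median(study, n_boot=200, seed=8)
    assert c.se != a.se


def test_weighted_mode_degenerate_ratios():
    gx = np.array([0.05, 0.1, 0.2])
    study = make_study(gx, [0.01] * 3, 0.25 * gx, [0.01] * 3)
    for bw in (0.5, 1.0, 3.0):
        assert weighted_mode(study, bandwidth_factor=bw, n_boot=50, seed=1).beta == pytest.approx(0.25)


def test_weighted_mode_plurality_cluster(rng):
    # 7 SNPs at true ratio 0.2, 3 scattered outliers
    gx = rng.uniform(0.08, 0.2, 10)
    gy = 0.2 * gx
    gy[7:] = gx[7:] * np.array([1.0, -0.6, 1.8])
    study = make_study(gx, [0.005] * 10, gy, [0.004] * 10)
    res = weighted_mode(study, n_boot=50, seed=3)
    assert abs(res.beta - 0.2) < 0.05


def test_weighted_mode_seeded_determinism(rng):
    study = random_study(rng, j=8)
    a = weighted_mode(study, n_boot=100, seed=5)
    b = weighted_mode(study, n_boot=100, seed=5)
    assert (a.beta, a.se) == (b.beta, b.se)


# ---------------------------------------------------------------------------
# cross-estimator invariances

def test_sign_equivariance_all_estimators(rng):
    """Negating every exposure beta negates each estimate and leaves the
    SE unchanged (bit-identical for the bootstrap estimators thanks to
    orientation before resampling)."""
    study = random_study(rng, j=12)
    flipped = make_study(-study.exposure_beta, study.exposure_se,
                         study.outcome_beta, study.outcome_se)
    for fn, kwargs, tol in [
        (ivw, {}, 1e-15),
        (mr_egger, {}, 1e-12),
        (weighted_median, {"n_boot": 100, "seed": 11}, 1e-15),
        (weighted_mode, {"n_boot": 100, "seed": 11}, 1e-9),
    ]:
        a = fn(study, **kwargs)
        b = fn(flipped, **kwargs)
        assert b.beta == pytest.approx(-a.beta, abs=tol)
        assert b.se == pytest.approx(a.se, abs=tol)


def test_pvalues_consistent_with_z_or_t(two_snp_study):
    res = ivw(two_snp_study, random_effects=False)
    assert res.pval == pytest.approx(2 * stats.norm.sf(abs(res.beta) / res.se))
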