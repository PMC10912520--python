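"""Two-step mediation Mendelian randomization.

Decomposes the total causal effect of an exposure on an outcome into a
mediator-borne (indirect) component and a residual (direct) component,
all on the log-odds scale:

    indirect = beta_em * beta_mo          (product of coefficients)
    direct   = total - indirect           (difference method)

``beta_em`` comes from an exposure-to-mediator IVW fit and ``beta_mo``
either from a univariable mediator-to-outcome IVW fit (using mediator
instruments) or, by default, from the mediator coefficient of a
multivariable IVW regression that adjusts the outcome effects for the
exposure.  The proportion mediated is the quotient of the indirect and
total effects on the log scale; when the two effects point in opposite
directions the mediation is flagged non-causal and the proportion
withheld.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .mr_estimators import EstimatorError, MRResult, ivw
from .summary_io import HarmonizedStudy


@dataclass(frozen=True)
class Effect:
    """A point estimate with its standard error (log-odds scale)."""

    beta: float
    se: float

    def __post_init__(self) -> None:
        if not (self.se > 0):
            raise EstimatorError(f"standard error must be positive, got {self.se}")

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    def or_ci(self, level: float = 0.95) -> tuple[float, float]:
        z = stats.norm.ppf(0.5 + level / 2)
        return float(np.exp(self.beta - z * self.se)), float(np.exp(self.beta + z * self.se))

    @property
    def pval(self) -> float:
        return float(min(1.0, max(np.nextafter(0, 1), 2 * stats.norm.sf(abs(self.beta) / self.se))))


@dataclass
class MediationResult:
    """Total / direct / indirect decomposition for one mediator."""

    mediator: str
    total: Effect
    step1: Effect          # exposure -> mediator
    step2: Effect          # mediator -> outcome (adjusted when MVMR is used)
    indirect: Effect
    direct: Effect
    prop_mediated: float | None
    prop_mediated_se: float | None
    prop_unstable: bool
    non_causal: bool
    p_indirect: float
    outcome: str = ""

    def __post_init__(self) -> None:
        if abs(self.indirect.beta - self.step1.beta * self.step2.beta) > 1e-9:
            raise EstimatorError("indirect effect must equal the product of the two steps")
        if abs(self.direct.beta + self.indirect.beta - self.total.beta) > 1e-9:
            raise EstimatorError("decomposition must be additive on the log-OR scale")


def product_effect(step1: Effect, step2: Effect) -> Effect:
    """Indirect effect with first-order delta-method SE.

    No covariance term: the two legs come from non-overlapping
    two-sample estimates.
    """
    beta = step1.beta * step2.beta
    se = float(np.sqrt(step1.beta**2 * step2.se**2 + step2.beta**2 * step1.se**2))
    if se <= 0:
        se = np.finfo(float).tiny ** 0.5
    return Effect(beta, se)


def proportion_mediated(total: Effect, indirect: Effect) -> tuple[float, float, bool]:
    """(proportion, delta-method SE, instability flag) of indirect/total
    on the log scale.  Flagged unstable when |total| < 2 x total SE."""
    if total.beta == 0:
        raise EstimatorError("proportion mediated undefined for a zero total effect")
    prop = indirect.beta / total.beta
    var = (indirect.se**2 / total.beta**2
           + indirect.beta**2 * total.se**2 / total.beta**4)
    unstable = abs(total.beta) < 2 * total.se
    return float(prop), float(np.sqrt(var)), unstable


def mvmr_ivw(
    exposure_beta: np.ndarray,
    mediator_beta: np.ndarray,
    outcome_beta: np.ndarray,
    outcome_se: np.ndarray,
) -> tuple[Effect, Effect]:
    """Multivariable IVW: outcome effects regressed jointly on exposure
    and mediator effects, no intercept, weights 1/outcome_se².

    Returns (direct exposure effect, mediator effect), both with
    multiplicative random-effects SE scaling at J-2 degrees of freedom.
    """
    x = np.column_stack([np.asarray(exposure_beta, float), np.asarray(mediator_beta, float)])
    y = np.asarray(outcome_beta, float)
    se = np.asarray(outcome_se, float)
    j = len(y)
    if j < 3:
        raise EstimatorError(f"multivariable IVW requires at least 3 instruments, got {j}")
    w = 1.0 / se**2
    # nested reduction: an identically-zero regressor contributes nothing,
    # and the fit collapses to the univariable IVW on the other column
    zero = [bool(np.all(x[:, k] == 0)) for k in range(2)]
    if any(zero):
        if all(zero):
            raise EstimatorError("both exposure and mediator effects are identically zero")
        k = 0 if not zero[0] else 1
        sxx = float(np.sum(w * x[:, k] ** 2))
        beta = float(np.sum(w * x[:, k] * y)) / sxx
        q = float(np.sum(w * (y - beta * x[:, k]) ** 2))
        scale = max(1.0, q / (j - 1))
        fitted = Effect(beta, float(np.sqrt(scale / sxx)))
        null = Effect(0.0, np.inf)
        return (fitted, null) if k == 0 else (null, fitted)
    xtwx = x.T @ (w[:, None] * x)
    if np.linalg.cond(xtwx) > 1e12:
        raise EstimatorError("exposure and mediator effects are collinear; MVMR design is rank-deficient")
    xtwy = x.T @ (w * y)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = y - x @ coef
    q = float(np.sum(w * resid**2))
    scale = max(1.0, q / (j - 2))
    cov = np.linalg.inv(xtwx) * scale
    return (
        Effect(float(coef[0]), float(np.sqrt(cov[0, 0]))),
        Effect(float(coef[1]), float(np.sqrt(cov[1, 1]))),
    )


def _ivw_effect(study: HarmonizedStudy, leg: str) -> Effect:
    try:
        res: MRResult = ivw(study, random_effects=True)
    except EstimatorError as exc:
        raise EstimatorError(f"mediation leg {leg!r}: {exc}") from exc
    return Effect(res.beta, res.se)


def two_step_mediation(
    exp_out: HarmonizedStudy,
    exp_med: HarmonizedStudy,
    med_out: HarmonizedStudy | None = None,
    use_mvmr_direct: bool = True,
    mvmr_study: HarmonizedStudy | None = None,
    mediator_label: str = "mediator",
    outcome_label: str = "",
) -> MediationResult:
    """Two-step mediation MR with mediated-proportion decomposition.

    ``total`` and ``step1`` are random-effects IVW fits of the
    exposure-outcome and exposure-mediator studies.  ``step2`` is either
    the univariable mediator-outcome IVW (``use_mvmr_direct=False``,
    requires ``med_out``) or the exposure-adjusted mediator coefficient
    from a multivariable IVW fit (the default), taken from
    ``mvmr_study`` when supplied, else from mediator effects carried on
    ``exp_out``.  The indirect effect is the product of the two steps
    with a first-order delta-method SE; the direct effect is the
    difference from the total.
    """
    total = _ivw_effect(exp_out, "exposure->outcome")
    step1 = _ivw_effect(exp_med, "exposure->mediator")

    if use_mvmr_direct:
        source = mvmr_study if mvmr_study is not None else exp_out
        if not source.has_mediator:
            raise EstimatorError(
                "mediation leg 'mvmr': study carries no mediator effects; "
                "harmonize with the mediator table or pass mvmr_study"
            )
        try:
            _, step2 = mvmr_ivw(
                source.exposure_beta, source.mediator_beta,
                source.outcome_beta, source.outcome_se,
            )
        except EstimatorError as exc:
            raise EstimatorError(f"mediation leg 'mvmr': {exc}") from exc
    else:
        if med_out is None:
            raise EstimatorError("mediation leg 'mediator->outcome': study not supplied")
        step2 = _ivw_effect(med_out, "mediator->outcome")

    indirect = product_effect(step1, step2)
    direct = Effect(total.beta - indirect.beta, float(np.sqrt(total.se**2 + indirect.se**2)))
    p_indirect = indirect.pval
    non_causal = (
        np.sign(indirect.beta) != np.sign(total.beta)
        and indirect.beta != 0
        and total.beta != 0
    )
    if non_causal or total.beta == 0:
        prop, prop_se, unstable = None, None, True
    else:
        prop, prop_se, unstable = proportion_mediated(total, indirect)
    return MediationResult(
        mediator=mediator_label,
        outcome=outcome_label,
        total=total,
        step1=step1,
        step2=step2,
        indirect=indirect,
        direct=direct,
        prop_mediated=prop,
        prop_mediated_se=prop_se,
        prop_unstable=unstable,
        non_causal=bool(non_causal),
        p_indirect=p_indirect,
    )


def mediation_table(results: list[MediationResult]):
    """One row per (outcome, mediator): ORs with 95% CIs for the total,
    direct and mediation effects plus the mediation p-value."""
    import pandas as pd

    if not results:
        raise ValueError("mediation_table requires at least one result")
    rows = []
    for r in results:
        row = {"outcome": r.outcome, "mediator": r.mediator}
        for label, eff in (("total", r.total), ("direct", r.direct), ("mediation", r.indirect)):
            lo, hi = eff.or_ci()
            row[f"{label}_or"] = eff.odds_ratio
            row[f"{label}_ci_low"] = lo
            row[f"{label}_ci_high"] = hi
        row["mediation_p"] = r.p_indirect
        row["prop_mediated"] = np.nan if r.prop_mediated is None else r.prop_mediated
        row["prop_mediated_se"] = np.nan if r.prop_mediated_se is None else r.prop_mediated_se
        row["non_causal"] = r.non_causal
        rows.append(row)
    return pd.DataFrame(rows)
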