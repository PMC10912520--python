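"""Synthetic GWAS summary statistics with known ground truth.

Generates two-sample (and, for mediation, three-table) summary
statistics directly at the summary level — no individual-level
genotypes — for a causal chain

    exposure --(beta_em)--> mediator --(beta_mo)--> outcome
        \\------------------(beta_direct)-------------/

so that ``beta_total = beta_direct + beta_em * beta_mo`` holds exactly
on the log-odds scale in every simulation.

Per SNP j the true instrument effect ``gamma_j`` has magnitude drawn
uniformly in [0.5, 1.5] x ``instrument_sd`` with random sign (bounded
away from zero so Wald ratios stay well conditioned); observed betas
add independent Gaussian estimation noise at the configured SEs, one
draw per study (two-sample designs share no samples).  A configurable
fraction of SNPs receives a direct (pleiotropic) outcome effect
``alpha_j ~ N(pleiotropy_mean, pleiotropy_sd)`` drawn independently of
instrument strength, so the InSIDE condition holds by construction.
Deliberately weak instruments are generated with
``|gamma| = sqrt(3) * se_exposure``, putting their expected F-statistic
at about 4, well below the conventional F >= 10 screen.

When ``n_snps_mediator > 0`` the tables additionally contain that many
mediator-specific instruments: SNPs with no exposure effect, a mediator
effect of the same construction (spread ``instrument_sd_mediator``) and
an outcome effect ``beta_mo`` times it.  These are the variants a
mediator GWAS would supply for the mediator-to-outcome leg of a
two-step mediation analysis.

Features of real data deliberately not emulated: allele-frequency
spectra tied to effect sizes, case-control ascertainment, genomic
coordinates, and sample overlap between studies.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy import stats

from . import mr_estimators
from .summary_io import HarmonizedStudy, LDMatrix, SummaryStatRecord, harmonize

#: non-palindromic allele pairs used for simulated variants
_NON_PALINDROMIC_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


class ConfigError(ValueError):
    """A simulation configuration violates its invariants."""


@dataclass(frozen=True)
class SimulationConfig:
    """Generating parameters for one synthetic two-sample (or mediation) study.

    Effects are on the log-odds scale.  ``prop_mediated_target``, when
    set, overrides ``beta_mo`` so that the indirect effect equals the
    target proportion of ``beta_total``.
    """

    n_snps: int = 50
    beta_total: float = 0.2
    beta_em: float = 0.3
    beta_mo: float = 1.0 / 3.0
    prop_mediated_target: float | None = None
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    invalid_fraction: float = 0.0
    instrument_sd: float = 0.1
    se_exposure: float = 0.01
    se_outcome: float = 0.02
    se_mediator: float = 0.01
    n_weak: int = 0
    n_snps_mediator: int = 0
    instrument_sd_mediator: float = 0.15
    ld_block_size: int | None = None
    ld_r2: float = 0.0
    palindromic_fraction: float = 0.0
    n_samples: int = 500_000
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ConfigError("n_snps must be >= 1")
        for name in ("instrument_sd", "se_exposure", "se_outcome", "se_mediator",
                     "instrument_sd_mediator"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.pleiotropy_sd < 0:
            raise ConfigError("pleiotropy_sd must be >= 0")
        for name in ("invalid_fraction", "palindromic_fraction"):
            if not (0 <= getattr(self, name) <= 1):
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.prop_mediated_target is not None and not (0 <= self.prop_mediated_target <= 1):
            raise ConfigError("prop_mediated_target must lie in [0, 1]")
        if not (0 <= self.n_weak <= self.n_snps):
            raise ConfigError("n_weak must lie in [0, n_snps]")
        if self.n_snps_mediator < 0:
            raise ConfigError("n_snps_mediator must be >= 0")
        if self.ld_block_size is not None and self.ld_block_size < 1:
            raise ConfigError("ld_block_size must be >= 1")
        if not (0 <= self.ld_r2 <= 1):
            raise ConfigError("ld_r2 must lie in [0, 1]")
        if self.prop_mediated_target is None and self.beta_em == 0 and self.beta_mo != 0:
            # indirect effect is still well-defined (zero path); nothing to check
            pass
        if self.prop_mediated_target is not None and self.beta_em == 0:
            raise ConfigError("prop_mediated_target requires a nonzero beta_em")

    @property
    def effective_beta_mo(self) -> float:
        """Mediator-to-outcome effect after applying ``prop_mediated_target``."""
        if self.prop_mediated_target is None:
            return self.beta_mo
        return self.prop_mediated_target * self.beta_total / self.beta_em

    @property
    def beta_indirect(self) -> float:
        return self.beta_em * self.effective_beta_mo

    @property
    def beta_direct(self) -> float:
        return self.beta_total - self.beta_indirect

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - valid
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


@dataclass
class SimulationTruth:
    """Generating parameters carried alongside simulated tables."""

    beta_total: float
    beta_direct: float
    beta_indirect: float
    beta_em: float
    beta_mo: float
    gamma: np.ndarray            # true SNP-exposure effects (0 for mediator-only SNPs)
    gamma_mediator: np.ndarray   # true direct SNP-mediator effects (mediator-only SNPs)
    alpha: np.ndarray            # per-SNP direct (pleiotropic) outcome effects
    valid_mask: np.ndarray       # False where alpha != 0 was planted
    weak_mask: np.ndarray        # True for deliberately weak instruments
    mediator_instrument_mask: np.ndarray  # True for mediator-specific SNPs

    def __post_init__(self) -> None:
        if abs(self.beta_direct + self.beta_indirect - self.beta_total) > 1e-12:
            raise ConfigError("truth decomposition must be additive")


@dataclass
class SimulatedStudy:
    """Three summary-statistics tables sharing one SNP panel, plus truth."""

    exposure: list[SummaryStatRecord]
    mediator: list[SummaryStatRecord]
    outcome: list[SummaryStatRecord]
    truth: SimulationTruth
    ld: LDMatrix | None = None
    config: SimulationConfig | None = None


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    return np.clip(p, np.nextafter(0, 1), 1.0)


def _records(
    snps: Sequence[str],
    alleles: Sequence[tuple[str, str]],
    eaf: np.ndarray,
    beta: np.ndarray,
    se: np.ndarray,
    n: int,
) -> list[SummaryStatRecord]:
    pvals = _two_sided_p(beta, se)
    return [
        SummaryStatRecord(
            snp_id=s, effect_allele=a[0], other_allele=a[1],
            beta=float(b), se=float(sd), pval=float(p), eaf=float(f), n=n,
        )
        for s, a, f, b, sd, p in zip(snps, alleles, eaf, beta, se, pvals)
    ]


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Draw one synthetic exposure/mediator/outcome study triple.

    Identical configs (including seed) yield bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    j_exp = config.n_snps
    j_med = config.n_snps_mediator
    j = j_exp + j_med

    # true SNP-exposure effects: bounded-away-from-zero magnitudes, random sign
    mag = rng.uniform(0.5, 1.5, size=j_exp) * config.instrument_sd
    sign = rng.choice([-1.0, 1.0], size=j_exp)
    gamma = mag * sign
    weak_mask = np.zeros(j, dtype=bool)
    if config.n_weak:
        weak_idx = rng.choice(j_exp, size=config.n_weak, replace=False)
        # E[(gamma_hat/se)^2] = (gamma/se)^2 + 1 = 4  =>  |gamma| = sqrt(3) se
        gamma[weak_idx] = np.sign(gamma[weak_idx]) * np.sqrt(3.0) * config.se_exposure
        weak_mask[weak_idx] = True

    # direct (pleiotropic) outcome effects, independent of gamma (InSIDE)
    alpha = np.zeros(j)
    valid_mask = np.ones(j, dtype=bool)
    n_invalid = int(round(config.invalid_fraction * j_exp))
    if n_invalid:
        inv_idx = rng.choice(j_exp, size=n_invalid, replace=False)
        alpha[inv_idx] = config.pleiotropy_mean + config.pleiotropy_sd * rng.standard_normal(n_invalid)
        valid_mask[inv_idx] = False

    # mediator-specific instruments: no exposure path
    gamma_med = np.zeros(j)
    med_mask = np.zeros(j, dtype=bool)
    if j_med:
        mag_m = rng.uniform(0.5, 1.5, size=j_med) * config.instrument_sd_mediator
        gamma_med[j_exp:] = mag_m * rng.choice([-1.0, 1.0], size=j_med)
        med_mask[j_exp:] = True

    gamma_full = np.concatenate([gamma, np.zeros(j_med)])
    beta_mo = config.effective_beta_mo
    true_exposure = gamma_full
    true_mediator = config.beta_em * gamma_full + gamma_med
    # pleiotropy is directional relative to the exposure-increasing allele:
    # alpha enters with the sign of gamma so that re-orienting instruments
    # to gamma >= 0 (as Egger does) exposes a mean pleiotropic effect mu_alpha
    orient = np.where(gamma_full != 0, np.sign(gamma_full), 1.0)
    true_outcome = (
        config.beta_direct * gamma_full
        + beta_mo * true_mediator
        + orient * alpha
    )

    obs_exposure = true_exposure + config.se_exposure * rng.standard_normal(j)
    obs_mediator = true_mediator + config.se_mediator * rng.standard_normal(j)
    obs_outcome = true_outcome + config.se_outcome * rng.standard_normal(j)

    snps = [f"rs{i + 1:06d}" for i in range(j)]
    eaf = rng.uniform(0.05, 0.95, size=j)
    n_pal = int(round(config.palindromic_fraction * j))
    pal_positions = rng.choice(j, size=n_pal, replace=False) if n_pal else np.array([], dtype=int)
    is_pal = np.zeros(j, dtype=bool)
    is_pal[pal_positions] = True
    alleles = [
        _PALINDROMIC_PAIRS[rng.integers(len(_PALINDROMIC_PAIRS))]
        if is_pal[i]
        else _NON_PALINDROMIC_PAIRS[rng.integers(len(_NON_PALINDROMIC_PAIRS))]
        for i in range(j)
    ]

    se_exp = np.full(j, config.se_exposure)
    se_med = np.full(j, config.se_mediator)
    se_out = np.full(j, config.se_outcome)

    truth = SimulationTruth(
        beta_total=config.beta_total,
        beta_direct=config.beta_direct,
        beta_indirect=config.beta_indirect,
        beta_em=config.beta_em,
        beta_mo=beta_mo,
        gamma=gamma_full,
        gamma_mediator=gamma_med,
        alpha=alpha,
        valid_mask=valid_mask,
        weak_mask=weak_mask,
        mediator_instrument_mask=med_mask,
    )
    ld = simulate_ld_blocks(config, n_snps=j) if config.ld_block_size is not None else None
    return SimulatedStudy(
        exposure=_records(snps, alleles, eaf, obs_exposure, se_exp, config.n_samples),
        mediator=_records(snps, alleles, eaf, obs_mediator, se_med, config.n_samples),
        outcome=_records(snps, alleles, eaf, obs_outcome, se_out, config.n_samples),
        truth=truth,
        ld=ld,
        config=config,
    )


def simulate_ld_blocks(config: SimulationConfig, n_snps: int | None = None) -> LDMatrix:
    """Block-diagonal exchangeable LD: within-block off-diagonal r² equal
    to ``ld_r2``, zero between blocks, unit diagonal."""
    if config.ld_block_size is None or config.ld_block_size < 1:
        raise ConfigError("ld_block_size must be >= 1")
    j = n_snps if n_snps is not None else config.n_snps + config.n_snps_mediator
    r2 = np.eye(j)
    size = config.ld_block_size
    for start in range(0, j, size):
        stop = min(start + size, j)
        block = np.full((stop - start, stop - start), config.ld_r2)
        np.fill_diagonal(block, 1.0)
        r2[start:stop, start:stop] = block
    return LDMatrix(snps=[f"rs{i + 1:06d}" for i in range(j)], r2=r2)


def exposure_outcome_study(sim: SimulatedStudy) -> HarmonizedStudy:
    """Harmonize the exposure and outcome tables of a simulated study."""
    return harmonize(sim.exposure, sim.outcome)


def exposure_mediator_study(sim: SimulatedStudy) -> HarmonizedStudy:
    return harmonize(sim.exposure, sim.mediator)


def mediator_outcome_study(sim: SimulatedStudy) -> HarmonizedStudy:
    """Harmonize mediator (as exposure) against outcome."""
    return harmonize(sim.mediator, sim.outcome)


def write_truth(truth: SimulationTruth, path: str | Path, snps: Sequence[str]) -> None:
    """Per-SNP truth sidecar TSV (scalar effects repeated in a header comment)."""
    import pandas as pd

    df = pd.DataFrame({
        "snp": list(snps),
        "gamma": truth.gamma,
        "gamma_mediator": truth.gamma_mediator,
        "alpha": truth.alpha,
        "valid": truth.valid_mask.astype(int),
        "weak": truth.weak_mask.astype(int),
        "mediator_instrument": truth.mediator_instrument_mask.astype(int),
    })
    with open(path, "w") as fh:
        fh.write(
            f"# beta_total={truth.beta_total!r}\tbeta_direct={truth.beta_direct!r}"
            f"\tbeta_indirect={truth.beta_indirect!r}\tbeta_em={truth.beta_em!r}"
            f"\tbeta_mo={truth.beta_mo!r}\n"
        )
        df.to_csv(fh, sep="\t", index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# calibration harness

_CALIBRATION_ESTIMATORS = ("ivw_fe", "ivw_re", "egger", "weighted_median", "weighted_mode")


@dataclass
class CalibrationSummary:
    """Aggregate operating characteristics of one estimator over replicates."""

    estimator: str
    n_reps: int
    alpha: float
    rejection_rate: float
    mean_estimate: float
    empirical_se: float
    mean_reported_se: float
    ci_coverage: float
    mc_se_rejection: float
    mc_se_mean: float
    true_beta: float
    mean_intercept: float | None = None
    intercept_rejection_rate: float | None = None
    estimates: np.ndarray | None = None


def replicate_seeds(master_seed: int, n_reps: int) -> list[int]:
    """Deterministic per-replicate seeds spawned from one master seed.

    Uses NumPy's SeedSequence spawning, so replicates are reproducible
    and statistically independent; each seed is reduced below 2^31.
    """
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n_reps)]


def calibration_run(
    config: SimulationConfig,
    n_reps: int,
    estimator: str = "ivw_re",
    alpha: float = 0.05,
    n_boot: int = 200,
) -> CalibrationSummary:
    """Operating characteristics of one estimator across simulated replicates.

    Each replicate re-draws a study from ``config`` with a seed spawned
    from ``config.seed``, harmonizes exposure against outcome, applies
    the named estimator and records the estimate, its reported SE and
    CI, and whether the two-sided test at ``alpha`` rejects.  Coverage
    is measured against the true total effect.
    """
    if n_reps < 1:
        raise ConfigError("n_reps must be >= 1")
    if estimator not in _CALIBRATION_ESTIMATORS:
        raise ValueError(
            f"unknown estimator {estimator!r}; valid labels: {', '.join(_CALIBRATION_ESTIMATORS)}"
        )
    seeds = replicate_seeds(config.seed, n_reps)
    estimates = np.empty(n_reps)
    ses = np.empty(n_reps)
    rejects = np.empty(n_reps, dtype=bool)
    covered = np.empty(n_reps, dtype=bool)
    intercepts: list[float] = []
    intercept_rejects: list[bool] = []
    truth = config.beta_total

    for i, seed in enumerate(seeds):
        sim = simulate_study(dataclasses.replace(config, seed=seed))
        study = exposure_outcome_study(sim)
        if estimator == "ivw_fe":
            res = mr_estimators.ivw(study, random_effects=False)
        elif estimator == "ivw_re":
            res = mr_estimators.ivw(study, random_effects=True)
        elif estimator == "egger":
            res = mr_estimators.mr_egger(study)
            intercepts.append(res.extras["intercept"])
            intercept_rejects.append(res.extras["intercept_p"] < alpha)
        elif estimator == "weighted_median":
            res = mr_estimators.weighted_median(study, n_boot=n_boot, seed=seed)
        else:
            res = mr_estimators.weighted_mode(study, n_boot=n_boot, seed=seed)
        estimates[i] = res.beta
        ses[i] = res.se
        rejects[i] = res.pval < alpha
        covered[i] = res.ci_low <= truth <= res.ci_high

    rate = float(np.mean(rejects))
    emp_se = float(np.std(estimates, ddof=1)) if n_reps > 1 else 0.0
    return CalibrationSummary(
        estimator=estimator,
        n_reps=n_reps,
        alpha=alpha,
        rejection_rate=rate,
        mean_estimate=float(np.mean(estimates)),
        empirical_se=emp_se,
        mean_reported_se=float(np.mean(ses)),
        ci_coverage=float(np.mean(covered)),
        mc_se_rejection=float(np.sqrt(rate * (1 - rate) / n_reps)),
        mc_se_mean=emp_se / np.sqrt(n_reps),
        true_beta=truth,
        mean_intercept=float(np.mean(intercepts)) if intercepts else None,
        intercept_rejection_rate=float(np.mean(intercept_rejects)) if intercept_rejects else None,
        estimates=estimates,
    )
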