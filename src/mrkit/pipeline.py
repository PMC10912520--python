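"""End-to-end orchestration of the MR workflow.

``run_univariable`` executes instrument selection, all four causal
estimators and the full diagnostics battery on one exposure/outcome
pair; ``run_mediation`` adds the two-step mediation decomposition for
each requested mediator.  Every run writes tab-separated result tables,
a plain-text log recording thresholds, seeds and per-stage SNP
attrition, and a machine-readable JSON sidecar of all parameters.
Identical config + inputs + seed produce byte-identical outputs.

Multiple-testing correction across outcomes is deliberately not applied
by default; ``fdr=True`` adds a Benjamini-Hochberg column for users who
want it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diagnostics, mr_estimators, summary_io
from .instrument_selection import (
    DEFAULT_F_MIN,
    DEFAULT_P_THRESHOLD,
    DEFAULT_R2_MAX,
    select_instruments,
)
from .mediation import MediationResult, mediation_table, two_step_mediation
from .summary_io import read_ld_matrix, read_summary_stats

_FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """All inputs, thresholds and options for one pipeline run."""

    exposure_path: str
    outcome_path: str
    output_dir: str
    mediator_paths: dict[str, str] = field(default_factory=dict)
    ld_path: str | None = None
    p_exposure: float = DEFAULT_P_THRESHOLD
    p_outcome_exclusion: float = DEFAULT_P_THRESHOLD
    r2_max: float = DEFAULT_R2_MAX
    f_min: float = DEFAULT_F_MIN
    presso_p: float = 0.05
    n_boot: int = 1000
    n_sim: int = 1000
    seed: int = 42
    use_mvmr_direct: bool = True
    fdr: bool = False
    exclude_snps: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("p_exposure", "p_outcome_exclusion", "presso_p"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if not (0 <= self.r2_max <= 1):
            raise ValueError(f"r2_max must lie in [0, 1], got {self.r2_max}")
        if self.f_min < 0:
            raise ValueError("f_min must be >= 0")
        if self.seed is None:
            raise ValueError("seed must be set")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a config from YAML; keyword overrides (e.g. CLI flags) win."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - valid
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)


def _mr_results_frame(results: list[mr_estimators.MRResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        lo, hi = r.or_ci
        rows.append({
            "method": r.method,
            "nsnp": r.n_snp,
            "beta": r.beta,
            "se": r.se,
            "or": r.odds_ratio,
            "or_ci_low": lo,
            "or_ci_high": hi,
            "pval": r.pval,
            "egger_intercept": r.extras.get("intercept", np.nan),
            "egger_intercept_p": r.extras.get("intercept_p", np.nan),
        })
    return pd.DataFrame(rows)


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


class _RunLog:
    def __init__(self) -> None:
        self.lines: list[str] = []

    def add(self, msg: str) -> None:
        self.lines.append(msg)

    def write(self, path: Path) -> None:
        path.write_text("\n".join(self.lines) + "\n")


def run_univariable(config: PipelineConfig) -> dict:
    """Instrument selection, the four estimators, and all diagnostics.

    Writes instruments.tsv, audit.tsv, mr_results.tsv, heterogeneity.tsv,
    presso.tsv, loo.tsv, single_snp.tsv, run.log and params.json under
    ``config.output_dir``; returns the result bundle in memory.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _RunLog()
    log.add(f"parameters: {json.dumps(dataclasses.asdict(config), sort_keys=True)}")

    stage = "read_inputs"
    try:
        exposure = read_summary_stats(config.exposure_path)
        outcome = read_summary_stats(config.outcome_path)
        ld = read_ld_matrix(config.ld_path) if config.ld_path else None
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    log.add(f"read {len(exposure)} exposure and {len(outcome)} outcome SNPs")

    stage = "select_instruments"
    try:
        iset = select_instruments(
            exposure, outcome, ld=ld,
            p_threshold=config.p_exposure,
            p_outcome_exclusion=config.p_outcome_exclusion,
            r2_max=config.r2_max,
            f_min=config.f_min,
            exclude_snps=config.exclude_snps or None,
        )
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    study = iset.study
    for stage_name, count in sorted(iset.attrition.items()):
        log.add(f"attrition {stage_name}: {count}")
    log.add(f"instruments kept: {study.n_snp} (min F = {iset.f_statistics.min():.3f})")

    audit_df = pd.DataFrame(
        {"snp": list(iset.audit), "disposition": list(iset.audit.values())}
    ).sort_values("snp", kind="stable")
    _write(audit_df, out / "audit.tsv")
    summary_io.write_harmonized(study, out / "instruments.tsv")

    stage = "estimators"
    try:
        results = mr_estimators.run_all_estimators(study, n_boot=config.n_boot, seed=config.seed)
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    mr_df = _mr_results_frame(results)
    if config.fdr:
        mr_df["pval_bh"] = _benjamini_hochberg(mr_df["pval"].to_numpy())
    _write(mr_df, out / "mr_results.tsv")

    stage = "diagnostics"
    try:
        q_ivw = diagnostics.cochran_q(study, "ivw")
        q_egger = diagnostics.cochran_q(study, "egger") if study.n_snp >= 3 else None
        het_rows = [{"method": "ivw", "q": q_ivw[0], "df": q_ivw[1], "p": q_ivw[2]}]
        if q_egger:
            het_rows.append({"method": "egger", "q": q_egger[0], "df": q_egger[1], "p": q_egger[2]})
        _write(pd.DataFrame(het_rows), out / "heterogeneity.tsv")

        if study.n_snp >= 4:
            presso = diagnostics.mr_presso(
                study, n_sim=config.n_sim,
                outlier_threshold=config.presso_p, seed=config.seed,
            )
            presso_df = pd.DataFrame({
                "snp": study.snps,
                "outlier_p": [presso.outlier_p[s] for s in study.snps],
                "outlier": [s in presso.outliers for s in study.snps],
            })
            presso_df.insert(0, "global_p", presso.global_p)
            _write(presso_df, out / "presso.tsv")
            log.add(
                f"mr_presso global_p={presso.global_p:.6g} "
                f"outliers={sorted(presso.outliers)}"
            )
        else:
            presso = None
            log.add("mr_presso skipped: fewer than 4 instruments")

        loo = diagnostics.leave_one_out(study)
        _write(pd.DataFrame(
            [{"excluded_snp": s, "beta": r.beta, "se": r.se, "pval": r.pval} for s, r in loo]
        ), out / "loo.tsv")
        singles = diagnostics.single_snp(study)
        _write(pd.DataFrame(
            [{"snp": s, "beta": r.beta, "se": r.se, "pval": r.pval} for s, r in singles]
        ), out / "single_snp.tsv")
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    log.write(out / "run.log")
    (out / "params.json").write_text(
        json.dumps(dataclasses.asdict(config), indent=2, sort_keys=True) + "\n"
    )
    return {
        "instruments": iset,
        "mr_results": results,
        "heterogeneity": {"ivw": q_ivw, "egger": q_egger},
        "presso": presso,
        "leave_one_out": loo,
        "single_snp": singles,
    }


def run_mediation(config: PipelineConfig, mediators: list[str] | None = None) -> dict:
    """Two-step mediation for each requested mediator label.

    For every mediator: exposure instruments are selected against the
    outcome and harmonized with the mediator table (step 1 and, when
    MVMR is used, the adjusted step 2); mediator instruments are
    selected against the outcome for the univariable step 2.  Emits a
    per-mediator decomposition table shaped like a classical mediation
    summary (total / direct / mediation ORs with CIs).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    labels = mediators if mediators is not None else sorted(config.mediator_paths)
    if not labels:
        raise PipelineError("stage 'mediation' failed: no mediator tables supplied")
    log = _RunLog()
    log.add(f"parameters: {json.dumps(dataclasses.asdict(config), sort_keys=True)}")

    stage = "read_inputs"
    try:
        exposure = read_summary_stats(config.exposure_path)
        outcome = read_summary_stats(config.outcome_path)
        med_tables = {m: read_summary_stats(config.mediator_paths[m]) for m in labels}
        ld = read_ld_matrix(config.ld_path) if config.ld_path else None
    except KeyError as exc:
        raise PipelineError(f"stage {stage!r} failed: no table for mediator {exc}") from exc
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    results: list[MediationResult] = []
    for label in labels:
        med = med_tables[label]
        try:
            exp_set = select_instruments(
                exposure, outcome, mediator=med, ld=ld,
                p_threshold=config.p_exposure,
                p_outcome_exclusion=config.p_outcome_exclusion,
                r2_max=config.r2_max, f_min=config.f_min,
                exclude_snps=config.exclude_snps or None,
            )
            med_set = select_instruments(
                med, outcome, ld=ld,
                p_threshold=config.p_exposure,
                p_outcome_exclusion=config.p_outcome_exclusion,
                r2_max=config.r2_max, f_min=config.f_min,
            )
        except Exception as exc:
            raise PipelineError(f"stage 'select[{label}]' failed: {exc}") from exc
        exp_out = exp_set.study
        # step 1 reuses the exposure instruments with the mediator as outcome
        exp_med = summary_io.HarmonizedStudy(
            snps=list(exp_out.snps),
            effect_allele=list(exp_out.effect_allele),
            other_allele=list(exp_out.other_allele),
            exposure_beta=exp_out.exposure_beta,
            exposure_se=exp_out.exposure_se,
            outcome_beta=exp_out.mediator_beta,
            outcome_se=exp_out.mediator_se,
        )
        mvmr_study = None
        if config.use_mvmr_direct:
            mvmr_study = _combined_mvmr_study(exp_out, med_set.study, exposure)
        try:
            res = two_step_mediation(
                exp_out=exp_out,
                exp_med=exp_med,
                med_out=med_set.study,
                use_mvmr_direct=config.use_mvmr_direct,
                mvmr_study=mvmr_study,
                mediator_label=label,
            )
        except Exception as exc:
            raise PipelineError(f"stage 'mediation[{label}]' failed: {exc}") from exc
        results.append(res)
        log.add(
            f"mediator {label}: total={res.total.beta:.6g} indirect={res.indirect.beta:.6g} "
            f"direct={res.direct.beta:.6g} prop_mediated="
            f"{'NA' if res.prop_mediated is None else format(res.prop_mediated, '.6g')} "
            f"non_causal={res.non_causal}"
        )

    table = mediation_table(results)
    if config.fdr:
        table["mediation_p_bh"] = _benjamini_hochberg(table["mediation_p"].to_numpy())
    _write(table, out / "mediation.tsv")
    log.write(out / "mediation_run.log")
    (out / "mediation_params.json").write_text(
        json.dumps(dataclasses.asdict(config), indent=2, sort_keys=True) + "\n"
    )
    return {"results": results, "table": table}


def _combined_mvmr_study(exp_out, med_out, exposure_records):
    """Union of exposure- and mediator-selected instruments for MVMR.

    Exposure instruments carry their harmonized exposure/mediator/
    outcome effects; mediator instruments contribute their mediator and
    outcome effects with the exposure effect taken from the exposure
    table (near-zero for genuine mediator-specific variants).
    """
    exp_lookup = {r.snp_id: r for r in exposure_records}
    snps = list(exp_out.snps)
    ea = list(exp_out.effect_allele)
    oa = list(exp_out.other_allele)
    xb = list(exp_out.exposure_beta)
    xs = list(exp_out.exposure_se)
    mb = list(exp_out.mediator_beta)
    ms = list(exp_out.mediator_se)
    yb = list(exp_out.outcome_beta)
    ys = list(exp_out.outcome_se)
    seen = set(snps)
    for i, snp in enumerate(med_out.snps):
        if snp in seen:
            continue
        exp_rec = exp_lookup.get(snp)
        if exp_rec is None:
            continue
        # med_out rows are aligned to the mediator table's effect allele;
        # re-express the exposure beta on that allele
        flip = _orientation(
            med_out.effect_allele[i], med_out.other_allele[i],
            exp_rec.effect_allele, exp_rec.other_allele,
        )
        if flip is None:
            continue
        snps.append(snp)
        ea.append(med_out.effect_allele[i])
        oa.append(med_out.other_allele[i])
        xb.append(flip * exp_rec.beta)
        xs.append(exp_rec.se)
        mb.append(med_out.exposure_beta[i])
        ms.append(med_out.exposure_se[i])
        yb.append(med_out.outcome_beta[i])
        ys.append(med_out.outcome_se[i])
        seen.add(snp)
    return summary_io.HarmonizedStudy(
        snps=snps, effect_allele=ea, other_allele=oa,
        exposure_beta=np.array(xb), exposure_se=np.array(xs),
        outcome_beta=np.array(yb), outcome_se=np.array(ys),
        mediator_beta=np.array(mb), mediator_se=np.array(ms),
    )


def _orientation(ea_ref: str, oa_ref: str, ea: str, oa: str) -> float | None:
    """+1 / -1 when (ea, oa) matches (ea_ref, oa_ref) in the same /
    swapped orientation (directly or strand-complemented); None when the
    allele sets are incompatible."""
    comp = summary_io.COMPLEMENT
    if (ea, oa) in ((ea_ref, oa_ref), (comp[ea_ref], comp[oa_ref])):
        return 1.0
    if (ea, oa) in ((oa_ref, ea_ref), (comp[oa_ref], comp[ea_ref])):
        return -1.0
    return None


def _benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up)."""
    p = np.asarray(pvals, float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(n)
    adj[order] = np.minimum(ranked, 1.0)
    return adj
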