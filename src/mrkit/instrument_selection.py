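"""Instrument-variable selection for two-sample MR.

Filters are applied in a fixed order, each recording per-SNP
dispositions in an audit trail:

1. genome-wide significance on the exposure (p < 5e-8 by default);
2. optional user-supplied exclusion list (e.g. known confounder loci);
3. greedy LD pruning at r² < 0.1 against an explicit LD matrix;
4. exclusion of SNPs associated with the outcome at p < 5e-8;
5. harmonization (palindromic / missing / allele-mismatch drops);
6. per-SNP instrument-strength screen F = (beta/se)² >= 10.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .summary_io import (
    HarmonizedStudy,
    LDMatrix,
    SummaryStatRecord,
    ValidationError,
    harmonize,
)

DEFAULT_P_THRESHOLD = 5e-8
DEFAULT_R2_MAX = 0.1
DEFAULT_F_MIN = 10.0

#: audit stage labels, in pipeline order
STAGES = (
    "significance",
    "confounder_exclusion",
    "ld_prune",
    "outcome_associated",
    "palindromic",
    "missing_in_outcome",
    "missing_in_mediator",
    "allele_mismatch",
    "weak_instrument",
    "kept",
)


class SelectionError(ValueError):
    """The selection pipeline cannot produce a non-empty instrument set."""


@dataclass
class InstrumentSet:
    """Surviving instruments with per-SNP strength and a full audit trail.

    ``audit`` maps every candidate snp_id to ``"kept"`` or the label of
    the stage that removed it; exactly one label per SNP.
    """

    study: HarmonizedStudy
    f_statistics: np.ndarray
    audit: dict[str, str]

    def __post_init__(self) -> None:
        self.f_statistics = np.asarray(self.f_statistics, dtype=float)
        if len(self.f_statistics) != self.study.n_snp:
            raise ValidationError("one F-statistic per kept SNP required")

    @property
    def attrition(self) -> dict[str, int]:
        """SNP counts per audit stage (only stages that occurred)."""
        return dict(Counter(self.audit.values()))


def f_statistic(beta: float, se: float) -> float:
    """Single-instrument strength approximation F = (beta/se)²."""
    if se <= 0:
        raise ValidationError(f"se must be positive, got {se}")
    return (beta / se) ** 2


def filter_significance(
    records: Sequence[SummaryStatRecord],
    threshold: float = DEFAULT_P_THRESHOLD,
) -> list[SummaryStatRecord]:
    """Keep SNPs reaching genome-wide significance (p < threshold), order preserved."""
    return [r for r in records if r.pval < threshold]


def exclude_outcome_associated(
    records: Sequence[SummaryStatRecord],
    outcome: Sequence[SummaryStatRecord],
    threshold: float = DEFAULT_P_THRESHOLD,
) -> list[SummaryStatRecord]:
    """Drop SNPs associated with the outcome at p < threshold.

    SNPs absent from the outcome table are untouched by this filter.
    """
    lookup = {r.snp_id: r.pval for r in outcome}
    return [r for r in records if lookup.get(r.snp_id, 1.0) >= threshold]


def ld_prune(
    records: Sequence[SummaryStatRecord],
    ld: LDMatrix,
    r2_max: float = DEFAULT_R2_MAX,
) -> list[SummaryStatRecord]:
    """Greedy LD pruning: keep the most significant remaining SNP, discard
    everything at r² >= ``r2_max`` with any kept SNP.

    Ties on p-value break lexicographically on snp_id for determinism.
    The kept set is maximal: no discarded SNP could be re-added without
    violating the r² bound against a kept SNP.  Output preserves the
    input record order.
    """
    pos = {}
    for r in records:
        try:
            pos[r.snp_id] = ld.index_of(r.snp_id)
        except KeyError:
            raise ValidationError(f"SNP {r.snp_id!r} absent from LD matrix") from None
    order = sorted(records, key=lambda r: (r.pval, r.snp_id))
    kept_ids: list[str] = []
    for cand in order:
        i = pos[cand.snp_id]
        if all(ld.r2[i, pos[k]] < r2_max for k in kept_ids):
            kept_ids.append(cand.snp_id)
    kept = set(kept_ids)
    return [r for r in records if r.snp_id in kept]


def select_instruments(
    exposure: Sequence[SummaryStatRecord],
    outcome: Sequence[SummaryStatRecord],
    mediator: Sequence[SummaryStatRecord] | None = None,
    ld: LDMatrix | None = None,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    p_outcome_exclusion: float = DEFAULT_P_THRESHOLD,
    r2_max: float = DEFAULT_R2_MAX,
    f_min: float = DEFAULT_F_MIN,
    exclude_snps: Sequence[str] | None = None,
) -> InstrumentSet:
    """Run the full selection pipeline and return instruments plus audit.

    Raises :class:`SelectionError` (with per-stage attrition counts)
    when no SNP survives.  ``exclude_snps`` removes user-flagged
    variants (e.g. secondary-phenotype hits) after the significance
    filter.
    """
    audit: dict[str, str] = {}

    current = list(exposure)
    survivors = filter_significance(current, p_threshold)
    _mark_dropped(audit, current, survivors, "significance")
    current = survivors

    if exclude_snps:
        excluded = set(exclude_snps)
        survivors = [r for r in current if r.snp_id not in excluded]
        _mark_dropped(audit, current, survivors, "confounder_exclusion")
        current = survivors

    if ld is not None and current:
        survivors = ld_prune(current, ld, r2_max)
        _mark_dropped(audit, current, survivors, "ld_prune")
        current = survivors

    if current:
        survivors = exclude_outcome_associated(current, outcome, p_outcome_exclusion)
        _mark_dropped(audit, current, survivors, "outcome_associated")
        current = survivors

    if not current:
        raise SelectionError(_attrition_message(audit, len(exposure)))

    try:
        study = harmonize(current, outcome, mediator)
    except Exception:
        for r in current:
            audit.setdefault(r.snp_id, "no_shared_instruments")
        raise SelectionError(_attrition_message(audit, len(exposure)))
    audit.update(study.drop_log)

    f_all = (study.exposure_beta / study.exposure_se) ** 2
    strong = f_all >= f_min
    for snp, ok in zip(study.snps, strong):
        audit[snp] = "kept" if ok else "weak_instrument"
    if not np.any(strong):
        raise SelectionError(_attrition_message(audit, len(exposure)))
    final = study.subset(strong)
    return InstrumentSet(study=final, f_statistics=f_all[strong], audit=audit)


def _mark_dropped(audit, before, after, stage) -> None:
    kept = {r.snp_id for r in after}
    for r in before:
        if r.snp_id not in kept:
            audit[r.snp_id] = stage


def _attrition_message(audit: Mapping[str, str], n_candidates: int) -> str:
    counts = Counter(audit.values())
    detail = ", ".join(f"{stage}: {counts[stage]}" for stage in STAGES if counts.get(stage))
    extra = {k: v for k, v in counts.items() if k not in STAGES}
    if extra:
        detail += ", " + ", ".join(f"{k}: {v}" for k, v in sorted(extra.items()))
    return (
        f"no instruments survive selection ({n_candidates} candidates; "
        f"attrition — {detail})"
    )
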