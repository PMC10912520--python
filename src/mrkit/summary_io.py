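"""Reading, validating and harmonizing GWAS summary statistics.

Summary-statistics tables are tab-separated text with a mandatory header
row.  Canonical column names are ``snp``, ``effect_allele``,
``other_allele``, ``eaf``, ``beta``, ``se``, ``pval``, ``n``; other
dialects are handled through an explicit ``column_map`` (no sniffing).
Missing values are written as ``.`` or left empty.

Harmonization aligns the SNP effects of two (optionally three) studies
to a shared effect allele per SNP.  Palindromic variants (A/T or C/G)
are removed unconditionally — no allele-frequency-based strand
inference is attempted — and every dropped SNP is recorded with exactly
one reason.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical column order for summary-statistics tables
CANONICAL_COLUMNS = ("snp", "effect_allele", "other_allele", "eaf", "beta", "se", "pval", "n")
MANDATORY_COLUMNS = ("snp", "effect_allele", "other_allele", "beta", "se", "pval")

#: canonical column order for harmonized tables
HARMONIZED_COLUMNS = (
    "snp",
    "effect_allele",
    "other_allele",
    "exposure_beta",
    "exposure_se",
    "outcome_beta",
    "outcome_se",
)


class SchemaError(ValueError):
    """A table is missing a mandatory column."""


class ValidationError(ValueError):
    """A value violates a record invariant."""


class HarmonizationError(ValueError):
    """Harmonization cannot produce a non-empty instrument set."""


@dataclass(frozen=True)
class SummaryStatRecord:
    """One SNP's association with one trait.

    ``beta`` is the per-allele effect of ``effect_allele`` on the trait
    (log-odds for binary traits, standardized units otherwise);
    ``se`` its standard error.  ``eaf`` and ``n`` are optional.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    eaf: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if not self.snp_id:
            raise ValidationError("snp_id must be a non-empty string")
        for name, allele in (("effect_allele", self.effect_allele), ("other_allele", self.other_allele)):
            if allele not in VALID_ALLELES:
                raise ValidationError(f"{name} {allele!r} not one of A/C/G/T (snp {self.snp_id})")
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"effect and other allele identical for snp {self.snp_id}")
        if not (self.se > 0) or not math.isfinite(self.se):
            raise ValidationError(f"se must be positive and finite, got {self.se} (snp {self.snp_id})")
        if not math.isfinite(self.beta):
            raise ValidationError(f"beta must be finite (snp {self.snp_id})")
        if not (0 < self.pval <= 1):
            raise ValidationError(f"pval must lie in (0, 1], got {self.pval} (snp {self.snp_id})")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            raise ValidationError(f"eaf must lie in [0, 1], got {self.eaf} (snp {self.snp_id})")
        if self.n is not None and self.n <= 0:
            raise ValidationError(f"n must be positive, got {self.n} (snp {self.snp_id})")

    @property
    def alleles(self) -> frozenset:
        return frozenset((self.effect_allele, self.other_allele))


def is_palindromic(record: SummaryStatRecord) -> bool:
    """True iff the allele pair is strand-ambiguous ({A,T} or {C,G})."""
    return record.other_allele == COMPLEMENT[record.effect_allele]


@dataclass
class HarmonizedStudy:
    """Exposure and outcome (optionally mediator) effects aligned to a
    shared effect allele per SNP.

    ``drop_log`` maps each SNP removed during harmonization to the single
    reason it was dropped (``palindromic``, ``missing_in_outcome``,
    ``missing_in_mediator`` or ``allele_mismatch``).
    """

    snps: list[str]
    effect_allele: list[str]
    other_allele: list[str]
    exposure_beta: np.ndarray
    exposure_se: np.ndarray
    outcome_beta: np.ndarray
    outcome_se: np.ndarray
    mediator_beta: np.ndarray | None = None
    mediator_se: np.ndarray | None = None
    drop_log: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        arrays = [self.exposure_beta, self.exposure_se, self.outcome_beta, self.outcome_se]
        if self.mediator_beta is not None:
            arrays += [self.mediator_beta, self.mediator_se]
        for name in ("exposure_beta", "exposure_se", "outcome_beta", "outcome_se",
                     "mediator_beta", "mediator_se"):
            arr = getattr(self, name)
            if arr is not None:
                setattr(self, name, np.asarray(arr, dtype=float))
        n = len(self.snps)
        if n < 1:
            raise HarmonizationError("harmonized study must contain at least one SNP")
        if len(set(self.snps)) != n:
            raise ValidationError("duplicate snp_id in harmonized study")
        for arr in [self.effect_allele, self.other_allele, *arrays]:
            if len(arr) != n:
                raise ValidationError("harmonized arrays must share one length")
        if np.any(self.exposure_se <= 0) or np.any(self.outcome_se <= 0):
            raise ValidationError("all standard errors must be positive")
        if self.mediator_se is not None and np.any(self.mediator_se <= 0):
            raise ValidationError("all standard errors must be positive")

    @property
    def n_snp(self) -> int:
        return len(self.snps)

    @property
    def has_mediator(self) -> bool:
        return self.mediator_beta is not None

    def subset(self, index: Sequence[int] | np.ndarray) -> "HarmonizedStudy":
        """Restrict to the SNPs at ``index`` (positions or boolean mask)."""
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return HarmonizedStudy(
            snps=[self.snps[i] for i in idx],
            effect_allele=[self.effect_allele[i] for i in idx],
            other_allele=[self.other_allele[i] for i in idx],
            exposure_beta=self.exposure_beta[idx],
            exposure_se=self.exposure_se[idx],
            outcome_beta=self.outcome_beta[idx],
            outcome_se=self.outcome_se[idx],
            mediator_beta=None if self.mediator_beta is None else self.mediator_beta[idx],
            mediator_se=None if self.mediator_se is None else self.mediator_se[idx],
        )


@dataclass
class LDMatrix:
    """Squared-correlation (r²) matrix over an ordered SNP panel."""

    snps: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        n = len(self.snps)
        if len(set(self.snps)) != n:
            raise ValidationError("duplicate snp_id in LD matrix")
        if self.r2.shape != (n, n):
            raise ValidationError(f"LD matrix shape {self.r2.shape} does not match {n} SNPs")
        if not np.allclose(self.r2, self.r2.T, atol=1e-12):
            raise ValidationError("LD matrix must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-12):
            raise ValidationError("LD matrix diagonal must be exactly 1")
        if np.any(self.r2 < -1e-12) or np.any(self.r2 > 1 + 1e-12):
            raise ValidationError("LD r² entries must lie in [0, 1]")

    def index_of(self, snp_id: str) -> int:
        try:
            return self.snps.index(snp_id)
        except ValueError:
            raise KeyError(f"SNP {snp_id!r} absent from LD matrix") from None


# ---------------------------------------------------------------------------
# table I/O

def _parse_optional_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return float(value)


def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> list[SummaryStatRecord]:
    """Read a tab-separated summary-statistics table.

    Parameters
    ----------
    path
        File with a mandatory header row; ``.`` or empty denotes missing.
    column_map
        Maps canonical names (``snp``, ``beta``, ...) to the file's
        column names, for non-canonical dialects.

    Raises
    ------
    SchemaError
        if a mandatory column is absent (the message names it).
    ValidationError
        if a row violates a record invariant (the message cites the
        1-based data row number).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["."], keep_default_na=True)
    mapping = dict(column_map) if column_map else {}
    rename = {v: k for k, v in mapping.items()}
    df = df.rename(columns=rename)
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"mandatory column {col!r} missing from {path.name}")
    records: list[SummaryStatRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = row._asdict()
        try:
            rec = SummaryStatRecord(
                snp_id=str(row["snp"]),
                effect_allele=str(row["effect_allele"]).upper(),
                other_allele=str(row["other_allele"]).upper(),
                beta=float(row["beta"]),
                se=float(row["se"]),
                pval=float(row["pval"]),
                eaf=_parse_optional_float(row.get("eaf")) if "eaf" in row else None,
                n=None if "n" not in row or pd.isna(row.get("n")) else int(float(row["n"])),
            )
        except (ValidationError, TypeError, ValueError) as exc:
            raise ValidationError(f"{path.name} row {i}: {exc}") from exc
        if rec.snp_id in seen:
            raise ValidationError(f"{path.name} row {i}: duplicated snp_id {rec.snp_id!r}")
        seen.add(rec.snp_id)
        records.append(rec)
    return records


def write_summary_stats(records: Iterable[SummaryStatRecord], path: str | Path) -> None:
    """Write records as a canonical tab-separated table ('.' for missing)."""
    rows = []
    for r in records:
        rows.append({
            "snp": r.snp_id,
            "effect_allele": r.effect_allele,
            "other_allele": r.other_allele,
            "eaf": "." if r.eaf is None else repr(r.eaf),
            "beta": repr(r.beta),
            "se": repr(r.se),
            "pval": repr(r.pval),
            "n": "." if r.n is None else str(r.n),
        })
    pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_ld_matrix(path: str | Path) -> LDMatrix:
    """Read an LD matrix from TSV (header row and first column list snp_ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    snps = [str(s) for s in df.index]
    if list(df.columns) != snps:
        raise SchemaError("LD matrix header and first column must list the same snp_ids in order")
    return LDMatrix(snps=snps, r2=df.to_numpy(dtype=float))


def write_ld_matrix(ld: LDMatrix, path: str | Path) -> None:
    pd.DataFrame(ld.r2, index=ld.snps, columns=ld.snps).to_csv(path, sep="\t")


def write_harmonized(study: HarmonizedStudy, path: str | Path) -> None:
    """Write a harmonized study in the canonical column order."""
    data = {
        "snp": study.snps,
        "effect_allele": study.effect_allele,
        "other_allele": study.other_allele,
        "exposure_beta": study.exposure_beta,
        "exposure_se": study.exposure_se,
        "outcome_beta": study.outcome_beta,
        "outcome_se": study.outcome_se,
    }
    if study.has_mediator:
        data["mediator_beta"] = study.mediator_beta
        data["mediator_se"] = study.mediator_se
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_harmonized(path: str | Path) -> HarmonizedStudy:
    df = pd.read_csv(path, sep="\t")
    for col in HARMONIZED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"mandatory column {col!r} missing from {Path(path).name}")
    return HarmonizedStudy(
        snps=[str(s) for s in df["snp"]],
        effect_allele=[str(a) for a in df["effect_allele"]],
        other_allele=[str(a) for a in df["other_allele"]],
        exposure_beta=df["exposure_beta"].to_numpy(float),
        exposure_se=df["exposure_se"].to_numpy(float),
        outcome_beta=df["outcome_beta"].to_numpy(float),
        outcome_se=df["outcome_se"].to_numpy(float),
        mediator_beta=df["mediator_beta"].to_numpy(float) if "mediator_beta" in df.columns else None,
        mediator_se=df["mediator_se"].to_numpy(float) if "mediator_se" in df.columns else None,
    )


# ---------------------------------------------------------------------------
# harmonization

def _align_to(exposure: SummaryStatRecord, other: SummaryStatRecord) -> SummaryStatRecord | None:
    """Re-express ``other`` on the exposure's effect allele.

    Returns None when the allele sets are incompatible.  Handles same-
    orientation, swapped-allele and strand-complement encodings; only
    non-palindromic SNPs reach this point, so complement matching is
    unambiguous.
    """
    ea, oa = exposure.effect_allele, exposure.other_allele
    cea, coa = COMPLEMENT[ea], COMPLEMENT[oa]
    if (other.effect_allele, other.other_allele) in ((ea, oa), (cea, coa)):
        return dataclasses.replace(other, effect_allele=ea, other_allele=oa)
    if (other.effect_allele, other.other_allele) in ((oa, ea), (coa, cea)):
        return dataclasses.replace(
            other,
            effect_allele=ea,
            other_allele=oa,
            beta=-other.beta,
            eaf=None if other.eaf is None else 1.0 - other.eaf,
        )
    return None


def _check_unique(records: Sequence[SummaryStatRecord], label: str) -> dict[str, SummaryStatRecord]:
    index: dict[str, SummaryStatRecord] = {}
    for r in records:
        if r.snp_id in index:
            raise ValidationError(f"duplicated snp_id {r.snp_id!r} in {label} study")
        index[r.snp_id] = r
    return index


def harmonize(
    exposure: Sequence[SummaryStatRecord],
    outcome: Sequence[SummaryStatRecord],
    mediator: Sequence[SummaryStatRecord] | None = None,
) -> HarmonizedStudy:
    """Align outcome (and mediator) effects to the exposure's effect allele.

    Palindromic SNPs are dropped unconditionally; SNPs missing from any
    supplied study or with incompatible allele sets are dropped with a
    logged reason.  Raises :class:`HarmonizationError` when no SNP
    survives.
    """
    _check_unique(exposure, "exposure")
    out_index = _check_unique(outcome, "outcome")
    med_index = _check_unique(mediator, "mediator") if mediator is not None else None

    drop_log: dict[str, str] = {}
    snps, eas, oas = [], [], []
    exp_b, exp_s, out_b, out_s = [], [], [], []
    med_b, med_s = [], []

    for exp in exposure:
        if is_palindromic(exp):
            drop_log[exp.snp_id] = "palindromic"
            continue
        out = out_index.get(exp.snp_id)
        if out is None:
            drop_log[exp.snp_id] = "missing_in_outcome"
            continue
        med = None
        if med_index is not None:
            med = med_index.get(exp.snp_id)
            if med is None:
                drop_log[exp.snp_id] = "missing_in_mediator"
                continue
        out_aligned = _align_to(exp, out)
        med_aligned = _align_to(exp, med) if med is not None else None
        if out_aligned is None or (med is not None and med_aligned is None):
            drop_log[exp.snp_id] = "allele_mismatch"
            continue
        snps.append(exp.snp_id)
        eas.append(exp.effect_allele)
        oas.append(exp.other_allele)
        exp_b.append(exp.beta)
        exp_s.append(exp.se)
        out_b.append(out_aligned.beta)
        out_s.append(out_aligned.se)
        if med_aligned is not None:
            med_b.append(med_aligned.beta)
            med_s.append(med_aligned.se)

    if not snps:
        raise HarmonizationError(
            f"no shared instruments after harmonization ({len(drop_log)} candidates dropped)"
        )
    return HarmonizedStudy(
        snps=snps,
        effect_allele=eas,
        other_allele=oas,
        exposure_beta=np.array(exp_b),
        exposure_se=np.array(exp_s),
        outcome_beta=np.array(out_b),
        outcome_se=np.array(out_s),
        mediator_beta=np.array(med_b) if med_index is not None else None,
        mediator_se=np.array(med_s) if med_index is not None else None,
        drop_log=drop_log,
    )
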