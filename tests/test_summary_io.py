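"""Summary-statistics I/O, record validation and allele harmonization."""

import dataclasses

import numpy as np
import pytest

from mrkit import (
    HarmonizationError,
    LDMatrix,
    SchemaError,
    SummaryStatRecord,
    ValidationError,
    harmonize,
    is_palindromic,
    read_ld_matrix,
    read_summary_stats,
    write_ld_matrix,
    write_summary_stats,
)
from mrkit.summary_io import read_harmonized, write_harmonized

from conftest import make_record, make_study


# ---------------------------------------------------------------------------
# record validation

@pytest.mark.parametrize(
    "kwargs",
    [
        {"se": 0.0},
        {"se": -0.1},
        {"ea": "N"},
        {"oa": "AT"},
        {"ea": "A", "oa": "A"},
        {"pval": 0.0},
        {"pval": 1.5},
        {"eaf": 1.2},
        {"n": 0},
    ],
)
def test_record_invariants_rejected(kwargs):
    with pytest.raises(ValidationError):
        make_record(**kwargs)


@pytest.mark.parametrize(
    "ea,oa,expected",
    [("A", "T", True), ("T", "A", True), ("C", "G", True), ("G", "C", True),
     ("A", "G", False), ("C", "T", False), ("A", "C", False)],
)
def test_is_palindromic(ea, oa, expected):
    assert is_palindromic(make_record(ea=ea, oa=oa)) is expected


# ---------------------------------------------------------------------------
# table round trips and error reporting

def test_write_read_round_trip(tmp_path):
    records = [
        make_record("rs1", "A", "G", 0.1, 0.01, 1e-10, 0.3, 5000),
        make_record("rs2", "C", "T", -0.05, 0.02, 0.04, None, None),
        make_record("rs3", "G", "T", 0.0, 0.015, 1.0, 0.5, 100),
    ]
    path = tmp_path / "stats.tsv"
    write_summary_stats(records, path)
    assert read_summary_stats(path) == records


def test_read_missing_column_names_it(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("snp\teffect_allele\tother_allele\tbeta\tpval\nrs1\tA\tG\t0.1\t0.5\n")
    with pytest.raises(SchemaError, match="se"):
        read_summary_stats(path)


def test_read_invalid_se_cites_row(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text(
        "snp\teffect_allele\tother_allele\tbeta\tse\tpval\n"
        "rs1\tA\tG\t0.1\t0.01\t0.5\n"
        "rs2\tA\tG\t0.1\t0\t0.5\n"
    )
    with pytest.raises(ValidationError, match="row 2"):
        read_summary_stats(path)


def test_read_column_map_and_case_folding(tmp_path):
    path = tmp_path / "dialect.tsv"
    path.write_text(
        "rsid\tA1\tA2\tb\tstderr\tp\n"
        "rs1\ta\tg\t0.1\t0.01\t1e-9\n"
    )
    recs = read_summary_stats(path, column_map={
        "snp": "rsid", "effect_allele": "A1", "other_allele": "A2",
        "beta": "b", "se": "stderr", "pval": "p",
    })
    assert recs[0].effect_allele == "A" and recs[0].other_allele == "G"
    assert recs[0].eaf is None and recs[0].n is None


def test_duplicate_snp_id_is_hard_error(tmp_path):
    path = tmp_path / "dup.tsv"
    path.write_text(
        "snp\teffect_allele\tother_allele\tbeta\tse\tpval\n"
        "rs1\tA\tG\t0.1\t0.01\t0.5\n"
        "rs1\tA\tG\t0.2\t0.01\t0.5\n"
    )
    with pytest.raises(ValidationError, match="rs1"):
        read_summary_stats(path)


def test_harmonized_table_round_trip(tmp_path):
    study = make_study([0.1, -0.2], [0.01, 0.02], [0.02, 0.03], [0.005, 0.01],
                       mediator_beta=[0.05, -0.01], mediator_se=[0.01, 0.01])
    path = tmp_path / "harm.tsv"
    write_harmonized(study, path)
    back = read_harmonized(path)
    assert back.snps == study.snps
    np.testing.assert_allclose(back.outcome_beta, study.outcome_beta)
    np.testing.assert_allclose(back.mediator_beta, study.mediator_beta)


def test_ld_matrix_round_trip_and_validation(tmp_path):
    ld = LDMatrix(snps=["rs1", "rs2"], r2=np.array([[1.0, 0.3], [0.3, 1.0]]))
    path = tmp_path / "ld.tsv"
    write_ld_matrix(ld, path)
    back = read_ld_matrix(path)
    assert back.snps == ld.snps
    np.testing.assert_allclose(back.r2, ld.r2)
    with pytest.raises(ValidationError, match="symmetric"):
        LDMatrix(snps=["rs1", "rs2"], r2=np.array([[1.0, 0.3], [0.1, 1.0]]))
    with pytest.raises(ValidationError, match="diagonal"):
        LDMatrix(snps=["rs1", "rs2"], r2=np.array([[0.9, 0.3], [0.3, 1.0]]))


# ---------------------------------------------------------------------------
# harmonization behaviour

def test_harmonize_flips_swapped_alleles():
    exp = [make_record("rs1", "A", "G", beta=0.10, eaf=0.30)]
    out = [make_record("rs1", "G", "A", beta=-0.05, eaf=0.70)]
    study = harmonize(exp, out)
    assert study.outcome_beta[0] == pytest.approx(0.05)
    assert study.effect_allele == ["A"]


def test_harmonize_strand_complement_same_orientation():
    exp = [make_record("rs1", "A", "G", beta=0.10)]
    out = [make_record("rs1", "T", "C", beta=0.04)]
    study = harmonize(exp, out)
    assert study.outcome_beta[0] == pytest.approx(0.04)


@pytest.mark.parametrize(
    "outcome_rec,reason",
    [
        (make_record("rs2", "A", "G"), "missing_in_outcome"),
        (make_record("rs1", "A", "C"), "allele_mismatch"),
    ],
)
def test_harmonize_drop_reasons(outcome_rec, reason):
    exp = [make_record("rs1", "A", "G"), make_record("rs9", "C", "T")]
    out = [outcome_rec, make_record("rs9", "C", "T")]
    study = harmonize(exp, out)
    assert study.drop_log == {"rs1": reason}
    assert study.snps == ["rs9"]


def test_harmonize_drops_palindromic_unconditionally():
    exp = [make_record("rs1", "A", "T", eaf=0.10), make_record("rs2", "C", "T")]
    out = [make_record("rs1", "A", "T", eaf=0.10), make_record("rs2", "C", "T")]
    study = harmonize(exp, out)
    assert "rs1" not in study.snps
    assert study.drop_log["rs1"] == "palindromic"


def test_harmonize_empty_intersection_raises():
    exp = [make_record("rs1", "A", "G")]
    out = [make_record("rs2", "A", "G")]
    with pytest.raises(HarmonizationError, match="no shared instruments"):
        harmonize(exp, out)


def test_harmonize_each_dropped_snp_has_one_reason():
    # mixture of palindromic, missing, mismatching and clean SNPs
    exp = [
        make_record("rs1", "A", "T"),          # palindromic
        make_record("rs2", "A", "G"),          # missing from outcome
        make_record("rs3", "A", "G"),          # allele mismatch
        make_record("rs4", "C", "T"),          # clean
        make_record("rs5", "G", "T"),          # clean, swapped in outcome
    ]
    out = [
        make_record("rs1", "A", "T"),
        make_record("rs3", "A", "C"),
        make_record("rs4", "C", "T"),
        make_record("rs5", "T", "G", beta=-0.2),
    ]
    study = harmonize(exp, out)
    assert sorted(study.snps) == ["rs4", "rs5"]
    assert len(study.drop_log) == len(exp) - study.n_snp
    assert study.outcome_beta[study.snps.index("rs5")] == pytest.approx(0.2)


def test_harmonize_idempotent():
    exp = [make_record("rs1", "A", "G", beta=0.1), make_record("rs2", "C", "T", beta=-0.3)]
    out = [make_record("rs1", "G", "A", beta=-0.05), make_record("rs2", "C", "T", beta=0.02)]
    first = harmonize(exp, out)
    # re-express the harmonized pair as records and harmonize again
    exp2 = [
        dataclasses.replace(e, effect_allele=ea, other_allele=oa, beta=b)
        for e, ea, oa, b in zip(exp, first.effect_allele, first.other_allele, first.exposure_beta)
    ]
    out2 = [
        dataclasses.replace(e, effect_allele=ea, other_allele=oa, beta=b, eaf=None)
        for e, ea, oa, b in zip(exp, first.effect_allele, first.other_allele, first.outcome_beta)
    ]
    second = harmonize(exp2, out2)
    assert second.snps == first.snps
    np.testing.assert_array_equal(second.outcome_beta, first.outcome_beta)
    np.testing.assert_array_equal(second.exposure_beta, first.exposure_beta)


def test_harmonize_invariant_under_outcome_allele_swap():
    """Swapping effect/other alleles and negating beta in the outcome
    table is a pure re-encoding; the harmonized study must not change."""
    exp = [make_record("rs1", "A", "G", beta=0.1), make_record("rs2", "C", "T", beta=0.2)]
    out = [make_record("rs1", "A", "G", beta=0.05, eaf=0.4),
           make_record("rs2", "C", "T", beta=-0.01, eaf=0.6)]
    swapped = [
        dataclasses.replace(
            r, effect_allele=r.other_allele, other_allele=r.effect_allele,
            beta=-r.beta, eaf=1 - r.eaf,
        )
        for r in out
    ]
    a, b = harmonize(exp, out), harmonize(exp, swapped)
    assert a.snps == b.snps
    np.testing.assert_array_equal(a.outcome_beta, b.outcome_beta)
    np.testing.assert_array_equal(a.outcome_se, b.outcome_se)


def test_harmonize_result_never_larger_than_inputs(rng):
    for _ in range(20):
        n_exp, n_out = rng.integers(1, 8, size=2)
        exp = [make_record(f"rs{i}", "A", "G") for i in rng.choice(10, n_exp, replace=False)]
        out = [make_record(f"rs{i}", "A", "G") for i in rng.choice(10, n_out, replace=False)]
        try:
            study = harmonize(exp, out)
        except HarmonizationError:
            continue
        assert study.n_snp <= min(len(exp), len(out))
        assert study.n_snp + len(study.drop_log) == len(exp)
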