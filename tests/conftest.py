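import numpy as np
import pytest

from mrkit import HarmonizedStudy, SummaryStatRecord


def make_record(snp="rs1", ea="A", oa="G", beta=0.1, se=0.01, pval=1e-10, eaf=0.3, n=10000):
    return SummaryStatRecord(
        snp_id=snp, effect_allele=ea, other_allele=oa,
        beta=beta, se=se, pval=pval, eaf=eaf, n=n,
    )


def make_study(gx, se_gx, gy, se_gy, mediator_beta=None, mediator_se=None):
    """Harmonized study from raw arrays with synthetic allele labels."""
    j = len(gx)
    return HarmonizedStudy(
        snps=[f"rs{i+1}" for i in range(j)],
        effect_allele=["A"] * j,
        other_allele=["G"] * j,
        exposure_beta=np.asarray(gx, float),
        exposure_se=np.asarray(se_gx, float),
        outcome_beta=np.asarray(gy, float),
        outcome_se=np.asarray(se_gy, float),
        mediator_beta=None if mediator_beta is None else np.asarray(mediator_beta, float),
        mediator_se=None if mediator_se is None else np.asarray(mediator_se, float),
    )


def random_study(rng, j=None, mediator=False):
    """A random well-conditioned harmonized study for property tests."""
    if j is None:
        j = int(rng.integers(2, 21))
    gx = rng.uniform(0.05, 0.2, j) * rng.choice([-1, 1], j)
    se_gx = rng.uniform(0.005, 0.02, j)
    gy = rng.normal(0.2 * gx, 0.02)
    se_gy = rng.uniform(0.01, 0.05, j)
    kwargs = {}
    if mediator:
        kwargs = {
            "mediator_beta": rng.normal(0.3 * gx, 0.01),
            "mediator_se": rng.uniform(0.005, 0.02, j),
        }
    return make_study(gx, se_gx, gy, se_gy, **kwargs)


@pytest.fixture
def two_snp_study():
    """Hand-checkable two-instrument study: Wald ratios 0.2 and 0.3 with
    IVW weights 400 and 100."""
    return make_study(
        gx=[0.1, 0.1], se_gx=[0.01, 0.01],
        gy=[0.02, 0.03], se_gy=[0.005, 0.01],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
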