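import numpy as np
import pytest
from hypothesis import strategies as st

from mrpipe.sumstats import AssociationRecord, HarmonizedInstrument, SumstatsTable


def make_record(
    snp_id="rs1",
    chrom="1",
    pos=1000,
    effect_allele="A",
    other_allele="G",
    beta=0.1,
    se=0.01,
    pvalue=1e-10,
    eaf=0.3,
    n=10000,
):
    return AssociationRecord(
        snp_id=snp_id,
        chrom=chrom,
        pos=pos,
        effect_allele=effect_allele,
        other_allele=other_allele,
        beta=beta,
        se=se,
        pvalue=pvalue,
        eaf=eaf,
        n=n,
    )


def make_instrument(
    snp_id="rs1",
    beta_exposure=0.1,
    se_exposure=0.01,
    beta_outcome=0.05,
    se_outcome=0.01,
    effect_allele="A",
    other_allele="G",
    eaf_exposure=0.3,
):
    return HarmonizedInstrument(
        snp_id=snp_id,
        effect_allele=effect_allele,
        other_allele=other_allele,
        beta_exposure=beta_exposure,
        se_exposure=se_exposure,
        beta_outcome=beta_outcome,
        se_outcome=se_outcome,
        pvalue_exposure=1e-10,
        pvalue_outcome=0.5,
        eaf_exposure=eaf_exposure,
    )


def random_instruments(rng, n, beta=0.5, het_sd=0.0):
    """n instruments whose true Wald ratio is `beta` plus optional spread."""
    out = []
    for j in range(n):
        bx = rng.uniform(0.05, 0.4) * rng.choice([-1.0, 1.0])
        sy = rng.uniform(0.005, 0.05)
        by = beta * bx + rng.normal(0.0, het_sd) * abs(bx)
        out.append(
            make_instrument(
                snp_id=f"rs{j + 1}",
                beta_exposure=bx,
                se_exposure=rng.uniform(0.002, 0.01),
                beta_outcome=by,
                se_outcome=sy,
            )
        )
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


# hypothesis strategy for valid association records
_alleles = st.sampled_from("ACGT")


@st.composite
def association_records(draw, snp_id=None):
    ea = draw(_alleles)
    oa = draw(_alleles.filter(lambda a: a != ea))
    return AssociationRecord(
        snp_id=snp_id or draw(st.from_regex(r"rs[0-9]{1,7}", fullmatch=True)),
        chrom=draw(st.sampled_from([str(c) for c in range(1, 23)])),
        pos=draw(st.integers(min_value=1, max_value=2**31)),
        effect_allele=ea,
        other_allele=oa,
        beta=draw(st.floats(-2, 2, allow_nan=False)),
        se=draw(st.floats(1e-6, 1.0, allow_nan=False, exclude_min=True)),
        pvalue=draw(st.floats(1e-300, 1.0, exclude_min=False)),
        eaf=draw(st.one_of(st.none(), st.floats(0.0, 1.0))),
        n=draw(st.one_of(st.none(), st.integers(1, 10**7))),
    )


@st.composite
def sumstats_tables(draw, min_size=1, max_size=8):
    n = draw(st.integers(min_size, max_size))
    records = [
        draw(association_records(snp_id=f"rs{i + 1}")) for i in range(n)
    ]
    return SumstatsTable(records=tuple(records), trait_label="hyp")
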