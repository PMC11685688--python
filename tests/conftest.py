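import math

import pytest
from scipy import stats

from mrscan.gwas_io import AssociationRecord, SummaryDataset, VariantKey
from mrscan.harmonize import HarmonizedPair, KEPT_AS_IS


def make_record(
    chrom="1",
    pos=1_000_000,
    ea="A",
    oa="G",
    beta=0.1,
    se=0.01,
    pvalue=None,
    eaf=0.3,
    n=10_000,
):
    """Association record with p derived from beta/se unless given."""
    if pvalue is None:
        pvalue = max(2 * stats.norm.sf(abs(beta) / se), 5e-324)
    return AssociationRecord(
        variant=VariantKey(str(chrom), pos, ea, oa),
        beta=beta, se=se, pvalue=pvalue, eaf=eaf, n=n,
    )


def make_dataset(records, trait_name="trait", trait_type="binary"):
    ds = SummaryDataset(trait_name=trait_name, trait_type=trait_type)
    for rec in records:
        ds.add(rec)
    return ds


def make_pair(beta_exp, se_exp, beta_out, se_out, pos=1_000_000, chrom="1"):
    """Already-harmonized pair for estimator tests."""
    return HarmonizedPair(
        variant=VariantKey(str(chrom), pos, "A", "G"),
        beta_exp=beta_exp, se_exp=se_exp,
        beta_out=beta_out, se_out=se_out,
        action=KEPT_AS_IS,
    )


@pytest.fixture
def two_snp_pairs():
    """The worked inverse-variance example: ratios (0.2, 0.05) and (0.4, 0.1),
    i.e. weights 400 and 100, pooled estimate 0.24, Q = 3.2."""
    return [
        make_pair(1.0, 0.1, 0.2, 0.05, pos=1_000_000),
        make_pair(1.0, 0.1, 0.4, 0.10, pos=2_000_000),
    ]


def assert_records_equal(a, b):
    assert a.variant == b.variant
    for f in ("beta", "se", "pvalue"):
        assert getattr(a, f) == getattr(b, f), f
    for f in ("eaf",):
        x, y = getattr(a, f), getattr(b, f)
        assert (x is None) == (y is None)
        if x is not None:
            assert math.isclose(x, y, rel_tol=0, abs_tol=0)
    assert a.n == b.n
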