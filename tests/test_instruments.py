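"""Instrument selection filters, clumping and strength statistics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mrscan.exceptions import ConfigurationError, DomainError
from mrscan.instruments import (
    assemble_instrument_set,
    clump,
    cross_trait_pleiotropy_filter,
    exclude_outcome_associated,
    f_statistic,
    select_by_pvalue,
    snp_r2,
    zero_ld,
)

from conftest import make_dataset, make_record


class TestSelectByPvalue:
    def test_threshold_is_inclusive_and_sorted(self):
        ds = make_dataset([
            make_record(pos=1, pvalue=1e-9),
            make_record(pos=2, pvalue=1e-7),
            make_record(pos=3, pvalue=5e-8),
        ])
        hits = select_by_pvalue(ds)
        assert [r.variant.pos for r in hits] == [1, 3]

    def test_no_hits_is_empty(self):
        ds = make_dataset([make_record(pos=i, pvalue=1.0) for i in range(1, 5)])
        assert select_by_pvalue(ds) == []

    def test_matches_brute_force_on_random_records(self):
        rng = np.random.default_rng(0)
        recs = [
            make_record(chrom=str(rng.integers(1, 23)), pos=int(p),
                        pvalue=float(10 ** rng.uniform(-12, 0)))
            for p in rng.choice(10**6, size=1000, replace=False)
        ]
        ds = make_dataset(recs)
        got = select_by_pvalue(ds, 5e-8)
        expected = sorted(
            (r for r in ds if r.pvalue <= 5e-8),
            key=lambda r: (r.pvalue, r.variant.sort_key()),
        )
        assert got == expected

    def test_ties_break_by_coordinate(self):
        ds = make_dataset([
            make_record(chrom="2", pos=5, pvalue=1e-9),
            make_record(chrom="1", pos=9, pvalue=1e-9),
        ])
        hits = select_by_pvalue(ds)
        assert [(r.variant.chrom, r.variant.pos) for r in hits] == [("1", 9), ("2", 5)]


def ld_from_table(table):
    """LD lookup from {(posA, posB): r} on a single chromosome."""
    def lookup(a, b):
        if a == b:
            return 1.0
        return table.get((a.pos, b.pos), table.get((b.pos, a.pos), 0.0))
    return lookup


class TestClump:
    def test_single_candidate_is_its_own_index(self):
        rec = make_record(pvalue=1e-10)
        assert clump([rec], zero_ld) == [rec]

    def test_window_removes_nearby_snp(self):
        """Middle SNP 50 kb from the top hit falls inside the 100-kb window
        even at r2 = 0; the far SNP survives."""
        top = make_record(pos=1_000_000, pvalue=1e-12)
        near = make_record(pos=1_050_000, pvalue=1e-9)
        far = make_record(pos=2_000_000, pvalue=1e-8)
        out = clump([top, near, far], zero_ld)
        assert out == [top, far]

    def test_r2_rule_removes_distant_correlated_snp(self):
        """500 kb apart is outside the window but r2 = 0.5 > 0.001 removes it."""
        a = make_record(pos=1_000_000, pvalue=1e-12)
        b = make_record(pos=1_500_000, pvalue=1e-9)
        ld = ld_from_table({(1_000_000, 1_500_000): np.sqrt(0.5)})
        assert clump([a, b], ld) == [a]

    def test_different_chromosomes_ignore_window(self):
        a = make_record(chrom="1", pos=1_000_000, pvalue=1e-12)
        b = make_record(chrom="2", pos=1_010_000, pvalue=1e-9)
        assert clump([a, b], zero_ld) == [a, b]

    def test_negative_parameters_rejected(self):
        with pytest.raises(ConfigurationError):
            clump([], zero_ld, r2_threshold=-0.1)
        with pytest.raises(ConfigurationError):
            clump([], zero_ld, window_kb=-1)

    def test_deterministic(self):
        rng = np.random.default_rng(4)
        recs = [
            make_record(pos=int(p), pvalue=float(10 ** rng.uniform(-12, -8)))
            for p in rng.choice(10**7, size=40, replace=False)
        ]
        assert clump(recs, zero_ld) == clump(list(reversed(recs)), zero_ld)


def brute_force_reference_clump(records, ld, r2_threshold, window_kb):
    """Independent greedy reference: explicit conflict matrix + set removal."""
    order = sorted(
        range(len(records)),
        key=lambda i: (records[i].pvalue, records[i].variant.sort_key()),
    )
    n = len(records)
    conflict = [[False] * n for _ in range(n)]
    for i, j in itertools.combinations(range(n), 2):
        vi, vj = records[i].variant, records[j].variant
        close = vi.chrom == vj.chrom and abs(vi.pos - vj.pos) <= window_kb * 1000
        correlated = ld(vi, vj) ** 2 > r2_threshold
        conflict[i][j] = conflict[j][i] = close or correlated
    alive = set(order)
    picked = []
    for i in order:
        if i not in alive:
            continue
        picked.append(i)
        alive.discard(i)
        alive -= {j for j in alive if conflict[i][j]}
    return [records[i] for i in picked]


def enumerate_small_clump_instances():
    """Small instances over enumerated LD levels and position layouts."""
    rng = np.random.default_rng(20)
    instances = []
    for n_snps in (2, 3, 5, 8):
        for rho in (0.0, 0.02, 0.5, 0.9):
            for layout in ("tight", "spread", "mixed"):
                if layout == "tight":
                    positions = 1_000_000 + np.arange(n_snps) * 10_000
                elif layout == "spread":
                    positions = 1_000_000 + np.arange(n_snps) * 500_000
                else:
                    positions = np.sort(rng.choice(5_000_000, n_snps, replace=False)) + 1
                chroms = rng.choice(["1", "1", "2"], size=n_snps)
                pvals = 10 ** rng.uniform(-12, -8, size=n_snps)
                recs = [
                    make_record(chrom=chroms[i], pos=int(positions[i]),
                                pvalue=float(pvals[i]))
                    for i in range(n_snps)
                ]
                table = {}
                for i, j in itertools.combinations(range(n_snps), 2):
                    if chroms[i] == chroms[j] and rng.random() < 0.6:
                        table[(int(positions[i]), int(positions[j]))] = rho
                instances.append((recs, ld_from_table(table)))
    return instances


def test_clump_matches_reference_on_enumerated_small_instances():
    """Greedy output equals an independent reference implementation, and no
    retained pair violates either the r2 or the window rule."""
    for recs, ld in enumerate_small_clump_instances():
        got = clump(recs, ld, 0.001, 100)
        ref = brute_force_reference_clump(recs, ld, 0.001, 100)
        assert got == ref
        for a, b in itertools.combinations(got, 2):
            va, vb = a.variant, b.variant
            assert ld(va, vb) ** 2 <= 0.001
            if va.chrom == vb.chrom:
                assert abs(va.pos - vb.pos) > 100_000


class TestOutcomeExclusion:
    def test_strongly_outcome_associated_removed(self):
        snp = make_record(pos=100)
        outcome = make_dataset([make_record(pos=100, pvalue=1e-6)], "cancer")
        assert exclude_outcome_associated([snp], outcome) == []

    def test_weakly_associated_retained(self):
        snp = make_record(pos=100)
        outcome = make_dataset([make_record(pos=100, pvalue=0.5)], "cancer")
        assert exclude_outcome_associated([snp], outcome) == [snp]

    def test_missing_from_outcome_retained_here(self):
        snp = make_record(pos=100)
        outcome = make_dataset([make_record(pos=999, pvalue=0.5)], "cancer")
        assert exclude_outcome_associated([snp], outcome) == [snp]

    def test_matches_brute_force_on_mixed_set(self):
        rng = np.random.default_rng(8)
        snps = [make_record(pos=i * 1000) for i in range(1, 11)]
        out_p = {i * 1000: float(10 ** rng.uniform(-8, 0)) for i in range(1, 11)}
        outcome = make_dataset(
            [make_record(pos=p, pvalue=pv) for p, pv in out_p.items()], "cancer"
        )
        got = exclude_outcome_associated(snps, outcome, 5e-5)
        expected = [s for s in snps if out_p[s.variant.pos] > 5e-5]
        assert got == expected

    def test_commutes_with_exposure_pvalue_filter(self):
        """Exposure-p selection and outcome exclusion are order-insensitive."""
        rng = np.random.default_rng(9)
        recs = [
            make_record(pos=i, pvalue=float(10 ** rng.uniform(-10, 0)))
            for i in range(1, 50)
        ]
        ds = make_dataset(recs)
        outcome = make_dataset(
            [make_record(pos=i, pvalue=float(10 ** rng.uniform(-7, 0)))
             for i in range(1, 50)], "cancer"
        )
        a = exclude_outcome_associated(select_by_pvalue(ds), outcome)
        pre = exclude_outcome_associated(list(ds), outcome)
        b = [r for r in select_by_pvalue(ds) if r in pre]
        assert a == b


class TestCrossTraitFilter:
    def _others(self, n_sig, n_null, pos=100):
        sig = [make_dataset([make_record(pos=pos, pvalue=1e-9)], f"s{i}")
               for i in range(n_sig)]
        null = [make_dataset([make_record(pos=pos, pvalue=0.3)], f"n{i}")
                for i in range(n_null)]
        return sig + null

    def test_empty_other_exposures_is_identity(self):
        snps = [make_record(pos=100)]
        assert cross_trait_pleiotropy_filter(snps, []) == snps

    def test_significant_in_five_of_nine_removed(self):
        snp = make_record(pos=100)
        assert cross_trait_pleiotropy_filter([snp], self._others(5, 4)) == []

    def test_significant_in_four_of_nine_retained(self):
        snp = make_record(pos=100)
        assert cross_trait_pleiotropy_filter([snp], self._others(4, 5)) == [snp]


class TestSnpR2:
    def test_eaf_formula_hand_value(self):
        rec = make_record(beta=0.1, eaf=0.5)
        assert snp_r2(rec) == pytest.approx(0.005)

    def test_zero_beta_zero_r2(self):
        assert snp_r2(make_record(beta=0.0, eaf=0.3, pvalue=1.0)) == 0.0

    def test_z_fallback_hand_value(self):
        rec = make_record(beta=0.1, se=0.01, eaf=None, n=10_000)  # z = 10
        assert snp_r2(rec) == pytest.approx(100 / 10098)

    def test_fallback_without_n_is_domain_error(self):
        rec = make_record(eaf=None, n=None)
        with pytest.raises(DomainError):
            snp_r2(rec)


class TestFStatistic:
    @pytest.mark.parametrize(
        "r2,n,k,expected",
        [
            (0.0, 1000, 5, 0.0),
            (0.02, 10_000, 10, 0.02 * 9989 / (0.98 * 10)),  # ~20.3857
            (0.5, 103, 1, 101.0),
        ],
    )
    def test_hand_values(self, r2, n, k, expected):
        assert f_statistic(r2, n, k) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("r2,n,k", [(1.0, 100, 1), (-0.1, 100, 1), (0.1, 5, 5), (0.1, 100, 0)])
    def test_domain_errors(self, r2, n, k):
        with pytest.raises(DomainError):
            f_statistic(r2, n, k)

    @given(
        r2a=st.floats(min_value=0.0, max_value=0.98),
        dr=st.floats(min_value=1e-6, max_value=0.01),
        n=st.integers(min_value=100, max_value=10**6),
        k=st.integers(min_value=1, max_value=50),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_monotone_in_r2_and_k(self, r2a, dr, n, k):
        """F increases with explained variance and decreases with more
        instruments at fixed total R2."""
        r2b = min(r2a + dr, 0.99)
        assert f_statistic(r2b, n, k) > f_statistic(r2a, n, k)
        if n > k + 2:
            assert f_statistic(r2a, n, k + 1) < f_statistic(r2a, n, k) or r2a == 0.0


def test_assemble_instrument_set_consistency():
    """Stored F recomputes from (r2_total, n, k)."""
    recs = [make_record(pos=p, beta=0.05, eaf=0.3, n=80_000) for p in (1, 2, 3)]
    iset = assemble_instrument_set("trait", recs)
    assert iset.k == 3
    assert iset.r2_total == pytest.approx(sum(snp_r2(r) for r in recs))
    assert iset.f_stat == pytest.approx(f_statistic(iset.r2_total, 80_000, 3))
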