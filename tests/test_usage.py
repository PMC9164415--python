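"""Codon / codon-pair usage census and usage-weighted FSS."""

import numpy as np
import pytest

from frameshift_kit import count_usage, expected_counts, usage_table, weighted_mean_fss
from frameshift_kit.genetic_code import CODONS
from frameshift_kit.simulate import random_cds_batch
from frameshift_kit.usage import PAIR_UNITS, UsageRecord


def _by_unit(records):
    return {r.unit: r for r in records}


class TestCounting:
    def test_single_cds_direct_counts(self):
        recs = _by_unit(count_usage(["ATGAAATAA"], unit="codon"))
        assert recs["ATG"].observed == 1
        assert recs["AAA"].observed == 1
        assert recs["TAA"].observed == 1
        assert sum(r.observed for r in recs.values()) == 3

    def test_single_cds_pair_counts(self):
        recs = _by_unit(count_usage(["ATGAAATAA"], unit="codon_pair"))
        assert recs["ATG-AAA"].observed == 1
        assert recs["AAA-TAA"].observed == 1
        assert sum(r.observed for r in recs.values()) == 2

    def test_pair_adjacency_contract(self, rng):
        """An n-codon CDS contributes exactly n-1 adjacent pairs; pairs never
        cross record boundaries."""
        seqs = random_cds_batch(20, 30, rng)
        recs = count_usage(seqs, unit="codon_pair")
        assert sum(r.observed for r in recs) == 20 * 29

    def test_codon_conservation(self, rng):
        seqs = random_cds_batch(100, 25, rng)
        recs = count_usage(seqs, unit="codon")
        assert sum(r.observed for r in recs) == 100 * 25

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            count_usage([], unit="codon")


class TestExpectations:
    def test_pair_expectation_closed_form(self):
        """Two-codon toy: E(a,b) = N_a N_b / N^2 * P from the marginals."""
        # 6 AAA, 4 CCC in one CDS -> 9 adjacent pairs
        cds = "AAA" * 6 + "CCC" * 4
        recs = count_usage([cds], unit="codon_pair")
        by = _by_unit(recs)
        n_pairs = 9
        p_a, p_c = 0.6, 0.4
        assert by["AAA-AAA"].expected == pytest.approx(p_a * p_a * n_pairs)
        assert by["AAA-CCC"].expected == pytest.approx(p_a * p_c * n_pairs)
        assert by["CCC-CCC"].expected == pytest.approx(p_c * p_c * n_pairs)

    def test_expectations_sum_to_observed_total(self, rng):
        seqs = random_cds_batch(30, 40, rng)
        for unit in ("codon", "codon_pair"):
            recs = count_usage(seqs, unit=unit)
            assert sum(r.expected for r in recs) == pytest.approx(
                sum(r.observed for r in recs))

    def test_uniform_usage_is_independence_fixed_point(self):
        """Uniform pair counts with uniform marginals give E = O, chi2 = 0."""
        records = [
            UsageRecord(unit=u, observed=4, expected=np.nan, chi2=np.nan,
                        status="over", frequency=1 / 4096)
            for u in PAIR_UNITS
        ]
        e = expected_counts(records, unit="codon_pair")
        np.testing.assert_allclose(e, 4.0)

    def test_codon_expectation_uniform_over_synonyms(self):
        # 6 AAA(K) + 2 AAG(K): class K has 2 codons -> E = 4 each
        recs = _by_unit(count_usage(["AAA" * 6 + "AAG" * 2], unit="codon"))
        assert recs["AAA"].expected == pytest.approx(4.0)
        assert recs["AAG"].expected == pytest.approx(4.0)
        assert recs["AAA"].status == "over"
        assert recs["AAG"].status == "under"

    def test_chi2_zero_iff_observed_equals_expected(self):
        recs = count_usage(["AAA" * 4 + "AAG" * 4], unit="codon")
        for r in recs:
            if r.unit in ("AAA", "AAG"):
                assert r.chi2 == 0.0 and r.status == "equal"

    def test_status_partition(self, rng):
        seqs = random_cds_batch(10, 50, rng)
        recs = count_usage(seqs, unit="codon_pair")
        assert len(recs) == 4096
        n = sum(r.status in ("over", "under", "absent", "equal") for r in recs)
        assert n == 4096


class TestWeightedFss:
    def _records(self, freqs, statuses):
        total = sum(freqs)
        return [
            UsageRecord(unit=CODONS[i], observed=int(f * 100), expected=1.0,
                        chi2=0.0, status=s, frequency=f / total)
            for i, (f, s) in enumerate(zip(freqs, statuses))
        ]

    def test_equal_usage_equals_unweighted_mean(self):
        recs = self._records([1, 1, 1], ["over", "over", "over"])
        fss = [2.0, -4.0, 8.0]
        assert weighted_mean_fss(recs, fss).value == pytest.approx(2.0)

    def test_all_weight_on_one_unit(self):
        recs = self._records([0, 5, 0], ["absent", "over", "absent"])
        assert weighted_mean_fss(recs, [1.0, -7.0, 3.0]).value == -7.0

    def test_subset_restriction_and_hand_computation(self):
        recs = self._records([2, 3, 5], ["over", "under", "over"])
        fss = [10.0, -20.0, 4.0]
        all_v = weighted_mean_fss(recs, fss, subset="all").value
        over_v = weighted_mean_fss(recs, fss, subset="over").value
        assert all_v == pytest.approx((2 * 10 + 3 * -20 + 5 * 4) / 10)
        assert over_v == pytest.approx((2 * 10 + 5 * 4) / 7)

    def test_monotone_in_weight_shift_toward_high_fss(self):
        fss = [1.0, 5.0]
        low = [UsageRecord("AAA", 8, 1, 0, "over", 0.8),
               UsageRecord("AAC", 2, 1, 0, "over", 0.2)]
        high = [UsageRecord("AAA", 2, 1, 0, "over", 0.2),
                UsageRecord("AAC", 8, 1, 0, "over", 0.8)]
        assert (weighted_mean_fss(high, fss).value
                > weighted_mean_fss(low, fss).value)

    def test_empty_subset_rejected(self):
        recs = self._records([1, 1, 1], ["over", "over", "over"])
        with pytest.raises(ValueError, match="under"):
            weighted_mean_fss(recs, [1, 2, 3], subset="under")

    def test_mismatched_lengths_rejected(self):
        recs = self._records([1, 1], ["over", "over"])
        with pytest.raises(ValueError, match="same units"):
            weighted_mean_fss(recs, [1.0])


def test_usage_table_schema(rng):
    seqs = random_cds_batch(5, 30, rng)
    df = usage_table(seqs, unit="codon")
    assert list(df.columns) == [
        "unit", "observed", "expected", "chi2", "status", "frequency", "fss"]
    assert len(df) == 64
    assert df["frequency"].sum() == pytest.approx(1.0)
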