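"""Substitution enumeration, FSS sums, and alternative genetic codes."""

import numpy as np
import pytest

from frameshift_kit import (
    compatible_codes,
    enumerate_substitutions,
    random_codes,
    rank_code,
    standard_code,
    substitution_stats,
    sum_fss,
)
from frameshift_kit.code_optimality import pool_sum_fss
from frameshift_kit.genetic_code import CODONS, CodonTable
from frameshift_kit.scoring import ScoringMatrix

#: Synonym-class sizes of the standard code (6x3, 4x5, 3, 2x9, 1x2).
SGC_CLASS_SIZES = sorted([6, 6, 6, 4, 4, 4, 4, 4, 3, 2, 2, 2, 2, 2, 2, 2, 2, 2, 1, 1])


def _flat_matrix(value: float) -> ScoringMatrix:
    from frameshift_kit.genetic_code import AA_LETTERS

    scores = {(a, b): value for a in AA_LETTERS for b in AA_LETTERS}
    return ScoringMatrix("flat", scores)


class TestEnumeration:
    @pytest.mark.parametrize(
        "kind,total", [("RCS", 4096), ("ICS", 256), ("FCS", 512),
                       ("FCS_FF", 256), ("FCS_RF", 256)]
    )
    def test_exhaustive_counts(self, kind, total):
        assert len(enumerate_substitutions(kind)) == total

    def test_ics_unchanged_count(self):
        stats = substitution_stats("ICS")
        assert stats["unchanged"] == 64

    def test_forward_shift_construction(self):
        """AAA shifted forward with incoming G gives AAG, synonymous K->K."""
        recs = [r for r in enumerate_substitutions("FCS_FF")
                if r.from_codon == "AAA" and r.to_codon == "AAG"]
        assert len(recs) == 1
        assert recs[0].cls == "SYN" and not recs[0].unchanged

    def test_fcs_against_brute_force_shift_oracle(self, sgc, gon250):
        """Every FCS record matches an independent string-level shift."""
        expected = set()
        for c in CODONS:
            for b in "ACGT":
                expected.add((c, c[1] + c[2] + b, "FCS_FF"))
                expected.add((c, b + c[0] + c[1], "FCS_RF"))
        got = {(r.from_codon, r.to_codon, r.kind)
               for r in enumerate_substitutions("FCS", sgc, gon250)}
        assert got == expected

    def test_classes_partition_the_enumeration(self):
        for kind in ("RCS", "ICS", "FCS"):
            s = substitution_stats(kind)
            assert s["SYN"] + s["POS"] + s["NEG"] == s["total"]
            assert s["unchanged"] <= s["SYN"]


class TestStructuralCells:
    """Class counts fixed by the code's combinatorics alone."""

    def test_forward_frameshift_column(self):
        s = substitution_stats("FCS_FF")
        assert s["unchanged"] == 4      # the four triplet monomers
        assert s["SYN"] == 14           # 4 unchanged + 10 changed synonymous

    def test_forward_and_reverse_columns_identical(self):
        ff = substitution_stats("FCS_FF")
        rf = substitution_stats("FCS_RF")
        for key in ("unchanged", "SYN", "POS", "NEG"):
            assert ff[key] == rf[key]

    def test_interchangeable_column(self):
        s = substitution_stats("ICS")
        assert s["SYN"] == 192
        assert s["total"] - s["unchanged"] == 192  # changed = 192

    def test_random_synonymous_count_by_class_census(self):
        """Exhaustive third-class-aware census: sum over synonym classes of
        n^2 (including the 3x3 stop block) gives 244 synonymous RCSs."""
        s = substitution_stats("RCS")
        sizes = [len(v) for v in standard_code().synonym_classes.values()] + [3]
        assert s["SYN"] == sum(n * n for n in sizes) == 244


class TestSumFss:
    def test_zero_matrix_gives_zero_sum(self):
        assert sum_fss(matrix=_flat_matrix(0.0)).sum_fss == 0.0

    def test_flat_matrix_counts_substitutions(self):
        # every FCS scores 1 (stop pairs too: min_core=1>0 ... star-star=1)
        m = _flat_matrix(1.0)
        assert sum_fss(matrix=m).sum_fss == 512.0

    def test_matches_independent_double_loop(self, sgc, gon250):
        total = 0.0
        for c in CODONS:
            for b in "ACGT":
                for shifted in (c[1] + c[2] + b, b + c[0] + c[1]):
                    total += gon250.score(sgc[c], sgc[shifted])
        assert sum_fss(sgc, gon250).sum_fss == pytest.approx(total)

    @pytest.mark.parametrize("name", ["GON250", "BLOSUM62", "PAM250"])
    def test_mean_fss_exceeds_mean_rss(self, name):
        """Frameshift substitutions are systematically milder than random
        ones under every bundled matrix."""
        fss = substitution_stats("FCS", matrix=name)["mean_score"]
        rss = substitution_stats("RCS", matrix=name)["mean_score"]
        assert fss > rss


class TestRandomCodes:
    def test_preserves_degeneracy_class_sizes_and_stops(self, sgc):
        for code in random_codes(20, seed=7):
            sizes = sorted(len(v) for v in code.synonym_classes.values())
            assert sizes == SGC_CLASS_SIZES
            assert set(code.stop_codons) == set(sgc.stop_codons)
            assert len(code.synonym_classes) == 20

    def test_same_seed_same_stream(self):
        a = [c.assignment for c in random_codes(50, seed=11)]
        b = [c.assignment for c in random_codes(50, seed=11)]
        assert a == b

    def test_proportional_swap_method(self, sgc):
        for code in random_codes(5, seed=3, method="proportional_swap"):
            sizes = sorted(len(v) for v in code.synonym_classes.values())
            assert sizes == SGC_CLASS_SIZES


class TestCompatibleCodes:
    def test_full_enumeration_count(self):
        assert len(compatible_codes()) == 13824

    def test_wobble_constrained_count(self):
        assert len(compatible_codes(wobble_constrained=True)) == 1152

    def test_contains_identity(self, sgc):
        codes = compatible_codes(wobble_constrained=True)
        identity = [c for c in codes if c.assignment == dict(sgc.assignment)]
        assert len(identity) >= 1

    def test_per_aa_codon_counts_preserved(self, sgc):
        code = compatible_codes(wobble_constrained=True)[37]
        got = sorted(len(v) for v in code.synonym_classes.values())
        assert got == SGC_CLASS_SIZES
        assert len(code.stop_codons) == 3


class TestRankCode:
    def test_rank_one_among_self_copies(self, sgc, gon250):
        pool = [CodonTable(f"c{i}", dict(sgc.assignment)) for i in range(5)]
        rank, pct = rank_code(sgc, pool, gon250)
        assert rank == 1 and pct == pytest.approx(0.2)

    def test_matches_sort_oracle(self, gon250):
        pool = list(random_codes(30, seed=5))
        target = pool[7]
        rank, _ = rank_code(target, pool, gon250)
        sums = pool_sum_fss(pool, gon250)
        assert rank == 1 + int((sums > sums[7]).sum())

    def test_invariant_under_pool_permutation(self, sgc, gon250, rng):
        pool = list(random_codes(40, seed=9))
        rank1, _ = rank_code(sgc, pool, gon250)
        shuffled = [pool[i] for i in rng.permutation(len(pool))]
        rank2, _ = rank_code(sgc, shuffled, gon250)
        assert rank1 == rank2
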