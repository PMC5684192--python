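"""Clonotype sharing, the >=10-cell rule and the percentile threshold."""

import pytest

from temra_repertoire import (
    Repertoire,
    ValidationError,
    cell_mass_fraction,
    highly_represented,
    overlap_report,
    percentile_threshold,
    shared_fraction,
)
from tests.conftest import random_repertoire


def rep(clones, donor="d1", subset="TEM"):
    return Repertoire(donor, subset, clones)


class TestSharedFraction:
    def test_partial_overlap(self):
        src = rep({"CAHF": 1, "CAYF": 1, "CAEF": 1})
        ref = rep({"CAHF": 5, "CAQF": 2}, subset="TCM")
        assert shared_fraction(src, ref) == pytest.approx(1 / 3)

    def test_identity_and_disjoint(self):
        a = rep({"CAHF": 2, "CAYF": 3})
        assert shared_fraction(a, a) == 1.0
        assert shared_fraction(a, rep({"CAQF": 1}, subset="TCM")) == 0.0

    def test_reference_abundance_is_irrelevant(self):
        src = rep({"CAHF": 1, "CAYF": 1})
        assert shared_fraction(src, rep({"CAHF": 1}, subset="TCM")) == \
            shared_fraction(src, rep({"CAHF": 999}, subset="TCM"))

    def test_asymmetric(self):
        a = rep({"CAHF": 1, "CAYF": 1, "CAEF": 1, "CAWF": 1})
        b = rep({"CAHF": 1}, subset="TCM")
        assert shared_fraction(a, b) == 0.25
        assert shared_fraction(b, a) == 1.0


class TestHighlyRepresented:
    def test_threshold_is_inclusive(self, small_rep):
        # counts 12, 10, 9, 1 -> "at least 10 cells" keeps 12 and 10
        assert highly_represented(small_rep, 10) == {"CASSF", "CARGF"}

    def test_min_cells_one_keeps_everything(self, small_rep):
        assert highly_represented(small_rep, 1) == set(small_rep.clones)

    def test_matches_bruteforce_on_random_repertoire(self, rng):
        r = random_repertoire(rng, 500, max_count=40)
        for t in (1, 5, 10, 40, 41):
            assert highly_represented(r, t) == \
                {c for c, n in r.clones.items() if n >= t}

    def test_monotone_in_threshold(self, rng):
        r = random_repertoire(rng, 200)
        prev = highly_represented(r, 1)
        for t in range(2, 20):
            cur = highly_represented(r, t)
            assert cur <= prev
            prev = cur


class TestCellMass:
    def test_arithmetic(self, small_rep):
        assert cell_mass_fraction(small_rep, {"CASSF", "CARGF"}) == \
            pytest.approx(22 / 32)

    def test_full_and_empty_sets(self, small_rep):
        assert cell_mass_fraction(small_rep, set(small_rep.clones)) == 1.0
        assert cell_mass_fraction(small_rep, set()) == 0.0

    def test_unknown_clonotype_rejected(self, small_rep):
        with pytest.raises(ValidationError):
            cell_mass_fraction(small_rep, {"CQQQF"})


class TestPercentileThreshold:
    def test_one_dominant_clone_in_hundred(self):
        clones = {f"CA{'ACDEFGHIKLMNPQRSTVWY'[i % 20]}{i // 20}F"
                  .replace("0", "A").replace("1", "C").replace("2", "D")
                  .replace("3", "E").replace("4", "F"): 1
                  for i in range(99)}
        clones["CDWMF"] = 50
        t = percentile_threshold(rep(clones), top_fraction=0.01)
        assert t == 2  # exactly 1/100 clonotypes has count >= 2

    def test_enumerated_example(self):
        r = rep({"CAHF": 20, "CAYF": 15, "CAEF": 10, "CAWF": 5, "CAVF": 1})
        # brute force: smallest t with fraction(count >= t) <= 0.4 is 11
        assert percentile_threshold(r, top_fraction=0.4) == 11

    @staticmethod
    def _brute_force(counts, tf):
        """Independent enumeration of the threshold contract: smallest t
        selecting a non-empty set of at most tf of the clonotypes, else
        the smallest t selecting exactly the maximal-count clones."""
        n, mx = len(counts), max(counts)
        for t in range(1, mx + 2):
            sel = sum(c >= t for c in counts)
            if 0 < sel and sel / n <= tf:
                return t
        return max(c for c in counts if c < mx) + 1

    def test_matches_bruteforce_enumeration(self, rng):
        for size, max_count in ((300, 30), (50, 8), (1000, 200)):
            r = random_repertoire(rng, size, max_count=max_count)
            counts = list(r.clones.values())
            for tf in (0.01, 0.05, 0.2, 0.5):
                assert percentile_threshold(r, tf) == \
                    self._brute_force(counts, tf)

    def test_all_tied_returns_sentinel_with_warning(self):
        r = rep({"CAHF": 3, "CAYF": 3, "CAEF": 3})
        with pytest.warns(UserWarning, match="tied"):
            assert percentile_threshold(r, 0.1) == 4

    def test_dominant_clone_fallback(self):
        # 1/3 > 0.05: no non-empty selection satisfies the fraction, so the
        # threshold selecting exactly the top clone is returned
        r = rep({"CAHF": 9, "CAYF": 2, "CAEF": 1})
        assert percentile_threshold(r, 0.05) == 3

    @pytest.mark.parametrize("tf", [0.0, 1.0, -0.2, 1.5])
    def test_invalid_fraction_rejected(self, small_rep, tf):
        with pytest.raises(ValidationError):
            percentile_threshold(small_rep, tf)


class TestOverlapReport:
    def test_composite_fields_match_components(self, rng):
        src = random_repertoire(rng, 150, max_count=30,
                                subset="TEMRA_GPR56pos")
        # reference sharing ~half the clonotypes
        keys = list(src.clones)
        ref_clones = {k: 1 for k in keys[:75]}
        ref_clones["CQQQF"] = 2
        ref = rep(ref_clones, subset="TEM")
        (s,) = overlap_report(src, [ref], min_cells=10)
        high = highly_represented(src, 10)
        assert s.n_source_clonotypes == src.richness
        assert s.fraction_shared == pytest.approx(shared_fraction(src, ref))
        assert s.n_high_clonotypes == len(high)
        if high:
            assert s.fraction_shared_high == pytest.approx(
                len(high & ref.clones.keys()) / len(high))
        assert s.cell_mass_fraction_high == pytest.approx(
            cell_mass_fraction(src, high))

    def test_empty_source_rejected(self):
        with pytest.raises(ValidationError):
            Repertoire("d", "TEM", {})
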