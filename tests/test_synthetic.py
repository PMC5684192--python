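"""Synthetic cohort generator: determinism, Zipf skew, linked sharing."""

import json

import numpy as np
import pytest

from temra_repertoire import (
    CohortSpec,
    SubsetSpec,
    ValidationError,
    fit_constant_fraction,
    paper_like_spec,
    random_cdr3,
    read_composition_table,
    sample_linked_cohort,
    sample_repertoire,
    shared_fraction,
    write_cohort,
)
from temra_repertoire.diversity import diversity_summary
from temra_repertoire.models import AMINO_ACIDS


class TestRandomCdr3:
    def test_structure_and_length_bounds(self, rng):
        for _ in range(200):
            s = random_cdr3(rng, (8, 20))
            assert s[0] == "C" and s[-1] == "F"
            assert 8 <= len(s) <= 20
            assert set(s) <= AMINO_ACIDS

    def test_deterministic_under_seed(self):
        a = [random_cdr3(np.random.default_rng(5)) for _ in range(10)]
        b = [random_cdr3(np.random.default_rng(5)) for _ in range(10)]
        assert a == b

    def test_rejection_yields_no_duplicates(self, rng):
        taken: set[str] = set()
        for _ in range(10_000):
            s = random_cdr3(rng, (8, 12), taken=taken)
            assert s not in taken
            taken.add(s)


class TestSampleRepertoire:
    def test_uniform_limit_is_nearly_polyclonal(self, rng):
        spec = SubsetSpec("TN", n_clonotypes_pool=50_000, zipf_exponent=0.0,
                          total_cells=1000)
        rep = sample_repertoire(spec, rng)
        assert diversity_summary(rep).normalized_clonality < 0.05

    def test_pool_of_one_is_monoclonal(self, rng):
        spec = SubsetSpec("TEM", n_clonotypes_pool=1, zipf_exponent=1.0,
                          total_cells=100)
        rep = sample_repertoire(spec, rng)
        assert rep.richness == 1
        assert diversity_summary(rep).normalized_clonality == 1.0

    def test_clonality_nondecreasing_in_zipf_exponent(self):
        """Average clonality over 20 seeds rises monotonically with the
        skew exponent at fixed pool and cell numbers."""
        means = []
        for z in (0.0, 0.5, 1.0, 1.5, 2.0):
            vals = []
            for seed in range(20):
                rng = np.random.default_rng(seed)
                spec = SubsetSpec("TEM", n_clonotypes_pool=500,
                                  zipf_exponent=z, total_cells=800)
                vals.append(diversity_summary(
                    sample_repertoire(spec, rng)).normalized_clonality)
            means.append(np.mean(vals))
        assert all(b > a for a, b in zip(means, means[1:]))

    def test_conserves_total_cells(self, rng):
        spec = SubsetSpec("TEM", n_clonotypes_pool=200, zipf_exponent=1.0,
                          total_cells=777)
        assert sample_repertoire(spec, rng).total_cells == 777


class TestLinkedCohort:
    def test_full_determinism_and_seed_sensitivity(self):
        a = sample_linked_cohort(paper_like_spec(seed=3, n_donors=2))
        b = sample_linked_cohort(paper_like_spec(seed=3, n_donors=2))
        c = sample_linked_cohort(paper_like_spec(seed=4, n_donors=2))
        for da, db in zip(a.donors, b.donors):
            for s in da.repertoires:
                assert da.repertoires[s].clones == db.repertoires[s].clones
        assert a.donors[0].repertoires["TEM"].clones != \
            c.donors[0].repertoires["TEM"].clones
        assert a.composition.equals(b.composition)

    def test_share_probability_one_gives_full_overlap(self):
        subsets = [
            SubsetSpec("TEM", n_clonotypes_pool=400, zipf_exponent=0.5,
                       total_cells=800),
            SubsetSpec("TEMRA_GPR56pos", n_clonotypes_pool=100,
                       zipf_exponent=1.0, total_cells=500,
                       share_from=[("TEM", 1.0)]),
        ]
        cohort = sample_linked_cohort(CohortSpec(subsets=subsets, n_donors=2,
                                                 seed=9))
        for d in cohort.donors:
            assert shared_fraction(d.repertoires["TEMRA_GPR56pos"],
                                   d.repertoires["TEM"]) == 1.0

    def test_measured_sharing_matches_parameter(self):
        """Sharing probability 0.55 (GPR56+ TEMRA from TEM) is recovered
        within 3 binomial standard errors, pooled over 20 seeded donors."""
        p = 0.55
        shared = total = 0
        for seed in range(20):
            cohort = sample_linked_cohort(paper_like_spec(seed=seed,
                                                          n_donors=1))
            d = cohort.donors[0]
            src = d.repertoires["TEMRA_GPR56pos"]
            ref = d.repertoires["TEM"]
            shared += len(src.clones.keys() & ref.clones.keys())
            total += src.richness
        se = np.sqrt(p * (1 - p) / total)
        assert abs(shared / total - p) <= 3 * se

    def test_composition_closes_the_loop_noise_free(self, tmp_path):
        spec = paper_like_spec(seed=2, n_donors=11)
        spec.noise_sd = 0.0
        cohort = sample_linked_cohort(spec)
        write_cohort(cohort, tmp_path)
        obs = read_composition_table(tmp_path / "composition.tsv")
        fit = fit_constant_fraction(obs)
        assert fit.c_hat == pytest.approx(0.008, abs=1e-6)

    def test_manifest_records_parameters(self, tmp_path):
        cohort = sample_linked_cohort(paper_like_spec(seed=6, n_donors=2))
        manifest = write_cohort(cohort, tmp_path)
        on_disk = json.loads((tmp_path / "manifest.json").read_text())
        assert on_disk == manifest
        assert on_disk["seed"] == 6
        assert on_disk["composition"]["c"] == 0.008
        assert {s["subset"] for s in on_disk["subsets"]} == {
            "TN", "TCM", "TEM", "TEMRA_GPR56neg", "TEMRA_GPR56pos"}

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValidationError):
            SubsetSpec("TEM", n_clonotypes_pool=0, zipf_exponent=1.0,
                       total_cells=10)
        with pytest.raises(ValidationError):
            SubsetSpec("TEM", n_clonotypes_pool=10, zipf_exponent=1.0,
                       total_cells=10, share_from=[("TCM", 0.7),
                                                   ("TN", 0.7)])
        with pytest.raises(ValidationError):
            CohortSpec(subsets=[SubsetSpec("A", 10, 0.0, 10,
                                           share_from=[("missing", 0.5)])])
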