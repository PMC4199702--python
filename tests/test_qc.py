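import itertools

import numpy as np
import pytest

from exhet import (
    GeneticMap,
    SimConfig,
    distortion_test,
    drop_duplicate_individuals,
    drop_redundant_markers,
    estimate_H,
    filter_markers_by_distortion,
    filter_missingness,
    flag_outlier_individuals,
    iterative_distortion_filter,
    marker_segregation,
    mask_tight_double_recombinants,
    qc_pipeline,
    simulate_population,
)
from conftest import make_matrix
from _oracles import mask_double_recombinants_reference


class TestEstimateH:
    def test_all_heterozygous(self):
        assert estimate_H(make_matrix([[1, 1], [1, 1]])) == 1.0

    def test_missing_excluded_from_denominator(self):
        m = make_matrix([[1, -1], [0, -1]])
        assert estimate_H(m) == 0.5

    def test_per_chromosome(self):
        m = make_matrix([[1, 0], [1, 2]], chroms=["1", "2"], positions=[1, 1])
        H = estimate_H(m, per_chromosome=True)
        assert H["1"] == 1.0 and H["2"] == 0.0

    def test_all_missing_is_an_error(self):
        with pytest.raises(ValueError):
            estimate_H(make_matrix([[-1, -1]]))


class TestDistortionTest:
    def test_exact_agreement_with_null(self):
        assert distortion_test(463, 74, 463, H_null=0.074) == pytest.approx(1.0)

    def test_missing_heterozygotes_under_mendelian_null(self):
        assert distortion_test(500, 0, 500, H_null=0.5) < 1e-15

    def test_null_choice_drives_retention(self):
        # same marker, opposite decisions under the two nulls
        assert distortion_test(199, 2, 199, H_null=0.005) > 1e-15
        assert distortion_test(199, 2, 199, H_null=0.5) < 1e-15

    def test_mendelian_null_equals_textbook_1_2_1(self):
        n_a, n_h, n_b = 30, 45, 25
        total = n_a + n_h + n_b
        expected = np.array([0.25, 0.5, 0.25]) * total
        chi2 = (((np.array([n_a, n_h, n_b]) - expected) ** 2) / expected).sum()
        from scipy.stats import chi2 as chi2_dist

        assert distortion_test(n_a, n_h, n_b, 0.5) == pytest.approx(chi2_dist.sf(chi2, 2))

    def test_zero_total_is_an_error(self):
        with pytest.raises(ValueError):
            distortion_test(0, 0, 0, 0.5)
        with pytest.raises(ValueError):
            distortion_test(1, 1, 1, 0.0)

    def test_extreme_statistics_stay_ordered_on_log_scale(self):
        m = make_matrix([[0] * 2] * 2000)  # 2000 individuals, all A at both markers
        seg = marker_segregation(m, H_null=0.5)
        assert (seg["log10_p"] < -300).all()  # far below float underflow of p itself


class TestDistortionFilter:
    def test_alpha_zero_removes_nothing(self):
        m = make_matrix([[0, 1], [2, 1], [0, 0]])
        out, report = filter_markers_by_distortion(m, H_null=0.5, alpha=0.0)
        assert out.n_markers == 2 and not report.removed_markers

    def test_type_one_error_control(self):
        # unlinked markers simulated under the model, tested at the matching null
        config = SimConfig(n_individuals=500, n_markers=400, map_length_cm=1e6, seed=11)
        m = simulate_population(config)
        H_null = 0.6373**6
        out, report = filter_markers_by_distortion(m, H_null, alpha=0.05)
        n_removed = len(report.removed_markers)
        assert 5 <= n_removed <= 45  # ~alpha * n_markers = 20

    def test_per_chromosome_override(self):
        geno = [[0, 0]] * 80 + [[1, 1]] * 40 + [[2, 2]] * 80
        m = make_matrix(geno, chroms=["1", "2"], positions=[1, 1])
        p = distortion_test(80, 40, 80, H_null=0.5)
        assert 1e-30 < p < 1e-15
        out, _ = filter_markers_by_distortion(
            m, H_null=0.5, alpha=1e-15, per_chromosome_alpha={"1": 1e-30}
        )
        assert list(out.markers.index) == ["m1"]

    def test_iterative_H_reestimation_converges(self):
        rng = np.random.default_rng(3)
        clean = rng.choice([0, 1, 2], p=[0.46, 0.08, 0.46], size=(300, 40))
        bad = np.ones((300, 10), dtype=np.int8)  # all-heterozygous markers
        m = make_matrix(np.hstack([clean, bad]))
        out, report, history = iterative_distortion_filter(m, alpha=1e-15)
        assert out.n_markers == 40
        assert report.H_before > report.H_after
        diffs = np.abs(np.diff(history))
        assert all(d1 >= d2 for d1, d2 in zip(diffs, diffs[1:]))


class TestMissingness:
    def test_complete_matrix_unchanged(self, tiny_matrix):
        m = make_matrix([[0, 1], [2, 1]])
        out, report = filter_missingness(m)
        assert out.equals(m) and not report.removed_markers

    def test_threshold_is_inclusive(self):
        geno = np.zeros((100, 2), dtype=np.int8)
        geno[:60, 0] = -1  # 60% missing -> removed
        geno[:59, 1] = -1  # 59% missing -> retained
        out, report = filter_missingness(make_matrix(geno))
        assert list(out.markers.index) == ["m2"]
        assert report.removed_markers[0][0] == "m1"

    def test_individual_filter_after_marker_filter(self):
        # individual is 50% missing only until the bad marker is removed
        geno = np.array([[-1, 0, -1], [0, 0, 0], [-1, 2, 2], [0, 2, 2]], dtype=np.int8)
        out, report = filter_missingness(make_matrix(geno), 0.5, 0.5)
        assert out.n_markers == 2
        assert [i for i, _ in report.removed_individuals] == ["i1"]

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            filter_missingness(make_matrix([[0]]), max_marker_missing=1.5)


class TestDuplicates:
    def test_identical_individual_removed_keeping_less_missing(self):
        geno = np.zeros((3, 10), dtype=np.int8)
        geno[1, 5] = -1  # i2 is i1 with one missing call
        geno[2] = 2
        out, report = drop_duplicate_individuals(make_matrix(geno))
        assert out.individuals == ["i1", "i3"]
        assert report.removed_individuals == [("i2", "duplicate_of:i1")]

    def test_below_threshold_pair_retained(self):
        geno = np.zeros((2, 100), dtype=np.int8)
        geno[1, :11] = 2  # 89% shared
        out, _ = drop_duplicate_individuals(make_matrix(geno), min_share=0.90)
        assert out.n_individuals == 2

    def test_chain_forms_single_group(self):
        # A~B and B~C above threshold, A~C below: connected component collapses
        rng = np.random.default_rng(0)
        a = rng.choice([0, 2], size=100).astype(np.int8)
        b = a.copy()
        b[:8] = 2 - b[:8]  # A~B share 92%
        c = b.copy()
        c[50:59] = 2 - c[50:59]  # B~C share 91%, A~C share <= 85%
        m = make_matrix(np.stack([a, b, c]), individuals=["A", "B", "C"])
        out, report = drop_duplicate_individuals(m, min_share=0.90)
        assert out.individuals == ["A"]
        assert {i for i, _ in report.removed_individuals} == {"B", "C"}

    def test_idempotent(self):
        geno = np.zeros((3, 10), dtype=np.int8)
        geno[2] = 1
        once, _ = drop_duplicate_individuals(make_matrix(geno))
        twice, rep = drop_duplicate_individuals(once)
        assert twice.equals(once) and not rep.removed_individuals


class TestRedundantMarkers:
    def test_identical_close_markers_collapse(self):
        geno = np.array([[0, 0, 2], [1, 1, 0], [2, 2, 1]], dtype=np.int8)
        m = make_matrix(geno, positions=[1000, 1500, 2000])
        out, report = drop_redundant_markers(m, window_bp=2000)
        assert list(out.markers.index) == ["m1", "m3"]
        assert report.removed_markers == [("m2", "redundant_with:m1")]

    def test_distant_identical_markers_kept(self):
        geno = np.array([[0, 0], [1, 1]], dtype=np.int8)
        m = make_matrix(geno, positions=[1000, 50_000])
        out, _ = drop_redundant_markers(m, window_bp=2000)
        assert out.n_markers == 2


class TestDoubleRecombinantMasking:
    def test_canonical_double_recombinant_masked(self):
        m = make_matrix([[0, 0, 2, 0, 0]], positions=[1000, 2000, 3000, 4000, 5000])
        out, report = mask_tight_double_recombinants(m, window=2000, units="bp")
        assert list(out.geno[0]) == [0, 0, -1, 0, 0]
        assert report.masked_genotype_count == 1

    def test_wide_interior_run_untouched(self):
        m = make_matrix([[0, 0, 2, 2, 2, 0, 0]], positions=[1, 1000, 2000, 3000, 4000, 5000, 6000])
        out, report = mask_tight_double_recombinants(m, window=2000, units="bp")
        assert report.masked_genotype_count == 0
        assert out.equals(m)

    def test_chromosome_ends_never_masked(self):
        m = make_matrix([[2, 0, 0, 0, 2]], positions=[1, 2, 3, 4, 5])
        out, _ = mask_tight_double_recombinants(m, window=10, units="bp")
        assert list(out.geno[0]) == [2, -1, -1, -1, 2]  # interior run masked, ends kept

    def test_missing_calls_are_transparent(self):
        m = make_matrix([[0, -1, 2, -1, 0]], positions=[1000, 2000, 3000, 4000, 5000])
        out, _ = mask_tight_double_recombinants(m, window=4000, units="bp")
        assert list(out.geno[0]) == [0, -1, -1, -1, 0]

    def test_exhaustive_patterns_match_reference(self):
        positions = [1000, 2000, 3000, 4000, 5000]
        window = 2500
        for pattern in itertools.product([-1, 0, 1, 2], repeat=5):
            m = make_matrix([list(pattern)], positions=positions)
            out, _ = mask_tight_double_recombinants(m, window=window, units="bp")
            expected = mask_double_recombinants_reference(list(pattern), positions, window)
            assert list(out.geno[0]) == expected, pattern

    def test_cm_units_require_map(self):
        m = make_matrix([[0, 2, 0]])
        with pytest.raises(ValueError):
            mask_tight_double_recombinants(m, window=2.0, units="cM")

    def test_cm_based_masking_uses_map_positions(self):
        import pandas as pd

        m = make_matrix([[0, 2, 0]], positions=[1, 10_000_000, 20_000_000])
        table = pd.DataFrame(
            {"chrom": ["1"] * 3, "pos": m.markers["pos"], "cm": [0.0, 0.9, 1.8]},
            index=m.markers.index,
        )
        out, _ = mask_tight_double_recombinants(m, window=2.0, units="cM", genetic_map=GeneticMap(table))
        assert list(out.geno[0]) == [0, -1, 0]

    def test_masking_only_ever_sets_missing(self):
        config = SimConfig(n_individuals=50, n_markers=60, map_length_cm=30, error_rate=0.02, seed=5)
        m = simulate_population(config)
        out, _ = mask_tight_double_recombinants(m, window=25_000, units="bp")
        changed = out.geno != m.geno
        assert np.all(out.geno[changed] == -1)

    def test_idempotent(self):
        config = SimConfig(n_individuals=60, n_markers=80, map_length_cm=40, error_rate=0.05, seed=9)
        m = simulate_population(config)
        once, rep1 = mask_tight_double_recombinants(m, window=25_000, units="bp")
        twice, rep2 = mask_tight_double_recombinants(once, window=25_000, units="bp")
        assert rep1.masked_genotype_count > 0
        assert rep2.masked_genotype_count == 0
        assert twice.equals(once)


class TestOutliers:
    def test_homogeneous_population_unflagged(self):
        # widely spaced markers: per-individual proportions then concentrate,
        # unlike a short dense linkage group where a few blocks dominate
        m = simulate_population(SimConfig(n_individuals=200, n_markers=300, map_length_cm=3000, seed=21))
        out, report = flag_outlier_individuals(m, k=3.0)
        assert not report.flagged_individuals
        assert out.equals(m)

    def test_gross_heterozygosity_outlier_flagged(self):
        rng = np.random.default_rng(1)
        geno = rng.choice([0, 1, 2], p=[0.467, 0.067, 0.466], size=(100, 200)).astype(np.int8)
        geno[0] = rng.choice([0, 1, 2], p=[0.1, 0.8, 0.1], size=200)
        _, report = flag_outlier_individuals(make_matrix(geno), k=3.0)
        assert [i for i, _ in report.flagged_individuals] == ["i1"]

    def test_infinite_k_flags_nothing(self):
        m = make_matrix([[0, 0], [1, 1], [2, 2]])
        _, report = flag_outlier_individuals(m, k=np.inf)
        assert not report.flagged_individuals

    def test_removal_is_opt_in(self):
        rng = np.random.default_rng(1)
        geno = rng.choice([0, 2], size=(50, 100)).astype(np.int8)
        geno[0] = 1
        kept, _ = flag_outlier_individuals(make_matrix(geno), k=3.0, remove=False)
        removed, _ = flag_outlier_individuals(make_matrix(geno), k=3.0, remove=True)
        assert kept.n_individuals == 50 and removed.n_individuals == 49


class TestPipeline:
    def test_clean_simulated_data_survives_defaults(self):
        # widely spaced markers so that no two lines are genuine near-duplicates
        m = simulate_population(SimConfig(n_individuals=150, n_markers=300, map_length_cm=3000, seed=8))
        out, report = qc_pipeline(m)
        assert out.n_individuals == m.n_individuals
        assert not report.removed_markers and not report.removed_individuals
        assert report.H_before == pytest.approx(report.H_after)

    def test_report_serialises(self, tmp_path):
        m = simulate_population(SimConfig(n_individuals=40, n_markers=30, map_length_cm=20, seed=2))
        _, report = qc_pipeline(m)
        path = tmp_path / "report.tsv"
        report.write_tsv(path)
        assert path.read_text().startswith("kind\tid\treason")
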