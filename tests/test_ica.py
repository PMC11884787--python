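"""Tests of spatial ICA decomposition, selection, scoring, and the rolled null."""

import numpy as np
import pytest

from conftest import make_recording
from moviemap.ica import (
    SelectionThresholds,
    SpatialICA,
    auto_select_candidates,
    make_rolled_component,
    rank_component_percentile,
    rolled_null_experiment,
    sample_gradient_profile,
    score_candidate_map,
    score_component,
    spatial_ica,
)
from moviemap.sheet import GradientLine
from moviemap.simulate import SimulationConfig, simulate_cohort
from moviemap.stats import ContractError


class TestSpatialICA:
    def test_rank_one_structure_recovered(self, sheet):
        rng = np.random.default_rng(0)
        pattern = np.sign(rng.standard_normal(sheet.n_units))  # non-Gaussian
        tc = rng.standard_normal(80)
        data = np.outer(pattern, tc) + 1e-4 * rng.standard_normal((sheet.n_units, 80))
        comp = spatial_ica(make_recording(data), n_components=2, seed=0)
        corrs = [
            abs(np.corrcoef(comp.maps[:, j], pattern)[0, 1])
            for j in range(comp.n_components)
        ]
        assert max(corrs) > 0.99

    def test_two_nongaussian_sources_unmixed(self, sheet):
        rng = np.random.default_rng(1)
        s1 = rng.uniform(-1, 1, sheet.n_units) ** 3
        s2 = np.sign(rng.standard_normal(sheet.n_units))
        mix = rng.standard_normal((2, 90))
        data = np.outer(s1, mix[0]) + np.outer(s2, mix[1])
        data += 1e-3 * rng.standard_normal(data.shape)
        comp = spatial_ica(make_recording(data), n_components=2, seed=0)
        for src in (s1, s2):
            corrs = [
                abs(np.corrcoef(comp.maps[:, j], src)[0, 1]) for j in range(2)
            ]
            assert max(corrs) > 0.95

    def test_deterministic_given_seed(self, small_bundle):
        a = spatial_ica(small_bundle.recordings[0], n_components=5, seed=3)
        b = spatial_ica(small_bundle.recordings[0], n_components=5, seed=3)
        assert np.array_equal(a.maps, b.maps)

    def test_spatial_maps_are_decorrelated(self, small_bundle):
        comp = spatial_ica(small_bundle.recordings[0], n_components=6, seed=0)
        c = np.corrcoef(comp.maps.T)
        off = c[~np.eye(len(c), dtype=bool)]
        assert np.abs(off).max() < 1e-6

    def test_invalid_component_count_rejected(self, small_bundle):
        with pytest.raises(ContractError):
            spatial_ica(small_bundle.recordings[0], n_components=10_000)


class TestProfiles:
    def test_constant_map_gives_constant_profile(self, maps, lines_parallel, sheet):
        prof = sample_gradient_profile(np.ones(sheet.n_units), lines_parallel)
        assert np.allclose(prof.values, 1.0)

    def test_eccentricity_map_profile_is_monotone(self, sheet, lines_parallel):
        prof = sample_gradient_profile(sheet.eccentricity, lines_parallel)
        assert np.all(np.diff(prof.values) > 0)

    def test_positionwise_mean_of_two_lines(self, sheet):
        vals = np.zeros(sheet.n_units)
        l1 = GradientLine(np.array([0, 1, 2]), "parallel", "left", ("V1v",))
        l2 = GradientLine(np.array([3, 4, 5]), "parallel", "left", ("V1v",))
        vals[[0, 1, 2]] = [1, 2, 3]
        vals[[3, 4, 5]] = [3, 2, 1]
        prof = sample_gradient_profile(vals, [l1, l2])
        assert np.allclose(prof.values, [2, 2, 2])

    def test_mismatched_lengths_rejected(self, sheet):
        l1 = GradientLine(np.array([0, 1, 2]), "parallel", "left", ("V1v",))
        l2 = GradientLine(np.array([3, 4]), "parallel", "left", ("V1v",))
        with pytest.raises(ContractError):
            sample_gradient_profile(np.zeros(sheet.n_units), [l1, l2])


class TestScoring:
    def test_truth_scores_one_and_sign_invariance(self, maps, lines_parallel):
        sf = maps.spatial_frequency
        assert score_component(sf, sf, lines_parallel) == pytest.approx(1.0)
        assert score_component(-sf, sf, lines_parallel) == pytest.approx(1.0)
        assert score_component(-sf, sf, lines_parallel, absolute=False) == pytest.approx(
            -1.0
        )

    @pytest.mark.parametrize(
        "selected, expected",
        [([0], 100.0), ([30], 0.0)],
    )
    def test_percentile_extremes(self, selected, expected):
        scores = np.linspace(1, 0, 31)  # descending: index 0 is best
        assert rank_component_percentile(scores, selected) == pytest.approx(expected)

    def test_percentile_averaging_of_multiple_selections(self):
        scores = np.array([0.9, 0.8, 0.7, 0.6, 0.5])  # ranks 1..5 of 5
        # ranks {1, 3}: percentiles (100, 50) -> mean 75
        assert rank_component_percentile(scores, [0, 2]) == pytest.approx(75.0)

    def test_tied_scores_share_mean_rank(self):
        scores = np.array([0.5, 0.5, 0.1])
        # both tied at mean rank 1.5 -> percentile 100*(3-1.5)/2 = 75
        assert rank_component_percentile(scores, [0]) == pytest.approx(75.0)
        assert rank_component_percentile(scores, [1]) == pytest.approx(75.0)

    def test_empty_selection_is_unavailable(self):
        assert np.isnan(rank_component_percentile(np.arange(5.0), []))


class TestSelection:
    def test_planted_truth_map_is_selected(
        self, sheet, maps, lines_parallel, lines_perpendicular
    ):
        rng = np.random.default_rng(2)
        noisy_sf = maps.spatial_frequency + 0.05 * rng.standard_normal(sheet.n_units)
        scored = score_candidate_map(
            noisy_sf, sheet, lines_parallel, lines_perpendicular
        )
        assert scored["label"] == "spatial_frequency"
        noisy_mer = maps.meridian + 0.05 * rng.standard_normal(sheet.n_units)
        scored = score_candidate_map(
            noisy_mer, sheet, lines_parallel, lines_perpendicular
        )
        assert scored["label"] == "meridian"

    def test_hemisphere_asymmetric_gradient_rejected(
        self, sheet, maps, lines_parallel, lines_perpendicular
    ):
        lateralized = maps.spatial_frequency.copy()
        lateralized[sheet.hemi_slice("right")] = 0.0
        scored = score_candidate_map(
            lateralized, sheet, lines_parallel, lines_perpendicular
        )
        assert scored["label"] == "neither"

    def test_smooth_noise_selection_rate_is_low(
        self, sheet, lines_parallel, lines_perpendicular
    ):
        from scipy import ndimage

        rng = np.random.default_rng(7)
        n_sel = 0
        n_maps = 120
        for _ in range(n_maps):
            g = [
                ndimage.gaussian_filter(
                    rng.standard_normal((sheet.height, sheet.width)), 2.0, mode="wrap"
                ).ravel()
                for _ in range(2)
            ]
            scored = score_candidate_map(
                np.concatenate(g), sheet, lines_parallel, lines_perpendicular
            )
            n_sel += scored["label"] != "neither"
        assert n_sel / n_maps < 0.10


class TestRolledComponents:
    def test_rolling_is_a_value_permutation(self, sheet, maps):
        for mode in ("hemisphere_swap", "circular_shift"):
            rolled = make_rolled_component(maps.meridian, sheet, mode=mode)
            assert np.allclose(np.sort(rolled), np.sort(maps.meridian))

    def test_hemisphere_swap_is_an_involution(self, sheet, maps):
        once = make_rolled_component(maps.spatial_frequency, sheet, "hemisphere_swap")
        twice = make_rolled_component(once, sheet, "hemisphere_swap")
        assert np.allclose(twice, maps.spatial_frequency)

    def test_rolling_preserves_local_smoothness(self, sheet):
        from scipy import ndimage

        rng = np.random.default_rng(3)
        smooth = np.concatenate(
            [
                ndimage.gaussian_filter(
                    rng.standard_normal((sheet.height, sheet.width)), 2.0, mode="wrap"
                ).ravel()
                for _ in range(2)
            ]
        )

        def lag1(v):
            g = sheet.to_grid(v, "left")
            return np.corrcoef(g[:, :-1].ravel(), g[:, 1:].ravel())[0, 1]

        rolled = make_rolled_component(smooth, sheet, "circular_shift")
        assert abs(lag1(rolled) - lag1(smooth)) < 0.15 * abs(lag1(smooth))

    def test_rolled_spatial_frequency_loses_monotonicity(
        self, sheet, maps, lines_parallel, lines_perpendicular
    ):
        rolled = make_rolled_component(maps.spatial_frequency, sheet, "circular_shift")
        scored = score_candidate_map(rolled, sheet, lines_parallel, lines_perpendicular)
        assert scored["label"] == "neither"

    def test_rolled_meridian_loses_boundary_alignment(
        self, sheet, maps, lines_parallel, lines_perpendicular
    ):
        rolled = make_rolled_component(maps.meridian, sheet, "circular_shift")
        scored = score_candidate_map(rolled, sheet, lines_parallel, lines_perpendicular)
        assert scored["label"] != "meridian"


class TestEndToEnd:
    def test_planted_cohort_model_selects_and_ranks_high(self):
        cfg = SimulationConfig(n_participants=1, map_coupling=0.5, snr=1.0, seed=305)
        b = simulate_cohort(cfg)
        res = SpatialICA(
            b.recordings[0],
            b.sheet,
            b.lines_parallel,
            b.lines_perpendicular,
            n_components=20,
        ).fit(seed=0)
        assert len(res.evaluation) > 0
        assert res.evaluation["percentile"].mean() > 50

    def test_rolled_null_counts_and_binomial(self):
        cfg = SimulationConfig(n_participants=1, map_coupling=0.5, snr=1.0, seed=302)
        b = simulate_cohort(cfg)
        res = rolled_null_experiment(
            b.recordings,
            b.sheet,
            b.lines_parallel,
            b.lines_perpendicular,
            n_components=20,
            seed=0,
        )
        total = res.n_selected_original + res.n_selected_rolled
        assert total > 0
        assert res.binomial.trials == total
        # hashed ids leak nothing about the origin
        assert set(res.selections.columns) == {"id", "origin", "label"}
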