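"""Tests of the shared response model and cross-participant map transfer."""

import numpy as np
import pytest

from conftest import make_recording
from moviemap.sheet import GroundTruthMaps
from moviemap.simulate import SimulationConfig, simulate_cohort
from moviemap.srm import (
    SRM,
    anatomical_average_baseline,
    fit_new_participant,
    fit_srm,
    flipped_baseline,
    leave_one_out_experiment,
    predict_map,
    select_k_crossval,
    transform_map_to_shared,
)
from moviemap.stats import ContractError


def _orthonormal(rng, n, k):
    q, _ = np.linalg.qr(rng.standard_normal((n, k)))
    return q


def _principal_angles(a, b):
    """Angles between the column spans of two orthonormal bases."""
    sv = np.linalg.svd(a.T @ b, compute_uv=False)
    return np.arccos(np.clip(sv, -1, 1))


class TestFit:
    def test_noiseless_construct_and_recover(self):
        rng = np.random.default_rng(0)
        k, t, n_units = 5, 60, 300
        s_true = rng.standard_normal((k, t))
        data, w_true = [], []
        for _ in range(4):
            w = _orthonormal(rng, n_units, k)
            w_true.append(w)
            data.append(w @ s_true)
        model = fit_srm(data, k=k, seed=1)
        assert model.residual(data) < 1e-6
        for w_hat, w in zip(model.bases, w_true):
            assert _principal_angles(w_hat, w).max() < 1e-4

    def test_objective_never_increases(self, small_bundle):
        model = fit_srm(
            [r.movie_data(0) for r in small_bundle.recordings], k=6, seed=0
        )
        assert np.all(np.diff(model.objective) <= 1e-8)

    def test_bases_are_orthonormal(self, small_bundle):
        model = fit_srm(
            [r.movie_data(0) for r in small_bundle.recordings], k=6, seed=0
        )
        for w in model.bases:
            assert np.abs(w.T @ w - np.eye(6)).max() < 1e-8

    def test_single_participant_k1_matches_svd(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((100, 40))
        model = fit_srm([x], k=1, seed=0)
        u, s, vt = np.linalg.svd(x, full_matrices=False)
        # the k=1 fit spans the top singular direction; the residual equals
        # the rank-1 truncation error
        resid = np.linalg.norm(x - model.bases[0] @ model.shared_timecourse)
        expected = np.linalg.norm(x - s[0] * np.outer(u[:, 0], vt[0]))
        assert resid == pytest.approx(expected, rel=1e-6)

    def test_t_smaller_than_k_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ContractError):
            fit_srm([rng.standard_normal((50, 4))], k=8)


class TestTransform:
    def test_in_span_map_roundtrips_exactly(self):
        rng = np.random.default_rng(4)
        w = _orthonormal(rng, 80, 6)
        v = rng.standard_normal(6)
        assert np.allclose(transform_map_to_shared(w @ v, w), v)

    def test_orthogonal_complement_annihilated(self):
        rng = np.random.default_rng(5)
        w = _orthonormal(rng, 80, 6)
        m = rng.standard_normal(80)
        m -= w @ (w.T @ m)
        assert np.abs(transform_map_to_shared(m, w)).max() < 1e-10

    def test_linearity_on_basis_columns(self):
        rng = np.random.default_rng(6)
        w = _orthonormal(rng, 80, 6)
        m = w[:, 1] + w[:, 4]
        v = transform_map_to_shared(m, w)
        assert np.allclose(v, np.eye(6)[1] + np.eye(6)[4])


class TestFrozenProjection:
    def test_new_participant_recovers_subspace(self):
        rng = np.random.default_rng(7)
        k, t = 5, 60
        s = rng.standard_normal((k, t))
        data = [_orthonormal(rng, 200, k) @ s for _ in range(3)]
        model = fit_srm(data, k=k, seed=0)
        w_star = _orthonormal(rng, 200, k)
        w_test = fit_new_participant(model, w_star @ model.shared_timecourse)
        assert _principal_angles(w_test, w_star).max() < 1e-6
        assert np.abs(w_test.T @ w_test - np.eye(k)).max() < 1e-8

    def test_noise_participant_gives_weak_prediction(self, default_bundle):
        b = default_bundle
        rng = np.random.default_rng(8)
        train = [r.movie_data(0) for r in b.recordings[:6]]
        model = fit_srm(train, k=10, seed=0)
        w_noise = fit_new_participant(
            model, rng.standard_normal(train[0].shape)
        )
        template = np.mean(
            [
                transform_map_to_shared(r.maps.spatial_frequency, w)
                for r, w in zip(b.recordings[:6], model.bases)
            ],
            axis=0,
        )
        from moviemap.ica import score_component

        r = score_component(
            predict_map(model, template, w_noise),
            b.recordings[6].maps.spatial_frequency,
            b.lines_parallel,
            absolute=False,
        )
        assert abs(r) < 0.6  # white noise cannot lock onto the shared response

    def test_t_mismatch_rejected(self, small_bundle):
        model = fit_srm([r.movie_data(0) for r in small_bundle.recordings], k=4)
        with pytest.raises(ContractError):
            fit_new_participant(model, small_bundle.recordings[0].data[:, :10])


class TestPredict:
    def test_zero_template_gives_zero_map(self):
        rng = np.random.default_rng(9)
        w = _orthonormal(rng, 50, 4)
        model = fit_srm([rng.standard_normal((50, 30))], k=4, seed=0)
        assert np.allclose(predict_map(model, np.zeros(4), w), 0.0)

    def test_closed_loop_reconstruction(self, sheet, lines_parallel):
        rng = np.random.default_rng(10)
        w = _orthonormal(rng, sheet.n_units, 6)
        v = rng.standard_normal(6)
        truth = w @ v
        model = fit_srm([rng.standard_normal((sheet.n_units, 30))], k=6, seed=0)
        from moviemap.ica import score_component

        pred = predict_map(model, v, w)
        assert score_component(pred, truth, lines_parallel, absolute=False) == pytest.approx(
            1.0
        )


class TestFlipped:
    def test_double_flip_is_identity(self, small_bundle):
        rec = small_bundle.recordings[0]
        assert np.array_equal(
            flipped_baseline(flipped_baseline(rec)).data, rec.data
        )

    def test_palindromic_time_course_unchanged(self, sheet):
        t = 21
        tc = np.concatenate([np.arange(11), np.arange(10)[::-1]]).astype(float)
        data = np.tile(tc, (sheet.n_units, 1))
        rec = make_recording(data)
        assert np.array_equal(flipped_baseline(rec).data, rec.data)

    def test_flip_reverses_each_movie_separately(self):
        cfg = SimulationConfig(n_participants=1, n_timepoints=30, n_movies=2, seed=4)
        rec = simulate_cohort(cfg).recordings[0]
        flipped = flipped_baseline(rec)
        for m in range(2):
            assert np.array_equal(
                flipped.movie_data(m), rec.movie_data(m)[:, ::-1]
            )


class TestAnatomicalBaseline:
    def test_identical_maps_give_perfect_correlation(self, maps, lines_parallel):
        _, r = anatomical_average_baseline(
            [maps, maps, maps], "spatial_frequency", maps.spatial_frequency, lines_parallel
        )
        assert r == pytest.approx(1.0)

    def test_single_other_participant_equals_their_map(self, maps, lines_parallel):
        avg, _ = anatomical_average_baseline(
            [maps], "spatial_frequency", maps.spatial_frequency, lines_parallel
        )
        assert np.array_equal(avg, maps.spatial_frequency)

    def test_jitter_degrades_monotonically(self, sheet, maps, lines_parallel):
        from moviemap.sheet import jitter_maps

        from moviemap.sheet import trace_gradient_lines

        lines_perp = trace_gradient_lines(sheet, "perpendicular")
        rs = []
        for scale in (0.0, 1.0, 2.0, 4.0):
            others = [
                jitter_maps(maps, sheet, scale, seed=100 + i) for i in range(6)
            ]
            _, r = anatomical_average_baseline(
                others, "meridian", maps.meridian, lines_perp
            )
            rs.append(r)
        assert all(a >= b - 1e-9 for a, b in zip(rs, rs[1:]))


class TestLeaveOneOut:
    def test_transfer_beats_flipped_on_default_cohort(self, default_bundle):
        res = leave_one_out_experiment(
            default_bundle, k=10, n_boot=500, seed=0, test_participants=[0, 1]
        )
        assert res.mean_corr("spatial_frequency") > res.mean_corr(
            "spatial_frequency", "corr_flipped"
        )
        assert res.tests["spatial_frequency:real_vs_flipped"].mean_diff > 0

    def test_too_few_participants_rejected(self, sheet, maps):
        cfg = SimulationConfig(n_participants=2, n_timepoints=40, n_movies=1, seed=0)
        bundle = simulate_cohort(cfg)
        with pytest.raises(ContractError):
            leave_one_out_experiment(bundle)


class TestSelectK:
    def test_generative_rank_is_found(self):
        rng = np.random.default_rng(11)
        k_true, t = 5, 80
        s = rng.standard_normal((k_true, t))
        data = [
            _orthonormal(rng, 150, k_true) @ s
            + 0.1 * rng.standard_normal((150, t))
            for _ in range(4)
        ]
        best, curve = select_k_crossval(data, k_grid=[2, 5, 10], seed=0)
        scores = dict(zip(curve["k"], curve["score"]))
        assert scores[5] > scores[2]
        assert best in (5, 10)  # plateau at or after the true rank

    def test_full_rank_noiseless_reconstructs_perfectly(self):
        rng = np.random.default_rng(12)
        k_true = 4
        s = rng.standard_normal((k_true, 60))
        data = [_orthonormal(rng, 100, k_true) @ s for _ in range(3)]
        _, curve = select_k_crossval(data, k_grid=[4], seed=0)
        assert curve["score"].iloc[0] == pytest.approx(1.0, abs=1e-6)

    def test_default_without_grid_is_ten(self):
        best, curve = select_k_crossval([], k_grid=None)
        assert best == 10 and curve.empty

    def test_empty_grid_rejected(self):
        with pytest.raises(ContractError):
            select_k_crossval([], k_grid=[])
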