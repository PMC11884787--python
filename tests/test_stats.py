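"""Unit and property tests for the shared statistics core."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from moviemap.stats import (
    ContractError,
    DegenerateInputError,
    binomial_two_tailed,
    bootstrap_mean_difference,
    fisher_z,
    inverse_fisher_z,
    kruskal_stress,
    mds_embed,
    partial_corr,
    pearson_corr,
)


class TestPearson:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ((1, 2, 3), (1, 2, 3), 1.0),
            ((1, 2, 3), (3, 2, 1), -1.0),
            ((1, 0, -1), (0, 1, 0), 0.0),
        ],
    )
    def test_hand_computed_values(self, x, y, expected):
        assert pearson_corr(x, y) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            pearson_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_length_mismatch_and_short_input(self):
        with pytest.raises(ContractError):
            pearson_corr([1, 2, 3], [1, 2])
        with pytest.raises(ContractError):
            pearson_corr([1, 2], [2, 1])


class TestPartialCorr:
    def test_constant_confound_is_noop_beyond_intercept(self):
        # a constant column duplicates the intercept -> rank deficient
        with pytest.raises(ContractError):
            partial_corr([1, 2, 3, 4], [4, 3, 2, 1], np.ones(4))

    def test_linear_confound_leaves_clean_signal(self):
        rng = np.random.default_rng(0)
        t = np.arange(50.0)
        x = rng.standard_normal(50) + t
        y = rng.standard_normal(50) - t
        # after removing the shared trend, the residuals are independent noise
        assert abs(partial_corr(x, y, t)) < 0.3

    def test_shared_confound_makes_residuals_degenerate(self):
        c = np.arange(10.0)
        with pytest.raises(DegenerateInputError):
            partial_corr(c, c, c)

    def test_matches_two_stage_least_squares_oracle(self):
        # residualize-then-correlate via an independent OLS implementation
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        n = 200
        conf = rng.standard_normal(n)
        x = rng.standard_normal(n) + conf
        y = rng.standard_normal(n) + conf
        design = sm.add_constant(conf)
        rx = sm.OLS(x, design).fit().resid
        ry = sm.OLS(y, design).fit().resid
        expected = np.corrcoef(rx, ry)[0, 1]
        assert partial_corr(x, y, conf) == pytest.approx(expected, abs=1e-10)


class TestFisher:
    def test_symmetry_point_and_known_value(self):
        assert fisher_z(0.0) == 0.0
        # high-precision evaluation of 0.5*ln((1+r)/(1-r)) at r = 0.88
        assert fisher_z(0.88) == pytest.approx(0.5 * math.log(1.88 / 0.12), rel=1e-9)
        assert fisher_z(0.88) == pytest.approx(1.375768, abs=1e-6)

    def test_out_of_range_rejected(self):
        with pytest.raises(ContractError):
            fisher_z(1.5)

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(min_value=-0.999999, max_value=0.999999))
    def test_roundtrip_identity(self, r):
        assert inverse_fisher_z(fisher_z(r)) == pytest.approx(r, abs=1e-12)

    def test_extremes_are_finite(self):
        assert np.isfinite(fisher_z(1.0))
        assert np.isfinite(fisher_z(-1.0))


class TestBootstrap:
    def test_unanimous_sign_hits_p_floor(self):
        res = bootstrap_mean_difference([0.5] * 8, n_boot=500, seed=1)
        assert res.p_two_tailed == 0.0
        assert res.p_label == "< 0.004"  # 2 / n_boot

    def test_two_participant_enumeration(self):
        # diffs (-1, 2): the 4 equiprobable pseudosamples have means
        # (-1, 0.5, 0.5, 2); opposite-sign mass 0.25, doubled -> p = 0.5
        res = bootstrap_mean_difference([-1.0, 2.0], n_boot=100_000, seed=3)
        assert res.p_two_tailed == pytest.approx(0.5, abs=0.02)

    def test_single_participant_identity(self):
        res = bootstrap_mean_difference([0.3], n_boot=100, seed=0)
        assert res.p_two_tailed == 0.0
        assert res.ci_low == res.ci_high == pytest.approx(0.3)

    def test_zero_observed_mean_is_degenerate(self):
        res = bootstrap_mean_difference([-1.0, 1.0], n_boot=100, seed=0)
        assert res.degenerate and res.p_two_tailed == 1.0

    def test_ci_brackets_observed_mean(self):
        rng = np.random.default_rng(5)
        diffs = rng.standard_normal(20) + 0.3
        res = bootstrap_mean_difference(diffs, n_boot=2000, seed=2)
        assert res.ci_low <= res.mean_diff <= res.ci_high

    def test_empty_input_rejected(self):
        with pytest.raises(ContractError):
            bootstrap_mean_difference([], n_boot=10, seed=0)


class TestBinomial:
    def test_thirteen_of_fourteen(self):
        res = binomial_two_tailed(13, 14, 0.5)
        assert res.p_two_tailed == pytest.approx(30 / 16384, rel=1e-12)
        assert round(res.p_two_tailed, 3) == 0.002

    def test_null_center_caps_at_one(self):
        assert binomial_two_tailed(7, 14, 0.5).p_two_tailed == 1.0

    def test_all_successes_exact_rational(self):
        assert binomial_two_tailed(14, 14, 0.5).p_two_tailed == pytest.approx(
            2 / 16384, rel=1e-12
        )

    @settings(derandomize=True, max_examples=120)
    @given(st.integers(min_value=1, max_value=12), st.data())
    def test_matches_exhaustive_enumeration(self, n, data):
        """Doubling-rule p agrees with exact counting of all 2^n outcomes."""
        s = data.draw(st.integers(min_value=0, max_value=n))
        lower = sum(math.comb(n, k) for k in range(s + 1))
        upper = sum(math.comb(n, k) for k in range(s, n + 1))
        expected = min(Fraction(1), 2 * Fraction(min(lower, upper), 2**n))
        assert binomial_two_tailed(s, n, 0.5).p_two_tailed == pytest.approx(
            float(expected), rel=1e-12
        )

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ContractError):
            binomial_two_tailed(5, 4, 0.5)
        with pytest.raises(ContractError):
            binomial_two_tailed(1, 4, 1.0)


def _smacof_oracle(delta, n_dims, seeds=range(8), n_iter=300):
    """Minimal stress-majorization MDS, independent of the implementation."""
    n = delta.shape[0]
    best = None
    for seed in seeds:
        rng = np.random.default_rng(seed)
        x = rng.standard_normal((n, n_dims))
        for _ in range(n_iter):
            d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(d > 0, delta / d, 0.0)
            b = -ratio
            np.fill_diagonal(b, ratio.sum(axis=1))
            x = (b @ x) / n
        s = kruskal_stress(delta, x)
        if best is None or s < best:
            best = s
    return best


class TestMDS:
    def test_planar_points_embed_exactly(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        delta = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        emb = mds_embed(delta, n_dims=2, seed=0)
        assert emb.stress < 1e-6

    def test_two_points_always_embeddable(self):
        delta = np.array([[0.0, 3.7], [3.7, 0.0]])
        assert mds_embed(delta, n_dims=2, seed=0).stress == pytest.approx(0.0, abs=1e-9)

    def test_tetrahedron_matches_smacof_oracle(self):
        delta = np.ones((4, 4)) - np.eye(4)
        emb = mds_embed(delta, n_dims=2, seed=0)
        oracle = _smacof_oracle(delta, 2)
        assert emb.stress == pytest.approx(oracle, abs=0.01)

    def test_stress_nonincreasing_in_dims(self):
        rng = np.random.default_rng(4)
        pts = rng.standard_normal((6, 4))
        delta = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        stresses = [mds_embed(delta, n_dims=d, seed=0).stress for d in (1, 2, 3)]
        assert stresses[0] >= stresses[1] - 1e-9
        assert stresses[1] >= stresses[2] - 1e-9

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ContractError):
            mds_embed(np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ContractError):
            mds_embed(-np.ones((2, 2)) + np.eye(2))
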