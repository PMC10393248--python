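"""Nonlinear measures: oracles, known dynamics, degenerate inputs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tensoreeg.bands import decompose_bands
from tensoreeg.features import (
    DegenerateSeriesError,
    EmbeddingConfig,
    FeatureConfig,
    MEASURE_NAMES,
    RecurrencePlot,
    correlation_dimension,
    dfa,
    embed,
    extract_features,
    feature_vector,
    recurrence_matrix,
    rqa_measures,
    sample_entropy,
    vertical_line_measures,
)
from conftest import (
    random_recurrence_plot,
    rqa_bruteforce,
    sampen_bruteforce,
)


class TestSampleEntropy:
    def test_constant_series_is_zero(self):
        """SD = 0 gives r = 0; with <= matching all templates agree."""
        assert sample_entropy(np.full(50, 3.14)) == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(size=rng.integers(60, 300))
        assert abs(sample_entropy(x) - sampen_bruteforce(x)) <= 1e-12

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(30, 120))
    def test_bruteforce_property(self, seed, n):
        x = np.random.default_rng(seed).standard_normal(n)
        ours, oracle = sample_entropy(x), sampen_bruteforce(x)
        if np.isfinite(oracle):
            assert abs(ours - oracle) <= 1e-12
        else:  # no m- or (m+1)-matches: sentinel values must agree
            assert repr(ours) == repr(oracle)

    def test_period_two_series_near_zero(self):
        """Deterministic continuation: m-matches always extend to m+1."""
        x = np.tile([1.0, -1.0], 5000)
        assert sample_entropy(x) <= 0.01

    def test_too_short_errors(self):
        with pytest.raises(ValueError, match="too short"):
            sample_entropy(np.arange(3.0), m=2)


class TestCorrelationDimension:
    def test_sinusoid_is_near_one(self):
        """A limit cycle has attractor dimension 1."""
        x = np.sin(2 * np.pi * 0.013 * np.arange(5000))
        assert 0.8 <= correlation_dimension(x) <= 1.2

    def test_white_noise_fills_embedding(self):
        x = np.random.default_rng(0).standard_normal(2000)
        assert correlation_dimension(x, emb_dim=10) >= 3.0

    def test_constant_series_errors(self):
        with pytest.raises(DegenerateSeriesError):
            correlation_dimension(np.ones(1000))


class TestDFA:
    def test_white_noise_exponent(self):
        x = np.random.default_rng(1).standard_normal(8192)
        assert 0.45 <= dfa(x) <= 0.55

    def test_random_walk_exponent(self):
        x = np.cumsum(np.random.default_rng(1).standard_normal(8192))
        assert 1.4 <= dfa(x) <= 1.6

    def test_exponent_ordering_white_pink_walk(self):
        """alpha(white) < alpha(low-passed) < alpha(walk) on fixed seeds."""
        rng = np.random.default_rng(2)
        w = rng.standard_normal(4096)
        pinkish = np.convolve(w, np.ones(8) / 8, mode="same")
        walk = np.cumsum(rng.standard_normal(4096))
        assert dfa(w) < dfa(pinkish) < dfa(walk)

    def test_short_series_errors(self):
        with pytest.raises(ValueError, match="too short"):
            dfa(np.random.default_rng(3).standard_normal(32))


class TestRecurrencePlot:
    def test_attained_rr_matches_target(self):
        rng = np.random.default_rng(4)
        for seed in range(5):
            x = np.random.default_rng(seed).standard_normal(800)
            rp = recurrence_matrix(x)
            assert abs(rp.attained_rr - 0.05) <= 0.005

    def test_matrix_equals_bruteforce_thresholding(self):
        """50-sample series, m=3: matrix equals explicit distance thresholding."""
        x = np.random.default_rng(5).standard_normal(50)
        cfg = EmbeddingConfig(emb_dim=3, delay=1, recurrence_rate=0.1)
        rp = recurrence_matrix(x, cfg)
        pts = embed(x, 3, 1)
        n = pts.shape[0]
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2))
        expected = d <= rp.epsilon
        np.fill_diagonal(expected, True)
        np.testing.assert_array_equal(rp.matrix, expected)
        assert np.array_equal(rp.matrix, rp.matrix.T)

    def test_constant_series_errors(self):
        with pytest.raises(DegenerateSeriesError):
            recurrence_matrix(np.zeros(100))


def _plot_from(matrix: np.ndarray, **cfg_kw) -> RecurrencePlot:
    cfg = EmbeddingConfig(**cfg_kw)
    n = matrix.shape[0]
    off = ~np.eye(n, dtype=bool)
    return RecurrencePlot(
        matrix=matrix, epsilon=1.0,
        attained_rr=float(matrix[off].mean()), config=cfg,
    )


class TestRQAMeasures:
    def test_saturated_plot(self):
        """All-ones plot: full laminar columns, longest off-LOI diagonal 19.

        The two corner diagonals have length 1, so the standard DET
        denominator keeps them: DET = 378/380.
        """
        rp = _plot_from(np.ones((20, 20), dtype=bool))
        vals = rqa_measures(rp)
        assert vals["LAM"] == 1.0
        assert vals["Lmax"] == 19.0
        assert vals["TT"] == 20.0
        assert vals["DET"] == pytest.approx(378 / 380)
        assert vertical_line_measures(rp)["AvgVertWhiteLen"] == 0.0

    def test_empty_plot_conventions(self):
        """No off-LOI recurrences: line measures all zero by convention."""
        rp = _plot_from(np.eye(30, dtype=bool))
        vals = rqa_measures(rp)
        assert vals["DET"] == 0.0 and vals["LAM"] == 0.0
        assert vals["TT"] == 0.0 and vals["Lentr"] == 0.0
        # columns hold only the LOI point: runs of length 1 < vmin

    def test_checkerboard_white_runs(self):
        n = 30
        m = np.indices((n, n)).sum(axis=0) % 2 == 0
        rp = _plot_from(m)
        v = vertical_line_measures(rp)
        assert v["AvgVertWhiteLen"] == 1.0
        assert v["VertEnt"] == 0.0  # no recurrent run reaches vmin

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_all_nine_measures_match_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mat = random_recurrence_plot(rng, 30)
        rp = _plot_from(mat)
        expected = rqa_bruteforce(mat)
        got = rqa_measures(rp) | vertical_line_measures(rp)
        for key, val in expected.items():
            assert got[key] == pytest.approx(val, abs=1e-12), key

    def test_affine_invariance_of_rqa(self):
        """Fixed-RR thresholding is quantile-based, so y -> a*y + b changes nothing."""
        x = np.random.default_rng(6).standard_normal(400)
        a = rqa_measures(recurrence_matrix(x))
        b = rqa_measures(recurrence_matrix(3.7 * x - 11.0))
        for key in a:
            assert a[key] == pytest.approx(b[key], rel=1e-12)

    def test_determinism_drops_under_shuffling(self):
        """DET of a noisy sinusoid beats all 20 shuffled surrogates."""
        rng = np.random.default_rng(7)
        x = np.sin(2 * np.pi * 0.02 * np.arange(600)) + 0.3 * rng.standard_normal(600)
        det0 = rqa_measures(recurrence_matrix(x))["DET"]
        for _ in range(20):
            det_s = rqa_measures(recurrence_matrix(rng.permutation(x)))["DET"]
            assert det_s < det0


class TestExtractFeatures:
    def test_19_channels_6_bands_gives_114_vectors(self):
        rng = np.random.default_rng(8)
        cfg = FeatureConfig(max_points=200)
        signals = {
            f"ch{i}": decompose_bands(rng.standard_normal(2000), 500.0)
            for i in range(19)
        }
        features, missing = extract_features(signals, cfg)
        assert len(features) == 114 and not missing
        for vec in features.values():
            assert set(vec) == set(MEASURE_NAMES) and len(vec) == 12

    def test_all_zero_recording_flagged_missing(self):
        signals = {"ch0": decompose_bands(np.zeros(2000), 500.0)}
        features, missing = extract_features(signals)
        assert not features
        assert len(missing) == 6
        assert all("degenerate" in m["reason"] or "constant" in m["reason"]
                   for m in missing)

    def test_deterministic_given_input_and_config(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(2000)
        cfg = FeatureConfig(max_points=300)
        a = feature_vector(x, cfg)
        b = feature_vector(x.copy(), cfg)
        assert a == b
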