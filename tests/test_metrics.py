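import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pathrank.backproject import back_project
from pathrank.metrics import (
    autocorrelation,
    dft_magnitudes,
    fft_score,
    normalize_profile,
    rank_features,
)
from pathrank.models import FeatureMatrix, RankingConfig


def autocorr_oracle(x, lag):
    """Literal double-loop evaluation of the lag autocorrelation."""
    n = len(x)
    mean = sum(x) / n
    num = 0.0
    for t in range(lag, n):
        num += (x[t] - mean) * (x[t - lag] - mean)
    den = 0.0
    for t in range(n):
        den += (x[t] - mean) ** 2
    return 0.0 if den == 0.0 else num / den


def dft_oracle(x):
    """Direct O(k^2) summation of the DFT, magnitudes of bins 1..k-1."""
    k = len(x)
    mags = []
    for m in range(1, k):
        re = sum(x[n] * math.cos(2 * math.pi * n * m / k) for n in range(k))
        im = -sum(x[n] * math.sin(2 * math.pi * n * m / k) for n in range(k))
        mags.append(math.hypot(re, im))
    return np.array(mags)


class TestAutocorrelation:
    def test_constant_sequence_is_zero(self):
        assert autocorrelation(np.full(32, 3.5), 5) == 0.0

    def test_alternating_hand_values(self):
        x = np.array([1, -1, 1, -1, 1, -1, 1, -1], dtype=float)
        assert autocorrelation(x, 2) == pytest.approx(0.75, abs=1e-15)
        assert autocorrelation(x, 1) == pytest.approx(-0.875, abs=1e-15)

    def test_periodic_closed_form(self):
        """Exactly periodic zero-mean x with period p: r_p = (n-p)/n."""
        x = np.tile([1.0, -1.0], 256)  # n=512, p=2
        assert autocorrelation(x, 2) == 510 / 512

    def test_lag_out_of_range(self):
        with pytest.raises(ValueError, match="lag"):
            autocorrelation(np.arange(10.0), 10)
        with pytest.raises(ValueError, match="lag"):
            autocorrelation(np.arange(10.0), 0)

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(20):
            x = rng.normal(size=64)
            r = autocorrelation(x, int(rng.integers(1, 63)))
            assert -1.0 <= r <= 1.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(seed=st.integers(0, 10_000), lag=st.integers(1, 31))
    def test_matches_double_loop_oracle(self, seed, lag):
        x = np.random.default_rng(seed).normal(size=32)
        assert autocorrelation(x, lag) == pytest.approx(autocorr_oracle(x.tolist(), lag), abs=1e-12)

    def test_affine_invariance(self, rng):
        x = rng.normal(size=50)
        assert autocorrelation(3.0 * x - 7.0, 4) == pytest.approx(autocorrelation(x, 4), rel=1e-12)
        assert autocorrelation(-2.0 * x, 4) == pytest.approx(autocorrelation(x, 4), rel=1e-12)


class TestDFTMagnitudes:
    def test_constant_all_energy_in_dc(self):
        assert np.all(dft_magnitudes(np.full(16, 2.0)) < 1e-12)

    def test_single_cosine_closed_form(self):
        x = np.cos(2 * np.pi * np.arange(8) / 8)
        mags = dft_magnitudes(x)
        assert mags[0] == pytest.approx(4.0, abs=1e-9)
        assert mags[6] == pytest.approx(4.0, abs=1e-9)
        assert np.all(np.delete(mags, [0, 6]) <= 1e-9)

    def test_conjugate_symmetry(self, rng):
        x = rng.normal(size=32)
        mags = dft_magnitudes(x)
        np.testing.assert_allclose(mags, mags[::-1], rtol=1e-9)

    @pytest.mark.parametrize("k", [8, 16, 32, 64])
    def test_fast_path_matches_direct_oracle(self, k):
        x = np.random.default_rng(k).normal(size=k)
        np.testing.assert_allclose(dft_magnitudes(x), dft_oracle(x), rtol=1e-8, atol=1e-10)

    @pytest.mark.parametrize("k", [7, 12, 100])
    def test_non_pow2_fallback_matches_oracle(self, k):
        x = np.random.default_rng(k).normal(size=k)
        np.testing.assert_allclose(dft_magnitudes(x), dft_oracle(x), rtol=1e-8, atol=1e-10)

    def test_force_direct_agrees_with_fast_path(self, rng):
        x = rng.normal(size=16)
        np.testing.assert_allclose(
            dft_magnitudes(x, force_direct=True), dft_magnitudes(x), rtol=1e-8
        )

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            dft_magnitudes(np.array([1.0]))


class TestFFTScore:
    def test_constant_scores_zero(self):
        assert fft_score(np.full(32, 9.0)) == 0.0

    def test_cosine_descending_magnitude(self):
        x = np.cos(2 * np.pi * np.arange(8) / 8)
        assert fft_score(x) == pytest.approx(6.0, abs=1e-9)  # 4/1 + 4/2

    def test_cosine_frequency_index(self):
        x = np.cos(2 * np.pi * np.arange(8) / 8)
        assert fft_score(x, "frequency_index") == pytest.approx(4 + 4 / 7, abs=1e-9)

    def test_scale_equivariance(self, rng):
        x = rng.normal(size=64)
        assert fft_score(3.0 * x) == pytest.approx(3.0 * fft_score(x), rel=1e-12)
        assert fft_score(-2.0 * x) == pytest.approx(2.0 * fft_score(x), rel=1e-12)

    def test_nonnegative_and_zero_iff_constant(self, rng):
        assert fft_score(rng.normal(size=32)) > 0.0

    def test_unknown_weighting_rejected(self):
        with pytest.raises(ValueError, match="weighting"):
            fft_score(np.arange(8.0), "sideways")


class TestNormalizeProfile:
    def test_none_is_identity(self, rng):
        x = rng.normal(size=20)
        assert normalize_profile(x, "none") is x

    def test_zscore_constant_to_zeros(self):
        np.testing.assert_array_equal(normalize_profile(np.full(5, 3.0), "zscore"), 0.0)

    def test_minmax_endpoints(self):
        np.testing.assert_array_equal(normalize_profile(np.array([0.0, 2.0]), "minmax"), [0.0, 1.0])

    def test_zscore_unit_variance(self, rng):
        z = normalize_profile(rng.normal(5, 3, size=200), "zscore")
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std() == pytest.approx(1.0, rel=1e-12)

    def test_zscore_makes_fft_score_scale_invariant(self, rng):
        x = rng.normal(size=64)
        a = fft_score(normalize_profile(5.0 * x + 2.0, "zscore"))
        b = fft_score(normalize_profile(x, "zscore"))
        assert a == pytest.approx(b, rel=1e-9)


class TestRankFeatures:
    def _bp(self, profiles):
        n = profiles.shape[0]
        fm = FeatureMatrix(
            [f"s{i}" for i in range(n)],
            [f"f{j}" for j in range(profiles.shape[1])],
            profiles,
        )
        return back_project(np.arange(n), fm), fm

    def test_planted_cosine_beats_matched_noise(self):
        rng = np.random.default_rng(0)
        t = np.linspace(0, 1, 512, endpoint=False)
        signal = np.cos(2 * np.pi * 3 * t)
        noise = rng.normal(0, signal.std(), size=512)
        bp, fm = self._bp(np.column_stack([signal, noise]))
        for metric in ("fft", "autocorrelation"):
            ranking = rank_features(bp, fm.feature_names, RankingConfig(metric=metric))
            assert ranking.entries[0].feature_name == "f0"

    def test_all_constant_ties_keep_input_order(self):
        bp, fm = self._bp(np.ones((16, 4)))
        ranking = rank_features(bp, fm.feature_names, RankingConfig(n_bins=16, lag=3))
        assert [e.feature_name for e in ranking.entries] == ["f0", "f1", "f2", "f3"]
        assert all(e.score == 0.0 for e in ranking.entries)
        assert [e.rank for e in ranking.entries] == [1, 2, 3, 4]

    def test_lag_must_be_below_profile_length(self):
        bp, fm = self._bp(np.random.default_rng(1).normal(size=(16, 2)))
        cfg = RankingConfig(n_bins=512, lag=22, metric="autocorrelation")
        with pytest.raises(ValueError, match="lag"):
            rank_features(bp, fm.feature_names, cfg)

    def test_config_lag_precondition(self):
        with pytest.raises(ValueError, match="lag"):
            RankingConfig(n_bins=512, lag=600, metric="autocorrelation")

    def test_columnwise_scores_match_scalar_metric(self, rng):
        profiles = rng.normal(size=(64, 7))
        bp, fm = self._bp(profiles)
        cfg = RankingConfig(n_bins=64, lag=5, metric="fft")
        ranking = rank_features(bp, fm.feature_names, cfg)
        by_name = {e.feature_name: e.score for e in ranking.entries}
        for j in range(7):
            assert by_name[f"f{j}"] == pytest.approx(fft_score(profiles[:, j]), rel=1e-12)
        cfg_ac = RankingConfig(n_bins=64, lag=5, metric="autocorrelation")
        ranking_ac = rank_features(bp, fm.feature_names, cfg_ac)
        by_name = {e.feature_name: e.score for e in ranking_ac.entries}
        for j in range(7):
            assert by_name[f"f{j}"] == pytest.approx(autocorrelation(profiles[:, j], 5), abs=1e-12)

    def test_non_pow2_profile_length_direct_dft(self, rng):
        profiles = rng.normal(size=(100, 3))
        bp, fm = self._bp(profiles)
        ranking = rank_features(bp, fm.feature_names, RankingConfig(n_bins=100, lag=10))
        by_name = {e.feature_name: e.score for e in ranking.entries}
        for j in range(3):
            assert by_name[f"f{j}"] == pytest.approx(fft_score(profiles[:, j]), rel=1e-10)
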