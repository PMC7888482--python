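"""Tests for the feature zoo, each against an independent brute-force oracle."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from strucdyn.features import (
    DEFAULT_FEATURES,
    FEATURE_REGISTRY,
    auto_mi_first_min_diff,
    compute_features,
    motif2_freq,
    motif3_diffquant_freq,
    sampen,
    sliding_sampen_stationarity,
    visibility_degrees,
    visibility_outlier90,
)
from strucdyn.preprocess import BoldMatrix, zscore

# ---------------------------------------------------------------------------
# independent oracles (simple, slow, string/loop based)


def motif2_brute(ts, word):
    symbols = "".join("u" if d > 0 else "d" for d in np.diff(ts))
    grams = [symbols[i : i + len(word)] for i in range(len(symbols) - len(word) + 1)]
    return grams.count(word) / len(grams)


def motif3_brute(ts, word):
    from scipy.stats import rankdata

    d = np.diff(ts)
    ranks = rankdata(d)
    symbols = "".join(
        "a" if r <= len(d) / 3 else ("c" if r > 2 * len(d) / 3 else "b") for r in ranks
    )
    grams = [symbols[i : i + len(word)] for i in range(len(symbols) - len(word) + 1)]
    return grams.count(word) / len(grams)


def sampen_brute(x, m=2, r=0.1):
    n = len(x)
    tol = r * np.std(x, ddof=1)
    counts = []
    for length in (m, m + 1):
        c = 0
        for i in range(n - m):
            for j in range(i + 1, n - m):
                if max(abs(x[i + k] - x[j + k]) for k in range(length)) <= tol:
                    c += 1
        counts.append(c)
    b, a = counts
    if b == 0:
        return math.nan
    if a == 0:
        return math.inf
    return -math.log(a / b)


def visibility_degrees_brute(x):
    n = len(x)
    deg = np.zeros(n, dtype=int)
    for a in range(n):
        for b in range(a + 1, n):
            visible = all(
                x[c] < x[b] + (x[a] - x[b]) * (b - c) / (b - a) for c in range(a + 1, b)
            )
            if visible:
                deg[a] += 1
                deg[b] += 1
    return deg


# ---------------------------------------------------------------------------


class TestMotif2:
    def test_monotone_series(self):
        x = np.arange(20.0)
        assert motif2_freq(x, "uuuu") == 1.0
        assert motif2_freq(x, "uduu") == 0.0

    def test_hand_example(self):
        # diffs of [0,1,0,1,2,3] have signs u,d,u,u,u -> 4-grams {uduu, duuu}
        assert motif2_freq([0.0, 1, 0, 1, 2, 3], "uduu") == pytest.approx(0.5)

    def test_foreign_characters_rejected(self):
        with pytest.raises(ValueError, match="motif word"):
            motif2_freq(np.arange(10.0), "uxdu")

    @given(arrays(np.float64, st.integers(10, 40), elements=st.floats(-5, 5, width=64)))
    def test_binary_four_words_partition(self, x):
        words = [f"{a}{b}{c}{d}" for a in "ud" for b in "ud" for c in "ud" for d in "ud"]
        total = sum(motif2_freq(x, w) for w in words)
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            x = rng.standard_normal(rng.integers(12, 60))
            word = "".join(rng.choice(list("ud"), 4))
            assert motif2_freq(x, word) == pytest.approx(motif2_brute(x, word), abs=1e-12)


class TestMotif3:
    def test_matches_brute_force(self, rng):
        for _ in range(20):
            x = rng.standard_normal(rng.integers(12, 60))
            word = "".join(rng.choice(list("abc"), 4))
            assert motif3_diffquant_freq(x, word) == pytest.approx(
                motif3_brute(x, word), abs=1e-12
            )

    def test_three_letter_words_partition(self, rng):
        x = rng.standard_normal(30)
        words = [f"{a}{b}{c}" for a in "abc" for b in "abc" for c in "abc"]
        total = sum(motif3_diffquant_freq(x, w) for w in words)
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_constant_increments_collapse_to_middle_tercile(self):
        x = np.arange(20.0)  # all diffs tie -> average rank -> all 'b'
        assert motif3_diffquant_freq(x, "aabb") == 0.0
        assert motif3_diffquant_freq(x, "bbbb") == 1.0


class TestSampen:
    def test_periodic_two_cycle_near_zero(self):
        x = np.tile([1.0, 2.0], 100) + 1e-6 * np.arange(200)  # break exact sd ties
        assert sampen(x) == pytest.approx(0.0, abs=0.01)

    def test_matches_brute_force_on_white_noise(self, rng):
        x = rng.standard_normal(300)
        assert sampen(x) == pytest.approx(sampen_brute(x), abs=1e-10)

    def test_periodic_below_shuffled(self, rng):
        x = np.tile([1.0, 2.0], 150) + 0.05 * rng.standard_normal(300)
        shuffled = rng.permutation(x)
        assert sampen(x) < sampen(shuffled)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            sampen(np.arange(5.0))


class TestSlidingSampen:
    def test_identical_windows_give_zero(self, rng):
        seg = rng.standard_normal(100)
        x = np.tile(seg, 10)
        assert sliding_sampen_stationarity(x) == pytest.approx(0.0, abs=1e-12)

    def test_stationary_ratio_small_when_defined(self):
        finite = []
        for seed in range(12):
            x = np.random.default_rng(seed).standard_normal(2000)
            r = sliding_sampen_stationarity(x)
            if np.isfinite(r):
                finite.append(r)
        assert len(finite) >= 6
        assert all(r < 0.5 for r in finite)

    def test_nonstationary_exceeds_stationary_paired(self):
        for seed in (0, 3, 4):  # seeds where both ratios are defined
            rng = np.random.default_rng(seed)
            stat = rng.standard_normal(2000)
            nonstat = np.concatenate(
                [rng.standard_normal(1000),
                 np.tile([1.0, -1.0], 500) + 0.05 * rng.standard_normal(1000)]
            )
            r_stat = sliding_sampen_stationarity(stat)
            r_non = sliding_sampen_stationarity(nonstat)
            if np.isfinite(r_stat) and np.isfinite(r_non):
                assert r_non > r_stat

    def test_constant_window_identified(self):
        x = np.concatenate([np.zeros(100), np.random.default_rng(0).standard_normal(900)])
        with pytest.raises(ValueError, match="window 0"):
            sliding_sampen_stationarity(x)


class TestAutoMutualInformation:
    def test_noisy_oscillation_first_minimum_at_decorrelation_lag(self):
        """For an oscillatory increment process the automutual information
        peaks at the half- and full-period lags (anticorrelation is still
        dependence) and dips where the oscillation decorrelates, a quarter
        period in: period 24 -> first minimum at lag 6."""
        for seed in range(5):
            rng = np.random.default_rng(seed)
            t = np.arange(6000)
            x = np.cumsum(np.sin(2 * np.pi * t / 24) + 0.3 * rng.standard_normal(6000))
            assert abs(auto_mi_first_min_diff(x) - 6) <= 1

    def test_periodic_alignment_lag_is_a_maximum_not_returned(self, rng):
        # diffs repeat with period 12: MI peaks at lag 12, so the first
        # minimum must come earlier
        t = np.arange(6000)
        x = np.cumsum(np.sin(2 * np.pi * t / 12) + 0.2 * rng.standard_normal(6000))
        assert auto_mi_first_min_diff(x) < 12

    def test_white_noise_first_minimum_at_lag_one(self):
        hits = sum(
            auto_mi_first_min_diff(np.cumsum(np.random.default_rng(s).standard_normal(2000))) == 1
            for s in range(11)
        )
        assert hits > 5  # majority of seeds

    def test_estimators_agree_on_first_minimum(self, rng):
        t = np.arange(1500)
        x = np.cumsum(np.sin(2 * np.pi * t / 24) + 0.3 * rng.standard_normal(1500))
        assert auto_mi_first_min_diff(x, estimator="hist") == auto_mi_first_min_diff(
            x, estimator="ksg"
        )

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            auto_mi_first_min_diff(np.arange(20.0), max_lag=20)


class TestVisibilityGraph:
    def test_valley_all_visible(self):
        deg = visibility_degrees(np.array([0.0, -1.0, 0.0]))
        np.testing.assert_array_equal(deg, [2, 2, 2])

    def test_peak_blocks_endpoints(self):
        deg = visibility_degrees(np.array([0.0, 2.0, 0.0]))
        np.testing.assert_array_equal(deg, [1, 2, 1])

    def test_hand_ratios(self, rng):
        x = rng.standard_normal(200)
        assert visibility_outlier90(x) >= 1.0
        assert visibility_outlier90(np.array([0.0, -1.0, 0.0]) + rng.normal(0, 1e-9, 3)) == pytest.approx(1.0, abs=1e-6)

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            x = rng.standard_normal(rng.integers(5, 60))
            np.testing.assert_array_equal(visibility_degrees(x), visibility_degrees_brute(x))

    def test_matches_networkx(self, rng):
        nx = pytest.importorskip("networkx")
        x = rng.standard_normal(80)
        g = nx.visibility_graph(x)
        deg_nx = np.array([g.degree[i] for i in range(80)])
        np.testing.assert_array_equal(visibility_degrees(x), deg_nx)

    def test_consecutive_points_always_connected(self, rng):
        x = rng.standard_normal(50)
        assert np.all(visibility_degrees(x) >= 1)


class TestInvariances:
    @pytest.mark.parametrize(
        "func",
        [
            lambda x: motif2_freq(x, "uduu"),
            lambda x: motif3_diffquant_freq(x, "aabb"),
            lambda x: sampen(x),
            visibility_outlier90,
        ],
    )
    def test_shift_invariance(self, func, rng):
        x = rng.standard_normal(200)
        assert func(x + 17.0) == pytest.approx(func(x), abs=1e-9)

    @pytest.mark.parametrize(
        "func",
        [
            lambda x: motif2_freq(x, "uduu"),
            lambda x: motif3_diffquant_freq(x, "aabb"),
            visibility_outlier90,
        ],
    )
    def test_positive_rescale_invariance(self, func, rng):
        x = rng.standard_normal(200)
        assert func(3.7 * x) == pytest.approx(func(x), abs=1e-9)


class TestFeatureTable:
    def test_registry_has_tags_and_default_features_resolve(self):
        for name in DEFAULT_FEATURES:
            spec = FEATURE_REGISTRY[name]
            assert spec.tag
            assert callable(spec.func)

    def test_compute_features_table_shape(self, rng):
        bold = BoldMatrix(rng.standard_normal((3, 400)), tr=0.72)
        bold = BoldMatrix(
            np.vstack([zscore(r) for r in bold.values]), tr=0.72, region_ids=bold.region_ids
        )
        table = compute_features(bold, ["rlfp", "motif2_uduu", "visibility_ol90"])
        assert table.shape == (3, 3)
        assert list(table.index) == bold.region_ids
        assert np.all(np.isfinite(table.values))

    def test_unknown_feature_rejected(self, rng):
        bold = BoldMatrix(rng.standard_normal((2, 100)), tr=0.72)
        with pytest.raises(KeyError, match="unknown features"):
            compute_features(bold, ["nope"])

    def test_every_feature_fast_on_hcp_length(self, rng):
        import time

        x = zscore(np.cumsum(rng.standard_normal(1200)))
        bold = BoldMatrix(x[None, :], tr=0.72)
        for name in DEFAULT_FEATURES:
            t0 = time.time()
            FEATURE_REGISTRY[name].func(bold.values[0], bold.tr)
            assert time.time() - t0 < 1.0, name
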