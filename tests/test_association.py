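"""Tests for rank-correlation inference and the Model/Results interface."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from strucdyn.association import (
    StrengthDynamicsModel,
    bh_fdr,
    feature_ranking,
    group_level_analysis,
    individual_sweep,
    partial_spearman,
    spearman,
)


def _panel(rng, n_subjects=6, n_regions=20, coupled=True):
    """A small synthetic feature/strength/volume panel without the generator."""
    regions = [f"r{i:02d}" for i in range(n_regions)]
    strengths = {}
    feats = {}
    base_strength = rng.uniform(1, 100, n_regions)
    volumes = pd.Series(rng.uniform(50, 4000, n_regions), index=regions, name="volume")
    for s in range(n_subjects):
        st = base_strength * rng.uniform(0.8, 1.2, n_regions)
        signal = rankdata(st) / n_regions if coupled else rng.standard_normal(n_regions)
        feats[s] = pd.DataFrame(
            {"f": signal + 0.1 * rng.standard_normal(n_regions)}, index=regions
        )
        strengths[s] = pd.Series(st, index=regions)
    features = pd.concat(feats, names=["subject", "region_id"])
    strength = pd.concat(strengths, names=["subject", "region_id"])
    return features, strength, volumes


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.array([1.0, 2, 3, 7, 20])
        assert spearman(x, x**3).rho == pytest.approx(1.0)

    def test_hand_rank_example(self):
        # d^2 = (4, 1, 1, 1, 1): rho = 1 - 6*8 / (5*(25-1)) = 0.6
        res = spearman([1, 2, 3, 4, 5], [3, 1, 2, 5, 4])
        assert res.rho == pytest.approx(0.6)
        assert res.n == 5

    def test_invariant_to_monotone_transform(self, rng):
        x = rng.standard_normal(30)
        y = rng.standard_normal(30)
        assert spearman(np.exp(x), y).rho == pytest.approx(spearman(x, y).rho)

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman(np.ones(10), np.arange(10.0))


class TestPartialSpearman:
    def test_identical_variables_give_one(self, rng):
        x = rng.standard_normal(30)
        z = rng.standard_normal(30)
        assert partial_spearman(x, x.copy(), z).rho == pytest.approx(1.0, abs=1e-12)

    def test_symmetry_in_x_and_y(self, rng):
        x, y, z = rng.standard_normal((3, 25))
        assert partial_spearman(x, y, z).rho == pytest.approx(
            partial_spearman(y, x, z).rho, abs=1e-12
        )

    def test_confound_only_null_is_small(self):
        """When x and y are both monotone in z plus tiny independent jitter,
        controlling for z removes (almost) all of the association.  The
        residual ranks are jitter-dominated, so individual seeds scatter at
        the 1/sqrt(n) scale; the bulk of the distribution stays small."""
        vals = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            z = rng.standard_normal(200)
            x = np.exp(z) + 1e-3 * rng.standard_normal(200)
            y = z**3 + 1e-3 * rng.standard_normal(200)
            vals.append(abs(partial_spearman(x, y, z).rho))
        vals = np.asarray(vals)
        assert np.median(vals) < 0.1
        assert np.mean(vals < 0.15) >= 0.85

    def test_residual_method_equals_recursion_without_ties(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            x, y, z = rng.standard_normal((3, 6))
            res = partial_spearman(x, y, z)
            rxy = spearman(x, y).rho
            rxz = spearman(x, z).rho
            ryz = spearman(y, z).rho
            recursion = (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
            assert res.rho == pytest.approx(recursion, abs=1e-10)

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(99)
        hits = sum(
            partial_spearman(*rng.standard_normal((3, 34))).p < 0.05 for _ in range(500)
        )
        assert 0.02 < hits / 500 < 0.08

    def test_permutation_p_close_to_asymptotic(self, rng):
        x, y, z = rng.standard_normal((3, 7))
        asym = partial_spearman(x, y, z)
        perm = partial_spearman(x, y, z, permutation=True)
        assert perm.rho == asym.rho
        assert 0 <= perm.p <= 1

    def test_permutation_limited_to_small_n(self, rng):
        x, y, z = rng.standard_normal((3, 20))
        with pytest.raises(ValueError, match="permutation"):
            partial_spearman(x, y, z, permutation=True)


class TestBhFdr:
    def test_hand_step_up_example(self):
        adjusted, reject = bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]), q=0.05)
        np.testing.assert_allclose(adjusted, 0.04)
        assert reject.all()

    def test_all_ones_rejects_none(self):
        adjusted, reject = bh_fdr(np.ones(10))
        assert not reject.any()
        np.testing.assert_allclose(adjusted, 1.0)

    def test_single_p_unchanged(self):
        adjusted, _ = bh_fdr(np.array([0.03]))
        assert adjusted[0] == pytest.approx(0.03)

    def test_adjusted_at_least_raw(self, rng):
        p = rng.uniform(size=50)
        adjusted, _ = bh_fdr(p)
        assert np.all(adjusted >= p - 1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.1, 1.5]))


class TestPanelAnalyses:
    def test_group_level_recovers_coupling(self, rng):
        features, strengths, volumes = _panel(rng, coupled=True)
        out = group_level_analysis(features, strengths, volumes)
        assert out.loc["f", "rho_v"] > 0.5
        assert out.loc["f", "p"] < 0.05

    def test_volume_feature_self_confound_null(self, rng):
        features, strengths, volumes = _panel(rng)
        # replace the feature with (jittered) volume itself: controlling for
        # volume must remove essentially all association
        vol_feat = features.copy()
        regions = features.index.get_level_values(-1)
        vol_feat["f"] = volumes.loc[regions].values + rng.normal(0, 1e-6, len(features))
        out = group_level_analysis(vol_feat, strengths, volumes)
        assert abs(out.loc["f", "rho_v"]) < 0.35

    def test_single_subject_group_equals_individual(self, rng):
        features, strengths, volumes = _panel(rng, n_subjects=1)
        grp = group_level_analysis(features, strengths, volumes)
        s0 = features.index.get_level_values(0)[0]
        res = partial_spearman(
            strengths.loc[s0].values, features.loc[s0, "f"].values, volumes.values
        )
        assert grp.loc["f", "rho_v"] == pytest.approx(res.rho, abs=1e-12)

    def test_individual_sweep_degenerate_identical_subjects(self, rng):
        features, strengths, volumes = _panel(rng, n_subjects=1)
        f2 = pd.concat({0: features.loc[0], 1: features.loc[0]}, names=["subject", "region_id"])
        s2 = pd.concat({0: strengths.loc[0], 1: strengths.loc[0]}, names=["subject", "region_id"])
        sweep = individual_sweep(f2, s2, volumes, "f")
        assert sweep.table["rho_v"].nunique() == 1
        assert sweep.fraction_significant in (0.0, 1.0)

    def test_individual_sweep_null_fdr_calibrated(self):
        rng = np.random.default_rng(1234)
        features, strengths, volumes = _panel(rng, n_subjects=40, n_regions=34, coupled=False)
        sweep = individual_sweep(features, strengths, volumes, "f", q=0.05)
        bound = 0.05 + 3 * np.sqrt(0.05 / 40)
        assert sweep.fraction_significant <= bound

    def test_misaligned_labels_rejected(self, rng):
        features, strengths, volumes = _panel(rng)
        with pytest.raises(ValueError, match="volumes missing"):
            group_level_analysis(features, strengths, volumes.iloc[:-3])


class TestFeatureRanking:
    def test_single_feature_rank_one(self):
        table = pd.DataFrame({"f": [0.5, 0.6]})
        out = feature_ranking(table)
        assert out.loc["f", "rank"] == 1

    def test_duplicated_feature_tie_broken_lexically(self):
        table = pd.DataFrame({"b_copy": [0.5, 0.7], "a_copy": [0.5, 0.7]})
        out = feature_ranking(table)
        assert out.loc["a_copy", "rank"] == 1
        assert out.loc["b_copy", "rank"] == 2

    def test_matches_brute_force_sort(self):
        table = pd.DataFrame(
            {"f1": [0.2, 0.4], "f2": [-0.9, -0.7], "f3": [0.5, 0.5]},
            index=["s0", "s1"],
        )
        out = feature_ranking(table)
        means = table.mean()
        expected = means.abs().sort_values(ascending=False).index.tolist()
        assert out.index.tolist() == expected
        assert out.loc["f2", "rank"] == 1


class TestModelResults:
    def test_fit_matches_standalone_operations(self, rng):
        features, strengths, volumes = _panel(rng)
        model = StrengthDynamicsModel(features, strengths, volumes)
        res = model.fit()
        manual = group_level_analysis(features, strengths, volumes)
        pd.testing.assert_frame_equal(res.group, manual)
        assert set(res.sweeps) == {"f"}
        assert "rho_V" in res.summary()

    def test_group_rho_dominates_individual_median(self, small_study):
        """Averaging across subjects concentrates signal: the group-level
        |rho_V| should be at least the median per-subject |rho_V|."""
        model = StrengthDynamicsModel.from_study(small_study, feature_names=["rlfp"])
        res = model.fit()
        assert abs(res.group.loc["rlfp", "rho_v"]) >= res.sweeps["rlfp"].median_abs_rho
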