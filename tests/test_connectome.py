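"""Connectivity index, segmentation, rsFC, outliers, cohort models."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import hypoconn as hc


class TestConnectivityIndex:
    def test_saturated_and_minimal_values(self):
        assert hc.connectivity_index(5000 * 100, v_seed=100) == pytest.approx(1.0)
        assert hc.connectivity_index(1, v_seed=100) == 0.0

    def test_spot_value_high_precision(self):
        # ln(250000)/ln(500000) computed independently at high precision
        from decimal import Decimal, getcontext

        getcontext().prec = 50
        oracle = float(Decimal(250000).ln() / Decimal(500000).ln())
        ci = hc.connectivity_index(250_000, v_seed=100, n_samples_per_voxel=5000)
        assert ci == pytest.approx(oracle, abs=1e-12)
        assert ci == pytest.approx(0.94718, abs=5e-6)

    def test_monotone_in_waytotal_decreasing_in_vseed(self):
        ws = np.linspace(10, 400_000, 60)
        cis = [hc.connectivity_index(w, v_seed=100) for w in ws]
        assert np.all(np.diff(cis) > 0)
        vs = [10, 50, 100, 500]
        cis_v = [hc.connectivity_index(10_000, v_seed=v) for v in vs]
        assert np.all(np.diff(cis_v) < 0)

    def test_zero_waytotal_missing(self):
        with pytest.warns(UserWarning, match="waytotal"):
            assert np.isnan(hc.connectivity_index(0, v_seed=10))


class TestGroupAverage:
    def _map(self, value, seed_mask_value=0.5):
        prob = np.zeros((4, 4, 4))
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[1:3, 1:3, 1:3] = True
        prob[mask] = value
        return hc.StreamlineMap(grid_shape=(4, 4, 4), seed_mask=mask,
                                probability=prob)

    def test_identity_for_identical_maps(self):
        m = self._map(0.4)
        avg = hc.group_average_map([m, self._map(0.4)])
        np.testing.assert_allclose(avg.probability, m.probability)

    def test_equal_weights_mean(self):
        avg = hc.group_average_map([self._map(0.2), self._map(0.6)])
        assert avg.seed_values[0] == pytest.approx(0.4)

    def test_weighted_mean(self):
        avg = hc.group_average_map([self._map(0.2), self._map(0.6)],
                                   weights=np.array([1.0, 3.0]))
        assert avg.seed_values[0] == pytest.approx(0.5)

    def test_grid_mismatch_rejected(self):
        other = hc.StreamlineMap(grid_shape=(5, 5, 5),
                                 seed_mask=np.ones((5, 5, 5), bool),
                                 probability=np.zeros((5, 5, 5)))
        with pytest.raises(hc.ValidationError, match="grid"):
            hc.group_average_map([self._map(0.2), other])


class TestSegmentation:
    def test_noiseless_two_level_exact_recovery(self):
        smap, gt = hc.gen_streamline_map(hc.MapEffectSpec(noise_sd=0.0), seed=0)
        seg = hc.kmeans_segment(smap, seed=0)
        assert seg.converged
        inter = (seg.hotspot_mask & gt["hotspot_mask"]).sum()
        dice = 2 * inter / (seg.hotspot_mask.sum() + gt["hotspot_mask"].sum())
        assert dice == 1.0

    def test_uniform_map_does_not_segment(self):
        prob = np.zeros((5, 5, 5))
        mask = np.zeros((5, 5, 5), bool)
        mask[1:4, 1:4, 1:4] = True
        prob[mask] = 0.3
        smap = hc.StreamlineMap(grid_shape=(5, 5, 5), seed_mask=mask,
                                probability=prob)
        seg = hc.kmeans_segment(smap, seed=0)
        assert not seg.converged
        assert seg.hotspot_mask is None

    def test_noisy_recovery_dice(self):
        dices = []
        for seed in range(20):
            smap, gt = hc.gen_streamline_map(
                hc.MapEffectSpec(noise_sd=0.05), seed=seed)
            seg = hc.kmeans_segment(smap, seed=seed)
            assert seg.converged
            inter = (seg.hotspot_mask & gt["hotspot_mask"]).sum()
            dices.append(2 * inter / (seg.hotspot_mask.sum()
                                      + gt["hotspot_mask"].sum()))
        assert min(dices) >= 0.95

    def test_affine_rescaling_invariance(self):
        smap, _ = hc.gen_streamline_map(hc.MapEffectSpec(noise_sd=0.03), seed=4)
        seg1 = hc.kmeans_segment(smap, seed=1)
        rescaled = hc.StreamlineMap(
            grid_shape=smap.grid_shape, seed_mask=smap.seed_mask,
            probability=np.where(smap.seed_mask, 0.1 + 0.8 * smap.probability, 0.0),
        )
        seg2 = hc.kmeans_segment(rescaled, seed=1)
        np.testing.assert_array_equal(seg1.hotspot_mask, seg2.hotspot_mask)
        assert seg2.separation == pytest.approx(seg1.separation, rel=1e-9)


class TestSubregionComparison:
    def test_identical_samples_p_near_one(self):
        a = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        out = hc.compare_subregion_streamlines(a, a.copy(), paired=False,
                                               test="mann_whitney")
        assert out["p"] > 0.9

    def test_mann_whitney_matches_rank_enumeration(self):
        # 4 + 4 samples: exact p from exhaustive enumeration of rank
        # assignments equals scipy's exact Mann–Whitney p
        a = np.array([1.0, 2.0, 3.0, 10.0])
        b = np.array([4.0, 5.0, 6.0, 7.0])
        out = hc.compare_subregion_streamlines(a, b, paired=False,
                                               test="mann_whitney")
        pooled = np.concatenate([a, b])
        u_obs = stats.mannwhitneyu(a, b, alternative="two-sided").statistic
        count = total = 0
        for ix in itertools.combinations(range(8), 4):
            xa = pooled[list(ix)]
            xb = np.delete(pooled, list(ix))
            u = stats.mannwhitneyu(xa, xb, alternative="two-sided").statistic
            n = 16 - u  # reflected U
            count += max(u, n) >= max(u_obs, 16 - u_obs)
            total += 1
        assert out["p"] == pytest.approx(count / total, abs=0.02)

    def test_shift_power(self):
        hits = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            b = rng.standard_normal(34)
            a = b + 2.0
            out = hc.compare_subregion_streamlines(a, b, paired=True)
            hits += out["p"] < 0.001
        assert hits >= 27


class TestRsFC:
    def test_identical_series_clipped(self):
        x = np.random.default_rng(0).standard_normal(100)
        with pytest.warns(UserWarning, match="clipped"):
            r, z = hc.roi_rsfc(x, x)
        assert r == pytest.approx(1.0)
        assert np.isfinite(z)

    def test_anticorrelated_series(self):
        x = np.random.default_rng(1).standard_normal(100)
        with pytest.warns(UserWarning, match="clipped"):
            r, z = hc.roi_rsfc(x, -x)
        assert r == pytest.approx(-1.0)
        assert z < -8

    def test_independent_noise_small_r(self):
        small = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            r, z = hc.roi_rsfc(rng.standard_normal(200), rng.standard_normal(200))
            small += abs(r) < 0.2
        assert small >= 38

    def test_zero_variance_missing(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            r, z = hc.roi_rsfc(np.ones(50), np.arange(50.0))
        assert np.isnan(r)


class TestTukey:
    def test_fence_arithmetic_keeps_small_range(self):
        # {1,2,3,4}: Q1 = 1.75, Q3 = 3.25, fences [−0.5, 5.5] → keep all
        kept, removed = hc.tukey_remove_outliers(np.array([1.0, 2.0, 3.0, 4.0]))
        assert removed.size == 0

    def test_fence_arithmetic_removes_extreme(self):
        # {1,2,3,100}: Q3 + 1.5·IQR = 27.6 · removal of 100
        kept, removed = hc.tukey_remove_outliers(np.array([1.0, 2.0, 3.0, 100.0]))
        assert list(removed) == [3]
        assert list(kept) == [1.0, 2.0, 3.0]

    def test_all_equal_nothing_removed(self):
        kept, removed = hc.tukey_remove_outliers(np.full(6, 2.5))
        assert removed.size == 0
        assert kept.size == 6


class TestGroupCompare:
    def _cohort(self, delta, seed, n=17):
        spec = hc.CohortSpec(n_per_group=n, effect_delta=delta)
        df, _ = hc.gen_cohort_table(spec, seed=seed)
        return df

    def test_planted_difference_detected(self):
        hits = 0
        for seed in range(25):
            res = hc.group_compare(self._cohort(-1.0, seed), "rsfc_lh_dlhpc")
            hits += res.p < 0.05
        assert hits >= 20  # ≥ 80 % power at Δ = 1 pooled sd, n = 17 + 17

    def test_outlier_sensitivity_harness(self):
        # an injected extreme value flips the conclusion only when the
        # Tukey filter is disabled
        df = self._cohort(-0.85, seed=12)
        df.loc[df.index[0], "rsfc_lh_dlhpc"] = 5.0  # lean outlier, upward
        with_f = hc.group_compare(df, "rsfc_lh_dlhpc", tukey=True)
        without = hc.group_compare(df, "rsfc_lh_dlhpc", tukey=False)
        assert with_f.removed_per_group[0] >= 1
        assert with_f.p < without.p

    def test_group_extinguished_by_filtering_raises(self):
        # a tiny group whose members are mostly pooled-fence outliers
        df = pd.DataFrame({
            "group": ["a"] * 3 + ["b"] * 17,
            "m": [0.0, 100.0, -100.0] + list(np.random.default_rng(0)
                                             .standard_normal(17)),
        })
        with pytest.raises(hc.ValidationError, match="extinguished"):
            hc.group_compare(df, "m")


class TestLogisticElimination:
    def test_perfect_separation_flagged(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "group": ["lean"] * 10 + ["overweight_obese"] * 10,
            "sep": np.r_[np.zeros(10), np.ones(10)] + 0.001 * rng.standard_normal(20),
            "noise": rng.standard_normal(20),
        })
        with pytest.warns(UserWarning, match="separation"):
            rep = hc.logistic_backward_elimination(df, ["sep", "noise"])
        assert "sep" in rep.separation_flagged

    def test_orthogonal_predictors_vif_one(self):
        n = 40
        x1 = np.r_[np.ones(n // 2), -np.ones(n // 2)]
        x2 = np.tile([1.0, -1.0], n // 2)  # orthogonal to x1
        rng = np.random.default_rng(1)
        y = (x1 + rng.standard_normal(n) > 0)
        df = pd.DataFrame({"group": np.where(y, "a", "b"), "x1": x1, "x2": x2})
        rep = hc.logistic_backward_elimination(df, ["x1", "x2"])
        for v in rep.vif.values():
            assert v == pytest.approx(1.0, abs=1e-8)

    def test_aic_never_increases_along_path(self):
        df, _ = hc.gen_cohort_table(hc.CohortSpec(effect_delta=-1.5), seed=5)
        rep = hc.logistic_backward_elimination(
            df, hc.synth.CONNECTIVITY_METRICS + hc.synth.BEHAVIOURAL_COVARIATES)
        diffs = np.diff(rep.aic_path)
        assert np.all(diffs <= 1e-9)

    def test_signal_metric_retained(self):
        kept = 0
        for seed in range(10):
            df, _ = hc.gen_cohort_table(
                hc.CohortSpec(effect_delta=-1.5), seed=seed)
            rep = hc.logistic_backward_elimination(
                df, hc.synth.CONNECTIVITY_METRICS)
            kept += "rsfc_lh_dlhpc" in rep.retained
        assert kept >= 8
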