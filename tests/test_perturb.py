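"""Permutation tests, FOV-shuffle null, width-scaling simulation, summaries."""

import numpy as np
import pandas as pd
import pytest

from ablmap import SimParams, simulate_cohort
from ablmap.events import classify_cohort
from ablmap.perturb import (
    ei_balance,
    fov_shuffle_similarity_null,
    nearest_target_distance,
    offdiag_mean_from_curves,
    permutation_group_test,
    spatial_effect_profile,
    stability_overlap,
    width_scaling_similarity_sim,
)
from ablmap.tuning import sorted_profiles, tuning_curves


class TestPermutationGroupTest:
    def test_deterministic_and_n_perm_honored(self, rng):
        vals = {"a": rng.normal(0, 1, 6), "b": rng.normal(0.5, 1, 6)}
        r1 = permutation_group_test(vals, n_perm=200, seed=5)
        r2 = permutation_group_test(vals, n_perm=200, seed=5)
        assert r1.p_value == r2.p_value
        assert r1.n_null == 200

    def test_extreme_separation_reaches_minimal_p(self, rng):
        vals = {"a": rng.normal(0, 1, 8), "b": rng.normal(50, 1, 8)}
        r = permutation_group_test(vals, n_perm=200, seed=1)
        assert r.p_value == pytest.approx(1 / 201)

    def test_constant_values_give_p_one(self):
        vals = {"a": np.full(4, 2.0), "b": np.full(4, 2.0)}
        assert permutation_group_test(vals, n_perm=100, seed=0).p_value == 1.0

    def test_valid_under_the_null(self, rng):
        # same-distribution cohorts: P(p <= alpha) <= alpha + MC tolerance
        alpha, n_sims = 0.05, 300
        rejections = 0
        for s in range(n_sims):
            r = np.random.default_rng(s)
            vals = {"a": r.normal(0, 1, 8), "b": r.normal(0, 1, 8)}
            rejections += permutation_group_test(vals, n_perm=200, seed=s).p_value <= alpha
        assert rejections / n_sims <= alpha + 0.03

    def test_requires_two_cohorts_selected(self, rng):
        vals = {c: rng.normal(0, 1, 4) for c in "abc"}
        with pytest.raises(ValueError, match="cohorts"):
            permutation_group_test(vals)
        r = permutation_group_test(vals, cohorts=("a", "c"), n_perm=50, seed=0)
        assert 0 < r.p_value <= 1


def _responsive_curves_by_fov(ds, day=5):
    resp = classify_cohort(ds)
    out = {}
    for f in ds.fov_ids():
        c = tuning_curves(ds.tensor(f, day))
        out[f] = c[resp.get(f, day).responsive]
    return out


class TestFovShuffle:
    def test_single_fov_null_is_degenerate(self, rng):
        curves = {"f0": rng.normal(0, 1, (20, 34))}
        with pytest.warns(UserWarning, match="identity"):
            res = fov_shuffle_similarity_null(curves, n_shuffle=50, seed=0)
        np.testing.assert_allclose(res.null, res.observed, atol=1e-12)

    def test_shuffle_preserves_single_neuron_curves(self, rng):
        # the draw only regroups neurons: pooled pseudo-FOV contents are a
        # permutation of the pooled input curves
        curves = {f"f{i}": rng.normal(0, 1, (10, 34)) for i in range(3)}
        pool = np.concatenate(list(curves.values()))
        sizes = [10, 10, 10]
        perm = np.random.default_rng(0).permutation(30)
        parts = np.split(perm, np.cumsum(sizes)[:-1])
        regrouped = np.concatenate([pool[p] for p in parts])
        assert {tuple(row) for row in regrouped} == {tuple(row) for row in pool}

    def test_shared_latents_raise_observed_above_shuffled_mean(self):
        # with FOV-shared tuning structure (k > 0) the shuffle destroys local
        # co-tuning, so the observed off-diagonal mean exceeds the null mean
        # in expectation (averaged over generator seeds)
        diffs = []
        for seed in range(8):
            p = SimParams(seed=400 + seed, n_mice=1, n_fov_per_mouse=4, neurons_per_fov=(110, 120))
            ds = simulate_cohort(p)
            res = fov_shuffle_similarity_null(_responsive_curves_by_fov(ds), n_shuffle=60, seed=seed)
            diffs.append(res.observed - res.null.mean())
        assert np.mean(diffs) > 0.01

    def test_envelope_is_ordered_quantile_band(self, rng):
        curves = {f"f{i}": rng.normal(0, 1, (15, 34)) for i in range(4)}
        res = fov_shuffle_similarity_null(curves, n_shuffle=200, seed=3)
        lo, hi = res.ci
        assert lo <= hi
        assert (res.null < lo).mean() <= 0.05 and (res.null > hi).mean() <= 0.05


class TestWidthScaling:
    @staticmethod
    def _shared_shape_curves(rng, n=30):
        # all neurons share one shape per bin, so the bin-average profile
        # equals every member's own profile (identity scaling is exact)
        shape = np.exp(-np.arange(34) / 8.0)
        amps = rng.uniform(10, 80, n)
        curves = amps[:, None] * shape[None, rng.permutation(34)]
        return curves

    def test_identity_scaling_changes_nothing(self, rng):
        curves = rng.normal(1, 0.5, (25, 34)) + 2.0
        bins = np.ones(25, int)
        res = width_scaling_similarity_sim(curves, bins, target_profiles=None)
        np.testing.assert_allclose(res.scaled_curves, curves, rtol=1e-13, atol=0)
        assert abs(res.offdiag_change) < 1e-12

    def test_bin_average_target_on_shared_shapes_is_identity(self, rng):
        curves = self._shared_shape_curves(rng)
        bins = np.ones(len(curves), int)
        target = {1: np.nanmean(sorted_profiles(curves), axis=0)}
        res = width_scaling_similarity_sim(curves, bins, target)
        np.testing.assert_allclose(res.scaled_curves, curves, atol=1e-10)
        assert abs(res.offdiag_change) < 1e-9

    def test_narrower_profile_lowers_off_diagonal_mean(self, rng):
        p = SimParams(seed=77, n_mice=1, n_fov_per_mouse=2, neurons_per_fov=(130, 140))
        ds = simulate_cohort(p)
        curves = np.concatenate(list(_responsive_curves_by_fov(ds).values()))
        bins = np.ones(len(curves), int)
        base_prof = np.nanmean(sorted_profiles(curves), axis=0)
        narrow = {1: base_prof**2}   # pointwise <=, equal at rank 1
        flat = {1: np.ones(34)}
        assert width_scaling_similarity_sim(curves, bins, narrow).offdiag_change < 0
        assert width_scaling_similarity_sim(curves, bins, flat).offdiag_change > 0

    def test_best_stimulus_and_amplitude_preserved(self, rng):
        curves = np.abs(rng.normal(5, 2, (40, 34))) + 0.1
        bins = np.ones(40, int)
        target = {1: np.linspace(1, 0.01, 34)}
        res = width_scaling_similarity_sim(curves, bins, target)
        np.testing.assert_array_equal(res.scaled_curves.argmax(axis=1), curves.argmax(axis=1))
        np.testing.assert_allclose(res.scaled_curves.max(axis=1), curves.max(axis=1), atol=1e-12)


class TestStabilityOverlap:
    @staticmethod
    def _frame(sets_by_day, fov="f0"):
        rows = []
        all_ids = sorted(set().union(*sets_by_day.values()) | {"pad1", "pad2"})
        for day, members in sets_by_day.items():
            for nid in all_ids:
                rows.append((nid, fov, day, nid in members))
        return pd.DataFrame(rows, columns=["neuron_id", "fov_id", "day", "responsive"])

    def test_set_arithmetic_examples(self):
        f = self._frame({5: {"a", "b", "c"}, 7: {"b", "c", "d"}})
        ov = stability_overlap(f)
        assert ov["overlap"].iloc[0] == pytest.approx(2 / 4)
        assert stability_overlap(f, denominator="first")["overlap"].iloc[0] == pytest.approx(2 / 3)
        assert stability_overlap(f, denominator="total")["overlap"].iloc[0] == pytest.approx(2 / 6)

    def test_identical_and_disjoint_sets(self):
        same = stability_overlap(self._frame({5: {"a", "b"}, 7: {"a", "b"}}))
        disjoint = stability_overlap(self._frame({5: {"a"}, 7: {"b"}}))
        assert same["overlap"].iloc[0] == 1.0
        assert disjoint["overlap"].iloc[0] == 0.0

    def test_no_responsive_neurons_gives_missing_value(self):
        ov = stability_overlap(self._frame({5: set(), 7: set()}))
        assert np.isnan(ov["overlap"].iloc[0])

    def test_spared_restriction(self):
        f = self._frame({5: {"a", "b"}, 7: {"a", "b"}})
        ov = stability_overlap(f, spared_ids={"a"})
        assert ov["overlap"].iloc[0] == 1.0


class TestSpatialProfile:
    def test_nearest_distance_matches_brute_force(self, rng):
        pos = rng.uniform(0, 300, (200, 3))
        targets = rng.uniform(0, 300, (12, 3))
        fast = nearest_target_distance(pos, targets)
        brute = np.array([min(np.linalg.norm(p - t) for t in targets) for p in pos])
        np.testing.assert_allclose(fast, brute, atol=1e-9)

    def test_single_distance_population_fills_one_bin(self):
        pos = np.tile([50.0, 0, 0], (10, 1))
        prof = spatial_effect_profile(pos, np.zeros((1, 3)), np.ones(10), np.arange(0, 201, 25))
        populated = prof.dropna(subset=["mean_effect"])
        assert len(populated) == 1
        assert populated["bin_left_um"].iloc[0] == 50.0

    def test_empty_bins_are_missing_not_zero(self, rng):
        pos = rng.uniform(0, 40, (30, 3))
        prof = spatial_effect_profile(pos, np.zeros((1, 3)), np.ones(30), np.array([0, 100, 200, 300]))
        assert np.isnan(prof["mean_effect"].iloc[-1])

    def test_exponential_decay_scale_recovered_from_binned_profile(self, rng):
        from scipy.optimize import curve_fit

        L = 120.0
        pos = rng.uniform(0, 400, (3000, 3))
        targets = rng.uniform(100, 300, (8, 3))
        d = nearest_target_distance(pos, targets)
        effects = np.exp(-d / L) + rng.normal(0, 0.05, len(d))
        prof = spatial_effect_profile(pos, targets, effects, np.arange(0, 401, 25)).dropna()
        centers = (prof["bin_left_um"] + prof["bin_right_um"]) / 2
        popt, _ = curve_fit(lambda x, a, l: a * np.exp(-x / l), centers, prof["mean_effect"], p0=(1, 80))
        assert popt[1] == pytest.approx(L, rel=0.2)


class TestEiBalance:
    @staticmethod
    def _frame(rows):
        return pd.DataFrame(rows, columns=["neuron_id", "mouse_id", "day", "responsive", "best_amplitude"])

    def test_equal_totals_give_half(self):
        rows = [("e0", "m", 5, True, 0.5), ("e1", "m", 5, False, np.nan),
                ("i0", "m", 5, True, 0.25), ("i1", "m", 5, True, 0.25),
                ("e2", "m", 5, False, np.nan), ("e3", "m", 5, False, np.nan),
                ("e4", "m", 5, False, np.nan), ("e5", "m", 5, False, np.nan),
                ("e6", "m", 5, False, np.nan), ("e7", "m", 5, False, np.nan),
                ("e8", "m", 5, False, np.nan), ("e9", "m", 5, False, np.nan)]
        inhib = {f"e{i}": False for i in range(10)} | {"i0": True, "i1": True}
        # frac_E = 0.1, amp_E = 0.5; frac_I = 1.0, amp_I = 0.25 -> rescale
        bal = ei_balance(self._frame(rows), inhib)
        te, ti = bal["total_E"].iloc[0], bal["total_I"].iloc[0]
        assert te == pytest.approx(0.1 * 0.5)
        assert ti == pytest.approx(1.0 * 0.25)
        assert bal["balance"].iloc[0] == pytest.approx(te / (te + ti))

    def test_no_responsive_inhibitory_gives_one(self):
        rows = [("e0", "m", 5, True, 1.0), ("i0", "m", 5, False, np.nan)]
        bal = ei_balance(self._frame(rows), {"e0": False, "i0": True})
        assert bal["balance"].iloc[0] == 1.0

    def test_printed_arithmetic_example(self):
        # frac_E=0.1 amp_E=0.5 vs frac_I=0.2 amp_I=0.25 -> equal totals -> 0.5
        rows = []
        for i in range(10):
            rows.append((f"e{i}", "m", 5, i == 0, 0.5 if i == 0 else np.nan))
        for i in range(10):
            rows.append((f"i{i}", "m", 5, i < 2, 0.25 if i < 2 else np.nan))
        inhib = {f"e{i}": False for i in range(10)} | {f"i{i}": True for i in range(10)}
        bal = ei_balance(self._frame(rows), inhib)
        assert bal["balance"].iloc[0] == pytest.approx(0.5)

    def test_absent_class_gives_missing(self):
        rows = [("e0", "m", 5, True, 1.0)]
        bal = ei_balance(self._frame(rows), {"e0": False})
        assert np.isnan(bal["balance"].iloc[0])
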