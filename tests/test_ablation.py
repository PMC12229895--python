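"""Target selection, category sets and the spared-network mask."""

import numpy as np
import pandas as pd
import pytest

from ablmap import SimParams, simulate_cohort
from ablmap.ablation import (
    AblationPlan,
    assign_categories,
    build_spared_mask,
    merged_responsive_ranking,
    select_targets,
)
from ablmap.events import classify_cohort


@pytest.fixture(scope="module")
def cohort():
    p = SimParams(seed=31, n_mice=1, n_fov_per_mouse=2, neurons_per_fov=(120, 130), p_absent=0.0)
    return simulate_cohort(p, cohort="responsive_ablation")


@pytest.fixture(scope="module")
def resp(cohort):
    return classify_cohort(cohort)


def _brute_merge(entries):
    """Reference dedup: sort all (id, amp) entries by amp desc, keep first per id."""
    order = sorted(entries, key=lambda e: (-e[1], e[0]))
    seen, out = set(), []
    for nid, amp in order:
        if nid not in seen:
            seen.add(nid)
            out.append((nid, amp))
    return out


class TestSelectTargets:
    def test_responsive_merge_matches_brute_force(self, cohort, resp):
        fov = cohort.fov_ids()[0]
        ids = cohort.fov_neurons(fov)["neuron_id"].to_numpy()
        res3, res5 = resp.get(fov, 3), resp.get(fov, 5)
        entries = []
        for res in (res3, res5):
            for i in np.flatnonzero(res.responsive):
                entries.append((ids[i], float(res.mean_amp[i, res.significant[i]].mean())))
        expected = _brute_merge(entries)
        ranking = merged_responsive_ranking(res3, res5, ids)
        assert list(ranking["neuron_id"]) == [e[0] for e in expected]
        np.testing.assert_allclose(ranking["amplitude"], [e[1] for e in expected])
        # dedup property: unique ids, length = |union of the two day lists|
        assert ranking["neuron_id"].is_unique
        union = set(ids[res3.responsive]) | set(ids[res5.responsive])
        assert len(ranking) == len(union)

    def test_duplicate_neuron_keeps_higher_ranked_entry(self):
        # a neuron responsive on both days appears once, at the position of
        # its larger amplitude in the merged distribution
        class FakeRes:
            def __init__(self, day, amps):
                n, s = len(amps), 4
                self.day = day
                self.responsive = np.array([a is not None for a in amps])
                self.significant = np.tile(self.responsive[:, None], (1, s))
                self.mean_amp = np.array([[a or 0.0] * s for a in amps])

        ids = np.array(["n0", "n1", "n2"])
        res_a = FakeRes(3, [5.0, 9.0, None])
        res_b = FakeRes(5, [7.0, None, 6.0])
        ranking = merged_responsive_ranking(res_a, res_b, ids)
        assert list(ranking["neuron_id"]) == ["n1", "n0", "n2"]  # n0 at its max (7.0)
        assert ranking.set_index("neuron_id").loc["n0", "amplitude"] == 7.0

    def test_quota_honored_within_four_to_eight(self, cohort, resp):
        for n in (4, 8):
            plan = select_targets(resp, cohort, "responsive", n_per_fov=n)
            for fov in cohort.fov_ids():
                assert len(plan.target_ids(fov)) == n

    def test_ineligible_neurons_skipped_with_reason(self, cohort, resp):
        plan = select_targets(resp, cohort, "responsive", n_per_fov=6)
        skipped = plan.frame[plan.frame["skip_reason"] == "ineligible"]
        assert (~skipped["eligible"].astype(bool)).all()
        assert not any(plan.frame.loc[~plan.frame["eligible"].astype(bool), "selected"])

    def test_nonresponsive_mode_avoids_responsive_neurons(self, cohort, resp):
        plan = select_targets(resp, cohort, "nonresponsive", n_per_fov=6)
        for fov in cohort.fov_ids():
            res3, res5 = resp.get(fov, 3), resp.get(fov, 5)
            ids = cohort.fov_neurons(fov)["neuron_id"].to_numpy()
            responsive_ids = set(ids[res3.responsive]) | set(ids[res5.responsive])
            assert not (set(plan.target_ids(fov)) & responsive_ids)

    def test_all_responsive_yields_empty_nonresponsive_plan(self, cohort, resp):
        import unittest.mock as mock

        fov = cohort.fov_ids()[0]
        res3, res5 = resp.get(fov, 3), resp.get(fov, 5)
        with mock.patch.object(res3, "responsive", np.ones_like(res3.responsive)), \
             mock.patch.object(res5, "responsive", np.ones_like(res5.responsive)):
            with pytest.warns(UserWarning, match="candidates|targets"):
                plan = select_targets(resp, cohort, "nonresponsive", n_per_fov=4)
        assert plan.target_ids(fov) == []

    def test_inhibitory_mode_targets_interneurons_by_amplitude(self, cohort, resp):
        plan = select_targets(resp, cohort, "inhibitory", n_per_fov=4)
        inhib = set(cohort.neurons.loc[cohort.neurons["inhibitory"], "neuron_id"])
        assert set(plan.target_ids()) <= inhib

    def test_deterministic_under_input_order_permutation(self, cohort, resp):
        a = select_targets(resp, cohort, "responsive", n_per_fov=6)
        b = select_targets(resp, cohort, "responsive", n_per_fov=6)
        assert a.target_ids() == b.target_ids()


class TestCategories:
    def test_control_sets_populated_and_disjoint(self, cohort, resp):
        cats = assign_categories(resp, cohort)
        for fov, sets in cats.items():
            assert len(sets["high"]) == 5 and len(sets["low"]) == 5
            assert not (set(sets["high"]) & set(sets["low"]))

    def test_high_category_excludes_ablated_interneurons(self, cohort, resp):
        plan = select_targets(resp, cohort, "inhibitory", n_per_fov=4)
        cats = assign_categories(resp, cohort, plan)
        targeted = set(plan.target_ids())
        for sets in cats.values():
            assert not (set(sets["high"]) & targeted)

    def test_tie_break_is_deterministic_by_neuron_id(self):
        class FakeRes:
            def __init__(self, day, amps):
                n, s = len(amps), 3
                self.day = day
                self.responsive = np.ones(n, bool)
                self.significant = np.ones((n, s), bool)
                self.mean_amp = np.tile(np.asarray(amps, float)[:, None], (1, s))

        ids = np.array(["n_b", "n_a", "n_c"])
        res = FakeRes(3, [2.0, 2.0, 2.0])
        ranking = merged_responsive_ranking(res, FakeRes(5, [2.0, 2.0, 2.0]), ids)
        assert list(ranking["neuron_id"]) == ["n_a", "n_b", "n_c"]


class TestSparedMask:
    def test_distance_boundary_at_15_um(self, cohort, resp):
        plan = select_targets(resp, cohort, "responsive", n_per_fov=6)
        ds = cohort.copy()
        fov = ds.fov_ids()[0]
        target = plan.target_ids(fov)[0]
        t_row = ds.neurons["neuron_id"] == target
        t_pos = ds.neurons.loc[t_row, ["x_um", "y_um", "z_um"]].iloc[0].to_numpy()
        others = ds.neurons[(ds.neurons["fov_id"] == fov) & ~ds.neurons["neuron_id"].isin(plan.target_ids(fov))]
        near_id, far_id = others["neuron_id"].iloc[0], others["neuron_id"].iloc[1]
        ds.neurons.loc[ds.neurons["neuron_id"] == near_id, ["x_um", "y_um", "z_um"]] = t_pos + [14.9, 0, 0]
        ds.neurons.loc[ds.neurons["neuron_id"] == far_id, ["x_um", "y_um", "z_um"]] = t_pos + [15.1, 0, 0]
        mask = build_spared_mask(ds, plan, categories=None)
        frame = mask.frame.set_index("neuron_id")
        assert not frame.loc[near_id, "spared"]
        assert frame.loc[near_id, "reason"] == "within_radius"
        assert frame.loc[far_id, "spared"] or frame.loc[far_id, "reason"] != "within_radius"
        # exactly 15 um is inside the sphere
        ds.neurons.loc[ds.neurons["neuron_id"] == far_id, ["x_um", "y_um", "z_um"]] = t_pos + [15.0, 0, 0]
        frame = build_spared_mask(ds, plan, categories=None).frame.set_index("neuron_id")
        assert frame.loc[far_id, "reason"] == "within_radius"

    def test_failed_targets_still_excluded(self, cohort, resp):
        plan = select_targets(resp, cohort, "responsive", n_per_fov=6)
        plan.frame.loc[plan.frame["selected"], "success"] = False
        mask = build_spared_mask(cohort, plan, categories=None)
        frame = mask.frame.set_index("neuron_id")
        for t in plan.target_ids():
            assert frame.loc[t, "reason"] == "targeted"

    def test_missing_position_conservatively_excluded(self, cohort, resp):
        plan = select_targets(resp, cohort, "responsive", n_per_fov=4)
        ds = cohort.copy()
        victim = ds.neurons.loc[~ds.neurons["neuron_id"].isin(plan.target_ids()), "neuron_id"].iloc[0]
        ds.neurons.loc[ds.neurons["neuron_id"] == victim, "x_um"] = np.nan
        frame = build_spared_mask(ds, plan, categories=None).frame.set_index("neuron_id")
        assert not frame.loc[victim, "spared"]

    def test_matches_brute_force_distance_check(self, cohort, resp):
        plan = select_targets(resp, cohort, "responsive", n_per_fov=8)
        cats = assign_categories(resp, cohort, plan)
        mask = build_spared_mask(cohort, plan, cats).frame.set_index("neuron_id")
        for fov in cohort.fov_ids():
            neurons = cohort.fov_neurons(fov)
            pos = neurons[["x_um", "y_um", "z_um"]].to_numpy()
            targets = plan.target_ids(fov)
            t_pos = neurons.set_index("neuron_id").loc[targets, ["x_um", "y_um", "z_um"]].to_numpy()
            cat_ids = set(cats[fov]["low"])  # responsive-ablation cohort filters low only
            for j, nid in enumerate(neurons["neuron_id"]):
                d = np.sqrt(((pos[j] - t_pos) ** 2).sum(axis=1)).min()
                expected = not (nid in targets or d <= 15.0 or nid in cat_ids)
                assert bool(mask.loc[nid, "spared"]) == expected, nid

    def test_spared_counts_comparable_across_modes(self, cohort, resp):
        counts = {}
        for mode in ("responsive", "nonresponsive"):
            plan = select_targets(resp, cohort, mode, n_per_fov=6)
            cats = assign_categories(resp, cohort, plan)
            mask = build_spared_mask(cohort, plan, cats)
            counts[mode] = mask.frame["spared"].sum()
        a, b = counts.values()
        assert abs(a - b) / max(a, b) < 0.1
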