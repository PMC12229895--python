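"""Generator properties: determinism, stationarity, drift, injected effects."""

import numpy as np
import pandas as pd
import pytest

from ablmap import (
    AblationEffectParams,
    SimParams,
    export_truth,
    inject_ablation,
    simulate_cohort,
)
from ablmap.ablation import select_targets
from ablmap.events import classify_cohort
from ablmap.tuning import split_half_tuning_correlation, tuning_curves, _row_corr

TINY = dict(n_mice=1, n_fov_per_mouse=2, neurons_per_fov=(60, 70))


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        p = SimParams(seed=9, **TINY)
        a, b = simulate_cohort(p), simulate_cohort(p)
        for key in a.tensors:
            np.testing.assert_array_equal(a.tensors[key].A, b.tensors[key].A, err_msg=str(key))
            np.testing.assert_array_equal(a.tensors[key].pre, b.tensors[key].pre)
        pd.testing.assert_frame_equal(a.neurons, b.neurons)

    def test_subsetting_reproduces_shared_fovs(self):
        small = simulate_cohort(SimParams(seed=9, n_mice=1, n_fov_per_mouse=2, neurons_per_fov=(60, 70)))
        large = simulate_cohort(SimParams(seed=9, n_mice=1, n_fov_per_mouse=4, neurons_per_fov=(60, 70)))
        fov = small.fov_ids()[0]
        np.testing.assert_array_equal(small.tensor(fov, 5).A, large.tensor(fov, 5).A)

    @pytest.mark.parametrize(
        "bad",
        [dict(p_responsive=1.2), dict(drift_rho=-0.1), dict(n_mice=0), dict(neurons_per_fov=(0, 0)),
         dict(inhibitory_width_factor=0.5)],
    )
    def test_invalid_params_rejected(self, bad):
        kwargs = dict(TINY)
        kwargs.update({k: v for k, v in bad.items() if k not in ("n_mice", "neurons_per_fov")})
        if "n_mice" in bad:
            kwargs["n_mice"] = 0
        if "neurons_per_fov" in bad:
            kwargs["neurons_per_fov"] = (0, 0)
        with pytest.raises(ValueError):
            SimParams(**kwargs)


class TestStructure:
    def test_shapes_days_and_flags(self, small_cohort, small_params):
        assert small_cohort.days == (1, 3, 5, 7, 9, 11, 15)
        for fov in small_cohort.fov_ids():
            tt = small_cohort.tensor(fov, 7)
            assert tt.A.shape[1:] == (34, 10)
            n = tt.n_neurons
            assert small_params.neurons_per_fov[0] <= n <= small_params.neurons_per_fov[1]
        inhib_frac = small_cohort.neurons["inhibitory"].mean()
        assert 0.02 < inhib_frac < 0.25

    def test_inhibitory_neurons_have_broader_tuning(self):
        # width factor 1.8 on ~2500 neurons: interneurons' true curves are broader
        ds = simulate_cohort(SimParams(seed=5, n_mice=2, n_fov_per_mouse=4, neurons_per_fov=(150, 160)))
        truth = export_truth(ds)
        t5 = truth.frame[(truth.frame["day"] == 5) & truth.frame["responsive_true"]]
        curves = truth.tuning[t5.index.to_numpy()]
        prof = np.sort(curves, axis=1)[:, ::-1]
        with np.errstate(invalid="ignore"):
            width = prof[:, 14] / prof[:, 0]
        inh = t5["inhibitory"].to_numpy()
        assert np.nanmean(width[inh]) > np.nanmean(width[~inh]) + 0.05

    def test_stationarity_no_trend_without_ablation(self):
        # per-day responsive fraction and responsive-pool amplitude: across
        # seeds, the per-seed regression slopes scatter around zero (their
        # confidence interval covers 0)
        days = np.array([1, 3, 5, 7, 9, 11, 15], dtype=float)
        slopes = {"frac": [], "amp": []}
        for seed in range(12):
            ds = simulate_cohort(SimParams(seed=seed, **TINY))
            truth = export_truth(ds).frame
            per_day = truth.groupby("day").apply(
                lambda g: pd.Series(
                    {"frac": g["responsive_true"].mean(), "amp": g.loc[g["responsive_true"], "amp_true"].mean()}
                ),
                include_groups=False,
            )
            for col in slopes:
                series = per_day[col].to_numpy()
                slopes[col].append(np.polyfit(days, series / series.mean(), 1)[0])
        for col, vals in slopes.items():
            vals = np.asarray(vals)
            se = vals.std(ddof=1) / np.sqrt(len(vals))
            assert abs(vals.mean()) < max(2.5 * se, 0.005), (col, vals.mean(), se)


class TestDrift:
    def test_noise_free_full_retention_gives_unit_cross_day_correlation(self):
        p = SimParams(seed=3, drift_rho=1.0, noise_sigma=1e-9, drop_rate=0.0, p_responsive=1.0,
                      gain_rate=0.0, p_absent=0.0, **TINY)
        ds = simulate_cohort(p)
        fov = ds.fov_ids()[0]
        c1 = tuning_curves(ds.tensor(fov, 1))
        c15 = tuning_curves(ds.tensor(fov, 15))
        r = _row_corr(c1, c15)
        np.testing.assert_allclose(r, 1.0, atol=1e-5)

    def test_cross_day_correlation_depends_only_on_lag(self):
        # symmetric drift: mean field correlation at lag 1 session is the same
        # for every adjacent 2-day pair, and decays with lag
        ds = simulate_cohort(SimParams(seed=21, n_mice=1, n_fov_per_mouse=3, neurons_per_fov=(150, 160),
                                       p_absent=0.0))
        truth = export_truth(ds)
        frame = truth.frame
        by_day = {}
        for day in (1, 3, 5, 7, 9, 11):
            sel = frame["day"] == day
            by_day[day] = truth.tuning[sel.to_numpy().nonzero()[0]]
        resp_all = None
        for day in by_day:
            r = frame.loc[frame["day"] == day, "responsive_true"].to_numpy()
            resp_all = r if resp_all is None else (resp_all & r)
        lag1 = []
        for d1, d2 in [(1, 3), (3, 5), (5, 7), (7, 9), (9, 11)]:
            r = _row_corr(by_day[d1][resp_all], by_day[d2][resp_all])
            lag1.append(np.nanmean(r))
        assert np.std(lag1) < 0.04  # same lag, same expected correlation
        lag3 = np.nanmean(_row_corr(by_day[1][resp_all], by_day[7][resp_all]))
        assert lag3 < min(lag1)


def _plan_and_inject(ds, effects, n_per_fov=5):
    resp = classify_cohort(ds)
    plan = select_targets(resp, ds, "responsive", n_per_fov=n_per_fov)
    return plan, inject_ablation(ds, plan, effects)


@pytest.fixture(scope="module")
def base():
    p = SimParams(seed=17, n_mice=1, n_fov_per_mouse=2, neurons_per_fov=(100, 110), p_absent=0.0)
    return simulate_cohort(p, cohort="responsive_ablation")


class TestInjection:

    def test_null_intervention_identical_on_spared(self, base):
        plan, ds0 = _plan_and_inject(base, AblationEffectParams())
        for fov in base.fov_ids():
            ids = base.fov_neurons(fov)["neuron_id"].to_numpy()
            spared = ~np.isin(ids, plan.target_ids(fov))
            for day in base.days:
                np.testing.assert_array_equal(
                    base.tensor(fov, day).A[spared], ds0.tensor(fov, day).A[spared]
                )

    def test_targets_masked_from_day7_and_baseline_untouched(self, base):
        plan, ds2 = _plan_and_inject(base, AblationEffectParams(reliability_dip=0.4))
        fov = base.fov_ids()[0]
        ids = base.fov_neurons(fov)["neuron_id"].to_numpy()
        t_idx = np.flatnonzero(np.isin(ids, plan.target_ids(fov)))
        for day in (7, 9, 11, 15):
            assert not ds2.tensor(fov, day).present[t_idx].any()
        for day in (1, 3, 5):
            np.testing.assert_array_equal(base.tensor(fov, day).A, ds2.tensor(fov, day).A)

    def test_missing_target_rejected_with_ids(self, base):
        plan, _ = _plan_and_inject(base, AblationEffectParams())
        plan.frame.loc[len(plan.frame)] = ["ghost_fov", "ghost_n999", 1, 1.0, True, True, pd.NA, ""]
        with pytest.raises(ValueError, match="ghost_n999"):
            inject_ablation(base, plan, AblationEffectParams())

    def test_reliability_dip_recovers_on_schedule(self, base):
        # dip 0.5 with tau = 1.5 d: split-half reliability of day-5-responsive
        # spared neurons drops on day 7 and is back near baseline by day 11
        eff = AblationEffectParams(reliability_dip=0.5, recovery_tau_days=1.5)
        plan, ds2 = _plan_and_inject(base, eff)
        resp = classify_cohort(base)
        drops = {}
        for day in (5, 7, 11):
            vals_b, vals_a = [], []
            for fov in base.fov_ids():
                ids = base.fov_neurons(fov)["neuron_id"].to_numpy()
                spared = ~np.isin(ids, plan.target_ids(fov))
                sel = resp.get(fov, 5).responsive & spared
                vals_b.append(np.nanmean(split_half_tuning_correlation(base.tensor(fov, day))[sel]))
                vals_a.append(np.nanmean(split_half_tuning_correlation(ds2.tensor(fov, day))[sel]))
            drops[day] = np.mean(vals_b) - np.mean(vals_a)
        assert drops[5] == pytest.approx(0.0, abs=1e-12)  # pre-ablation untouched
        assert drops[7] > 0.1
        assert abs(drops[11]) < 0.05  # recovered within tolerance

    def test_gain_alignment_raises_correlation_to_ablated_reference(self, base):
        aligned = _plan_and_inject(base, AblationEffectParams(gain_alignment=0.8, gain_boost=0.5))
        nullal = _plan_and_inject(base, AblationEffectParams(gain_alignment=0.0, gain_boost=0.5))
        resp5 = classify_cohort(base)

        def mean_ref_corr(plan, ds2):
            vals = []
            resp2 = classify_cohort(ds2)
            for fov in base.fov_ids():
                ids = base.fov_neurons(fov)["neuron_id"].to_numpy()
                t_idx = np.flatnonzero(np.isin(ids, plan.target_ids(fov)))
                ref = tuning_curves(base.tensor(fov, 5))[t_idx].mean(axis=0)
                spared = ~np.isin(ids, plan.target_ids(fov))
                gained = spared & ~resp5.get(fov, 5).responsive & resp2.get(fov, 15).responsive
                curves = tuning_curves(ds2.tensor(fov, 15))[gained]
                if len(curves):
                    vals.extend(_row_corr(curves, np.tile(ref, (len(curves), 1))))
            return np.nanmean(vals)

        assert mean_ref_corr(*aligned) > mean_ref_corr(*nullal) + 0.15


class TestTruthExport:
    def test_ids_bijective_with_neuron_records(self, small_cohort):
        truth = export_truth(small_cohort)
        per_day = truth.frame[truth.frame["day"] == 1]
        assert set(per_day["neuron_id"]) == set(small_cohort.neurons["neuron_id"])
        assert per_day["neuron_id"].is_unique

    def test_true_responsive_counts_match_state_chain(self, small_cohort):
        truth = export_truth(small_cohort)
        state = small_cohort.sim_state
        for fov, fst in state.fovs.items():
            sub = truth.frame[truth.frame["fov_id"] == fov]
            for di, day in enumerate(small_cohort.days):
                gi = int(np.where(fst.grid_days == day)[0][0])
                assert sub[sub["day"] == day]["responsive_true"].sum() == fst.resp[gi].sum()

    def test_snr_column_reproduces_noise_schedule(self):
        p = SimParams(seed=2, n_mice=1, n_fov_per_mouse=1, neurons_per_fov=(80, 80), p_absent=0.0)
        ds = simulate_cohort(p, cohort="responsive_ablation")
        eff = AblationEffectParams(reliability_dip=0.5, recovery_tau_days=1.5)
        plan, ds2 = _plan_and_inject(ds, eff)
        truth = export_truth(ds2)
        fov = ds.fov_ids()[0]
        ids = ds.fov_neurons(fov)["neuron_id"].to_numpy()
        spared_ids = set(ids) - set(plan.target_ids(fov))
        sub = truth.frame[truth.frame["neuron_id"].isin(spared_ids)]
        k7 = sub[sub["day"] == 7]["noise_sd"].to_numpy() / p.noise_sigma
        np.testing.assert_allclose(k7, 1.0 / (1.0 - 0.5), rtol=1e-9)
        k11 = sub[sub["day"] == 11]["noise_sd"].to_numpy() / p.noise_sigma
        np.testing.assert_allclose(k11, 1.0 / (1.0 - 0.5 * np.exp(-4 / 1.5)), rtol=1e-9)

    def test_rejected_on_non_simulated_data(self, small_cohort, tmp_path):
        from ablmap import load_dataset, save_dataset

        loaded = load_dataset(save_dataset(small_cohort, tmp_path / "c"))
        with pytest.raises(ValueError, match="simulated"):
            export_truth(loaded)
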