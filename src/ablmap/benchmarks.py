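"""Reference analyses on synthetic study conditions.

Each function here reruns one well-defined slice of the pipeline from
scratch on generated inputs — the stimulus battery, the exact-test floor,
estimator calibrations, null-model coverage, generator parameter recovery,
the microablation phenocopy, and brute-force oracle equivalences — and
returns the measured quantities with the problem size used.  The acceptance
script and the corresponding tests are thin wrappers around these functions.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit

from ._rng import child_seed, stream
from .ablation import build_spared_mask, merged_responsive_ranking, select_targets
from .dataset import TrialTensor, build_stimulus_set, pixels_to_um
from .events import classify_cohort, classify_responsiveness, signed_rank_pvalues
from .experiment import demo_effects, normalize_to_baseline, per_day_metrics, run_experiment
from .perturb import (
    fov_shuffle_similarity_null,
    nearest_target_distance,
    permutation_group_test,
    spatial_effect_profile,
    width_scaling_similarity_sim,
)
from .repmap import similarity_matrix
from .simulate import SimParams, inject_ablation, simulate_cohort
from .tuning import (
    estimate_drift_rho,
    signal_correlations,
    sorted_profiles,
    split_half_tuning_correlation,
    tuning_curves,
)

# ---------------------------------------------------------------------------
# printed-number checks
# ---------------------------------------------------------------------------

def stimulus_metrics() -> dict:
    ss = build_stimulus_set()
    return {
        "n_stimuli": ss.n_stimuli,
        "max_pt_frequency_khz": float(ss.pt_frequencies_khz.max()),
    }


def roi_displacement_um() -> float:
    """Two-pixel ROI matching tolerance in the 367-um / 256-px time series."""
    return pixels_to_um(2)


# ---------------------------------------------------------------------------
# exact signed-rank / BH family floor
# ---------------------------------------------------------------------------

def exact_test_metrics() -> dict:
    """Minimal exact p for n=10 and the BH(34) family consequences.

    Constructed through the classification path: one all-positive stimulus
    among 33 nulls is *not* responsive (q = p*34 = 0.066), three such stimuli
    are (q = p*34/3 = 0.022).  The minimal p is cross-checked against the
    full 2^10 sign-pattern enumeration.
    """
    d = np.linspace(1.0, 2.0, 10)
    p_impl = float(signed_rank_pvalues(d[None, :])[0])

    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ge = le = 0
    for signs in itertools.product((0, 1), repeat=10):
        w = sum(r for r, s in zip(ranks, signs) if s)
        ge += w >= w_obs
        le += w <= w_obs
    p_enum = min(1.0, 2 * min(ge, le) / 2**10)

    def _classify(n_min_p):
        diffs = np.zeros((34, 10))
        for s in range(n_min_p):
            diffs[s] = d
        A = diffs[None, :, :]
        tt = TrialTensor("toy", 5, A, np.zeros_like(A), np.ones(1, bool))
        return classify_responsiveness(tt)

    single = _classify(1)
    triple = _classify(3)
    return {
        "signed_rank_min_p_n10": p_impl,
        "signed_rank_enum_dev": abs(p_impl - p_enum),
        "bh_q_single_min_p": float(single.q[0, 0]),
        "single_min_p_responsive": float(single.responsive[0]),
        "bh_q_three_min_p": float(triple.q[0, 0]),
        "three_min_p_responsive": float(triple.responsive[0]),
    }


# ---------------------------------------------------------------------------
# split-half reliability calibration
# ---------------------------------------------------------------------------

def split_half_attenuation(seed: int, n_neurons: int = 1000, n_repeats: int = 10) -> dict:
    """Monte-Carlo check of E[r] = s^2 / (s^2 + n^2/5) at 10 x n_neurons splits."""
    rng = stream(seed, "attenuation")
    sigma_s, sigma_n = 1.0, 1.2
    sig = rng.normal(0, sigma_s, (n_neurons, 34))
    A = sig[:, :, None] + rng.normal(0, sigma_n, (n_neurons, 34, 10))
    tt = TrialTensor("calib", 5, A, np.zeros_like(A), np.ones(n_neurons, bool))
    r = split_half_tuning_correlation(tt, n_repeats=n_repeats, seed=child_seed(seed, "split"))
    expected = sigma_s**2 / (sigma_s**2 + sigma_n**2 / 5)
    observed = float(np.nanmean(r))
    return {
        "observed_mean_r": observed,
        "expected_mean_r": expected,
        "abs_error": abs(observed - expected),
        "n_splits": n_neurons * n_repeats,
    }


# ---------------------------------------------------------------------------
# null calibrations
# ---------------------------------------------------------------------------

def permutation_calibration(seed: int, n_sims: int = 600, n_mice: int = 8, alpha: float = 0.05) -> dict:
    """Rejection rate of the cohort permutation test under the null."""
    rejections = 0
    for i in range(n_sims):
        rng = stream(seed, "permnull", i)
        vals = {"a": rng.normal(0, 1, n_mice), "b": rng.normal(0, 1, n_mice)}
        res = permutation_group_test(vals, n_perm=200, seed=child_seed(seed, "perm", i))
        rejections += res.p_value <= alpha
    return {"rejection_rate": rejections / n_sims, "n_sims": n_sims, "alpha": alpha}


def shuffle_coverage(seed: int, n_sims: int = 300, n_shuffle: int = 200) -> dict:
    """Coverage of the FOV-shuffle 95% envelope with no shared tuning (k=0).

    With ``latent_share=0`` neurons are exchangeable across FOVs, so the
    observed off-diagonal mean should fall inside the 2.5-97.5 percentile
    envelope in ~95% of simulations.
    """
    inside = 0
    for i in range(n_sims):
        p = SimParams(
            seed=child_seed(seed, "covsim", i),
            n_mice=1,
            n_fov_per_mouse=4,
            neurons_per_fov=(60, 70),
            latent_share=0.0,
            days=(5, 7),
            p_absent=0.0,
        )
        ds = simulate_cohort(p)
        curves = {f: tuning_curves(ds.tensor(f, 5)) for f in ds.fov_ids()}
        res = fov_shuffle_similarity_null(curves, n_shuffle=n_shuffle, seed=child_seed(seed, "covshuf", i))
        inside += res.inside_ci
    return {"coverage": inside / n_sims, "n_sims": n_sims}


def shuffle_direction(seed: int, n_sims: int = 8) -> dict:
    """Observed minus shuffled off-diagonal mean with shared tuning (k>0)."""
    diffs = []
    for i in range(n_sims):
        p = SimParams(seed=child_seed(seed, "dirsim", i), n_mice=1, n_fov_per_mouse=4,
                      neurons_per_fov=(110, 120))
        ds = simulate_cohort(p)
        resp = classify_cohort(ds)
        curves = {}
        for f in ds.fov_ids():
            c = tuning_curves(ds.tensor(f, 5))
            curves[f] = c[resp.get(f, 5).responsive]
        res = fov_shuffle_similarity_null(curves, n_shuffle=60, seed=child_seed(seed, "dirshuf", i))
        diffs.append(res.observed - float(res.null.mean()))
    return {"mean_observed_minus_shuffled": float(np.mean(diffs)), "n_sims": n_sims}


# ---------------------------------------------------------------------------
# generator parameter recovery
# ---------------------------------------------------------------------------

def drift_recovery(seed: int) -> dict:
    """Recover the per-2-day tuning retention from a default control cohort."""
    p = SimParams(seed=child_seed(seed, "drift"), n_mice=2, n_fov_per_mouse=3, neurons_per_fov=(150, 170))
    ds = simulate_cohort(p)
    rho_hat = estimate_drift_rho(ds, seed=child_seed(seed, "driftsplit"))
    return {
        "true_rho": p.drift_rho,
        "estimated_rho": rho_hat,
        "abs_error": abs(rho_hat - p.drift_rho),
        "n_neurons": int(len(ds.neurons)),
    }


def spatial_recovery(seed: int, true_scale_um: float = 120.0) -> dict:
    """Recover the spatial decay length of the injected reliability dip.

    Per spared neuron the trial-noise ratio (day 7 over baseline days) is an
    estimate of the noise multiplier 1/(1 - dip*exp(-d/L)); binned by
    distance to the nearest target and fitted with an exponential it returns
    the decay length.
    """
    p = SimParams(seed=child_seed(seed, "spatial"), n_mice=2, n_fov_per_mouse=3,
                  neurons_per_fov=(150, 170), p_absent=0.0)
    ds = simulate_cohort(p, cohort="responsive_ablation")
    resp = classify_cohort(ds)
    plan = select_targets(resp, ds, "responsive", n_per_fov=6)
    effects = demo_effects(spatial_scale_um=true_scale_um)
    ds2 = inject_ablation(ds, plan, effects)

    dists, eff_vals, positions, t_positions = [], [], [], []
    for fov in ds2.fov_ids():
        neurons = ds2.fov_neurons(fov)
        ids = neurons["neuron_id"].to_numpy()
        pos = neurons[["x_um", "y_um", "z_um"]].to_numpy(float)
        targets = plan.target_ids(fov)
        t_idx = np.flatnonzero(np.isin(ids, targets))
        spared = ~np.isin(ids, targets)

        def noise_sd(day):
            A = ds2.tensor(fov, day).A
            return np.nanstd(A, axis=2).mean(axis=1)

        base = 0.5 * (noise_sd(3) + noise_sd(5))
        ratio = noise_sd(7) / base
        eff = 1.0 - 1.0 / np.maximum(ratio, 1e-9)  # = dip * exp(-d/L)
        positions.append(pos[spared])
        t_positions.append(pos[t_idx])
        eff_vals.append(eff[spared])
        dists.append(nearest_target_distance(pos[spared], pos[t_idx]))

    prof_frames = [
        spatial_effect_profile(P, T, E, np.arange(0, 401, 40))
        for P, T, E in zip(positions, t_positions, eff_vals)
    ]
    prof = pd.concat(prof_frames).groupby("bin_left_um", as_index=False).agg(
        bin_right_um=("bin_right_um", "first"), mean_effect=("mean_effect", "mean")
    ).dropna()
    centers = (prof["bin_left_um"] + prof["bin_right_um"]) / 2
    popt, _ = curve_fit(
        lambda x, a, ell: a * np.exp(-x / ell), centers, prof["mean_effect"], p0=(0.5, 80.0), maxfev=10000
    )
    est = float(popt[1])
    return {
        "true_scale_um": true_scale_um,
        "estimated_scale_um": est,
        "rel_error": abs(est - true_scale_um) / true_scale_um,
        "n_neurons": int(sum(len(e) for e in eff_vals)),
    }


# ---------------------------------------------------------------------------
# phenocopy of the microablation phenomenology
# ---------------------------------------------------------------------------

def phenocopy(seed: int, n_mice: int = 6, n_fov: int = 3) -> dict:
    """Full pipeline on a responsive-ablation vs control pair of cohorts.

    Assertable signatures: day-7 disturbance of the similarity map
    (cohort permutation test significant for the normalised off-diagonal and
    diagonal means), recovery by day 9 (test no longer significant), a
    delayed best-amplitude rise, elevated signal correlation among gained
    neurons, and the tuning-width scaling simulation (identity scaling inert,
    narrower profiles lowering the off-diagonal mean).
    """
    base = SimParams(n_mice=n_mice, n_fov_per_mouse=n_fov, neurons_per_fov=(140, 160))
    runs = run_experiment(seed=seed, base_params=base)
    mets = pd.concat([per_day_metrics(r) for r in runs.values()], ignore_index=True)
    cols = ["offdiag_single_trial", "diag_single_trial", "width", "best_amplitude"]
    norm = normalize_to_baseline(mets, cols)

    out: dict = {"n_mice_per_cohort": n_mice}
    for col in ("offdiag_single_trial", "diag_single_trial"):
        cn = f"{col}_norm"
        for day in (7, 9):
            vals = {
                c: norm[(norm["cohort"] == c) & (norm["day"] == day)][cn].to_numpy()
                for c in ("responsive_ablation", "control")
            }
            res = permutation_group_test(vals, n_perm=200, seed=child_seed(seed, "ph", col, day))
            out[f"{col}_day{day}_p"] = res.p_value
        by = norm.groupby(["cohort", "day"])[cn].mean()
        out[f"{col}_day7_ratio"] = float(by[("responsive_ablation", 7)] / by[("control", 7)])

    amp = norm.groupby(["cohort", "day"])["best_amplitude_norm"].mean()
    out["best_amplitude_late_ratio"] = float(
        np.mean([amp[("responsive_ablation", d)] for d in (11, 15)])
        / np.mean([amp[("control", d)] for d in (11, 15)])
    )
    wid = norm.groupby(["cohort", "day"])["width_norm"].mean()
    out["width_day7_ratio"] = float(wid[("responsive_ablation", 7)] / wid[("control", 7)])

    for cohort, run in runs.items():
        n_pairs, mean_r, frac_hi = _gained_pair_stats(run)
        tag = "ablation" if cohort == "responsive_ablation" else "control"
        out[f"gained_pair_mean_r_{tag}"] = mean_r
        out[f"gained_pair_frac_high_{tag}"] = frac_hi
        out[f"gained_pair_n_{tag}"] = n_pairs

    # tuning-width scaling simulation on the ablation cohort's day-5 curves
    run = runs["responsive_ablation"]
    curves, bins = [], []
    for fov in run.ds.fov_ids():
        res = run.resp.get(fov, 5)
        use = run.spared.spared_array(run.ds, fov) & res.responsive
        curves.append(tuning_curves(run.ds.tensor(fov, 5))[use])
        bins.append(res.amp_bin[use])
    curves = np.concatenate(curves)
    bins = np.concatenate(bins)
    ident = width_scaling_similarity_sim(curves, bins, None)
    prof_by_bin = {
        b: np.nanmean(sorted_profiles(curves[bins == b]), axis=0) for b in np.unique(bins)
    }
    narrow = {b: p**2 for b, p in prof_by_bin.items()}
    res_narrow = width_scaling_similarity_sim(curves, bins, narrow)
    out["width_sim_identity_change"] = abs(ident.offdiag_change)
    out["width_sim_narrow_change"] = res_narrow.offdiag_change
    out["width_sim_n_neurons"] = int(len(curves))
    return out


def phenocopy_null(seed: int, n_mice: int = 4, n_fov: int = 3) -> dict:
    """Ablation plan executed with all effect parameters zero vs control.

    With a null intervention the spared network is statistically identical
    to the control simulation, so the day-7 cohort permutation test should
    not be significant.
    """
    from .simulate import AblationEffectParams

    base = SimParams(n_mice=n_mice, n_fov_per_mouse=n_fov, neurons_per_fov=(140, 160))
    runs = run_experiment(seed=seed, effects=AblationEffectParams(), base_params=base)
    mets = pd.concat([per_day_metrics(r) for r in runs.values()], ignore_index=True)
    norm = normalize_to_baseline(mets, ["offdiag_single_trial"])
    vals = {
        c: norm[(norm["cohort"] == c) & (norm["day"] == 7)]["offdiag_single_trial_norm"].to_numpy()
        for c in ("responsive_ablation", "control")
    }
    res = permutation_group_test(vals, n_perm=200, seed=child_seed(seed, "phnull"))
    return {"day7_p": res.p_value, "n_mice_per_cohort": n_mice}


def _gained_pair_stats(run, day: int = 15):
    rs = []
    for fov in run.ds.fov_ids():
        tt = run.ds.tensor(fov, day)
        res = run.resp.get(fov, day)
        res5 = run.resp.get(fov, 5)
        spared = run.spared.spared_array(run.ds, fov)
        gained = spared & tt.present & ~res5.responsive & res.responsive
        if gained.sum() < 2:
            continue
        pc = signal_correlations(tuning_curves(tt), res.best_amplitude, gained)
        rs.extend(pc.frame["r"])
    rs = np.asarray(rs)
    if not len(rs):
        return 0, np.nan, np.nan
    return int(len(rs)), float(rs.mean()), float((rs > 0.7).mean())


# ---------------------------------------------------------------------------
# brute-force oracle equivalences
# ---------------------------------------------------------------------------

def oracle_checks(seed: int) -> dict:
    """Implementation vs independent brute-force references on toy inputs."""
    rng = stream(seed, "oracle")

    # similarity diagonal: C(10,2)=45 pair correlations per element
    A = rng.normal(0, 1, (8, 4, 10)) + rng.normal(0, 1, (8, 4, 1))
    tt = TrialTensor("toy", 5, A, np.zeros_like(A), np.ones(8, bool))
    sm = similarity_matrix(tt, "single_trial")
    ref, count_diag = _brute_single_trial(A)
    sim_dev = float(np.abs(sm.M - ref).max())

    # target-selection merge/dedup on a small toy FOV
    p = SimParams(seed=child_seed(seed, "oraclesim"), n_mice=1, n_fov_per_mouse=1,
                  neurons_per_fov=(120, 120), days=(3, 5, 7), p_absent=0.0)
    ds = simulate_cohort(p)
    resp = classify_cohort(ds)
    fov = ds.fov_ids()[0]
    ids = ds.fov_neurons(fov)["neuron_id"].to_numpy()
    res3, res5 = resp.get(fov, 3), resp.get(fov, 5)
    entries = []
    for res in (res3, res5):
        for i in np.flatnonzero(res.responsive):
            entries.append((ids[i], float(res.mean_amp[i, res.significant[i]].mean())))
    order = sorted(entries, key=lambda e: (-e[1], e[0]))
    seen, brute = set(), []
    for nid, _ in order:
        if nid not in seen:
            seen.add(nid)
            brute.append(nid)
    ranking = merged_responsive_ranking(res3, res5, ids)
    merge_mismatches = int(sum(a != b for a, b in zip(brute, ranking["neuron_id"])))

    # 15-um spared mask vs O(N*M) distances
    plan = select_targets(resp, ds, "responsive", n_per_fov=6)
    mask = build_spared_mask(ds, plan, categories=None).frame.set_index("neuron_id")
    pos = ds.fov_neurons(fov)[["x_um", "y_um", "z_um"]].to_numpy()
    targets = plan.target_ids(fov)
    t_pos = ds.fov_neurons(fov).set_index("neuron_id").loc[targets, ["x_um", "y_um", "z_um"]].to_numpy()
    mask_mismatches = 0
    for j, nid in enumerate(ids):
        d = min(np.linalg.norm(pos[j] - t) for t in t_pos)
        expected = not (nid in targets or d <= 15.0)
        mask_mismatches += int(bool(mask.loc[nid, "spared"]) != expected)

    # nearest-distance kernel
    P = rng.uniform(0, 300, (150, 3))
    T = rng.uniform(0, 300, (9, 3))
    fast = nearest_target_distance(P, T)
    brute_d = np.array([min(np.linalg.norm(x - t) for t in T) for x in P])
    dist_dev = float(np.abs(fast - brute_d).max())

    return {
        "similarity_diag_pair_count": int(count_diag),
        "similarity_oracle_max_dev": sim_dev,
        "merge_oracle_mismatches": merge_mismatches,
        "spared_mask_oracle_mismatches": mask_mismatches,
        "nearest_distance_oracle_max_dev": dist_dev,
    }


def _brute_single_trial(A):
    N, S, T = A.shape
    M = np.zeros((S, S))
    count_diag = None
    for s1 in range(S):
        for s2 in range(S):
            vals = []
            for t1 in range(T):
                for t2 in range(T):
                    if s1 == s2 and t1 >= t2:
                        continue
                    vals.append(np.corrcoef(A[:, s1, t1], A[:, s2, t2])[0, 1])
            M[s1, s2] = np.mean(vals)
            if s1 == s2:
                count_diag = len(vals)
    return M, count_diag
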