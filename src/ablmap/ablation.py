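"""Microablation target selection, category sets, spared-network mask.

Targets are chosen from the two pre-ablation baseline sessions (days 3 and
5).  Three modes mirror the experimental cohorts:

``responsive``
    Per day, each responsive neuron's amplitude is its mean over the stimuli
    with significant responses; the two days' descending amplitude
    distributions are merged, sorted by amplitude and deduplicated keeping
    the higher-ranked entry; targets come from the top.
``nonresponsive``
    Neurons responsive on neither day are ranked per day by absolute mean
    amplitude ascending; the two ranks are averaged and targets come from
    the smallest average rank (closest to zero response).
``inhibitory``
    Responsive interneurons first (responsive-mode criterion restricted to
    inhibitory neurons), topped up with non-significant interneurons of
    largest evoked amplitude (averaged over the two days) until the per-FOV
    count is reached.

The spared-network mask excludes every targeted neuron (successful or not),
every neuron within a 15-um sphere around targeted neurons, and the
cohort-appropriate high/low-category sets that equalise analyses across
cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import CohortDataset
from .events import CohortResponsiveness

MODES = ("responsive", "nonresponsive", "inhibitory")

#: digital-exclusion category sets applied per cohort
COHORT_CATEGORY_EXCLUSIONS = {
    "responsive_ablation": ("low",),
    "nonresponsive_ablation": ("high",),
    "inhibitory_ablation": ("high",),
    "control": ("high", "low"),
}


@dataclass
class AblationPlan:
    """Ordered per-FOV candidate list with selection flags.

    ``frame`` columns: fov_id, neuron_id, rank (1-based merged position),
    amplitude (ranking key), selected, eligible, success, skip_reason.
    """

    mode: str
    n_per_fov: int
    frame: pd.DataFrame

    def target_ids(self, fov_id: str | None = None) -> list[str]:
        f = self.frame.loc[self.frame["selected"].astype(bool)]
        if fov_id is not None:
            f = f[f["fov_id"] == fov_id]
        return list(f["neuron_id"])

    def candidates(self, fov_id: str) -> pd.DataFrame:
        return self.frame[self.frame["fov_id"] == fov_id].reset_index(drop=True)


def _responsive_day_amplitudes(res) -> dict[int, float]:
    """neuron index -> mean amplitude over that neuron's significant stimuli."""
    out = {}
    for i in np.flatnonzero(res.responsive):
        sig = res.significant[i]
        out[i] = float(res.mean_amp[i, sig].mean())
    return out


def merged_responsive_ranking(res_a, res_b, ids: np.ndarray, restrict: np.ndarray | None = None) -> pd.DataFrame:
    """Merged, amplitude-sorted, deduplicated responsive distribution of two days.

    Each responsive neuron contributes one entry per day at its
    significant-stimulus mean amplitude; entries are sorted descending by
    amplitude (ties broken by neuron id for determinism) and duplicates keep
    the higher-ranked (larger-amplitude) entry.
    """
    entries = []
    for res in (res_a, res_b):
        for i, amp in _responsive_day_amplitudes(res).items():
            if restrict is None or restrict[i]:
                entries.append((ids[i], i, amp, res.day))
    if not entries:
        return pd.DataFrame(columns=["neuron_id", "index", "amplitude", "day", "rank"])
    tab = pd.DataFrame(entries, columns=["neuron_id", "index", "amplitude", "day"])
    tab = tab.sort_values(["amplitude", "neuron_id"], ascending=[False, True], kind="stable")
    tab = tab.drop_duplicates("neuron_id", keep="first").reset_index(drop=True)
    tab["rank"] = np.arange(1, len(tab) + 1)
    return tab


def _nonresponsive_ranking(res_a, res_b, ids: np.ndarray, present: np.ndarray) -> pd.DataFrame:
    """Average-rank ordering of neurons responsive on neither day."""
    cand = present & ~res_a.responsive & ~res_b.responsive
    idx = np.flatnonzero(cand)
    if len(idx) == 0:
        return pd.DataFrame(columns=["neuron_id", "index", "amplitude", "rank"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        amp_a = np.abs(np.nanmean(res_a.mean_amp[idx], axis=1))
        amp_b = np.abs(np.nanmean(res_b.mean_amp[idx], axis=1))
    rank_a = pd.Series(amp_a).rank(method="average").to_numpy()
    rank_b = pd.Series(amp_b).rank(method="average").to_numpy()
    avg_rank = (rank_a + rank_b) / 2.0
    tab = pd.DataFrame(
        {
            "neuron_id": ids[idx],
            "index": idx,
            "amplitude": (amp_a + amp_b) / 2.0,
            "avg_rank": avg_rank,
        }
    )
    tab = tab.sort_values(["avg_rank", "neuron_id"], ascending=[True, True], kind="stable").reset_index(drop=True)
    tab["rank"] = np.arange(1, len(tab) + 1)
    return tab.drop(columns="avg_rank")


def select_targets(
    resp: CohortResponsiveness,
    ds: CohortDataset,
    mode: str,
    n_per_fov: int = 6,
    baseline_days: tuple[int, int] = (3, 5),
) -> AblationPlan:
    """Build the ablation plan for ``mode`` with ``n_per_fov`` targets per FOV.

    Ineligible neurons (occluded nuclei etc.) are skipped with a reason;
    FOVs with fewer candidates than requested yield truncated plans with a
    warning.  Selection is deterministic given the inputs (stable sorts,
    neuron-id tie-breaks).
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    if not 1 <= n_per_fov:
        raise ValueError("n_per_fov must be positive")
    da, db = baseline_days
    rows = []
    for fov_id in ds.fov_ids():
        neurons = ds.fov_neurons(fov_id)
        ids = neurons["neuron_id"].to_numpy()
        eligible = neurons["eligible"].to_numpy(bool)
        inhib = neurons["inhibitory"].to_numpy(bool)
        res_a, res_b = resp.get(fov_id, da), resp.get(fov_id, db)
        present = np.isfinite(res_a.mean_amp).any(axis=1) & np.isfinite(res_b.mean_amp).any(axis=1)

        if mode == "responsive":
            ranking = merged_responsive_ranking(res_a, res_b, ids)
        elif mode == "nonresponsive":
            ranking = _nonresponsive_ranking(res_a, res_b, ids, present)
            if ranking.empty:
                warnings.warn(f"FOV {fov_id}: no nonresponsive candidates", stacklevel=2)
        else:
            ranking = _inhibitory_ranking(res_a, res_b, ids, inhib, present)
            if ranking.empty:
                warnings.warn(f"FOV {fov_id}: no interneuron candidates", stacklevel=2)

        n_sel = 0
        for _, row in ranking.iterrows():
            i = int(row["index"])
            take = eligible[i] and n_sel < n_per_fov
            reason = "" if take else ("ineligible" if not eligible[i] else "quota_reached")
            rows.append((fov_id, row["neuron_id"], int(row["rank"]), float(row["amplitude"]), take, bool(eligible[i]), pd.NA, reason))
            n_sel += int(take)
        if n_sel < n_per_fov:
            warnings.warn(f"FOV {fov_id}: only {n_sel} of {n_per_fov} targets available ({mode})", stacklevel=2)
    frame = pd.DataFrame(
        rows,
        columns=["fov_id", "neuron_id", "rank", "amplitude", "selected", "eligible", "success", "skip_reason"],
    )
    return AblationPlan(mode=mode, n_per_fov=n_per_fov, frame=frame)


def _inhibitory_ranking(res_a, res_b, ids, inhib, present) -> pd.DataFrame:
    # responsive interneurons first, by the merged responsive criterion
    resp_part = merged_responsive_ranking(res_a, res_b, ids, restrict=inhib)
    # then apparent-responsive interneurons: non-significant, largest evoked amplitude
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        best_a = np.nanmax(res_a.mean_amp, axis=1)
        best_b = np.nanmax(res_b.mean_amp, axis=1)
    avg_best = (best_a + best_b) / 2.0
    nonsig = inhib & present & ~res_a.responsive & ~res_b.responsive & np.isfinite(avg_best)
    idx = np.flatnonzero(nonsig)
    extra = pd.DataFrame({"neuron_id": ids[idx], "index": idx, "amplitude": avg_best[idx]})
    extra = extra.sort_values(["amplitude", "neuron_id"], ascending=[False, True], kind="stable")
    out = pd.concat([resp_part[["neuron_id", "index", "amplitude"]], extra], ignore_index=True)
    out = out.drop_duplicates("neuron_id", keep="first").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


# ---------------------------------------------------------------------------
# high / low category sets
# ---------------------------------------------------------------------------

def assign_categories(
    resp: CohortResponsiveness,
    ds: CohortDataset,
    plan: AblationPlan | None = None,
    n_category: int = 5,
    baseline_days: tuple[int, int] = (3, 5),
) -> dict:
    """High- and low-category neuron sets per FOV.

    High: the ``n_category`` responsive neurons with the highest merged
    baseline amplitudes (for the inhibitory cohort, excluding ablated
    interneurons, passed via ``plan``).  Low: the ``n_category``
    nonresponsive neurons with minimum absolute amplitude.  Shortfalls take
    all available and log a warning.
    """
    da, db = baseline_days
    out = {}
    targeted = set(plan.target_ids()) if plan is not None and plan.mode == "inhibitory" else set()
    for fov_id in ds.fov_ids():
        neurons = ds.fov_neurons(fov_id)
        ids = neurons["neuron_id"].to_numpy()
        res_a, res_b = resp.get(fov_id, da), resp.get(fov_id, db)
        present = np.isfinite(res_a.mean_amp).any(axis=1) & np.isfinite(res_b.mean_amp).any(axis=1)
        high_rank = merged_responsive_ranking(res_a, res_b, ids)
        high_rank = high_rank[~high_rank["neuron_id"].isin(targeted)]
        low_rank = _nonresponsive_ranking(res_a, res_b, ids, present)
        high = list(high_rank["neuron_id"].head(n_category))
        low = list(low_rank["neuron_id"].head(n_category))
        for name, got in (("high", high), ("low", low)):
            if len(got) < n_category:
                warnings.warn(f"FOV {fov_id}: only {len(got)} {name}-category neurons available", stacklevel=2)
        out[fov_id] = {"high": high, "low": low}
    return out


# ---------------------------------------------------------------------------
# spared mask
# ---------------------------------------------------------------------------

@dataclass
class SparedMask:
    """Per-neuron spared flag with the primary exclusion reason."""

    frame: pd.DataFrame  # neuron_id, fov_id, spared, reason

    def spared_array(self, ds: CohortDataset, fov_id: str) -> np.ndarray:
        sub = self.frame[self.frame["fov_id"] == fov_id]
        lookup = dict(zip(sub["neuron_id"], sub["spared"]))
        ids = ds.fov_neurons(fov_id)["neuron_id"]
        return np.array([bool(lookup.get(n, True)) for n in ids])

    @property
    def spared_ids(self) -> set:
        f = self.frame
        return set(f.loc[f["spared"], "neuron_id"])


def build_spared_mask(
    ds: CohortDataset,
    plan: AblationPlan,
    categories: dict | None = None,
    cohort: str | None = None,
    radius_um: float = 15.0,
) -> SparedMask:
    """Exclude targets, a 15-um sphere around them, and category sets.

    A neuron is excluded if it was targeted (successful ablation or not), if
    its 3-D Euclidean distance to any targeted neuron is <= ``radius_um``
    (boundary inclusive: exactly 15 um is excluded), or if it belongs to a
    category set the cohort digitally filters out.  Neurons with missing
    positions are conservatively excluded.  Each neuron records one primary
    reason, in that priority order.
    """
    rows = []
    for fov_id in ds.fov_ids():
        neurons = ds.fov_neurons(fov_id)
        ids = neurons["neuron_id"].to_numpy()
        pos = neurons[["x_um", "y_um", "z_um"]].to_numpy(float)
        fov_cohort = cohort or str(neurons["cohort"].iloc[0])
        cat_names = COHORT_CATEGORY_EXCLUSIONS.get(fov_cohort, ())
        targets = plan.target_ids(fov_id)
        t_idx = [int(np.flatnonzero(ids == t)[0]) for t in targets]
        reason = np.array([""] * len(ids), dtype=object)
        if t_idx:
            t_pos = pos[t_idx]
            dist = np.sqrt(((pos[:, None, :] - t_pos[None, :, :]) ** 2).sum(axis=2)).min(axis=1)
            near = dist <= radius_um
            reason[near] = "within_radius"
        missing = ~np.isfinite(pos).all(axis=1)
        reason[missing & (reason == "")] = "missing_position"
        if categories:
            cats = categories.get(fov_id, {})
            for cat, label in (("high", "high_category"), ("low", "low_category")):
                if cat in cat_names:
                    sel = np.isin(ids, list(cats.get(cat, [])))
                    reason[sel & (reason == "")] = label
        reason[t_idx] = "targeted"
        for nid, r in zip(ids, reason):
            rows.append((nid, fov_id, r == "", r))
    return SparedMask(frame=pd.DataFrame(rows, columns=["neuron_id", "fov_id", "spared", "reason"]))
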