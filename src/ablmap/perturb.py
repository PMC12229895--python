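"""Perturbation inference machinery.

Cohort permutation tests (200 label shuffles of mouse-level statistics), the
FOV-shuffle similarity null (500 reassignments of neurons across FOVs with a
95% percentile envelope), the tuning-width scaling simulation, consecutive-day
responsiveness stability, spatial effect-versus-distance profiles, and the
excitatory/inhibitory balance ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import stream
from .tuning import sorted_profiles


@dataclass
class PermutationResult:
    """Observed statistic with its permutation/shuffle null."""

    observed: float
    null: np.ndarray
    p_value: float | None
    ci: tuple[float, float] | None
    seed: int

    @property
    def n_null(self) -> int:
        return len(self.null)

    @property
    def inside_ci(self) -> bool:
        if self.ci is None:
            raise ValueError("no confidence envelope computed")
        return self.ci[0] <= self.observed <= self.ci[1]


# ---------------------------------------------------------------------------
# cohort permutation test
# ---------------------------------------------------------------------------

def permutation_group_test(
    values_by_cohort: dict[str, np.ndarray],
    n_perm: int = 200,
    seed: int = 0,
    cohorts: tuple[str, str] | None = None,
) -> PermutationResult:
    """Two-sided permutation test on mouse-level statistics across cohorts.

    The statistic is the difference of cohort means (first minus second of
    ``cohorts``; defaults to the two cohorts given); labels are permuted over
    the pooled mouse values ``n_perm`` times and the p-value is the fraction
    of null draws at least as extreme in absolute value, with add-one
    smoothing: ``p = (1 + #extreme) / (n_perm + 1)``.
    """
    if cohorts is None:
        if len(values_by_cohort) != 2:
            raise ValueError("specify cohorts=(a, b) when more than two cohorts are given")
        cohorts = tuple(values_by_cohort)
    a, b = cohorts
    xa = np.asarray(values_by_cohort[a], dtype=float)
    xb = np.asarray(values_by_cohort[b], dtype=float)
    if len(xa) < 2 or len(xb) < 2:
        raise ValueError("need at least 2 mice per cohort")
    pooled = np.concatenate([xa, xb])
    na = len(xa)
    observed = float(xa.mean() - xb.mean())
    rng = stream(seed, "permtest")
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(pooled)
        null[i] = perm[:na].mean() - perm[na:].mean()
    p = (1.0 + np.sum(np.abs(null) >= abs(observed) - 1e-12)) / (n_perm + 1.0)
    return PermutationResult(observed=observed, null=null, p_value=float(p), ci=None, seed=seed)


# ---------------------------------------------------------------------------
# FOV-shuffle similarity null
# ---------------------------------------------------------------------------

def offdiag_mean_from_curves(curves: np.ndarray) -> float:
    """Off-diagonal mean of the trial-averaged similarity matrix of one set of curves."""
    V = np.asarray(curves, dtype=float)
    sd = V.std(axis=1)
    V = V[sd > 0]
    if V.shape[0] < 2:
        return np.nan
    R = np.corrcoef(V.T, rowvar=True)  # stimulus x stimulus across neurons
    iu = np.triu_indices(R.shape[0], k=1)
    return float(np.nanmean(R[iu]))


def fov_shuffle_similarity_null(
    curves_by_fov: dict[str, np.ndarray],
    n_shuffle: int = 500,
    seed: int = 0,
) -> PermutationResult:
    """Null distribution of the off-diagonal similarity mean under FOV shuffling.

    Each draw randomly reassigns the pooled neurons (trial-averaged tuning
    curves, single-neuron properties preserved exactly) to pseudo-FOVs of
    the original sizes, rebuilds each pseudo-FOV's trial-averaged similarity
    matrix, and records the across-FOV mean of the off-diagonal mean.  The
    envelope is the 2.5/97.5 percentile band of the ``n_shuffle`` draws.
    """
    fovs = sorted(curves_by_fov)
    sizes = [np.asarray(curves_by_fov[f]).shape[0] for f in fovs]
    pool = np.concatenate([np.asarray(curves_by_fov[f], dtype=float) for f in fovs], axis=0)
    if len(fovs) == 1:
        warnings.warn("single FOV: the shuffle is the identity and the null is degenerate", stacklevel=2)
    observed = float(np.nanmean([offdiag_mean_from_curves(curves_by_fov[f]) for f in fovs]))
    rng = stream(seed, "fovshuffle")
    splits = np.cumsum(sizes)[:-1]
    null = np.empty(n_shuffle)
    for i in range(n_shuffle):
        perm = rng.permutation(pool.shape[0])
        parts = np.split(perm, splits)
        null[i] = np.nanmean([offdiag_mean_from_curves(pool[part]) for part in parts])
    ci = (float(np.percentile(null, 2.5)), float(np.percentile(null, 97.5)))
    return PermutationResult(observed=observed, null=null, p_value=None, ci=ci, seed=seed)


# ---------------------------------------------------------------------------
# tuning-width scaling simulation
# ---------------------------------------------------------------------------

@dataclass
class WidthScalingResult:
    """Baseline vs profile-scaled similarity comparison."""

    scaled_curves: np.ndarray
    offdiag_baseline: float
    offdiag_scaled: float

    @property
    def offdiag_change(self) -> float:
        return self.offdiag_scaled - self.offdiag_baseline


def scale_tuning_curves(
    curves: np.ndarray,
    bins: np.ndarray,
    target_profiles: dict[int, np.ndarray] | None = None,
) -> np.ndarray:
    """Impose sorted-normalised profiles on tuning curves, preserving peaks.

    Each neuron's descending-sorted curve is replaced by its own peak
    amplitude times the target profile of its best-amplitude bin, written
    back in the neuron's own stimulus order; the best stimulus identity and
    best amplitude are preserved.  With ``target_profiles=None`` every
    neuron's target is its own profile and the curves are returned unchanged
    (identity scaling).  Neurons with non-positive peak are left untouched.
    """
    curves = np.asarray(curves, dtype=float)
    own = sorted_profiles(curves)
    out = curves.copy()
    for i in range(curves.shape[0]):
        if not np.isfinite(own[i]).all():
            continue
        order = np.argsort(-curves[i], kind="stable")
        peak = curves[i, order[0]]
        target = own[i] if target_profiles is None else np.asarray(target_profiles[int(bins[i])], dtype=float)
        out[i, order] = peak * target
    return out


def width_scaling_similarity_sim(
    curves: np.ndarray,
    bins: np.ndarray,
    target_profiles: dict[int, np.ndarray] | None = None,
) -> WidthScalingResult:
    """Rebuild the trial-averaged similarity matrix after profile scaling."""
    scaled = scale_tuning_curves(curves, bins, target_profiles)
    return WidthScalingResult(
        scaled_curves=scaled,
        offdiag_baseline=offdiag_mean_from_curves(curves),
        offdiag_scaled=offdiag_mean_from_curves(scaled),
    )


# ---------------------------------------------------------------------------
# responsiveness stability
# ---------------------------------------------------------------------------

def stability_overlap(
    resp_frame: pd.DataFrame,
    spared_ids: set | None = None,
    denominator: str = "union",
) -> pd.DataFrame:
    """Fraction of neurons responsive on both of two consecutive sessions.

    ``denominator`` selects the normaliser: ``"union"`` (default, Jaccard
    overlap), ``"first"`` (the first day's responsive set) or ``"total"``
    (all neurons scored on both days).  Computed per FOV for each adjacent
    session pair, restricted to ``spared_ids`` when given.
    """
    if denominator not in ("union", "first", "total"):
        raise ValueError(f"unknown denominator {denominator!r}")
    f = resp_frame
    if spared_ids is not None:
        f = f[f["neuron_id"].isin(spared_ids)]
    rows = []
    for fov_id, sub in f.groupby("fov_id"):
        days = sorted(sub["day"].unique())
        for d1, d2 in zip(days[:-1], days[1:]):
            s1 = set(sub.loc[(sub["day"] == d1) & sub["responsive"], "neuron_id"])
            s2 = set(sub.loc[(sub["day"] == d2) & sub["responsive"], "neuron_id"])
            if denominator == "union":
                denom = len(s1 | s2)
            elif denominator == "first":
                denom = len(s1)
            else:
                denom = sub.loc[sub["day"].isin([d1, d2]), "neuron_id"].nunique()
            rows.append((fov_id, d1, d2, len(s1 & s2), denom, len(s1 & s2) / denom if denom else np.nan))
    return pd.DataFrame(rows, columns=["fov_id", "day_from", "day_to", "n_both", "n_denom", "overlap"])


# ---------------------------------------------------------------------------
# spatial effect profile
# ---------------------------------------------------------------------------

def nearest_target_distance(positions: np.ndarray, target_positions: np.ndarray) -> np.ndarray:
    """3-D Euclidean distance from each neuron to its nearest ablated target."""
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    target_positions = np.atleast_2d(np.asarray(target_positions, dtype=float))
    if target_positions.shape[0] == 0:
        return np.full(positions.shape[0], np.inf)
    d = np.sqrt(((positions[:, None, :] - target_positions[None, :, :]) ** 2).sum(axis=2))
    return d.min(axis=1)


def spatial_effect_profile(
    positions: np.ndarray,
    target_positions: np.ndarray,
    effects: np.ndarray,
    bin_edges_um: np.ndarray,
) -> pd.DataFrame:
    """Average per-neuron effect values binned by distance to the nearest target.

    Empty bins yield NaN (missing), never zero.
    """
    dist = nearest_target_distance(positions, target_positions)
    effects = np.asarray(effects, dtype=float)
    edges = np.asarray(bin_edges_um, dtype=float)
    rows = []
    for k in range(len(edges) - 1):
        sel = (dist >= edges[k]) & (dist < edges[k + 1]) & np.isfinite(effects)
        rows.append(
            (edges[k], edges[k + 1], int(sel.sum()), float(effects[sel].mean()) if sel.any() else np.nan)
        )
    return pd.DataFrame(rows, columns=["bin_left_um", "bin_right_um", "n_neurons", "mean_effect"])


# ---------------------------------------------------------------------------
# excitation / inhibition balance
# ---------------------------------------------------------------------------

def ei_balance(resp_frame: pd.DataFrame, inhibitory: dict | pd.Series) -> pd.DataFrame:
    """E/I balance ratio per mouse per day.

    Per cell class, total response = (fraction of responsive neurons) x
    (mean best response amplitude of responsive neurons); the balance is
    ``total_E / (total_E + total_I)`` in [0, 1].  NaN when both totals
    vanish or a class is absent.
    """
    f = resp_frame.copy()
    if isinstance(inhibitory, dict):
        f["inhibitory"] = f["neuron_id"].map(inhibitory)
    else:
        f["inhibitory"] = f["neuron_id"].map(dict(inhibitory))
    rows = []
    for (mouse_id, day), sub in f.groupby(["mouse_id", "day"]):
        totals = {}
        for label, cls in (("E", False), ("I", True)):
            cell = sub[sub["inhibitory"] == cls]
            if cell.empty:
                totals[label] = np.nan
                continue
            frac = cell["responsive"].mean()
            amps = cell.loc[cell["responsive"], "best_amplitude"]
            totals[label] = frac * amps.mean() if len(amps) else 0.0
        te, ti = totals["E"], totals["I"]
        if np.isnan(te) or np.isnan(ti) or (te + ti) == 0:
            bal = np.nan
        else:
            bal = te / (te + ti)
        rows.append((mouse_id, day, te, ti, bal))
    return pd.DataFrame(rows, columns=["mouse_id", "day", "total_E", "total_I", "balance"])
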