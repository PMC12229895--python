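"""Single-neuron and pairwise tuning statistics.

Covers split-half tuning reliability (same-day and across-day), the
15th-stimulus tuning-width statistic over sorted normalised tuning curves,
within-FOV signal correlations with high-correlation pair fractions per
best-amplitude bin, correlation profiles of spared neurons against frozen
day-5 reference (high-category) tuning, and the drift-retention estimator
used for generator parameter recovery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import stream
from .dataset import CohortDataset, TrialTensor, amp_bin
from .events import CohortResponsiveness

WIDTH_RANK = 15  # sorted-stimulus index (1-based) of the width statistic


def tuning_curves(tensor: TrialTensor) -> np.ndarray:
    """Trial-mean tuning curves (N, S); NaN rows for absent neurons."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(tensor.A, axis=2)


def _row_corr(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation between matching rows of two (N, S) arrays."""
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    num = (xc * yc).sum(axis=1)
    den = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return out


def split_half_tuning_correlation(
    tensor_a: TrialTensor,
    tensor_b: TrialTensor | None = None,
    n_repeats: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Mean split-half tuning correlation per neuron.

    Same-day (``tensor_b`` omitted): trials are pseudorandomly split into two
    disjoint halves stratified by stimulus (5+5 of the 10 trials), the
    half-mean tuning curves are correlated, and the value is averaged over
    ``n_repeats`` splits (trial-to-trial response reliability).  Across-day:
    one half is drawn from each tensor independently.  Repeats with a
    zero-variance half curve are skipped; neurons with no valid repeat get
    NaN.
    """
    rng = stream(seed, "split", tensor_a.fov_id, tensor_a.day, tensor_b.day if tensor_b is not None else "same")
    A = tensor_a.A
    B = tensor_b.A if tensor_b is not None else A
    n, S, T = A.shape
    half = T // 2
    if half < 2:
        raise ValueError("need at least 4 trials per stimulus to split")
    vals = np.full((n_repeats, n), np.nan)
    for r in range(n_repeats):
        perm_a = rng.permuted(np.tile(np.arange(T), (S, 1)), axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            if tensor_b is None:
                ordered = np.take_along_axis(A, perm_a[None, :, :], axis=2)
                m1 = np.nanmean(ordered[:, :, :half], axis=2)
                m2 = np.nanmean(ordered[:, :, half:], axis=2)
            else:
                perm_b = rng.permuted(np.tile(np.arange(B.shape[2]), (S, 1)), axis=1)
                m1 = np.nanmean(np.take_along_axis(A, perm_a[None, :, :], axis=2)[:, :, :half], axis=2)
                m2 = np.nanmean(np.take_along_axis(B, perm_b[None, :, :], axis=2)[:, :, : B.shape[2] // 2], axis=2)
        ok = np.isfinite(m1).all(axis=1) & np.isfinite(m2).all(axis=1)
        vals[r, ok] = _row_corr(m1[ok], m2[ok])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(vals, axis=0)


# ---------------------------------------------------------------------------
# tuning width
# ---------------------------------------------------------------------------

def sorted_profiles(curves: np.ndarray) -> np.ndarray:
    """Descending-sorted tuning curves normalised to a unit peak (N, S).

    Neurons with non-positive peak are excluded (NaN row).
    """
    curves = np.asarray(curves, dtype=float)
    prof = np.sort(curves, axis=1)[:, ::-1]
    peak = prof[:, 0].copy()
    bad = ~(peak > 0) | ~np.isfinite(curves).all(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        prof = prof / peak[:, None]
    prof[bad] = np.nan
    return prof


def tuning_width(curves: np.ndarray, rank: int = WIDTH_RANK) -> np.ndarray:
    """Per-neuron width statistic: normalised amplitude at sorted rank ``rank``.

    0 for one-hot tuning, 1 for flat tuning; invariant to amplitude scaling.
    """
    return sorted_profiles(curves)[:, rank - 1]


def width_profile_by_bin(curves: np.ndarray, bins: np.ndarray, rank: int = WIDTH_RANK) -> pd.DataFrame:
    """Average sorted normalised profile and width per best-amplitude bin."""
    prof = sorted_profiles(curves)
    rows = []
    for b in sorted(set(int(x) for x in bins if x > 0)):
        sel = (bins == b) & np.isfinite(prof).all(axis=1)
        if not sel.any():
            continue
        mean_prof = prof[sel].mean(axis=0)
        rows.append((b, int(sel.sum()), mean_prof[rank - 1], mean_prof))
    return pd.DataFrame(rows, columns=["amp_bin", "n_neurons", "width", "profile"])


# ---------------------------------------------------------------------------
# signal correlations
# ---------------------------------------------------------------------------

@dataclass
class PairCorrelations:
    """Within-FOV signal-correlation pair table plus exclusion bookkeeping."""

    frame: pd.DataFrame  # columns i, j, r, pair_bin
    n_excluded_constant: int

    def high_fraction(self, threshold: float = 0.7, by_bin: bool = True) -> pd.DataFrame:
        f = self.frame
        if f.empty:
            return pd.DataFrame(columns=["amp_bin", "n_pairs", "fraction_high"])
        if by_bin:
            grp = f.groupby("pair_bin")
            out = grp["r"].agg(n_pairs="size", fraction_high=lambda r: float((r > threshold).mean()))
            return out.reset_index().rename(columns={"pair_bin": "amp_bin"})
        return pd.DataFrame(
            {"amp_bin": [0], "n_pairs": [len(f)], "fraction_high": [float((f["r"] > threshold).mean())]}
        )


def signal_correlations(
    curves: np.ndarray,
    best_amplitude: np.ndarray,
    mask: np.ndarray,
) -> PairCorrelations:
    """Pairwise Pearson correlations of trial-averaged tuning curves.

    All unordered pairs of neurons selected by ``mask`` (within one FOV);
    each pair is assigned the best-amplitude bin of the mean of the two best
    amplitudes.  Pairs involving a constant curve are excluded and counted.
    """
    idx = np.flatnonzero(mask)
    if len(idx) < 2:
        return PairCorrelations(frame=pd.DataFrame(columns=["i", "j", "r", "pair_bin"]), n_excluded_constant=0)
    sub = np.asarray(curves, dtype=float)[idx]
    sd = sub.std(axis=1)
    ok = sd > 0
    R = np.corrcoef(sub[ok]) if ok.sum() >= 2 else np.empty((0, 0))
    keep = idx[ok]
    rows = []
    for a in range(len(keep)):
        for b in range(a + 1, len(keep)):
            pair_amp = 0.5 * (best_amplitude[keep[a]] + best_amplitude[keep[b]])
            rows.append((int(keep[a]), int(keep[b]), float(R[a, b]), int(amp_bin(np.array([pair_amp]))[0])))
    n_const = int((~ok).sum())
    n_excluded = n_const * (len(idx) - 1) - n_const * (n_const - 1) // 2 if n_const else 0
    return PairCorrelations(
        frame=pd.DataFrame(rows, columns=["i", "j", "r", "pair_bin"]),
        n_excluded_constant=n_excluded,
    )


# ---------------------------------------------------------------------------
# reference (high-category) correlation profiles
# ---------------------------------------------------------------------------

REFERENCE_BINS = np.round(np.arange(-0.6, 1.01, 0.2), 10)  # 8 bins, [-0.6, 1.0] step 0.2


@dataclass
class ReferenceProfile:
    """Binned correlation-to-reference fractions per day and day-5 group."""

    frame: pd.DataFrame    # day, group, bin_left, bin_right, fraction, fraction_bs
    summary: pd.DataFrame  # day, group, n_pairs, frac_above


def day5_groups(resp_by_day: dict[int, np.ndarray], day5: int = 5) -> np.ndarray:
    """Partition neurons by day-5 responsiveness history.

    Returns an array of strings: ``"R5"`` (responsive on day 5), ``"G"``
    (unresponsive on day 5 but responsive on some other day), ``""`` (never
    responsive).  The two groups are disjoint by construction.
    """
    resp5 = resp_by_day[day5]
    any_other = np.zeros_like(resp5, dtype=bool)
    for d, r in resp_by_day.items():
        if d != day5:
            any_other |= r
    out = np.where(resp5, "R5", np.where(any_other, "G", ""))
    return out.astype(object)


def reference_correlation_profile(
    curves_by_day: dict[int, np.ndarray],
    resp_by_day: dict[int, np.ndarray],
    spared: np.ndarray,
    reference_idx: np.ndarray,
    reference_day: int = 5,
    baseline_days: tuple[int, ...] = (1, 3),
    bins: np.ndarray = REFERENCE_BINS,
    threshold: float = 0.6,
    responsive_only: bool = False,
) -> ReferenceProfile:
    """Correlations of spared-neuron tuning to frozen day-5 reference tuning.

    For each day, each spared neuron is correlated with every reference
    neuron's day-``reference_day`` curve; each neuron x reference pair is one
    observation pooled into the distribution.  The distribution is split by
    day-5 responsiveness group (R5 vs G), binned into the 8 correlation bins
    from -0.6 to 1.0, normalised within group x day, and baseline-subtracted
    (mean of ``baseline_days``).  With ``responsive_only`` the profile uses
    only spared neurons responsive on the day under analysis.
    """
    reference_idx = np.asarray(reference_idx, dtype=int)
    if len(reference_idx) == 0:
        raise ValueError("empty reference set")
    ref_curves = np.asarray(curves_by_day[reference_day], dtype=float)[reference_idx]
    groups = day5_groups(resp_by_day, day5=reference_day)
    days = sorted(curves_by_day)
    rows, summ = [], []
    edges = np.asarray(bins, dtype=float)
    for day in days:
        curves = np.asarray(curves_by_day[day], dtype=float)
        for grp in ("R5", "G"):
            sel = spared & (groups == grp)
            if responsive_only:
                sel = sel & resp_by_day[day]
            sel &= np.isfinite(curves).all(axis=1)
            r_pool = []
            for i in np.flatnonzero(sel):
                if i in reference_idx:
                    continue  # a neuron is never correlated with itself
                rr = _row_corr(np.tile(curves[i], (len(ref_curves), 1)), ref_curves)
                r_pool.extend(rr[np.isfinite(rr)])
            r_pool = np.asarray(r_pool)
            counts, _ = np.histogram(r_pool, bins=edges)
            frac = counts / len(r_pool) if len(r_pool) else np.full(len(edges) - 1, np.nan)
            for k in range(len(edges) - 1):
                rows.append((day, grp, edges[k], edges[k + 1], frac[k]))
            summ.append((day, grp, len(r_pool), float((r_pool > threshold).mean()) if len(r_pool) else np.nan))
    frame = pd.DataFrame(rows, columns=["day", "group", "bin_left", "bin_right", "fraction"])
    base = (
        frame[frame["day"].isin(baseline_days)]
        .groupby(["group", "bin_left"])["fraction"]
        .mean()
        .rename("baseline")
        .reset_index()
    )
    frame = frame.merge(base, on=["group", "bin_left"], how="left")
    frame["fraction_bs"] = frame["fraction"] - frame["baseline"]
    summary = pd.DataFrame(summ, columns=["day", "group", "n_pairs", "frac_above"])
    return ReferenceProfile(frame=frame.drop(columns="baseline"), summary=summary)


# ---------------------------------------------------------------------------
# drift retention estimation (generator parameter recovery)
# ---------------------------------------------------------------------------

def estimate_drift_rho(
    ds: CohortDataset,
    resp: CohortResponsiveness | None = None,
    seed: int = 0,
) -> float:
    """Estimate the per-2-day tuning retention from cross-day correlations.

    For every adjacent 2-day session pair, the cross-day correlation of
    trial-mean tuning curves (neurons responsive on both days) is divided by
    the geometric mean of the two days' full-curve reliabilities
    (Spearman-Brown-corrected split-half values), which removes trial-noise
    attenuation.  The estimate is the pooled mean of these corrected ratios.
    """
    if resp is None:
        from .events import classify_cohort

        resp = classify_cohort(ds)
    ratios = []
    days = list(ds.days)
    for fov_id in ds.fov_ids():
        for da, db in zip(days[:-1], days[1:]):
            if db - da != 2:
                continue  # only 2-day lags estimate the per-step retention
            ta, tb = ds.tensor(fov_id, da), ds.tensor(fov_id, db)
            both = resp.get(fov_id, da).responsive & resp.get(fov_id, db).responsive
            if both.sum() < 3:
                continue
            ca, cb = tuning_curves(ta), tuning_curves(tb)
            r_cross = _row_corr(ca[both], cb[both])
            r_a = split_half_tuning_correlation(ta, seed=seed)[both]
            r_b = split_half_tuning_correlation(tb, seed=seed)[both]
            sb_a = 2 * r_a / (1 + r_a)
            sb_b = 2 * r_b / (1 + r_b)
            with np.errstate(invalid="ignore", divide="ignore"):
                ratio = r_cross / np.sqrt(sb_a * sb_b)
            ratios.extend(ratio[np.isfinite(ratio)])
    if not ratios:
        return np.nan
    return float(np.clip(np.mean(ratios), 0.0, 1.0))
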