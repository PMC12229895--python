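"""Single-neuron statistical front end.

Turns raw soma/neuropil fluorescence traces into %dF/F, extracts per-trial
evoked amplitudes, and classifies sound responsiveness with an exact Wilcoxon
signed-rank test per stimulus followed by Benjamini-Hochberg correction across
the 34-stimulus family within each neuron.

The signed-rank test is evaluated vectorised over (neuron, stimulus) cells
with the exact null distribution of the positive-rank sum (dynamic-programming
table) for n <= ``EXACT_MAX_N`` usable differences and a normal approximation
with continuity and tie corrections above.  Zero differences are discarded
before ranking (the dominant convention; this changes the attainable minimal
p and is therefore fixed, not configurable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import AMP_BIN_EDGES, CohortDataset, TrialTensor, amp_bin

EXACT_MAX_N = 15

# ---------------------------------------------------------------------------
# dF/F from raw traces
# ---------------------------------------------------------------------------

FRAME_RATE_HZ = 5.0


@dataclass
class DffTrace:
    """%dF/F per frame at 5 Hz plus the rolling baseline it was computed from."""

    dff: np.ndarray
    f0: np.ndarray
    valid: np.ndarray  # False where F0 <= 0 (flagged, not propagated)


def compute_dff(
    soma: np.ndarray,
    neuropil: np.ndarray | None = None,
    contamination_ratio: float = 0.7,
    window: int = 201,
    percentile: float = 30.0,
) -> DffTrace:
    """Neuropil-corrected dF/F with a rolling rank-order baseline.

    ``F_corr = soma - r * neuropil``; ``F0(t)`` is the 30th percentile of
    ``F_corr`` over the 201-frame window centred on ``t`` (100 before, 100
    after; truncated at the trace edges); ``dff = (F_corr - F0) / F0``.
    Frames with non-positive ``F0`` are flagged invalid and masked (NaN).
    """
    soma = np.asarray(soma, dtype=float)
    if soma.ndim != 1:
        raise ValueError("trace must be 1-D (single neuron)")
    if neuropil is None:
        neuropil = np.zeros_like(soma)
    neuropil = np.asarray(neuropil, dtype=float)
    if neuropil.shape != soma.shape:
        raise ValueError("soma and neuropil traces must have the same length")
    if not 0.0 <= contamination_ratio <= 1.0:
        raise ValueError(f"contamination_ratio must be in [0, 1], got {contamination_ratio}")
    if len(soma) <= window // 2:
        raise ValueError(f"trace length {len(soma)} too short for window {window}")
    f_corr = soma - contamination_ratio * neuropil
    f0 = (
        pd.Series(f_corr)
        .rolling(window=window, center=True, min_periods=1)
        .quantile(percentile / 100.0)
        .to_numpy()
    )
    valid = f0 > 0
    dff = np.full_like(f_corr, np.nan)
    dff[valid] = (f_corr[valid] - f0[valid]) / f0[valid]
    return DffTrace(dff=dff, f0=f0, valid=valid)


def extract_amplitudes(dff: np.ndarray | DffTrace, onsets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial evoked amplitude and matched prestimulus baseline amplitude.

    For an onset frame ``i`` at 5 Hz the evoked amplitude is
    ``mean(dff[i+1], dff[i+2]) - mean(dff[i-2], dff[i-1])`` (post window
    200-400 ms minus prestimulus window, two frames each).  The prestimulus
    "spontaneous amplitude" used as the paired null is computed identically on
    the window ending at the onset: ``mean(dff[i-2], dff[i-1]) -
    mean(dff[i-4], dff[i-3])``.  Onsets too close to an edge (or overlapping
    masked frames) yield NaN for that trial.
    """
    if isinstance(dff, DffTrace):
        dff = dff.dff
    dff = np.asarray(dff, dtype=float)
    onsets = np.asarray(onsets)
    flat = onsets.reshape(-1)
    n = len(dff)
    amps = np.full(flat.shape, np.nan)
    pres = np.full(flat.shape, np.nan)
    for j, i in enumerate(flat):
        i = int(i)
        if i - 4 < 0 or i + 2 >= n:
            continue
        post = dff[i + 1 : i + 3]
        base = dff[i - 2 : i]
        spont = dff[i - 4 : i - 2]
        if np.isnan(post).any() or np.isnan(base).any():
            continue
        amps[j] = post.mean() - base.mean()
        if not np.isnan(spont).any():
            pres[j] = base.mean() - spont.mean()
    return amps.reshape(onsets.shape), pres.reshape(onsets.shape)


# ---------------------------------------------------------------------------
# exact Wilcoxon signed-rank, vectorised
# ---------------------------------------------------------------------------

@lru_cache(maxsize=64)
def _signrank_cdf(n: int) -> np.ndarray:
    """CDF of the positive-rank sum W+ under the exact signed-rank null."""
    m = n * (n + 1) // 2
    counts = np.zeros(m + 1)
    counts[0] = 1.0
    for k in range(1, n + 1):
        new = counts.copy()
        new[k:] += counts[:-k]
        counts = new
    return np.cumsum(counts) / 2.0**n


def signed_rank_pvalues(diffs: np.ndarray, min_trials: int = 5, exact_max_n: int = EXACT_MAX_N) -> np.ndarray:
    """Two-sided signed-rank p-values along the last axis of ``diffs``.

    NaN entries are masked trials; zero differences are discarded before
    ranking.  Cells with fewer than ``min_trials`` valid trials get NaN
    (excluded from the multiple-testing family); cells whose valid
    differences are all zero get p = 1.  Exact null for n <= ``exact_max_n``
    usable differences without ties in |d|; normal approximation with
    continuity and tie corrections otherwise.
    """
    diffs = np.asarray(diffs, dtype=float)
    shape = diffs.shape[:-1]
    d = diffs.reshape(-1, diffs.shape[-1])
    valid = np.isfinite(d)
    nonzero = valid & (d != 0)
    n_valid = valid.sum(axis=1)
    n_use = nonzero.sum(axis=1)

    absd = np.where(nonzero, np.abs(d), np.inf)
    ranks = stats.rankdata(absd, axis=1)
    w_plus = np.where(nonzero & (d > 0), ranks, 0.0).sum(axis=1)

    # ties in |d| among usable entries invalidate the exact table
    sorted_abs = np.sort(absd, axis=1)
    with np.errstate(invalid="ignore"):
        has_tie = np.any((np.diff(sorted_abs, axis=1) == 0) & np.isfinite(sorted_abs[:, 1:]), axis=1)

    p = np.full(d.shape[0], np.nan)
    p[(n_valid >= min_trials) & (n_use == 0)] = 1.0

    exact_mask = (n_valid >= min_trials) & (n_use > 0) & (n_use <= exact_max_n) & ~has_tie
    for n in np.unique(n_use[exact_mask]):
        cdf = _signrank_cdf(int(n))
        sel = exact_mask & (n_use == n)
        w = w_plus[sel].astype(int)
        lower = cdf[w]
        upper = 1.0 - np.where(w > 0, cdf[w - 1], 0.0)
        p[sel] = np.minimum(1.0, 2.0 * np.minimum(lower, upper))

    approx_mask = (n_valid >= min_trials) & (n_use > 0) & ~exact_mask
    if approx_mask.any():
        p[approx_mask] = _signrank_normal_approx(d[approx_mask], nonzero[approx_mask], ranks[approx_mask], w_plus[approx_mask])
    return p.reshape(shape)


def _signrank_normal_approx(d, nonzero, ranks, w_plus):
    n = nonzero.sum(axis=1).astype(float)
    mn = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    # tie correction: sum(t^3 - t)/48 over groups of tied |d|
    tie_corr = np.zeros(len(d))
    for i in range(len(d)):
        vals = np.abs(d[i][nonzero[i]])
        _, counts = np.unique(vals, return_counts=True)
        tie_corr[i] = np.sum(counts**3 - counts) / 48.0
    var = var - tie_corr
    dev = w_plus - mn
    num = dev - 0.5 * np.sign(dev)  # continuity correction toward the mean
    with np.errstate(invalid="ignore", divide="ignore"):
        z = num / np.sqrt(var)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p[var <= 0] = 1.0
    return np.minimum(p, 1.0)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values row-wise over the last axis.

    NaN entries are excluded from the family (their adjusted value stays
    NaN); the family size per row is the number of finite entries.
    """
    p = np.asarray(p, dtype=float)
    shape = p.shape
    p2 = np.atleast_2d(p.reshape(-1, shape[-1]))
    q = np.full_like(p2, np.nan)
    for i in range(p2.shape[0]):
        row = p2[i]
        finite = np.isfinite(row)
        m = int(finite.sum())
        if m == 0:
            continue
        vals = row[finite]
        order = np.argsort(vals, kind="stable")
        ranked = vals[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(adj, 1.0)
        q[i, finite] = out
    return q.reshape(shape)


# ---------------------------------------------------------------------------
# responsiveness classification
# ---------------------------------------------------------------------------

@dataclass
class Responsiveness:
    """Per-neuron x per-stimulus test results for one FOV on one day."""

    fov_id: str
    day: int
    p: np.ndarray            # (N, S) raw signed-rank p; NaN = excluded cell
    q: np.ndarray            # (N, S) BH-adjusted within neuron
    significant: np.ndarray  # (N, S) q < alpha
    responsive: np.ndarray   # (N,) any significant stimulus
    mean_amp: np.ndarray     # (N, S) trial-mean amplitude
    best_stimulus: np.ndarray  # (N,) 0-based index into stimuli, -1 if none
    best_amplitude: np.ndarray  # (N,) NaN if not responsive
    amp_bin: np.ndarray      # (N,) 1..4 for responsive neurons, 0 otherwise
    alpha: float

    def to_frame(self, neuron_ids, mouse_id: str | None = None, cohort: str | None = None) -> pd.DataFrame:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            min_q = np.nanmin(np.where(np.isfinite(self.q), self.q, np.inf), axis=1)
        min_q[~np.isfinite(min_q)] = np.nan
        frame = pd.DataFrame(
            {
                "neuron_id": np.asarray(neuron_ids),
                "fov_id": self.fov_id,
                "day": self.day,
                "responsive": self.responsive,
                "best_stimulus": self.best_stimulus,
                "best_amplitude": self.best_amplitude,
                "amp_bin": self.amp_bin,
                "min_q": min_q,
                "n_significant": self.significant.sum(axis=1),
            }
        )
        if mouse_id is not None:
            frame.insert(1, "mouse_id", mouse_id)
        if cohort is not None:
            frame.insert(2, "cohort", cohort)
        return frame


def classify_responsiveness(
    tensor: TrialTensor,
    alpha: float = 0.05,
    min_trials: int = 5,
) -> Responsiveness:
    """Classify each neuron as sound responsive on this session.

    Per stimulus, the ten evoked amplitudes are compared against the ten
    matched prestimulus baselines with a two-sided exact signed-rank test;
    the 34 p-values per neuron are BH-adjusted and a neuron is responsive if
    any adjusted value is below ``alpha``.  The best stimulus is the one with
    the largest trial-mean amplitude among the significant stimuli only.
    """
    diffs = tensor.A - tensor.pre
    p = signed_rank_pvalues(diffs, min_trials=min_trials)
    q = bh_adjust(p)
    significant = np.where(np.isfinite(q), q < alpha, False)
    responsive = significant.any(axis=1) & tensor.present
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_amp = np.nanmean(tensor.A, axis=2)

    n = tensor.n_neurons
    best_stimulus = np.full(n, -1, dtype=int)
    best_amplitude = np.full(n, np.nan)
    masked_amp = np.where(significant, mean_amp, -np.inf)
    any_sig = significant.any(axis=1)
    idx = np.argmax(masked_amp, axis=1)
    best_stimulus[any_sig & tensor.present] = idx[any_sig & tensor.present]
    sel = best_stimulus >= 0
    best_amplitude[sel] = mean_amp[sel, best_stimulus[sel]]
    assert not (responsive & ~sel).any(), "responsive neuron without a significant stimulus"

    bins = np.zeros(n, dtype=int)
    bins[sel] = amp_bin(best_amplitude[sel])
    if np.any(best_amplitude[sel] >= AMP_BIN_EDGES[-1]):
        warnings.warn("best amplitude above the top category edge; clamped into bin 4", stacklevel=2)
    return Responsiveness(
        fov_id=tensor.fov_id,
        day=tensor.day,
        p=p,
        q=q,
        significant=significant,
        responsive=responsive,
        mean_amp=mean_amp,
        best_stimulus=best_stimulus,
        best_amplitude=best_amplitude,
        amp_bin=bins,
        alpha=alpha,
    )


@dataclass
class CohortResponsiveness:
    """Classification results for every FOV x day of a cohort dataset."""

    results: dict  # {(fov_id, day): Responsiveness}
    frame: pd.DataFrame  # tidy, one row per neuron x day

    def get(self, fov_id: str, day: int) -> Responsiveness:
        return self.results[(fov_id, int(day))]


def classify_cohort(ds: CohortDataset, alpha: float = 0.05, min_trials: int = 5) -> CohortResponsiveness:
    """Run :func:`classify_responsiveness` over every FOV and session."""
    results = {}
    frames = []
    for _, mouse in ds.mice.iterrows():
        mouse_id, cohort = mouse["mouse_id"], mouse["cohort"]
        for fov_id in ds.fov_ids(mouse_id):
            ids = ds.fov_neurons(fov_id)["neuron_id"].to_numpy()
            for day in ds.days:
                res = classify_responsiveness(ds.tensor(fov_id, day), alpha=alpha, min_trials=min_trials)
                results[(fov_id, day)] = res
                frames.append(res.to_frame(ids, mouse_id=mouse_id, cohort=cohort))
    frame = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["neuron_id", "mouse_id", "cohort", "fov_id", "day", "responsive"])
    )
    return CohortResponsiveness(results=results, frame=frame)


def summarize_responsiveness(resp: CohortResponsiveness, ds: CohortDataset) -> pd.DataFrame:
    """Per FOV x day summary: present/responsive counts, fraction, mean best amplitude."""
    rows = []
    for (fov_id, day), res in sorted(resp.results.items()):
        tt = ds.tensor(fov_id, day)
        n_present = int(tt.present.sum())
        n_resp = int(res.responsive.sum())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean_best = float(np.nanmean(res.best_amplitude)) if n_resp else np.nan
        rows.append(
            (
                fov_id,
                day,
                n_present,
                n_resp,
                n_resp / n_present if n_present else np.nan,
                mean_best,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["fov_id", "day", "n_present", "n_responsive", "frac_responsive", "mean_best_amplitude"],
    )
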