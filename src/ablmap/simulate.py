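"""Synthetic cohort generator with parameterised ablation effects.

The generator emulates the statistical structure the downstream analyses
assume: ~140-180 neurons per FOV of which ~10-14% are sound responsive, 34
stimuli x 10 trials over seven sessions (days 1,3,5,7,9,11,15), ~10%
inhibitory neurons with broader tuning, gradual symmetric tuning drift, and
parameterised microablation effects with exponential recovery.

Model
-----
Each FOV draws ``k`` latent stimulus factors ``M`` (k x 34); neuron ``n``
carries static factor loadings with a common mean (the FOV's own stimulus
preference) plus idiosyncratic parts, and a latent tuning field
``g_nd = sqrt(c) * v_n M_d / sqrt(k) + sqrt(1-c) * e_nd``.  Both the factor
matrix and the private fields evolve as stationary AR(1) across an internal
2-day grid with per-step retention ``rho`` (so cross-day field correlation
is ``rho**lag`` and depends only on the lag: symmetric drift), and the
shared component gives within-FOV tuning co-structure that reassigning
neurons across FOVs destroys.  The noiseless tuning curve is
``amp_n * exp(beta_n * (g - max g))`` when the neuron's responsiveness state
(a two-state Markov chain with stationary probability ``p_responsive``) is
on, zero otherwise.  Trial amplitudes add i.i.d. Gaussian noise; prestimulus
baselines are zero-mean draws of the same noise.

All randomness flows from ``SimParams.seed`` through named streams (per
mouse / FOV / purpose), so subsetting the cohort reproduces draws exactly.
Ablation effects are injected by *recomposing* amplitudes from the stored
simulation state and the dataset's own noise residuals, so the null
intervention (all effect parameters zero) returns bit-identical data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import stream
from .dataset import DEFAULT_DAYS, CohortDataset, StimulusSet, TrialTensor, build_stimulus_set

__all__ = [
    "SimParams",
    "AblationEffectParams",
    "TruthTable",
    "simulate_cohort",
    "inject_ablation",
    "export_truth",
]


@dataclass(frozen=True)
class SimParams:
    """Generator settings; defaults are the study conditions the analyses assume."""

    n_mice: int = 4
    n_fov_per_mouse: int = 7
    neurons_per_fov: tuple[int, int] = (140, 180)  # uniform range
    p_responsive: float = 0.12       # stationary responsive probability
    p_inhibitory: float = 0.10
    amp_lognormal: tuple[float, float] = (3.357, 0.963)  # ln %dF/F; quartiles match the 15/55 bin edges
    n_latent: int = 5                # FOV-shared stimulus factors
    latent_share: float = 0.3        # weight of shared covariance in Sigma
    drift_rho: float = 0.85          # per-2-day tuning retention
    drop_rate: float = 0.30          # P(responsive -> not) per 2-day step
    gain_rate: float | None = None   # derived from stationarity when None
    noise_sigma: float = 5.0         # trial noise s.d., %dF/F
    tuning_sharpness: float = 0.5    # beta in exp(beta * (g - max g))
    inhibitory_width_factor: float = 1.8  # >= 1; divides beta for interneurons
    p_absent: float = 0.02           # per-day quality-gate dropout
    p_ineligible: float = 0.05       # occluded nuclei etc., unusable as targets
    ablation_success_rate: float = 0.9
    n_trials: int = 10
    days: tuple[int, ...] = DEFAULT_DAYS
    fov_size_um: tuple[float, float, float] = (367.0, 367.0, 200.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_responsive", "p_inhibitory", "drop_rate", "p_absent", "p_ineligible", "ablation_success_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.drift_rho <= 1.0:
            raise ValueError(f"drift_rho must be in [0, 1], got {self.drift_rho}")
        if self.n_mice < 1 or self.n_fov_per_mouse < 1 or self.neurons_per_fov[0] < 1:
            raise ValueError("cohort must contain at least one mouse, FOV and neuron")
        if self.inhibitory_width_factor < 1.0:
            raise ValueError("inhibitory_width_factor must be >= 1")

    @property
    def stationary_gain_rate(self) -> float:
        if self.gain_rate is not None:
            return self.gain_rate
        p = self.p_responsive
        return self.drop_rate * p / (1.0 - p)


@dataclass(frozen=True)
class AblationEffectParams:
    """Parameterised spared-network effects of microablation (all zero = null).

    Effects switch on after the day-6 intervention and relax back with time
    constant ``recovery_tau_days``; when ``spatial_scale_um`` is set, each
    spared neuron's effect magnitude is further scaled by
    ``exp(-distance_to_nearest_target / spatial_scale_um)``.
    """

    reliability_dip: float = 0.0     # fractional drop in trial SNR on day 7
    narrowing_factor: float = 0.0    # tail compression (exponent increment) for day-5-responsive neurons
    gain_boost: float = 0.0          # fractional increase of the gain rate post-ablation
    gain_alignment: float = 0.0      # corr of gained neurons' tuning with the ablated reference
    ei_shift: float = 0.0            # transient amplitude asymmetry: exc * (1+e), inh * (1-e)
    recovery_tau_days: float = 2.0
    spatial_scale_um: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.reliability_dip < 1.0:
            raise ValueError("reliability_dip must be in [0, 1)")
        if not 0.0 <= self.gain_alignment <= 1.0:
            raise ValueError("gain_alignment must be in [0, 1]")
        if self.recovery_tau_days <= 0:
            raise ValueError("recovery_tau_days must be positive")

    @property
    def is_null(self) -> bool:
        return (
            self.reliability_dip == 0
            and self.narrowing_factor == 0
            and self.gain_boost == 0
            and self.gain_alignment == 0
            and self.ei_shift == 0
        )


# ---------------------------------------------------------------------------
# simulation state (kept in memory, not serialised)
# ---------------------------------------------------------------------------

@dataclass
class _FovState:
    fov_id: str
    mouse_id: str
    grid_days: np.ndarray      # internal 2-day grid, e.g. 1,3,...,15
    g: np.ndarray              # (G, N, S) latent tuning fields on the grid
    amp: np.ndarray            # (N,) best amplitude scale
    beta: np.ndarray           # (N,) tuning sharpness
    inhibitory: np.ndarray     # (N,) bool
    resp: np.ndarray           # (G, N) bool baseline responsiveness states
    resp_u: np.ndarray         # (G, N) uniforms driving the chain (index 0 = init)
    present: np.ndarray        # (D_obs, N) bool quality gate per observed day
    positions: np.ndarray      # (N, 3) um
    eligible: np.ndarray | None = None  # usable as ablation target

    # effect bookkeeping filled by inject_ablation
    resp_eff: np.ndarray | None = None
    noise_scale: np.ndarray | None = None  # (D_obs, N) multiplier on trial noise


@dataclass
class SimState:
    params: SimParams
    cohort: str
    fovs: dict = field(default_factory=dict)
    effects: AblationEffectParams | None = None


def _grid(days: tuple[int, ...]) -> np.ndarray:
    return np.arange(days[0], days[-1] + 1, 2)


def _grid_index(days: tuple[int, ...]) -> np.ndarray:
    grid = _grid(days)
    off = [d for d in days if d not in grid]
    if off:
        raise ValueError(f"session days must lie on the 2-day grid from day {days[0]}, got {off}")
    return np.array([int(np.where(grid == d)[0][0]) for d in days])


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def simulate_cohort(
    params: SimParams,
    cohort: str = "control",
    stimuli: StimulusSet | None = None,
    mouse_prefix: str | None = None,
) -> CohortDataset:
    """Simulate a cohort dataset; ``cohort`` labels every mouse.

    The same ``params.seed`` with the same prefix reproduces the dataset
    bit-exactly.  Distinct cohorts of one experiment should use distinct
    prefixes (default: derived from the cohort label) so their draws differ.
    """
    stimuli = stimuli or build_stimulus_set()
    S = stimuli.n_stimuli
    prefix = mouse_prefix if mouse_prefix is not None else cohort[:4]
    state = SimState(params=params, cohort=cohort)
    grid = _grid(params.days)
    gidx = _grid_index(params.days)

    mice_rows, neuron_rows, tensors = [], [], {}
    for im in range(params.n_mice):
        mouse_id = f"{prefix}{im:02d}"
        mice_rows.append((mouse_id, cohort))
        for kf in range(params.n_fov_per_mouse):
            fov_id = f"{mouse_id}_f{kf:02d}"
            fst = _simulate_fov(params, S, mouse_id, fov_id, grid)
            state.fovs[fov_id] = fst
            for j in range(len(fst.amp)):
                neuron_rows.append(
                    (
                        f"{fov_id}_n{j:03d}",
                        mouse_id,
                        fov_id,
                        cohort,
                        fst.positions[j, 0],
                        fst.positions[j, 1],
                        fst.positions[j, 2],
                        bool(fst.inhibitory[j]),
                        bool(fst.eligible[j]),
                    )
                )
            for di, day in enumerate(params.days):
                A, pre = _compose_day(params, fst, gidx[di], di)
                tensors[(fov_id, day)] = TrialTensor(fov_id=fov_id, day=day, A=A, pre=pre, present=fst.present[di])
    ds = CohortDataset(
        stimuli=stimuli,
        mice=pd.DataFrame(mice_rows, columns=["mouse_id", "cohort"]),
        neurons=pd.DataFrame(
            neuron_rows,
            columns=["neuron_id", "mouse_id", "fov_id", "cohort", "x_um", "y_um", "z_um", "inhibitory", "eligible"],
        ),
        tensors=tensors,
        days=params.days,
        sim_state=state,
    )
    return ds


def _simulate_fov(params: SimParams, S: int, mouse_id: str, fov_id: str, grid: np.ndarray) -> _FovState:
    seed = params.seed
    G = len(grid)
    n = int(stream(seed, "nfov", fov_id).integers(params.neurons_per_fov[0], params.neurons_per_fov[1] + 1))

    # k latent stimulus factors per FOV; neuron loadings share a common mean
    # (the FOV's own stimulus preference) plus idiosyncratic parts, which is
    # what gives within-FOV tuning co-structure that FOV-shuffling destroys
    rng_struct = stream(seed, "structure", fov_id)
    k = params.n_latent
    loadings = (2.0 * np.ones(k) + rng_struct.standard_normal((n, k))) / np.sqrt(5.0)

    rng_cells = stream(seed, "cells", fov_id)
    amp = np.exp(rng_cells.normal(params.amp_lognormal[0], params.amp_lognormal[1], size=n))
    inhibitory = rng_cells.random(n) < params.p_inhibitory
    beta = np.full(n, params.tuning_sharpness)
    beta[inhibitory] /= params.inhibitory_width_factor
    positions = rng_cells.random((n, 3)) * np.asarray(params.fov_size_um)
    eligible = rng_cells.random(n) >= params.p_ineligible

    # both the FOV factor matrix and the private fields drift as stationary
    # AR(1) on the 2-day grid, so the full field correlates as rho**lag
    rng_drift = stream(seed, "drift", fov_id)
    rho = params.drift_rho
    innov = np.sqrt(1 - rho**2)
    M = np.empty((G, k, S))
    eps = np.empty((G, n, S))
    M[0] = rng_struct.standard_normal((k, S))
    eps[0] = rng_drift.standard_normal((n, S))
    for t in range(1, G):
        M[t] = rho * M[t - 1] + innov * rng_struct.standard_normal((k, S))
        eps[t] = rho * eps[t - 1] + innov * rng_drift.standard_normal((n, S))
    c = params.latent_share
    g = np.sqrt(c) * np.einsum("nk,tks->tns", loadings, M) / np.sqrt(k) + np.sqrt(1 - c) * eps

    rng_state = stream(seed, "respstate", fov_id)
    resp_u = rng_state.random((G, n))
    resp = _run_chain(resp_u, params.p_responsive, params.drop_rate, params.stationary_gain_rate)

    rng_gate = stream(seed, "quality", fov_id)
    D_obs = len(params.days)
    present = rng_gate.random((D_obs, n)) >= params.p_absent

    fst = _FovState(
        fov_id=fov_id,
        mouse_id=mouse_id,
        grid_days=grid,
        g=g,
        amp=amp,
        beta=beta,
        inhibitory=inhibitory,
        resp=resp,
        resp_u=resp_u,
        present=present,
        positions=positions,
        eligible=eligible,
    )
    return fst


def _run_chain(u: np.ndarray, p0: float, drop: float, gain: float, gain_mult: np.ndarray | None = None) -> np.ndarray:
    """Two-state Markov chain driven by stored uniforms (coupled across reruns).

    ``gain_mult[k, n]`` multiplies the gain rate of neuron ``n`` at step ``k``
    (1 = unchanged); the stored uniforms couple reruns monotonically, so a
    null multiplier reproduces the baseline chain bit-exactly.
    """
    G, n = u.shape
    resp = np.zeros((G, n), dtype=bool)
    resp[0] = u[0] < p0
    for k in range(1, G):
        gain_k = gain if gain_mult is None else gain * np.minimum(gain_mult[k], 1.0 / max(gain, 1e-12))
        stay = resp[k - 1] & (u[k] >= drop)
        enter = ~resp[k - 1] & (u[k] < gain_k)
        resp[k] = stay | enter
    return resp


def _signal_curves(fst: _FovState, gi: int, resp: np.ndarray | None = None,
                   shape_exponent: np.ndarray | None = None, amp_scale: np.ndarray | None = None,
                   g_override: np.ndarray | None = None) -> np.ndarray:
    """Noiseless tuning curves (N, S) at grid index ``gi``."""
    g = fst.g[gi] if g_override is None else g_override
    shape = np.exp(fst.beta[:, None] * (g - g.max(axis=1, keepdims=True)))
    if shape_exponent is not None:
        shape = shape ** shape_exponent[:, None]
    on = fst.resp[gi] if resp is None else resp
    amp = fst.amp if amp_scale is None else fst.amp * amp_scale
    return np.where(on[:, None], amp[:, None], 0.0) * shape


def _compose_day(params: SimParams, fst: _FovState, gi: int, di: int) -> tuple[np.ndarray, np.ndarray]:
    n = len(fst.amp)
    S = fst.g.shape[2]
    rng = stream(params.seed, "noise", fst.fov_id, int(fst.grid_days[gi]))
    E = rng.normal(0.0, params.noise_sigma, size=(n, S, params.n_trials))
    pre = rng.normal(0.0, params.noise_sigma, size=(n, S, params.n_trials))
    signal = _signal_curves(fst, gi)
    A = signal[:, :, None] + E
    absent = ~fst.present[di]
    A[absent] = np.nan
    pre[absent] = np.nan
    return A, pre


# ---------------------------------------------------------------------------
# ablation injection
# ---------------------------------------------------------------------------

def inject_ablation(ds: CohortDataset, plan, effects: AblationEffectParams) -> CohortDataset:
    """Apply a microablation plan with parameterised spared-network effects.

    Targeted neurons are masked absent from day 7 onward; spared neurons are
    perturbed per ``effects`` with exponential recovery.  Days 1-5 are
    untouched.  Success flags are drawn per target (probability
    ``SimParams.ablation_success_rate``) and written into ``plan.frame``.
    Requires a dataset produced by :func:`simulate_cohort` in this process.
    """
    state: SimState = ds.sim_state
    if state is None or not isinstance(state, SimState):
        raise ValueError("inject_ablation needs a simulated dataset (sim_state missing)")
    params = state.params
    known = set(ds.neurons["neuron_id"])
    missing = [t for t in plan.target_ids() if t not in known]
    if missing:
        raise ValueError(f"plan targets absent from dataset: {missing}")

    out = ds.copy()
    out.sim_state = SimState(params=params, cohort=state.cohort, fovs=dict(state.fovs), effects=effects)
    gidx = _grid_index(params.days)
    post_days = np.asarray(params.days, dtype=float)
    sched = np.where(post_days > ds.ablation_day, np.exp(-(post_days - 7.0) / effects.recovery_tau_days), 0.0)

    for fov_id in ds.fov_ids():
        fst = state.fovs[fov_id]
        new_fst = _inject_fov(out, plan, effects, params, fst, fov_id, gidx, sched)
        out.sim_state.fovs[fov_id] = new_fst

    # draw success flags into the plan (analysis side only consumes them)
    rng = stream(params.seed, "ablation_success")
    frame = plan.frame
    sel = frame["selected"].to_numpy(bool)
    frame.loc[sel, "success"] = rng.random(int(sel.sum())) < params.ablation_success_rate
    return out


def _inject_fov(out, plan, effects, params, fst: _FovState, fov_id, gidx, sched):
    neurons = out.fov_neurons(fov_id)
    ids = neurons["neuron_id"].to_numpy()
    id_to_row = {nid: j for j, nid in enumerate(ids)}
    targets = [id_to_row[t] for t in plan.target_ids(fov_id)]
    n = len(ids)
    G = fst.resp.shape[0]
    day5_gi = int(np.where(fst.grid_days == 5)[0][0])

    spared_like = np.ones(n, dtype=bool)
    spared_like[targets] = False

    # spatial effect multiplier
    m = np.ones(n)
    if effects.spatial_scale_um is not None and targets:
        pos = fst.positions
        d = np.sqrt(((pos[:, None, :] - pos[targets][None, :, :]) ** 2).sum(axis=2)).min(axis=1)
        m = np.exp(-d / effects.spatial_scale_um)

    # responsiveness chain rerun with boosted gain after ablation (coupled
    # uniforms); the boost persists post-ablation (recruitment pressure, not a
    # transient) and is amplitude-weighted (capped), so recruitment favours
    # strong responders and the responsive pool's mean amplitude rises with a
    # delay as gained neurons accumulate
    post_step = (fst.grid_days > out.ablation_day).astype(float)
    amp_w = np.minimum(fst.amp / np.median(fst.amp), 4.0)
    gain_mult = 1.0 + effects.gain_boost * post_step[:, None] * (amp_w * spared_like)[None, :]
    resp_eff = _run_chain(
        fst.resp_u, params.p_responsive, params.drop_rate, params.stationary_gain_rate,
        gain_mult=gain_mult,
    )
    # pre-ablation grid steps must match the baseline chain exactly
    pre_mask = fst.grid_days <= out.ablation_day
    resp_eff[pre_mask] = fst.resp[pre_mask]
    resp_eff[:, ~spared_like] = fst.resp[:, ~spared_like]

    # gained set: unresponsive on day 5, responsive on some post-ablation day
    post_gis = np.where(fst.grid_days > out.ablation_day)[0]
    gained = spared_like & ~fst.resp[day5_gi] & resp_eff[post_gis].any(axis=0)

    # reference field: mean day-5 tuning field of the targeted neurons
    g_ref = None
    if targets and effects.gain_alignment > 0:
        ref = fst.g[day5_gi, targets].mean(axis=0)
        sd = ref.std()
        if sd > 0:
            g_ref = ref / sd

    new_fst = _FovState(
        fov_id=fst.fov_id, mouse_id=fst.mouse_id, grid_days=fst.grid_days,
        g=fst.g.copy(), amp=fst.amp, beta=fst.beta, inhibitory=fst.inhibitory,
        resp=fst.resp, resp_u=fst.resp_u, present=fst.present.copy(), positions=fst.positions,
        eligible=fst.eligible,
    )
    new_fst.resp_eff = resp_eff
    noise_scale = np.ones((len(params.days), n))

    a = effects.gain_alignment
    if g_ref is not None and gained.any():
        for gi in post_gis:
            new_fst.g[gi, gained] = a * g_ref[None, :] + np.sqrt(1 - a**2) * fst.g[gi, gained]

    for di, day in enumerate(params.days):
        gi = gidx[di]
        w = sched[di]
        tt_old = out.tensor(fov_id, day)
        if day <= out.ablation_day:
            continue
        old_signal = _signal_curves(fst, gi)
        eff_w = w * m  # per-neuron effect weight

        shape_exp = 1.0 + effects.narrowing_factor * eff_w * (spared_like & fst.resp[day5_gi])
        amp_scale = np.where(
            fst.inhibitory, 1.0 - effects.ei_shift * eff_w, 1.0 + effects.ei_shift * eff_w
        )
        amp_scale[~spared_like] = 1.0
        new_signal = _signal_curves(
            new_fst, gi, resp=resp_eff[gi], shape_exponent=shape_exp, amp_scale=amp_scale,
        )
        kappa = 1.0 / np.clip(1.0 - effects.reliability_dip * eff_w, 0.05, 1.0)
        kappa[~spared_like] = 1.0
        noise_scale[di] = kappa

        E = tt_old.A - old_signal[:, :, None]
        A = new_signal[:, :, None] + kappa[:, None, None] * E
        pre = kappa[:, None, None] * tt_old.pre
        present = tt_old.present.copy()
        present[targets] = False
        A[~present] = np.nan
        pre[~present] = np.nan
        out.tensors[(fov_id, day)] = TrialTensor(fov_id=fov_id, day=day, A=A, pre=pre, present=present)
        new_fst.present[di] = present
    new_fst.noise_scale = noise_scale
    return new_fst


# ---------------------------------------------------------------------------
# ground truth export
# ---------------------------------------------------------------------------

@dataclass
class TruthTable:
    """Per neuron x day ground truth of a simulated cohort.

    ``frame`` rows align with ``tuning`` rows; ``tuning`` holds the noiseless
    tuning curve (amp x shape, zero when unresponsive) for each row.
    """

    frame: pd.DataFrame
    tuning: np.ndarray


def export_truth(ds: CohortDataset) -> TruthTable:
    """Export generator ground truth (state, tuning, reliability SNR) per neuron-day."""
    state: SimState = ds.sim_state
    if state is None or not isinstance(state, SimState):
        raise ValueError("export_truth is only supported for simulated datasets")
    params = state.params
    gidx = _grid_index(params.days)
    rows, curves = [], []
    for fov_id in ds.fov_ids():
        fst = state.fovs[fov_id]
        ids = ds.fov_neurons(fov_id)["neuron_id"].to_numpy()
        resp = fst.resp_eff if fst.resp_eff is not None else fst.resp
        for di, day in enumerate(params.days):
            gi = gidx[di]
            signal = _signal_curves(fst, gi, resp=resp[gi])
            nscale = fst.noise_scale[di] if fst.noise_scale is not None else np.ones(len(ids))
            sig_sd = signal.std(axis=1)
            noise_sd = params.noise_sigma * nscale
            for j, nid in enumerate(ids):
                rows.append(
                    (
                        nid,
                        fov_id,
                        fst.mouse_id,
                        day,
                        bool(resp[gi, j]),
                        bool(fst.present[di, j]),
                        float(fst.amp[j]),
                        float(noise_sd[j]),
                        float(sig_sd[j] / noise_sd[j]) if noise_sd[j] > 0 else np.inf,
                        bool(fst.inhibitory[j]),
                    )
                )
                curves.append(signal[j])
    frame = pd.DataFrame(
        rows,
        columns=[
            "neuron_id", "fov_id", "mouse_id", "day", "responsive_true", "present",
            "amp_true", "noise_sd", "snr", "inhibitory",
        ],
    )
    return TruthTable(frame=frame, tuning=np.asarray(curves))
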