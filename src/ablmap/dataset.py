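"""Shared data model: stimulus set, trial tensors, cohort container, storage.

The central currency of the pipeline is the trial tensor ``A[neuron,
stimulus, trial]`` of sound-evoked response amplitudes (%dF/F) for one field
of view (FOV) on one imaging day, together with matching prestimulus baseline
draws.  A :class:`CohortDataset` bundles the tensors of every mouse / FOV /
session with the neuron table (stable identities, 3-D positions, inhibitory
flags, cohort labels) and the stimulus set.

Sessions are labelled by their printed day numbers ``{1, 3, 5, 7, 9, 11, 15}``;
the ablation (or sham) event falls on day 6, strictly between the third and
fourth sessions, and is an attribute of the dataset rather than a session.
Neurons absent on a day (quality gate) are stored as NaN rows under a
``present`` mask and are excluded from every downstream statistic.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

SCHEMA_VERSION = "ablmap-cohort-1"

#: session day labels; 2-day spacing except the final 4-day gap
DEFAULT_DAYS: tuple[int, ...] = (1, 3, 5, 7, 9, 11, 15)

#: best-amplitude category edges in %dF/F (left-closed, right-open)
AMP_BIN_EDGES: tuple[float, ...] = (0.0, 15.0, 25.0, 55.0, 1000.0)

COHORTS = ("responsive_ablation", "nonresponsive_ablation", "inhibitory_ablation", "control")

NEURON_COLUMNS = ["neuron_id", "mouse_id", "fov_id", "cohort", "x_um", "y_um", "z_um", "inhibitory", "eligible"]


class DatasetError(ValueError):
    """Structural problem in a cohort dataset (missing session, bad shape...)."""


class SchemaError(DatasetError):
    """On-disk container does not carry the expected schema version tag."""


# ---------------------------------------------------------------------------
# stimulus set
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusSet:
    """The standard stimulus battery: pure tones (PT) plus complex sounds (CS).

    ``table`` has one row per stimulus with columns ``stimulus_id`` (1-based),
    ``stim_class`` ('PT'/'CS'), ``pt_frequency_khz`` (NaN for CS) and
    ``duration_ms``.  Complex sounds carry no spectral content here; only
    their identity and duration matter downstream.
    """

    table: pd.DataFrame

    @property
    def n_stimuli(self) -> int:
        return len(self.table)

    @property
    def pt_frequencies_khz(self) -> np.ndarray:
        tab = self.table
        return tab.loc[tab["stim_class"] == "PT", "pt_frequency_khz"].to_numpy(float)


def build_stimulus_set(
    n_pt: int = 19,
    n_cs: int = 15,
    f0_khz: float = 2.0,
    step_octaves: float = 0.25,
    pt_duration_ms: float = 50.0,
    cs_duration_ms: float = 70.0,
) -> StimulusSet:
    """Build the stimulus set: ``n_pt`` tones at ``f0 * 2**(k*step)`` plus ``n_cs`` complex sounds.

    Defaults give the standard 34-stimulus battery: 19 quarter-octave tones
    from 2 kHz (topping out at ~45 kHz, 50 ms) and 15 complex sounds (70 ms).
    """
    if n_pt < 1 or n_cs < 0:
        raise ValueError(f"need n_pt >= 1 and n_cs >= 0, got ({n_pt}, {n_cs})")
    if f0_khz <= 0 or step_octaves <= 0:
        raise ValueError(f"need positive f0_khz and step_octaves, got ({f0_khz}, {step_octaves})")
    freqs = f0_khz * 2.0 ** (step_octaves * np.arange(n_pt))
    rows = []
    for k, f in enumerate(freqs):
        rows.append((k + 1, "PT", f, pt_duration_ms))
    for j in range(n_cs):
        rows.append((n_pt + j + 1, "CS", np.nan, cs_duration_ms))
    table = pd.DataFrame(rows, columns=["stimulus_id", "stim_class", "pt_frequency_khz", "duration_ms"])
    return StimulusSet(table=table)


# ---------------------------------------------------------------------------
# trial tensors and cohort container
# ---------------------------------------------------------------------------

@dataclass
class TrialTensor:
    """Trial-resolved response amplitudes for one FOV on one day.

    ``A[n, s, t]`` is the evoked amplitude (%dF/F) of neuron ``n`` to stimulus
    ``s`` on trial ``t``; ``pre`` holds the matched prestimulus baseline
    values used as the paired null in responsiveness tests.  Rows where
    ``present`` is False are NaN throughout.
    """

    fov_id: str
    day: int
    A: np.ndarray
    pre: np.ndarray
    present: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.pre = np.asarray(self.pre, dtype=float)
        self.present = np.asarray(self.present, dtype=bool)
        if self.A.ndim != 3 or self.A.shape != self.pre.shape:
            raise DatasetError(f"A and pre must be matching 3-D arrays, got {self.A.shape} vs {self.pre.shape}")
        if self.present.shape != (self.A.shape[0],):
            raise DatasetError("present mask must have one entry per neuron")
        if np.isnan(self.A[self.present]).any():
            raise DatasetError(f"non-finite amplitudes for present neurons in {self.fov_id} day {self.day}")

    @property
    def n_neurons(self) -> int:
        return self.A.shape[0]

    @property
    def n_stimuli(self) -> int:
        return self.A.shape[1]

    @property
    def n_trials(self) -> int:
        return self.A.shape[2]


@dataclass
class CohortDataset:
    """All sessions of all FOVs of a cohort of mice, plus metadata tables.

    ``mice``    : DataFrame (mouse_id, cohort)
    ``neurons`` : DataFrame (neuron_id, mouse_id, fov_id, cohort, x_um, y_um,
                  z_um, inhibitory, eligible); row order within a FOV matches
                  the tensor row order.
    ``tensors`` : {(fov_id, day): TrialTensor}
    """

    stimuli: StimulusSet
    mice: pd.DataFrame
    neurons: pd.DataFrame
    tensors: dict
    days: tuple = DEFAULT_DAYS
    ablation_day: int = 6
    sim_state: object = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.days = tuple(int(d) for d in self.days)
        if any(d2 <= d1 for d1, d2 in zip(self.days, self.days[1:])):
            raise DatasetError(f"session days must be strictly increasing, got {self.days}")
        if self.ablation_day in self.days:
            raise DatasetError(f"ablation day {self.ablation_day} cannot coincide with a session")

    # -- accessors ---------------------------------------------------------
    def fov_ids(self, mouse_id: str | None = None) -> list[str]:
        tab = self.neurons
        if mouse_id is not None:
            tab = tab[tab["mouse_id"] == mouse_id]
        return list(dict.fromkeys(tab["fov_id"]))

    def fov_neurons(self, fov_id: str) -> pd.DataFrame:
        sub = self.neurons[self.neurons["fov_id"] == fov_id]
        return sub.reset_index(drop=True)

    def tensor(self, fov_id: str, day: int) -> TrialTensor:
        try:
            return self.tensors[(fov_id, int(day))]
        except KeyError:
            raise DatasetError(f"no session for FOV {fov_id!r} on day {day}") from None

    def cohort_of(self, mouse_id: str) -> str:
        row = self.mice[self.mice["mouse_id"] == mouse_id]
        if row.empty:
            raise DatasetError(f"unknown mouse {mouse_id!r}")
        return str(row["cohort"].iloc[0])

    @property
    def baseline_days(self) -> tuple[int, ...]:
        return tuple(d for d in self.days if d < self.ablation_day)

    def copy(self) -> "CohortDataset":
        return CohortDataset(
            stimuli=self.stimuli,
            mice=self.mice.copy(),
            neurons=self.neurons.copy(),
            tensors={
                k: TrialTensor(t.fov_id, t.day, t.A.copy(), t.pre.copy(), t.present.copy())
                for k, t in self.tensors.items()
            },
            days=self.days,
            ablation_day=self.ablation_day,
            sim_state=self.sim_state,
        )


# ---------------------------------------------------------------------------
# storage: directory with HDF5 arrays + CSV sidecars + JSON schema tag
# ---------------------------------------------------------------------------

def save_dataset(ds: CohortDataset, path: str | Path) -> Path:
    """Write ``ds`` to directory ``path`` (created if needed).

    Layout: ``cohort.h5`` holding ``A``/``pre``/``present`` per FOV and day,
    ``neurons.csv`` / ``mice.csv`` / ``stimuli.csv`` sidecars, and
    ``meta.json`` with the schema-version tag.  The round trip is bit-exact
    for all float arrays.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "schema_version": SCHEMA_VERSION,
        "days": list(ds.days),
        "ablation_day": ds.ablation_day,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    ds.mice.to_csv(path / "mice.csv", index=False)
    ds.neurons.to_csv(path / "neurons.csv", index=False)
    ds.stimuli.table.to_csv(path / "stimuli.csv", index=False)
    with h5py.File(path / "cohort.h5", "w") as h5:
        for (fov_id, day), tt in sorted(ds.tensors.items()):
            grp = h5.require_group(f"{fov_id}/day{day:02d}")
            grp.create_dataset("A", data=tt.A)
            grp.create_dataset("pre", data=tt.pre)
            grp.create_dataset("present", data=tt.present)
    return path


def load_dataset(path: str | Path) -> CohortDataset:
    """Load a dataset written by :func:`save_dataset`, validating structure."""
    path = Path(path)
    meta_file = path / "meta.json"
    if not meta_file.exists():
        raise SchemaError(f"{path} is not a cohort container (meta.json missing)")
    meta = json.loads(meta_file.read_text())
    if meta.get("schema_version") != SCHEMA_VERSION:
        raise SchemaError(
            f"schema version mismatch: found {meta.get('schema_version')!r}, expected {SCHEMA_VERSION!r}"
        )
    days = tuple(int(d) for d in meta["days"])
    mice = pd.read_csv(path / "mice.csv") if (path / "mice.csv").stat().st_size else pd.DataFrame(columns=["mouse_id", "cohort"])
    neurons = pd.read_csv(path / "neurons.csv")
    if neurons.empty:
        neurons = pd.DataFrame(columns=NEURON_COLUMNS)
    stim_table = pd.read_csv(path / "stimuli.csv")
    tensors: dict = {}
    with h5py.File(path / "cohort.h5", "r") as h5:
        for fov_id in h5:
            for day_key in h5[fov_id]:
                day = int(day_key.replace("day", ""))
                grp = h5[fov_id][day_key]
                tensors[(fov_id, day)] = TrialTensor(
                    fov_id=fov_id,
                    day=day,
                    A=grp["A"][()],
                    pre=grp["pre"][()],
                    present=grp["present"][()],
                )
    ds = CohortDataset(
        stimuli=StimulusSet(table=stim_table),
        mice=mice,
        neurons=neurons,
        tensors=tensors,
        days=days,
        ablation_day=int(meta["ablation_day"]),
    )
    missing = [
        (fov_id, day)
        for fov_id in ds.fov_ids()
        for day in days
        if (fov_id, day) not in tensors
    ]
    if missing:
        listing = ", ".join(f"FOV {f!r} day {d}" for f, d in missing)
        raise DatasetError(f"sessions missing from container: {listing}")
    return ds


# ---------------------------------------------------------------------------
# FOV inclusion validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Per-FOV inclusion outcome; ``frame`` lists pass/fail with reasons."""

    frame: pd.DataFrame

    @property
    def passed_fovs(self) -> list[str]:
        return list(self.frame.loc[self.frame["passed"], "fov_id"])

    @property
    def failed_fovs(self) -> list[str]:
        return list(self.frame.loc[~self.frame["passed"], "fov_id"])


def validate_dataset(
    ds: CohortDataset,
    responsiveness: pd.DataFrame | None = None,
    min_rois: int = 100,
    min_responsive: int = 10,
    strict_greater: bool = True,
) -> ValidationReport:
    """Apply FOV inclusion criteria: >= ``min_rois`` quality-passing neurons and
    more than ``min_responsive`` sound-responsive neurons on baseline days.

    ``responsiveness`` is a tidy table with at least ``neuron_id``, ``fov_id``,
    ``day``, ``responsive`` columns (as produced by
    :func:`ablmap.events.classify_cohort`); if omitted it is computed on the
    fly.  A neuron counts as responsive here if it is responsive on at least
    one baseline day.  With ``strict_greater`` (default) exactly
    ``min_responsive`` responsive neurons fails the criterion.
    """
    if responsiveness is None:
        from .events import classify_cohort

        responsiveness = classify_cohort(ds).frame
    base = set(ds.baseline_days)
    rows = []
    for fov_id in ds.fov_ids():
        n_rois = _quality_roi_count(ds, fov_id)
        sub = responsiveness[
            (responsiveness["fov_id"] == fov_id)
            & responsiveness["day"].isin(base)
            & responsiveness["responsive"]
        ]
        n_resp = sub["neuron_id"].nunique()
        reasons = []
        if n_rois < min_rois:
            reasons.append(f"ROI count {n_rois} < {min_rois}")
        ok_resp = n_resp > min_responsive if strict_greater else n_resp >= min_responsive
        if not ok_resp:
            cmp = ">" if strict_greater else ">="
            reasons.append(f"responsive count {n_resp} not {cmp} {min_responsive}")
        rows.append((fov_id, n_rois, n_resp, not reasons, "; ".join(reasons)))
    frame = pd.DataFrame(rows, columns=["fov_id", "n_rois", "n_responsive", "passed", "reasons"])
    return ValidationReport(frame=frame)


def _quality_roi_count(ds: CohortDataset, fov_id: str) -> int:
    """Neurons present on every baseline session of the FOV."""
    present = None
    for day in ds.baseline_days:
        tt = ds.tensor(fov_id, day)
        present = tt.present if present is None else (present & tt.present)
    if present is None:
        return len(ds.fov_neurons(fov_id))
    return int(present.sum())


def pixels_to_um(n_pixels: float, fov_extent_um: float = 367.0, n_pixels_across: int = 256) -> float:
    """Convert an in-plane pixel displacement to micrometres.

    Defaults describe the time-series imaging geometry: a 367-um FOV sampled
    at 256 pixels across, so the 2-pixel ROI-matching tolerance corresponds
    to ~2.87 um.
    """
    if fov_extent_um <= 0 or n_pixels_across <= 0:
        raise ValueError("FOV extent and pixel count must be positive")
    return float(n_pixels) * fov_extent_um / n_pixels_across


def amp_bin(values: np.ndarray, edges: tuple[float, ...] = AMP_BIN_EDGES) -> np.ndarray:
    """Best-amplitude category (1..4) per value; left-closed right-open bins.

    Values below the first edge fall in bin 1, values at or above the last
    edge clamp into the top bin (with a warning upstream where relevant).
    NaN maps to 0 (unbinned).
    """
    values = np.asarray(values, dtype=float)
    inner = np.asarray(edges[1:-1], dtype=float)
    out = np.digitize(values, inner, right=False) + 1
    out = np.clip(out, 1, len(edges) - 1)
    out[~np.isfinite(values)] = 0
    return out
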