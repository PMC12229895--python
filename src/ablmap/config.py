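"""Analysis configuration: every decision threshold surfaced in one mapping.

The defaults are the study's printed constants (significance level 0.05,
high-correlation threshold 0.7, reference-correlation threshold 0.6,
15-um exclusion radius, the four best-amplitude bins, baseline days,
permutation/shuffle counts).  ``load_config`` merges a YAML or JSON file
over the defaults and rejects unknown keys, so every run's thresholds are
explicit and loggable.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

DEFAULTS: dict = {
    "alpha": 0.05,
    "high_corr_threshold": 0.7,
    "reference_corr_threshold": 0.6,
    "exclusion_radius_um": 15.0,
    "amp_bin_edges": [0.0, 15.0, 25.0, 55.0, 1000.0],
    "baseline_days": [1, 3, 5],
    "category_baseline_days": [3, 5],
    "n_perm": 200,
    "n_shuffle": 500,
    "n_split_repeats": 10,
    "min_trials": 5,
    "n_targets_per_fov": 6,
}


def load_config(path: str | Path | None = None) -> dict:
    """Defaults merged with an optional YAML/JSON override file."""
    cfg = dict(DEFAULTS)
    if path is None:
        return cfg
    path = Path(path)
    text = path.read_text()
    overrides = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    overrides = overrides or {}
    unknown = set(overrides) - set(DEFAULTS)
    if unknown:
        raise KeyError(f"unknown config keys: {sorted(unknown)}")
    cfg.update(overrides)
    return cfg
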