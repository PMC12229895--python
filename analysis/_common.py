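"""Shared setup for the numbered analysis drivers.

Each driver simulates the same three-cohort experiment deterministically
from one seed (so drivers are independently re-runnable without binary
intermediates), at a scale of 4 mice x 3 FOVs per cohort.
"""

from __future__ import annotations

import argparse
import warnings
from pathlib import Path

from ablmap.config import load_config
from ablmap.experiment import run_experiment
from ablmap.simulate import SimParams

ANALYSIS_DIR = Path(__file__).resolve().parent
RESULTS_DIR = ANALYSIS_DIR.parent / "results"

COHORTS = ("responsive_ablation", "nonresponsive_ablation", "control")


def parse_args(description: str) -> argparse.Namespace:
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--seed", type=int, default=2025)
    parser.add_argument("--config", type=str, default=str(ANALYSIS_DIR / "config.yaml"))
    parser.add_argument("--out", type=str, default=str(RESULTS_DIR))
    args = parser.parse_args()
    warnings.filterwarnings("ignore")
    args.config = load_config(args.config)
    args.out = Path(args.out)
    args.out.mkdir(parents=True, exist_ok=True)
    return args


def base_params(seed: int) -> SimParams:
    return SimParams(seed=seed, n_mice=4, n_fov_per_mouse=3, neurons_per_fov=(140, 160))


def experiment(seed: int, cohorts=COHORTS):
    return run_experiment(seed=seed, cohorts=cohorts, base_params=base_params(seed))
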