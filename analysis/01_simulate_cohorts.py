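"""Simulate the three experimental cohorts and validate FOV inclusion.

Builds responsive-ablation, nonresponsive-ablation and control cohorts (4
mice x 3 FOVs each), runs target selection and effect injection for the
ablation cohorts, applies the FOV inclusion criteria (>=100 quality ROIs,
>10 baseline-responsive neurons), and summarises cohort composition.

Writes: 01_fov_validation.csv, 01_cohort_composition.csv, 01_ablation_plans.csv
"""

import pandas as pd

from _common import COHORTS, experiment, parse_args
from ablmap import validate_dataset


def main() -> None:
    args = parse_args(__doc__)
    runs = experiment(args.seed)

    validation, composition, plans = [], [], []
    for cohort in COHORTS:
        run = runs[cohort]
        report = validate_dataset(run.ds, run.resp.frame)
        rep = report.frame.copy()
        rep.insert(0, "cohort", cohort)
        validation.append(rep)
        spared = run.spared.frame
        composition.append(
            {
                "cohort": cohort,
                "n_mice": run.ds.mice.shape[0],
                "n_fovs": len(run.ds.fov_ids()),
                "n_neurons": len(run.ds.neurons),
                "n_inhibitory": int(run.ds.neurons["inhibitory"].sum()),
                "n_targeted": int((spared["reason"] == "targeted").sum()),
                "n_within_radius": int((spared["reason"] == "within_radius").sum()),
                "n_category_excluded": int(spared["reason"].isin(["high_category", "low_category"]).sum()),
                "n_spared": int(spared["spared"].sum()),
            }
        )
        if run.plan is not None:
            pf = run.plan.frame
            pf = pf[pf["selected"].astype(bool)].copy()
            pf.insert(0, "cohort", cohort)
            plans.append(pf)

    validation = pd.concat(validation, ignore_index=True)
    composition = pd.DataFrame(composition)
    plans = pd.concat(plans, ignore_index=True)
    validation.to_csv(args.out / "01_fov_validation.csv", index=False)
    composition.to_csv(args.out / "01_cohort_composition.csv", index=False)
    plans.to_csv(args.out / "01_ablation_plans.csv", index=False)

    print(f"seed {args.seed}: simulated {len(composition)} cohorts")
    print(composition.to_string(index=False))
    n_fail = int((~validation["passed"]).sum())
    print(f"FOV inclusion: {len(validation) - n_fail}/{len(validation)} FOVs pass", end="")
    print(f" ({n_fail} failures)" if n_fail else "")
    per_fov = plans.groupby(["cohort", "fov_id"])["selected"].sum()
    print(f"targets per FOV: min {per_fov.min()}, max {per_fov.max()} (requested {runs[COHORTS[0]].plan.n_per_fov})")


if __name__ == "__main__":
    main()
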