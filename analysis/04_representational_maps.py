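"""Representational similarity matrices, MDS embedding, pairwise decoding.

Builds per-FOV single-trial similarity matrices on spared neurons,
grand-averages them per cohort and day, summarises diagonal / off-diagonal
means normalised to baseline, embeds the control day-5 grand matrix with
classical MDS, and estimates pairwise decoding accuracy on a random subset
of stimulus pairs.

Writes: 04_map_summary.csv, 04_grand_matrix_day5_control.csv,
04_mds_day5_control.csv, 04_decoding.csv
"""

import pandas as pd

from _common import COHORTS, experiment, parse_args
from ablmap.repmap import mds_embed, pairwise_decode, similarity_matrix, summarize_map


def main() -> None:
    args = parse_args(__doc__)
    runs = experiment(args.seed)

    summaries = []
    grand_day5 = None
    for cohort in COHORTS:
        run = runs[cohort]
        mats = []
        for fov in run.ds.fov_ids():
            spared = run.spared.spared_array(run.ds, fov)
            for day in run.ds.days:
                tt = run.ds.tensor(fov, day)
                mats.append(similarity_matrix(tt, "single_trial", neuron_mask=spared & tt.present))
        summ = summarize_map(mats, baseline_days=tuple(args.config["baseline_days"]))
        frame = summ.frame.copy()
        frame.insert(0, "cohort", cohort)
        summaries.append(frame)
        if cohort == "control":
            grand_day5 = summ.grand[5]

    summary = pd.concat(summaries, ignore_index=True)
    summary.to_csv(args.out / "04_map_summary.csv", index=False)
    labels = [f"s{i+1:02d}" for i in range(grand_day5.shape[0])]
    pd.DataFrame(grand_day5, index=labels, columns=labels).to_csv(args.out / "04_grand_matrix_day5_control.csv")

    coords, evals = mds_embed(grand_day5)
    mds = pd.DataFrame({"stimulus": labels, "mds1": coords[:, 0], "mds2": coords[:, 1]})
    mds.to_csv(args.out / "04_mds_day5_control.csv", index=False)

    decode_rows = []
    run = runs["control"]
    for fov in run.ds.fov_ids()[:3]:  # one mouse's FOVs; 40 random pairs each
        spared = run.spared.spared_array(run.ds, fov)
        for day in (5, 7):
            tt = run.ds.tensor(fov, day)
            acc, _ = pairwise_decode(tt, pairs=40, seed=args.seed, neuron_mask=spared & tt.present)
            decode_rows.append(("control", fov, day, 40, acc))
    decoding = pd.DataFrame(decode_rows, columns=["cohort", "fov_id", "day", "n_pairs", "accuracy"])
    decoding.to_csv(args.out / "04_decoding.csv", index=False)

    print(f"seed {args.seed}: representational maps for {len(COHORTS)} cohorts")
    print("normalised off-diagonal mean (single-trial):")
    print(summary.pivot_table(index="day", columns="cohort", values="offdiag_norm").round(3).to_string())
    pos = evals[evals > 0]
    print(f"MDS: top-2 eigenvalues explain {pos[:2].sum() / pos.sum():.0%} of positive inertia")
    print("pairwise decoding accuracy (control):", decoding.groupby("day")["accuracy"].mean().round(3).to_dict())


if __name__ == "__main__":
    main()
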