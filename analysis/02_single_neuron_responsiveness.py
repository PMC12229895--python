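"""Single-neuron responsiveness over days: fractions, bins, stability, E/I.

For each cohort and day, summarises the fraction of sound-responsive spared
neurons, best-amplitude bin occupancy, the consecutive-day responsiveness
overlap (drift of responsiveness), and the excitatory/inhibitory balance of
total responses per mouse.

Writes: 02_responsive_fraction.csv, 02_amp_bin_occupancy.csv,
02_stability_overlap.csv, 02_ei_balance.csv
"""

import pandas as pd

from _common import COHORTS, experiment, parse_args
from ablmap.perturb import ei_balance, stability_overlap


def main() -> None:
    args = parse_args(__doc__)
    runs = experiment(args.seed)

    fractions, bins, overlaps, balances = [], [], [], []
    for cohort in COHORTS:
        run = runs[cohort]
        frame = run.resp.frame
        spared = frame[frame["neuron_id"].isin(run.spared.spared_ids)]
        frac = (
            spared.groupby(["mouse_id", "day"])["responsive"].mean().reset_index()
        )
        frac.insert(0, "cohort", cohort)
        fractions.append(frac)

        resp_rows = spared[spared["responsive"] & (spared["amp_bin"] > 0)]
        occ = resp_rows.groupby(["day", "amp_bin"]).size().rename("n").reset_index()
        occ["fraction"] = occ["n"] / occ.groupby("day")["n"].transform("sum")
        occ.insert(0, "cohort", cohort)
        bins.append(occ)

        ov = stability_overlap(frame, spared_ids=run.spared.spared_ids)
        ov.insert(0, "cohort", cohort)
        overlaps.append(ov)

        inhib = dict(zip(run.ds.neurons["neuron_id"], run.ds.neurons["inhibitory"]))
        bal = ei_balance(spared, inhib)
        bal.insert(0, "cohort", cohort)
        balances.append(bal)

    fractions = pd.concat(fractions, ignore_index=True)
    bins = pd.concat(bins, ignore_index=True)
    overlaps = pd.concat(overlaps, ignore_index=True)
    balances = pd.concat(balances, ignore_index=True)
    fractions.to_csv(args.out / "02_responsive_fraction.csv", index=False)
    bins.to_csv(args.out / "02_amp_bin_occupancy.csv", index=False)
    overlaps.to_csv(args.out / "02_stability_overlap.csv", index=False)
    balances.to_csv(args.out / "02_ei_balance.csv", index=False)

    print(f"seed {args.seed}: responsiveness summaries for {len(COHORTS)} cohorts")
    print("responsive fraction (cohort means per day):")
    print(fractions.groupby(["cohort", "day"])["responsive"].mean().unstack(0).round(3).to_string())
    base_occ = bins[bins["day"].isin(args.config["baseline_days"])]
    print("baseline amp-bin occupancy:", base_occ.groupby("amp_bin")["fraction"].mean().round(3).to_dict())
    ov = overlaps.groupby(["cohort", "day_to"])["overlap"].mean().unstack(0).round(3)
    print("consecutive-day overlap (union denominator):")
    print(ov.to_string())
    print("mean E/I balance:", balances.groupby("cohort")["balance"].mean().round(3).to_dict())


if __name__ == "__main__":
    main()
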