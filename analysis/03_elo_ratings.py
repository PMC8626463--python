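#!/usr/bin/env python
"""Rate the dynamic group with daily Elo snapshots and check recovery.

Runs the sequential rating over the detected replacement stream
(k = 20, start 1000, normal-CDF expectation), snapshots every cow every
residence day, computes each calved cow's pre-calving 7-day mean, and
compares rating order against the generator's latent hierarchy.
"""

import sys
from pathlib import Path

import pandas as pd
from scipy.stats import spearmanr

from brushdom import EloConfig, io, mean_elo_precalving, run_elo

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    data = ROOT / "scratch" / "simdata"
    roster = io.read_roster(data / "roster.csv")
    replacements = io.read_replacements(data / "replacements.csv")
    latent = pd.read_csv(data / "ground_truth.csv").set_index("cow_id")[
        "latent_dominance"]

    cfg = EloConfig()
    last_day = replacements["time"].max().normalize()
    traj = run_elo(replacements, roster, cfg, last_day=last_day)
    daily = traj.daily.copy()
    daily["date"] = daily["date"].dt.strftime("%Y-%m-%d")
    daily.to_csv(data / "elo_daily.csv", index=False)

    first_day = replacements["time"].min().normalize()
    means = {}
    for _, cow in roster.iterrows():
        calving_day = cow["calving_time"].normalize()
        if calving_day > last_day:
            continue
        if calving_day - pd.Timedelta(days=7) < first_day:
            continue
        m = mean_elo_precalving(traj, cow)
        if m is not None:
            means[cow["cow_id"]] = m
    means = pd.Series(means, name="mean_elo_7d")
    means.rename_axis("cow_id").to_csv(data / "mean_elo.csv")

    final = traj.final_ratings()
    days = traj.daily.groupby("cow_id").size()
    rated = days[days >= 7].index
    summary = pd.DataFrame([{
        "events_rated": len(traj.events),
        "cows_rated": int(traj.daily["cow_id"].nunique()),
        "cows_scored_precalving": len(means),
        "final_rating_spread": round(final.max() - final.min(), 1),
        "spearman_latent_final": round(
            spearmanr(latent[rated], final[rated]).statistic, 3),
        "spearman_latent_precalving_mean": round(
            spearmanr(latent[means.index], means).statistic, 3),
    }])
    summary.to_csv(ROOT / "results" / "elo_summary.csv", index=False)
    print(summary.T.to_string(header=False))


if __name__ == "__main__":
    sys.exit(main())
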