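#!/usr/bin/env python
"""Helmet ranking and its sensitivity to the choice of strain metric.

Ranks the 17 helmets by each strain metric's 95th-percentile peak
averaged across the three locations, quantifies ranking agreement with
Kendall's tau over the 10 metric pairs, and correlates the 7 kinematic
metrics with the 5 strain summaries over all 51 impacts (35 + 10 tests).
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from helmstrain import headmetrics, kinio, ranking, synthio, tractstrain


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-elements", type=int, default=2000)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    cfg = synthio.GeneratorConfig(seed=args.seed, n_elements=args.n_elements)
    records = synthio.generate_kinematics_ensemble(cfg)
    prepared = {k: kinio.prepare_record(r) for k, r in records.items()}
    summaries = {}
    for key, fields in synthio.iter_strain_ensemble(cfg, records):
        tab = tractstrain.compute_peak_table(
            fields["F"], fields["regions"], fields["fibers"],
            fields["element_ids"])
        summaries[key] = tractstrain.summarize_peaks(tab)
    summary_df = pd.DataFrame(summaries).T
    summary_df.index.names = ["helmet_id", "location"]
    metric_df = headmetrics.metric_table(prepared.values()).join(summary_df)

    ranks = ranking.ranking_table(summary_df)
    tau = ranking.kendall_tau_matrix(ranks)
    corr = ranking.metric_correlations(metric_df)

    args.out_dir.mkdir(parents=True, exist_ok=True)
    ranks.to_csv(args.out_dir / "ranking_table.csv")
    tau.to_csv(args.out_dir / "kendall_tau.csv")
    corr["kin_strain"].to_csv(
        args.out_dir / "kinematic_strain_correlations.csv", index=False)
    corr["strain_strain"].to_csv(
        args.out_dir / "strain_strain_correlations.csv", index=False)

    iu = np.triu_indices(len(tau), k=1)
    taus = tau.to_numpy()[iu]
    print("best helmet per metric:")
    print(ranks.idxmin().to_string())
    print(f"\nKendall tau across metric pairs: "
          f"{taus.min():.2f} to {taus.max():.2f} "
          f"({(taus > 0.8).sum()} of {taus.size} pairs above 0.8)")
    strong = corr["kin_strain"].query("strong")
    print(f"{len(strong)} of 35 kinematic-strain pairs strongly "
          f"correlated (r > 0.7); angular metrics dominate:")
    print(strong.groupby("kinematic").size().to_string())


if __name__ == "__main__":
    main()
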