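"""Spatial and latency mixed-effects models over the classified electrodes.

Fits three subject-random-intercept models on the electrode table from the
screening step: Talairach y ~ category (are omission-responsive sites more
posterior?), peak latency ~ category (do omission responses peak later?),
and Talairach y ~ omission peak amplitude.  Also prints the two-stage
(within-subject mean, across-subject median) latency summaries.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from omission_hfa import simulate, stats


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--dir", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()
    table = pd.read_csv(args.dir / "electrode_table.tsv", sep="\t")

    electrodes = [
        simulate.ElectrodeInfo(r.electrode, r.subject, -55.0, r.y, 5.0)
        for r in table.itertuples()
    ]
    categories = table["category"].to_numpy()
    responsive = table[table["category"] != "none"]
    peaks = pd.DataFrame(
        {
            "electrode": responsive["electrode"],
            "subject": responsive["subject"],
            "y": responsive["y"],
            "group": np.where(
                responsive["category"].isin(["omission_active", "both"]),
                "Omission",
                "BaGa",
            ),
            "latency_ms": responsive["peak_latency_ms"],
            "amplitude": responsive["peak_amplitude"],
        }
    ).dropna(subset=["latency_ms"])

    omission_ids = table.loc[
        table["category"].isin(["omission_active", "both"]), "electrode"
    ].tolist()
    results = {
        "position_mm": stats.lme_position(categories, electrodes).to_dict(),
        "latency_ms": stats.lme_latency(peaks, categories, electrodes).to_dict(),
        "amplitude_position": stats.lme_amplitude_position(
            peaks, electrodes, electrode_subset=omission_ids
        ).to_dict(),
    }
    for group in ("Omission", "BaGa"):
        sub = peaks[peaks["group"] == group]
        med, per = stats.two_stage_aggregate(
            sub["latency_ms"].to_numpy(), sub["subject"].to_numpy()
        )
        results[f"{group.lower()}_latency_two_stage_median_ms"] = med
        print(f"{group}: two-stage median latency {med:.1f} ms "
              f"(subjects: {per.round(1).to_dict()})")
    p = results["position_mm"]
    l = results["latency_ms"]
    print(f"position coefficient {p['coef']:.2f} mm (SE {p['se']:.2f}, "
          f"p={p['pvalue']:.2g}) — negative = omission sites more posterior")
    print(f"latency coefficient {l['coef']:.1f} ms (SE {l['se']:.1f}, "
          f"p={l['pvalue']:.2g}) — positive = omission responses later")
    with open(args.dir / "lme_results.json", "w") as fh:
        json.dump(results, fh, indent=2)


if __name__ == "__main__":
    main()
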