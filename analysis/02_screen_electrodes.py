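"""Mass-univariate electrode screening and classification.

For each subject: paired t of every electrode x response timepoint against
the -20..0 ms baseline, Benjamini-Hochberg over the pooled electrode x
timepoint family, and classification into omission-active / syllable-active
/ both / none.  Writes the per-electrode table with peak latency and
amplitude, and prints the category breakdown.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from omission_hfa import hfa, pipeline, stats


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--dir", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()
    cfg = pipeline.RunConfig.load(args.dir / "config.yaml")
    truth = json.loads((args.dir / "truth_classes.json").read_text())

    rows = []
    for path in sorted(args.dir.glob("*_epochs.h5")):
        subject = path.name.split("_")[0]
        ep = hfa.load_epochs(path)
        st_om = stats.screen(
            stats.ttest_vs_baseline(
                ep,
                stats.GROUPS["Omission"],
                baseline_ms=cfg.ttest_baseline_ms,
                response_ms=cfg.response_ms,
            ),
            alpha=cfg.alpha,
            method=cfg.fdr_method,
        )
        st_sy = stats.screen(
            stats.ttest_vs_baseline(
                ep,
                stats.GROUPS["BaGa"],
                baseline_ms=cfg.ttest_baseline_ms,
                response_ms=cfg.response_ms,
            ),
            alpha=cfg.alpha,
            method=cfg.fdr_method,
        )
        cats = stats.classify_electrodes(st_om, st_sy, min_run=cfg.min_run)
        peaks = stats.peak_analysis(ep, window_ms=cfg.response_ms)
        pk = {(r["electrode"], r["group"]): r for _, r in peaks.iterrows()}
        for i, e in enumerate(ep.electrodes):
            cat = cats[i]
            group = "Omission" if cat in ("omission_active", "both") else "BaGa"
            entry = pk.get((e.id, group))
            rows.append(
                {
                    "electrode": e.id,
                    "subject": subject,
                    "y": e.y,
                    "category": cat,
                    "true_class": truth.get(e.id, ""),
                    "peak_latency_ms": entry["latency_ms"]
                    if entry is not None
                    else None,
                    "peak_amplitude": entry["amplitude"]
                    if entry is not None
                    else None,
                }
            )
    table = pd.DataFrame(rows)
    table.to_csv(args.dir / "electrode_table.tsv", sep="\t", index=False)
    print("electrode categories:")
    print(table["category"].value_counts().to_string())
    print(f"wrote {args.dir / 'electrode_table.tsv'}")


if __name__ == "__main__":
    main()
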