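"""Behavioral performance: hit rate, false alarms, reaction times.

Scores the simulated button presses against each block's schedule with a
1.5 s response window and aggregates over subjects and blocks.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from omission_hfa import paradigm


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--dir", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()
    presses = json.loads((args.dir / "button_presses.json").read_text())

    n_targets = n_hits = n_fa = n_syll = 0
    medians = []
    for subject, blocks in presses.items():
        for b, times in enumerate(blocks):
            sched = paradigm.read_events_tsv(
                args.dir / f"{subject}_block{b}_events.tsv"
            )
            resp = [paradigm.BehavioralResponse(t, b) for t in times]
            s = paradigm.behavioral_summary(sched, resp)
            n_targets += s["n_targets"]
            n_hits += s["n_hits"]
            n_fa += s["n_false_alarms"]
            n_syll += sum(
                e.syllable in ("Ba", "Ga") for e in sched.slot2_events
            )
            if s["rt_defined"]:
                medians.append(s["median_rt"])
    summary = {
        "hit_rate": n_hits / n_targets,
        "false_alarm_rate": n_fa / n_syll,
        "median_rt_s": float(np.median(medians)),
        "n_targets": n_targets,
    }
    print(
        f"hit rate {100 * summary['hit_rate']:.1f}% over {n_targets} targets; "
        f"false alarms {100 * summary['false_alarm_rate']:.2f}%; "
        f"median RT {1e3 * summary['median_rt_s']:.0f} ms"
    )
    with open(args.dir / "behavioral_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)


if __name__ == "__main__":
    main()
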