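"""Simulate the synthetic study and stage it for the downstream analyses.

Renders the default design — 6 subjects, 3 blocks each of 19 omission /
8 target / 68+68 syllable trials, 16 STG electrodes plus 32 reference-grid
channels per subject — through preprocessing and HFA epoching, then writes
per-subject epochs (HDF5), events and electrode tables (TSV), ground-truth
classes and simulated button presses (JSON) under the run directory.
"""

import argparse
import json
from pathlib import Path

from omission_hfa import hfa, paradigm, pipeline, simulate


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--dir", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()
    args.dir.mkdir(parents=True, exist_ok=True)

    cfg = pipeline.default_config(seed=args.seed)
    cfg.save(args.dir / "config.yaml")
    ds = pipeline.simulate_dataset(cfg)

    presses = {}
    for name, sd in ds.subjects.items():
        hfa.save_epochs(sd.epochs, args.dir / f"{name}_epochs.h5")
        simulate.write_electrodes_tsv(sd.electrodes, args.dir / f"{name}_electrodes.tsv")
        for b, sched in enumerate(sd.schedules):
            paradigm.write_events_tsv(sched, args.dir / f"{name}_block{b}_events.tsv")
        presses[name] = [
            [r.press_time for r in block] for block in sd.presses
        ]
        excluded = sorted(
            {c for rep in sd.reports for c in rep.excluded_channels}
        )
        print(
            f"{name}: {sd.epochs.n_trials} epochs x {sd.epochs.n_channels} "
            f"STG channels; CAR excluded {excluded or 'none'}"
        )
    with open(args.dir / "truth_classes.json", "w") as fh:
        json.dump(ds.truth.classes, fh, indent=2)
    with open(args.dir / "button_presses.json", "w") as fh:
        json.dump(presses, fh, indent=2)
    print(f"staged dataset in {args.dir}")


if __name__ == "__main__":
    main()
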