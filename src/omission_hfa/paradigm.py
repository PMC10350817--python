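"""Stimulus paradigm: triplet syllable streams with omissions and targets.

The task presents a predictable stream of syllable triplets, "La-La-Ba"
alternating with "La-La-Ga".  The third (slot-2) syllable is occasionally
omitted or replaced by a target "Ta" that the subject answers with a button
press.  Because the expected third syllable alternates deterministically,
an omission at a given triplet is unambiguously an "omitted Ba" or an
"omitted Ga".  A separate control task replaces *every* third syllable with
an omission, so that any rhythm-induced activity can be separated from
violated expectations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Condition labels for slot-2 events; slot-0/1 events are always "La".
SYLLABLES = ("La", "Ba", "Ga", "Ta", "OmittedBa", "OmittedGa", "ExpectedOmission")
AUDIBLE = frozenset({"La", "Ba", "Ga", "Ta"})

#: Default slot-2 condition counts for one block of the main task.
DEFAULT_COUNTS = {"omission": 19, "target": 8, "Ba": 68, "Ga": 68}

#: Default timing (seconds): syllable duration and inter-stimulus gaps.
DEFAULT_TIMING = {"syllable_dur": 0.400, "isi_within": 0.200, "isi_between": 0.200}


@dataclass(frozen=True)
class StimulusEvent:
    """One timed syllable (or silent omission) in the stream.

    ``expected`` records which syllable ("Ba" or "Ga") the alternation rule
    predicts at a slot-2 position; it is ``None`` for slot-0/1 "La" events.
    """

    onset: float
    duration: float
    syllable: str
    triplet_index: int
    slot: int
    expected: str | None = None

    def __post_init__(self) -> None:
        if self.syllable not in SYLLABLES:
            raise ValueError(f"unknown syllable {self.syllable!r}")
        if self.slot not in (0, 1, 2):
            raise ValueError(f"slot must be 0, 1 or 2, got {self.slot}")


@dataclass
class BlockSchedule:
    """An ordered stimulus stream for one block, with condition bookkeeping."""

    events: list[StimulusEvent]
    counts: dict[str, int]
    seed: int | None = None
    timing: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TIMING))

    @property
    def slot2_events(self) -> list[StimulusEvent]:
        return [e for e in self.events if e.slot == 2]

    @property
    def duration(self) -> float:
        last = self.events[-1]
        return last.onset + last.duration

    def __len__(self) -> int:
        return len(self.events)


@dataclass(frozen=True)
class BehavioralResponse:
    """A button press, in seconds from block start."""

    press_time: float
    block: int = 0


def _validate_timing(timing: dict[str, float]) -> dict[str, float]:
    t = dict(DEFAULT_TIMING)
    t.update(timing or {})
    for key in ("syllable_dur", "isi_within", "isi_between"):
        if t[key] <= 0:
            raise ValueError(f"timing[{key!r}] must be positive, got {t[key]}")
    return t


def _expected_syllable(triplet_index: int) -> str:
    # The expectation alternates Ba, Ga, Ba, Ga ... regardless of what is
    # actually played (omissions/targets replace the expected syllable).
    return "Ba" if triplet_index % 2 == 0 else "Ga"


def generate_schedule(
    counts: dict[str, int] | None = None,
    timing: dict[str, float] | None = None,
    seed: int = 0,
) -> BlockSchedule:
    """Generate one block of the main task.

    Slot-2 conditions are a uniformly random (seeded) arrangement of the
    requested condition multiset, constrained by the alternation rule: the
    *expected* syllable at triplet ``k`` is Ba for even ``k`` and Ga for odd
    ``k``, and an omission or target replaces whatever was expected there.
    Requested counts are honored exactly; infeasible counts (e.g. more "Ba"
    presentations than Ba-expected slots) are rejected.

    Parameters
    ----------
    counts
        Slot-2 condition counts with keys ``omission``, ``target``, ``Ba``,
        ``Ga``.  Defaults to the per-block design 19/8/68/68.
    timing
        ``syllable_dur``, ``isi_within``, ``isi_between`` in seconds.
    seed
        Seeds the condition arrangement; fixed seed gives a bit-identical
        schedule.
    """
    c = dict(DEFAULT_COUNTS)
    c.update(counts or {})
    for key, val in c.items():
        if val < 0 or val != int(val):
            raise ValueError(f"counts[{key!r}] must be a non-negative integer")
    t = _validate_timing(timing or {})

    n_triplets = c["omission"] + c["target"] + c["Ba"] + c["Ga"]
    if n_triplets == 0:
        raise ValueError("total slot-2 count must be positive")

    n_ba_slots = math.ceil(n_triplets / 2)  # even triplet indices expect Ba
    n_ga_slots = n_triplets // 2
    n_repl_ba = n_ba_slots - c["Ba"]  # replacements needed on Ba-expected slots
    n_repl_ga = n_ga_slots - c["Ga"]
    if n_repl_ba < 0 or n_repl_ga < 0:
        raise ValueError(
            "counts infeasible: more Ba/Ga presentations requested than "
            "slots expecting them under the alternation rule"
        )
    assert n_repl_ba + n_repl_ga == c["omission"] + c["target"]

    rng = np.random.default_rng(seed)
    # Replacement kinds, shuffled, then split between Ba- and Ga-expected
    # slots; slot positions within each parity drawn without replacement.
    repl_kinds = np.array(["omission"] * c["omission"] + ["target"] * c["target"])
    rng.shuffle(repl_kinds)
    ba_slots = np.arange(0, n_triplets, 2)
    ga_slots = np.arange(1, n_triplets, 2)
    repl_at: dict[int, str] = {}
    chosen_ba = rng.choice(ba_slots, size=n_repl_ba, replace=False)
    chosen_ga = rng.choice(ga_slots, size=n_repl_ga, replace=False)
    for idx, kind in zip(
        np.concatenate([chosen_ba, chosen_ga]), repl_kinds, strict=True
    ):
        repl_at[int(idx)] = str(kind)

    events: list[StimulusEvent] = []
    triplet_period = 3 * t["syllable_dur"] + 2 * t["isi_within"] + t["isi_between"]
    step = t["syllable_dur"] + t["isi_within"]
    for k in range(n_triplets):
        t0 = k * triplet_period
        expected = _expected_syllable(k)
        kind = repl_at.get(k)
        if kind == "omission":
            slot2 = f"Omitted{expected}"
        elif kind == "target":
            slot2 = "Ta"
        else:
            slot2 = expected
        for slot in (0, 1):
            events.append(
                StimulusEvent(t0 + slot * step, t["syllable_dur"], "La", k, slot)
            )
        events.append(
            StimulusEvent(t0 + 2 * step, t["syllable_dur"], slot2, k, 2, expected)
        )

    realized = {
        "omission": sum(e.syllable.startswith("Omitted") for e in events),
        "target": sum(e.syllable == "Ta" for e in events),
        "Ba": sum(e.syllable == "Ba" for e in events),
        "Ga": sum(e.syllable == "Ga" for e in events),
    }
    assert realized == c, "internal error: condition counts not conserved"
    return BlockSchedule(events=events, counts=c, seed=seed, timing=t)


def generate_control_schedule(
    n_triplets: int,
    timing: dict[str, float] | None = None,
    seed: int = 0,
) -> BlockSchedule:
    """Generate the expected-omission control task.

    Identical stream structure to the main task, but every slot-2 syllable is
    replaced by a (fully expected) omission.  No randomness is involved; the
    ``seed`` is recorded for provenance only.
    """
    if n_triplets < 1:
        raise ValueError(f"n_triplets must be >= 1, got {n_triplets}")
    t = _validate_timing(timing or {})
    events: list[StimulusEvent] = []
    triplet_period = 3 * t["syllable_dur"] + 2 * t["isi_within"] + t["isi_between"]
    step = t["syllable_dur"] + t["isi_within"]
    for k in range(n_triplets):
        t0 = k * triplet_period
        for slot in (0, 1):
            events.append(
                StimulusEvent(t0 + slot * step, t["syllable_dur"], "La", k, slot)
            )
        events.append(
            StimulusEvent(
                t0 + 2 * step,
                t["syllable_dur"],
                "ExpectedOmission",
                k,
                2,
                _expected_syllable(k),
            )
        )
    counts = {"expected_omission": n_triplets}
    return BlockSchedule(events=events, counts=counts, seed=seed, timing=t)


def behavioral_summary(
    schedule: BlockSchedule,
    responses: list[BehavioralResponse],
    response_window: float = 1.5,
) -> dict[str, float | int | None]:
    """Score button presses against the schedule.

    A hit is the first unclaimed press within ``response_window`` seconds
    after a "Ta" onset; presses attributed to a "Ba"/"Ga" onset by the same
    rule are false alarms.  Reaction-time summaries (median and median
    absolute deviation) are computed over hits only; with zero hits they are
    ``None`` and ``rt_defined`` is False.
    """
    if response_window <= 0:
        raise ValueError("response_window must be positive")
    if not schedule.events:
        raise ValueError("empty schedule")

    presses = sorted(r.press_time for r in responses)
    claimed = [False] * len(presses)

    def first_unclaimed(onset: float) -> int | None:
        for i, p in enumerate(presses):
            if claimed[i]:
                continue
            if p < onset:
                continue
            if p > onset + response_window:
                return None
            return i
        return None

    target_onsets = [e.onset for e in schedule.slot2_events if e.syllable == "Ta"]
    syll_onsets = [
        e.onset for e in schedule.slot2_events if e.syllable in ("Ba", "Ga")
    ]

    rts: list[float] = []
    for onset in target_onsets:
        i = first_unclaimed(onset)
        if i is not None:
            claimed[i] = True
            rts.append(presses[i] - onset)
    n_fa = 0
    for onset in syll_onsets:
        i = first_unclaimed(onset)
        if i is not None:
            claimed[i] = True
            n_fa += 1

    hit_rate = len(rts) / len(target_onsets) if target_onsets else float("nan")
    fa_rate = n_fa / len(syll_onsets) if syll_onsets else 0.0
    rt_arr = np.asarray(rts)
    return {
        "n_targets": len(target_onsets),
        "n_hits": len(rts),
        "n_false_alarms": n_fa,
        "hit_rate": hit_rate,
        "false_alarm_rate": fa_rate,
        "median_rt": float(np.median(rt_arr)) if rts else None,
        "rt_mad": float(np.median(np.abs(rt_arr - np.median(rt_arr))))
        if rts
        else None,
        "rt_defined": bool(rts),
    }


# ---------------------------------------------------------------------------
# events.tsv I/O (BIDS dialect: seconds, '.' for missing values)

_TSV_COLUMNS = ["onset", "duration", "trial_type", "triplet_index", "slot", "expected"]


def schedule_to_frame(schedule: BlockSchedule) -> pd.DataFrame:
    rows = [
        {
            "onset": e.onset,
            "duration": e.duration,
            "trial_type": e.syllable,
            "triplet_index": e.triplet_index,
            "slot": e.slot,
            "expected": e.expected if e.expected is not None else ".",
        }
        for e in schedule.events
    ]
    return pd.DataFrame(rows, columns=_TSV_COLUMNS)


def write_events_tsv(schedule: BlockSchedule, path) -> None:
    schedule_to_frame(schedule).to_csv(path, sep="\t", index=False, na_rep=".")


def read_events_tsv(path) -> BlockSchedule:
    df = pd.read_csv(path, sep="\t", na_values=["."], keep_default_na=False)
    events = [
        StimulusEvent(
            onset=float(r.onset),
            duration=float(r.duration),
            syllable=str(r.trial_type),
            triplet_index=int(r.triplet_index),
            slot=int(r.slot),
            expected=None if pd.isna(r.expected) else str(r.expected),
        )
        for r in df.itertuples()
    ]
    counts = {
        "omission": sum(e.syllable.startswith("Omitted") for e in events),
        "target": sum(e.syllable == "Ta" for e in events),
        "Ba": sum(e.syllable == "Ba" for e in events),
        "Ga": sum(e.syllable == "Ga" for e in events),
    }
    return BlockSchedule(events=events, counts=counts)
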