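"""High-frequency-activity envelope extraction, epoching, normalization.

HFA is the amplitude envelope of the 70-170 Hz band, extracted on the
continuous cleaned signal (fourth-order Butterworth band-pass, zero phase,
then the Hilbert analytic-signal magnitude) and resampled 1200 -> 400 Hz
with a polyphase antialiasing resampler.  Epochs are cut around slot-2
event onsets — for omissions, the *expected* onset time of the missing
syllable — covering both the pre-stimulus baselines and the 500 ms
response period.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import h5py
import numpy as np
from scipy.fft import next_fast_len
from scipy.signal import butter, hilbert, resample_poly, sosfiltfilt

from omission_hfa.paradigm import BlockSchedule
from omission_hfa.simulate import ElectrodeInfo, Recording


@dataclass
class Envelope:
    """Continuous non-negative HFA amplitude, channels x samples."""

    data: np.ndarray
    fs: float
    band: tuple[float, float]
    electrodes: list[ElectrodeInfo] = field(default_factory=list)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]


@dataclass
class EnvelopeEpochs:
    """Trial-locked HFA: trials x channels x time.

    ``times`` holds bin-left-edge times in ms relative to (expected)
    stimulus onset; bins are half-open [t, t + dt).  ``conditions`` gives
    the slot-2 condition label of each trial.
    """

    data: np.ndarray
    times: np.ndarray  # ms
    conditions: np.ndarray  # str per trial
    fs: float
    electrodes: list[ElectrodeInfo] = field(default_factory=list)
    dropped: list[int] = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def time_mask(self, window_ms: tuple[float, float]) -> np.ndarray:
        lo, hi = window_ms
        return (self.times >= lo) & (self.times < hi)

    def select(self, conditions) -> "EnvelopeEpochs":
        keep = np.isin(self.conditions, list(conditions))
        return EnvelopeEpochs(
            data=self.data[keep],
            times=self.times,
            conditions=self.conditions[keep],
            fs=self.fs,
            electrodes=self.electrodes,
        )


def extract_envelope(
    rec: Recording,
    band: tuple[float, float] = (70.0, 170.0),
    order: int = 4,
    fs_out: float = 400.0,
) -> Envelope:
    """Band-pass, Hilbert envelope, polyphase resample to ``fs_out``.

    The envelope is computed at the acquisition rate and then resampled;
    tiny negative ringing introduced by the antialiasing filter is clipped
    at zero (its magnitude is checked to be a negligible fraction of the
    total envelope mass).
    """
    lo, hi = band
    if not 0 < lo < hi < rec.fs / 2:
        raise ValueError(f"band {band} must satisfy 0 < low < high < fs/2")
    if fs_out > rec.fs:
        raise ValueError("fs_out must not exceed the input rate")
    sos = butter(order, band, btype="bandpass", fs=rec.fs, output="sos")
    bp = sosfiltfilt(sos, rec.data, axis=1)
    n = bp.shape[1]
    # zero-pad to a fast FFT length for the analytic signal, then truncate
    env = np.abs(hilbert(bp, N=next_fast_len(n), axis=1))[:, :n]
    frac = Fraction(fs_out / rec.fs).limit_denominator(1000)
    env = resample_poly(env, frac.numerator, frac.denominator, axis=1)
    neg_mass = -env[env < 0].sum()
    total = np.abs(env).sum()
    if total > 0 and neg_mass / total > 1e-3:
        warnings.warn(
            f"clipped negative envelope mass {neg_mass / total:.2e} of total",
            RuntimeWarning,
        )
    np.clip(env, 0.0, None, out=env)
    return Envelope(data=env, fs=fs_out, band=band, electrodes=rec.electrodes)


def epoch(
    env: Envelope,
    schedule: BlockSchedule,
    window_ms: tuple[float, float] = (-200.0, 500.0),
) -> EnvelopeEpochs:
    """Cut one epoch per slot-2 event, locked to (expected) onsets.

    Omission trials are locked to the time at which the omitted syllable
    was expected — the scheduled slot-2 onset.  Epochs that would extend
    past the recording are dropped with a warning, never truncated.
    """
    if not schedule.slot2_events:
        raise ValueError("schedule has no slot-2 events")
    lo_ms, hi_ms = window_ms
    if hi_ms <= lo_ms:
        raise ValueError("window must be increasing")
    dt_ms = 1e3 / env.fs
    offs_lo = int(round(lo_ms / dt_ms))
    offs_hi = int(round(hi_ms / dt_ms))  # exclusive
    times = np.arange(offs_lo, offs_hi) * dt_ms
    n_time = offs_hi - offs_lo

    trials = []
    conditions = []
    dropped: list[int] = []
    for i, ev in enumerate(schedule.slot2_events):
        onset_idx = int(round(ev.onset * env.fs))
        a, b = onset_idx + offs_lo, onset_idx + offs_hi
        if a < 0 or b > env.data.shape[1]:
            dropped.append(i)
            continue
        trials.append(env.data[:, a:b])
        conditions.append(ev.syllable)
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} epoch(s) outside the recording extent",
            RuntimeWarning,
        )
    if not trials:
        raise ValueError("no epochs fit inside the recording")
    data = np.stack(trials)
    assert data.shape[2] == n_time
    return EnvelopeEpochs(
        data=data,
        times=times,
        conditions=np.array(conditions),
        fs=env.fs,
        electrodes=env.electrodes,
        dropped=dropped,
    )


def baseline_normalize(
    ep: EnvelopeEpochs, baseline_ms: tuple[float, float] = (-200.0, 0.0)
) -> EnvelopeEpochs:
    """Divide each trial x channel by its own pre-stimulus baseline mean.

    Produces relative power change (1.0 = baseline level).  Trials with a
    zero baseline mean on any channel are dropped with a diagnostic.
    """
    mask = ep.time_mask(baseline_ms)
    if not mask.any():
        raise ValueError(f"baseline {baseline_ms} outside the epoch window")
    base = ep.data[:, :, mask].mean(axis=2)  # trials x channels
    bad = np.flatnonzero((base == 0).any(axis=1))
    keep = np.setdiff1d(np.arange(ep.n_trials), bad)
    if bad.size:
        warnings.warn(
            f"dropped {bad.size} trial(s) with zero baseline mean", RuntimeWarning
        )
    if keep.size == 0:
        raise ValueError("all trials have zero baseline mean")
    data = ep.data[keep] / base[keep][:, :, None]
    return EnvelopeEpochs(
        data=data,
        times=ep.times,
        conditions=ep.conditions[keep],
        fs=ep.fs,
        electrodes=ep.electrodes,
        dropped=list(bad),
    )


def save_epochs(ep: EnvelopeEpochs, path) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("data", data=ep.data.astype(np.float32))
        d.attrs["fs"] = ep.fs
        f.create_dataset("times_ms", data=ep.times)
        f.create_dataset(
            "conditions", data=[c.encode() for c in ep.conditions]
        )
        g = f.create_group("electrodes")
        g.create_dataset("id", data=[e.id.encode() for e in ep.electrodes])
        g.create_dataset("subject", data=[e.subject.encode() for e in ep.electrodes])
        for ax in "xyz":
            g.create_dataset(ax, data=[getattr(e, ax) for e in ep.electrodes])


def load_epochs(path) -> EnvelopeEpochs:
    with h5py.File(path, "r") as f:
        data = f["data"][...].astype(float)
        fs = float(f["data"].attrs["fs"])
        times = f["times_ms"][...]
        conditions = np.array([c.decode() for c in f["conditions"]])
        g = f["electrodes"]
        electrodes = [
            ElectrodeInfo(
                id=i.decode(), subject=s.decode(), x=float(x), y=float(y), z=float(z)
            )
            for i, s, x, y, z in zip(g["id"], g["subject"], g["x"], g["y"], g["z"])
        ]
    return EnvelopeEpochs(
        data=data, times=times, conditions=conditions, fs=fs, electrodes=electrodes
    )
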