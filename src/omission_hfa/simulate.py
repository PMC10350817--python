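"""Synthetic ECoG recordings with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: subdural electrodes along the superior temporal gyrus (Talairach
coordinates, y = anterior-posterior axis, more negative = more posterior),
1/f-shaped background noise with 50/60 Hz-family line contamination, and
condition-specific bursts of band-limited (70-170 Hz) activity.  Electrodes
fall into three classes: ``syllable_only`` (respond to heard syllables,
anterior/middle STG), ``omission_and_syllable`` (additionally respond to
omitted expected syllables, posterior STG, with a later peak), and
``silent``.  All effect sizes, latencies and noise levels live in
:class:`GroundTruth`, so parameter-recovery tests can compare pipeline
estimates against the exact quantities that generated the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd
from numpy.random import Generator, default_rng
from scipy.fft import next_fast_len

from omission_hfa.paradigm import BehavioralResponse, BlockSchedule

#: Response classes for STG analysis electrodes; "grid" marks non-auditory
#: channels elsewhere on the clinical implant that only take part in
#: preprocessing (notably the common average reference), never in analysis.
CLASSES = ("syllable_only", "omission_and_syllable", "silent", "grid")
RESPONSIVE = frozenset({"syllable_only", "omission_and_syllable"})


@dataclass(frozen=True)
class ElectrodeInfo:
    """One subdural contact with Talairach coordinates in mm."""

    id: str
    subject: str
    x: float
    y: float
    z: float


@dataclass
class NoiseModel:
    """Background-noise configuration.

    ``one_over_f_exponent`` is the negative log-log slope of the background
    power spectral density; ECoG spectra typically fall off with exponents
    around 2-3.  Line noise is injected at 60 Hz and harmonics with
    heterogeneous per-channel amplitudes (log-normal spread), and a small
    fraction of channels carry grossly excessive line noise so that robust
    channel-exclusion rules have something to catch.
    """

    one_over_f_exponent: float = 2.0
    broadband_sigma: float = 8.0  # uV, total background std per channel
    line_amplitudes: dict[float, float] = field(
        default_factory=lambda: {60.0: 5.0, 120.0: 2.0, 180.0: 1.0}
    )
    line_heterogeneity: float = 0.4  # sigma of log per-channel line gain
    line_outlier_prob: float = 0.05
    line_outlier_gain: float = 25.0
    channel_gain_sigma: float = 0.1  # sigma of log per-channel broadband gain


@dataclass
class GroundTruth:
    """Generative parameters plus the per-electrode class assignment.

    Amplitudes are peak HFA-envelope heights in the same units as the raw
    signal (uV); latencies are ms from (expected) stimulus onset.  The
    omission response peaks ``latency_shift_omission_ms`` later than the
    syllable response and only on ``omission_and_syllable`` electrodes,
    whose mean y-coordinate sits ``posterior_shift_mm`` behind the
    syllable-only population.  Omission amplitude grows toward posterior
    sites at ``amp_posterior_gradient_per_mm`` (fractional change per mm).
    """

    classes: dict[str, str] = field(default_factory=dict)
    amp_syllable: float = 2.0
    amp_omission: float = 1.0
    amp_target: float = 2.4
    latency_syllable_ms: float = 160.0
    latency_shift_omission_ms: float = 121.0
    burst_sigma_syllable_ms: float = 45.0
    burst_sigma_omission_ms: float = 60.0
    latency_jitter_syllable_ms: float = 8.0
    latency_jitter_omission_ms: float = 20.0
    trial_gain_sigma: float = 0.2  # sigma of log per-trial amplitude gain
    amp_posterior_gradient_per_mm: float = 0.02
    posterior_shift_mm: float = 6.7
    noise: NoiseModel = field(default_factory=NoiseModel)

    @property
    def latency_omission_ms(self) -> float:
        return self.latency_syllable_ms + self.latency_shift_omission_ms


@dataclass
class Recording:
    """Raw multichannel signal plus its electrode and event metadata."""

    data: np.ndarray  # channels x samples
    fs: float
    electrodes: list[ElectrodeInfo]
    events: BlockSchedule | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if len(self.electrodes) != self.data.shape[0]:
            raise ValueError(
                f"{self.data.shape[0]} channels but "
                f"{len(self.electrodes)} electrode entries"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def channel_ids(self) -> list[str]:
        return [e.id for e in self.electrodes]


def make_electrode_layout(
    n_per_subject: int,
    subjects: list[str],
    y_range: tuple[float, float] = (-40.0, 0.0),
    posterior_fraction: float = 0.3,
    silent_fraction: float = 0.2,
    posterior_shift_mm: float = 6.7,
    y_sd: float = 6.0,
    subject_y_sd: float = 3.0,
    n_grid_per_subject: int = 0,
    seed: int = 0,
    truth: GroundTruth | None = None,
) -> tuple[list[ElectrodeInfo], GroundTruth]:
    """Draw electrode positions and classes for each subject.

    Syllable-only electrodes are drawn around the anterior end of
    ``y_range`` minus one sd; omission-class electrodes around a mean
    shifted ``posterior_shift_mm`` toward posterior (more negative y).
    Every subject gets at least one electrode of each responsive class.

    ``n_grid_per_subject`` adds noise-only "grid" channels scattered over
    the rest of the implant; they model the referencing context of a
    clinical grid (the common average is computed over far more channels
    than the STG analysis set) and are dropped before envelope analysis.
    ``subject_y_sd`` shifts each subject's whole implant along the
    anterior-posterior axis (inter-individual coverage differences), which
    is what the mixed models' subject random intercepts absorb.
    """
    if n_per_subject < 2:
        raise ValueError("n_per_subject must be >= 2")
    if not subjects:
        raise ValueError("subject list must be non-empty")
    rng = default_rng(seed)
    n_om = max(1, round(posterior_fraction * n_per_subject))
    n_sil = min(round(silent_fraction * n_per_subject), n_per_subject - n_om - 1)
    n_syl = n_per_subject - n_om - n_sil
    assert n_syl >= 1

    mu_ant = (y_range[0] + y_range[1]) / 2 + posterior_shift_mm / 2
    mu_post = mu_ant - posterior_shift_mm

    electrodes: list[ElectrodeInfo] = []
    classes: dict[str, str] = {}
    for subj in subjects:
        subj_shift = rng.normal(0.0, subject_y_sd)
        labels = (
            ["omission_and_syllable"] * n_om
            + ["syllable_only"] * n_syl
            + ["silent"] * n_sil
            + ["grid"] * n_grid_per_subject
        )
        for k, cls in enumerate(labels):
            if cls == "omission_and_syllable":
                y = subj_shift + rng.normal(mu_post, y_sd)
                x, z = rng.normal(-55.0, 3.0), rng.normal(5.0, 4.0)
            elif cls == "syllable_only":
                y = subj_shift + rng.normal(mu_ant, y_sd)
                x, z = rng.normal(-55.0, 3.0), rng.normal(5.0, 4.0)
            elif cls == "silent":
                y = subj_shift + rng.uniform(*y_range)
                x, z = rng.normal(-55.0, 3.0), rng.normal(5.0, 4.0)
            else:  # grid channels scattered over the rest of the implant
                y = subj_shift + rng.uniform(-70.0, 30.0)
                x, z = rng.normal(-50.0, 8.0), rng.normal(25.0, 15.0)
            eid = f"{subj}_e{k:02d}" if cls != "grid" else f"{subj}_g{k:02d}"
            electrodes.append(
                ElectrodeInfo(
                    id=eid, subject=subj, x=float(x), y=float(y), z=float(z)
                )
            )
            classes[eid] = cls

    base = truth if truth is not None else GroundTruth()
    out = replace(base, classes=classes, posterior_shift_mm=posterior_shift_mm)
    return electrodes, out


def one_over_f_noise(
    n_samples: int, fs: float, exponent: float, rng: Generator
) -> np.ndarray:
    """Unit-variance Gaussian noise with PSD proportional to f**-exponent.

    The shaping is flattened below 0.5 Hz to keep the variance finite; the
    configured slope holds over the analysis range (~1-200 Hz).
    """
    n_fft = next_fast_len(n_samples, real=True)
    white = rng.standard_normal(n_fft)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n_fft, 1.0 / fs)
    scale = np.zeros_like(f)
    scale[1:] = np.maximum(f[1:], 0.5) ** (-exponent / 2.0)
    x = np.fft.irfft(spec * scale, n_fft)[:n_samples]
    return x / x.std()


def _constant_modulus_carrier(
    n_samples: int, fs: float, band: tuple[float, float], rng: Generator
) -> np.ndarray:
    """Band-limited carrier whose instantaneous envelope is exactly 1.

    A flat-band analytic signal is synthesized directly in the frequency
    domain (random complex Gaussian amplitudes over the band, positive
    frequencies only); its real part divided by its own envelope keeps the
    in-band phase structure while making the injected burst envelope equal
    to the modulating bump — amplitude and latency ground truth stay exact
    while the extraction path (filter + Hilbert) is genuinely exercised.
    """
    n_fft = next_fast_len(n_samples)
    f = np.fft.fftfreq(n_fft, 1.0 / fs)
    sel = (f >= band[0]) & (f <= band[1])
    spec = np.zeros(n_fft, dtype=complex)
    k = int(sel.sum())
    spec[sel] = rng.standard_normal(k) + 1j * rng.standard_normal(k)
    z = np.fft.ifft(spec)[:n_samples]  # analytic: positive frequencies only
    return np.real(z) / np.maximum(np.abs(z), 1e-30)


def synthesize_recording(
    schedule: BlockSchedule,
    layout: list[ElectrodeInfo],
    truth: GroundTruth,
    fs: float = 1200.0,
    seed: int = 0,
    band: tuple[float, float] = (70.0, 170.0),
    pad: float = 1.0,
    carrier: str = "noise",
) -> Recording:
    """Render one block of raw signal for the given layout and truth.

    Background = per-channel 1/f noise plus shared-phase line-noise
    sinusoids with heterogeneous per-channel amplitudes.  Each slot-2 event
    adds, on the responsive channels for its condition, a burst of
    band-limited activity whose envelope is a Gaussian bump (class- and
    condition-specific amplitude and latency, with per-trial gain and
    latency jitter).  Omission events drive only omission-class channels;
    expected omissions (control task) drive nothing.

    ``carrier`` selects the burst fine structure: ``"noise"`` (default,
    constant-modulus band-limited noise) or ``"tone"`` (pure tone at the
    band center, useful for exact-envelope checks).
    """
    if not schedule.events:
        raise ValueError("schedule has no events")
    if fs < 400:
        raise ValueError("fs must be >= 400 Hz")
    rng = default_rng(seed)
    n_ch = len(layout)
    n_samples = int(round((schedule.duration + pad) * fs))
    t = np.arange(n_samples) / fs
    nm = truth.noise

    data = np.empty((n_ch, n_samples))
    ch_gain = np.exp(rng.normal(0.0, nm.channel_gain_sigma, size=n_ch))
    for c in range(n_ch):
        data[c] = (
            one_over_f_noise(n_samples, fs, nm.one_over_f_exponent, rng)
            * nm.broadband_sigma
            * ch_gain[c]
        )

    # Line noise: shared phase per frequency, heterogeneous per-channel
    # amplitude, occasional gross outlier channels.
    line_gain = np.exp(rng.normal(0.0, nm.line_heterogeneity, size=n_ch))
    outliers = rng.random(n_ch) < nm.line_outlier_prob
    line_gain[outliers] *= nm.line_outlier_gain
    for freq, base_amp in nm.line_amplitudes.items():
        phase = rng.uniform(0.0, 2.0 * np.pi)
        tone = np.sin(2.0 * np.pi * freq * t + phase)
        data += (base_amp * line_gain)[:, None] * tone[None, :]

    # Evoked bursts: accumulate each channel's envelope track, then
    # modulate a single band-limited carrier.
    env_track = np.zeros((n_ch, n_samples))
    y_coords = np.array([e.y for e in layout])
    cls = np.array([truth.classes.get(e.id, "silent") for e in layout])
    syllable_ch = np.flatnonzero(np.isin(cls, list(RESPONSIVE)))
    omission_ch = np.flatnonzero(cls == "omission_and_syllable")
    y_om_med = np.median(y_coords[omission_ch]) if omission_ch.size else 0.0

    for ev in schedule.slot2_events:
        if ev.syllable in ("Ba", "Ga", "Ta"):
            chans = syllable_ch
            amp = truth.amp_target if ev.syllable == "Ta" else truth.amp_syllable
            amps = np.full(chans.size, amp)
            lat = truth.latency_syllable_ms / 1e3
            sigma = truth.burst_sigma_syllable_ms / 1e3
            jitter = truth.latency_jitter_syllable_ms / 1e3
        elif ev.syllable in ("OmittedBa", "OmittedGa"):
            chans = omission_ch
            grad = truth.amp_posterior_gradient_per_mm
            amps = truth.amp_omission * np.clip(
                1.0 + grad * (y_om_med - y_coords[chans]), 0.2, None
            )
            lat = truth.latency_omission_ms / 1e3
            sigma = truth.burst_sigma_omission_ms / 1e3
            jitter = truth.latency_jitter_omission_ms / 1e3
        else:  # ExpectedOmission: no response
            continue
        if chans.size == 0:
            continue
        gains = np.exp(rng.normal(0.0, truth.trial_gain_sigma, size=chans.size))
        lats = ev.onset + lat + rng.normal(0.0, jitter, size=chans.size)
        for ch, a, g, mu in zip(chans, amps, gains, lats):
            lo = max(0, int((mu - 4 * sigma) * fs))
            hi = min(n_samples, int((mu + 4 * sigma) * fs) + 1)
            if hi <= lo:
                continue
            tt = t[lo:hi]
            env_track[ch, lo:hi] += a * g * np.exp(
                -0.5 * ((tt - mu) / sigma) ** 2
            )

    if carrier == "tone":
        f0 = (band[0] + band[1]) / 2.0
        for c in range(n_ch):
            phase = rng.uniform(0.0, 2.0 * np.pi)
            data[c] += env_track[c] * np.cos(2.0 * np.pi * f0 * t + phase)
    elif carrier == "noise":
        for c in range(n_ch):
            if env_track[c].any():
                data[c] += env_track[c] * _constant_modulus_carrier(
                    n_samples, fs, band, rng
                )
    else:
        raise ValueError(f"unknown carrier {carrier!r}")

    return Recording(data=data, fs=fs, electrodes=list(layout), events=schedule)


def simulate_button_presses(
    schedule: BlockSchedule,
    rt_median: float = 0.534,
    rt_spread: float = 0.1,
    hit_prob: float = 0.92,
    fa_prob: float = 0.002,
    seed: int = 0,
    block: int = 0,
) -> list[BehavioralResponse]:
    """Draw button presses for targets (hits) and Ba/Ga trials (false alarms).

    Reaction times follow a log-normal distribution with the given median;
    ``rt_spread`` (seconds) sets the log-scale spread as rt_spread/rt_median,
    so the RT standard deviation is approximately ``rt_spread`` and a zero
    spread collapses to the median exactly.
    """
    if not 0.0 <= hit_prob <= 1.0 or not 0.0 <= fa_prob <= 1.0:
        raise ValueError("hit_prob and fa_prob must lie in [0, 1]")
    if rt_median <= 0 or rt_spread < 0:
        raise ValueError("rt_median must be positive and rt_spread non-negative")
    rng = default_rng(seed)
    sigma = rt_spread / rt_median
    presses: list[BehavioralResponse] = []
    for ev in schedule.slot2_events:
        if ev.syllable == "Ta":
            if rng.random() < hit_prob:
                rt = rt_median * np.exp(sigma * rng.standard_normal())
                presses.append(BehavioralResponse(ev.onset + rt, block))
        elif ev.syllable in ("Ba", "Ga"):
            if rng.random() < fa_prob:
                rt = rt_median * np.exp(sigma * rng.standard_normal())
                presses.append(BehavioralResponse(ev.onset + rt, block))
    presses.sort(key=lambda r: r.press_time)
    return presses


# ---------------------------------------------------------------------------
# Persistence: HDF5 for the signal, BIDS-style TSV for electrode tables.


def save_recording(rec: Recording, path) -> None:
    """Write signal + electrode table to HDF5 (events go in a sidecar TSV)."""
    with h5py.File(path, "w") as f:
        dset = f.create_dataset("data", data=rec.data.astype(np.float32))
        dset.attrs["fs"] = rec.fs
        g = f.create_group("electrodes")
        g.create_dataset("id", data=[e.id.encode() for e in rec.electrodes])
        g.create_dataset("subject", data=[e.subject.encode() for e in rec.electrodes])
        for ax in "xyz":
            g.create_dataset(ax, data=[getattr(e, ax) for e in rec.electrodes])


def load_recording(path, events: BlockSchedule | None = None) -> Recording:
    with h5py.File(path, "r") as f:
        data = f["data"][...].astype(float)
        fs = float(f["data"].attrs["fs"])
        g = f["electrodes"]
        electrodes = [
            ElectrodeInfo(
                id=i.decode(),
                subject=s.decode(),
                x=float(x),
                y=float(y),
                z=float(z),
            )
            for i, s, x, y, z in zip(g["id"], g["subject"], g["x"], g["y"], g["z"])
        ]
    return Recording(data=data, fs=fs, electrodes=electrodes, events=events)


def electrodes_to_frame(electrodes: list[ElectrodeInfo]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"name": e.id, "subject": e.subject, "x": e.x, "y": e.y, "z": e.z}
            for e in electrodes
        ]
    )


def write_electrodes_tsv(electrodes: list[ElectrodeInfo], path) -> None:
    electrodes_to_frame(electrodes).to_csv(path, sep="\t", index=False)
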