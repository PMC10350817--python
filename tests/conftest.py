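import numpy as np
import pytest
from hypothesis import settings

from omission_hfa import hfa, paradigm, pipeline, simulate

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def tiny_dataset() -> pipeline.SimulatedDataset:
    """One subject, 8 electrodes, one reduced-count block."""
    return pipeline.make_fixtures("tiny", seed=7)


@pytest.fixture(scope="session")
def tiny_schedule() -> paradigm.BlockSchedule:
    return paradigm.generate_schedule(
        counts={"omission": 6, "target": 2, "Ba": 12, "Ga": 12}, seed=3
    )


@pytest.fixture(scope="session")
def default_schedule() -> paradigm.BlockSchedule:
    return paradigm.generate_schedule(seed=11)


def tone_recording(
    freq: float, amp: float = 1.0, fs: float = 1200.0, dur: float = 4.0
) -> simulate.Recording:
    """A single-channel pure sinusoid with minimal electrode metadata."""
    t = np.arange(int(dur * fs)) / fs
    data = amp * np.sin(2 * np.pi * freq * t)[None, :]
    elec = [simulate.ElectrodeInfo("e0", "S1", -55.0, -20.0, 5.0)]
    return simulate.Recording(data=data, fs=fs, electrodes=elec)


def synthetic_epochs(
    rng: np.random.Generator,
    n_trials_per_condition: dict[str, int],
    n_channels: int = 3,
    n_times: int = 40,
    means: dict[str, float] | None = None,
    noise_sd: float = 1.0,
) -> hfa.EnvelopeEpochs:
    """Gaussian epochs with condition-specific means, for statistics oracles."""
    conds = []
    rows = []
    for c, n in n_trials_per_condition.items():
        mu = (means or {}).get(c, 0.0)
        for _ in range(n):
            rows.append(mu + noise_sd * rng.standard_normal((n_channels, n_times)))
            conds.append(c)
    times = np.arange(n_times) * 2.5 - 20.0  # covers a -20..0 baseline
    electrodes = [
        simulate.ElectrodeInfo(f"e{i}", "S1", -55.0, -20.0 - i, 5.0)
        for i in range(n_channels)
    ]
    return hfa.EnvelopeEpochs(
        data=np.stack(rows),
        times=times,
        conditions=np.array(conds),
        fs=400.0,
        electrodes=electrodes,
    )
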