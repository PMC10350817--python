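"""End-to-end orchestration: config, simulated datasets, full analysis runs.

:class:`RunConfig` is the single source of truth for every analysis window
and filter setting, so the t-test baseline (-20..0 ms) and the
normalization baseline (-200..0 ms) cannot silently diverge between
modules.  :func:`simulate_dataset` renders raw blocks and carries them
through preprocessing and envelope epoching per subject;
:func:`analyze_dataset` runs the electrode statistics, mixed-effects
models, condition GLM and contrast suite; :func:`run_all` writes the
result tables plus a machine-readable manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from omission_hfa import glmcontrast, hfa, paradigm, preprocess, simulate, stats

log = logging.getLogger("omission_hfa")

_TUPLE_FIELDS = {
    "band",
    "notch_freqs",
    "epoch_window_ms",
    "ttest_baseline_ms",
    "norm_baseline_ms",
    "response_ms",
    "y_range",
}


@dataclass
class RunConfig:
    """All pipeline parameters with their standard defaults.

    Signal defaults follow the acquisition/analysis convention: 1200 Hz
    sampling; 0.05 Hz second-order high-pass; notches at 60/120/180 Hz;
    70-170 Hz fourth-order band-pass; envelope resampled to 400 Hz;
    epoch window -200..500 ms with the t-test baseline at -20..0 ms and
    the normalization baseline at -200..0 ms; FDR alpha 0.05; 95% CIs.
    """

    # paradigm
    counts: dict[str, int] = field(
        default_factory=lambda: dict(paradigm.DEFAULT_COUNTS)
    )
    timing: dict[str, float] = field(
        default_factory=lambda: dict(paradigm.DEFAULT_TIMING)
    )
    n_blocks: int = 3
    # layout / simulation
    subjects: list[str] = field(
        default_factory=lambda: [f"S{i}" for i in range(1, 7)]
    )
    n_electrodes_per_subject: int = 16
    n_grid_per_subject: int = 32
    posterior_fraction: float = 0.3
    silent_fraction: float = 0.2
    y_range: tuple[float, float] = (-40.0, 0.0)
    subject_y_sd: float = 3.0
    truth: simulate.GroundTruth = field(default_factory=simulate.GroundTruth)
    fs: float = 1200.0
    seed: int = 0
    # preprocessing
    hp_cutoff: float = 0.05
    hp_order: int = 2
    notch_freqs: tuple[float, ...] = (60.0, 120.0, 180.0)
    notch_bandwidth: float = 1.0
    exclusion_factor: float = 10.0
    # envelope / epochs
    band: tuple[float, float] = (70.0, 170.0)
    band_order: int = 4
    fs_out: float = 400.0
    epoch_window_ms: tuple[float, float] = (-200.0, 500.0)
    ttest_baseline_ms: tuple[float, float] = (-20.0, 0.0)
    norm_baseline_ms: tuple[float, float] = (-200.0, 0.0)
    response_ms: tuple[float, float] = (0.0, 500.0)
    # statistics
    alpha: float = 0.05
    fdr_method: str = "fdr_bh"
    # electrode-level significance requires a run of >= min_run consecutive
    # significant bins: 4 bins = 10 ms, the envelope's own correlation time
    # for a 100 Hz-wide band, so isolated noise bins never classify an
    # electrode while real (>100 ms) responses always do
    min_run: int = 4
    ci_level: float = 0.95
    ci_width: str = "half"
    # behavior
    hit_prob: float = 0.92
    fa_prob: float = 0.002
    rt_median: float = 0.534
    rt_spread: float = 0.1
    response_window: float = 1.5
    out_dir: str = "results/run"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "truth" in d and isinstance(d["truth"], dict):
            td = dict(d["truth"])
            if "noise" in td and isinstance(td["noise"], dict):
                nd = dict(td["noise"])
                if "line_amplitudes" in nd:
                    nd["line_amplitudes"] = {
                        float(k): float(v)
                        for k, v in nd["line_amplitudes"].items()
                    }
                td["noise"] = simulate.NoiseModel(**nd)
            d["truth"] = simulate.GroundTruth(**td)
        for key in _TUPLE_FIELDS & d.keys():
            d[key] = tuple(d[key])
        if "counts" in d:
            d["counts"] = {k: int(v) for k, v in d["counts"].items()}
        return cls(**d)

    def save(self, path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            if path.suffix in (".yml", ".yaml"):
                yaml.safe_dump(_jsonable(self.to_dict()), fh, sort_keys=False)
            else:
                json.dump(_jsonable(self.to_dict()), fh, indent=2)

    @classmethod
    def load(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            if path.suffix in (".yml", ".yaml"):
                d = yaml.safe_load(fh)
            else:
                d = json.load(fh)
        return cls.from_dict(d)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {
            (k if isinstance(k, str) else float(k)): _jsonable(v)
            for k, v in obj.items()
        }
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


@dataclass
class SubjectData:
    """One subject's epoched HFA plus simulation provenance."""

    subject: str
    electrodes: list[simulate.ElectrodeInfo]
    epochs: hfa.EnvelopeEpochs
    reports: list[preprocess.PreprocessReport]
    schedules: list[paradigm.BlockSchedule]
    presses: list[list[paradigm.BehavioralResponse]]


@dataclass
class SimulatedDataset:
    config: RunConfig
    truth: simulate.GroundTruth
    subjects: dict[str, SubjectData]


def _child_seed(base: int, *key: int) -> int:
    ss = np.random.SeedSequence([base, *key])
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_dataset(config: RunConfig) -> SimulatedDataset:
    """Simulate, preprocess and epoch every subject and block."""
    layout, truth = simulate.make_electrode_layout(
        n_per_subject=config.n_electrodes_per_subject,
        subjects=config.subjects,
        y_range=config.y_range,
        posterior_fraction=config.posterior_fraction,
        silent_fraction=config.silent_fraction,
        posterior_shift_mm=config.truth.posterior_shift_mm,
        subject_y_sd=config.subject_y_sd,
        n_grid_per_subject=config.n_grid_per_subject,
        seed=_child_seed(config.seed, 0),
        truth=config.truth,
    )
    subjects: dict[str, SubjectData] = {}
    for s_idx, subj in enumerate(config.subjects):
        all_elecs = [e for e in layout if e.subject == subj]
        # STG analysis set: grid channels only support the reference
        keep = np.array(
            [truth.classes[e.id] != "grid" for e in all_elecs], dtype=bool
        )
        elecs = [e for e, k in zip(all_elecs, keep) if k]
        epoch_parts = []
        cond_parts = []
        reports = []
        schedules = []
        presses = []
        times = None
        for b in range(config.n_blocks):
            sched = paradigm.generate_schedule(
                config.counts, config.timing, seed=_child_seed(config.seed, 1, s_idx, b)
            )
            rec = simulate.synthesize_recording(
                sched,
                all_elecs,
                truth,
                fs=config.fs,
                seed=_child_seed(config.seed, 2, s_idx, b),
                band=config.band,
            )
            clean, report = preprocess.preprocess(
                rec,
                hp_cutoff=config.hp_cutoff,
                hp_order=config.hp_order,
                notch_freqs=config.notch_freqs,
                notch_bandwidth=config.notch_bandwidth,
                exclusion_factor=config.exclusion_factor,
            )
            stg = simulate.Recording(
                clean.data[keep], clean.fs, elecs, clean.events
            )
            env = hfa.extract_envelope(
                stg, band=config.band, order=config.band_order, fs_out=config.fs_out
            )
            ep = hfa.epoch(env, sched, window_ms=config.epoch_window_ms)
            epoch_parts.append(ep.data)
            cond_parts.append(ep.conditions)
            times = ep.times
            reports.append(report)
            schedules.append(sched)
            presses.append(
                simulate.simulate_button_presses(
                    sched,
                    rt_median=config.rt_median,
                    rt_spread=config.rt_spread,
                    hit_prob=config.hit_prob,
                    fa_prob=config.fa_prob,
                    seed=_child_seed(config.seed, 3, s_idx, b),
                    block=b,
                )
            )
            log.info(
                "subject %s block %d: %d epochs, %d channel(s) excluded from CAR",
                subj,
                b,
                ep.n_trials,
                len(report.excluded_channels),
            )
        epochs = hfa.EnvelopeEpochs(
            data=np.concatenate(epoch_parts, axis=0),
            times=times,
            conditions=np.concatenate(cond_parts),
            fs=config.fs_out,
            electrodes=elecs,
        )
        subjects[subj] = SubjectData(
            subject=subj,
            electrodes=elecs,
            epochs=epochs,
            reports=reports,
            schedules=schedules,
            presses=presses,
        )
    return SimulatedDataset(config=config, truth=truth, subjects=subjects)


@dataclass
class SubjectAnalysis:
    subject: str
    stats_omission: stats.ElectrodeStats
    stats_syllable: stats.ElectrodeStats
    categories: np.ndarray
    peaks: pd.DataFrame
    glm: glmcontrast.ConditionGLMResult
    contrasts: dict


@dataclass
class AnalysisResult:
    config: RunConfig
    per_subject: dict[str, SubjectAnalysis]
    electrode_table: pd.DataFrame
    lme_position: stats.LMEResult | None
    lme_latency: stats.LMEResult | None
    lme_amplitude: stats.LMEResult | None
    behavioral: dict


def analyze_subject(sd: SubjectData, config: RunConfig) -> SubjectAnalysis:
    """Screening, classification, peaks, GLM and contrasts for one subject."""
    ep = sd.epochs
    st_om = stats.ttest_vs_baseline(
        ep,
        stats.GROUPS["Omission"],
        baseline_ms=config.ttest_baseline_ms,
        response_ms=config.response_ms,
    )
    st_sy = stats.ttest_vs_baseline(
        ep,
        stats.GROUPS["BaGa"],
        baseline_ms=config.ttest_baseline_ms,
        response_ms=config.response_ms,
    )
    stats.screen(st_om, alpha=config.alpha, method=config.fdr_method)
    stats.screen(st_sy, alpha=config.alpha, method=config.fdr_method)
    categories = stats.classify_electrodes(st_om, st_sy, min_run=config.min_run)
    peaks = stats.peak_analysis(ep, window_ms=config.response_ms)
    glm = glmcontrast.fit_condition_glm(
        ep,
        ci_level=config.ci_level,
        ci_width=config.ci_width,
        window_ms=config.response_ms,
    )
    contrasts = glmcontrast.contrast_suite(glm, average_window_ms=config.response_ms)
    log.info(
        "subject %s: categories %s",
        sd.subject,
        dict(zip(*np.unique(categories, return_counts=True))),
    )
    return SubjectAnalysis(
        subject=sd.subject,
        stats_omission=st_om,
        stats_syllable=st_sy,
        categories=categories,
        peaks=peaks,
        glm=glm,
        contrasts=contrasts,
    )


def _behavioral_aggregate(ds: SimulatedDataset) -> dict:
    n_targets = n_hits = n_fa = n_syll = 0
    rts: list[float] = []
    for sd in ds.subjects.values():
        for sched, presses in zip(sd.schedules, sd.presses):
            summ = paradigm.behavioral_summary(
                sched, presses, response_window=ds.config.response_window
            )
            n_targets += summ["n_targets"]
            n_hits += summ["n_hits"]
            n_fa += summ["n_false_alarms"]
            n_syll += sum(
                e.syllable in ("Ba", "Ga") for e in sched.slot2_events
            )
            if summ["rt_defined"]:
                rts.extend([summ["median_rt"]] * summ["n_hits"])
    return {
        "n_targets": n_targets,
        "n_hits": n_hits,
        "hit_rate": n_hits / n_targets if n_targets else float("nan"),
        "false_alarm_rate": n_fa / n_syll if n_syll else float("nan"),
        "median_rt": float(np.median(rts)) if rts else None,
    }


def analyze_dataset(ds: SimulatedDataset) -> AnalysisResult:
    """Per-subject analysis plus the three group-level mixed-effects models."""
    per_subject = {
        name: analyze_subject(sd, ds.config) for name, sd in ds.subjects.items()
    }
    rows = []
    all_electrodes: list[simulate.ElectrodeInfo] = []
    all_categories: list[str] = []
    peak_frames = []
    for name, sd in ds.subjects.items():
        sa = per_subject[name]
        all_electrodes.extend(sd.electrodes)
        all_categories.extend(sa.categories)
        peak_frames.append(sa.peaks)
        peaks_by = {
            (r["electrode"], r["group"]): r for _, r in sa.peaks.iterrows()
        }
        for i, e in enumerate(sd.electrodes):
            cat = sa.categories[i]
            group = "Omission" if cat in ("omission_active", "both") else "BaGa"
            pk = peaks_by.get((e.id, group))
            rows.append(
                {
                    "electrode": e.id,
                    "subject": e.subject,
                    "y": e.y,
                    "category": cat,
                    "true_class": ds.truth.classes.get(e.id, ""),
                    "t_max": float(
                        np.maximum(
                            sa.stats_omission.t[i].max(),
                            sa.stats_syllable.t[i].max(),
                        )
                    ),
                    "p_min": float(
                        min(sa.stats_omission.p[i].min(), sa.stats_syllable.p[i].min())
                    ),
                    "peak_latency_ms": pk["latency_ms"] if pk is not None else np.nan,
                    "peak_amplitude": pk["amplitude"] if pk is not None else np.nan,
                }
            )
    table = pd.DataFrame(rows)
    categories = np.array(all_categories)
    peaks = pd.concat(peak_frames, ignore_index=True)

    def _try(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except ValueError as err:
            log.warning("LME skipped: %s", err)
            return None

    omission_ids = [
        e.id
        for e, c in zip(all_electrodes, categories)
        if c in ("omission_active", "both")
    ]
    return AnalysisResult(
        config=ds.config,
        per_subject=per_subject,
        electrode_table=table,
        lme_position=_try(stats.lme_position, categories, all_electrodes),
        lme_latency=_try(stats.lme_latency, peaks, categories, all_electrodes),
        lme_amplitude=_try(
            stats.lme_amplitude_position,
            peaks,
            all_electrodes,
            electrode_subset=omission_ids,
        ),
        behavioral=_behavioral_aggregate(ds),
    )


def run_all(config: RunConfig, out_dir=None) -> AnalysisResult:
    """Simulate, analyze, and write tables + manifest to ``out_dir``."""
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds = simulate_dataset(config)
    res = analyze_dataset(ds)

    res.electrode_table.to_csv(out / "electrodes.tsv", sep="\t", index=False)
    for name, sd in ds.subjects.items():
        paradigm.write_events_tsv(sd.schedules[0], out / f"{name}_block0_events.tsv")
    lme = {
        "position_mm": res.lme_position.to_dict() if res.lme_position else None,
        "latency_ms": res.lme_latency.to_dict() if res.lme_latency else None,
        "amplitude_position": res.lme_amplitude.to_dict()
        if res.lme_amplitude
        else None,
    }
    with open(out / "lme_summaries.json", "w") as fh:
        json.dump(lme, fh, indent=2)
    with open(out / "behavioral.json", "w") as fh:
        json.dump(_jsonable(res.behavioral), fh, indent=2)
    for name, sa in res.per_subject.items():
        for cname, m in sa.contrasts["maps"].items():
            glmcontrast.write_score_tsv(m, out / f"{name}_score_{cname}.tsv")

    checksums = {}
    for name, sd in ds.subjects.items():
        checksums[f"epochs_{name}"] = hashlib.sha256(
            np.ascontiguousarray(sd.epochs.data).tobytes()
        ).hexdigest()
    manifest = {
        "config": _jsonable(config.to_dict()),
        "config_hash": hashlib.sha256(
            json.dumps(_jsonable(config.to_dict()), sort_keys=True).encode()
        ).hexdigest(),
        "stage_checksums": checksums,
        "n_epochs": {n: sd.epochs.n_trials for n, sd in ds.subjects.items()},
        "categories": res.electrode_table["category"].value_counts().to_dict(),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return res


def tiny_config(seed: int = 0) -> RunConfig:
    """1 subject, 8 electrodes, 1 block at reduced trial counts."""
    return RunConfig(
        counts={"omission": 6, "target": 2, "Ba": 12, "Ga": 12},
        n_blocks=1,
        subjects=["S1"],
        n_electrodes_per_subject=8,
        n_grid_per_subject=16,
        seed=seed,
    )


def default_config(seed: int = 0) -> RunConfig:
    """6 subjects, 3 blocks each at the full per-block design counts."""
    return RunConfig(seed=seed)


def make_fixtures(size: str = "tiny", seed: int = 0) -> SimulatedDataset:
    """Build a packaged dataset for the test suite ('tiny' or 'default')."""
    if size == "tiny":
        cfg = tiny_config(seed)
    elif size == "default":
        cfg = default_config(seed)
    else:
        raise ValueError("size must be 'tiny' or 'default'")
    return simulate_dataset(cfg)
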