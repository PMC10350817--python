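# omission-hfa

Analysis pipeline for **high-frequency-activity (HFA) responses to omitted
expected sounds** in intracranial (ECoG) recordings over the superior
temporal gyrus (STG), with a synthetic-data generator standing in for
patient recordings.

When a predictable stream of syllable triplets ("La-La-Ba" alternating
with "La-La-Ga") occasionally omits its third syllable, auditory cortex
produces activity at the moment the sound *should* have occurred.  This
package implements the full analysis chain used to characterize such
omission responses, for researchers in auditory neuroscience and
predictive-coding electrophysiology:

- **paradigm** — triplet stimulus schedules with omissions and "Ta"
  targets (exact per-block counts 19/8/68/68), the expected-omission
  control task, and button-press scoring (hit rate, false alarms,
  median RT).
- **simulate** — synthetic raw recordings at 1200 Hz: 1/f background,
  50/60 Hz-family line noise with outlier channels, and band-limited
  (70–170 Hz) evoked bursts whose amplitude and latency depend on
  electrode class and anterior–posterior position, with exact ground
  truth for parameter-recovery testing.
- **preprocess** — DC correction, zero-phase 0.05 Hz high-pass,
  60/120/180 Hz notches, and common-average referencing with robust
  (median + 10×MAD) line-noise channel exclusion.
- **hfa** — 70–170 Hz band-pass + Hilbert envelope on the continuous
  signal, polyphase resampling 1200→400 Hz, epoching −200..+500 ms
  around (expected) stimulus onsets, baseline normalization.
- **stats** — mass-univariate paired *t* vs. pre-stimulus baseline with
  Benjamini–Hochberg FDR over the pooled electrodes × timepoints family;
  electrode classification; peak latency/amplitude; three linear
  mixed-effects models with subject random intercepts
  (y ~ category, latency ~ category, y ~ omission amplitude).
- **glmcontrast** — the per-timepoint no-intercept condition GLM

  *y* ~ *x*₁ + *x*₂ + *x*₃ + *x*₄ + *x*₅,  *x*ᵢ ∈ {Ba, Ga, OmittedBa, OmittedGa, Ta}

  whose coefficients βᵢ are condition means (disjoint indicators), and
  the CI-scaled **differential score**

  score = (βᵢ − βⱼ) / (CIᵢ + CIⱼ)

  contrasting condition pairs; |score| ≥ 1 marks a coefficient
  difference exceeding the summed 95 % CI half-widths.
- **pipeline** — `RunConfig` (single source of truth for every window,
  band and threshold), end-to-end orchestration, fixtures, and the
  `omission-hfa` CLI.

The numbered scripts under `analysis/` run the study end to end
(`01_simulate_dataset.py` → `05_behavior.py`), writing tables under
`results/`.

## Worked example

```python
from omission_hfa import pipeline

cfg = pipeline.RunConfig(
    subjects=["S1", "S2", "S3"], n_blocks=2,
    n_electrodes_per_subject=12, n_grid_per_subject=24, seed=7,
)
ds = pipeline.simulate_dataset(cfg)     # raw -> preprocessed -> epoched HFA
res = pipeline.analyze_dataset(ds)      # screening, LMEs, GLM contrasts

counts = res.electrode_table["category"].value_counts()
print({str(k): int(v) for k, v in counts.items()})
print(f"posterior shift: {res.lme_position.coef:.1f} mm "
      f"(SE {res.lme_position.se:.1f})")
print(f"latency shift:   {res.lme_latency.coef:.0f} ms "
      f"(SE {res.lme_latency.se:.0f})")
```

prints (seed 7):

```
{'syllable_active': 20, 'both': 12, 'none': 4}
posterior shift: -3.7 mm (SE 2.0)
latency shift:   115 ms (SE 4)
```

meaning: 12 electrodes respond to both heard syllables and omissions,
20 to syllables only; omission-responsive sites lie more posterior on
the Talairach y-axis than syllable-only sites, and their HFA peaks
~115 ms later — both recovering the generator's configured effects
(−6.7 mm, +121 ms) within two standard errors at this small 3-subject
example scale.

The same run from the shell:

```bash
omission-hfa run-all --seed 7 --out-dir results/run
```

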