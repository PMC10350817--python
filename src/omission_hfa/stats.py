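"""Electrode-level statistics: t/FDR screening, classification, peaks, LMEs.

The screening stage runs, for each electrode and response timepoint, a
paired t-test of the across-trial envelope against each trial's own
pre-stimulus baseline mean, then controls the false discovery rate with
Benjamini-Hochberg over the pooled electrodes x timepoints family.
Electrodes are categorized by whether they show significant HFA
*increases* (positive t) to omissions and/or to heard syllables, and three
linear mixed-effects models (subject random intercepts, REML) quantify the
spatial and temporal structure of those categories:

- anterior-posterior position (Talairach y) ~ category
- peak latency ~ category
- Talairach y ~ omission peak amplitude
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from omission_hfa.hfa import EnvelopeEpochs
from omission_hfa.simulate import ElectrodeInfo

CATEGORIES = ("omission_active", "syllable_active", "both", "none")

#: Default condition groups for screening and peak analysis.
GROUPS = {
    "BaGa": ("Ba", "Ga"),
    "Omission": ("OmittedBa", "OmittedGa"),
}


@dataclass
class ElectrodeStats:
    """Per electrode x response-timepoint t/p maps, with optional FDR mask."""

    t: np.ndarray  # channels x timepoints
    p: np.ndarray
    times: np.ndarray  # ms, response timepoints
    electrode_ids: list[str]
    conditions: tuple[str, ...]
    n_trials: int
    zero_variance: np.ndarray | None = None
    mask: np.ndarray | None = None
    alpha: float | None = None


@dataclass
class LMEResult:
    """A single fixed-effect estimate from a random-intercept model."""

    coef: float
    se: float
    pvalue: float
    random_intercept_var: float
    resid_var: float
    n_obs: int
    n_groups: int
    group_sizes: dict[str, int] = field(default_factory=dict)
    converged: bool = True
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "coef": self.coef,
            "se": self.se,
            "pvalue": self.pvalue,
            "random_intercept_var": self.random_intercept_var,
            "resid_var": self.resid_var,
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
            "converged": self.converged,
            "flags": self.flags,
        }


def ttest_vs_baseline(
    ep: EnvelopeEpochs,
    conditions: tuple[str, ...],
    baseline_ms: tuple[float, float] = (-20.0, 0.0),
    response_ms: tuple[float, float] = (0.0, 500.0),
) -> ElectrodeStats:
    """Paired t of each response timepoint vs the per-trial baseline mean.

    For every electrode and timepoint in the response window, the
    across-trial values of (envelope[t] - trial baseline mean) are tested
    against zero.  Baseline and response come from the same trials, so the
    test is paired.  Timepoints with zero across-trial variance are flagged
    and assigned p = 1.
    """
    sel = ep.select(conditions)
    n = sel.n_trials
    if n < 2:
        raise ValueError(f"need >= 2 trials for conditions {conditions}, got {n}")
    bmask = sel.time_mask(baseline_ms)
    rmask = sel.time_mask(response_ms)
    if not bmask.any() or not rmask.any():
        raise ValueError("baseline or response window outside the epoch")
    base = sel.data[:, :, bmask].mean(axis=2)  # trials x channels
    diff = sel.data[:, :, rmask] - base[:, :, None]
    mean = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    zero_var = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[zero_var] = 0.0
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 1)
    p[zero_var] = 1.0
    return ElectrodeStats(
        t=t,
        p=p,
        times=sel.times[rmask],
        electrode_ids=[e.id for e in sel.electrodes],
        conditions=tuple(conditions),
        n_trials=n,
        zero_variance=zero_var,
    )


def fdr_correct(
    pvals: np.ndarray, alpha: float = 0.05, method: str = "fdr_bh"
) -> np.ndarray:
    """Benjamini-Hochberg (or BY) over the pooled family; returns a mask.

    The family is the full collection passed in — for electrode screening
    that is every electrode x timepoint p-value pooled together.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value collection")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p.ravel(), alpha=alpha, method=method)
    return reject.reshape(p.shape)


def screen(
    stats: ElectrodeStats, alpha: float = 0.05, method: str = "fdr_bh"
) -> ElectrodeStats:
    """Attach the FDR mask (pooled electrodes x timepoints) to a t/p map."""
    stats.mask = fdr_correct(stats.p, alpha=alpha, method=method)
    stats.alpha = alpha
    return stats


def _has_increase(stats: ElectrodeStats, min_run: int = 1) -> np.ndarray:
    """Per-electrode flag: any run of >= min_run significant positive-t bins."""
    if stats.mask is None:
        raise ValueError("run screen()/fdr_correct first; mask missing")
    sig = stats.mask & (stats.t > 0)
    if min_run <= 1:
        return sig.any(axis=1)
    out = np.zeros(sig.shape[0], dtype=bool)
    for i, row in enumerate(sig):
        run = 0
        for v in row:
            run = run + 1 if v else 0
            if run >= min_run:
                out[i] = True
                break
    return out


def classify_electrodes(
    omission_stats: ElectrodeStats,
    syllable_stats: ElectrodeStats,
    min_run: int = 1,
) -> np.ndarray:
    """Assign each electrode to omission_active / syllable_active / both / none.

    An electrode is omission-active if any FDR-significant positive-t
    timepoint exists in its omission screening map (analogously for heard
    syllables); the labels returned are mutually exclusive, with ``both``
    marking the intersection.
    """
    if omission_stats.electrode_ids != syllable_stats.electrode_ids:
        raise ValueError("electrode sets differ between the two screening maps")
    om = _has_increase(omission_stats, min_run)
    sy = _has_increase(syllable_stats, min_run)
    out = np.full(om.shape, "none", dtype=object)
    out[om & sy] = "both"
    out[om & ~sy] = "omission_active"
    out[~om & sy] = "syllable_active"
    return out.astype(str)


def peak_analysis(
    ep: EnvelopeEpochs,
    groups: dict[str, tuple[str, ...]] | None = None,
    window_ms: tuple[float, float] = (0.0, 500.0),
) -> pd.DataFrame:
    """Peak latency and amplitude of the trial-averaged envelope.

    For each electrode and condition group, trials are averaged and the
    maximum over the response window gives the amplitude; its time gives
    the latency (ties broken to the earliest timepoint).  Groups with no
    trials are omitted (flagged via the frame's ``attrs['missing_groups']``).
    """
    groups = groups or GROUPS
    mask = ep.time_mask(window_ms)
    if not mask.any():
        raise ValueError("window outside the epoch")
    times = ep.times[mask]
    rows = []
    missing = []
    for name, conds in groups.items():
        sel = ep.select(conds)
        if sel.n_trials == 0:
            missing.append(name)
            continue
        avg = sel.data.mean(axis=0)[:, mask]  # channels x window
        idx = avg.argmax(axis=1)  # first max = earliest tie
        for c, e in enumerate(ep.electrodes):
            rows.append(
                {
                    "electrode": e.id,
                    "subject": e.subject,
                    "y": e.y,
                    "group": name,
                    "latency_ms": float(times[idx[c]]),
                    "amplitude": float(avg[c, idx[c]]),
                    "n_trials": sel.n_trials,
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["missing_groups"] = missing
    return out


# ---------------------------------------------------------------------------
# Linear mixed-effects analyses (subject random intercept, REML, Wald p)


def _fit_lme(df: pd.DataFrame, response: str, predictor: str) -> LMEResult:
    flags: list[str] = []
    n_groups = df["subject"].nunique()
    if n_groups < 2:
        flags.append("degenerate_random_effect: single subject")
    if df[predictor].nunique() < 2:
        flags.append(f"degenerate_predictor: {predictor} is constant")
        return LMEResult(
            coef=float("nan"),
            se=float("nan"),
            pvalue=float("nan"),
            random_intercept_var=float("nan"),
            resid_var=float("nan"),
            n_obs=len(df),
            n_groups=n_groups,
            group_sizes=df["subject"].value_counts().to_dict(),
            converged=False,
            flags=flags,
        )
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = sm.MixedLM(
            endog=df[response].to_numpy(dtype=float),
            exog=sm.add_constant(df[predictor].to_numpy(dtype=float)),
            groups=df["subject"].to_numpy(),
        )
        fit = None
        last_err: Exception | None = None
        # gradient-based optimizers can hit a singular Hessian when the
        # random-intercept variance sits on the boundary; fall back to
        # derivative-free methods
        for method in (None, "powell", "nm"):
            try:
                fit = (
                    model.fit(reml=True)
                    if method is None
                    else model.fit(reml=True, method=method)
                )
                break
            except (np.linalg.LinAlgError, ValueError) as err:
                last_err = err
                flags.append(f"fit_retry[{method or 'default'}]: {err}")
        if fit is None:
            flags.append(f"fit_failed: {last_err}")
            return LMEResult(
                coef=float("nan"),
                se=float("nan"),
                pvalue=float("nan"),
                random_intercept_var=float("nan"),
                resid_var=float("nan"),
                n_obs=len(df),
                n_groups=n_groups,
                group_sizes=df["subject"].value_counts().to_dict(),
                converged=False,
                flags=flags,
            )
    for w in caught:
        if issubclass(w.category, ConvergenceWarning):
            converged = False
            flags.append(f"convergence: {w.message}")
    return LMEResult(
        coef=float(fit.fe_params[1]),
        se=float(fit.bse_fe[1]),
        pvalue=float(fit.pvalues[1]),
        random_intercept_var=float(np.asarray(fit.cov_re)[0, 0]),
        resid_var=float(fit.scale),
        n_obs=len(df),
        n_groups=n_groups,
        group_sizes=df["subject"].value_counts().to_dict(),
        converged=converged,
        flags=flags,
    )


def _omission_indicator(categories: np.ndarray) -> np.ndarray:
    """1 for omission-responsive electrodes (incl. both), 0 for syllable-only,
    NaN for silent electrodes (excluded from the comparison)."""
    cats = np.asarray(categories)
    out = np.full(cats.shape, np.nan)
    out[np.isin(cats, ["omission_active", "both"])] = 1.0
    out[cats == "syllable_active"] = 0.0
    return out


def lme_position(
    categories: np.ndarray, electrodes: list[ElectrodeInfo]
) -> LMEResult:
    """Talairach y ~ category(omission vs syllable) + (1 | subject).

    A negative coefficient means omission-responsive electrodes sit more
    posterior (smaller y) than syllable-only electrodes.
    """
    ind = _omission_indicator(categories)
    df = pd.DataFrame(
        {
            "y": [e.y for e in electrodes],
            "is_omission": ind,
            "subject": [e.subject for e in electrodes],
        }
    ).dropna()
    if df["is_omission"].nunique() < 2:
        raise ValueError("both electrode categories must be represented")
    return _fit_lme(df, "y", "is_omission")


def lme_latency(
    peaks: pd.DataFrame,
    categories: np.ndarray,
    electrodes: list[ElectrodeInfo],
) -> LMEResult:
    """Peak latency ~ category + (1 | subject).

    Each electrode contributes the latency of its own response type:
    omission-group latency for omission-responsive electrodes, Ba/Ga-group
    latency for syllable-only electrodes.  A positive coefficient means
    omission responses peak later.
    """
    ind = {e.id: v for e, v in zip(electrodes, _omission_indicator(categories))}
    rows = []
    for _, r in peaks.iterrows():
        v = ind.get(r["electrode"])
        if v is None or np.isnan(v):
            continue
        want = "Omission" if v == 1.0 else "BaGa"
        if r["group"] != want:
            continue
        rows.append(
            {
                "latency_ms": r["latency_ms"],
                "is_omission": v,
                "subject": r["subject"],
            }
        )
    df = pd.DataFrame(rows)
    if df.empty or df["is_omission"].nunique() < 2:
        raise ValueError("both electrode categories must be represented")
    return _fit_lme(df, "latency_ms", "is_omission")


def lme_amplitude_position(
    peaks: pd.DataFrame,
    electrodes: list[ElectrodeInfo],
    electrode_subset: list[str] | None = None,
) -> LMEResult:
    """Talairach y ~ omission peak amplitude + (1 | subject).

    A negative coefficient means larger omission responses sit more
    posterior.  ``electrode_subset`` restricts the fit (typically to
    omission-responsive electrodes).
    """
    om = peaks[peaks["group"] == "Omission"]
    if electrode_subset is not None:
        om = om[om["electrode"].isin(electrode_subset)]
    if om.empty:
        raise ValueError("no omission peaks available")
    df = om.rename(columns={"amplitude": "omission_amplitude"})[
        ["y", "omission_amplitude", "subject"]
    ]
    return _fit_lme(df, "y", "omission_amplitude")


def two_stage_aggregate(
    values: np.ndarray,
    subjects: np.ndarray,
    within: str = "mean",
    across: str = "median",
) -> tuple[float, pd.Series]:
    """Aggregate electrode-level values within subjects, then across them.

    Mirrors group-level summary conventions for unbalanced electrode
    counts: each subject contributes one number (the ``within`` statistic
    over its electrodes) and the group summary is the ``across`` statistic
    over subjects.  Returns (summary, per-subject series).
    """
    s = pd.Series(np.asarray(values, dtype=float), index=np.asarray(subjects))
    per_subject = s.groupby(level=0).agg(within)
    return float(per_subject.agg(across)), per_subject


def mad(values) -> float:
    """Plain median absolute deviation (no normal consistency scaling)."""
    v = np.asarray(values, dtype=float)
    return float(np.median(np.abs(v - np.median(v))))
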