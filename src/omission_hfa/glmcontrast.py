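"""Condition GLM and the confidence-interval-scaled differential score.

For every electrode and timepoint, the trialwise HFA envelope is regressed
on five mutually exclusive condition indicators (Ba, Ga, OmittedBa,
OmittedGa, Ta) with *no intercept*.  With disjoint indicators this ordinary
least squares fit has a closed form: each coefficient is the condition mean
and its standard error uses the residual variance pooled across conditions.
A coefficient is deemed to affect HFA when its 95% confidence interval
excludes zero.

Two conditions i, j are then contrasted with the differential score

    score = (beta_i - beta_j) / (CI_i + CI_j)

a Fisher-style discriminant: large coefficient differences and tight
confidence intervals both push the score away from zero.  |score| >= 1
means the coefficient difference exceeds the summed CI half-widths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from omission_hfa.hfa import EnvelopeEpochs
from omission_hfa.stats import fdr_correct

#: Fit order of the condition indicators.
CONDITIONS = ("Ba", "Ga", "OmittedBa", "OmittedGa", "Ta")

#: The four published contrast panels.
CONTRASTS = (
    ("Ba", "Ga"),
    ("Ba", "OmittedBa"),
    ("Ga", "OmittedGa"),
    ("OmittedBa", "OmittedGa"),
)


@dataclass
class ConditionGLMResult:
    """Per electrode x timepoint coefficients and CI half-widths."""

    conditions: tuple[str, ...]
    beta: dict[str, np.ndarray]  # condition -> channels x time
    ci: dict[str, np.ndarray]  # half-widths, same shape
    se: dict[str, np.ndarray]
    pvalues: dict[str, np.ndarray]
    n_trials: dict[str, int]
    dof: int
    ci_level: float
    ci_width: str  # "half" or "full" as used in score denominators
    times: np.ndarray
    electrode_ids: list[str]
    excluded_conditions: list[str] = field(default_factory=list)

    def significant(self, condition: str) -> np.ndarray:
        """CI-excludes-zero flag for one condition's coefficients."""
        return np.abs(self.beta[condition]) > self.ci[condition]

    def fdr_mask(self, alpha: float = 0.05) -> dict[str, np.ndarray]:
        """BH mask over the pooled coefficient x electrode x time family."""
        conds = [c for c in self.conditions if c not in self.excluded_conditions]
        stacked = np.stack([self.pvalues[c] for c in conds])
        mask = fdr_correct(stacked, alpha=alpha)
        return {c: mask[k] for k, c in enumerate(conds)}


@dataclass
class DifferentialScoreMap:
    """CI-scaled contrast between two condition coefficients."""

    pair: tuple[str, str]
    score: np.ndarray  # channels x time, NaN where the denominator is 0
    times: np.ndarray
    electrode_ids: list[str]
    n_undefined: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c, eid in enumerate(self.electrode_ids):
            for k, t in enumerate(self.times):
                rows.append(
                    {"electrode": eid, "time_ms": float(t), "score": self.score[c, k]}
                )
        return pd.DataFrame(rows)


def fit_condition_glm(
    ep: EnvelopeEpochs,
    conditions: tuple[str, ...] = CONDITIONS,
    ci_level: float = 0.95,
    ci_width: str = "half",
    window_ms: tuple[float, float] | None = None,
) -> ConditionGLMResult:
    """No-intercept OLS of trial envelopes on condition indicators.

    Computed in closed form, vectorized over electrodes x timepoints:
    with disjoint indicator predictors the design matrix is orthogonal, so
    beta_c is the condition mean and SE_c = s / sqrt(n_c) with the pooled
    residual variance s^2 = SSE / (N - k).  Conditions with fewer than two
    trials are excluded and flagged.
    """
    if not 0 < ci_level < 1:
        raise ValueError("ci_level must lie in (0, 1)")
    if ci_width not in ("half", "full"):
        raise ValueError("ci_width must be 'half' or 'full'")
    if window_ms is not None:
        tmask = ep.time_mask(window_ms)
    else:
        tmask = np.ones_like(ep.times, dtype=bool)
    times = ep.times[tmask]

    included = []
    excluded = []
    n_trials: dict[str, int] = {}
    for c in conditions:
        n = int((ep.conditions == c).sum())
        n_trials[c] = n
        (included if n >= 2 else excluded).append(c)
    if not included:
        raise ValueError("no condition has >= 2 trials")

    n_total = sum(n_trials[c] for c in included)
    k = len(included)
    dof = n_total - k
    if dof < 1:
        raise ValueError("not enough trials for a residual variance estimate")

    beta: dict[str, np.ndarray] = {}
    sse = 0.0
    for c in included:
        x = ep.data[ep.conditions == c][:, :, tmask]  # trials x ch x time
        m = x.mean(axis=0)
        beta[c] = m
        sse = sse + ((x - m[None]) ** 2).sum(axis=0)
    s2 = sse / dof
    tcrit = sps.t.ppf(0.5 + ci_level / 2.0, df=dof)
    width_factor = 1.0 if ci_width == "half" else 2.0

    se: dict[str, np.ndarray] = {}
    ci: dict[str, np.ndarray] = {}
    pvalues: dict[str, np.ndarray] = {}
    for c in included:
        se_c = np.sqrt(s2 / n_trials[c])
        se[c] = se_c
        ci[c] = width_factor * tcrit * se_c
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = np.where(se_c > 0, beta[c] / se_c, 0.0)
        pvalues[c] = 2.0 * sps.t.sf(np.abs(tstat), df=dof)
    return ConditionGLMResult(
        conditions=tuple(conditions),
        beta=beta,
        ci=ci,
        se=se,
        pvalues=pvalues,
        n_trials=n_trials,
        dof=dof,
        ci_level=ci_level,
        ci_width=ci_width,
        times=times,
        electrode_ids=[e.id for e in ep.electrodes],
        excluded_conditions=excluded,
    )


def differential_score(
    res: ConditionGLMResult, i: str, j: str
) -> DifferentialScoreMap:
    """(beta_i - beta_j) / (CI_i + CI_j), elementwise.

    Antisymmetric in (i, j).  Cells with a zero denominator are returned
    as NaN and counted in ``n_undefined`` rather than propagating infinities.
    """
    if i == j:
        raise ValueError("contrast requires two distinct conditions")
    for c in (i, j):
        if c not in res.beta:
            raise ValueError(f"condition {c!r} was not fitted")
    denom = res.ci[i] + res.ci[j]
    num = res.beta[i] - res.beta[j]
    score = np.full_like(num, np.nan)
    ok = denom > 0
    score[ok] = num[ok] / denom[ok]
    return DifferentialScoreMap(
        pair=(i, j),
        score=score,
        times=res.times,
        electrode_ids=res.electrode_ids,
        n_undefined=int((~ok).sum()),
    )


def contrast_suite(
    res: ConditionGLMResult,
    average_window_ms: tuple[float, float] = (0.0, 500.0),
) -> dict[str, DifferentialScoreMap | dict[str, float | np.ndarray]]:
    """The four published condition contrasts, plus time-averaged variants.

    The time-averaged variant (mean score over the response window) serves
    electrodes whose omission responses are temporally diffuse rather than
    sharply time-locked.  Contrasts whose conditions were excluded from the
    fit are reported under ``flags`` instead of raising.
    """
    maps: dict[str, DifferentialScoreMap] = {}
    flags: list[str] = []
    for i, j in CONTRASTS:
        name = f"{i}_vs_{j}"
        if i in res.excluded_conditions or j in res.excluded_conditions:
            flags.append(f"{name}: condition missing from fit")
            continue
        maps[name] = differential_score(res, i, j)
    sel = (res.times >= average_window_ms[0]) & (res.times < average_window_ms[1])
    averaged = {
        name: np.nanmean(m.score[:, sel], axis=1) for name, m in maps.items()
    }
    return {"maps": maps, "time_averaged": averaged, "flags": flags}


def write_score_tsv(m: DifferentialScoreMap, path) -> None:
    m.to_frame().to_csv(path, sep="\t", index=False)


def save_scores_h5(maps: dict[str, DifferentialScoreMap], path) -> None:
    """Write a set of score maps as HDF5 arrays (one dataset per contrast)."""
    import h5py

    with h5py.File(path, "w") as f:
        for name, m in maps.items():
            d = f.create_dataset(name, data=m.score)
            d.attrs["pair"] = ",".join(m.pair)
            d.attrs["n_undefined"] = m.n_undefined
        f.create_dataset("times_ms", data=next(iter(maps.values())).times)
        f.create_dataset(
            "electrodes",
            data=[e.encode() for e in next(iter(maps.values())).electrode_ids],
        )


def load_scores_h5(path) -> dict[str, DifferentialScoreMap]:
    import h5py

    out: dict[str, DifferentialScoreMap] = {}
    with h5py.File(path, "r") as f:
        times = f["times_ms"][...]
        ids = [e.decode() for e in f["electrodes"]]
        for name in f:
            if name in ("times_ms", "electrodes"):
                continue
            d = f[name]
            out[name] = DifferentialScoreMap(
                pair=tuple(d.attrs["pair"].split(",")),
                score=d[...],
                times=times,
                electrode_ids=ids,
                n_undefined=int(d.attrs["n_undefined"]),
            )
    return out
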