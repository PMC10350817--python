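"""Screening statistics, electrode classification, peaks, and LMEs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy import stats as sps

from omission_hfa import simulate, stats
from tests.conftest import synthetic_epochs

# ---------------------------------------------------------------------------
# independent oracles


def bh_stepup_bruteforce(p: np.ndarray, alpha: float) -> np.ndarray:
    """Literal Benjamini-Hochberg: largest k with p_(k) <= k*alpha/m."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    k_star = 0
    for k in range(1, m + 1):
        if sorted_p[k - 1] <= k * alpha / m:
            k_star = k
    mask = np.zeros(m, dtype=bool)
    mask[order[:k_star]] = True
    return mask


def paired_t_bruteforce(diffs: np.ndarray) -> float:
    """Paired t from its definition, one cell at a time."""
    n = diffs.size
    return diffs.mean() / (diffs.std(ddof=1) / np.sqrt(n))


class TestTtestVsBaseline:
    def test_matches_definition_to_1e10(self):
        rng = np.random.default_rng(0)
        ep = synthetic_epochs(rng, {"OmittedBa": 10, "OmittedGa": 10})
        res = stats.ttest_vs_baseline(ep, ("OmittedBa", "OmittedGa"))
        sel = ep.select(("OmittedBa", "OmittedGa"))
        bmask = sel.time_mask((-20, 0))
        rmask = sel.time_mask((0, 500))
        base = sel.data[:, :, bmask].mean(axis=2)
        for c in range(ep.n_channels):
            for k in range(rmask.sum()):
                d = sel.data[:, c, np.flatnonzero(rmask)[k]] - base[:, c]
                assert res.t[c, k] == pytest.approx(
                    paired_t_bruteforce(d), abs=1e-10
                )

    def test_null_data_gives_small_t(self):
        rng = np.random.default_rng(1)
        ep = synthetic_epochs(rng, {"Ba": 40, "Ga": 40})
        res = stats.ttest_vs_baseline(ep, ("Ba", "Ga"))
        # identical response/baseline distribution: |t| stays modest
        assert np.abs(res.t).mean() < 1.5

    def test_constant_offset_gives_positive_t(self):
        rng = np.random.default_rng(2)
        ep = synthetic_epochs(rng, {"Ba": 30})
        ep.data[:, :, ep.time_mask((0, 500))] += 3.0
        res = stats.ttest_vs_baseline(ep, ("Ba",))
        assert (res.t > 0).all()

    def test_zero_variance_flagged_with_p_one(self):
        rng = np.random.default_rng(3)
        ep = synthetic_epochs(rng, {"Ba": 5}, noise_sd=0.0)
        res = stats.ttest_vs_baseline(ep, ("Ba",))
        assert res.zero_variance.all()
        assert (res.p == 1.0).all()

    def test_single_trial_rejected(self):
        rng = np.random.default_rng(4)
        ep = synthetic_epochs(rng, {"Ba": 1})
        with pytest.raises(ValueError):
            stats.ttest_vs_baseline(ep, ("Ba",))


class TestFdrCorrect:
    def test_spec_example_all_rejected(self):
        mask = stats.fdr_correct(np.array([0.01, 0.02, 0.03, 0.04]), alpha=0.05)
        assert mask.all()

    def test_all_ones_none_rejected(self):
        assert not stats.fdr_correct(np.ones(10)).any()

    @given(
        p=hnp.arrays(
            float,
            st.integers(1, 300),
            elements=st.floats(0, 1, allow_nan=False),
        ),
        alpha=st.sampled_from([0.01, 0.05, 0.1]),
    )
    @settings(max_examples=200, deadline=None)
    def test_mask_equals_bruteforce_stepup(self, p, alpha):
        ours = stats.fdr_correct(p, alpha=alpha)
        assert np.array_equal(ours, bh_stepup_bruteforce(p, alpha))

    def test_shape_preserved_for_2d_family(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=(7, 13))
        mask = stats.fdr_correct(p)
        assert mask.shape == p.shape
        assert np.array_equal(mask.ravel(), bh_stepup_bruteforce(p.ravel(), 0.05))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            stats.fdr_correct(np.array([]))


class TestClassifyElectrodes:
    def _stats_with_mask(self, t, mask, ids):
        n_t = t.shape[1]
        return stats.ElectrodeStats(
            t=t,
            p=np.where(mask, 0.001, 0.5),
            times=np.arange(n_t) * 2.5,
            electrode_ids=ids,
            conditions=("x",),
            n_trials=10,
            mask=mask,
            alpha=0.05,
        )

    def test_truth_table(self):
        ids = ["a", "b", "c", "d"]
        t = np.ones((4, 5))
        om_mask = np.zeros((4, 5), bool)
        sy_mask = np.zeros((4, 5), bool)
        om_mask[0, 2] = om_mask[1, 1] = True  # a, b omission-significant
        sy_mask[1, 3] = sy_mask[2, 0] = True  # b, c syllable-significant
        om = self._stats_with_mask(t, om_mask, ids)
        sy = self._stats_with_mask(t, sy_mask, ids)
        cats = stats.classify_electrodes(om, sy)
        assert list(cats) == ["omission_active", "both", "syllable_active", "none"]

    def test_negative_t_does_not_count(self):
        ids = ["a"]
        t = -np.ones((1, 5))
        mask = np.ones((1, 5), bool)
        om = self._stats_with_mask(t, mask, ids)
        sy = self._stats_with_mask(t, np.zeros((1, 5), bool), ids)
        assert stats.classify_electrodes(om, sy)[0] == "none"

    def test_order_invariance(self):
        rng = np.random.default_rng(6)
        ids = [f"e{i}" for i in range(6)]
        t = rng.standard_normal((6, 10))
        m1 = rng.random((6, 10)) < 0.2
        m2 = rng.random((6, 10)) < 0.2
        om = self._stats_with_mask(t, m1, ids)
        sy = self._stats_with_mask(t, m2, ids)
        cats = stats.classify_electrodes(om, sy)
        perm = np.array([3, 1, 4, 0, 5, 2])
        om_p = self._stats_with_mask(t[perm], m1[perm], [ids[i] for i in perm])
        sy_p = self._stats_with_mask(t[perm], m2[perm], [ids[i] for i in perm])
        cats_p = stats.classify_electrodes(om_p, sy_p)
        assert list(cats_p) == [cats[i] for i in perm]

    def test_mismatched_electrodes_rejected(self):
        om = self._stats_with_mask(np.ones((1, 2)), np.ones((1, 2), bool), ["a"])
        sy = self._stats_with_mask(np.ones((1, 2)), np.ones((1, 2), bool), ["b"])
        with pytest.raises(ValueError):
            stats.classify_electrodes(om, sy)

    def test_min_run_requires_consecutive_bins(self):
        ids = ["a", "b"]
        t = np.ones((2, 6))
        mask = np.zeros((2, 6), bool)
        mask[0, [1, 3, 5]] = True  # isolated bins only
        mask[1, [1, 2, 3]] = True  # run of three
        om = self._stats_with_mask(t, mask, ids)
        sy = self._stats_with_mask(t, np.zeros((2, 6), bool), ids)
        cats = stats.classify_electrodes(om, sy, min_run=3)
        assert list(cats) == ["none", "omission_active"]


class TestPeakAnalysis:
    def test_gaussian_bump_latency_and_tie_rule(self):
        rng = np.random.default_rng(7)
        ep = synthetic_epochs(
            rng, {"OmittedBa": 4}, n_channels=2, n_times=220, noise_sd=0.0
        )
        times = ep.times
        bump = np.exp(-0.5 * ((times - 300.0) / 40.0) ** 2)
        ep.data[:, 0, :] = bump
        two_peaks = np.zeros_like(times)
        resp = (times >= 0) & (times < 500)
        two_peaks[np.argmin(np.abs(times - 100.0))] = 1.0
        two_peaks[np.argmin(np.abs(times - 400.0))] = 1.0
        ep.data[:, 1, :] = two_peaks
        pk = stats.peak_analysis(ep, {"Omission": ("OmittedBa",)})
        ch0 = pk[pk.electrode == "e0"].iloc[0]
        ch1 = pk[pk.electrode == "e1"].iloc[0]
        assert ch0["latency_ms"] == pytest.approx(300.0, abs=2.5)
        assert ch1["latency_ms"] == pytest.approx(100.0)  # earliest of the tie
        assert resp.any()

    def test_amplitude_recovers_bump_height(self, tiny_dataset):
        sd = tiny_dataset.subjects["S1"]
        truth = tiny_dataset.truth
        pk = stats.peak_analysis(sd.epochs)
        syl = [
            e.id
            for e in sd.electrodes
            if truth.classes[e.id] != "silent"
        ]
        amp = pk[(pk.group == "BaGa") & pk.electrode.isin(syl)]["amplitude"]
        # trial-averaged peak ~ amp_syllable (log-normal trial gain has
        # mean exp(sigma^2/2) ~ 1.02) on top of a small noise-envelope floor
        assert amp.mean() == pytest.approx(truth.amp_syllable, rel=0.2)

    def test_missing_group_flagged(self):
        rng = np.random.default_rng(8)
        ep = synthetic_epochs(rng, {"Ba": 3})
        pk = stats.peak_analysis(ep)
        assert pk.attrs["missing_groups"] == ["Omission"]
        assert set(pk["group"]) == {"BaGa"}


def _electrodes_from_frame(df):
    return [
        simulate.ElectrodeInfo(r.electrode, r.subject, -55.0, r.y, 5.0)
        for r in df.itertuples()
    ]


class TestLmePosition:
    def _make(self, shift, n_per_subj=20, n_subj=4, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(n_subj):
            subj_off = rng.normal(0, 2.0)
            for i in range(n_per_subj):
                is_om = i < n_per_subj // 2
                rows.append(
                    {
                        "electrode": f"S{s}_e{i}",
                        "subject": f"S{s}",
                        "y": -20.0
                        + subj_off
                        + (shift if is_om else 0.0)
                        + rng.normal(0, 4.0),
                        "cat": "both" if is_om else "syllable_active",
                    }
                )
        df = pd.DataFrame(rows)
        return df["cat"].to_numpy(), _electrodes_from_frame(df)

    def test_null_shift_small_coefficient(self):
        cats, elecs = self._make(0.0, seed=1)
        res = stats.lme_position(cats, elecs)
        assert abs(res.coef) < 3 * res.se
        assert res.pvalue > 0.01

    def test_recovers_posterior_shift(self):
        cats, elecs = self._make(-6.7, n_per_subj=40, n_subj=6, seed=2)
        res = stats.lme_position(cats, elecs)
        assert res.coef == pytest.approx(-6.7, abs=2 * res.se)
        assert res.pvalue < 0.01

    def test_single_subject_flagged(self):
        cats, elecs = self._make(-5.0, n_subj=1, seed=3)
        res = stats.lme_position(cats, elecs)
        assert any("degenerate_random_effect" in f for f in res.flags)

    def test_single_category_rejected(self):
        cats, elecs = self._make(0.0, seed=4)
        with pytest.raises(ValueError):
            stats.lme_position(np.array(["both"] * len(cats)), elecs)


class TestLmeLatency:
    def test_recovers_latency_shift(self):
        rng = np.random.default_rng(9)
        rows = []
        cats = []
        elecs = []
        for s in range(5):
            for i in range(12):
                is_om = i < 5
                cats.append("both" if is_om else "syllable_active")
                e = simulate.ElectrodeInfo(f"S{s}_e{i}", f"S{s}", -55, -20, 5)
                elecs.append(e)
                for group, base in (("BaGa", 160.0), ("Omission", 281.0)):
                    rows.append(
                        {
                            "electrode": e.id,
                            "subject": e.subject,
                            "y": e.y,
                            "group": group,
                            "latency_ms": base + rng.normal(0, 10),
                            "amplitude": 1.0,
                            "n_trials": 20,
                        }
                    )
        peaks = pd.DataFrame(rows)
        res = stats.lme_latency(peaks, np.array(cats), elecs)
        assert res.coef == pytest.approx(121.0, abs=2 * res.se)

    def test_two_stage_aggregate_matches_hand_computation(self):
        # 3-subject toy table: within-subject means then across-subject median
        values = np.array([100.0, 120.0, 200.0, 240.0, 300.0])
        subjects = np.array(["S1", "S1", "S2", "S2", "S3"])
        total, per_subject = stats.two_stage_aggregate(values, subjects)
        assert per_subject["S1"] == pytest.approx(110.0)
        assert per_subject["S2"] == pytest.approx(220.0)
        assert per_subject["S3"] == pytest.approx(300.0)
        assert total == pytest.approx(220.0)  # median of (110, 220, 300)


class TestLmeAmplitudePosition:
    def test_posterior_amplitude_gradient_detected(self):
        rng = np.random.default_rng(10)
        rows = []
        elecs = []
        for s in range(5):
            for i in range(10):
                y = rng.normal(-25, 6)
                e = simulate.ElectrodeInfo(f"S{s}_e{i}", f"S{s}", -55, y, 5)
                elecs.append(e)
                rows.append(
                    {
                        "electrode": e.id,
                        "subject": e.subject,
                        "y": y,
                        "group": "Omission",
                        "latency_ms": 280.0,
                        # amplitude grows toward posterior (smaller y)
                        "amplitude": 1.0 - 0.03 * y + rng.normal(0, 0.05),
                        "n_trials": 19,
                    }
                )
        res = stats.lme_amplitude_position(pd.DataFrame(rows), elecs)
        assert res.coef < 0
        assert res.pvalue < 0.05

    def test_independent_amplitude_null(self):
        rng = np.random.default_rng(11)
        rows = []
        elecs = []
        for s in range(4):
            for i in range(10):
                y = rng.normal(-25, 6)
                e = simulate.ElectrodeInfo(f"S{s}_e{i}", f"S{s}", -55, y, 5)
                elecs.append(e)
                rows.append(
                    {
                        "electrode": e.id,
                        "subject": e.subject,
                        "y": y,
                        "group": "Omission",
                        "latency_ms": 280.0,
                        "amplitude": rng.normal(1.0, 0.2),
                        "n_trials": 19,
                    }
                )
        res = stats.lme_amplitude_position(pd.DataFrame(rows), elecs)
        assert abs(res.coef) < 3 * res.se

    def test_constant_amplitude_flagged(self):
        rows = []
        elecs = []
        for s in range(2):
            for i in range(3):
                e = simulate.ElectrodeInfo(f"S{s}_e{i}", f"S{s}", -55, -20.0 - i, 5)
                elecs.append(e)
                rows.append(
                    {
                        "electrode": e.id,
                        "subject": e.subject,
                        "y": e.y,
                        "group": "Omission",
                        "latency_ms": 280.0,
                        "amplitude": 1.0,
                        "n_trials": 19,
                    }
                )
        res = stats.lme_amplitude_position(pd.DataFrame(rows), elecs)
        assert not res.converged
        assert any("degenerate_predictor" in f for f in res.flags)


class TestMad:
    def test_plain_mad(self):
        assert stats.mad([1.0, 2.0, 3.0, 4.0, 100.0]) == 1.0
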