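"""No-intercept condition GLM and differential-score behavior."""

import numpy as np
import pytest
import statsmodels.api as sm

from omission_hfa import glmcontrast
from tests.conftest import synthetic_epochs

FIVE = {"Ba": 6, "Ga": 5, "OmittedBa": 4, "OmittedGa": 4, "Ta": 3}


class TestFitConditionGlm:
    def test_noiseless_coefficients_are_condition_values(self):
        rng = np.random.default_rng(0)
        ep = synthetic_epochs(
            rng,
            {"Ba": 3, "Ga": 3},
            means={"Ba": 2.0, "Ga": 1.0},
            noise_sd=0.0,
        )
        res = glmcontrast.fit_condition_glm(ep, conditions=("Ba", "Ga"))
        np.testing.assert_allclose(res.beta["Ba"], 2.0)
        np.testing.assert_allclose(res.beta["Ga"], 1.0)

    def test_coefficients_equal_condition_means(self):
        rng = np.random.default_rng(1)
        ep = synthetic_epochs(rng, FIVE)
        res = glmcontrast.fit_condition_glm(ep)
        for c in FIVE:
            expected = ep.data[ep.conditions == c].mean(axis=0)
            np.testing.assert_allclose(res.beta[c], expected, atol=1e-10)

    def test_matches_statsmodels_ols_cell_by_cell(self):
        """Independent route: per-cell OLS on explicit indicator columns."""
        rng = np.random.default_rng(2)
        ep = synthetic_epochs(rng, FIVE, n_channels=2, n_times=6)
        res = glmcontrast.fit_condition_glm(ep)
        conds = list(FIVE)
        X = np.column_stack([(ep.conditions == c).astype(float) for c in conds])
        for ch in (0, 1):
            for k in (0, 3, 5):
                fit = sm.OLS(ep.data[:, ch, k], X).fit()
                ci = fit.conf_int(alpha=0.05)
                for ic, c in enumerate(conds):
                    assert res.beta[c][ch, k] == pytest.approx(
                        fit.params[ic], abs=1e-10
                    )
                    assert res.se[c][ch, k] == pytest.approx(
                        fit.bse[ic], abs=1e-10
                    )
                    half = (ci[ic, 1] - ci[ic, 0]) / 2
                    assert res.ci[c][ch, k] == pytest.approx(half, abs=1e-10)

    def test_ci_shrinks_as_inverse_sqrt_n(self):
        rng = np.random.default_rng(3)
        small = synthetic_epochs(rng, {"Ba": 10, "Ga": 10})
        big = synthetic_epochs(rng, {"Ba": 160, "Ga": 160})
        ci_small = glmcontrast.fit_condition_glm(
            small, conditions=("Ba", "Ga")
        ).ci["Ba"].mean()
        ci_big = glmcontrast.fit_condition_glm(big, conditions=("Ba", "Ga")).ci[
            "Ba"
        ].mean()
        assert ci_small / ci_big == pytest.approx(4.0, rel=0.15)

    def test_sparse_condition_excluded_with_flag(self):
        rng = np.random.default_rng(4)
        ep = synthetic_epochs(rng, {"Ba": 5, "Ga": 5, "Ta": 1})
        res = glmcontrast.fit_condition_glm(ep)
        assert res.excluded_conditions == ["OmittedBa", "OmittedGa", "Ta"]
        assert "Ta" not in res.beta

    def test_significance_is_ci_excluding_zero(self):
        rng = np.random.default_rng(5)
        ep = synthetic_epochs(
            rng, {"Ba": 30, "Ga": 30}, means={"Ba": 5.0}, noise_sd=1.0
        )
        res = glmcontrast.fit_condition_glm(ep, conditions=("Ba", "Ga"))
        assert res.significant("Ba").all()
        assert res.significant("Ga").mean() < 0.2

    def test_fdr_mask_family(self):
        rng = np.random.default_rng(6)
        ep = synthetic_epochs(rng, {"Ba": 20, "Ga": 20}, means={"Ba": 4.0})
        res = glmcontrast.fit_condition_glm(ep, conditions=("Ba", "Ga"))
        mask = res.fdr_mask(alpha=0.05)
        assert set(mask) == {"Ba", "Ga"}
        assert mask["Ba"].mean() > 0.9


class TestDifferentialScore:
    def _result_2x2(self, b_i, b_j, ci_i, ci_j):
        shape = (1, 1)
        return glmcontrast.ConditionGLMResult(
            conditions=("Ba", "Ga"),
            beta={"Ba": np.full(shape, b_i), "Ga": np.full(shape, b_j)},
            ci={"Ba": np.full(shape, ci_i), "Ga": np.full(shape, ci_j)},
            se={"Ba": np.full(shape, ci_i), "Ga": np.full(shape, ci_j)},
            pvalues={"Ba": np.full(shape, 0.5), "Ga": np.full(shape, 0.5)},
            n_trials={"Ba": 5, "Ga": 5},
            dof=8,
            ci_level=0.95,
            ci_width="half",
            times=np.array([0.0]),
            electrode_ids=["e0"],
        )

    def test_direct_arithmetic(self):
        res = self._result_2x2(2.0, 1.0, 0.5, 0.5)
        m = glmcontrast.differential_score(res, "Ba", "Ga")
        assert m.score[0, 0] == pytest.approx(1.0)

    def test_antisymmetry_exact(self):
        rng = np.random.default_rng(7)
        ep = synthetic_epochs(rng, FIVE)
        res = glmcontrast.fit_condition_glm(ep)
        ab = glmcontrast.differential_score(res, "Ba", "OmittedBa")
        ba = glmcontrast.differential_score(res, "OmittedBa", "Ba")
        np.testing.assert_array_equal(ab.score, -ba.score)

    def test_scale_invariance(self):
        rng = np.random.default_rng(8)
        ep = synthetic_epochs(rng, FIVE)
        res1 = glmcontrast.fit_condition_glm(ep)
        ep.data *= 37.0
        res2 = glmcontrast.fit_condition_glm(ep)
        s1 = glmcontrast.differential_score(res1, "Ba", "Ga").score
        s2 = glmcontrast.differential_score(res2, "Ba", "Ga").score
        np.testing.assert_allclose(s1, s2, rtol=1e-10)

    def test_identical_conditions_score_near_zero(self):
        rng = np.random.default_rng(9)
        ep = synthetic_epochs(rng, {"Ba": 40, "Ga": 40}, n_times=100)
        res = glmcontrast.fit_condition_glm(ep, conditions=("Ba", "Ga"))
        s = glmcontrast.differential_score(res, "Ba", "Ga").score
        assert np.abs(s).mean() < 0.5
        assert (np.abs(s) >= 1.0).mean() <= 0.05

    def test_zero_denominator_flagged_not_infinite(self):
        res = self._result_2x2(2.0, 1.0, 0.0, 0.0)
        m = glmcontrast.differential_score(res, "Ba", "Ga")
        assert np.isnan(m.score[0, 0])
        assert m.n_undefined == 1

    def test_same_condition_rejected(self):
        res = self._result_2x2(2.0, 1.0, 0.5, 0.5)
        with pytest.raises(ValueError):
            glmcontrast.differential_score(res, "Ba", "Ba")


class TestContrastSuite:
    def test_four_named_maps(self):
        rng = np.random.default_rng(10)
        ep = synthetic_epochs(rng, FIVE)
        suite = glmcontrast.contrast_suite(glmcontrast.fit_condition_glm(ep))
        assert set(suite["maps"]) == {
            "Ba_vs_Ga",
            "Ba_vs_OmittedBa",
            "Ga_vs_OmittedGa",
            "OmittedBa_vs_OmittedGa",
        }
        assert suite["flags"] == []

    def test_identical_conditions_all_maps_near_zero(self):
        rng = np.random.default_rng(11)
        ep = synthetic_epochs(rng, {c: 30 for c in FIVE}, n_times=100)
        suite = glmcontrast.contrast_suite(glmcontrast.fit_condition_glm(ep))
        for m in suite["maps"].values():
            assert np.abs(m.score).mean() < 0.5

    def test_time_average_is_mean_of_map(self):
        rng = np.random.default_rng(12)
        ep = synthetic_epochs(rng, FIVE, n_times=60)
        suite = glmcontrast.contrast_suite(
            glmcontrast.fit_condition_glm(ep), average_window_ms=(0, 500)
        )
        m = suite["maps"]["Ba_vs_Ga"]
        sel = (m.times >= 0) & (m.times < 500)
        np.testing.assert_allclose(
            suite["time_averaged"]["Ba_vs_Ga"],
            m.score[:, sel].mean(axis=1),
        )

    def test_missing_condition_yields_partial_suite(self):
        rng = np.random.default_rng(13)
        ep = synthetic_epochs(rng, {"Ba": 5, "Ga": 5, "OmittedBa": 5})
        suite = glmcontrast.contrast_suite(glmcontrast.fit_condition_glm(ep))
        assert "Ba_vs_Ga" in suite["maps"]
        assert "Ga_vs_OmittedGa" not in suite["maps"]
        assert any("OmittedGa" in f for f in suite["flags"])

    def test_score_tsv_export(self, tmp_path):
        rng = np.random.default_rng(14)
        ep = synthetic_epochs(rng, FIVE, n_channels=1, n_times=3)
        res = glmcontrast.fit_condition_glm(ep)
        m = glmcontrast.differential_score(res, "Ba", "Ga")
        path = tmp_path / "score.tsv"
        glmcontrast.write_score_tsv(m, path)
        header = path.read_text().splitlines()[0].split("\t")
        assert header == ["electrode", "time_ms", "score"]

    def test_score_h5_round_trip(self, tmp_path):
        rng = np.random.default_rng(15)
        ep = synthetic_epochs(rng, FIVE, n_channels=2, n_times=5)
        suite = glmcontrast.contrast_suite(glmcontrast.fit_condition_glm(ep))
        path = tmp_path / "scores.h5"
        glmcontrast.save_scores_h5(suite["maps"], path)
        back = glmcontrast.load_scores_h5(path)
        assert set(back) == set(suite["maps"])
        for name, m in suite["maps"].items():
            np.testing.assert_allclose(back[name].score, m.score)
            assert back[name].pair == m.pair
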