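"""Modified t-test, Z transformation and covariate-adjusted single-case tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ppaudit.singlecase import (CrawfordDeficitModel, adjusted_singlecase,
                                crawford_t, p_to_z, select_covariates,
                                single_case_table, z_threshold)


class TestCrawfordT:
    def test_closed_form_example(self):
        # oracle: t = 10 / (5 sqrt(29/28)) and the t27 upper tail
        t, df, p = crawford_t(60.0, 50.0, 5.0, 28)
        t_expected = 10.0 / (5.0 * np.sqrt(29.0 / 28.0))
        assert t == pytest.approx(t_expected)
        assert t == pytest.approx(1.965, abs=5e-4)
        assert df == 27
        assert p == pytest.approx(stats.t.sf(t_expected, 27))
        assert p == pytest.approx(0.030, abs=1e-3)

    def test_case_at_control_mean(self):
        t, _, p = crawford_t(50.0, 50.0, 5.0, 28)
        assert t == 0.0
        assert p == pytest.approx(0.5)
        assert p_to_z(p) == pytest.approx(0.0)

    def test_large_n_limit_is_plain_z(self):
        t, _, _ = crawford_t(60.0, 50.0, 5.0, 10**6)
        assert t == pytest.approx(2.0, abs=1e-4)

    def test_deficit_direction_sign_convention(self):
        # a worse case is z > 0 whether 'worse' means higher or lower
        _, _, p_hi = crawford_t(60.0, 50.0, 5.0, 28, higher_worse=True)
        _, _, p_lo = crawford_t(25.0, 35.0, 3.0, 28, higher_worse=False)
        assert p_to_z(p_hi) > 0
        assert p_to_z(p_lo) > 0
        # a better-than-controls case lands on the other tail
        _, _, p_good = crawford_t(40.0, 50.0, 5.0, 28, higher_worse=True)
        assert p_to_z(p_good) < 0

    def test_degenerate_norms_rejected(self):
        with pytest.raises(ValueError):
            crawford_t(1.0, 0.0, 0.0, 28)
        with pytest.raises(ValueError):
            crawford_t(1.0, 0.0, 1.0, 1)

    def test_type_one_error_calibration(self):
        """Null patients drawn from the control distribution are flagged at
        the nominal 5% rate (the defining property of the modified t)."""
        rng = np.random.default_rng(123)
        n_sim, n_ctrl = 2000, 28
        ctrl = rng.normal(size=(n_sim, n_ctrl))
        pats = rng.normal(size=n_sim)
        rate = 0
        mu = ctrl.mean(axis=1)
        sd = ctrl.std(axis=1, ddof=1)
        for i in range(n_sim):
            _, _, p = crawford_t(pats[i], mu[i], sd[i], n_ctrl)
            rate += p < 0.05
        assert rate / n_sim == pytest.approx(0.05, abs=0.015)


class TestZTransform:
    def test_bonferroni_z_values(self):
        assert z_threshold(0.05, 12) == pytest.approx(2.64, abs=5e-3)
        assert z_threshold(0.05, 1) == pytest.approx(1.645, abs=5e-4)
        assert z_threshold(0.5, 1) == 0.0

    def test_p_to_z_matches_quantile(self):
        assert p_to_z(0.05 / 12) == pytest.approx(2.6383, abs=1e-4)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(min_value=-5.0, max_value=5.0))
    def test_roundtrip_identity(self, z):
        assert p_to_z(stats.norm.sf(z)) == pytest.approx(z, abs=1e-10)

    def test_invalid_p_rejected(self):
        for bad in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                p_to_z(bad)


class TestAdjustedSingleCase:
    def _controls(self, seed=0, n=28, slope=0.0):
        rng = np.random.default_rng(seed)
        x = rng.uniform(50, 80, n)
        y = 10.0 + slope * x + rng.normal(0, 2.0, n)
        return x, y

    def test_patient_on_regression_line(self):
        x, y = self._controls(slope=0.5)
        beta = np.polyfit(x, y, 1)
        x_star = 65.0
        y_star = float(np.polyval(beta, x_star))
        t, df, p = adjusted_singlecase(y_star, [x_star], y, x[:, None])
        assert t == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(0.5, abs=1e-9)
        assert df == len(y) - 2

    def test_zero_slope_covariate_agrees_with_crawford(self):
        """With an uninformative covariate the adjusted t tracks the plain
        modified t (df differs by the number of covariates)."""
        ts_adj, ts_raw = [], []
        for s in range(60):
            x, y = self._controls(seed=s, slope=0.0)
            u = np.random.default_rng(1000 + s).uniform(-2.0, 3.0)
            y_star = y.mean() + u * y.std(ddof=1)
            t_adj, df_adj, _ = adjusted_singlecase(y_star, [x.mean()], y, x[:, None])
            t_raw, df_raw, _ = crawford_t(y_star, y.mean(), y.std(ddof=1), len(y))
            ts_adj.append(t_adj)
            ts_raw.append(t_raw)
            assert df_raw - df_adj == 1
        assert np.corrcoef(ts_adj, ts_raw)[0, 1] > 0.99
        assert np.mean(ts_adj) == pytest.approx(np.mean(ts_raw), rel=0.05)

    def test_extreme_covariate_leverage_shrinks_t(self):
        x, y = self._controls(slope=0.5)
        dev = 8.0
        ts = []
        for x_star in (65.0, 95.0, 140.0):
            beta = np.polyfit(x, y, 1)
            y_star = float(np.polyval(beta, x_star)) + dev
            t, _, _ = adjusted_singlecase(y_star, [x_star], y, x[:, None])
            ts.append(abs(t))
        assert ts[0] > ts[1] > ts[2]

    def test_missing_patient_covariate_rejected(self):
        x, y = self._controls()
        with pytest.raises(ValueError, match="missing"):
            adjusted_singlecase(10.0, [np.nan], y, x[:, None])

    def test_rank_deficiency_rejected(self):
        x, y = self._controls()
        X = np.column_stack([x, x])  # duplicated covariate
        with pytest.raises(ValueError):
            adjusted_singlecase(10.0, [65.0, 65.0], y, X)


class TestCovariateSelection:
    def _cohort(self, seed=0, n=28, coupled=True):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({"age": rng.uniform(50, 80, n),
                           "cpm": rng.normal(30, 4, n)})
        for task in ("p1", "p2"):
            noise = rng.normal(size=n)
            df[task] = noise
        if coupled:
            df["p2"] = -0.2 * df["cpm"] + rng.normal(0, 0.3, n)
        return df

    def test_strong_covariate_selected(self):
        df = self._cohort(coupled=True)
        sel = select_covariates(df, ["age", "cpm"], outcomes=["p1", "p2"])
        assert "cpm" in sel

    def test_constant_candidate_warned_and_excluded(self):
        df = self._cohort()
        df["edu"] = 12.0
        with pytest.warns(UserWarning, match="constant"):
            sel = select_covariates(df, ["edu"], outcomes=["p1"])
        assert sel == []

    def test_collinear_candidates_rejected(self):
        df = self._cohort()
        df["age2"] = df["age"] * 2.0
        with pytest.raises(ValueError, match="collinear"):
            select_covariates(df, ["age", "age2"], outcomes=["p1"])


class TestResultTableAndModel:
    def _cohort(self, seed=1):
        from ppaudit.cohort import generate_cohort

        cohort, _ = generate_cohort(seed=seed)
        return cohort

    def test_bonferroni_consistency(self):
        cohort = self._cohort()
        table = single_case_table(cohort)
        zc = z_threshold(0.05, 12)
        flagged = table["impaired_bonferroni"]
        assert (flagged == (table["p_one_tailed"] < 0.05 / 12)).all()
        assert (flagged == (table["z"] > zc)).all()

    def test_adjusted_rows_present_with_covariates(self):
        cohort = self._cohort()
        table = single_case_table(cohort, covariates=["age", "cpm"])
        assert set(table["adjusted"].unique()) == {False, True}
        raw = table[~table["adjusted"]]
        assert len(raw) == 18 * 12

    def test_estimator_api_matches_functions(self):
        cohort = self._cohort()
        ctrl = cohort[cohort.group == "control"]
        pats = cohort[cohort.group != "control"]
        cols = ["p1", "p3", "r4"]
        model = CrawfordDeficitModel().fit(ctrl[cols])
        z = model.z_scores(pats[cols])
        t, _, p = crawford_t(pats["p1"].to_numpy(), ctrl["p1"].mean(),
                             ctrl["p1"].std(ddof=1), len(ctrl))
        assert np.allclose(z["p1"].to_numpy(), stats.norm.isf(p))
        flags = model.predict(pats[cols])
        assert flags.shape == z.shape
        # sklearn parameter plumbing
        assert CrawfordDeficitModel(**model.get_params()).get_params() == \
            model.get_params()
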