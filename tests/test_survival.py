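"""Survival stage: product-limit, cumulative events, Cox partial likelihood."""

import numpy as np
import pandas as pd
import pytest

from cardiolens import survival as sv
from cardiolens.synthgen import simulate_survival


def make_data(time, event, **cols):
    n = len(time)
    covs = pd.DataFrame(cols if cols else None, index=range(n))
    return sv.SurvivalData(time=np.asarray(time, dtype=float),
                           event=np.asarray(event), covariates=covs)


class TestKaplanMeier:
    def test_no_events_flat_curve(self):
        km = sv.km_estimate(make_data([1, 2, 3], [0, 0, 0]))["0.0"]
        assert km.probability_at(3.0) == 1.0

    def test_hand_product_limit(self):
        km = sv.km_estimate(make_data([1, 2, 3, 4, 5], [1, 1, 0, 1, 0]))["0.0"]
        assert km.probability_at(1) == pytest.approx(0.8)
        assert km.probability_at(2) == pytest.approx(0.6)
        assert km.probability_at(4) == pytest.approx(0.3)

    def test_all_events_at_first_step(self):
        km = sv.km_estimate(make_data([0.01] * 4, [1] * 4))["0.0"]
        assert km.probability_at(0.02) == 0.0

    def test_matches_hand_product_limit_random(self):
        rng = np.random.default_rng(0)
        t = np.round(rng.uniform(0.5, 5, 10), 1)
        e = rng.integers(0, 2, 10)
        km = sv.km_estimate(make_data(t, e))["0.0"]
        # independent product-limit computation
        s = 1.0
        order = np.argsort(t)
        surv_at = {}
        at_risk = len(t)
        for i, idx in enumerate(order):
            d = sum((t == t[idx]) & (e == 1))
            n_r = sum(t >= t[idx])
            if t[idx] not in surv_at:
                if d > 0:
                    s *= (1 - d / n_r)
                surv_at[t[idx]] = s
        for tt, ss in surv_at.items():
            assert km.probability_at(tt) == pytest.approx(ss)

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            make_data([-1, 2], [1, 0])


class TestCumulativeEvents:
    def test_no_events_flat_zero(self):
        times, frac = sv.cumulative_events(make_data([1, 2], [0, 0]))
        assert frac.max() == 0.0

    def test_terminal_value_is_event_fraction(self):
        """A 3.34% mortality cohort ends at cumulative fraction 0.0334."""
        n = 155_435
        n_dead = 5196
        time = np.linspace(0.1, 7.0, n)
        event = np.zeros(n, dtype=int)
        event[:n_dead] = 1
        _, frac = sv.cumulative_events(make_data(time, event))
        assert frac[-1] == pytest.approx(n_dead / n)
        assert frac[-1] == pytest.approx(0.0334, abs=5e-5)

    def test_duplication_invariance(self):
        t = [1.0, 2.0, 3.0]
        e = [1, 0, 1]
        t1, f1 = sv.cumulative_events(make_data(t, e))
        t2, f2 = sv.cumulative_events(make_data(t * 2, e * 2))
        np.testing.assert_array_equal(t1, t2)
        np.testing.assert_allclose(f1, f2)

    def test_curve_nondecreasing(self):
        rng = np.random.default_rng(1)
        t = rng.uniform(0, 7, 100)
        e = rng.integers(0, 2, 100)
        _, frac = sv.cumulative_events(make_data(t, e))
        assert np.all(np.diff(frac) >= 0)


class TestCoxFit:
    def test_grid_search_oracle_six_subjects(self):
        """Newton solution matches brute-force partial-likelihood grid search."""
        time = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        event = [1, 0, 1, 1, 0, 1]
        x = np.array([1.0, 1.0, 0.0, 1.0, 0.0, 0.0])
        data = make_data(time, event, a=x)
        fit = sv.cox_fit(data, ["a"])

        def neg_pl(beta):  # no ties -> plain partial likelihood
            ll = 0.0
            for i in range(6):
                if event[i]:
                    risk = [j for j in range(6) if time[j] >= time[i]]
                    ll += beta * x[i] - np.log(sum(np.exp(beta * x[j])
                                                   for j in risk))
            return -ll

        grid = np.arange(-3, 3, 1e-4)
        best = grid[np.argmin([neg_pl(b) for b in grid])]
        assert fit["a"].beta == pytest.approx(best, abs=1e-3)

    def test_independent_covariate_null(self):
        rng = np.random.default_rng(2)
        n = 50_000
        x = rng.binomial(1, 0.4, n).astype(float)
        t, e = simulate_survival(np.zeros((n, 1)), np.zeros(1), 0.03, seed=3)
        fit = sv.cox_fit(make_data(t, e, a=x), ["a"])
        assert abs(fit["a"].beta) < 0.05

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            sv.cox_fit(make_data([1, 2], [0, 0], a=[0.0, 1.0]))

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError):
            sv.cox_fit(make_data([1, 2, 3], [1, 1, 0], a=[1.0, 1.0, 1.0]))

    def test_matches_lifelines_with_ties(self):
        """Independent implementation check against lifelines (Efron ties)."""
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(3)
        n = 500
        x1 = rng.binomial(1, 0.3, n).astype(float)
        x2 = rng.normal(0, 1, n)
        t, e = simulate_survival(np.column_stack([x1, x2]),
                                 np.array([0.6, 0.2]), 0.05, seed=4)
        t = np.ceil(t * 2) / 2  # year-granularity ties
        fit = sv.cox_fit(make_data(t, e, a=x1, b=x2))
        df = pd.DataFrame({"a": x1, "b": x2, "T": t, "E": e})
        cph = CoxPHFitter().fit(df, "T", "E")
        for c in ("a", "b"):
            assert fit[c].beta == pytest.approx(cph.params_[c], abs=1e-5)
            assert fit[c].se == pytest.approx(cph.standard_errors_[c], abs=1e-5)
        assert fit.log_likelihood == pytest.approx(cph.log_likelihood_, abs=1e-4)

    def test_complemented_flag_inverts_hr(self):
        rng = np.random.default_rng(4)
        n = 2000
        x = rng.binomial(1, 0.4, n).astype(float)
        t, e = simulate_survival(x[:, None], np.array([0.5]), 0.05, seed=5)
        hr = sv.cox_fit(make_data(t, e, a=x), ["a"])["a"].hr
        hr_c = sv.cox_fit(make_data(t, e, a=1 - x), ["a"])["a"].hr
        assert hr_c == pytest.approx(1 / hr, rel=1e-6)

    def test_breslow_close_to_efron_sparse_ties(self):
        rng = np.random.default_rng(5)
        n = 400
        x = rng.binomial(1, 0.5, n).astype(float)
        t, e = simulate_survival(x[:, None], np.array([0.7]), 0.05, seed=6)
        data = make_data(t, e, a=x)
        b_efron = sv.cox_fit(data, ties="efron")["a"].beta
        b_breslow = sv.cox_fit(data, ties="breslow")["a"].beta
        # continuous times: no ties, the two likelihoods coincide
        assert b_efron == pytest.approx(b_breslow, abs=1e-9)

    def test_large_n_recovery_with_events_rate(self):
        """Planted log-HR recovered at n=20,000 (10-replicate average)."""
        betas = []
        for rep in range(10):
            rng = np.random.default_rng(100 + rep)
            n = 20_000
            x = rng.binomial(1, 0.32, n).astype(float)
            t, e = simulate_survival(x[:, None], np.array([np.log(1.7)]),
                                     0.006, seed=200 + rep)
            assert e.mean() >= 0.02
            betas.append(sv.cox_fit(make_data(t, e, a=x), ["a"])["a"].beta)
        assert abs(np.mean(betas) - np.log(1.7)) < 0.05 * np.log(1.7)


class TestHazardRatios:
    def _cohort(self):
        rng = np.random.default_rng(6)
        n = 4000
        age = rng.normal(0, 10, n)
        male = rng.binomial(1, 0.4, n).astype(float)
        hyp = rng.binomial(1, 0.32, n).astype(float)
        x = np.column_stack([age, male, hyp])
        t, e = simulate_survival(x, np.array([0.03, 0.3, 0.5]), 0.02, seed=7)
        return make_data(t, e, age=age, is_male=male, hypertension=hyp)

    def test_table_has_requested_rows(self):
        table = sv.hazard_ratios(self._cohort(), mode="adjusted",
                                 covariates=["hypertension", "is_male"])
        assert list(table.index) == ["hypertension", "is_male"]
        assert (table["HR"] > 0).all()

    def test_univariate_equals_single_fits(self):
        data = self._cohort()
        table = sv.hazard_ratios(data, mode="univariate",
                                 covariates=["hypertension"])
        solo = sv.cox_fit(data, ["hypertension"])["hypertension"]
        assert table.loc["hypertension", "HR"] == pytest.approx(solo.hr)

    def test_adjusted_with_empty_set_falls_back_to_univariate(self):
        data = self._cohort()
        adj = sv.hazard_ratios(data, mode="adjusted",
                               covariates=["hypertension"], adjustment=())
        uni = sv.hazard_ratios(data, mode="univariate",
                               covariates=["hypertension"])
        assert adj.loc["hypertension", "HR"] == \
            pytest.approx(uni.loc["hypertension", "HR"])

    def test_invalid_mode_rejected(self):
        with pytest.raises(ValueError):
            sv.hazard_ratios(self._cohort(), mode="bogus")
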