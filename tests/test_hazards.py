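import subprocess
import sys
import warnings

import numpy as np
import pandas as pd
import pytest

import lifescore as ls
from lifescore.codebook import FactorCodebook, FactorSpec
from lifescore.hazards import (
    HazardEstimate,
    _censoring_survival,
    cumulative_hazard,
    direction_from_ci,
    estimates_frame,
    estimates_from_frame,
    fit_factor_cox,
    fit_finegray,
)


def _binary_cb(name="factor_x"):
    return FactorCodebook(
        [FactorSpec(name, "binary", {"kind": "bernoulli", "p": 0.5}, 0.0,
                    {"kind": "equals", "value": 1})]
    )


def efron_neg_loglik(beta, time, event, x):
    """Independent Efron-tie partial likelihood (literal textbook form)."""
    ll = 0.0
    for t in np.unique(time[event == 1]):
        D = np.flatnonzero((time == t) & (event == 1))
        R = np.flatnonzero(time >= t)
        r_sum = np.exp(beta * x[R]).sum()
        d_sum = np.exp(beta * x[D]).sum()
        m = len(D)
        ll += beta * x[D].sum()
        for l in range(m):
            ll -= np.log(r_sum - (l / m) * d_sum)
    return -ll


class TestCoxOracle:
    def test_small_n_coefficient_matches_bruteforce(self, survival_frame_factory):
        from scipy.optimize import minimize_scalar

        rng = np.random.default_rng(5)
        df = survival_frame_factory(rng, 30, beta=0.8)
        # introduce ties to exercise the Efron correction
        df["event_time"] = np.round(df["event_time"], 1).clip(lower=0.1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = fit_factor_cox(df, "factor_x", _binary_cb(), adjustment=())[0]
        res = minimize_scalar(
            efron_neg_loglik,
            bounds=(-4, 4),
            method="bounded",
            args=(df["event_time"].to_numpy(), df["ckd_event"].to_numpy(),
                  df["factor_x"].to_numpy(dtype=float)),
            options={"xatol": 1e-10},
        )
        assert np.log(est.hr) == pytest.approx(res.x, abs=1e-4)

    def test_hr_invariant_to_time_rescaling(self, survival_frame_factory):
        rng = np.random.default_rng(6)
        df = survival_frame_factory(rng, 300, beta=0.4)
        days = df.copy()
        days["event_time"] = days["event_time"] * 365.25
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = fit_factor_cox(df, "factor_x", _binary_cb())[0]
            b = fit_factor_cox(days, "factor_x", _binary_cb())[0]
        assert np.log(a.hr) == pytest.approx(np.log(b.hr), abs=1e-6)

    def test_single_level_factor_rejected(self, survival_frame_factory):
        rng = np.random.default_rng(7)
        df = survival_frame_factory(rng, 50)
        df["factor_x"] = 1
        with pytest.raises(ValueError, match="levels"):
            fit_factor_cox(df, "factor_x", _binary_cb())

    def test_separation_yields_flagged_indeterminate(self):
        # exposure perfectly predicts early events -> monotone likelihood
        n = 24
        df = pd.DataFrame(
            {
                "factor_x": [1] * 12 + [0] * 12,
                "age": 57.0,
                "sex": ["male"] * n,
                "event_time": list(np.linspace(0.1, 1.2, 12)) + [5.0] * 12,
                "ckd_event": [1] * 12 + [0] * 12,
            }
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = fit_factor_cox(df, "factor_x", _binary_cb(), adjustment=())[0]
        assert est.flagged or est.ci_high > 1e3 or not np.isfinite(est.ci_high)
        if est.flagged:
            assert est.direction == "indeterminate"


class TestDirections:
    @pytest.mark.parametrize(
        "hr,lo,hi,expected",
        [
            (0.77, 0.74, 0.79, "healthy"),
            (1.36, 1.31, 1.41, "unhealthy"),
            (1.06, 0.99, 1.13, "indeterminate"),
            (0.66, 0.62, 0.69, "healthy"),
        ],
    )
    def test_ci_rule(self, hr, lo, hi, expected):
        assert direction_from_ci(hr, lo, hi) == expected
        est = HazardEstimate("f", "exposed", hr, lo, hi, 0.01)
        assert est.direction == expected

    def test_inconsistent_interval_rejected(self):
        with pytest.raises(ValueError):
            HazardEstimate("f", "exposed", 1.5, 1.6, 1.7, 0.01)

    def test_polytomous_direction_from_highest_level(self):
        ests = [
            HazardEstimate("meat", "once_wk", 1.02, 0.95, 1.10, 0.5),
            HazardEstimate("meat", "daily_plus", 1.40, 1.31, 1.50, 1e-5),
        ]
        assert ls.assign_direction(ests) == {"meat": "unhealthy"}

    def test_round_trip_through_frame(self):
        ests = [
            HazardEstimate("a", "exposed", 0.8, 0.7, 0.9, 0.01),
            HazardEstimate("b", "exposed", np.nan, np.nan, np.nan, np.nan, flagged=True),
        ]
        back = estimates_from_frame(estimates_frame(ests))
        assert back[0].direction == "healthy"
        assert back[1].flagged and back[1].direction == "indeterminate"


class TestFineGray:
    def _competing_frame(self, rng, n=300, beta=0.5, death_rate=0.6):
        x = rng.integers(0, 2, n)
        age = rng.normal(57, 8, n)
        male = rng.integers(0, 2, n)
        t_ckd = rng.exponential(1.0, n) * np.exp(-beta * x)
        t_death = rng.exponential(1.0 / death_rate, n)
        cens = rng.uniform(0.3, 3.0, n)
        time = np.minimum(np.minimum(t_ckd, t_death), cens)
        status = np.select(
            [t_ckd <= np.minimum(t_death, cens), t_death <= np.minimum(t_ckd, cens)],
            [1, 2], default=0,
        )
        return pd.DataFrame(
            {
                "factor_x": x, "age": age,
                "sex": np.where(male == 1, "male", "female"),
                "event_time": time,
                "ckd_event": (status == 1).astype(int),
                "event_type": np.select([status == 1, status == 2],
                                        ["ckd", "death"], default="censored"),
            }
        )

    def test_reduces_to_cause_specific_without_competing_events(self, survival_frame_factory):
        rng = np.random.default_rng(8)
        df = survival_frame_factory(rng, 250, beta=0.5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with pytest.warns(UserWarning, match="no competing events"):
                fg = fit_finegray(df, "factor_x", _binary_cb())[0]
            cs = fit_factor_cox(df, "factor_x", _binary_cb())[0]
        assert np.log(fg.hr) == pytest.approx(np.log(cs.hr), abs=1e-6)

    def test_competing_mortality_on_exposed_arm_shrinks_subdistribution_hr(self):
        """Exposed-arm deaths remove CKD opportunity: FG HR < cause-specific HR."""
        rng = np.random.default_rng(9)
        n = 4000
        x = rng.integers(0, 2, n)
        t_ckd = rng.exponential(2.0, n) * np.exp(-0.3 * x)
        t_death = np.where(x == 1, rng.exponential(0.7, n), rng.exponential(20.0, n))
        cens = np.full(n, 3.0)
        time = np.minimum(np.minimum(t_ckd, t_death), cens)
        status = np.select(
            [t_ckd <= np.minimum(t_death, cens), t_death <= np.minimum(t_ckd, cens)],
            [1, 2], default=0,
        )
        df = pd.DataFrame(
            {
                "factor_x": x, "age": 57.0, "sex": "male",
                "event_time": time,
                "ckd_event": (status == 1).astype(int),
                "event_type": np.select([status == 1, status == 2],
                                        ["ckd", "death"], default="censored"),
            }
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fg = fit_finegray(df, "factor_x", _binary_cb(), adjustment=())[0]
            cs = fit_factor_cox(df, "factor_x", _binary_cb(), adjustment=())[0]
        assert fg.hr < cs.hr

    def test_censoring_weights_match_hand_kaplan_meier(self):
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        status = np.array([1, 0, 2, 0, 1, 0])
        g = _censoring_survival(time, status)
        # KM of censoring: drops at t=2 (5 at risk) and t=4 (3 at risk)
        np.testing.assert_allclose(g(np.array([2.0])), [1.0])        # left limit
        np.testing.assert_allclose(g(np.array([2.5])), [1 - 1 / 5])
        np.testing.assert_allclose(g(np.array([4.5])), [(1 - 1 / 5) * (1 - 1 / 3)])

    def test_matches_r_cmprsk_reference(self, tmp_path):
        rng = np.random.default_rng(10)
        df = self._competing_frame(rng, n=150)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fg = fit_finegray(df, "factor_x", _binary_cb(), adjustment=())[0]
        fixture = tmp_path / "fg.csv"
        status = np.select(
            [df["event_type"] == "ckd", df["event_type"] == "death"], [1, 2], default=0
        )
        pd.DataFrame({"time": df["event_time"], "status": status, "x": df["factor_x"]}).to_csv(
            fixture, index=False
        )
        script = tmp_path / "crr.R"
        script.write_text(
            "suppressMessages(library(cmprsk))\n"
            f"d <- read.csv('{fixture}')\n"
            "fit <- crr(d$time, d$status, cbind(x=d$x), failcode=1, cencode=0)\n"
            "cat(sprintf('%.8f', fit$coef))\n"
        )
        try:
            res = subprocess.run(
                ["Rscript", str(script)], capture_output=True, text=True, timeout=120
            )
        except (FileNotFoundError, subprocess.TimeoutExpired):
            pytest.skip("Rscript unavailable")
        assert res.returncode == 0, res.stderr
        r_coef = float(res.stdout.strip())
        assert np.log(fg.hr) == pytest.approx(r_coef, abs=5e-3)


class TestCumulativeHazard:
    def test_single_event_closed_form(self):
        df = pd.DataFrame(
            {"grp": ["a", "a"], "event_time": [1.0, 2.0], "ckd_event": [1, 0]}
        )
        curves = cumulative_hazard(df, "grp")
        assert curves["a"]["cumulative_hazard"].loc[1.0] == pytest.approx(0.5)

    def test_no_events_flat_zero(self):
        df = pd.DataFrame(
            {"grp": ["a"] * 5, "event_time": np.arange(1.0, 6.0), "ckd_event": 0}
        )
        curves = cumulative_hazard(df, "grp")
        assert (curves["a"]["cumulative_hazard"] == 0).all()

    def test_equals_bruteforce_sum(self):
        rng = np.random.default_rng(11)
        t = rng.uniform(0.5, 5.0, 10).round(1)
        e = rng.integers(0, 2, 10)
        df = pd.DataFrame({"grp": "g", "event_time": t, "ckd_event": e})
        curves = cumulative_hazard(df, "grp")
        expected = 0.0
        for u in np.sort(np.unique(t[e == 1])):
            expected += (t[e == 1] == u).sum() / (t >= u).sum()
        assert curves["g"]["cumulative_hazard"].iloc[-1] == pytest.approx(expected)

    def test_empty_grouping_rejected(self):
        df = pd.DataFrame({"grp": [], "event_time": [], "ckd_event": []})
        with pytest.raises(ValueError):
            cumulative_hazard(df, "grp")
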