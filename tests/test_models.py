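"""Model fitting: nesting limits, parameter recovery, LRT and pseudo-R²."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from statsmodels.miscmodels.ordinal_model import OrderedModel

from _oracles import chi2_sf_by_integration
from dreamgraph import glmm
from dreamgraph.stats import (
    LedgerRowSpec,
    build_ledger,
    fit_model,
    lr_test,
    nagelkerke_r2,
)


def _sim_logistic(rng, n=300, beta=(-0.5, 0.8), sigma=0.0, n_groups=20):
    grp = rng.integers(0, n_groups, n)
    x = rng.normal(size=n)
    u = rng.normal(0, sigma, n_groups)[grp] if sigma > 0 else 0.0
    eta = beta[0] + beta[1] * x + u
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    return y, x, grp


class TestBinomial:
    def test_zero_variance_limit_matches_plain_logistic(self, rng):
        """Random-intercept variance pinned to 0 reproduces plain logistic ML."""
        y, x, grp = _sim_logistic(rng)
        X = np.column_stack([np.ones_like(x), x])
        mine = glmm.fit_binomial(y, X, groups=grp, sigma_fixed=0.0)
        ref = sm.Logit(y, X).fit(disp=0)
        assert np.allclose(mine.beta, ref.params, atol=1e-3)
        assert mine.loglik == pytest.approx(ref.llf, abs=1e-6)

    def test_two_by_two_slope_is_log_odds_ratio(self):
        # counts: x=0 -> 30/70 successes, x=1 -> 55/45
        y = np.r_[np.ones(30), np.zeros(70), np.ones(55), np.zeros(45)]
        x = np.r_[np.zeros(100), np.ones(100)]
        X = np.column_stack([np.ones(200), x])
        fit = glmm.fit_binomial(y, X)
        log_or = np.log((55 / 45) / (30 / 70))
        assert fit.beta[1] == pytest.approx(log_or, abs=1e-5)

    def test_random_intercept_fit_matches_lme4(self, rng, tmp_path):
        """Quadrature ML agrees with R lme4::glmer (adaptive GH, nAGQ=25)."""
        y, x, grp = _sim_logistic(rng, n=200, sigma=0.8)
        df = pd.DataFrame({"y": y.astype(int), "x": x, "g": grp})
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        X = np.column_stack([np.ones_like(x), x])
        mine = glmm.fit_binomial(y, X, groups=grp)
        rscript = textwrap.dedent(
            f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- glmer(y ~ x + (1|g), data=d, family=binomial, nAGQ=25)
            cat(sprintf("%.8f %.8f %.8f %.8f", as.numeric(logLik(m)),
                fixef(m)[1], fixef(m)[2], sqrt(unlist(VarCorr(m)))))
            """
        )
        out = subprocess.run(
            ["Rscript", "-e", rscript], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        ll, b0, b1, sd = map(float, out.stdout.split())
        assert mine.loglik == pytest.approx(ll, abs=1e-3)
        assert mine.beta[0] == pytest.approx(b0, abs=2e-2)
        assert mine.beta[1] == pytest.approx(b1, abs=2e-2)
        assert mine.sigma == pytest.approx(sd, abs=5e-2)


class TestOrdinal:
    @staticmethod
    def _sim_ordinal(rng, n, beta, cuts, sigma=0.0, n_groups=20):
        grp = rng.integers(0, n_groups, n)
        x = rng.normal(size=n)
        u = rng.normal(0, sigma, n_groups)[grp] if sigma > 0 else 0.0
        eta = beta * x + u
        cum = 1 / (1 + np.exp(-(np.asarray(cuts)[None, :] - eta[:, None])))
        cum = np.hstack([cum, np.ones((n, 1))])
        y = (rng.random(n)[:, None] > cum).sum(axis=1)
        return y, x, grp

    def test_fixed_effects_fit_matches_statsmodels(self, rng):
        y, x, _ = self._sim_ordinal(rng, 400, 1.1, [-1.5, -0.5, 0.5, 1.5])
        mine = glmm.fit_ordinal(y, x[:, None])
        ref = OrderedModel(y, x[:, None], distr="logit").fit(method="bfgs", disp=0)
        assert mine.loglik == pytest.approx(ref.llf, abs=1e-3)
        assert mine.beta[0] == pytest.approx(np.asarray(ref.params)[0], abs=1e-3)

    def test_slope_recovery_at_n2000(self, rng):
        """Known proportional-odds slope recovered within +/- 0.15."""
        y, x, _ = self._sim_ordinal(rng, 2000, 0.8, [-1.5, -0.5, 0.5, 1.5])
        fit = glmm.fit_ordinal(y, x[:, None])
        assert fit.beta[0] == pytest.approx(0.8, abs=0.15)

    def test_random_intercept_recovers_sigma(self, rng):
        y, x, grp = self._sim_ordinal(
            rng, 2000, 0.8, [-1.5, -0.5, 0.5, 1.5], sigma=0.8, n_groups=25
        )
        fit = glmm.fit_ordinal(y, x[:, None], groups=grp)
        assert fit.beta[0] == pytest.approx(0.8, abs=0.15)
        assert fit.sigma == pytest.approx(0.8, abs=0.25)

    def test_thresholds_monotone(self, rng):
        y, x, _ = self._sim_ordinal(rng, 300, 0.5, [-1.0, 0.0, 1.0])
        fit = glmm.fit_ordinal(y, x[:, None])
        assert (np.diff(fit.thresholds) > 0).all()


class TestLrTest:
    @staticmethod
    def _fit_pair(rng, n=200):
        y, x, grp = _sim_logistic(rng, n=n, sigma=0.0)
        df = pd.DataFrame(
            {
                "y": y,
                "x": x,
                "participant_id": [f"p{g}" for g in grp],
                "night_id": "n1",
            }
        )
        nested = fit_model(df, "y", (), "binomial", random=("participant_id",))
        full = fit_model(df, "y", ("x",), "binomial", random=("participant_id",))
        return nested, full

    def test_identical_models_give_p_one(self, rng):
        nested, _ = self._fit_pair(rng)
        chi2, df, p = lr_test(nested, nested)
        assert chi2 == 0 and p == 1.0

    def test_textbook_quantile(self):
        import scipy.stats as sps

        assert sps.chi2.sf(3.84, 1) == pytest.approx(0.05, abs=5e-4)

    def test_p_matches_numeric_integration_oracle(self, rng):
        import scipy.stats as sps

        for _ in range(10):
            chi2 = float(rng.uniform(0.1, 12))
            df = int(rng.integers(1, 5))
            assert sps.chi2.sf(chi2, df) == pytest.approx(
                chi2_sf_by_integration(chi2, df), rel=1e-6
            )

    def test_real_nested_pair(self, rng):
        nested, full = self._fit_pair(rng)
        chi2, df, p = lr_test(nested, full)
        assert chi2 >= 0 and df == 1 and 0 <= p <= 1

    def test_family_mismatch_rejected(self, rng):
        nested, full = self._fit_pair(rng)
        bad = fit_model(
            pd.DataFrame(
                {"y": rng.normal(size=nested.n_obs), "participant_id": "p1",
                 "night_id": "n1"}
            ),
            "y", (), "gaussian", random=(),
        )
        with pytest.raises(ValueError):
            lr_test(nested, bad)


class TestNagelkerke:
    def test_equal_logliks_give_zero(self, rng):
        nested, _ = self._pair(rng)
        assert nagelkerke_r2(nested, nested) == 0.0

    @staticmethod
    def _pair(rng):
        return TestLrTest._fit_pair(rng)

    def test_separable_toy_data_approaches_one(self):
        y = np.r_[np.zeros(20), np.ones(20)]
        x = np.r_[np.zeros(20), np.ones(20)]
        df = pd.DataFrame({"y": y, "x": x, "participant_id": "p1", "night_id": "n1"})
        with pytest.warns(UserWarning, match="separation"):
            null = fit_model(df, "y", (), "binomial", random=())
            full = fit_model(df, "y", ("x",), "binomial", random=())
        assert nagelkerke_r2(full, null) > 0.95

    def test_formula_from_raw_logliks(self, rng):
        nested, full = self._pair(rng)
        n = full.n_obs
        expect = (1 - np.exp((2 / n) * (nested.loglik - full.loglik))) / (
            1 - np.exp((2 / n) * nested.loglik)
        )
        assert nagelkerke_r2(full, nested) == pytest.approx(
            np.clip(expect, 0, 1), abs=1e-12
        )

    def test_monotone_along_nested_chain(self, rng):
        y, x, grp = _sim_logistic(rng, n=250, sigma=0.0)
        z = rng.normal(size=250)
        df = pd.DataFrame(
            {"y": y, "x": x, "z": z,
             "participant_id": [f"p{g}" for g in grp], "night_id": "n1"}
        )
        null = fit_model(df, "y", (), "binomial", random=())
        f1 = fit_model(df, "y", ("x",), "binomial", random=())
        f2 = fit_model(df, "y", ("x", "z"), "binomial", random=())
        r = [nagelkerke_r2(m, null) for m in (null, f1, f2)]
        assert r[0] <= r[1] + 1e-9 and r[1] <= r[2] + 1e-9


class TestLedger:
    def test_constant_predictor_is_uninformative(self, rng):
        y, x, grp = _sim_logistic(rng, n=200, sigma=0.0)
        df = pd.DataFrame(
            {"y": y, "x": x, "const_col": 1.0,
             "participant_id": [f"p{g}" for g in grp], "night_id": "n1"}
        )
        rows = build_ledger(
            df, "y", "binomial",
            (LedgerRowSpec("Constant", ("const_col",), (), "Null"),),
            random=("participant_id",),
        )
        assert rows[0].pseudo_r2_change == pytest.approx(0.0, abs=1e-4)
        assert rows[0].p > 0.9

    def test_rows_labeled_baseline_plus_predictor(self):
        from dreamgraph.stats import stage_discernment_rows, time_of_night_rows

        labels = [r.label for r in time_of_night_rows(("trc", "mean_lcc"))]
        assert labels == ["Sleep Stage", "Sleep Stage + TRC", "Sleep Stage + LCC"]
        labels = [r.label for r in stage_discernment_rows(("trc", "mean_lcc"))]
        assert labels == ["TRC", "LCC", "TRC + LCC", "LCC + TRC"]

    def test_gaussian_ledger_runs_with_night_intercept(self, rng):
        n = 120
        grp = rng.integers(0, 12, n)
        df = pd.DataFrame(
            {
                "minutes_since_lights_off": rng.uniform(60, 480, n),
                "stage": rng.choice(["REM", "N2"], n),
                "trc": rng.normal(50, 15, n),
                "participant_id": [f"p{g}" for g in grp],
                "night_id": rng.choice(["n1", "n2"], n),
            }
        )
        from dreamgraph.stats import time_of_night_rows

        rows = build_ledger(
            df, "minutes_since_lights_off", "gaussian",
            time_of_night_rows(("trc",)),
        )
        assert len(rows) == 2
        assert all(np.isfinite(r.p) for r in rows)
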