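"""Data filters, truncated/censored likelihood, MCMC fit and diagnostics."""

import numpy as np
import pandas as pd
import pytest

from alediff.siler import SilerParams, adult_life_expectancy, hazard, survival
from alediff.survival_fit import (
    MCMCConfig,
    age_at_first_reproduction,
    filter_records,
    fit_siler,
    gelman_rubin,
    log_likelihood,
    product_limit,
    survivorship_check,
)

from conftest import make_records


class TestAgeAtFirstReproduction:
    def test_degenerate(self):
        assert age_at_first_reproduction([3.0] * 12) == 3.0

    def test_linear_interpolation_definition(self):
        # order statistics 1..100: the 10% point interpolates to 10.9
        assert age_at_first_reproduction(range(1, 101), 0.10) == pytest.approx(10.9)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            age_at_first_reproduction([])


class TestFilterRecords:
    def make(self, n_f, n_m, species="sp1"):
        rng = np.random.default_rng(0)
        rows = []
        for sex, n in (("female", n_f), ("male", n_m)):
            ends = 2.0 + rng.exponential(10.0, n)
            rows.append(
                pd.DataFrame(
                    {
                        "species": species,
                        "sex": sex,
                        "entry_age": 2.0,
                        "end_age": ends,
                        "event": "death",
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def test_min_per_sex_flags_group(self):
        df = self.make(34, 200)
        filtered, report = filter_records(df, min_per_sex=35)
        assert ("sp1", "female") in report["ineligible_groups"]
        assert set(filtered["sex"]) == {"male"}

    def test_window_rule(self):
        df = self.make(50, 50)
        df.loc[0, "end_age"] = 3.0  # window on ages: ends before window start
        filtered, report = filter_records(df, window=(5.0, 100.0), min_per_sex=1)
        assert report["window"] >= 1
        assert (filtered["end_age"] >= 5.0).all()

    def test_outlier_quantile_exact(self):
        df = self.make(100, 100)
        cut = np.quantile(df["end_age"], 0.99)
        expected_removed = (df["end_age"] > cut).sum()
        filtered, report = filter_records(df, min_per_sex=1)
        assert report["outlier"] == expected_removed
        assert (filtered["end_age"] <= cut).all()


class TestLogLikelihood:
    def test_single_death_plugin_oracle(self, mammal_params):
        alpha, x = 2.0, 14.0
        rec = pd.DataFrame(
            {"species": "s", "sex": "f", "entry_age": [alpha], "end_age": [x], "event": ["death"]}
        )
        expected = (
            np.log(hazard(mammal_params, x))
            + np.log(survival(mammal_params, x))
            - np.log(survival(mammal_params, alpha))
        )
        assert log_likelihood(rec, mammal_params, alpha) == pytest.approx(expected)

    def test_single_censored_plugin_oracle(self, mammal_params):
        alpha, y = 2.0, 9.0
        rec = pd.DataFrame(
            {"species": "s", "sex": "f", "entry_age": [alpha], "end_age": [y], "event": ["censored"]}
        )
        expected = np.log(survival(mammal_params, y)) - np.log(
            survival(mammal_params, alpha)
        )
        assert log_likelihood(rec, mammal_params, alpha) == pytest.approx(expected)

    def test_invalid_window_rejected(self, mammal_params):
        rec = pd.DataFrame(
            {"species": "s", "sex": "f", "entry_age": [5.0], "end_age": [4.0], "event": ["death"]}
        )
        with pytest.raises(ValueError):
            log_likelihood(rec, mammal_params, 2.0)

    def test_permutation_invariance(self, mammal_params, death_records):
        shuffled = death_records.sample(frac=1.0, random_state=3)
        assert log_likelihood(death_records, mammal_params, 2.0) == pytest.approx(
            log_likelihood(shuffled, mammal_params, 2.0)
        )


class TestGelmanRubin:
    def test_identical_chains_near_one(self):
        rng = np.random.default_rng(0)
        chain = rng.standard_normal((500, 1))
        stat = gelman_rubin(np.stack([chain, chain]))
        # B = 0, so the PSRF is sqrt((n-1)/n), within 1/n of one
        assert list(stat.values())[0] == pytest.approx(1.0, abs=2e-3)

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(1)
        c1 = rng.normal(0, 1, (500, 1))
        c2 = rng.normal(5, 1, (500, 1))
        stat = gelman_rubin(np.stack([c1, c2]))
        assert list(stat.values())[0] > 1.1

    def test_single_chain_errors(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.zeros((1, 100, 5)))


class TestSurvivorshipGate:
    def test_incomplete_followup_fails(self):
        # 60 individuals, only 20 deaths observed: product-limit stays high
        rec = make_records(
            SilerParams(-2, 1, 0.02, -50, 0.1), 2.0, 60, seed=5, censor_frac=0.0
        )
        rec.loc[rec["end_age"] > rec["end_age"].quantile(0.3), "event"] = "censored"
        km = product_limit(rec, 2.0)
        assert km["survival"].iloc[-1] > 0.4
        assert not survivorship_check(rec, 2.0, threshold=0.1)

    def test_extinct_cohort_passes(self, death_records):
        assert survivorship_check(death_records, 2.0, threshold=0.1)

    def test_product_limit_matches_lifelines(self, death_records):
        lifelines = pytest.importorskip("lifelines")
        kmf = lifelines.KaplanMeierFitter()
        sub = death_records.iloc[:200]
        kmf.fit(
            sub["end_age"],
            event_observed=(sub["event"] == "death"),
            entry=sub["entry_age"],
        )
        ours = product_limit(sub, 2.0)
        theirs = kmf.survival_function_at_times(ours["time"]).to_numpy()
        np.testing.assert_allclose(ours["survival"], theirs, atol=1e-10)


class TestFitSiler:
    CFG = dict(n_chains=4, n_iter=6000, burn_in=1001, thinning=10)

    def test_determinism(self, death_records):
        cfg = MCMCConfig(seed=5, **self.CFG)
        sub = death_records.iloc[:300]
        a = fit_siler(sub, 2.0, cfg)
        b = fit_siler(sub, 2.0, cfg)
        np.testing.assert_array_equal(a.draws, b.draws)
        np.testing.assert_array_equal(a.ale_draws, b.ale_draws)

    def test_recovery_and_ale(self, mammal_params, death_records):
        """Posterior concentrates near the generating model at n=800."""
        fit = fit_siler(death_records, 2.0, MCMCConfig(seed=2, **self.CFG))
        assert fit.converged
        true_ale = adult_life_expectancy(mammal_params, 2.0)
        assert fit.flat_ale.mean() == pytest.approx(true_ale, rel=0.06)
        lo, hi = fit.credible_interval("b1")
        assert lo < mammal_params.b1 < hi

    def test_posterior_concentration_with_n(self, mammal_params):
        """Credible intervals shrink as the sample grows."""
        widths = {}
        for n in (250, 2000):
            rec = make_records(mammal_params, 2.0, n, seed=17)
            fit = fit_siler(rec, 2.0, MCMCConfig(seed=3, **self.CFG))
            lo, hi = fit.credible_interval("b1")
            widths[n] = hi - lo
        assert widths[2000] < widths[250]

    def test_constant_hazard_ale_approaches_reciprocal(self, exponential_params):
        rec = make_records(exponential_params, 2.0, 1000, seed=23)
        fit = fit_siler(rec, 2.0, MCMCConfig(seed=4, **self.CFG))
        assert fit.flat_ale.mean() == pytest.approx(50.0, rel=0.10)
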