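"""Likelihood, MAP/EBE fits and the bootstrap pooling stage."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from hpaxis import StructuralParams, VarianceComponents
from hpaxis.estimate import (FitResult, map_fit, neg2ll_individual,
                             periods_from_event_table, predict_period,
                             profile_or_bootstrap_se, stepwise_fit)
from hpaxis.population import typical_individual
from hpaxis.synthetic_data import generate_cohort, generate_trial, trial2_design


@pytest.fixture(scope="module")
def endo_table(theta, omega_zero):
    """One noiseless typical subject on the trial-2 design."""
    cohort = generate_cohort(1, 77)
    table, truth = generate_trial(trial2_design(), cohort, theta, omega_zero,
                                  seed=78, with_ruv=False)
    return table, truth


class TestNeg2LL:
    def test_matches_density_sum_oracle(self, theta, omega, endo_table):
        # independent oracle: sum of Gaussian log-densities at the predictions
        table, truth = endo_table
        specs = periods_from_event_table(table)[1]
        endo = [s for s in specs if s.kind == "endogenous"]
        # a 5-observation toy set
        toy = endo[0]
        toy.obs = toy.obs.iloc[:5].reset_index(drop=True)
        ind = typical_individual(theta, BW=truth[1]["BW"], subject_id=1)
        got = neg2ll_individual([toy], ind, omega, mode="full", warmup=48.0)

        preds = predict_period(ind, toy, mode="full", warmup=48.0)
        ll = 0.0
        for _, r in toy.obs.iterrows():
            mu = preds[(r["t_abs"], r["DVTYPE"])]
            sig = omega.sigma_prop_ACTH if r["DVTYPE"] == "acth_pmolL" \
                else omega.sigma_prop_cortisol
            ll += norm.logpdf(r["DV"], loc=mu, scale=sig * mu)
        assert got == pytest.approx(-2.0 * ll, rel=1e-6)

    def test_sigma_doubling_changes_by_analytic_amount(self, theta, omega,
                                                       endo_table):
        table, truth = endo_table
        specs = periods_from_event_table(table)[1]
        toy = [s for s in specs if s.kind == "endogenous"][0]
        ind = typical_individual(theta, BW=truth[1]["BW"], subject_id=1)
        sig1 = {"sigma_prop_ACTH": 0.3, "sigma_prop_cortisol": 0.3}
        sig2 = {"sigma_prop_ACTH": 0.6, "sigma_prop_cortisol": 0.6}
        n = len(toy.obs)
        v1 = neg2ll_individual([toy], ind, sig1, mode="full", warmup=48.0)
        v2 = neg2ll_individual([toy], ind, sig2, mode="full", warmup=48.0)
        # residual term shrinks by 3/4 of its value; log-variance grows by 2log2
        ssq = v1 - n * math.log(2 * math.pi) - _logvar_sum(toy, ind, 0.3, theta)
        expected = v2 - v1
        assert expected == pytest.approx(-0.75 * ssq + n * 2 * math.log(2.0),
                                         rel=1e-6)


def _logvar_sum(spec, ind, sigma, theta):
    preds = predict_period(ind, spec, mode="full", warmup=48.0)
    out = 0.0
    for _, r in spec.obs.iterrows():
        mu = max(preds[(r["t_abs"], r["DVTYPE"])], 1e-3)
        out += 2.0 * math.log(sigma * mu)
    return out


class TestMapFit:
    def test_zero_noise_recovers_zero_etas(self, theta, omega, endo_table):
        table, truth = endo_table
        specs = periods_from_event_table(table)[1]
        etas, _, info = map_fit(specs, theta, omega, BW=truth[1]["BW"],
                                subject_id=1, warmup=24.0)
        assert info["converged"]
        assert max(abs(v) for v in etas.values()) < 1e-3

    def test_recovers_known_nonzero_etas(self, theta, omega):
        true_etas = {"SA1": -0.3, "Kout": 0.2, "Base": 0.25, "EC50": 0.2}
        om = VarianceComponents()
        cohort = generate_cohort(1, 55)
        # bake the etas into the generating parameters via a shifted typical
        shifted = theta.replace(**{k: getattr(theta, k) * math.exp(v)
                                   for k, v in true_etas.items()})
        table, truth = generate_trial(trial2_design(), cohort, shifted,
                                      VarianceComponents(**{k: 0.0 for k in
                                                            om.to_dict()}),
                                      seed=56, with_ruv=False)
        specs = periods_from_event_table(table)[1]
        # tight sigmas: rich noise-free data should dominate the prior
        sig = {"sigma_prop_ACTH": 0.02, "sigma_prop_cortisol": 0.02}
        etas, _, info = map_fit(specs, theta, om, BW=truth[1]["BW"],
                                subject_id=1, sigmas=sig, warmup=48.0,
                                max_nfev=120)
        for k, v in true_etas.items():
            assert etas[k] == pytest.approx(v, abs=0.01)

    def test_empty_observations_return_prior_mode(self, theta, omega):
        etas, iov, info = map_fit([], theta, omega, BW=70.0)
        assert all(v == 0.0 for v in etas.values())
        assert info["objective"] == 0.0


class TestStepwiseContracts:
    def test_zero_iteration_fit_returns_init(self, theta, omega, endo_table):
        table, _ = endo_table
        init = theta.replace(CL=120.0, Base=1.5)
        fits = stepwise_fit(table, init, omega, free_step1=(), free_step2=(),
                            free_step3=(), fit_etas=False)
        assert [f.step for f in fits] == ["step1_pk", "step2_endogenous",
                                         "step3_joint"]
        for f in fits:
            assert f.fixed_effects == init.to_dict()

    def test_missing_period_types_rejected(self, theta, omega, endo_table):
        table, _ = endo_table
        endo_only = table[table["PERIOD"] == 0]
        with pytest.raises(ValueError, match="DEX"):
            stepwise_fit(endo_only, theta, omega, free_step1=(),
                         free_step2=(), free_step3=(), fit_etas=False)
        dex_only = table[table["PERIOD"] > 0]
        with pytest.raises(ValueError, match="endogenous"):
            stepwise_fit(dex_only, theta, omega, free_step1=(),
                         free_step2=(), free_step3=(), fit_etas=False)


class TestBootstrap:
    def _fake_fit(self, theta, values_by_subject):
        return FitResult(step="step1_pk", fixed_effects=theta.to_dict(),
                         neg2ll=0.0, converged=True,
                         diagnostics={"per_subject": values_by_subject})

    def test_degenerate_subjects_give_zero_width(self, theta):
        per = {i: {"BW": 70.0, "CL": 106.0, "Vc": 2.15, "F": 0.344,
                   "Ntr": 2.12, "Q": 89.9, "Vp": 61.7,
                   "MTT_points": [(5.0, 0.868)]} for i in range(8)}
        df = profile_or_bootstrap_se(self._fake_fit(theta, per), n_boot=30,
                                     seed=0)
        width = (df["hi"] - df["lo"]).abs()
        assert (width < 1e-9).all()

    def test_deterministic_given_seed(self, theta):
        rng = np.random.default_rng(1)
        per = {i: {"BW": 70.0, "CL": float(106 * np.exp(rng.normal(0, 0.2))),
                   "MTT_points": []} for i in range(10)}
        fit = self._fake_fit(theta, per)
        a = profile_or_bootstrap_se(fit, n_boot=40, seed=5)
        b = profile_or_bootstrap_se(fit, n_boot=40, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_small_n_boot_warns(self, theta):
        per = {i: {"BW": 70.0, "CL": 100.0 + i, "MTT_points": []}
               for i in range(5)}
        with pytest.warns(UserWarning, match="n_boot"):
            profile_or_bootstrap_se(self._fake_fit(theta, per), n_boot=5, seed=0)

    def test_pooling_interval_coverage(self, theta):
        # scaled-down coverage check of the two-stage bootstrap: per-subject
        # estimates drawn from the lognormal IIV model, 12 replicate cohorts
        rng = np.random.default_rng(42)
        hits, total = 0, 0
        for _ in range(12):
            per = {i: {"BW": 70.0,
                       "CL": float(106.0 * np.exp(rng.normal(0, 0.114))),
                       "F": min(float(0.344 * np.exp(rng.normal(0, 0.48))), 1.0),
                       "Vp": float(61.7 * np.exp(rng.normal(0, 0.122))),
                       "MTT_points": []} for i in range(13)}
            df = profile_or_bootstrap_se(self._fake_fit(theta, per), n_boot=150,
                                         seed=int(rng.integers(2 ** 31)))
            for param, truth in (("CL", 106.0), ("F", 0.344), ("Vp", 61.7)):
                row = df[df["param"] == param].iloc[0]
                hits += int(row["lo"] <= truth <= row["hi"])
                total += 1
        assert hits / total >= 0.8
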