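"""Scenario engine: typical trajectories, population bands, comparisons."""

import numpy as np
import pandas as pd
import pytest

from hpaxis import DoseEvent, Scenario, simulate_individual
from hpaxis.model_core import bound_from_unbound
from hpaxis.simulate import (cah_comparison, dosing_time_comparison,
                             simulate_population)


class TestTypicalHealthy:
    def test_states_non_negative(self, healthy_sim):
        f = healthy_sim.frame
        for col in ("acth", "cortisol_total", "cortisol_unbound",
                    "production_rate"):
            assert (f[col] >= 0).all()

    def test_acth_peak_precedes_cortisol_peak(self, healthy_sim):
        f = healthy_sim.frame
        t_acth = f.loc[f["acth"].idxmax(), "time"]
        t_cort = f.loc[f["cortisol_total"].idxmax(), "time"]
        assert t_acth < t_cort

    def test_production_stays_below_half_emax(self, healthy_sim, theta):
        assert healthy_sim.peak_production_rate() < 0.5 * theta.Emax

    def test_daytime_cortisol_above_ic50_equivalent(self, healthy_sim, theta):
        # the feedback premise: total cortisol above ~160 nmol/L through the day
        total_ic50 = bound_from_unbound(theta.IC50, theta)
        f = healthy_sim.frame
        day = f[(f["clock"] >= 6.0) & (f["clock"] <= 15.0)]
        assert (day["cortisol_total"] > total_ic50).all()

    def test_24h_periodicity_after_warmup(self, theta):
        out = simulate_individual(theta, Scenario(t_end=48.0, warmup=72.0))
        f = out.frame
        day1 = f[f["time"] <= 24.0 + 1e-9].reset_index(drop=True)
        day2 = f[f["time"] >= 24.0 - 1e-9].reset_index(drop=True)
        for col in ("acth", "cortisol_total"):
            scale = day1[col].max()
            err = np.max(np.abs(day1[col].values - day2[col].values)) / scale
            assert err < 1e-4

    def test_severe_cah_has_no_cortisol(self, severity_sims):
        f = severity_sims[0.0].frame
        assert f["cortisol_total"].max() < 1e-9
        assert f["production_rate"].max() == 0.0


class TestDexSuppression:
    def test_acth_relaxes_to_base(self, theta):
        # DEX window across the whole run: pulsatile secretion off, A -> Base
        sc = Scenario(t_start=0.0, t_end=24.0, warmup=48.0,
                      dex_windows=[(-48.0, 25.0)])
        out = simulate_individual(theta, sc)
        acth = out.frame["acth"]
        assert acth.iloc[-1] == pytest.approx(theta.Base, rel=1e-6)
        assert np.max(np.abs(acth - theta.Base)) < 1e-4 * theta.Base


class TestPopulation:
    def test_single_zero_omega_subject_equals_typical(self, theta, omega_zero,
                                                      healthy_sim):
        outs, bands = simulate_population(theta, omega_zero, Scenario(), 1, 0)
        np.testing.assert_allclose(outs[0].frame["acth"],
                                   healthy_sim.frame["acth"], rtol=1e-9)
        med = bands[bands["channel"] == "acth"]["p50"].values
        np.testing.assert_allclose(med, healthy_sim.frame["acth"], rtol=1e-9)

    def test_seed_gives_identical_bands(self, theta, omega):
        sc = Scenario(grid_step=0.25)
        _, b1 = simulate_population(theta, omega, sc, 3, 42)
        _, b2 = simulate_population(theta, omega, sc, 3, 42)
        pd.testing.assert_frame_equal(b1, b2)

    def test_bands_ordered(self, theta, omega):
        sc = Scenario(grid_step=0.25)
        _, bands = simulate_population(theta, omega, sc, 5, 7)
        assert (bands["p5"] <= bands["p50"]).all()
        assert (bands["p50"] <= bands["p95"]).all()


class TestCahComparison:
    def test_fold_monotone_in_activity(self, severity_sims):
        acts = sorted(severity_sims)  # ascending activity
        peaks = [severity_sims[a].morning_acth_peak()[0] for a in acts]
        # lower remaining activity => higher ACTH peak
        assert all(p1 >= p2 - 1e-9 for p1, p2 in zip(peaks, peaks[1:]))

    def test_healthy_fold_is_one(self, theta):
        df = cah_comparison(theta, [1.0])
        assert df["fold_vs_healthy"].iloc[0] == pytest.approx(1.0)

    def test_rejects_invalid_activity(self, theta):
        with pytest.raises(ValueError):
            cah_comparison(theta, [1.5])


class TestDosingTime:
    def test_zero_dose_equals_untreated(self, theta):
        df = dosing_time_comparison(theta, 0.0, [7.0], activity=0.0)
        u = df[df["regimen"] == "untreated"].iloc[0]
        d = df[df["regimen"] == "dose_07.00h"].iloc[0]
        assert d["acth_morning_peak_pmolL"] == pytest.approx(
            u["acth_morning_peak_pmolL"], rel=1e-9)

    def test_dose_event_validation(self):
        with pytest.raises(ValueError):
            DoseEvent(time=7.0, amount_mg=0.0, route="oral_granule")
        with pytest.raises(ValueError):
            DoseEvent(time=7.0, amount_mg=5.0, route="intramuscular")
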