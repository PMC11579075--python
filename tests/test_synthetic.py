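"""Virtual-trial generator: designs, cohorts, ground truth, exclusion rule."""

import numpy as np
import pandas as pd
import pytest

from hpaxis.estimate import periods_from_event_table, predict_period
from hpaxis.io_tables import validate_event_table
from hpaxis.params import ACTH_PG_PER_PMOL
from hpaxis.population import typical_individual
from hpaxis.synthetic_data import (AGE_RANGE, BW_RANGE, apply_exclusion_rule,
                                   generate_cohort, generate_trial,
                                   trial1_design, trial2_design)


class TestCohort:
    def test_ranges(self):
        c = generate_cohort(200, 1)
        assert c["BW_KG"].between(*BW_RANGE).all()
        assert c["AGE_Y"].between(*AGE_RANGE).all()

    def test_seed_stability(self):
        pd.testing.assert_frame_equal(generate_cohort(5, 9), generate_cohort(5, 9))

    def test_empty(self):
        assert len(generate_cohort(0, 1)) == 0


class TestDesigns:
    def test_trial1_layout(self):
        d = trial1_design()
        assert len(d.periods) == 4
        assert [p.doses[0][1] for p in d.periods] == [0.5, 2.0, 5.0, 10.0]
        assert d.n_oral_occasions == 4
        # pre-dose + 16 half-hourly + 4 hourly cortisol samples
        n_cort = sum(1 for t, ch in d.periods[0].samples
                     if ch == "cortisol_total_nmolL")
        assert n_cort == 21

    def test_trial2_layout(self):
        d = trial2_design()
        assert len(d.periods) == 4
        endo = d.periods[0]
        n_acth = sum(1 for _, ch in endo.samples if ch == "acth_pmolL")
        assert n_acth == 25    # hourly 15:00 -> 15:00 inclusive
        n_cu = sum(1 for _, ch in endo.samples
                   if ch == "cortisol_unbound_nmolL")
        assert n_cu == 3
        routes = [p.doses[0][2] for p in d.periods[1:] if p.doses]
        assert routes == ["oral_granule", "iv_bolus"]

    def test_washout_enforced(self):
        with pytest.raises(ValueError):
            trial1_design(washout_days=3)


class TestGeneration:
    @pytest.fixture(scope="class")
    def trial2_noiseless(self, theta, omega_zero):
        cohort = generate_cohort(1, 5)
        return generate_trial(trial2_design(), cohort, theta, omega_zero,
                              seed=9, with_ruv=False)

    def test_table_validates(self, trial2_noiseless):
        table, _ = trial2_noiseless
        validate_event_table(table)

    def test_zero_omega_matches_typical_prediction(self, trial2_noiseless,
                                                   theta):
        table, truth = trial2_noiseless
        specs = periods_from_event_table(table)[1]
        ind = typical_individual(theta, BW=truth[1]["BW"], subject_id=1)
        for spec in specs:
            preds = predict_period(ind, spec, mode="full", warmup=72.0,
                                   rtol=1e-8, atol=1e-10)
            for _, r in spec.obs.iterrows():
                assert r["DV"] == pytest.approx(preds[(r["t_abs"], r["DVTYPE"])],
                                                rel=1e-6)

    def test_predose_acth_suppressed_to_base(self, trial2_noiseless, theta):
        table, _ = trial2_noiseless
        pre = table[(table["EVID"] == 0) & (table["DVTYPE"] == "acth_pmolL")
                    & (table["PERIOD"] > 0)]
        # DEX clamps ACTH at baseline, far below the 20 pg/mL exclusion level
        assert np.allclose(pre["DV"], theta.Base, rtol=0.01)
        assert (pre["DV"] * ACTH_PG_PER_PMOL < 20.0).all()

    def test_truth_sidecar_contents(self, trial2_noiseless):
        _, truth = trial2_noiseless
        rec = truth[1]
        assert set(rec) >= {"BW", "age", "etas", "occ_mtt_factor", "params",
                            "noiseless"}
        assert rec["etas"]["CL"] == 0.0


class TestExclusionRule:
    @pytest.fixture(scope="class")
    def cohort3(self):
        return generate_cohort(3, 21)

    def test_compliant_cohort_untouched(self, theta, omega, cohort3):
        table, _ = generate_trial(trial2_design(), cohort3, theta, omega,
                                  seed=2, warmup=48.0, rtol=1e-6, atol=1e-8)
        filtered, logdf = apply_exclusion_rule(table)
        assert len(logdf) == 0
        pd.testing.assert_frame_equal(filtered, table)

    def test_forced_nonsuppressed_subject_excluded(self, theta, omega, cohort3):
        table, _ = generate_trial(trial2_design(), cohort3, theta, omega,
                                  seed=2, warmup=48.0, rtol=1e-6, atol=1e-8,
                                  force_no_suppression={2})
        filtered, logdf = apply_exclusion_rule(table)
        assert sorted(logdf["ID"].unique()) == [2]
        assert set(filtered["ID"]) == {1, 3}

    def test_infinite_threshold_is_identity(self, theta, omega, cohort3):
        table, _ = generate_trial(trial2_design(), cohort3, theta, omega,
                                  seed=2, warmup=48.0, rtol=1e-6, atol=1e-8,
                                  force_no_suppression={2})
        filtered, logdf = apply_exclusion_rule(table, threshold_pg_ml=np.inf)
        assert len(logdf) == 0
        pd.testing.assert_frame_equal(filtered, table)
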