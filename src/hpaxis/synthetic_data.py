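"""Virtual-trial generator with known ground truth.

Emulates the two cross-over designs the model was built for:

* **trial 1** (healthy volunteers, default n=16): four DEX-suppressed
  periods, single oral immediate-release hydrocortisone granule doses of
  0.5 / 2 / 5 / 10 mg at 07:00; total cortisol sampled pre-dose, half-hourly
  to 8 h and hourly to 12 h post-dose; ACTH measured pre-dose. One week
  washout between periods (each period carries its own occasion for IOV).
* **trial 2** (healthy volunteers, default n=13): an endogenous period with
  hourly ACTH and total cortisol from 15:00 to 15:00 (25 samples each) and
  unbound cortisol at 22:00, 07:00 and 09:00; then DEX-only, DEX + 20 mg
  oral and DEX + 20 mg IV-bolus periods sampled pre-dose and at 0.25-12 h
  post 07:00, with unbound cortisol pre-dose and 2 h post-dose.

DEX dosing is represented as a suppression window opening 12 h before the
07:00 period start (with the all-or-none suppression model only the window
matters). Covariates are drawn uniformly over the observed cohort ranges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import population
from .estimate import PeriodSpec, predict_period
from .params import ACTH_PG_PER_PMOL, StructuralParams, VarianceComponents
from .simulate import DoseEvent

__all__ = ["PeriodPlan", "TrialDesign", "trial1_design", "trial2_design",
           "generate_cohort", "generate_trial", "apply_exclusion_rule"]

log = logging.getLogger(__name__)

#: sampling offset of "pre-dose" samples relative to the 07:00 dose, h
PREDOSE_OFFSET = -0.05

#: post-dose sampling template of the trial-2 intervention periods, h
_T2_POST = (0.25, 0.5, 0.75, 1.0, 1.25, 1.5, 2.0, 2.5, 3.0,
            4.0, 5.0, 6.0, 8.0, 10.0, 12.0)


@dataclass
class PeriodPlan:
    """Blueprint of one trial period (times absolute: 24*day + clock)."""

    index: int
    day: int                       # study day of the 07:00 period start
    dex: bool
    doses: list = field(default_factory=list)     # (clock, amount_mg, route)
    occasion: int = 0
    #: list of (t_abs, DVTYPE)
    samples: list = field(default_factory=list)

    @property
    def dex_on(self) -> float:
        """DEX window opens 12 h before the 07:00 period start."""
        return 24.0 * self.day + 7.0 - 12.0


@dataclass
class TrialDesign:
    design_id: str
    periods: list

    @property
    def n_oral_occasions(self) -> int:
        occs = {p.occasion for p in self.periods
                for (_, _, route) in p.doses if route == "oral_granule"}
        return max(len(occs), 1)


def trial1_design(washout_days: int = 7) -> TrialDesign:
    """Four DEX periods, single oral 0.5/2/5/10 mg doses at 07:00."""
    if washout_days < 7:
        raise ValueError("washout between periods must be at least 7 days")
    periods = []
    for i, dose in enumerate((0.5, 2.0, 5.0, 10.0)):
        day = i * washout_days
        t0 = 24.0 * day
        samples = [(t0 + 7.0 + PREDOSE_OFFSET, "acth_pmolL"),
                   (t0 + 7.0 + PREDOSE_OFFSET, "cortisol_total_nmolL")]
        samples += [(t0 + 7.0 + dt, "cortisol_total_nmolL")
                    for dt in np.arange(0.5, 8.0 + 1e-9, 0.5)]
        samples += [(t0 + 7.0 + dt, "cortisol_total_nmolL")
                    for dt in (9.0, 10.0, 11.0, 12.0)]
        periods.append(PeriodPlan(index=i, day=day, dex=True,
                                  doses=[(7.0, dose, "oral_granule")],
                                  occasion=i, samples=samples))
    return TrialDesign("trial1", periods)


def trial2_design(washout_days: int = 7) -> TrialDesign:
    """Endogenous 24-h period plus DEX-only, DEX+20 mg oral, DEX+20 mg IV."""
    if washout_days < 7:
        raise ValueError("washout between periods must be at least 7 days")
    endo_samples = []
    for t in np.arange(15.0, 39.0 + 1e-9, 1.0):   # 15:00 -> 15:00, 25 samples
        endo_samples.append((float(t), "acth_pmolL"))
        endo_samples.append((float(t), "cortisol_total_nmolL"))
    for t in (22.0, 31.0, 33.0):                  # 22:00, 07:00, 09:00
        endo_samples.append((float(t), "cortisol_unbound_nmolL"))
    periods = [PeriodPlan(index=0, day=0, dex=False, doses=[],
                          samples=sorted(endo_samples))]
    for i, route in enumerate((None, "oral_granule", "iv_bolus"), start=1):
        day = i * washout_days
        t0 = 24.0 * day
        samples = [(t0 + 7.0 + PREDOSE_OFFSET, "acth_pmolL"),
                   (t0 + 7.0 + PREDOSE_OFFSET, "cortisol_total_nmolL"),
                   (t0 + 7.0 + PREDOSE_OFFSET, "cortisol_unbound_nmolL")]
        samples += [(t0 + 7.0 + dt, "cortisol_total_nmolL") for dt in _T2_POST]
        samples.append((t0 + 9.0, "cortisol_unbound_nmolL"))  # 2 h post-dose
        doses = [] if route is None else [(7.0, 20.0, route)]
        periods.append(PeriodPlan(index=i, day=day, dex=True, doses=doses,
                                  occasion=0, samples=sorted(samples)))
    return TrialDesign("trial2", periods)


#: covariate ranges of the pooled study population
BW_RANGE = (64.7, 102.0)
AGE_RANGE = (21.0, 60.0)


def generate_cohort(n: int, seed) -> pd.DataFrame:
    """Covariate table: BW and age uniform over the observed cohort ranges."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "ID": np.arange(1, n + 1, dtype=int),
        "BW_KG": rng.uniform(*BW_RANGE, size=n),
        "AGE_Y": rng.uniform(*AGE_RANGE, size=n),
    })


def _period_spec(plan: PeriodPlan, sid: int, bw: float, age: float) -> PeriodSpec:
    t0 = 24.0 * plan.day
    doses = [DoseEvent(time=t0 + clock, amount_mg=amt, route=route,
                       occasion=plan.occasion)
             for clock, amt, route in plan.doses]
    t_end = max(t for t, _ in plan.samples) + 0.5
    obs = pd.DataFrame({"t_abs": [t for t, _ in plan.samples],
                        "DVTYPE": [ch for _, ch in plan.samples],
                        "DV": np.nan})
    return PeriodSpec(subject_id=sid, period=plan.index, occasion=plan.occasion,
                      kind="dex" if plan.dex else "endogenous", BW=bw, age=age,
                      doses=doses,
                      dex_windows=[(plan.dex_on, t_end)] if plan.dex else [],
                      obs=obs)


def generate_trial(design: TrialDesign, cohort: pd.DataFrame,
                   theta: StructuralParams | None = None,
                   omega: VarianceComponents | None = None,
                   seed: int = 0, with_ruv: bool = True,
                   warmup: float = 72.0, rtol: float = 1e-8,
                   atol: float = 1e-10,
                   force_no_suppression: set = frozenset()):
    """Simulate one virtual trial; returns ``(event_table, truth)``.

    ``truth`` maps subject id to the hidden ground truth (etas, IOV factors,
    individual parameters, noiseless predictions). Subjects listed in
    ``force_no_suppression`` are simulated with DEX having no effect on
    pulsatile secretion (a non-compliant / non-suppressed participant, for
    exercising the exclusion rule).
    """
    theta = theta or StructuralParams()
    omega = omega or VarianceComponents()
    rng = np.random.default_rng(seed)
    rows, truth = [], {}
    for _, subj in cohort.iterrows():
        sid, bw, age = int(subj["ID"]), float(subj["BW_KG"]), float(subj["AGE_Y"])
        ind = population.sample_individual(theta, omega, BW=bw,
                                           n_occasions=design.n_oral_occasions,
                                           rng=rng, subject_id=sid, age=age)
        if sid in force_no_suppression:
            ind.params = ind.params.replace(I_DEX=0.0)
        truth[sid] = {"BW": bw, "age": age, "etas": dict(ind.etas),
                      "occ_mtt_factor": dict(ind.occ_mtt_factor),
                      "params": ind.params.to_dict(), "noiseless": {}}
        for plan in design.periods:
            spec = _period_spec(plan, sid, bw, age)
            preds = predict_period(ind, spec, mode="full", warmup=warmup,
                                   rtol=rtol, atol=atol)
            t0 = 24.0 * plan.day
            if plan.dex:
                rows.append(_row(sid, plan, plan.dex_on, 1,
                                 route="dex_marker", bw=bw, age=age))
            for clock, amt, route in plan.doses:
                rows.append(_row(sid, plan, t0 + clock, 1, route=route,
                                 amt=amt, bw=bw, age=age))
            for t_abs, ch in plan.samples:
                mu = preds[(t_abs, ch)]
                truth[sid]["noiseless"][(plan.index, t_abs, ch)] = mu
                if with_ruv:
                    sig = omega.sigma_prop_ACTH if ch == "acth_pmolL" \
                        else omega.sigma_prop_cortisol
                    chan = "ACTH" if ch == "acth_pmolL" else "cortisol_total"
                    dv = float(population.apply_residual_error(mu, chan, sig, rng))
                else:
                    dv = mu
                rows.append(_row(sid, plan, t_abs, 0, dvtype=ch, dv=dv,
                                 bw=bw, age=age))
    table = pd.DataFrame(rows).sort_values(
        ["ID", "PERIOD", "DAY", "CLOCK"], kind="stable").reset_index(drop=True)
    from .io_tables import validate_event_table

    return validate_event_table(table), truth


def _row(sid, plan, t_abs, evid, route=None, amt=np.nan, dvtype=None,
         dv=np.nan, bw=np.nan, age=np.nan):
    return {"ID": sid, "PERIOD": plan.index, "OCC": plan.occasion,
            "CLOCK": round(t_abs % 24.0, 6), "DAY": int(t_abs // 24.0),
            "EVID": evid, "ROUTE": route, "AMT_MG": amt,
            "DVTYPE": dvtype, "DV": dv, "BW_KG": bw, "AGE_Y": age}


def apply_exclusion_rule(table: pd.DataFrame, threshold_pg_ml: float = 20.0):
    """Drop subjects whose DEX-period pre-dose ACTH exceeds the threshold.

    Pre-dose ACTH records are the ACTH observations in DEX-marked periods
    taken at or before the first hydrocortisone dose of that period (all
    ACTH observations, for dose-free DEX periods). Returns
    ``(filtered_table, exclusion_log)``.
    """
    t_abs = 24.0 * table["DAY"] + table["CLOCK"]
    tab = table.assign(_t=t_abs)
    bad_rows = []
    for (sid, per), g in tab.groupby(["ID", "PERIOD"], sort=True):
        dosed = g[(g["EVID"] == 1) & (g["ROUTE"] != "dex_marker")]
        if not (g["ROUTE"] == "dex_marker").any():
            continue
        t_cut = dosed["_t"].min() if len(dosed) else np.inf
        pre = g[(g["EVID"] == 0) & (g["DVTYPE"] == "acth_pmolL")
                & (g["_t"] <= t_cut)]
        over = pre[pre["DV"] * ACTH_PG_PER_PMOL > threshold_pg_ml]
        for _, r in over.iterrows():
            bad_rows.append({"ID": int(sid), "PERIOD": int(per),
                             "t_abs": float(r["_t"]),
                             "acth_pg_ml": float(r["DV"] * ACTH_PG_PER_PMOL)})
    excluded = sorted({r["ID"] for r in bad_rows})
    if excluded:
        log.info("excluding %d subject(s) with pre-dose ACTH > %.3g pg/mL: %s",
                 len(excluded), threshold_pg_ml, excluded)
    filtered = table[~table["ID"].isin(excluded)].reset_index(drop=True)
    return filtered, pd.DataFrame(bad_rows,
                                  columns=["ID", "PERIOD", "t_abs", "acth_pg_ml"])
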