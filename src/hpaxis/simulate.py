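"""Scenario engine: integrate the model for individuals and populations.

Scenarios are defined on an absolute time axis in hours (``24*day + clock``,
day 0 starting at midnight). Dosing events and dexamethasone (DEX)
suppression windows are handled as integration restarts; oral doses drive
the analytic transit input from their administration time onwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import odeint

from . import model_core, population
from .model_core import OralInput, bound_from_unbound, unbound_from_total
from .params import HC_NMOL_PER_MG, StructuralParams, VarianceComponents

__all__ = ["DoseEvent", "Scenario", "SimOutput", "integrate_model",
           "simulate_individual", "simulate_population", "percentile_bands",
           "cah_comparison", "dosing_time_comparison", "vpc_summary"]

ROUTES = ("oral_granule", "iv_bolus", "dex_marker")

#: default solver settings (stiff-capable adaptive integrator)
RTOL = 1e-8
ATOL = 1e-10
MAX_STEP = 0.25  # h; guarantees the narrow morning surge is never stepped over


@dataclass
class DoseEvent:
    """A dosing record on the absolute time axis."""

    time: float          # absolute h (24*day + clock)
    amount_mg: float
    route: str           # oral_granule | iv_bolus | dex_marker
    occasion: int = 0

    def __post_init__(self):
        if self.route not in ROUTES:
            raise ValueError(f"unknown route {self.route!r}")
        if self.route != "dex_marker" and not self.amount_mg > 0:
            raise ValueError("dose amount must be > 0")


@dataclass
class Scenario:
    """A simulation scenario for one (or a population of) subject(s)."""

    activity: float = 1.0
    BW: float = 70.0
    doses: list = field(default_factory=list)
    t_start: float = 0.0
    t_end: float = 24.0
    warmup: float = 72.0
    grid_step: float = 0.05
    #: DEX suppression windows, list of (t_on, t_off) absolute h
    dex_windows: list = field(default_factory=list)

    def __post_init__(self):
        if self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")
        self.doses = sorted(self.doses, key=lambda d: d.time)


@dataclass
class SimOutput:
    """Deterministic trajectory of one subject plus scalar summaries."""

    subject_id: int
    frame: pd.DataFrame   # time, clock, acth, cortisol_total, cortisol_unbound,
                          # production_rate, feedback_factor
    params: StructuralParams

    def _last_day(self) -> pd.DataFrame:
        t1 = self.frame["time"].iloc[-1]
        return self.frame[self.frame["time"] >= t1 - 24.0]

    def morning_acth_peak(self, window=(3.0, 10.0)):
        """(value pmol/L, clock h) of the ACTH maximum in the morning window
        of the final simulated day."""
        d = self._last_day()
        m = d[(d["clock"] >= window[0]) & (d["clock"] <= window[1])]
        i = m["acth"].idxmax()
        return float(m.loc[i, "acth"]), float(m.loc[i, "clock"])

    def peak_production_rate(self) -> float:
        """Maximum cortisol production rate (nmol/h) over the final day."""
        return float(self._last_day()["production_rate"].max())

    def nocturnal_acth_min(self) -> float:
        """Minimum ACTH concentration (pmol/L) over the final day."""
        return float(self._last_day()["acth"].min())

    def acth_auc(self, clock_from=0.0, clock_to=12.0) -> float:
        """ACTH AUC (pmol/L*h) over a clock window of the final day."""
        d = self._last_day()
        m = d[(d["clock"] >= clock_from) & (d["clock"] <= clock_to)]
        return float(np.trapezoid(m["acth"].values, m["time"].values))


def integrate_model(p: StructuralParams, t0: float, t1: float, y0, t_eval,
                    oral_inputs=(), iv_events=(), dex_windows=(),
                    rtol=RTOL, atol=ATOL, max_step=MAX_STEP,
                    const_production=0.0):
    """Integrate the joint-model ODE from ``t0`` to ``t1``.

    Dosing times and DEX-window edges are integration restarts; ``iv_events``
    is a sequence of ``(time, amount_nmol)`` bolus additions to the central
    compartment. Returns the state matrix (4 x len(t_eval)) at ``t_eval``.
    """
    t_eval = np.asarray(t_eval, dtype=float)
    if t_eval.size and (t_eval[0] < t0 - 1e-9 or t_eval[-1] > t1 + 1e-9):
        raise ValueError("t_eval must lie within [t0, t1]")
    breakpoints = {t0, t1}
    for inp in oral_inputs:
        if t0 < inp.t_dose < t1:
            breakpoints.add(inp.t_dose)
    iv_by_time: dict[float, float] = {}
    for t_iv, amt in iv_events:
        iv_by_time[t_iv] = iv_by_time.get(t_iv, 0.0) + amt
        if t0 < t_iv < t1:
            breakpoints.add(t_iv)
    for a, b in dex_windows:
        for edge in (a, b):
            if t0 < edge < t1:
                breakpoints.add(edge)
    bps = sorted(breakpoints)

    y = np.asarray(y0, dtype=float).copy()
    c_params = model_core.pack_params(p)
    out = np.empty((4, t_eval.size))
    for k, (seg_a, seg_b) in enumerate(zip(bps[:-1], bps[1:])):
        y[2] += iv_by_time.get(seg_a, 0.0)
        mid = 0.5 * (seg_a + seg_b)
        dex = any(a <= mid < b for a, b in dex_windows)
        active = tuple(inp for inp in oral_inputs if inp.t_dose < seg_b)

        # grid points exactly at an interior breakpoint belong to the
        # preceding segment (value just before any bolus applied there)
        lower = (t_eval >= seg_a) if k == 0 else (t_eval > seg_a)
        idx = np.nonzero(lower & (t_eval <= seg_b))[0]
        ts_solve = np.union1d(t_eval[idx], [seg_a, seg_b])
        doses_arr = model_core.pack_oral_inputs(active)
        ys, info = odeint(
            model_core.rhs_fast, y, ts_solve,
            args=(c_params, doses_arr, dex, const_production), tfirst=True,
            rtol=rtol, atol=atol, hmax=0.0 if np.isinf(max_step) else max_step,
            mxstep=100000, full_output=True)
        if info["message"] != "Integration successful.":
            raise RuntimeError(
                f"ODE solver failed on segment [{seg_a:.3f}, {seg_b:.3f}] "
                f"(dex={dex}, {len(active)} oral inputs): {info['message']}")
        if idx.size:
            pos = np.searchsorted(ts_solve, t_eval[idx])
            out[:, idx] = ys[pos].T
        y = ys[-1].copy()
    return out, y


def _build_inputs(ind: population.IndividualParams, doses):
    """Split dose events into transit-input objects and IV bolus tuples."""
    p = ind.params
    orals, ivs = [], []
    for d in doses:
        if d.route == "oral_granule":
            orals.append(OralInput(t_dose=d.time, dose_mg=d.amount_mg,
                                   MTT=ind.mtt_for_occasion(d.amount_mg, d.occasion),
                                   F=p.F, Ntr=p.Ntr))
        elif d.route == "iv_bolus":
            ivs.append((d.time, d.amount_mg * HC_NMOL_PER_MG))
    return tuple(orals), tuple(ivs)


def simulate_individual(ind, sc: Scenario, rtol=RTOL, atol=ATOL) -> SimOutput:
    """Deterministic trajectory (no residual error) on the scenario grid.

    ``ind`` is an :class:`~hpaxis.population.IndividualParams` or a
    :class:`~hpaxis.params.StructuralParams` (interpreted as the typical
    subject at ``sc.BW``). ``sc.activity`` overrides the parameter set's
    enzymatic-activity knob.
    """
    if isinstance(ind, StructuralParams):
        ind = population.typical_individual(ind, BW=sc.BW)
    p = ind.params.replace(activity=sc.activity)
    ind = replace(ind, params=p)

    t0 = sc.t_start - sc.warmup
    y0 = [p.Base, 0.0, 0.0, 0.0]
    t_eval = np.arange(sc.t_start, sc.t_end + 0.5 * sc.grid_step, sc.grid_step)
    orals, ivs = _build_inputs(ind, sc.doses)
    states, _ = integrate_model(p, t0, sc.t_end, y0, t_eval,
                                oral_inputs=orals, iv_events=ivs,
                                dex_windows=tuple(sc.dex_windows),
                                rtol=rtol, atol=atol)
    acth = np.maximum(states[0], 0.0)
    ct = np.maximum(states[2], 0.0) / p.Vc
    cu = unbound_from_total(ct, p)
    frame = pd.DataFrame({
        "time": t_eval,
        "clock": t_eval % 24.0,
        "acth": acth,
        "cortisol_total": ct,
        "cortisol_unbound": cu,
        "production_rate": model_core.cortisol_production_rate(acth, p),
        "feedback_factor": model_core.feedback_factor(cu, p),
    })
    return SimOutput(subject_id=ind.subject_id, frame=frame, params=p)


CHANNELS = ("acth", "cortisol_total", "cortisol_unbound")
_RUV_CHANNEL = {"acth": "ACTH", "cortisol_total": "cortisol_total",
                "cortisol_unbound": "cortisol_unbound"}


def simulate_population(theta: StructuralParams, omega: VarianceComponents,
                        sc: Scenario, n: int, rng_seed: int,
                        with_ruv: bool = False, rtol=RTOL, atol=ATOL):
    """Simulate ``n`` sampled subjects under one scenario.

    Returns ``(outputs, bands)`` where ``bands`` holds the 5th/50th/95th
    percentile of each channel at each grid time across subjects (the 90%
    prediction band of the population). With ``with_ruv`` the percentiles are
    taken over observations with proportional residual error applied.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng_seed)
    n_occ = len({d.occasion for d in sc.doses if d.route == "oral_granule"}) or 1
    outputs = []
    for i in range(n):
        ind = population.sample_individual(theta, omega, BW=sc.BW,
                                           n_occasions=n_occ, rng=rng,
                                           subject_id=i)
        outputs.append(simulate_individual(ind, sc, rtol=rtol, atol=atol))
    sig = {"acth": omega.sigma_prop_ACTH, "cortisol_total": omega.sigma_prop_cortisol,
           "cortisol_unbound": omega.sigma_prop_cortisol}
    stacks = {}
    for ch in CHANNELS:
        m = np.vstack([o.frame[ch].values for o in outputs])
        if with_ruv:
            m = np.vstack([
                population.apply_residual_error(row, _RUV_CHANNEL[ch], sig[ch], rng)
                for row in m])
        stacks[ch] = m
    bands = percentile_bands(stacks, outputs[0].frame["time"].values)
    return outputs, bands


def percentile_bands(stacks: dict, times) -> pd.DataFrame:
    """Tidy 5/50/95 percentile table from per-channel subject x time matrices."""
    rows = []
    for ch, m in stacks.items():
        p5, p50, p95 = np.percentile(m, [5, 50, 95], axis=0)
        rows.append(pd.DataFrame({"channel": ch, "time": times,
                                  "p5": p5, "p50": p50, "p95": p95}))
    return pd.concat(rows, ignore_index=True)


def cah_comparison(theta: StructuralParams, activities, n: int = 0,
                   rng_seed: int = 0, BW: float = 70.0, warmup: float = 72.0,
                   omega: VarianceComponents | None = None) -> pd.DataFrame:
    """Morning ACTH peak fold-change versus the healthy state per CAH severity.

    Fold-changes are computed on typical (zero-eta, noise-free) subjects; if
    ``n > 0`` the median over a sampled population is reported alongside.
    """
    activities = list(activities)
    if any(not 0.0 <= a <= 1.0 for a in activities):
        raise ValueError("activities must lie in [0, 1]")
    sc0 = Scenario(BW=BW, warmup=warmup, t_start=0.0, t_end=24.0)

    def typical_peak(act):
        out = simulate_individual(theta, replace_scenario(sc0, activity=act))
        return out.morning_acth_peak()[0]

    healthy = typical_peak(1.0)
    rows = []
    for act in activities:
        peak = typical_peak(act) if act != 1.0 else healthy
        row = {"activity": act, "acth_morning_peak_pmolL": peak,
               "fold_vs_healthy": peak / healthy}
        if n > 0:
            if omega is None:
                raise ValueError("omega required for population fold-changes")
            _, bands = simulate_population(
                theta, omega, replace_scenario(sc0, activity=act), n, rng_seed)
            b = bands[bands["channel"] == "acth"]
            morning = b[(b["time"] % 24 >= 3) & (b["time"] % 24 <= 10)]
            row["acth_morning_peak_median_pmolL"] = float(morning["p50"].max())
        rows.append(row)
    df = pd.DataFrame(rows)
    if n > 0:
        healthy_med = df.loc[df["activity"] == 1.0, "acth_morning_peak_median_pmolL"]
        if len(healthy_med):
            df["fold_vs_healthy_median"] = (
                df["acth_morning_peak_median_pmolL"] / float(healthy_med.iloc[0]))
    return df


def replace_scenario(sc: Scenario, **kw) -> Scenario:
    return replace(sc, **kw)


def dosing_time_comparison(theta: StructuralParams, dose_mg: float, times,
                           activity: float = 0.0, BW: float = 70.0,
                           warmup: float = 72.0) -> pd.DataFrame:
    """Compare hydrocortisone dosing clock times in (severe) CAH.

    Simulates the typical subject untreated, treated daily at each clock time
    in ``times``, and the healthy reference. Reports the morning ACTH peak,
    the first clock time total cortisol exceeds the total-cortisol equivalent
    of IC50, ACTH AUC over 00:00-12:00, and ratios to the untreated and
    healthy references.
    """
    total_ic50 = bound_from_unbound(theta.IC50, theta)
    sc0 = Scenario(BW=BW, warmup=warmup, t_start=0.0, t_end=24.0)

    def run(label, act, dose_clock=None):
        doses = []
        if dose_clock is not None and dose_mg > 0:
            # chronic daily dosing, including warm-up days
            day0 = int(np.floor((sc0.t_start - warmup) / 24.0)) - 1
            for day in range(day0, 2):
                doses.append(DoseEvent(time=24.0 * day + dose_clock,
                                       amount_mg=dose_mg, route="oral_granule",
                                       occasion=0))
        sc = replace_scenario(sc0, activity=act, doses=doses)
        out = simulate_individual(theta, sc)
        d = out._last_day()
        above = d[d["cortisol_total"] > total_ic50]
        first_above = float(above["clock"].iloc[0]) if len(above) else np.nan
        peak, peak_t = out.morning_acth_peak()
        return {"regimen": label, "acth_morning_peak_pmolL": peak,
                "acth_peak_clock_h": peak_t,
                "first_clock_total_above_ic50_h": first_above,
                "acth_auc_00_12_pmolL_h": out.acth_auc(0.0, 12.0)}

    rows = [run("untreated", activity)]
    for tt in times:
        rows.append(run(f"dose_{tt:05.2f}h", activity, dose_clock=tt))
    rows.append(run("healthy", 1.0))
    df = pd.DataFrame(rows)
    untreated = df.loc[df["regimen"] == "untreated"].iloc[0]
    healthy = df.loc[df["regimen"] == "healthy"].iloc[0]
    df["acth_peak_ratio_vs_untreated"] = (
        df["acth_morning_peak_pmolL"] / untreated["acth_morning_peak_pmolL"])
    df["acth_peak_ratio_vs_healthy"] = (
        df["acth_morning_peak_pmolL"] / healthy["acth_morning_peak_pmolL"])
    df["acth_auc_ratio_vs_untreated"] = (
        df["acth_auc_00_12_pmolL_h"] / untreated["acth_auc_00_12_pmolL_h"])
    return df


def vpc_summary(observed: pd.DataFrame, theta: StructuralParams,
                omega: VarianceComponents, n_sim: int, rng_seed: int,
                quantiles=(5.0, 50.0, 95.0), ci=90.0,
                rtol=1e-6, atol=1e-8, warmup: float = 24.0) -> pd.DataFrame:
    """Visual-predictive-check table: observed vs simulated percentiles.

    ``observed`` is an EventTable data frame. The same trial layout (same
    subjects' covariates, dosing and sampling times) is re-simulated ``n_sim``
    times with fresh random effects and residual error; within each
    (channel, time) bin the observed 5/50/95th percentiles are compared with
    the simulation-based ``ci``% interval of the same percentile. Bins with
    no observations are flagged rather than dropped.
    """
    from .estimate import periods_from_event_table, predict_period

    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    obs = observed[observed["EVID"] == 0].copy()
    if obs.empty:
        raise ValueError("no observation records in the event table")
    obs["t_abs"] = 24.0 * obs["DAY"] + obs["CLOCK"]

    subjects = periods_from_event_table(observed)
    rng = np.random.default_rng(rng_seed)

    def simulate_replicate():
        rows = []
        for sid, periods in subjects.items():
            bw = periods[0].BW
            n_occ = max((d.occasion for p_ in periods for d in p_.doses
                         if d.route == "oral_granule"), default=-1) + 1
            ind = population.sample_individual(theta, omega, BW=bw,
                                               n_occasions=max(n_occ, 1), rng=rng)
            for per in periods:
                pred = predict_period(ind, per, warmup=warmup, rtol=rtol, atol=atol)
                for (t_abs, ch), mu in pred.items():
                    sig = omega.sigma_prop_ACTH if ch == "acth_pmolL" \
                        else omega.sigma_prop_cortisol
                    dv = population.apply_residual_error(mu, "ACTH" if ch ==
                                                         "acth_pmolL" else "cortisol_total",
                                                         sig, rng)
                    rows.append((ch, round(t_abs, 6), dv))
        return pd.DataFrame(rows, columns=["DVTYPE", "t_abs", "DV"])

    bins = sorted({(ch, round(t, 6)) for ch, t in
                   zip(obs["DVTYPE"], obs["t_abs"])})
    qs = np.asarray(quantiles)
    sim_stats = np.full((n_sim, len(bins), qs.size), np.nan)
    for r in range(n_sim):
        rep = simulate_replicate()
        grouped = rep.groupby(["DVTYPE", "t_abs"])["DV"]
        stats = grouped.apply(lambda v: np.percentile(v, qs))
        for b, key in enumerate(bins):
            if key in stats.index:
                sim_stats[r, b, :] = stats.loc[key]

    lo_q, hi_q = (100.0 - ci) / 2.0, 100.0 - (100.0 - ci) / 2.0
    rows = []
    for b, (ch, t_abs) in enumerate(bins):
        sel = obs[(obs["DVTYPE"] == ch) & (np.isclose(obs["t_abs"], t_abs))]
        empty = sel.empty
        for k, q in enumerate(qs):
            obs_q = np.nan if empty else float(np.percentile(sel["DV"], q))
            sims = sim_stats[:, b, k]
            sims = sims[np.isfinite(sims)]
            lo = float(np.percentile(sims, lo_q)) if sims.size else np.nan
            hi = float(np.percentile(sims, hi_q)) if sims.size else np.nan
            if not empty and sims.size:
                # rank-based inclusion: for a calibrated model the observed
                # percentile is exchangeable with the replicates, so its rank
                # falls in the central ci% of [0, n_sim] with probability ci
                # (interpolated percentile endpoints are anti-conservative
                # at finite n_sim)
                rank = float(np.sum(sims < obs_q)
                             + 0.5 * np.sum(sims == obs_q))
                inside = (sims.size * lo_q / 100.0 <= rank
                          <= sims.size * hi_q / 100.0)
            else:
                inside = False
            rows.append({"channel": ch, "t_abs": t_abs, "quantile": q,
                         "observed": obs_q, "sim_lo": lo, "sim_hi": hi,
                         "inside": bool(inside), "empty_bin": empty})
    return pd.DataFrame(rows)
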