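"""Desk-scale parameter estimation for the joint HPA / hydrocortisone model.

The estimation workflow mirrors a three-step population analysis:

* **Step 1 (PK)** — hydrocortisone kinetics fitted on DEX-suppressed periods
  only. Because dexamethasone (DEX) clamps ACTH at its baseline, the
  endogenous contribution in those periods is a constant zero-order cortisol
  input, so each period reduces to a fast 3-state problem with an analytic
  pre-dose steady state. Per-subject parameters are estimated by weighted
  least squares; typical values are pooled (geometric means on the
  covariate-normalized scale; the dose-MTT power law by log-log regression
  across occasions).
* **Step 2 (endogenous)** — ACTH secretion, cortisol production and feedback
  parameters fitted on the endogenous 24-h profiles plus the DEX-only
  period, with each subject's PK fixed at its Step-1 individual estimates.
  Alternates per-subject MAP fits of the random effects with pooled
  refinement of the fixed effects.
* **Step 3 (joint)** — all free fixed effects re-estimated together from the
  Step-2 values on the complete dataset.

This is a two-stage / MAP-EBE emulation of a full nonlinear mixed-effects
fit: variance components are held fixed at their supplied values and the
marginal likelihood is approximated by the joint (fixed effects + posterior
mode) objective. Weakly identified parameters (Ka; the Hill exponents and
Imax around the feedback plateau) are excluded from estimation by default.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from . import model_core, population
from .population import _OMEGA_BY_PARAM
from .model_core import OralInput, bound_from_unbound, unbound_from_total
from .params import HC_NMOL_PER_MG, StructuralParams, VarianceComponents
from .simulate import DoseEvent, integrate_model

__all__ = ["PeriodSpec", "FitResult", "periods_from_event_table",
           "predict_period", "neg2ll_individual", "map_fit", "stepwise_fit",
           "profile_or_bootstrap_se"]

log = logging.getLogger(__name__)

_PRED_FLOOR = 1e-3   # concentration floor for the proportional-error scale
LOG2PI = math.log(2.0 * math.pi)

#: parameters never estimated (fixed by convention in the reference model)
NEVER_ESTIMATED = ("n_surge", "I_DEX", "Imax", "NS", "Kd", "Bmax",
                   "theta_BW_SA1", "Ka", "activity")

CHANNEL_SIGMA = {"acth_pmolL": "sigma_prop_ACTH",
                 "cortisol_total_nmolL": "sigma_prop_cortisol",
                 "cortisol_unbound_nmolL": "sigma_prop_cortisol"}


@dataclass
class PeriodSpec:
    """One subject-period: regimen, DEX window and observation schedule."""

    subject_id: int
    period: int
    occasion: int
    kind: str                 # "endogenous" | "dex"
    BW: float
    age: float
    doses: list               # DoseEvent on the absolute time axis (no dex markers)
    dex_windows: list         # [(t_on, t_off)]
    obs: pd.DataFrame         # columns t_abs, DVTYPE, DV

    @property
    def has_iv(self) -> bool:
        return any(d.route == "iv_bolus" for d in self.doses)

    @property
    def has_oral(self) -> bool:
        return any(d.route == "oral_granule" for d in self.doses)


def periods_from_event_table(df: pd.DataFrame) -> dict:
    """Split a validated event table into per-subject :class:`PeriodSpec` lists."""
    out: dict[int, list[PeriodSpec]] = {}
    t_abs = 24.0 * df["DAY"] + df["CLOCK"]
    df = df.assign(_t=t_abs)
    for (sid, per), g in df.groupby(["ID", "PERIOD"], sort=True):
        doses, markers = [], []
        for _, r in g[g["EVID"] == 1].iterrows():
            if r["ROUTE"] == "dex_marker":
                markers.append(r["_t"])
            else:
                doses.append(DoseEvent(time=r["_t"], amount_mg=r["AMT_MG"],
                                       route=r["ROUTE"], occasion=int(r["OCC"])))
        obs = g[g["EVID"] == 0][["_t", "DVTYPE", "DV"]].rename(
            columns={"_t": "t_abs"}).reset_index(drop=True)
        t_end = float(g["_t"].max()) + 0.5
        dex_windows = [(float(m), t_end) for m in markers]
        spec = PeriodSpec(
            subject_id=int(sid), period=int(per),
            occasion=int(g["OCC"].iloc[0]),
            kind="dex" if markers else "endogenous",
            BW=float(g["BW_KG"].iloc[0]), age=float(g["AGE_Y"].iloc[0]),
            doses=doses, dex_windows=dex_windows, obs=obs)
        out.setdefault(int(sid), []).append(spec)
    return out


def _oral_inputs(ind: population.IndividualParams, doses):
    orals, ivs = [], []
    for d in doses:
        if d.route == "oral_granule":
            orals.append(OralInput(t_dose=d.time, dose_mg=d.amount_mg,
                                   MTT=ind.mtt_for_occasion(d.amount_mg, d.occasion),
                                   F=ind.params.F, Ntr=ind.params.Ntr))
        elif d.route == "iv_bolus":
            ivs.append((d.time, d.amount_mg * HC_NMOL_PER_MG))
    return tuple(orals), tuple(ivs)


def predict_period(ind: population.IndividualParams, spec: PeriodSpec,
                   mode: str = "full", warmup: float = 48.0,
                   rtol: float = 1e-6, atol: float = 1e-8,
                   const_production: float | None = None,
                   max_step: float | None = None) -> dict:
    """Model predictions at the period's observation times.

    ``mode="full"`` integrates the complete joint model, starting ``warmup``
    hours before the first event from ACTH at baseline and empty cortisol
    states. ``mode="pk_only"`` exploits the DEX clamp: enzymatic production
    is replaced by the constant input ``const_production`` (default: the
    production rate at the subject's baseline ACTH) and the integration
    starts directly from the analytic pre-dose steady state — valid only for
    DEX-suppressed periods. Returns ``{(t_abs, DVTYPE): prediction}``.
    """
    p = ind.params
    times = np.sort(spec.obs["t_abs"].unique()) if len(spec.obs) else np.array([])
    events = [d.time for d in spec.doses] + [w[0] for w in spec.dex_windows]
    anchor = min([times[0] if times.size else np.inf] + events)
    if not np.isfinite(anchor):
        return {}
    t_end = max([times[-1] if times.size else -np.inf] + events) + 1e-6
    orals, ivs = _oral_inputs(ind, spec.doses)

    if mode == "pk_only":
        if spec.kind != "dex":
            raise ValueError("pk_only predictions require a DEX-suppressed period")
        if const_production is None:
            const_production = model_core.cortisol_production_rate(
                p.Base, p.replace(activity=1.0))
        p = p.replace(activity=0.0)
        cu0 = const_production / p.CL
        y0 = [p.Base, 0.0, bound_from_unbound(cu0, p) * p.Vc, cu0 * p.Vp]
        t0 = anchor - 0.25
        dex = [(t0, t_end + 1.0)]
        # no active surges under the DEX clamp: larger steps are safe
        max_step = 2.0 if max_step is None else max_step
    elif mode == "full":
        y0 = [p.Base, 0.0, 0.0, 0.0]
        t0 = anchor - warmup
        dex = list(spec.dex_windows)
        const_production = 0.0
    else:
        raise ValueError(f"unknown prediction mode {mode!r}")

    states, _ = integrate_model(p, t0, t_end, y0, times, oral_inputs=orals,
                                iv_events=ivs, dex_windows=dex,
                                rtol=rtol, atol=atol,
                                max_step=max_step if max_step is not None else 0.25,
                                const_production=const_production)
    acth = np.maximum(states[0], 0.0)
    ct = np.maximum(states[2], 0.0) / p.Vc
    cu = unbound_from_total(ct, p)
    by_time = {t: (a, c, u) for t, a, c, u in zip(times, acth, ct, cu)}
    preds = {}
    for t in times:
        a, c, u = by_time[t]
        preds[(t, "acth_pmolL")] = float(a)
        preds[(t, "cortisol_total_nmolL")] = float(c)
        preds[(t, "cortisol_unbound_nmolL")] = float(u)
    return preds


def _spec_residuals(specs, ind, sigmas, mode="full", channels=None,
                    scales=None, **kw):
    """Stacked proportional residuals and their log-variances.

    By default residuals are scaled by the likelihood error SD sigma*pred
    (the proportional-error model). The least-squares fitting stages instead
    pass ``scales`` — error SDs frozen at a reference prediction (IRLS): a
    current-prediction scale inside a pure least-squares cost would reward
    systematic over-prediction, an observation-based scale the reverse.
    """
    res, logvars = [], []
    i = 0
    for spec in specs:
        preds = predict_period(ind, spec, mode=mode, **kw)
        for t, ch, dv in zip(spec.obs["t_abs"].values, spec.obs["DVTYPE"].values,
                             spec.obs["DV"].values):
            if channels is not None and ch not in channels:
                continue
            pred = max(preds[(t, ch)], _PRED_FLOOR)
            sd = sigmas[CHANNEL_SIGMA[ch]] * pred
            scale = sd if scales is None else scales[i]
            res.append((dv - pred) / scale)
            logvars.append(2.0 * math.log(sd))
            i += 1
    return np.asarray(res), np.asarray(logvars)


def _frozen_scales(specs, ind, sigmas, mode="full", channels=None, **kw):
    """Error SDs sigma*max(pred, floor) at a reference parameter point."""
    out = []
    for spec in specs:
        preds = predict_period(ind, spec, mode=mode, **kw)
        for t, ch in zip(spec.obs["t_abs"].values, spec.obs["DVTYPE"].values):
            if channels is not None and ch not in channels:
                continue
            pred = max(preds[(t, ch)], _PRED_FLOOR)
            out.append(sigmas[CHANNEL_SIGMA[ch]] * pred)
    return np.asarray(out)


def neg2ll_individual(specs, ind: population.IndividualParams, sigmas,
                      mode: str = "full", channels=None, **kw) -> float:
    """-2 log-likelihood of one subject's observations under proportional error.

    ``sigmas`` maps ``sigma_prop_ACTH``/``sigma_prop_cortisol`` to fractional
    SDs (a :class:`~hpaxis.params.VarianceComponents` works). Predictions at
    or below the floor of 1e-3 concentration units are floored for the error
    scale.
    """
    if isinstance(sigmas, VarianceComponents):
        sigmas = sigmas.to_dict()
    r, logvar = _spec_residuals(specs, ind, sigmas, mode=mode,
                                channels=channels, **kw)
    return float(np.sum(r * r) + np.sum(logvar) + r.size * LOG2PI)


@dataclass
class FitResult:
    """Outcome of one estimation step."""

    step: str
    fixed_effects: dict
    ebes: dict = field(default_factory=dict)       # sid -> {eta name: value}
    neg2ll: float = math.nan
    converged: bool = True
    n_obs: int = 0
    diagnostics: dict = field(default_factory=dict)

    @property
    def theta(self) -> StructuralParams:
        return StructuralParams.from_dict(self.fixed_effects)


# ---------------------------------------------------------------------------
# MAP / EBE fit of random effects for one subject
# ---------------------------------------------------------------------------

def _build_individual(theta, BW, etas, occ_mtt_eta, sid, pk_overrides=None):
    ind = population._individual_from_etas(theta, BW, etas, occ_mtt_eta, sid, 40.0)
    if pk_overrides:
        ind = population.IndividualParams(
            subject_id=ind.subject_id, BW=ind.BW, age=ind.age, etas=ind.etas,
            occ_mtt_factor=ind.occ_mtt_factor,
            params=ind.params.replace(**pk_overrides))
    return ind


def map_fit(specs, theta: StructuralParams, omega: VarianceComponents, BW: float,
            iiv_names=("SA1", "Kout", "Base", "EC50"), iov_occasions=(),
            subject_id: int = 0, mode: str = "full", sigmas=None,
            pk_overrides=None, n_starts: int = 3, tol: float = 1e-6,
            max_nfev: int = 60, **predict_kw):
    """Posterior-mode (MAP) estimate of one subject's random effects.

    Minimizes the individual -2 log-likelihood plus the Gaussian prior
    ``eta' Omega^-1 eta`` over the named etas (plus one MTT IOV eta per
    occasion in ``iov_occasions``). Gauss-Newton on the stacked
    (data, prior) residuals with ``n_starts`` starting points including
    zero; best solution by the exact objective. Returns
    ``(etas, iov_etas, info)``; an empty observation set returns the prior
    mode (all zeros).
    """
    sigmas = (sigmas or VarianceComponents())
    if isinstance(sigmas, VarianceComponents):
        sigmas = sigmas.to_dict()
    n_obs = sum(len(s.obs) for s in specs)
    iiv_names = list(iiv_names)
    iov_occasions = list(iov_occasions)
    k = len(iiv_names) + len(iov_occasions)
    if n_obs == 0 or k == 0:
        return ({n: 0.0 for n in iiv_names},
                {o: 0.0 for o in iov_occasions},
                {"converged": True, "n_obs": n_obs, "objective": 0.0})

    # prior covariance on the free eta block
    cov = np.zeros((k, k))
    for i, name in enumerate(iiv_names):
        w = getattr(omega, population._OMEGA_BY_PARAM[name])
        if w <= 0:
            raise ValueError(f"map_fit requires omega > 0 for eta on {name!r}")
        cov[i, i] = w * w
    if "Base" in iiv_names and "EC50" in iiv_names:
        block, _ = omega.base_ec50_cov_matrix()
        i, j = iiv_names.index("Base"), iiv_names.index("EC50")
        cov[i, j] = cov[j, i] = block[0, 1]
    for j, _occ in enumerate(iov_occasions):
        if omega.omega_IOV_MTT <= 0:
            raise ValueError("map_fit requires omega_IOV_MTT > 0 for IOV etas")
        jj = len(iiv_names) + j
        cov[jj, jj] = omega.omega_IOV_MTT ** 2
    L = np.linalg.cholesky(cov)
    Linv = np.linalg.inv(L)

    def split(x):
        etas = dict(zip(iiv_names, x[:len(iiv_names)]))
        iov = dict(zip(iov_occasions, x[len(iiv_names):]))
        return etas, iov

    ind0 = _build_individual(theta, BW, {n: 0.0 for n in iiv_names},
                             {o: 0.0 for o in iov_occasions}, subject_id,
                             pk_overrides)
    sd_ref = _frozen_scales(specs, ind0, sigmas, mode=mode, **predict_kw)

    def residuals(x):
        try:
            etas, iov = split(x)
            ind = _build_individual(theta, BW, etas, iov, subject_id, pk_overrides)
            r, _ = _spec_residuals(specs, ind, sigmas, mode=mode,
                                   scales=sd_ref, **predict_kw)
            return np.concatenate([r, Linv @ x])
        except (RuntimeError, ArithmeticError):
            return np.full(n_obs + k, 1e6)

    def exact_objective(x):
        etas, iov = split(x)
        ind = _build_individual(theta, BW, etas, iov, subject_id, pk_overrides)
        n2 = neg2ll_individual(specs, ind, sigmas, mode=mode, **predict_kw)
        return n2 + float(x @ np.linalg.solve(cov, x))

    sds = np.sqrt(np.diag(cov))
    starts = [np.zeros(k)]
    for s in (0.5, -0.5):
        if len(starts) >= max(n_starts, 1):
            break
        starts.append(s * sds)
    best = None
    for x0 in starts[:max(n_starts, 1)]:
        try:
            sol = least_squares(residuals, x0, method="lm", xtol=tol, ftol=tol,
                                diff_step=1e-3, max_nfev=max_nfev)
        except Exception as exc:  # pragma: no cover - numerical corner
            log.warning("map_fit start failed: %s", exc)
            continue
        obj = exact_objective(sol.x)
        if best is None or obj < best[1]:
            best = (sol, obj)
    if best is None:
        log.warning("map_fit: all starts failed for subject %s", subject_id)
        zeros = np.zeros(k)
        etas, iov = split(zeros)
        return etas, iov, {"converged": False, "n_obs": n_obs,
                           "objective": exact_objective(zeros)}
    sol, obj = best
    etas, iov = split(sol.x)
    return etas, iov, {"converged": bool(sol.success), "n_obs": n_obs,
                       "objective": obj, "nfev": sol.nfev}


# ---------------------------------------------------------------------------
# stepwise workflow
# ---------------------------------------------------------------------------

def _hill_ridge_member(theta: StructuralParams, phi: float,
                      a_star: float = 5.0) -> StructuralParams | None:
    """Production triple with EC50 scaled by exp(phi), preserving the curve's
    value and log-log slope at the operating ACTH level ``a_star``.

    The healthy data constrain the sigmoidal production curve mainly around
    a_star (and at Base through the DEX-period baseline), leaving a soft
    one-dimensional ridge through (Emax, EC50, gammaE); this parametrizes
    that ridge so a cheap profile search can traverse it.
    """
    r0 = (a_star / theta.EC50) ** theta.gammaE
    v0 = theta.Emax * r0 / (1.0 + r0)              # value at a_star
    s0 = theta.gammaE / (1.0 + r0)                 # d log v / d log A
    ec50 = theta.EC50 * math.exp(phi)
    q = math.log(a_star / ec50)
    # solve r = (a_star/ec50)^(s0*(1+r)) for r > 0
    r = r0
    for _ in range(80):
        r_new = math.exp(s0 * (1.0 + r) * q)
        if not np.isfinite(r_new) or r_new > 1e6:
            return None
        if abs(r_new - r) < 1e-12 * max(r, 1.0):
            r = r_new
            break
        r = 0.5 * r + 0.5 * r_new
    gamma = s0 * (1.0 + r)
    emax = v0 * (1.0 + r) / r
    if not (0.5 < gamma < 10.0 and 0.0 < emax < 1e6):
        return None
    try:
        return theta.replace(EC50=ec50, gammaE=gamma, Emax=emax)
    except ValueError:
        return None


#: default free fixed effects per step
FREE_STEP1 = ("F", "CL", "Vc", "Q", "Vp", "MTT_ref", "theta_dose_MTT", "Ntr")
FREE_STEP2 = ("SA1", "SW1", "Pt1", "SA2", "SW2", "Pt2", "Kout", "Base",
              "Emax", "EC50", "gammaE", "IC50", "gammaI")
FREE_STEP3 = FREE_STEP1 + FREE_STEP2

_ALLO = {"CL": 0.75, "Q": 0.75, "Vc": 1.0, "Vp": 1.0}
_PK_IIV = ("F", "CL", "Vp", "Ntr")   # PK parameters carrying IIV


def _bw_scale(name, BW):
    return (BW / 70.0) ** _ALLO.get(name, 0.0)


def _gmean(values):
    values = np.asarray(values, dtype=float)
    return float(np.exp(np.mean(np.log(values))))


def _pool_pk(per_subject: dict, theta: StructuralParams,
             subset=None) -> dict:
    """Pool per-subject PK estimates into typical values.

    Geometric means on the allometry-normalized scale; the dose-MTT power law
    by OLS of log(MTT) on log(dose/5) across all subject-occasions.
    """
    sids = sorted(per_subject) if subset is None else list(subset)
    pooled = {}
    for name in ("CL", "Vc", "Q", "Vp", "F", "Ntr"):
        vals = [per_subject[s][name] / _bw_scale(name, per_subject[s]["BW"])
                for s in sids if name in per_subject[s]]
        if vals:
            pooled[name] = min(_gmean(vals), 1.0) if name == "F" else _gmean(vals)
    xs, ys = [], []
    for s in sids:
        for (dose, mtt) in per_subject[s].get("MTT_points", []):
            xs.append(math.log(dose / 5.0))
            ys.append(math.log(mtt))
    if xs:
        slope, intercept = np.polyfit(xs, ys, 1) if len(set(xs)) > 1 else (
            theta.theta_dose_MTT, float(np.mean(ys)))
        pooled["MTT_ref"] = float(np.exp(intercept))
        pooled["theta_dose_MTT"] = float(slope)
    return pooled


#: prior SD of the log constant-baseline input b (propagates the Base IIV
#: through the steep production curve, ~ gammaE * omega_Base)
_B_PRIOR_SD = 0.75


def _individual_for_step2(theta, BW, sid, pk_est, etas):
    """Individual with PK fixed at step-1 estimates and endo etas applied."""
    pk_overrides = {k: pk_est[k] for k in ("CL", "Vc", "Q", "Vp", "F", "Ntr")
                    if k in pk_est}
    return _build_individual(theta, BW, etas, {}, sid, pk_overrides)


def _theta_with(theta: StructuralParams, names, x) -> StructuralParams:
    updates = {}
    for n, v in zip(names, x):
        if n in ("Pt1", "Pt2"):
            updates[n] = float(v) % 24.0
        else:
            # clip the log value: keeps the optimizer from wandering into
            # overflow territory during trial steps
            updates[n] = float(np.exp(np.clip(v, -20.0, 20.0)))
    if updates.get("F", 0.0) > 1.0:
        updates["F"] = 1.0
    return theta.replace(**updates)


def _pack_theta(theta: StructuralParams, names):
    return np.array([getattr(theta, n) if n in ("Pt1", "Pt2")
                     else math.log(getattr(theta, n)) for n in names])


def stepwise_fit(table: pd.DataFrame, theta_init: StructuralParams | None = None,
                 omega: VarianceComponents | None = None,
                 free_step1=FREE_STEP1, free_step2=FREE_STEP2,
                 free_step3=FREE_STEP3, fit_etas: bool = True,
                 n_outer: int = 2, rtol: float = 1e-6, atol: float = 1e-8,
                 warmup: float = 24.0, max_nfev_pooled: int = 10,
                 likelihood_polish: bool = True,
                 verbose: bool = False) -> list[FitResult]:
    """Three-step estimation on an event table; returns one FitResult per step.

    Variance components (``omega``, including the residual sigmas) are held
    fixed. Passing empty ``free_step*`` tuples (and ``fit_etas=False``)
    performs a zero-iteration fit that returns ``theta_init`` unchanged.
    """
    theta = theta_init or StructuralParams()
    omega = omega or VarianceComponents()
    sigmas = omega.to_dict()
    subjects = periods_from_event_table(table)
    dex_specs = {s: [p for p in specs if p.kind == "dex"]
                 for s, specs in subjects.items()}
    endo_specs = {s: [p for p in specs if p.kind == "endogenous"
                      or (p.kind == "dex" and not p.doses)]
                  for s, specs in subjects.items()}
    endo_sids = [s for s, specs in endo_specs.items()
                 if any(p.kind == "endogenous" for p in specs)]
    if not any(dex_specs.values()):
        raise ValueError("no DEX-suppressed periods in the dataset (required for Step 1)")
    if not endo_sids:
        raise ValueError("no endogenous period in the dataset (required for Step 2)")
    results = []

    # ------- Step 1: PK on DEX periods (joint penalized least squares) -------
    # Fixed effects and every subject's random effects (etas on F/CL/Vp/Ntr,
    # one MTT IOV eta per oral occasion, the log baseline input b) are
    # estimated together in one sparse Gauss-Newton problem with the Gaussian
    # eta priors as extra residual rows. Error scales are frozen at the
    # current iterate and refreshed once (IRLS), so the pure least-squares
    # cost stays an unbiased surrogate for the proportional-error likelihood.
    pk_sids = sorted(s for s in dex_specs if dex_specs[s])
    pk_kw = dict(mode="pk_only", channels=("cortisol_total_nmolL",
                                           "cortisol_unbound_nmolL"),
                 rtol=rtol, atol=atol)
    occ_dose_by_sid = {sid: {d.occasion: d.amount_mg for p_ in dex_specs[sid]
                             for d in p_.doses if d.route == "oral_granule"}
                       for sid in pk_sids}
    theta1 = theta
    pk_ests: dict[int, dict] = {}

    def _b0_for(sid):
        # anchor the baseline input to the pre-dose cortisol level
        base = model_core.apply_covariates(theta, dex_specs[sid][0].BW)
        pre = []
        for p_ in dex_specs[sid]:
            cort = p_.obs[p_.obs["DVTYPE"] == "cortisol_total_nmolL"]
            if len(cort):
                pre.append(float(cort.sort_values("t_abs")["DV"].iloc[0]))
        if not pre:
            return model_core.cortisol_production_rate(
                theta.Base, theta.replace(activity=1.0))
        ct = max(float(np.median(pre)), 1.0)
        return base.CL * unbound_from_total(ct, base)

    names1 = [n for n in free_step1 if n not in NEVER_ESTIMATED]
    if names1 and pk_sids:
        nf = len(names1)
        layout = {sid: ([("eta", n) for n in _PK_IIV]
                        + [("iov", o) for o in sorted(occ_dose_by_sid[sid])]
                        + [("b", None)]) for sid in pk_sids}
        offs, pos = {}, nf
        for sid in pk_sids:
            offs[sid] = pos
            pos += len(layout[sid])
        nx = pos
        x0 = np.zeros(nx)
        x0[:nf] = _pack_theta(theta, names1)
        b0 = {sid: _b0_for(sid) for sid in pk_sids}
        prior_center = np.zeros(nx - nf)
        prior_sd = np.empty(nx - nf)
        for sid in pk_sids:
            for j, (kind, key) in enumerate(layout[sid]):
                i = offs[sid] + j - nf
                if kind == "eta":
                    w = getattr(omega, _OMEGA_BY_PARAM[key])
                elif kind == "iov":
                    w = omega.omega_IOV_MTT
                else:
                    x0[offs[sid] + j] = math.log(b0[sid])
                    prior_center[i] = math.log(b0[sid])
                    w = _B_PRIOR_SD
                prior_sd[i] = max(w, 1e-6)   # omega=0 pins the eta at zero

        def build_subject_pk(th, x, sid):
            base = model_core.apply_covariates(th, dex_specs[sid][0].BW)
            over, occf, b = {}, {}, b0[sid]
            for j, (kind, key) in enumerate(layout[sid]):
                v = float(x[offs[sid] + j])
                if kind == "eta":
                    over[key] = getattr(base, key) * math.exp(v)
                elif kind == "iov":
                    occf[key] = math.exp(v)
                else:
                    b = math.exp(v)
            over["F"] = min(over.get("F", base.F), 1.0)
            over["Ntr"] = min(over.get("Ntr", base.Ntr), 15.0)
            ind = population.IndividualParams(
                subject_id=sid, BW=dex_specs[sid][0].BW, etas={},
                occ_mtt_factor=occf, params=base.replace(**over))
            return ind, b

        n_data_by_sid = {sid: sum(int((p_.obs["DVTYPE"] != "acth_pmolL").sum())
                                  for p_ in dex_specs[sid]) for sid in pk_sids}
        n_data = sum(n_data_by_sid.values())

        def make_resid(scales_by_sid):
            def residuals(x):
                th = _theta_with(theta, names1, x[:nf])
                parts = []
                for sid in pk_sids:
                    try:
                        ind, b = build_subject_pk(th, x, sid)
                        r, _ = _spec_residuals(dex_specs[sid], ind, sigmas,
                                               scales=scales_by_sid[sid],
                                               const_production=b, **pk_kw)
                    except (RuntimeError, ArithmeticError):
                        r = np.full(n_data_by_sid[sid], 1e3)
                    parts.append(r)
                parts.append((x[nf:] - prior_center) / prior_sd)
                return np.concatenate(parts)
            return residuals

        from scipy.sparse import lil_matrix

        spar = lil_matrix((n_data + nx - nf, nx), dtype=int)
        row = 0
        for sid in pk_sids:
            n = n_data_by_sid[sid]
            spar[row:row + n, :nf] = 1
            spar[row:row + n, offs[sid]:offs[sid] + len(layout[sid])] = 1
            row += n
        for i in range(nx - nf):
            spar[row + i, nf + i] = 1

        x_cur = x0.copy()
        for irls in range(max(n_outer, 1)):
            th_c = _theta_with(theta, names1, x_cur[:nf])
            sd_by_sid = {}
            for sid in pk_sids:
                ind, b = build_subject_pk(th_c, x_cur, sid)
                sd_by_sid[sid] = _frozen_scales(dex_specs[sid], ind, sigmas,
                                                const_production=b, **pk_kw)
            sol = least_squares(make_resid(sd_by_sid), x_cur, method="trf",
                                jac_sparsity=spar, diff_step=1e-3,
                                xtol=1e-9, ftol=1e-9, x_scale="jac",
                                bounds=(x0 - 2.5, x0 + 2.5),
                                max_nfev=max_nfev_pooled * (4 if irls else 10))
            x_cur = sol.x
            if verbose:
                log.info("step 1 irls %d: cost %.1f nfev %d", irls,
                         2 * sol.cost, sol.nfev)
        theta1 = _theta_with(theta, names1, x_cur[:nf])
        for sid in pk_sids:
            ind, b = build_subject_pk(theta1, x_cur, sid)
            est = {"BW": dex_specs[sid][0].BW, "b": b, "converged": True}
            for n in ("CL", "Vc", "Q", "Vp", "F", "Ntr"):
                est[n] = getattr(ind.params, n)
            est["MTT_points"] = [
                (dose, model_core.mtt_for_dose(dose, theta1)
                 * ind.occ_mtt_factor.get(occ, 1.0))
                for occ, dose in sorted(occ_dose_by_sid[sid].items())]
            pk_ests[sid] = est
    else:
        for sid in pk_sids:
            bw = dex_specs[sid][0].BW
            base = model_core.apply_covariates(theta, bw)
            pk_ests[sid] = {"BW": bw, **{n: getattr(base, n) for n in
                                         ("CL", "Vc", "Q", "Vp", "F", "Ntr")},
                            "MTT_points": []}

    ebes1 = {}
    for sid, est in pk_ests.items():
        base = model_core.apply_covariates(theta1, est["BW"])
        ebes1[sid] = {n: math.log(est[n] / getattr(base, n))
                      for n in _PK_IIV if n in est}
    res1 = FitResult(step="step1_pk", fixed_effects=theta1.to_dict(),
                     ebes=ebes1,
                     n_obs=sum(len(p.obs) for specs in dex_specs.values()
                               for p in specs),
                     diagnostics={"per_subject": pk_ests})
    results.append(res1)
    if verbose:
        log.info("step 1 done: %s", {k: round(v, 3) for k, v in
                                     res1.fixed_effects.items() if k in FREE_STEP1})

    # ------- Step 2: endogenous model (joint penalized least squares) -------
    theta2 = theta1
    ebes2: dict[int, dict] = {s: {} for s in endo_sids}
    endo_iiv = ("SA1", "Kout", "Base", "EC50")
    names2 = [n for n in free_step2 if n not in NEVER_ESTIMATED]
    if names2 and endo_sids:
        nf2 = len(names2)
        offs2 = {sid: nf2 + 4 * i for i, sid in enumerate(endo_sids)}
        nx2 = nf2 + 4 * len(endo_sids)
        x0 = np.zeros(nx2)
        x0[:nf2] = _pack_theta(theta1, names2)
        # prior: correlated (Base, EC50) block plus independent SA1/Kout etas
        cov2, _ = omega.base_ec50_cov_matrix()
        omega4 = np.zeros((4, 4))
        omega4[0, 0] = max(omega.omega_SA1, 1e-6) ** 2
        omega4[1, 1] = max(omega.omega_Kout, 1e-6) ** 2
        omega4[2:, 2:] = cov2 if cov2[0, 0] > 0 else np.eye(2) * 1e-12
        Linv2 = np.linalg.inv(np.linalg.cholesky(omega4 + np.eye(4) * 1e-12))

        def build_subject_endo(th, x, sid):
            etas = {n: float(x[offs2[sid] + j])
                    for j, n in enumerate(endo_iiv)}
            return _individual_for_step2(th, endo_specs[sid][0].BW, sid,
                                         pk_ests[sid], etas), etas

        n2_by_sid = {sid: sum(len(p_.obs) for p_ in endo_specs[sid])
                     for sid in endo_sids}
        n_data2 = sum(n2_by_sid.values())

        def endo_subject_resid(th, ind, sid, scales):
            parts, i = [], 0
            for spec in endo_specs[sid]:
                mode = "full" if spec.kind == "endogenous" else "pk_only"
                kw = {"warmup": warmup} if mode == "full" else {}
                n = len(spec.obs)
                sl = scales[i:i + n] if scales is not None else None
                r, _ = _spec_residuals([spec], ind, sigmas, mode=mode,
                                       scales=sl, rtol=rtol, atol=atol, **kw)
                parts.append(r)
                i += n
            return np.concatenate(parts)

        def make_resid2(sd_by_sid):
            def residuals(x):
                th = _theta_with(theta1, names2, x[:nf2])
                parts = []
                for sid in endo_sids:
                    try:
                        ind, _ = build_subject_endo(th, x, sid)
                        r = endo_subject_resid(th, ind, sid, sd_by_sid[sid])
                    except (RuntimeError, ArithmeticError):
                        r = np.full(n2_by_sid[sid], 1e3)
                    parts.append(r)
                for sid in endo_sids:
                    parts.append(Linv2 @ x[offs2[sid]:offs2[sid] + 4])
                return np.concatenate(parts)
            return residuals

        from scipy.sparse import lil_matrix

        spar2 = lil_matrix((n_data2 + 4 * len(endo_sids), nx2), dtype=int)
        row = 0
        for sid in endo_sids:
            n = n2_by_sid[sid]
            spar2[row:row + n, :nf2] = 1
            spar2[row:row + n, offs2[sid]:offs2[sid] + 4] = 1
            row += n
        for k, sid in enumerate(endo_sids):
            spar2[row + 4 * k:row + 4 * k + 4, offs2[sid]:offs2[sid] + 4] = 1

        x_cur = x0.copy()
        for irls in range(max(n_outer, 1)):
            th_c = _theta_with(theta1, names2, x_cur[:nf2])
            sd_by_sid = {}
            for sid in endo_sids:
                ind, _ = build_subject_endo(th_c, x_cur, sid)
                sd_by_sid[sid] = _frozen_scales(
                    [sp for sp in endo_specs[sid]], ind, sigmas,
                    mode="full", rtol=rtol, atol=atol, warmup=warmup)                     if all(sp.kind == "endogenous" for sp in endo_specs[sid])                     else np.concatenate([
                        _frozen_scales([sp], ind, sigmas,
                                       mode="full" if sp.kind == "endogenous"
                                       else "pk_only",
                                       rtol=rtol, atol=atol,
                                       **({"warmup": warmup}
                                          if sp.kind == "endogenous" else {}))
                        for sp in endo_specs[sid]])
            sol = least_squares(make_resid2(sd_by_sid), x_cur, method="trf",
                                jac_sparsity=spar2, diff_step=1e-3,
                                xtol=1e-9, ftol=1e-9, x_scale="jac",
                                bounds=(x0 - 2.5, x0 + 2.5),
                                max_nfev=max_nfev_pooled * (4 if irls else 10))
            x_cur = sol.x
            if verbose:
                log.info("step 2 irls %d: cost %.1f nfev %d", irls,
                         2 * sol.cost, sol.nfev)
        theta2 = _theta_with(theta1, names2, x_cur[:nf2])
        for sid in endo_sids:
            _, etas = build_subject_endo(theta2, x_cur, sid)
            ebes2[sid] = etas
    elif fit_etas and endo_sids:
        for sid in endo_sids:
            pk_over = {k: pk_ests[sid][k] for k in
                       ("CL", "Vc", "Q", "Vp", "F", "Ntr") if k in pk_ests[sid]}
            etas, _, _ = map_fit(endo_specs[sid], theta2, omega,
                                 endo_specs[sid][0].BW, iiv_names=endo_iiv,
                                 subject_id=sid, mode="full", sigmas=sigmas,
                                 pk_overrides=pk_over, n_starts=1,
                                 rtol=rtol, atol=atol, warmup=warmup,
                                 max_nfev=25)
            ebes2[sid] = etas
    res2 = FitResult(step="step2_endogenous", fixed_effects=theta2.to_dict(),
                     ebes=ebes2,
                     n_obs=sum(len(p.obs) for s in endo_sids
                               for p in endo_specs[s]))
    results.append(res2)

    # ---------------- Step 3: joint re-estimation ----------------
    names3 = [n for n in free_step3 if n not in NEVER_ESTIMATED]
    iov3 = {}
    for sid, est in pk_ests.items():
        occ_d = {d.occasion: d.amount_mg for p_ in subjects[sid] for d in p_.doses
                 if d.route == "oral_granule"}
        iov3[sid] = {}
        for dose, mtt in est.get("MTT_points", []):
            occ = [o for o, dmg in occ_d.items() if dmg == dose][0]
            iov3[sid][occ] = mtt / model_core.mtt_for_dose(dose, theta2)

    def individual3(th, sid):
        """Individual at candidate fixed effects with all etas frozen."""
        specs = subjects[sid]
        est = pk_ests.get(sid, {})
        base = model_core.apply_covariates(th, specs[0].BW)
        pk_over = {}
        for n in ("CL", "Vc", "Q", "Vp", "F", "Ntr"):
            eta = ebes1.get(sid, {}).get(n, None)
            if eta is not None:
                pk_over[n] = getattr(base, n) * math.exp(eta)
            elif n in est:
                pk_over[n] = est[n]
        pk_over["F"] = min(pk_over.get("F", base.F), 1.0)
        ind = _build_individual(th, specs[0].BW, ebes2.get(sid, {}), {}, sid,
                                pk_over)
        # per-occasion IOV factors frozen at their step-1 etas (relative to
        # the step-3 starting law), so the candidate MTT law stays identified
        ind.occ_mtt_factor.update(iov3.get(sid, {}))
        return ind

    def per_spec3(th, fn):
        """Apply fn(spec, ind, mode, kw) over all subject-periods, in order."""
        out = []
        for sid, specs in subjects.items():
            ind = individual3(th, sid)
            for spec in specs:
                if spec.kind == "dex":
                    b = model_core.cortisol_production_rate(
                        ind.params.Base, ind.params.replace(activity=1.0))
                    out.append(fn(spec, ind, "pk_only",
                                  {"const_production": b}))
                else:
                    out.append(fn(spec, ind, "full", {"warmup": warmup}))
        return out

    def all_residuals(th: StructuralParams, scales=None):
        parts, i = [], 0

        def fn(spec, ind, mode, kw):
            nonlocal i
            n = len(spec.obs)
            sl = scales[i:i + n] if scales is not None else None
            r, _ = _spec_residuals([spec], ind, sigmas, mode=mode, scales=sl,
                                   rtol=rtol, atol=atol, **kw)
            i += n
            return r

        return np.concatenate(per_spec3(th, fn))

    def step3_scales(th):
        return np.concatenate(per_spec3(
            th, lambda spec, ind, mode, kw: _frozen_scales(
                [spec], ind, sigmas, mode=mode, rtol=rtol, atol=atol, **kw)))

    def exact_neg2ll(th):
        """Exact proportional-error -2 log-likelihood at frozen etas."""
        return float(sum(per_spec3(
            th, lambda spec, ind, mode, kw: neg2ll_individual(
                [spec], ind, sigmas, mode=mode, rtol=rtol, atol=atol, **kw))))

    n_obs_all = int((table["EVID"] == 0).sum())
    # the step objective is the exact proportional-error -2 log-likelihood at
    # frozen etas; the Gauss-Newton search uses the frozen-scale surrogate and
    # the final value is chosen best-of, so the objective is never worsened
    start_cost = exact_neg2ll(theta2)
    candidates = [(theta2, start_cost)]
    converged = True
    if names3:
        sd3 = step3_scales(theta2)
        x_start3 = _pack_theta(theta2, names3)

        def step3_resid(x):
            try:
                return all_residuals(
                    _theta_with(theta2, names3,
                                np.clip(x, x_start3 - 2.5, x_start3 + 2.5)),
                    scales=sd3)
            except (RuntimeError, ArithmeticError):
                return np.full(n_obs_all, 1e6)

        sol = least_squares(step3_resid, x_start3, method="lm",
                            xtol=1e-6, ftol=1e-6, diff_step=1e-3,
                            max_nfev=max_nfev_pooled * (len(names3) + 1))
        cand = _theta_with(theta2, names3,
                           np.clip(sol.x, x_start3 - 2.5, x_start3 + 2.5))
        try:
            candidates.append((cand, exact_neg2ll(cand)))
            converged = bool(sol.success)
        except (RuntimeError, ArithmeticError):
            log.warning("step 3 candidate failed the likelihood evaluation")
            converged = False

        # Likelihood polish: the least-squares surrogate carries none of the
        # log-variance term of the proportional-error likelihood; that term
        # is what separates the (Emax, EC50, gammaE) ridge. Refine the
        # endocrine block against the exact -2 log-likelihood by coordinate
        # descent: derivative-free search over the typicals at frozen etas,
        # alternated with per-subject posterior-mode refreshes (both steps
        # are monotone in the joint penalized objective).
        polish_names = [n for n in ("Emax", "EC50", "gammaE", "SA1", "Kout",
                                    "Base", "IC50", "gammaI") if n in names3]
        if likelihood_polish and polish_names:
            from scipy.optimize import minimize

            cov4, _ = omega.base_ec50_cov_matrix()
            omega4 = np.diag([max(omega.omega_SA1, 1e-6) ** 2,
                              max(omega.omega_Kout, 1e-6) ** 2, 1.0, 1.0])
            omega4[2:, 2:] = cov4 if cov4[0, 0] > 0 else np.eye(2) * 1e-12
            om4_inv = np.linalg.inv(omega4 + np.eye(4) * 1e-12)

            def eta_prior():
                tot = 0.0
                for sid in endo_sids:
                    e = ebes2.get(sid, {})
                    v = np.array([e.get(n, 0.0) for n in endo_iiv])
                    tot += float(v @ om4_inv @ v)
                return tot

            def joint_obj(th):
                return exact_neg2ll(th) + eta_prior()

            th_best = min(candidates, key=lambda c: c[1])[0]
            best_obj = joint_obj(th_best)
            best_ebes = {s_: dict(e) for s_, e in ebes2.items()}

            def refresh_base_ec50(th):
                """Re-fit only the (Base, EC50) etas (the pair coupled to the
                production ridge); cheap enough to run per ridge candidate."""
                for sid in endo_sids:
                    pk_over = {k: pk_ests[sid][k] for k in
                               ("CL", "Vc", "Q", "Vp", "F", "Ntr")
                               if k in pk_ests[sid]}
                    etas, _, _ = map_fit(endo_specs[sid], th, omega,
                                         endo_specs[sid][0].BW,
                                         iiv_names=("Base", "EC50"),
                                         subject_id=sid, mode="full",
                                         sigmas=sigmas, pk_overrides=pk_over,
                                         n_starts=1, rtol=rtol, atol=atol,
                                         warmup=warmup, max_nfev=20)
                    cur = dict(ebes2.get(sid, {}))
                    cur.update(etas)
                    ebes2[sid] = cur

            # profile scan along the production-curve ridge
            if all(n in names3 for n in ("Emax", "EC50", "gammaE")):
                for phi in (-0.45, -0.3, -0.15, 0.15, 0.3):
                    th_c = _hill_ridge_member(th_best, phi)
                    if th_c is None:
                        continue
                    saved = {s_: dict(e) for s_, e in ebes2.items()}
                    try:
                        refresh_base_ec50(th_c)
                        obj_c = joint_obj(th_c)
                    except (RuntimeError, ArithmeticError):
                        ebes2.update(saved)
                        continue
                    if verbose:
                        log.info("ridge scan phi=%+.2f: EC50=%.2f Emax=%.0f "
                                 "gammaE=%.2f obj=%.1f (best %.1f)", phi,
                                 th_c.EC50, th_c.Emax, th_c.gammaE, obj_c,
                                 best_obj)
                    if obj_c < best_obj:
                        best_obj = obj_c
                        th_best = th_c
                        best_ebes = {s_: dict(e) for s_, e in ebes2.items()}
                    ebes2.update(saved)
                ebes2.update(best_ebes)

            for _round in range(2):
                x_p0 = _pack_theta(th_best, polish_names)

                def nll(x):
                    try:
                        return exact_neg2ll(_theta_with(
                            th_best, polish_names,
                            np.clip(x, x_p0 - 2.0, x_p0 + 2.0)))
                    except (RuntimeError, ArithmeticError):
                        return 1e12

                polished = minimize(nll, x_p0, method="Nelder-Mead",
                                    options={"maxfev": 30 * len(polish_names),
                                             "xatol": 1e-4, "fatol": 1e-3})
                cand_th = _theta_with(th_best, polish_names,
                                      np.clip(polished.x, x_p0 - 2.0,
                                              x_p0 + 2.0))
                if float(polished.fun) + eta_prior() < best_obj:
                    th_best = cand_th
                    best_obj = float(polished.fun) + eta_prior()
                    best_ebes = {s_: dict(e) for s_, e in ebes2.items()}
                # refresh the endocrine etas at the polished typicals
                for sid in endo_sids:
                    pk_over = {k: pk_ests[sid][k] for k in
                               ("CL", "Vc", "Q", "Vp", "F", "Ntr")
                               if k in pk_ests[sid]}
                    etas, _, _ = map_fit(endo_specs[sid], th_best, omega,
                                         endo_specs[sid][0].BW,
                                         iiv_names=endo_iiv, subject_id=sid,
                                         mode="full", sigmas=sigmas,
                                         pk_overrides=pk_over, n_starts=1,
                                         rtol=rtol, atol=atol, warmup=warmup,
                                         max_nfev=30)
                    ebes2[sid] = etas
                obj = joint_obj(th_best)
                if obj < best_obj:
                    best_obj = obj
                    best_ebes = {s_: dict(e) for s_, e in ebes2.items()}
                else:       # eta refresh did not help: restore and stop
                    ebes2.update(best_ebes)
                    break
                if verbose:
                    log.info("polish round %d: joint objective %.1f",
                             _round, best_obj)
            ebes2.update(best_ebes)
            candidates.append((th_best, exact_neg2ll(th_best)))

    theta3, end_cost = min(candidates, key=lambda c: c[1])
    res3 = FitResult(step="step3_joint", fixed_effects=theta3.to_dict(),
                     ebes={**ebes1, **{f"endo_{s}": e for s, e in ebes2.items()}},
                     neg2ll=end_cost, converged=converged, n_obs=n_obs_all,
                     diagnostics={"start_cost": start_cost,
                                  "per_subject_pk": pk_ests})
    results.append(res3)
    return results


# ---------------------------------------------------------------------------
# bootstrap uncertainty
# ---------------------------------------------------------------------------

def profile_or_bootstrap_se(fit: FitResult, n_boot: int = 50, seed: int = 0,
                            level: float = 0.95) -> pd.DataFrame:
    """Case-resampling bootstrap intervals for the pooled PK fixed effects.

    Resamples subjects (with replacement) from the per-subject Step-1/Step-3
    estimates stored in ``fit.diagnostics`` and re-runs the pooling stage —
    a two-stage bootstrap that quantifies the sampling variability of the
    typical values without refitting individuals. Percentile intervals at
    ``level``.
    """
    if not fit.converged:
        raise ValueError("bootstrap requires a converged fit")
    if n_boot < 10:
        warnings.warn(f"n_boot={n_boot} < 10: intervals will be unreliable")
    per_subject = fit.diagnostics.get("per_subject") \
        or fit.diagnostics.get("per_subject_pk")
    if not per_subject:
        raise ValueError("fit carries no per-subject estimates to resample")
    theta = fit.theta
    sids = sorted(per_subject)
    rng = np.random.default_rng(seed)
    draws: dict[str, list] = {}
    for _ in range(n_boot):
        sample = list(rng.choice(sids, size=len(sids), replace=True))
        pooled = _pool_pk(per_subject, theta, subset=sample)
        for k, v in pooled.items():
            draws.setdefault(k, []).append(v)
    a = (1.0 - level) / 2.0
    rows = []
    for k, vals in draws.items():
        lo, hi = np.percentile(vals, [100 * a, 100 * (1 - a)])
        rows.append({"param": k, "estimate": fit.fixed_effects.get(k, np.nan),
                     "lo": float(lo), "hi": float(hi)})
    return pd.DataFrame(rows)
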