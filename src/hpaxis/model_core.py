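"""Structural model: deterministic functions and the ODE right-hand side.

State vector for one individual (see :func:`hpa_ode_rhs`):

==================  ======================================================
``A_acth``          ACTH concentration, pmol/L (secretion rates in pmol/h
                    are interpreted per implicit unit volume, i.e. pmol/L/h)
``A_depot``         drug amount in the absorption depot, nmol
``A_central_total`` total (bound + unbound) cortisol amount in the central
                    compartment, nmol
``A_periph``        unbound-equivalent cortisol amount in the peripheral
                    compartment, nmol
==================  ======================================================

Kinetics (CL, Q) act on the unbound concentration; the measured quantity
"total cortisol" is the binding transform of the unbound concentration.
Oral input enters the depot through an analytic transit-chain forcing
function, so no transit-compartment states are carried.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .params import HC_NMOL_PER_MG, StructuralParams

__all__ = [
    "surge_rate",
    "pulsatile_secretion",
    "feedback_factor",
    "cortisol_production_rate",
    "bound_from_unbound",
    "unbound_from_total",
    "mtt_for_dose",
    "transit_input_rate",
    "apply_covariates",
    "OralInput",
    "hpa_ode_rhs",
    "acth_pg_per_ml",
]

STATE_NAMES = ("A_acth", "A_depot", "A_central_total", "A_periph")

_REF_BW = 70.0    # kg, reference body weight
_REF_DOSE = 5.0   # mg, reference oral dose for MTT


def surge_rate(t_clock, SA, SW, Pt, n):
    """Periodic bell-shaped secretion rate (pmol/h) at clock time ``t_clock``.

    A single surge is ``SA / (((t - Pt)/SW)**n + 1)``; the function is
    extended periodically by summing the adjacent-day images (day offsets
    -1, 0, +1), whose polynomial tails are non-negligible 12 h away from the
    peak for n = 4.
    """
    if SW <= 0:
        raise ValueError(f"surge width SW must be > 0, got {SW!r}")
    n = int(n)
    if n <= 0 or n % 2:
        raise ValueError(f"surge exponent n must be a positive even integer, got {n!r}")
    t = np.asarray(t_clock, dtype=float) % 24.0
    total = 0.0
    for d in (-1.0, 0.0, 1.0):
        x = (t + 24.0 * d - Pt) / SW
        total = total + SA / (x ** n + 1.0)
    return total if isinstance(total, np.ndarray) else float(total)


def pulsatile_secretion(t_clock, p: StructuralParams, SA1=None):
    """Sum of the morning and midday surges, pmol/h.

    ``SA1`` overrides the morning amplitude (used for the covariate/eta
    adjusted value); default is ``p.SA1``.
    """
    a1 = p.SA1 if SA1 is None else SA1
    return (surge_rate(t_clock, a1, p.SW1, p.Pt1, p.n_surge)
            + surge_rate(t_clock, p.SA2, p.SW2, p.Pt2, p.n_surge))


def feedback_factor(Cu, p: StructuralParams):
    """Fraction of pulsatile ACTH secretion remaining at unbound cortisol ``Cu``.

    Sigmoidal Imax inhibition, ``1 - Imax * Cu^g / (IC50^g + Cu^g)``; applies
    only to the pulsatile secretion, never to the zero-order baseline.
    """
    Cu = np.asarray(Cu, dtype=float)
    if np.any(Cu < 0):
        raise ValueError("unbound cortisol concentration must be >= 0")
    r = (Cu / p.IC50) ** p.gammaI
    out = 1.0 - p.Imax * r / (1.0 + r)
    return out if out.ndim else float(out)


def cortisol_production_rate(A, p: StructuralParams):
    """ACTH-driven cortisol production rate, nmol/h (sigmoidal Emax).

    Scaled by ``p.activity``, the remaining adrenal enzymatic activity
    (1 = healthy, 0.2 = mild CAH, 0 = severe CAH).
    """
    A = np.asarray(A, dtype=float)
    if np.any(A < 0):
        raise ValueError("ACTH concentration must be >= 0")
    r = (A / p.EC50) ** p.gammaE
    out = p.activity * p.Emax * r / (1.0 + r)
    return out if out.ndim else float(out)


def bound_from_unbound(Cu, p: StructuralParams):
    """Total cortisol concentration (nmol/L) at unbound concentration ``Cu``.

    Saturable CBG binding plus linear albumin binding:
    ``total = Cu + Bmax*Cu/(Kd + Cu) + NS*Cu``; strictly increasing in Cu.
    """
    Cu = np.asarray(Cu, dtype=float)
    if np.any(Cu < 0):
        raise ValueError("unbound cortisol concentration must be >= 0")
    out = Cu * (1.0 + p.NS) + p.Bmax * Cu / (p.Kd + Cu)
    return out if out.ndim else float(out)


def unbound_from_total(Ct, p: StructuralParams):
    """Unbound cortisol concentration (nmol/L) for a total concentration ``Ct``.

    Closed-form positive root of the quadratic obtained from the binding
    equation; the round trip through :func:`bound_from_unbound` is exact to
    floating-point precision (well inside the 1e-8 contract).
    """
    Ct = np.asarray(Ct, dtype=float)
    if np.any(Ct < 0):
        raise ValueError("total cortisol concentration must be >= 0")
    a = 1.0 + p.NS
    b = a * p.Kd + p.Bmax - Ct
    # positive root of a*Cu^2 + b*Cu - Ct*Kd = 0, written to avoid cancellation
    disc = np.sqrt(b * b + 4.0 * a * p.Kd * Ct)
    out = 2.0 * p.Kd * Ct / (b + disc)
    if not np.all(np.isfinite(out)):
        raise ArithmeticError(f"binding inversion failed for Ct={Ct!r}")
    return out if out.ndim else float(out)


def mtt_for_dose(dose_mg, p: StructuralParams):
    """Mean transit time (h) for an oral dose, power law around the 5 mg reference."""
    dose_mg = np.asarray(dose_mg, dtype=float)
    if np.any(dose_mg <= 0):
        raise ValueError("dose must be > 0")
    out = p.MTT_ref * (dose_mg / _REF_DOSE) ** p.theta_dose_MTT
    return out if out.ndim else float(out)


def transit_input_rate(t_since_dose, dose_nmol, MTT, Ntr, F):
    """Analytic transit-chain input to the absorption depot, nmol/h.

    ``F*dose * Ktr * (Ktr*t)^Ntr * exp(-Ktr*t) / Gamma(Ntr+1)`` with
    ``Ktr = (Ntr+1)/MTT``; integrates to ``F*dose`` over [0, inf). Non-integer
    ``Ntr`` is supported through the gamma function.
    """
    if MTT <= 0:
        raise ValueError(f"MTT must be > 0, got {MTT!r}")
    if Ntr < 0:
        raise ValueError(f"Ntr must be >= 0, got {Ntr!r}")
    t = np.asarray(t_since_dose, dtype=float)
    ktr = (Ntr + 1.0) / MTT
    x = ktr * t
    with np.errstate(divide="ignore", invalid="ignore"):
        log_rate = Ntr * np.log(x) - x - gammaln(Ntr + 1.0)
    rate = F * dose_nmol * ktr * np.where(x > 0, np.exp(log_rate), 1.0 if Ntr == 0 else 0.0)
    rate = np.where(t < 0, 0.0, rate)
    return rate if rate.ndim else float(rate)


def apply_covariates(p: StructuralParams, BW: float, dose_mg: float | None = None) -> StructuralParams:
    """Scale parameters to an individual's body weight (and oral dose).

    SA1 scales with a power model in BW (exponent ``theta_BW_SA1``); CL and Q
    with theory-based allometry (exponent 0.75); Vc and Vp linearly in BW.
    If ``dose_mg`` is given, MTT_ref is replaced by the dose-specific MTT so
    the returned parameter set is fully individualized for that occasion.
    """
    if BW <= 0:
        raise ValueError(f"body weight must be > 0, got {BW!r}")
    f = BW / _REF_BW
    updates = dict(
        SA1=p.SA1 * f ** p.theta_BW_SA1,
        CL=p.CL * f ** 0.75,
        Q=p.Q * f ** 0.75,
        Vc=p.Vc * f,
        Vp=p.Vp * f,
    )
    if dose_mg is not None:
        updates["MTT_ref"] = mtt_for_dose(dose_mg, p)
    return p.replace(**updates)


@dataclass
class OralInput:
    """One active oral dose driving the analytic transit input."""

    t_dose: float     # absolute time of administration, h
    dose_mg: float
    MTT: float        # h, already individualized (dose power law x IOV)
    F: float          # bioavailability in effect for this occasion
    Ntr: float        # number of transit compartments for this individual

    @property
    def dose_nmol(self) -> float:
        return self.dose_mg * HC_NMOL_PER_MG

    def rate(self, t_abs: float) -> float:
        if t_abs <= self.t_dose:
            return 0.0
        return transit_input_rate(t_abs - self.t_dose, self.dose_nmol,
                                  self.MTT, self.Ntr, self.F)


def hpa_ode_rhs(t_abs, y, p: StructuralParams, oral_inputs=(), dex_active=False,
                const_production=0.0):
    """Right-hand side of the joint model ODE at absolute time ``t_abs`` (h).

    ``oral_inputs`` is a sequence of :class:`OralInput`; ``dex_active``
    switches the pulsatile-secretion multiplier from the cortisol feedback
    factor to the constant ``1 - I_DEX`` (dexamethasone suppression).
    ``const_production`` (nmol/h) is an optional zero-order cortisol input,
    used by reduced PK-only fits to represent a constant endogenous baseline.
    The clock time used by the surge functions is ``t_abs mod 24``.
    """
    A_acth = max(y[0], 0.0)
    A_depot = y[1]
    A_central = max(y[2], 0.0)
    A_periph = y[3]

    Ct = A_central / p.Vc
    # closed-form binding inversion (scalar fast path)
    a = 1.0 + p.NS
    b = a * p.Kd + p.Bmax - Ct
    Cu = 2.0 * p.Kd * Ct / (b + math.sqrt(b * b + 4.0 * a * p.Kd * Ct)) if Ct > 0 else 0.0
    Cp = A_periph / p.Vp

    if dex_active:
        suppression = 1.0 - p.I_DEX
    else:
        r = (Cu / p.IC50) ** p.gammaI
        suppression = 1.0 - p.Imax * r / (1.0 + r)

    if suppression != 0.0:
        t_clock = t_abs % 24.0
        sec = 0.0
        n = p.n_surge
        for d in (-24.0, 0.0, 24.0):
            x1 = (t_clock + d - p.Pt1) / p.SW1
            x2 = (t_clock + d - p.Pt2) / p.SW2
            sec += p.SA1 / (x1 ** n + 1.0) + p.SA2 / (x2 ** n + 1.0)
    else:
        sec = 0.0

    dacth = p.Base * p.Kout + suppression * sec - p.Kout * A_acth

    input_rate = 0.0
    for inp in oral_inputs:
        dt = t_abs - inp.t_dose
        if dt > 0:
            # scalar fast path of transit_input_rate (called once per solver step)
            ktr = (inp.Ntr + 1.0) / inp.MTT
            x = ktr * dt
            if x < 500.0:  # tail is numerically zero beyond this
                log_pulse = inp.Ntr * math.log(x) - x - math.lgamma(inp.Ntr + 1.0) if x > 0 else 0.0
                input_rate += inp.F * inp.dose_nmol * ktr * math.exp(log_pulse)
    ddepot = input_rate - p.Ka * A_depot

    if p.activity != 0.0 and A_acth > 0.0:
        rE = (A_acth / p.EC50) ** p.gammaE
        production = p.activity * p.Emax * rE / (1.0 + rE)
    else:
        production = 0.0

    dcentral = production + const_production + p.Ka * A_depot \
        - p.CL * Cu - p.Q * Cu + p.Q * Cp
    dperiph = p.Q * Cu - p.Q * Cp
    return [dacth, ddepot, dcentral, dperiph]


# ---------------------------------------------------------------------------
# compiled fast path for the ODE right-hand side (used by the integrator;
# hpa_ode_rhs above is the reference implementation and remains the API)
# ---------------------------------------------------------------------------

try:
    from numba import njit as _njit
except ImportError:      # pragma: no cover - numba is an optional accelerator
    _njit = None

_PARAM_ORDER = ("SA1", "SW1", "Pt1", "SA2", "SW2", "Pt2", "n_surge", "Kout",
                "Base", "I_DEX", "Emax", "EC50", "gammaE", "Imax", "IC50",
                "gammaI", "Ka", "CL", "Vc", "Q", "Vp", "NS", "Kd", "Bmax",
                "activity")


def pack_params(p: StructuralParams) -> np.ndarray:
    return np.array([float(getattr(p, n)) for n in _PARAM_ORDER])


def pack_oral_inputs(oral_inputs) -> np.ndarray:
    """Rows [t_dose, F*dose_nmol, ktr, Ntr, lgamma(Ntr+1)]."""
    if not oral_inputs:
        return np.zeros((0, 5))
    return np.array([[inp.t_dose, inp.F * inp.dose_nmol,
                      (inp.Ntr + 1.0) / inp.MTT, inp.Ntr,
                      math.lgamma(inp.Ntr + 1.0)] for inp in oral_inputs])


def _rhs_fast_py(t_abs, y, c, doses, dex_active, const_production):
    (SA1, SW1, Pt1, SA2, SW2, Pt2, n_surge, Kout, Base, I_DEX, Emax, EC50,
     gammaE, Imax, IC50, gammaI, Ka, CL, Vc, Q, Vp, NS, Kd, Bmax,
     activity) = c
    A_acth = max(y[0], 0.0)
    A_depot = y[1]
    A_central = max(y[2], 0.0)

    Ct = A_central / Vc
    a = 1.0 + NS
    b = a * Kd + Bmax - Ct
    Cu = 2.0 * Kd * Ct / (b + math.sqrt(b * b + 4.0 * a * Kd * Ct)) \
        if Ct > 0.0 else 0.0
    Cp = y[3] / Vp

    if dex_active:
        suppression = 1.0 - I_DEX
    else:
        r = (Cu / IC50) ** gammaI
        suppression = 1.0 - Imax * r / (1.0 + r)

    sec = 0.0
    if suppression != 0.0:
        tc = t_abs % 24.0
        n = int(n_surge)
        for d in (-24.0, 0.0, 24.0):
            x1 = (tc + d - Pt1) / SW1
            x2 = (tc + d - Pt2) / SW2
            sec += SA1 / (x1 ** n + 1.0) + SA2 / (x2 ** n + 1.0)

    dacth = Base * Kout + suppression * sec - Kout * A_acth

    input_rate = 0.0
    for k in range(doses.shape[0]):
        dt = t_abs - doses[k, 0]
        if dt > 0.0:
            x = doses[k, 2] * dt
            if x < 500.0:
                lp = doses[k, 3] * math.log(x) - x - doses[k, 4] if x > 0 else 0.0
                input_rate += doses[k, 1] * doses[k, 2] * math.exp(lp)
    ddepot = input_rate - Ka * A_depot

    if activity != 0.0 and A_acth > 0.0:
        rE = (A_acth / EC50) ** gammaE
        production = activity * Emax * rE / (1.0 + rE)
    else:
        production = 0.0

    dcentral = production + const_production + Ka * A_depot \
        - CL * Cu - Q * Cu + Q * Cp
    dperiph = Q * Cu - Q * Cp
    return np.array([dacth, ddepot, dcentral, dperiph])


rhs_fast = _njit(cache=True)(_rhs_fast_py) if _njit is not None else _rhs_fast_py


def acth_pg_per_ml(conc_pmol_per_l):
    """Convert ACTH pmol/L to pg/mL (MW 4541.1 g/mol)."""
    from .params import ACTH_PG_PER_PMOL

    return np.asarray(conc_pmol_per_l, dtype=float) * ACTH_PG_PER_PMOL
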