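"""Random-effects layer: individual parameter sets and residual error.

Between-subject variability is log-normal: an individual's parameter is the
typical (covariate-adjusted) value times ``exp(eta)``, ``eta ~ N(0, Omega)``.
The (Base, EC50) pair is drawn jointly from its 2x2 covariance block; all
other etas are independent. Between-occasion variability acts on the mean
transit time MTT (one independent log-normal factor per oral dosing
occasion). Residual error is proportional Gaussian per channel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import model_core
from .params import StructuralParams, VarianceComponents

__all__ = ["IndividualParams", "sample_individual", "typical_individual",
           "apply_residual_error"]

log = logging.getLogger(__name__)

#: structural parameters carrying interindividual variability
IIV_PARAMS = ("SA1", "Kout", "Base", "EC50", "Ntr", "F", "CL", "Vp")

_OMEGA_BY_PARAM = {
    "SA1": "omega_SA1", "Kout": "omega_Kout", "Base": "omega_Base",
    "EC50": "omega_EC50", "Ntr": "omega_Ntr", "F": "omega_F",
    "CL": "omega_CL", "Vp": "omega_Vp",
}


@dataclass
class IndividualParams:
    """Covariate-adjusted, eta-perturbed parameter set for one subject."""

    subject_id: int
    BW: float
    age: float = 40.0
    etas: dict = field(default_factory=dict)
    #: occasion index -> log-normal IOV factor on MTT
    occ_mtt_factor: dict = field(default_factory=dict)
    params: StructuralParams = None

    def mtt_for_occasion(self, dose_mg: float, occasion: int = 0) -> float:
        """Dose- and occasion-specific mean transit time, h."""
        return model_core.mtt_for_dose(dose_mg, self.params) * \
            self.occ_mtt_factor.get(occasion, 1.0)


def _individual_from_etas(theta: StructuralParams, BW: float, etas: dict,
                          occ_mtt_eta: dict, subject_id: int, age: float) -> IndividualParams:
    p = model_core.apply_covariates(theta, BW)
    updates = {}
    for name, eta in etas.items():
        if name not in IIV_PARAMS:
            raise KeyError(f"no interindividual variability defined on {name!r}")
        updates[name] = getattr(p, name) * float(np.exp(eta))
    if "F" in updates and updates["F"] > 1.0:
        log.warning("subject %s: sampled F=%.3f > 1, clipped to 1", subject_id, updates["F"])
        updates["F"] = 1.0
    p = p.replace(**updates)
    occ_factor = {occ: float(np.exp(e)) for occ, e in occ_mtt_eta.items()}
    return IndividualParams(subject_id=subject_id, BW=BW, age=age, etas=dict(etas),
                            occ_mtt_factor=occ_factor, params=p)


def typical_individual(theta: StructuralParams, BW: float = 70.0,
                       subject_id: int = 0, age: float = 40.0) -> IndividualParams:
    """The zero-eta (typical) individual at body weight ``BW``."""
    etas = {name: 0.0 for name in IIV_PARAMS}
    return _individual_from_etas(theta, BW, etas, {}, subject_id, age)


def sample_individual(theta: StructuralParams, omega: VarianceComponents,
                      BW: float, n_occasions: int = 1, rng=None,
                      subject_id: int = 0, age: float = 40.0) -> IndividualParams:
    """Draw one individual: lognormal IIV plus per-occasion IOV on MTT.

    ``rng`` is a ``numpy.random.Generator`` or an integer seed. Setting every
    variance component to zero reproduces the typical individual exactly.
    """
    rng = np.random.default_rng(rng)
    cov2, adjusted = omega.base_ec50_cov_matrix()
    if adjusted:
        log.warning("Base-EC50 covariance implies |corr| > 1; "
                    "projected to corr = +/-%.3f", omega.MAX_CORR)
    # eigenvalue check of the (projected) block
    if np.linalg.eigvalsh(cov2).min() < -1e-12:
        raise ValueError("Base-EC50 covariance block is not positive semi-definite")

    etas = {}
    eta_be = rng.multivariate_normal([0.0, 0.0], cov2, method="cholesky") \
        if cov2.any() else np.zeros(2)
    etas["Base"], etas["EC50"] = float(eta_be[0]), float(eta_be[1])
    for name in ("SA1", "Kout", "Ntr", "F", "CL", "Vp"):
        w = getattr(omega, _OMEGA_BY_PARAM[name])
        etas[name] = float(rng.normal(0.0, w)) if w > 0 else 0.0
    occ_mtt_eta = {occ: (float(rng.normal(0.0, omega.omega_IOV_MTT))
                         if omega.omega_IOV_MTT > 0 else 0.0)
                   for occ in range(n_occasions)}
    return _individual_from_etas(theta, BW, etas, occ_mtt_eta, subject_id, age)


def apply_residual_error(true_values, channel: str, sigma: float, rng=None):
    """Proportional residual error: ``obs = true * (1 + eps)``, eps ~ N(0, sigma^2).

    ``channel`` must be ``"ACTH"`` or ``"cortisol_total"`` (unbound cortisol
    observations reuse the cortisol sigma, ``"cortisol_unbound"``). Negative
    draws are floored at zero and counted in the log.
    """
    if channel not in ("ACTH", "cortisol_total", "cortisol_unbound"):
        raise ValueError(f"unknown observation channel {channel!r}")
    true_values = np.asarray(true_values, dtype=float)
    if np.any(true_values < 0):
        raise ValueError("true concentrations must be >= 0")
    rng = np.random.default_rng(rng)
    obs = true_values * (1.0 + rng.normal(0.0, sigma, size=true_values.shape)) \
        if sigma > 0 else true_values.copy()
    n_neg = int(np.sum(obs < 0))
    if n_neg:
        log.info("floored %d negative %s observations at 0", n_neg, channel)
        obs = np.maximum(obs, 0.0)
    return obs if obs.ndim else float(obs)
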