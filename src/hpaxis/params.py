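"""Model parameters for the joint HPA-axis / hydrocortisone model.

The model couples three sub-systems for one individual:

* circadian pulsatile ACTH secretion (two bell-shaped surge functions on a
  24-h clock plus a zero-order baseline with first-order elimination),
* ACTH-driven adrenal cortisol production (sigmoidal Emax) with negative
  feedback of unbound cortisol on the pulsatile secretion (sigmoidal Imax),
* two-compartment hydrocortisone/cortisol kinetics acting on unbound drug,
  with saturable binding to corticosteroid-binding globulin (CBG) and linear
  binding to albumin, and transit-compartment oral absorption.

``StructuralParams`` holds the population typical values (fixed effects);
``VarianceComponents`` holds the log-normal between-subject (IIV),
between-occasion (IOV) and proportional residual (RUV) variability.
Defaults are the final estimates of the joint model this package implements.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = [
    "StructuralParams",
    "VarianceComponents",
    "HC_NMOL_PER_MG",
    "ACTH_PG_PER_PMOL",
    "load_params",
    "dump_params",
]

#: hydrocortisone molecular weight 362.46 g/mol -> nmol per mg
HC_NMOL_PER_MG = 1e6 / 362.46  # 2758.9...

#: ACTH(1-39) molecular weight 4541.1 g/mol -> pg per pmol (for pg/mL <-> pmol/L)
ACTH_PG_PER_PMOL = 4541.1 / 1000.0


@dataclass
class StructuralParams:
    """Population typical (fixed-effect) parameters.

    Reference individual: 70 kg body weight, 5 mg oral dose. Clock times are
    decimal hours after midnight.
    """

    # --- ACTH secretion and elimination ---
    SA1: float = 1300.0          # morning surge amplitude, pmol/h (70 kg)
    theta_BW_SA1: float = 6.53   # body-weight power exponent on SA1
    SW1: float = 0.606           # morning surge width, h
    Pt1: float = 6.3             # morning surge peak time, h (06:18)
    SA2: float = 50.0            # midday surge amplitude, pmol/h
    SW2: float = 2.33            # midday surge width, h
    Pt2: float = 11.8            # midday surge peak time, h (11:48)
    n_surge: int = 4             # surge exponent (even positive integer)
    Kout: float = 0.613          # ACTH elimination rate constant, 1/h
    Base: float = 1.29           # ACTH baseline concentration, pmol/L
    I_DEX: float = 1.0           # fractional DEX suppression of pulses (0-1)
    # --- ACTH-dependent cortisol production ---
    Emax: float = 5400.0         # maximal cortisol production rate, nmol/h
    EC50: float = 6.63           # ACTH conc. at half-maximal production, pmol/L
    gammaE: float = 2.94         # production Hill exponent
    # --- cortisol feedback on ACTH pulsatile secretion ---
    Imax: float = 0.999          # maximal fractional pulse suppression
    IC50: float = 4.60           # unbound cortisol at half-max suppression, nmol/L
    gammaI: float = 5.33         # suppression Hill exponent
    # --- hydrocortisone / cortisol pharmacokinetics ---
    Ka: float = 24.0             # depot absorption rate constant, 1/h
    MTT_ref: float = 0.868       # mean transit time at the 5 mg dose, h
    theta_dose_MTT: float = 0.179  # dose power exponent on MTT
    Ntr: float = 2.12            # number of transit compartments (real, >= 0)
    F: float = 0.344             # oral bioavailability
    CL: float = 106.0            # unbound clearance, L/h (70 kg)
    Vc: float = 2.15             # central volume, L (70 kg)
    Q: float = 89.9              # intercompartmental flow, L/h (70 kg)
    Vp: float = 61.7             # peripheral volume, L (70 kg)
    # --- plasma protein binding ---
    NS: float = 4.15             # nonspecific (albumin) binding ratio
    Kd: float = 9.71             # CBG dissociation constant, nmol/L
    Bmax: float = 424.1          # CBG maximal binding capacity, nmol/L
    # --- disease severity ---
    activity: float = 1.0        # remaining adrenal enzymatic activity (0-1)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = ("SW1", "SW2", "Kout", "EC50", "IC50", "Ka", "MTT_ref",
                    "CL", "Vc", "Q", "Vp", "Kd", "Emax", "Bmax")
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)!r}")
        for name in ("F", "Imax", "I_DEX", "activity"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {getattr(self, name)!r}")
        if self.n_surge not in (2, 4, 6, 8):
            raise ValueError(f"n_surge must be an even integer in {{2,4,6,8}}, got {self.n_surge!r}")
        if self.Ntr < 0:
            raise ValueError(f"Ntr must be >= 0, got {self.Ntr!r}")
        for name in ("Pt1", "Pt2"):
            if not 0.0 <= getattr(self, name) < 24.0:
                raise ValueError(f"{name} must lie in [0, 24), got {getattr(self, name)!r}")
        if self.Base < 0 or self.SA1 < 0 or self.SA2 < 0:
            raise ValueError("amplitudes and Base must be non-negative")

    def replace(self, **kwargs) -> "StructuralParams":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, mapping: dict) -> "StructuralParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise KeyError(f"unknown structural parameter keys: {sorted(unknown)}")
        return cls(**mapping)


@dataclass
class VarianceComponents:
    """Random-effect and residual-error magnitudes.

    ``omega_*`` are log-scale standard deviations (printed CV% / 100 under the
    usual log-normal reporting convention); ``cov_Base_EC50`` is the log-scale
    covariance of the correlated (Base, EC50) pair; ``sigma_*`` are
    proportional residual SDs (fraction of the prediction).
    """

    omega_SA1: float = 0.449
    omega_Kout: float = 0.537
    omega_Base: float = 0.246
    omega_EC50: float = 0.276
    cov_Base_EC50: float = 0.0686
    omega_Ntr: float = 0.430
    omega_F: float = 0.480
    omega_CL: float = 0.114
    omega_Vp: float = 0.122
    omega_IOV_MTT: float = 0.286
    sigma_prop_ACTH: float = 0.537
    sigma_prop_cortisol: float = 0.395

    #: cap applied to the Base-EC50 correlation when the printed covariance
    #: implies |rho| > 1 (the printed triple is mutually inconsistent)
    MAX_CORR = 0.999

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if f.name.startswith(("omega_", "sigma_")) and getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be >= 0")

    def base_ec50_cov_matrix(self):
        """2x2 log-scale covariance of (Base, EC50), projected to be PSD.

        Returns (matrix, adjusted_flag). If the implied correlation exceeds
        ``MAX_CORR`` in magnitude, the covariance is shrunk to the cap.
        """
        import numpy as np

        w1, w2 = self.omega_Base, self.omega_EC50
        cov = self.cov_Base_EC50
        adjusted = False
        if w1 > 0 and w2 > 0:
            rho = cov / (w1 * w2)
            if abs(rho) > self.MAX_CORR:
                cov = math.copysign(self.MAX_CORR * w1 * w2, cov)
                adjusted = True
        else:
            cov = 0.0
        return np.array([[w1 * w1, cov], [cov, w2 * w2]]), adjusted

    def scaled(self, factor: float) -> "VarianceComponents":
        """All omegas/sigmas (and the covariance, by factor^2) multiplied."""
        out = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            out[f.name] = v * (factor * factor if f.name.startswith("cov_") else factor)
        return VarianceComponents(**out)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, mapping: dict) -> "VarianceComponents":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise KeyError(f"unknown variance component keys: {sorted(unknown)}")
        return cls(**mapping)


def load_params(path) -> tuple[StructuralParams, VarianceComponents]:
    """Read a flat YAML/JSON mapping of parameter overrides.

    Keys prefixed ``omega_``/``sigma_``/``cov_`` go to ``VarianceComponents``;
    everything else to ``StructuralParams``. Missing keys keep their defaults.
    """
    path = Path(path)
    text = path.read_text()
    mapping = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    mapping = mapping or {}
    var_keys = {k: v for k, v in mapping.items()
                if k.startswith(("omega_", "sigma_", "cov_"))}
    struct_keys = {k: v for k, v in mapping.items() if k not in var_keys}
    theta = StructuralParams().to_dict()
    theta.update(struct_keys)
    omega = VarianceComponents().to_dict()
    omega.update(var_keys)
    return StructuralParams.from_dict(theta), VarianceComponents.from_dict(omega)


def dump_params(theta: StructuralParams, omega: VarianceComponents, path) -> None:
    path = Path(path)
    mapping = {**theta.to_dict(), **omega.to_dict()}
    if path.suffix == ".json":
        path.write_text(json.dumps(mapping, indent=2))
    else:
        path.write_text(yaml.safe_dump(mapping, sort_keys=False))
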