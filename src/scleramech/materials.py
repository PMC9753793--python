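"""Domain types for the biphasic conewise-linear-elastic (CLE) mechanics chain.

The sclera is modelled as a biphasic solid: an incompressible porous elastic
matrix saturated with water, coupled by Darcy drag.  Under unconfined
compression between frictionless impermeable platens the axial direction is
compressed (compressive modulus branch) while the radial and circumferential
directions are stretched (tensile branch), so a conewise linear elastic solid
is characterised here by four constants:

``H_A_plus``
    aggregate modulus on the tensile branch (radial/hoop), Pa.  This is the
    "tensile stiffness" reported per compression step.
``H_A_minus``
    aggregate modulus on the compressive branch (axial), Pa.
``lambda2``
    off-diagonal (normal-normal coupling) modulus, Pa.
``k``
    hydraulic conductivity, m^4 N^-1 s^-1 ("permeability").

Sign convention: compressive axial strain and stress are positive throughout
the mechanics modules; any reporting-sign conversion happens at the table
layer.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np

from .exceptions import InvalidInputError, InvalidParameterError

__all__ = [
    "CLEMaterial",
    "SampleGeometry",
    "RampHoldStep",
    "StressTrace",
    "DEFAULT_SAMPLE_RADIUS_M",
]

#: 1 mm diameter cylindrical biopsy punches -> 0.5 mm radius.
DEFAULT_SAMPLE_RADIUS_M = 0.5e-3


def _require_positive(name: str, value: float) -> float:
    value = float(value)
    if not np.isfinite(value) or value <= 0.0:
        raise InvalidParameterError(f"{name} must be finite and > 0, got {value!r}")
    return value


@dataclass(frozen=True)
class CLEMaterial:
    """Constitutive parameters of the tension-compression nonlinear biphasic solid."""

    H_A_plus: float
    H_A_minus: float
    lambda2: float
    k: float

    def __post_init__(self):
        _require_positive("H_A_plus", self.H_A_plus)
        _require_positive("H_A_minus", self.H_A_minus)
        _require_positive("k", self.k)
        lam = float(self.lambda2)
        if not np.isfinite(lam):
            raise InvalidParameterError(f"lambda2 must be finite, got {lam!r}")
        if lam < 0.0:
            raise InvalidParameterError(f"lambda2 must be >= 0, got {lam!r}")
        if lam >= self.H_A_plus:
            raise InvalidParameterError(
                "lambda2 must be < H_A_plus for a well-posed unconfined response "
                f"(lambda2={lam!r}, H_A_plus={self.H_A_plus!r})"
            )
        if self.H_A_plus < self.H_A_minus:
            warnings.warn(
                "H_A_plus < H_A_minus: tensile modulus below compressive modulus is "
                "unusual for sclera (permitted, but check parameter units)",
                stacklevel=2,
            )
        if self.equilibrium_modulus() <= 0.0:
            raise InvalidParameterError(
                "parameter combination yields non-positive equilibrium unconfined "
                f"modulus: {self}"
            )

    def equilibrium_modulus(self) -> float:
        """Drained (long-time) unconfined compression modulus, Pa.

        E_eq = H_A_minus - 2*lambda2^2 / (H_A_plus + lambda2); the long-time
        stress equals ``E_eq * step_strain``.  Reduces to the isotropic drained
        Young's modulus when H_A_plus = H_A_minus and lambda2 is the Lame
        constant.
        """
        return self.H_A_minus - 2.0 * self.lambda2**2 / (self.H_A_plus + self.lambda2)

    @property
    def shape_param(self) -> float:
        """Dimensionless constant of the characteristic equation J1(x) - beta*x*J0(x)."""
        return self.H_A_plus / (self.H_A_plus - self.lambda2)

    def instantaneous_modulus(self) -> float:
        """Short-time (undrained, incompressible) unconfined modulus, Pa."""
        return self.H_A_minus - self.lambda2 + 0.5 * (self.H_A_plus - self.lambda2)

    def to_dict(self) -> dict:
        return {
            "H_A_plus": self.H_A_plus,
            "H_A_minus": self.H_A_minus,
            "lambda2": self.lambda2,
            "k": self.k,
        }


@dataclass(frozen=True)
class SampleGeometry:
    """Cylindrical sample geometry in the step's reference configuration."""

    radius: float = DEFAULT_SAMPLE_RADIUS_M
    thickness_ref: float = 50e-6

    def __post_init__(self):
        _require_positive("radius", self.radius)
        _require_positive("thickness_ref", self.thickness_ref)

    @property
    def area(self) -> float:
        return float(np.pi * self.radius**2)

    def to_dict(self) -> dict:
        return {"radius": self.radius, "thickness_ref": self.thickness_ref}


@dataclass(frozen=True)
class RampHoldStep:
    """One ramp-and-hold compression step in its own reference configuration."""

    step_strain: float
    ramp_duration: float
    hold_duration: float
    sample_times: np.ndarray = field(repr=False)

    def __post_init__(self):
        if not (0.0 < self.step_strain < 1.0):
            raise InvalidParameterError(
                f"step_strain must lie in (0, 1), got {self.step_strain!r}"
            )
        _require_positive("ramp_duration", self.ramp_duration)
        _require_positive("hold_duration", self.hold_duration)
        times = np.asarray(self.sample_times, dtype=float)
        if times.ndim != 1 or times.size == 0:
            raise InvalidInputError("sample_times must be a non-empty 1-D array")
        if times[0] < 0.0:
            raise InvalidInputError("sample_times must start at t >= 0")
        if not np.all(np.diff(times) > 0.0):
            raise InvalidInputError("sample_times must be strictly increasing")
        object.__setattr__(self, "sample_times", times)

    @property
    def t_end(self) -> float:
        return self.ramp_duration + self.hold_duration

    def strain_at(self, t) -> np.ndarray:
        """Applied engineering compressive strain at time(s) ``t``."""
        t = np.asarray(t, dtype=float)
        return self.step_strain * np.clip(t / self.ramp_duration, 0.0, 1.0)

    def to_dict(self) -> dict:
        return {
            "step_strain": self.step_strain,
            "ramp_duration": self.ramp_duration,
            "hold_duration": self.hold_duration,
        }


@dataclass(frozen=True)
class StressTrace:
    """Sampled axial engineering stress vs time for one step of one sample.

    Stress is relative to the step's baseline, compression positive.
    """

    times: np.ndarray
    stress: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        stress = np.asarray(self.stress, dtype=float)
        if times.ndim != 1 or stress.ndim != 1 or times.size != stress.size:
            raise InvalidInputError("times and stress must be equal-length 1-D arrays")
        if times.size and not np.all(np.diff(times) > 0.0):
            raise InvalidInputError("times must be strictly increasing")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "stress", stress)

    def to_csv(self, path, sidecar: bool = True) -> None:
        """Write ``time_s,stress_Pa`` CSV plus a JSON sidecar of metadata."""
        path = Path(path)
        arr = np.column_stack([self.times, self.stress])
        header = "time_s,stress_Pa"
        np.savetxt(path, arr, delimiter=",", header=header, comments="")
        if sidecar:
            path.with_suffix(path.suffix + ".json").write_text(
                json.dumps(self.meta, indent=2, sort_keys=True, default=float)
            )

    @classmethod
    def from_csv(cls, path) -> "StressTrace":
        path = Path(path)
        arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        sidecar = path.with_suffix(path.suffix + ".json")
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return cls(times=arr[:, 0], stress=arr[:, 1], meta=meta)


def isotropic_material(H_A: float, nu: float, k: float) -> CLEMaterial:
    """Isotropic biphasic material expressed in CLE fields.

    ``H_A`` is the (confined) aggregate modulus ``lambda + 2*mu`` and ``nu``
    the drained Poisson's ratio; the off-diagonal modulus becomes the Lame
    constant ``lambda = H_A * nu / (1 - nu)``.
    """
    H_A = _require_positive("H_A", H_A)
    if not (0.0 <= nu < 0.5):
        raise InvalidParameterError(f"drained Poisson ratio must be in [0, 0.5), got {nu!r}")
    lam = H_A * nu / (1.0 - nu)
    return CLEMaterial(H_A_plus=H_A, H_A_minus=H_A, lambda2=lam, k=k)


def log_spaced_times(
    ramp_duration: float,
    hold_duration: float,
    n_ramp: int = 12,
    n_hold: int = 110,
    first_hold_offset: float = 0.5,
) -> np.ndarray:
    """Sampling grid: t=0, uniform ramp coverage, log-spaced hold coverage."""
    ramp = np.linspace(0.0, ramp_duration, n_ramp + 1)
    hold = ramp_duration + np.geomspace(first_hold_offset, hold_duration, n_hold)
    return np.unique(np.concatenate([ramp, hold]))
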