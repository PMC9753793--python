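"""Per-step estimation of (H_A_plus, k) from raw load-time records.

The measurement chain mirrors the unconfined-compression protocol: a tare
load flattens the sample (500 uN on a 1 mm disk = 636 Pa engineering
stress), three incremental ramp-and-hold steps each apply a nominal 5%
additional compressive strain, and the biphasic CLE model is fit
independently to each step in its own reference configuration.

Fitting is two-stage:

1. the equilibrium plateau of the hold phase fixes the drained modulus
   ``E_eq_hat = plateau_stress / applied_strain`` (and, under the packaged
   ``lambda2 = 0`` convention, the compressive aggregate modulus directly);
2. ``(log10 H_A_plus, log10 k)`` are then estimated by multi-start nonlinear
   least squares of the series forward model against the full ramp+hold
   stress residual (engineering stress).

Free parameters are exactly the two properties reported per step; the
applied-strain deviation from target is carried through as a covariate for
the statistical model rather than corrected mechanically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from . import cle_forward
from .exceptions import (
    ConvergenceError,
    InsufficientRelaxationError,
    InvalidInputError,
    MissingPairError,
)
from .materials import CLEMaterial, RampHoldStep, SampleGeometry

__all__ = [
    "RawCompressionRecord",
    "StepFitResult",
    "FitOptions",
    "load_to_stress",
    "fit_step",
    "aggregate_eye",
    "interocular_difference",
    "iod_table",
]

TARE_LOAD_UN = 500.0  # uN


def load_to_stress(load_uN, diameter_m: float):
    """Engineering stress (Pa) from load (uN) on the reference circular area.

    500 uN on a 1 mm diameter disk gives 636.6 Pa (printed as 636 Pa).
    """
    if not (diameter_m > 0.0):
        raise InvalidInputError(f"diameter must be > 0, got {diameter_m!r}")
    area = np.pi * (diameter_m / 2.0) ** 2
    return np.asarray(load_uN, dtype=float) * 1e-6 / area


@dataclass(frozen=True)
class RawCompressionRecord:
    """One step of one compression test, in raw load units."""

    sample_id: str
    eye_id: str
    step_index: int
    times: np.ndarray
    load_uN: np.ndarray
    diameter_m: float = 1.0e-3
    thickness_ref_m: float = 50e-6
    target_strain: float = 0.05
    applied_strain: float = 0.05
    ramp_duration: float = 10.0

    def __post_init__(self):
        if self.step_index not in (1, 2, 3):
            raise InvalidInputError(f"step_index must be 1..3, got {self.step_index}")
        t = np.asarray(self.times, dtype=float)
        f = np.asarray(self.load_uN, dtype=float)
        if t.shape != f.shape or t.ndim != 1:
            raise InvalidInputError("times and load must be matching 1-D arrays")
        if not np.all(np.isfinite(f)):
            raise InvalidInputError("load contains non-finite values")
        if abs(self.applied_strain - self.target_strain) > 0.03:
            raise InvalidInputError(
                f"applied strain {self.applied_strain} implausibly far from "
                f"target {self.target_strain}"
            )
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "load_uN", f)

    @property
    def strain_deviation(self) -> float:
        """Delta-eps = applied - target strain (dimensionless)."""
        return self.applied_strain - self.target_strain

    def stress_trace(self) -> tuple[np.ndarray, np.ndarray]:
        """Baseline-subtracted engineering stress (Pa) vs time from step start."""
        stress = load_to_stress(self.load_uN - self.load_uN[0], self.diameter_m)
        return self.times - self.times[0], stress


@dataclass(frozen=True)
class StepFitResult:
    H_A_plus_hat: float
    k_hat: float
    E_eq_hat: float
    strain_deviation: float
    sse: float
    converged: bool
    n_starts_used: int
    sample_id: str = ""
    eye_id: str = ""
    step_index: int = 0


@dataclass(frozen=True)
class FitOptions:
    """Search configuration for the stage-2 nonlinear fit."""

    h_bounds: tuple = (1e3, 1e8)       # Pa
    k_bounds: tuple = (1e-18, 1e-12)   # m^4/(N s)
    n_starts: int = 5
    plateau_fraction: float = 0.05     # tail fraction averaged for the plateau
    relaxation_tol: float = 0.05       # max projected residual transient at trace end
    ftol: float = 1e-10
    lambda2: float = 0.0               # packaged coupling convention


def _plateau(times: np.ndarray, stress: np.ndarray, opts: FitOptions) -> float:
    """Tail-mean plateau with an exponential-extrapolation relaxation check.

    A slowly decaying trace is locally flat, so closeness of late samples to
    the tail mean is not evidence of equilibration.  Instead the tail
    (t >= T/4) is fit with ``a + b*exp(-t/tau)`` over a small grid of decay
    times and the trace is rejected when the projected residual transient at
    the final sample exceeds ``relaxation_tol`` of the plateau.  The fitted
    intercept ``a`` is the plateau estimate: it subtracts the residual
    transient that a plain tail mean would fold into the equilibrium modulus.
    """
    T = times[-1]
    tail = times >= 0.25 * T
    t_tail, s_tail = times[tail], stress[tail]
    best = None
    for tau in T * np.array([1 / 24, 1 / 12, 1 / 6, 1 / 3, 2 / 3, 1.5]):
        design = np.column_stack([np.ones_like(t_tail), np.exp(-t_tail / tau)])
        coef, res_, *_ = np.linalg.lstsq(design, s_tail, rcond=None)
        sse = float(np.sum((design @ coef - s_tail) ** 2))
        if best is None or sse < best[0]:
            best = (sse, coef, tau)
    _, (a_hat, b_hat), tau_hat = best
    if a_hat <= 0.0:
        raise InsufficientRelaxationError("non-positive plateau stress")
    residual_T = abs(b_hat) * np.exp(-T / tau_hat)
    if residual_T > opts.relaxation_tol * a_hat:
        raise InsufficientRelaxationError(
            f"hold phase not equilibrated: projected residual transient is "
            f"{residual_T / a_hat:.1%} of the plateau "
            f"(> {opts.relaxation_tol:.0%})"
        )
    n_tail = max(3, int(np.ceil(opts.plateau_fraction * stress.size)))
    tail_mean = float(np.mean(stress[-n_tail:]))
    # guard against a degenerate exponential fit pulling the intercept away
    if abs(a_hat - tail_mean) > 0.05 * tail_mean:
        return tail_mean
    return float(a_hat)


def fit_step(
    record: RawCompressionRecord,
    geometry: SampleGeometry | None = None,
    options: FitOptions = FitOptions(),
) -> StepFitResult:
    """Estimate (H_A_plus, k) for one compression step.

    Raises :class:`InsufficientRelaxationError` when the hold never reaches
    its plateau and :class:`ConvergenceError` when every start fails.
    """
    if geometry is None:
        geometry = SampleGeometry(radius=record.diameter_m / 2.0,
                                  thickness_ref=record.thickness_ref_m)
    times, stress = record.stress_trace()
    plateau = _plateau(times, stress, options)
    eps = record.applied_strain
    e_eq_hat = plateau / eps
    lam2 = options.lambda2
    # invert E_eq = H_minus - 2 lam2^2/(H_plus + lam2) for H_minus given a trial
    # H_plus; with the default lam2 = 0 this is simply H_minus = E_eq.

    hold_mask = times > 0.0
    t_fit = times[hold_mask]
    s_fit = stress[hold_mask]
    step = RampHoldStep(
        step_strain=eps,
        ramp_duration=record.ramp_duration,
        hold_duration=max(times[-1] - record.ramp_duration, record.ramp_duration),
        sample_times=t_fit,
    )

    def residuals(x: np.ndarray) -> np.ndarray:
        h_plus = 10.0 ** x[0]
        k = 10.0 ** x[1]
        h_minus = e_eq_hat + 2.0 * lam2**2 / (h_plus + lam2)
        with warnings.catch_warnings():
            # trial points may briefly put H_A_plus below the plateau modulus
            warnings.simplefilter("ignore")
            material = CLEMaterial(H_A_plus=h_plus, H_A_minus=h_minus,
                                   lambda2=lam2, k=k)
        model = cle_forward.ramp_hold_stress(material, geometry, step)
        return model.stress - s_fit

    lo = np.log10([options.h_bounds[0], options.k_bounds[0]])
    hi = np.log10([options.h_bounds[1], options.k_bounds[1]])
    # log-spaced multi-starts across the interior of the search box, pairing
    # high moduli with low conductivities so the trial gel-diffusion times
    # sweep the plausible range
    frac = np.linspace(0.15, 0.85, options.n_starts)
    starts = np.column_stack([lo[0] + frac * (hi[0] - lo[0]),
                              hi[1] - frac * (hi[1] - lo[1])])

    best = None
    failures = []
    for x0 in starts:
        try:
            sol = least_squares(residuals, x0, bounds=(lo, hi), method="trf",
                                ftol=options.ftol, xtol=1e-12, gtol=1e-12)
        except Exception as exc:  # pragma: no cover - diagnostic path
            failures.append(f"start {x0}: {exc}")
            continue
        sse = float(np.sum(sol.fun**2))
        if best is None or sse < best[0]:
            best = (sse, sol)
    if best is None:
        raise ConvergenceError(
            "all multi-starts failed:\n" + "\n".join(failures)
        )
    sse, sol = best
    return StepFitResult(
        H_A_plus_hat=float(10.0 ** sol.x[0]),
        k_hat=float(10.0 ** sol.x[1]),
        E_eq_hat=float(e_eq_hat),
        strain_deviation=record.strain_deviation,
        sse=sse,
        converged=bool(sol.status > 0),
        n_starts_used=len(starts),
        sample_id=record.sample_id,
        eye_id=record.eye_id,
        step_index=record.step_index,
    )


def fits_to_frame(fits: Iterable[StepFitResult]) -> pd.DataFrame:
    rows = [
        {
            "sample_id": f.sample_id,
            "eye_id": f.eye_id,
            "step": f.step_index,
            "H_A_plus": f.H_A_plus_hat,
            "k": f.k_hat,
            "E_eq": f.E_eq_hat,
            "strain_deviation": f.strain_deviation,
            "sse": f.sse,
            "converged": f.converged,
        }
        for f in fits
    ]
    return pd.DataFrame(rows)


def aggregate_eye(fits: pd.DataFrame | Iterable[StepFitResult]) -> pd.DataFrame:
    """Average step-fit results across samples within eye x step.

    Multiple punches tested from the same eye are arithmetically averaged;
    the mean strain deviation is carried along for the statistical model.
    """
    df = fits if isinstance(fits, pd.DataFrame) else fits_to_frame(fits)
    if df.empty:
        raise InvalidInputError("no step fits to aggregate")
    value_cols = [c for c in ("H_A_plus", "k", "E_eq", "strain_deviation") if c in df]
    return (
        df.groupby(["eye_id", "step"], as_index=False)[value_cols]
        .mean()
        .sort_values(["eye_id", "step"], ignore_index=True)
    )


def interocular_difference(treated, contralateral):
    """IOD = treated - contralateral; multi-step inputs are differenced per
    step and then averaged."""
    t = np.asarray(treated, dtype=float)
    c = np.asarray(contralateral, dtype=float)
    if t.shape != c.shape:
        raise InvalidInputError("treated and contralateral shapes differ")
    diff = t - c
    return float(np.mean(diff)) if diff.ndim else float(diff)


def iod_table(per_eye: pd.DataFrame, manifest: pd.DataFrame,
              value_cols: Sequence[str] = ("H_A_plus", "k")) -> pd.DataFrame:
    """Per-animal, per-step interocular differences from a per-eye table.

    ``manifest`` maps ``eye_id`` to ``animal_id`` and ``eye_role``
    (treated/contralateral).  Raises :class:`MissingPairError` when an animal
    lacks one eye.
    """
    merged = per_eye.merge(manifest[["eye_id", "animal_id", "eye_role"]], on="eye_id")
    wide = merged.pivot_table(index=["animal_id", "step"], columns="eye_role",
                              values=list(value_cols))
    missing = wide.index[wide.isna().any(axis=1)].get_level_values("animal_id").unique()
    if len(missing):
        raise MissingPairError(missing)
    out = pd.DataFrame(index=wide.index)
    for col in value_cols:
        out[f"iod_{col}"] = wide[(col, "treated")] - wide[(col, "contralateral")]
    return out.reset_index()
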