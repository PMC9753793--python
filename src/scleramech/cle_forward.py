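"""Closed-form series solution of ramp-and-hold unconfined compression.

A biphasic CLE disk of radius ``a`` compressed axially between frictionless,
impermeable platens with a free-draining rim relaxes by radial fluid
exudation.  The dilatation obeys a radial diffusion equation with diffusivity
``H_A_plus * k``, and separation of variables gives eigenvalues ``alpha_n``
that are the positive roots of the characteristic function

    C(x) = J1(x) - beta * x * J0(x),      beta = H_A_plus / (H_A_plus - lambda2).

The axial engineering stress response (compression positive) to a step of
strain ``eps0`` applied at t=0 is

    sigma(t) = eps0 * [ E_eq + sum_n B_n * exp(-t / tau_n) ],

with ``E_eq`` the drained unconfined modulus, modal amplitudes
``B_n = H_A_plus / (beta^2 alpha_n^2 - 2 beta + 1)`` and time constants
``tau_n = a^2 / (H_A_plus * k * alpha_n^2)``.  A finite loading ramp is
handled by Duhamel superposition of the step response, which is exact for
this linear model.  The independent finite-difference solver in
:mod:`scleramech.fd_oracle` cross-checks every piece of this algebra at run
time.
"""

from __future__ import annotations

import functools
import math

import numpy as np
from scipy.optimize import brentq
from scipy.special import j0, j1, jn_zeros

from .exceptions import (
    InvalidInputError,
    InvalidParameterError,
    SeriesConvergenceError,
)
from .materials import CLEMaterial, RampHoldStep, SampleGeometry, StressTrace

__all__ = [
    "characteristic_roots",
    "equilibrium_modulus",
    "gel_diffusion_time",
    "ramp_hold_stress",
    "step_stress",
    "series_coefficients",
    "isotropic_ramp_hold_stress",
]

#: hard cap on series terms (fixed truncation policy)
MAX_ROOTS = 200
#: a new term must contribute at least this fraction of the running sum
TRUNCATION_RTOL = 1e-10


def _characteristic(x: float, beta: float) -> float:
    return j1(x) - beta * x * j0(x)


@functools.lru_cache(maxsize=128)
def _cached_roots(beta: float, n_roots: int) -> tuple:
    return tuple(_compute_roots(beta, n_roots))


def _compute_roots(beta: float, n_roots: int) -> np.ndarray:
    if beta == 0.0:
        return jn_zeros(1, n_roots)

    # Roots of C(x) = J1 - beta*x*J0 live only in the intervals (b_m, a_{m+1})
    # between a zero b_m of J1 and the next zero a_{m+1} of J0 (taking b_0 = 0):
    # on (a_m, b_m) J0 and J1 have opposite signs so C cannot vanish for beta>0.
    n_scan = n_roots + 4
    a_zeros = jn_zeros(0, n_scan + 1)  # zeros of J0
    b_zeros = np.concatenate([[0.0], jn_zeros(1, n_scan)])  # zeros of J1 incl. 0
    roots: list[float] = []
    scanned_hi = 0.0
    for m in range(n_scan):
        lo, hi = b_zeros[m], a_zeros[m]
        scanned_hi = hi
        # inset the bracket: at lo the J1 factor vanishes so C is dominated by
        # the -beta*x*J0 term even for tiny beta; a relative inset keeps that
        # dominance while avoiding the exact zero.
        lo_in = lo + max(1e-12 * max(lo, 1.0), 1e-13)
        hi_in = hi - 1e-12 * hi
        f_lo = _characteristic(lo_in, beta)
        f_hi = _characteristic(hi_in, beta)
        if f_lo == 0.0:
            roots.append(lo_in)
        elif f_hi == 0.0:
            roots.append(hi_in)
        elif f_lo * f_hi < 0.0:
            roots.append(brentq(_characteristic, lo_in, hi_in, args=(beta,),
                                xtol=1e-300, rtol=1e-14, maxiter=200))
        # else: no root in this interval (happens for the first interval when
        # beta < 1/2, where the smallest root defers to the next bracket).
        if len(roots) == n_roots:
            return np.asarray(roots)
    raise SeriesConvergenceError(
        f"failed to bracket {n_roots} characteristic roots for shape_param="
        f"{beta!r} while scanning (0, {scanned_hi:.6g})",
        terms_used=len(roots),
    )


def characteristic_roots(shape_param: float, n_roots: int) -> np.ndarray:
    """First ``n_roots`` positive roots of ``J1(x) - shape_param*x*J0(x)``.

    Roots are strictly increasing and refined to relative tolerance 1e-12.
    ``shape_param = 0`` returns the positive zeros of J1; very large values
    approach the zeros of J0.
    """
    if not isinstance(n_roots, (int, np.integer)) or n_roots < 1:
        raise InvalidParameterError(f"n_roots must be a positive integer, got {n_roots!r}")
    shape_param = float(shape_param)
    if not math.isfinite(shape_param) or shape_param < 0.0:
        raise InvalidParameterError(
            f"shape_param must be finite and >= 0, got {shape_param!r}"
        )
    return np.asarray(_cached_roots(shape_param, int(n_roots)))


def equilibrium_modulus(material: CLEMaterial) -> float:
    """Drained long-time unconfined modulus E_eq, Pa (long-time stress = E_eq*strain)."""
    e_eq = material.equilibrium_modulus()
    if e_eq <= 0.0:
        raise InvalidParameterError(f"equilibrium modulus non-positive for {material}")
    return e_eq


def gel_diffusion_time(material: CLEMaterial, geometry: SampleGeometry) -> float:
    """Characteristic consolidation time a^2 / (H_A_plus * k), s."""
    return geometry.radius**2 / (material.H_A_plus * material.k)


def series_coefficients(
    material: CLEMaterial, geometry: SampleGeometry, n_roots: int = MAX_ROOTS
):
    """Modal amplitudes B_n (Pa) and time constants tau_n (s) of the step response."""
    beta = material.shape_param
    alpha = characteristic_roots(beta, n_roots)
    tau_gel = gel_diffusion_time(material, geometry)
    tau = tau_gel / alpha**2
    B = material.H_A_plus / (beta**2 * alpha**2 - 2.0 * beta + 1.0)
    return B, tau


def step_stress(
    material: CLEMaterial,
    geometry: SampleGeometry,
    times,
    n_roots: int = MAX_ROOTS,
) -> np.ndarray:
    """Stress response to a unit step of compressive strain at t=0 (Pa per unit strain)."""
    t = np.asarray(times, dtype=float)
    B, tau = series_coefficients(material, geometry, n_roots)
    e_eq = equilibrium_modulus(material)
    decay = np.exp(-t[:, None] / tau[None, :])
    return e_eq + decay @ B


def _ramp_series(t: np.ndarray, t_r: float, B: np.ndarray, tau: np.ndarray) -> np.ndarray:
    """sum_n B_n tau_n [exp(-(t-t_r)_+/tau) - exp(-t/tau)] evaluated stably."""
    t = t[:, None]
    tau = tau[None, :]
    Btau = (B * tau[0])[None, :]
    during = t <= t_r
    # during ramp: B*tau*(1 - exp(-t/tau)); after: B*tau*exp(-(t-t_r)/tau)*(1-exp(-t_r/tau))
    term_during = Btau * (-np.expm1(-t / tau))
    term_after = Btau * np.exp(-np.maximum(t - t_r, 0.0) / tau) * (-np.expm1(-t_r / tau))
    return np.sum(np.where(during, term_during, term_after), axis=1)


def ramp_hold_stress(
    material: CLEMaterial,
    geometry: SampleGeometry,
    step: RampHoldStep,
    n_roots: int | None = None,
) -> StressTrace:
    """Axial stress trace for a finite-ramp-and-hold compression step.

    Stress is relative to the step baseline (zero at t=0), compression
    positive; the maximum occurs at ramp end and the hold phase decays
    monotonically toward ``equilibrium_modulus * step_strain``.

    Series truncation: terms are added until the next term contributes less
    than ``TRUNCATION_RTOL`` of the accumulated transient at the earliest
    (positive) sample time, with a hard cap of ``MAX_ROOTS`` roots.  The number
    of terms used is recorded in the trace metadata.
    """
    t = step.sample_times
    if t.size == 0:
        raise InvalidInputError("sample_times is empty")
    eps0 = step.step_strain
    t_r = step.ramp_duration
    e_eq = equilibrium_modulus(material)

    B, tau = series_coefficients(material, geometry, MAX_ROOTS)
    # truncation point from the per-term transient magnitude at the earliest
    # informative time (ramp superposition bounds each term by B_n*tau_n*min(t,t_r))
    t_ref = max(t[t > 0.0].min() if np.any(t > 0.0) else t_r, 1e-6 * t_r)
    contrib = B * tau * (-np.expm1(-min(t_ref, t_r) / tau))
    csum = np.cumsum(contrib)
    small = contrib[1:] < TRUNCATION_RTOL * csum[:-1]
    if np.any(small):
        n_terms = int(np.argmax(small)) + 1
    else:
        # cap reached: accept if the last term is already negligible (the
        # tail of B_n*tau_n decays like alpha_n^-4, so a 1e-5 last-term
        # contribution bounds the tail well below sampling noise)
        n_terms = MAX_ROOTS
        if contrib[-1] > 1e-5 * csum[-1]:
            raise SeriesConvergenceError(
                f"series not converged within {MAX_ROOTS} terms at reference "
                f"time {t_ref:.3g} s (last-term share "
                f"{contrib[-1] / csum[-1]:.2e})",
                terms_used=MAX_ROOTS,
            )
    if n_roots is not None:
        n_terms = min(n_terms, int(n_roots))
    B, tau = B[:n_terms], tau[:n_terms]

    rate = eps0 / t_r
    stress = rate * (e_eq * np.minimum(t, t_r) + _ramp_series(t, t_r, B, tau))
    meta = {
        "material": material.to_dict(),
        "geometry": geometry.to_dict(),
        "step": step.to_dict(),
        "n_series_terms": n_terms,
        "model": "cle_series",
    }
    return StressTrace(times=t, stress=stress, meta=meta)


def isotropic_ramp_hold_stress(
    H_A: float,
    nu: float,
    k: float,
    geometry: SampleGeometry,
    step: RampHoldStep,
    n_roots: int = MAX_ROOTS,
) -> StressTrace:
    """Classical isotropic biphasic unconfined-compression solution.

    Reference formula coded directly from the isotropic constants (aggregate
    modulus ``H_A = lambda + 2 mu`` and drained Poisson's ratio ``nu``): the
    characteristic equation is ``J1(x) - (1-nu)/(1-2nu) * x * J0(x) = 0``, the
    drained modulus is the Young's modulus ``E = mu (3 lambda + 2 mu) /
    (lambda + mu)`` and the modal amplitudes follow from the residue of the
    Laplace-domain solution.  Used as the reduction target for the CLE code
    path when ``H_A_plus = H_A_minus``.
    """
    if not (0.0 <= nu < 0.5):
        raise InvalidParameterError(f"nu must be in [0, 0.5), got {nu!r}")
    lam = H_A * nu / (1.0 - nu)
    mu = 0.5 * (H_A - lam)
    E_y = mu * (3.0 * lam + 2.0 * mu) / (lam + mu)
    C = (1.0 - nu) / (1.0 - 2.0 * nu)
    alpha = characteristic_roots(C, n_roots)
    tau = geometry.radius**2 / (H_A * k * alpha**2)
    B = H_A / (C**2 * alpha**2 - 2.0 * C + 1.0)
    # truncate identically to the CLE path for a like-for-like comparison
    t = step.sample_times
    rate = step.step_strain / step.ramp_duration
    stress = rate * (E_y * np.minimum(t, step.ramp_duration)
                     + _ramp_series(t, step.ramp_duration, B, tau))
    meta = {"model": "isotropic_reference", "H_A": H_A, "nu": nu, "k": k}
    return StressTrace(times=t, stress=stress, meta=meta)
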