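import numpy as np
import pytest

from scleramech.materials import (
    CLEMaterial,
    RampHoldStep,
    SampleGeometry,
    log_spaced_times,
)


@pytest.fixture(scope="session")
def geometry():
    return SampleGeometry()


@pytest.fixture(scope="session")
def default_material():
    """Posterior mouse-sclera-like parameter set (lambda2 = 0 convention)."""
    return CLEMaterial(H_A_plus=1.0e6, H_A_minus=5.0e4, lambda2=0.0, k=3.0e-16)


@pytest.fixture(scope="session")
def coupled_material():
    """A material with nonzero off-diagonal coupling, for the general paths."""
    return CLEMaterial(H_A_plus=1.0e6, H_A_minus=2.0e5, lambda2=1.2e5, k=5.0e-16)


@pytest.fixture(scope="session")
def default_step():
    times = log_spaced_times(10.0, 3000.0)
    return RampHoldStep(step_strain=0.05, ramp_duration=10.0,
                        hold_duration=3000.0, sample_times=times)


@pytest.fixture(scope="session")
def fast_step():
    """Short protocol for a fast-relaxing material (test-size problems)."""
    times = log_spaced_times(2.0, 400.0, n_ramp=8, n_hold=60, first_hold_offset=0.1)
    return RampHoldStep(step_strain=0.05, ramp_duration=2.0,
                        hold_duration=400.0, sample_times=times)


@pytest.fixture(scope="session")
def fast_material():
    """Higher-conductivity material whose relaxation fits in fast_step."""
    return CLEMaterial(H_A_plus=1.0e6, H_A_minus=5.0e4, lambda2=0.0, k=3.0e-15)


def draw_valid_material(rng: np.random.Generator, lambda2_zero=False) -> CLEMaterial:
    """Random material inside the fitting bounds with E_eq > 0 guaranteed."""
    h = 10.0 ** rng.uniform(5.0, 6.5)
    e = h * 10.0 ** rng.uniform(-1.8, -0.8)
    k = 10.0 ** rng.uniform(-16.3, -15.0)
    if lambda2_zero:
        lam = 0.0
    else:
        lam_cap = 0.8 * np.sqrt(e * h / 2.0)  # keeps E_eq well above 0
        lam = rng.uniform(0.0, min(lam_cap, 0.6 * h))
    return CLEMaterial(H_A_plus=h, H_A_minus=e, lambda2=lam, k=k)
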