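"""Seeded synthetic-data generator for the whole analysis chain.

Generates every input the pipeline consumes — paired-eye cohort manifests
with true material parameters, raw unconfined-compression load traces
(simulated with the finite-difference oracle, never the series model, so
parameter recovery is not an inverse crime), refraction and OCT interface
tables, and plate/slide assay data — from a single config and master seed.

The packaged "fd-study" configuration transcribes the study estimands:
refractive-shift means/SDs of -2.35/1.11 D (1-week form deprivation),
-4.07/0.72 D (3-week), 0.02/0.37 D (naive); multiplicative treated-eye
effects 0.708 on tensile modulus and 1.801 on conductivity at 1 week, 0.601
and 2.314 at 3 weeks (1 + percent/100 of the reported percent interocular
differences); applied-strain jitter of up to 1.5 percentage points around
the 5% step target; 22 animals per arm for refraction and 6 per arm for
compression testing.

Determinism: every random draw flows through a per-entity seed derived from
(master seed, entity keys), so outputs are stable under re-ordering of the
generation calls.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import fd_oracle
from .exceptions import InvalidParameterError
from .materials import CLEMaterial, RampHoldStep, SampleGeometry, log_spaced_times
from .uct_fitting import TARE_LOAD_UN, RawCompressionRecord

__all__ = [
    "ArmConfig",
    "MaterialConfig",
    "ProtocolConfig",
    "BiometryConfig",
    "AssayConfig",
    "CohortConfig",
    "fd_study_config",
    "generate_cohort",
    "generate_uct_traces",
    "generate_refraction_biometry",
    "generate_assay_data",
]


def _rng(seed: int, *keys) -> np.random.Generator:
    """Entity-keyed generator: deterministic, order-independent."""
    entropy = [int(seed)] + [zlib.crc32(str(k).encode()) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))


@dataclass(frozen=True)
class ArmConfig:
    """Per-arm cohort sizes and treated-eye effects."""

    n_animals_refraction: int = 22
    n_animals_uct: int = 6
    h_effect: float = 1.0          # multiplicative, treated / contralateral H_A_plus
    k_effect: float = 1.0          # multiplicative on hydraulic conductivity
    e_eq_effect: float | None = None  # defaults to h_effect
    re_iod_mean: float = 0.0       # D
    re_iod_sd: float = 0.37        # D
    ihc_chac_effect: float = 1.0   # treated/contra ratio of C-4-S staining
    ihc_chb_effect: float = 1.0    # same for dermatan sulfate

    def __post_init__(self):
        if (self.n_animals_refraction < 0 or self.n_animals_uct < 0
                or self.n_animals_refraction + self.n_animals_uct < 1):
            raise InvalidParameterError("arm animal counts must be >= 0 with >= 1 total")
        for name in ("h_effect", "k_effect", "ihc_chac_effect", "ihc_chb_effect"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0 (multiplicative)")

    @property
    def e_effect(self) -> float:
        return self.h_effect if self.e_eq_effect is None else self.e_eq_effect


@dataclass(frozen=True)
class MaterialConfig:
    """Baseline (contralateral/naive) scleral material parameters.

    Means are for a posterior-sclera punch; between-animal and between-eye
    variability is lognormal so parameters stay positive, matching the
    log-link analysis model.
    """

    h_plus_mean: float = 1.0e6     # Pa
    e_eq_mean: float = 5.0e4       # Pa (drained unconfined modulus)
    k_mean: float = 3.0e-16        # m^4/(N s)
    sd_log_animal_h: float = 0.25
    sd_log_animal_k: float = 0.35
    sd_log_animal_e: float = 0.25
    sd_log_eye_h: float = 0.08
    sd_log_eye_k: float = 0.12
    sd_log_eye_e: float = 0.08

    def __post_init__(self):
        for name, val in asdict(self).items():
            if name.startswith("sd_") and val < 0:
                raise InvalidParameterError(f"{name} must be >= 0")


@dataclass(frozen=True)
class ProtocolConfig:
    """Compression protocol and measurement-noise settings."""

    n_steps: int = 3
    target_strain: float = 0.05
    ramp_duration: float = 10.0         # s
    hold_duration: float = 3000.0       # s (long enough to equilibrate)
    n_ramp_samples: int = 12
    n_hold_samples: int = 110
    strain_jitter_halfwidth: float = 0.015  # +/- 1.5 percentage points
    load_noise_uN: float = 10.0
    # per-step log-scale sensitivity of the true properties to strain
    # deviation (compression closes pores: conductivity falls fastest)
    strain_sens_log_h: float = -3.0
    strain_sens_log_k: float = -8.0
    samples_per_eye: int = 1
    diameter_m: float = 1.0e-3
    thickness_um: float = 50.0
    oracle_n_radial: int = 64
    oracle_dt: float = 0.75


@dataclass(frozen=True)
class BiometryConfig:
    """Physical component means/SDs (um) with zero configured treatment effect."""

    means: tuple = (105.0, 320.0, 2000.0, 650.0, 230.0)   # CCT, ACD, LT, VCD, RT
    sd_animal: tuple = (3.0, 10.0, 30.0, 25.0, 8.0)
    sd_eye: tuple = (2.0, 5.0, 10.0, 12.0, 4.0)
    refractive_index: float = 1.39
    opacity_rate: float = 0.0
    re_contra_mean: float = -0.1   # D, absolute refraction of untreated eyes
    re_contra_sd: float = 0.5


@dataclass(frozen=True)
class AssayConfig:
    """Plate-reader and IHC generator settings."""

    sgag_mass_fraction_ug_mg: float = 10.0
    sgag_sd_log_animal: float = 0.15
    sgag_sd_log_eye: float = 0.08
    dry_mass_mg: float = 0.15
    digest_volume_mL: float = 0.2
    dna_total_ug: float = 1.5
    dmmb_slope: float = 0.02       # AU per ug/mL
    dmmb_intercept: float = 0.05
    dmmb_standards: tuple = (0.0, 5.0, 10.0, 20.0, 40.0)
    pico_slope: float = 0.05
    pico_intercept: float = 0.02
    pico_standards: tuple = (0.0, 2.0, 5.0, 10.0, 20.0)
    plate_noise_au: float = 0.005
    ihc_shape: tuple = (64, 160)
    ihc_band: tuple = (24, 40)     # rows of the scleral band
    ihc_background: float = 300.0
    ihc_buffer_intensity: float = 500.0
    ihc_chac_ratio: float = 1.7    # baseline treated-section / buffer ratio
    ihc_chb_ratio: float = 1.6


@dataclass(frozen=True)
class CohortConfig:
    """Master generator configuration (one seeded config drives everything)."""

    arms: dict = field(default_factory=lambda: {"naive": ArmConfig()})
    material: MaterialConfig = MaterialConfig()
    protocol: ProtocolConfig = ProtocolConfig()
    biometry: BiometryConfig = BiometryConfig()
    assay: AssayConfig = AssayConfig()
    baseline_re_iod_mean: float = -0.13
    baseline_re_iod_sd: float = 0.67

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        arms = {name: ArmConfig(**a) for name, a in d.pop("arms", {}).items()}
        return cls(
            arms=arms,
            material=MaterialConfig(**d.pop("material", {})),
            protocol=ProtocolConfig(**{k: tuple(v) if isinstance(v, list) else v
                                       for k, v in d.pop("protocol", {}).items()}),
            biometry=BiometryConfig(**{k: tuple(v) if isinstance(v, list) else v
                                       for k, v in d.pop("biometry", {}).items()}),
            assay=AssayConfig(**{k: tuple(v) if isinstance(v, list) else v
                                 for k, v in d.pop("assay", {}).items()}),
            **d,
        )

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def fd_study_config() -> CohortConfig:
    """Configuration transcribing the study's reported estimands."""
    return CohortConfig(
        arms={
            "FD1": ArmConfig(
                n_animals_refraction=22, n_animals_uct=6,
                h_effect=0.708, k_effect=1.801,
                re_iod_mean=-2.35, re_iod_sd=1.11,
                ihc_chac_effect=0.75, ihc_chb_effect=1.0,
            ),
            "FD3": ArmConfig(
                n_animals_refraction=22, n_animals_uct=6,
                h_effect=0.601, k_effect=2.314,
                re_iod_mean=-4.07, re_iod_sd=0.72,
                ihc_chac_effect=0.75, ihc_chb_effect=0.70,
            ),
            "naive": ArmConfig(
                n_animals_refraction=22, n_animals_uct=6,
                re_iod_mean=0.02, re_iod_sd=0.37,
            ),
        },
    )


# ---------------------------------------------------------------------------
# cohort manifest

def generate_cohort(config: CohortConfig, seed: int) -> pd.DataFrame:
    """Animal/eye manifest with per-eye true material parameters.

    Paired eyes share animal-level lognormal random effects; the treated
    eye's parameters are the contralateral eye's times the arm effect times
    eye-level lognormal noise.  Naive animals keep the OD/OS labels, with OD
    taking the "treated" slot of the interocular-difference convention.
    """
    mat = config.material
    rows = []
    for arm_name, arm in config.arms.items():
        n_total = arm.n_animals_refraction + arm.n_animals_uct
        for i in range(n_total):
            endpoint = "uct" if i < arm.n_animals_uct else "refraction"
            animal_id = f"{arm_name}_a{i:03d}"
            rng = _rng(seed, "cohort", arm_name, i)
            base_h = mat.h_plus_mean * np.exp(rng.normal(0.0, mat.sd_log_animal_h))
            base_k = mat.k_mean * np.exp(rng.normal(0.0, mat.sd_log_animal_k))
            base_e = mat.e_eq_mean * np.exp(rng.normal(0.0, mat.sd_log_animal_e))
            contra = {
                "H_A_plus_true": base_h,
                "k_true": base_k,
                "E_eq_true": base_e,
            }
            eff = (arm.h_effect, arm.k_effect, arm.e_effect)
            eye_noise = rng.normal(0.0, [mat.sd_log_eye_h, mat.sd_log_eye_k,
                                         mat.sd_log_eye_e])
            treated = {
                "H_A_plus_true": base_h * eff[0] * np.exp(eye_noise[0]),
                "k_true": base_k * eff[1] * np.exp(eye_noise[1]),
                "E_eq_true": base_e * eff[2] * np.exp(eye_noise[2]),
            }
            for side, role, params in (("OD", "treated", treated),
                                       ("OS", "contralateral", contra)):
                rows.append({
                    "animal_id": animal_id,
                    "arm": arm_name,
                    "endpoint": endpoint,
                    "eye_id": f"{animal_id}_{side}",
                    "eye_side": side,
                    "eye_role": role,
                    **params,
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# compression traces

def generate_uct_traces(
    manifest: pd.DataFrame, config: CohortConfig, seed: int
) -> tuple[list, pd.DataFrame]:
    """Raw load-time records for every compression-tested eye.

    Stress is computed with the finite-difference oracle from the eye's true
    parameters (scaled per step by the strain-deviation sensitivities),
    offset by the tare stress and the accumulated equilibrium stresses of
    earlier steps, converted to load and corrupted with additive load-cell
    noise.  Returns the records plus a per-step truth table.
    """
    proto = config.protocol
    geometry = SampleGeometry(radius=proto.diameter_m / 2.0,
                              thickness_ref=proto.thickness_um * 1e-6)
    grid = fd_oracle.GridSpec(n_radial=proto.oracle_n_radial, dt=proto.oracle_dt)
    area = np.pi * (proto.diameter_m / 2.0) ** 2
    tare_stress = TARE_LOAD_UN * 1e-6 / area
    alpha1_sq = 1.8412 ** 2  # first eigenvalue at the lambda2=0 convention

    eyes = manifest[manifest["endpoint"] == "uct"]
    records: list[RawCompressionRecord] = []
    truth_rows = []
    for _, eye in eyes.iterrows():
        for s in range(proto.samples_per_eye):
            sample_id = f"{eye.eye_id}_s{s}"
            baseline = tare_stress
            for step_idx in range(1, proto.n_steps + 1):
                rng = _rng(seed, "uct", eye.eye_id, s, step_idx)
                dev = rng.uniform(-proto.strain_jitter_halfwidth,
                                  proto.strain_jitter_halfwidth)
                applied = proto.target_strain + dev
                h_step = eye.H_A_plus_true * np.exp(proto.strain_sens_log_h * dev)
                k_step = eye.k_true * np.exp(proto.strain_sens_log_k * dev)
                e_step = eye.E_eq_true * np.exp(proto.strain_sens_log_h * dev)
                material = CLEMaterial(H_A_plus=h_step, H_A_minus=e_step,
                                       lambda2=0.0, k=k_step)
                # hold "until stress relaxed and equilibrated": extend the
                # configured hold for slow-draining eyes so every trace
                # reaches within ~1% of its plateau (7 leading time
                # constants)
                tau1 = geometry.radius**2 / (h_step * k_step) / alpha1_sq
                hold = max(proto.hold_duration, 7.0 * tau1)
                times = log_spaced_times(proto.ramp_duration, hold,
                                         n_ramp=proto.n_ramp_samples,
                                         n_hold=proto.n_hold_samples)
                step = RampHoldStep(step_strain=applied,
                                    ramp_duration=proto.ramp_duration,
                                    hold_duration=hold,
                                    sample_times=times)
                trace = fd_oracle.solve_unconfined(material, geometry, step, grid)
                stress_abs = trace.stress + baseline
                load = stress_abs * area / 1e-6
                if proto.load_noise_uN > 0:
                    load = load + rng.normal(0.0, proto.load_noise_uN, load.shape)
                records.append(RawCompressionRecord(
                    sample_id=sample_id, eye_id=eye.eye_id, step_index=step_idx,
                    times=times, load_uN=load, diameter_m=proto.diameter_m,
                    thickness_ref_m=proto.thickness_um * 1e-6,
                    target_strain=proto.target_strain, applied_strain=applied,
                    ramp_duration=proto.ramp_duration,
                ))
                truth_rows.append({
                    "sample_id": sample_id, "eye_id": eye.eye_id,
                    "animal_id": eye.animal_id, "arm": eye.arm,
                    "step": step_idx, "applied_strain": applied,
                    "strain_deviation": dev,
                    "H_A_plus_step": h_step, "k_step": k_step, "E_eq_step": e_step,
                })
                baseline += e_step * applied  # next step's equilibrium offset
    return records, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# refraction + biometry

_COMPONENTS = ("CCT", "ACD", "LT", "VCD", "RT")
_IFACE_ORDER = ("cornea_anterior", "cornea_posterior", "lens_anterior",
                "lens_posterior", "retina_inner", "rpe")


def generate_refraction_biometry(
    manifest: pd.DataFrame, config: CohortConfig, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Refraction table (D, per eye) and OCT interface table (optical um).

    The refractive shift of each treated eye is drawn per arm (Gaussian);
    biometry components carry animal- and eye-level Gaussian noise with zero
    configured treatment effect, and interface positions are constructed so
    the derived physical lengths reproduce the configured components after
    division by the refractive index.
    """
    bio = config.biometry
    re_rows, iface_rows = [], []
    for animal_id, grp in manifest.groupby("animal_id", sort=True):
        arm_name = grp["arm"].iloc[0]
        arm = config.arms[arm_name]
        rng = _rng(seed, "invivo", animal_id)
        re_contra = rng.normal(bio.re_contra_mean, bio.re_contra_sd)
        iod = rng.normal(arm.re_iod_mean, arm.re_iod_sd)
        animal_shift = rng.normal(0.0, bio.sd_animal)
        for _, eye in grp.iterrows():
            re_val = re_contra + iod if eye.eye_role == "treated" else re_contra
            re_rows.append({
                "animal_id": animal_id, "arm": arm_name, "eye_id": eye.eye_id,
                "eye_side": eye.eye_side, "eye_role": eye.eye_role,
                "refraction_d": re_val,
            })
            comps = (np.asarray(bio.means) + animal_shift
                     + rng.normal(0.0, bio.sd_eye))
            optical = np.concatenate([[0.0], np.cumsum(comps)]) * bio.refractive_index
            row = dict(zip(_IFACE_ORDER, optical))
            row.update({
                "animal_id": animal_id, "arm": arm_name, "eye_id": eye.eye_id,
                "eye_role": eye.eye_role,
                "refractive_index": bio.refractive_index,
                "opacity": bool(rng.uniform() < bio.opacity_rate),
            })
            iface_rows.append(row)
    return pd.DataFrame(re_rows), pd.DataFrame(iface_rows)


# ---------------------------------------------------------------------------
# assays

def generate_assay_data(
    manifest: pd.DataFrame, config: CohortConfig, seed: int
) -> dict:
    """Plates (DMMB + picogreen), dry masses, slide image sets, and truth.

    Plates carry known true concentrations run through the configured linear
    standard curves with additive absorbance noise (triplicates); slides are
    banded "sclera" images with configured treated/control intensity ratios
    and Poisson counting noise, masks included.
    """
    from .assays import PlateData, SlideImageSet

    a = config.assay
    dmmb_standards = tuple(
        (c, a.dmmb_intercept + a.dmmb_slope * c) for c in a.dmmb_standards
    )
    pico_standards = tuple(
        (c, a.pico_intercept + a.pico_slope * c) for c in a.pico_standards
    )
    dmmb_samples, pico_samples, dry_mass = {}, {}, {}
    truth_rows, slides = [], {}
    for animal_id, grp in manifest.groupby("animal_id", sort=True):
        arm = config.arms[grp["arm"].iloc[0]]
        rng = _rng(seed, "assay", animal_id)
        animal_log = rng.normal(0.0, a.sgag_sd_log_animal)
        for _, eye in grp.iterrows():
            frac = a.sgag_mass_fraction_ug_mg * np.exp(
                animal_log + rng.normal(0.0, a.sgag_sd_log_eye)
            )
            mass = a.dry_mass_mg
            conc = frac * mass / a.digest_volume_mL  # ug/mL in the digest
            dna_conc = a.dna_total_ug / a.digest_volume_mL
            dmmb_samples[eye.eye_id] = tuple(
                a.dmmb_intercept + a.dmmb_slope * conc
                + rng.normal(0.0, a.plate_noise_au) for _ in range(3)
            )
            pico_samples[eye.eye_id] = tuple(
                a.pico_intercept + a.pico_slope * dna_conc
                + rng.normal(0.0, a.plate_noise_au) for _ in range(3)
            )
            dry_mass[eye.eye_id] = mass
            chac_ratio = a.ihc_chac_ratio * (
                arm.ihc_chac_effect if eye.eye_role == "treated" else 1.0
            )
            chb_ratio = a.ihc_chb_ratio * (
                arm.ihc_chb_effect if eye.eye_role == "treated" else 1.0
            )
            slides[eye.eye_id] = _make_slide(a, chac_ratio, chb_ratio,
                                             eye.eye_id, rng)
            truth_rows.append({
                "eye_id": eye.eye_id, "animal_id": animal_id,
                "arm": grp["arm"].iloc[0], "eye_role": eye.eye_role,
                "sgag_mass_fraction_true": frac,
                "sgag_concentration_true": conc,
                "chac_ratio_true": chac_ratio, "chb_ratio_true": chb_ratio,
            })
    return {
        "dmmb_plate": PlateData(standards=dmmb_standards, samples=dmmb_samples,
                                assay="DMMB_525nm"),
        "picogreen_plate": PlateData(standards=pico_standards,
                                     samples=pico_samples, assay="picogreen"),
        "dry_mass_mg": dry_mass,
        "slides": slides,
        "truth": pd.DataFrame(truth_rows),
    }


def _make_slide(a: AssayConfig, chac_ratio: float, chb_ratio: float,
                slide_id: str, rng: np.random.Generator):
    from .assays import SlideImageSet

    shape = tuple(a.ihc_shape)
    band = slice(a.ihc_band[0], a.ihc_band[1])
    mask = np.zeros(shape, dtype=bool)
    mask[band, :] = True

    def image(sclera_intensity: float) -> np.ndarray:
        base = np.full(shape, a.ihc_background, dtype=float)
        base[band, :] = sclera_intensity
        img = rng.poisson(base).astype(np.uint16)
        return np.minimum(img, 4095).astype(np.uint16)  # 12-bit container

    return SlideImageSet(
        chac=image(a.ihc_buffer_intensity * chac_ratio),
        chb=image(a.ihc_buffer_intensity * chb_ratio),
        buffer_only=image(a.ihc_buffer_intensity),
        mask_chac=mask, mask_chb=mask, mask_buffer=mask,
        slide_id=slide_id,
    )
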