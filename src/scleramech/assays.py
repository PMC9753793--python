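"""Plate-reader quantification (DMMB / picogreen) and IHC image ratios.

Sulfated GAG content is read from absorbance at 525 nm against a chondroitin
sulfate standard curve; DNA from the picogreen assay against a lambda-DNA
curve.  Wells are run in triplicate and averaged before inverse prediction.
sGAG content is reported as a mass fraction (ug sGAG / mg dry sclera) and a
mass ratio (ug sGAG / ug DNA).

Immunostained slides carry three sections (chondroitinase-AC-treated,
chondroitinase-B-treated, buffer-only control); relative GAG content is the
mean masked scleral pixel intensity of a treated section divided by the same
slide's buffer-only control, which cancels slide-level gain and nonspecific
staining.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError

__all__ = [
    "PlateData",
    "SlideImageSet",
    "StandardCurve",
    "fit_standard_curve",
    "quantify_sgag",
    "ihc_normalized_intensity",
]


@dataclass(frozen=True)
class PlateData:
    """Standards and per-sample triplicate absorbances for one plate."""

    standards: tuple            # ((concentration ug/mL, absorbance AU), ...)
    samples: dict               # sample_id -> (A1, A2, A3)
    assay: str = "DMMB_525nm"   # or "picogreen"

    def __post_init__(self):
        if len(self.standards) < 3:
            raise InvalidInputError("need >= 3 standards")
        concs = [c for c, _ in self.standards]
        if len(set(concs)) < 3:
            raise InvalidInputError("need >= 3 distinct standard concentrations")


@dataclass(frozen=True)
class StandardCurve:
    slope: float           # AU per (ug/mL)
    intercept: float       # AU
    r_squared: float
    conc_range: tuple      # (min, max) of the standards, ug/mL

    def predict_concentration(self, absorbance, flag_out_of_range: bool = True):
        """Inverse prediction; values outside the standard range are flagged.

        Returns ``(concentration, in_range)`` arrays.
        """
        a = np.asarray(absorbance, dtype=float)
        conc = (a - self.intercept) / self.slope
        in_range = (conc >= self.conc_range[0] - 1e-12) & (conc <= self.conc_range[1] + 1e-12)
        if flag_out_of_range and not np.all(in_range):
            import warnings

            warnings.warn("sample absorbance outside the standard range", stacklevel=2)
        return conc, in_range


def fit_standard_curve(standards) -> StandardCurve:
    """Ordinary least squares absorbance ~ concentration (fitted intercept).

    The intercept is estimated rather than forced through zero because DMMB
    baselines are nonzero.
    """
    arr = np.asarray(standards, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise InvalidInputError("standards must be >= 3 (concentration, absorbance) pairs")
    conc, absb = arr[:, 0], arr[:, 1]
    if np.unique(conc).size < 3:
        raise InvalidInputError("need >= 3 distinct standard concentrations")
    design = np.column_stack([conc, np.ones_like(conc)])
    coef, *_ = np.linalg.lstsq(design, absb, rcond=None)
    slope, intercept = float(coef[0]), float(coef[1])
    if slope == 0.0:
        raise InvalidInputError("degenerate standards: zero slope")
    fitted = design @ coef
    ss_res = float(np.sum((absb - fitted) ** 2))
    ss_tot = float(np.sum((absb - absb.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return StandardCurve(slope=slope, intercept=intercept, r_squared=r2,
                         conc_range=(float(conc.min()), float(conc.max())))


def _triplicate_mean(values) -> float:
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise InvalidInputError("no finite triplicate absorbances")
    return float(vals.mean())


def quantify_sgag(
    plate: PlateData,
    dry_mass_mg: dict,
    dna_plate: PlateData | None = None,
    digest_volume_mL: float = 0.2,
) -> pd.DataFrame:
    """Per-sample sGAG mass fraction (ug/mg) and, when DNA is measured,
    sGAG/DNA mass ratio (ug/ug).

    Triplicates are averaged first; concentration (ug/mL) from the standard
    curve times the digest volume gives the total mass in the digest.
    """
    curve = fit_standard_curve(plate.standards)
    dna_curve = fit_standard_curve(dna_plate.standards) if dna_plate else None
    rows = []
    for sample_id, triplicate in plate.samples.items():
        if sample_id not in dry_mass_mg:
            raise InvalidInputError(f"missing dry mass for sample {sample_id!r}")
        mass = float(dry_mass_mg[sample_id])
        if mass <= 0.0:
            raise InvalidInputError(f"non-positive dry mass for {sample_id!r}")
        mean_abs = _triplicate_mean(triplicate)
        conc, in_range = curve.predict_concentration(mean_abs, flag_out_of_range=False)
        total_ug = float(conc) * digest_volume_mL
        row = {
            "sample_id": sample_id,
            "sgag_concentration_ug_mL": float(conc),
            "sgag_total_ug": total_ug,
            "sgag_mass_fraction_ug_mg": total_ug / mass,
            "in_standard_range": bool(in_range),
        }
        if dna_curve is not None and sample_id in dna_plate.samples:
            dna_abs = _triplicate_mean(dna_plate.samples[sample_id])
            dna_conc, _ = dna_curve.predict_concentration(dna_abs, flag_out_of_range=False)
            dna_total = float(dna_conc) * digest_volume_mL
            row["dna_total_ug"] = dna_total
            row["sgag_per_dna_ug_ug"] = total_ug / dna_total if dna_total > 0 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SlideImageSet:
    """Three stitched 12-bit sections of one slide plus scleral masks."""

    chac: np.ndarray
    chb: np.ndarray
    buffer_only: np.ndarray
    mask_chac: np.ndarray
    mask_chb: np.ndarray
    mask_buffer: np.ndarray
    slide_id: str = ""

    def __post_init__(self):
        for name in ("chac", "chb", "buffer_only"):
            img = np.asarray(getattr(self, name))
            mask = np.asarray(getattr(self, f"mask_{'buffer' if name == 'buffer_only' else name}"))
            if img.shape != mask.shape:
                raise InvalidInputError(f"{name}: image and mask shapes differ")
            if not mask.any():
                raise InvalidInputError(f"{name}: empty scleral mask")


def ihc_normalized_intensity(slide: SlideImageSet, threshold: float | None = None) -> dict:
    """Buffer-normalised mean scleral intensity of the treated sections.

    ``ratio = mean(masked treated) / mean(masked buffer-only)``; a ratio of 1
    means no specific signal above the control.  Averaging is over all pixels
    within the mask; an optional intensity threshold (applied to all three
    sections identically) is off by default.
    """

    def masked_mean(img, mask) -> float:
        vals = np.asarray(img, dtype=float)[np.asarray(mask, dtype=bool)]
        if threshold is not None:
            vals = vals[vals >= threshold]
        if vals.size == 0:
            raise InvalidInputError("mask (after thresholding) selects no pixels")
        return float(vals.mean())

    control = masked_mean(slide.buffer_only, slide.mask_buffer)
    if control == 0.0:
        raise InvalidInputError(
            f"zero-mean buffer-only control on slide {slide.slide_id!r}: "
            "cannot normalise"
        )
    return {
        "slide_id": slide.slide_id,
        "chac_ratio": masked_mean(slide.chac, slide.mask_chac) / control,
        "chb_ratio": masked_mean(slide.chb, slide.mask_chb) / control,
        "control_mean": control,
    }
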