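"""Ocular biometry from OCT optical path lengths.

SD-OCT reports optical path lengths; dividing by an average tissue
refractive index of 1.39 converts them to physical distances.  Interfaces
are marked front-to-back (anterior cornea, posterior cornea, anterior lens,
posterior lens, inner retina, RPE), 0-referenced at the anterior corneal
surface, and the derived quantities are central corneal thickness (CCT),
anterior chamber depth (ACD), lens thickness (LT), vitreous chamber depth
(VCD), retinal thickness (RT) and axial length (AL = anterior cornea to
RPE).  Under this segmentation CCT+ACD+LT+VCD+RT = AL exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError, SegmentationError

__all__ = [
    "DEFAULT_REFRACTIVE_INDEX",
    "INTERFACE_NAMES",
    "InterfaceSet",
    "optical_to_physical",
    "derive_biometry",
    "biometry_table",
]

DEFAULT_REFRACTIVE_INDEX = 1.39

INTERFACE_NAMES = (
    "cornea_anterior",
    "cornea_posterior",
    "lens_anterior",
    "lens_posterior",
    "retina_inner",
    "rpe",
)

#: derived quantity -> (front interface, back interface)
_SEGMENTS = {
    "CCT": ("cornea_anterior", "cornea_posterior"),
    "ACD": ("cornea_posterior", "lens_anterior"),
    "LT": ("lens_anterior", "lens_posterior"),
    "VCD": ("lens_posterior", "retina_inner"),
    "RT": ("retina_inner", "rpe"),
    "AL": ("cornea_anterior", "rpe"),
}


def optical_to_physical(length_optical_um, refractive_index: float = DEFAULT_REFRACTIVE_INDEX):
    """Physical distance (um) = optical path length (um) / refractive index."""
    if refractive_index < 1.0:
        raise InvalidInputError(
            f"refractive index must be >= 1, got {refractive_index!r}"
        )
    return np.asarray(length_optical_um, dtype=float) / refractive_index


@dataclass(frozen=True)
class InterfaceSet:
    """Axial interface positions (optical um) for one eye, front-to-back."""

    positions: dict
    refractive_index: float = DEFAULT_REFRACTIVE_INDEX
    eye_id: str = ""

    def __post_init__(self):
        missing = [n for n in INTERFACE_NAMES if n not in self.positions]
        if missing:
            raise InvalidInputError(f"missing interfaces: {missing}")
        if self.refractive_index < 1.0:
            raise InvalidInputError("refractive index must be >= 1")
        vals = [float(self.positions[n]) for n in INTERFACE_NAMES]
        for (na, va), (nb, vb) in zip(
            zip(INTERFACE_NAMES, vals), zip(INTERFACE_NAMES[1:], vals[1:])
        ):
            if vb <= va:
                raise SegmentationError(
                    f"interfaces not strictly increasing: {na}={va} >= {nb}={vb}"
                )

    def ordered(self) -> np.ndarray:
        return np.array([float(self.positions[n]) for n in INTERFACE_NAMES])


def derive_biometry(interfaces: InterfaceSet) -> dict:
    """Physical biometric record (um): CCT, ACD, LT, VCD, RT, AL."""
    n = interfaces.refractive_index
    pos = {name: float(interfaces.positions[name]) for name in INTERFACE_NAMES}
    out = {}
    for quantity, (front, back) in _SEGMENTS.items():
        out[quantity] = float(optical_to_physical(pos[back] - pos[front], n))
    return out


def biometry_table(interface_rows: pd.DataFrame,
                   drop_opacity: bool = True) -> pd.DataFrame:
    """Derive biometry for a table of interface positions (one row per eye).

    Expects columns ``eye_id``, the six interface names (optical um),
    ``refractive_index`` (optional) and ``opacity`` (optional flag).  Eyes
    flagged ``opacity`` are excluded before analysis, mirroring the in vivo
    exclusion rule for significant corneal/lens opacities.
    """
    df = interface_rows.copy()
    if drop_opacity and "opacity" in df:
        df = df[~df["opacity"].astype(bool)]
    records = []
    for _, row in df.iterrows():
        iface = InterfaceSet(
            positions={n: row[n] for n in INTERFACE_NAMES},
            refractive_index=float(row.get("refractive_index", DEFAULT_REFRACTIVE_INDEX)),
            eye_id=str(row.get("eye_id", "")),
        )
        rec = derive_biometry(iface)
        rec["eye_id"] = iface.eye_id
        records.append(rec)
    return pd.DataFrame(records)
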