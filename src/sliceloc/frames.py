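"""Coordinate conventions, plane parameterization and anteroposterior routing.

Atlas frame semantics are fixed: x runs left-to-right, y dorsal-to-ventral,
z anterior-to-posterior.  A section plane is parameterized by its
anteroposterior (AP) position ``d_um`` at an in-plane anchor point and two
tilt angles: ``alpha`` (mediolateral, rotation about the dorsoventral axis)
and ``beta`` (dorsoventral, rotation about the left-right axis).

Reference-atlas plate numbers (1..132, spaced 100 um) double as continuous
AP labels; the conversion functions here fix the origin at plate 1 -> 0 um.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

#: Spacing between consecutive reference-atlas coronal plates, micrometers.
ARA_SPACING_UM = 100.0
#: Valid reference-atlas plate range (continuous labels allowed in between).
ARA_MIN, ARA_MAX = 1.0, 132.0
#: Anteroposterior extent spanned by the plate series, micrometers.
ARA_EXTENT_UM = (ARA_MAX - ARA_MIN) * ARA_SPACING_UM


class GroupLabel(enum.Enum):
    """AP group of a section, routing it to a pipeline branch.

    A: most anterior plates (olfactory bulb; segmented directly).
    B / Bprime: anterior / posterior mono-component ranges (quadrant split).
    C: posterior plates prone to detachment into cerebra + brainstem.
    """

    A = "A"
    B = "B"
    BPRIME = "Bprime"
    C = "C"


# Plate ranges (inclusive) for each group.
GROUP_RANGES: dict[GroupLabel, tuple[int, int]] = {
    GroupLabel.A: (1, 22),
    GroupLabel.B: (23, 83),
    GroupLabel.C: (84, 103),
    GroupLabel.BPRIME: (104, 132),
}


@dataclass(frozen=True)
class BrainFrame:
    """Physical frame of a labeled volume.

    Axis semantics are immutable: axis 0 = x (left->right), axis 1 = y
    (dorsal->ventral), axis 2 = z (anterior->posterior).
    """

    voxel_size_um: tuple[float, float, float]
    shape_vox: tuple[int, int, int]
    origin_um: tuple[float, float, float] = (0.0, 0.0, 0.0)

    AXIS_SEMANTICS = ("left->right", "dorsal->ventral", "anterior->posterior")

    def __post_init__(self) -> None:
        if len(self.voxel_size_um) != 3 or any(v <= 0 for v in self.voxel_size_um):
            raise ValueError(f"voxel sizes must be 3 positive reals, got {self.voxel_size_um}")
        if len(self.shape_vox) != 3 or any(int(s) <= 0 for s in self.shape_vox):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape_vox}")
        object.__setattr__(self, "voxel_size_um", tuple(float(v) for v in self.voxel_size_um))
        object.__setattr__(self, "shape_vox", tuple(int(s) for s in self.shape_vox))
        object.__setattr__(self, "origin_um", tuple(float(v) for v in self.origin_um))

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical span covered by voxel centers on each axis."""
        return tuple(
            (n - 1) * v for n, v in zip(self.shape_vox, self.voxel_size_um)
        )

    def center_um(self) -> tuple[float, float, float]:
        """Physical coordinates of the volume center."""
        return tuple(o + e / 2 for o, e in zip(self.origin_um, self.extent_um))

    def ap_range_um(self) -> tuple[float, float]:
        """Min and max AP (z) coordinate covered by voxel centers."""
        return self.origin_um[2], self.origin_um[2] + self.extent_um[2]


@dataclass(frozen=True)
class PlaneParams:
    """Oblique slicing-plane coordinates in the atlas frame.

    ``d_um`` is the AP (z) coordinate of the plane at the in-plane anchor
    point ``center_xy_um``; positive ``alpha_deg`` tips the right hemisphere
    (larger x) posterior, positive ``beta_deg`` tips the ventral side
    (larger y) posterior.
    """

    alpha_deg: float
    beta_deg: float
    d_um: float
    center_xy_um: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not (abs(self.alpha_deg) < 90 and abs(self.beta_deg) < 90):
            raise ValueError(
                f"angles must satisfy |alpha|,|beta| < 90 deg, got "
                f"alpha={self.alpha_deg}, beta={self.beta_deg}"
            )
        object.__setattr__(self, "center_xy_um", tuple(float(c) for c in self.center_xy_um))


def ara_section_to_ap(section_number: float | np.ndarray) -> float | np.ndarray:
    """Convert a (possibly fractional) plate number to AP micrometers.

    Plate 1 anchors the origin (0 um); consecutive plates are 100 um apart.
    """
    s = np.asarray(section_number, dtype=float)
    if np.any(s < ARA_MIN) or np.any(s > ARA_MAX):
        raise ValueError(
            f"section number must lie in [{ARA_MIN:g}, {ARA_MAX:g}], got {section_number}"
        )
    out = (s - ARA_MIN) * ARA_SPACING_UM
    return float(out) if np.isscalar(section_number) or out.ndim == 0 else out


def ap_to_ara_section(ap_um: float | np.ndarray) -> float | np.ndarray:
    """Exact inverse of :func:`ara_section_to_ap` on [0, 13100] um."""
    z = np.asarray(ap_um, dtype=float)
    if np.any(z < 0) or np.any(z > ARA_EXTENT_UM):
        raise ValueError(f"AP position must lie in [0, {ARA_EXTENT_UM:g}] um, got {ap_um}")
    out = z / ARA_SPACING_UM + ARA_MIN
    return float(out) if np.isscalar(ap_um) or out.ndim == 0 else out


def group_of_section(section_number: float) -> GroupLabel:
    """Map a plate number to its AP group (fractional values round half-up)."""
    s = float(section_number)
    if not (ARA_MIN <= s <= ARA_MAX):
        raise ValueError(f"section number must lie in [{ARA_MIN:g}, {ARA_MAX:g}], got {s}")
    n = int(math.floor(s + 0.5))
    n = min(max(n, 1), 132)
    for group, (lo, hi) in GROUP_RANGES.items():
        if lo <= n <= hi:
            return group
    raise AssertionError("group ranges must partition 1..132")  # pragma: no cover


def plane_geometry(
    plane: PlaneParams, frame: BrainFrame | None = None
) -> Callable[[np.ndarray, np.ndarray], np.ndarray]:
    """Return the plane's height function z(x, y) in micrometers.

    z(x, y) = d + tan(alpha) * (x - x_c) + tan(beta) * (y - y_c), so the AP
    value at the anchor point equals ``d_um`` exactly.  When ``frame`` is
    given, ``d_um`` is validated against the volume's AP extent.
    """
    if frame is not None:
        lo, hi = frame.ap_range_um()
        if not (lo <= plane.d_um <= hi):
            raise ValueError(
                f"plane d={plane.d_um:g} um outside the volume AP extent [{lo:g}, {hi:g}]"
            )
    ta = math.tan(math.radians(plane.alpha_deg))
    tb = math.tan(math.radians(plane.beta_deg))
    xc, yc = plane.center_xy_um

    def z_of_xy(x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return plane.d_um + ta * (np.asarray(x, float) - xc) + tb * (np.asarray(y, float) - yc)

    return z_of_xy


def quadrant_centers_um(
    bbox_xy_um: Sequence[float],
) -> dict[int, tuple[float, float]]:
    """Centers of the 4 equal quadrants of a physical (x, y) bounding box.

    Quadrant numbering: Q1 dorsal-left, Q2 dorsal-right, Q3 ventral-left,
    Q4 ventral-right (y grows ventral, x grows rightward).
    """
    x0, x1, y0, y1 = (float(v) for v in bbox_xy_um)
    xm, ym = (x0 + x1) / 2, (y0 + y1) / 2
    xl, xr = (x0 + xm) / 2, (xm + x1) / 2
    yd, yv = (y0 + ym) / 2, (ym + y1) / 2
    return {1: (xl, yd), 2: (xr, yd), 3: (xl, yv), 4: (xr, yv)}
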