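"""Coronal Cobb angle and sagittal T4–T12 kyphosis from endplate planes.

Both angles follow the classical radiographic construction: each fitted 3D
endplate plane is projected onto the relevant anatomical view (coronal x–z
for Cobb, sagittal y–z for kyphosis) and the angle between the two
projected endplate trace lines is reported, unsigned, in degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import LabelledVolume, Plane3D
from .geometry import endplate_plane

__all__ = ["CurveAngles", "cobb_angle", "kyphosis_angle", "measure_curve"]


@dataclass(frozen=True)
class CurveAngles:
    """Per-position curve angles, degrees, unsigned."""

    cobb_deg: float
    kyphosis_deg: float


def _projected_line_angle(upper: Plane3D, lower: Plane3D, drop_axis: int) -> float:
    """Angle between the two planes' trace lines in a world projection.

    ``drop_axis`` is the world axis orthogonal to the view (1 = anterior
    for the coronal view, 0 = lateral for the sagittal view).  The trace
    line of a plane in the view is perpendicular to the projection of its
    normal, so the angle between traces equals the angle between the
    projected normals, folded to [0°, 90°].
    """
    keep = [ax for ax in range(3) if ax != drop_axis]
    angles = []
    for plane in (upper, lower):
        v = plane.normal[keep]
        nv = np.linalg.norm(v)
        if nv < 1e-8:
            raise ValueError(
                "endplate normal is orthogonal to the view plane — "
                "projected trace line is degenerate"
            )
        angles.append(v / nv)
    cosang = float(np.clip(abs(angles[0] @ angles[1]), 0.0, 1.0))
    return math.degrees(math.acos(cosang))


def cobb_angle(upper_endplate: Plane3D, lower_endplate: Plane3D) -> float:
    """Coronal Cobb angle between two endplate planes, degrees.

    Standard Cobb method on the coronal projection: the angle between the
    projected trace lines of the superior endplate of the upper end
    vertebra and the inferior endplate of the lower end vertebra.
    Symmetric in its arguments.
    """
    return _projected_line_angle(upper_endplate, lower_endplate, drop_axis=1)


def kyphosis_angle(t4_superior: Plane3D, t12_inferior: Plane3D) -> float:
    """Sagittal kyphosis angle (T4 superior vs T12 inferior endplate)."""
    return _projected_line_angle(t4_superior, t12_inferior, drop_axis=0)


def measure_curve(
    vol: LabelledVolume,
    upper_level: str,
    lower_level: str,
) -> CurveAngles:
    """Fit the end-vertebra endplates of a volume and measure both angles.

    ``upper_level`` / ``lower_level`` are the vertebral-body names of the
    designated end vertebrae (a manifest input, as in clinical practice).
    The kyphosis convention (upper superior vs lower inferior endplate)
    assumes the measured segment spans T4–T12.
    """
    upper = endplate_plane(vol, f"VB_{upper_level}", "superior")
    lower = endplate_plane(vol, f"VB_{lower_level}", "inferior")
    return CurveAngles(
        cobb_deg=cobb_angle(upper, lower),
        kyphosis_deg=kyphosis_angle(upper, lower),
    )
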