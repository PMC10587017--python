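"""Vertebral axial rotation from endplate-true axial sections.

Each endplate's anterior–posterior (AP) axis is the line from the spinal
canal's centre of volume to the vertebral body's centre of volume in the
endplate's true axial section (the canal lies posterior to the body, so
the axis points anterior).  Axial rotation of an endplate is the angle
between its AP axis and the AP axis of the lower endplate of the first
distal neutrally rotated vertebra, measured after projecting both axes
into the reference endplate's axial plane.  Rotations are reported as
unsigned magnitudes with a sign flag that is positive when the anterior
body has rotated toward the curve convexity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import math
import numpy as np
import pandas as pd

from .core import AxialSection, LabelledVolume, Plane3D
from .geometry import endplate_plane, resample_true_axial

__all__ = ["APAxis", "RotationProfile", "derive_ap_axis", "axial_rotation",
           "rotation_profile"]


@dataclass(eq=False)
class APAxis:
    """Anterior–posterior axis of one axial section.

    ``origin`` and ``direction`` are in the section's 2D in-plane
    coordinates (mm); ``direction`` is unit length and points anterior.
    ``provenance`` records how the axis was constructed, including the QA
    extreme points (most anterior / most posterior body voxels along the
    axis), which are logged but not used for the primary axis.
    """

    origin: np.ndarray
    direction: np.ndarray
    section: AxialSection
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(2)
        d = np.asarray(self.direction, dtype=float).reshape(2)
        n = np.linalg.norm(d)
        if n < 1e-12:
            raise ValueError("AP axis direction is degenerate")
        self.direction = d / n

    @property
    def direction_world(self) -> np.ndarray:
        """The axis direction as a 3D world unit vector."""
        return self.direction @ self.section.basis

    @property
    def origin_world(self) -> np.ndarray:
        return self.section.origin + self.origin @ self.section.basis


def derive_ap_axis(
    section: AxialSection,
    body_label: str,
    canal_label: str = "CANAL",
) -> APAxis:
    """Derive the AP axis of an axial section: canal CoV → body CoV.

    The two-CoV line is used as the primary construction because extreme
    boundary points are noise-sensitive on voxel masks; the most anterior
    and most posterior body points along the derived axis are still
    computed and stored in ``provenance`` for QA.

    Raises
    ------
    ValueError
        If either mask is empty in the section, or the two CoVs coincide
        (degenerate section).
    """
    body = section.centroid(body_label)
    canal = section.centroid(canal_label)
    d = body - canal
    if np.linalg.norm(d) < 1e-6:
        raise ValueError(
            "body and canal centres of volume coincide — degenerate section"
        )
    axis = APAxis(origin=body, direction=d, section=section)
    proj = section.coords[body_label] @ axis.direction
    pts = section.coords[body_label]
    axis.provenance.update(
        construction="canal-CoV to body-CoV",
        body_label=body_label,
        canal_label=canal_label,
        most_anterior=pts[int(np.argmax(proj))].tolist(),
        most_posterior=pts[int(np.argmin(proj))].tolist(),
    )
    return axis


def axial_rotation(
    axis: APAxis,
    reference: APAxis,
    convexity: str = "left",
    method: str = "transport",
) -> tuple[float, float]:
    """Axial rotation of ``axis`` relative to ``reference``, degrees.

    The test axis is brought into the reference endplate's axial plane
    (the shared plane of comparison) and the angle to the reference AP
    axis is measured there.  Two ways of bringing it into the plane are
    provided:

    ``"transport"`` (default)
        Rotate the test axis by the minimal (geodesic) rotation that
        aligns its own section plane with the reference plane.  This
        compensates the coronal/sagittal tilt between the two endplates
        and preserves in-plane angles.
    ``"projection"``
        Orthogonally project the test axis into the reference plane.
        Simpler, but for endplates tilted by ``τ`` relative to the
        reference it compresses a rotation ``ρ`` by up to
        ``(1 − cos τ)·ρ`` (≈ 1–2° at clinically typical magnitudes),
        which is why it is not the default.

    Returns
    -------
    (magnitude, signed)
        ``magnitude`` is the unsigned angle in [0°, 180°); ``signed`` is
        positive when the anterior body has rotated toward the curve
        convexity (``'left'`` = world +x).

    Raises
    ------
    ValueError
        If the test axis (projection) or section plane (transport) is
        (near-)perpendicular to the reference plane.
    """
    if convexity not in ("left", "right"):
        raise ValueError("convexity must be 'left' or 'right'")
    n = reference.section.normal
    d = axis.direction_world
    if method == "transport":
        n_t = axis.section.normal
        c = float(n_t @ n)
        if c < 1e-6:
            raise ValueError(
                "section planes are (near-)perpendicular — cannot transport"
            )
        rot_axis = np.cross(n_t, n)
        s = np.linalg.norm(rot_axis)
        if s > 1e-12:
            k = rot_axis / s
            ang = math.atan2(s, c)
            d = (d * math.cos(ang) + np.cross(k, d) * math.sin(ang)
                 + k * (k @ d) * (1 - math.cos(ang)))
        proj = d - (d @ n) * n   # numerical cleanup; d is already in-plane
    elif method == "projection":
        proj = d - (d @ n) * n
    else:
        raise ValueError("method must be 'transport' or 'projection'")
    if np.linalg.norm(proj) < 1e-6:
        raise ValueError(
            "AP axis is perpendicular to the reference axial plane — "
            "projection is degenerate"
        )
    proj = proj / np.linalg.norm(proj)
    ref = reference.direction_world
    signed_ccw = math.degrees(
        math.atan2(float(np.cross(ref, proj) @ n), float(ref @ proj))
    )
    sign_to_convex = -1.0 if convexity == "left" else 1.0
    signed = sign_to_convex * signed_ccw
    return abs(signed), signed


def _endplate_section(
    vol: LabelledVolume,
    body_label: str,
    side: str,
    canal_label: str,
    inset_vox: float = 1.5,
) -> AxialSection:
    """True axial section at an endplate, sampled just inside the body.

    The section plane is the fitted endplate plane shifted ``inset_vox``
    voxels into the vertebral body along its normal.  Sampling the slab at
    the exact endplate surface would intersect the voxel staircase of the
    surface and yield a partial (crescent-shaped) body cross-section whose
    centroid is laterally biased; a slab fully interior to the body cuts a
    complete elliptical cross-section, and the axial rotation is constant
    through the rigid body.
    """
    plane = endplate_plane(vol, body_label, side)
    inward = -1.0 if side == "superior" else 1.0  # normals point cranially
    shift = inset_vox * float(np.mean(vol.spacing))
    inner = Plane3D(plane.centre + inward * shift * plane.normal,
                    plane.normal)
    return resample_true_axial(vol, inner, [body_label, canal_label])


@dataclass(eq=False)
class RotationProfile:
    """Per-endplate and per-vertebra axial rotation against the neutral
    reference, plus the apical and peri-apical summaries.

    ``per_endplate`` has one row per measured endplate (columns: level,
    endplate, rotation_deg, signed_deg, provenance fields); per-vertebra
    rotation is the mean of a vertebra's two endplate rotations.  The
    peri-apical mean covers exactly the apical vertebra plus the two
    vertebrae above and the two below.
    """

    per_endplate: pd.DataFrame
    per_vertebra: dict[str, float]          #: level → unsigned degrees
    per_vertebra_signed: dict[str, float]
    apical_rotation: float
    periapical_mean: float
    apex_level: str
    neutral_level: str


def rotation_profile(
    vol: LabelledVolume,
    levels: list[str],
    apex_index: int,
    neutral_index: int,
    convexity: str = "left",
    canal_label: str = "CANAL",
) -> RotationProfile:
    """Measure the axial-rotation profile of a labelled spine volume.

    ``levels`` are vertebra names ordered caudal to cranial; rotation is
    measured for the apical vertebra, the two above, the two below, and
    the neutral reference vertebra, each endplate against the AP axis of
    the neutral vertebra's lower endplate.

    Raises
    ------
    ValueError
        If the apex is too close to the span ends for a peri-apical
        window, or any required body label is missing (listing them).
    """
    if not (2 <= apex_index <= len(levels) - 3):
        raise ValueError(
            "apex must lie strictly inside the measured span with two "
            "vertebrae above and two below"
        )
    if not (0 <= neutral_index < len(levels)):
        raise ValueError("neutral_index outside the measured span")
    measured = sorted(set(range(apex_index - 2, apex_index + 3))
                      | {neutral_index})
    missing = [f"VB_{levels[i]}" for i in measured
               if f"VB_{levels[i]}" not in vol.label_map]
    if canal_label not in vol.label_map:
        missing.append(canal_label)
    if missing:
        raise ValueError(f"missing labels required for rotation: {missing}")

    neutral = levels[neutral_index]
    ref_section = _endplate_section(vol, f"VB_{neutral}", "inferior",
                                    canal_label)
    ref_axis = derive_ap_axis(ref_section, f"VB_{neutral}", canal_label)

    rows = []
    signed_by_level: dict[str, list[float]] = {}
    for i in measured:
        level = levels[i]
        body = f"VB_{level}"
        for side in ("inferior", "superior"):
            if i == neutral_index and side == "inferior":
                axis = ref_axis
                mag, signed = 0.0, 0.0   # self-reference is exactly zero
            else:
                section = _endplate_section(vol, body, side, canal_label)
                axis = derive_ap_axis(section, body, canal_label)
                mag, signed = axial_rotation(axis, ref_axis, convexity)
            rows.append({
                "level": level,
                "endplate": side,
                "rotation_deg": mag,
                "signed_deg": signed,
                **{f"qa_{k}": v for k, v in axis.provenance.items()
                   if k in ("most_anterior", "most_posterior")},
            })
            signed_by_level.setdefault(level, []).append(signed)

    per_signed = {lv: float(np.mean(v)) for lv, v in signed_by_level.items()}
    per_mag = {lv: abs(v) for lv, v in per_signed.items()}
    apex_level = levels[apex_index]
    peri = [levels[i] for i in range(apex_index - 2, apex_index + 3)]
    return RotationProfile(
        per_endplate=pd.DataFrame(rows),
        per_vertebra=per_mag,
        per_vertebra_signed=per_signed,
        apical_rotation=per_mag[apex_level],
        periapical_mean=float(np.mean([per_mag[lv] for lv in peri])),
        apex_level=apex_level,
        neutral_level=neutral,
    )
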