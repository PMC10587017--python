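"""Disc and nucleus shape/position metrics.

Two families of measurements, per disc and per position:

* **CoV distance** ``d`` — the Euclidean distance between the centre of
  volume of the nucleus pulposus (NP) and the centre of volume of the
  whole intervertebral disc (IVD = annulus fibrosus ∪ NP), quantifying
  lateralisation of the nucleus within the disc.
* **Mid-coronal asymmetry** ``EC − XC`` — in the 1-voxel coronal slab
  through a structure's own CoV, the distance from the CoV to the
  concave-side lateral border (EC) minus the distance to the convex-side
  border (XC).  Zero for a shape mirror-symmetric about its CoV; positive
  when volume is shifted toward the convexity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import LabelledVolume
from .geometry import centre_of_volume

__all__ = ["DiscMetrics", "compose_ivd", "cov_distance",
           "midcoronal_asymmetry", "disc_report"]


@dataclass(frozen=True)
class DiscMetrics:
    """Metrics of one structure (IVD or NP) of one disc in one position."""

    disc_id: str
    structure: str            #: ``"IVD"`` or ``"NP"``
    d_mm: float               #: NP-CoV to IVD-CoV distance (same per disc)
    EC_mm: float
    XC_mm: float
    asymmetry_mm: float       #: EC − XC
    EC_lateral_mm: float      #: pure-lateral (x-component) variant
    XC_lateral_mm: float
    asymmetry_lateral_mm: float


def compose_ivd(np_mask: np.ndarray, af_mask: np.ndarray) -> np.ndarray:
    """Voxelwise union of nucleus and annulus masks: the total disc.

    Raises
    ------
    ValueError
        If the masks overlap (inconsistent segmentation) or differ in grid
        shape.
    """
    np_mask = np.asarray(np_mask, dtype=bool)
    af_mask = np.asarray(af_mask, dtype=bool)
    if np_mask.shape != af_mask.shape:
        raise ValueError("NP and AF masks are on different grids")
    if np.any(np_mask & af_mask):
        raise ValueError(
            "NP and AF masks overlap — inconsistent disc segmentation"
        )
    return np_mask | af_mask


def cov_distance(np_mask: np.ndarray, ivd_mask: np.ndarray,
                 affine: np.ndarray) -> float:
    """Euclidean distance between the NP and IVD centres of volume, mm."""
    return float(np.linalg.norm(
        centre_of_volume(np_mask, affine) - centre_of_volume(ivd_mask, affine)
    ))


def _extreme_voxel(pts: np.ndarray, cov: np.ndarray, side: str) -> np.ndarray:
    """Extreme-lateral point of a slab point set, deterministic tie-break.

    Among voxels sharing the extreme lateral (x) coordinate within a
    numerical hair, the one closest to the CoV's axial height (z) wins.
    """
    x = pts[:, 0]
    target = x.max() if side == "max" else x.min()
    tied = np.abs(x - target) < 1e-9
    cand = pts[tied]
    return cand[int(np.argmin(np.abs(cand[:, 2] - cov[2])))]


def midcoronal_asymmetry(
    mask: np.ndarray,
    affine: np.ndarray,
    convexity: str,
    cov: np.ndarray | None = None,
) -> tuple[float, float, float, dict]:
    """EC/XC lateral asymmetry of a structure in its mid-coronal plane.

    The mid-coronal plane is the 1-voxel coronal slab through the
    structure's own CoV.  The most-lateral member points on each side are
    found in the slab; EC is the distance from the concave-side extreme to
    the CoV and XC from the convex-side extreme.  Distances are full 3D
    Euclidean distances; the pure-lateral (x-component) variant is also
    returned in the extras dict.

    Parameters
    ----------
    convexity
        Which side of the curve is convex, ``'left'`` (world +x) or
        ``'right'``; determines which border is EC and which XC.

    Returns
    -------
    (EC_mm, XC_mm, asymmetry_mm, extras)
        ``asymmetry_mm = EC_mm - XC_mm``; ``extras`` carries the extreme
        points and the lateral-only variant.
    """
    if convexity not in ("left", "right"):
        raise ValueError("convexity side must be 'left' or 'right'")
    mask = np.asarray(mask, dtype=bool)
    affine = np.asarray(affine, dtype=float)
    if cov is None:
        cov = centre_of_volume(mask, affine)
    cov = np.asarray(cov, dtype=float).reshape(3)
    idx = np.argwhere(mask)
    if len(idx) == 0:
        raise ValueError("empty mask")
    pts = idx @ affine[:3, :3].T + affine[:3, 3]
    dy = float(np.linalg.norm(affine[:3, 1]))
    slab = np.abs(pts[:, 1] - cov[1]) <= 0.5 * dy
    if not np.any(slab):
        raise ValueError("mid-coronal slab through the CoV is empty")
    spts = pts[slab]
    left = _extreme_voxel(spts, cov, "max")     # +x = subject left
    right = _extreme_voxel(spts, cov, "min")
    convex_pt, concave_pt = (left, right) if convexity == "left" else (right, left)
    ec = float(np.linalg.norm(concave_pt - cov))
    xc = float(np.linalg.norm(convex_pt - cov))
    ec_lat = float(abs(concave_pt[0] - cov[0]))
    xc_lat = float(abs(convex_pt[0] - cov[0]))
    extras = {
        "concave_point": concave_pt,
        "convex_point": convex_pt,
        "EC_lateral_mm": ec_lat,
        "XC_lateral_mm": xc_lat,
        "asymmetry_lateral_mm": ec_lat - xc_lat,
    }
    return ec, xc, ec - xc, extras


def _disc_metrics(vol: LabelledVolume, disc: str,
                  convexity: str) -> list[DiscMetrics]:
    np_name, af_name = f"NP_{disc}", f"AF_{disc}"
    for name in (np_name, af_name):
        if name not in vol.label_map:
            raise ValueError(f"disc {disc!r}: missing label {name!r}")
    npm = vol.mask(np_name)
    ivd = compose_ivd(npm, vol.mask(af_name))
    d = cov_distance(npm, ivd, vol.affine)
    out = []
    for structure, m in (("IVD", ivd), ("NP", npm)):
        ec, xc, asym, extras = midcoronal_asymmetry(m, vol.affine, convexity)
        out.append(DiscMetrics(
            disc_id=disc, structure=structure, d_mm=d,
            EC_mm=ec, XC_mm=xc, asymmetry_mm=asym,
            EC_lateral_mm=extras["EC_lateral_mm"],
            XC_lateral_mm=extras["XC_lateral_mm"],
            asymmetry_lateral_mm=extras["asymmetry_lateral_mm"],
        ))
    return out


def disc_report(
    vol_pair: tuple[LabelledVolume, LabelledVolume],
    apical_levels: list[str],
    apical_disc: str,
    convexity: str,
) -> pd.DataFrame:
    """Per-disc, per-position disc metrics over the apical region.

    ``apical_levels`` lists the disc identifiers of the apical region (the
    apical disc and its two neighbours); ``vol_pair`` is the
    (neutral, extended) volume pair.  Returns a tidy table with one row
    per disc × position × structure, plus ``delta_*`` columns (extended
    minus neutral) on the neutral rows' ordering, and summary rows are
    left to the statistics stage.

    Raises
    ------
    ValueError
        If a requested disc is missing from either position (the error
        names the disc).
    """
    positions = dict(zip(("NSP", "ESP"), vol_pair))
    if apical_disc not in apical_levels:
        raise ValueError("apical_disc must be one of apical_levels")
    rows = []
    for disc in apical_levels:
        for pos, vol in positions.items():
            for name in (f"NP_{disc}", f"AF_{disc}"):
                if name not in vol.label_map:
                    raise ValueError(
                        f"disc {disc!r} missing in position {pos} "
                        f"(no label {name!r})"
                    )
            for m in _disc_metrics(vol, disc, convexity):
                rows.append({
                    "disc_id": disc,
                    "position": pos,
                    "structure": m.structure,
                    "apical": disc == apical_disc,
                    "d_mm": m.d_mm,
                    "EC_mm": m.EC_mm,
                    "XC_mm": m.XC_mm,
                    "asymmetry_mm": m.asymmetry_mm,
                    "asymmetry_lateral_mm": m.asymmetry_lateral_mm,
                })
    df = pd.DataFrame(rows)
    # per-disc deltas (ESP − NSP), aligned by disc and structure
    wide = df.pivot_table(index=["disc_id", "structure"], columns="position",
                          values=["d_mm", "asymmetry_mm"])
    for metric in ("d_mm", "asymmetry_mm"):
        delta = (wide[(metric, "ESP")] - wide[(metric, "NSP")]).rename(
            f"delta_{metric}")
        df = df.merge(delta.reset_index(), on=["disc_id", "structure"],
                      how="left")
    return df
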