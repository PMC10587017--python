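"""Geometric primitives: endplate-plane fitting, true-axial resampling,
centres of volume.

These are the building blocks of every measurement stage.  A vertebral
endplate is represented by a total-least-squares plane fitted to the
endplate voxel layer; a "true axial" section is the voxel slab
perpendicular to that plane, which is where anterior–posterior axes and
axial rotations are defined.
"""

from __future__ import annotations

import numpy as np

from .core import AxialSection, LabelledVolume, Plane3D

__all__ = [
    "fit_endplate_plane",
    "endplate_points",
    "endplate_plane",
    "resample_true_axial",
    "centre_of_volume",
]

_Z = np.array([0.0, 0.0, 1.0])
_Y = np.array([0.0, 1.0, 0.0])


def _orient_cranial(n: np.ndarray) -> np.ndarray:
    """Flip ``n`` so its z component is positive (y, then x, break ties)."""
    for c in (2, 1, 0):
        if abs(n[c]) > 1e-12:
            return n if n[c] > 0 else -n
    raise ValueError("zero normal")


def fit_endplate_plane(points: np.ndarray) -> Plane3D:
    """Fit a total-least-squares plane to a cloud of world-mm points.

    The plane centre is the point centroid; the normal is the direction of
    least variance, oriented cranially (positive z component, positive y on
    a tie).

    Raises
    ------
    ValueError
        If fewer than 3 points are given, the points are (near-)collinear,
        or the cloud is isotropic enough that the least-variance direction
        is ambiguous — both signal an unusable endplate segmentation.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise ValueError("plane fit needs at least 3 points of dimension 3")
    centre = pts.mean(axis=0)
    _, s, vt = np.linalg.svd(pts - centre, full_matrices=False)
    scale = max(s[0], 1e-12)
    if s[1] < 1e-8 * scale:
        raise ValueError("degenerate endplate: points are collinear")
    if (s[1] - s[2]) < 1e-6 * scale:
        raise ValueError(
            "degenerate endplate: least-variance direction is ambiguous "
            "(isotropic point cloud)"
        )
    return Plane3D(centre, _orient_cranial(vt[2]))


def _principal_axis_near_z(pts: np.ndarray) -> np.ndarray:
    """Principal (PCA) direction of ``pts`` closest to the cranial axis."""
    c = pts - pts.mean(axis=0)
    cov = c.T @ c / len(c)
    _, vecs = np.linalg.eigh(cov)
    k = int(np.argmax(np.abs(vecs.T @ _Z)))
    return _orient_cranial(vecs[:, k].copy())


def endplate_points(
    vol: LabelledVolume,
    label: str,
    side: str,
    n_iter: int = 4,
) -> np.ndarray:
    """World-mm points of the superior or inferior endplate surface of a body.

    The endplate surface is extracted as the extreme voxel of every grid
    column along the grid axis most parallel to the body's own axis (its
    principal direction closest to cranial), i.e. a one-voxel-thick height
    map of the cranial (or caudal) body surface.  Columns that terminate on
    the body's lateral wall rather than the endplate — which happens on the
    downhill side of tilted bodies — are removed by iterating a
    total-least-squares plane fit with one-sided trimming: points more than
    one voxel on the body side of the fitted plane are dropped and the
    plane refitted.
    """
    if side not in ("superior", "inferior"):
        raise ValueError("side must be 'superior' or 'inferior'")
    mask = vol.mask(label)
    idx = np.argwhere(mask)
    if len(idx) < 3:
        raise ValueError(f"label {label!r} has too few voxels for an endplate")
    pts_all = idx @ vol.affine[:3, :3].T + vol.affine[:3, 3]
    axis = _principal_axis_near_z(pts_all)

    # grid axis most parallel to the body axis, signed toward the surface
    cols = vol.affine[:3, :3] / np.linalg.norm(vol.affine[:3, :3], axis=0)
    ax = int(np.argmax(np.abs(cols.T @ axis)))
    o1, o2 = [d for d in range(3) if d != ax]
    up = np.sign(cols[:, ax] @ axis) > 0  # does +index step go cranial?
    want_max = up if side == "superior" else not up

    order = np.lexsort((idx[:, ax], idx[:, o2], idx[:, o1]))
    s = idx[order]
    boundary = np.any(np.diff(s[:, [o1, o2]], axis=0) != 0, axis=1)
    if want_max:
        take = np.append(boundary, True)        # last row of each column
    else:
        take = np.insert(boundary, 0, True)     # first row of each column
    surf = s[take]
    pts = surf @ vol.affine[:3, :3].T + vol.affine[:3, 3]

    # one-sided robust trim: wall points always lie on the body side
    spacing = float(np.mean(vol.spacing))
    inward = -1.0 if side == "superior" else 1.0  # normals are cranial
    keep = np.ones(len(pts), dtype=bool)
    for _ in range(max(1, n_iter)):
        plane = fit_endplate_plane(pts[keep])
        r = plane.signed_distance(pts)
        new_keep = inward * r <= 1.0 * spacing
        if new_keep.sum() < 8 or np.array_equal(new_keep, keep):
            break
        keep = new_keep
    return pts[keep]


def endplate_plane(vol: LabelledVolume, label: str, side: str) -> Plane3D:
    """Fitted plane of the named body's superior or inferior endplate."""
    return fit_endplate_plane(endplate_points(vol, label, side))


def _inplane_basis(normal: np.ndarray) -> np.ndarray:
    """Two orthonormal in-plane axes for a plane with unit ``normal``.

    The first axis is the projection of world x (falling back to world y
    when the normal is along x), so that for near-axial planes the 2D frame
    stays close to the world (left, anterior) axes.
    """
    ref = np.array([1.0, 0.0, 0.0])
    if abs(normal @ ref) > 0.9:
        ref = _Y
    e1 = ref - (ref @ normal) * normal
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    return np.vstack([e1, e2])


def resample_true_axial(
    vol: LabelledVolume,
    plane: Plane3D,
    labels: list[str] | tuple[str, ...],
    half_thickness: float | None = None,
) -> AxialSection:
    """Extract the true axial section of a volume at an endplate plane.

    Per requested label, collects the voxel centres lying within
    ``half_thickness`` (default: half the mean voxel size, i.e. exactly one
    voxel layer) of the plane and projects them into plane coordinates.

    Raises
    ------
    ValueError
        If the plane misses the volume entirely, or a requested label has
        no voxels in the slab (the error names the label).
    """
    spacing = float(np.mean(vol.spacing))
    if half_thickness is None:
        half_thickness = 0.5 * spacing

    # quick reject: plane must intersect the voxel bounding box
    shape = np.array(vol.data.shape, dtype=float)
    corners_idx = np.array(
        [[i, j, k] for i in (0, shape[0] - 1)
         for j in (0, shape[1] - 1) for k in (0, shape[2] - 1)]
    )
    corners = corners_idx @ vol.affine[:3, :3].T + vol.affine[:3, 3]
    d = plane.signed_distance(corners)
    if d.min() > half_thickness or d.max() < -half_thickness:
        raise ValueError("section plane lies outside the volume")

    basis = _inplane_basis(plane.normal)
    coords: dict[str, np.ndarray] = {}
    for name in labels:
        pts = vol.world_coords(vol.mask(name))
        if len(pts):
            keep = np.abs(plane.signed_distance(pts)) <= half_thickness
            pts = pts[keep]
        if len(pts) == 0:
            raise ValueError(
                f"label {name!r} does not intersect the section plane"
            )
        coords[name] = (pts - plane.centre) @ basis.T
    return AxialSection(
        origin=plane.centre,
        normal=plane.normal,
        basis=basis,
        coords=coords,
        spacing=spacing,
        half_thickness=half_thickness,
    )


def centre_of_volume(mask: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """Centre of volume (unweighted centroid) of a voxel mask, in world mm.

    ``mask`` is a 3D boolean array; ``affine`` maps voxel indices (voxel
    centres) to world mm.

    Raises
    ------
    ValueError
        If the mask is empty.
    """
    mask = np.asarray(mask, dtype=bool)
    idx = np.argwhere(mask)
    if len(idx) == 0:
        raise ValueError("centre of volume of an empty mask is undefined")
    affine = np.asarray(affine, dtype=float)
    return idx.mean(axis=0) @ affine[:3, :3].T + affine[:3, 3]
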