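"""Core data containers shared by all measurement stages.

The package works in a fixed right-handed world frame, in millimetres:

* ``+x`` — subject left
* ``+y`` — anterior
* ``+z`` — cranial

so the coronal plane is x–z and the sagittal plane is y–z.  The I/O layer
(:mod:`spinemorph.io_manifest`) reorients volumes into this frame on load;
every other module assumes it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Plane3D", "LabelledVolume", "AxialSection"]


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("cannot normalise a zero-length vector")
    return v / n


@dataclass(eq=False)
class Plane3D:
    """A plane in world coordinates: a centre point and a unit normal.

    Used for fitted vertebral endplates.  The normal is normalised on
    construction and, by package convention, oriented cranially
    (positive z component; positive y breaks the tie).
    """

    centre: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        self.centre = np.asarray(self.centre, dtype=float).reshape(3)
        self.normal = _unit(np.asarray(self.normal, dtype=float).reshape(3))

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Signed distance of ``points`` (N, 3) from the plane, in mm."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - self.centre) @ self.normal


@dataclass(eq=False)
class LabelledVolume:
    """A labelled voxel volume: integer labels, a name map and a mm affine.

    Parameters
    ----------
    data
        Integer voxel array, one label value per structure, 0 = background.
    label_map
        Mapping from structure name (e.g. ``"VB_T8"``, ``"CANAL"``,
        ``"NP_T8T9"``) to its integer label.
    affine
        4x4 voxel-to-world transform; voxel coordinates are voxel-centre
        based, world units are millimetres.
    """

    data: np.ndarray
    label_map: dict[str, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label volume must have an integer dtype")
        self.affine = np.asarray(self.affine, dtype=float).reshape(4, 4)
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")

    # -- basic queries ---------------------------------------------------
    @property
    def spacing(self) -> np.ndarray:
        """Voxel spacing along each voxel axis, in mm."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def label(self, name: str) -> int:
        try:
            return self.label_map[name]
        except KeyError:
            raise KeyError(
                f"label {name!r} not present in volume "
                f"(available: {sorted(self.label_map)})"
            ) from None

    def mask(self, name: str) -> np.ndarray:
        """Boolean mask of the named structure."""
        return self.data == self.label(name)

    def world_coords(self, mask: np.ndarray) -> np.ndarray:
        """World-mm coordinates (N, 3) of the voxel centres in ``mask``."""
        idx = np.argwhere(mask)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def validate(self) -> None:
        """Check the container invariants; raise ``ValueError`` on failure."""
        if self.data.min() < 0:
            raise ValueError("labels must be non-negative")
        present = set(np.unique(self.data).tolist())
        missing = [n for n, v in self.label_map.items() if v not in present]
        if missing:
            raise ValueError(
                f"structures with no voxels: {sorted(missing)}"
            )


@dataclass(eq=False)
class AxialSection:
    """A true axial (endplate-perpendicular) section through a volume.

    Holds, per requested label, the in-plane 2D coordinates (mm) of the
    voxel centres lying within half a slab thickness of the section plane,
    plus the plane frame needed to map 2D coordinates back to world mm.

    ``basis`` is a (2, 3) array whose rows are the two orthonormal in-plane
    axes; a 2D point ``q`` maps to world via ``origin + q @ basis``.
    """

    origin: np.ndarray
    normal: np.ndarray
    basis: np.ndarray
    coords: dict[str, np.ndarray]
    spacing: float
    half_thickness: float = field(default=0.5)

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.normal = _unit(self.normal)
        self.basis = np.asarray(self.basis, dtype=float).reshape(2, 3)
        g = self.basis @ self.basis.T
        if not np.allclose(g, np.eye(2), atol=1e-9):
            raise ValueError("in-plane basis is not orthonormal")
        if np.max(np.abs(self.basis @ self.normal)) > 1e-9:
            raise ValueError("in-plane basis is not orthogonal to the normal")

    def world_points(self, name: str) -> np.ndarray:
        """World-mm coordinates of the section voxels of ``name``."""
        return self.origin + self.coords[name] @ self.basis

    def centroid(self, name: str) -> np.ndarray:
        """In-plane centroid (2,) of the named mask, mm."""
        pts = self.coords[name]
        if pts.size == 0:
            raise ValueError(f"empty section mask for label {name!r}")
        return pts.mean(axis=0)
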