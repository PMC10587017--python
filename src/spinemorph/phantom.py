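"""Synthetic scoliotic-spine phantom with exact analytic ground truth.

The phantom stands in for patient imaging: it builds a labelled voxel
volume of a thoracic spine segment (vertebral bodies, spinal canal,
intervertebral discs split into annulus fibrosus and nucleus pulposus)
whose deformity — coronal Cobb angle, sagittal kyphosis, per-vertebra
axial rotation, apical disc wedge, and lateralised nucleus pulposus — is
prescribed exactly, so that every downstream measurement can be checked
against closed-form truth.

Geometry
--------
The centreline runs cranially along z.  Its coronal deflection is a single
cosine arch ``x(z) = A sin(pi z / H)`` whose amplitude is solved in closed
form so the end-vertebra endplate tilts produce exactly the requested Cobb
angle; the sagittal profile is a circular-arc-like curve whose tangent
angle varies linearly with height, scaled so the T4-superior / T12-inferior
endplate tilts produce exactly the requested kyphosis.  Each vertebral body
is a rigid elliptic cylinder whose endplates are normal to the local
centreline tangent, axially rotated by a cosine taper that peaks at the
apex and reaches exactly zero at both end vertebrae.  Discs fill the
inter-body gaps; the apical disc's coronal wedge is set to
``disc_wedge_deg`` by an extra coronal tilt of its two neighbouring
vertebrae, and its nucleus is displaced ``np_offset_mm`` toward the curve
convexity.

All ground truth (endplate frames, angles, rotations, CoV offsets, wedge
asymmetry) is computed from this constructive geometry *before*
voxelisation.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

from .core import LabelledVolume, Plane3D

__all__ = [
    "PhantomParams",
    "PhantomTruth",
    "EndplateTruth",
    "DiscTruth",
    "generate_phantom",
    "paired_phantom",
    "draw_cohort",
    "DEFORMITY_FIELDS",
]

_THORACOLUMBAR = [f"T{i}" for i in range(1, 13)] + [f"L{i}" for i in range(1, 6)]

#: Parameters that describe deformity magnitude (the quantities the
#: extension manoeuvre changes); only these may differ within a
#: neutral/extended phantom pair.
DEFORMITY_FIELDS = frozenset(
    {"cobb_deg", "kyphosis_deg", "max_axial_rotation_deg",
     "np_offset_mm", "disc_wedge_deg"}
)


@dataclass(frozen=True)
class PhantomParams:
    """Constructive parameters of the synthetic scoliotic spine.

    Defaults reproduce a neutral-supine thoracic curve of the magnitude the
    measurement suite is designed around: 45° coronal Cobb, 23° T4–T12
    kyphosis, 16° apical axial rotation, a 4 mm lateralised nucleus
    pulposus and an 8° apical disc wedge, on a T4–T12 (9-vertebra) segment
    at 1 mm isotropic voxels.

    ``obliquity_deg`` tilts the whole spine (about the world x then y axes)
    relative to the voxel grid, emulating the scanner-vs-anatomy obliquity
    of real acquisitions; without it the apical structures would be
    perfectly lattice-aligned, a degenerate configuration real data never
    shows, in which thin-slab voxelisation errors are coherent instead of
    averaging out.
    """

    n_vertebrae: int = 9
    cobb_deg: float = 45.0
    kyphosis_deg: float = 23.0
    apex_index: int = 4
    max_axial_rotation_deg: float = 16.0
    np_offset_mm: float = 4.0
    disc_wedge_deg: float = 8.0
    voxel_mm: float = 1.0
    body_radius_mm: float = 16.0
    body_height_mm: float = 20.0
    disc_height_mm: float = 5.0
    canal_radius_mm: float = 6.0
    canal_offset_mm: float = 21.0
    convexity: str = "left"
    caudal_level: str = "T12"
    obliquity_deg: tuple[float, float] = (3.0, 3.0)
    surface_jitter: float = 0.0
    seed: int = 0

    # derived, fixed shape ratios
    @property
    def body_ap_radius_mm(self) -> float:
        """Anterior–posterior semi-axis of the elliptic vertebral body."""
        return 0.75 * self.body_radius_mm

    @property
    def np_radii_mm(self) -> tuple[float, float]:
        return 0.45 * self.body_radius_mm, 0.45 * self.body_ap_radius_mm

    @property
    def np_height_mm(self) -> float:
        return 0.55 * self.disc_height_mm

    def validate(self) -> None:
        p = self
        for name in ("voxel_mm", "body_radius_mm", "body_height_mm",
                     "disc_height_mm", "canal_radius_mm", "canal_offset_mm"):
            if getattr(p, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if p.n_vertebrae < 3:
            raise ValueError("need at least 3 vertebrae")
        if not (0.0 <= p.max_axial_rotation_deg <= 45.0):
            raise ValueError("max_axial_rotation_deg must be in [0, 45]")
        if not (1 <= p.apex_index <= p.n_vertebrae - 2):
            raise ValueError(
                "apex_index must be strictly inside the measured span"
            )
        if p.convexity not in ("left", "right"):
            raise ValueError("convexity must be 'left' or 'right'")
        if not (0.0 <= p.cobb_deg < 120.0) or not (0.0 <= p.kyphosis_deg < 90.0):
            raise ValueError("implausible curve angles")
        if p.np_offset_mm < 0 or p.disc_wedge_deg < 0:
            raise ValueError("np_offset_mm and disc_wedge_deg must be >= 0")
        if not (0.0 <= p.surface_jitter <= 0.5):
            raise ValueError("surface_jitter is limited to 0.5 voxel")
        if max(abs(o) for o in p.obliquity_deg) > 10.0:
            raise ValueError("obliquity is limited to 10 degrees per axis")
        if p.caudal_level not in _THORACOLUMBAR:
            raise ValueError(f"unknown caudal level {p.caudal_level!r}")

    # -- level naming ----------------------------------------------------
    def level_names(self) -> list[str]:
        """Vertebra names, caudal to cranial (default T12 ... T4)."""
        i0 = _THORACOLUMBAR.index(self.caudal_level)
        idx = [i0 - k for k in range(self.n_vertebrae)]
        if min(idx) < 0:
            raise ValueError("segment extends above T1")
        return [_THORACOLUMBAR[i] for i in idx]


@dataclass(eq=False)
class EndplateTruth:
    """Analytic frame of one endplate: centre, normal, anterior axis."""

    centre: np.ndarray
    normal: np.ndarray
    ap_dir: np.ndarray

    def plane(self) -> Plane3D:
        return Plane3D(self.centre, self.normal)


@dataclass(eq=False)
class DiscTruth:
    """Analytic per-disc truth for the apical-region discs."""

    name: str
    has_np: bool
    d_mm: float                 #: NP-CoV to IVD-CoV distance
    ivd_asym_mm: float          #: true concave-minus-convex (EC-XC) of the IVD
    np_asym_mm: float
    wedge_deg: float            #: coronal wedge between bounding endplates
    ivd_cov: np.ndarray
    np_cov: np.ndarray | None


@dataclass(eq=False)
class PhantomTruth:
    """Ground truth computed from the constructive geometry (pre-voxel)."""

    params: PhantomParams
    level_names: list[str]
    endplates: dict[tuple[str, str], EndplateTruth]
    true_cobb_deg: float
    true_kyphosis_deg: float
    rotation_deg: dict[str, float]      #: unsigned injected axial rotation
    apex_level: str
    neutral_level: str
    convexity: str
    disc_names: list[str]               #: all discs, caudal to cranial
    np_disc_names: list[str]            #: apical-region discs carrying an NP
    apical_disc: str
    discs: dict[str, DiscTruth]

    @property
    def apical_rotation_deg(self) -> float:
        return self.rotation_deg[self.apex_level]

    @property
    def periapical_mean_deg(self) -> float:
        i = self.level_names.index(self.apex_level)
        peri = self.level_names[i - 2: i + 3]
        return float(np.mean([self.rotation_deg[lv] for lv in peri]))

    def to_json_dict(self) -> dict:
        """JSON-serialisable summary (for the phantom sidecar file)."""
        return {
            "level_names": self.level_names,
            "true_cobb_deg": self.true_cobb_deg,
            "true_kyphosis_deg": self.true_kyphosis_deg,
            "rotation_deg": self.rotation_deg,
            "apex_level": self.apex_level,
            "neutral_level": self.neutral_level,
            "convexity": self.convexity,
            "disc_names": self.disc_names,
            "np_disc_names": self.np_disc_names,
            "apical_disc": self.apical_disc,
            "discs": {
                n: {
                    "d_mm": t.d_mm,
                    "ivd_asym_mm": t.ivd_asym_mm,
                    "np_asym_mm": t.np_asym_mm,
                    "wedge_deg": t.wedge_deg,
                }
                for n, t in self.discs.items()
            },
            "params": dataclasses.asdict(self.params),
        }


# ---------------------------------------------------------------------------
# small vector helpers


def _unit(v):
    return v / np.linalg.norm(v)


def _rodrigues(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rotation matrix about a unit axis (right-handed)."""
    k = _unit(np.asarray(axis, dtype=float))
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return (
        math.cos(angle_rad) * np.eye(3)
        + math.sin(angle_rad) * kx
        + (1 - math.cos(angle_rad)) * np.outer(k, k)
    )


def _align_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal (geodesic) rotation matrix taking unit vector a onto b."""
    c = float(a @ b)
    k = np.cross(a, b)
    s = float(np.linalg.norm(k))
    if s < 1e-12:
        if c < 0:
            raise ValueError("antipodal vectors have no minimal rotation")
        return np.eye(3)
    return _rodrigues(k / s, math.atan2(s, c))


def _taper(i: int, apex: int, n: int) -> float:
    """Cosine rotation taper: 1 at the apex, exactly 0 at both ends."""
    if i == apex:
        return 1.0
    if i in (0, n - 1):
        return 0.0
    span = apex if i < apex else (n - 1 - apex)
    return math.cos(0.5 * math.pi * abs(i - apex) / span)


# ---------------------------------------------------------------------------
# constructive geometry


class _Geometry:
    """Analytic frames of every structure, pre-voxelisation."""

    def __init__(self, p: PhantomParams):
        p.validate()
        self.p = p
        n, bh, dh = p.n_vertebrae, p.body_height_mm, p.disc_height_mm
        self.H = n * bh + (n - 1) * dh
        self.zmid = bh / 2 + np.arange(n) * (bh + dh)
        self.s_cx = 1.0 if p.convexity == "left" else -1.0

        # coronal arch amplitude: end-vertebra tangent tilts sum to cobb_deg
        cobb = math.radians(p.cobb_deg)
        cend = math.cos(math.pi * self.zmid[0] / self.H)
        self.A = (
            self.s_cx * self.H * math.tan(cobb / 2) / (math.pi * cend)
            if p.cobb_deg > 0 else 0.0
        )
        # sagittal: tangent angle linear in z, spanning the mid-height range
        kyph = math.radians(p.kyphosis_deg)
        self.Kp = (
            kyph * self.H / (self.zmid[-1] - self.zmid[0])
            if p.kyphosis_deg > 0 else 0.0
        )
        # scanner-vs-anatomy obliquity: the whole spine is tilted relative
        # to the voxel grid about the segment's mid-point
        ox, oy = (math.radians(o) for o in p.obliquity_deg)
        self.R_obl = (_rodrigues(np.array([0.0, 1.0, 0.0]), oy)
                      @ _rodrigues(np.array([1.0, 0.0, 0.0]), ox))
        self.mid = np.array([0.0, 0.0, self.H / 2])
        self._build_frames()
        self._build_discs()

    def world_point(self, pt: np.ndarray) -> np.ndarray:
        """Map a point of the anatomical construction into the (oblique)
        voxel-grid world frame."""
        return self.R_obl @ (np.asarray(pt, dtype=float) - self.mid) + self.mid

    # centreline -----------------------------------------------------------
    def x(self, z):
        return self.A * np.sin(np.pi * z / self.H)

    def dx(self, z):
        return self.A * np.pi / self.H * np.cos(np.pi * z / self.H)

    def _phi(self, z):
        return self.Kp * (z / self.H - 0.5)

    def y(self, z):
        if self.Kp == 0.0:
            return np.zeros_like(np.asarray(z, dtype=float))
        return -(self.H / self.Kp) * (
            np.log(np.cos(self._phi(z))) - math.log(math.cos(self.Kp / 2))
        )

    def dy(self, z):
        if self.Kp == 0.0:
            return np.zeros_like(np.asarray(z, dtype=float))
        return np.tan(self._phi(z))

    def centre(self, z):
        return np.array([float(self.x(z)), float(self.y(z)), float(z)])

    # vertebral frames -----------------------------------------------------
    def _build_frames(self) -> None:
        p, n = self.p, self.p.n_vertebrae
        apex = p.apex_index
        yhat = np.array([0.0, 1.0, 0.0])

        tangents, anteriors, laterals = [], [], []
        for z in self.zmid:
            t = _unit(np.array([float(self.dx(z)), float(self.dy(z)), 1.0]))
            ant = _unit(yhat - (yhat @ t) * t)
            lat = np.cross(ant, t)
            tangents.append(t)
            anteriors.append(ant)
            laterals.append(lat)

        # extra coronal tilt of the apical disc's neighbours so that the
        # apical disc wedge equals disc_wedge_deg exactly
        th = [math.degrees(math.atan(float(self.dx(z)))) for z in self.zmid]
        self.natural_wedge_deg = abs(th[apex] - th[apex + 1])
        extra = p.disc_wedge_deg - self.natural_wedge_deg
        if abs(extra) > 1e-9:
            if apex + 1 >= n - 1 or apex <= 0:
                raise ValueError(
                    "disc wedge adjustment would tilt an end vertebra; "
                    "move apex_index away from the segment ends"
                )
            for i, half in ((apex, +0.5), (apex + 1, -0.5)):
                r = _rodrigues(anteriors[i],
                               self.s_cx * half * math.radians(extra))
                tangents[i] = r @ tangents[i]
                laterals[i] = r @ laterals[i]

        # Zero-rotation (untwisted) anterior directions: the neutral
        # vertebra's anterior axis transported geodesically into each
        # endplate plane.  Axial rotation has no absolute meaning between
        # differently tilted endplates; prescribing it against the
        # transported reference makes the injected value exactly the
        # quantity the AP-axis measurement defines (the angle to the
        # neutral vertebra's AP axis, compared in a shared plane).
        for i in range(1, n):
            zero_ant = _align_rotation(tangents[0], tangents[i]) @ anteriors[0]
            anteriors[i] = zero_ant
            laterals[i] = np.cross(zero_ant, tangents[i])

        # axial rotation: anterior axis tips toward the convexity
        self.rotation = np.array(
            [p.max_axial_rotation_deg * _taper(i, apex, n) for i in range(n)]
        )
        for i in range(n):
            r = _rodrigues(tangents[i],
                           -self.s_cx * math.radians(self.rotation[i]))
            anteriors[i] = r @ anteriors[i]
            laterals[i] = r @ laterals[i]

        self.t = [self.R_obl @ v for v in tangents]
        self.ant = [self.R_obl @ v for v in anteriors]
        self.lat = [self.R_obl @ v for v in laterals]
        self.c = [self.world_point(self.centre(z)) for z in self.zmid]

    def endplate(self, i: int, side: str) -> EndplateTruth:
        sgn = +1.0 if side == "superior" else -1.0
        centre = self.c[i] + sgn * (self.p.body_height_mm / 2) * self.t[i]
        return EndplateTruth(centre, self.t[i].copy(), self.ant[i].copy())

    # discs ----------------------------------------------------------------
    def _build_discs(self) -> None:
        p = self.p
        a, b = p.body_radius_mm, p.body_ap_radius_mm
        self.discs = []
        for i in range(p.n_vertebrae - 1):
            lo = self.endplate(i, "superior")
            hi = self.endplate(i + 1, "inferior")
            centre = (lo.centre + hi.centre) / 2
            axis = _unit(self.t[i] + self.t[i + 1])
            yhat = self.R_obl @ np.array([0.0, 1.0, 0.0])
            ant = _unit(yhat - (yhat @ axis) * axis)
            lat = np.cross(ant, axis)

            # bounding planes as linear height fields w(u, v) in disc frame
            def _coeffs(pl: EndplateTruth):
                wn = pl.normal @ axis
                return (
                    (pl.centre - centre) @ pl.normal / wn,
                    -(lat @ pl.normal) / wn,
                    -(ant @ pl.normal) / wn,
                )

            b0, bu, bv = _coeffs(lo)
            t0, tu, tv = _coeffs(hi)
            h0, hu, hv = t0 - b0, tu - bu, tv - bv
            if h0 - math.hypot(hu * a, hv * b) <= 0.25 * p.voxel_mm:
                raise ValueError(
                    f"vertebral bodies {i} and {i + 1} (nearly) interpenetrate"
                    " — geometry is dimensionally impossible"
                )
            # analytic CoV of the wedged elliptic disc slab
            ubar = hu * a * a / 4 / h0
            vbar = hv * b * b / 4 / h0
            m0, mu, mv = (t0 + b0) / 2, (tu + bu) / 2, (tv + bv) / 2
            wbar = (m0 * h0 + mu * hu * a * a / 4 + mv * hv * b * b / 4) / h0
            cov = centre + ubar * lat + vbar * ant + wbar * axis

            # coronal wedge between the bounding endplates
            def _cor(nrm):
                return math.degrees(math.atan2(nrm[0], nrm[2]))

            self.discs.append(dict(
                index=i, centre=centre, axis=axis, ant=ant, lat=lat,
                lo=lo, hi=hi,
                beta=(b0, bu, bv), tau=(t0, tu, tv),
                cov=cov, ubar=ubar, vbar=vbar, wbar=wbar,
                wedge_deg=abs(_cor(lo.normal) - _cor(hi.normal)),
            ))

    def np_centre(self, disc: dict, offset_mm: float) -> np.ndarray:
        """Nucleus centre: the disc CoV shifted laterally toward convexity."""
        u = disc["ubar"] + self.s_cx * offset_mm
        return (disc["centre"] + u * disc["lat"]
                + disc["vbar"] * disc["ant"] + disc["wbar"] * disc["axis"])

    def check_np_fits(self, disc: dict, offset_mm: float) -> None:
        p = self.p
        a, b = p.body_radius_mm, p.body_ap_radius_mm
        an, bn = p.np_radii_mm
        u_c = disc["ubar"] + self.s_cx * offset_mm
        v_c, w_c = disc["vbar"], disc["wbar"]
        if abs(u_c) + an > 0.95 * a or abs(v_c) + bn > 0.95 * b:
            raise ValueError(
                "np_offset_mm too large: nucleus would breach the annulus"
            )
        t0, tu, tv = disc["tau"]
        b0, bu, bv = disc["beta"]
        top_min = t0 + tu * u_c + tv * v_c - math.hypot(tu * an, tv * bn)
        bot_max = b0 + bu * u_c + bv * v_c + math.hypot(bu * an, bv * bn)
        hh = p.np_height_mm / 2
        if top_min - (w_c + hh) < 0.05 or (w_c - hh) - bot_max < 0.05:
            raise ValueError(
                "nucleus pulposus does not fit inside the disc "
                "(reduce np_offset_mm or disc_wedge_deg)"
            )


# ---------------------------------------------------------------------------
# voxelisation


def _paint(data, sel_idx, value):
    data[sel_idx] = value


def generate_phantom(params: PhantomParams) -> tuple[LabelledVolume, PhantomTruth]:
    """Build a labelled scoliotic-spine volume and its analytic truth.

    Voxelisation uses a centre-of-voxel membership test (labels stay
    integral; no anti-aliasing).  Structures are painted in the order
    bodies, canal, annulus, nucleus, with overlap checks that reject
    dimensionally impossible geometries (interpenetrating bodies, canal
    intersecting a body).

    Returns
    -------
    (LabelledVolume, PhantomTruth)
    """
    p = params
    geo = _Geometry(p)
    n = p.n_vertebrae
    vox = p.voxel_mm
    a, b = p.body_radius_mm, p.body_ap_radius_mm
    bh, dh = p.body_height_mm, p.disc_height_mm
    names = p.level_names()
    rng = np.random.default_rng(p.seed)

    # ---- label map
    label_map: dict[str, int] = {}
    nxt = 1
    for nm in names:
        label_map[f"VB_{nm}"] = nxt
        nxt += 1
    label_map["CANAL"] = nxt
    canal_label = nxt
    nxt += 1
    disc_names = [f"{names[i + 1]}{names[i]}" for i in range(n - 1)]
    apex = p.apex_index
    np_disc_idx = [j for j in (apex - 1, apex, apex + 1) if 0 <= j < n - 1]
    for j in range(n - 1):
        label_map[f"AF_{disc_names[j]}"] = nxt
        nxt += 1
    for j in np_disc_idx:
        label_map[f"NP_{disc_names[j]}"] = nxt
        nxt += 1

    # ---- grid
    zs = np.linspace(0.0, geo.H, 256)
    cl = np.stack([geo.x(zs), geo.y(zs), zs], axis=1)
    cl = (cl - geo.mid) @ geo.R_obl.T + geo.mid
    pad = 0.6 * bh
    lo = np.array([cl[:, 0].min() - a - pad,
                   cl[:, 1].min() - (p.canal_offset_mm + p.canal_radius_mm + 6.0),
                   cl[:, 2].min() - dh - 6.0])
    hi = np.array([cl[:, 0].max() + a + pad, cl[:, 1].max() + b + pad,
                   cl[:, 2].max() + dh + 6.0])
    shape = np.ceil((hi - lo) / vox).astype(int) + 1
    affine = np.eye(4)
    affine[:3, :3] *= vox
    affine[:3, 3] = lo
    data = np.zeros(tuple(shape), dtype=np.int16)

    def _world_grid(centre, reach):
        """Index grids and world points for an axis-aligned bbox."""
        i0 = np.maximum(np.floor((centre - reach - lo) / vox).astype(int), 0)
        i1 = np.minimum(np.ceil((centre + reach - lo) / vox).astype(int) + 1,
                        shape)
        ii, jj, kk = np.meshgrid(*(np.arange(i0[d], i1[d]) for d in range(3)),
                                 indexing="ij")
        pts = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3) * vox + lo
        return (ii.ravel(), jj.ravel(), kk.ravel()), pts

    def _jitter(pts):
        if p.surface_jitter > 0:
            return pts + rng.uniform(-p.surface_jitter * vox,
                                     p.surface_jitter * vox, pts.shape)
        return pts

    def _obb_reach(frame_axes, half_extents):
        r = np.zeros(3)
        for ax, h in zip(frame_axes, half_extents):
            r += np.abs(ax) * h
        return r + 2 * vox

    # ---- vertebral bodies
    for i in range(n):
        reach = _obb_reach((geo.lat[i], geo.ant[i], geo.t[i]), (a, b, bh / 2))
        idx, pts = _world_grid(geo.c[i], reach)
        d = _jitter(pts) - geo.c[i]
        u, v, w = d @ geo.lat[i], d @ geo.ant[i], d @ geo.t[i]
        inside = ((u / a) ** 2 + (v / b) ** 2 <= 1.0) & (np.abs(w) <= bh / 2)
        sel = tuple(ax[inside] for ax in idx)
        if np.any(data[sel] != 0):
            raise ValueError(
                f"vertebral body {names[i]} overlaps another body — "
                "geometry is dimensionally impossible"
            )
        _paint(data, sel, label_map[f"VB_{names[i]}"])

    # ---- spinal canal (per-vertebra segments, continuous through discs)
    hl = bh / 2 + dh / 2
    for i in range(n):
        cc = geo.c[i] - p.canal_offset_mm * geo.ant[i]
        reach = _obb_reach((geo.lat[i], geo.ant[i], geo.t[i]),
                           (p.canal_radius_mm, p.canal_radius_mm, hl))
        idx, pts = _world_grid(cc, reach)
        d = _jitter(pts) - cc
        u, v, w = d @ geo.lat[i], d @ geo.ant[i], d @ geo.t[i]
        inside = (u ** 2 + v ** 2 <= p.canal_radius_mm ** 2) & (np.abs(w) <= hl)
        sel = tuple(ax[inside] for ax in idx)
        body_hit = (data[sel] >= 1) & (data[sel] <= n)
        if np.any(body_hit):
            raise ValueError(
                "spinal canal intersects a vertebral body — geometry is "
                "dimensionally impossible (canal_offset_mm too small?)"
            )
        _paint(data, sel, canal_label)

    # ---- discs (annulus, then nucleus into the apical-region discs)
    disc_truth: dict[str, DiscTruth] = {}
    an, bn = p.np_radii_mm
    for j, disc in enumerate(geo.discs):
        reach = _obb_reach((disc["lat"], disc["ant"], disc["axis"]),
                           (a, b, dh / 2 + 0.6 * a))
        idx, pts = _world_grid(disc["centre"], reach)
        pj = _jitter(pts)
        d = pj - disc["centre"]
        u, v = d @ disc["lat"], d @ disc["ant"]
        tube = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        above = (pj - disc["lo"].centre) @ disc["lo"].normal >= 0.0
        below = (pj - disc["hi"].centre) @ disc["hi"].normal <= 0.0
        inside = tube & above & below
        sel = tuple(ax[inside] for ax in idx)
        free = data[sel] == 0
        sel = tuple(s[free] for s in sel)
        af_label = label_map[f"AF_{disc_names[j]}"]
        _paint(data, sel, af_label)

        has_np = j in np_disc_idx
        off = 0.0
        np_cov = None
        if has_np:
            off = p.np_offset_mm * _np_taper(j, apex, n)
            geo.check_np_fits(disc, off)
            np_cov = geo.np_centre(disc, off)
            dnp = _jitter(pts) - np_cov
            un, vn, wn = (dnp @ disc["lat"], dnp @ disc["ant"],
                          dnp @ disc["axis"])
            in_np = ((un / an) ** 2 + (vn / bn) ** 2 <= 1.0) \
                & (np.abs(wn) <= p.np_height_mm / 2)
            seln = tuple(ax[in_np] for ax in idx)
            keep = data[seln] == af_label
            seln = tuple(s[keep] for s in seln)
            _paint(data, seln, label_map[f"NP_{disc_names[j]}"])

        disc_truth[disc_names[j]] = DiscTruth(
            name=disc_names[j],
            has_np=has_np,
            d_mm=float(off),
            ivd_asym_mm=float(2.0 * geo.s_cx * disc["ubar"]),
            np_asym_mm=0.0,
            wedge_deg=float(disc["wedge_deg"]),
            ivd_cov=disc["cov"],
            np_cov=np_cov,
        )

    vol = LabelledVolume(data=data, label_map=label_map, affine=affine)
    vol.validate()

    # ---- truth (angles via the same closed-form projections used to
    # prescribe the geometry; equal to the injected parameters)
    from .curve_angles import cobb_angle, kyphosis_angle

    endplates = {}
    for i, nm in enumerate(names):
        endplates[(nm, "superior")] = geo.endplate(i, "superior")
        endplates[(nm, "inferior")] = geo.endplate(i, "inferior")
    truth = PhantomTruth(
        params=p,
        level_names=names,
        endplates=endplates,
        true_cobb_deg=cobb_angle(endplates[(names[-1], "superior")].plane(),
                                 endplates[(names[0], "inferior")].plane()),
        true_kyphosis_deg=kyphosis_angle(
            endplates[(names[-1], "superior")].plane(),
            endplates[(names[0], "inferior")].plane()),
        rotation_deg={nm: float(geo.rotation[i]) for i, nm in enumerate(names)},
        apex_level=names[apex],
        neutral_level=names[0],
        convexity=p.convexity,
        disc_names=disc_names,
        np_disc_names=[disc_names[j] for j in np_disc_idx],
        apical_disc=disc_names[apex],
        discs=disc_truth,
    )
    return vol, truth


def _np_taper(j: int, apex: int, n: int) -> float:
    """Nucleus-offset taper over discs: 1 at the apical disc."""
    if j == apex:
        return 1.0
    span = apex if j < apex else (n - 1 - apex)
    span = max(span, 1)
    return math.cos(0.5 * math.pi * abs(j - apex) / span)


def paired_phantom(
    params: PhantomParams, extension_delta: dict
) -> tuple[tuple[LabelledVolume, PhantomTruth],
           tuple[LabelledVolume, PhantomTruth]]:
    """Generate a neutral/extended phantom pair.

    ``extension_delta`` overrides deformity magnitudes only (Cobb,
    kyphosis, axial rotation, nucleus offset, disc wedge) — the rigid
    dimensions (voxel size, body/disc/canal geometry, segment) are shared,
    emulating the same spine imaged in two positions.

    Returns ``((neutral_vol, neutral_truth), (extended_vol, extended_truth))``.
    """
    bad = set(extension_delta) - DEFORMITY_FIELDS
    if bad:
        raise ValueError(
            f"extension overrides may only touch deformity magnitudes "
            f"{sorted(DEFORMITY_FIELDS)}; got {sorted(bad)}"
        )
    nsp = generate_phantom(params)
    esp = generate_phantom(dataclasses.replace(params, **extension_delta))
    return nsp, esp


# ---------------------------------------------------------------------------
# cohort simulation


#: Study-condition distributions for the simulated cohort: per-subject
#: neutral-position means/SDs (kyphosis 23° ± 2.6, Cobb 45° ± 7.8, apical
#: rotation 16° ± 6.6, apical nucleus offset 4.6 mm ± 1.6).
COHORT_NSP = {
    "kyphosis_deg": (23.0, 2.6),
    "cobb_deg": (45.0, 7.8),
    "max_axial_rotation_deg": (16.0, 6.6),
    "np_offset_mm": (4.6, 1.6),
}
#: Extension-induced changes.  The kyphosis reduction is the intervention;
#: the coronal and axial reductions are coupled to it in a chain (the
#: three-plane coupling the measurement suite exists to quantify): the
#: Cobb change tracks the kyphosis change and the rotation change tracks
#: the Cobb change, each with independent noise.  Means give the cohort
#: effects (−10° kyphosis, −9° Cobb, −7° apical rotation, −0.9 mm nucleus
#: offset); the noise SDs make the paired kyphosis/Cobb effects strongly
#: significant at n = 10 and leave the coupling correlations around 0.8.
COHORT_DELTA = {
    "kyphosis_deg": (-10.0, 4.0),       # intervention: mean, sd
    "cobb_deg": (0.9, 1.8),             # slope on kyphosis delta, noise sd
    "max_axial_rotation_deg": (0.78, 2.5),  # slope on cobb delta, noise sd
    "np_offset_mm": (-0.9, 0.8),        # independent: mean, sd
}
_CLIP = {
    "kyphosis_deg": (2.0, 45.0),
    "cobb_deg": (12.0, 70.0),
    "max_axial_rotation_deg": (0.0, 38.0),
    # upper bound keeps the nucleus inside the annulus of the default disc
    "np_offset_mm": (0.5, 5.5),
}


def draw_cohort(
    n_subjects: int,
    rng: np.random.Generator | int,
    base: PhantomParams | None = None,
) -> list[tuple[PhantomParams, dict]]:
    """Draw per-subject phantom parameters for a paired-position cohort.

    Returns a list of ``(neutral_params, extension_overrides)`` suitable
    for :func:`paired_phantom`.  Draws follow :data:`COHORT_NSP` /
    :data:`COHORT_DELTA` (with the coupled change chain described there),
    truncated to the generator's valid ranges; the disc wedge is tied to
    the coronal curve (8° at a 45° Cobb, scaled proportionally) in both
    positions.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    base = base or PhantomParams()

    def _clip(key, v):
        return float(np.clip(v, *_CLIP[key]))

    cohort = []
    for _ in range(n_subjects):
        nsp_vals = {k: _clip(k, rng.normal(m, s))
                    for k, (m, s) in COHORT_NSP.items()}
        d_kyph = rng.normal(*COHORT_DELTA["kyphosis_deg"])
        slope_c, sd_c = COHORT_DELTA["cobb_deg"]
        d_cobb = slope_c * d_kyph + rng.normal(0.0, sd_c)
        slope_r, sd_r = COHORT_DELTA["max_axial_rotation_deg"]
        d_rot = slope_r * d_cobb + rng.normal(0.0, sd_r)
        d_np = rng.normal(*COHORT_DELTA["np_offset_mm"])
        esp_vals = {
            "kyphosis_deg": _clip("kyphosis_deg",
                                  nsp_vals["kyphosis_deg"] + d_kyph),
            "cobb_deg": _clip("cobb_deg", nsp_vals["cobb_deg"] + d_cobb),
            "max_axial_rotation_deg": _clip(
                "max_axial_rotation_deg",
                nsp_vals["max_axial_rotation_deg"] + d_rot),
            "np_offset_mm": _clip("np_offset_mm",
                                  nsp_vals["np_offset_mm"] + d_np),
        }
        nsp_vals["disc_wedge_deg"] = 8.0 * nsp_vals["cobb_deg"] / 45.0
        esp_vals["disc_wedge_deg"] = 8.0 * esp_vals["cobb_deg"] / 45.0
        cohort.append((dataclasses.replace(base, **nsp_vals), esp_vals))
    return cohort
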