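"""Shared fixtures: phantoms at the study's voxel sizes, generated once per
session, plus small hand-built volumes for unit tests."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from spinemorph import LabelledVolume, generate_phantom, paired_phantom
from spinemorph.phantom import PhantomParams

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: Extension overrides matching the extended-position cohort magnitudes.
ESP_OVERRIDES = {
    "cobb_deg": 36.0,
    "kyphosis_deg": 13.0,
    "max_axial_rotation_deg": 9.0,
    "np_offset_mm": 3.0,
    "disc_wedge_deg": 5.0,
}


@pytest.fixture(scope="session")
def nsp_phantom():
    """Neutral-position phantom at 1 mm voxels (cohort-mean deformity)."""
    return generate_phantom(PhantomParams())


@pytest.fixture(scope="session")
def phantom_pair():
    """(neutral, extended) 1 mm phantom pair at the cohort means."""
    return paired_phantom(PhantomParams(), ESP_OVERRIDES)


@pytest.fixture(scope="session")
def coarse_phantom():
    """Quick 1.5 mm phantom for invariance and I/O tests."""
    return generate_phantom(PhantomParams(voxel_mm=1.5))


@pytest.fixture()
def tiny_volume():
    """A small hand-built labelled volume: offset blocks on a 1 mm grid."""
    data = np.zeros((24, 24, 24), dtype=np.int16)
    data[4:10, 8:16, 6:18] = 1          # "body"-like block
    data[14:20, 10:14, 8:16] = 2        # "canal"-like block
    affine = np.eye(4)
    affine[:3, 3] = [-12.0, -12.0, -12.0]
    return LabelledVolume(data=data, label_map={"A": 1, "B": 2},
                          affine=affine)


# ---------------------------------------------------------------------------
# independent oracles (exhaustive per-voxel scans, no vectorised shortcuts)


def brute_force_cov(mask: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """Centre of volume by explicit per-voxel accumulation."""
    acc = np.zeros(3)
    n = 0
    for i in range(mask.shape[0]):
        for j in range(mask.shape[1]):
            for k in range(mask.shape[2]):
                if mask[i, j, k]:
                    acc += affine[:3, :3] @ np.array([i, j, k], float) \
                        + affine[:3, 3]
                    n += 1
    if n == 0:
        raise ValueError("empty")
    return acc / n


def brute_force_extremes(mask, affine, cov):
    """Mid-coronal slab extremes by exhaustive scan (tie: nearest CoV z)."""
    dy = float(np.linalg.norm(affine[:3, 1]))
    best = {"min": None, "max": None}
    for i in range(mask.shape[0]):
        for j in range(mask.shape[1]):
            for k in range(mask.shape[2]):
                if not mask[i, j, k]:
                    continue
                p = affine[:3, :3] @ np.array([i, j, k], float) + affine[:3, 3]
                if abs(p[1] - cov[1]) > 0.5 * dy:
                    continue
                for side, better in (("max", lambda a, b: a > b + 1e-9),
                                     ("min", lambda a, b: a < b - 1e-9)):
                    cur = best[side]
                    if cur is None or better(p[0], cur[0]) or (
                        abs(p[0] - cur[0]) <= 1e-9
                        and abs(p[2] - cov[2]) < abs(cur[2] - cov[2])
                    ):
                        best[side] = p
    return best["min"], best["max"]
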