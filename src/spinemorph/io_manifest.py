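"""Volume and manifest I/O: NIfTI labelled volumes, JSON label-map
sidecars, and the YAML cohort manifest.

Orientation convention
----------------------
The package world frame is +x = subject left, +y = anterior, +z = cranial,
in millimetres.  On load, the voxel axes are permuted/flipped so that they
align with the world axes with positive steps; all measurement modules
assume this canonical orientation, so the conversion happens in exactly
one place.  The loader takes the file's affine at face value — it cannot
detect a mislabelled world frame, only a permuted or flipped voxel layout.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .core import LabelledVolume

__all__ = ["load_volume", "save_volume", "load_manifest", "validate_manifest"]

_VERTEBRA_VOCAB = [f"T{i}" for i in range(1, 13)] + [f"L{i}" for i in range(1, 6)]
_CANONICAL = ("R", "A", "S")   # nibabel axcodes of an axis-aligned layout


def _sidecar_path(path: Path) -> Path:
    stem = path.name
    for suffix in (".nii.gz", ".nii"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    return path.with_name(stem + ".labels.json")


def save_volume(vol: LabelledVolume, path, truth=None) -> Path:
    """Write a labelled volume as NIfTI plus a JSON label-map sidecar.

    ``truth``, if given, must have a ``to_json_dict`` method (the phantom
    ground truth) and is embedded in the sidecar.
    """
    path = Path(path)
    img = nib.Nifti1Image(vol.data.astype(np.int16), vol.affine)
    nib.save(img, str(path))
    sidecar = {"label_map": vol.label_map}
    if truth is not None:
        sidecar["truth"] = truth.to_json_dict()
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def load_volume(path, label_map: dict[str, int] | None = None) -> LabelledVolume:
    """Load a labelled NIfTI volume, reoriented to the canonical frame.

    The label map is taken from the JSON sidecar written by
    :func:`save_volume` unless supplied explicitly.

    Raises
    ------
    ValueError
        On non-integer voxel data or a non-invertible affine.
    FileNotFoundError
        If the volume or (when needed) its sidecar is missing.
    """
    path = Path(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        if not np.allclose(data, np.round(data)):
            raise ValueError(f"{path}: voxel values are not integer labels")
        data = np.round(data).astype(np.int32)
    affine = img.affine
    if affine is None or abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError(f"{path}: affine is missing or not invertible")

    ornt = nib.orientations.ornt_transform(
        nib.orientations.io_orientation(affine),
        nib.orientations.axcodes2ornt(_CANONICAL),
    )
    data = nib.orientations.apply_orientation(data, ornt)
    affine = affine @ nib.orientations.inv_ornt_aff(ornt, img.shape)

    if label_map is None:
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise FileNotFoundError(
                f"no label map given and sidecar {sidecar} not found"
            )
        label_map = json.loads(sidecar.read_text())["label_map"]
    vol = LabelledVolume(data=np.ascontiguousarray(data),
                         label_map=dict(label_map), affine=affine)
    vol.validate()
    return vol


def load_sidecar_truth(path) -> dict | None:
    """Ground-truth dict from a phantom sidecar, if present."""
    sidecar = _sidecar_path(Path(path))
    if not sidecar.exists():
        return None
    return json.loads(sidecar.read_text()).get("truth")


# ---------------------------------------------------------------------------
# cohort manifest


def load_manifest(path) -> dict:
    """Parse the YAML cohort manifest (no cross-validation; see
    :func:`validate_manifest`)."""
    with open(path) as fh:
        manifest = yaml.safe_load(fh)
    if not isinstance(manifest, dict) or "subjects" not in manifest:
        raise ValueError("manifest must be a mapping with a 'subjects' list")
    return manifest


def validate_manifest(manifest: dict, load_volumes: bool = False):
    """Validate a cohort manifest; return ``(manifest, errors)``.

    Each subject entry requires: ``id``, ``nsp`` and ``esp`` volume paths,
    ``levels`` (vertebra names, caudal to cranial), ``apex_level``,
    ``neutral_level``, ``end_vertebrae`` (lower, upper) and ``convexity``.
    Errors are aggregated into a human-readable list rather than raised
    one at a time.  With ``load_volumes=True`` the referenced volumes are
    opened and their label maps cross-checked.
    """
    errors: list[str] = []
    subjects = manifest.get("subjects", [])
    if not subjects:
        errors.append("manifest lists no subjects")
    for idx, sub in enumerate(subjects):
        sid = sub.get("id", f"#{idx}")
        for key in ("nsp", "esp", "levels", "apex_level", "neutral_level",
                    "end_vertebrae", "convexity"):
            if key not in sub:
                errors.append(f"subject {sid}: missing field {key!r}")
        levels = sub.get("levels", [])
        bad = [lv for lv in levels if lv not in _VERTEBRA_VOCAB]
        if bad:
            errors.append(f"subject {sid}: unknown vertebra names {bad}")
        apex = sub.get("apex_level")
        if apex is not None and levels:
            if apex not in levels:
                errors.append(f"subject {sid}: apex {apex!r} not in levels")
            else:
                i = levels.index(apex)
                if i < 2 or i > len(levels) - 3:
                    errors.append(
                        f"subject {sid}: peri-apical span (apex ± 2) "
                        f"incomplete for apex {apex!r}"
                    )
        neutral = sub.get("neutral_level")
        if neutral is not None and levels and neutral not in levels:
            errors.append(f"subject {sid}: neutral {neutral!r} not in levels")
        if sub.get("convexity") not in ("left", "right", None):
            errors.append(f"subject {sid}: convexity must be left|right")
        ev = sub.get("end_vertebrae")
        if ev is not None and levels:
            if len(ev) != 2 or any(v not in levels for v in ev):
                errors.append(
                    f"subject {sid}: end_vertebrae must name two levels"
                )
        if load_volumes:
            maps = {}
            for pos in ("nsp", "esp"):
                p = sub.get(pos)
                if p is None:
                    continue
                try:
                    maps[pos] = load_volume(p).label_map
                except (OSError, ValueError) as exc:
                    errors.append(f"subject {sid}: cannot load {pos}: {exc}")
            if len(maps) == 2 and maps["nsp"] != maps["esp"]:
                errors.append(
                    f"subject {sid}: NSP and ESP label maps differ"
                )
            for pos, lm in maps.items():
                for lv in levels:
                    if f"VB_{lv}" not in lm:
                        errors.append(
                            f"subject {sid}: {pos} volume missing VB_{lv}"
                        )
    return manifest, errors
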