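"""End-to-end measurement pipeline: one subject, one pair, one cohort.

Glue over the measurement modules: given a labelled volume and the manual
choices a reader would supply (end vertebrae, apex, neutral vertebra,
convexity side), produce the full set of curve and disc measurements, and
aggregate paired cohorts into the statistics tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import LabelledVolume
from .curve_angles import measure_curve
from .disc_morphometry import disc_report
from .phantom import PhantomParams, PhantomTruth, draw_cohort, paired_phantom
from .stats_report import build_report
from .vertebral_rotation import RotationProfile, rotation_profile

__all__ = ["SubjectSpec", "SpineMeasurements", "measure_subject",
           "measure_pair", "simulate_cohort", "cohort_report"]


@dataclass(frozen=True)
class SubjectSpec:
    """The manual inputs of one subject's measurement.

    These encode the choices the observers make on real data: the measured
    levels, the apex and reference vertebrae, the Cobb end vertebrae and
    the curve's convex side.
    """

    levels: tuple[str, ...]          #: vertebra names, caudal to cranial
    apex_index: int
    neutral_index: int = 0
    end_lower_index: int = 0
    end_upper_index: int = -1
    convexity: str = "left"
    disc_names: tuple[str, ...] = ()
    apical_disc: str | None = None

    @staticmethod
    def from_truth(truth: PhantomTruth) -> "SubjectSpec":
        """Build the measurement spec a phantom's ground truth implies."""
        return SubjectSpec(
            levels=tuple(truth.level_names),
            apex_index=truth.level_names.index(truth.apex_level),
            neutral_index=truth.level_names.index(truth.neutral_level),
            convexity=truth.convexity,
            disc_names=tuple(truth.np_disc_names),
            apical_disc=truth.apical_disc,
        )


@dataclass(eq=False)
class SpineMeasurements:
    """All measurements of one volume in one position."""

    cobb_deg: float
    kyphosis_deg: float
    rotation: RotationProfile

    @property
    def apical_rotation_deg(self) -> float:
        return self.rotation.apical_rotation

    @property
    def periapical_rotation_deg(self) -> float:
        return self.rotation.periapical_mean


def measure_subject(vol: LabelledVolume, spec: SubjectSpec) -> SpineMeasurements:
    """Measure curve angles and the rotation profile of one volume."""
    levels = list(spec.levels)
    angles = measure_curve(vol, levels[spec.end_upper_index],
                           levels[spec.end_lower_index])
    rot = rotation_profile(vol, levels, spec.apex_index, spec.neutral_index,
                           convexity=spec.convexity)
    return SpineMeasurements(
        cobb_deg=angles.cobb_deg,
        kyphosis_deg=angles.kyphosis_deg,
        rotation=rot,
    )


def measure_pair(
    nsp: LabelledVolume,
    esp: LabelledVolume,
    spec: SubjectSpec,
    subject: str = "subject",
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Measure a neutral/extended pair.

    Returns ``(curve_rows, disc_table)``: two tidy per-position rows of
    the curve outcomes, and the per-disc metric table (or None when the
    spec names no discs).
    """
    rows = []
    for pos, vol in (("NSP", nsp), ("ESP", esp)):
        m = measure_subject(vol, spec)
        rows.append({
            "subject": subject, "position": pos,
            "kyphosis_deg": m.kyphosis_deg,
            "cobb_deg": m.cobb_deg,
            "periapical_rotation_deg": m.periapical_rotation_deg,
            "apical_rotation_deg": m.apical_rotation_deg,
        })
    discs = None
    if spec.disc_names:
        discs = disc_report((nsp, esp), list(spec.disc_names),
                            spec.apical_disc or spec.disc_names[0],
                            spec.convexity)
        for row in rows:
            sel = discs[discs.position == row["position"]]
            ivd = sel[sel.structure == "IVD"]
            npd = sel[sel.structure == "NP"]
            row["ivd_asym_mm"] = float(ivd[ivd.apical].asymmetry_mm.mean())
            row["np_asym_mm"] = float(npd[npd.apical].asymmetry_mm.mean())
            row["cov_d_mm"] = float(ivd.d_mm.mean())
            row["cov_d_apical_mm"] = float(ivd[ivd.apical].d_mm.mean())
    return pd.DataFrame(rows), discs


def simulate_cohort(
    n_subjects: int = 10,
    seed: int = 0,
    voxel_mm: float = 1.5,
    base: PhantomParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate and measure a simulated paired-position phantom cohort.

    Per subject, neutral-position deformity parameters and their
    extension-induced changes are drawn from the study-condition
    distributions (:data:`spinemorph.phantom.COHORT_NSP` /
    ``COHORT_DELTA``), a phantom pair is voxelised at ``voxel_mm``, and
    the full measurement pipeline is run on both volumes.

    Returns
    -------
    (cohort, truth)
        ``cohort`` — tidy per-subject, per-position measurement table
        ready for :func:`spinemorph.stats_report.build_report`;
        ``truth`` — the matching table of injected ground-truth values.
    """
    import dataclasses as _dc

    base = base or PhantomParams(voxel_mm=voxel_mm)
    base = _dc.replace(base, voxel_mm=voxel_mm)
    rng = np.random.default_rng(seed)
    frames, truth_rows = [], []
    for k, (params, overrides) in enumerate(draw_cohort(n_subjects, rng, base)):
        sid = f"S{k + 1:02d}"
        (vn, tn), (ve, te) = paired_phantom(params, overrides)
        spec = SubjectSpec.from_truth(tn)
        rows, _ = measure_pair(vn, ve, spec, subject=sid)
        frames.append(rows)
        for pos, tr in (("NSP", tn), ("ESP", te)):
            truth_rows.append({
                "subject": sid, "position": pos,
                "kyphosis_deg": tr.true_kyphosis_deg,
                "cobb_deg": tr.true_cobb_deg,
                "periapical_rotation_deg": tr.periapical_mean_deg,
                "apical_rotation_deg": tr.apical_rotation_deg,
            })
    return pd.concat(frames, ignore_index=True), pd.DataFrame(truth_rows)


def cohort_report(cohort: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Shortcut to :func:`spinemorph.stats_report.build_report`."""
    return build_report(cohort, alpha=alpha)
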