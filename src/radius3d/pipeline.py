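"""End-to-end cohort workflow: frames -> indices -> statistics -> report.

``measure_patient`` turns one patient's landmarks (plus optional shaft
clouds) into frame-coordinate triads and indices; ``summarize_cohort``
aggregates per-patient measurements into the cohort report: per-point
positions pre/post, displacement magnitudes with modal direction labels,
plane-area comparison, repeated-measures testing of the three points'
movement, optional rater reliability and 2D-3D correlations.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import stats as rstats
from .frame import (
    AnatomicalFrame,
    AxisLine,
    build_frame,
    fit_long_axis,
    locate_origin,
    register_rigid,
)
from .indices import (
    POINT_NAMES,
    DisplacementRecord,
    ReferenceTriad,
    TriadIndices,
    compute_indices,
    direction_label,
    displacement,
    ri_2d,
    vt_2d,
)

logger = logging.getLogger("radius3d")

__all__ = ["RunConfig", "PatientMeasurement", "CohortReport", "measure_patient", "summarize_cohort", "run_cohort"]

POINTS_AND_CENTROID = POINT_NAMES + ("centroid",)


@dataclass
class RunConfig:
    """Configuration of one cohort run."""

    landmarks_path: Optional[Path] = None
    shaft_dir: Optional[Path] = None  # expects <patient_id>_pre.ply / _post.ply
    sides: Mapping[str, str] = field(default_factory=dict)  # per-patient, default right
    axis_method: str = "pca_centroids"
    icp_max_iter: int = 200
    icp_tol: float = 1e-6
    dead_zone_mm: float = 0.0
    alpha: float = 0.05
    seed: int = 0
    out_dir: Optional[Path] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class PatientMeasurement:
    """Frame-coordinate triads, indices and displacement for one patient."""

    patient_id: str
    side: str
    pre_triad: ReferenceTriad
    post_triad: ReferenceTriad
    pre_indices: TriadIndices
    post_indices: TriadIndices
    disp: DisplacementRecord
    vt2d_pre: float
    vt2d_post: float
    ri2d_pre: float
    ri2d_post: float
    frame: Optional[AnatomicalFrame] = None
    registration_rms: Optional[float] = None
    registration_converged: Optional[bool] = None


@dataclass
class CohortReport:
    """Cohort-level summary mirroring the per-point results layout."""

    n_patients: int
    positions: dict
    displacements: dict
    plane_area: dict
    friedman: dict
    posthoc: list
    normality: dict
    correlations: dict
    direction_counts: dict
    icc: dict

    def to_dict(self) -> dict:
        return {
            "n_patients": self.n_patients,
            "positions": self.positions,
            "displacements": self.displacements,
            "plane_area": self.plane_area,
            "friedman": self.friedman,
            "posthoc": self.posthoc,
            "normality": self.normality,
            "correlations": self.correlations,
            "direction_counts": self.direction_counts,
            "icc": self.icc,
        }


def _sagittal(p) -> tuple[float, float]:
    return (p.x, p.y)


def _coronal(p) -> tuple[float, float]:
    return (p.z, p.y)


def _mirror_left(m: np.ndarray) -> np.ndarray:
    out = m.copy()
    out[..., 2] = -out[..., 2]
    return out


def measure_patient(
    patient_id: str,
    landmarks_pre: Mapping,
    landmarks_post: Mapping,
    side: str = "right",
    shaft_pre=None,
    shaft_post=None,
    axis_method: str = "pca_centroids",
    icp_max_iter: int = 200,
    icp_tol: float = 1e-6,
    dead_zone_mm: float = 0.0,
) -> PatientMeasurement:
    """Measure one patient.

    With shaft clouds, the frame is built on the postoperative image (long
    axis fit, articular origin, sigmoid base / styloid landmarks) and the
    preoperative data are brought into it by rigid ICP of the intact shaft.
    Without clouds the landmarks are taken as already expressed in a shared
    anatomical frame (identity).  Left wrists are mirrored (z negated) after
    the frame transform so cohort statistics pool sides.
    """
    frame_obj: Optional[AnatomicalFrame] = None
    reg_rms = reg_conv = None

    pre_pts = np.vstack([np.asarray(landmarks_pre[n], float) for n in POINT_NAMES])
    post_pts = np.vstack([np.asarray(landmarks_post[n], float) for n in POINT_NAMES])

    if shaft_post is not None:
        axis = fit_long_axis(shaft_post, method=axis_method, distal_ref=landmarks_post["styloid"])
        origin = locate_origin(axis, np.asarray(landmarks_post["origin"], float))
        frame_obj = build_frame(
            axis,
            sigmoid_base=landmarks_post["sigmoid_base"],
            styloid=landmarks_post["styloid"],
            origin=origin,
            side=side,  # type: ignore[arg-type]
        )
        if shaft_pre is not None:
            reg = register_rigid(shaft_pre, shaft_post, max_iter=icp_max_iter, tol=icp_tol)
            reg_rms, reg_conv = reg.rms, reg.converged
            pre_pts = reg.apply(pre_pts)
            logger.info("%s: ICP rms=%.4g mm, converged=%s (%d iters)", patient_id, reg.rms, reg.converged, reg.n_iter)
        rot, org = frame_obj.rotation, frame_obj.origin
        pre_pts = (pre_pts - org) @ rot.T
        post_pts = (post_pts - org) @ rot.T
        logger.info("%s: frame built (axis method %s)", patient_id, axis_method)

    if side == "left":
        pre_pts, post_pts = _mirror_left(pre_pts), _mirror_left(post_pts)
        logger.info("%s: left wrist mirrored to right-handed convention", patient_id)

    pre_triad = ReferenceTriad.from_matrix(pre_pts)
    post_triad = ReferenceTriad.from_matrix(post_pts)
    disp = displacement(pre_triad, post_triad, side=side, dead_zone=dead_zone_mm)

    return PatientMeasurement(
        patient_id=patient_id,
        side=side,
        pre_triad=pre_triad,
        post_triad=post_triad,
        pre_indices=compute_indices(pre_triad),
        post_indices=compute_indices(post_triad),
        disp=disp,
        vt2d_pre=vt_2d(_sagittal(pre_triad.p_sigmoid_volar), _sagittal(pre_triad.p_sigmoid_dorsal)),
        vt2d_post=vt_2d(_sagittal(post_triad.p_sigmoid_volar), _sagittal(post_triad.p_sigmoid_dorsal)),
        ri2d_pre=ri_2d(_coronal(pre_triad.p_styloid), _coronal(pre_triad.p_sigmoid_volar)),
        ri2d_post=ri_2d(_coronal(post_triad.p_styloid), _coronal(post_triad.p_sigmoid_volar)),
        frame=frame_obj,
        registration_rms=reg_rms,
        registration_converged=reg_conv,
    )


def _mean_sd(values) -> dict:
    arr = np.asarray(values, dtype=float)
    return {"mean": float(arr.mean()), "sd": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0, "n": len(arr)}


def _modal_label(labels: Sequence[str]) -> str:
    counts = Counter(labels)
    top = max(counts.values())
    return sorted(lab for lab, c in counts.items() if c == top)[0]


def _stat_or_note(fn, *args, **kwargs) -> dict:
    try:
        return fn(*args, **kwargs).to_dict()
    except ValueError as exc:
        return {"note": str(exc)}


def summarize_cohort(
    measurements: Sequence[PatientMeasurement],
    alpha: float = 0.05,
    rater_tables: Optional[Mapping] = None,
) -> CohortReport:
    """Aggregate per-patient measurements into the cohort report.

    ``rater_tables`` optionally maps a measurement name (e.g. "vt3d",
    "ri3d") to a subjects x raters matrix for ICC computation.
    """
    if not measurements:
        raise ValueError("no measurements to summarise")
    n = len(measurements)

    positions: dict = {}
    for stage in ("pre", "post"):
        positions[stage] = {}
        for pname in POINTS_AND_CENTROID:
            vecs = []
            for m in measurements:
                triad = m.pre_triad if stage == "pre" else m.post_triad
                idx = m.pre_indices if stage == "pre" else m.post_indices
                if pname == "centroid":
                    vecs.append(idx.centroid.as_array())
                else:
                    vecs.append(getattr(triad, f"p_{pname}").as_array())
            vecs = np.asarray(vecs)
            positions[stage][pname] = {
                **_mean_sd(np.linalg.norm(vecs, axis=1)),
                "modal_label": _modal_label(
                    [direction_label(v, side=m.side) for v, m in zip(vecs, measurements)]
                ),
            }

    displacements: dict = {}
    mags = {pname: np.array([m.disp.magnitudes[pname] for m in measurements]) for pname in POINTS_AND_CENTROID}
    for pname in POINTS_AND_CENTROID:
        displacements[pname] = {
            **_mean_sd(mags[pname]),
            "modal_label": _modal_label([m.disp.labels[pname] for m in measurements]),
        }

    normality = {
        pname: _stat_or_note(rstats.shapiro_wilk, mags[pname]) for pname in POINTS_AND_CENTROID
    }

    point_matrix = np.column_stack([mags[p] for p in POINT_NAMES])
    friedman_res = _stat_or_note(rstats.friedman, point_matrix)
    try:
        posthoc = [r.to_dict() for r in rstats.scheffe_posthoc(point_matrix, alpha=alpha, labels=list(POINT_NAMES))]
    except ValueError as exc:
        posthoc = [{"note": str(exc)}]

    areas_pre = np.array([m.pre_indices.plane_area for m in measurements])
    areas_post = np.array([m.post_indices.plane_area for m in measurements])
    try:
        area_test = rstats.wilcoxon_signed_rank(areas_pre, areas_post).to_dict()
    except ValueError as exc:
        area_test = {"note": f"no change ({exc})"}
    plane_area = {
        "pre": _mean_sd(areas_pre),
        "post": _mean_sd(areas_post),
        "wilcoxon": area_test,
    }

    vt3 = [m.pre_indices.vt_deg for m in measurements] + [m.post_indices.vt_deg for m in measurements]
    vt2 = [m.vt2d_pre for m in measurements] + [m.vt2d_post for m in measurements]
    ri3 = [m.pre_indices.ri_deg for m in measurements] + [m.post_indices.ri_deg for m in measurements]
    ri2 = [m.ri2d_pre for m in measurements] + [m.ri2d_post for m in measurements]
    correlations = {
        "vt_3d_vs_2d": _stat_or_note(rstats.pearson_r, vt3, vt2),
        "ri_3d_vs_2d": _stat_or_note(rstats.pearson_r, ri3, ri2),
    }

    # dorsal/palmar case classification: sign of the preoperative centroid's
    # x-coordinate (after side mirroring, +x is dorsal)
    counts = Counter()
    for m in measurements:
        x = m.pre_indices.centroid.x
        counts["dorsal" if x > 0 else "palmar" if x < 0 else "neutral"] += 1
    direction_counts = {k: counts.get(k, 0) for k in ("dorsal", "palmar", "neutral")}

    icc: dict = {}
    if rater_tables:
        for name, table in rater_tables.items():
            icc[name] = _stat_or_note(rstats.icc_two_way, table)

    return CohortReport(
        n_patients=n,
        positions=positions,
        displacements=displacements,
        plane_area=plane_area,
        friedman=friedman_res,
        posthoc=posthoc,
        normality=normality,
        correlations=correlations,
        direction_counts=direction_counts,
        icc=icc,
    )


def measurements_to_frame(measurements: Sequence[PatientMeasurement]) -> pd.DataFrame:
    """Per-patient long-format measurement table (one row per stage)."""
    rows = []
    for m in measurements:
        for stage in ("pre", "post"):
            triad = m.pre_triad if stage == "pre" else m.post_triad
            idx = m.pre_indices if stage == "pre" else m.post_indices
            row = {"patient_id": m.patient_id, "side": m.side, "stage": stage}
            for pname in POINT_NAMES:
                p = getattr(triad, f"p_{pname}")
                row.update({f"{pname}_x": p.x, f"{pname}_y": p.y, f"{pname}_z": p.z})
            row.update(
                {
                    "centroid_x": idx.centroid.x,
                    "centroid_y": idx.centroid.y,
                    "centroid_z": idx.centroid.z,
                    "area_mm2": idx.plane_area,
                    "vt3d_deg": idx.vt_deg,
                    "ri3d_deg": idx.ri_deg,
                    "vt2d_deg": m.vt2d_pre if stage == "pre" else m.vt2d_post,
                    "ri2d_deg": m.ri2d_pre if stage == "pre" else m.ri2d_post,
                }
            )
            rows.append(row)
        drow = {"patient_id": m.patient_id, "side": m.side, "stage": "displacement"}
        for pname in POINTS_AND_CENTROID:
            v = m.disp.vectors[pname]
            drow.update(
                {
                    f"{pname}_x": v[0],
                    f"{pname}_y": v[1],
                    f"{pname}_z": v[2],
                    f"{pname}_mag": m.disp.magnitudes[pname],
                    f"{pname}_label": m.disp.labels[pname],
                }
            )
        rows.append(drow)
    return pd.DataFrame(rows)


def render_text(report: CohortReport) -> str:
    """Human-readable report, mm and degrees rounded to one decimal."""
    d = report.to_dict()
    lines = [f"Cohort report (n = {d['n_patients']})", ""]
    lines.append("Reference point positions relative to the origin (mm):")
    for stage in ("pre", "post"):
        lines.append(f"  {stage}-operative:")
        for pname, s in d["positions"][stage].items():
            lines.append(f"    {pname:>15}: {s['mean']:.1f} +/- {s['sd']:.1f} mm, {s['modal_label']}")
    lines.append("")
    lines.append("Displacement with reduction (post - pre, mm):")
    for pname, s in d["displacements"].items():
        lines.append(f"    {pname:>15}: {s['mean']:.1f} +/- {s['sd']:.1f} mm, {s['modal_label']}")
    lines.append("")
    fr = d["friedman"]
    if "statistic" in fr:
        lines.append(f"Friedman test across reference points: chi2 = {fr['statistic']:.2f}, p = {fr['p_value']:.4g}")
    else:
        lines.append(f"Friedman test across reference points: {fr.get('note', 'n/a')}")
    for ph in d["posthoc"]:
        if "pair" in ph:
            flag = "significant" if ph["significant"] else "n.s."
            lines.append(f"    {ph['pair'][0]} vs {ph['pair'][1]}: chi2 = {ph['statistic']:.2f}, p = {ph['p_value']:.4g} ({flag})")
    lines.append("")
    pa = d["plane_area"]
    lines.append(
        f"Plane area: pre {pa['pre']['mean']:.1f} +/- {pa['pre']['sd']:.1f} mm^2, "
        f"post {pa['post']['mean']:.1f} +/- {pa['post']['sd']:.1f} mm^2"
    )
    wt = pa["wilcoxon"]
    if "statistic" in wt:
        lines.append(f"    Wilcoxon signed-rank: W = {wt['statistic']:.1f}, p = {wt['p_value']:.4g}")
    else:
        lines.append(f"    Wilcoxon signed-rank: {wt.get('note', 'n/a')}")
    lines.append("")
    for key, label in (("vt_3d_vs_2d", "3D-VT vs 2D-VT"), ("ri_3d_vs_2d", "3D-RI vs 2D-RI")):
        c = d["correlations"][key]
        if "statistic" in c:
            lines.append(f"Pearson {label}: r = {c['statistic']:.2f}, p = {c['p_value']:.4g}")
        else:
            lines.append(f"Pearson {label}: {c.get('note', 'n/a')}")
    lines.append("")
    dc = d["direction_counts"]
    lines.append(
        f"Displacement direction: {dc['dorsal']} dorsal, {dc['palmar']} palmar, {dc['neutral']} neutral"
    )
    if d["icc"]:
        lines.append("")
        lines.append("Rater reliability (ICC):")
        for name, s in d["icc"].items():
            if "statistic" in s:
                lines.append(f"    {name}: ICC = {s['statistic']:.2f} ({s['method']})")
            else:
                lines.append(f"    {name}: {s.get('note', 'n/a')}")
    return "\n".join(lines) + "\n"


def run_cohort(config: RunConfig, landmarks: Optional[Mapping] = None) -> tuple[CohortReport, pd.DataFrame]:
    """Execute the full workflow for a cohort.

    Landmarks come either from ``config.landmarks_path`` or pre-parsed via
    ``landmarks``.  Shaft clouds, when ``config.shaft_dir`` is set, are read
    from ``<patient_id>_pre.ply|stl`` / ``<patient_id>_post.ply|stl``.
    Outputs (report JSON, report text, measurement CSV) are written to
    ``config.out_dir`` when set.  Per-patient failures carry the patient id
    and stage in the raised error.
    """
    from .io import load_mesh_vertices, read_landmarks, write_report

    if landmarks is None:
        if config.landmarks_path is None:
            raise ValueError("run_cohort needs either a landmarks_path or a parsed landmarks mapping")
        landmarks = read_landmarks(config.landmarks_path)

    measurements = []
    for pid in sorted(landmarks):
        side = config.sides.get(pid, "right")
        shaft_pre = shaft_post = None
        if config.shaft_dir is not None:
            for stage in ("pre", "post"):
                for ext in (".ply", ".stl"):
                    candidate = Path(config.shaft_dir) / f"{pid}_{stage}{ext}"
                    if candidate.exists():
                        if stage == "pre":
                            shaft_pre = load_mesh_vertices(candidate)
                        else:
                            shaft_post = load_mesh_vertices(candidate)
                        break
        try:
            measurements.append(
                measure_patient(
                    pid,
                    landmarks[pid]["pre"],
                    landmarks[pid]["post"],
                    side=side,
                    shaft_pre=shaft_pre,
                    shaft_post=shaft_post,
                    axis_method=config.axis_method,
                    icp_max_iter=config.icp_max_iter,
                    icp_tol=config.icp_tol,
                    dead_zone_mm=config.dead_zone_mm,
                )
            )
        except Exception as exc:
            raise RuntimeError(f"patient {pid}: measurement failed: {exc}") from exc

    report = summarize_cohort(measurements, alpha=config.alpha)
    table = measurements_to_frame(measurements)

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_report(report.to_dict(), out / "report.json")
        (out / "report.txt").write_text(render_text(report))
        table.to_csv(out / "measurements.csv", index=False, float_format="%.12g")
    return report, table
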