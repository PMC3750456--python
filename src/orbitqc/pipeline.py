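"""Per-case orchestration and cohort roll-up.

``run_case`` executes the full reconstruction-control workflow on one
patient case: segment the unaffected and affected orbit pre-operatively
and the reconstructed (and unaffected) orbit post-operatively, build the
mirrored unaffected-side template, register it to the reconstructed side
over an ROI of unaffected bone, map signed deviations over the nine wall
regions, and measure implant coverage. Every stage logs its parameters and
summary numbers; outputs are deterministic given the configuration and
carry its hash for provenance. Completed stages leave on-disk markers so
an interrupted run resumes where it stopped.

``run_cohort`` aggregates per-case volume reports (or a cohort CSV) into
group summaries and paired tests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as qio
from .deviation import colorize, deviation_summary, signed_distance
from .regions import implant_coverage, label_regions, segment_implant
from .registration import (RegistrationParams, RoiSelector, estimate_midsagittal,
                           extract_surface, icp_register, reflect_mesh)
from .segmentation import (SegmentationParams, anterior_clip_plane, clip_anterior,
                           compute_volume, per_slice_profile, seed_from_landmarks,
                           segment_cavity, threshold_bone)
from .types import OrbitMask, Plane, RigidTransform, SurfaceMesh

__all__ = ["PipelineConfig", "PipelineStageError", "run_case", "run_cohort"]

REPORT_SCHEMA_VERSION = 1


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and a hint."""

    def __init__(self, stage: str, message: str, hint: str = ""):
        self.stage = stage
        self.hint = hint
        super().__init__(f"stage {stage!r} failed: {message}"
                         + (f" (hint: {hint})" if hint else ""))


@dataclass
class PipelineConfig:
    """Configuration of a single-case run.

    Thresholds are per modality: CT intensities are HU-like while CBCT is
    uncalibrated, so ``bone_threshold_postop`` must match the post-op
    scanner profile.
    """

    preop_volume: str = ""
    postop_volume: str = ""
    landmarks: str = ""
    output_dir: str = ""
    case_id: str = "case"
    affected_side: str = "right"
    affected_wall: str = "floor"
    bone_threshold_preop: float = 300.0
    bone_threshold_postop: float = 180.0
    closing_radius_mm: float = 1.0
    max_volume_ml: float = 60.0
    seed_depth_mm: float = 15.0
    smooth_sigma_vox: float = 1.0
    registration: RegistrationParams = field(default_factory=RegistrationParams)
    deviation_max_correspondence_mm: float = 5.0
    clamp_mm: float = 1.5
    half_angle_deg: float = 45.0
    implant_threshold: float = 1200.0
    implant_min_voxels: int = 10
    projection_distance_mm: float = 2.0
    transition_band_mm: float = 2.0

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        doc = dict(doc)
        reg = doc.pop("registration", None)
        cfg = cls(**doc)
        if reg is not None:
            cfg.registration = RegistrationParams(**reg)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        """Provenance hash over everything that influences the results.

        The output directory is excluded: writing the same analysis to a
        different location must not change (or appear to change) it.
        """
        d = self.to_dict()
        d.pop("output_dir", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _unaffected(side: str) -> str:
    return "left" if side == "right" else "right"


class _CaseRun:
    """Stage driver with on-disk markers, resumability and a plain-text log."""

    def __init__(self, config: PipelineConfig):
        self.cfg = config
        self.out = Path(config.output_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.stage_dir = self.out / "stages"
        self.stage_dir.mkdir(exist_ok=True)
        self.hash = config.config_hash()
        self.log_lines: list[str] = []

    def log(self, stage: str, **info):
        parts = " ".join(f"{k}={v}" for k, v in info.items())
        self.log_lines.append(f"[{stage}] {parts}")

    def marker(self, stage: str) -> Path:
        return self.stage_dir / f"{stage}.done"

    def is_done(self, stage: str) -> bool:
        m = self.marker(stage)
        return m.exists() and m.read_text().strip() == self.hash

    def mark(self, stage: str):
        self.marker(stage).write_text(self.hash + "\n")

    def run_stage(self, stage: str, func, hint: str = "",
                  save=None, load=None):
        """Execute a stage, or resume it from its cached artifact.

        ``save``/``load`` persist the stage result under ``stages/`` so an
        interrupted run resumes from the last completed stage (markers are
        keyed by the config hash, so a config change invalidates them).
        """
        if load is not None and self.is_done(stage):
            try:
                result = load()
                self.log(stage, resumed=True)
                return result
            except Exception:
                pass  # fall through to recompute
        try:
            result = func()
        except PipelineStageError:
            raise
        except Exception as e:
            raise PipelineStageError(stage, str(e), hint) from e
        if save is not None:
            save(result)
        self.mark(stage)
        return result

    # ---- cached-artifact helpers ---------------------------------------
    def mask_io(self, stage: str, side: str):
        path = self.stage_dir / f"{stage}.nii.gz"

        def save(mask: OrbitMask):
            from .types import VolumeImage

            qio.write_volume(VolumeImage(mask.mask.astype(np.uint8),
                                         mask.spacing, mask.origin), path)

        def load() -> OrbitMask:
            vol = qio.read_volume(path)
            return OrbitMask(mask=vol.data > 0, side=side, spacing=vol.spacing,
                             origin=vol.origin, clipped=True)
        return save, load

    def mesh_io(self, stage: str):
        path = self.stage_dir / f"{stage}.npz"

        def save(mesh: SurfaceMesh):
            np.savez_compressed(path, vertices=mesh.vertices, faces=mesh.faces)

        def load() -> SurfaceMesh:
            with np.load(path) as d:
                return SurfaceMesh(d["vertices"], d["faces"])
        return save, load

    def write_log(self):
        (self.out / "case.log").write_text(
            f"# config_hash={self.hash}\n" + "\n".join(self.log_lines) + "\n")


def _segment(volume, landmarks, side, cfg: PipelineConfig, threshold) -> OrbitMask:
    params = SegmentationParams(
        bone_threshold=threshold,
        cavity_seed=seed_from_landmarks(volume, landmarks, side,
                                        depth_mm=cfg.seed_depth_mm),
        closing_radius_mm=cfg.closing_radius_mm,
        max_volume_ml=cfg.max_volume_ml,
    )
    bone = threshold_bone(volume, params)
    mask = segment_cavity(volume, bone, params, side)
    pts = landmarks.sides[side]
    plane = anterior_clip_plane(pts["L"], pts["M"])
    return clip_anterior(mask, plane)


def _csv_with_hash(df: pd.DataFrame, path: Path, config_hash: str):
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False)


def run_case(config: PipelineConfig) -> dict:
    """Run the full per-case analysis; returns the volume report dict.

    Outputs under ``config.output_dir``: ``volumes.json``,
    ``deviation.ply`` (color-coded template), ``deviation.csv``
    (per-vertex), ``region_summary.csv``, ``implant_coverage.csv``,
    ``per_slice_unaffected.csv``, ``transform.json`` and ``case.log``.
    """
    run = _CaseRun(config)
    cfg = config
    aff = cfg.affected_side
    una = _unaffected(aff)

    # -- landmarks ---------------------------------------------------------
    def load_landmarks():
        if not os.path.exists(cfg.landmarks):
            raise FileNotFoundError(f"landmark file not found: {cfg.landmarks}")
        return qio.read_landmarks(cfg.landmarks, require_sides=(aff, una),
                                  require_midline=True)
    landmarks = run.run_stage("landmarks", load_landmarks,
                              hint="provide a JSON/CSV landmark file with L/M per side")
    run.log("landmarks", path=cfg.landmarks)

    def load_volumes():
        return qio.read_volume(cfg.preop_volume), qio.read_volume(cfg.postop_volume)
    preop, postop = run.run_stage("volumes", load_volumes,
                                  hint="check volume paths and formats")
    run.log("volumes", preop=cfg.preop_volume, postop=cfg.postop_volume)

    # -- segmentation and volumetry ---------------------------------------
    masks: dict[str, OrbitMask] = {}
    volumes: dict[str, float] = {}
    for name, vol, side, thr in (
        ("unaffected_CT", preop, una, cfg.bone_threshold_preop),
        ("affected_CT", preop, aff, cfg.bone_threshold_preop),
        ("unaffected_CBCT", postop, una, cfg.bone_threshold_postop),
        ("reconstructed_CBCT", postop, aff, cfg.bone_threshold_postop),
    ):
        stage = f"segment_{name}"
        save, load = run.mask_io(stage, side)
        masks[name] = run.run_stage(
            stage, lambda v=vol, s=side, t=thr: _segment(v, landmarks, s, cfg, t),
            hint="adjust bone threshold / closing radius for this modality",
            save=save, load=load)
        volumes[name] = compute_volume(masks[name])
        run.log(stage, side=side, threshold=thr,
                volume_ml=round(volumes[name], 3))

    profile = per_slice_profile(masks["unaffected_CT"])
    _csv_with_hash(profile, run.out / "per_slice_unaffected.csv", run.hash)

    # -- mirror template ---------------------------------------------------
    def build_template():
        plane = estimate_midsagittal(landmarks)
        tmpl = extract_surface(masks["unaffected_CT"],
                               smooth_sigma_vox=cfg.smooth_sigma_vox)
        return plane, reflect_mesh(tmpl, plane)

    mirror_path = run.stage_dir / "mirror.npz"

    def save_mirror(result):
        plane, mesh = result
        np.savez_compressed(mirror_path, normal=plane.normal, point=plane.point,
                            vertices=mesh.vertices, faces=mesh.faces)

    def load_mirror():
        with np.load(mirror_path) as d:
            return (Plane(d["normal"], d["point"]),
                    SurfaceMesh(d["vertices"], d["faces"]))

    mirror_plane, template = run.run_stage("mirror", build_template,
                                           hint="need >= 3 non-collinear midline landmarks",
                                           save=save_mirror, load=load_mirror)
    run.log("mirror", normal=np.round(mirror_plane.normal, 4).tolist(),
            template_vertices=template.n_vertices)

    def build_target():
        return extract_surface(masks["reconstructed_CBCT"],
                               smooth_sigma_vox=cfg.smooth_sigma_vox)
    save, load = run.mesh_io("target_surface")
    target = run.run_stage("target_surface", build_target, save=save, load=load)

    # -- labeling and ROI --------------------------------------------------
    def build_labels():
        return label_regions(template, landmarks, mirror_plane, aff,
                             half_angle_deg=cfg.half_angle_deg)
    labeling = run.run_stage("regions", build_labels,
                             hint="apex landmark missing or rim landmarks degenerate")

    def build_roi():
        return RoiSelector.from_labels(labeling.labels,
                                       exclude_walls=(cfg.affected_wall,))
    roi = run.run_stage("roi", build_roi,
                        hint="ROI empty after excluding the reconstructed wall")
    run.log("roi", included=int(roi.include.sum()),
            excluded_wall=cfg.affected_wall)

    # -- registration ------------------------------------------------------
    def register():
        return icp_register(template, roi, target, cfg.registration)

    reg_path = run.stage_dir / "register.json"

    def save_register(result):
        t, rep = result
        with open(reg_path, "w") as fh:
            json.dump({"matrix": t.to_matrix().tolist(), "report": rep}, fh)

    def load_register():
        with open(reg_path) as fh:
            doc = json.load(fh)
        return RigidTransform.from_matrix(np.array(doc["matrix"])), doc["report"]

    transform, reg_report = run.run_stage("register", register,
                                          hint="check pre-alignment / ROI choice",
                                          save=save_register, load=load_register)
    run.log("register", **{k: (round(v, 6) if isinstance(v, float) else v)
                           for k, v in reg_report.items()})
    with open(run.out / "transform.json", "w") as fh:
        json.dump({"matrix_4x4_row_major": transform.to_matrix().ravel().tolist(),
                   "report": reg_report, "config_hash": run.hash},
                  fh, indent=1, sort_keys=True)

    # -- deviation mapping -------------------------------------------------
    def deviate():
        moved = SurfaceMesh(transform.apply(template.vertices), template.faces)
        dev, closest = signed_distance(
            moved, target,
            max_correspondence_mm=cfg.deviation_max_correspondence_mm,
            clamp_mm=cfg.clamp_mm, return_closest=True)
        moved.colors = colorize(dev)
        moved.scalars = dev.values
        return moved, dev, closest
    moved, dev, foot_points = run.run_stage("deviate", deviate)
    summary = deviation_summary(dev, labeling.labels)
    run.log("deviate", clamp_mm=cfg.clamp_mm,
            mean_abs_mm=round(float(np.nanmean(np.abs(dev.values))), 4),
            missing_fraction=round(dev.missing_fraction, 4))

    qio.write_mesh(moved, run.out / "deviation.ply", with_colors=True)
    per_vertex = pd.DataFrame({
        "vertex_id": np.arange(moved.n_vertices),
        "region": labeling.labels,
        "deviation_mm": dev.values,
    })
    _csv_with_hash(per_vertex, run.out / "deviation.csv", run.hash)
    _csv_with_hash(summary, run.out / "region_summary.csv", run.hash)

    # -- implant coverage --------------------------------------------------
    def implant():
        imp = segment_implant(postop, cfg.implant_threshold,
                              min_voxels=cfg.implant_min_voxels)
        cov = implant_coverage(labeling, moved, imp,
                               projection_distance_mm=cfg.projection_distance_mm,
                               transition_band_mm=cfg.transition_band_mm,
                               surface_points=foot_points)
        return imp, cov
    imp, coverage = run.run_stage("implant", implant)
    run.log("implant", voxels=imp.voxel_count, components=imp.n_components)
    _csv_with_hash(coverage, run.out / "implant_coverage.csv", run.hash)

    # -- report ------------------------------------------------------------
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "case_id": cfg.case_id,
        "affected_side": aff,
        "config_hash": run.hash,
        "volumes_ml": {k: round(v, 4) for k, v in volumes.items()},
        "voxel_counts": {k: masks[k].voxel_count for k in masks},
        "enlargement_ml": round(volumes["affected_CT"] - volumes["unaffected_CT"], 4),
        "registration": reg_report,
        "deviation_missing_fraction": round(dev.missing_fraction, 4),
    }
    with open(run.out / "volumes.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    run.write_log()
    return report


def run_cohort(source, output_dir, group_column: str = "group") -> dict:
    """Aggregate case reports into cohort statistics.

    ``source`` is a directory of per-case ``volumes.json`` reports or a
    cohort CSV of case records. Writes ``cohort_summary.csv`` and
    ``cohort_stats.json``; with a single case, summaries are produced and
    tests are skipped with a notice.
    """
    from .stats import group_summary, modality_agreement, paired_volume_test

    records = _load_records(source)
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)

    stratifiers = [s for s in ("gender", "fracture_class", "group")
                   if s in records.columns]
    summaries = {}
    if stratifiers:
        for s in stratifiers:
            summaries[s] = group_summary(records, (s,))
        pd.concat(summaries.values(), keys=summaries.keys()) \
            .to_csv(out / "cohort_summary.csv")
    else:
        # volume-only reports: overall mean/SD without stratification
        desc = records.describe().T
        desc.to_csv(out / "cohort_summary.csv")

    stats_doc: dict = {"n_cases": int(len(records))}
    if len(records) < 3:
        stats_doc["notice"] = "fewer than 3 cases: paired tests skipped"
    else:
        agree = modality_agreement(records["unaffected_CT"],
                                   records["unaffected_CBCT"])
        stats_doc["modality_agreement"] = dataclasses.asdict(agree)
        tests = {}
        tests["affected_vs_unaffected"] = dataclasses.asdict(
            paired_volume_test(records["unaffected_CT"], records["affected_CT"]))
        tests["reconstructed_vs_unaffected"] = dataclasses.asdict(
            paired_volume_test(records["unaffected_CBCT"],
                               records["reconstructed_CBCT"]))
        if group_column in records.columns:
            for grp, sub in records.groupby(group_column):
                if len(sub) >= 3:
                    tests[f"reduction_{grp}"] = dataclasses.asdict(
                        paired_volume_test(sub["affected_CT"],
                                           sub["reconstructed_CBCT"]))
        stats_doc["paired_tests"] = tests
    with open(out / "cohort_stats.json", "w") as fh:
        json.dump(stats_doc, fh, indent=1, sort_keys=True, default=float)
    return stats_doc


def _load_records(source) -> pd.DataFrame:
    source = Path(source)
    if source.is_dir():
        rows = []
        versions = set()
        for path in sorted(source.rglob("volumes.json")):
            with open(path) as fh:
                doc = json.load(fh)
            versions.add(doc.get("schema_version"))
            row = {"case_id": doc.get("case_id", path.parent.name)}
            row.update(doc.get("volumes_ml", {}))
            rows.append(row)
        if not rows:
            raise ValueError(f"no volumes.json reports found under {source}")
        if len(versions) > 1:
            raise ValueError(f"heterogeneous report schema versions: {sorted(versions)}")
        return pd.DataFrame(rows)
    if source.suffix.lower() == ".csv":
        return pd.read_csv(source)
    raise ValueError(f"cohort source must be a directory or CSV, got {source}")
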