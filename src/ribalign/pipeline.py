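"""End-to-end experiment orchestration: phantom -> segment -> mesh -> register -> evaluate.

One experiment emulates the phantom-study protocol: a fixed phantom
with a fixed fracture layout is "scanned" (model side), then for each
replicate and each pose condition ("position") the patient side is
simulated (bend + rigid motion + landmark noise), the model is rigidly
registered to the noisy patient landmarks, every fracture is mapped
through the recovered transform, and the skin-surface distance between
the mapped and true fracture sites is recorded.

Determinism: the model side depends only on the phantom spec; replicate
``r`` at position ``j`` uses seed ``base_seed + r*1000 + j``, so runs
with identical config and seed produce byte-identical records.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .errors import OffSurfaceError, ParameterError
from .evaluation import (
    EvalSummary,
    LocalizationRecord,
    SurfaceDistance,
    localization_rate,
    records_to_csv,
    summarize_accuracy,
)
from .landmarks import LandmarkSet
from .meshing import SurfaceMesh, extract_surface, remove_internal_faces, simplify, smooth_laplacian
from .phantom import (
    DeformationSpec,
    PhantomSpec,
    generate_labels,
    generate_torso_volume,
    place_fractures,
    place_landmarks,
    simulate_pose_change,
)
from .registration import estimate_rigid_transform
from .segmentation import remove_bed, segment_body, segment_bone

__all__ = ["ExperimentConfig", "ExperimentReport", "ModelSide", "build_model_side",
           "run_experiment", "report_render"]


@dataclass
class ExperimentConfig:
    """Full description of one reproducible experiment."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    deformations: list[DeformationSpec] = field(default_factory=lambda: [DeformationSpec()])
    n_fractures: int = 16
    replicates: int = 1
    base_seed: int = 0
    metric_mode: str = "geodesic"
    projection_tol_mm: float = 40.0
    miss_threshold_mm: float | None = None
    smooth_iterations: int = 10
    skin_target_faces: int | None = 20000
    bone_target_faces: int | None = None
    ambient_occlusion: bool = False

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ParameterError("replicates must be >= 1")
        if self.metric_mode not in ("geodesic", "euclidean"):
            raise ParameterError(f"metric_mode must be geodesic|euclidean, got {self.metric_mode!r}")
        if not self.deformations:
            raise ParameterError("need at least one deformation condition")

    def to_dict(self) -> dict:
        def _jsonify(obj):
            if isinstance(obj, (tuple, list)):
                return [_jsonify(x) for x in obj]
            if isinstance(obj, dict):
                return {k: _jsonify(v) for k, v in obj.items()}
            return obj

        return _jsonify(dataclasses.asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        ph = d.pop("phantom", {})
        if isinstance(ph, dict):
            for key in ("torso_half_axes", "voxel_spacing", "landmark_names", "grid_shape"):
                if key in ph and ph[key] is not None:
                    ph[key] = tuple(ph[key])
            ph = PhantomSpec(**ph)
        defs = [
            DeformationSpec(**{**dd, "rigid_rotation": tuple(dd.get("rigid_rotation", (0, 0, 0))),
                               "rigid_translation": tuple(dd.get("rigid_translation", (0, 0, 0)))})
            if isinstance(dd, dict) else dd
            for dd in d.pop("deformations", [{}])
        ]
        return cls(phantom=ph, deformations=defs, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def save_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


@dataclass
class ModelSide:
    """Everything derived from the CT side of the experiment (built once)."""

    skin_mesh: SurfaceMesh
    bone_mesh: SurfaceMesh
    landmarks: LandmarkSet
    fracture_names: list[str]
    fracture_points: np.ndarray
    voxel_diagonal: float
    z_extent: tuple[float, float]


def build_model_side(config: ExperimentConfig) -> ModelSide:
    """Run phantom generation, segmentation and meshing for the model side."""
    spec = config.phantom
    volume = generate_torso_volume(spec)
    volume = remove_bed(volume) if spec.bed_enabled else volume
    body = segment_body(volume)
    bone = segment_bone(volume, body=body)

    def _mesh(mask, name, target):
        m = extract_surface(mask, name=name)
        m = smooth_laplacian(m, iterations=config.smooth_iterations)
        if config.ambient_occlusion:
            m = remove_internal_faces(m)
        if target is not None and target < m.n_faces:
            m = simplify(m, target)
        return m

    skin_mesh = _mesh(body, "skin", config.skin_target_faces)
    bone_mesh = _mesh(bone, "bone", config.bone_target_faces)
    landmarks = place_landmarks(spec)
    fractures = place_fractures(spec, config.n_fractures, seed=spec.seed)
    c = spec.half_axes[2]
    return ModelSide(
        skin_mesh=skin_mesh,
        bone_mesh=bone_mesh,
        landmarks=landmarks,
        fracture_names=[f.name for f in fractures],
        fracture_points=np.array([f.point for f in fractures]),
        voxel_diagonal=float(np.linalg.norm(spec.spacing)),
        z_extent=(-c, c),
    )


@dataclass
class ExperimentReport:
    """Aggregate result of :func:`run_experiment` (JSON-serialisable)."""

    config: dict
    version: str
    overall: dict
    per_position: list[dict]
    records: list[dict]
    schema: int = 1

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ExperimentReport":
        d = json.loads(text)
        if d.get("schema") != 1:
            raise ParameterError(f"unsupported report schema {d.get('schema')!r}")
        return cls(**d)


def _summary_dict(s: EvalSummary) -> dict:
    return {
        "n_total": s.n_total,
        "n_localized": s.n_localized,
        "n_measured": s.n_measured,
        "mean_cm": s.mean_cm,
        "sd_cm": s.sd_cm,
        "localization_rate": s.localization_rate,
        "metric_mode": s.metric_mode,
    }


def run_experiment(
    config: ExperimentConfig,
    output_dir: str | Path | None = None,
    model: ModelSide | None = None,
) -> ExperimentReport:
    """Execute the configured experiment; optionally write records + manifest.

    Patient-side skin meshes depend only on the deformation condition
    (bend + rigid), not on the landmark noise, so one evaluator per
    position is shared across replicates, and in geodesic mode one
    distance field per (position, true fracture site) serves every
    replicate.  A prebuilt ``model`` side may be passed when sweeping
    conditions that leave the phantom unchanged.
    """
    if model is None:
        model = build_model_side(config)

    all_records: list[LocalizationRecord] = []
    row_meta: list[dict] = []

    for j, deform in enumerate(config.deformations):
        truth_deform = dataclasses.replace(deform, landmark_noise_sd=0.0)
        true_pts, _ = simulate_pose_change(model.fracture_points, truth_deform,
                                           z_extent=model.z_extent)
        patient_vertices, _ = simulate_pose_change(model.skin_mesh.vertices, truth_deform,
                                                   z_extent=model.z_extent)
        patient_skin = SurfaceMesh(patient_vertices, model.skin_mesh.faces, "skin")
        evaluator = SurfaceDistance(patient_skin, projection_tol=config.projection_tol_mm)
        fields = None
        if config.metric_mode == "geodesic":
            fields = [evaluator.geodesic_field(tp) for tp in true_pts]

        for r in range(config.replicates):
            seed = config.base_seed + r * 1000 + j
            d = dataclasses.replace(deform, seed=seed)
            patient_lms, _ = simulate_pose_change(model.landmarks, d, z_extent=model.z_extent)
            reg = estimate_rigid_transform(model.landmarks, patient_lms)
            localized = reg.transform.apply(model.fracture_points)
            for i, (name, tp, lp) in enumerate(zip(model.fracture_names, true_pts, localized)):
                try:
                    if fields is not None:
                        dist = evaluator.geodesic_from_field(*fields[i], lp)
                    else:
                        dist = evaluator(lp, tp, mode=config.metric_mode)
                except OffSurfaceError:
                    # The mapped mark fell too far outside the body to
                    # project onto the skin: the fracture is not localized.
                    dist = None
                is_hit = dist is not None and (
                    config.miss_threshold_mm is None or dist <= config.miss_threshold_mm
                )
                rec = LocalizationRecord(
                    fracture_id=f"rep{r:03d}_pos{j}_{name}",
                    true_point=tp,
                    localized_point=lp if is_hit else None,
                    method="mr",
                    distance_mm=dist if is_hit else None,
                )
                all_records.append(rec)
                row_meta.append({"replicate": r, "position": j, "fre_rms": reg.fre_rms})

    overall = summarize_accuracy(all_records, metric_mode=config.metric_mode)
    per_position = []
    for j in range(len(config.deformations)):
        recs = [rec for rec, m in zip(all_records, row_meta) if m["position"] == j]
        per_position.append(_summary_dict(summarize_accuracy(recs, config.metric_mode)))

    record_dicts = []
    for rec, m in zip(all_records, row_meta):
        record_dicts.append({
            "fracture_id": rec.fracture_id,
            "replicate": m["replicate"],
            "position": m["position"],
            "fre_rms": round(m["fre_rms"], 9),
            "distance_mm": None if rec.distance_mm is None else round(rec.distance_mm, 9),
            "localized": rec.localized,
        })

    report = ExperimentReport(
        config=config.to_dict(),
        version=__version__,
        overall=_summary_dict(overall),
        per_position=per_position,
        records=record_dicts,
    )

    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        records_to_csv(all_records, out / "records.csv")
        (out / "report.json").write_text(report.to_json() + "\n")
        config.save_yaml(out / "config.yaml")
        manifest = {
            "version": __version__,
            "base_seed": config.base_seed,
            "files": {
                f.name: hashlib.sha256(f.read_bytes()).hexdigest()
                for f in sorted(out.iterdir()) if f.name != "manifest.yaml"
            },
        }
        (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    return report


def verify_manifest(output_dir: str | Path) -> list[str]:
    """Return the names of files whose content no longer matches the manifest."""
    out = Path(output_dir)
    manifest = yaml.safe_load((out / "manifest.yaml").read_text())
    bad = []
    for name, digest in manifest["files"].items():
        f = out / name
        if not f.exists() or hashlib.sha256(f.read_bytes()).hexdigest() != digest:
            bad.append(name)
    return bad


def report_render(report: ExperimentReport) -> str:
    """Human-readable summary of an experiment report."""
    lines = [f"ribalign experiment report (v{report.version})"]
    cfg = report.config
    lines.append(
        f"  phantom seed {cfg['phantom']['seed']}, {cfg['n_fractures']} fractures, "
        f"{len(cfg['deformations'])} position(s), {cfg['replicates']} replicate(s), "
        f"metric: {cfg['metric_mode']}"
    )
    ov = report.overall
    if ov["n_measured"] == 0:
        lines.append("  NO MEASURED RECORDS")
    else:
        lines.append(
            f"  overall: {ov['mean_cm']:.2f} +/- {ov['sd_cm']:.2f} cm over "
            f"{ov['n_measured']} measured records; localization rate "
            f"{ov['localization_rate']:.2f}% ({ov['n_localized']}/{ov['n_total']})"
        )
    for j, pos in enumerate(report.per_position):
        if pos["n_measured"] == 0:
            lines.append(f"    position {j}: no measured records")
        else:
            lines.append(
                f"    position {j}: {pos['mean_cm']:.2f} +/- {pos['sd_cm']:.2f} cm, "
                f"rate {pos['localization_rate']:.2f}%"
            )
    return "\n".join(lines)
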