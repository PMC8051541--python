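"""End-to-end splint pipeline: configuration, staging, reporting.

One config drives the whole chain

    limb scan (or synthetic preset)
      -> offset shell -> plane crops -> isotropic remesh   (draft)
      -> mass-spring relaxation                            (optimize)
      -> strut solid + fastening blocks                    (solidify)
      -> two-piece split                                   (split)

Every formerly interactive action — cut planes, block anchors, the split
plane — is a config entry, which is the point of the tool: the same config
and seed always reproduce the same splint, bit for bit.

Intermediate hand-offs are OBJ (shells, lattices) and binary STL (solids),
so any stage can be resumed from its predecessor's artifact.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import mesh_core, shell_draft, solidify, synthetic_limb
from . import lattice_optimize as lopt
from .mesh_core import SurfaceMesh, extract_lattice, read_mesh, validate_mesh, write_mesh
from .shell_draft import CutPlane, RemeshParams
from .solidify import BlockSpec, StrutParams, block_pose_from_anchor

log = logging.getLogger(__name__)

STAGES = ("generate", "draft", "optimize", "solidify", "split")


class ConfigError(ValueError):
    pass


class ResumeError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Full parameter set of a splint run.  All lengths in mm.

    The offset distance is tied to the strut radius (the bar centerlines sit
    one bar-radius above the skin); overriding that link requires
    ``allow_offset_mismatch``.
    """

    input_path: str | None = None
    preset: str | None = "wrist_default"
    seed: int = 0
    offset_distance_mm: float = 2.0
    cut_planes: list = field(default_factory=lambda: [
        {"point": [0.0, 0.0, 40.0], "normal": [0.0, 0.0, 1.0],
         "keep_side": "positive"},
        {"point": [0.0, 0.0, 210.0], "normal": [0.0, 0.0, 1.0],
         "keep_side": "negative"},
    ])
    remesh: dict = field(default_factory=lambda: {
        "target_edge_mm": 12.0, "iterations": 10, "smoothing_weight": 0.6})
    grade_gamma: float | None = None   # density grading before optimization
    optimizer: dict = field(default_factory=dict)
    strut: dict = field(default_factory=lambda: {"diameter_mm": 4.0})
    # six strap blocks: three per flank at ~25 deg above/below the split
    # seam, at three axial stations
    blocks: list = field(default_factory=lambda: [
        {"anchor": [s * 136.0, s * 63.0, z]}
        for s in (1.0, -1.0) for z in (75.0, 125.0, 175.0)
    ])
    block_defaults: dict = field(default_factory=lambda: {
        "dimensions": [20.0, 12.0, 10.0], "hole_diameter": 4.0,
        "embed": 2.0})
    split_plane: dict = field(default_factory=lambda: {
        "point": [0.0, 0.0, 125.0], "normal": [0.0, 1.0, 0.0]})
    allow_offset_mismatch: bool = False
    output_dir: str = "splint_out"
    log_level: str = "INFO"

    def validate(self) -> None:
        diameter = float(self.strut.get("diameter_mm", 4.0))
        if not self.allow_offset_mismatch and \
                abs(self.offset_distance_mm - diameter / 2.0) > 1e-9:
            raise ConfigError(
                f"offset_distance_mm={self.offset_distance_mm} must equal "
                f"strut radius {diameter / 2.0} (set allow_offset_mismatch "
                "to override)")
        if self.input_path is None and self.preset is None:
            raise ConfigError("either input_path or preset is required")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    # -- typed parameter views ---------------------------------------------

    def cut_plane_objs(self) -> list[CutPlane]:
        return [CutPlane(tuple(c["point"]), tuple(c["normal"]),
                         c.get("keep_side", "positive"))
                for c in self.cut_planes]

    def remesh_params(self) -> RemeshParams:
        return RemeshParams(
            target_edge_length=float(self.remesh.get("target_edge_mm", 12.0)),
            iterations=int(self.remesh.get("iterations", 10)),
            smoothing_weight=float(self.remesh.get("smoothing_weight", 0.6)))

    def optimizer_params(self) -> lopt.OptimizerParams:
        o = self.optimizer
        return lopt.OptimizerParams(
            stiffness=float(o.get("k", 1.0)),
            mass=float(o.get("m", 1.0)),
            damping=float(o.get("c", 1.0)),
            dt=float(o.get("dt", 0.2)),
            fscale=float(o.get("fscale", 1.2)),
            mode=o.get("mode", "bilateral"),
            max_iterations=int(o.get("max_iterations", 2000)),
            tolerance=o.get("tolerance"))

    def strut_params(self) -> StrutParams:
        return StrutParams(
            diameter=float(self.strut.get("diameter_mm", 4.0)),
            voxel_pitch=self.strut.get("voxel_pitch_mm"))

    def block_specs(self, surface: SurfaceMesh) -> list[BlockSpec]:
        defaults = self.block_defaults
        specs = []
        for b in self.blocks:
            if "anchor" in b:
                specs.append(block_pose_from_anchor(
                    surface, np.asarray(b["anchor"], dtype=float),
                    dimensions=tuple(b.get("dimensions",
                                           defaults["dimensions"])),
                    hole_diameter=float(b.get("hole_diameter",
                                              defaults["hole_diameter"])),
                    embed=float(b.get("embed", defaults["embed"]))))
            else:
                specs.append(BlockSpec(
                    tuple(b["center"]), tuple(b["frame"]),
                    tuple(b.get("dimensions", defaults["dimensions"])),
                    float(b.get("hole_diameter", defaults["hole_diameter"])),
                    b.get("hole_axis", "y")))
        return specs

    def split_plane_obj(self) -> CutPlane:
        return CutPlane(tuple(self.split_plane["point"]),
                        tuple(self.split_plane["normal"]), "positive")


def demo_config(seed: int = 0) -> PipelineConfig:
    """The published wrist-demo parameters: 2 mm offset shell, 4 mm struts,
    six strap blocks, one split plane — on the synthetic wrist preset."""
    return PipelineConfig(seed=seed)


@dataclass
class RunReport:
    config: dict
    config_hash: str
    stages: dict = field(default_factory=dict)
    artifacts: dict = field(default_factory=dict)
    validation: dict = field(default_factory=dict)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=_jsonable)

    def stage(self, name: str, seconds: float, **stats) -> None:
        self.stages[name] = {"seconds": round(seconds, 3), **stats}


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o))


def _mesh_stats(mesh: SurfaceMesh) -> dict:
    return {"vertices": mesh.n_vertices, "faces": mesh.n_faces}


def run_pipeline(config: PipelineConfig, start_stage: str = "generate",
                 artifact: str | None = None) -> RunReport:
    """Execute the pipeline from ``start_stage`` to the end.

    When resuming, ``artifact`` must be the preceding stage's output: the
    limb mesh for "draft", the draft shell OBJ for "optimize", the optimized
    shell OBJ for "solidify", the whole-splint STL for "split".  Outputs:
    cropped_shell.obj, draft_shell.obj, optimized_shell.obj, splint_solid.stl,
    piece_top.stl, piece_bottom.stl, report.json in the output directory.
    """
    config.validate()
    if start_stage not in STAGES:
        raise ResumeError(f"unknown stage {start_stage!r}; one of {STAGES}")
    first = STAGES.index(start_stage)
    if first > 0 and artifact is None:
        raise ResumeError(f"resuming at {start_stage!r} requires an artifact")

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=config.to_dict(),
                       config_hash=config.config_hash())

    limb = cropped = draft = opt_shell = None
    solid = None

    def do(stage):
        return STAGES.index(stage) >= first

    # generate / load the limb surface
    if do("generate") and first == 0:
        t0 = time.perf_counter()
        if config.input_path:
            limb = read_mesh(config.input_path)
        else:
            params = synthetic_limb.preset(config.preset, seed=config.seed)
            limb = synthetic_limb.generate_limb(params)
        rep = validate_mesh(limb, expect_closed=True)
        if not rep.ok(True):
            raise mesh_core.MeshValidationError(
                "input limb mesh is not watertight")
        limb_path = out / "limb.obj"
        write_mesh(limb, limb_path)
        report.stage("generate", time.perf_counter() - t0,
                     **_mesh_stats(limb), volume_mm3=rep.volume_mm3)
        report.artifacts["limb"] = str(limb_path)

    if do("draft"):
        t0 = time.perf_counter()
        if first == STAGES.index("draft"):
            limb = read_mesh(artifact)
            if validate_mesh(limb, expect_closed=True).boundary_loop_count:
                raise ResumeError("draft stage expects a closed limb mesh")
        shell = shell_draft.offset_surface(limb, config.offset_distance_mm)
        cropped = shell
        for plane in config.cut_plane_objs():
            cropped = shell_draft.plane_cut(cropped, plane)
        draft = shell_draft.remesh_isotropic(cropped, config.remesh_params())
        write_mesh(cropped, out / "cropped_shell.obj")
        write_mesh(draft, out / "draft_shell.obj")
        report.stage("draft", time.perf_counter() - t0,
                     cropped=_mesh_stats(cropped), draft=_mesh_stats(draft))
        report.artifacts["cropped_shell"] = str(out / "cropped_shell.obj")
        report.artifacts["draft_shell"] = str(out / "draft_shell.obj")

    if do("optimize"):
        t0 = time.perf_counter()
        if first == STAGES.index("optimize"):
            draft_path = Path(artifact)
        else:
            draft_path = out / "draft_shell.obj"
        # the written OBJ is the canonical hand-off: reload it even in a
        # full run, so resumed runs are byte-identical to uninterrupted ones
        draft = read_mesh(draft_path)
        if not len(draft.boundary_edges()):
            raise ResumeError("optimize stage expects an open draft shell")
        side = draft_path.parent / "cropped_shell.obj"
        if side.exists():
            cropped = read_mesh(side)
        else:
            log.info("no cropped_shell.obj beside the draft; projecting "
                     "onto the draft shell itself")
            cropped = draft
        lattice = extract_lattice(draft)
        if config.grade_gamma:
            lattice = lopt.grade_lattice(lattice, cropped,
                                         gamma=float(config.grade_gamma))
        opt_report: dict = {}
        optimized = lopt.optimize(lattice, cropped,
                                  config.optimizer_params(),
                                  report=opt_report)
        opt_shell = SurfaceMesh(optimized.nodes,
                                np.asarray(optimized.source_faces))
        write_mesh(opt_shell, out / "optimized_shell.obj")
        report.stage("optimize", time.perf_counter() - t0, **opt_report)
        report.artifacts["optimized_shell"] = str(out / "optimized_shell.obj")

    if do("solidify"):
        t0 = time.perf_counter()
        opt_path = Path(artifact) if first == STAGES.index("solidify") \
            else out / "optimized_shell.obj"
        opt_shell = read_mesh(opt_path)
        if not len(opt_shell.boundary_edges()):
            raise ResumeError(
                "solidify stage expects an open optimized shell")
        lattice = extract_lattice(opt_shell)
        solid = solidify.strut_solid(lattice, config.strut_params())
        blocks = config.block_specs(opt_shell)
        if blocks:
            solid = solidify.attach_blocks(solid, blocks)
            channels = solidify.count_through_channels(solid, blocks)
        else:
            channels = 0
        rep = validate_mesh(solid.mesh, expect_closed=True)
        write_mesh(solid.mesh, out / "splint_solid.stl")
        report.stage("solidify", time.perf_counter() - t0,
                     **_mesh_stats(solid.mesh), volume_mm3=rep.volume_mm3,
                     blocks=len(blocks), through_channels=channels)
        report.validation["splint_solid"] = {
            "watertight": rep.watertight,
            "winding_consistent": rep.winding_consistent,
            "volume_mm3": rep.volume_mm3}
        report.artifacts["splint_solid"] = str(out / "splint_solid.stl")

    if do("split"):
        t0 = time.perf_counter()
        solid_path = Path(artifact) if first == STAGES.index("split") \
            else out / "splint_solid.stl"
        mesh = read_mesh(solid_path)
        if len(mesh.boundary_edges()):
            raise ResumeError("split stage expects a closed solid")
        solid = solidify.SolidModel(mesh, stage="loaded")
        top, bottom = solidify.split_solid(solid, config.split_plane_obj())
        names = {"piece_top": top, "piece_bottom": bottom}
        stats = {}
        for name, piece in names.items():
            rep = validate_mesh(piece.mesh, expect_closed=True)
            write_mesh(piece.mesh, out / f"{name}.stl")
            report.validation[name] = {
                "watertight": rep.watertight,
                "winding_consistent": rep.winding_consistent,
                "volume_mm3": rep.volume_mm3}
            report.artifacts[name] = str(out / f"{name}.stl")
            stats[name] = rep.volume_mm3
        report.stage("split", time.perf_counter() - t0, **stats)

    report.save(out / "report.json")
    report.artifacts["report"] = str(out / "report.json")
    return report


def stage_resume(config: PipelineConfig, stage: str,
                 artifact: str) -> RunReport:
    """Continue the pipeline from ``stage``, seeded with the preceding
    stage's artifact file."""
    return run_pipeline(config, start_stage=stage, artifact=artifact)
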