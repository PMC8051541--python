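"""Shared fixtures and independent geometric oracles.

The voxel-parity volume oracle and the brute-force closest-point oracle here
are deliberately independent of the package's own spatial code paths: they
rasterize or enumerate directly, so they can arbitrate disagreements.
"""

from __future__ import annotations

import numpy as np
import pytest

from splintforge._spatial import _moller_trumbore
from splintforge.mesh_core import SurfaceMesh
from splintforge.pipeline import demo_config, run_pipeline
from splintforge.synthetic_limb import LimbParams, generate_limb, preset


# ---------------------------------------------------------------------------
# oracles


def voxel_occupancy(mesh: SurfaceMesh, pitch: float,
                    bounds=None) -> tuple[np.ndarray, float]:
    """Rasterize a closed mesh into a boolean grid by ray-parity counting.

    Columns of voxel centers are classified by counting crossings of a +z
    ray; centers between an odd and the next even crossing are inside.
    Returns (occupancy grid, pitch) — volume is ``occ.sum() * pitch**3``.
    """
    v = mesh.vertices
    lo = v.min(axis=0) - pitch if bounds is None else np.asarray(bounds[0])
    hi = v.max(axis=0) + pitch if bounds is None else np.asarray(bounds[1])
    # offset centers off lattice planes to dodge edge-grazing rays
    xs = np.arange(lo[0] + 0.5 * pitch, hi[0], pitch) + 0.123456e-3
    ys = np.arange(lo[1] + 0.5 * pitch, hi[1], pitch) + 0.654321e-3
    zs = np.arange(lo[2] + 0.5 * pitch, hi[2], pitch)
    tris = v[mesh.faces]
    occ = np.zeros((len(xs), len(ys), len(zs)), dtype=bool)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    origins = np.stack([X.ravel(), Y.ravel(),
                        np.full(X.size, lo[2] - 1.0)], axis=1)
    direction = np.array([[0.0, 0.0, 1.0]])
    chunk = max(1, int(4e6 / max(len(tris), 1)))
    for s in range(0, len(origins), chunk):
        block = origins[s:s + chunk]
        t = _moller_trumbore(block, np.repeat(direction, len(block), axis=0),
                             tris)
        t = np.where(np.isfinite(t), t, np.nan)
        t_sorted = np.sort(t, axis=1)
        for r in range(len(block)):
            hits = t_sorted[r][~np.isnan(t_sorted[r])]
            # collapse duplicate hits (shared edges/vertices)
            if len(hits) > 1:
                hits = hits[np.concatenate(
                    [[True], np.diff(hits) > 1e-9])]
            z0 = lo[2] - 1.0
            for k in range(0, len(hits) - 1, 2):
                inside = (zs > z0 + hits[k]) & (zs < z0 + hits[k + 1])
                occ.reshape(-1, len(zs))[s + r][inside] = True
    return occ, pitch


def voxel_volume(mesh: SurfaceMesh, pitch: float) -> float:
    occ, p = voxel_occupancy(mesh, pitch)
    return float(occ.sum()) * p**3


def brute_force_closest_distance(points: np.ndarray,
                                 mesh: SurfaceMesh) -> np.ndarray:
    """Exact unsigned distance by scanning every triangle per point."""
    from splintforge._spatial import closest_point_on_triangles
    tris = mesh.vertices[mesh.faces]
    out = np.empty(len(points))
    for i, p in enumerate(points):
        cp = closest_point_on_triangles(np.broadcast_to(p, tris[:, 0].shape),
                                        tris)
        out[i] = np.linalg.norm(cp - p, axis=1).min()
    return out


# ---------------------------------------------------------------------------
# meshes


SMALL_LIMB = LimbParams(
    length=140.0, proximal_semi_axes=(30.0, 25.0),
    distal_semi_axes=(22.0, 18.0), bump_center=0.6, bump_amplitude=3.0,
    bump_sigma=12.0, noise_amplitude=0.15, axial_samples=60,
    radial_samples=32, seed=0)


@pytest.fixture(scope="session")
def wrist_limb() -> SurfaceMesh:
    return generate_limb(preset("wrist_default"))


@pytest.fixture(scope="session")
def small_limb() -> SurfaceMesh:
    return generate_limb(SMALL_LIMB)


def small_pipeline_config(output_dir: str, seed: int = 0):
    """Reduced-size pipeline configuration for fast end-to-end tests."""
    cfg = demo_config(seed=seed)
    cfg.output_dir = output_dir
    cfg.cut_planes = [
        {"point": [0.0, 0.0, 25.0], "normal": [0.0, 0.0, 1.0],
         "keep_side": "positive"},
        {"point": [0.0, 0.0, 115.0], "normal": [0.0, 0.0, 1.0],
         "keep_side": "negative"},
    ]
    cfg.remesh = {"target_edge_mm": 11.0, "iterations": 8,
                  "smoothing_weight": 0.6}
    cfg.strut = {"diameter_mm": 4.0, "voxel_pitch_mm": 1.0}
    cfg.blocks = [{"anchor": [s * 100.0, s * 47.0, z]}
                  for s in (1.0, -1.0) for z in (50.0, 90.0)]
    cfg.split_plane = {"point": [0.0, 0.0, 70.0], "normal": [0.0, 1.0, 0.0]}
    return cfg


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """One reduced-size end-to-end pipeline run, shared across tests."""
    out = tmp_path_factory.mktemp("small_run")
    cfg = small_pipeline_config(str(out))
    # swap in the small synthetic limb via a pre-written input mesh
    from splintforge.mesh_core import write_mesh
    limb = generate_limb(SMALL_LIMB)
    limb_path = out / "input_limb.obj"
    write_mesh(limb, limb_path)
    cfg.input_path = str(limb_path)
    cfg.preset = None
    report = run_pipeline(cfg)
    return {"config": cfg, "report": report, "dir": out, "limb": limb}


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """The full wrist-demo pipeline at published parameters (2 mm offset,
    4 mm struts, 6 blocks, one split plane); shared by the acceptance suite."""
    out = tmp_path_factory.mktemp("demo_run")
    cfg = demo_config(seed=0)
    cfg.output_dir = str(out)
    report = run_pipeline(cfg)
    limb = generate_limb(preset("wrist_default", seed=0))
    return {"config": cfg, "report": report, "dir": out, "limb": limb}
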