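"""Mass-spring optimizer physics: forces, integration, convergence."""

import numpy as np
import pytest

from splintforge.mesh_core import LatticeGraph, SurfaceMesh, extract_lattice
from splintforge.lattice_optimize import (
    ConsistencyError,
    DegenerateEdgeError,
    OptimizerParameterError,
    OptimizerParams,
    build_springs,
    grade_lattice,
    optimize,
    quality,
    spring_forces,
    step,
    total_energy,
    uniform_rest_length,
)


def two_node_lattice(length=10.0):
    return LatticeGraph(np.array([[0.0, 0, 0], [length, 0, 0]]),
                        np.array([[0, 1]]))


def plane_surface(size=100.0):
    v = np.array([[-size, -size, 0.0], [size, -size, 0], [size, size, 0],
                  [-size, size, 0]])
    f = np.array([[0, 1, 2], [0, 2, 3]])
    return SurfaceMesh(v, f)


# ---------------------------------------------------------------------------
# construction


def test_rest_length_single_edge():
    lat = two_node_lattice(10.0)
    assert uniform_rest_length(lat, 1.2) == pytest.approx(12.0)
    sys_ = build_springs(lat, None, OptimizerParams())
    np.testing.assert_allclose(sys_.rest_lengths, 12.0)
    np.testing.assert_allclose(sys_.velocities, 0.0)


def test_rest_length_uniform_grid():
    h = 5.0
    nodes = np.array([[0.0, 0, 0], [h, 0, 0], [2 * h, 0, 0], [3 * h, 0, 0]])
    lat = LatticeGraph(nodes, np.array([[0, 1], [1, 2], [2, 3]]))
    # all edges equal h: RMS edge length is h, so L0 = 1.2 h
    assert uniform_rest_length(lat, 1.2) == pytest.approx(1.2 * h)


def test_build_rejects_lattice_far_from_surface():
    lat = LatticeGraph(np.array([[0.0, 0, 50.0], [10.0, 0, 50.0]]),
                       np.array([[0, 1]]))
    with pytest.raises(ConsistencyError):
        build_springs(lat, plane_surface(), OptimizerParams())


def test_boundary_nodes_flagged_from_shell_loops(small_limb):
    from splintforge.shell_draft import (CutPlane, RemeshParams, offset_surface,
                                         plane_cut, remesh_isotropic)
    shell = offset_surface(small_limb, 2.0)
    c = plane_cut(shell, CutPlane((0, 0, 25.0), (0, 0, 1.0), "positive"))
    c = plane_cut(c, CutPlane((0, 0, 115.0), (0, 0, 1.0), "negative"))
    draft = remesh_isotropic(c, RemeshParams(11.0, iterations=6))
    lat = extract_lattice(draft)
    sys_ = build_springs(lat, c, OptimizerParams())
    n_boundary_vertices = sum(len(l) for l in draft.boundary_loops())
    assert sys_.boundary.sum() == n_boundary_vertices


# ---------------------------------------------------------------------------
# forces


def test_force_zero_at_rest_length():
    lat = two_node_lattice(12.0)
    sys_ = build_springs(lat, None, OptimizerParams(fscale=1.0))
    f = spring_forces(sys_, OptimizerParams(fscale=1.0))
    np.testing.assert_allclose(f, 0.0, atol=1e-12)


def test_compressed_spring_pushes_nodes_apart():
    lat = two_node_lattice(8.0)
    sys_ = build_springs(lat, None, OptimizerParams())
    sys_.rest_lengths[:] = 12.0
    f = spring_forces(sys_, OptimizerParams(stiffness=1.0))
    np.testing.assert_allclose(np.linalg.norm(f, axis=1), [4.0, 4.0])
    assert f[0, 0] < 0 < f[1, 0]  # directed apart along the edge


def test_equilateral_triangle_at_rest_has_zero_net_force():
    a = np.array([[0.0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0]])
    lat = LatticeGraph(a, np.array([[0, 1], [1, 2], [0, 2]]))
    p = OptimizerParams(fscale=1.0)
    sys_ = build_springs(lat, None, p)
    np.testing.assert_allclose(spring_forces(sys_, p), 0.0, atol=1e-12)


def test_forces_match_per_edge_loop_oracle():
    rng = np.random.default_rng(11)
    nodes = rng.normal(scale=5.0, size=(6, 3))
    edges = np.array([[0, 1], [1, 2], [2, 3], [3, 4], [4, 5], [0, 5],
                      [1, 4], [2, 5]])
    lat = LatticeGraph(nodes, edges)
    p = OptimizerParams(stiffness=1.7)
    sys_ = build_springs(lat, None, p)
    forces = spring_forces(sys_, p)

    oracle = np.zeros_like(nodes)
    for (i, j), L0 in zip(edges, sys_.rest_lengths):
        d = nodes[j] - nodes[i]
        L = np.linalg.norm(d)
        u = d / L
        f = p.stiffness * (L0 - L)
        oracle[i] -= f * u
        oracle[j] += f * u
    np.testing.assert_allclose(forces, oracle, atol=1e-12)


def test_newtons_third_law_forces_sum_to_zero():
    rng = np.random.default_rng(5)
    nodes = rng.normal(scale=8.0, size=(20, 3))
    edges = np.array([[i, (i + 3) % 20] for i in range(20)]
                     + [[i, (i + 1) % 20] for i in range(20)])
    lat = LatticeGraph(nodes, np.unique(np.sort(edges, axis=1), axis=0))
    p = OptimizerParams()
    sys_ = build_springs(lat, None, p)
    total = spring_forces(sys_, p).sum(axis=0)
    scale = np.abs(spring_forces(sys_, p)).max()
    np.testing.assert_allclose(total / scale, 0.0, atol=1e-9)


def test_repulsive_only_mode_never_pulls():
    lat = two_node_lattice(20.0)
    p = OptimizerParams(mode="repulsive_only", fscale=0.5)  # L0 = 10 < 20
    sys_ = build_springs(lat, None, p)
    f = spring_forces(sys_, p)
    np.testing.assert_allclose(f, 0.0, atol=1e-12)  # stretched: clamped


def test_zero_length_edge_raises():
    lat = two_node_lattice(10.0)
    sys_ = build_springs(lat, None, OptimizerParams())
    sys_.positions[1] = sys_.positions[0]
    with pytest.raises(DegenerateEdgeError):
        spring_forces(sys_, OptimizerParams())


# ---------------------------------------------------------------------------
# integration


def test_velocity_decay_is_exact_under_zero_force():
    lat = two_node_lattice(12.0)
    p = OptimizerParams(fscale=1.0, damping=1.0, dt=0.2)  # factor 0.8
    sys_ = build_springs(lat, None, p)
    sys_.velocities[:] = [[1.0, 2.0, -1.0], [0.5, 0.0, 3.0]]
    v0 = sys_.velocities.copy()
    x0 = sys_.positions.copy()
    step(sys_, p)
    np.testing.assert_allclose(sys_.velocities, 0.8 * v0, atol=5e-12)
    np.testing.assert_allclose(sys_.positions, x0 + 0.2 * 0.8 * v0,
                               atol=5e-12)


def test_symmetric_spring_keeps_midpoint_stationary():
    lat = two_node_lattice(8.0)
    p = OptimizerParams()
    sys_ = build_springs(lat, None, p)
    mid0 = sys_.positions.mean(axis=0)
    for _ in range(50):
        step(sys_, p)
    np.testing.assert_allclose(sys_.positions.mean(axis=0), mid0, atol=1e-12)


def test_single_step_matches_arithmetic_oracle_on_plane():
    nodes = np.array([[0.0, 0, 0], [10, 0, 0], [10, 10, 0], [0, 10, 0]])
    edges = np.array([[0, 1], [1, 2], [2, 3], [0, 3]])
    lat = LatticeGraph(nodes, edges)
    p = OptimizerParams(stiffness=2.0, mass=1.5, damping=1.0, dt=0.3,
                        fscale=1.2)
    surface = plane_surface()
    sys_ = build_springs(lat, surface, p)

    # independent straight-line arithmetic
    L0 = 1.2 * 10.0
    f = np.zeros_like(nodes)
    for i, j in edges:
        d = nodes[j] - nodes[i]
        L = np.linalg.norm(d)
        u = d / L
        s = 2.0 * (L0 - L)
        f[i] -= s * u
        f[j] += s * u
    factor = 1.0 - 1.0 * 0.3 / 1.5
    v = (0.3 / 1.5) * f * factor
    x = nodes + 0.3 * v
    x[:, 2] = 0.0          # projection onto the plane
    v[:, 2] = 0.0          # normal velocity removed

    step(sys_, p)
    np.testing.assert_allclose(sys_.positions, x, atol=1e-12)
    np.testing.assert_allclose(sys_.velocities, v, atol=1e-12)


def test_energy_decays_on_free_damped_system():
    rng = np.random.default_rng(3)
    nodes = rng.normal(scale=5.0, size=(6, 3))
    edges = np.array([[0, 1], [1, 2], [2, 3], [3, 4], [4, 5], [0, 5],
                      [1, 4], [2, 5]])
    lat = LatticeGraph(nodes, edges)
    p = OptimizerParams()
    sys_ = build_springs(lat, None, p)
    energies = [total_energy(sys_, p)]
    for _ in range(150):
        step(sys_, p)
        energies.append(total_energy(sys_, p))
    e = np.asarray(energies)
    assert np.all(np.diff(e[5:]) <= 1e-10)
    assert e[-1] < 1e-2 * e[0]


def test_invalid_damping_factor_rejected():
    with pytest.raises(OptimizerParameterError):
        OptimizerParams(damping=6.0, dt=0.2, mass=1.0)  # factor < 0
    with pytest.raises(OptimizerParameterError):
        OptimizerParams(damping=0.0)                    # factor == 1


# ---------------------------------------------------------------------------
# optimization


def test_two_node_system_converges_to_rest_length():
    lat = two_node_lattice(8.0)
    p = OptimizerParams(fscale=1.5, tolerance=1e-7, max_iterations=5000)
    out = optimize(lat, None, p)
    dist = np.linalg.norm(out.nodes[1] - out.nodes[0])
    assert dist == pytest.approx(12.0, abs=1e-3)


def test_lattice_at_rest_length_is_a_fixed_point():
    h = 10.0
    nodes = np.array([[0.0, 0, 0], [h, 0, 0], [h / 2, h * np.sqrt(3) / 2, 0]])
    lat = LatticeGraph(nodes, np.array([[0, 1], [1, 2], [0, 2]]))
    rep = {}
    out = optimize(lat, None, OptimizerParams(fscale=1.0), report=rep)
    assert rep["converged"] and rep["iterations"] <= 3
    np.testing.assert_allclose(out.nodes, nodes, atol=0.05 * h)


def test_optimize_preserves_connectivity_and_is_deterministic(small_limb):
    from splintforge.shell_draft import (CutPlane, RemeshParams, offset_surface,
                                         plane_cut, remesh_isotropic)
    shell = offset_surface(small_limb, 2.0)
    c = plane_cut(shell, CutPlane((0, 0, 25.0), (0, 0, 1.0), "positive"))
    c = plane_cut(c, CutPlane((0, 0, 115.0), (0, 0, 1.0), "negative"))
    draft = remesh_isotropic(c, RemeshParams(11.0, iterations=6))
    lat = extract_lattice(draft)
    p = OptimizerParams(max_iterations=300)
    a = optimize(lat, c, p)
    b = optimize(lat, c, p)
    assert np.array_equal(a.edges, lat.edges)
    assert np.array_equal(a.nodes, b.nodes)  # bitwise determinism


def test_optimized_nodes_lie_on_surface_and_rim(small_limb):
    from splintforge._spatial import SurfaceIndex
    from splintforge.shell_draft import (CutPlane, RemeshParams, offset_surface,
                                         plane_cut, remesh_isotropic)
    shell = offset_surface(small_limb, 2.0)
    c = plane_cut(shell, CutPlane((0, 0, 25.0), (0, 0, 1.0), "positive"))
    c = plane_cut(c, CutPlane((0, 0, 115.0), (0, 0, 1.0), "negative"))
    draft = remesh_isotropic(c, RemeshParams(11.0, iterations=6))
    lat = extract_lattice(draft)
    p = OptimizerParams(max_iterations=300)
    sys_ = build_springs(lat, c, p)
    out = optimize(lat, c, p)
    index = SurfaceIndex(c.vertices, c.faces)
    _, dist, _ = index.query(out.nodes)
    assert dist.max() < 1e-6
    _, rim_d = sys_.boundary_polyline.query(out.nodes[sys_.boundary])
    assert rim_d.max() < 1e-6


# ---------------------------------------------------------------------------
# quality statistics


def test_quality_of_unit_equilateral_triangle():
    nodes = np.array([[0.0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0]])
    lat = LatticeGraph(nodes, np.array([[0, 1], [1, 2], [0, 2]]))
    q = quality(lat, np.array([[0, 1, 2]]))
    assert q.triangle_area_cv == pytest.approx(0.0, abs=1e-12)
    assert q.min_inner_angle_deg == pytest.approx(60.0, abs=1e-9)
    assert q.edge_length_cv == pytest.approx(0.0, abs=1e-12)


def test_quality_area_ratio_of_two_triangles():
    nodes = np.array([[0.0, 0, 0], [1, 0, 0], [0, 2, 0], [-4, 0, 0]])
    faces = np.array([[0, 1, 2], [0, 2, 3]])
    edges = np.unique(np.sort(np.vstack(
        [faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]]), axis=1),
        axis=0)
    q = quality(LatticeGraph(nodes, edges), faces)
    assert q.triangle_area_max / q.triangle_area_min == pytest.approx(4.0)


def test_quality_mean_edge_matches_direct_recomputation():
    rng = np.random.default_rng(9)
    nodes = rng.normal(size=(8, 3))
    edges = np.unique(np.sort(rng.integers(0, 8, size=(20, 2)), axis=1),
                      axis=0)
    edges = edges[edges[:, 0] != edges[:, 1]]
    lat = LatticeGraph(nodes, edges)
    q = quality(lat)
    direct = np.mean([np.linalg.norm(nodes[i] - nodes[j])
                      for i, j in edges])
    assert q.edge_length_mean == pytest.approx(direct, abs=1e-12)


def test_grading_then_optimizing_equalizes_triangles(small_limb):
    from splintforge.shell_draft import (CutPlane, RemeshParams, offset_surface,
                                         plane_cut, remesh_isotropic)
    shell = offset_surface(small_limb, 2.0)
    c = plane_cut(shell, CutPlane((0, 0, 25.0), (0, 0, 1.0), "positive"))
    c = plane_cut(c, CutPlane((0, 0, 115.0), (0, 0, 1.0), "negative"))
    draft = remesh_isotropic(c, RemeshParams(11.0, iterations=6))
    lat = extract_lattice(draft)
    graded = grade_lattice(lat, c, gamma=2.5)
    q0 = quality(graded, graded.source_faces)
    out = optimize(graded, c, OptimizerParams())
    q1 = quality(out, out.source_faces)
    assert q1.edge_length_cv < q0.edge_length_cv
    assert q1.triangle_area_min > q0.triangle_area_min
    assert q1.triangle_area_max < q0.triangle_area_max
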