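"""Strut solids, fastening blocks, and the two-piece split."""

import numpy as np
import pytest

from splintforge.mesh_core import LatticeGraph, validate_mesh
from splintforge.shell_draft import CutPlane, ParameterError
from splintforge.solidify import (
    BlockSpec,
    OrientedBox,
    PlacementError,
    SolidModel,
    Sphere,
    SplitError,
    StrutParams,
    _extract,
    attach_blocks,
    count_through_channels,
    estimate_volume,
    measure_strut_diameter,
    split_solid,
    strut_solid,
)

from conftest import voxel_occupancy, voxel_volume


def single_edge_lattice(length=20.0):
    return LatticeGraph(np.array([[0.0, 0, 0], [length, 0, 0]]),
                        np.array([[0, 1]]))


def triangle_lattice(side=15.0):
    nodes = side * np.array([[0.0, 0, 0], [1, 0, 0],
                             [0.5, np.sqrt(3) / 2, 0]])
    return LatticeGraph(nodes, np.array([[0, 1], [1, 2], [0, 2]]))


# ---------------------------------------------------------------------------
# strut solids


def test_capsule_volume_matches_closed_form():
    solid = strut_solid(single_edge_lattice(20.0), StrutParams(diameter=4.0))
    rep = validate_mesh(solid.mesh, expect_closed=True)
    assert rep.ok(True)
    expected = np.pi * 2.0**2 * 20.0 + 4.0 / 3.0 * np.pi * 2.0**3
    assert solid.volume() == pytest.approx(expected, rel=0.02)


def test_sphere_volume_via_sdf_extraction():
    mesh = _extract([Sphere((0.0, 0.0, 0.0), 2.0)], [], pitch=0.25)
    expected = 4.0 / 3.0 * np.pi * 2.0**3
    assert mesh.volume() == pytest.approx(expected, rel=0.02)
    assert validate_mesh(mesh, expect_closed=True).ok(True)


def test_triangle_cell_volume_matches_voxel_oracle():
    lat = triangle_lattice(15.0)
    solid = strut_solid(lat, StrutParams(diameter=4.0, voxel_pitch=0.25))
    oracle = voxel_volume(solid.mesh, pitch=0.25)
    assert solid.volume() == pytest.approx(oracle, rel=0.03)


def test_volume_close_to_inclusion_exclusion_estimate():
    # near-collinear sparse path: node spheres are the only overlaps
    nodes = np.array([[0.0, 0, 0], [30, 0, 0], [60, 2, 0]])
    lat = LatticeGraph(nodes, np.array([[0, 1], [1, 2]]))
    params = StrutParams(diameter=4.0, voxel_pitch=0.25)
    solid = strut_solid(lat, params)
    est = estimate_volume(lat, params.radius)
    assert solid.volume() == pytest.approx(est, rel=0.05)
    prim_sum = sum(p.volume() for p in solid.positive)
    assert solid.volume() <= prim_sum


def test_volume_monotone_in_diameter():
    lat = triangle_lattice(15.0)
    vols = [strut_solid(lat, StrutParams(diameter=d, voxel_pitch=0.5)).volume()
            for d in (3.0, 4.0, 5.0)]
    assert vols[0] < vols[1] < vols[2]


def test_empty_lattice_rejected():
    with pytest.raises((ParameterError, Exception)):
        strut_solid(LatticeGraph(np.zeros((0, 3)),
                                 np.zeros((0, 2), dtype=int)),
                    StrutParams())


def test_short_edge_warns(caplog):
    import logging
    lat = single_edge_lattice(3.0)  # shorter than the 4 mm diameter
    with caplog.at_level(logging.WARNING, logger="splintforge.solidify"):
        strut_solid(lat, StrutParams(diameter=4.0))
    assert any("shorter" in r.message for r in caplog.records)


def test_pitch_coarser_than_quarter_diameter_rejected():
    with pytest.raises(ParameterError):
        StrutParams(diameter=4.0, voxel_pitch=1.5)


def test_strut_cross_section_diameter():
    solid = strut_solid(single_edge_lattice(30.0), StrutParams(diameter=4.0))
    d = measure_strut_diameter(solid, np.array([0.0, 0, 0]),
                               np.array([30.0, 0, 0]))
    assert d == pytest.approx(4.0, rel=0.05)


# ---------------------------------------------------------------------------
# blocks


def _box_solid(extent=20.0, pitch=0.5) -> SolidModel:
    box = OrientedBox((0.0, 0.0, 0.0),
                      tuple(np.eye(3).ravel()),
                      (extent / 2,) * 3)
    mesh = _extract([box], [], pitch=pitch)
    return SolidModel(mesh, positive=[box], pitch=pitch)


def test_block_union_volume_matches_voxel_oracle():
    solid = _box_solid(20.0)
    # block overlapping one face, no hole
    block = BlockSpec(center=(12.0, 0.0, 0.0),
                      frame=tuple(np.eye(3).ravel()),
                      dimensions=(8.0, 8.0, 8.0), hole_diameter=0.0)
    merged = attach_blocks(solid, [block])
    rep = validate_mesh(merged.mesh, expect_closed=True)
    assert rep.ok(True)
    oracle = voxel_volume(merged.mesh, pitch=0.5)
    assert merged.volume() == pytest.approx(oracle, rel=0.03)
    # analytic: cube + block - overlap (block spans x in [8, 16]; cube to 10)
    expected = 20.0**3 + 8.0**3 - 2.0 * 8.0 * 8.0
    assert merged.volume() == pytest.approx(expected, rel=0.03)


def test_hole_as_wide_as_block_rejected():
    with pytest.raises(ParameterError):
        BlockSpec(center=(0, 0, 0), frame=tuple(np.eye(3).ravel()),
                  dimensions=(20.0, 12.0, 10.0), hole_diameter=12.0,
                  hole_axis="x")


def test_nonorthonormal_frame_rejected():
    with pytest.raises(ParameterError):
        BlockSpec(center=(0, 0, 0), frame=tuple(np.ones(9)),
                  dimensions=(20.0, 12.0, 10.0))


def test_far_block_raises_placement_error():
    solid = _box_solid(20.0)
    block = BlockSpec(center=(100.0, 0.0, 0.0),
                      frame=tuple(np.eye(3).ravel()),
                      dimensions=(8.0, 8.0, 8.0), hole_diameter=0.0)
    with pytest.raises(PlacementError):
        attach_blocks(solid, [block])


def test_block_hole_is_an_open_through_channel():
    solid = _box_solid(20.0)
    block = BlockSpec(center=(12.0, 0.0, 0.0),
                      frame=tuple(np.eye(3).ravel()),
                      dimensions=(8.0, 12.0, 12.0), hole_diameter=4.0,
                      hole_axis="y")
    merged = attach_blocks(solid, [block])
    assert count_through_channels(merged, [block]) == 1
    # a hole-less block is not counted as a channel
    no_hole = BlockSpec(center=(12.0, 0.0, 0.0),
                        frame=tuple(np.eye(3).ravel()),
                        dimensions=(8.0, 12.0, 12.0), hole_diameter=0.0)
    merged2 = attach_blocks(solid, [no_hole])
    assert count_through_channels(merged2, [no_hole]) == 0


# ---------------------------------------------------------------------------
# split


def _ball(radius=10.0, pitch=0.4) -> SolidModel:
    mesh = _extract([Sphere((0.0, 0.0, 0.0), radius)], [], pitch=pitch)
    return SolidModel(mesh, pitch=pitch)


def test_sphere_split_gives_half_balls():
    ball = _ball(10.0)
    top, bottom = split_solid(ball, CutPlane((0, 0, 0), (0, 0, 1.0),
                                             "positive"))
    half = 2.0 / 3.0 * np.pi * 10.0**3
    for piece in (top, bottom):
        rep = validate_mesh(piece.mesh, expect_closed=True)
        assert rep.ok(True)
        assert piece.volume() == pytest.approx(half, rel=0.01)
    assert top.volume() + bottom.volume() == \
        pytest.approx(ball.volume(), rel=0.01)


def test_cube_split_quarters():
    solid = _box_solid(20.0)
    a, b = split_solid(solid, CutPlane((-5.0, 0, 0), (1.0, 0, 0),
                                       "positive"))
    assert a.volume() / b.volume() == pytest.approx(3.0, rel=0.01)


def test_split_plane_missing_solid_raises():
    ball = _ball(5.0, pitch=0.4)
    with pytest.raises(SplitError):
        split_solid(ball, CutPlane((0, 0, 50.0), (0, 0, 1.0), "positive"))


def test_split_then_reunion_recovers_volume():
    ball = _ball(8.0, pitch=0.4)
    top, bottom = split_solid(ball, CutPlane((0, 0, 1.5), (0, 0, 1.0),
                                             "positive"))
    lo = ball.mesh.vertices.min(axis=0) - 1.0
    hi = ball.mesh.vertices.max(axis=0) + 1.0
    occ_a, p = voxel_occupancy(top.mesh, 0.4, bounds=(lo, hi))
    occ_b, _ = voxel_occupancy(bottom.mesh, 0.4, bounds=(lo, hi))
    union_vol = float((occ_a | occ_b).sum()) * p**3
    assert union_vol == pytest.approx(ball.volume(), rel=0.02)
    # pieces do not interpenetrate: overlap is confined to the cut plane
    overlap = float((occ_a & occ_b).sum()) * p**3
    assert overlap < 0.005 * ball.volume()
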