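"""Parametric limb-segment meshes standing in for a surface scan.

The generator lofts superellipse cross-sections along a (possibly curved)
axis, with a Gaussian radial bump emulating a bony prominence such as the
ulnar styloid, plus seeded, spatially smoothed radial noise.  The output is
always a watertight genus-0 mesh, so every downstream stage of the splint
pipeline can be exercised without a 3D scanner.

Cross-sections are superellipses |x/a|^p + |y/b|^p = 1 (p = 2 gives an
ellipse); semi-axes interpolate linearly from the proximal to the distal end.
All coordinates are millimetres; the limb axis is +z.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .mesh_core import SurfaceMesh

__all__ = ["LimbParams", "generate_limb", "PRESETS", "preset"]


class LimbParameterError(ValueError):
    """Invalid synthetic limb parameters."""


@dataclass(frozen=True)
class LimbParams:
    """Shape parameters of the synthetic limb segment.

    length : axial extent, mm.
    proximal_semi_axes / distal_semi_axes : (a, b) of the superellipse at the
        two ends, mm; the distal end must not be wider (limbs taper).
    cross_section_exponent : superellipse exponent p; 2 = ellipse, larger
        values flatten towards a rounded rectangle.
    axis_curvature : bend of the limb axis in the x-z plane, 1/mm; the axis
        is offset by curvature * z^2 / 2 (osculating-circle approximation).
    bump_center : axial position of the bump as a fraction of length.
    bump_amplitude, bump_sigma : height (mm) and spatial width (mm) of a
        Gaussian radial bump on the +x side.
    noise_amplitude : standard deviation (mm) of smoothed radial noise.
    axial_samples, radial_samples : loft grid resolution.
    seed : noise generator seed; output is deterministic for a given seed.
    """

    length: float = 250.0
    proximal_semi_axes: tuple[float, float] = (45.0, 35.0)
    distal_semi_axes: tuple[float, float] = (30.0, 25.0)
    cross_section_exponent: float = 2.0
    axis_curvature: float = 0.0
    bump_center: float = 0.65
    bump_amplitude: float = 4.0
    bump_sigma: float = 18.0
    noise_amplitude: float = 0.0
    axial_samples: int = 120
    radial_samples: int = 64
    seed: int = 0

    def validate(self) -> None:
        pa, pb = self.proximal_semi_axes
        da, db = self.distal_semi_axes
        if min(self.length, pa, pb, da, db) <= 0:
            raise LimbParameterError("all lengths must be positive")
        if da > pa or db > pb:
            raise LimbParameterError("distal semi-axes must not exceed proximal")
        if self.cross_section_exponent <= 0:
            raise LimbParameterError("cross_section_exponent must be positive")
        if self.bump_sigma <= 0:
            raise LimbParameterError("bump_sigma must be positive")
        if not 0.0 <= self.bump_center <= 1.0:
            raise LimbParameterError("bump_center must be in [0, 1]")
        if self.noise_amplitude >= 0.1 * min(pa, pb, da, db):
            raise LimbParameterError(
                "noise_amplitude must stay below 10% of the smallest semi-axis")
        if self.axial_samples < 4 or self.radial_samples < 8:
            raise LimbParameterError("grid too coarse")


def _superellipse(theta: np.ndarray, a, b, p: float):
    """Point on |x/a|^p + |y/b|^p = 1 at parameter theta, vectorized.

    a, b may be arrays broadcasting against theta.
    """
    c, s = np.cos(theta), np.sin(theta)
    x = a * np.sign(c) * np.abs(c) ** (2.0 / p)
    y = b * np.sign(s) * np.abs(s) ** (2.0 / p)
    return x, y


def generate_limb(params: LimbParams) -> SurfaceMesh:
    """Build the watertight limb mesh.

    The loft grid has ``axial_samples`` rings of ``radial_samples`` vertices;
    both ends are capped with triangle fans.  The bump and the noise displace
    vertices along the local outward radial direction, so surface normals stay
    well defined.  Two calls with identical params produce bitwise-identical
    arrays.
    """
    params.validate()
    na, nr = params.axial_samples, params.radial_samples
    L = params.length
    p = params.cross_section_exponent

    z = np.linspace(0.0, L, na)
    frac = z / L
    theta = 2.0 * np.pi * np.arange(nr) / nr

    pa, pb = params.proximal_semi_axes
    da, db = params.distal_semi_axes
    a = pa + (da - pa) * frac          # (na,)
    b = pb + (db - pb) * frac

    zz = np.broadcast_to(z[:, None], (na, nr))
    tt = np.broadcast_to(theta[None, :], (na, nr))
    x, y = _superellipse(tt, a[:, None], b[:, None], p)

    # radial displacement field: bump + smoothed noise
    r = np.hypot(x, y)
    mean_radius = 0.5 * (a + b)
    arc = tt.copy()
    arc[arc > np.pi] -= 2.0 * np.pi    # signed angle to the +x bump direction
    arc = np.abs(arc) * mean_radius[:, None]
    dz = zz - params.bump_center * L
    bump = params.bump_amplitude * np.exp(
        -(dz**2 + arc**2) / (2.0 * params.bump_sigma**2))

    disp = bump
    if params.noise_amplitude > 0:
        rng = np.random.default_rng(params.seed)
        raw = rng.standard_normal((na, nr))
        smooth = gaussian_filter(raw, sigma=(2.0, 2.0), mode=("nearest", "wrap"))
        smooth /= smooth.std()
        disp = disp + params.noise_amplitude * smooth

    scale = (r + disp) / np.where(r > 0, r, 1.0)
    x, y = x * scale, y * scale

    # curved axis: offset in x (the bump plane, preserving mirror symmetry)
    x = x + params.axis_curvature * zz**2 / 2.0

    verts = np.empty((na * nr + 2, 3))
    verts[: na * nr, 0] = x.ravel()
    verts[: na * nr, 1] = y.ravel()
    verts[: na * nr, 2] = zz.ravel()
    # cap centers on the axis
    verts[na * nr] = (params.axis_curvature * 0.0, 0.0, 0.0)
    verts[na * nr + 1] = (params.axis_curvature * L**2 / 2.0, 0.0, L)

    faces = []
    for i in range(na - 1):
        r0 = i * nr
        r1 = (i + 1) * nr
        for j in range(nr):
            jn = (j + 1) % nr
            # outward winding (CCW seen from outside)
            faces.append((r0 + j, r0 + jn, r1 + j))
            faces.append((r0 + jn, r1 + jn, r1 + j))
    c0, c1 = na * nr, na * nr + 1
    for j in range(nr):
        jn = (j + 1) % nr
        faces.append((c0, jn, j))                          # proximal cap (-z)
        faces.append((c1, (na - 1) * nr + j, (na - 1) * nr + jn))  # distal cap
    mesh = SurfaceMesh(verts, np.asarray(faces, dtype=np.int64), closed=True)
    return mesh


PRESETS: dict[str, LimbParams] = {
    # Wrist-like segment: 250 mm, tapering 45x35 -> 30x25 mm, 4 mm styloid bump
    "wrist_default": LimbParams(noise_amplitude=0.2, seed=0),
    # Circular cylinder, handy for closed-form checks
    "cylinder": LimbParams(
        length=200.0, proximal_semi_axes=(30.0, 30.0),
        distal_semi_axes=(30.0, 30.0), bump_amplitude=0.0,
        noise_amplitude=0.0),
    # Strong taper + bent axis + boxier cross-section: stresses the offset
    "high_curvature": LimbParams(
        length=250.0, proximal_semi_axes=(50.0, 38.0),
        distal_semi_axes=(26.0, 20.0), cross_section_exponent=3.0,
        axis_curvature=8e-4, bump_amplitude=6.0, bump_sigma=14.0,
        noise_amplitude=0.2),
}


def preset(name: str, seed: int | None = None) -> LimbParams:
    """Look up a named preset, optionally overriding the noise seed."""
    try:
        params = PRESETS[name]
    except KeyError:
        raise LimbParameterError(
            f"unknown preset {name!r}; choose from {sorted(PRESETS)}") from None
    if seed is not None:
        params = replace(params, seed=seed)
    return params
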