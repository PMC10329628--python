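"""Procedural liver-like organ surfaces.

Real pipelines start from a patient surface segmented out of a
preoperative CT scan; that geometry is not shippable, so tests and
experiments run on procedurally generated stand-ins: an ellipsoid radial
field perturbed by band-limited spherical-harmonic noise plus a few
Gaussian lobes, evaluated on an icosphere so the result is watertight and
consistently oriented by construction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.special import sph_harm_y

from .geometry import SurfaceMesh

__all__ = ["OrganShapeSpec", "generate_organ"]


@dataclass(frozen=True)
class OrganShapeSpec:
    """Shape parameters of the procedural organ.

    base_radii : semi-axes of the underlying ellipsoid (m); the default
        (0.14, 0.10, 0.08) approximates an adult liver envelope.
    lobe_count : number of Gaussian surface bumps emulating lobes.
    bump_amplitude : perturbation amplitude as a fraction of the local
        radius, in [0, 0.5].
    smoothness : spherical-harmonic band limit of the noise field; higher
        means finer (but still smooth) surface detail.
    seed : RNG seed; a fixed seed yields a bitwise-identical mesh.
    """

    base_radii: tuple[float, float, float] = (0.14, 0.10, 0.08)
    lobe_count: int = 2
    bump_amplitude: float = 0.15
    smoothness: int = 6
    seed: int = 0

    def __post_init__(self):
        if any(r <= 0 for r in self.base_radii):
            raise ValueError("base_radii must be positive")
        if not 0.0 <= self.bump_amplitude <= 0.5:
            raise ValueError("bump_amplitude must lie in [0, 0.5]")


def _sh_noise(dirs: np.ndarray, band_limit: int, rng: np.random.Generator) -> np.ndarray:
    """Band-limited random scalar field on the unit sphere, max|.| = 1."""
    theta = np.arccos(np.clip(dirs[:, 2], -1.0, 1.0))  # polar
    phi = np.arctan2(dirs[:, 1], dirs[:, 0])           # azimuth
    f = np.zeros(len(dirs))
    for ell in range(2, band_limit + 1):
        decay = (1.0 + ell) ** -1.5
        for m in range(0, ell + 1):
            y = sph_harm_y(ell, m, theta, phi)
            f += decay * rng.normal() * y.real
            if m > 0:
                f += decay * rng.normal() * y.imag
    peak = np.abs(f).max()
    return f / peak if peak > 0 else f


def generate_organ(spec: OrganShapeSpec = OrganShapeSpec(), faces: int = 5120) -> SurfaceMesh:
    """Generate a watertight, outward-oriented organ surface.

    The icosphere subdivision level is chosen to reach at least ``faces``
    triangles (icospheres have 20 * 4**s faces). With ``bump_amplitude``
    0 the result is exactly the base ellipsoid.
    """
    rng = np.random.default_rng(spec.seed)
    sub = max(1, math.ceil(math.log(max(faces, 20) / 20.0, 4.0)))
    ico = trimesh.creation.icosphere(subdivisions=sub)
    dirs = np.asarray(ico.vertices)
    dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)

    band = spec.smoothness
    min_band = 2 + (spec.lobe_count > 0)
    if band < min_band:
        warnings.warn(
            f"spherical-harmonic band limit {band} too low to resolve "
            f"{spec.lobe_count} lobes; clamped to {min_band}", stacklevel=2)
        band = min_band

    bump = np.zeros(len(dirs))
    if spec.bump_amplitude > 0:
        bump += 0.6 * _sh_noise(dirs, band, rng)
        for _ in range(spec.lobe_count):
            center = rng.normal(size=3)
            center /= np.linalg.norm(center)
            ang = np.arccos(np.clip(dirs @ center, -1.0, 1.0))
            bump += 0.8 * np.exp(-(ang / 0.6) ** 2)
        peak = np.abs(bump).max()
        if peak > 0:
            bump = spec.bump_amplitude * bump / peak

    radii = np.asarray(spec.base_radii)
    vertices = dirs * radii * (1.0 + bump)[:, None]
    return SurfaceMesh(vertices, np.asarray(ico.faces))
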