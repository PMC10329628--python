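"""Synthetic training-data generation and grid encodings.

Each training sample couples one random attachment region (the Dirichlet
node set, 5-50% of the surface) with F simulated manipulations: a random
force applied over a small random surface patch, solved to equilibrium,
and observed as a partial deformed surface (10-100% of surface nodes,
seen from a fixed virtual camera). The F deformed partial surfaces are
encoded as normalized distance fields DF_1..DF_F on the embedding grid;
the attachment is encoded as a binary voxel mask M through the one-to-one
node-voxel correspondence. Samples whose simulation fails to converge or
whose maximal nodal displacement exceeds 0.3 m are rejected and redrawn.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import trimesh
from scipy import ndimage

from .fe_solver import BoundaryConditions, HexFE, Material, SolveOptions, SolveResult
from .geometry import HexModel, RegularGrid, SurfaceMesh, fit_grid, signed_distance_field

__all__ = [
    "AttachmentRegion",
    "ForceSpec",
    "FrameRecord",
    "SampleRecord",
    "GridTensor",
    "DatasetConfig",
    "sample_attachment",
    "sample_force",
    "extract_visible_surface",
    "encode",
    "encode_pointclouds",
    "encode_legacy",
    "decode_mask",
    "generate_dataset",
    "load_dataset",
    "load_pointcloud",
]

MAX_L2_DISPLACEMENT = 0.3  # m; samples above this cap are discarded


@dataclass(frozen=True)
class AttachmentRegion:
    nodes: np.ndarray      # surface-node indices fixed to zero displacement
    coverage: float        # fraction of surface nodes
    seed_node: int


@dataclass(frozen=True)
class ForceSpec:
    patch_nodes: np.ndarray  # loaded surface nodes
    direction: np.ndarray    # unit vector
    magnitude: float         # total force (N), split uniformly over the patch

    def loads(self) -> dict[int, np.ndarray]:
        per = self.direction * (self.magnitude / len(self.patch_nodes))
        return {int(n): per for n in self.patch_nodes}


@dataclass
class FrameRecord:
    force: ForceSpec
    result: SolveResult
    visible_nodes: np.ndarray
    visible_coverage: float


@dataclass
class SampleRecord:
    attachment: AttachmentRegion
    frames: list[FrameRecord]

    @property
    def F(self) -> int:
        return len(self.frames)


@dataclass
class GridTensor:
    """F normalized distance fields plus the binary attachment mask, all
    of shape (nx, ny, nz)."""

    df: np.ndarray    # (F, nx, ny, nz), in [0, 1]
    mask: np.ndarray  # (nx, ny, nz), values {0, 1}


def _grow_region(positions: np.ndarray, pool: np.ndarray, seed_idx: int,
                 count: int, eta: float, rng: np.random.Generator) -> np.ndarray:
    """Pick `count` nodes from `pool` with the lowest distance-plus-noise
    score relative to the seed node: score_i = |x_i - x_seed| + eta u_i,
    u_i ~ U(0,1). With eta = 0 this is exact nearest-neighbor growth."""
    d = np.linalg.norm(positions[pool] - positions[seed_idx], axis=1)
    score = d + eta * rng.uniform(size=len(pool))
    return pool[np.argsort(score, kind="stable")[:count]]


def _organ_diameter(model: HexModel) -> float:
    p = model.nodes[model.surface_nodes]
    return float(np.linalg.norm(p.max(0) - p.min(0)))


def sample_attachment(model: HexModel, coverage_range: tuple[float, float] = (0.05, 0.50),
                      rng: np.random.Generator | None = None,
                      noise_eta: float | None = None) -> AttachmentRegion:
    """Random attachment region: an irregular patch around a random surface
    node covering a uniform fraction of the surface nodes."""
    rng = np.random.default_rng() if rng is None else rng
    surf = model.surface_nodes
    if len(surf) == 0:
        raise ValueError("model has no surface nodes")
    cov = rng.uniform(*coverage_range)
    k = max(1, round(cov * len(surf)))
    seed = int(surf[rng.integers(len(surf))])
    eta = 0.3 * _organ_diameter(model) if noise_eta is None else noise_eta
    nodes = _grow_region(model.nodes, surf, seed, k, eta, rng)
    return AttachmentRegion(nodes=np.sort(nodes), coverage=k / len(surf), seed_node=seed)


def sample_force(model: HexModel, attachment: AttachmentRegion | np.ndarray,
                 rng: np.random.Generator | None = None,
                 patch_range: tuple[float, float] = (0.01, 0.05),
                 magnitude_range: tuple[float, float] = (0.5, 30.0),
                 noise_eta: float | None = None) -> ForceSpec:
    """Random manipulation force: uniform direction on the sphere, total
    magnitude uniform in `magnitude_range`, spread over a small random
    surface patch disjoint from the attachment (an AttachmentRegion or a
    plain node-index array)."""
    rng = np.random.default_rng() if rng is None else rng
    att_nodes = attachment.nodes if isinstance(attachment, AttachmentRegion) \
        else np.asarray(attachment, dtype=np.int64)
    surf = model.surface_nodes
    free = np.setdiff1d(surf, att_nodes)
    if len(free) == 0:
        raise ValueError("attachment covers the whole surface; no node to load")
    cov = rng.uniform(*patch_range)
    k = min(max(1, round(cov * len(surf))), len(free))
    seed = int(free[rng.integers(len(free))])
    eta = 0.3 * _organ_diameter(model) if noise_eta is None else noise_eta
    patch = _grow_region(model.nodes, free, seed, k, eta, rng)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    magnitude = float(rng.uniform(*magnitude_range))
    return ForceSpec(patch_nodes=np.sort(patch), direction=direction, magnitude=magnitude)


def extract_visible_surface(model: HexModel, deformed: np.ndarray,
                            camera_dir: np.ndarray = np.array([0.0, 0.0, 1.0]),
                            coverage_range: tuple[float, float] = (0.10, 1.00),
                            rng: np.random.Generator | None = None,
                            noise_eta: float | None = None) -> np.ndarray:
    """Surface nodes visible from a fixed virtual camera looking along
    ``camera_dir``, grown to a random target coverage.

    Candidate nodes lie on boundary quads whose deformed outward normal
    faces the camera (normal . camera_dir < 0) and survive a voxel
    z-buffer occlusion test along the view direction. A contiguous-ish
    region is grown inside the candidates with the distance-plus-noise
    metric; if the target exceeds the candidate count the whole candidate
    set is returned.
    """
    rng = np.random.default_rng() if rng is None else rng
    camera_dir = np.asarray(camera_dir, float)
    camera_dir = camera_dir / np.linalg.norm(camera_dir)
    quads = model.surface_faces
    p = deformed[quads]  # (Q, 4, 3)
    normals = np.cross(p[:, 2] - p[:, 0], p[:, 3] - p[:, 1])  # outward quad normal
    facing = quads[normals @ camera_dir < 0.0]
    cand = np.unique(facing)
    if len(cand) == 0:
        raise ValueError("no camera-facing surface found")

    # voxel z-buffer over all surface nodes, bins transverse to the camera
    h = model.grid.spacing
    ez = camera_dir
    ex = np.cross(ez, [1.0, 0.0, 0.0])
    if np.linalg.norm(ex) < 1e-8:
        ex = np.cross(ez, [0.0, 1.0, 0.0])
    ex /= np.linalg.norm(ex)
    ey = np.cross(ez, ex)
    allsurf = model.surface_nodes
    uv = np.round(deformed[allsurf] @ np.stack([ex, ey]).T / h).astype(np.int64)
    depth = deformed[allsurf] @ ez
    bins: dict[tuple[int, int], list[int]] = {}
    for i, key in enumerate(map(tuple, uv)):
        bins.setdefault(key, []).append(i)
    idx = {int(n): i for i, n in enumerate(allsurf)}

    def occluded(n: int) -> bool:
        i = idx[int(n)]
        others = np.asarray(bins[tuple(uv[i])])
        gap = depth[i] - depth[others]
        # a genuine occluder is clearly nearer the camera AND far away in
        # 3D; nearby blockers are the node's own staircase wall, which
        # must not self-occlude the voxelized surface of a smooth organ
        far = np.linalg.norm(deformed[allsurf[others]] - deformed[allsurf[i]],
                             axis=1) > 3.0 * h
        return bool(np.any((gap > 1.5 * h) & far))

    cand = cand[~np.array([occluded(n) for n in cand])]
    if len(cand) == 0:
        raise ValueError("all camera-facing nodes occluded")

    cov = rng.uniform(*coverage_range)
    target = max(1, round(cov * len(allsurf)))
    if target >= len(cand):
        return np.sort(cand)
    seed = int(cand[rng.integers(len(cand))])
    eta = 0.3 * _organ_diameter(model) if noise_eta is None else noise_eta
    return np.sort(_grow_region(deformed, cand, seed, target, eta, rng))


# ---------------------------------------------------------------------------
# Grid encodings
# ---------------------------------------------------------------------------

def _distance_field(points: np.ndarray, grid: RegularGrid) -> np.ndarray:
    """Normalized distance field of a voxelized point cloud: points are
    snapped to their containing voxel, and each voxel carries the distance
    from its center to the nearest occupied voxel center, divided by the
    grid bounding-box diagonal. Exactly 0 in occupied voxels."""
    occ = np.zeros(grid.dims, dtype=bool)
    ijk = grid.point_to_voxel(points)
    occ[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = True
    d = ndimage.distance_transform_edt(~occ, sampling=grid.spacing)
    return (d / grid.diagonal).astype(np.float64)


def encode(sample: SampleRecord, model: HexModel, grid: RegularGrid | None = None) -> GridTensor:
    """Encode one sample: DF_i from the deformed visible surface of frame i
    (positions, not displacements) and the binary attachment mask M."""
    grid = model.grid if grid is None else grid
    dfs = []
    for fr in sample.frames:
        if len(fr.visible_nodes) == 0:
            raise ValueError("empty visible surface cannot be encoded")
        pos = model.nodes[fr.visible_nodes] + fr.result.displacements[fr.visible_nodes]
        dfs.append(_distance_field(pos, grid))
    mask = np.zeros(grid.dims, dtype=np.uint8)
    v = model.node_to_voxel[sample.attachment.nodes]
    mask[v[:, 0], v[:, 1], v[:, 2]] = 1
    return GridTensor(df=np.stack(dfs), mask=mask)


def encode_pointclouds(clouds: list[np.ndarray], grid: RegularGrid) -> np.ndarray:
    """Inference-time encoding of F acquired (pre-aligned) point clouds as
    stacked normalized distance fields."""
    return np.stack([_distance_field(np.asarray(c, float), grid) for c in clouds])


def decode_mask(mask: np.ndarray, model: HexModel) -> np.ndarray:
    """Invert the mask encoding: the surface nodes whose voxel is set."""
    v = model.node_to_voxel[model.surface_nodes]
    on = mask[v[:, 0], v[:, 1], v[:, 2]].astype(bool)
    return model.surface_nodes[on]


def _legacy_splat(rest_nodes: np.ndarray, displacements: np.ndarray,
                  visible_nodes: np.ndarray, legacy_grid: RegularGrid,
                  sdf: np.ndarray) -> np.ndarray:
    """Gaussian-splat the visible nodes' displacement vectors onto the
    grid (sigma = 1 cell, unit kernel mass per node) and append the
    rest-geometry SDF channel: shape (4, gx, gy, gz). Displacement and
    SDF channels are normalized by the grid diagonal so all input
    encodings share the scale of the distance fields."""
    vis = np.asarray(visible_nodes, dtype=np.int64)
    if len(vis) == 0:
        raise ValueError("empty visible surface cannot be encoded")
    disp = displacements[vis] / legacy_grid.diagonal
    out = np.zeros((4,) + legacy_grid.dims)
    centers = legacy_grid.voxel_centers()
    h = legacy_grid.spacing
    rad = 3  # kernel support radius in cells (3 sigma)
    dims = np.asarray(legacy_grid.dims)
    ijk0 = legacy_grid.point_to_voxel(rest_nodes[vis])
    offs = np.stack(np.meshgrid(*([np.arange(-rad, rad + 1)] * 3), indexing="ij"),
                    axis=-1).reshape(-1, 3)
    for n in range(len(vis)):
        cells = ijk0[n] + offs
        ok = np.all((cells >= 0) & (cells < dims), axis=1)
        cells = cells[ok]
        c = centers[cells[:, 0], cells[:, 1], cells[:, 2]]
        w = np.exp(-np.sum((c - rest_nodes[vis[n]]) ** 2, axis=1) / (2.0 * h ** 2))
        w /= w.sum()
        for comp in range(3):
            out[comp, cells[:, 0], cells[:, 1], cells[:, 2]] += w * disp[n, comp]
    out[3] = sdf / legacy_grid.diagonal
    return out


def encode_legacy(sample: SampleRecord, model: HexModel, mesh: SurfaceMesh,
                  legacy_grid: RegularGrid, frame: int = 0,
                  sdf: np.ndarray | None = None) -> np.ndarray:
    """Input tensor of the displacement-based network variant: the three
    displacement components of the visible nodes splatted onto the grid
    with a Gaussian kernel (sigma = 1 cell, kernel mass 1 per node), plus
    the signed distance field of the rest geometry: shape (4, gx, gy, gz).

    The canonical grid for this variant is 64^3; any resolution is
    accepted so reduced-scale comparisons stay affordable.
    """
    fr = sample.frames[frame]
    if sdf is None:
        sdf = signed_distance_field(mesh, legacy_grid)
    return _legacy_splat(model.nodes, fr.result.displacements, fr.visible_nodes,
                         legacy_grid, sdf)


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DatasetConfig:
    n_samples: int = 100
    frames: int = 3
    grid_dims: tuple[int, int, int] = (31, 32, 26)
    attachment_coverage: tuple[float, float] = (0.05, 0.50)
    visible_coverage: tuple[float, float] = (0.10, 1.00)
    # measured on the default organ at E = 5 kPa: 0.5 N deforms by a few
    # mm, 30 N reaches 0.1-0.4 m, so the 0.3 m stability cap is operative
    force_patch_coverage: tuple[float, float] = (0.01, 0.05)
    force_magnitude: tuple[float, float] = (0.5, 30.0)
    camera_dir: tuple[float, float, float] = (0.0, 0.0, 1.0)
    material: Material = field(default_factory=Material)
    solver: SolveOptions = field(default_factory=lambda: SolveOptions(n_steps=2))
    seed: int = 0
    max_rejection_window: int = 100  # abort if >95% rejected over this window


def _simulate_sample(model: HexModel, fe: HexFE, cfg: DatasetConfig,
                     rng: np.random.Generator) -> SampleRecord | None:
    """Draw and simulate one candidate sample; None if any stability
    filter rejects it (non-convergence or displacement cap)."""
    att = sample_attachment(model, cfg.attachment_coverage, rng)
    frames: list[FrameRecord] = []
    used: list[ForceSpec] = []
    for _ in range(cfg.frames):
        for _ in range(20):  # frames must differ in patch AND magnitude
            force = sample_force(model, att, rng, cfg.force_patch_coverage,
                                 cfg.force_magnitude)
            if all(force.magnitude != o.magnitude
                   or set(force.patch_nodes) != set(o.patch_nodes) for o in used):
                break
        used.append(force)
        bcs = BoundaryConditions(fixed_nodes=att.nodes, loads=force.loads())
        try:
            res = fe.solve(bcs, cfg.solver)
        except (ValueError, FloatingPointError):
            return None
        if not res.converged or res.max_displacement > MAX_L2_DISPLACEMENT:
            return None
        deformed = model.nodes + res.displacements
        vis = extract_visible_surface(model, deformed, np.asarray(cfg.camera_dir),
                                      cfg.visible_coverage, rng)
        frames.append(FrameRecord(force=force, result=res, visible_nodes=vis,
                                  visible_coverage=len(vis) / len(model.surface_nodes)))
    return SampleRecord(attachment=att, frames=frames)


def generate_dataset(mesh: SurfaceMesh, cfg: DatasetConfig, out_path: str | Path,
                     model: HexModel | None = None) -> dict:
    """Generate exactly ``cfg.n_samples`` valid samples and store them,
    with their encodings, in an HDF5 file. Returns a small summary dict
    (kept/rejected counts, model sizes).

    Rejected draws (solver non-convergence or >0.3 m displacement) are
    resampled; generation is deterministic for a fixed ``cfg.seed``.
    """
    if model is None:
        grid = fit_grid(mesh, cfg.grid_dims)
        from .geometry import voxelize
        model = voxelize(mesh, grid)
    fe = HexFE(model, cfg.material)
    rng = np.random.default_rng(cfg.seed)
    rejected = 0
    window: list[bool] = []

    with h5py.File(str(out_path), "w") as f:
        f.attrs["config"] = json.dumps({
            "n_samples": cfg.n_samples, "frames": cfg.frames,
            "grid_dims": list(cfg.grid_dims), "seed": cfg.seed,
            "attachment_coverage": list(cfg.attachment_coverage),
            "visible_coverage": list(cfg.visible_coverage),
            "force_patch_coverage": list(cfg.force_patch_coverage),
            "force_magnitude": list(cfg.force_magnitude),
            "camera_dir": list(cfg.camera_dir),
            "young_modulus": cfg.material.young_modulus,
            "poisson_ratio": cfg.material.poisson_ratio,
        })
        f.attrs["grid_origin"] = model.grid.origin
        f.attrs["grid_spacing"] = model.grid.spacing
        f.attrs["grid_dims"] = model.grid.dims
        kept = 0
        while kept < cfg.n_samples:
            rec = _simulate_sample(model, fe, cfg, rng)
            window.append(rec is None)
            if len(window) > cfg.max_rejection_window:
                window.pop(0)
            if rec is None:
                rejected += 1
                if (len(window) == cfg.max_rejection_window
                        and np.mean(window) > 0.95):
                    raise RuntimeError(
                        f"rejection rate {np.mean(window):.0%} over the last "
                        f"{cfg.max_rejection_window} attempts; loosen the force "
                        "range or check the model")
                continue
            tensor = encode(rec, model)
            g = f.create_group(f"samples/{kept}")
            kw = dict(track_times=False)
            g.create_dataset("df", data=tensor.df.astype(np.float32), **kw)
            g.create_dataset("mask", data=tensor.mask, **kw)
            g.create_dataset("attachment_nodes", data=rec.attachment.nodes, **kw)
            g.attrs["attachment_coverage"] = rec.attachment.coverage
            g.attrs["attachment_seed_node"] = rec.attachment.seed_node
            for i, fr in enumerate(rec.frames):
                gf = g.create_group(f"frames/{i}")
                gf.create_dataset("patch_nodes", data=fr.force.patch_nodes, **kw)
                gf.create_dataset("direction", data=fr.force.direction, **kw)
                gf.attrs["magnitude"] = fr.force.magnitude
                gf.create_dataset("displacements",
                                  data=fr.result.displacements.astype(np.float32), **kw)
                gf.create_dataset("visible_nodes", data=fr.visible_nodes, **kw)
                gf.attrs["visible_coverage"] = fr.visible_coverage
                gf.attrs["converged"] = bool(fr.result.converged)
                gf.attrs["max_displacement"] = fr.result.max_displacement
            kept += 1
    return {"kept": kept, "rejected": rejected,
            "n_nodes": model.n_nodes, "n_cells": model.n_cells}


def load_dataset(path: str | Path):
    """Load a generated dataset: (df (N, F, nx, ny, nz) float32,
    masks (N, nx, ny, nz) uint8, meta dict)."""
    with h5py.File(str(path), "r") as f:
        n = len(f["samples"])
        dfs, masks = [], []
        for i in range(n):
            dfs.append(f[f"samples/{i}/df"][()])
            masks.append(f[f"samples/{i}/mask"][()])
        meta = json.loads(f.attrs["config"])
        meta["grid_origin"] = np.asarray(f.attrs["grid_origin"])
        meta["grid_spacing"] = float(f.attrs["grid_spacing"])
    return np.stack(dfs), np.stack(masks), meta


def load_pointcloud(path: str | Path) -> np.ndarray:
    """Read a PLY/XYZ point cloud as an (n, 3) array (meters)."""
    path = Path(path)
    if path.suffix.lower() == ".xyz":
        return np.loadtxt(path, usecols=(0, 1, 2), ndmin=2)
    obj = trimesh.load(str(path))
    return np.asarray(obj.vertices, dtype=np.float64)


def file_digest(path: str | Path) -> str:
    """SHA-256 of a file, for reproducibility checks."""
    hsh = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            hsh.update(chunk)
    return hsh.hexdigest()
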