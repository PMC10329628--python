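"""Surface meshes, regular grids, and hexahedral FE models.

The deformable organ is represented by a closed triangulated surface
(meters). For simulation and for the voxel encodings consumed by the
network, the surface is embedded in a regular grid of cubic cells; the
cells inside the organ or overlapping its boundary form a hexahedral
finite-element mesh whose nodes are grid lattice points, giving a
one-to-one correspondence between FE nodes and grid voxels.

Conventions: cells are addressed by 0-based integer triples ``(i, j, k)``
with x fastest when flattened; all positions are in meters; scalar fields
on the grid are arrays of shape ``(nx, ny, nz)`` indexed ``[i, j, k]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy.spatial import cKDTree

__all__ = [
    "SurfaceMesh",
    "RegularGrid",
    "HexModel",
    "fit_grid",
    "voxelize",
    "signed_distance_field",
    "winding_number",
    "point_surface_distance",
    "write_vtk_hex",
]

# Local node offsets of a hexahedron in VTK ordering (bottom quad CCW,
# then top quad), used both for meshing and for VTK export.
HEX_OFFSETS = np.array(
    [
        [0, 0, 0],
        [1, 0, 0],
        [1, 1, 0],
        [0, 1, 0],
        [0, 0, 1],
        [1, 0, 1],
        [1, 1, 1],
        [0, 1, 1],
    ],
    dtype=np.int64,
)

# The 6 quad faces of a hex, as indices into HEX_OFFSETS, outward order.
HEX_FACES = np.array(
    [
        [0, 3, 2, 1],  # -z
        [4, 5, 6, 7],  # +z
        [0, 1, 5, 4],  # -y
        [2, 3, 7, 6],  # +y
        [0, 4, 7, 3],  # -x
        [1, 2, 6, 5],  # +x
    ],
    dtype=np.int64,
)


@dataclass(frozen=True)
class SurfaceMesh:
    """Closed, consistently oriented triangulated organ boundary.

    Parameters
    ----------
    vertices : (V, 3) float array, positions in meters.
    faces : (F, 3) int array of vertex-index triples, outward oriented.
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "vertices", np.asarray(self.vertices, dtype=np.float64))
        object.__setattr__(self, "faces", np.asarray(self.faces, dtype=np.int64))
        tm = self.to_trimesh()
        if not tm.is_watertight:
            raise ValueError("surface mesh is not watertight")
        if tm.volume <= 0:
            raise ValueError("surface mesh has non-positive enclosed volume "
                             "(normals inconsistently oriented?)")

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)

    @classmethod
    def load(cls, path: str | Path) -> "SurfaceMesh":
        """Read an STL/OBJ/PLY surface mesh."""
        tm = trimesh.load_mesh(str(path), process=True)
        if tm.volume < 0:
            tm.invert()
        return cls(np.asarray(tm.vertices), np.asarray(tm.faces))

    def save(self, path: str | Path) -> None:
        self.to_trimesh().export(str(path))

    @property
    def vertex_normals(self) -> np.ndarray:
        return np.asarray(self.to_trimesh().vertex_normals)

    @property
    def bounds(self) -> np.ndarray:
        """(2, 3) min/max corner of the axis-aligned bounding box."""
        return np.vstack([self.vertices.min(0), self.vertices.max(0)])

    @property
    def extent(self) -> np.ndarray:
        b = self.bounds
        return b[1] - b[0]

    @property
    def diameter(self) -> float:
        """Bounding-box diagonal, the characteristic organ size."""
        return float(np.linalg.norm(self.extent))

    @property
    def volume(self) -> float:
        return float(self.to_trimesh().volume)


@dataclass(frozen=True)
class RegularGrid:
    """Axis-aligned grid of cubic cells: ``dims`` cells of edge ``spacing``
    starting at ``origin`` (the min corner)."""

    origin: np.ndarray
    spacing: float
    dims: tuple[int, int, int]

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=np.float64))
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if any(d < 2 for d in self.dims):
            raise ValueError("grid needs at least 2 cells per axis")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.dims

    @property
    def max_corner(self) -> np.ndarray:
        return self.origin + self.spacing * np.asarray(self.dims)

    @property
    def diagonal(self) -> float:
        """Bounding-box diagonal (m), used to normalize distance fields."""
        return float(self.spacing * np.linalg.norm(self.dims))

    def voxel_centers(self) -> np.ndarray:
        """(nx, ny, nz, 3) array of cell-center positions."""
        axes = [self.origin[a] + self.spacing * (np.arange(self.dims[a]) + 0.5)
                for a in range(3)]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.stack([gx, gy, gz], axis=-1)

    def point_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Map points to containing-cell (i, j, k), clipped to the grid."""
        ijk = np.floor((np.atleast_2d(points) - self.origin) / self.spacing).astype(np.int64)
        return np.clip(ijk, 0, np.asarray(self.dims) - 1)

    def contains_mesh(self, mesh: SurfaceMesh, margin_cells: float = 0.0) -> bool:
        pad = margin_cells * self.spacing
        b = mesh.bounds
        return bool(np.all(b[0] >= self.origin + pad) and np.all(b[1] <= self.max_corner - pad))


@dataclass
class HexModel:
    """Grid-embedded hexahedral FE mesh with grid correspondence.

    ``node_to_voxel`` maps each node to the grid voxel sharing its lattice
    index; it is injective because the grid carries a one-cell margin
    around the organ, so node lattice indices never reach ``dims``.
    """

    grid: RegularGrid
    nodes: np.ndarray          # (N, 3) rest positions (m)
    hexes: np.ndarray          # (E, 8) node indices, VTK ordering
    kept_cells: np.ndarray     # (E, 3) grid cell (i, j, k)
    surface_nodes: np.ndarray  # (S,) node indices on the retained boundary
    node_to_voxel: np.ndarray  # (N, 3) voxel (i, j, k) per node
    surface_faces: np.ndarray = field(default=None)  # (Q, 4) boundary quads

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_cells(self) -> int:
        return len(self.hexes)

    def voxel_flat(self, ijk: np.ndarray) -> np.ndarray:
        """Flatten (i, j, k) voxel triples x-fastest."""
        nx, ny, _ = self.grid.dims
        ijk = np.atleast_2d(ijk)
        return ijk[:, 0] + nx * (ijk[:, 1] + ny * ijk[:, 2])

    def surface_node_mask(self) -> np.ndarray:
        m = np.zeros(self.n_nodes, dtype=bool)
        m[self.surface_nodes] = True
        return m

    def surface_voxel_field(self) -> np.ndarray:
        """Binary (nx, ny, nz) field marking voxels mapped from surface nodes."""
        f = np.zeros(self.grid.dims, dtype=bool)
        v = self.node_to_voxel[self.surface_nodes]
        f[v[:, 0], v[:, 1], v[:, 2]] = True
        return f


def fit_grid(mesh: SurfaceMesh, target_dims: tuple[int, int, int] = (31, 32, 26)) -> RegularGrid:
    """Fit a regular grid of cubic cells around a surface mesh.

    A single spacing is used for all axes (the grid cell is the FE element,
    so cells must be cubes); it is the smallest spacing for which every
    axis fits its requested cell count with at least one empty cell of
    margin on each side. The grid therefore overhangs the organ on the
    shorter axes.
    """
    dims = tuple(int(d) for d in target_dims)
    if any(d < 2 for d in dims):
        raise ValueError("need at least 2 cells per axis")
    extent = mesh.extent
    if np.any(extent <= 0):
        raise ValueError("degenerate mesh: zero extent on some axis")
    # tiny inflation keeps the margin strictly > 1 cell on the tightest
    # axis, so boundary triangles never touch the outermost cell layer;
    # axes with < 4 cells cannot carry full margins and only guarantee
    # containment (such grids are not meant for FE meshing)
    spacing = float(max(extent[a] / max(dims[a] - 2, 1) for a in range(3))) * (1.0 + 1e-6)
    center = mesh.bounds.mean(axis=0)
    origin = center - 0.5 * spacing * np.asarray(dims)
    return RegularGrid(origin=origin, spacing=spacing, dims=dims)


# ---------------------------------------------------------------------------
# Inside / distance queries (winding number, point-triangle distance)
# ---------------------------------------------------------------------------

def winding_number(mesh: SurfaceMesh, points: np.ndarray, chunk: int = 2048) -> np.ndarray:
    """Generalized winding number of each point w.r.t. the closed surface.

    ~1 inside, ~0 outside for a watertight, outward-oriented mesh. Computed
    from the summed signed solid angles of the triangles (van Oosterom &
    Strackee formula), vectorized in chunks of points.
    """
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    tv = mesh.vertices[mesh.faces]  # (T, 3, 3)
    out = np.empty(len(points))
    for s in range(0, len(points), chunk):
        p = points[s:s + chunk]
        a = tv[None, :, 0] - p[:, None]  # (P, T, 3)
        b = tv[None, :, 1] - p[:, None]
        c = tv[None, :, 2] - p[:, None]
        la = np.linalg.norm(a, axis=-1)
        lb = np.linalg.norm(b, axis=-1)
        lc = np.linalg.norm(c, axis=-1)
        num = np.einsum("ptk,ptk->pt", a, np.cross(b, c))
        den = (la * lb * lc + np.einsum("ptk,ptk->pt", a, b) * lc
               + np.einsum("ptk,ptk->pt", b, c) * la
               + np.einsum("ptk,ptk->pt", c, a) * lb)
        out[s:s + chunk] = np.arctan2(num, den).sum(axis=1) / (2.0 * np.pi)
    return out


def _point_tri_distance_pairs(pts: np.ndarray, tris: np.ndarray) -> np.ndarray:
    """Distance for paired points (P,3) and triangles (P,3,3)."""
    a, b, c = tris[:, 0], tris[:, 1], tris[:, 2]
    n = np.cross(b - a, c - a)
    nn = np.einsum("ij,ij->i", n, n)
    nn = np.where(nn == 0, 1.0, nn)
    # barycentric coordinates of the in-plane projection
    ap = pts - a
    d_plane = np.einsum("ij,ij->i", ap, n) / np.sqrt(nn)
    w = np.einsum("ij,ij->i", np.cross(b - a, ap), n) / nn  # weight of c
    v = np.einsum("ij,ij->i", np.cross(ap, c - a), n) / nn  # weight of b
    u = 1.0 - v - w
    inside = (u >= 0) & (v >= 0) & (w >= 0)

    def seg_dist(p, s0, s1):
        d = s1 - s0
        t = np.einsum("ij,ij->i", p - s0, d) / np.maximum(
            np.einsum("ij,ij->i", d, d), 1e-300)
        t = np.clip(t, 0.0, 1.0)
        return np.linalg.norm(p - (s0 + t[:, None] * d), axis=1)

    edge = np.minimum.reduce([seg_dist(pts, a, b), seg_dist(pts, b, c),
                              seg_dist(pts, c, a)])
    return np.where(inside, np.abs(d_plane), edge)


def point_surface_distance(mesh: SurfaceMesh, points: np.ndarray) -> np.ndarray:
    """Exact unsigned Euclidean distance from each point to the surface.

    A KD-tree over a dense surface sampling gives a tight upper bound per
    point; only triangles whose centroid can beat that bound are tested
    exactly.
    """
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    tv = mesh.vertices[mesh.faces]
    centroids = tv.mean(axis=1)
    # dense sampling: vertices, centroids, edge midpoints -> upper bound
    samples = np.vstack([mesh.vertices, centroids,
                         0.5 * (tv[:, 0] + tv[:, 1]),
                         0.5 * (tv[:, 1] + tv[:, 2]),
                         0.5 * (tv[:, 2] + tv[:, 0])])
    ub = cKDTree(samples).query(points)[0]
    r_tri = np.linalg.norm(tv - centroids[:, None], axis=-1).max()
    ctree = cKDTree(centroids)
    cand = ctree.query_ball_point(points, ub + r_tri + 1e-12)
    pi = np.concatenate([np.full(len(c), i) for i, c in enumerate(cand)])
    ti = np.concatenate([np.asarray(c, dtype=np.int64) for c in cand])
    d = _point_tri_distance_pairs(points[pi], tv[ti])
    out = np.full(len(points), np.inf)
    np.minimum.at(out, pi, d)
    return out


def signed_distance_field(mesh: SurfaceMesh, grid: RegularGrid) -> np.ndarray:
    """Signed Euclidean distance from each voxel center to the surface,
    negative inside the organ. Requires a watertight mesh (the sign comes
    from the winding number)."""
    centers = grid.voxel_centers().reshape(-1, 3)
    d = point_surface_distance(mesh, centers)
    inside = winding_number(mesh, centers) > 0.5
    return np.where(inside, -d, d).reshape(grid.dims)


# ---------------------------------------------------------------------------
# Voxelization
# ---------------------------------------------------------------------------

def _tri_box_overlap(tris: np.ndarray, box_centers: np.ndarray, half: float) -> np.ndarray:
    """Separating-axis triangle/axis-aligned-cube overlap test for paired
    triangles (P,3,3) and cube centers (P,3) of half-edge ``half``."""
    v = tris - box_centers[:, None, :]  # (P, 3, 3) triangle in box frame
    sep = np.zeros(len(tris), dtype=bool)

    # box face normals: triangle AABB vs box
    sep |= np.any((v.min(axis=1) > half) | (v.max(axis=1) < -half), axis=1)

    # triangle normal
    e = np.stack([v[:, 1] - v[:, 0], v[:, 2] - v[:, 1], v[:, 0] - v[:, 2]], axis=1)
    n = np.cross(e[:, 0], e[:, 1])
    d = np.einsum("ij,ij->i", n, v[:, 0])
    r = half * np.abs(n).sum(axis=1)
    sep |= np.abs(d) > r + 1e-12

    # 9 cross-product axes  a = e_i x axis_j
    for i in range(3):
        for j in range(3):
            ax = np.zeros((len(tris), 3))
            ej = e[:, i]
            # cross(ej, unit_j)
            ax[:, (j + 1) % 3] = ej[:, (j + 2) % 3]
            ax[:, (j + 2) % 3] = -ej[:, (j + 1) % 3]
            proj = np.einsum("pk,pvk->pv", ax, v)
            r = half * np.abs(ax).sum(axis=1)
            sep |= (proj.min(axis=1) > r + 1e-12) | (proj.max(axis=1) < -r - 1e-12)
    return ~sep


def voxelize(mesh: SurfaceMesh, grid: RegularGrid) -> HexModel:
    """Embed the surface in the grid and keep the cells inside the organ or
    overlapping its boundary; build the hexahedral FE mesh on them.

    Nodes shared by adjacent kept cells are deduplicated; surface nodes are
    the nodes on quad faces not shared by two kept cells.
    """
    nx, ny, nz = grid.dims
    dims = np.array(grid.dims)

    def cell_centers(ijk):
        return grid.origin + grid.spacing * (ijk + 0.5)

    inside = np.zeros(grid.dims, dtype=bool)
    # restrict the (costly) winding-number test to cells near the mesh bbox
    b = mesh.bounds
    lo = np.maximum(np.floor((b[0] - grid.origin) / grid.spacing).astype(int) - 1, 0)
    hi = np.minimum(np.ceil((b[1] - grid.origin) / grid.spacing).astype(int) + 1, dims)
    ii, jj, kk = np.meshgrid(*[np.arange(lo[a], hi[a]) for a in range(3)], indexing="ij")
    near = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    if len(near):
        w = winding_number(mesh, cell_centers(near))
        inside[near[:, 0], near[:, 1], near[:, 2]] = w > 0.5

    # cells overlapping the boundary: SAT per (triangle, candidate cell) pair
    tv = mesh.vertices[mesh.faces]
    overlap = np.zeros(grid.dims, dtype=bool)
    pair_t, pair_c = [], []
    for t in range(len(tv)):
        tlo = np.maximum(np.floor((tv[t].min(0) - grid.origin) / grid.spacing).astype(int), 0)
        thi = np.minimum(np.floor((tv[t].max(0) - grid.origin) / grid.spacing).astype(int) + 1, dims)
        if np.any(thi <= tlo):
            continue
        ci, cj, ck = np.meshgrid(*[np.arange(tlo[a], thi[a]) for a in range(3)], indexing="ij")
        cand = np.stack([ci.ravel(), cj.ravel(), ck.ravel()], axis=1)
        pair_t.append(np.full(len(cand), t))
        pair_c.append(cand)
    if pair_t:
        pair_t = np.concatenate(pair_t)
        pair_c = np.concatenate(pair_c)
        hit = _tri_box_overlap(tv[pair_t], cell_centers(pair_c), grid.spacing / 2.0)
        hc = pair_c[hit]
        overlap[hc[:, 0], hc[:, 1], hc[:, 2]] = True

    kept_cells = np.argwhere(inside | overlap)
    if len(kept_cells) == 0:
        raise ValueError("mesh outside grid: no cell kept")

    # node lattice indices per cell corner, deduplicated
    corner = kept_cells[:, None, :] + HEX_OFFSETS[None]  # (E, 8, 3)
    lat_flat = (corner[..., 0] + (nx + 1) * (corner[..., 1] + (ny + 1) * corner[..., 2]))
    uniq, inv = np.unique(lat_flat.ravel(), return_inverse=True)
    hexes = inv.reshape(-1, 8)
    li = uniq % (nx + 1)
    lj = (uniq // (nx + 1)) % (ny + 1)
    lk = uniq // ((nx + 1) * (ny + 1))
    lattice = np.stack([li, lj, lk], axis=1)
    nodes = grid.origin + grid.spacing * lattice

    if np.any(lattice >= dims):
        raise ValueError("kept cells touch the grid's far boundary; the grid "
                         "needs a one-cell margin for the node-voxel map")
    node_to_voxel = lattice.copy()

    # boundary quads: faces appearing exactly once among kept cells
    quads = hexes[:, HEX_FACES].reshape(-1, 4)  # (E*6, 4)
    key = np.sort(quads, axis=1)
    _, first, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
    surface_faces = quads[first[counts == 1]]
    surface_nodes = np.unique(surface_faces)

    return HexModel(grid=grid, nodes=nodes, hexes=hexes, kept_cells=kept_cells,
                    surface_nodes=surface_nodes, node_to_voxel=node_to_voxel,
                    surface_faces=surface_faces)


def write_vtk_hex(model: HexModel, path: str | Path,
                  point_data: dict[str, np.ndarray] | None = None) -> None:
    """Write the hex mesh as a VTK-legacy unstructured grid (ASCII)."""
    lines = ["# vtk DataFile Version 3.0", "hexahedral FE model", "ASCII",
             "DATASET UNSTRUCTURED_GRID",
             f"POINTS {model.n_nodes} double"]
    lines += [" ".join(f"{x:.9g}" for x in p) for p in model.nodes]
    lines.append(f"CELLS {model.n_cells} {model.n_cells * 9}")
    lines += ["8 " + " ".join(map(str, h)) for h in model.hexes]
    lines.append(f"CELL_TYPES {model.n_cells}")
    lines += ["12"] * model.n_cells
    if point_data:
        lines.append(f"POINT_DATA {model.n_nodes}")
        for name, arr in point_data.items():
            arr = np.asarray(arr)
            if arr.ndim == 1:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines += [f"{v:.9g}" for v in arr]
            else:
                lines.append(f"VECTORS {name} double")
                lines += [" ".join(f"{x:.9g}" for x in p) for p in arr]
    Path(path).write_text("\n".join(lines) + "\n")
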