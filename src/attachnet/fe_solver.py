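"""Static hyperelastic FE solver on the grid-embedded hexahedral mesh.

The organ is modeled as a compressible Neo-Hookean solid,

    W(F) = mu/2 (I1 - 3) - mu ln J + lambda/2 (ln J)^2,

with Lame parameters derived from Young's modulus E and Poisson's ratio
nu (defaults E = 5000 Pa, nu = 0.48, typical soft-tissue values for a
near-incompressible liver). Elements are trilinear hexahedra integrated
with 2x2x2 Gauss quadrature; because every cell of the embedding grid is
the same axis-aligned cube, the reference shape-function gradients are
shared by all elements, which keeps assembly fully vectorized.

Equilibrium is solved with Newton-Raphson under incremental loading,
an energy backtracking line search, and automatic step halving when an
increment inverts elements or fails to converge. Dirichlet constraints
(attachments at zero displacement, or prescribed target displacements
for registration) are imposed exactly by elimination of the constrained
degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .geometry import HEX_OFFSETS, HexModel

__all__ = [
    "Material",
    "BoundaryConditions",
    "SolveOptions",
    "SolveResult",
    "element_energy_force_stiffness",
    "HexFE",
    "solve_static",
    "register",
]

# local corner signs (+-1) matching HEX_OFFSETS
_XI = 2.0 * HEX_OFFSETS.astype(np.float64) - 1.0

# 2x2x2 Gauss points in the reference cube [-1, 1]^3 (weights all 1)
_GP = np.array([[sx / np.sqrt(3.0), sy / np.sqrt(3.0), sz / np.sqrt(3.0)]
                for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)])


def _shape_gradients(xi: np.ndarray) -> np.ndarray:
    """dN_a/dxi at points xi (G, 3) -> (G, 8, 3)."""
    g = np.empty((len(xi), 8, 3))
    for a in range(8):
        sa = _XI[a]
        f = 0.125 * np.stack([
            sa[0] * (1 + sa[1] * xi[:, 1]) * (1 + sa[2] * xi[:, 2]),
            (1 + sa[0] * xi[:, 0]) * sa[1] * (1 + sa[2] * xi[:, 2]),
            (1 + sa[0] * xi[:, 0]) * (1 + sa[1] * xi[:, 1]) * sa[2],
        ], axis=-1)
        g[:, a, :] = f
    return g


_DN_DXI = _shape_gradients(_GP)  # (8, 8, 3)


@dataclass(frozen=True)
class Material:
    """Isotropic Neo-Hookean material (E in Pa, nu dimensionless)."""

    young_modulus: float = 5000.0
    poisson_ratio: float = 0.48

    def __post_init__(self):
        if self.young_modulus <= 0:
            raise ValueError("Young's modulus must be positive")
        if not 0.0 <= self.poisson_ratio < 0.5:
            raise ValueError("Poisson's ratio must lie in [0, 0.5)")

    @property
    def lame_mu(self) -> float:
        return self.young_modulus / (2.0 * (1.0 + self.poisson_ratio))

    @property
    def lame_lambda(self) -> float:
        nu = self.poisson_ratio
        return self.young_modulus * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))


@dataclass
class BoundaryConditions:
    """Dirichlet and load data for a static solve.

    fixed_nodes : node indices clamped to zero displacement (attachments).
    prescribed : node -> target displacement (m); a NaN component leaves
        that component free (needed e.g. for symmetry conditions).
    loads : node -> external force vector (N).
    """

    fixed_nodes: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    prescribed: dict[int, np.ndarray] = field(default_factory=dict)
    loads: dict[int, np.ndarray] = field(default_factory=dict)

    def validate(self, n_nodes: int) -> None:
        fx = set(int(i) for i in np.asarray(self.fixed_nodes).ravel())
        pr = set(int(i) for i in self.prescribed)
        ld = set(int(i) for i in self.loads)
        if fx & pr or fx & ld or pr & ld:
            raise ValueError("fixed, prescribed and loaded node sets must be disjoint")
        for s in (fx, pr, ld):
            if s and (min(s) < 0 or max(s) >= n_nodes):
                raise ValueError("boundary-condition node index out of range")


@dataclass(frozen=True)
class SolveOptions:
    n_steps: int = 5          # incremental load steps
    max_iter: int = 25        # Newton iterations per step
    tol: float = 1e-6         # relative residual tolerance
    max_halvings: int = 4     # recursive step halving on failure
    max_ls: int = 12          # backtracking line-search trials


@dataclass
class SolveResult:
    displacements: np.ndarray  # (N, 3), meters
    converged: bool
    iterations: int
    residual_norm: float

    @property
    def max_displacement(self) -> float:
        return float(np.linalg.norm(self.displacements, axis=1).max())


def element_energy_force_stiffness(X: np.ndarray, u: np.ndarray, material: Material):
    """Energy (J), nodal forces (N) and tangent stiffness (N/m) of one
    trilinear hexahedron with nodal rest positions ``X`` (8, 3) and
    displacements ``u`` (8, 3).

    Forces are the internal forces dW/du (the negated equilibrium forces);
    the tangent is their symmetric Jacobian d2W/du2, both from 2x2x2
    Gauss quadrature of the Neo-Hookean energy density.
    """
    X = np.asarray(X, float)
    u = np.asarray(u, float)
    mu, lam = material.lame_mu, material.lame_lambda
    energy = 0.0
    force = np.zeros((8, 3))
    K = np.zeros((24, 24))
    for g in range(8):
        dN_dxi = _DN_DXI[g]                      # (8, 3)
        J0 = X.T @ dN_dxi                        # (3, 3) reference Jacobian
        detJ0 = np.linalg.det(J0)
        if detJ0 <= 0:
            raise ValueError("inverted reference element")
        dN_dX = dN_dxi @ np.linalg.inv(J0)       # (8, 3)
        F = np.eye(3) + u.T @ dN_dX              # deformation gradient
        Jd = np.linalg.det(F)
        if Jd <= 0:
            raise FloatingPointError("element inversion (J <= 0)")
        Finv = np.linalg.inv(F)
        lnJ = np.log(Jd)
        w = detJ0  # unit Gauss weights
        energy += w * (0.5 * mu * (np.trace(F.T @ F) - 3.0) - mu * lnJ
                       + 0.5 * lam * lnJ ** 2)
        P = mu * (F - Finv.T) + lam * lnJ * Finv.T
        force += w * dN_dX @ P.T
        # dP_iJ/dF_kL = mu d_ik d_JL + (mu - lam lnJ) Finv_Jk Finv_Li
        #              + lam Finv_Ji Finv_Lk
        G1 = dN_dX @ Finv                        # (8, 3): a, k
        Kc = (mu * np.einsum("aJ,bJ,ik->aibk", dN_dX, dN_dX, np.eye(3))
              + (mu - lam * lnJ) * np.einsum("ak,bi->aibk", G1, G1)
              + lam * np.einsum("ai,bk->aibk", G1, G1))
        K += w * Kc.reshape(24, 24)
    return energy, force, K


class HexFE:
    """Vectorized assembly and Newton solver for a :class:`HexModel`."""

    def __init__(self, model: HexModel, material: Material = Material()):
        self.model = model
        self.material = material
        h = model.grid.spacing
        # all elements are the same cube: shared reference gradients
        detJ0 = (h / 2.0) ** 3
        self.dN_dX = _DN_DXI * (2.0 / h)         # (G, 8, 3)
        self.w = detJ0                           # per-gp weight
        self.n_dof = 3 * model.n_nodes
        dofs = (3 * model.hexes[:, :, None] + np.arange(3)).reshape(-1, 24)
        self._edofs = dofs
        self._rows = np.repeat(dofs, 24, axis=1).ravel()
        self._cols = np.tile(dofs, (1, 24)).ravel()

    # -- batched element quantities ------------------------------------
    def _def_grads(self, u: np.ndarray) -> np.ndarray:
        ue = u.reshape(-1, 3)[self.model.hexes]  # (E, 8, 3)
        F = np.einsum("eai,gaj->egij", ue, self.dN_dX)
        F += np.eye(3)
        return F

    def energy(self, u: np.ndarray) -> float:
        """Total strain energy; +inf if any quadrature point is inverted."""
        F = self._def_grads(u)
        Jd = np.linalg.det(F)
        if np.any(Jd <= 0):
            return np.inf
        mu, lam = self.material.lame_mu, self.material.lame_lambda
        I1 = np.einsum("egij,egij->eg", F, F)
        lnJ = np.log(Jd)
        Wd = 0.5 * mu * (I1 - 3.0) - mu * lnJ + 0.5 * lam * lnJ ** 2
        return float(self.w * Wd.sum())

    def internal_forces(self, u: np.ndarray) -> np.ndarray:
        F = self._def_grads(u)
        Jd = np.linalg.det(F)
        if np.any(Jd <= 0):
            raise FloatingPointError("element inversion (J <= 0)")
        mu, lam = self.material.lame_mu, self.material.lame_lambda
        Finv = np.linalg.inv(F)
        lnJ = np.log(Jd)
        P = mu * F + (lam * lnJ - mu)[..., None, None] * np.transpose(Finv, (0, 1, 3, 2))
        fe = self.w * np.einsum("egiJ,gaJ->eai", P, self.dN_dX)
        f = np.zeros(self.n_dof)
        np.add.at(f, self._edofs, fe.reshape(-1, 24))
        return f

    def tangent(self, u: np.ndarray) -> sp.csr_matrix:
        F = self._def_grads(u)
        Jd = np.linalg.det(F)
        if np.any(Jd <= 0):
            raise FloatingPointError("element inversion (J <= 0)")
        mu, lam = self.material.lame_mu, self.material.lame_lambda
        Finv = np.linalg.inv(F)
        lnJ = np.log(Jd)
        G1 = np.einsum("gaJ,egJk->egak", self.dN_dX, Finv)
        c = mu - lam * lnJ  # (E, G)
        K1 = mu * np.einsum("gaJ,gbJ->ab", self.dN_dX, self.dN_dX)  # shared
        Ke = np.einsum("ab,ik->aibk", K1, np.eye(3))[None].repeat(len(F), axis=0)
        # both geometric terms are X^T diag(w) X in the flattened (node,
        # component) index, lowered to batched GEMMs
        E = len(F)
        X = G1.reshape(E, 8, 24)
        Xt = X.transpose(0, 2, 1)
        Mc = np.matmul(Xt * c[:, None, :], X).reshape(E, 8, 3, 8, 3)
        M0 = np.matmul(Xt, X).reshape(E, 8, 3, 8, 3)
        Ke += Mc.transpose(0, 1, 4, 3, 2) + lam * M0
        vals = (self.w * Ke.reshape(-1, 24, 24)).ravel()
        K = sp.coo_matrix((vals, (self._rows, self._cols)),
                          shape=(self.n_dof, self.n_dof))
        return K.tocsr()

    # -- boundary conditions -------------------------------------------
    def _dirichlet(self, bcs: BoundaryConditions):
        """Constrained-DOF mask and target values (at full load)."""
        fixed = np.zeros(self.n_dof, dtype=bool)
        vals = np.zeros(self.n_dof)
        for n in np.asarray(bcs.fixed_nodes, dtype=np.int64).ravel():
            fixed[3 * n:3 * n + 3] = True
        for n, tgt in bcs.prescribed.items():
            tgt = np.asarray(tgt, float)
            for c in range(3):
                if not np.isnan(tgt[c]):
                    fixed[3 * n + c] = True
                    vals[3 * n + c] = tgt[c]
        return fixed, vals

    def _external(self, bcs: BoundaryConditions) -> np.ndarray:
        f = np.zeros(self.n_dof)
        for n, vec in bcs.loads.items():
            f[3 * n:3 * n + 3] = np.asarray(vec, float)
        return f

    # -- Newton-Raphson -------------------------------------------------
    def solve(self, bcs: BoundaryConditions, opts: SolveOptions = SolveOptions()) -> SolveResult:
        bcs.validate(self.model.n_nodes)
        fixed, pvals = self._dirichlet(bcs)
        if not np.any(fixed):
            raise ValueError("underconstrained: no Dirichlet constraint removes "
                             "rigid-body motion")
        f_full = self._external(bcs)
        free = ~fixed
        mu_lam_scale = self.material.lame_lambda * self.model.grid.spacing ** 2
        f_ref = max(np.linalg.norm(f_full), mu_lam_scale)

        u = np.zeros(self.n_dof)
        total_iters = 0
        resid = 0.0

        def factorize(u):
            Kff = self.tangent(u)[free][:, free].tocsc()
            try:
                # symmetric-structure ordering is measurably faster than
                # the default COLAMD on these meshes
                return splu(Kff, permc_spec="MMD_AT_PLUS_A",
                            options={"SymmetricMode": True})
            except RuntimeError as exc:
                raise ValueError("underconstrained or singular stiffness") from exc

        def newton(u, scale, budget):
            """One increment to load fraction `scale`; returns (u, ok, res).

            Modified Newton: the factorized tangent is reused across
            iterations (a solve is ~20x cheaper than a factorization) and
            refreshed only when the line search fails or the residual
            contracts by less than half.
            """
            nonlocal total_iters
            u = u.copy()
            u[fixed] = scale * pvals[fixed]
            f_ext = scale * f_full
            try:
                r = self.internal_forces(u) - f_ext
            except FloatingPointError:
                return u, False, np.inf
            res = np.linalg.norm(r[free])
            it = 0
            lu = None
            fresh = False
            while res > opts.tol * f_ref and it < budget:
                if lu is None:
                    lu = factorize(u)
                    fresh = True
                du_f = lu.solve(-r[free])
                if not np.all(np.isfinite(du_f)):
                    raise ValueError("underconstrained or singular stiffness")
                # backtracking line search on the potential energy
                pot0 = self.energy(u) - f_ext @ u
                slope = r[free] @ du_f  # directional derivative (negative)
                alpha, ok = 1.0, False
                for _ in range(opts.max_ls):
                    u_try = u.copy()
                    u_try[free] += alpha * du_f
                    pot = self.energy(u_try) - f_ext @ u_try
                    if pot <= pot0 + 1e-4 * alpha * slope or (
                            slope >= 0 and np.isfinite(pot) and pot <= pot0 + 1e-12 * abs(pot0)):
                        ok = True
                        break
                    alpha *= 0.5
                if not ok:
                    if not fresh:
                        lu = None  # stale direction: retry with a fresh tangent
                        continue
                    return u, False, res
                u = u_try
                try:
                    r = self.internal_forces(u) - f_ext
                except FloatingPointError:
                    return u, False, np.inf
                res_new = np.linalg.norm(r[free])
                if res_new > 0.5 * res:  # slow contraction: refresh next round
                    lu = None
                fresh = False
                res = res_new
                it += 1
                total_iters += 1
            return u, res <= opts.tol * f_ref, res

        def advance(u, s0, s1, depth):
            u_new, ok, res = newton(u, s1, opts.max_iter)
            if ok:
                return u_new, True, res
            if depth >= opts.max_halvings:
                return u_new, False, res
            mid = 0.5 * (s0 + s1)
            u_mid, ok, res = advance(u, s0, mid, depth + 1)
            if not ok:
                return u_mid, False, res
            return advance(u_mid, mid, s1, depth + 1)

        ok = True
        for s in range(1, opts.n_steps + 1):
            s0 = (s - 1) / opts.n_steps
            s1 = s / opts.n_steps
            u, ok, resid = advance(u, s0, s1, 0)
            if not ok:
                break

        disp = u.reshape(-1, 3)
        return SolveResult(displacements=disp, converged=bool(ok),
                           iterations=total_iters, residual_norm=float(resid))


def save_deformed_ply(model: HexModel, displacements: np.ndarray, path) -> None:
    """Write the deformed nodal positions as a PLY point cloud."""
    import trimesh
    cloud = trimesh.PointCloud(model.nodes + np.asarray(displacements))
    cloud.export(str(path))


def solve_static(model: HexModel, material: Material, bcs: BoundaryConditions,
                 opts: SolveOptions = SolveOptions()) -> SolveResult:
    """Static equilibrium under attachments, prescribed displacements and
    surface loads (convenience wrapper around :class:`HexFE`)."""
    return HexFE(model, material).solve(bcs, opts)


def register(model: HexModel, material: Material, attachments: np.ndarray,
             control_targets: dict[int, np.ndarray],
             opts: SolveOptions = SolveOptions()) -> SolveResult:
    """Deform the rest model so control nodes reach target displacements
    while candidate attachment nodes stay fixed (FE registration).

    ``control_targets`` maps node index -> target displacement (m). An
    empty attachment set is allowed: the control constraints then carry
    the full Dirichlet load.
    """
    attachments = np.asarray(attachments, dtype=np.int64).ravel()
    overlap = set(attachments.tolist()) & set(int(n) for n in control_targets)
    if overlap:
        raise ValueError(f"control nodes {sorted(overlap)[:5]}... are attachments")
    bcs = BoundaryConditions(
        fixed_nodes=attachments,
        prescribed={int(n): np.asarray(t, float) for n, t in control_targets.items()},
    )
    return HexFE(model, material).solve(bcs, opts)
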