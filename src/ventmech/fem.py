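"""Quasi-static finite-element inflation of a ventricle mesh.

Total-Lagrangian formulation on 8-node hexahedra: internal virtual work
from the second Piola-Kirchhoff stress of the (an)isotropic modified
Mooney-Rivlin energy, endocardial pressure applied as a follower load on
the deformed surface, full Newton iterations with the analytic consistent
tangent (material + geometric + load stiffness), line-search halving and
adaptive load stepping.  Near-incompressibility is handled by the
volumetric penalty evaluated with selective reduced (single-point)
integration to avoid locking.

The inertial term of the momentum balance is dropped: the cardiac cycle
is traversed as a sequence of quasi-static equilibria, which is all the
four reported time points require.  Density is carried in the solver
configuration for documentation only.

Units: lengths mm, stresses kPa, pressures mmHg at the interface
(converted internally), forces mN, volumes reported in mm^3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.integrate import quad
from scipy.optimize import brentq

from .constitutive import MaterialParams, energy_C, pk2_C, tangent_C
from .geometry import (FiberField, VentricleMesh, MMHG_TO_KPA,
                       _hex_shape_grad, hex_gauss_points)

__all__ = [
    "SolverConfig",
    "SolutionField",
    "solve_inflation",
    "cavity_volume",
    "thick_sphere_inflation",
    "thick_sphere_pressure",
    "NewtonError",
]


class NewtonError(RuntimeError):
    """Raised when the Newton loop fails to converge."""


@dataclass(frozen=True)
class SolverConfig:
    load_steps: int = 6
    newton_tol: float = 1e-8        # relative residual
    max_newton_iters: int = 30
    max_line_search: int = 6
    max_step_halvings: int = 8
    density: float = 1.06e-6        # kg/mm^3, informational (inertia dropped)
    verbose: bool = False


@dataclass
class SolutionField:
    """Converged equilibrium state of an inflation solve.

    Besides the raw quadrature-point tensors, the solution carries a
    nodally recovered stress/strain field (volume-averaged projection of
    element values to nodes), the standard smoothing used for stress
    evaluation at arbitrary points.
    """

    displacement: np.ndarray        # (N, 3) mm
    gp_coords: np.ndarray           # (E*G, 3) reference quadrature positions
    gp_stress: np.ndarray           # (E*G, 3, 3) Cauchy stress, kPa
    gp_strain: np.ndarray           # (E*G, 3, 3) Green-Lagrange strain
    node_coords: np.ndarray         # (N, 3) reference node positions
    nodal_stress: np.ndarray        # (N, 3, 3) recovered Cauchy stress
    nodal_strain: np.ndarray        # (N, 3, 3) recovered Green-Lagrange strain
    cavity_volume: float            # mm^3, deformed
    applied_pressure: float         # mmHg
    residual_norm: float
    newton_trace: list = field(default_factory=list, repr=False)


# -- assembly helpers --------------------------------------------------------


class _Discretization:
    """Precomputed reference-configuration quantities for one mesh."""

    def __init__(self, mesh: VentricleMesh, fibers: FiberField):
        self.mesh = mesh
        self.fibers = fibers
        X = mesh.nodes[mesh.elements]            # (E, 8, 3)
        pts, wts = hex_gauss_points(2)
        E = mesh.n_elements
        G = len(pts)
        self.G = G
        gradN = np.empty((G, 8, 3))
        shapeN = np.empty((G, 8))
        for g, p in enumerate(pts):
            shapeN[g], gradN[g] = _hex_shape_grad(*p)
        J = np.einsum("eai,gaj->egij", X, gradN)             # (E, G, 3, 3)
        detJ = np.linalg.det(J)
        if np.any(detJ <= 0):
            raise ValueError("non-positive reference Jacobian")
        Jinv = np.linalg.inv(J)
        self.dN = np.einsum("gaj,egji->egai", gradN, Jinv)    # dN/dX (E,G,8,3)
        self.w = detJ * wts[None, :]                          # (E, G)
        self.gp_coords = np.einsum("ga,eai->egi", shapeN, X).reshape(E * G, 3)

        # single-point rule for the volumetric penalty (selective reduced
        # integration); collapsed pole elements keep full integration for
        # the volumetric term, which removes their spurious compliance
        p0, w0 = hex_gauss_points(1)
        _, g0 = _hex_shape_grad(*p0[0])
        J0 = np.einsum("eai,aj->eij", X, g0)
        det0 = np.linalg.det(J0)
        self.dN0 = np.einsum("aj,eji->eai", g0, np.linalg.inv(J0))  # (E, 8, 3)
        self.degenerate = np.array(
            [len(set(el)) < 8 for el in mesh.elements])              # (E,)
        self.w0 = det0 * w0[0] * (~self.degenerate)                  # (E,)
        self.w_volfull = self.w * self.degenerate[:, None]           # (E, G)

        self.n_f = fibers.n_f                                 # (E, 3)
        self.dofmap = (3 * mesh.elements[:, :, None] + np.arange(3)).reshape(E, 24)

    def deformation(self, u: np.ndarray):
        """F at the full and reduced quadrature points."""
        ue = u.reshape(-1, 3)[self.mesh.elements]             # (E, 8, 3)
        F = np.eye(3) + np.einsum("eai,egaj->egij", ue, self.dN)
        F0 = np.eye(3) + np.einsum("eai,eaj->eij", ue, self.dN0)
        return F, F0

    def internal_force_energy(self, params: MaterialParams, u: np.ndarray):
        """Assembled internal force (global vector) and total strain energy."""
        F, F0 = self.deformation(u)
        C = np.einsum("egki,egkj->egij", F, F)
        C0 = np.einsum("eki,ekj->eij", F0, F0)
        nf = self.n_f[:, None, :]
        S = pk2_C(params, C, np.broadcast_to(nf, C.shape[:2] + (3,)), volumetric=False)
        S0 = _pk2_vol(params, C0)
        Sv = _pk2_vol(params, C)                              # full-rule volumetric
        P = np.einsum("egik,egkj->egij", F, S)                # 1st PK, isochoric
        P0 = np.einsum("eik,ekj->eij", F0, S0)
        Pv = np.einsum("egik,egkj->egij", F, Sv)
        fe = np.einsum("egij,egaj,eg->eai", P, self.dN, self.w) \
            + np.einsum("eij,eaj,e->eai", P0, self.dN0, self.w0) \
            + np.einsum("egij,egaj,eg->eai", Pv, self.dN, self.w_volfull)
        Wd = energy_C(params, C, np.broadcast_to(nf, C.shape[:2] + (3,)),
                      volumetric=False)
        J0 = np.sqrt(np.linalg.det(C0))
        Jg = np.sqrt(np.linalg.det(C))
        Wv = 0.5 * params.kappa * (J0 - 1.0) ** 2
        Wvf = 0.5 * params.kappa * (Jg - 1.0) ** 2
        energy = float(np.sum(Wd * self.w) + np.sum(Wv * self.w0)
                       + np.sum(Wvf * self.w_volfull))
        fint = np.zeros(u.size)
        np.add.at(fint, self.dofmap.ravel(), fe.reshape(len(fe), 24).ravel())
        return fint, energy

    def tangent(self, params: MaterialParams, u: np.ndarray) -> sp.csr_matrix:
        """Consistent tangent of the internal force (sparse, symmetric)."""
        F, F0 = self.deformation(u)
        C = np.einsum("egki,egkj->egij", F, F)
        C0 = np.einsum("eki,ekj->eij", F0, F0)
        nf = np.broadcast_to(self.n_f[:, None, :], C.shape[:2] + (3,))
        S = pk2_C(params, C, nf, volumetric=False)
        D = tangent_C(params, C, nf, volumetric=False)        # dS/dE
        S0 = _pk2_vol(params, C0)
        D0 = _tangent_vol(params, C0)

        # B operator: dE_IJ(u)[delta u_a,i] = sym(F_iI dN_a,J)
        B = np.einsum("egiI,egaJ->egaiIJ", F, self.dN)
        B = 0.5 * (B + np.swapaxes(B, -1, -2))
        DB = np.einsum("egIJKL,egbkKL->egbkIJ", D, B)
        Kmat = np.einsum("egaiIJ,egbkIJ,eg->eaibk", B, DB, self.w)
        geo = np.einsum("egaI,egIJ,egbJ,eg->eab", self.dN, S, self.dN, self.w)
        Kmat += np.einsum("eab,ik->eaibk", geo, np.eye(3))

        B0 = np.einsum("eiI,eaJ->eaiIJ", F0, self.dN0)
        B0 = 0.5 * (B0 + np.swapaxes(B0, -1, -2))
        DB0 = np.einsum("eIJKL,ebkKL->ebkIJ", D0, B0)
        Kmat += np.einsum("eaiIJ,ebkIJ,e->eaibk", B0, DB0, self.w0)
        geo0 = np.einsum("eaI,eIJ,ebJ,e->eab", self.dN0, S0, self.dN0, self.w0)
        Kmat += np.einsum("eab,ik->eaibk", geo0, np.eye(3))

        if np.any(self.degenerate):
            Sv = _pk2_vol(params, C)
            Dv = _tangent_vol(params, C)
            DBv = np.einsum("egIJKL,egbkKL->egbkIJ", Dv, B)
            Kmat += np.einsum("egaiIJ,egbkIJ,eg->eaibk", B, DBv, self.w_volfull)
            geov = np.einsum("egaI,egIJ,egbJ,eg->eab", self.dN, Sv, self.dN,
                             self.w_volfull)
            Kmat += np.einsum("eab,ik->eaibk", geov, np.eye(3))

        Ke = Kmat.reshape(-1, 24, 24)
        rows = np.repeat(self.dofmap, 24, axis=1).ravel()
        cols = np.tile(self.dofmap, (1, 24)).ravel()
        K = sp.coo_matrix((Ke.ravel(), (rows, cols)),
                          shape=(u.size, u.size)).tocsr()
        return K


def _pk2_vol(params: MaterialParams, C: np.ndarray) -> np.ndarray:
    J = np.sqrt(np.linalg.det(C))[..., None, None]
    Cinv = np.linalg.inv(C)
    return params.kappa * (J - 1.0) * J * Cinv


def _tangent_vol(params: MaterialParams, C: np.ndarray) -> np.ndarray:
    J = np.sqrt(np.linalg.det(C))[..., None, None, None, None]
    Cinv = np.linalg.inv(C)
    CiCi = np.einsum("...ij,...kl->...ijkl", Cinv, Cinv)
    dCinv = -0.5 * (np.einsum("...ik,...jl->...ijkl", Cinv, Cinv)
                    + np.einsum("...il,...jk->...ijkl", Cinv, Cinv))
    return params.kappa * J * (2.0 * J - 1.0) * CiCi \
        + 2.0 * params.kappa * (J - 1.0) * J * dCinv


# quad-face quadrature (2x2)
_QPTS = np.array([[x, y] for y in (-1 / np.sqrt(3), 1 / np.sqrt(3))
                  for x in (-1 / np.sqrt(3), 1 / np.sqrt(3))])


def _quad_shapes():
    Ns, dNs = [], []
    for xi, eta in _QPTS:
        N = 0.25 * np.array([(1 - xi) * (1 - eta), (1 + xi) * (1 - eta),
                             (1 + xi) * (1 + eta), (1 - xi) * (1 + eta)])
        dN = 0.25 * np.array([[-(1 - eta), -(1 - xi)], [(1 - eta), -(1 + xi)],
                              [(1 + eta), (1 - xi)], [-(1 + eta), (1 + xi)]])
        Ns.append(N)
        dNs.append(dN)
    return np.array(Ns), np.array(dNs)


_QN, _QdN = _quad_shapes()
_EPS = np.zeros((3, 3, 3))
_EPS[0, 1, 2] = _EPS[1, 2, 0] = _EPS[2, 0, 1] = 1.0
_EPS[0, 2, 1] = _EPS[2, 1, 0] = _EPS[1, 0, 2] = -1.0


def _follower_load(faces: np.ndarray, coords: np.ndarray, p_kpa: float,
                   ndof: int):
    """Follower pressure force and load stiffness on deformed face quads.

    Faces are oriented with outward-from-solid normals (pointing into the
    cavity); the applied traction is -p n per unit deformed area, i.e.
    the pressure pushes the wall away from the cavity.
    """
    x = coords[faces]                                         # (m, 4, 3)
    xg = np.einsum("ga,mai->mgi", _QN, x)
    t1 = np.einsum("ga,mai->mgi", _QdN[:, :, 0], x)
    t2 = np.einsum("ga,mai->mgi", _QdN[:, :, 1], x)
    nvec = np.cross(t1, t2)                                   # area-weighted
    fe = -p_kpa * np.einsum("ga,mgi->mai", _QN, nvec)
    f = np.zeros(ndof)
    dof = (3 * faces[:, :, None] + np.arange(3)).reshape(-1, 12)
    np.add.at(f, dof.ravel(), fe.reshape(-1, 12).ravel())

    # load stiffness: d f_a / d x_b
    # d(nvec)_i/dx_{b m} = eps_imk dN_b^1 t2_k + eps_ijm t1_j dN_b^2
    dn1 = np.einsum("imk,gb,fgk->fgbim", _EPS, _QdN[:, :, 0], t2)
    dn2 = np.einsum("ijm,fgj,gb->fgbim", _EPS, t1, _QdN[:, :, 1])
    Kf = -p_kpa * np.einsum("ga,fgbim->faibm", _QN, dn1 + dn2)
    rows = np.repeat(dof, 12, axis=1).ravel()
    cols = np.tile(dof, (1, 12)).ravel()
    K = sp.coo_matrix((Kf.reshape(-1, 12, 12).ravel(), (rows, cols)),
                      shape=(ndof, ndof)).tocsr()
    return f, K


def cavity_volume(mesh: VentricleMesh, displacement: np.ndarray | None = None) -> float:
    """Deformed cavity volume (mm^3) via the divergence theorem.

    The endocardial surface is closed by the base plane z = 0; with the
    base ring held on that plane its cap contributes nothing to the flux
    integral, so the volume is -1/3 int x . n dA over the endocardial
    faces (n outward from the solid, i.e. into the cavity).
    """
    coords = mesh.nodes if displacement is None else mesh.nodes + displacement
    zb = coords[mesh.base_nodes, 2]
    ring = np.intersect1d(mesh.base_nodes, np.unique(mesh.endo_faces))
    if np.any(np.abs(coords[ring, 2] - coords[ring, 2].mean()) > 1e-6 * (1 + np.abs(zb).max())):
        raise ValueError("endocardial base ring does not lie on a single plane; "
                         "cannot close the cavity surface")
    x = coords[mesh.endo_faces]
    xg = np.einsum("ga,mai->mgi", _QN, x)
    t1 = np.einsum("ga,mai->mgi", _QdN[:, :, 0], x)
    t2 = np.einsum("ga,mai->mgi", _QdN[:, :, 1], x)
    nvec = np.cross(t1, t2)
    flux = np.einsum("mgi,mgi->", xg - np.array([0.0, 0.0, coords[ring, 2].mean()]), nvec)
    vol = -flux / 3.0
    if vol <= 0:
        raise ValueError(f"non-positive cavity volume {vol:.3g}")
    return float(vol)


def _constraint_transform(mesh: VentricleMesh) -> sp.csr_matrix:
    """Sparse map from reduced to full dofs encoding the base constraint.

    Base-plane nodes keep only their radial in-plane dof (axial and
    circumferential displacements are fixed: the basal ring stays on the
    valve plane and does not spin, but expands freely).  All other nodes
    keep their three Cartesian dofs.  The constraint directions are
    defined in the mesh's own frame, so the reduced problem co-rotates
    with rigid rotations of the mesh about its long axis.
    """
    base = set(mesh.base_nodes.tolist())
    rows, cols, vals = [], [], []
    m = 0
    for n in range(mesh.n_nodes):
        if n in base:
            x, y = mesh.nodes[n, 0], mesh.nodes[n, 1]
            r = np.hypot(x, y)
            if r < 1e-12:
                continue  # on-axis base node: fully fixed
            rows += [3 * n, 3 * n + 1]
            cols += [m, m]
            vals += [x / r, y / r]
            m += 1
        else:
            rows += [3 * n, 3 * n + 1, 3 * n + 2]
            cols += [m, m + 1, m + 2]
            vals += [1.0, 1.0, 1.0]
            m += 3
    return sp.csr_matrix((vals, (rows, cols)), shape=(3 * mesh.n_nodes, m))


def solve_inflation(mesh: VentricleMesh, fibers: FiberField,
                    params: MaterialParams | dict[str, MaterialParams],
                    pressure: float, config: SolverConfig = SolverConfig(),
                    ) -> SolutionField:
    """Inflate the chamber to ``pressure`` (mmHg) on the endocardium.

    Pressure is ramped in adaptive load steps, each solved by full Newton
    with line search; the epicardium is traction-free and the base is
    constrained as described in ``_constraint_transform``.  Per-region material
    parameters may be given as a mapping region tag -> params (a single
    ``MaterialParams`` applies everywhere).
    """
    if pressure < 0:
        raise ValueError("pressure must be non-negative")
    if isinstance(params, dict):
        regions = set(mesh.region_tag)
        if regions != {"RV"} or set(params) != {"RV"}:
            raise NotImplementedError("per-region parameters beyond a single "
                                      "RV region are not supported yet")
        params = params["RV"]

    disc = _Discretization(mesh, fibers)
    ndof = 3 * mesh.n_nodes
    T = _constraint_transform(mesh)
    u = np.zeros(ndof)
    trace = []

    p_kpa_total = pressure * MMHG_TO_KPA
    t, dt = 0.0, 1.0 / config.load_steps
    halvings = 0
    fast = 0
    while t < 1.0 - 1e-12:
        dt = min(dt, 1.0 - t)
        p_now = (t + dt) * p_kpa_total
        u_trial, iters = _newton(disc, params, u, p_now, T, config, trace)
        if u_trial is None:
            halvings += 1
            if halvings > config.max_step_halvings:
                raise NewtonError(
                    f"Newton failed at load fraction {t + dt:.4f} after "
                    f"{config.max_step_halvings} step halvings; trace: {trace[-3:]}")
            dt *= 0.5
            continue
        u = u_trial
        t += dt
        fast = fast + 1 if iters <= 5 else 0
        if fast >= 2:
            dt *= 2.0
            fast = 0

    F, _ = disc.deformation(u)
    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise NewtonError("inverted element in converged state")
    C = np.einsum("egki,egkj->egij", F, F)
    nf = np.broadcast_to(disc.n_f[:, None, :], C.shape[:2] + (3,))
    S = pk2_C(params, C, nf)  # full stress incl. volumetric for reporting
    sigma = np.einsum("egik,egkl,egjl->egij", F, S, F) / J[..., None, None]
    Egl = 0.5 * (C - np.eye(3))
    res_norm = trace[-1]["residual"] if trace else 0.0
    vol = cavity_volume(mesh, u.reshape(-1, 3))
    EG = mesh.n_elements * disc.G
    nodal_stress = _recover_nodal(mesh, sigma.mean(axis=1))
    nodal_strain = _recover_nodal(mesh, Egl.mean(axis=1))
    return SolutionField(
        displacement=u.reshape(-1, 3),
        gp_coords=disc.gp_coords,
        gp_stress=sigma.reshape(EG, 3, 3),
        gp_strain=Egl.reshape(EG, 3, 3),
        node_coords=mesh.nodes,
        nodal_stress=nodal_stress,
        nodal_strain=nodal_strain,
        cavity_volume=vol,
        applied_pressure=pressure,
        residual_norm=res_norm,
        newton_trace=trace,
    )


def _recover_nodal(mesh: VentricleMesh, elem_field: np.ndarray) -> np.ndarray:
    """Average element-mean tensors onto nodes (stress recovery)."""
    E = mesh.n_elements
    num = np.zeros((mesh.n_nodes, 9))
    den = np.zeros(mesh.n_nodes)
    flat = elem_field.reshape(E, 9)
    for a in range(8):
        np.add.at(num, mesh.elements[:, a], flat)
        np.add.at(den, mesh.elements[:, a], 1.0)
    den[den == 0] = 1.0
    return (num / den[:, None]).reshape(-1, 3, 3)


def _newton(disc, params, u0, p_kpa, T, config, trace):
    """One load step of full Newton with line search; None on failure.

    ``T`` maps reduced dofs to full dofs (boundary conditions by
    congruence transformation): solve T' K T dq = -T' R, du = T dq.
    """
    mesh = disc.mesh
    u = u0.copy()
    Tt = T.T.tocsr()

    def residual(uv):
        coords = mesh.nodes + uv.reshape(-1, 3)
        fint, _ = disc.internal_force_energy(params, uv)
        fext, Kext = _follower_load(mesh.endo_faces, coords, p_kpa, uv.size)
        return fint - fext, fext, Kext

    R, fext, Kext = residual(u)
    ref = max(np.linalg.norm(Tt @ fext), 1e-8)
    abs_floor = 1e-9  # mN; covers the unloaded state where fext vanishes
    rnorm = np.linalg.norm(Tt @ R)
    for it in range(config.max_newton_iters):
        if rnorm < config.newton_tol * ref or rnorm < abs_floor:
            trace.append({"pressure_kpa": p_kpa, "iters": it, "residual": rnorm / ref})
            return u, it
        K = disc.tangent(params, u) - Kext
        Kred = (Tt @ K @ T).tocsc()
        try:
            dq = spla.spsolve(Kred, -(Tt @ R))
        except RuntimeError:
            return None, it
        if not np.all(np.isfinite(dq)):
            return None, it
        step = T @ dq
        alpha = 1.0
        for _ in range(config.max_line_search + 1):
            try:
                R_new, fext, Kext = residual(u + alpha * step)
                new_norm = np.linalg.norm(Tt @ R_new)
            except (ValueError, FloatingPointError):
                new_norm = np.inf
            if new_norm < rnorm or new_norm < config.newton_tol * ref:
                break
            alpha *= 0.5
        else:
            return None, it
        u = u + alpha * step
        R, rnorm = R_new, new_norm
    if rnorm < config.newton_tol * ref:
        trace.append({"pressure_kpa": p_kpa, "iters": config.max_newton_iters,
                      "residual": rnorm / ref})
        return u, config.max_newton_iters
    return None, config.max_newton_iters


# -- semi-analytic thick-sphere benchmark ------------------------------------


def _sphere_What_prime(params: MaterialParams, lam: float) -> float:
    """d/d lam of the through-wall energy density for spherical inflation.

    Incompressible kinematics: stretches (lam^-2, lam, lam) so
    I1 = lam^-4 + 2 lam^2, I2 = 2 lam^-2 + lam^4.
    """
    I1 = lam**-4 + 2.0 * lam**2
    W1 = params.c1 + params.D1 * params.D2 * np.exp(params.D2 * (I1 - 3.0))
    W2 = params.c2
    dI1 = -4.0 * lam**-5 + 4.0 * lam
    dI2 = -4.0 * lam**-3 + 4.0 * lam**3
    return W1 * dI1 + W2 * dI2


def thick_sphere_pressure(inner_radius: float, outer_radius: float,
                          params: MaterialParams, inflated_inner: float) -> float:
    """Internal pressure (kPa) sustaining the given inflated inner radius.

    Exact incompressible solution: P = int_{lam_b}^{lam_a}
    What'(lam) / (lam^3 - 1) d lam with lam_a = a/A, lam_b = b/B and
    b^3 = B^3 + a^3 - A^3; evaluated by adaptive quadrature.
    """
    A, B, a = float(inner_radius), float(outer_radius), float(inflated_inner)
    if not 0 < A < B:
        raise ValueError("need 0 < inner_radius < outer_radius")
    b = (B**3 + a**3 - A**3) ** (1.0 / 3.0)
    lam_a, lam_b = a / A, b / B

    def integrand(lam):
        d = lam**3 - 1.0
        if abs(d) < 1e-9:
            # removable singularity: What'(lam) ~ What''(1) (lam - 1)
            h = 1e-5
            return (_sphere_What_prime(params, 1.0 + h)
                    - _sphere_What_prime(params, 1.0 - h)) / (2 * h) / 3.0
        return _sphere_What_prime(params, lam) / d

    val, _ = quad(integrand, lam_b, lam_a, limit=200, epsabs=1e-12, epsrel=1e-12)
    return float(val)


def thick_sphere_inflation(inner_radius: float, outer_radius: float,
                           params: MaterialParams, pressure: float,
                           max_stretch: float = 3.0) -> tuple[float, float]:
    """Inflated inner radius and cavity volume at ``pressure`` (kPa).

    Root-finds the incompressible thick-sphere pressure relation on the
    stable branch.  Raises if the pressure is outside the solvable range
    of the bracket [A, max_stretch * A].
    """
    A = float(inner_radius)
    if pressure == 0.0:
        return A, 4.0 / 3.0 * np.pi * A**3

    def f(a):
        return thick_sphere_pressure(inner_radius, outer_radius, params, a) - pressure

    lo, hi = A * (1 + 1e-12), A * max_stretch
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise ValueError(
            f"pressure {pressure} kPa outside solvable range "
            f"[{flo + pressure:.4g}, {fhi + pressure:.4g}] on the bracket")
    a = brentq(f, lo, hi, xtol=1e-10 * A)
    return float(a), float(4.0 / 3.0 * np.pi * a**3)
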