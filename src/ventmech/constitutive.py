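"""Modified Mooney-Rivlin strain-energy models for passive myocardium.

The isotropic form is

    W = c1 (I1 - 3) + c2 (I2 - 3) + D1 [exp(D2 (I1 - 3)) - 1]

and the anisotropic form adds an exponential fiber-invariant term

    W += (K1 / K2) [exp(K2 (I4 - 1)^2) - 1]

with I1, I2 the invariants of the right Cauchy-Green tensor C = F^T F and
I4 = n_f . C n_f the squared stretch along the (unit) fiber direction n_f.
Near-incompressibility is enforced with a quadratic volumetric penalty
(kappa/2)(J - 1)^2.  Stresses are derived analytically from the energy:
the second Piola-Kirchhoff tensor S = 2 dW/dC and its push-forward Cauchy
stress sigma = J^-1 F S F^T.

All stress-like quantities are in kPa; stretches and invariants are
dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, field
from typing import Literal

import numpy as np
from scipy.optimize import brentq, least_squares

__all__ = [
    "MaterialParams",
    "DeformationState",
    "BiaxialDataset",
    "BIAXIAL_RATIOS",
    "bar_stress_strain",
    "invariants",
    "strain_energy",
    "stress_from_energy",
    "biaxial_response",
    "fit_biaxial",
]

_I3 = np.eye(3)


@dataclass(frozen=True)
class MaterialParams:
    """Parameters of the (an)isotropic modified Mooney-Rivlin energy.

    ``c1, c2, D1, K1`` are in kPa; ``D2, K2`` are dimensionless exponents;
    ``kappa`` (kPa) is the volumetric penalty stiffness.  By default
    ``kappa = 100 (c1 + D1)``, large enough for near-incompressible
    response without ruining the tangent conditioning.
    """

    c1: float = 1.0
    c2: float = 0.0
    D1: float = 0.5
    D2: float = 3.0
    K1: float = 1.0
    K2: float = 3.0
    kappa: float | None = None
    model_kind: Literal["isotropic", "anisotropic"] = "anisotropic"

    def __post_init__(self):
        if self.c1 < 0 or self.D1 < 0 or self.K1 < 0:
            raise ValueError("c1, D1, K1 must be non-negative")
        if self.D2 <= 0 or self.K2 <= 0:
            raise ValueError("D2 and K2 must be positive")
        if self.kappa is None:
            object.__setattr__(self, "kappa", 100.0 * (self.c1 + self.D1))
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")

    @property
    def k1_eff(self) -> float:
        return self.K1 if self.model_kind == "anisotropic" else 0.0

    def scaled(self, factor: float) -> "MaterialParams":
        """Scale the stiffness-like parameters (c1, c2, D1, K1) by ``factor``.

        Used by the volume-matching material calibration; the exponents
        D2, K2 stay frozen and kappa follows the scaled c1 + D1.
        """
        return replace(
            self,
            c1=self.c1 * factor,
            c2=self.c2 * factor,
            D1=self.D1 * factor,
            K1=self.K1 * factor,
            kappa=self.kappa * factor,
        )


# Frozen exponents shared by all participants (biaxial-fit convention).
S1_FROZEN = {"c2": 0.0, "D2": 3.0, "K2": 3.0}


@dataclass(frozen=True)
class DeformationState:
    """Kinematic state at a material point.

    Built from the deformation gradient F; caches C = F^T F, the
    Green-Lagrange strain E = (C - I)/2, J = det F and the invariants.
    """

    F: np.ndarray
    n_f: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))

    def __post_init__(self):
        F = np.asarray(self.F, dtype=float)
        if F.shape != (3, 3):
            raise ValueError("F must be 3x3")
        n = np.asarray(self.n_f, dtype=float)
        n = n / np.linalg.norm(n)
        object.__setattr__(self, "F", F)
        object.__setattr__(self, "n_f", n)

    @property
    def C(self) -> np.ndarray:
        return self.F.T @ self.F

    @property
    def E(self) -> np.ndarray:
        return 0.5 * (self.C - _I3)

    @property
    def J(self) -> float:
        return float(np.linalg.det(self.F))

    @property
    def I1(self) -> float:
        return float(np.trace(self.C))

    @property
    def I2(self) -> float:
        C = self.C
        return float(0.5 * (np.trace(C) ** 2 - np.sum(C * C)))

    @property
    def I4(self) -> float:
        return float(self.n_f @ self.C @ self.n_f)


def bar_stress_strain(L0: float, L: float, YM: float) -> tuple[float, float]:
    """1D bar illustration: engineering strain (L-L0)/L0 and stress YM*strain."""
    if L0 <= 0:
        raise ValueError("reference length L0 must be positive")
    if YM < 0:
        raise ValueError("Young's modulus must be non-negative")
    strain = (L - L0) / L0
    return strain, YM * strain


def invariants(C: np.ndarray, n_f: np.ndarray) -> tuple[float, float, float]:
    """I1 = tr C, I2 = (I1^2 - C:C)/2 and fiber invariant I4 = n.C.n."""
    C = np.asarray(C, dtype=float)
    if C.shape != (3, 3) or not np.allclose(C, C.T, atol=1e-10 * max(1.0, abs(C).max())):
        raise ValueError("C must be a symmetric 3x3 tensor")
    n = np.asarray(n_f, dtype=float)
    n = n / np.linalg.norm(n)
    I1 = float(np.trace(C))
    I2 = float(0.5 * (I1**2 - np.sum(C * C)))
    I4 = float(n @ C @ n)
    return I1, I2, I4


# -- energy / stress kernels ------------------------------------------------
#
# The vectorized kernels below take C with shape (..., 3, 3) and fiber
# directions with shape (..., 3); they are the work-horses of the FE
# assembly.  The public scalar API wraps them for a single state.


def _invariants_bar(C: np.ndarray):
    """Full and deviatoric (J-normalized) invariants of C, batched."""
    I1 = np.trace(C, axis1=-2, axis2=-1)
    I2 = 0.5 * (I1**2 - np.einsum("...ij,...ij->...", C, C))
    J2 = np.linalg.det(C)
    J = np.sqrt(J2)
    I1b = J2 ** (-1.0 / 3.0) * I1
    I2b = J2 ** (-2.0 / 3.0) * I2
    return I1, I2, I1b, I2b, J


# exponential arguments are clamped here; the cap is far beyond any
# physical state and only tames line-search trial states
_EXP_CAP = 250.0


def _exp(x):
    return np.exp(np.minimum(x, _EXP_CAP))


def _energy_terms(params: MaterialParams, I1b, I2b, I4, J, volumetric: bool = True):
    c1, c2, D1, D2 = params.c1, params.c2, params.D1, params.D2
    K1, K2 = params.k1_eff, params.K2
    W = c1 * (I1b - 3.0) + c2 * (I2b - 3.0) + D1 * (_exp(D2 * (I1b - 3.0)) - 1.0)
    if K1 > 0.0:
        W = W + (K1 / K2) * (_exp(K2 * (I4 - 1.0) ** 2) - 1.0)
    if volumetric:
        W = W + 0.5 * params.kappa * (J - 1.0) ** 2
    return W


def energy_C(params: MaterialParams, C: np.ndarray, n_f: np.ndarray,
             volumetric: bool = True) -> np.ndarray:
    """Strain energy density from C (batched).

    The isotropic terms act on the deviatoric invariants I1b = J^-2/3 I1,
    I2b = J^-4/3 I2 so the reference state is stress-free under the
    volumetric-penalty treatment of near-incompressibility (on exactly
    isochoric states the deviatoric and full invariants coincide).  The
    fiber term uses the full I4.
    """
    _, _, I1b, I2b, J = _invariants_bar(C)
    I4 = np.einsum("...i,...ij,...j->...", n_f, C, n_f)
    return _energy_terms(params, I1b, I2b, I4, J, volumetric)


def pk2_C(params: MaterialParams, C: np.ndarray, n_f: np.ndarray,
          volumetric: bool = True) -> np.ndarray:
    """Second Piola-Kirchhoff stress S = 2 dW/dC (batched, analytic)."""
    C = np.asarray(C, dtype=float)
    I1, I2, I1b, I2b, J = _invariants_bar(C)
    up = (..., None, None)
    I1, I2, I1b, I2b, J = I1[up], I2[up], I1b[up], I2b[up], J[up]
    Cinv = np.linalg.inv(C)
    c1, c2, D1, D2 = params.c1, params.c2, params.D1, params.D2
    K1, K2 = params.k1_eff, params.K2
    W1 = c1 + D1 * D2 * _exp(D2 * (I1b - 3.0))
    # A1 = d(I1b)/dC, A2 = d(I2b)/dC
    A1 = J ** (-2.0 / 3.0) * (_I3 - (I1 / 3.0) * Cinv)
    A2 = J ** (-4.0 / 3.0) * (I1 * _I3 - C - (2.0 * I2 / 3.0) * Cinv)
    S = 2.0 * W1 * A1 + 2.0 * c2 * A2
    if K1 > 0.0:
        I4 = np.einsum("...i,...ij,...j->...", n_f, C, n_f)[up]
        nn = n_f[..., :, None] * n_f[..., None, :]
        W4 = 2.0 * K1 * (I4 - 1.0) * _exp(K2 * (I4 - 1.0) ** 2)
        S = S + 2.0 * W4 * nn
    if volumetric:
        S = S + params.kappa * (J - 1.0) * J * Cinv
    return S


def tangent_C(params: MaterialParams, C: np.ndarray, n_f: np.ndarray,
              volumetric: bool = True) -> np.ndarray:
    """Material tangent D = dS/dE = 2 dS/dC (batched, minor-symmetrized)."""
    C = np.asarray(C, dtype=float)
    I1, I2, I1b, I2b, J = _invariants_bar(C)
    up1 = (..., None, None)
    up2 = (..., None, None, None, None)
    Cinv = np.linalg.inv(C)
    c1, c2, D1, D2 = params.c1, params.c2, params.D1, params.D2
    K1, K2 = params.k1_eff, params.K2

    def outer(X, Y):
        return np.einsum("...ij,...kl->...ijkl", X, Y)

    Isym = 0.5 * (np.einsum("ik,jl->ijkl", _I3, _I3)
                  + np.einsum("il,jk->ijkl", _I3, _I3))
    dCinv = -0.5 * (np.einsum("...ik,...jl->...ijkl", Cinv, Cinv)
                    + np.einsum("...il,...jk->...ijkl", Cinv, Cinv))
    eye = np.broadcast_to(_I3, C.shape)

    A1 = J[up1] ** (-2.0 / 3.0) * (_I3 - (I1[up1] / 3.0) * Cinv)
    A2 = J[up1] ** (-4.0 / 3.0) * (I1[up1] * _I3 - C - (2.0 * I2[up1] / 3.0) * Cinv)
    # dA1/dC and dA2/dC (major- and minor-symmetric)
    dA1 = -outer(A1, Cinv) / 3.0 \
        + J[up2] ** (-2.0 / 3.0) * (-outer(Cinv, eye) / 3.0
                                    - (I1[up2] / 3.0) * dCinv)
    dI2dC = I1[up1] * _I3 - C
    dA2 = -2.0 / 3.0 * outer(A2, Cinv) \
        + J[up2] ** (-4.0 / 3.0) * (outer(eye, eye) - Isym
                                    - 2.0 / 3.0 * outer(Cinv, dI2dC)
                                    - (2.0 * I2[up2] / 3.0) * dCinv)
    W1 = c1 + D1 * D2 * _exp(D2 * (I1b[up2] - 3.0))
    W11 = D1 * D2**2 * _exp(D2 * (I1b[up2] - 3.0))
    CC = 4.0 * W11 * outer(A1, A1) + 4.0 * W1 * dA1 + 4.0 * c2 * dA2
    if K1 > 0.0:
        I4 = np.einsum("...i,...ij,...j->...", n_f, C, n_f)[up2]
        nn = n_f[..., :, None] * n_f[..., None, :]
        W44 = 2.0 * K1 * _exp(K2 * (I4 - 1.0) ** 2) * (1.0 + 2.0 * K2 * (I4 - 1.0) ** 2)
        CC = CC + 4.0 * W44 * outer(nn, nn)
    if volumetric:
        kappa = params.kappa
        CC = CC + kappa * J[up2] * (2.0 * J[up2] - 1.0) * outer(Cinv, Cinv) \
            + 2.0 * kappa * (J[up2] - 1.0) * J[up2] * dCinv
    return CC


def strain_energy(params: MaterialParams, state: DeformationState) -> float:
    """Strain energy density W (kPa) at the given deformation state."""
    return float(energy_C(params, state.C, state.n_f))


def stress_from_energy(params: MaterialParams, state: DeformationState
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Analytic second Piola-Kirchhoff stress S = dW/dE and Cauchy stress.

    Returns ``(S, sigma)`` with sigma = J^-1 F S F^T.  Raises on inverted
    states (J <= 0).
    """
    J = state.J
    if J <= 0:
        raise ValueError(f"inverted deformation state (J = {J:.3g})")
    S = pk2_C(params, state.C, state.n_f)
    sigma = (state.F @ S @ state.F.T) / J
    return S, sigma


# -- biaxial protocol --------------------------------------------------------

BIAXIAL_RATIOS: dict[str, tuple[float, float]] = {
    "10:10": (1.0, 1.0),
    "7.5:10": (0.75, 1.0),
    "5:10": (0.5, 1.0),
    "10:7.5": (1.0, 0.75),
    "10:5": (1.0, 0.5),
}


@dataclass
class BiaxialDataset:
    """Loading-branch biaxial records: in-plane stretches and Cauchy stresses.

    ``records`` is a structured array-like of columns (ratio_label,
    stretch_fiber, stretch_crossfiber, stress_fiber, stress_crossfiber).
    """

    ratio_label: np.ndarray
    stretch_fiber: np.ndarray
    stretch_crossfiber: np.ndarray
    stress_fiber: np.ndarray
    stress_crossfiber: np.ndarray

    def __len__(self) -> int:
        return len(self.stretch_fiber)


def _plane_stress_state(lam1: float, lam2: float) -> DeformationState:
    """Incompressible thin-sheet kinematics, fiber along axis 1."""
    lam3 = 1.0 / (lam1 * lam2)
    F = np.diag([lam1, lam2, lam3])
    return DeformationState(F=F, n_f=np.array([1.0, 0.0, 0.0]))


def _biaxial_point(params: MaterialParams, lam1: float, lam2: float
                   ) -> tuple[float, float]:
    """In-plane Cauchy stresses under exact incompressibility.

    The through-thickness condition sigma_33 = 0 is enforced by the
    reaction pressure p: sigma_ii = sigma^iso_ii - sigma^iso_33 for the
    isochoric part evaluated without the volumetric penalty.
    """
    state = _plane_stress_state(lam1, lam2)
    S = pk2_C(params, state.C, state.n_f, volumetric=False)
    sig = state.F @ S @ state.F.T  # J = 1
    return float(sig[0, 0] - sig[2, 2]), float(sig[1, 1] - sig[2, 2])


def biaxial_response(params: MaterialParams,
                     stretch_grid: np.ndarray | None = None,
                     ratios: dict[str, tuple[float, float]] | None = None,
                     max_stress: float = 60.0) -> BiaxialDataset:
    """Simulate the five-ratio biaxial protocol.

    For each fiber:cross-fiber target stress ratio, the controlling axis
    stretch runs over ``stretch_grid`` while the other axis stretch is
    solved so the Cauchy-stress ratio matches the prescribed ratio (the
    usual load-ratio-controlled biaxial rig behaviour).  Equibiaxial 10:10
    uses equal stretches directly.
    """
    if stretch_grid is None:
        stretch_grid = np.linspace(1.0, 1.25, 11)
    if ratios is None:
        ratios = BIAXIAL_RATIOS
    labels, l1s, l2s, s1s, s2s = [], [], [], [], []
    for label, (r1, r2) in ratios.items():
        for lam in stretch_grid:
            if np.isclose(lam, 1.0):
                lam1 = lam2 = 1.0
            elif np.isclose(r1, r2):
                lam1 = lam2 = lam
            else:
                # the more-loaded axis is driven; solve the other stretch so
                # that sigma_1 * r2 = sigma_2 * r1
                def mismatch(lam_other, lam=lam):
                    if r1 >= r2:
                        s1, s2 = _biaxial_point(params, lam, lam_other)
                    else:
                        s1, s2 = _biaxial_point(params, lam_other, lam)
                    return s1 * r2 - s2 * r1

                # the secondary stretch may be below or above the driven one
                # (a stiff fiber needs lam_cross > lam_fiber to keep the
                # ratio); scan a generous range for a sign change
                grid = np.linspace(0.6, max(1.6, 1.5 * lam), 41)
                vals = np.array([mismatch(g) for g in grid])
                sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
                if len(sign_change) == 0:
                    raise RuntimeError(
                        f"plane-stress ratio solve failed at ratio {label}, "
                        f"stretch {lam:.4f}: no sign change on "
                        f"[{grid[0]:.2f}, {grid[-1]:.2f}]")
                k = sign_change[0]
                lam_other = brentq(mismatch, grid[k], grid[k + 1], xtol=1e-12)
                lam1, lam2 = (lam, lam_other) if r1 >= r2 else (lam_other, lam)
            s1, s2 = _biaxial_point(params, lam1, lam2)
            labels.append(label)
            l1s.append(lam1)
            l2s.append(lam2)
            s1s.append(s1)
            s2s.append(s2)
    return BiaxialDataset(np.array(labels), np.array(l1s), np.array(l2s),
                          np.array(s1s), np.array(s2s))


def fit_biaxial(data: BiaxialDataset, init: MaterialParams | None = None,
                frozen: dict[str, float] | None = None):
    """Least-squares recovery of (c1, D1, K1) from biaxial stress data.

    c2, D2, K2 stay frozen (S1-style convention).  Returns the fitted
    ``MaterialParams`` and a report dict with residual norm and per-curve
    RMSE.  Because the model stress is linear in (c1, D1, K1) at fixed
    exponents, the fit is well-posed whenever at least two distinct
    stretch levels are present.
    """
    if init is None:
        init = MaterialParams(c1=1.0, D1=0.5, K1=1.0)
    frozen = dict(S1_FROZEN if frozen is None else frozen)
    if len(np.unique(np.round(data.stretch_fiber, 12))) < 2:
        raise ValueError("rank-deficient biaxial design: need >= 2 stretch levels")

    lam1 = np.asarray(data.stretch_fiber, float)
    lam2 = np.asarray(data.stretch_crossfiber, float)
    obs = np.concatenate([data.stress_fiber, data.stress_crossfiber])

    def model(theta):
        c1, D1, K1 = np.abs(theta)
        p = MaterialParams(c1=c1, c2=frozen.get("c2", 0.0), D1=D1,
                           D2=frozen.get("D2", 3.0), K1=K1,
                           K2=frozen.get("K2", 3.0), model_kind="anisotropic")
        s1 = np.empty_like(lam1)
        s2 = np.empty_like(lam1)
        for i in range(len(lam1)):
            s1[i], s2[i] = _biaxial_point(p, lam1[i], lam2[i])
        return np.concatenate([s1, s2])

    theta0 = np.array([init.c1, init.D1, init.K1], float)
    res = least_squares(lambda t: model(t) - obs, theta0, method="lm",
                        xtol=1e-12, ftol=1e-12)
    c1, D1, K1 = np.abs(res.x)
    fitted = MaterialParams(c1=c1, c2=frozen.get("c2", 0.0), D1=D1,
                            D2=frozen.get("D2", 3.0), K1=K1,
                            K2=frozen.get("K2", 3.0), model_kind="anisotropic")
    fit = model(res.x)
    report = {"residual_norm": float(np.linalg.norm(fit - obs))}
    half = len(lam1)
    report["rmse_fiber"] = float(np.sqrt(np.mean((fit[:half] - obs[:half]) ** 2)))
    report["rmse_crossfiber"] = float(np.sqrt(np.mean((fit[half:] - obs[half:]) ** 2)))
    per_curve = {}
    for label in np.unique(data.ratio_label):
        m = data.ratio_label == label
        mm = np.concatenate([m, m])
        per_curve[str(label)] = float(np.sqrt(np.mean((fit[mm] - obs[mm]) ** 2)))
    report["rmse_per_ratio"] = per_curve
    return fitted, report
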