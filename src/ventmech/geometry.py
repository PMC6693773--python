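"""Idealized ventricle geometries, fiber fields, pressures and cohorts.

The study's imaging data is not deposited, so an idealized stand-in is
generated: a thick-walled truncated half-ellipsoid chamber described both
as a short-axis slice stack (the contour representation the pre-shrink
procedure operates on) and as a structured two-layer 8-node hexahedral
mesh with a rule-based fiber field (constant helix angle per layer,
measured from the local circumferential direction).

Conventions: the long axis is +z with the base plane at z = 0 and the
apex below it; contours are stored counter-clockwise viewed from the
base; lengths in mm, volumes returned in mm^3 (1 cm^3 = 1000 mm^3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .cohort import Cohort, Participant, TIME_POINTS

__all__ = [
    "SliceStack",
    "VentricleMesh",
    "FiberField",
    "PressureProfile",
    "SyntheticCohortSpec",
    "make_idealized_ventricle",
    "mesh_from_stack",
    "assign_fibers",
    "make_pressure_profile",
    "generate_synthetic_cohort",
    "polygon_area",
    "export_mesh_vtk",
]

MMHG_TO_KPA = 0.1333224


def polygon_area(xy: np.ndarray) -> float:
    """Signed shoelace area of a closed planar polyline (CCW positive)."""
    x, y = xy[:, 0], xy[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass
class SliceStack:
    """Short-axis contour representation of a chamber wall.

    ``slices`` holds (z, inner contour, outer contour) from base (z = 0)
    toward the apex; contours are (n, 2) CCW polylines in mm.  The closed
    apex is carried as explicit inner/outer apex z positions so wall and
    cavity volumes of the apex cap are well defined.
    """

    slices: list[tuple[float, np.ndarray, np.ndarray]]
    long_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    apex_inner_z: float = 0.0
    apex_outer_z: float = 0.0

    def __post_init__(self):
        zs = [s[0] for s in self.slices]
        if not all(zs[i] > zs[i + 1] for i in range(len(zs) - 1)):
            raise ValueError("slices must be ordered from base toward apex (decreasing z)")
        for z, inner, outer in self.slices:
            ai, ao = polygon_area(inner), polygon_area(outer)
            if ai <= 0 or ao <= 0:
                raise ValueError(f"contours at z={z} must be CCW with positive area")
            if ao <= ai:
                raise ValueError(f"outer contour must enclose inner at z={z}")

    @property
    def n_slices(self) -> int:
        return len(self.slices)

    def wall_volume(self) -> float:
        """Wall volume by the prismatic (trapezoidal) rule plus apex caps."""
        zs = np.array([s[0] for s in self.slices])
        wall = np.array([polygon_area(o) - polygon_area(i) for _, i, o in self.slices])
        vol = float(np.sum(0.5 * (wall[1:] + wall[:-1]) * (zs[:-1] - zs[1:])))
        # apex cap: cone from the last slice's contours to the apex points
        z_last, inner, outer = self.slices[-1]
        vol += polygon_area(outer) * (z_last - self.apex_outer_z) / 3.0
        vol -= polygon_area(inner) * (z_last - self.apex_inner_z) / 3.0
        return vol

    def cavity_volume(self) -> float:
        """Cavity volume by the prismatic rule plus the inner apex cone."""
        zs = np.array([s[0] for s in self.slices])
        area = np.array([polygon_area(i) for _, i, _ in self.slices])
        vol = float(np.sum(0.5 * (area[1:] + area[:-1]) * (zs[:-1] - zs[1:])))
        z_last = self.slices[-1][0]
        vol += area[-1] * (z_last - self.apex_inner_z) / 3.0
        return vol


@dataclass
class VentricleMesh:
    """Structured 8-node hexahedral shell mesh.

    ``elements`` follow the usual corner ordering (bottom quad 0-3 CCW,
    top quad 4-7); elements touching the apex pole are collapsed hexes.
    ``endo_faces``/``epi_faces`` are (m, 4) node quads oriented so their
    bilinear normal points out of the solid wall.
    """

    nodes: np.ndarray                 # (N, 3) mm
    elements: np.ndarray              # (E, 8) int
    layer_tag: np.ndarray             # (E,) 0 = endo ... n_layers-1 = epi
    region_tag: np.ndarray            # (E,) str, "RV" by default
    endo_faces: np.ndarray            # (m, 4) int
    epi_faces: np.ndarray
    base_nodes: np.ndarray            # node ids on the base plane z = 0
    long_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    n_layers: int = 2

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.elements].mean(axis=1)


@dataclass
class FiberField:
    """Unit fiber direction per element, plus the local frame used."""

    n_f: np.ndarray            # (E, 3)
    circumferential: np.ndarray
    longitudinal: np.ndarray


def _ellipsoid_point(u: float, phi: np.ndarray, a: float, c: float) -> np.ndarray:
    """Lower-half ellipsoid surface point; u = 0 apex, u = pi/2 base."""
    su, cu = np.sin(u), np.cos(u)
    return np.stack([a * su * np.cos(phi), a * su * np.sin(phi),
                     -c * cu * np.ones_like(phi)], axis=-1)


def make_idealized_ventricle(long_axis_len: float = 50.0, endo_radius: float = 25.0,
                             wall_thickness: float = 5.0, n_slices: int = 8,
                             n_circ: int = 16, n_layers: int = 2
                             ) -> tuple[SliceStack, VentricleMesh]:
    """Truncated half-ellipsoid thick-walled chamber, open at the base.

    The endocardial surface is the lower half of an ellipsoid with
    equatorial radius ``endo_radius`` and polar semi-axis
    ``long_axis_len``; the epicardium is offset by ``wall_thickness`` in
    both.  Returns the matching slice stack and hexahedral mesh.
    """
    a, c, t = float(endo_radius), float(long_axis_len), float(wall_thickness)
    if min(a, c, t) <= 0:
        raise ValueError("all dimensions must be positive")
    if t >= a:
        raise ValueError(f"wall thickness {t} must be smaller than endo radius {a}")
    if n_slices < 3 or n_circ < 8:
        raise ValueError("need n_slices >= 3 and n_circ >= 8")

    phi = 2.0 * np.pi * np.arange(n_circ) / n_circ
    # base first (u = pi/2), moving toward the apex; both contours of a
    # short-axis slice share the z of the endocardial ellipsoid
    us = np.pi / 2.0 * (1.0 - np.arange(n_slices) / n_slices)
    slices = []
    for u in us:
        inner = _ellipsoid_point(u, phi, a, c)[:, :2]
        z = -c * np.cos(u)
        r_out = (a + t) * np.sqrt(max(0.0, 1.0 - (z / (c + t)) ** 2))
        outer = np.stack([r_out * np.cos(phi), r_out * np.sin(phi)], axis=-1)
        slices.append((z, inner, outer))
    stack = SliceStack(slices, apex_inner_z=-c, apex_outer_z=-(c + t))
    mesh = mesh_from_stack(stack, n_layers=n_layers)
    return stack, mesh


def _resample_contour(contour: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed CCW contour at n points of equal arc length."""
    pts = np.vstack([contour, contour[:1]])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, s[-1], n, endpoint=False)
    x = np.interp(targets, s, pts[:, 0])
    y = np.interp(targets, s, pts[:, 1])
    return np.stack([x, y], axis=-1)


def mesh_from_stack(stack: SliceStack, n_layers: int = 2,
                    n_circ: int | None = None) -> VentricleMesh:
    """Build a structured hex mesh from a slice stack.

    Node rings are placed on each slice by transmural interpolation
    between the (resampled) inner and outer contours; the apex is closed
    by one pole node per transmural sheet, giving collapsed hexes in the
    last longitudinal strip.
    """
    if n_circ is None:
        n_circ = len(stack.slices[0][1])
    n_s = stack.n_slices
    n_sheet = n_layers + 1
    rings = []  # rings[j][ir] -> (n_circ, 3)
    for z, inner, outer in stack.slices:
        inn = _resample_contour(inner, n_circ)
        out = _resample_contour(outer, n_circ)
        ring = []
        for ir in range(n_sheet):
            s = ir / n_layers
            xy = (1.0 - s) * inn + s * out
            ring.append(np.column_stack([xy, np.full(n_circ, z)]))
        rings.append(ring)

    nodes = []
    index = {}
    for j in range(n_s):
        for ir in range(n_sheet):
            for k in range(n_circ):
                index[(j, ir, k)] = len(nodes)
                nodes.append(rings[j][ir][k])
    # pole nodes, one per sheet, interpolated between apex points
    pole = {}
    cen = rings[-1][0].mean(axis=0)[:2] * 0.0  # apex on the long axis
    for ir in range(n_sheet):
        s = ir / n_layers
        z = (1.0 - s) * stack.apex_inner_z + s * stack.apex_outer_z
        pole[ir] = len(nodes)
        nodes.append(np.array([cen[0], cen[1], z]))
    nodes = np.array(nodes)

    def nid(j, ir, k):
        return index[(j, ir, k % n_circ)]

    elements, layer_tag = [], []
    endo_faces, epi_faces = [], []
    for j in range(n_s - 1):
        for k in range(n_circ):
            for ir in range(n_layers):
                elements.append([
                    nid(j, ir, k), nid(j + 1, ir, k),
                    nid(j + 1, ir, k + 1), nid(j, ir, k + 1),
                    nid(j, ir + 1, k), nid(j + 1, ir + 1, k),
                    nid(j + 1, ir + 1, k + 1), nid(j, ir + 1, k + 1),
                ])
                layer_tag.append(ir)
            endo_faces.append([nid(j, 0, k), nid(j, 0, k + 1),
                               nid(j + 1, 0, k + 1), nid(j + 1, 0, k)])
            epi_faces.append([nid(j, n_layers, k + 1), nid(j, n_layers, k),
                              nid(j + 1, n_layers, k), nid(j + 1, n_layers, k + 1)])
    # apex strip: last ring collapses onto the pole nodes
    j = n_s - 1
    for k in range(n_circ):
        for ir in range(n_layers):
            elements.append([
                nid(j, ir, k), pole[ir], pole[ir], nid(j, ir, k + 1),
                nid(j, ir + 1, k), pole[ir + 1], pole[ir + 1], nid(j, ir + 1, k + 1),
            ])
            layer_tag.append(ir)
        endo_faces.append([nid(j, 0, k), nid(j, 0, k + 1), pole[0], pole[0]])
        epi_faces.append([nid(j, n_layers, k + 1), nid(j, n_layers, k),
                          pole[n_layers], pole[n_layers]])

    elements = np.array(elements, dtype=int)
    mesh = VentricleMesh(
        nodes=nodes, elements=elements,
        layer_tag=np.array(layer_tag, dtype=int),
        region_tag=np.full(len(elements), "RV", dtype=object),
        endo_faces=np.array(endo_faces, dtype=int),
        epi_faces=np.array(epi_faces, dtype=int),
        base_nodes=np.array([index[(0, ir, k)] for ir in range(n_sheet)
                             for k in range(n_circ)], dtype=int),
        n_layers=n_layers,
    )
    _check_jacobians(mesh)
    _orient_faces(mesh)
    return mesh


_GAUSS_1D = np.array([-1.0, 1.0]) / np.sqrt(3.0)


def _hex_shape_grad(xi, eta, zeta):
    """Trilinear shape functions and parametric gradients at one point."""
    signs = np.array([[-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
                      [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1]], dtype=float)
    s = signs
    N = 0.125 * (1 + s[:, 0] * xi) * (1 + s[:, 1] * eta) * (1 + s[:, 2] * zeta)
    dN = np.empty((8, 3))
    dN[:, 0] = 0.125 * s[:, 0] * (1 + s[:, 1] * eta) * (1 + s[:, 2] * zeta)
    dN[:, 1] = 0.125 * s[:, 1] * (1 + s[:, 0] * xi) * (1 + s[:, 2] * zeta)
    dN[:, 2] = 0.125 * s[:, 2] * (1 + s[:, 0] * xi) * (1 + s[:, 1] * eta)
    return N, dN


def hex_gauss_points(order: int = 2):
    """(points, weights) of the tensor Gauss rule on [-1,1]^3."""
    if order == 1:
        return np.zeros((1, 3)), np.array([8.0])
    g = _GAUSS_1D
    pts = np.array([[x, y, z] for z in g for y in g for x in g])
    return pts, np.ones(8)


def _check_jacobians(mesh: VentricleMesh) -> None:
    pts, _ = hex_gauss_points(2)
    X = mesh.nodes[mesh.elements]  # (E, 8, 3)
    for p in pts:
        _, dN = _hex_shape_grad(*p)
        J = np.einsum("eai,aj->eij", X, dN)
        det = np.linalg.det(J)
        if np.any(det <= 0):
            bad = int(np.argmin(det))
            raise ValueError(f"non-positive Jacobian in element {bad} "
                             f"(det = {det[bad]:.3g})")


def _orient_faces(mesh: VentricleMesh) -> None:
    """Flip face quads whose bilinear normal points into the wall."""
    cen = mesh.nodes.mean(axis=0)
    for faces, inward_positive in [(mesh.endo_faces, True), (mesh.epi_faces, False)]:
        quad = mesh.nodes[faces]  # (m, 4, 3)
        e1 = quad[:, 1] - quad[:, 0]
        e2 = quad[:, 3] - quad[:, 0]
        n = np.cross(e1, e2)
        mid = quad.mean(axis=1)
        outward = mid - cen  # roughly radial
        dots = np.einsum("mi,mi->m", n, outward)
        flip = dots > 0 if inward_positive else dots < 0
        faces[flip] = faces[flip][:, ::-1]


def assign_fibers(mesh: VentricleMesh, endo_angle: float = 40.0,
                  epi_angle: float = -45.0) -> FiberField:
    """Rule-based per-layer helix angles (degrees from circumferential).

    Elements in the innermost layer get ``endo_angle``, the outermost
    ``epi_angle``; intermediate layers interpolate linearly.  The angle
    rotates the local circumferential direction toward the local
    longitudinal (meridian) direction in the wall tangent plane.  The
    frame is built from the mesh's own long axis, so the field co-rotates
    with rigid motions of the mesh.
    """
    z_dir = mesh.long_axis / np.linalg.norm(mesh.long_axis)
    cent = mesh.element_centroids()
    axial = np.einsum("ei,i->e", cent, z_dir)[:, None] * z_dir
    radial = cent - axial
    r = np.linalg.norm(radial, axis=1)
    degenerate = r < 1e-9 * max(1.0, np.abs(cent).max())
    if np.any(degenerate):
        warnings.warn(f"{int(degenerate.sum())} apex elements have a degenerate "
                      "local frame; falling back to slice-plane tangent")
        radial[degenerate] = np.array([1.0, 0.0, 0.0]) - z_dir[0] * z_dir
    r_hat = radial / np.linalg.norm(radial, axis=1, keepdims=True)
    e_c = np.cross(z_dir, r_hat)
    e_c /= np.linalg.norm(e_c, axis=1, keepdims=True)

    # meridian direction from the slice-to-slice element edges (faces
    # [1,2,5,6] sit one ring closer to the apex than [0,3,4,7]),
    # orthogonalized against e_c; convention: points from apex to base
    X = mesh.nodes[mesh.elements]
    along = X[:, [0, 3, 4, 7]].mean(axis=1) - X[:, [1, 2, 5, 6]].mean(axis=1)
    along -= np.einsum("ei,ei->e", along, e_c)[:, None] * e_c
    norms = np.linalg.norm(along, axis=1, keepdims=True)
    small = norms[:, 0] < 1e-12
    if np.any(small):
        fallback = np.cross(e_c[small], r_hat[small])
        along[small] = fallback
        norms = np.linalg.norm(along, axis=1, keepdims=True)
    e_l = along / norms

    if mesh.n_layers > 1:
        frac = mesh.layer_tag / (mesh.n_layers - 1)
    else:
        frac = np.zeros(mesh.n_elements)
    ang = np.deg2rad(endo_angle + (epi_angle - endo_angle) * frac)[:, None]
    n_f = np.cos(ang) * e_c + np.sin(ang) * e_l
    n_f /= np.linalg.norm(n_f, axis=1, keepdims=True)
    return FiberField(n_f=n_f, circumferential=e_c, longitudinal=e_l)


@dataclass
class PressureProfile:
    """Key-point pressures (mmHg) over one cardiac period (s).

    Key points: bf (begin-filling, minimum pressure), ef (end-filling,
    end-diastole pressure), be (begin-ejection, maximum pressure), ee
    (end-ejection, end-systole pressure); piecewise-linear in between.
    """

    key_points: dict[str, tuple[float, float]]
    period: float = 0.8

    def __post_init__(self):
        p = {k: v[1] for k, v in self.key_points.items()}
        if not (p["bf"] <= p["ef"] < p["be"] and p["ee"] < p["be"]):
            raise ValueError(f"pressure ordering violated: {p}")
        if any(v < 0 for v in p.values()):
            raise ValueError("pressures must be non-negative")
        ts = [self.key_points[k][0] for k in TIME_POINTS]
        if not all(ts[i] < ts[i + 1] for i in range(3)):
            raise ValueError("key-point times must increase bf < ef < be < ee")

    def pressure(self, t: float) -> float:
        """Piecewise-linear pressure at time t (periodic)."""
        ts = np.array([self.key_points[k][0] for k in TIME_POINTS])
        ps = np.array([self.key_points[k][1] for k in TIME_POINTS])
        tt = np.mod(t, self.period)
        ts_ext = np.r_[ts, ts[0] + self.period]
        ps_ext = np.r_[ps, ps[0]]
        return float(np.interp(tt, ts_ext, ps_ext))

    def at(self, key: str) -> float:
        return self.key_points[key][1]


def make_pressure_profile(p_max: float, p_min: float | None = None,
                          p_ed: float | None = None, p_es: float | None = None,
                          period: float = 0.8) -> PressureProfile:
    """Pressure schedule from the cycle's key-point pressures (mmHg).

    Only maximum pressures are reported for the cohort, so the remaining
    key points default to configurable fractions of ``p_max``: minimum
    0.1, end-diastole 0.6, end-systole 0.35.  Diastole occupies the first
    ~60% of the period.
    """
    if p_min is None:
        p_min = 0.1 * p_max
    if p_ed is None:
        p_ed = 0.6 * p_max
    if p_es is None:
        p_es = 0.35 * p_max
    if not (p_min <= p_es < p_max and p_min <= p_ed < p_max):
        raise ValueError(
            f"need p_min <= p_es < p_max and p_min <= p_ed < p_max, got "
            f"p_min={p_min}, p_ed={p_ed}, p_es={p_es}, p_max={p_max}")
    key_points = {"bf": (0.0, p_min), "ef": (0.60 * period, p_ed),
                  "be": (0.65 * period, p_max), "ee": (0.95 * period, p_es)}
    return PressureProfile(key_points=key_points, period=period)


# -- synthetic cohorts -------------------------------------------------------

# per-time-point group stress means (kPa) and pooled spreads mirroring the
# published 2G tables; these are the generator's study conditions
_BG_STRESS_MEAN = {"bf": 3.07, "ef": 21.42, "be": 52.93, "ee": 12.76}
_WG_STRESS_GAP = {"bf": 2.10, "ef": 12.92, "be": 34.01, "ee": 9.56}
_STRESS_SD_SCALE = {"bf": 1.20 / 9.0, "ef": 1.0, "be": 24.6 / 9.0, "ee": 5.7 / 9.0}
_STRAIN_MEAN = {"bf": 0.030, "ef": 0.391, "be": 0.501, "ee": 0.100}
_STRAIN_SD = {"bf": 0.010, "ef": 0.119, "be": 0.127, "ee": 0.016}


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Conditions for a synthetic BG/WG cohort.

    ``group_effect`` is the additive WG-minus-BG mean stress offset at
    end-filling (kPa); the offsets at the other time points scale with the
    published gap structure.  ``noise_sd`` is the end-filling stress SD.
    Strains carry no group effect; delta-EF is drawn with a negative
    rank association (target magnitude ``rank_corr``) to end-filling
    stress.
    """

    n_per_group: int = 6
    group_effect: float = 12.9
    noise_sd: float = 9.0
    rank_corr: float = 0.65
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ValueError("need n_per_group >= 2")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


def generate_synthetic_cohort(spec: SyntheticCohortSpec) -> Cohort:
    """Draw a reproducible synthetic TOF-like cohort.

    Stress: BG values normal around the published BG means; WG values
    offset by the group effect (scaled per time point); both share the
    published heteroscedastic spread.  Strain: both groups around the
    published TOF means (no effect).  delta-EF: Gaussian-copula coupled to
    end-filling stress with negative correlation, then shifted so the
    median split reproduces even groups on average.
    """
    rng = np.random.default_rng(spec.seed)
    participants = []
    n = spec.n_per_group
    zs_ef = {}
    for gi, grp in enumerate(["BG", "WG"]):
        for i in range(n):
            pid = f"S{gi * n + i + 1}"
            stress = {}
            z_ef = None
            for tp in TIME_POINTS:
                z = rng.standard_normal()
                if tp == "ef":
                    z_ef = z
                mean = _BG_STRESS_MEAN[tp]
                if grp == "WG":
                    mean += spec.group_effect * _WG_STRESS_GAP[tp] / _WG_STRESS_GAP["ef"]
                sd = spec.noise_sd * _STRESS_SD_SCALE[tp]
                stress[tp] = max(0.05, mean + sd * z)
            strain = {tp: max(0.001, _STRAIN_MEAN[tp] + _STRAIN_SD[tp] * rng.standard_normal())
                      for tp in TIME_POINTS}
            rho = spec.rank_corr
            z_ind = rng.standard_normal()
            z_def = -rho * z_ef + np.sqrt(max(0.0, 1.0 - rho**2)) * z_ind
            delta_ef = -5.1 + 8.5 * z_def - (2.0 if grp == "WG" else -2.0)
            edv = float(np.exp(rng.normal(np.log(330.0), 0.25)))
            ef = float(np.clip(rng.normal(41.6, 6.8), 15, 65))
            esv = edv * (1.0 - ef / 100.0)
            p_max = float(np.clip(rng.normal(40.0, 12.0), 12, 80))
            participants.append(Participant(
                id=pid, group=grp, sex=rng.choice(["M", "F"]), age=float(rng.uniform(10, 60)),
                p_max=p_max, edv=edv, esv=esv, ef=ef,
                edvi=edv / 1.7, esvi=esv / 1.7, delta_ef=float(delta_ef),
                stress_1g={"bf": stress["bf"], "be": max(0.05, stress["be"] - 2.0)},
                stress_2g=dict(stress),
                strain_1g={"bf": strain["bf"], "be": max(0.001, strain["be"] - 0.1)},
                strain_2g=dict(strain),
            ))
            zs_ef[pid] = z_ef
    return Cohort(participants, provenance=f"synthetic(seed={spec.seed})")


def export_mesh_vtk(mesh: VentricleMesh, path, point_data: dict | None = None,
                    cell_data: dict | None = None) -> None:
    """Write the mesh as legacy ASCII VTK (unstructured grid, hexahedra)."""
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nventmech mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        for p in mesh.nodes:
            fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        E = mesh.n_elements
        fh.write(f"CELLS {E} {E * 9}\n")
        for el in mesh.elements:
            fh.write("8 " + " ".join(str(i) for i in el) + "\n")
        fh.write(f"CELL_TYPES {E}\n" + "12\n" * E)
        if point_data:
            fh.write(f"POINT_DATA {mesh.n_nodes}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr)
                if arr.ndim == 2 and arr.shape[1] == 3:
                    fh.write(f"VECTORS {name} double\n")
                    for v in arr:
                        fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
                else:
                    fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    for v in arr:
                        fh.write(f"{float(v):.9g}\n")
        if cell_data:
            fh.write(f"CELL_DATA {E}\n")
            for name, arr in cell_data.items():
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                for v in np.asarray(arr, dtype=float):
                    fh.write(f"{v:.9g}\n")
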