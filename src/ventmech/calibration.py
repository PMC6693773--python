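"""Zero-load geometry estimation and the two-reference (2G) cycle.

In vivo imaging shows the ventricle under pressure, so the unloaded
(zero-load) configuration that mechanics must start from is unknown.  The
pre-shrink procedure estimates it: every short-axis slice of the
minimum-volume in-vivo geometry is shrunk — the inner contour more, the
outer contour just enough less that wall (muscle) volume is conserved —
and the slice spacing is reduced along the long axis; the shrunk
geometry is re-inflated to the phase's pressure and the shrink rate is
iterated until the pressurized cavity volume matches the imaged volume
(relative error < 0.5%).

Because active contraction shortens the sarcomere zero-stress length,
diastole and systole get *different* zero-load geometries: the diastolic
one starts from a 2% shrink, the systolic one (reflecting 10-15%
sarcomere shortening) from 15%, and is calibrated against the
end-systole-pressure volume.  A 2G model is literally two models — the
diastolic geometry serves the filling states (bf, ef), the systolic
geometry the ejection states (be, ee).  The 1G model uses the diastolic
geometry alone with only minimum and maximum pressure, so its ef/ee
states are aliased copies of be/bf.

Material stiffness is calibrated per phase by scaling (c1, D1, K1) with
one common factor until inflated volumes match prescribed
pressure-volume targets (relative error < 0.2%).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .constitutive import MaterialParams
from .fem import SolverConfig, SolutionField, cavity_volume, solve_inflation
from .geometry import (FiberField, PressureProfile, SliceStack, VentricleMesh,
                       assign_fibers, mesh_from_stack, polygon_area,
                       _resample_contour)

__all__ = [
    "ZeroLoadGeometry",
    "TwoGModel",
    "CalibrationConfig",
    "CalibrationError",
    "preshrink",
    "calibrate_zero_load",
    "calibrate_material",
    "run_cardiac_cycle_2g",
    "run_cardiac_cycle_1g",
]


class CalibrationError(RuntimeError):
    """Raised when a calibration loop cannot reach its target."""


@dataclass(frozen=True)
class CalibrationConfig:
    init_shrink_diastole: float = 0.02
    init_shrink_systole: float = 0.15
    volume_tol: float = 0.005        # geometry calibration, relative
    param_volume_tol: float = 0.002  # material calibration, relative
    max_outer_iters: int = 30
    shrink_bounds: tuple[float, float] = (0.0, 0.5)
    n_layers: int = 2
    fiber_angles: tuple[float, float] = (40.0, -45.0)  # endo, epi (degrees)

    def __post_init__(self):
        if not 0 < self.volume_tol < 1:
            raise ValueError("volume_tol must be in (0, 1)")
        for s in (self.init_shrink_diastole, self.init_shrink_systole):
            if not 0 < s < 0.5:
                raise ValueError("initial shrinks must be in (0, 0.5)")


@dataclass
class ZeroLoadGeometry:
    phase: str                       # "diastole" or "systole"
    slice_stack: SliceStack
    mesh: VentricleMesh
    fibers: FiberField
    shrink_rate_short_axis: float
    shrink_rate_long_axis: float
    source_wall_volume: float

    def wall_volume_drift(self) -> float:
        return abs(self.slice_stack.wall_volume() / self.source_wall_volume - 1.0)


@dataclass
class TwoGModel:
    diastole_geom: ZeroLoadGeometry
    systole_geom: ZeroLoadGeometry
    params_diastole: MaterialParams
    params_systole: MaterialParams
    pressure_profile: PressureProfile
    target_volumes: dict[str, float] = field(default_factory=dict)  # tp -> mm^3


def preshrink(stack: SliceStack, inner_rate: float,
              long_axis_rate: float | None = None) -> SliceStack:
    """Shrink a slice stack toward a zero-load candidate geometry.

    Each inner contour is scaled about its centroid by (1 - inner_rate).
    The outer contour scale is the closed-form root that keeps the
    slice's wall volume contribution conserved after the long-axis
    spacing contracts by (1 - long_axis_rate): the wall area is inflated
    by 1/(1 - long_axis_rate) so area x spacing is invariant.  Total wall
    volume is conserved to within the prismatic-rule error (< 0.1%).
    """
    if long_axis_rate is None:
        long_axis_rate = inner_rate
    if not 0 <= inner_rate < 1:
        raise ValueError("inner_rate must be in [0, 1)")
    if not 0 <= long_axis_rate < 1:
        raise ValueError("long_axis_rate must be in [0, 1)")
    if inner_rate == 0 and long_axis_rate == 0:
        return copy.deepcopy(stack)
    axial = 1.0 - long_axis_rate
    new_slices = []
    for z, inner, outer in stack.slices:
        ci = inner.mean(axis=0)
        co = outer.mean(axis=0)
        a_in, a_out = polygon_area(inner), polygon_area(outer)
        wall = a_out - a_in
        s_in = 1.0 - inner_rate
        a_in_new = a_in * s_in**2
        a_out_new = wall / axial + a_in_new
        s_out = np.sqrt(a_out_new / a_out)
        inner_new = ci + s_in * (inner - ci)
        outer_new = co + s_out * (outer - co)
        # wall-inversion guard: outer must still enclose inner
        n_chk = max(len(inner_new), len(outer_new), 32)
        ri = _resample_contour(inner_new - ci, n_chk)
        ro = _resample_contour(outer_new - ci, n_chk)
        if np.hypot(*ro.T).min() <= np.hypot(*ri.T).max():
            raise CalibrationError(
                f"wall inversion at z={z:.2f}: inner shrink {inner_rate} "
                f"forces outer scale {s_out:.3f} inside the inner contour")
        new_slices.append((z * axial, inner_new, outer_new))
    # apex cap: the inner apex height scales with the long axis; the outer
    # apex height is solved so the cap's wall volume is conserved exactly
    z_last, inner_old, outer_old = stack.slices[-1]
    a_in_old, a_out_old = polygon_area(inner_old), polygon_area(outer_old)
    cap_wall = (a_out_old * (z_last - stack.apex_outer_z)
                - a_in_old * (z_last - stack.apex_inner_z)) / 3.0
    zl_new, inner_new, outer_new = new_slices[-1]
    a_in_new, a_out_new = polygon_area(inner_new), polygon_area(outer_new)
    zi_new = stack.apex_inner_z * axial
    zo_new = zl_new - (3.0 * cap_wall + a_in_new * (zl_new - zi_new)) / a_out_new
    return SliceStack(new_slices, long_axis=stack.long_axis.copy(),
                      apex_inner_z=zi_new, apex_outer_z=zo_new)


def _build(stack: SliceStack, config: CalibrationConfig):
    mesh = mesh_from_stack(stack, n_layers=config.n_layers)
    fibers = assign_fibers(mesh, *config.fiber_angles)
    return mesh, fibers


def _inflated_volume(stack: SliceStack, pressure: float, params: MaterialParams,
                     config: CalibrationConfig, solver: SolverConfig) -> float:
    mesh, fibers = _build(stack, config)
    if pressure == 0.0:
        return cavity_volume(mesh)
    sol = solve_inflation(mesh, fibers, params, pressure, solver)
    return sol.cavity_volume


def calibrate_zero_load(source_stack: SliceStack, target_volume: float,
                        applied_pressure: float, params: MaterialParams,
                        config: CalibrationConfig = CalibrationConfig(),
                        solver: SolverConfig = SolverConfig(),
                        phase: str = "diastole") -> tuple[ZeroLoadGeometry, list]:
    """Find the shrink rate whose re-inflated cavity volume hits the target.

    The signed relative volume error is monotone decreasing in the shrink
    rate, so the root is found by bracketing plus secant updates starting
    from the phase's conventional initial shrink (2% diastole, 15%
    systole).  Returns the calibrated geometry and the iteration trace of
    (shrink, inflated volume, relative error) triples.

    ``target_volume`` is in mm^3 and ``applied_pressure`` in mmHg (the
    minimum pressure for the diastolic phase, the end-systole pressure
    for the systolic phase).
    """
    if target_volume <= 0:
        raise ValueError("target_volume must be positive")
    s0 = (config.init_shrink_diastole if phase == "diastole"
          else config.init_shrink_systole)
    wall0 = source_stack.wall_volume()
    trace: list[dict] = []

    def err(s: float) -> float:
        stack = preshrink(source_stack, s)
        vol = _inflated_volume(stack, applied_pressure, params, config, solver)
        e = vol / target_volume - 1.0
        trace.append({"shrink": s, "volume": vol, "rel_error": e})
        return e

    lo, hi = config.shrink_bounds
    # zero-pressure degenerate case: accept shrink 0 if the source already
    # matches the target
    if applied_pressure == 0.0:
        e0 = err(0.0)
        if abs(e0) < config.volume_tol:
            return _finish(source_stack, 0.0, phase, wall0, config), trace

    s = min(max(s0, lo + 1e-6), hi - 1e-6)
    e = err(s)
    if abs(e) < config.volume_tol:
        return _finish(preshrink(source_stack, s), s, phase, wall0, config), trace

    # expand a bracket: error decreases with shrink
    s_lo, e_lo, s_hi, e_hi = None, None, None, None
    if e > 0:
        s_lo, e_lo = s, e
        step = max(0.05, s)
        probe = s
        while probe < hi - 1e-9:
            probe = min(hi - 1e-9, probe + step)
            ep = err(probe)
            if abs(ep) < config.volume_tol:
                return _finish(preshrink(source_stack, probe), probe, phase,
                               wall0, config), trace
            if ep < 0:
                s_hi, e_hi = probe, ep
                break
            s_lo, e_lo = probe, ep
            step *= 2.0
    else:
        s_hi, e_hi = s, e
        probe = s
        step = max(0.02, s / 2)
        while probe > lo + 1e-9:
            probe = max(lo, probe - step)
            ep = err(probe)
            if abs(ep) < config.volume_tol:
                return _finish(preshrink(source_stack, probe), probe, phase,
                               wall0, config), trace
            if ep > 0:
                s_lo, e_lo = probe, ep
                break
            s_hi, e_hi = probe, ep
            step *= 2.0
    if s_lo is None or s_hi is None:
        raise CalibrationError(
            f"no shrink in [{lo}, {hi}] reaches target volume "
            f"{target_volume / 1000:.2f} cm^3 at {applied_pressure} mmHg; "
            f"trace: {[(round(t['shrink'], 4), round(t['rel_error'], 4)) for t in trace]}")

    # secant iterations inside the bracket, falling back to bisection
    for _ in range(config.max_outer_iters):
        denom = e_hi - e_lo
        s_new = s_lo - e_lo * (s_hi - s_lo) / denom if abs(denom) > 1e-15 else 0.5 * (s_lo + s_hi)
        if not (s_lo < s_new < s_hi):
            s_new = 0.5 * (s_lo + s_hi)
        e_new = err(s_new)
        if abs(e_new) < config.volume_tol:
            return _finish(preshrink(source_stack, s_new), s_new, phase,
                           wall0, config), trace
        if e_new > 0:
            s_lo, e_lo = s_new, e_new
        else:
            s_hi, e_hi = s_new, e_new
    raise CalibrationError(
        f"shrink iteration did not converge within {config.max_outer_iters} "
        f"iterations; last error {e_new:.4g}")


def _finish(stack: SliceStack, shrink: float, phase: str, wall0: float,
            config: CalibrationConfig) -> ZeroLoadGeometry:
    mesh, fibers = _build(stack, config)
    geom = ZeroLoadGeometry(phase=phase, slice_stack=stack, mesh=mesh,
                            fibers=fibers, shrink_rate_short_axis=shrink,
                            shrink_rate_long_axis=shrink,
                            source_wall_volume=wall0)
    drift = geom.wall_volume_drift()
    if drift > 1e-3:
        raise CalibrationError(f"wall volume drifted by {drift:.2%} during pre-shrink")
    return geom


def calibrate_material(geometry: ZeroLoadGeometry,
                       pressure_volume_targets: list[tuple[float, float]],
                       base_params: MaterialParams,
                       tol: float = 0.002,
                       solver: SolverConfig = SolverConfig(),
                       scale_bounds: tuple[float, float] = (1e-3, 1e3),
                       ) -> tuple[MaterialParams, list]:
    """Scale (c1, D1, K1) by a common factor to match volume targets.

    Inflated volume at fixed pressure decreases monotonically with the
    stiffness scale, so a single target is solved by bracketed root
    finding on log-scale; multiple targets minimize the summed relative
    volume error with the same scalar.  Targets are (mmHg, mm^3) pairs.
    Raises if no scale within ``scale_bounds`` reaches the target(s).
    """
    if not pressure_volume_targets:
        raise ValueError("need at least one pressure-volume target")
    trace: list[dict] = []
    mesh, fibers = geometry.mesh, geometry.fibers

    def vol_errors(scale: float) -> np.ndarray:
        p = base_params.scaled(scale)
        errs = []
        for pressure, vtarget in pressure_volume_targets:
            if pressure == 0.0:
                v = cavity_volume(mesh)
            else:
                v = solve_inflation(mesh, fibers, p, pressure, solver).cavity_volume
            errs.append(v / vtarget - 1.0)
        trace.append({"scale": scale, "rel_errors": errs})
        return np.array(errs)

    def mean_err(scale: float) -> float:
        return float(vol_errors(scale).mean())

    def done(scale: float) -> bool:
        return float(np.max(np.abs(trace[-1]["rel_errors"]))) < tol

    e1 = mean_err(1.0)
    if done(1.0):
        return base_params.scaled(1.0), trace
    lo, hi = scale_bounds
    # stiffer -> smaller volume -> negative error; expand a log-scale bracket
    s_lo, s_hi = 1.0, 1.0
    e_lo = e_hi = e1
    factor = 2.0
    while e_lo < 0 and s_lo > lo:       # too stiff at s_lo: soften
        s_lo = max(lo, s_lo / factor)
        e_lo = mean_err(s_lo)
        if done(s_lo):
            return base_params.scaled(s_lo), trace
    while e_hi > 0 and s_hi < hi:       # too soft at s_hi: stiffen
        s_hi = min(hi, s_hi * factor)
        e_hi = mean_err(s_hi)
        if done(s_hi):
            return base_params.scaled(s_hi), trace
    if e_lo < 0 or e_hi > 0:
        raise CalibrationError(
            f"volume targets unreachable with stiffness scale in {scale_bounds}; "
            f"errors at bounds: {e_lo:.3g}, {e_hi:.3g}")
    # secant on log-scale within the bracket, bisection fallback
    for _ in range(40):
        x_lo, x_hi = np.log(s_lo), np.log(s_hi)
        denom = e_hi - e_lo
        x_new = x_lo - e_lo * (x_hi - x_lo) / denom if abs(denom) > 1e-15 \
            else 0.5 * (x_lo + x_hi)
        if not (x_lo < x_new < x_hi) and not (x_hi < x_new < x_lo):
            x_new = 0.5 * (x_lo + x_hi)
        s_new = float(np.exp(x_new))
        e_new = mean_err(s_new)
        if done(s_new):
            return base_params.scaled(s_new), trace
        if e_new > 0:    # still too soft: move the soft end up
            s_lo, e_lo = s_new, e_new
        else:
            s_hi, e_hi = s_new, e_new
    raise CalibrationError(
        f"material calibration did not reach tol {tol}; last error {e_new:.3g} "
        f"(inconsistent multi-point targets?)")


def run_cardiac_cycle_2g(model: TwoGModel,
                         solver: SolverConfig = SolverConfig(),
                         n_periods: int = 3,
                         periodicity_tol: float = 1e-3,
                         ) -> dict[str, SolutionField]:
    """Quasi-static 2G cycle at the four key time points.

    The diastolic geometry is inflated to the bf and ef pressures, the
    systolic geometry to the be and ee pressures.  The schedule is
    repeated for ``n_periods`` periods; the solution is accepted when the
    last two periods differ by less than ``periodicity_tol`` (for this
    hyperelastic quasi-static model the response is periodic from the
    second period on, and the check certifies it).  Returns the final
    period's states keyed by time point.
    """
    prof = model.pressure_profile
    plan = {"bf": (model.diastole_geom, model.params_diastole),
            "ef": (model.diastole_geom, model.params_diastole),
            "be": (model.systole_geom, model.params_systole),
            "ee": (model.systole_geom, model.params_systole)}
    periods: list[dict[str, SolutionField]] = []
    for _ in range(n_periods):
        states = {}
        for tp, (geom, params) in plan.items():
            try:
                states[tp] = solve_inflation(geom.mesh, geom.fibers, params,
                                             prof.at(tp), solver)
            except Exception as exc:
                raise RuntimeError(f"cycle solve failed at time point {tp!r}: {exc}") from exc
        periods.append(states)
    if n_periods >= 2:
        diff = _period_difference(periods[-2], periods[-1])
        if diff > periodicity_tol:
            raise RuntimeError(
                f"last two periods differ by {diff:.3g} > {periodicity_tol}")
        periods[-1]["_periodicity"] = diff  # type: ignore[assignment]
    return periods[-1]


def _period_difference(a: dict, b: dict) -> float:
    num = den = 0.0
    for tp in ("bf", "ef", "be", "ee"):
        sa, sb = a[tp].gp_stress, b[tp].gp_stress
        num += float(np.abs(sa - sb).sum())
        den += float(np.abs(sb).sum())
    return num / max(den, 1e-30)


def run_cardiac_cycle_1g(geometry: ZeroLoadGeometry, p_min: float, p_max: float,
                         params: MaterialParams,
                         solver: SolverConfig = SolverConfig(),
                         ) -> dict[str, SolutionField]:
    """One-reference cycle: only bf (minimum pressure) and be (maximum).

    Downstream summaries alias ef := be and ee := bf when a four-point
    table is requested; the aliasing is flagged there.
    """
    states = {}
    for tp, p in [("bf", p_min), ("be", p_max)]:
        states[tp] = solve_inflation(geometry.mesh, geometry.fibers, params,
                                     p, solver)
    return states
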