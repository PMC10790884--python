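"""Simplified reference tissue model (SRTM): forward model and
simultaneous coupled fitting.

Model
-----
The SRTM expresses a target-region TAC as a function of the
reference-region TAC without arterial sampling:

    C_T(t) = R1 * C_R(t) + (k2 - R1 * k2a) * [C_R (*) exp(-k2a * t)](t)

with k2 = R1 * k2REF and k2a = k2 / (1 + BP_ND). R1 is the
target/reference delivery ratio, k2REF the reference efflux rate (per
minute at the API; seconds internally) and BP_ND the non-displaceable
binding potential. DVR = BP_ND + 1.

Fitting
-------
All ROI TACs of one scan are fitted simultaneously with a single shared
("coupled") k2REF: an outer bounded 1-D minimization profiles k2REF
over [0.01, 1.0] /min, and for each candidate the ROIs separate into
independent 2-parameter weighted NLLS problems in (R1, BP_ND). Each
inner problem is itself solved by profiling: given k2REF and a
candidate apparent efflux rate k2a, the model is linear in R1, so R1
has a closed-form weighted least-squares solution and only k2a needs a
1-D search. The forward curve is computed on a uniform fine grid
(default 1 s) with an exact-trapezoid recursive convolution and then
interval-averaged onto the frame schedule, matching what the scanner
measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.signal import lfilter

from .frames import SECONDS_PER_MINUTE, FrameSchedule
from .tac import TACSet

# parameter bounds (rates per minute)
R1_BOUNDS = (0.1, 3.0)
BP_BOUNDS = (-0.5, 10.0)
K2REF_BOUNDS = (0.01, 1.0)
DEFAULT_GRID_STEP = 1.0  # seconds


@dataclass(frozen=True)
class SRTMParams:
    """Per-ROI SRTM parameters; rates per minute."""

    r1: float
    k2ref: float
    bp_nd: float

    def __post_init__(self) -> None:
        if self.r1 <= 0:
            raise ValueError("R1 must be positive")
        if self.k2ref <= 0:
            raise ValueError("k2REF must be positive")
        if self.bp_nd <= -1:
            raise ValueError("BP_ND must exceed -1 (k2a must be positive)")

    @property
    def k2(self) -> float:
        return self.r1 * self.k2ref

    @property
    def k2a(self) -> float:
        return self.k2 / (1.0 + self.bp_nd)

    @property
    def dvr(self) -> float:
        return self.bp_nd + 1.0


@dataclass
class SRTMFit:
    """Result of a coupled fit: per-ROI parameters, one shared k2REF."""

    params: dict  # roi_id -> SRTMParams
    k2ref: float
    wrss: dict  # roi_id -> weighted residual sum of squares
    converged: bool
    iterations: int
    total_wrss: float = field(default=np.nan)
    objective_trace: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.isnan(self.total_wrss):
            self.total_wrss = float(sum(self.wrss.values()))


def bpnd_to_dvr(bp: float) -> float:
    """Distribution volume ratio from binding potential: DVR = BP_ND + 1."""
    bp = np.asarray(bp, dtype=float)
    if np.any(bp <= -1):
        raise ValueError("BP_ND must exceed -1")
    out = bp + 1.0
    return float(out) if out.ndim == 0 else out


def _exp_conv(curve: np.ndarray, k: float, dt: float) -> np.ndarray:
    """Trapezoid-exact convolution y(t) = int_0^t curve(s) exp(-k (t-s)) ds
    on a uniform grid, via the recursion
    y[i] = a y[i-1] + dt/2 (curve[i] + a curve[i-1]), a = exp(-k dt)."""
    a = np.exp(-k * dt)
    y = lfilter([dt / 2.0, a * dt / 2.0], [1.0, -a], curve)
    if curve[0] != 0.0:
        # lfilter starts from y[0] = dt/2 * curve[0]; the integral at t=0 is 0
        n = len(curve)
        y -= (dt / 2.0 * curve[0]) * np.exp(-k * dt * np.arange(n))
    else:
        y[0] = 0.0
    return y


def srtm_forward(
    params: SRTMParams, reference: np.ndarray, grid: np.ndarray
) -> np.ndarray:
    """Evaluate the SRTM target curve on the reference's fine grid.

    ``reference`` is the dense reference curve sampled on ``grid``, a
    uniform grid in seconds starting at 0. Rates in ``params`` are per
    minute. At t = 0 the target equals R1 * C_R(0).
    """
    grid = np.asarray(grid, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if grid.ndim != 1 or grid[0] != 0.0:
        raise ValueError("grid must be 1-D and start at 0")
    steps = np.diff(grid)
    if not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
        raise ValueError("grid must be uniform")
    dt = float(steps[0])
    k2 = params.k2 / SECONDS_PER_MINUTE
    k2a = params.k2a / SECONDS_PER_MINUTE
    conv = _exp_conv(reference, k2a, dt)
    return params.r1 * reference + (k2 - params.r1 * k2a) * conv


def frame_average(curve: np.ndarray, grid: np.ndarray, schedule: FrameSchedule) -> np.ndarray:
    """Interval-average a dense curve onto the frame schedule (trapezoid).

    PET frames measure interval-averaged activity, so model curves must
    be averaged over each frame, not sampled at midpoints.
    """
    grid = np.asarray(grid, dtype=float)
    curve = np.asarray(curve, dtype=float)
    if grid[0] > schedule.starts[0] or grid[-1] < schedule.ends[-1] - 1e-9:
        raise ValueError("fine grid does not cover the frame schedule")
    dt = grid[1] - grid[0]
    # cumulative trapezoid integral on the fine grid
    cum = np.concatenate([[0.0], np.cumsum((curve[1:] + curve[:-1]) / 2.0 * dt)])

    def integral(t: float) -> float:
        # exact for the piecewise-linear interpolant of the sampled curve
        idx = np.searchsorted(grid, t, side="right") - 1
        idx = min(max(idx, 0), len(grid) - 1)
        if idx == len(grid) - 1:
            return cum[-1]
        frac = t - grid[idx]
        c_t = curve[idx] + (curve[idx + 1] - curve[idx]) * frac / dt
        return cum[idx] + (curve[idx] + c_t) / 2.0 * frac

    starts, ends = schedule.starts, schedule.ends
    vals = np.array([integral(e) - integral(s) for s, e in zip(starts, ends)])
    return vals / schedule.durations


class _FramePackager:
    """Precomputed frame-averaging for repeated evaluation on one grid."""

    def __init__(self, grid: np.ndarray, schedule: FrameSchedule):
        dt = grid[1] - grid[0]
        si = np.rint(schedule.starts / dt).astype(int)
        ei = np.rint(schedule.ends / dt).astype(int)
        if not (np.allclose(schedule.starts, grid[si], atol=1e-9)
                and np.allclose(schedule.ends, grid[ei], atol=1e-9)):
            raise ValueError("frame boundaries must lie on the fine grid")
        self.si, self.ei, self.dt = si, ei, dt
        self.durations = schedule.durations

    def __call__(self, curve: np.ndarray) -> np.ndarray:
        cum = np.concatenate([[0.0], np.cumsum((curve[1:] + curve[:-1]) / 2.0 * self.dt)])
        return (cum[self.ei] - cum[self.si]) / self.durations


def _make_grid(schedule: FrameSchedule, step: float) -> np.ndarray:
    n = int(round(schedule.total_duration / step))
    return np.arange(n + 1) * step


def dense_reference(
    tacset: TACSet, grid: np.ndarray, n_iter: int = 8
) -> np.ndarray:
    """Reconstruct a dense reference curve from its frame-averaged TAC.

    Frame values are interval averages, not point samples, so plain
    midpoint interpolation is biased wherever the curve bends. Starting
    from the midpoint interpolant (anchored at (0, 0): activity is zero
    at injection), the midpoint knot values are corrected by fixed-point
    iteration until the interpolant's own frame averages reproduce the
    measured values.
    """
    schedule = tacset.schedule
    mid = schedule.midpoints()
    measured = tacset.reference.values
    packager = _FramePackager(grid, schedule)
    knots_t = np.concatenate([[0.0], mid])
    v = measured.copy()
    for _ in range(n_iter):
        curve = np.interp(grid, knots_t, np.concatenate([[0.0], v]))
        v = v + (measured - packager(curve))
    return np.interp(grid, knots_t, np.concatenate([[0.0], v]))


def _fit_one_roi(
    target: np.ndarray,
    weights: np.ndarray,
    ref_dense: np.ndarray,
    grid: np.ndarray,
    k2ref: float,
    packager: _FramePackager,
    xatol: float,
) -> tuple[float, float, float]:
    """Weighted NLLS for one ROI given the shared k2REF.

    Profiles k2a: for fixed k2a the model is C_T = R1 * b(k2a) with
    basis b = C_R + (k2REF - k2a) * conv(C_R, exp(-k2a t)), so R1 solves
    in closed form (clipped to bounds). Returns (r1, bp, wrss).
    """
    dt = grid[1] - grid[0]
    k2ref_s = k2ref / SECONDS_PER_MINUTE
    # k2a range implied by R1 and BP bounds
    lo = R1_BOUNDS[0] * k2ref / (1.0 + BP_BOUNDS[1])
    hi = R1_BOUNDS[1] * k2ref / (1.0 + BP_BOUNDS[0])

    def solve(k2a: float) -> tuple[float, float]:
        k2a_s = k2a / SECONDS_PER_MINUTE
        conv = _exp_conv(ref_dense, k2a_s, dt)
        basis = packager(ref_dense + (k2ref_s - k2a_s) * conv)
        denom = np.dot(weights * basis, basis)
        r1 = np.dot(weights * basis, target) / denom if denom > 0 else R1_BOUNDS[0]
        r1 = float(np.clip(r1, *R1_BOUNDS))
        resid = target - r1 * basis
        return r1, float(np.dot(weights * resid, resid))

    res = minimize_scalar(
        lambda k2a: solve(k2a)[1], bounds=(lo, hi), method="bounded",
        options={"xatol": xatol},
    )
    k2a = float(res.x)
    r1, wrss = solve(k2a)
    bp = float(np.clip(r1 * k2ref / k2a - 1.0, *BP_BOUNDS))
    return r1, bp, wrss


def fit_srtm_coupled(
    tacset: TACSet,
    grid_step: float = DEFAULT_GRID_STEP,
    k2ref_bounds: tuple = K2REF_BOUNDS,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> SRTMFit:
    """Fit all ROI TACs simultaneously with one shared k2REF.

    Minimizes the summed weighted residual sum of squares over
    {R1_i, BP_i} and a single k2REF by profiling: a bounded outer 1-D
    search over k2REF, with the separable per-ROI problems solved
    exactly inside each outer evaluation. Deterministic.
    """
    if len(tacset) < 1:
        raise ValueError("need at least one target TAC")
    if not np.any(tacset.reference.values > 0):
        raise ValueError("reference TAC must be positive somewhere")
    schedule = tacset.schedule
    grid = _make_grid(schedule, grid_step)
    ref_dense = dense_reference(tacset, grid)
    packager = _FramePackager(grid, schedule)
    roi_ids = tacset.roi_ids
    targets = {rid: tacset.tacs[rid].values for rid in roi_ids}
    weights = {rid: tacset.tacs[rid].weights for rid in roi_ids}

    trace: list[float] = []

    def objective(k2ref: float) -> float:
        total = 0.0
        for rid in roi_ids:
            _, _, wrss = _fit_one_roi(
                targets[rid], weights[rid], ref_dense, grid, k2ref, packager,
                xatol=1e-7,
            )
            total += wrss
        trace.append(total)
        return total

    res = minimize_scalar(
        objective, bounds=k2ref_bounds, method="bounded",
        options={"xatol": 1e-6, "maxiter": max_iter},
    )
    k2ref = float(res.x)
    params, wrss = {}, {}
    for rid in roi_ids:
        r1, bp, w = _fit_one_roi(
            targets[rid], weights[rid], ref_dense, grid, k2ref, packager, xatol=1e-9
        )
        params[rid] = SRTMParams(r1=r1, k2ref=k2ref, bp_nd=bp)
        wrss[rid] = w
    converged = bool(res.success) and res.nit < max_iter
    return SRTMFit(params=params, k2ref=k2ref, wrss=wrss,
                   converged=converged, iterations=int(res.nfev),
                   objective_trace=trace)


def fit_srtm_uncoupled(tacset: TACSet, **kwargs) -> dict:
    """Fit each ROI independently with its own k2REF (no coupling).

    Serves as the comparison arm for the coupling's variance benefit.
    Returns roi_id -> SRTMFit (each with a single ROI).
    """
    out = {}
    for rid in tacset.roi_ids:
        single = TACSet(tacs={rid: tacset.tacs[rid]}, reference=tacset.reference,
                        schedule=tacset.schedule)
        out[rid] = fit_srtm_coupled(single, **kwargs)
    return out
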