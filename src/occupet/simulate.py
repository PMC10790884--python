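"""Synthetic data with known ground truth for every pipeline stage.

Generates reference-region curves, ROI TACs from SRTM parameters,
baseline/blocking scan pairs with a planted occupancy field, 4D dynamic
phantoms, and rs-fMRI voxel series with planted parcel correlation
structure. Every stochastic draw is seeded and recorded in a
ground-truth ledger so recovery can be scored exactly.

Frame noise is zero-mean Gaussian with standard deviation
``noise_cv * peak / sqrt(duration_f / max_duration)`` — longer frames
accumulate more counts and are less noisy, a simple proxy for count
statistics that deliberately ignores decay and randoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .frames import DEFAULT_FRAMING, FrameSchedule, load_frame_schedule
from .parcellation import VoxelTimeSeriesSet
from .srtm import DEFAULT_GRID_STEP, SRTMParams, _make_grid, frame_average, srtm_forward
from .tac import TACSet, TimeActivityCurve, default_weights

DEFAULT_K2REF = 0.14  # /min, typical reference-region efflux for this tracer class


@dataclass(frozen=True)
class GroundTruthLedger:
    """True parameters behind a simulated study."""

    roi_ids: list
    r1: np.ndarray
    bp_baseline: np.ndarray
    bp_blocking: np.ndarray
    occupancy: np.ndarray  # percent
    k2ref_baseline: float
    k2ref_blocking: float
    reference_params: dict
    noise_cv: float
    seed: int
    true_labels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        expected = self.bp_baseline * (1.0 - self.occupancy / 100.0)
        if not np.allclose(self.bp_blocking, expected, rtol=0, atol=1e-12):
            raise ValueError("ledger violates BP_block = BP_base * (1 - Occ/100)")


def simulate_reference_curve(
    grid: np.ndarray,
    model: str = "gamma_variate",
    amplitude: float = 10.0,
    alpha: float = 1.0,
    beta: float = 300.0,
    lambdas: tuple = (1.0 / 2400.0, 1.0 / 120.0),
) -> np.ndarray:
    """Dense reference-region (cerebellum-like) curve on ``grid`` (s).

    ``gamma_variate``: A * t^alpha * exp(-t/beta), peaking at
    t = alpha * beta; ``biexponential``: A * (exp(-l1 t) - exp(-l2 t))
    with l2 > l1. Both start at 0, rise to a single early peak and wash
    out. ``amplitude`` rescales so the peak equals its value.
    """
    grid = np.asarray(grid, dtype=float)
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    if model == "gamma_variate":
        if alpha <= 0 or beta <= 0:
            raise ValueError("gamma-variate alpha and beta must be positive")
        curve = grid**alpha * np.exp(-grid / beta)
    elif model == "biexponential":
        l1, l2 = lambdas
        if not 0 < l1 < l2:
            raise ValueError("biexponential requires 0 < lambda1 < lambda2")
        curve = np.exp(-l1 * grid) - np.exp(-l2 * grid)
    else:
        raise ValueError(f"unknown reference model {model!r}")
    peak = curve.max()
    if peak <= 0:
        raise ValueError("reference curve is not positive anywhere on the grid")
    return amplitude * curve / peak


def _noise_sd(noise_cv: float, peak: float, schedule: FrameSchedule) -> np.ndarray:
    rel_dur = schedule.durations / schedule.durations.max()
    return noise_cv * peak / np.sqrt(rel_dur)


def simulate_study(
    n_rois: int = 8,
    r1_range: tuple = (0.7, 1.3),
    bp_range: tuple = (0.2, 4.0),
    occupancy_range: tuple = (20.0, 75.0),
    occupancy_field: np.ndarray | None = None,
    r1_values: np.ndarray | None = None,
    bp_values: np.ndarray | None = None,
    k2ref: float = DEFAULT_K2REF,
    noise_cv: float = 0.0,
    reference_noise_scale: float = 1.0 / np.sqrt(10.0),
    framing=None,
    weighting: str = "duration",
    grid_step: float = DEFAULT_GRID_STEP,
    reference_kwargs: dict | None = None,
    seed: int = 0,
) -> tuple[TACSet, TACSet, GroundTruthLedger]:
    """Simulate a baseline + blocking scan pair with known occupancy.

    Per-ROI R1 and baseline BP_ND are drawn uniformly from their ranges;
    the occupancy field (percent, in [0, 100]) fixes blocking BP via
    BP_block = BP_base * (1 - Occ/100). R1 and k2REF are shared across
    the two scans. TACs are frame-averaged SRTM forward curves plus
    duration-scaled Gaussian noise.

    Passing explicit ``r1_values``/``bp_values``/``occupancy_field``
    fixes the ground truth so replicate runs under different seeds
    redraw only the noise. The reference TAC's noise is scaled down by
    ``reference_noise_scale`` (default 1/sqrt(10)): the cerebellum
    reference region is roughly an order of magnitude larger than a
    single parcel, so its voxel-averaged TAC is correspondingly less
    noisy.
    """
    rng = np.random.default_rng(seed)
    schedule = load_frame_schedule(framing or DEFAULT_FRAMING)
    ref_kwargs = dict(reference_kwargs or {})
    grid = _make_grid(schedule, grid_step)
    reference_dense = simulate_reference_curve(grid, **ref_kwargs)

    r1 = (np.asarray(r1_values, dtype=float) if r1_values is not None
          else rng.uniform(*r1_range, size=n_rois))
    bp_base = (np.asarray(bp_values, dtype=float) if bp_values is not None
               else rng.uniform(*bp_range, size=n_rois))
    if r1.shape != (n_rois,) or bp_base.shape != (n_rois,):
        raise ValueError("r1/bp value arrays must have length n_rois")
    if occupancy_field is None:
        occupancy_field = rng.uniform(*occupancy_range, size=n_rois)
    occupancy_field = np.asarray(occupancy_field, dtype=float)
    if occupancy_field.shape != (n_rois,):
        raise ValueError("occupancy field length must equal n_rois")
    if np.any((occupancy_field < 0) | (occupancy_field > 100)):
        raise ValueError("occupancy field values must lie in [0, 100]")
    bp_block = bp_base * (1.0 - occupancy_field / 100.0)

    weights = default_weights(schedule, weighting)
    ref_frames = frame_average(reference_dense, grid, schedule)

    def make_scan(bp_values: np.ndarray, scan_rng: np.random.Generator) -> TACSet:
        tacs = {}
        for idx in range(n_rois):
            params = SRTMParams(r1=float(r1[idx]), k2ref=k2ref, bp_nd=float(bp_values[idx]))
            dense = srtm_forward(params, reference_dense, grid)
            clean = frame_average(dense, grid, schedule)
            if noise_cv > 0:
                sd = _noise_sd(noise_cv, clean.max(), schedule)
                clean = clean + scan_rng.normal(0.0, 1.0, size=len(schedule)) * sd
            tacs[idx] = TimeActivityCurve(idx, clean, schedule, weights)
        ref_vals = ref_frames
        if noise_cv > 0 and reference_noise_scale > 0:
            sd = _noise_sd(noise_cv * reference_noise_scale, ref_frames.max(), schedule)
            ref_vals = ref_frames + scan_rng.normal(0.0, 1.0, size=len(schedule)) * sd
        reference = TimeActivityCurve("reference", ref_vals, schedule, weights)
        return TACSet(tacs=tacs, reference=reference, schedule=schedule)

    baseline = make_scan(bp_base, np.random.default_rng(rng.integers(2**31)))
    blocking = make_scan(bp_block, np.random.default_rng(rng.integers(2**31)))
    ledger = GroundTruthLedger(
        roi_ids=list(range(n_rois)),
        r1=r1,
        bp_baseline=bp_base,
        bp_blocking=bp_block,
        occupancy=occupancy_field,
        k2ref_baseline=k2ref,
        k2ref_blocking=k2ref,
        reference_params={"model": "gamma_variate", **ref_kwargs},
        noise_cv=noise_cv,
        seed=seed,
    )
    return baseline, blocking, ledger


def simulate_dynamic_phantom(
    labels: np.ndarray, tacset: TACSet, voxel_noise: float = 0.0, seed: int = 0
) -> np.ndarray:
    """Paint a 4D dynamic image from per-label TACs.

    Every voxel of label i carries that label's TAC plus independent
    Gaussian voxel noise (SD = ``voxel_noise``); background stays 0.
    The reference TAC's label paints the reference region.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    n_frames = len(tacset.schedule)
    curves = {int(rid): tac.values for rid, tac in tacset.tacs.items()}
    if isinstance(tacset.reference.roi_id, (int, np.integer)):
        curves[int(tacset.reference.roi_id)] = tacset.reference.values
    present = [int(v) for v in np.unique(labels) if v != 0]
    missing = [v for v in present if v not in curves]
    if missing:
        raise ValueError(f"labels without a TAC: {missing}")
    out = np.zeros(labels.shape + (n_frames,), dtype=float)
    for lab in present:
        sel = labels == lab
        out[sel] = curves[lab]
    if voxel_noise > 0:
        out[labels > 0] += rng.normal(0.0, voxel_noise, size=out[labels > 0].shape)
    return out


def plant_parcels(mask: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """Partition a mask into k spatially compact parcels (labels 1..k)
    by seeded k-means on voxel coordinates."""
    from sklearn.cluster import KMeans

    mask = np.asarray(mask, dtype=bool)
    coords = np.argwhere(mask).astype(float)
    km = KMeans(n_clusters=k, n_init=3, random_state=seed).fit(coords)
    vol = np.zeros(mask.shape, dtype=np.int32)
    vol[mask] = km.labels_ + 1
    return vol


def simulate_rsfmri(
    mask: np.ndarray,
    true_labels: np.ndarray,
    within_r: float = 0.8,
    between_r: float = 0.0,
    n_timepoints: int = 180,
    n_subjects: int = 1,
    seed: int = 0,
) -> VoxelTimeSeriesSet:
    """Resting-state voxel series with planted parcel structure.

    Each parcel's voxels mix a shared latent series so that the expected
    within-parcel correlation is ``within_r`` and the across-parcel
    correlation is ``between_r`` (via a global component). The default
    180 timepoints mirror a ~7.5 min resting-state run at TR 2.46 s.
    """
    if not 0.0 <= between_r < within_r <= 1.0:
        raise ValueError("need 0 <= between_r < within_r <= 1")
    if n_timepoints < 2:
        raise ValueError("need at least 2 timepoints")
    mask = np.asarray(mask, dtype=bool)
    lab = np.asarray(true_labels)[mask]
    parcels = np.unique(lab)
    rng = np.random.default_rng(seed)
    n_vox = int(mask.sum())
    subjects = []
    a_global = np.sqrt(between_r)
    a_parcel = np.sqrt(within_r - between_r)
    a_noise = np.sqrt(1.0 - within_r)
    for _ in range(n_subjects):
        g = rng.standard_normal(n_timepoints)
        latents = {p: rng.standard_normal(n_timepoints) for p in parcels}
        noise = rng.standard_normal((n_vox, n_timepoints))
        ts = np.empty((n_vox, n_timepoints))
        for p in parcels:
            sel = lab == p
            ts[sel] = a_global * g + a_parcel * latents[p] + a_noise * noise[sel]
        subjects.append(ts)
    return VoxelTimeSeriesSet(subjects=subjects, mask=mask)
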