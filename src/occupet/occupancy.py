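"""Percent receptor occupancy from baseline/blocking BP_ND, ROI
filtering with refit, and study summary statistics.

Occupancy is the fractional reduction of binding potential from the
baseline scan to the post-drug (blocking) scan:

    Occ(%) = 100 * (BP_baseline - BP_blocking) / BP_baseline

ROIs with low baseline binding potential (< 0.2), low distribution
volume ratio (< 1.2), or physically impossible occupancy (< 0% or
> 100%) are discarded, and the coupled SRTM fit is repeated with the
remaining ROIs until the retained set is stable. Strict inequalities;
boundary values are retained.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .srtm import SRTMFit, bpnd_to_dvr, fit_srtm_coupled
from .tac import TACSet

REASONS = ("none", "low_bp", "low_dvr", "impossible_occupancy")


@dataclass(frozen=True)
class OccupancyRecord:
    roi_name: str | int
    bp_baseline: float
    bp_blocking: float
    occupancy_percent: float
    retained: bool
    discard_reason: str = "none"

    def __post_init__(self) -> None:
        if self.discard_reason not in REASONS:
            raise ValueError(f"unknown discard reason {self.discard_reason!r}")


@dataclass(frozen=True)
class OccupancySummary:
    n_retained: int
    bp_mean: float
    bp_sd: float
    occupancy_mean: float
    occupancy_sd: float
    occupancy_min: float
    occupancy_max: float
    top: pd.DataFrame  # columns roi, occupancy


def compute_occupancy(bp_baseline: float, bp_blocking: float) -> float:
    """Percent occupancy; may fall outside [0, 100] (filters handle that)."""
    bp_baseline = np.asarray(bp_baseline, dtype=float)
    bp_blocking = np.asarray(bp_blocking, dtype=float)
    if np.any(bp_baseline == 0):
        raise ValueError("occupancy undefined for zero baseline BP_ND")
    out = 100.0 * (bp_baseline - bp_blocking) / bp_baseline
    return float(out) if out.ndim == 0 else out


def apply_roi_filters(
    records: list[OccupancyRecord],
    bp_min: float = 0.2,
    dvr_min: float = 1.2,
    occupancy_bounds: tuple = (0.0, 100.0),
) -> tuple[list[OccupancyRecord], list[OccupancyRecord]]:
    """Split records into (retained, discarded) by the discard rules.

    Rules are evaluated on the baseline scan's BP/DVR with strict
    comparisons; the recorded reason is the first failing rule in the
    order low_bp, low_dvr, impossible_occupancy.
    """
    lo, hi = occupancy_bounds
    retained, discarded = [], []
    for rec in records:
        reason = "none"
        if rec.bp_baseline < bp_min:
            reason = "low_bp"
        elif bpnd_to_dvr(rec.bp_baseline) < dvr_min:
            reason = "low_dvr"
        elif rec.occupancy_percent < lo or rec.occupancy_percent > hi:
            reason = "impossible_occupancy"
        if reason == "none":
            retained.append(replace(rec, retained=True, discard_reason="none"))
        else:
            discarded.append(replace(rec, retained=False, discard_reason=reason))
    return retained, discarded


def _records_from_fits(base: SRTMFit, block: SRTMFit) -> list[OccupancyRecord]:
    recs = []
    for rid in base.params:
        bp_b = base.params[rid].bp_nd
        bp_k = block.params[rid].bp_nd
        occ = compute_occupancy(bp_b, bp_k) if bp_b != 0 else np.nan
        recs.append(OccupancyRecord(rid, bp_b, bp_k, occ, retained=True))
    return recs


def _subset(tacset: TACSet, roi_ids) -> TACSet:
    return TACSet(
        tacs={rid: tacset.tacs[rid] for rid in roi_ids},
        reference=tacset.reference,
        schedule=tacset.schedule,
    )


def filter_refit_loop(
    tacs_baseline: TACSet,
    tacs_blocking: TACSet,
    bp_min: float = 0.2,
    dvr_min: float = 1.2,
    occupancy_bounds: tuple = (0.0, 100.0),
    max_passes: int = 5,
    **fit_kwargs,
) -> pd.DataFrame:
    """Fit both scans, filter, drop, refit until the retained set is stable.

    Each scan gets its own coupled k2REF. Returns one row per input ROI
    with the final BP values, occupancy, retention flag and reason; for
    discarded ROIs the values from the pass in which they were dropped
    are kept.
    """
    base_ids = set(tacs_baseline.roi_ids)
    if base_ids != set(tacs_blocking.roi_ids):
        raise ValueError("baseline and blocking scans must share ROI ids")
    active = sorted(base_ids, key=str)
    final: dict = {}
    for _ in range(max_passes):
        fit_base = fit_srtm_coupled(_subset(tacs_baseline, active), **fit_kwargs)
        fit_block = fit_srtm_coupled(_subset(tacs_blocking, active), **fit_kwargs)
        records = _records_from_fits(fit_base, fit_block)
        retained, discarded = apply_roi_filters(
            records, bp_min=bp_min, dvr_min=dvr_min, occupancy_bounds=occupancy_bounds
        )
        for rec in retained + discarded:
            final[rec.roi_name] = rec
        if not retained:
            raise ValueError(
                "all ROIs discarded: "
                + ", ".join(f"{r.roi_name}:{r.discard_reason}" for r in discarded)
            )
        new_active = sorted((r.roi_name for r in retained), key=str)
        if new_active == active:
            break
        active = new_active
    rows = [final[rid] for rid in sorted(final, key=str)]
    return pd.DataFrame(
        {
            "roi": [r.roi_name for r in rows],
            "bp_baseline": [r.bp_baseline for r in rows],
            "bp_blocking": [r.bp_blocking for r in rows],
            "occupancy_percent": [r.occupancy_percent for r in rows],
            "retained": [r.retained for r in rows],
            "discard_reason": [r.discard_reason for r in rows],
        }
    )


def summarize(
    bp: np.ndarray, occupancy: np.ndarray, roi_names=None, top_k: int = 7
) -> OccupancySummary:
    """Study summary over per-ROI per-subject baseline BP and occupancy.

    ``bp`` and ``occupancy`` are (n_rois, n_subjects) arrays (a single
    column is fine). Per-ROI means are taken over subjects; the study
    mean and sample SD (n - 1) are computed over the per-ROI means, as
    are the min/max and the top-k ranking.
    """
    bp = np.atleast_2d(np.asarray(bp, dtype=float))
    occupancy = np.atleast_2d(np.asarray(occupancy, dtype=float))
    if bp.shape != occupancy.shape or bp.shape[0] < 1:
        raise ValueError("bp and occupancy must be equal-shape, nonempty (rois x subjects)")
    if roi_names is None:
        roi_names = [f"roi_{i}" for i in range(bp.shape[0])]
    bp_roi = bp.mean(axis=1)
    occ_roi = occupancy.mean(axis=1)
    order = np.argsort(occ_roi)[::-1][:top_k]
    top = pd.DataFrame(
        {"roi": [roi_names[i] for i in order], "occupancy": occ_roi[order]}
    )
    sd = lambda x: float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
    return OccupancySummary(
        n_retained=int(bp.shape[0]),
        bp_mean=float(bp_roi.mean()),
        bp_sd=sd(bp_roi),
        occupancy_mean=float(occ_roi.mean()),
        occupancy_sd=sd(occ_roi),
        occupancy_min=float(occ_roi.min()),
        occupancy_max=float(occ_roi.max()),
        top=top,
    )


def summarize_fixture(rows, top_k: int = 7) -> OccupancySummary:
    """Summarize the packaged per-ROI reference table."""
    bp = np.array([r.bp_baseline for r in rows])
    occ = np.array([r.occupancy for r in rows])
    return summarize(bp, occ, roi_names=[r.roi_name for r in rows], top_k=top_k)
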