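"""ROI time-activity-curve extraction from dynamic PET.

A ROI's TAC value for a frame is the unweighted mean over the ROI's
voxels of that frame's volume; the reference region is extracted
identically from its designated label. Inputs are assumed pre-aligned
(registration is upstream of this package).
"""

from __future__ import annotations

import numpy as np

from .frames import FrameSchedule
from .tac import TACSet, TimeActivityCurve, default_weights


def extract_roi_tacs(
    dynamic: np.ndarray,
    labels: np.ndarray,
    schedule: FrameSchedule,
    roi_ids=None,
    reference_id: int = None,
    weighting: str = "duration",
) -> TACSet:
    """Extract per-ROI TACs and the reference TAC from a 4D image.

    Parameters
    ----------
    dynamic
        4D array (x, y, z, frames).
    labels
        3D integer label volume on the same grid; 0 is background.
    roi_ids
        Target ROI labels; defaults to all nonzero labels except the
        reference.
    reference_id
        Label of the reference region (cerebellum in the study design).
    """
    dynamic = np.asarray(dynamic, dtype=float)
    labels = np.asarray(labels)
    if dynamic.ndim != 4 or labels.ndim != 3:
        raise ValueError("need a 4D dynamic image and a 3D label image")
    if dynamic.shape[:3] != labels.shape:
        raise ValueError(
            f"geometry mismatch: dynamic {dynamic.shape[:3]} vs labels {labels.shape}"
        )
    if dynamic.shape[3] != len(schedule):
        raise ValueError(
            f"dynamic image has {dynamic.shape[3]} frames, schedule {len(schedule)}"
        )
    if reference_id is None:
        raise ValueError("a reference label is required")
    present = set(int(v) for v in np.unique(labels) if v != 0)
    if roi_ids is None:
        roi_ids = sorted(present - {int(reference_id)})
    missing = [rid for rid in list(roi_ids) + [reference_id] if int(rid) not in present]
    if missing:
        raise ValueError(f"labels absent from label image: {missing}")

    w = default_weights(schedule, weighting)
    flat = dynamic.reshape(-1, dynamic.shape[3])
    lab_flat = labels.ravel()

    def roi_mean(rid: int) -> np.ndarray:
        sel = lab_flat == int(rid)
        if not sel.any():
            raise ValueError(f"ROI {rid} has no voxels")
        return flat[sel].mean(axis=0)

    tacs = {
        int(rid): TimeActivityCurve(int(rid), roi_mean(rid), schedule, w)
        for rid in roi_ids
    }
    reference = TimeActivityCurve(int(reference_id), roi_mean(reference_id), schedule, w)
    return TACSet(tacs=tacs, reference=reference, schedule=schedule)
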