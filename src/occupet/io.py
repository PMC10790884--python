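"""Readers and writers: NIfTI volumes, TSV tables, and the packaged
baseline-BP/occupancy reference table.

NIfTI handling goes through nibabel; affines are preserved on round
trips. ROI label volumes are nonnegative integers with 0 reserved for
background. TSV is used for all tabular interchange (TACs, fits,
occupancy records).
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .frames import FrameSchedule
from .tac import TACSet, TimeActivityCurve

N_SUBJECTS = 4


def read_dynamic_image(path, schedule: FrameSchedule | None = None):
    """Read a 4D dynamic PET NIfTI.

    Returns ``(data, affine)`` with data shaped (x, y, z, frames). If a
    schedule is given, the 4th-dimension length must match its frame
    count.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected a 4D dynamic image, got shape {data.shape}")
    if schedule is not None and data.shape[3] != len(schedule):
        raise ValueError(
            f"dynamic image has {data.shape[3]} volumes but schedule has "
            f"{len(schedule)} frames"
        )
    return data, img.affine


def read_label_image(path):
    """Read a 3D integer ROI label NIfTI.

    Returns ``(labels, affine)``; labels are nonnegative integers with
    0 meaning background.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D label image, got shape {data.shape}")
    labels = np.rint(data).astype(np.int32)
    if not np.allclose(data, labels, atol=1e-6):
        raise ValueError("label image contains non-integer values")
    if labels.min() < 0:
        raise ValueError("label image contains negative labels")
    return labels, img.affine


def write_image(path, data: np.ndarray, affine: np.ndarray | None = None) -> None:
    """Write an array as NIfTI, defaulting to an identity affine."""
    if affine is None:
        affine = np.eye(4)
    arr = np.asarray(data)
    if arr.dtype.kind in "iu":
        arr = arr.astype(np.int32)
    nib.save(nib.Nifti1Image(arr, affine), str(path))


def label_set(labels: np.ndarray) -> list[int]:
    """Distinct nonzero labels present in a label volume."""
    return sorted(int(v) for v in np.unique(labels) if v != 0)


def check_geometry(affine_a: np.ndarray, affine_b: np.ndarray, shape_a, shape_b) -> None:
    if tuple(shape_a[:3]) != tuple(shape_b[:3]):
        raise ValueError(f"image grids differ: {tuple(shape_a[:3])} vs {tuple(shape_b[:3])}")
    if not np.allclose(affine_a, affine_b, atol=1e-4):
        raise ValueError("image affines differ; inputs must be pre-aligned")


# ---------------------------------------------------------------------------
# TAC tables

def write_tacs_tsv(path, tacset: TACSet) -> None:
    """One row per ROI (reference row included), columns = frames."""
    sched = tacset.schedule
    cols = [f"frame_{i}" for i in range(len(sched))]
    rows = {str(tacset.reference.roi_id): tacset.reference.values}
    for roi_id, tac in tacset.tacs.items():
        rows[str(roi_id)] = tac.values
    df = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    df.index.name = "roi"
    df.to_csv(path, sep="\t")


def read_tacs_tsv(path, schedule: FrameSchedule, reference_row: str,
                  weights: np.ndarray | None = None) -> TACSet:
    df = pd.read_csv(path, sep="\t", index_col="roi")
    df.index = df.index.astype(str)
    if df.shape[1] != len(schedule):
        raise ValueError(
            f"TAC table has {df.shape[1]} frame columns but schedule has {len(schedule)}"
        )
    if reference_row not in df.index:
        raise ValueError(f"reference row {reference_row!r} not found in TAC table")
    mk = lambda rid: TimeActivityCurve(
        roi_id=rid, values=df.loc[rid].to_numpy(), schedule=schedule, weights=weights
    )
    tacs = {rid: mk(rid) for rid in df.index if rid != reference_row}
    return TACSet(tacs=tacs, reference=mk(reference_row), schedule=schedule)


# ---------------------------------------------------------------------------
# Packaged reference table (baseline BP_ND and percent occupancy, 137 ROIs
# x 4 subjects + mean)

@dataclass(frozen=True)
class ROITableRow:
    """One ROI row: per-subject + mean baseline BP_ND and occupancy (%)."""

    roi_name: str
    bp_baseline: np.ndarray  # 4 subject values
    bp_mean: float
    occupancy: np.ndarray  # 4 subject values, percent
    occupancy_mean: float

    def mean_consistent(self, tol: float = 0.011) -> bool:
        """Printed mean equals mean of printed subject cells at 2-dp rounding."""
        return (
            abs(round(float(np.mean(self.bp_baseline)), 2) - self.bp_mean) <= tol
            and abs(round(float(np.mean(self.occupancy)), 2) - self.occupancy_mean) <= tol
        )


def load_table1_fixture(validate: bool = True) -> list[ROITableRow]:
    """Load the packaged per-ROI baseline-BP/occupancy table (137 rows).

    With ``validate`` (default), rows whose printed mean disagrees with
    the mean of the printed subject cells beyond 2-dp rounding tolerance
    raise, naming the offending rows.
    """
    ref = importlib.resources.files("occupet").joinpath("data/table1.tsv")
    with importlib.resources.as_file(ref) as p:
        df = pd.read_csv(p, sep="\t")
    rows = [
        ROITableRow(
            roi_name=str(r.roi),
            bp_baseline=np.array([r.bp_s1, r.bp_s2, r.bp_s3, r.bp_s4]),
            bp_mean=float(r.bp_mean),
            occupancy=np.array([r.occ_s1, r.occ_s2, r.occ_s3, r.occ_s4]),
            occupancy_mean=float(r.occ_mean),
        )
        for r in df.itertuples()
    ]
    if validate:
        bad = [row.roi_name for row in rows if not row.mean_consistent()]
        if bad:
            raise ValueError(f"fixture rows fail mean-consistency: {bad}")
    return rows


def fixture_to_frame(rows: list[ROITableRow]) -> pd.DataFrame:
    """Flatten fixture rows to a DataFrame (one row per ROI)."""
    return pd.DataFrame(
        {
            "roi": [r.roi_name for r in rows],
            **{f"bp_s{i+1}": [r.bp_baseline[i] for r in rows] for i in range(N_SUBJECTS)},
            "bp_mean": [r.bp_mean for r in rows],
            **{f"occ_s{i+1}": [r.occupancy[i] for r in rows] for i in range(N_SUBJECTS)},
            "occ_mean": [r.occupancy_mean for r in rows],
        }
    )
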