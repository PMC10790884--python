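"""Time-activity curves and per-frame fit weights.

TAC values are radioactivity concentrations per frame in arbitrary but
consistent units and are assumed decay-corrected upstream; no decay
handling exists anywhere in this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .frames import FrameSchedule


@dataclass(frozen=True)
class TimeActivityCurve:
    """Per-ROI activity concentration per frame with fit weights."""

    roi_id: int | str
    values: np.ndarray
    schedule: FrameSchedule
    weights: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        weights = (
            np.ones_like(values)
            if self.weights is None
            else np.asarray(self.weights, dtype=float)
        )
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "weights", weights)
        n = len(self.schedule)
        if values.shape != (n,) or weights.shape != (n,):
            raise ValueError(
                f"values/weights length must equal schedule length {n}, "
                f"got {values.shape} / {weights.shape}"
            )
        if np.any(weights < 0) or not np.any(weights > 0):
            raise ValueError("weights must be nonnegative with at least one positive")


@dataclass(frozen=True)
class TACSet:
    """A set of target TACs plus the reference-region TAC on one schedule."""

    tacs: dict  # roi_id -> TimeActivityCurve
    reference: TimeActivityCurve
    schedule: FrameSchedule = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.schedule is None:
            object.__setattr__(self, "schedule", self.reference.schedule)
        n = len(self.schedule)
        for roi_id, tac in self.tacs.items():
            if len(tac.schedule) != n or not np.allclose(
                tac.schedule.starts, self.schedule.starts
            ):
                raise ValueError(f"TAC {roi_id!r} is not on the shared schedule")
        if len(self.reference.schedule) != n:
            raise ValueError("reference TAC is not on the shared schedule")
        if self.reference.roi_id in self.tacs:
            raise ValueError("reference roi_id must not be among target roi_ids")

    @property
    def roi_ids(self) -> list:
        return list(self.tacs.keys())

    def __len__(self) -> int:
        return len(self.tacs)


def default_weights(schedule: FrameSchedule, scheme: str = "duration") -> np.ndarray:
    """Per-frame weights for weighted least squares.

    ``uniform`` weights every frame 1. ``duration`` (the default) weights
    each frame by its duration relative to the longest frame — longer
    frames accumulate more counts, so their measured concentration has
    lower variance.
    """
    if scheme == "uniform":
        return np.ones(len(schedule))
    if scheme == "duration":
        return schedule.durations / schedule.durations.max()
    raise ValueError(f"unknown weighting scheme {scheme!r}; use 'uniform' or 'duration'")
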