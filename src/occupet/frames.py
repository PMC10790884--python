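"""Dynamic-PET frame schedules.

A dynamic PET acquisition is a contiguous sequence of frames; each frame
measures the interval-averaged radioactivity concentration over its
duration. All times are stored internally in seconds from injection.
Rate constants elsewhere in the package are expressed per minute (the
PET convention); :data:`SECONDS_PER_MINUTE` is the single conversion
point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

SECONDS_PER_MINUTE = 60.0

#: The study protocol: 30 frames over 90 minutes.
DEFAULT_FRAMING = [(4, 15.0), (4, 30.0), (3, 60.0), (2, 120.0), (5, 240.0), (12, 300.0)]


@dataclass(frozen=True)
class FrameSchedule:
    """Ordered acquisition frames given by start times and durations (s).

    Invariants: starts strictly increasing, durations positive, frames
    contiguous (``start[i+1] == start[i] + duration[i]``), at least one
    frame.
    """

    starts: np.ndarray
    durations: np.ndarray

    def __post_init__(self) -> None:
        starts = np.asarray(self.starts, dtype=float)
        durations = np.asarray(self.durations, dtype=float)
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "durations", durations)
        if starts.ndim != 1 or starts.size < 1 or starts.shape != durations.shape:
            raise ValueError("starts and durations must be 1-D, equal-length, nonempty")
        if np.any(durations <= 0):
            raise ValueError("frame durations must be positive")
        if np.any(np.diff(starts) <= 0):
            raise ValueError("frame starts must be strictly increasing")
        if not np.allclose(starts[1:], starts[:-1] + durations[:-1], rtol=0, atol=1e-9):
            raise ValueError("frames must be contiguous")

    def __len__(self) -> int:
        return int(self.starts.size)

    @property
    def ends(self) -> np.ndarray:
        return self.starts + self.durations

    @property
    def total_duration(self) -> float:
        """Seconds from injection to the end of the last frame."""
        return float(self.ends[-1])

    def midpoints(self) -> np.ndarray:
        return frame_midpoints(self)

    def to_spec(self) -> list[tuple[int, float]]:
        """Re-compress the expanded schedule into (count, duration) runs."""
        spec: list[tuple[int, float]] = []
        for d in self.durations:
            if spec and spec[-1][1] == d:
                spec[-1] = (spec[-1][0] + 1, d)
            else:
                spec.append((1, float(d)))
        return spec


def load_frame_schedule(spec: list[tuple[int, float]]) -> FrameSchedule:
    """Expand a run-length framing spec into a contiguous schedule.

    Parameters
    ----------
    spec
        Pairs of (frame count, frame duration in seconds), e.g. the
        study's 30-frame protocol ``[(4, 15), (4, 30), (3, 60), (2, 120),
        (5, 240), (12, 300)]`` covering 90 min.
    """
    if not spec:
        raise ValueError("framing spec is empty")
    durations = []
    for count, dur in spec:
        if int(count) != count or count < 1:
            raise ValueError(f"frame count must be a positive integer, got {count!r}")
        if dur <= 0:
            raise ValueError(f"frame duration must be positive, got {dur!r}")
        durations.extend([float(dur)] * int(count))
    durations = np.asarray(durations)
    starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    return FrameSchedule(starts=starts, durations=durations)


def frame_midpoints(schedule: FrameSchedule) -> np.ndarray:
    """Midpoint time of each frame in seconds; strictly increasing."""
    return schedule.starts + schedule.durations / 2.0
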