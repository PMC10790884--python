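"""Study configuration: frame protocol, reference region, parcellation
and filter settings, gathered in one validated object that can round-trip
through YAML."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .frames import DEFAULT_FRAMING


@dataclass
class StudyConfig:
    """Pipeline settings with the study defaults.

    Filter thresholds follow the discard rules: baseline BP_ND below
    ``bp_min`` (0.2), DVR below ``dvr_min`` (1.2), or occupancy outside
    ``occupancy_bounds`` ([0, 100] percent) discards a ROI.
    """

    framing: list = field(default_factory=lambda: [list(p) for p in DEFAULT_FRAMING])
    reference_label: int | str = "cerebellum"
    n_parcels: int = 200
    correlation_threshold: float = 0.5
    bp_min: float = 0.2
    dvr_min: float = 1.2
    occupancy_bounds: tuple = (0.0, 100.0)
    seed: int = 0
    weighting: str = "duration"

    def __post_init__(self) -> None:
        if self.n_parcels < 1:
            raise ValueError("n_parcels must be >= 1")
        if self.bp_min <= 0 or self.dvr_min <= 0:
            raise ValueError("filter thresholds must be positive")
        lo, hi = self.occupancy_bounds
        if not lo < hi:
            raise ValueError("occupancy bounds must be ordered")
        if self.weighting not in ("uniform", "duration"):
            raise ValueError(f"unknown weighting scheme {self.weighting!r}")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "occupancy_bounds" in raw:
            raw["occupancy_bounds"] = tuple(raw["occupancy_bounds"])
        return cls(**raw)
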