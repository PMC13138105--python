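"""Frame schedules and time-activity curves.

A dynamic PET acquisition is described by a :class:`FrameSchedule` (frame
start/end times in minutes) and, per region, a :class:`TimeActivityCurve`
holding the frame-averaged, decay-corrected activity concentration in
kBq/mL.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FrameSchedule", "TimeActivityCurve", "default_schedule"]


@dataclass(frozen=True)
class FrameSchedule:
    """Start and end times (minutes) of the frames of a dynamic scan.

    Frames must be strictly ordered and non-overlapping; gaps are allowed.
    """

    start: np.ndarray
    end: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.start, dtype=float)
        end = np.asarray(self.end, dtype=float)
        object.__setattr__(self, "start", start)
        object.__setattr__(self, "end", end)
        if start.ndim != 1 or end.ndim != 1 or start.size != end.size:
            raise ValueError("frame start/end must be 1-D arrays of equal length")
        if start.size == 0:
            raise ValueError("schedule must contain at least one frame")
        if not np.all(np.isfinite(start)) or not np.all(np.isfinite(end)):
            raise ValueError("frame times must be finite")
        bad = np.nonzero(end <= start)[0]
        if bad.size:
            raise ValueError(f"frame {bad[0]}: end ({end[bad[0]]}) <= start ({start[bad[0]]})")
        if start.size > 1:
            overlap = np.nonzero(start[1:] < end[:-1] - 1e-12)[0]
            if overlap.size:
                i = overlap[0]
                raise ValueError(
                    f"frames {i} and {i + 1} overlap: start[{i + 1}]={start[i + 1]} < end[{i}]={end[i]}"
                )
            if np.any(np.diff(start) <= 0):
                raise ValueError("frame start times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return int(self.start.size)

    @property
    def mid(self) -> np.ndarray:
        """Frame mid-times, minutes."""
        return (self.start + self.end) / 2.0

    @property
    def duration(self) -> np.ndarray:
        """Frame durations, minutes."""
        return self.end - self.start

    @property
    def t_end(self) -> float:
        """End of the acquisition, minutes."""
        return float(self.end[-1])

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n_frames

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FrameSchedule):
            return NotImplemented
        return np.array_equal(self.start, other.start) and np.array_equal(self.end, other.end)


def default_schedule() -> FrameSchedule:
    """Default 90-min human dynamic framing: 6x0.5, 3x1, 2x2, 16x5 min.

    A typical bolus-injection framing (fine early frames over the bolus
    peak, 5-min frames thereafter). Used by the simulator and fixtures;
    any valid schedule may be substituted.
    """
    dur = np.concatenate([
        np.full(6, 0.5),
        np.full(3, 1.0),
        np.full(2, 2.0),
        np.full(16, 5.0),
    ])
    end = np.cumsum(dur)
    start = end - dur
    return FrameSchedule(start, end)


@dataclass
class TimeActivityCurve:
    """Frame-averaged activity concentration (kBq/mL) for one region.

    ``values[i]`` is the mean concentration over frame ``i`` of
    ``schedule``. Values may be slightly negative after noise; they must
    be finite.
    """

    region_id: str
    values: np.ndarray
    schedule: FrameSchedule = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("TAC values must be a 1-D array")
        if self.values.size != self.schedule.n_frames:
            raise ValueError(
                f"region {self.region_id!r}: {self.values.size} values for "
                f"{self.schedule.n_frames} frames"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"region {self.region_id!r}: non-finite activity values")

    def __len__(self) -> int:
        return self.values.size

    def with_values(self, values: np.ndarray) -> "TimeActivityCurve":
        return TimeActivityCurve(self.region_id, values, self.schedule)
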