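"""Frame timing for dynamic PET acquisitions.

All time–activity curves, integrals and late-window averages in this
package are anchored to a :class:`FrameSchedule`: per-frame start times
and durations in seconds, with frame *midpoints* serving as the nominal
sample times of decay-corrected, frame-averaged data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["FrameSchedule", "pib_frame_schedule"]


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous, non-overlapping frame timing of a dynamic scan.

    Parameters
    ----------
    start_s : array-like
        Frame start times in seconds, strictly increasing, first frame at 0.
    duration_s : array-like
        Frame durations in seconds, all positive.  Frames must be
        contiguous: ``start_s[i+1] == start_s[i] + duration_s[i]``.
    """

    start_s: np.ndarray
    duration_s: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.start_s, dtype=float)
        dur = np.asarray(self.duration_s, dtype=float)
        if start.ndim != 1 or dur.ndim != 1 or start.size != dur.size:
            raise ValueError("start_s and duration_s must be 1-D and of equal length")
        if start.size == 0:
            raise ValueError("schedule must contain at least one frame")
        if np.any(dur <= 0):
            raise ValueError("all frame durations must be positive")
        if np.any(np.diff(start) <= 0):
            raise ValueError("frame start times must be strictly increasing")
        if not np.allclose(start[1:], start[:-1] + dur[:-1]):
            raise ValueError("frames must be contiguous and non-overlapping")
        object.__setattr__(self, "start_s", start)
        object.__setattr__(self, "duration_s", dur)

    @property
    def n_frames(self) -> int:
        return self.start_s.size

    @property
    def end_s(self) -> np.ndarray:
        """Frame end times in seconds."""
        return self.start_s + self.duration_s

    @property
    def midpoint_s(self) -> np.ndarray:
        """Frame midpoints in seconds."""
        return self.start_s + self.duration_s / 2.0

    @property
    def midpoint_min(self) -> np.ndarray:
        """Frame midpoints in minutes (the TAC time grid)."""
        return self.midpoint_s / 60.0

    @property
    def duration_min(self) -> np.ndarray:
        return self.duration_s / 60.0

    @property
    def total_duration_s(self) -> float:
        return float(self.end_s[-1] - self.start_s[0])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "frame_start_s": self.start_s.tolist(),
            "frame_duration_s": self.duration_s.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "FrameSchedule":
        payload = json.loads(Path(path).read_text())
        try:
            return cls(
                np.asarray(payload["frame_start_s"], dtype=float),
                np.asarray(payload["frame_duration_s"], dtype=float),
            )
        except KeyError as exc:  # pragma: no cover - defensive
            raise ValueError(f"frame schedule file {path} missing key {exc}") from exc

    @classmethod
    def from_durations(cls, duration_s) -> "FrameSchedule":
        dur = np.asarray(duration_s, dtype=float)
        start = np.concatenate([[0.0], np.cumsum(dur)[:-1]])
        return cls(start, dur)


def pib_frame_schedule() -> FrameSchedule:
    """The 70-minute dynamic [11C]PiB reconstruction schedule.

    12 x 5 s, 6 x 10 s, 3 x 20 s, 4 x 30 s, 5 x 60 s, 4 x 5 min and
    4 x 10 min — 38 frames totalling 4200 s (70 min).  Early frames are
    short to resolve the arterial bolus; late frames are long to limit
    noise in the Logan linear phase and the 50–70 min static window.
    """
    durations = [5.0] * 12 + [10.0] * 6 + [20.0] * 3 + [30.0] * 4 + [60.0] * 5 + [300.0] * 4 + [600.0] * 4
    return FrameSchedule.from_durations(durations)
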