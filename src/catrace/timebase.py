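"""Recording time base: uniform frame clock plus stimulus-event annotations.

All user-facing times are seconds from the start of the recording; frames are
0-based internally.  Recordings in this domain are slow time-lapse series
(default 0.1 Hz, i.e. one frame every 10 s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["TimeBase"]


@dataclass(frozen=True)
class TimeBase:
    """Uniform sampling clock with named stimulus events.

    Parameters
    ----------
    n_frames
        Number of frames in the recording (>= 1).
    sampling_interval_s
        Seconds per frame; default 10 s (0.1 Hz).
    events
        Sequence of ``(label, time_s)`` stimulus annotations.  Every event
        must fall inside the recording.
    """

    n_frames: int
    sampling_interval_s: float = 10.0
    events: tuple[tuple[str, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.sampling_interval_s <= 0:
            raise ValueError(
                f"sampling_interval_s must be > 0, got {self.sampling_interval_s}"
            )
        if self.n_frames < 1:
            raise ValueError(f"n_frames must be >= 1, got {self.n_frames}")
        object.__setattr__(self, "events", tuple((str(l), float(t)) for l, t in self.events))
        end = self.duration_s
        for label, t in self.events:
            if not 0 <= t <= end:
                raise ValueError(
                    f"event {label!r} at t={t} s lies outside the recording "
                    f"[0, {end}] s"
                )

    @property
    def duration_s(self) -> float:
        """Time of the last frame, in seconds."""
        return (self.n_frames - 1) * self.sampling_interval_s

    @property
    def times(self) -> np.ndarray:
        """Frame times in seconds, shape ``(n_frames,)``."""
        return np.arange(self.n_frames) * self.sampling_interval_s

    def frame_of(self, time_s: float) -> int:
        """Nearest frame index to ``time_s``; exact half-frame ties round earlier."""
        if not 0 <= time_s <= self.duration_s:
            raise ValueError(
                f"time {time_s} s outside recording [0, {self.duration_s}] s"
            )
        # ceil(x - 0.5) rounds half-way cases down (toward the earlier frame)
        return int(math.ceil(time_s / self.sampling_interval_s - 0.5))

    def window(self, t_start_s: float, t_end_s: float) -> np.ndarray:
        """Indices of frames with time in ``[t_start_s, t_end_s]`` (inclusive)."""
        t = self.times
        idx = np.nonzero((t >= t_start_s - 1e-9) & (t <= t_end_s + 1e-9))[0]
        return idx

    def event_time(self, label: str) -> float:
        """Time of the (first) event with the given label."""
        for lab, t in self.events:
            if lab == label:
                return t
        raise KeyError(f"no event labelled {label!r}")

    def has_event(self, label: str) -> bool:
        return any(lab == label for lab, _ in self.events)

    def with_events(self, events) -> "TimeBase":
        return TimeBase(self.n_frames, self.sampling_interval_s, tuple(events))
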