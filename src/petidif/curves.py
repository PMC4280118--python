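"""Core temporal containers: frame schedules, time-activity curves, input functions.

All times are stored in seconds post-injection; activity is kBq/mL. Blood-sample
tables on disk use minutes (the bedside convention) and are converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


class InsufficientDataError(ValueError):
    """Raised when a fit or extraction has too few usable samples."""


@dataclass(frozen=True)
class FrameSchedule:
    """Start/end times (seconds) of the dynamic acquisition frames.

    Frames must be contiguous-or-gapped, strictly increasing and
    non-overlapping. The first frame may have any (positive) length.
    """

    frame_starts: np.ndarray
    frame_ends: np.ndarray

    def __post_init__(self):
        starts = np.asarray(self.frame_starts, dtype=float)
        ends = np.asarray(self.frame_ends, dtype=float)
        object.__setattr__(self, "frame_starts", starts)
        object.__setattr__(self, "frame_ends", ends)
        if starts.ndim != 1 or starts.shape != ends.shape:
            raise ValueError("frame_starts and frame_ends must be 1-D and equal length")
        if starts.size == 0:
            raise ValueError("empty frame schedule")
        if not np.all(ends > starts):
            raise ValueError("each frame must end after it starts")
        if not np.all(starts[1:] >= ends[:-1] - 1e-9):
            raise ValueError("frames must be non-overlapping and increasing")

    @classmethod
    def from_durations(cls, durations, first_start: float = 0.0) -> "FrameSchedule":
        durations = np.asarray(durations, dtype=float)
        ends = first_start + np.cumsum(durations)
        starts = np.concatenate([[first_start], ends[:-1]])
        return cls(starts, ends)

    @classmethod
    def hrrt_osem(cls, first_frame_s: float = 10.0, max_time_s: float | None = None
                  ) -> "FrameSchedule":
        """HRRT OSEM-style schedule: a short variable first frame followed by
        2x7, 2x8, 3x10, 2x15, 2x30, 1x45, 2x60, 1x90, 1x120, 1x210, 22x300 s.

        ``max_time_s`` truncates the schedule (dropping whole frames) for
        shorter simulated scans.
        """
        durs = ([first_frame_s] + [7] * 2 + [8] * 2 + [10] * 3 + [15] * 2
                + [30] * 2 + [45] + [60] * 2 + [90] + [120] + [210] + [300] * 22)
        sched = cls.from_durations(durs)
        if max_time_s is not None:
            keep = sched.frame_ends <= max_time_s + 1e-9
            if not keep.any():
                raise ValueError("max_time_s shorter than the first frame")
            sched = cls(sched.frame_starts[keep], sched.frame_ends[keep])
        return sched

    @property
    def n_frames(self) -> int:
        return self.frame_starts.size

    @property
    def mid_times(self) -> np.ndarray:
        return 0.5 * (self.frame_starts + self.frame_ends)

    @property
    def durations(self) -> np.ndarray:
        return self.frame_ends - self.frame_starts

    @property
    def total_time(self) -> float:
        return float(self.frame_ends[-1])

    def averaging_matrix(self, times: np.ndarray) -> np.ndarray:
        """Linear operator M with (M @ values)[i] = frame-i time average.

        Trapezoidal integration over each frame interval divided by its
        duration, with frame edges handled by linear interpolation between
        the surrounding grid points.
        """
        times = np.asarray(times, dtype=float)
        n = times.size
        M = np.zeros((self.n_frames, n))
        for i, (t0, t1) in enumerate(zip(self.frame_starts, self.frame_ends)):
            row = M[i]
            inside = np.nonzero((times > t0) & (times < t1))[0]
            # node sequence: t0, interior grid points, t1
            nodes = np.concatenate([[t0], times[inside], [t1]])
            seg = np.diff(nodes)
            w = np.zeros(nodes.size)
            w[:-1] += seg / 2.0
            w[1:] += seg / 2.0
            row[inside] += w[1:-1]
            for t_edge, w_edge in ((t0, w[0]), (t1, w[-1])):
                j = np.searchsorted(times, t_edge)
                if j < n and times[j] == t_edge:
                    row[j] += w_edge
                else:  # split linearly between the bracketing grid points
                    frac = (t_edge - times[j - 1]) / (times[j] - times[j - 1])
                    row[j - 1] += w_edge * (1.0 - frac)
                    row[j] += w_edge * frac
            row /= (t1 - t0)
        return M

    def frame_average(self, times: np.ndarray, values: np.ndarray) -> np.ndarray:
        """Average a densely-sampled curve over each frame interval."""
        return self.averaging_matrix(times) @ np.asarray(values, dtype=float)

    def to_dict(self) -> dict:
        return {"frame_starts_s": self.frame_starts.tolist(),
                "frame_ends_s": self.frame_ends.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "FrameSchedule":
        return cls(np.asarray(d["frame_starts_s"]), np.asarray(d["frame_ends_s"]))


@dataclass
class TimeActivityCurve:
    """A sampled activity curve: (times [s], activity [kBq/mL]) pairs.

    Shared by blood curves, tissue curves and ICA component curves. Linear
    interpolation is the sampling model throughout.
    """

    times: np.ndarray
    values: np.ndarray
    name: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be 1-D and equal length")
        if self.times.size and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    def __call__(self, t) -> np.ndarray:
        """Linear interpolation at arbitrary times (clamped at the ends)."""
        return np.interp(t, self.times, self.values)

    def with_values(self, values: np.ndarray, name: str | None = None
                    ) -> "TimeActivityCurve":
        return TimeActivityCurve(self.times.copy(), np.asarray(values, float),
                                 self.name if name is None else name)

    def resample(self, dt: float, t_start: float | None = None,
                 t_end: float | None = None) -> "TimeActivityCurve":
        """Resample onto a uniform grid of spacing ``dt`` seconds."""
        t0 = self.times[0] if t_start is None else t_start
        t1 = self.times[-1] if t_end is None else t_end
        grid = np.arange(t0, t1 + 0.5 * dt, dt)
        return TimeActivityCurve(grid, self(grid), self.name)

    def auc(self, t0: float | None = None, t1: float | None = None) -> float:
        """Trapezoidal area under the curve on [t0, t1] (defaults: full span)."""
        t0 = self.times[0] if t0 is None else t0
        t1 = self.times[-1] if t1 is None else t1
        inside = (self.times > t0) & (self.times < t1)
        tt = np.concatenate([[t0], self.times[inside], [t1]])
        vv = np.concatenate([[self(t0)], self.values[inside], [self(t1)]])
        return float(np.trapezoid(vv, tt))


@dataclass
class InputFunction(TimeActivityCurve):
    """Metabolite-corrected parent-plasma curve driving the kinetic model.

    ``provenance`` records which extraction produced the underlying
    whole-blood curve: continuous arterial sampling ("ABSS"), carotid-signal
    hottest pixels ("CS"), or ICA unmixing ("ICA"). ``calibration`` carries
    the one-point scale factor applied, if any.
    """

    provenance: str = "ABSS"
    calibration: dict = field(default_factory=dict)

    @property
    def parent_plasma(self) -> np.ndarray:
        return self.values
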