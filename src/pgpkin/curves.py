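"""Core data containers for frame-resolved PET curves.

Everything downstream (input-function corrections, compartment fitting,
SUV analysis) consumes one of two currencies:

* :class:`TimeActivityCurve` -- decay-corrected activity concentration
  (kBq/cc) averaged over contiguous acquisition frames, the form in which
  dynamic PET data and blood-counter traces arrive; and
* :class:`InputFunction` -- a metabolite- and plasma-corrected parent
  concentration curve on a fine time grid, the quantity that drives the
  kinetic model.

Time is kept in seconds everywhere inside the package; rate constants are
converted to per-minute only at reporting boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FrameSchedule",
    "TimeActivityCurve",
    "InputFunction",
    "default_schedule",
    "frame_average",
]


@dataclass(frozen=True)
class FrameSchedule:
    """An ordered, contiguous set of acquisition frames.

    Parameters
    ----------
    start_s, end_s : array-like of float
        Frame boundaries in seconds post-injection.  Frames must be
        contiguous (``end[i] == start[i+1]``), non-overlapping, and of
        strictly positive duration.
    """

    start_s: np.ndarray
    end_s: np.ndarray

    def __init__(self, start_s: Iterable[float], end_s: Iterable[float]):
        start = np.asarray(list(start_s), dtype=float)
        end = np.asarray(list(end_s), dtype=float)
        if start.shape != end.shape or start.ndim != 1 or start.size == 0:
            raise ValueError("start_s and end_s must be equal-length 1-D sequences")
        if np.any(end <= start):
            raise ValueError("every frame must have strictly positive duration")
        if start.size > 1 and not np.allclose(end[:-1], start[1:]):
            raise ValueError("frames must be contiguous: end[i] == start[i+1]")
        object.__setattr__(self, "start_s", start)
        object.__setattr__(self, "end_s", end)

    @classmethod
    def from_durations(cls, durations_s: Sequence[float], t0: float = 0.0) -> "FrameSchedule":
        edges = t0 + np.concatenate([[0.0], np.cumsum(np.asarray(durations_s, dtype=float))])
        return cls(edges[:-1], edges[1:])

    def __len__(self) -> int:
        return int(self.start_s.size)

    @property
    def durations_s(self) -> np.ndarray:
        return self.end_s - self.start_s

    @property
    def midpoints_s(self) -> np.ndarray:
        return 0.5 * (self.start_s + self.end_s)

    @property
    def total_s(self) -> float:
        return float(self.end_s[-1] - self.start_s[0])

    def restrict(self, t_max_s: float) -> "FrameSchedule":
        """Keep only frames that end at or before ``t_max_s``."""
        keep = self.end_s <= t_max_s + 1e-9
        if not np.any(keep):
            raise ValueError(f"no frames end within t_max = {t_max_s} s")
        return FrameSchedule(self.start_s[keep], self.end_s[keep])


def default_schedule() -> FrameSchedule:
    """The 30-min dynamic framing used throughout: 12 x 5 s, 6 x 10 s,
    4 x 1 min, 2 x 2 min, 2 x 5 min, 1 x 10 min (1800 s total)."""
    durations = [5.0] * 12 + [10.0] * 6 + [60.0] * 4 + [120.0] * 2 + [300.0] * 2 + [600.0]
    return FrameSchedule.from_durations(durations)


@dataclass(frozen=True)
class TimeActivityCurve:
    """Frame-averaged, decay-corrected concentration series (kBq/cc).

    ``values[i]`` is the average concentration over the half-open frame
    ``[schedule.start_s[i], schedule.end_s[i])``.  ``source`` records where
    the curve came from (``"image-ROI"``, ``"blood-counter"``, or
    ``"derived"``).
    """

    schedule: FrameSchedule
    values: np.ndarray
    source: str = "derived"

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (len(self.schedule),):
            raise ValueError(
                f"values length {vals.shape} does not match schedule length {len(self.schedule)}"
            )
        if not np.all(np.isfinite(vals)):
            raise ValueError("TAC values must be finite")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.schedule)

    @property
    def midpoints_s(self) -> np.ndarray:
        return self.schedule.midpoints_s

    @property
    def durations_s(self) -> np.ndarray:
        return self.schedule.durations_s

    def auc(self) -> float:
        """Area under the curve as sum(value x duration) (kBq*s/cc).

        Frame values are interval averages, so this rectangle rule is the
        exact integral of the underlying piecewise signal.
        """
        return float(np.sum(self.values * self.durations_s))

    def restrict(self, t_max_s: float) -> "TimeActivityCurve":
        keep = self.schedule.end_s <= t_max_s + 1e-9
        return TimeActivityCurve(
            FrameSchedule(self.schedule.start_s[keep], self.schedule.end_s[keep]),
            self.values[keep],
            source=self.source,
        )

    def with_values(self, values: np.ndarray, source: str | None = None) -> "TimeActivityCurve":
        return TimeActivityCurve(self.schedule, values, source=source or self.source)

    # ---- I/O -----------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame_start_s": self.schedule.start_s,
                "frame_end_s": self.schedule.end_s,
                "value_kBq_per_cc": self.values,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, source: str = "derived") -> "TimeActivityCurve":
        df = pd.read_csv(path)
        required = {"frame_start_s", "frame_end_s", "value_kBq_per_cc"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"TAC CSV missing columns: {sorted(missing)}")
        sched = FrameSchedule(df["frame_start_s"].to_numpy(), df["frame_end_s"].to_numpy())
        return cls(sched, df["value_kBq_per_cc"].to_numpy(), source=source)


def frame_average(times_s: np.ndarray, values: np.ndarray, schedule: FrameSchedule) -> np.ndarray:
    """Average a piecewise-linear sampled curve over each frame of a schedule.

    Exact for a curve that is linear between samples (and therefore exact
    for linear curves: the frame average equals the midpoint value).  The
    sample grid must cover the schedule span.
    """
    t = np.asarray(times_s, dtype=float)
    f = np.asarray(values, dtype=float)
    if t[0] > schedule.start_s[0] + 1e-9 or t[-1] < schedule.end_s[-1] - 1e-9:
        raise ValueError("fine grid does not cover the frame-schedule span")

    # cumulative integral of the piecewise-linear interpolant at grid points
    seg = 0.5 * (f[1:] + f[:-1]) * np.diff(t)
    cum = np.concatenate([[0.0], np.cumsum(seg)])

    def integral_at(x: np.ndarray) -> np.ndarray:
        # F(x) for x inside [t[0], t[-1]]: cumulative at the left grid point
        # plus the exact trapezoid over the partial segment.
        x = np.clip(x, t[0], t[-1])
        idx = np.clip(np.searchsorted(t, x, side="right") - 1, 0, t.size - 2)
        fl = f[idx]
        fx = np.interp(x, t, f)
        return cum[idx] + 0.5 * (fl + fx) * (x - t[idx])

    area = integral_at(schedule.end_s) - integral_at(schedule.start_s)
    return area / schedule.durations_s


@dataclass(frozen=True)
class InputFunction:
    """Fine-grid arterial parent-compound plasma concentration C_a(t).

    ``provenance`` lists each correction applied exactly once, e.g.
    ``("dispersion(tau=28s)", "plasma-ratio(0.64)", "metabolites(WT-saline)")``.
    """

    times_s: np.ndarray
    values: np.ndarray
    provenance: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        t = np.asarray(self.times_s, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.shape != v.shape:
            raise ValueError("times_s and values must be matching 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times_s must be strictly ascending")
        if np.any(v < -1e-12) or not np.all(np.isfinite(v)):
            raise ValueError("input-function values must be finite and non-negative")
        names = [p.split("(")[0] for p in self.provenance]
        if len(names) != len(set(names)):
            raise ValueError("each correction may appear in provenance only once")
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "values", np.clip(v, 0.0, None))

    def __call__(self, t: np.ndarray) -> np.ndarray:
        """Linear interpolation, constant beyond the grid ends."""
        return np.interp(np.asarray(t, dtype=float), self.times_s, self.values)

    def with_correction(self, values: np.ndarray, tag: str) -> "InputFunction":
        return InputFunction(self.times_s, values, self.provenance + (tag,))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"time_s": self.times_s, "value_kBq_per_cc": self.values}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "InputFunction":
        df = pd.read_csv(path)
        return cls(df["time_s"].to_numpy(), df["value_kBq_per_cc"].to_numpy())
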