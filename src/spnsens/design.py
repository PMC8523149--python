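"""Session layout: recording windows around an I.P. injection.

Time conventions used throughout the package:

* session time is in seconds with the injection at ``t = 0`` (configurable);
* recording windows are half-open intervals ``[start, end)`` in session time,
  disjoint and sorted;
* "recorded time" concatenates the windows into a gap-free axis starting at 0,
  which is the coordinate system used for interval shuffling and circular
  velocity shifts;
* frame indices are 0-based at ``sample_rate_hz`` (10 Hz by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["SessionDesign", "DesignError"]


class DesignError(ValueError):
    """Raised when a session layout violates its invariants."""


#: default window layout, minutes −10..−5, −5..0, 0..5, 10..15 around injection
DEFAULT_WINDOWS: tuple[tuple[float, float], ...] = (
    (-600.0, -300.0),
    (-300.0, 0.0),
    (0.0, 300.0),
    (600.0, 900.0),
)


@dataclass(frozen=True)
class SessionDesign:
    """Recording-window layout of one imaging session.

    Parameters
    ----------
    session_id:
        Free-form identifier, e.g. ``"cocaine1"``.
    injection_time_s:
        Injection moment in session time; exactly one window must end at it
        and one must start at it.
    windows:
        Ordered, disjoint half-open ``[start, end)`` intervals (seconds).
    sample_rate_hz:
        Imaging frame rate.
    """

    session_id: str = "session"
    injection_time_s: float = 0.0
    windows: tuple[tuple[float, float], ...] = DEFAULT_WINDOWS
    sample_rate_hz: float = 10.0

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise DesignError("sample_rate_hz must be positive")
        if not self.windows:
            raise DesignError("at least one recording window is required")
        ws = [tuple(map(float, w)) for w in self.windows]
        for a, b in ws:
            if not b > a:
                raise DesignError(f"empty or inverted window [{a}, {b})")
        for (a0, b0), (a1, b1) in zip(ws, ws[1:]):
            if a1 < b0:
                raise DesignError("windows must be disjoint and sorted")
        inj = self.injection_time_s
        if not any(np.isclose(b, inj) for _, b in ws):
            raise DesignError("one window must end at the injection time")
        if not any(np.isclose(a, inj) for a, _ in ws):
            raise DesignError("one window must start at the injection time")
        object.__setattr__(self, "windows", tuple(ws))

    # -- derived geometry ---------------------------------------------------

    @property
    def window_durations_s(self) -> np.ndarray:
        return np.array([b - a for a, b in self.windows])

    @property
    def total_recorded_s(self) -> float:
        return float(self.window_durations_s.sum())

    @property
    def recorded_offsets_s(self) -> np.ndarray:
        """Recorded-time coordinate at which each window begins."""
        d = self.window_durations_s
        return np.concatenate([[0.0], np.cumsum(d)[:-1]])

    def frames_per_window(self) -> np.ndarray:
        return np.rint(self.window_durations_s * self.sample_rate_hz).astype(int)

    @property
    def n_frames(self) -> int:
        return int(self.frames_per_window().sum())

    def frame_times(self) -> np.ndarray:
        """Session-time stamps of every recorded frame, concatenated."""
        dt = 1.0 / self.sample_rate_hz
        parts = [
            a + dt * np.arange(n)
            for (a, _), n in zip(self.windows, self.frames_per_window())
        ]
        return np.concatenate(parts)

    def segment_slices(self) -> list[slice]:
        """Frame-index slice of each recording window in the concatenated trace."""
        n = self.frames_per_window()
        edges = np.concatenate([[0], np.cumsum(n)])
        return [slice(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]

    # -- time mappings ------------------------------------------------------

    def contains(self, t: np.ndarray | float) -> np.ndarray:
        """Whether session times fall inside a recorded window."""
        t = np.asarray(t, dtype=float)
        ok = np.zeros(t.shape, dtype=bool)
        for a, b in self.windows:
            ok |= (t >= a) & (t < b)
        return ok

    def to_recorded(self, t: np.ndarray | float) -> np.ndarray:
        """Map session times inside windows onto the gap-free recorded axis."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.full(t.shape, np.nan)
        for (a, b), off in zip(self.windows, self.recorded_offsets_s):
            m = (t >= a) & (t < b)
            out[m] = t[m] - a + off
        if np.isnan(out).any():
            raise DesignError("time outside recorded windows")
        return out

    def to_session(self, r: np.ndarray | float) -> np.ndarray:
        """Inverse of :meth:`to_recorded`."""
        r = np.atleast_1d(np.asarray(r, dtype=float))
        out = np.full(r.shape, np.nan)
        total = self.total_recorded_s
        if ((r < 0) | (r > total)).any():
            raise DesignError("recorded time out of range")
        durs = self.window_durations_s
        for (a, _), off, d in zip(self.windows, self.recorded_offsets_s, durs):
            m = (r >= off) & (r < off + d)
            out[m] = r[m] - off + a
        # allow the exact right edge
        out[np.isclose(r, total)] = self.windows[-1][1]
        return out

    def pre_post_windows(self, half_width_s: float = 300.0) -> tuple[
        tuple[float, float], tuple[float, float]
    ]:
        """The analysis windows: last ``half_width_s`` before and first after injection."""
        inj = self.injection_time_s
        return (inj - half_width_s, inj), (inj, inj + half_width_s)

    def to_dict(self) -> dict:
        return {
            "session_id": self.session_id,
            "injection_time_s": self.injection_time_s,
            "windows": [list(w) for w in self.windows],
            "sample_rate_hz": self.sample_rate_hz,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SessionDesign":
        return cls(
            session_id=d.get("session_id", "session"),
            injection_time_s=float(d.get("injection_time_s", 0.0)),
            windows=tuple(tuple(w) for w in d["windows"]),
            sample_rate_hz=float(d.get("sample_rate_hz", 10.0)),
        )
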