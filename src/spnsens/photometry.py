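"""Fiber photometry dF/F via control-channel regression.

The isosbestic 405 nm channel carries motion and bleaching artifacts but no
sensor signal; regressing the 470 nm channel on it yields a fitted control
whose residual fraction is the dopamine dF/F::

    dF/F = (ch470 - (slope*ch405 + intercept)) / (slope*ch405 + intercept)

Binning into half-open time bins (e.g. 0-5 and 10-15 min after injection) is
the only smoothing applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import linregress

__all__ = [
    "PhotometrySignal",
    "DffTrace",
    "ControlFit",
    "fit_control",
    "compute_dff",
    "bin_dff",
]


@dataclass
class PhotometrySignal:
    times_s: np.ndarray
    ch470: np.ndarray
    ch405: np.ndarray
    sample_rate_hz: float

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, float)
        self.ch470 = np.asarray(self.ch470, float)
        self.ch405 = np.asarray(self.ch405, float)
        if not (len(self.times_s) == len(self.ch470) == len(self.ch405)):
            raise ValueError("channel lengths differ")
        if not (
            np.all(np.isfinite(self.ch470)) and np.all(np.isfinite(self.ch405))
        ):
            raise ValueError("non-finite photometry samples")


@dataclass
class DffTrace:
    times_s: np.ndarray
    dff: np.ndarray


@dataclass(frozen=True)
class ControlFit:
    slope: float
    intercept: float
    r_squared: float


def fit_control(
    signal: PhotometrySignal,
    fit_window: tuple[float, float] | None = None,
) -> ControlFit:
    """OLS of ch470 on ch405 over ``fit_window`` (default: whole recording).

    A pre-injection ``fit_window`` keeps an additive sensor response out of
    the fitted control; the full-recording default follows the plain
    regression procedure.
    """
    if fit_window is None:
        m = np.ones(len(signal.times_s), dtype=bool)
    else:
        m = (signal.times_s >= fit_window[0]) & (signal.times_s < fit_window[1])
    x, y = signal.ch405[m], signal.ch470[m]
    if len(x) < 3 or np.ptp(x) == 0:
        raise ValueError("degenerate_control")
    res = linregress(x, y)
    return ControlFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def compute_dff(signal: PhotometrySignal, coeffs: ControlFit) -> DffTrace:
    """Residual dF/F against the fitted control channel."""
    control = coeffs.slope * signal.ch405 + coeffs.intercept
    if np.any(control <= 0):
        raise ValueError("nonpositive_baseline")
    return DffTrace(times_s=signal.times_s, dff=(signal.ch470 - control) / control)


def bin_dff(
    trace: DffTrace, bin_edges: list[tuple[float, float]]
) -> list[float | None]:
    """Arithmetic mean dF/F per half-open ``[start, end)`` bin.

    Empty bins are reported as ``None`` with a warning.
    """
    out: list[float | None] = []
    for a, b in bin_edges:
        m = (trace.times_s >= a) & (trace.times_s < b)
        if not m.any():
            warnings.warn(f"empty dF/F bin [{a}, {b})", stacklevel=2)
            out.append(None)
        else:
            out.append(float(trace.dff[m].mean()))
    return out
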