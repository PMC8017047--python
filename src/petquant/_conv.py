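"""Fine-grid convolution and frame-averaging primitives.

All kinetic forward models in this package are convolutions of the plasma
input with sums of decaying exponentials.  They are evaluated on a uniform
fine grid (default 0.05 min) with a causal trapezoidal recursion, then
averaged over the acquisition frames (duration averages, not mid-point
samples).
"""

from __future__ import annotations

import numpy as np
from scipy.signal import lfilter

FINE_DT = 0.05


def fine_grid(t_end: float, dt: float = FINE_DT) -> np.ndarray:
    """Uniform grid [0, t_end] guaranteed to include both endpoints."""
    n = int(round(t_end / dt))
    return np.linspace(0.0, n * dt, n + 1)


def expconv(x: np.ndarray, dt: float, theta: float) -> np.ndarray:
    """Causal convolution ``(x ⊛ e^{-θt})(t_n)`` on a uniform grid.

    Uses the exact recursion for piecewise-linear integrands,
    ``y[n] = e^{-θΔ} y[n-1] + Δ/2 (x[n] + e^{-θΔ} x[n-1])``,
    implemented as an IIR filter.
    """
    e = float(np.exp(-theta * dt))
    return lfilter([dt / 2.0, dt / 2.0 * e], [1.0, -e], np.asarray(x, dtype=float))


def cumulative_integral(x: np.ndarray, dt: float) -> np.ndarray:
    """Trapezoidal cumulative integral on the fine grid, anchored at 0."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    out[0] = 0.0
    np.cumsum((x[1:] + x[:-1]) * (dt / 2.0), out=out[1:])
    return out


def frame_averages(c_fine: np.ndarray, t_fine: np.ndarray, schedule) -> np.ndarray:
    """Duration-average of a fine-grid curve over each frame of a schedule.

    Frames shorter than the grid step fall back to mid-point interpolation.
    """
    dt = t_fine[1] - t_fine[0]
    integral = cumulative_integral(c_fine, dt)
    starts, ends, durs = schedule.start_times, schedule.end_times, schedule.durations
    i0 = np.interp(starts, t_fine, integral)
    i1 = np.interp(ends, t_fine, integral)
    out = (i1 - i0) / durs
    tiny = durs < dt
    if np.any(tiny):
        out = out.copy()
        out[tiny] = np.interp(schedule.mid_times[tiny], t_fine, c_fine)
    return out


class ConvolutionGrid:
    """Pre-sampled input-function curves on the fine grid, shared across many
    model evaluations against the same input function."""

    def __init__(self, input_fn, t_end: float, dt: float = FINE_DT):
        self.dt = dt
        self.t = fine_grid(t_end, dt)
        self.cp = np.asarray(input_fn.parent_plasma(self.t), dtype=float)
        self.cwb = np.asarray(input_fn.whole_blood_at(self.t), dtype=float)

    def expconv_cp(self, theta: float) -> np.ndarray:
        return expconv(self.cp, self.dt, theta)

    def averages(self, c_fine: np.ndarray, schedule) -> np.ndarray:
        return frame_averages(c_fine, self.t, schedule)

    def cp_integral_at(self, times) -> np.ndarray:
        """∫₀ᵗ Cp ds evaluated at arbitrary times (trapezoid on the fine grid)."""
        return np.interp(times, self.t, cumulative_integral(self.cp, self.dt))
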