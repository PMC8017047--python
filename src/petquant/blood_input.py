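"""Arterial input-function construction.

The metabolite-corrected input function is the product of the fitted total
plasma activity curve (tri-exponential past the peak, linear interpolation
through the measured rise before it) and the fitted plasma parent fraction
(a Hill function anchored at pf(0) = 1).  The tracer arrival delay between
the sampling site and the brain is estimated afterwards by fitting a
one-tissue model to the first minutes of the whole-brain TAC over a grid of
candidate shifts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import curve_fit, least_squares, minimize_scalar, nnls

from ._conv import FINE_DT, expconv, fine_grid, frame_averages
from .data_model import TimeActivityCurve

__all__ = [
    "BloodFitError",
    "TriExpFit",
    "HillFit",
    "InputFunction",
    "fit_triexponential",
    "fit_hill",
    "make_input",
    "fit_delay",
]


class BloodFitError(RuntimeError):
    """Raised when a blood-curve fit cannot be performed.

    Carries ``single_exp_fallback`` (a :class:`TriExpFit` with one active
    component, or None) when tri-exponential optimisation failed but a
    single-exponential fit succeeded.
    """

    def __init__(self, message: str, single_exp_fallback=None):
        super().__init__(message)
        self.single_exp_fallback = single_exp_fallback


@dataclass(frozen=True)
class TriExpFit:
    """Piecewise blood-curve model: linear through the measured samples up to
    the peak, then ``Σ Aᵢ e^{-λᵢ (t - t_peak)}``.  Evaluates to 0 for t < 0."""

    peak_time: float
    amplitudes: np.ndarray  # kBq·mL⁻¹, A ≥ 0
    rates: np.ndarray  # min⁻¹, λ > 0
    rise_times: np.ndarray
    rise_values: np.ndarray
    residual_rms: float = 0.0

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = np.zeros(t.shape)
        pre = (t >= 0) & (t < self.peak_time)
        post = t >= self.peak_time
        if np.any(pre):
            out[pre] = np.interp(t[pre], self.rise_times, self.rise_values)
        if np.any(post):
            dt = t[post] - self.peak_time
            out[post] = np.exp(-np.outer(dt, self.rates)) @ self.amplitudes
        return out


@dataclass(frozen=True)
class HillFit:
    """Parent-fraction model ``pf(t) = 1 − (1−a)·t^b / (t^b + c^b)``.

    ``a`` is the late-time plateau, ``c`` the half-transition time (pf(c) =
    (1+a)/2) and ``b`` the steepness; pf(0) = 1 by construction.
    """

    a: float
    b: float
    c: float

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        tb = np.where(t > 0, t, 0.0) ** self.b
        return 1.0 - ((1.0 - self.a) * tb) / (tb + self.c**self.b)


@dataclass(frozen=True)
class InputFunction:
    """Continuous metabolite-corrected plasma-parent curve plus the
    whole-blood curve, both shifted by the fitted arrival delay Δ (min):
    evaluation at ``t`` reads the underlying curves at ``t − Δ``."""

    plasma: object  # callable: total plasma activity
    parent_fraction: object  # callable in [0, 1]
    whole_blood: object  # callable
    delay: float = 0.0

    def parent_plasma(self, t):
        ts = np.asarray(t, dtype=float) - self.delay
        return np.clip(np.asarray(self.plasma(ts)) * np.asarray(self.parent_fraction(ts)), 0.0, None)

    def whole_blood_at(self, t):
        ts = np.asarray(t, dtype=float) - self.delay
        return np.clip(np.asarray(self.whole_blood(ts)), 0.0, None)

    def with_delay(self, delay: float) -> "InputFunction":
        return replace(self, delay=float(delay))


def _varpro_residual(log_lams, t, y):
    lams = np.exp(log_lams)
    basis = np.exp(-np.outer(t, lams))
    amps, _ = nnls(basis, y)
    return basis @ amps - y, amps


def fit_triexponential(times, values) -> TriExpFit:
    """Least-squares tri-exponential fit from the empirical peak onward.

    Amplitudes are constrained non-negative (solved by NNLS for each decay-
    rate candidate); decay rates are optimised in log space from several
    fixed starting triples.  Raises :class:`BloodFitError` on degenerate
    input or non-convergence (the latter carrying a single-exponential
    fallback when available).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 7:
        raise BloodFitError("need at least 7 samples spanning the peak")
    if not np.any(y > 0):
        raise BloodFitError("all-zero/negative samples: no peak to fit from")
    ipk = int(np.argmax(y))
    if t.size - ipk < 4:
        raise BloodFitError("too few samples after the peak")
    tpk = float(t[ipk])
    tail_t = t[ipk:] - tpk
    tail_y = y[ipk:]

    starts = [
        (2.0, 0.2, 0.02),
        (1.0, 0.1, 0.01),
        (4.0, 0.5, 0.05),
        (0.5, 0.05, 0.005),
    ]
    best = None
    for lam0 in starts:
        try:
            res = least_squares(
                lambda p: _varpro_residual(p, tail_t, tail_y)[0],
                x0=np.log(lam0),
                method="lm",
                xtol=1e-14,
                ftol=1e-14,
                max_nfev=4000,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    peak_val = float(tail_y.max())
    if best is None or not np.all(np.isfinite(best.x)):
        # single-exponential fallback for the error report
        fallback = None
        try:
            lam1 = max(-np.polyfit(tail_t, np.log(np.clip(tail_y, 1e-12, None)), 1)[0], 1e-6)
            a1 = float(np.sum(tail_y * np.exp(-lam1 * tail_t)) / np.sum(np.exp(-2 * lam1 * tail_t)))
            fallback = _assemble(t, y, ipk, np.array([a1]), np.array([lam1]), 0.0)
        except Exception:
            pass
        raise BloodFitError("tri-exponential fit did not converge", fallback)

    resid, amps = _varpro_residual(best.x, tail_t, tail_y)
    lams = np.exp(best.x)
    order = np.argsort(-lams)
    rms = float(np.sqrt(np.mean(resid**2)))
    return _assemble(t, y, ipk, amps[order], lams[order], rms / max(peak_val, 1e-12))


def _assemble(t, y, ipk, amps, lams, rel_rms) -> TriExpFit:
    tpk = float(t[ipk])
    if t[0] > 0:
        rise_t = np.concatenate(([0.0], t[: ipk + 1]))
        rise_v = np.concatenate(([0.0], y[: ipk + 1]))
    else:
        rise_t = t[: ipk + 1].copy()
        rise_v = y[: ipk + 1].copy()
    if rise_t.size == 1:  # peak at the very first sample at t=0
        rise_t = np.array([0.0])
        rise_v = np.array([y[ipk]])
    return TriExpFit(tpk, np.asarray(amps, float), np.asarray(lams, float), rise_t, rise_v, rel_rms)


def fit_hill(times, parent_fractions) -> HillFit:
    """Least-squares Hill fit of the plasma parent fraction.

    Warns (but still fits) when the measured trend is increasing, which
    usually indicates swapped columns or assay problems.
    """
    t = np.asarray(times, dtype=float)
    pf = np.asarray(parent_fractions, dtype=float)
    if t.size < 4:
        raise BloodFitError("need at least 4 parent-fraction samples")
    if np.any(pf < 0) or np.any(pf > 1):
        raise BloodFitError("parent fractions must lie in [0, 1]")
    if t.size >= 2 and np.polyfit(t, pf, 1)[0] > 1e-6:
        warnings.warn("parent fraction trend is increasing; Hill fit may be meaningless")

    if np.allclose(pf, 1.0):
        return HillFit(a=1.0, b=1.0, c=float(np.median(t[t > 0]) if np.any(t > 0) else 1.0))

    def model(tt, a, b, c):
        return HillFit(a, b, c)(tt)

    pf_min = float(np.clip(pf.min(), 0.0, 1.0))
    tpos = t[t > 0]
    c0 = float(np.median(tpos)) if tpos.size else 10.0
    popt, _ = curve_fit(
        model,
        t,
        pf,
        p0=(pf_min, 2.0, c0),
        bounds=([0.0, 0.01, 1e-3], [1.0, 25.0, 1e4]),
        maxfev=20000,
    )
    return HillFit(*[float(v) for v in popt])


def make_input(plasma: TriExpFit, hill: HillFit, whole_blood: TriExpFit) -> InputFunction:
    """Metabolite-corrected input: Cp(t) = total-plasma(t) × parent-fraction(t)."""
    return InputFunction(plasma=plasma, parent_fraction=hill, whole_blood=whole_blood, delay=0.0)


def fit_delay(
    whole_brain_tac: TimeActivityCurve,
    input_fn: InputFunction,
    vb: float = 0.05,
    window_min: float = 5.0,
    grid_half_width: float = 2.0,
    grid_step: float = 0.05,
) -> float:
    """Arrival delay Δ (min) between the blood sampling site and the brain.

    Fits a one-tissue model (with the fixed vascular term) to the early
    whole-brain TAC for every candidate shift on a uniform grid
    Δ ∈ [−grid_half_width, +grid_half_width] and returns the residual-
    minimising Δ.  The input function should thereafter be evaluated as
    ``input_fn.with_delay(Δ)``.
    """
    early = whole_brain_tac.truncate(window_min)
    if early.schedule.n_frames < 6:
        raise ValueError("whole-brain TAC must cover the early window with ≥ 6 frames")
    y = early.values
    if np.ptp(y) < 1e-12 * max(abs(y).max(), 1.0):
        warnings.warn("flat whole-brain TAC; returning delay 0")
        return 0.0

    n_steps = int(round(grid_half_width / grid_step))
    deltas = np.arange(-n_steps, n_steps + 1) * grid_step
    t_end = window_min + grid_half_width
    tf = fine_grid(t_end)
    base = input_fn.with_delay(0.0)
    cp0 = np.asarray(base.parent_plasma(tf))
    cwb0 = np.asarray(base.whole_blood_at(tf))

    best_delta, best_rss = 0.0, np.inf
    for d in deltas:
        # shifting the input by +d == evaluating curves at t-d
        cp = np.interp(tf - d, tf, cp0, left=0.0)
        cwb = np.interp(tf - d, tf, cwb0, left=0.0)
        cwb_frames = frame_averages(cwb, tf, early.schedule)
        target = y - vb * cwb_frames

        def rss_of_k2(log_k2):
            conv = frame_averages(expconv(cp, FINE_DT, np.exp(log_k2)), tf, early.schedule)
            a = (1.0 - vb) * conv
            denom = float(a @ a)
            k1 = max(float(a @ target) / denom, 0.0) if denom > 0 else 0.0
            r = k1 * a - target
            return float(r @ r)

        opt = minimize_scalar(rss_of_k2, bounds=(np.log(1e-4), np.log(5.0)), method="bounded")
        if opt.fun < best_rss:
            best_rss, best_delta = opt.fun, float(d)

    if abs(abs(best_delta) - grid_half_width) < 1e-9:
        warnings.warn("delay estimate lies on the search-grid boundary")
    return best_delta
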