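"""Logan graphical analysis and Ichise's multilinear analysis-1 (MA1).

Both methods linearise reversible tracer kinetics for frames past an
equilibration time t*:

* Logan:  ∫₀ᵀ C_T dt / C_T(T) = V_T · ∫₀ᵀ Cp dt / C_T(T) + b
* MA1:    C_T(T) = −(V_T/b) · ∫₀ᵀ Cp dt + (1/b) · ∫₀ᵀ C_T dt

t* is chosen once from the whole-brain TAC (maximum relative deviation from
the Logan regression line ≤ 10% by default) and reused for every region and
voxel.  Measured TACs are first corrected for the fixed vascular fraction,
``C_T = (C_PET − Vb·C_wb)/(1 − Vb)``, so these estimators target the same
tissue V_T as the compartmental gold standard.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._conv import ConvolutionGrid
from .blood_input import InputFunction
from .compartmental import DEFAULT_VB
from .data_model import TimeActivityCurve

__all__ = ["LinearFitResult", "select_t_star", "logan_vt", "ma1_vt", "tissue_correct"]

DEFAULT_T_STAR = 30.0  # fallback when the residual criterion is never met


@dataclass(frozen=True)
class LinearFitResult:
    vt: float  # mL·cm⁻³
    coefficients: tuple  # Logan: (slope, intercept); MA1: (b_cp, b_ct)
    t_star: float
    frames_used: np.ndarray  # indices into the TAC
    max_rel_residual_pct: float
    method: str


def tissue_correct(
    values: np.ndarray, schedule, input_fn: InputFunction, vb: float = DEFAULT_VB,
    grid: ConvolutionGrid | None = None,
) -> np.ndarray:
    """Remove the fixed vascular contribution from measured frame values."""
    if vb == 0.0:
        return np.asarray(values, dtype=float)
    if grid is None:
        grid = ConvolutionGrid(input_fn, schedule.total_end)
    cwb_frames = grid.averages(grid.cwb, schedule)
    return (np.asarray(values, dtype=float) - vb * cwb_frames) / (1.0 - vb)


def _integral_anchor0(times: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Trapezoidal ∫₀ᵗ of point samples, with a (0, 0) anchor."""
    t = np.concatenate(([0.0], times))
    v = np.concatenate(([0.0], values))
    seg = np.diff(t) * (v[1:] + v[:-1]) / 2.0
    return np.cumsum(seg)


def _prepare(tac: TimeActivityCurve, input_fn: InputFunction, vb: float,
             grid: ConvolutionGrid | None):
    schedule = tac.schedule
    if grid is None:
        grid = ConvolutionGrid(input_fn, schedule.total_end)
    ct = tissue_correct(tac.values, schedule, input_fn, vb, grid)
    mids = schedule.mid_times
    int_ct = _integral_anchor0(mids, ct)
    int_cp = grid.cp_integral_at(mids)
    return ct, mids, int_ct, int_cp


def logan_vt(
    tac: TimeActivityCurve,
    input_fn: InputFunction,
    t_star: float,
    vb: float = DEFAULT_VB,
    grid: ConvolutionGrid | None = None,
) -> LinearFitResult:
    """Logan-plot V_T: OLS slope of ∫C_T/C_T against ∫Cp/C_T past t*.

    Frames with non-positive tissue values are dropped with a warning; fewer
    than 3 usable frames is an error.
    """
    ct, mids, int_ct, int_cp = _prepare(tac, input_fn, vb, grid)
    sel = mids >= t_star - 1e-9
    usable = sel & (ct > 0)
    if np.any(sel & ~usable):
        warnings.warn("dropping frames with non-positive tissue activity from Logan fit")
    idx = np.flatnonzero(usable)
    if idx.size < 3:
        raise ValueError("fewer than 3 usable frames past t*")
    x = int_cp[idx] / ct[idx]
    y = int_ct[idx] / ct[idx]
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    max_rel = float(np.max(np.abs((y - fitted) / fitted))) * 100.0
    return LinearFitResult(
        vt=float(slope),
        coefficients=(float(slope), float(intercept)),
        t_star=float(t_star),
        frames_used=idx,
        max_rel_residual_pct=max_rel,
        method="logan",
    )


def ma1_vt(
    tac: TimeActivityCurve,
    input_fn: InputFunction,
    t_star: float,
    vb: float = DEFAULT_VB,
    grid: ConvolutionGrid | None = None,
) -> LinearFitResult:
    """MA1 V_T: two-regressor fit of C_T(T) on ∫Cp and ∫C_T past t*."""
    ct, mids, int_ct, int_cp = _prepare(tac, input_fn, vb, grid)
    idx = np.flatnonzero(mids >= t_star - 1e-9)
    if idx.size < 3:
        raise ValueError("fewer than 3 usable frames past t*")
    X = np.column_stack([int_cp[idx], int_ct[idx]])
    if np.linalg.matrix_rank(X) < 2:
        raise ValueError("singular MA1 design matrix")
    beta, *_ = np.linalg.lstsq(X, ct[idx], rcond=None)
    b_cp, b_ct = float(beta[0]), float(beta[1])
    if abs(b_ct) < 1e-15:
        raise ValueError("degenerate MA1 fit: coefficient of ∫C_T is zero")
    fitted = X @ beta
    denom = np.where(np.abs(fitted) > 1e-15, fitted, np.nan)
    max_rel = float(np.nanmax(np.abs((ct[idx] - fitted) / denom))) * 100.0
    return LinearFitResult(
        vt=-b_cp / b_ct,
        coefficients=(b_cp, b_ct),
        t_star=float(t_star),
        frames_used=idx,
        max_rel_residual_pct=max_rel,
        method="ma1",
    )


def select_t_star(
    whole_brain_tac: TimeActivityCurve,
    input_fn: InputFunction,
    criterion_pct: float = 10.0,
    vb: float = DEFAULT_VB,
    min_frames: int = 6,
) -> float:
    """Smallest frame mid-time whose Logan regression over all later frames
    has maximum |relative residual| ≤ ``criterion_pct``.

    The returned t* is shared by Logan, MA1 and every voxel of a session.
    Falls back (with a warning) to the last admissible candidate when the
    criterion is never met.
    """
    mids = whole_brain_tac.schedule.mid_times
    candidates = mids[: max(mids.size - min_frames + 1, 0)]
    if candidates.size == 0:
        raise ValueError(f"TAC too short: need ≥ {min_frames} frames after a candidate t*")
    grid = ConvolutionGrid(input_fn, whole_brain_tac.schedule.total_end)
    last = None
    for cand in candidates:
        try:
            fit = logan_vt(whole_brain_tac, input_fn, float(cand), vb, grid)
        except ValueError:
            continue
        last = float(cand)
        if fit.max_rel_residual_pct <= criterion_pct:
            return float(cand)
    warnings.warn(
        f"Logan linearity criterion ({criterion_pct}%) never met; using last candidate t*"
    )
    return last if last is not None else DEFAULT_T_STAR
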