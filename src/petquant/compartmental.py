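"""Two-tissue compartment model (2TCM): forward simulation and nonlinear fit.

The reversible 2TCM describes tracer exchange between arterial plasma and a
free/nonspecific tissue compartment (K1, k2) and between that compartment
and a specifically bound one (k3, k4).  Its tissue impulse response is the
bi-exponential

    h(t) = K1/(θ1−θ2) · [(θ1−k3−k4) e^{−θ1 t} + (k3+k4−θ2) e^{−θ2 t}],

with θ1,2 the roots of θ² − (k2+k3+k4)θ + k2k4.  The measured PET signal
adds a fixed vascular contribution:

    C_PET(t) = (1 − Vb)·(h ⊛ Cp)(t) + Vb·C_wb(t),   Vb = 0.05 by default.

The macro-parameter of interest is the total distribution volume
V_T = (K1/k2)(1 + k3/k4).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from ._conv import FINE_DT, ConvolutionGrid
from .blood_input import InputFunction
from .data_model import FrameSchedule, TimeActivityCurve

__all__ = [
    "KineticParameters",
    "FitDiagnostics",
    "simulate_2tcm",
    "fit_2tcm",
    "vt_from_micro",
    "DEFAULT_VB",
]

DEFAULT_VB = 0.05

_RATE_LO, _RATE_HI = 1e-6, 10.0

# Fixed deterministic multi-start grid: a half-fraction of the 2^4 corners of
# K1∈{0.1,0.4}, k2∈{0.05,0.2}, k3∈{0.01,0.1}, k4∈{0.01,0.05} (even parity).
_STARTS = [
    (0.1, 0.05, 0.01, 0.01),
    (0.1, 0.05, 0.1, 0.05),
    (0.1, 0.2, 0.01, 0.05),
    (0.1, 0.2, 0.1, 0.01),
    (0.4, 0.05, 0.01, 0.05),
    (0.4, 0.05, 0.1, 0.01),
    (0.4, 0.2, 0.01, 0.01),
    (0.4, 0.2, 0.1, 0.05),
]


@dataclass(frozen=True)
class KineticParameters:
    """2TCM micro-parameters; ``vt`` is the derived macro-parameter."""

    K1: float  # mL·cm⁻³·min⁻¹
    k2: float  # min⁻¹
    k3: float  # min⁻¹
    k4: float  # min⁻¹
    vb: float = DEFAULT_VB

    def __post_init__(self) -> None:
        if not (0.0 <= self.vb <= 1.0):
            raise ValueError("vb must lie in [0, 1]")
        if min(self.K1, self.k2, self.k3, self.k4) < 0:
            raise ValueError("rate constants must be non-negative")

    @property
    def vt(self) -> float:
        return vt_from_micro(self)


@dataclass(frozen=True)
class FitDiagnostics:
    rss: float
    se_pct: dict = field(default_factory=dict)  # parameter -> SE as % of estimate
    converged: bool = True
    n_iterations: int = 0
    boundary_hit: bool = False
    start_index: int = 0


def vt_from_micro(params, k2=None, k3=None, k4=None) -> float:
    """Total distribution volume V_T = (K1/k2)(1 + k3/k4).

    Accepts either a :class:`KineticParameters` or the four rates directly.
    """
    if k2 is None:
        K1, k2, k3, k4 = params.K1, params.k2, params.k3, params.k4
    else:
        K1 = params
    if k2 <= 0 or k4 <= 0:
        raise ValueError("k2 and k4 must be positive (reversible configuration)")
    return (K1 / k2) * (1.0 + k3 / k4)


def _impulse_coefficients(K1, k2, k3, k4):
    s = k2 + k3 + k4
    disc = s * s - 4.0 * k2 * k4
    if disc < -1e-10:
        raise ValueError("non-physical eigenvalues (negative discriminant)")
    root = np.sqrt(max(disc, 0.0))
    th1 = (s + root) / 2.0
    th2 = (s - root) / 2.0
    if th2 < -1e-12:
        raise ValueError("non-physical eigenvalues (negative rate)")
    if root < 1e-12:  # defective case: nudge apart, error O(root)
        root = 1e-12
        th1 = (s + root) / 2.0
        th2 = (s - root) / 2.0
    c1 = K1 * (th1 - k3 - k4) / root
    c2 = K1 * (k3 + k4 - th2) / root
    return c1, th1, c2, th2


def _tissue_fine(K1, k2, k3, k4, grid: ConvolutionGrid) -> np.ndarray:
    if K1 == 0.0:
        return np.zeros_like(grid.cp)
    c1, th1, c2, th2 = _impulse_coefficients(K1, k2, k3, k4)
    return c1 * grid.expconv_cp(th1) + c2 * grid.expconv_cp(th2)


def _model_frames(params: KineticParameters, grid: ConvolutionGrid, schedule) -> np.ndarray:
    ct = _tissue_fine(params.K1, params.k2, params.k3, params.k4, grid)
    c_pet = (1.0 - params.vb) * ct + params.vb * grid.cwb
    return grid.averages(c_pet, schedule)


def simulate_2tcm(
    params: KineticParameters,
    input_fn: InputFunction,
    schedule: FrameSchedule,
    fine_dt: float = FINE_DT,
    label: str = "",
) -> TimeActivityCurve:
    """Forward-simulate a frame-averaged 2TCM TAC for the given input function."""
    grid = ConvolutionGrid(input_fn, schedule.total_end, fine_dt)
    return TimeActivityCurve(schedule, _model_frames(params, grid, schedule), label)


def fit_2tcm(
    tac: TimeActivityCurve,
    input_fn: InputFunction,
    vb_fixed: float = DEFAULT_VB,
    fine_dt: float = FINE_DT,
):
    """Weighted nonlinear least-squares 2TCM fit with fixed vascular fraction.

    Rates are optimised in log space within (1e-6, 10) min⁻¹ from 8 fixed
    deterministic starting points; residuals are weighted by √(frame
    duration), i.e. uniform variance per unit scan time.  Returns
    ``(KineticParameters, FitDiagnostics)``.
    """
    schedule = tac.schedule
    grid = ConvolutionGrid(input_fn, schedule.total_end, fine_dt)
    y = tac.values
    w = np.sqrt(schedule.durations / schedule.durations.mean())
    scale = float(np.sum((w * y) ** 2)) or 1.0

    def residuals(logp):
        K1, k2, k3, k4 = np.exp(logp)
        p = KineticParameters(K1, k2, k3, k4, vb_fixed)
        return w * (_model_frames(p, grid, schedule) - y)

    lo, hi = np.log(_RATE_LO), np.log(_RATE_HI)
    best, best_idx = None, 0
    for i, start in enumerate(_STARTS):
        res = least_squares(
            residuals,
            x0=np.log(start),
            bounds=(lo, hi),
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
            max_nfev=400,
        )
        if best is None or res.cost < best.cost:
            best, best_idx = res, i
        if best.cost < 1e-20 * scale:  # essentially perfect fit
            break

    if best is None or not np.all(np.isfinite(best.x)):
        raise RuntimeError("2TCM fit failed to converge from every starting point")

    logp = best.x
    K1, k2, k3, k4 = np.exp(logp)
    params = KineticParameters(K1, k2, k3, k4, vb_fixed)
    rss = float(2.0 * best.cost)
    n, p = y.size, 4
    se_pct = {}
    try:
        jtj = best.jac.T @ best.jac
        cov = np.linalg.inv(jtj) * (rss / max(n - p, 1))
        # log-space SE is directly a relative (fractional) SE of the rate
        rel = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        se_pct = dict(zip(("K1", "k2", "k3", "k4"), (100.0 * rel).tolist()))
    except np.linalg.LinAlgError:
        pass
    boundary = bool(np.any(logp < lo + 1e-6) or np.any(logp > hi - 1e-6))
    diag = FitDiagnostics(
        rss=rss,
        se_pct=se_pct,
        converged=bool(best.success),
        n_iterations=int(best.nfev),
        boundary_hit=boundary,
        start_index=best_idx,
    )
    return params, diag
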