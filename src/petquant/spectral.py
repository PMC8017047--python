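"""Spectral analysis: nonnegative exponential-basis decomposition of a TAC.

The tissue response is modelled as a nonnegative sum of input-convolved
exponentials on a fixed logarithmic grid of decay rates β_j,

    C_T(t) ≈ Σ_j α_j · (Cp ⊛ e^{−β_j t})(t),   α_j ≥ 0,

solved by nonnegative least squares with the basis functions frame-averaged
exactly like the data.  Macro-parameters follow in closed form:
V_T = Σ α_j/β_j and the tissue impulse response IRF(t) = Σ α_j e^{−β_j t}
(IRF(0) ≈ K1; IRF at 120 min is the "IRF₁₂₀" outcome measure).  No trapping
(β = 0) component is included: the tracer is reversible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from ._conv import ConvolutionGrid
from .blood_input import InputFunction
from .compartmental import DEFAULT_VB
from .data_model import TimeActivityCurve
from .linearized import tissue_correct

__all__ = [
    "SpectralResult",
    "SpectralBasis",
    "default_beta_grid",
    "spectral_fit",
    "vt_from_spectrum",
    "irf_at",
]


def default_beta_grid(n: int = 100, t_max: float = 120.0, beta_max: float = 6.0) -> np.ndarray:
    """Logarithmic β grid from 1/(4·t_max) (slowest resolvable washout over a
    t_max-min acquisition) up to ``beta_max`` min⁻¹."""
    return np.geomspace(1.0 / (4.0 * t_max), beta_max, n)


@dataclass(frozen=True)
class SpectralResult:
    betas: np.ndarray  # min⁻¹, fixed grid
    alphas: np.ndarray  # ≥ 0
    residual_norm: float

    def __post_init__(self) -> None:
        if np.any(self.alphas < 0):
            raise ValueError("spectral amplitudes must be non-negative")

    @property
    def vt(self) -> float:
        return float(np.sum(self.alphas / self.betas))

    @property
    def n_components(self) -> int:
        return int(np.sum(self.alphas > 0))

    def irf(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return np.exp(-np.outer(t, self.betas)) @ self.alphas


class SpectralBasis:
    """Frame-averaged convolution basis for one input function + schedule;
    build once, reuse across regions/voxels of the same session."""

    def __init__(self, input_fn: InputFunction, schedule, betas=None,
                 grid: ConvolutionGrid | None = None):
        self.betas = np.asarray(betas if betas is not None else default_beta_grid(), float)
        if np.any(self.betas <= 0) or np.any(np.diff(self.betas) <= 0):
            raise ValueError("beta grid must be strictly positive and sorted")
        self.schedule = schedule
        self.grid = grid or ConvolutionGrid(input_fn, schedule.total_end)
        cols = [
            self.grid.averages(self.grid.expconv_cp(b), schedule) for b in self.betas
        ]
        self.matrix = np.column_stack(cols)

    def solve(self, ct_values: np.ndarray) -> SpectralResult:
        alphas, rnorm = nnls(self.matrix, np.asarray(ct_values, dtype=float))
        return SpectralResult(self.betas, alphas, float(rnorm))


def spectral_fit(
    tac: TimeActivityCurve,
    input_fn: InputFunction,
    beta_grid=None,
    vb: float = DEFAULT_VB,
    basis: SpectralBasis | None = None,
) -> SpectralResult:
    """Nonnegative least-squares spectral decomposition of one TAC.

    The measured TAC is vascular-corrected first, so the recovered spectrum
    describes the tissue response alone.  Warns when a clearly non-zero TAC
    yields an all-zero spectrum (β grid likely mis-specified).
    """
    if basis is None:
        basis = SpectralBasis(input_fn, tac.schedule, beta_grid)
    ct = tissue_correct(tac.values, tac.schedule, input_fn, vb, basis.grid)
    result = basis.solve(ct)
    if result.n_components == 0 and np.max(np.abs(ct)) > 1e-6 * max(np.max(np.abs(tac.values)), 1e-30):
        warnings.warn("all-zero spectrum for a non-zero TAC; check the beta grid")
    return result


def vt_from_spectrum(result: SpectralResult) -> float:
    """V_T = Σ α_j / β_j (mL·cm⁻³)."""
    return result.vt


def irf_at(result: SpectralResult, t: float = 120.0) -> float:
    """Impulse response function Σ α_j e^{−β_j t} at time t (min⁻¹)."""
    if t < 0:
        raise ValueError("t must be non-negative")
    return float(result.irf(np.atleast_1d(t))[0])
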