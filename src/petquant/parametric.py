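"""Voxelwise parametric maps, atlas region means, and SUV/SUVR quantification.

Each voxel TAC is fed through the same estimator used at the region level
(Logan, MA1, spectral V_T, or IRF₁₂₀), with the whole-brain t* shared by all
voxels.  Voxels whose data violate an estimator's preconditions are masked
rather than propagated as values.  SUV normalises activity by injected dose
per body weight; SUVR divides each region's SUV by that of the designated
pseudo-reference region (the corpus callosum in this tracer's cohort, which
has the lowest V_T — a true reference region devoid of binding does not
exist for a ubiquitously expressed target).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._conv import ConvolutionGrid
from .blood_input import InputFunction
from .compartmental import DEFAULT_VB
from .data_model import DynamicImage, RegionAtlas
from .spectral import SpectralBasis

__all__ = [
    "ParametricMap",
    "SuvrTable",
    "voxelwise_map",
    "voxelwise_sa_maps",
    "region_means",
    "suv_image",
    "suvr_regions",
    "DEFAULT_SUV_WINDOW",
]

METHODS = ("logan", "ma1", "sa_vt", "irf120")

#: the 100–120-min window correlates best with compartmental V_T
DEFAULT_SUV_WINDOW = (100.0, 120.0)


@dataclass(frozen=True)
class ParametricMap:
    """3-D parameter volume (V_T in mL·cm⁻³ or IRF in min⁻¹) with a validity mask."""

    values: np.ndarray  # NaN where invalid
    valid: np.ndarray  # bool
    method: str
    t_star: float

    def __post_init__(self) -> None:
        if self.values.shape != self.valid.shape:
            raise ValueError("values and validity mask must share a shape")


@dataclass(frozen=True)
class SuvrTable:
    table: pd.DataFrame  # columns: region, suv, suvr
    window: tuple
    reference: str


def _voxel_matrix(image: DynamicImage, mask: np.ndarray) -> np.ndarray:
    return image.data[mask]  # (n_voxels, n_frames)


def _default_mask(image: DynamicImage, atlas: RegionAtlas | None) -> np.ndarray:
    if atlas is not None:
        if atlas.labels.shape != image.data.shape[:3]:
            raise ValueError("atlas grid does not match image grid")
        return atlas.labels > 0
    return np.any(image.data != 0.0, axis=3)


def _corrected_voxels(image, input_fn, mask, vb, grid):
    cwb_frames = grid.averages(grid.cwb, image.schedule)
    return (_voxel_matrix(image, mask) - vb * cwb_frames) / (1.0 - vb)


def _integrals(image, input_fn, grid):
    mids = image.schedule.mid_times
    int_cp = grid.cp_integral_at(mids)
    return mids, int_cp


def _cum_trapz_rows(mids: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Row-wise ∫₀ᵗ of mid-time point samples with a (0,0) anchor."""
    t = np.concatenate(([0.0], mids))
    dt = np.diff(t)
    Vpad = np.concatenate([np.zeros((V.shape[0], 1)), V], axis=1)
    seg = dt * (Vpad[:, 1:] + Vpad[:, :-1]) / 2.0
    return np.cumsum(seg, axis=1)


def voxelwise_map(
    image: DynamicImage,
    input_fn: InputFunction,
    method: str,
    t_star: float,
    atlas: RegionAtlas | None = None,
    vb: float = DEFAULT_VB,
    beta_grid=None,
) -> ParametricMap:
    """Apply a regional estimator independently to every (masked-in) voxel.

    ``method`` ∈ {"logan", "ma1", "sa_vt", "irf120"}.  The t* must come from
    the whole-brain TAC of the same session.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method '{method}'; choose from {METHODS}")
    if method in ("sa_vt", "irf120"):
        vt_map, irf_map = voxelwise_sa_maps(image, input_fn, atlas, vb, beta_grid, t_star)
        return vt_map if method == "sa_vt" else irf_map

    mask = _default_mask(image, atlas)
    grid = ConvolutionGrid(input_fn, image.schedule.total_end)
    C = _corrected_voxels(image, input_fn, mask, vb, grid)
    mids, int_cp = _integrals(image, input_fn, grid)
    int_ct = _cum_trapz_rows(mids, C)
    sel = mids >= t_star - 1e-9
    if int(np.sum(sel)) < 3:
        raise ValueError("fewer than 3 frames past t*")
    Cu, Iu, Pu = C[:, sel], int_ct[:, sel], int_cp[sel]

    vals = np.full(mask.shape, np.nan)
    valid = np.zeros(mask.shape, dtype=bool)
    if method == "logan":
        ok = np.all(Cu > 0, axis=1)
        x = np.where(Cu > 0, Pu / np.where(Cu > 0, Cu, 1.0), 0.0)
        y = np.where(Cu > 0, Iu / np.where(Cu > 0, Cu, 1.0), 0.0)
        n = Pu.size
        sx, sy = x.sum(axis=1), y.sum(axis=1)
        sxx, sxy = (x * x).sum(axis=1), (x * y).sum(axis=1)
        denom = n * sxx - sx * sx
        ok &= np.abs(denom) > 1e-12 * np.maximum(sxx, 1.0)
        slope = np.where(ok, (n * sxy - sx * sy) / np.where(ok, denom, 1.0), np.nan)
        est = slope
    else:  # ma1
        a11 = float(Pu @ Pu)
        a12 = Iu @ Pu
        a22 = (Iu * Iu).sum(axis=1)
        b1 = Cu @ Pu
        b2 = (Cu * Iu).sum(axis=1)
        det = a11 * a22 - a12 * a12
        scale = np.maximum(a11 * a22, 1e-30)
        ok = np.abs(det) > 1e-12 * scale
        safe = np.where(ok, det, 1.0)
        beta_cp = (a22 * b1 - a12 * b2) / safe
        beta_ct = (a11 * b2 - a12 * b1) / safe
        ok &= np.abs(beta_ct) > 1e-15
        est = np.where(ok, -beta_cp / np.where(np.abs(beta_ct) > 1e-15, beta_ct, 1.0), np.nan)

    ok &= np.isfinite(est)
    flat_vals = np.where(ok, est, np.nan)
    vals[mask] = flat_vals
    valid[mask] = ok
    return ParametricMap(vals, valid, method, float(t_star))


def voxelwise_sa_maps(
    image: DynamicImage,
    input_fn: InputFunction,
    atlas: RegionAtlas | None = None,
    vb: float = DEFAULT_VB,
    beta_grid=None,
    t_star: float = 0.0,
    irf_time: float = 120.0,
):
    """Spectral V_T and IRF maps from a single NNLS pass per voxel."""
    mask = _default_mask(image, atlas)
    basis = SpectralBasis(input_fn, image.schedule, beta_grid)
    C = _corrected_voxels(image, input_fn, mask, vb, basis.grid)
    n_vox = C.shape[0]
    vt_flat = np.full(n_vox, np.nan)
    irf_flat = np.full(n_vox, np.nan)
    ok = np.zeros(n_vox, dtype=bool)
    decay = np.exp(-basis.betas * irf_time)
    inv_beta = 1.0 / basis.betas
    for i in range(n_vox):
        try:
            res = basis.solve(C[i])
        except Exception:
            continue
        vt_flat[i] = float(res.alphas @ inv_beta)
        irf_flat[i] = float(res.alphas @ decay)
        ok[i] = True

    def pack(flat, method):
        vals = np.full(mask.shape, np.nan)
        valid = np.zeros(mask.shape, dtype=bool)
        vals[mask] = flat
        valid[mask] = ok
        return ParametricMap(vals, valid, method, float(t_star))

    return pack(vt_flat, "sa_vt"), pack(irf_flat, "irf120")


def region_means(pmap: ParametricMap, atlas: RegionAtlas) -> pd.DataFrame:
    """Unweighted mean over valid voxels per region, with masked fractions."""
    if atlas.labels.shape != pmap.values.shape:
        raise ValueError("atlas grid does not match map grid")
    rows = []
    for lab, name in sorted(atlas.names.items()):
        sel = atlas.labels == lab
        n = int(sel.sum())
        good = sel & pmap.valid
        n_good = int(good.sum())
        if n_good == 0:
            warnings.warn(f"region '{name}' is fully masked in {pmap.method} map")
            mean = np.nan
        else:
            mean = float(pmap.values[good].mean())
        rows.append(
            {
                "region": name,
                "mean": mean,
                "n_voxels": n,
                "frac_masked": 1.0 - n_good / n if n else np.nan,
            }
        )
    return pd.DataFrame(rows)


def suv_image(
    image: DynamicImage, window: tuple, dose_mbq: float, weight_kg: float
) -> np.ndarray:
    """Standardized uptake value volume over a late time window (g·mL⁻¹).

    Duration-weighted mean concentration across the frames inside the
    window, divided by injected dose per body weight.  kBq·mL⁻¹ with MBq and
    kg cancel to SUV = C̄ · weight / dose.
    """
    if dose_mbq <= 0 or weight_kg <= 0:
        raise ValueError("dose and weight must be positive")
    t0, t1 = window
    sched = image.schedule
    sel = (sched.start_times >= t0 - 1e-9) & (sched.end_times <= t1 + 1e-9)
    if not np.any(sel) or abs(sched.durations[sel].sum() - (t1 - t0)) > 1e-6:
        raise ValueError(f"window {window} not fully covered by frames")
    durs = sched.durations[sel]
    mean_conc = np.tensordot(image.data[..., sel], durs, axes=([3], [0])) / durs.sum()
    return mean_conc * weight_kg / dose_mbq


def suvr_regions(
    suv_volume: np.ndarray, atlas: RegionAtlas, window: tuple = DEFAULT_SUV_WINDOW
) -> SuvrTable:
    """Per-region SUV means and their ratio to the pseudo-reference region."""
    if atlas.labels.shape != suv_volume.shape:
        raise ValueError("atlas grid does not match SUV volume")
    rows = []
    for lab, name in sorted(atlas.names.items()):
        sel = atlas.labels == lab
        rows.append({"region": name, "suv": float(suv_volume[sel].mean())})
    df = pd.DataFrame(rows)
    ref_name = atlas.reference_name
    ref_suv = float(df.loc[df["region"] == ref_name, "suv"].iloc[0])
    if ref_suv <= 0:
        raise ValueError("reference-region SUV is non-positive")
    df["suvr"] = df["suv"] / ref_suv
    return SuvrTable(df, tuple(window), ref_name)
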