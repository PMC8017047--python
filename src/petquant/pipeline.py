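"""End-to-end orchestration of the quantification comparison.

Runs every requested method (2TCM gold standard, Logan, MA1, spectral V_T,
IRF₁₂₀, SUVR) at the requested levels (region, voxel) on each subject-
session of a cohort, then assembles the three report tables of a method-
comparison study: correlation with the gold standard, mean ± SD with
percentage bias, and test–retest reliability (TRV/aTRV/ICC).  Only the
first 120 min of PET and blood data enter the kinetic fits; SUVR uses the
100–120-min window.  The 2TCM is fitted at the region level only — its
iterative nonlinear fit is unsuitable for voxel-level analysis.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__ as _version
from .blood_input import fit_delay, fit_hill, fit_triexponential, make_input
from .compartmental import fit_2tcm
from .data_model import WHOLE_BRAIN
from .linearized import logan_vt, ma1_vt, select_t_star
from .parametric import (
    DEFAULT_SUV_WINDOW,
    region_means,
    suv_image,
    suvr_regions,
    voxelwise_map,
    voxelwise_sa_maps,
)
from .reliability import (
    PairedMeasurements,
    atrv,
    icc,
    icc_classification,
    pearson_r,
    percent_bias,
    trv,
)
from .spectral import SpectralBasis, irf_at, spectral_fit, vt_from_spectrum
from .synthetic import Cohort

__all__ = ["RunManifest", "ResultStore", "run_quantification", "build_reports", "av_report"]

ALL_METHODS = ("2tcm", "logan", "ma1", "sa", "irf120", "suvr")
T_CUT = 120.0  # min of PET/blood data entering every kinetic fit


@dataclass
class RunManifest:
    config: dict
    seed: int
    methods: tuple
    levels: tuple
    version: str = _version
    stages: list = field(default_factory=list)
    warnings: list = field(default_factory=list)
    session_info: dict = field(default_factory=dict)  # (subject, session) -> t*, delay


@dataclass
class ResultStore:
    estimates: pd.DataFrame  # subject, session, region, method, level, parameter, value
    manifest: RunManifest

    def vt_table(self, method: str, level: str = "region", session: str = "test",
                 parameter: str = "VT") -> pd.DataFrame:
        df = self.estimates
        sel = df[
            (df.method == method) & (df.level == level)
            & (df.session == session) & (df.parameter == parameter)
        ]
        return sel.pivot(index="subject", columns="region", values="value")


def _session_input(record, cohort, refit_blood):
    if refit_blood:
        bt = record.arterial
        plasma_fit = fit_triexponential(bt.times, bt.plasma)
        wb_fit = fit_triexponential(bt.times, bt.whole_blood)
        hill_fit = fit_hill(bt.times, bt.parent_fraction)
        input_fn = make_input(plasma_fit, hill_fit, wb_fit)
        delay = fit_delay(record.tacs[WHOLE_BRAIN], input_fn)
        return input_fn.with_delay(delay), delay
    input_fn = cohort.truth.inputs[(record.subject_id, record.session)]
    return input_fn, input_fn.delay


def run_quantification(
    cohort: Cohort,
    methods=ALL_METHODS,
    levels=("region", "voxel"),
    refit_blood: bool = True,
    t_star_criterion_pct: float = 10.0,
) -> ResultStore:
    """Quantify every subject-session of a cohort with the requested methods.

    ``refit_blood=False`` bypasses the blood-fitting stage and uses the
    generator's ground-truth input functions (useful for isolating kinetic-
    model error from input-function error).
    """
    methods = tuple(methods)
    levels = tuple(levels)
    unknown = set(methods) - set(ALL_METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    if "2tcm" in methods and set(levels) == {"voxel"}:
        raise ValueError(
            "2TCM is restricted to the region level: its nonlinear fit is "
            "unsuitable for voxel-level analyses"
        )
    manifest = RunManifest(
        config=dataclasses.asdict(cohort.config),
        seed=cohort.seed,
        methods=methods,
        levels=levels,
    )
    rows: list = []
    if not methods:
        return ResultStore(pd.DataFrame(
            columns=["subject", "session", "region", "method", "level", "parameter", "value"]
        ), manifest)

    needs_kinetics = bool(set(methods) & {"2tcm", "logan", "ma1", "sa", "irf120"})
    for test_rec, retest_rec in cohort.records:
        for record in (test_rec, retest_rec):
            key = (record.subject_id, record.session)
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                _quantify_session(
                    record, cohort, methods, levels, refit_blood,
                    t_star_criterion_pct, rows, manifest, needs_kinetics,
                )
            manifest.warnings.extend(f"{key}: {w.message}" for w in caught)
            manifest.stages.append({"subject": record.subject_id,
                                    "session": record.session, "status": "done"})
    return ResultStore(pd.DataFrame(rows), manifest)


def _quantify_session(record, cohort, methods, levels, refit_blood,
                      t_star_criterion_pct, rows, manifest, needs_kinetics):
    sid, session = record.subject_id, record.session

    def emit(region, method, level, parameter, value):
        rows.append({"subject": sid, "session": session, "region": region,
                     "method": method, "level": level,
                     "parameter": parameter, "value": float(value)})

    input_fn = t_star = None
    tacs120 = {}
    if needs_kinetics:
        input_fn, delay = _session_input(record, cohort, refit_blood)
        tacs120 = {name: tac.truncate(T_CUT) for name, tac in record.tacs.items()}
        t_star = select_t_star(tacs120[WHOLE_BRAIN], input_fn, t_star_criterion_pct)
        manifest.session_info[(sid, session)] = {"t_star": t_star, "delay": delay}

    region_level = "region" in levels
    regions = list(tacs120)
    if region_level and "2tcm" in methods:
        for name in regions:
            params, _diag = fit_2tcm(tacs120[name], input_fn)
            emit(name, "2tcm", "region", "VT", params.vt)
    if region_level and "logan" in methods:
        for name in regions:
            emit(name, "logan", "region", "VT", logan_vt(tacs120[name], input_fn, t_star).vt)
    if region_level and "ma1" in methods:
        for name in regions:
            emit(name, "ma1", "region", "VT", ma1_vt(tacs120[name], input_fn, t_star).vt)
    if region_level and ("sa" in methods or "irf120" in methods):
        basis = SpectralBasis(input_fn, tacs120[WHOLE_BRAIN].schedule)
        for name in regions:
            res = spectral_fit(tacs120[name], input_fn, basis=basis)
            if "sa" in methods:
                emit(name, "sa", "region", "VT", vt_from_spectrum(res))
            if "irf120" in methods:
                emit(name, "irf120", "region", "IRF120", irf_at(res, 120.0))

    voxel_level = "voxel" in levels and record.image is not None
    if voxel_level and needs_kinetics:
        image120 = record.image.truncate(T_CUT)
        atlas = cohort.atlas
        maps = {}
        if "logan" in methods:
            maps["logan"] = voxelwise_map(image120, input_fn, "logan", t_star, atlas)
        if "ma1" in methods:
            maps["ma1"] = voxelwise_map(image120, input_fn, "ma1", t_star, atlas)
        if "sa" in methods or "irf120" in methods:
            sa_map, irf_map = voxelwise_sa_maps(image120, input_fn, atlas, t_star=t_star)
            if "sa" in methods:
                maps["sa"] = sa_map
            if "irf120" in methods:
                maps["irf120"] = irf_map
        for method, pmap in maps.items():
            parameter = "IRF120" if method == "irf120" else "VT"
            df = region_means(pmap, atlas)
            for _, r in df.iterrows():
                emit(r["region"], method, "voxel", parameter, r["mean"])
            brain = (atlas.labels > 0) & pmap.valid
            emit(WHOLE_BRAIN, method, "voxel", parameter, float(pmap.values[brain].mean()))

    if "suvr" in methods and record.image is not None:
        suv = suv_image(record.image, DEFAULT_SUV_WINDOW,
                        record.injected_dose_mbq, record.body_weight_kg)
        table = suvr_regions(suv, cohort.atlas, DEFAULT_SUV_WINDOW)
        for _, r in table.table.iterrows():
            emit(r["region"], "suvr", "region", "SUV", r["suv"])
            emit(r["region"], "suvr", "region", "SUVR", r["suvr"])


def _methods_present(store: ResultStore):
    df = store.estimates
    out = []
    for method in ("logan", "ma1", "sa", "irf120"):
        for level in ("region", "voxel"):
            parameter = "IRF120" if method == "irf120" else "VT"
            sub = df[(df.method == method) & (df.level == level) & (df.parameter == parameter)]
            if len(sub):
                out.append((method, level, parameter))
    return out


def build_reports(store: ResultStore, ground_truth: pd.DataFrame | None = None,
                  session: str = "test", bias_definition: str = "vs_average") -> dict:
    """Paper-style report tables from a populated result store.

    Returns a dict of DataFrames: ``correlation`` (Pearson r of each method
    against regional 2TCM V_T, per region), ``vt_comparison`` (mean ± SD and
    % bias per region × method), ``reliability`` (TRV/aTRV/ICC per region ×
    method), and ``recovery`` (bias/RMSE against ground truth) when truth is
    supplied.  SUVR is reported in its own table and never enters the
    correlation analysis by default.
    """
    df = store.estimates
    if df.empty:
        raise ValueError("result store is empty")
    gold = store.vt_table("2tcm", "region", session)
    if gold.empty:
        raise ValueError("2TCM results required to build comparison reports")
    regions = list(gold.columns)

    corr_rows, vt_rows, rel_rows = [], [], []
    for region in regions:
        ref = gold[region]
        vt_rows.append({
            "region": region, "method": "2tcm", "level": "region",
            "mean": ref.mean(), "sd": ref.std(ddof=1), "bias_pct": 0.0,
        })
    for method, level, parameter in _methods_present(store):
        tab = store.vt_table(method, level, session, parameter)
        for region in regions:
            if region not in tab.columns:
                continue
            alt = tab[region].reindex(gold.index)
            r, p = pearson_r(gold[region].to_numpy(), alt.to_numpy())
            corr_rows.append({"region": region, "method": method, "level": level,
                              "parameter": parameter, "r": r, "p": p})
            if parameter == "VT":
                vt_rows.append({
                    "region": region, "method": method, "level": level,
                    "mean": alt.mean(), "sd": alt.std(ddof=1),
                    "bias_pct": percent_bias(gold[region].to_numpy(), alt.to_numpy(),
                                             bias_definition),
                })

    method_levels = [("2tcm", "region", "VT")] + _methods_present(store)
    for method, level, parameter in method_levels:
        test_tab = store.vt_table(method, level, "test", parameter)
        retest_tab = store.vt_table(method, level, "retest", parameter)
        if test_tab.empty or retest_tab.empty:
            continue
        for region in test_tab.columns:
            t = test_tab[region]
            r = retest_tab[region].reindex(t.index)
            pairs = PairedMeasurements(tuple(t.index), t.to_numpy(), r.to_numpy(),
                                       parameter, region, method)
            icc_val = icc(pairs)
            rel_rows.append({
                "region": region, "method": method, "level": level, "parameter": parameter,
                "test_mean": t.mean(), "test_cov_pct": 100 * t.std(ddof=1) / t.mean(),
                "retest_mean": r.mean(), "retest_cov_pct": 100 * r.std(ddof=1) / r.mean(),
                "trv_pct": float(np.mean(trv(t.to_numpy(), r.to_numpy()))),
                "atrv_pct": float(np.mean(atrv(t.to_numpy(), r.to_numpy()))),
                "icc": icc_val, "icc_class": icc_classification(icc_val),
            })

    reports = {
        "correlation": pd.DataFrame(corr_rows),
        "vt_comparison": pd.DataFrame(vt_rows),
        "reliability": pd.DataFrame(rel_rows),
    }

    suvr = df[(df.method == "suvr") & (df.parameter == "SUVR") & (df.session == session)]
    if len(suvr):
        reports["suvr"] = suvr.pivot(index="subject", columns="region", values="value")

    if ground_truth is not None:
        rec_rows = []
        truth_vt = ground_truth.pivot_table(index=["subject", "session"], columns="region",
                                            values="VT")
        for method, level, parameter in method_levels:
            if parameter != "VT":
                continue
            for sess in ("test", "retest"):
                tab = store.vt_table(method, level, sess)
                if tab.empty:
                    continue
                tru = truth_vt.xs(sess, level="session").reindex(tab.index)
                common = [c for c in tab.columns if c in tru.columns]
                est = tab[common].to_numpy().ravel()
                tv = tru[common].to_numpy().ravel()
                rec_rows.append({
                    "method": method, "level": level, "session": sess,
                    "bias_vs_truth_pct": percent_bias(tv, est, "vs_reference"),
                    "rmse": float(np.sqrt(np.mean((est - tv) ** 2))),
                })
        reports["recovery"] = pd.DataFrame(rec_rows)
    return reports


def av_report(cohort: Cohort) -> pd.DataFrame:
    """Cohort arteriovenous-difference profile (mean ± SD per timepoint)."""
    from .reliability import av_profile_summary

    pairs = [
        (test.arterial, test.venous)
        for test, _retest in cohort.records
        if test.venous is not None
    ]
    if not pairs:
        raise ValueError("no venous tables in cohort")
    return av_profile_summary(pairs, cohort.config.av_times)
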