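"""Synthetic test–retest PET cohort generator.

Emulates a 10-subject test–retest study of a reversible, ubiquitously bound
radioligand: 45-frame/180-min acquisitions, 16 consolidated brain regions
whose V_T targets centre the whole brain at 13.2 mL·cm⁻³ with the corpus
callosum lowest, tri-exponential blood curves with a Hill-decaying parent
fraction, frame-duration-dependent Gaussian noise, a predominantly positive
retest shift (9/10 subjects up, median +10%), and an arteriovenous plasma
difference profile that crosses zero near 60 min.

Every stochastic draw flows from a single seed; identical seeds give
bit-identical cohorts.  Ground-truth micro-parameters, blood-curve
parameters, delays and session effects are stored alongside the data so
parameter recovery can be tested end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .blood_input import HillFit, InputFunction, TriExpFit
from .compartmental import KineticParameters, simulate_2tcm
from .data_model import (
    WHOLE_BRAIN,
    BloodSampleTable,
    DynamicImage,
    FrameSchedule,
    RegionAtlas,
    SubjectRecord,
    default_schedule,
)

__all__ = [
    "RegionSpec",
    "SimulationConfig",
    "GroundTruth",
    "Cohort",
    "generate_blood",
    "generate_subject",
    "generate_image",
    "generate_cohort",
    "build_atlas",
    "add_frame_noise",
    "DEFAULT_REGIONS",
]


@dataclass(frozen=True)
class RegionSpec:
    name: str
    vt_target: float  # mL·cm⁻³, cohort-mean target
    n_voxels: int


# 16 consolidated regions; V_T targets for whole brain, temporal, frontal,
# striatum, cerebellum and brainstem follow the reported cohort means, the
# remainder are plausible interpolations, and the corpus callosum sits below
# all others (only "lowest V_T" is known).  Voxel counts define the toy atlas.
DEFAULT_REGIONS = (
    RegionSpec("frontal", 14.1, 500),
    RegionSpec("temporal", 15.0, 500),
    RegionSpec("parietal", 13.0, 500),
    RegionSpec("occipital", 12.0, 500),
    RegionSpec("cingulate", 13.8, 400),
    RegionSpec("insula", 14.0, 300),
    RegionSpec("hippocampus", 13.0, 200),
    RegionSpec("amygdala", 13.5, 150),
    RegionSpec("striatum", 15.6, 400),
    RegionSpec("thalamus", 14.5, 300),
    RegionSpec("pallidum", 12.5, 150),
    RegionSpec("cerebellum", 14.1, 500),
    RegionSpec("brainstem", 12.2, 300),
    RegionSpec("white_matter", 10.5, 700),
    RegionSpec("precuneus", 13.0, 300),
    RegionSpec("corpus_callosum", 8.0, 64),
)

_BLOOD_TIMES = np.array(
    [0.25, 0.5, 0.75, 1.0, 1.25, 1.5, 1.75, 2.0, 2.5, 3.0, 4.0, 5.0, 8.0, 10.0,
     15.0, 20.0, 30.0, 45.0, 60.0, 90.0, 120.0, 150.0, 180.0]
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort (all defaults mirror the
    emulated test–retest study; see the methods note for rationale)."""

    n_subjects: int = 10
    regions: tuple = DEFAULT_REGIONS
    # kinetic priors (k2 is derived from the region's V_T target)
    k1_range: tuple = (0.25, 0.35)  # mL·cm⁻³·min⁻¹
    k3_range: tuple = (0.03, 0.07)  # min⁻¹
    k4_range: tuple = (0.02, 0.04)  # min⁻¹
    vb: float = 0.05
    # variability
    between_subject_sd: float = 0.17  # SD of log V_T scale across subjects
    region_jitter_sd: float = 0.03  # extra per-region log jitter
    noise_level: float = 0.05  # regional TAC frame noise (fraction)
    voxel_noise_level: float = 0.10  # extra voxel-level frame noise
    blood_noise: float = 0.02  # multiplicative blood-sample noise
    # retest session effect (multiplicative on K1, hence on V_T)
    retest_up_fraction: float = 0.9
    retest_up_median: float = 1.10
    retest_up_sd: float = 0.05  # SD of log effect
    retest_down_median: float = 0.93
    retest_down_sd: float = 0.03
    # arteriovenous difference profile (% of arterial, + means arterial higher)
    av_times: tuple = (30.0, 60.0, 120.0, 180.0)
    av_profile: tuple = (14.3, -1.5, -5.5, -25.0)
    av_profile_sd: tuple = (12.2, 5.9, 14.0, 21.0)
    n_venous_subjects: int = 4
    # blood-curve base parameters
    plasma_peak_time: float = 1.5  # min
    plasma_amplitudes: tuple = (90.0, 15.0, 4.0)  # kBq·mL⁻¹
    plasma_rates: tuple = (2.5, 0.25, 0.012)  # min⁻¹
    whole_blood_ratio: float = 0.85
    hill_a: float = 0.12
    hill_b: float = 1.8
    hill_c: float = 35.0  # min
    delay_range: tuple = (-0.5, 0.5)  # min, true arrival delay
    # dosimetry
    dose_range_mbq: tuple = (170.0, 190.0)
    weight_range_kg: tuple = (58.0, 95.0)
    # toy image geometry
    image_shape: tuple = (20, 20, 20)

    def __post_init__(self) -> None:
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            raise ValueError("region names must be unique")
        cc = min(self.regions, key=lambda r: r.vt_target)
        if cc.name != "corpus_callosum":
            raise ValueError("corpus callosum must carry the lowest V_T target")
        if any(lo <= 0 for lo, _ in (self.k1_range, self.k3_range, self.k4_range)):
            raise ValueError("kinetic rate priors must be positive")
        if sum(r.n_voxels for r in self.regions) > int(np.prod(self.image_shape)):
            raise ValueError("voxel budget smaller than the configured regions")

    @property
    def region_names(self) -> list:
        return [r.name for r in self.regions]

    @property
    def whole_brain_vt_target(self) -> float:
        w = np.array([r.n_voxels for r in self.regions], dtype=float)
        v = np.array([r.vt_target for r in self.regions], dtype=float)
        return float((w * v).sum() / w.sum())

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["regions"] = [asdict(r) for r in self.regions]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["regions"] = tuple(RegionSpec(**r) for r in d["regions"])
        for key, val in list(d.items()):
            if isinstance(val, list):
                d[key] = tuple(val)
        return cls(**d)


@dataclass
class GroundTruth:
    """Per subject × session × region micro-parameters and curve truths."""

    params: pd.DataFrame
    inputs: dict = field(default_factory=dict)  # (subject, session) -> InputFunction


@dataclass
class Cohort:
    config: SimulationConfig
    records: list  # list of (test SubjectRecord, retest SubjectRecord)
    truth: GroundTruth
    atlas: RegionAtlas
    seed: int = 0

    @property
    def subjects(self) -> list:
        return [pair[0].subject_id for pair in self.records]


def add_frame_noise(values: np.ndarray, schedule: FrameSchedule, level: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Gaussian frame noise with SD ∝ √(value/duration).

    Scaled so that a frame at the curve's duration-weighted mean value and
    mean duration has relative noise equal to ``level``.
    """
    if level == 0:
        return values.copy()
    durs = schedule.durations
    cbar = float(np.average(np.abs(values), weights=durs))
    if cbar == 0:
        return values.copy()
    sd = level * np.sqrt(np.clip(values, 0.0, None) * cbar * durs.mean() / durs)
    return values + rng.normal(0.0, 1.0, values.shape) * sd


def _jitter(rng, sd=0.1):
    return float(np.exp(rng.normal(0.0, sd)))


def _triexp_from_params(peak_time, amplitudes, rates) -> TriExpFit:
    amps = np.asarray(amplitudes, float)
    peak_val = float(amps.sum())
    return TriExpFit(
        peak_time=float(peak_time),
        amplitudes=amps,
        rates=np.asarray(rates, float),
        rise_times=np.array([0.0, float(peak_time)]),
        rise_values=np.array([0.0, peak_val]),
    )


def _draw_blood_truth(config: SimulationConfig, rng) -> tuple:
    # peak lands on a sampling time so zero-noise samples from the peak onward
    # lie exactly on the exponential manifold (round-trip recoverable)
    candidates = _BLOOD_TIMES[np.abs(_BLOOD_TIMES - config.plasma_peak_time) <= 0.5]
    peak = float(rng.choice(candidates))
    amps = np.array(config.plasma_amplitudes) * _jitter(rng, 0.12)
    rates = np.array(config.plasma_rates) * np.array([_jitter(rng, 0.08) for _ in range(3)])
    rates = -np.sort(-rates)  # keep ordering after jitter
    plasma = _triexp_from_params(peak, amps, rates)
    wb = _triexp_from_params(peak, amps * config.whole_blood_ratio, rates)
    hill = HillFit(
        a=float(np.clip(config.hill_a * _jitter(rng, 0.15), 0.0, 0.4)),
        b=config.hill_b * _jitter(rng, 0.08),
        c=config.hill_c * _jitter(rng, 0.12),
    )
    return plasma, wb, hill


def generate_blood(config: SimulationConfig, subject: str, session: str,
                   rng: np.random.Generator, with_venous: bool = False,
                   truth: tuple | None = None):
    """Arterial blood table (plus optional venous table) for one session.

    Returns ``(arterial, venous_or_None, input_truth)`` where ``input_truth``
    is the noise-free :class:`InputFunction` the samples were drawn from
    (delay 0; the arrival delay applies to the brain, not the artery).
    """
    plasma, wb, hill = truth if truth is not None else _draw_blood_truth(config, rng)
    t = _BLOOD_TIMES
    noise = config.blood_noise
    wb_samp = np.clip(wb(t) * (1.0 + rng.normal(0, noise, t.size)), 0.0, None)
    pl_samp = np.clip(plasma(t) * (1.0 + rng.normal(0, noise, t.size)), 0.0, None)
    pf_samp = np.clip(hill(t) + rng.normal(0, noise / 2.0, t.size), 0.0, 1.0)
    arterial = BloodSampleTable(t, wb_samp, pl_samp, pf_samp, site="arterial")

    venous = None
    if with_venous:
        vt_times = np.asarray(config.av_times, float)
        profile = np.asarray(config.av_profile, float) + rng.normal(
            0.0, np.asarray(config.av_profile_sd, float)
        )
        parent_art = plasma(vt_times) * hill(vt_times)
        parent_ven = parent_art * (1.0 - profile / 100.0)
        pf_v = hill(vt_times)
        plasma_v = np.clip(parent_ven / np.clip(pf_v, 1e-9, None), 0.0, None)
        venous = BloodSampleTable(
            vt_times, plasma_v * config.whole_blood_ratio, plasma_v, pf_v, site="venous"
        )
    input_truth = InputFunction(plasma=plasma, parent_fraction=hill, whole_blood=wb, delay=0.0)
    return arterial, venous, input_truth


def _draw_region_params(config: SimulationConfig, vt_region: float, rng) -> KineticParameters:
    K1 = rng.uniform(*config.k1_range)
    k3 = rng.uniform(*config.k3_range)
    k4 = rng.uniform(*config.k4_range)
    k2 = K1 * (1.0 + k3 / k4) / vt_region  # hit the V_T target exactly
    return KineticParameters(K1, k2, k3, k4, config.vb)


def generate_subject(
    config: SimulationConfig,
    subject_id: str,
    rng: np.random.Generator,
    subject_scale: float | None = None,
    retest_up: bool | None = None,
    with_venous: bool = False,
):
    """One subject's test and retest sessions plus their ground truth.

    ``subject_scale`` multiplies every regional V_T target (drawn lognormal
    when absent); ``retest_up`` forces the direction of the retest shift.
    Returns ``(test_record, retest_record, truth_rows, truth_inputs)``.
    """
    schedule = default_schedule()
    if subject_scale is None:
        subject_scale = _jitter(rng, config.between_subject_sd)
    if retest_up is None:
        retest_up = bool(rng.random() < config.retest_up_fraction)
    if retest_up:
        effect = float(np.exp(rng.normal(np.log(config.retest_up_median), config.retest_up_sd)))
        effect = max(effect, 1.0 + 1e-3)
    else:
        effect = float(np.exp(rng.normal(np.log(config.retest_down_median), config.retest_down_sd)))
        effect = min(effect, 1.0 - 1e-3)

    # micro-parameters are a stable subject trait; the session effect scales K1
    base_params = {}
    for spec in config.regions:
        vt_s = spec.vt_target * subject_scale * _jitter(rng, config.region_jitter_sd)
        base_params[spec.name] = _draw_region_params(config, vt_s, rng)

    counts = np.array([r.n_voxels for r in config.regions], dtype=float)
    weights = counts / counts.sum()

    truth_rows, truth_inputs, records = [], {}, []
    for session in ("test", "retest"):
        sess_effect = 1.0 if session == "test" else effect
        blood_truth = _draw_blood_truth(config, rng)
        arterial, venous, input_truth = generate_blood(
            config, subject_id, session, rng,
            with_venous=with_venous and session == "test", truth=blood_truth,
        )
        delay = float(rng.uniform(*config.delay_range))
        brain_input = input_truth.with_delay(delay)
        tacs, clean = {}, {}
        for spec in config.regions:
            p0 = base_params[spec.name]
            p = KineticParameters(p0.K1 * sess_effect, p0.k2, p0.k3, p0.k4, p0.vb)
            tac = simulate_2tcm(p, brain_input, schedule, label=spec.name)
            clean[spec.name] = tac.values
            noisy = add_frame_noise(tac.values, schedule, config.noise_level, rng)
            tacs[spec.name] = tac.__class__(schedule, noisy, spec.name)
            truth_rows.append(
                {
                    "subject": subject_id, "session": session, "region": spec.name,
                    "K1": p.K1, "k2": p.k2, "k3": p.k3, "k4": p.k4, "vb": p.vb,
                    "VT": p.vt, "session_effect": sess_effect,
                    "subject_scale": subject_scale, "delay": delay,
                }
            )
        wb_vals = np.sum([w * tacs[r.name].values for w, r in zip(weights, config.regions)], axis=0)
        tacs[WHOLE_BRAIN] = tacs[config.regions[0].name].__class__(schedule, wb_vals, WHOLE_BRAIN)
        wb_vt = float(np.dot(weights, [base_params[r.name].vt * sess_effect for r in config.regions]))
        truth_rows.append(
            {
                "subject": subject_id, "session": session, "region": WHOLE_BRAIN,
                "K1": np.nan, "k2": np.nan, "k3": np.nan, "k4": np.nan, "vb": config.vb,
                "VT": wb_vt, "session_effect": sess_effect,
                "subject_scale": subject_scale, "delay": delay,
            }
        )
        truth_inputs[(subject_id, session)] = brain_input
        records.append(
            SubjectRecord(
                subject_id=subject_id,
                session=session,
                injected_dose_mbq=float(rng.uniform(*config.dose_range_mbq)),
                body_weight_kg=float(rng.uniform(*config.weight_range_kg)),
                tacs=tacs,
                arterial=arterial,
                venous=venous,
            )
        )
    return records[0], records[1], truth_rows, truth_inputs


def build_atlas(config: SimulationConfig) -> RegionAtlas:
    """Deterministic block atlas: regions fill the flattened grid in order;
    remaining voxels are background."""
    flat = np.zeros(int(np.prod(config.image_shape)), dtype=np.int32)
    pos = 0
    names = {}
    ref_label = None
    for lab, spec in enumerate(config.regions, start=1):
        flat[pos : pos + spec.n_voxels] = lab
        pos += spec.n_voxels
        names[lab] = spec.name
        if spec.name == "corpus_callosum":
            ref_label = lab
    if ref_label is None:
        ref_label = min(names, key=lambda k: 0)  # pragma: no cover
    return RegionAtlas(flat.reshape(config.image_shape), names, ref_label)


def generate_image(record: SubjectRecord, config: SimulationConfig,
                   rng: np.random.Generator, atlas: RegionAtlas | None = None) -> tuple:
    """Toy 4-D image: each voxel's TAC is its region's TAC plus independent
    voxel noise.  Returns ``(DynamicImage, RegionAtlas)``."""
    if not record.tacs:
        raise ValueError("record carries no regional TACs")
    if atlas is None:
        atlas = build_atlas(config)
    schedule = next(iter(record.tacs.values())).schedule
    shape = config.image_shape
    data = np.zeros(shape + (schedule.n_frames,))
    lab_flat = atlas.labels.reshape(-1)
    flat = data.reshape(-1, schedule.n_frames)
    for lab, name in sorted(atlas.names.items()):
        sel = np.flatnonzero(lab_flat == lab)
        base = record.tacs[name].values
        if config.voxel_noise_level == 0:
            flat[sel] = base
        else:
            for idx in sel:
                flat[idx] = add_frame_noise(base, schedule, config.voxel_noise_level, rng)
    image = DynamicImage(data, schedule)
    record.image = image
    return image, atlas


def generate_cohort(config: SimulationConfig, seed: int, with_images: bool = False) -> Cohort:
    """Complete deterministic test–retest cohort.

    Subject V_T scales are drawn lognormally then centred to a unit cohort
    mean, so the cohort-average whole-brain V_T matches the configured
    target; exactly round(up_fraction·n) subjects receive an upward retest
    shift.  Venous tables are generated for the first ``n_venous_subjects``.
    """
    rng = np.random.default_rng(seed)
    n = config.n_subjects
    raw = np.exp(rng.normal(0.0, config.between_subject_sd, n))
    scales = raw / raw.mean()
    n_up = int(round(config.retest_up_fraction * n))
    up_flags = np.zeros(n, dtype=bool)
    up_flags[rng.permutation(n)[:n_up]] = True

    records, rows, inputs = [], [], {}
    for i in range(n):
        sid = f"sub{i + 1:02d}"
        sub_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
        test, retest, trows, tinputs = generate_subject(
            config, sid, sub_rng,
            subject_scale=float(scales[i]),
            retest_up=bool(up_flags[i]),
            with_venous=i < config.n_venous_subjects,
        )
        records.append((test, retest))
        rows.extend(trows)
        inputs.update(tinputs)

    atlas = build_atlas(config)
    if with_images:
        img_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
        for test, retest in records:
            for rec in (test, retest):
                generate_image(rec, config, img_rng, atlas)

    truth = GroundTruth(params=pd.DataFrame(rows), inputs=inputs)
    return Cohort(config=config, records=records, truth=truth, atlas=atlas, seed=seed)
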