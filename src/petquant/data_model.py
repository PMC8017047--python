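"""Core data types and I/O for dynamic PET quantification.

Unit conventions used throughout the package:

* time — minutes
* activity concentration — kBq·mL⁻¹ (decay-corrected; correction is assumed
  to have been applied upstream, as scanners conventionally do)
* rate constants — min⁻¹
* total distribution volume V_T — mL·cm⁻³
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "FrameSchedule",
    "TimeActivityCurve",
    "DynamicImage",
    "RegionAtlas",
    "BloodSampleTable",
    "SubjectRecord",
    "default_schedule",
    "truncate",
    "extract_regional_tacs",
    "WHOLE_BRAIN",
]

#: label used for the whole-brain TAC produced by :func:`extract_regional_tacs`
WHOLE_BRAIN = "whole_brain"

_EPS = 1e-9


@dataclass(frozen=True)
class FrameSchedule:
    """Frame timing of a dynamic acquisition.

    Frames may be contiguous or gapped but never overlap; all times in minutes.
    """

    start_times: np.ndarray
    durations: np.ndarray

    def __post_init__(self) -> None:
        starts = np.asarray(self.start_times, dtype=float)
        durs = np.asarray(self.durations, dtype=float)
        object.__setattr__(self, "start_times", starts)
        object.__setattr__(self, "durations", durs)
        if starts.ndim != 1 or durs.shape != starts.shape:
            raise ValueError("start_times and durations must be 1-D and equal length")
        if starts.size == 0:
            raise ValueError("schedule must contain at least one frame")
        if np.any(durs <= 0):
            raise ValueError("frame durations must be positive")
        if np.any(np.diff(starts) <= 0):
            raise ValueError("frame start times must be strictly increasing")
        if np.any(starts[1:] < starts[:-1] + durs[:-1] - _EPS):
            raise ValueError("frames must not overlap")

    @classmethod
    def from_durations(cls, durations, t0: float = 0.0) -> "FrameSchedule":
        durs = np.asarray(durations, dtype=float)
        starts = t0 + np.concatenate(([0.0], np.cumsum(durs)[:-1]))
        return cls(starts, durs)

    @property
    def n_frames(self) -> int:
        return self.start_times.size

    @property
    def end_times(self) -> np.ndarray:
        return self.start_times + self.durations

    @property
    def mid_times(self) -> np.ndarray:
        return self.start_times + self.durations / 2.0

    @property
    def total_end(self) -> float:
        return float(self.end_times[-1])

    def truncate(self, t_end: float) -> "FrameSchedule":
        """Keep exactly the frames whose end time is ≤ ``t_end``."""
        if t_end <= 0:
            raise ValueError("t_end must be positive")
        keep = self.end_times <= t_end + _EPS
        if not np.any(keep):
            raise ValueError(f"no frame ends at or before t_end={t_end} min")
        n = int(np.sum(keep))
        return FrameSchedule(self.start_times[:n], self.durations[:n])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"frame_start_min": self.start_times, "frame_duration_min": self.durations}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FrameSchedule":
        df = pd.read_csv(path)
        return cls(
            df["frame_start_min"].to_numpy(float), df["frame_duration_min"].to_numpy(float)
        )


def default_schedule() -> FrameSchedule:
    """The 45-frame, 180-min acquisition: 6 × 0.5, 3 × 1, 2 × 2, 34 × 5 min."""
    durations = [0.5] * 6 + [1.0] * 3 + [2.0] * 2 + [5.0] * 34
    return FrameSchedule.from_durations(durations)


@dataclass(frozen=True)
class TimeActivityCurve:
    """Decay-corrected activity concentration per frame for one region or voxel.

    Values may be negative: frame noise is not clipped.
    """

    schedule: FrameSchedule
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.shape != (self.schedule.n_frames,):
            raise ValueError(
                f"values length {vals.size} != frame count {self.schedule.n_frames}"
            )
        if not np.all(np.isfinite(vals)):
            raise ValueError("TAC values must be finite")

    def truncate(self, t_end: float) -> "TimeActivityCurve":
        sched = self.schedule.truncate(t_end)
        return TimeActivityCurve(sched, self.values[: sched.n_frames], self.label)


@dataclass(frozen=True)
class DynamicImage:
    """4-D voxel array (x, y, z, frame) with its frame schedule."""

    data: np.ndarray
    schedule: FrameSchedule
    voxel_size_mm: tuple = (2.0, 2.0, 2.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", arr)
        if arr.ndim != 4:
            raise ValueError("dynamic image must be 4-D (x, y, z, frame)")
        if arr.shape[3] != self.schedule.n_frames:
            raise ValueError("4th dimension must equal frame count")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def truncate(self, t_end: float) -> "DynamicImage":
        sched = self.schedule.truncate(t_end)
        return DynamicImage(self.data[..., : sched.n_frames], sched, self.voxel_size_mm)

    def save(self, image_path, timing_path=None) -> None:
        affine = np.diag(list(self.voxel_size_mm) + [1.0])
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), affine), str(image_path))
        if timing_path is not None:
            self.schedule.to_csv(timing_path)

    @classmethod
    def load(cls, image_path, timing_path) -> "DynamicImage":
        img = nib.load(str(image_path))
        voxdim = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asarray(img.dataobj, dtype=float), FrameSchedule.from_csv(timing_path), voxdim)


@dataclass(frozen=True)
class RegionAtlas:
    """Integer-labelled volume with region names and a pseudo-reference label.

    Label 0 is background.  The pseudo-reference region (corpus callosum in the
    default cohort) anchors SUVR quantification.
    """

    labels: np.ndarray
    names: dict
    reference_label: int

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if not np.issubdtype(lab.dtype, np.integer):
            lab = lab.astype(np.int32)
        object.__setattr__(self, "labels", lab)
        if lab.min() < 0:
            raise ValueError("labels must be non-negative (0 = background)")
        present = set(np.unique(lab).tolist()) - {0}
        missing = set(self.names) - present
        if missing:
            raise ValueError(f"named labels absent from volume: {sorted(missing)}")
        if self.reference_label not in self.names:
            raise ValueError("pseudo-reference label must be among named labels")

    @property
    def region_names(self) -> list:
        return [self.names[k] for k in sorted(self.names)]

    @property
    def reference_name(self) -> str:
        return self.names[self.reference_label]

    def label_for(self, name: str) -> int:
        for lab, nm in self.names.items():
            if nm == name:
                return lab
        raise KeyError(name)

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label

    def voxel_count(self, label: int) -> int:
        return int(np.sum(self.labels == label))

    def save(self, image_path, labelmap_path) -> None:
        nib.save(nib.Nifti1Image(self.labels.astype(np.int16), np.eye(4)), str(image_path))
        rows = [
            {"label": lab, "name": nm, "is_reference": int(lab == self.reference_label)}
            for lab, nm in sorted(self.names.items())
        ]
        pd.DataFrame(rows).to_csv(labelmap_path, index=False)

    @classmethod
    def load(cls, image_path, labelmap_path) -> "RegionAtlas":
        lab = np.asarray(nib.load(str(image_path)).dataobj).astype(np.int32)
        df = pd.read_csv(labelmap_path)
        names = dict(zip(df["label"].astype(int), df["name"]))
        ref = int(df.loc[df["is_reference"] == 1, "label"].iloc[0])
        return cls(lab, names, ref)


@dataclass(frozen=True)
class BloodSampleTable:
    """Discrete blood samples: whole-blood and total-plasma activity plus the
    unmetabolized (parent) fraction, at strictly increasing sample times."""

    times: np.ndarray
    whole_blood: np.ndarray
    plasma: np.ndarray
    parent_fraction: np.ndarray
    site: str = "arterial"

    def __post_init__(self) -> None:
        for name in ("times", "whole_blood", "plasma", "parent_fraction"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.times.size
        if any(getattr(self, k).size != n for k in ("whole_blood", "plasma", "parent_fraction")):
            raise ValueError("all columns must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if np.any(self.parent_fraction < -_EPS) or np.any(self.parent_fraction > 1 + _EPS):
            raise ValueError("parent fraction must lie in [0, 1]")
        if np.any(self.whole_blood < 0) or np.any(self.plasma < 0):
            raise ValueError("activities must be non-negative")
        if self.site not in ("arterial", "venous"):
            raise ValueError("site must be 'arterial' or 'venous'")

    @property
    def parent_plasma(self) -> np.ndarray:
        """Metabolite-corrected plasma activity at the sample times."""
        return self.plasma * self.parent_fraction

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": self.times,
                "whole_blood_kBq_ml": self.whole_blood,
                "plasma_kBq_ml": self.plasma,
                "parent_fraction": self.parent_fraction,
                "site": self.site,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "BloodSampleTable":
        df = pd.read_csv(path)
        return cls(
            df["time_min"].to_numpy(float),
            df["whole_blood_kBq_ml"].to_numpy(float),
            df["plasma_kBq_ml"].to_numpy(float),
            df["parent_fraction"].to_numpy(float),
            str(df["site"].iloc[0]),
        )


@dataclass
class SubjectRecord:
    """One subject-session: dosimetry, regional TACs (and/or a 4-D image) and
    the blood tables drawn during that session."""

    subject_id: str
    session: str  # "test" | "retest"
    injected_dose_mbq: float
    body_weight_kg: float
    tacs: dict = field(default_factory=dict)  # region name -> TimeActivityCurve
    image: DynamicImage | None = None
    arterial: BloodSampleTable | None = None
    venous: BloodSampleTable | None = None

    def __post_init__(self) -> None:
        if self.session not in ("test", "retest"):
            raise ValueError("session must be 'test' or 'retest'")
        if self.injected_dose_mbq <= 0:
            raise ValueError("injected dose must be positive")
        if self.body_weight_kg <= 0:
            raise ValueError("body weight must be positive")


def truncate(obj, t_end: float):
    """Truncate a TAC or dynamic image to the frames ending at or before ``t_end``."""
    if isinstance(obj, (TimeActivityCurve, DynamicImage)):
        return obj.truncate(t_end)
    raise TypeError(f"cannot truncate object of type {type(obj).__name__}")


def extract_regional_tacs(image: DynamicImage, atlas: RegionAtlas) -> dict:
    """Mean TAC per atlas region, plus a whole-brain TAC over all labelled voxels.

    Region means are unweighted voxel means per frame.  Raises if the grids
    differ or a named region has no voxels.
    """
    if image.data.shape[:3] != atlas.labels.shape:
        raise ValueError(
            f"image grid {image.data.shape[:3]} does not match atlas grid {atlas.labels.shape}"
        )
    flat = image.data.reshape(-1, image.schedule.n_frames)
    lab_flat = atlas.labels.reshape(-1)
    out: dict = {}
    for lab, name in sorted(atlas.names.items()):
        sel = lab_flat == lab
        if not np.any(sel):
            raise ValueError(f"region '{name}' (label {lab}) has no voxels")
        out[name] = TimeActivityCurve(image.schedule, flat[sel].mean(axis=0), label=name)
    brain = lab_flat > 0
    out[WHOLE_BRAIN] = TimeActivityCurve(
        image.schedule, flat[brain].mean(axis=0), label=WHOLE_BRAIN
    )
    return out
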