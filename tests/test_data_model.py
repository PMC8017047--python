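import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import petquant as pq
from petquant.data_model import WHOLE_BRAIN


class TestFrameSchedule:
    def test_default_schedule_matches_acquisition(self, schedule45):
        assert schedule45.n_frames == 45
        assert schedule45.total_end == pytest.approx(180.0)
        assert schedule45.mid_times[0] == pytest.approx(0.25)
        # 6×0.5 + 3×1 + 2×2 = 10 min after frame 11
        assert schedule45.end_times[10] == pytest.approx(10.0)

    def test_validation(self):
        with pytest.raises(ValueError):
            pq.FrameSchedule(np.array([0.0, 1.0]), np.array([2.0, 1.0]))  # overlap
        with pytest.raises(ValueError):
            pq.FrameSchedule(np.array([1.0, 0.5]), np.array([0.5, 0.5]))  # not increasing
        with pytest.raises(ValueError):
            pq.FrameSchedule(np.array([0.0]), np.array([-1.0]))

    @pytest.mark.parametrize(
        "t_end,n_expected",
        [(120.0, 33), (180.0, 45), (3.0, 6), (10.0, 11)],
    )
    def test_truncate_counts(self, schedule45, t_end, n_expected):
        assert schedule45.truncate(t_end).n_frames == n_expected

    def test_truncate_before_first_frame_end_errors(self, schedule45):
        with pytest.raises(ValueError):
            schedule45.truncate(0.25)

    @settings(derandomize=True, max_examples=40)
    @given(t_end=st.floats(min_value=0.6, max_value=200.0))
    def test_truncate_idempotent(self, t_end):
        sched = pq.default_schedule()
        once = sched.truncate(t_end)
        twice = once.truncate(t_end)
        np.testing.assert_array_equal(once.start_times, twice.start_times)
        np.testing.assert_array_equal(once.durations, twice.durations)


class TestTacAndImageTruncation:
    def test_tac_truncate_preserves_values(self, schedule45):
        vals = np.arange(45.0)
        tac = pq.TimeActivityCurve(schedule45, vals, "r")
        cut = pq.truncate(tac, 120.0)
        assert cut.schedule.n_frames == 33
        np.testing.assert_array_equal(cut.values, vals[:33])

    def test_image_truncate(self, schedule45):
        img = pq.DynamicImage(np.zeros((2, 2, 2, 45)), schedule45)
        assert pq.truncate(img, 120.0).data.shape == (2, 2, 2, 33)

    def test_tac_length_mismatch_rejected(self, schedule45):
        with pytest.raises(ValueError):
            pq.TimeActivityCurve(schedule45, np.zeros(10))


def _block_image_and_atlas(schedule, constants):
    """Phantom: one constant TAC per region block along x."""
    nx = len(constants)
    data = np.zeros((nx, 2, 2, schedule.n_frames))
    labels = np.zeros((nx, 2, 2), dtype=np.int32)
    for i, c in enumerate(constants):
        data[i] = c
        labels[i] = i + 1
    names = {i + 1: f"region{i + 1}" for i in range(nx)}
    return pq.DynamicImage(data, schedule), pq.RegionAtlas(labels, names, 1)


class TestExtractRegionalTacs:
    def test_uniform_image_returns_constant_tacs(self, schedule45):
        img, atlas = _block_image_and_atlas(schedule45, [3.5, 3.5])
        tacs = pq.extract_regional_tacs(img, atlas)
        for name in atlas.names.values():
            np.testing.assert_allclose(tacs[name].values, 3.5)

    def test_two_voxel_mean(self, schedule45):
        data = np.zeros((2, 1, 1, 45))
        data[0] = 1.0
        data[1] = 3.0
        img = pq.DynamicImage(data, schedule45)
        atlas = pq.RegionAtlas(np.ones((2, 1, 1), dtype=np.int32), {1: "r"}, 1)
        tacs = pq.extract_regional_tacs(img, atlas)
        np.testing.assert_allclose(tacs["r"].values, 2.0)

    def test_block_phantom_recovers_constants(self, schedule120):
        consts = [1.0, 2.5, 7.0]
        img, atlas = _block_image_and_atlas(schedule120, consts)
        tacs = pq.extract_regional_tacs(img, atlas)
        for c, name in zip(consts, atlas.region_names):
            np.testing.assert_allclose(tacs[name].values, c)

    def test_voxel_weighted_region_average_equals_whole_brain(self, schedule120, mini_cohort):
        rec = mini_cohort.records[0][0]
        img, atlas = rec.image, mini_cohort.atlas
        tacs = pq.extract_regional_tacs(img, atlas)
        counts = np.array([atlas.voxel_count(lab) for lab in sorted(atlas.names)])
        stacked = np.array([tacs[atlas.names[lab]].values for lab in sorted(atlas.names)])
        weighted = (counts[:, None] * stacked).sum(axis=0) / counts.sum()
        np.testing.assert_allclose(weighted, tacs[WHOLE_BRAIN].values, rtol=1e-10)

    def test_empty_region_error_names_region(self, schedule45):
        img = pq.DynamicImage(np.zeros((2, 1, 1, 45)), schedule45)
        labels = np.ones((2, 1, 1), dtype=np.int32)
        atlas = pq.RegionAtlas(labels, {1: "present"}, 1)
        ghost = pq.RegionAtlas.__new__(pq.RegionAtlas)  # bypass validation to probe extract
        object.__setattr__(ghost, "labels", labels)
        object.__setattr__(ghost, "names", {1: "present", 2: "ghost"})
        object.__setattr__(ghost, "reference_label", 1)
        with pytest.raises(ValueError, match="ghost"):
            pq.extract_regional_tacs(img, ghost)
        assert atlas.voxel_count(1) == 2


class TestRoundTrips:
    def test_schedule_csv_round_trip(self, schedule45, tmp_path):
        p = tmp_path / "timing.csv"
        schedule45.to_csv(p)
        back = pq.FrameSchedule.from_csv(p)
        np.testing.assert_allclose(back.start_times, schedule45.start_times)
        np.testing.assert_allclose(back.durations, schedule45.durations)

    def test_blood_csv_round_trip(self, tmp_path):
        t = np.array([1.0, 2.0, 5.0, 30.0])
        table = pq.BloodSampleTable(t, t * 2, t * 3, np.array([1.0, 0.9, 0.7, 0.3]))
        p = tmp_path / "blood.csv"
        table.to_csv(p)
        back = pq.BloodSampleTable.from_csv(p)
        np.testing.assert_allclose(back.parent_plasma, table.parent_plasma)
        assert back.site == "arterial"

    def test_image_nifti_round_trip(self, schedule120, tmp_path):
        rng = np.random.default_rng(0)
        img = pq.DynamicImage(rng.normal(5, 1, (3, 3, 3, 33)), schedule120)
        img.save(tmp_path / "pet.nii.gz", tmp_path / "timing.csv")
        back = pq.DynamicImage.load(tmp_path / "pet.nii.gz", tmp_path / "timing.csv")
        np.testing.assert_allclose(back.data, img.data, rtol=1e-6)

    def test_atlas_round_trip(self, tmp_path):
        labels = np.array([[[0, 1], [2, 2]]], dtype=np.int32)
        atlas = pq.RegionAtlas(labels, {1: "a", 2: "corpus_callosum"}, 2)
        atlas.save(tmp_path / "atlas.nii.gz", tmp_path / "labels.csv")
        back = pq.RegionAtlas.load(tmp_path / "atlas.nii.gz", tmp_path / "labels.csv")
        np.testing.assert_array_equal(back.labels, labels)
        assert back.reference_name == "corpus_callosum"


class TestBloodTableValidation:
    def test_rejects_bad_parent_fraction(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ValueError):
            pq.BloodSampleTable(t, t, t, np.array([0.5, 1.5, 0.5, 0.5]))

    def test_rejects_nonmonotone_times(self):
        t = np.array([1.0, 3.0, 2.0, 4.0])
        with pytest.raises(ValueError):
            pq.BloodSampleTable(t, t, t, np.full(4, 0.5))


class TestSubjectRecord:
    def test_rejects_nonpositive_dose(self):
        with pytest.raises(ValueError):
            pq.SubjectRecord("s", "test", 0.0, 70.0)

    def test_rejects_unknown_session(self):
        with pytest.raises(ValueError):
            pq.SubjectRecord("s", "baseline", 180.0, 70.0)
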