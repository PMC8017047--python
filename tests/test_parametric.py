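import numpy as np
import pytest

import petquant as pq
from petquant.parametric import region_means, suv_image, suvr_regions, voxelwise_map


def _uniform_image(tac, shape=(4, 4, 4)):
    data = np.broadcast_to(tac.values, shape + (tac.values.size,)).copy()
    return pq.DynamicImage(data, tac.schedule)


def _one_region_atlas(shape=(4, 4, 4)):
    return pq.RegionAtlas(np.ones(shape, dtype=np.int32), {1: "roi"}, 1)


class TestVoxelwiseMaps:
    @pytest.mark.parametrize("method", ["logan", "ma1", "sa_vt"])
    def test_uniform_image_matches_regional_estimate(self, canonical_tac, canonical_input,
                                                     method):
        img = _uniform_image(canonical_tac)
        atlas = _one_region_atlas()
        pmap = voxelwise_map(img, canonical_input, method, 30.0, atlas)
        assert pmap.valid.all()
        if method == "logan":
            ref = pq.logan_vt(canonical_tac, canonical_input, 30.0).vt
        elif method == "ma1":
            ref = pq.ma1_vt(canonical_tac, canonical_input, 30.0).vt
        else:
            ref = pq.spectral_fit(canonical_tac, canonical_input).vt
        np.testing.assert_allclose(pmap.values[atlas.labels > 0], ref, rtol=1e-3)

    def test_irf_map_matches_regional_irf(self, canonical_tac, canonical_input):
        img = _uniform_image(canonical_tac)
        atlas = _one_region_atlas()
        pmap = voxelwise_map(img, canonical_input, "irf120", 30.0, atlas)
        ref = pq.irf_at(pq.spectral_fit(canonical_tac, canonical_input), 120.0)
        np.testing.assert_allclose(pmap.values[atlas.labels > 0], ref, rtol=1e-6)

    def test_unknown_method_rejected(self, canonical_tac, canonical_input):
        with pytest.raises(ValueError, match="unknown method"):
            voxelwise_map(_uniform_image(canonical_tac), canonical_input, "patlak", 30.0)

    def test_zero_voxel_masked_for_logan_zero_vt_for_sa(self, canonical_tac, canonical_input):
        img = _uniform_image(canonical_tac, shape=(2, 1, 1))
        img.data[1] = 0.0
        atlas = _one_region_atlas(shape=(2, 1, 1))
        logan_map = voxelwise_map(img, canonical_input, "logan", 30.0, atlas, vb=0.0)
        assert logan_map.valid[0, 0, 0] and not logan_map.valid[1, 0, 0]
        assert np.isnan(logan_map.values[1, 0, 0])
        sa_map = voxelwise_map(img, canonical_input, "sa_vt", 30.0, atlas, vb=0.0)
        assert sa_map.valid[1, 0, 0]
        assert sa_map.values[1, 0, 0] == 0.0

    def test_two_block_phantom_block_means(self, canonical_input, schedule120):
        """Noiseless two-block phantom: region means of voxelwise maps match
        the blocks' ground-truth V_T."""
        vts = (12.0, 16.0)
        data = np.zeros((4, 2, 2, 33))
        labels = np.zeros((4, 2, 2), dtype=np.int32)
        for i, vt in enumerate(vts):
            K1, k3, k4 = 0.5, 0.02, 0.1
            k2 = K1 * (1 + k3 / k4) / vt
            p = pq.KineticParameters(K1, k2, k3, k4, 0.05)
            tac = pq.simulate_2tcm(p, canonical_input, schedule120)
            data[2 * i: 2 * i + 2] = tac.values
            labels[2 * i: 2 * i + 2] = i + 1
        img = pq.DynamicImage(data, schedule120)
        atlas = pq.RegionAtlas(labels, {1: "low", 2: "high"}, 1)
        for method in ("logan", "ma1", "sa_vt"):
            pmap = voxelwise_map(img, canonical_input, method, 30.0, atlas)
            means = region_means(pmap, atlas).set_index("region")["mean"]
            assert means["low"] == pytest.approx(12.0, rel=0.01)
            assert means["high"] == pytest.approx(16.0, rel=0.01)
            assert region_means(pmap, atlas)["frac_masked"].max() == 0.0


class TestRegionMeans:
    def _map(self, values, valid):
        return pq.ParametricMap(values, valid, "logan", 30.0)

    def test_constant_map(self):
        atlas = _one_region_atlas((2, 2, 1))
        pmap = self._map(np.full((2, 2, 1), 7.0), np.ones((2, 2, 1), bool))
        assert region_means(pmap, atlas)["mean"].iloc[0] == pytest.approx(7.0)

    def test_mean_of_two_values(self):
        atlas = _one_region_atlas((2, 1, 1))
        vals = np.array([10.0, 14.0]).reshape(2, 1, 1)
        pmap = self._map(vals, np.ones((2, 1, 1), bool))
        assert region_means(pmap, atlas)["mean"].iloc[0] == pytest.approx(12.0)

    def test_matches_brute_force_reaggregation(self):
        rng = np.random.default_rng(8)
        shape = (5, 5, 5)
        labels = rng.integers(0, 4, shape).astype(np.int32)
        labels[0, 0, 0] = 1  # ensure every named region present
        labels[0, 0, 1] = 2
        labels[0, 0, 2] = 3
        atlas = pq.RegionAtlas(labels, {1: "a", 2: "b", 3: "c"}, 1)
        values = rng.normal(12, 2, shape)
        valid = rng.random(shape) > 0.2
        values[~valid] = np.nan
        df = region_means(self._map(values, valid), atlas).set_index("region")
        for lab, name in atlas.names.items():
            acc, n = 0.0, 0
            for idx in np.ndindex(shape):
                if labels[idx] == lab and valid[idx]:
                    acc += values[idx]
                    n += 1
            assert df.loc[name, "mean"] == pytest.approx(acc / n, rel=1e-12)

    def test_fully_masked_region_warns_with_nan(self):
        atlas = _one_region_atlas((2, 1, 1))
        pmap = self._map(np.full((2, 1, 1), np.nan), np.zeros((2, 1, 1), bool))
        with pytest.warns(UserWarning, match="fully masked"):
            df = region_means(pmap, atlas)
        assert np.isnan(df["mean"].iloc[0])


class TestSuv:
    def _image(self, value, schedule):
        return pq.DynamicImage(np.full((2, 2, 2, schedule.n_frames), value), schedule)

    def test_worked_example(self, schedule120):
        suv = suv_image(self._image(5.0, schedule120), (100.0, 120.0), 185.0, 74.0)
        np.testing.assert_allclose(suv, 2.0)

    def test_doubling_dose_halves_suv(self, schedule120):
        img = self._image(5.0, schedule120)
        s1 = suv_image(img, (100.0, 120.0), 185.0, 74.0)
        s2 = suv_image(img, (100.0, 120.0), 370.0, 74.0)
        np.testing.assert_allclose(s2, s1 / 2.0)

    def test_equal_frames_match_unweighted_mean(self, schedule120):
        img = self._image(3.0, schedule120)
        suv = suv_image(img, (60.0, 80.0), 100.0, 50.0)
        np.testing.assert_allclose(suv, 3.0 * 50.0 / 100.0)

    def test_uncovered_window_rejected(self, schedule120):
        with pytest.raises(ValueError, match="not fully covered"):
            suv_image(self._image(1.0, schedule120), (115.0, 135.0), 185.0, 74.0)

    def test_nonpositive_dose_rejected(self, schedule120):
        with pytest.raises(ValueError):
            suv_image(self._image(1.0, schedule120), (100.0, 120.0), 0.0, 74.0)


class TestSuvr:
    def _atlas(self):
        labels = np.array([[[1, 1], [2, 2]]], dtype=np.int32)
        return pq.RegionAtlas(labels, {1: "target", 2: "corpus_callosum"}, 2)

    def test_reference_region_suvr_is_one(self):
        suv = np.array([[[3.0, 3.0], [1.5, 1.5]]])
        table = suvr_regions(suv, self._atlas())
        df = table.table.set_index("region")
        assert df.loc["corpus_callosum", "suvr"] == pytest.approx(1.0)
        assert df.loc["target", "suvr"] == pytest.approx(2.0)

    def test_global_rescaling_leaves_suvr_unchanged(self):
        suv = np.array([[[3.0, 2.0], [1.5, 1.0]]])
        t1 = suvr_regions(suv, self._atlas()).table.set_index("region")["suvr"]
        t2 = suvr_regions(5.0 * suv, self._atlas()).table.set_index("region")["suvr"]
        np.testing.assert_allclose(t1.to_numpy(), t2.to_numpy())

    def test_nonpositive_reference_rejected(self):
        suv = np.array([[[3.0, 3.0], [0.0, 0.0]]])
        with pytest.raises(ValueError, match="reference"):
            suvr_regions(suv, self._atlas())
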