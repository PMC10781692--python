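"""Seed FC, signed maps, target selection and ROI extraction oracles."""

import numpy as np
import pytest

from tmsdcm import connectivity as conn
from tmsdcm.synthetic import NCECM_REGIONS, embed_volume


@pytest.fixture
def embedded(block_atlas, rng):
    labels, affine, label_map = block_atlas
    series = rng.normal(size=(350, 5))
    img, limg = embed_volume(series, labels, affine, label_map, NCECM_REGIONS, 0.0, 0)
    data = np.asanyarray(img.dataobj)
    return data, affine, labels, label_map, series


class TestSeedAndExtraction:
    def test_tiny_sphere_returns_single_voxel_series(self, embedded):
        data, affine, *_ = embedded
        center = affine @ np.array([3, 3, 3, 1.0])
        seed = conn.SeedSpec(tuple(center[:3]), radius=1.0)
        ts = conn.seed_timecourse((data, affine), seed)
        assert np.allclose(ts, data[3, 3, 3])

    def test_homogeneous_region_mean_equals_region_series(self, embedded):
        data, affine, labels, label_map, series = embedded
        m = np.isin(labels, label_map["INS"])
        ts = conn.extract_roi_series((data, affine), m)
        assert np.allclose(ts, series[:, NCECM_REGIONS.index("INS")])

    def test_sphere_spanning_two_labels_is_count_weighted_mean(self, embedded):
        # brute-force voxel enumeration is the oracle
        data, affine, *_ = embedded
        center = affine @ np.array([4.5, 4, 4, 1.0])
        seed = conn.SeedSpec(tuple(center[:3]), radius=7.0)
        mask = conn.sphere_mask(data.shape[:3], affine, seed)
        expected = data[mask].mean(axis=0)
        assert np.allclose(conn.seed_timecourse((data, affine), seed), expected)

    def test_missing_sphere_rejected(self, embedded):
        data, affine, *_ = embedded
        with pytest.raises(ValueError, match="misses"):
            conn.seed_timecourse((data, affine), conn.SeedSpec((500.0, 0.0, 0.0), 2.0))

    def test_opposite_series_cancel(self, embedded, rng):
        data, affine, *_ = embedded
        s = rng.normal(size=data.shape[-1])
        vol = np.zeros(data.shape[:3] + (s.size,))
        vol[0, 0, 0] = s
        vol[0, 0, 1] = -s
        mask = np.zeros(data.shape[:3], bool)
        mask[0, 0, :2] = True
        assert np.allclose(conn.extract_roi_series((vol, affine), mask), 0.0)

    def test_empty_mask_rejected(self, embedded):
        data, affine, *_ = embedded
        with pytest.raises(ValueError, match="empty"):
            conn.extract_roi_series((data, affine), np.zeros(data.shape[:3], bool))


class TestFCMap:
    def test_identical_and_negated_voxels(self, rng):
        s = rng.normal(size=100)
        vol = np.zeros((2, 1, 1, 100))
        vol[0, 0, 0] = s
        vol[1, 0, 0] = -s
        m = conn.fc_map(s, (vol, np.eye(4)))
        assert m.data[0, 0, 0] == pytest.approx(1.0)
        assert m.data[1, 0, 0] == pytest.approx(-1.0)

    def test_planted_anticorrelation_recovered(self, rng):
        s = rng.normal(size=350)
        target_r = -0.9
        noise = rng.normal(size=350)
        v = target_r * s + np.sqrt(1 - target_r**2) * noise
        vol = np.zeros((1, 1, 1, 350))
        vol[0, 0, 0] = v
        m = conn.fc_map(s, (vol, np.eye(4)))
        assert m.data[0, 0, 0] == pytest.approx(-0.9, abs=0.05)

    def test_constant_voxel_flagged_as_zero(self, rng):
        s = rng.normal(size=50)
        vol = np.zeros((1, 1, 1, 50))
        m = conn.fc_map(s, (vol, np.eye(4)))
        assert m.data[0, 0, 0] == 0.0
        assert m.undefined[0, 0, 0]

    def test_constant_seed_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            conn.fc_map(np.ones(50), (np.zeros((1, 1, 1, 50)), np.eye(4)))

    def test_invariant_to_affine_rescaling_of_seed(self, rng):
        s = rng.normal(size=80)
        vol = rng.normal(size=(3, 2, 2, 80))
        m1 = conn.fc_map(s, (vol, np.eye(4)))
        m2 = conn.fc_map(5.0 * s - 2.0, (vol, np.eye(4)))
        assert np.allclose(m1.data, m2.data, atol=1e-12)


class TestFisherZ:
    def test_closed_form_values(self):
        r = np.array([[[0.0, 0.5, -0.5]]])
        m = conn.FCMap(r, "r", np.eye(4))
        z = conn.fisher_z(m)
        assert z.data[0, 0, 0] == 0.0
        assert z.data[0, 0, 1] == pytest.approx(np.arctanh(0.5))
        assert z.data[0, 0, 2] == pytest.approx(-np.arctanh(0.5))  # antisymmetry

    def test_exact_unity_clipped_with_warning(self):
        m = conn.FCMap(np.array([[[1.0]]]), "r", np.eye(4))
        with pytest.warns(UserWarning, match="clipped"):
            z = conn.fisher_z(m)
        assert np.isfinite(z.data).all()


class TestSignedMaps:
    def test_all_zero_maps_give_empty_masks(self):
        maps = [conn.FCMap(np.zeros((4, 4, 2)), "z", np.eye(4)) for _ in range(5)]
        _, pos, neg = conn.group_signed_maps(maps)
        assert not pos.any() and not neg.any()

    def test_constant_positive_effect_detected(self):
        rng = np.random.default_rng(0)
        maps = [conn.FCMap(np.full((2, 2, 2), 0.3) + rng.normal(0, 1e-6, (2, 2, 2)), "z", np.eye(4))
                for _ in range(26)]
        _, pos, neg = conn.group_signed_maps(maps)
        assert pos.all() and not neg.any()

    def test_masks_are_disjoint(self, rng):
        maps = [conn.FCMap(rng.normal(size=(10, 10, 5)), "z", np.eye(4)) for _ in range(8)]
        _, pos, neg = conn.group_signed_maps(maps)
        assert not (pos & neg).any()

    def test_needs_three_subjects(self):
        maps = [conn.FCMap(np.zeros((2, 2, 2)), "z", np.eye(4))] * 2
        with pytest.raises(ValueError):
            conn.group_signed_maps(maps)


class TestPairedDifference:
    def test_null_sessions_survive_fdr_rarely(self, rng):
        pre = [conn.FCMap(rng.normal(size=(10, 10, 5)), "z", np.eye(4)) for _ in range(20)]
        post = [conn.FCMap(rng.normal(size=(10, 10, 5)), "z", np.eye(4)) for _ in range(20)]
        _, sig = conn.paired_difference_map(pre, post, alpha=0.05)
        assert sig.mean() < 0.01  # FDR on a global null rejects almost nothing

    def test_planted_shift_detected(self, rng):
        pre = [conn.FCMap(rng.normal(size=(4, 4, 2)), "z", np.eye(4)) for _ in range(20)]
        post = [conn.FCMap(m.data + 2.0 + rng.normal(0, 0.1, (4, 4, 2)), "z", np.eye(4))
                for m in pre]
        tmap, sig = conn.paired_difference_map(pre, post)
        assert sig.all()
        assert tmap.data.min() > 0


class TestTargetSelection:
    def test_planted_anticorrelated_voxel_selected(self, block_atlas, rng):
        labels, affine, label_map = block_atlas
        series = rng.normal(size=(350, 5))
        img, limg = embed_volume(series, labels, affine, label_map, NCECM_REGIONS, 0.0, 1)
        data = np.asanyarray(img.dataobj).copy()
        sg = np.isin(labels, label_map["sgACC"])
        ref = data[sg].mean(axis=0)
        dlpfc = np.isin(labels, label_map["DLPFC"])
        # plant a strongly anticorrelated voxel inside the DLPFC mask
        ijk = tuple(np.argwhere(dlpfc)[0])
        noise = rng.normal(size=350)
        data[ijk] = -0.9 * (ref - ref.mean()) / ref.std() + np.sqrt(1 - 0.81) * noise
        coord, r = conn.select_target((data, affine), dlpfc, (labels, affine),
                                      tuple(label_map["sgACC"]))
        expected_mm = (affine @ np.array([*ijk, 1.0]))[:3]
        assert np.allclose(coord, expected_mm)
        assert r < -0.7

    def test_single_voxel_mask_returned_regardless(self, block_atlas, rng):
        labels, affine, label_map = block_atlas
        series = rng.normal(size=(100, 5))
        img, _ = embed_volume(series, labels, affine, label_map, NCECM_REGIONS, 0.5, 2)
        data = np.asanyarray(img.dataobj)
        mask = np.zeros(labels.shape, bool)
        mask[2, 2, 2] = True
        coord, _ = conn.select_target((data, affine), mask, (labels, affine),
                                      tuple(label_map["sgACC"]))
        assert np.allclose(coord, (affine @ np.array([2, 2, 2, 1.0]))[:3])

    def test_coordinates_are_mni_mm_integers_for_integer_affine(self, block_atlas):
        # output formatted like published per-patient rows (e.g. -26, 45, 28)
        labels, affine, _ = block_atlas
        mm = (affine @ np.array([1, 12, 10, 1.0]))[:3]
        assert mm.shape == (3,) and float(mm[0]) < 0


class TestROIMasks:
    def test_polarity_membership_and_left_restriction(self, block_atlas, rng):
        labels, affine, label_map = block_atlas
        pos = np.ones(labels.shape, bool)
        neg = np.ones(labels.shape, bool)
        masks = conn.build_roi_masks(pos, neg, (labels, affine), label_map)
        x_mm = conn.voxel_centers_mm(labels.shape, affine)[..., 0]
        for name in ("PCUN", "HIP", "INS"):
            assert masks.polarity[name] == "negative"
            assert not (masks.masks[name] & (x_mm > 0)).any()
        assert masks.polarity["sgACC"] == "negative"
        assert masks.laterality["sgACC"] == "bilateral"

    def test_full_overlap_returns_label(self, block_atlas):
        labels, affine, label_map = block_atlas
        masks = conn.build_roi_masks(np.ones(labels.shape, bool), np.ones(labels.shape, bool),
                                     (labels, affine), label_map)
        sg = np.isin(labels, label_map["sgACC"])
        assert np.array_equal(masks.masks["sgACC"], sg)

    def test_empty_intersection_names_roi(self, block_atlas):
        labels, affine, label_map = block_atlas
        empty = np.zeros(labels.shape, bool)
        with pytest.raises(ValueError, match="PCUN"):
            conn.build_roi_masks(empty, empty, (labels, affine),
                                 {"PCUN": label_map["PCUN"]})

    def test_atlas_fallback_uses_label(self, block_atlas):
        labels, affine, label_map = block_atlas
        empty = np.zeros(labels.shape, bool)
        with pytest.warns(UserWarning, match="atlas label"):
            masks = conn.build_roi_masks(empty, empty, (labels, affine),
                                         {"sgACC": label_map["sgACC"]},
                                         fallback_to_atlas=True)
        assert np.array_equal(masks.masks["sgACC"], np.isin(labels, label_map["sgACC"]))
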