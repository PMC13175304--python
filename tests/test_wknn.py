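"""Weighted-vote reclassification, cluster-size threshold, weight optimizer."""

import numpy as np
import pytest

from ntpet.phantom import build_phantom_geometry
from ntpet.wknn import (ClusterSizeThreshold, NeighborhoodWeights,
                        WkNNReclassifier, cluster_size_threshold,
                        ds_transfer_curve, optimize_weights, wknn_reclassify)

W = NeighborhoodWeights()          # [1.00, 1.60, 1.14, 0.68]
FULL_TIER_VOTE = 6 * 1.60 + 12 * 1.14 + 8 * 0.68     # = 28.72


def _cube(center=0, faces=0, edges=0, vertices=0):
    """3x3x3 label volume with one value per neighbor tier."""
    lab = np.zeros((3, 3, 3), dtype=int)
    for idx in np.ndindex(3, 3, 3):
        tier = sum(i != 1 for i in idx)
        lab[idx] = [center, faces, edges, vertices][tier]
    return lab


class TestWeights:
    def test_defaults_are_published_optimum(self):
        assert tuple(W.as_array) == (1.00, 1.60, 1.14, 0.68)

    def test_validation(self):
        with pytest.raises(ValueError):
            NeighborhoodWeights(0, 0, 0, 0)
        with pytest.raises(ValueError):
            NeighborhoodWeights(-1, 1, 1, 1)

    def test_normalization(self):
        w = NeighborhoodWeights(2.0, 3.2, 2.28, 1.36).normalized()
        assert tuple(np.round(w.as_array, 10)) == (1.00, 1.60, 1.14, 0.68)


class TestVote:
    def test_isolated_positive_removed(self):
        lab = _cube(center=1)
        new, cert = wknn_reclassify(lab, W)
        assert new[1, 1, 1] == 0
        assert cert[1, 1, 1] == pytest.approx(
            FULL_TIER_VOTE / (FULL_TIER_VOTE + 1.0))      # 28.72 / 29.72

    def test_unanimous_neighborhood_is_fixed_point(self):
        lab = np.ones((3, 3, 3), dtype=int)
        new, cert = wknn_reclassify(lab, W)
        assert np.all(new == 1)
        assert cert[1, 1, 1] == pytest.approx(1.0)

    def test_six_faces_do_not_flip_center(self):
        lab = _cube(center=0, faces=1)
        new, cert = wknn_reclassify(lab, W)
        null_vote = 1.0 + 12 * 1.14 + 8 * 0.68            # 20.12
        assert new[1, 1, 1] == 0
        assert cert[1, 1, 1] == pytest.approx(null_vote / (null_vote + 9.60))

    def test_out_of_bounds_neighbors_do_not_vote(self):
        # a lone voxel in a 1x1x1 domain votes only for itself
        lab = np.ones((1, 1, 1), dtype=int)
        new, cert = wknn_reclassify(lab, W)
        assert new[0, 0, 0] == 1 and cert[0, 0, 0] == 1.0

    def test_tie_keeps_original_label(self):
        w = NeighborhoodWeights(1.0, 1.0, 1.0, 1.0)
        lab = np.zeros((3, 3, 3), dtype=int)
        # 13 positives + 13 nulls + center: choose 13 non-center positives
        flat = [i for i in np.ndindex(3, 3, 3) if i != (1, 1, 1)]
        for i in flat[:13]:
            lab[i] = 1
        lab[1, 1, 1] = 1          # center positive: vote 14 vs 13 -> stays
        new, _ = wknn_reclassify(lab, w)
        assert new[1, 1, 1] == 1
        lab[1, 1, 1] = 0          # center null: vote 14 vs 13 -> stays null
        new, _ = wknn_reclassify(lab, w)
        assert new[1, 1, 1] == 0

    def test_permutation_invariance_within_tiers(self):
        rng = np.random.default_rng(0)
        lab = rng.integers(0, 2, size=(7, 7, 7))
        base, _ = wknn_reclassify(lab, W)
        # permute the face-neighbor labels of the center voxel
        for _ in range(5):
            lab2 = lab.copy()
            faces = [(4, 3, 3), (2, 3, 3), (3, 4, 3), (3, 2, 3), (3, 3, 4),
                     (3, 3, 2)]
            vals = [lab2[f] for f in faces]
            rng.shuffle(vals)
            for f, v in zip(faces, vals):
                lab2[f] = v
            new, _ = wknn_reclassify(lab2, W)
            assert new[3, 3, 3] == base[3, 3, 3]

    def test_single_simultaneous_pass(self):
        # a 2-voxel chain: each uses the other's ORIGINAL label
        lab = np.zeros((5, 1, 1), dtype=int)
        lab[1, 0, 0] = lab[2, 0, 0] = 1
        new, _ = wknn_reclassify(lab, W)
        # both computed from the pre-pass map; a cascading update would
        # let an early flip change its neighbor's vote
        votes_for_1_at_2 = 1.0 + 1.6     # itself + neighbor 1
        votes_for_0_at_2 = 1.6           # voxel 3
        assert new[2, 0, 0] == (0 if votes_for_0_at_2 > votes_for_1_at_2 else 1)

    def test_characterization_mode_ignores_unlabeled(self):
        lab = _cube(center=1, faces=0, edges=2)
        new, cert = wknn_reclassify(lab, W, mode="characterization")
        # nulls do not vote: 12 edge voxels of class 2 vs center class 1
        assert new[1, 1, 1] == 2
        assert cert[1, 1, 1] == pytest.approx(12 * 1.14 / (12 * 1.14 + 1.0))
        assert np.all(new[lab == 0] == 0)          # unlabeled untouched

    def test_isolated_labeled_voxel_keeps_label(self):
        lab = _cube(center=2)
        new, cert = wknn_reclassify(lab, W, mode="characterization")
        assert new[1, 1, 1] == 2 and cert[1, 1, 1] == 1.0

    def test_certainty_in_unit_interval(self):
        rng = np.random.default_rng(1)
        lab = rng.integers(0, 3, size=(8, 8, 8))
        _, cert = wknn_reclassify(lab, W)
        vals = cert[np.isfinite(cert)]
        assert np.all((vals > 0) & (vals <= 1))

    def test_empty_domain_rejected(self):
        with pytest.raises(ValueError):
            wknn_reclassify(np.zeros((3, 3, 3), int), W,
                            domain_mask=np.zeros((3, 3, 3), bool))


class TestClusterSizeThreshold:
    def test_small_cluster_removed_large_retained(self):
        mask = np.zeros((10, 10, 10), bool)
        mask[0, 0, :9] = True              # size 9 -> removed
        mask[5, 5:7, 0:5] = True           # size 10 -> retained
        out = cluster_size_threshold(mask, min_size=10)
        assert not out[0, 0, :9].any()
        assert out[5, 5:7, 0:5].all()

    def test_output_subset_of_input(self):
        rng = np.random.default_rng(2)
        mask = rng.random((12, 12, 12)) < 0.2
        out = cluster_size_threshold(mask, 10)
        assert not np.any(out & ~mask)

    def test_surviving_components_meet_minimum(self):
        from scipy import ndimage
        rng = np.random.default_rng(3)
        mask = rng.random((15, 15, 15)) < 0.15
        out = cluster_size_threshold(mask, 10)
        lab, n = ndimage.label(out, structure=np.ones((3, 3, 3)))
        sizes = np.bincount(lab.ravel())[1:]
        assert np.all(sizes >= 10)

    def test_connectivity_changes_components(self):
        mask = np.zeros((4, 4, 4), bool)
        mask[0, 0, 0] = mask[1, 1, 1] = True   # touch only diagonally
        assert not cluster_size_threshold(mask, 2, connectivity=6).any()
        assert cluster_size_threshold(mask, 2, connectivity=26).all() \
            == mask.all()

    def test_empty_mask_passthrough(self):
        mask = np.zeros((3, 3, 3), bool)
        assert not cluster_size_threshold(mask, 10).any()

    def test_transformer_wrapper(self):
        mask = np.zeros((6, 6, 6), bool)
        mask[0, 0, 0] = True
        out = ClusterSizeThreshold(min_size=2).fit(None).transform(mask)
        assert not out.any()


class TestWeightOptimization:
    def test_perfect_masks_stay_perfect(self):
        labels = build_phantom_geometry()
        truth = (labels > 0) & (labels != 1)
        w = optimize_weights([truth], [truth], domain_masks=[labels > 0])
        assert w.w_center == pytest.approx(1.0)
        new, _ = wknn_reclassify(truth.astype(int), w, labels > 0)
        assert np.array_equal(new == 1, truth)

    def test_degenerate_all_null_masks_rejected(self):
        z = np.zeros((5, 5, 5), bool)
        with pytest.raises(ValueError):
            optimize_weights([z], [z])

    def test_optimized_weights_do_not_hurt_recovery(self):
        labels = build_phantom_geometry()
        region = labels > 0
        truth = region & (labels != 1)
        rng = np.random.default_rng(4)
        idx = np.flatnonzero(truth.ravel())
        masks = []
        for _ in range(3):
            det = np.zeros(labels.shape, bool)
            det.ravel()[rng.choice(idx, int(0.72 * idx.size),
                                   replace=False)] = True
            masks.append(det)
        w = optimize_weights([truth] * 3, masks, domain_masks=[region] * 3)
        ds_default, ds_opt = [], []
        for det in masks:
            pre = det.astype(int)
            post_d, _ = wknn_reclassify(pre, NeighborhoodWeights(), region)
            post_o, _ = wknn_reclassify(pre, w, region)
            ds_default.append(np.mean(post_d[truth] == 1))
            ds_opt.append(np.mean(post_o[truth] == 1))
        assert np.mean(ds_opt) >= np.mean(ds_default) - 0.02


class TestTransferCurve:
    def test_fixed_points_and_identity_crossing(self):
        labels = build_phantom_geometry()
        truth = labels > 0
        rng = np.random.default_rng(5)
        curve = ds_transfer_curve(truth, [0.0, 0.35, 0.45, 0.55, 0.7, 1.0],
                                  reps=3, rng=rng)
        assert curve.ds_post.iloc[0] == 0.0
        assert curve.ds_post.iloc[-1] == 100.0
        assert (curve.ds_post.diff().dropna() >= -1e-9).all()
        below = curve[curve.fraction <= 0.45]
        above = curve[(curve.fraction >= 0.55) & (curve.fraction < 1.0)]
        assert (below.ds_post <= below.ds_pre + 1e-9).all()
        assert (above.ds_post >= above.ds_pre - 1e-9).all()

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            ds_transfer_curve(np.ones((3, 3, 3), bool), [1.5], reps=1,
                              rng=np.random.default_rng(0))


class TestDetectionModeSpecificity:
    @staticmethod
    def _isolated_subset(mask, max_count, rng):
        """Greedily pick up to max_count voxels of mask, none adjacent."""
        chosen = np.zeros(mask.shape, dtype=bool)
        blocked = np.zeros(mask.shape, dtype=bool)
        coords = np.argwhere(mask)
        rng.shuffle(coords)
        n = 0
        for x, y, z in coords:
            if n >= max_count or blocked[x, y, z]:
                continue
            chosen[x, y, z] = True
            blocked[max(x - 1, 0):x + 2, max(y - 1, 0):y + 2,
                    max(z - 1, 0):z + 2] = True
            n += 1
        return chosen

    def test_isolated_false_positives_fully_removed(self):
        labels = build_phantom_geometry()
        region = labels > 0
        signal = region & (labels != 1)
        null = region & (labels == 1)
        sig_idx = np.flatnonzero(signal.ravel())
        for seed in range(50):
            rng = np.random.default_rng(seed)
            det = np.zeros(labels.shape, bool)
            det.ravel()[rng.choice(sig_idx, int(0.9 * sig_idx.size),
                                   replace=False)] = True
            fps = self._isolated_subset(null, int(0.10 * null.sum()), rng)
            assert 0 < fps.sum() <= 0.10 * null.sum()
            det |= fps
            new, _ = wknn_reclassify(det.astype(int), W, region)
            assert not (new == 1)[null].any()

    def test_transformer_stores_certainty(self):
        labels = build_phantom_geometry()
        t = WkNNReclassifier(mode="detection")
        out = t.fit(None).transform((labels > 0).astype(int),
                                    domain_mask=labels > 0)
        assert out.shape == labels.shape
        assert np.isfinite(t.certainty_[labels > 0]).all()
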