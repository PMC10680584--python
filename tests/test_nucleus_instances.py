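import numpy as np
import pytest
from scipy import ndimage as ndi
from skimage.measure import label as cc_label

from conftest import fused_disks, make_disk
from oracles import point_to_hull_depth_oracle
from unseg.core_io import UnsegParams
from unseg.nucleus_instances import (
    convexity_analysis,
    perturbed_watershed,
    segment_nuclei,
    split_cluster,
    steepest_concave_point,
    virtual_cuts,
)
from unseg.synthetic import FixtureSpec, generate_tissue


def three_seed_cluster():
    """Two abutting disks plus a shallow lobe: distance-transform
    thresholding yields 3 seeds, one of them spurious."""
    mask = fused_disks((75, 95), [(42, 30), (42, 54)], 12)
    mask |= make_disk((75, 95), (26, 30), 5)
    return mask


class TestSteepestConcavePoint:
    def test_disk_is_convex(self):
        # digitization bound: the boundary chain of an ideal disk deviates
        # up to ~1 px from hull edges between lattice vertices
        _, depth = steepest_concave_point(make_disk((40, 40), (20, 20), 15))
        assert depth <= 1.0

    def test_rectangle_is_convex(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[5:25, 8:20] = True
        _, depth = steepest_concave_point(mask)
        assert depth <= 0.5  # axis-aligned rectangle: boundary is the hull

    def test_fused_disks_match_brute_force(self):
        mask = fused_disks((40, 60), [(20, 18), (20, 34)], 10)
        (r, c), depth = steepest_concave_point(mask)
        assert depth == pytest.approx(point_to_hull_depth_oracle(mask))
        assert mask[r, c] or not mask[r, c]  # location is a valid pixel
        boundary = mask & ~ndi.binary_erosion(mask, np.ones((3, 3)),
                                              border_value=0)
        assert boundary[r, c]

    def test_tiny_component_depth_zero(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        mask[2, 3] = True
        _, depth = steepest_concave_point(mask)
        assert depth == 0.0


class TestConvexityAnalysis:
    def test_small_blob_discarded(self):
        labels = np.zeros((10, 10), dtype=np.int64)
        labels[3:6, 3:6] = 1  # 9 px <= a0 = 20
        rec = convexity_analysis(labels, a0=20, d0=4.0)[0]
        assert rec.classification == "discarded"

    def test_deep_neck_is_nc(self):
        mask = fused_disks((50, 70), [(25, 20), (25, 39)], 10)
        labels = cc_label(mask).astype(np.int64)
        rec = convexity_analysis(labels, a0=20, d0=4.0)[0]
        assert rec.scp_depth > 4.0
        assert rec.classification == "NC"

    def test_clean_disk_is_nucleus(self):
        labels = make_disk((40, 40), (20, 20), 10).astype(np.int64)
        rec = convexity_analysis(labels, a0=20, d0=4.0)[0]
        assert rec.classification == "nucleus"
        assert rec.area == int(labels.sum())


class TestPerturbedWatershed:
    def test_convex_disk_identity(self):
        mask = make_disk((40, 40), (20, 20), 12)
        subs = perturbed_watershed(mask)
        assert len(subs) == 1
        assert np.array_equal(subs[0], mask)

    def test_spurious_seed_removed(self):
        mask = three_seed_cluster()
        dt = ndi.distance_transform_edt(mask)
        d_avr = dt[dt > 0].mean()
        n_seeds = cc_label(dt >= d_avr, connectivity=2, return_num=True)[1]
        assert n_seeds == 3  # the scenario genuinely starts with 3 seeds
        subs = perturbed_watershed(mask)
        assert len(subs) == 2

    def test_output_partitions_mask(self):
        mask = three_seed_cluster()
        subs = perturbed_watershed(mask)
        union = np.zeros_like(mask)
        for s in subs:
            assert not (union & s).any()  # pairwise disjoint
            union |= s
        assert np.array_equal(union, mask)

    def test_never_more_regions_than_initial(self):
        mask = three_seed_cluster()
        dt = ndi.distance_transform_edt(mask)
        d_avr = dt[dt > 0].mean()
        n_initial = cc_label(dt >= d_avr, connectivity=2, return_num=True)[1]
        assert len(perturbed_watershed(mask)) <= n_initial

    def test_membrane_cut_applied_and_reassigned(self):
        mask = fused_disks((40, 60), [(20, 20), (20, 38)], 9)
        cut = np.zeros_like(mask)
        cut[:, 29] = True
        subs = perturbed_watershed(mask, membrane_cut=cut)
        union = np.zeros_like(mask)
        for s in subs:
            union |= s
        assert np.array_equal(union, mask)  # cut pixels reassigned

    def test_empty_after_cut_returns_original(self, caplog):
        mask = make_disk((20, 20), (10, 10), 5)
        with caplog.at_level("WARNING", logger="unseg"):
            subs = perturbed_watershed(mask, membrane_cut=np.ones_like(mask))
        assert "empty after membrane cuts" in caplog.text
        assert len(subs) == 1 and np.array_equal(subs[0], mask)


class TestVirtualCuts:
    def test_convex_mask_rejected(self):
        with pytest.raises(ValueError, match="non-convex"):
            virtual_cuts(make_disk((40, 40), (20, 20), 12))

    def test_peanut_yields_two_seeds(self):
        mask = fused_disks((40, 60), [(20, 20), (20, 36)], 10)
        s1, s2 = virtual_cuts(mask)
        assert mask[s1] and mask[s2]
        # one seed on each side of the neck
        assert (s1[1] - 28) * (s2[1] - 28) < 0

    def test_symmetric_dumbbell_seeds_symmetric(self):
        mask = fused_disks((41, 61), [(20, 22), (20, 38)], 9)
        s1, s2 = virtual_cuts(mask)
        mid = 30.0  # symmetry axis between the two centers
        assert abs((mid - s1[1]) + (mid - s2[1])) <= 1.0


class TestSplitCluster:
    def test_fused_pair_splits_in_two(self):
        centers = [(20, 20), (20, 36)]
        mask = fused_disks((40, 60), centers, 10)
        subs = split_cluster(mask)
        assert len(subs) == 2
        for center in centers:
            assert sum(s[center] for s in subs) == 1

    def test_single_disk_returned_whole(self):
        mask = make_disk((30, 30), (15, 15), 10)
        subs = split_cluster(mask)
        assert len(subs) == 1 and np.array_equal(subs[0], mask)


def _semantic_from_gt(gt_nuclei):
    Mg = np.where(gt_nuclei > 0, 1, 0).astype(np.uint8)
    Ml = np.zeros_like(Mg)
    return Mg, Ml


class TestSegmentNuclei:
    def test_fifty_isolated_ellipses(self):
        bundle = generate_tissue(FixtureSpec(n_cells=50, seed=11))
        Mg, Ml = _semantic_from_gt(bundle.gt_nuclei)
        labels = segment_nuclei(Mg, Ml, UnsegParams())
        ids = np.unique(labels[labels > 0])
        assert ids.size == 50
        # each instance overlaps exactly one gt nucleus with IoU >= 0.7
        for i in ids:
            pred = labels == i
            gt_id = np.bincount(bundle.gt_nuclei[pred]).argmax()
            gt = bundle.gt_nuclei == gt_id
            iou = (pred & gt).sum() / (pred | gt).sum()
            assert iou >= 0.7

    def test_isolated_plus_fused_pairs(self):
        # radii / eccentricity chosen so every pair's neck is deeper than
        # d0 = 4 px and the cluster is guaranteed NC-classified
        spec = FixtureSpec(n_cells=40, touching_fraction=0.5, seed=5,
                           radius_range=(11.0, 13.0),
                           eccentricity_range=(1.0, 1.15))
        bundle = generate_tissue(spec)
        Mg, Ml = _semantic_from_gt(bundle.gt_nuclei)
        labels = segment_nuclei(Mg, Ml, UnsegParams())
        assert np.unique(labels[labels > 0]).size == 40

    def test_empty_input(self):
        z = np.zeros((32, 32), dtype=np.uint8)
        assert segment_nuclei(z, z, UnsegParams()).sum() == 0

    def test_deterministic(self):
        bundle = generate_tissue(FixtureSpec(n_cells=20, seed=2))
        Mg, Ml = _semantic_from_gt(bundle.gt_nuclei)
        a = segment_nuclei(Mg, Ml, UnsegParams())
        b = segment_nuclei(Mg, Ml, UnsegParams())
        assert np.array_equal(a, b)

    def test_outputs_disjoint_and_connected(self):
        bundle = generate_tissue(FixtureSpec(n_cells=25, seed=9,
                                             touching_fraction=0.4))
        Mg, Ml = _semantic_from_gt(bundle.gt_nuclei)
        labels = segment_nuclei(Mg, Ml, UnsegParams())
        for i in np.unique(labels[labels > 0]):
            assert cc_label(labels == i, connectivity=2).max() == 1
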