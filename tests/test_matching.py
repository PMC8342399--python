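"""Block matching and one-to-one sphere pairing."""

import numpy as np
import pandas as pd
import pytest

import shrinkvec as sv
from shrinkvec.matching import (BlockMatchResult, MatchParams, MatchSet,
                                block_match, match_scan_pair, pair_spheres)
from shrinkvec.segmentation import SegmentationParams, SphereSet
from shrinkvec.transforms import RigidTransform
from shrinkvec.volume import Volume


def _sphere_set(centroids):
    df = pd.DataFrame(centroids, columns=["x", "y", "z"])
    df.insert(0, "id", np.arange(len(df)))
    for col in ("radius_um", "voxels", "compactness", "contrast"):
        df[col] = 1.0
    return SphereSet(df, SegmentationParams())


def test_identical_scans_give_zero_coarse_and_unit_ncc(small_static_pair,
                                                       cavity_mask_for):
    _, pre, post, _ = small_static_pair
    spheres = sv.segment_spheres(pre, cavity_mask_for(pre))
    params = MatchParams(smooth_sigma=0.0)
    for c in spheres.centroids[:20]:
        bm = block_match(pre, post, RigidTransform(), c, params)
        assert bm.coarse_displacement == (0, 0, 0)
        assert bm.ncc_score == pytest.approx(1.0, abs=5e-6)


def test_integer_voxel_shift_recovered_exactly(small_static_pair,
                                               cavity_mask_for):
    """A rolled post scan yields coarse displacement (2, 0, -1) everywhere."""
    _, pre, _, _ = small_static_pair
    shift = (2, 0, -1)
    post = Volume(np.roll(pre.data, shift, axis=(0, 1, 2)),
                  pre.voxel_size, pre.origin)
    spheres = sv.segment_spheres(pre, cavity_mask_for(pre))
    params = MatchParams(smooth_sigma=0.0)
    interior = spheres.centroids[
        np.all(np.abs(spheres.centroids - 576.0) < 400.0, axis=1)]
    for c in interior[:20]:
        bm = block_match(pre, post, RigidTransform(), c, params)
        assert bm.coarse_displacement == shift


def test_zero_variance_block_routes_to_unmatched():
    flat = Volume(np.full((48, 48, 48), 777.0, dtype=np.float32),
                  np.full(3, 16.0))
    bm = block_match(flat, flat, RigidTransform(), (384.0, 384.0, 384.0),
                     MatchParams())
    assert bm.coarse_displacement is None and bm.ncc_score is None


def test_displacement_beyond_search_radius_lands_unmatched():
    """The true partner sits 20 voxels away; search radius is 10."""
    pre_set = _sphere_set([[400.0, 400.0, 400.0]])
    post_set = _sphere_set([[400.0 + 20 * 16.0, 400.0, 400.0]])
    coarse = {0: BlockMatchResult(None, None)}  # no peak within radius
    ms = pair_spheres(pre_set, post_set, coarse, RigidTransform(), 16.0,
                      MatchParams())
    assert len(ms) == 0
    assert ms.unmatched_pre == [0] and ms.unmatched_post == [0]


def test_identity_sets_pair_perfectly():
    pts = [[100.0, 100.0, 100.0], [200.0, 150.0, 120.0],
           [90.0, 260.0, 300.0]]
    coarse = {i: BlockMatchResult((0, 0, 0), 1.0) for i in range(3)}
    ms = pair_spheres(_sphere_set(pts), _sphere_set(pts), coarse,
                      RigidTransform(), 16.0,
                      MatchParams(outlier_threshold=0.0))
    assert len(ms) == 3
    assert (ms.matches["pre_id"] == ms.matches["post_id"]).all()
    np.testing.assert_allclose(
        ms.matches[["refined_dx", "refined_dy", "refined_dz"]], 0.0,
        atol=1e-9)


def test_conflict_resolved_by_smaller_residual():
    """Two pre spheres nearest one post sphere: closer pair wins."""
    pre_set = _sphere_set([[100.0, 100.0, 100.0], [110.0, 100.0, 100.0]])
    post_set = _sphere_set([[108.0, 100.0, 100.0]])
    coarse = {0: BlockMatchResult((0, 0, 0), 1.0),
              1: BlockMatchResult((0, 0, 0), 1.0)}
    ms = pair_spheres(pre_set, post_set, coarse, RigidTransform(), 16.0,
                      MatchParams(outlier_threshold=0.0))
    assert len(ms) == 1
    assert ms.matches["pre_id"].iloc[0] == 1  # residual 2 beats residual 8
    assert ms.unmatched_pre == [0]


def test_one_to_one_enforced_by_matchset():
    rows = pd.DataFrame([
        {"pre_id": 0, "post_id": 0, "du": 0, "dv": 0, "dw": 0,
         "refined_dx": 0.0, "refined_dy": 0.0, "refined_dz": 0.0,
         "residual_um": 0.0, "ncc_score": 1.0},
        {"pre_id": 0, "post_id": 1, "du": 0, "dv": 0, "dw": 0,
         "refined_dx": 0.0, "refined_dy": 0.0, "refined_dz": 0.0,
         "residual_um": 0.0, "ncc_score": 1.0},
    ])
    with pytest.raises(ValueError, match="one-to-one"):
        MatchSet(matches=rows, unmatched_pre=[], unmatched_post=[],
                 params=MatchParams())


def test_low_ncc_spheres_go_unmatched():
    pre_set = _sphere_set([[100.0, 100.0, 100.0]])
    post_set = _sphere_set([[100.0, 100.0, 100.0]])
    coarse = {0: BlockMatchResult((0, 0, 0), 0.1)}  # below min_ncc
    ms = pair_spheres(pre_set, post_set, coarse, RigidTransform(), 16.0,
                      MatchParams())
    assert len(ms) == 0 and ms.unmatched_pre == [0]


def test_contraction_phantom_pairs_true_partners(small_contraction_pair,
                                                 cavity_mask_for):
    """With spacing far above displacement, ≥99% of pairs are true partners."""
    from scipy.spatial import cKDTree

    spec, _, pre, post, truth = small_contraction_pair
    s_pre = sv.segment_spheres(pre, cavity_mask_for(pre))
    s_post = sv.segment_spheres(post, cavity_mask_for(post))
    ms = match_scan_pair(pre, post, s_pre, s_post, RigidTransform())
    assert len(ms) >= 0.99 * len(truth.table)
    lut_pre = s_pre.table.set_index("id")
    lut_post = s_post.table.set_index("id")
    tree_pre = cKDTree(truth.table[["x_pre", "y_pre", "z_pre"]].to_numpy())
    tree_post = cKDTree(truth.table[["x_post", "y_post", "z_post"]
                                    ].to_numpy())
    _, i_pre = tree_pre.query(
        lut_pre.loc[ms.matches["pre_id"], ["x", "y", "z"]].to_numpy())
    _, i_post = tree_post.query(
        lut_post.loc[ms.matches["post_id"], ["x", "y", "z"]].to_numpy())
    assert np.mean(i_pre == i_post) >= 0.99
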