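"""Pre/post sphere correspondence: block matching plus centroid gating.

For every sphere detected in the pre-cure scan, an intensity block centred
on its centroid is searched over the post-cure scan (at the rigidly posed
location) by exhaustive integer-displacement normalized cross-correlation.
The NCC peak gives a coarse displacement; the post-scan sphere centroid
nearest to the predicted location (within a gate) then refines the match to
sub-voxel precision, and conflicts are resolved globally by ascending
residual distance so each sphere appears in at most one pair.  Refined
displacements are expressed in the pre frame after mapping post centroids
through the inverse rigid transform.

The hybrid coarse/refined strategy avoids the integer-voxel quantization a
pure block match would impose on 2–4-voxel beads.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage.feature import match_template

from .segmentation import SphereSet
from .transforms import RigidTransform, invert
from .volume import Volume

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MatchParams:
    """Block-matching and gating configuration (voxel units unless noted).

    ``search_radius`` must exceed the largest expected displacement (the
    default 10 voxels = 160 μm is far above the tens-of-μm shrinkage this
    pipeline measures); ``gate_distance`` is in μm.
    """

    block_half_width: int = 7
    search_radius: int = 10
    gate_distance: float = 32.0
    min_ncc: float = 0.3
    smooth_sigma: float = 0.7
    outlier_neighbors: int = 8
    outlier_threshold: float = 2.0
    outlier_eps_um: float = 2.0
    rematch_passes: int = 2

    def __post_init__(self):
        if self.block_half_width < 1 or self.search_radius < 1:
            raise ValueError("block_half_width and search_radius must be >= 1")
        if self.gate_distance <= 0:
            raise ValueError("gate_distance must be > 0")


@dataclass(frozen=True)
class BlockMatchResult:
    coarse_displacement: tuple[int, int, int] | None  # voxels, post frame
    ncc_score: float | None


@dataclass
class MatchSet:
    """One-to-one pre/post correspondences.

    ``matches`` columns: pre_id, post_id, du, dv, dw (coarse, voxels),
    refined_dx/dy/dz (μm, pre frame), residual_um, ncc_score.
    """

    matches: pd.DataFrame
    unmatched_pre: list
    unmatched_post: list
    params: MatchParams

    def __post_init__(self):
        m = self.matches
        if len(m):
            if m["pre_id"].duplicated().any() or \
                    m["post_id"].duplicated().any():
                raise ValueError("MatchSet is not one-to-one")
            ncc = m["ncc_score"].to_numpy(dtype=float)
            if np.any((ncc < -1 - 1e-9) | (ncc > 1 + 1e-9)):
                raise ValueError("ncc_score outside [-1, 1]")
            for c in ("refined_dx", "refined_dy", "refined_dz"):
                if not np.all(np.isfinite(m[c])):
                    raise ValueError("refined displacement not finite")

    def __len__(self) -> int:
        return len(self.matches)


def _extract_block(data: np.ndarray, center_vox: np.ndarray, half: int):
    lo = center_vox - half
    hi = center_vox + half + 1
    lo_c = np.maximum(lo, 0)
    hi_c = np.minimum(hi, np.asarray(data.shape))
    if np.any(lo_c != lo) or np.any(hi_c != hi):
        warnings.warn("block near volume edge shrunk to fit", stacklevel=3)
    return data[lo_c[0]:hi_c[0], lo_c[1]:hi_c[1], lo_c[2]:hi_c[2]], lo_c


def block_match(pre: Volume, post: Volume, transform: RigidTransform,
                centroid_um, params: MatchParams) -> BlockMatchResult:
    """Coarse integer displacement of one sphere by exhaustive NCC search.

    Returns the displacement (post-frame voxels) of the pre-centred block
    relative to its rigidly posed position, and the NCC at the peak.  Ties
    are broken by smallest displacement magnitude, then lexicographically
    on (dx, dy, dz).  A zero-variance block yields a no-score sentinel.
    """
    c = np.asarray(centroid_um, dtype=float)
    half, R = params.block_half_width, params.search_radius
    pre_vox = np.rint(pre.world_to_voxel(c)).astype(int)
    template, _ = _extract_block(pre.data, pre_vox, half)
    if template.size == 0 or float(template.std()) < 1e-12:
        return BlockMatchResult(None, None)

    post_vox = np.rint(post.world_to_voxel(transform.apply(c))).astype(int)
    region, region_lo = _extract_block(post.data, post_vox, half + R)
    if any(rs < ts for rs, ts in zip(region.shape, template.shape)):
        return BlockMatchResult(None, None)

    scores = match_template(region.astype(np.float64),
                            template.astype(np.float64))
    scores = np.nan_to_num(scores, nan=-1.0, posinf=-1.0, neginf=-1.0)
    scores = np.clip(scores, -1.0, 1.0)  # float32 rounding in the NCC
    best = float(scores.max())
    cand = np.argwhere(scores >= best - 1e-10)
    # template centre voxel when placed at offset p: region_lo + p + half
    disp = cand + region_lo + half - post_vox
    order = np.lexsort((disp[:, 2], disp[:, 1], disp[:, 0],
                        np.sum(disp * disp, axis=1)))
    d = disp[order[0]]
    return BlockMatchResult(tuple(int(v) for v in d), best)


def pair_spheres(pre_set: SphereSet, post_set: SphereSet,
                 coarse: dict[int, BlockMatchResult],
                 transform: RigidTransform, voxel_size: float,
                 params: MatchParams) -> MatchSet:
    """Resolve sphere correspondences one-to-one from coarse displacements.

    For each pre sphere the predicted post-frame position is its posed
    centroid plus the coarse displacement; the nearest post centroid within
    ``gate_distance`` is a candidate, and candidates are accepted greedily
    in ascending residual order.
    """
    inv = invert(transform)
    pre_ids = pre_set.table["id"].to_numpy()
    post_ids = post_set.table["id"].to_numpy()
    post_xyz = post_set.centroids
    candidates = []
    no_score: list[int] = []
    if len(post_xyz):
        tree = cKDTree(post_xyz)
        for pid, c_pre in zip(pre_ids, pre_set.centroids):
            bm = coarse.get(int(pid))
            if bm is None or bm.coarse_displacement is None:
                no_score.append(int(pid))
                continue
            if bm.ncc_score is not None and bm.ncc_score < params.min_ncc:
                no_score.append(int(pid))
                continue
            predicted = transform.apply(c_pre) + \
                np.asarray(bm.coarse_displacement) * voxel_size
            hits = tree.query_ball_point(predicted, params.gate_distance)
            for j in hits:
                resid = float(np.linalg.norm(post_xyz[j] - predicted))
                candidates.append((resid, int(pid), int(post_ids[j]), bm))
    candidates.sort(key=lambda t: (t[0], t[1], t[2]))

    used_pre: set[int] = set()
    used_post: set[int] = set()
    rows = []
    pre_lookup = {int(i): c for i, c in zip(pre_ids, pre_set.centroids)}
    post_lookup = {int(i): c for i, c in zip(post_ids, post_xyz)}
    for resid, pid, qid, bm in candidates:
        if pid in used_pre or qid in used_post:
            continue
        used_pre.add(pid)
        used_post.add(qid)
        refined = inv.apply(post_lookup[qid]) - pre_lookup[pid]
        rows.append({
            "pre_id": pid, "post_id": qid,
            "du": bm.coarse_displacement[0], "dv": bm.coarse_displacement[1],
            "dw": bm.coarse_displacement[2],
            "refined_dx": refined[0], "refined_dy": refined[1],
            "refined_dz": refined[2],
            "residual_um": resid, "ncc_score": bm.ncc_score,
        })
    matches = pd.DataFrame(
        rows, columns=["pre_id", "post_id", "du", "dv", "dw", "refined_dx",
                       "refined_dy", "refined_dz", "residual_um", "ncc_score"])
    matches = _reject_field_outliers(matches, pre_lookup, params, used_pre,
                                     used_post)
    unmatched_pre = sorted(set(int(i) for i in pre_ids) - used_pre)
    unmatched_post = sorted(set(int(i) for i in post_ids) - used_post)
    if no_score:
        log.info("%d pre spheres had no usable block score", len(no_score))
    if unmatched_pre or unmatched_post:
        log.info("unmatched spheres: %d pre, %d post",
                 len(unmatched_pre), len(unmatched_post))
    return MatchSet(matches=matches, unmatched_pre=unmatched_pre,
                    unmatched_post=unmatched_post, params=params)


def _reject_field_outliers(matches: pd.DataFrame, pre_lookup: dict,
                           params: MatchParams, used_pre: set,
                           used_post: set) -> pd.DataFrame:
    """Normalized-median consistency test on the displacement field.

    Shrinkage is spatially smooth, so a match whose displacement deviates
    from the median of its nearest matched neighbours by much more than
    those neighbours deviate from each other is a correspondence error
    (typically a block lock-on to cavity-wall structure).  This is the
    universal outlier detection standard in particle image velocimetry;
    rejected spheres are returned to the unmatched pools.
    """
    k = params.outlier_neighbors
    if params.outlier_threshold <= 0 or len(matches) < k + 2:
        return matches
    pos = np.array([pre_lookup[int(i)] for i in matches["pre_id"]])
    disp = matches[["refined_dx", "refined_dy", "refined_dz"]
                   ].to_numpy(dtype=float)
    tree = cKDTree(pos)
    _, nbr = tree.query(pos, k=k + 1)
    nbr = nbr[:, 1:]  # drop self
    med = np.median(disp[nbr], axis=1)
    resid = np.linalg.norm(disp - med, axis=1)
    nbr_resid = np.median(
        np.linalg.norm(disp[nbr] - med[:, None, :], axis=2), axis=1)
    ratio = resid / (nbr_resid + params.outlier_eps_um)
    keep = ratio <= params.outlier_threshold
    if not keep.all():
        log.info("outlier test rejected %d of %d matches",
                 int((~keep).sum()), len(matches))
        for rec in matches.loc[~keep].itertuples(index=False):
            used_pre.discard(int(rec.pre_id))
            used_post.discard(int(rec.post_id))
    return matches.loc[keep].reset_index(drop=True)


def match_scan_pair(pre: Volume, post: Volume, pre_set: SphereSet,
                    post_set: SphereSet, transform: RigidTransform,
                    params: MatchParams | None = None) -> MatchSet:
    """Block-match every pre sphere, then pair centroids one-to-one.

    Volumes are lightly smoothed (``params.smooth_sigma`` voxels) before
    block extraction so the NCC reflects bead structure rather than
    per-voxel scanner noise; the same smoothing the segmenter applies.
    """
    params = params or MatchParams()
    if params.smooth_sigma > 0:
        from scipy.ndimage import gaussian_filter

        pre = Volume(gaussian_filter(pre.data.astype(np.float32),
                                     params.smooth_sigma),
                     pre.voxel_size, pre.origin)
        post = Volume(gaussian_filter(post.data.astype(np.float32),
                                      params.smooth_sigma),
                      post.voxel_size, post.origin)
    coarse = {
        int(pid): block_match(pre, post, transform, c, params)
        for pid, c in zip(pre_set.table["id"], pre_set.centroids)
    }
    ms = pair_spheres(pre_set, post_set, coarse, transform,
                      float(pre.voxel_size[0]), params)
    for _ in range(params.rematch_passes):
        n_before = len(ms)
        ms = _guided_rematch(pre_set, post_set, ms, transform,
                             float(pre.voxel_size[0]), params)
        if len(ms) == n_before:
            break
    return ms


def _guided_rematch(pre_set: SphereSet, post_set: SphereSet, ms: MatchSet,
                    transform: RigidTransform, voxel_size: float,
                    params: MatchParams) -> MatchSet:
    """Second-pass gating for unmatched spheres using the consensus field.

    Blocks centred on a sphere occasionally lock onto a *neighbouring*
    bead (tracer spheres look alike), so the first pass leaves the sphere
    unmatched or the outlier test removes it.  Because shrinkage is
    spatially smooth, the median displacement of the nearest matched
    spheres predicts where such a sphere must sit in the post scan; this
    pass re-gates unmatched pre spheres against still-unmatched post
    spheres around that prediction.
    """
    k = params.outlier_neighbors
    if not ms.unmatched_pre or not ms.unmatched_post or len(ms) < k + 2:
        return ms
    inv = invert(transform)
    matched_pos = np.array(
        [pre_set.table.set_index("id").loc[i, ["x", "y", "z"]]
         for i in ms.matches["pre_id"]], dtype=float)
    disp = ms.matches[["refined_dx", "refined_dy", "refined_dz"]
                      ].to_numpy(dtype=float)
    tree_matched = cKDTree(matched_pos)
    pre_lut = pre_set.table.set_index("id")
    post_lut = post_set.table.set_index("id")
    post_pos = post_lut.loc[ms.unmatched_post, ["x", "y", "z"]
                            ].to_numpy(dtype=float)
    tree_post = cKDTree(post_pos)
    candidates = []
    for pid in ms.unmatched_pre:
        c_pre = pre_lut.loc[pid, ["x", "y", "z"]].to_numpy(dtype=float)
        _, nbr = tree_matched.query(c_pre, k=k)
        d_hat = np.median(disp[nbr], axis=0)
        predicted = transform.apply(c_pre + d_hat)
        for j in tree_post.query_ball_point(predicted, params.gate_distance):
            resid = float(np.linalg.norm(post_pos[j] - predicted))
            candidates.append((resid, int(pid), int(ms.unmatched_post[j]),
                               d_hat))
    candidates.sort(key=lambda t: (t[0], t[1], t[2]))
    used_pre: set[int] = set()
    used_post: set[int] = set()
    rows = []
    for resid, pid, qid, d_hat in candidates:
        if pid in used_pre or qid in used_post:
            continue
        used_pre.add(pid)
        used_post.add(qid)
        c_pre = pre_lut.loc[pid, ["x", "y", "z"]].to_numpy(dtype=float)
        c_post = post_lut.loc[qid, ["x", "y", "z"]].to_numpy(dtype=float)
        refined = inv.apply(c_post) - c_pre
        coarse_vox = np.rint(d_hat / voxel_size).astype(int)
        rows.append({
            "pre_id": pid, "post_id": qid,
            "du": int(coarse_vox[0]), "dv": int(coarse_vox[1]),
            "dw": int(coarse_vox[2]),
            "refined_dx": refined[0], "refined_dy": refined[1],
            "refined_dz": refined[2],
            "residual_um": resid, "ncc_score": np.nan,
        })
    if not rows:
        return ms
    log.info("guided re-match recovered %d spheres", len(rows))
    merged = pd.concat([ms.matches, pd.DataFrame(rows)], ignore_index=True)
    all_used_pre = set(int(i) for i in merged["pre_id"])
    all_used_post = set(int(i) for i in merged["post_id"])
    pre_lookup = {int(i): c for i, c in
                  zip(pre_set.table["id"], pre_set.centroids)}
    merged = _reject_field_outliers(merged, pre_lookup, params,
                                    all_used_pre, all_used_post)
    unmatched_pre = sorted(set(int(i) for i in pre_set.table["id"])
                           - all_used_pre)
    unmatched_post = sorted(set(int(i) for i in post_set.table["id"])
                            - all_used_post)
    return MatchSet(matches=merged, unmatched_pre=unmatched_pre,
                    unmatched_post=unmatched_post, params=params)
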