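"""Helpers for building matched vector fields from prescribed displacements."""

import numpy as np
import pandas as pd

from shrinkvec.matching import BlockMatchResult, MatchParams, pair_spheres
from shrinkvec.segmentation import SegmentationParams, SphereSet
from shrinkvec.transforms import RigidTransform
from shrinkvec.vectors import compute_vectors


def sphere_set(centroids) -> SphereSet:
    df = pd.DataFrame(centroids, columns=["x", "y", "z"])
    df.insert(0, "id", np.arange(len(df)))
    for col in ("radius_um", "voxels", "compactness", "contrast"):
        df[col] = 1.0
    return SphereSet(df, SegmentationParams())


def field_for_displacements(disps, voxel=16.0):
    """Matched field where each post centroid = pre centroid + displacement."""
    pre_pts = [[100.0 + 40.0 * i, 200.0, 300.0] for i in range(len(disps))]
    post_pts = [list(np.add(p, d)) for p, d in zip(pre_pts, disps)]
    coarse = {i: BlockMatchResult(tuple(int(v) for v in
                                        np.rint(np.asarray(d) / voxel)), 1.0)
              for i, d in enumerate(disps)}
    ms = pair_spheres(sphere_set(pre_pts), sphere_set(post_pts), coarse,
                      RigidTransform(), voxel,
                      MatchParams(gate_distance=64.0, outlier_threshold=0.0))
    return compute_vectors(ms, sphere_set(pre_pts), sphere_set(post_pts),
                           RigidTransform(), voxel, "g1", "s1", "inc1")
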