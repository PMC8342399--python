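"""Rigid registration of the post-cure scan onto the pre-cure scan.

The post scan is aligned to the pre scan using only static tooth anatomy
(via a mask that excludes the composite), so that residual sphere motion
reflects polymerization shrinkage rather than sample repositioning.

Method: masked normalized cross-correlation (NCC) over the six rigid
parameters, maximized by a derivative-free Powell search within a
three-level multi-resolution schedule (Gaussian smoothing at scales
4/2/1 voxels with progressively denser mask sampling).  Everything is
deterministic: no random restarts, fixed sampling strides, fixed
iteration caps.

The recovered :class:`~shrinkvec.transforms.RigidTransform` maps points in
the fixed (pre) frame to the moving (post) frame, matching the phantom's
``rigid_pose`` convention.  Downstream stages map post-scan sphere
centroids back into the pre frame through its inverse rather than
resampling the post volume, which would blur 2–4-voxel beads;
:func:`resample` exists for QC overlays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.ndimage import gaussian_filter, map_coordinates

from .transforms import RigidTransform
from .volume import Volume


class RegistrationError(RuntimeError):
    pass


@dataclass
class RegistrationParams:
    """Multi-resolution schedule and optimizer caps.

    ``levels`` lists ``(scale, max_points)``: Gaussian smoothing sigma is
    ``scale / 2`` voxels and at most ``max_points`` mask voxels (taken with
    a deterministic stride) contribute to the NCC at that level.  Before
    the local search starts, the coarsest level is seeded by an exhaustive
    translation scan over ``capture_grid_voxels`` per axis, which extends
    the capture range beyond the texture correlation length.
    """

    levels: tuple = ((16, 10_000), (8, 20_000), (4, 40_000), (3, 60_000))
    capture_grid_voxels: tuple = (-6.0, -3.0, 0.0, 3.0, 6.0)
    maxiter_per_level: int = 8
    xtol: float = 2e-3
    ftol: float = 1e-9
    min_mask_voxels: int = 1000


@dataclass
class RegistrationResult:
    transform: RigidTransform
    final_similarity: float
    iterations: int
    converged: bool
    per_level_similarity: list = field(default_factory=list)


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return 0.0
    return float((a @ b) / denom)


def _params_to_transform(x: np.ndarray, center, voxel: float) -> RigidTransform:
    """x = (rz, ry, rx degrees, tx, ty, tz voxels) -> world-μm transform."""
    return RigidTransform(
        angles_zyx=tuple(x[:3]),
        translation=tuple(np.asarray(x[3:]) * voxel),
        center=tuple(center),
    )


def register_rigid(fixed: Volume, moving: Volume,
                   mask: np.ndarray | None = None,
                   params: RegistrationParams | None = None,
                   initial: RigidTransform | None = None
                   ) -> RegistrationResult:
    """Estimate the rigid transform mapping fixed-frame points into the moving scan.

    Parameters
    ----------
    fixed, moving
        Pre- and post-cure volumes on grids with equal voxel size.
    mask
        Boolean array on the fixed grid selecting the voxels that drive the
        similarity; by default every voxel is used, but excluding the
        composite region (see :func:`shrinkvec.phantom.registration_mask`)
        is strongly recommended.
    """
    params = params or RegistrationParams()
    if not np.allclose(fixed.voxel_size, moving.voxel_size):
        raise RegistrationError("fixed and moving voxel sizes differ")
    if mask is None:
        mask = np.ones(fixed.shape, dtype=bool)
    if mask.shape != fixed.shape:
        raise RegistrationError("mask shape does not match fixed volume")
    n_mask = int(mask.sum())
    if n_mask < params.min_mask_voxels:
        raise RegistrationError(
            f"degenerate mask: {n_mask} voxels < {params.min_mask_voxels}"
        )
    voxel = float(fixed.voxel_size[0])
    center = fixed.origin + np.asarray(fixed.shape) * fixed.voxel_size / 2.0
    idx_all = np.argwhere(mask)
    fdata = fixed.data.astype(np.float32, copy=False)
    mdata = moving.data.astype(np.float32, copy=False)

    x = np.zeros(6)
    if initial is not None:
        # express the initial transform in optimizer coordinates
        A, b = initial.matrix_offset()
        x[:3] = initial.rotation.as_euler("ZYX", degrees=True)
        x[3:] = (initial.apply(center) - center) / voxel

    total_iters = 0
    per_level = []
    sim0_finest = None
    first_level = True
    for scale, max_points in params.levels:
        sigma = scale / 2.0
        f_sm = gaussian_filter(fdata, sigma) if sigma > 0 else fdata
        m_sm = gaussian_filter(mdata, sigma) if sigma > 0 else mdata
        stride = max(1, int(np.ceil(len(idx_all) / max_points)))
        idx = idx_all[::stride]
        pts_world = fixed.voxel_to_world(idx)
        fvals = f_sm[idx[:, 0], idx[:, 1], idx[:, 2]].astype(np.float64)

        def neg_sim(p, _pts=pts_world, _f=fvals, _m=m_sm):
            t = _params_to_transform(p, center, voxel)
            mapped = t.apply(_pts)
            coords = moving.world_to_voxel(mapped).T
            mv = map_coordinates(_m, coords, order=1, mode="nearest")
            s = _ncc(_f, mv)
            if not np.isfinite(s):
                raise RegistrationError("non-finite similarity")
            return -s

        if first_level and initial is None and params.capture_grid_voxels:
            # deterministic translation scan seeds the local search
            grid = np.asarray(params.capture_grid_voxels, dtype=float)
            best = neg_sim(x)
            for tx in grid:
                for ty in grid:
                    for tz in grid:
                        cand = np.array([0.0, 0.0, 0.0, tx, ty, tz])
                        v = neg_sim(cand)
                        if v < best:
                            best, x = v, cand
        first_level = False

        res = optimize.minimize(
            neg_sim, x, method="Powell",
            options={"maxiter": params.maxiter_per_level,
                     "xtol": params.xtol, "ftol": params.ftol},
        )
        if -res.fun >= -neg_sim(x):
            x = np.asarray(res.x, dtype=float)
        total_iters += int(res.nit)
        per_level.append(float(-neg_sim(x)))
        if scale == params.levels[-1][0]:
            sim0_finest = float(-neg_sim(np.zeros(6)))

    final_sim = per_level[-1]
    transform = _params_to_transform(x, center, voxel)
    converged = bool(final_sim >= (sim0_finest if sim0_finest is not None
                                   else -1.0))
    return RegistrationResult(
        transform=transform, final_similarity=final_sim,
        iterations=total_iters, converged=converged,
        per_level_similarity=per_level,
    )


def resample(volume: Volume, transform: RigidTransform,
             interpolation: str = "linear", fill_value: float = 0.0,
             out_like: Volume | None = None) -> Volume:
    """Resample ``volume`` onto the fixed grid through ``transform``.

    ``out(x) = volume(transform(x))`` for every voxel centre ``x`` of the
    output grid, so ``resample(moving, result.transform)`` overlays the
    moving scan on the fixed one.  Out-of-field voxels take ``fill_value``.
    """
    orders = {"linear": 1, "bspline": 3}
    if interpolation not in orders:
        raise ValueError(f"interpolation must be one of {sorted(orders)}")
    ref = out_like or volume
    A, b = transform.matrix_offset()
    if not (np.all(np.isfinite(A)) and np.all(np.isfinite(b))):
        raise ValueError("transform must be finite")
    if out_like is None and transform.is_identity(tol=0.0):
        return volume.copy()
    nx, ny, nz = ref.shape
    idx = np.stack(np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                               indexing="ij"), axis=-1).reshape(-1, 3)
    world = ref.voxel_to_world(idx)
    mapped = world @ A.T + b
    coords = volume.world_to_voxel(mapped).T
    out = map_coordinates(
        volume.data.astype(np.float32, copy=False), coords,
        order=orders[interpolation], mode="constant", cval=fill_value,
    ).reshape(nx, ny, nz)
    return Volume(out, ref.voxel_size.copy(), ref.origin.copy())
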