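"""Detection of radiolucent tracer spheres with sub-voxel centroids.

Glass beads (and the air bubbles used as tracers in the hybrid composite)
appear as small LOW-attenuation blobs inside the brighter composite.  The
detector therefore works on a *contrast* image — the local composite level
minus the voxel value — restricted to a cavity mask:

1. light Gaussian smoothing (``smooth_sigma`` voxels) to suppress scanner
   noise without biasing symmetric blob centroids;
2. per-z-slice median of the masked voxels as the local composite level
   (composite layers are stratified in z, so the background varies with
   depth but not laterally);
3. threshold (Otsu within the mask by default), 26-connected components,
   and volume/compactness filters bracketing the expected bead sizes;
4. contrast-weighted centre of mass for each surviving component, in world
   μm using the voxel-centre convention.

Compactness is defined as component volume divided by the volume of the
sphere whose radius is half the component's bounding-box diagonal.  Under
this definition an ideal sphere scores 3^(-3/2) ≈ 0.19 (its bounding box
is a cube), so the default threshold of 0.06 keeps beads while discarding
plate- or thread-like segmentation debris.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

from .volume import Volume

log = logging.getLogger(__name__)


class SegmentationError(ValueError):
    pass


@dataclass(frozen=True)
class SegmentationParams:
    """Detector configuration.

    ``min_volume``/``max_volume`` (voxels) default to the volumes of 2- and
    6-voxel-diameter spheres (32–96 μm at 16 μm voxels), bracketing the
    40–70 μm tracer beads with partial-volume slack.  ``fixed_fraction``
    thresholds at that fraction of the 99.9th contrast percentile instead
    of Otsu; air-bubble data typically wants a lower fraction.
    """

    threshold_mode: str = "otsu_in_mask"
    fixed_fraction: float = 0.5
    min_volume: int = 4
    max_volume: int = 120
    min_compactness: float = 0.06
    connectivity: int = 26
    smooth_sigma: float = 0.7
    centroid_weight_power: float = 2.0

    def __post_init__(self):
        if self.threshold_mode not in ("otsu_in_mask", "fixed_fraction"):
            raise SegmentationError(
                f"unknown threshold_mode {self.threshold_mode!r}")
        if not (0 < self.min_volume < self.max_volume):
            raise SegmentationError("need 0 < min_volume < max_volume")
        if not (0 < self.min_compactness <= 1):
            raise SegmentationError("min_compactness must be in (0, 1]")
        if self.connectivity not in (6, 26):
            raise SegmentationError("connectivity must be 6 or 26")


@dataclass
class SphereSet:
    """Detected spheres: one row per sphere, sorted by centroid (x, y, z).

    ``table`` columns: id, x, y, z (μm), radius_um (equivalent-sphere
    radius), voxels, compactness, contrast.
    """

    table: pd.DataFrame
    params: SegmentationParams = field(default_factory=SegmentationParams)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def centroids(self) -> np.ndarray:
        return self.table[["x", "y", "z"]].to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path, params: SegmentationParams | None = None):
        return cls(pd.read_csv(path), params or SegmentationParams())


_EMPTY = pd.DataFrame(columns=["id", "x", "y", "z", "radius_um", "voxels",
                               "compactness", "contrast"])


def make_cavity_mask(volume: Volume, cavity_center, diameter: float,
                     depth: float, margin_voxels: float = 0.0,
                     transform=None) -> np.ndarray:
    """Boolean mask of the (eroded) cavity cylinder on the volume grid.

    ``cavity_center`` is ``(x, y, z_top)`` μm: the axis position and the
    occlusal opening of the cylinder.  ``margin_voxels`` erodes the
    cylinder inward on all faces.  If ``transform`` is given (the rigid
    pose of this scan relative to the reference frame in which the cavity
    is defined), membership is tested at the inverse-posed position, so the
    same physical cavity is masked in a re-posed scan.
    """
    cx, cy, z_top = (float(v) for v in cavity_center)
    vs = float(volume.voxel_size[0])
    m = margin_voxels * vs
    r = diameter / 2.0 - m
    z_lo, z_hi = z_top + m, z_top + depth - m
    nx, ny, nz = volume.shape
    if transform is not None and not transform.is_identity(tol=0.0):
        from .transforms import invert

        idx = np.stack(np.meshgrid(np.arange(nx), np.arange(ny),
                                   np.arange(nz), indexing="ij"),
                       axis=-1).reshape(-1, 3)
        q = invert(transform).apply(volume.voxel_to_world(idx))
        qx, qy, qz = (q[:, k].reshape(nx, ny, nz) for k in range(3))
    else:
        xs = volume.origin[0] + (np.arange(nx) + 0.5) * volume.voxel_size[0]
        ys = volume.origin[1] + (np.arange(ny) + 0.5) * volume.voxel_size[1]
        zs = volume.origin[2] + (np.arange(nz) + 0.5) * volume.voxel_size[2]
        qx = xs[:, None, None]
        qy = ys[None, :, None]
        qz = zs[None, None, :]
    mask = ((qx - cx) ** 2 + (qy - cy) ** 2 <= r * r) & \
        (qz >= z_lo) & (qz <= z_hi)
    mask = np.broadcast_to(mask, (nx, ny, nz)).copy()
    if r <= 0 or not mask.any():
        raise SegmentationError(
            "cavity mask is empty (margin >= radius, or cylinder outside grid)"
        )
    return mask


def estimate_centroid(indices: np.ndarray, weights: np.ndarray,
                      volume: Volume) -> np.ndarray:
    """Weight-averaged centre of mass of component voxels, in world μm."""
    idx = np.atleast_2d(np.asarray(indices))
    if idx.shape[0] == 0:
        raise SegmentationError("empty component")
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        log.warning("all-zero contrast weights; falling back to unweighted "
                    "centroid")
        w = np.ones(len(idx))
    cv = (idx * w[:, None]).sum(axis=0) / w.sum()
    return volume.voxel_to_world(cv)


def _structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(3, 3 if connectivity == 26 else 1)


def segment_spheres(volume: Volume, mask: np.ndarray,
                    params: SegmentationParams | None = None) -> SphereSet:
    """Detect radiolucent spheres inside ``mask``; see module docstring."""
    params = params or SegmentationParams()
    if mask.shape != volume.shape:
        raise SegmentationError("mask shape does not match volume")
    if not mask.any():
        raise SegmentationError("mask is empty")
    data = volume.data.astype(np.float32, copy=False)
    if not np.all(np.isfinite(data[mask])):
        raise SegmentationError("volume contains non-finite values in mask")
    if params.smooth_sigma > 0:
        data = ndimage.gaussian_filter(data, params.smooth_sigma)

    # per-slice composite level -> contrast image
    nz = volume.shape[2]
    level = np.full(nz, np.nan)
    counts = mask.sum(axis=(0, 1))
    for z in range(nz):
        if counts[z] >= 20:
            level[z] = np.median(data[:, :, z][mask[:, :, z]])
    if np.all(np.isnan(level)):
        raise SegmentationError("mask too thin to estimate composite level")
    valid = np.flatnonzero(~np.isnan(level))
    level = np.interp(np.arange(nz), valid, level[valid])
    contrast = (level[None, None, :] - data) * mask
    np.clip(contrast, 0.0, None, out=contrast)

    cvals = contrast[mask]
    if float(cvals.max() - cvals.min()) < 1e-9:
        return SphereSet(table=_EMPTY.copy(), params=params)
    if params.threshold_mode == "otsu_in_mask":
        thr = float(threshold_otsu(cvals))
    else:
        thr = params.fixed_fraction * float(np.percentile(cvals, 99.9))
    binary = contrast > thr
    labels, n = ndimage.label(binary, structure=_structure(params.connectivity))
    if n == 0:
        return SphereSet(table=_EMPTY.copy(), params=params)

    objects = ndimage.find_objects(labels)
    vs = float(volume.voxel_size[0])
    rows = []
    for lab, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        sub = labels[sl] == lab
        nvox = int(sub.sum())
        if not (params.min_volume <= nvox <= params.max_volume):
            continue
        ext = np.array([s.stop - s.start for s in sl], dtype=float)
        r_bb = 0.5 * np.sqrt(np.sum(ext ** 2))
        compact = nvox / ((4.0 / 3.0) * np.pi * r_bb ** 3)
        if compact < params.min_compactness:
            continue
        loc = np.argwhere(sub)
        idx = loc + np.array([s.start for s in sl])
        w = contrast[idx[:, 0], idx[:, 1], idx[:, 2]]
        # powers > 1 concentrate weight in the blob core, where the
        # contrast-to-noise ratio is highest
        centroid = estimate_centroid(idx, w ** params.centroid_weight_power,
                                     volume)
        rows.append({
            "x": centroid[0], "y": centroid[1], "z": centroid[2],
            "radius_um": (3.0 * nvox / (4.0 * np.pi)) ** (1.0 / 3.0) * vs,
            "voxels": nvox,
            "compactness": compact,
            "contrast": float(w.mean()),
        })
    if not rows:
        return SphereSet(table=_EMPTY.copy(), params=params)
    df = pd.DataFrame(rows).sort_values(["x", "y", "z"],
                                        kind="mergesort").reset_index(drop=True)
    df.insert(0, "id", np.arange(len(df)))
    return SphereSet(table=df, params=params)


def air_bubble_params(**overrides) -> SegmentationParams:
    """Preset for air-bubble tracers: same detector, lower fixed threshold."""
    base = dict(threshold_mode="fixed_fraction", fixed_fraction=0.35)
    base.update(overrides)
    return SegmentationParams(**base)
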