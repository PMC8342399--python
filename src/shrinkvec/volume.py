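"""Volumes and tabular outputs with explicit units and axis metadata.

Internal conventions, inherited by every other module:

* ``Volume.data`` is indexed ``[x, y, z]``; z index 0 is the occlusal
  (light-source) face and z increases toward the cavity floor.
* Voxel indexing is 0-based; the world coordinate (μm) of voxel ``i`` is
  ``origin + (i + 0.5) * voxel_size`` (voxel-centre convention).
* All world coordinates are micrometres.  MetaImage and NIfTI store
  spacings in millimetres, so readers multiply by 1000 and writers divide.

Supported on-disk formats: multi-page TIFF stacks (pages along z, each
page ``(y, x)``), MetaImage ``.mha``/``.mhd`` and NIfTI-1 ``.nii``/
``.nii.gz``.  Every file written gets a JSON provenance sidecar.
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__version__ = "0.1.0"

VECTOR_TABLE_COLUMNS = [
    "sphere_id", "group", "sample", "increment",
    "x_pre", "y_pre", "z_pre", "x_post", "y_post", "z_post",
    "dx", "dy", "dz", "magnitude",
]


class VolumeFormatError(ValueError):
    """Raised for unreadable, inconsistent or metadata-deficient volume files."""


@dataclass
class Volume:
    """3D scalar grid with voxel size (μm per axis) and world origin (μm)."""

    data: np.ndarray
    voxel_size: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.size == 0:
            raise ValueError("Volume.data must be a non-empty 3D array")
        self.voxel_size = np.broadcast_to(
            np.asarray(self.voxel_size, dtype=float), (3,)
        ).copy()
        self.origin = np.broadcast_to(
            np.asarray(self.origin, dtype=float), (3,)
        ).copy()
        if not np.all(self.voxel_size > 0):
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")
        if not np.all(np.isfinite(self.origin)):
            raise ValueError("origin must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        """World coordinates (μm) of voxel centres for index array ``(..., 3)``."""
        return self.origin + (np.asarray(idx, dtype=float) + 0.5) * self.voxel_size

    def world_to_voxel(self, pts: np.ndarray) -> np.ndarray:
        """Continuous voxel coordinates of world points (inverse of centres)."""
        return (np.asarray(pts, dtype=float) - self.origin) / self.voxel_size - 0.5

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.voxel_size.copy(), self.origin.copy())


# ---------------------------------------------------------------------------
# volume I/O


def _infer_format(path: Path) -> str:
    s = path.name.lower()
    if s.endswith((".tif", ".tiff")):
        return "tiff_stack"
    if s.endswith((".mha", ".mhd")):
        return "metaimage"
    if s.endswith((".nii", ".nii.gz")):
        return "nifti"
    raise VolumeFormatError(f"cannot infer volume format from {path.name!r}")


def read_volume(path, format: str | None = None,
                voxel_size_um=None, origin_um=None) -> Volume:
    """Read a volume from TIFF stack, MetaImage or NIfTI.

    ``voxel_size_um``/``origin_um`` override metadata; TIFF stacks without
    embedded spacing metadata *require* ``voxel_size_um``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt == "tiff_stack":
        vol = _read_tiff(path)
    elif fmt == "metaimage":
        vol = _read_metaimage(path)
    elif fmt == "nifti":
        vol = _read_nifti(path)
    else:
        raise VolumeFormatError(f"unknown format {fmt!r}")
    if voxel_size_um is not None:
        vol.voxel_size = np.broadcast_to(np.asarray(voxel_size_um, float), (3,)).copy()
    if vol.voxel_size is None or not np.all(np.asarray(vol.voxel_size) > 0):
        raise VolumeFormatError(
            f"{path.name}: no voxel size in metadata; pass voxel_size_um"
        )
    if origin_um is not None:
        vol.origin = np.broadcast_to(np.asarray(origin_um, float), (3,)).copy()
    return vol


def _read_tiff(path: Path) -> Volume:
    import tifffile

    with tifffile.TiffFile(str(path)) as tf:
        shapes = {p.shape for p in tf.pages}
        if len(shapes) > 1:
            for i, p in enumerate(tf.pages):
                if p.shape != tf.pages[0].shape:
                    raise VolumeFormatError(
                        f"{path.name}: slice {i} shape {p.shape} differs from "
                        f"slice 0 shape {tf.pages[0].shape}"
                    )
        arr = tf.asarray()  # (z, y, x)
        desc = tf.pages[0].tags.get("ImageDescription")
        meta = {}
        if desc is not None:
            try:
                meta = json.loads(desc.value)
            except (json.JSONDecodeError, TypeError):
                meta = {}
    if arr.ndim == 2:
        arr = arr[None]
    data = np.ascontiguousarray(arr.transpose(2, 1, 0))  # -> (x, y, z)
    vs = np.asarray(meta.get("voxel_size_um", [-1.0, -1.0, -1.0]), float)
    org = np.asarray(meta.get("origin_um", [0.0, 0.0, 0.0]), float)
    vol = Volume.__new__(Volume)
    vol.data, vol.voxel_size, vol.origin = data, vs, org
    return vol


def _read_metaimage(path: Path) -> Volume:
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    data = np.ascontiguousarray(arr.transpose(2, 1, 0))
    vs = np.asarray(img.GetSpacing(), float) * 1000.0  # mm -> μm
    org = np.asarray(img.GetOrigin(), float) * 1000.0
    return Volume(data, vs, org)


def _read_nifti(path: Path) -> Volume:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.ascontiguousarray(np.asanyarray(img.dataobj))
    zooms = np.asarray(img.header.get_zooms()[:3], float) * 1000.0
    org = np.asarray(img.affine[:3, 3], float) * 1000.0
    return Volume(data, zooms, org)


def write_volume(volume: Volume, path, format: str | None = None,
                 provenance: dict | None = None) -> Path:
    """Write a volume; format inferred from suffix unless given."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "tiff_stack":
        import tifffile

        meta = {
            "voxel_size_um": [float(v) for v in volume.voxel_size],
            "origin_um": [float(v) for v in volume.origin],
        }
        tifffile.imwrite(
            str(path),
            np.ascontiguousarray(volume.data.transpose(2, 1, 0)),
            description=json.dumps(meta),
            photometric="minisblack",
        )
    elif fmt == "metaimage":
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(
            np.ascontiguousarray(volume.data.transpose(2, 1, 0))
        )
        img.SetSpacing(tuple(float(v) / 1000.0 for v in volume.voxel_size))
        img.SetOrigin(tuple(float(v) / 1000.0 for v in volume.origin))
        sitk.WriteImage(img, str(path), useCompression=False)
    elif fmt == "nifti":
        import nibabel as nib

        aff = np.diag(list(volume.voxel_size / 1000.0) + [1.0])
        aff[:3, 3] = volume.origin / 1000.0
        nib.save(nib.Nifti1Image(volume.data, aff), str(path))
    else:
        raise VolumeFormatError(f"unknown format {fmt!r}")
    write_provenance(path, provenance)
    return path


def write_provenance(path, extra: dict | None = None) -> Path:
    """Write the JSON provenance sidecar ``<path>.provenance.json``."""
    path = Path(path)
    side = path.with_name(path.name + ".provenance.json")
    record = {"tool": "shrinkvec", "version": __version__, "file": path.name}
    if extra:
        record.update(extra)
    side.write_text(json.dumps(record, indent=2, sort_keys=True))
    return side


def config_hash(obj) -> str:
    """Stable sha256 of a JSON-serialisable configuration object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


# ---------------------------------------------------------------------------
# vector tables


def validate_vector_table(df: pd.DataFrame) -> None:
    missing = [c for c in VECTOR_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"vector table missing columns {missing}")
    if len(df):
        mag = np.sqrt(df["dx"] ** 2 + df["dy"] ** 2 + df["dz"] ** 2)
        if not np.allclose(df["magnitude"], mag, atol=1e-9, rtol=0):
            raise ValueError("magnitude inconsistent with (dx, dy, dz)")
        dup = df.duplicated(subset=["sample", "increment", "sphere_id"])
        if dup.any():
            raise ValueError("duplicate sphere_id within a (sample, increment)")


def write_vector_table(df: pd.DataFrame, path, provenance: dict | None = None) -> Path:
    """Write a per-sphere displacement table as CSV at full precision."""
    path = Path(path)
    validate_vector_table(df)
    df.to_csv(path, index=False, columns=VECTOR_TABLE_COLUMNS,
              float_format="%.17g")
    write_provenance(path, provenance)
    return path


def read_vector_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    validate_vector_table(df)
    return df
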