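"""Shrinkage-vector records, axial decomposition and glyph export.

A shrinkage vector is the 3D displacement (μm) of one tracer sphere
between the pre- and post-polymerization scans, expressed in the pre-scan
frame after rigid alignment.  The signed z component follows the scan
convention of this package: positive z points from the occlusal (light
source) face toward the cavity floor, so downward material movement gives
positive values and movement toward the light source gives negative
values.

Glyph files hold UNSCALED displacement vectors; the customary ×10
visibility scaling is written as named metadata so renderers can apply it
without destroying the quantitative field.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matching import MatchSet
from .segmentation import SphereSet
from .transforms import RigidTransform, invert
from .volume import (VECTOR_TABLE_COLUMNS, validate_vector_table,
                     write_provenance)

DEFAULT_GLYPH_SCALE = 10.0


@dataclass
class ShrinkageVectorField:
    """Labeled per-sphere displacement records.

    ``table`` columns are the vector-table schema plus ``z_component``
    (== dz, kept as an explicit column because the axial analysis treats
    it as its own measure).
    """

    table: pd.DataFrame
    voxel_size: float
    scale_hint: float = DEFAULT_GLYPH_SCALE
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        validate_vector_table(self.table)
        if "z_component" not in self.table.columns:
            self.table = self.table.assign(
                z_component=self.table["dz"].astype(float))
        if len(self.table) and not np.allclose(
                self.table["z_component"].astype(float),
                self.table["dz"].astype(float), atol=1e-12, rtol=0):
            raise ValueError("z_component must equal dz")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def magnitudes(self) -> np.ndarray:
        return self.table["magnitude"].to_numpy(dtype=float)

    @property
    def z_components(self) -> np.ndarray:
        return self.table["z_component"].to_numpy(dtype=float)


def compute_vectors(matchset: MatchSet, pre_set: SphereSet,
                    post_set: SphereSet, transform: RigidTransform,
                    voxel_size: float, group: str, sample: str,
                    increment: str) -> ShrinkageVectorField:
    """One labeled record per match: ``d = inv(pose)(post centroid) - pre centroid``."""
    if voxel_size <= 0:
        raise ValueError("voxel_size must be positive")
    pre_lookup = pre_set.table.set_index("id")
    post_lookup = post_set.table.set_index("id")
    inv = invert(transform)
    rows = []
    for rec in matchset.matches.itertuples(index=False):
        p = pre_lookup.loc[rec.pre_id]
        q = post_lookup.loc[rec.post_id]
        post_in_pre = inv.apply(np.array([q.x, q.y, q.z]))
        d = post_in_pre - np.array([p.x, p.y, p.z])
        rows.append({
            "sphere_id": int(rec.pre_id), "group": group, "sample": sample,
            "increment": increment,
            "x_pre": p.x, "y_pre": p.y, "z_pre": p.z,
            "x_post": post_in_pre[0], "y_post": post_in_pre[1],
            "z_post": post_in_pre[2],
            "dx": d[0], "dy": d[1], "dz": d[2],
            "magnitude": float(np.linalg.norm(d)),
        })
    table = pd.DataFrame(rows, columns=VECTOR_TABLE_COLUMNS)
    if not rows:
        table = table.astype({c: float for c in VECTOR_TABLE_COLUMNS[4:]})
    meta = {
        "n_unmatched_pre": len(matchset.unmatched_pre),
        "n_unmatched_post": len(matchset.unmatched_post),
    }
    return ShrinkageVectorField(table=table, voxel_size=voxel_size,
                                metadata=meta)


def concat_fields(fields, label: str | None = None) -> ShrinkageVectorField:
    """Pool several fields (e.g. cumulative successive increments).

    A cumulative row such as "liner + increment 1 + increment 2" is the
    concatenation of those scan pairs' records; ``label`` overrides the
    ``increment`` column of the pooled table.
    """
    fields = list(fields)
    if not fields:
        raise ValueError("no fields to concatenate")
    table = pd.concat([f.table for f in fields], ignore_index=True)
    if label is not None:
        # keep the originating increment, then relabel; sphere ids are
        # reassigned because uniqueness is per (sample, increment) and the
        # pooled records share one label
        if "source_increment" not in table.columns:
            table = table.assign(source_increment=table["increment"])
        table = table.assign(increment=label,
                             sphere_id=np.arange(len(table)))
    meta: dict = {}
    for f in fields:
        for k, v in f.metadata.items():
            meta[k] = meta.get(k, 0) + v
    return ShrinkageVectorField(table=table, voxel_size=fields[0].voxel_size,
                                scale_hint=fields[0].scale_hint, metadata=meta)


def summarize_field(fields) -> pd.DataFrame:
    """Per-(group, increment) n, mean ± SD of magnitude and of the z component.

    SD is the sample standard deviation (n − 1 denominator); cells with a
    single record report NaN SDs and are flagged ``n1``.
    """
    if isinstance(fields, ShrinkageVectorField):
        fields = [fields]
    table = pd.concat([f.table for f in fields], ignore_index=True)
    if table.empty:
        raise ValueError("nothing to summarize")
    rows = []
    for (grp, inc), sub in table.groupby(["group", "increment"], sort=True):
        n = len(sub)
        rows.append({
            "group": grp, "increment": inc, "n": n,
            "mean_magnitude": float(sub["magnitude"].mean()),
            "sd_magnitude": float(sub["magnitude"].std(ddof=1))
            if n > 1 else float("nan"),
            "mean_z": float(sub["dz"].mean()),
            "sd_z": float(sub["dz"].std(ddof=1)) if n > 1 else float("nan"),
            "n1": n == 1,
        })
    return pd.DataFrame(rows)


def noise_corrected_magnitudes(field: ShrinkageVectorField,
                               neighbors: int = 8
                               ) -> tuple[np.ndarray, float]:
    """Magnitudes debiased for centroid measurement noise.

    The magnitude of a noisy displacement vector is biased upward
    (``E|d + e|² = |d|² + 3σ²`` for isotropic per-component noise σ), the
    same noncentral-chi effect corrected for in MRI magnitude images.  σ is
    estimated from the field itself: because shrinkage is spatially smooth,
    each record's residual against the median displacement of its
    ``neighbors`` nearest records is essentially pure measurement noise.
    Returns ``(sqrt(max(|d|² − 3σ̂², 0)), σ̂)``; fields too small for a
    neighbourhood estimate are returned uncorrected with σ̂ = 0.
    """
    t = field.table
    mags = field.magnitudes
    if len(t) < neighbors + 2:
        return mags, 0.0
    from scipy.spatial import cKDTree

    pos = t[["x_pre", "y_pre", "z_pre"]].to_numpy(dtype=float)
    disp = t[["dx", "dy", "dz"]].to_numpy(dtype=float)
    _, nbr = cKDTree(pos).query(pos, k=neighbors + 1)
    resid = disp - np.median(disp[nbr[:, 1:]], axis=1)
    # median of 8 neighbours adds ~pi/(2k) relative variance to the residual
    mad_sigma = 1.4826 * np.median(np.abs(resid))
    sigma = float(mad_sigma / np.sqrt(1.0 + np.pi / (2 * neighbors)))
    corrected = np.sqrt(np.clip(mags ** 2 - 3.0 * sigma ** 2, 0.0, None))
    return corrected, sigma


# ---------------------------------------------------------------------------
# glyph polydata I/O (VTK legacy ASCII)


def export_glyphs(field: ShrinkageVectorField, path,
                  scale: float = DEFAULT_GLYPH_SCALE) -> Path:
    """Write the field as VTK legacy-ASCII polydata.

    Points are the pre-scan centroids (μm); the ``displacement`` vector
    array holds unscaled displacements; ``magnitude`` is a scalar array
    for color mapping; the glyph scale factor is stored as the
    ``glyph_scale`` field-data array (and echoed in the title line).
    Zero vectors are written like any other record.
    """
    if len(field) == 0:
        raise ValueError("cannot export an empty field")
    path = Path(path)
    t = field.table
    pts = t[["x_pre", "y_pre", "z_pre"]].to_numpy(dtype=float)
    vec = t[["dx", "dy", "dz"]].to_numpy(dtype=float)
    mag = t["magnitude"].to_numpy(dtype=float)
    n = len(t)

    def fmt(row):
        return " ".join(f"{v:.9g}" for v in row)

    lines = [
        "# vtk DataFile Version 3.0",
        f"shrinkage vectors (um); glyph_scale={scale:g}; "
        "displacements unscaled",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {n} double",
        *[fmt(p) for p in pts],
        f"VERTICES {n} {2 * n}",
        *[f"1 {i}" for i in range(n)],
        f"POINT_DATA {n}",
        "VECTORS displacement double",
        *[fmt(v) for v in vec],
        "SCALARS magnitude double 1",
        "LOOKUP_TABLE default",
        *[f"{v:.9g}" for v in mag],
        "FIELD FieldData 1",
        "glyph_scale 1 1 double",
        f"{scale:g}",
        "",
    ]
    path.write_text("\n".join(lines))
    write_provenance(path, {"n_points": n, "glyph_scale": scale})
    return path


def read_glyphs(path) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Parse a glyph file back: (points, vectors, magnitudes, scale)."""
    text = Path(path).read_text().splitlines()
    it = iter(enumerate(text))
    points = vectors = mags = None
    scale = DEFAULT_GLYPH_SCALE

    def read_rows(start: int, count: int, width: int) -> np.ndarray:
        vals: list[float] = []
        i = start
        while len(vals) < count * width:
            vals.extend(float(v) for v in text[i].split())
            i += 1
        return np.asarray(vals).reshape(count, width)

    for i, line in it:
        if line.startswith("POINTS"):
            n = int(line.split()[1])
            points = read_rows(i + 1, n, 3)
        elif line.startswith("VECTORS"):
            vectors = read_rows(i + 1, n, 3)
        elif line.startswith("SCALARS"):
            mags = read_rows(i + 2, n, 1).ravel()  # skip LOOKUP_TABLE
        elif line.startswith("glyph_scale"):
            scale = float(text[i + 1].strip())
    if points is None or vectors is None or mags is None:
        raise ValueError(f"{path}: not a shrinkvec glyph polydata file")
    return points, vectors, mags, scale
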