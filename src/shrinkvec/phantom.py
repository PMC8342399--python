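"""Synthetic restoration phantom with known sphere trajectories.

The phantom emulates a micro-CT scan pair of a restored cylindrical class-I
cavity: a dentin-like tooth block containing a cylindrical cavity filled
with one or more composite layers, radiolucent tracer spheres (glass beads
or air bubbles) embedded in the composite, a prescribed analytic shrinkage
deformation of the composite, a rigid pose offset between the two scans,
and additive Gaussian scanner noise.  Every sampled quantity is recorded in
a :class:`GroundTruth` table so downstream stages (registration,
segmentation, matching, vector computation) can be scored against truth.

Geometry and units
------------------
All world coordinates are μm; the z axis runs from the occlusal
(light-source) face at z = 0 toward the cavity floor.  The cavity axis is
centred in x/y; the cavity opening sits at ``cavity_top_z`` and the floor
at ``cavity_top_z + cavity_depth``.  Layer intervals are given in μm from
the cavity opening (0) toward the floor (``cavity_depth``).

The dentin carries a smooth, seeded random attenuation texture.  Real
dentin is not homogeneous either, and a featureless block would make the
rotational component of the rigid pose unobservable to registration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, map_coordinates

from .transforms import RigidTransform, invert
from .volume import Volume


class PhantomError(RuntimeError):
    pass


class ConfigurationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# deformation models


@dataclass(frozen=True)
class DeformationModel:
    """Analytic displacement field applied to the composite between scans.

    Kinds:

    * ``none`` — zero field.
    * ``uniform_contraction`` — ``u(p) = -s (p - center)`` with
      ``s = contraction_fraction``; isotropic shrinkage toward ``center``.
    * ``axial_drift`` — constant ``(0, 0, axial_shift)``; positive values
      move material toward the cavity floor.
    * ``swirl`` — rotation of the xy components about the centre axis by
      ``swirl_deg_per_mm × (radial distance in mm)`` degrees.
    * ``composite_sum`` — sum of the fields in ``parts``.
    """

    kind: str = "none"
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    contraction_fraction: float = 0.0
    axial_shift: float = 0.0
    swirl_deg_per_mm: float = 0.0
    parts: tuple = ()

    _KINDS = ("none", "uniform_contraction", "axial_drift", "swirl",
              "composite_sum")

    def __post_init__(self):
        if self.kind not in self._KINDS:
            raise ConfigurationError(
                f"unknown deformation kind {self.kind!r}; one of {self._KINDS}"
            )
        if self.kind == "composite_sum" and not self.parts:
            raise ConfigurationError("composite_sum requires non-empty parts")

    def to_dict(self) -> dict:
        d = {
            "kind": self.kind,
            "center": list(self.center),
            "contraction_fraction": self.contraction_fraction,
            "axial_shift": self.axial_shift,
            "swirl_deg_per_mm": self.swirl_deg_per_mm,
        }
        if self.parts:
            d["parts"] = [p.to_dict() for p in self.parts]
        return d


def evaluate_deformation(points, model: DeformationModel) -> np.ndarray:
    """Displacement (μm) of the field at one point or an ``(N, 3)`` array."""
    p = np.atleast_2d(np.asarray(points, dtype=float))
    c = np.asarray(model.center, dtype=float)
    if model.kind == "none":
        u = np.zeros_like(p)
    elif model.kind == "uniform_contraction":
        u = -model.contraction_fraction * (p - c)
    elif model.kind == "axial_drift":
        u = np.zeros_like(p)
        u[:, 2] = model.axial_shift
    elif model.kind == "swirl":
        d = p - c
        r_mm = np.hypot(d[:, 0], d[:, 1]) / 1000.0
        ang = np.radians(model.swirl_deg_per_mm * r_mm)
        ca, sa = np.cos(ang), np.sin(ang)
        u = np.zeros_like(p)
        u[:, 0] = ca * d[:, 0] - sa * d[:, 1] - d[:, 0]
        u[:, 1] = sa * d[:, 0] + ca * d[:, 1] - d[:, 1]
    elif model.kind == "composite_sum":
        u = np.zeros_like(p)
        for part in model.parts:
            u += evaluate_deformation(p, part)
    else:  # pragma: no cover - guarded in __post_init__
        raise ConfigurationError(f"unknown kind {model.kind!r}")
    if not np.all(np.isfinite(u)):
        raise ConfigurationError("deformation produced non-finite displacement")
    return u[0] if np.asarray(points).ndim == 1 else u


def inverse_deformation(points, model: DeformationModel) -> np.ndarray:
    """Pre-deformation positions of post-deformation points.

    Exact for ``none``, ``uniform_contraction``, ``axial_drift`` and
    ``swirl`` (which preserves radius); fixed-point iteration for
    ``composite_sum`` (valid for the small displacement gradients used
    here).
    """
    q = np.atleast_2d(np.asarray(points, dtype=float))
    c = np.asarray(model.center, dtype=float)
    if model.kind == "none":
        p = q.copy()
    elif model.kind == "uniform_contraction":
        s = model.contraction_fraction
        if s >= 1.0:
            raise ConfigurationError("contraction_fraction must be < 1")
        p = c + (q - c) / (1.0 - s)
    elif model.kind == "axial_drift":
        p = q.copy()
        p[:, 2] -= model.axial_shift
    elif model.kind == "swirl":
        d = q - c
        r_mm = np.hypot(d[:, 0], d[:, 1]) / 1000.0
        ang = -np.radians(model.swirl_deg_per_mm * r_mm)
        ca, sa = np.cos(ang), np.sin(ang)
        p = q.copy()
        p[:, 0] = c[0] + ca * d[:, 0] - sa * d[:, 1]
        p[:, 1] = c[1] + sa * d[:, 0] + ca * d[:, 1]
    elif model.kind == "composite_sum":
        p = q.copy()
        for _ in range(12):
            p = q - evaluate_deformation(p, model)
    else:  # pragma: no cover
        raise ConfigurationError(f"unknown kind {model.kind!r}")
    return p[0] if np.asarray(points).ndim == 1 else p


# ---------------------------------------------------------------------------
# phantom specification


@dataclass(frozen=True)
class Layer:
    """Composite layer: z interval in μm from the cavity opening."""

    label: str
    top_z: float
    bottom_z: float
    attenuation: float


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic restoration scene.

    The default is a desk-scale 160³-voxel grid (2.56 mm cube at 16 μm)
    holding a 1.6 mm × 1.2 mm cavity; :func:`full_scale_spec` gives the
    full 6 mm × 4 mm cavity on a correspondingly larger grid.  Attenuations
    are arbitrary units on a ladder that keeps tracer spheres radiolucent
    relative to composite: water 100 < bead 400 < dentin 700 < flowable
    1000 < hybrid 1400.
    """

    grid_shape: tuple[int, int, int] = (160, 160, 160)
    voxel_size: float = 16.0
    cavity_diameter: float = 1600.0
    cavity_depth: float = 1200.0
    cavity_top_z: float = 384.0
    tooth_radial_margin: float = 320.0
    layers: tuple[Layer, ...] = ()
    bead_count: int = 300
    bead_diameter_range: tuple[float, float] = (40.0, 70.0)
    bead_attenuation: float = 400.0
    water_attenuation: float = 100.0
    dentin_attenuation: float = 700.0
    composite_attenuation: float = 1000.0  # used when layers is empty
    texture_amplitude: float = 60.0
    texture_sigma_voxels: float = 3.0
    bead_min_spacing: float = 48.0
    wall_clearance: float = 32.0
    noise_sd: float = 0.0
    supersampling: int = 3
    seed: int = 0

    def __post_init__(self):
        nx, ny, nz = self.grid_shape
        vs = self.voxel_size
        if vs <= 0 or min(nx, ny, nz) < 8:
            raise ConfigurationError("grid too small or non-positive voxel size")
        dmin, dmax = self.bead_diameter_range
        if not (0 < dmin <= dmax < self.cavity_diameter):
            raise ConfigurationError(
                "bead_diameter_range must lie within (0, cavity_diameter)"
            )
        for a in (self.bead_attenuation, self.water_attenuation,
                  self.dentin_attenuation, self.composite_attenuation):
            if a < 0:
                raise ConfigurationError("attenuations must be non-negative")
        margin = 10 * vs
        if self.cavity_diameter / 2 + self.tooth_radial_margin + margin > \
                min(nx, ny) * vs / 2:
            raise ConfigurationError(
                "grid too small: cavity + tooth margin needs >= 10 voxels "
                "of clearance on x and y"
            )
        if self.cavity_top_z + self.cavity_depth + margin > nz * vs:
            raise ConfigurationError(
                "grid too small: cavity depth needs >= 10 voxels of "
                "clearance below the floor"
            )
        lays = self.effective_layers()
        prev_bottom = 0.0
        for lay in lays:
            if not (0.0 <= lay.top_z < lay.bottom_z <= self.cavity_depth):
                raise ConfigurationError(
                    f"layer {lay.label!r} interval outside cavity depth"
                )
            if lay.top_z < prev_bottom - 1e-9:
                raise ConfigurationError("layer intervals overlap")
            prev_bottom = lay.bottom_z

    def effective_layers(self) -> tuple[Layer, ...]:
        if self.layers:
            return self.layers
        return (Layer("composite", 0.0, self.cavity_depth,
                      self.composite_attenuation),)

    # geometry helpers -----------------------------------------------------
    @property
    def cavity_axis_xy(self) -> tuple[float, float]:
        nx, ny, _ = self.grid_shape
        return (nx * self.voxel_size / 2.0, ny * self.voxel_size / 2.0)

    @property
    def floor_center(self) -> tuple[float, float, float]:
        cx, cy = self.cavity_axis_xy
        return (cx, cy, self.cavity_top_z + self.cavity_depth)

    @property
    def tooth_radius(self) -> float:
        return self.cavity_diameter / 2.0 + self.tooth_radial_margin

    @property
    def tooth_bottom_z(self) -> float:
        return self.grid_shape[2] * self.voxel_size - 10 * self.voxel_size

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "grid_shape", "voxel_size", "cavity_diameter", "cavity_depth",
            "cavity_top_z", "tooth_radial_margin", "bead_count",
            "bead_diameter_range", "bead_attenuation", "water_attenuation",
            "dentin_attenuation", "composite_attenuation",
            "texture_amplitude", "texture_sigma_voxels", "bead_min_spacing",
            "wall_clearance", "noise_sd", "supersampling", "seed")}
        d["grid_shape"] = list(self.grid_shape)
        d["bead_diameter_range"] = list(self.bead_diameter_range)
        d["layers"] = [
            {"label": l.label, "top_z": l.top_z, "bottom_z": l.bottom_z,
             "attenuation": l.attenuation}
            for l in self.effective_layers()
        ]
        return d


def small_spec(**overrides) -> PhantomSpec:
    """Quick-study preset: 72³ voxels, 0.64 mm cavity, 60 beads."""
    base = dict(
        grid_shape=(72, 72, 72), cavity_diameter=640.0, cavity_depth=640.0,
        cavity_top_z=160.0, tooth_radial_margin=96.0, bead_count=60,
        texture_sigma_voxels=2.0,
    )
    base.update(overrides)
    return PhantomSpec(**base)


def full_scale_spec(**overrides) -> PhantomSpec:
    """Full-scale preset: the 6 mm diameter × 4 mm deep cylindrical cavity."""
    base = dict(
        grid_shape=(440, 440, 320), cavity_diameter=6000.0,
        cavity_depth=4000.0, cavity_top_z=480.0, bead_count=1500,
    )
    base.update(overrides)
    return PhantomSpec(**base)


@dataclass
class GroundTruth:
    """Sampled truth of a phantom pair: sphere trajectories, pose, field.

    ``table`` columns: id, x_pre..z_pre, x_post..z_post (both in the
    pre-scan frame, before the rigid pose), dx, dy, dz, radius_um.
    """

    table: pd.DataFrame
    rigid_pose: RigidTransform
    deformation: DeformationModel
    seed: int

    def __post_init__(self):
        t = self.table
        if t["id"].duplicated().any():
            raise ValueError("GroundTruth ids must be unique")
        for ax in "xyz":
            resid = (t[f"{ax}_post"] - t[f"{ax}_pre"]) - t[f"d{ax}"]
            if len(resid) and float(np.abs(resid.to_numpy()).max()) > 1e-9:
                raise ValueError("true_displacement != post - pre centres")


# ---------------------------------------------------------------------------
# rendering


def rasterize_sphere(volume: Volume, center, radius: float, attenuation: float,
                     supersampling: int = 3) -> Volume:
    """Blend an anti-aliased sphere into ``volume`` (in place).

    Each voxel overlapping the sphere is set to
    ``(1 - f) * old + f * attenuation`` where ``f`` is the voxel's coverage
    fraction estimated from ``supersampling³`` sub-samples, so partial-volume
    voxels take intermediate values exactly as beads do in a real scan.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if supersampling < 1:
        raise ValueError("supersampling must be >= 1")
    c = np.asarray(center, dtype=float)
    vs = volume.voxel_size
    cv = volume.world_to_voxel(c)
    r_vox = radius / vs
    lo = np.floor(cv - r_vox - 0.5).astype(int)
    hi = np.ceil(cv + r_vox + 0.5).astype(int)
    shape = np.asarray(volume.shape)
    if np.any(hi < 0) or np.any(lo > shape - 1):
        warnings.warn(f"sphere at {tuple(c)} μm lies fully outside the grid; "
                      "skipped", stacklevel=2)
        return volume
    lo = np.clip(lo, 0, shape - 1)
    hi = np.clip(hi, 0, shape - 1)
    ix, iy, iz = [np.arange(lo[k], hi[k] + 1) for k in range(3)]
    gx, gy, gz = np.meshgrid(ix, iy, iz, indexing="ij")
    idx = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)
    off1 = (np.arange(supersampling) + 0.5) / supersampling - 0.5
    ox, oy, oz = np.meshgrid(off1, off1, off1, indexing="ij")
    offs = np.stack([ox, oy, oz], axis=-1).reshape(-1, 3)
    # sub-sample world positions: (nvox, nsub, 3)
    pts = volume.origin + (idx[:, None, :] + offs[None, :, :] + 0.5) * vs
    d2 = np.sum((pts - c) ** 2, axis=-1)
    frac = np.mean(d2 <= radius * radius, axis=1)
    sel = frac > 0
    if np.any(sel):
        vals = volume.data[idx[sel, 0], idx[sel, 1], idx[sel, 2]]
        f = frac[sel].astype(volume.data.dtype, copy=False)
        volume.data[idx[sel, 0], idx[sel, 1], idx[sel, 2]] = (
            (1.0 - f) * vals + f * attenuation
        )
    return volume


def _place_beads(spec: PhantomSpec, rng: np.random.Generator):
    """Rejection-sample non-overlapping bead centres inside the composite."""
    cx, cy = spec.cavity_axis_xy
    cav_r = spec.cavity_diameter / 2.0
    layers = spec.effective_layers()
    weights = np.array([l.bottom_z - l.top_z for l in layers], dtype=float)
    weights /= weights.sum()
    dmin, dmax = spec.bead_diameter_range
    centers: list[np.ndarray] = []
    radii: list[float] = []
    for i in range(spec.bead_count):
        r = rng.uniform(dmin, dmax) / 2.0
        placed = False
        for _ in range(10_000):
            lay = layers[rng.choice(len(layers), p=weights)]
            rad_max = cav_r - spec.wall_clearance - r
            z_lo = spec.cavity_top_z + lay.top_z + spec.wall_clearance + r
            z_hi = spec.cavity_top_z + lay.bottom_z - spec.wall_clearance - r
            if rad_max <= 0 or z_hi <= z_lo:
                continue
            x, y = rng.uniform(-rad_max, rad_max, size=2)
            if x * x + y * y > rad_max * rad_max:
                continue
            z = rng.uniform(z_lo, z_hi)
            cand = np.array([cx + x, cy + y, z])
            ok = True
            for c_prev, r_prev in zip(centers, radii):
                if np.sum((cand - c_prev) ** 2) < \
                        (r + r_prev + spec.bead_min_spacing) ** 2:
                    ok = False
                    break
            if ok:
                centers.append(cand)
                radii.append(r)
                placed = True
                break
        if not placed:
            raise PhantomError(
                f"bead placement budget exhausted after {len(centers)} of "
                f"{spec.bead_count} beads"
            )
    return np.asarray(centers), np.asarray(radii)


def _render_scene(spec: PhantomSpec, texture: np.ndarray,
                  bead_centers: np.ndarray, bead_radii: np.ndarray,
                  deformation: DeformationModel | None,
                  pose: RigidTransform | None) -> Volume:
    """Render one scan of the scene.

    ``deformation`` shapes the composite region (material membership is
    tested at the inverse-deformed position); ``bead_centers`` are the
    scene positions of the beads for this scan; ``pose`` is the rigid pose
    of the whole scene relative to the grid (None = identity).
    """
    nx, ny, nz = spec.grid_shape
    vs = spec.voxel_size
    cx, cy = spec.cavity_axis_xy
    cav_r = spec.cavity_diameter / 2.0
    z_top = spec.cavity_top_z
    z_floor = z_top + spec.cavity_depth

    posed = pose is not None and not pose.is_identity(tol=0.0)
    xs = (np.arange(nx) + 0.5) * vs
    ys = (np.arange(ny) + 0.5) * vs
    zs = (np.arange(nz) + 0.5) * vs

    if posed:
        inv = invert(pose)
        A, b = inv.matrix_offset()
        X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
        pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
        q = pts @ A.T + b
        qx = q[:, 0].reshape(nx, ny, nz)
        qy = q[:, 1].reshape(nx, ny, nz)
        qz = q[:, 2].reshape(nx, ny, nz)
        del X, Y, Z, pts, q
    else:
        qx = xs[:, None, None]
        qy = ys[None, :, None]
        qz = zs[None, None, :]

    r2 = (qx - cx) ** 2 + (qy - cy) ** 2
    data = np.full((nx, ny, nz), spec.water_attenuation, dtype=np.float32)

    in_tooth = (r2 <= spec.tooth_radius ** 2) & (qz >= z_top) & \
        (qz <= spec.tooth_bottom_z)
    in_cavity = (r2 <= cav_r ** 2) & (qz >= z_top) & (qz <= z_floor)
    dentin = in_tooth & ~in_cavity
    tex = texture
    if posed:
        # static dentin texture sampled at the inverse-posed position
        coords = np.stack([qx.ravel() / vs - 0.5, qy.ravel() / vs - 0.5,
                           qz.ravel() / vs - 0.5])
        tex = map_coordinates(texture, coords, order=1, mode="nearest"
                              ).reshape(nx, ny, nz)
    data[dentin] = spec.dentin_attenuation + tex[dentin]

    # composite layers; membership tested at the inverse-deformed position
    cav_idx = np.nonzero(in_cavity)
    if cav_idx[0].size:
        if posed:
            pts_cav = np.stack([qx[cav_idx], qy[cav_idx], qz[cav_idx]], axis=1)
        else:
            pts_cav = np.stack([xs[cav_idx[0]], ys[cav_idx[1]],
                                zs[cav_idx[2]]], axis=1)
        if deformation is not None and deformation.kind != "none":
            pre_pts = inverse_deformation(pts_cav, deformation)
        else:
            pre_pts = pts_cav
        pr2 = (pre_pts[:, 0] - cx) ** 2 + (pre_pts[:, 1] - cy) ** 2
        depth = pre_pts[:, 2] - z_top
        inside_cyl = pr2 <= cav_r ** 2
        vals = data[cav_idx]
        for lay in spec.effective_layers():
            m = inside_cyl & (depth >= lay.top_z) & (depth <= lay.bottom_z)
            vals[m] = lay.attenuation
        data[cav_idx] = vals

    vol = Volume(data, np.full(3, vs), np.zeros(3))
    centers = pose.apply(bead_centers) if posed else bead_centers
    for c, r in zip(centers, bead_radii):
        rasterize_sphere(vol, c, r, spec.bead_attenuation,
                         supersampling=spec.supersampling)
    return vol


def generate_phantom(spec: PhantomSpec,
                     deformation: DeformationModel | None = None,
                     rigid_pose: RigidTransform | None = None,
                     seed: int | None = None
                     ) -> tuple[Volume, Volume, GroundTruth]:
    """Generate a pre/post scan pair and its ground truth.

    The pre scan is the undeformed scene plus noise; the post scan is the
    scene with each bead displaced by the deformation field, the composite
    region reshaped consistently, the whole scene rigidly re-posed, and an
    independent noise draw added (two physical scans never share noise).
    Identical ``(spec, deformation, rigid_pose, seed)`` give bit-identical
    outputs.
    """
    if deformation is None:
        deformation = DeformationModel(kind="none")
    if seed is None:
        seed = spec.seed
    ss = np.random.SeedSequence(seed)
    rng_place, rng_tex, rng_pre, rng_post = \
        [np.random.default_rng(s) for s in ss.spawn(4)]

    centers_pre, radii = _place_beads(spec, rng_place)
    disp = evaluate_deformation(centers_pre, deformation)
    centers_post = centers_pre + disp

    texture = np.zeros(spec.grid_shape, dtype=np.float32)
    if spec.texture_amplitude > 0:
        raw = rng_tex.standard_normal(spec.grid_shape)
        smooth = gaussian_filter(raw, spec.texture_sigma_voxels)
        smooth /= max(smooth.std(), 1e-12)
        texture = (spec.texture_amplitude * smooth).astype(np.float32)

    pre = _render_scene(spec, texture, centers_pre, radii,
                        deformation=None, pose=None)
    post = _render_scene(spec, texture, centers_post, radii,
                         deformation=deformation, pose=rigid_pose)

    if spec.noise_sd > 0:
        pre.data += rng_pre.normal(0.0, spec.noise_sd,
                                   pre.shape).astype(np.float32)
        post.data += rng_post.normal(0.0, spec.noise_sd,
                                     post.shape).astype(np.float32)

    table = pd.DataFrame({
        "id": np.arange(len(radii)),
        "x_pre": centers_pre[:, 0], "y_pre": centers_pre[:, 1],
        "z_pre": centers_pre[:, 2],
        "x_post": centers_post[:, 0], "y_post": centers_post[:, 1],
        "z_post": centers_post[:, 2],
        "dx": disp[:, 0], "dy": disp[:, 1], "dz": disp[:, 2],
        "radius_um": radii,
    })
    truth = GroundTruth(table=table,
                        rigid_pose=rigid_pose or RigidTransform(),
                        deformation=deformation, seed=seed)
    return pre, post, truth


def registration_mask(spec: PhantomSpec, dilate_voxels: int = 3,
                      erode_voxels: int = 3) -> np.ndarray:
    """Static-anatomy mask: dentin minus the cavity dilated by ``dilate_voxels``.

    Registration driven by this mask sees only tooth structure, so composite
    shrinkage cannot bias the recovered pose.  The dentin region is eroded
    by ``erode_voxels`` so the mask samples smooth texture interior rather
    than the water/dentin step edges, whose rendered-vs-interpolated
    sharpness would otherwise bias the NCC toward lattice-aligned shifts.
    """
    nx, ny, nz = spec.grid_shape
    vs = spec.voxel_size
    cx, cy = spec.cavity_axis_xy
    xs = (np.arange(nx) + 0.5) * vs
    ys = (np.arange(ny) + 0.5) * vs
    zs = (np.arange(nz) + 0.5) * vs
    r2 = (xs[:, None, None] - cx) ** 2 + (ys[None, :, None] - cy) ** 2
    z = zs[None, None, :]
    ero = erode_voxels * vs
    pad = dilate_voxels * vs + ero
    in_tooth = (r2 <= (spec.tooth_radius - ero) ** 2) & \
        (z >= spec.cavity_top_z + ero) & (z <= spec.tooth_bottom_z - ero)
    cav_r = spec.cavity_diameter / 2.0 + pad
    in_cav = (r2 <= cav_r ** 2) & (z >= spec.cavity_top_z - pad) & \
        (z <= spec.cavity_top_z + spec.cavity_depth + pad)
    return np.broadcast_to(in_tooth & ~in_cav, (nx, ny, nz)).copy()
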