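"""Synthetic tomographic phantoms of cortical bone.

Generates 3D grayscale volumes of a hollow cortical shell (a cylinder with
an optionally eccentric bore) containing ellipsoidal osteocyte lacunae and
straight canal pores, together with voxel-exact ground-truth labels and the
true geometric parameters of every object.  These phantoms stand in for
reconstructed synchrotron micro-CT scans of the mouse femur mid-diaphysis
and make every downstream measurement testable against analytic geometry.

Coordinate convention: voxel indices are 0-based ``(z, y, x)``; the physical
position of a voxel center is ``(i + 0.5) * voxel_size_um``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

# ground-truth phase codes
BACKGROUND = 0
BONE = 1
CANAL = 2
LACUNA = 3

PHASE_NAMES = {BACKGROUND: "background", BONE: "bone", CANAL: "canal", LACUNA: "lacuna"}


class PlacementError(RuntimeError):
    """Raised when lacunae or canals cannot be placed without overlap."""


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensity and noise parameters of a synthetic shell phantom.

    Lengths are in voxels unless suffixed ``_um``.  ``lacuna_semi_axes``
    ``(a, b, c)`` must satisfy ``a >= b >= c > 0``; ``a`` is aligned with
    ``lacuna_orientation`` (a unit vector in ``(z, y, x)`` order, or
    ``"random"`` for an independent uniform orientation per lacuna).
    ``lacuna_placement`` is either ``"poisson"`` (rejection sampling with a
    minimum surface gap of 2 voxels) or a lattice spacing ``(dz, dy, dx)``.
    """

    outer_radius: float = 40.0
    inner_radius: float = 30.0
    height: int = 60
    shell_center_offset: tuple[float, float] = (0.0, 0.0)  # (y, x) bore offset
    n_lacunae: int = 50
    lacuna_semi_axes: tuple[float, float, float] = (5.0, 2.0, 2.0)
    lacuna_orientation: tuple[float, float, float] | Literal["random"] = (1.0, 0.0, 0.0)
    lacuna_placement: tuple[float, float, float] | Literal["poisson"] = "poisson"
    n_canals: int = 2
    canal_radius: float = 3.0
    intensity_bone: float = 200.0
    intensity_pore: float = 20.0
    noise_sigma: float = 0.0
    voxel_size_um: float = 1.4
    seed: int = 0

    def validate(self) -> None:
        a, b, c = self.lacuna_semi_axes
        if not (self.inner_radius < self.outer_radius):
            raise ValueError(
                f"inner_radius ({self.inner_radius}) must be < outer_radius "
                f"({self.outer_radius})"
            )
        if not (a >= b >= c > 0):
            raise ValueError(f"lacuna semi-axes must satisfy a >= b >= c > 0, got {a, b, c}")
        if self.n_lacunae < 0 or self.n_canals < 0 or self.height < 1:
            raise ValueError("counts must be >= 0 and height >= 1")
        if self.voxel_size_um <= 0:
            raise ValueError("voxel_size_um must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class GroundTruth:
    """Voxel-exact truth for a phantom: phase labels, object IDs, parameters.

    ``object_labels`` is 0 for non-pore voxels; lacunae and canals share one
    positive ID space.  ``objects`` has one row per object with columns
    ``id, class, cz, cy, cx`` (voxel-center physical units of voxels, i.e.
    index + 0.5), semi-axes ``a, b, c`` and orientation ``oz, oy, ox``.
    """

    phase_labels: np.ndarray
    object_labels: np.ndarray
    objects: pd.DataFrame
    bone_voxel_count: int = 0


@dataclass
class VoxelVolume:
    """A 3D grayscale image with isotropic voxel size in micrometres."""

    data: np.ndarray
    voxel_size_um: float
    ground_truth: GroundTruth | None = None
    provenance: str = "phantom"

    def __post_init__(self) -> None:
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("volume must be 3D with every axis >= 1")
        if self.voxel_size_um <= 0:
            raise ValueError("voxel_size_um must be > 0")
        if self.ground_truth is not None and self.ground_truth.phase_labels.shape != self.data.shape:
            raise ValueError("ground truth shape mismatch")


def _unit(v: Sequence[float]) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("orientation vector must be nonzero")
    return v / n


def _rotation_to(axis: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping the local a-axis (1,0,0) in zyx onto ``axis``."""
    a = _unit(axis)
    # pick any vector not parallel to a
    helper = np.array([0.0, 0.0, 1.0]) if abs(a[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    b = np.cross(a, helper)
    b /= np.linalg.norm(b)
    c = np.cross(a, b)
    return np.stack([a, b, c], axis=1)  # columns are the local frame in zyx


def _ellipsoid_mask(shape, center, semi_axes, rot):
    """Boolean mask of voxels whose centers lie inside the rotated ellipsoid."""
    a, b, c = semi_axes
    r = max(semi_axes)
    lo = np.maximum(np.floor(center - r - 1).astype(int), 0)
    hi = np.minimum(np.ceil(center + r + 2).astype(int), shape)
    if np.any(lo >= hi):
        return None, None
    grids = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
    pts = np.stack(grids, axis=-1) + 0.5 - center  # voxel centers relative to center
    local = pts @ rot  # project onto local axes
    inside = (local[..., 0] / a) ** 2 + (local[..., 1] / b) ** 2 + (local[..., 2] / c) ** 2 <= 1.0
    return tuple(slice(l, h) for l, h in zip(lo, hi)), inside


def generate_phantom(spec: PhantomSpec) -> VoxelVolume:
    """Rasterize a hollow-shell phantom with planted lacunae and canals.

    The shell is a digital cylinder (center-of-voxel inclusion test) of outer
    radius ``outer_radius`` whose bore of radius ``inner_radius`` may be
    offset by ``shell_center_offset``.  Lacunae are solid digital ellipsoids
    carved from bone; canals are straight tubes parallel to Z spanning the
    full height.  Identical spec (including seed) gives bit-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    margin = 3
    side = int(np.ceil(2 * (spec.outer_radius + margin)))
    shape = (spec.height, side, side)
    cyx = np.array([side / 2.0, side / 2.0])

    yy, xx = np.meshgrid(np.arange(side) + 0.5, np.arange(side) + 0.5, indexing="ij")
    r2_outer = (yy - cyx[0]) ** 2 + (xx - cyx[1]) ** 2
    bore = cyx + np.asarray(spec.shell_center_offset, dtype=float)
    r2_inner = (yy - bore[0]) ** 2 + (xx - bore[1]) ** 2
    shell2d = (r2_outer <= spec.outer_radius**2) & (r2_inner > spec.inner_radius**2)

    phase = np.zeros(shape, dtype=np.uint8)
    phase[:, shell2d] = BONE

    objects: list[dict] = []
    object_labels = np.zeros(shape, dtype=np.int32)
    next_id = 1

    # --- canals: straight Z tubes whose full cross-section sits in the wall
    canal_rng = np.random.default_rng(rng.integers(2**31))
    canal_centers: list[np.ndarray] = []
    attempts = 0
    while len(canal_centers) < spec.n_canals:
        attempts += 1
        if attempts > 2000:
            raise PlacementError(
                "could not place canals inside the shell wall without overlap "
                "(wall too thin for canal_radius or too many canals)"
            )
        theta = canal_rng.uniform(0, 2 * np.pi)
        rad = canal_rng.uniform(spec.inner_radius + spec.canal_radius + 2,
                                spec.outer_radius - spec.canal_radius - 1)
        cand = cyx + rad * np.array([np.sin(theta), np.cos(theta)])
        # stay clear of the (possibly offset) bore
        if np.linalg.norm(cand - bore) < spec.inner_radius + spec.canal_radius + 2:
            continue
        if any(np.linalg.norm(cand - c) < 2 * spec.canal_radius + 2 for c in canal_centers):
            continue
        canal_centers.append(cand)
    for cc in canal_centers:
        tube2d = ((yy - cc[0]) ** 2 + (xx - cc[1]) ** 2 <= spec.canal_radius**2) & shell2d
        phase[:, tube2d] = CANAL
        object_labels[:, tube2d] = next_id
        objects.append(dict(id=next_id, cls="canal",
                            cz=shape[0] / 2.0, cy=cc[0], cx=cc[1],
                            a=spec.canal_radius, b=spec.canal_radius, c=spec.canal_radius,
                            oz=1.0, oy=0.0, ox=0.0))
        next_id += 1

    # --- lacunae
    a_ax = spec.lacuna_semi_axes[0]
    centers = _lacuna_centers(spec, rng, shape, cyx, bore, canal_centers)
    for ctr in centers:
        if spec.lacuna_orientation == "random":
            sub = np.random.default_rng(rng.integers(2**31))
            v = sub.normal(size=3)
            rot = _rotation_to(v)
            ori = _unit(v)
        else:
            rot = _rotation_to(np.asarray(spec.lacuna_orientation, float))
            ori = _unit(np.asarray(spec.lacuna_orientation, float))
        sl, inside = _ellipsoid_mask(shape, ctr, spec.lacuna_semi_axes, rot)
        if sl is None or not inside.any():
            continue
        region = phase[sl]
        carve = inside & (region == BONE)
        region[carve] = LACUNA
        object_labels[sl][carve] = next_id
        objects.append(dict(id=next_id, cls="lacuna",
                            cz=ctr[0], cy=ctr[1], cx=ctr[2],
                            a=spec.lacuna_semi_axes[0], b=spec.lacuna_semi_axes[1],
                            c=spec.lacuna_semi_axes[2],
                            oz=ori[0], oy=ori[1], ox=ori[2]))
        next_id += 1

    data = np.where(phase == BONE, spec.intensity_bone, spec.intensity_pore).astype(float)
    if spec.noise_sigma > 0:
        data = data + rng.normal(0.0, spec.noise_sigma, size=shape)

    obj_df = pd.DataFrame(objects, columns=["id", "cls", "cz", "cy", "cx",
                                            "a", "b", "c", "oz", "oy", "ox"])
    truth = GroundTruth(phase_labels=phase, object_labels=object_labels,
                        objects=obj_df, bone_voxel_count=int((phase == BONE).sum()))
    return VoxelVolume(data=data, voxel_size_um=spec.voxel_size_um, ground_truth=truth)


def _lacuna_extents(spec):
    """(extent_z, extent_xy): half-extent of one lacuna along Z and in XY.

    Orientation-aware for fixed orientations (tight ellipsoid bounds so
    elongated lacunae fit in thin cortical walls); the bounding sphere a is
    used for random orientations.
    """
    if spec.lacuna_orientation == "random":
        a = spec.lacuna_semi_axes[0]
        return a, a
    rot = _rotation_to(np.asarray(spec.lacuna_orientation, float))
    semis = np.asarray(spec.lacuna_semi_axes)
    # extent along world axis k: sqrt(sum_i (semi_i * frame_i[k])^2)
    ext = np.sqrt(((rot * semis[None, :]) ** 2).sum(axis=1))  # (z, y, x)
    return float(ext[0]), float(np.sqrt(ext[1] ** 2 + ext[2] ** 2))


def _separated(p, others, spec, gap=2.0):
    """Conservative non-touching test of p against all placed lacunae."""
    if not len(others):
        return True
    a, b, c = spec.lacuna_semi_axes
    diff = np.asarray(others) - p
    if spec.lacuna_orientation == "random":
        return bool((np.linalg.norm(diff, axis=1) >= 2 * a + gap).all())
    rot = _rotation_to(np.asarray(spec.lacuna_orientation, float))
    local = diff @ rot  # components along the shared principal axes
    scaled = np.linalg.norm(local / np.array([a, b, c]), axis=1)
    return bool((scaled >= 2.0 + gap / c).all())


def _lacuna_centers(spec, rng, shape, cyx, bore, canal_centers):
    """Candidate lacuna centers, either on a lattice or Poisson with min gap."""
    ez, exy = _lacuna_extents(spec)
    if spec.lacuna_placement != "poisson":
        dz, dy, dx = spec.lacuna_placement
        zs = np.arange(ez + 1, shape[0] - ez - 1, dz)
        ys = np.arange(exy + 1, shape[1] - exy - 1, dy)
        xs = np.arange(exy + 1, shape[2] - exy - 1, dx)
        pts = [np.array([z, y, x]) for z in zs for y in ys for x in xs]
        pts = [p for p in pts if _inside_wall(p, spec, cyx, bore, canal_centers,
                                              ez, exy)]
        if len(pts) < spec.n_lacunae:
            raise PlacementError(
                f"lattice holds only {len(pts)} admissible sites for "
                f"{spec.n_lacunae} lacunae"
            )
        return pts[: spec.n_lacunae]

    centers: list[np.ndarray] = []
    max_attempts = 10000 + 200 * spec.n_lacunae
    attempts = 0
    while len(centers) < spec.n_lacunae:
        attempts += 1
        if attempts > max_attempts:
            raise PlacementError(
                f"placed {len(centers)}/{spec.n_lacunae} lacunae after "
                f"{max_attempts} attempts; shell wall too crowded for "
                f"semi-axes {spec.lacuna_semi_axes} with 2-voxel minimum gap"
            )
        z = rng.uniform(ez + 0.5, shape[0] - ez - 0.5)
        theta = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(spec.inner_radius + exy, spec.outer_radius - exy)
        p = np.array([z, cyx[0] + rad * np.sin(theta), cyx[1] + rad * np.cos(theta)])
        if not _inside_wall(p, spec, cyx, bore, canal_centers, ez, exy):
            continue
        if not _separated(p, centers, spec):
            continue
        centers.append(p)
    return centers


def _inside_wall(p, spec, cyx, bore, canal_centers, ez, exy):
    """True when the lacuna's bounding box around p sits in the bone wall."""
    if p[0] < ez or p[0] > spec.height - ez:
        return False
    ryx = np.linalg.norm(p[1:] - cyx)
    if ryx > spec.outer_radius - exy - 0.5:
        return False
    if np.linalg.norm(p[1:] - bore) < spec.inner_radius + exy + 0.5:
        return False
    for cc in canal_centers:
        if np.linalg.norm(p[1:] - cc) < spec.canal_radius + exy + 1.5:
            return False
    return True


def hollow_cylinder_volume_um3(spec: PhantomSpec) -> float:
    """Analytic bone volume of the shell, π(R_o² − R_i²)·h·voxel³ in μm³."""
    return (
        np.pi
        * (spec.outer_radius**2 - spec.inner_radius**2)
        * spec.height
        * spec.voxel_size_um**3
    )
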