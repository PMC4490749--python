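"""Morphometric phenotypes of cortical bone microstructure.

Computes the per-specimen phenotype vector used for genetic mapping:

* ``Ct.Th.R`` / ``Ct.Th.R.sd`` — radial cortical thickness mean and standard
  deviation, measured along rays cast in polar coordinates from the bone
  centroid of each Z-slice (equal weight per angular bin rather than per
  unit volume, so thick regions are not over-weighted);
* ``Ca.Dn`` / ``Lc.Dn`` — canal and lacuna number densities per mm³ of
  calcified bone;
* ``Lc.V`` — mean lacuna volume (voxel counting, model-free);
* ``Lc.St`` — lacuna stretch, the shape anisotropy 1 − L3/L1 of the
  principal half-lengths, 0 for a sphere and → 1 for extreme rods or plates;
* ``Lc.Dt.Ob`` — lacuna distribution oblateness, the anisotropy type of the
  spatial spacing of lacunae (negative = prolate spacing: close in two
  orthogonal directions; positive = oblate spacing: close in only one).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .phantom import BONE, CANAL, LACUNA
from .segmentation import PhaseSegmentation, PoreComponent

PHENOTYPE_COLUMNS = [
    "ct_th_r_um", "ct_th_r_sd_um", "ca_dn_per_mm3", "lc_dn_per_mm3",
    "lc_v_um3", "lc_st", "lc_dt_ob", "n_lacunae", "n_canals", "bone_volume_mm3",
]


@dataclass
class ObjectMetrics:
    """Shape metrics of one pore object (volumes in μm³, lengths in μm)."""

    id: int
    cls: str
    volume_um3: float
    centroid_um: np.ndarray
    principal_half_lengths_um: tuple[float, float, float]  # L1 >= L2 >= L3
    stretch: float
    degenerate: bool = False


@dataclass
class OblatenessResult:
    value: float | None  # None when undefined (too few lacunae)
    isotropic: bool
    eigenvalues: np.ndarray | None = None


def object_shape_metrics(component: PoreComponent, voxel_size_um: float) -> ObjectMetrics:
    """Volume, centroid and covariance-based principal half-lengths.

    Half-lengths are ``L_i = sqrt(5 λ_i)`` with λ_i the eigenvalues of the
    voxel-center covariance — exact for solid ellipsoids, where the second
    moment along a semi-axis a is a²/5.  Stretch is 1 − L3/L1.
    """
    coords = component.voxels.astype(float) + 0.5  # voxel centers
    n = len(coords)
    if n == 0:
        raise ValueError("empty component")
    volume = n * voxel_size_um**3
    centroid = coords.mean(axis=0) * voxel_size_um
    if n == 1:
        half = voxel_size_um / 2.0
        return ObjectMetrics(component.id, component.cls, volume, centroid,
                             (half, half, half), 0.0, degenerate=True)
    cov = np.cov(coords.T, bias=True)
    # add the voxel's own second moment so a single slab is not flat
    cov += np.eye(3) / 12.0
    lams = np.sort(np.linalg.eigvalsh(cov))[::-1]
    lams = np.clip(lams, 0.0, None)
    L = np.sqrt(5.0 * lams) * voxel_size_um
    stretch = 1.0 - (L[2] / L[0]) if L[0] > 0 else 0.0
    return ObjectMetrics(component.id, component.cls, volume, centroid,
                         tuple(L), float(stretch))


def number_densities(seg: PhaseSegmentation) -> tuple[float, float, float]:
    """(Ca.Dn, Lc.Dn, bone volume): object counts per mm³ of calcified bone."""
    bv = seg.bone_volume_mm3
    if bv <= 0:
        raise ValueError("zero bone volume: densities undefined")
    ca = len(seg.canals()) / bv
    lc = len(seg.lacunae(include_border=True)) / bv
    return ca, lc, bv


def distribution_oblateness(centroids_um: np.ndarray, k_neighbors: int = 6,
                            isotropy_tol: float = 0.05) -> OblatenessResult:
    """Anisotropy type of lacuna spacing from k-nearest-neighbor geometry.

    For every lacuna the unit displacement directions to its k nearest
    neighbors (including any neighbors tied with the k-th distance, so
    regular lattices pool symmetric sets) are pooled into a 3×3
    second-moment tensor with eigenvalues μ1 ≥ μ2 ≥ μ3.  The neighbor cloud
    is the dual of the spacing ellipsoid — directions in which lacunae sit
    close contribute most of the near neighbors — so prolate spacing (close
    in two orthogonal directions, far in one) gives a planar direction
    cloud (μ1 ≈ μ2 ≫ μ3) and oblate spacing a linear one.  We therefore
    report

        Ob = 1 − 2 (μ2 − μ3) / (μ1 − μ3),

    negative for prolate spacing, positive for oblate spacing.  When the
    relative eigenvalue spread (μ1 − μ3)/μ1 is below ``isotropy_tol`` the
    distribution is isotropic and Ob is reported as 0 with a flag.
    """
    pts = np.asarray(centroids_um, dtype=float)
    if len(pts) < k_neighbors + 1:
        return OblatenessResult(value=None, isotropic=False)
    tree = cKDTree(pts)
    # query past k and keep every neighbor tied with the k-th distance, so
    # regular lattices pool symmetric neighbor sets (ties otherwise break
    # the symmetry that makes a cubic lattice exactly isotropic)
    kq = min(len(pts), k_neighbors + 9)
    dist, idx = tree.query(pts, k=kq)
    dk = dist[:, k_neighbors]
    keep = dist[:, 1:] <= dk[:, None] * (1.0 + 1e-9)
    disp = (pts[idx[:, 1:]] - pts[:, None, :])[keep]
    disp = disp / np.linalg.norm(disp, axis=1, keepdims=True)
    tensor = disp.T @ disp / len(disp)
    mus = np.sort(np.linalg.eigvalsh(tensor))[::-1]
    if mus[0] <= 0 or (mus[0] - mus[2]) / mus[0] < isotropy_tol:
        return OblatenessResult(value=0.0, isotropic=True, eigenvalues=mus)
    ob = 1.0 - 2.0 * (mus[1] - mus[2]) / (mus[0] - mus[2])
    return OblatenessResult(value=float(ob), isotropic=False, eigenvalues=mus)


def radial_cortical_thickness(
    seg: PhaseSegmentation,
    n_theta_bins: int = 360,
    solid_thickness: bool = False,
    sample_step: float = 0.25,
    return_profile: bool = False,
):
    """Angle-weighted shell thickness (mean, sd) in μm.

    Per Z-slice the bone-phase centroid is found and ``n_theta_bins`` rays
    are cast outward; thickness(θ, z) is the distance from the innermost to
    the outermost bone crossing along the ray, located to sub-voxel accuracy
    by linear interpolation of the (by default hole-filled) bone mask.  With
    ``solid_thickness`` intra-cortical pores interrupt the shell instead of
    counting as bone.  The mean and sd pool all valid (θ, z) bins with equal
    weight.  Raises when more than half of all bins have no bone crossing.
    """
    phase = seg.phase_labels
    nz, ny, nx = phase.shape
    if solid_thickness:
        mask = (phase == BONE).astype(float)
    else:
        mask = np.isin(phase, (BONE, CANAL, LACUNA)).astype(float)

    thetas = (np.arange(n_theta_bins) + 0.5) * (2 * np.pi / n_theta_bins)
    dirs = np.stack([np.sin(thetas), np.cos(thetas)], axis=1)  # (y, x)
    max_r = float(np.hypot(ny, nx))
    radii = np.arange(0.0, max_r, sample_step)

    thicknesses: list[float] = []
    profile_rows: list[np.ndarray] = []
    n_bins_total = 0
    for z in range(nz):
        bone2d = phase[z] == BONE
        if not bone2d.any():
            continue
        n_bins_total += n_theta_bins
        prof = np.full(n_theta_bins, np.nan)
        cz = np.array(ndimage.center_of_mass(bone2d)) + 0.5  # voxel-center coords
        iy, ix = int(cz[0] - 0.5), int(cz[1] - 0.5)
        if bone2d[iy, ix]:
            # ray origin inside the wall: the shell does not surround its
            # centroid, so no bin of this slice yields a radial thickness
            profile_rows.append(prof)
            continue
        # sample points (theta, r): y = cz0 + r*sin, x = cz1 + r*cos
        ys = cz[0] + radii[None, :] * dirs[:, 0:1]
        xs = cz[1] + radii[None, :] * dirs[:, 1:2]
        vals = ndimage.map_coordinates(mask[z], [ys - 0.5, xs - 0.5],
                                       order=1, mode="constant", cval=0.0)
        inside = vals >= 0.5  # (n_theta, n_r)
        for t in range(n_theta_bins):
            row = inside[t]
            if not row.any():
                continue
            first = int(np.argmax(row))
            last = len(row) - 1 - int(np.argmax(row[::-1]))
            r_in = _refine_crossing(radii, vals[t], first, rising=True)
            r_out = _refine_crossing(radii, vals[t], last, rising=False)
            thicknesses.append(r_out - r_in)
            prof[t] = r_out - r_in
        profile_rows.append(prof)

    if n_bins_total == 0:
        raise ValueError("no slice contains bone")
    if len(thicknesses) < 0.5 * n_bins_total:
        raise ValueError("shell not closed: more than 50% of angular bins have no bone crossing")
    if len(thicknesses) < n_bins_total:
        warnings.warn(
            f"{n_bins_total - len(thicknesses)} of {n_bins_total} angular bins "
            "had no bone crossing and were skipped", stacklevel=2)
    th = np.asarray(thicknesses) * seg.voxel_size_um
    if return_profile:
        # (n_slices, n_theta_bins) in μm, NaN where the bin had no crossing
        return float(th.mean()), float(th.std(ddof=0)), \
            np.asarray(profile_rows) * seg.voxel_size_um
    return float(th.mean()), float(th.std(ddof=0))


def _refine_crossing(radii, vals, idx, rising):
    """Linear sub-sample interpolation of the 0.5 crossing next to idx."""
    if rising:
        j = idx - 1
        if j < 0 or vals[j] >= 0.5:
            return radii[idx]
        frac = (0.5 - vals[j]) / (vals[idx] - vals[j])
        return radii[j] + frac * (radii[idx] - radii[j])
    j = idx + 1
    if j >= len(vals) or vals[j] >= 0.5:
        return radii[idx]
    frac = (vals[idx] - 0.5) / (vals[idx] - vals[j])
    return radii[idx] + frac * (radii[j] - radii[idx])


def assemble_phenotypes(
    seg: PhaseSegmentation,
    n_theta_bins: int = 360,
    k_neighbors: int = 6,
    specimen: str | None = None,
) -> pd.Series:
    """One specimen's phenotype row (see PHENOTYPE_COLUMNS for units).

    Lacuna shape means (Lc.V, Lc.St) pool non-border lacunae; densities count
    every lacuna and canal.  With zero lacunae the lacuna-derived fields are
    NaN while densities are still reported.
    """
    ca_dn, lc_dn, bv = number_densities(seg)
    shape_lacs = seg.lacunae(include_border=False)
    metrics = [object_shape_metrics(c, seg.voxel_size_um) for c in shape_lacs]
    lc_v = float(np.mean([m.volume_um3 for m in metrics])) if metrics else np.nan
    lc_st = float(np.mean([m.stretch for m in metrics])) if metrics else np.nan

    all_lacs = seg.lacunae(include_border=True)
    if all_lacs:
        cents = np.array([
            (c.voxels.astype(float) + 0.5).mean(axis=0) * seg.voxel_size_um
            for c in all_lacs
        ])
        ob = distribution_oblateness(cents, k_neighbors=k_neighbors)
        lc_dt_ob = ob.value if ob.value is not None else np.nan
    else:
        lc_dt_ob = np.nan

    ct_mean, ct_sd = radial_cortical_thickness(seg, n_theta_bins=n_theta_bins)
    row = pd.Series(
        {
            "ct_th_r_um": ct_mean,
            "ct_th_r_sd_um": ct_sd,
            "ca_dn_per_mm3": ca_dn,
            "lc_dn_per_mm3": lc_dn,
            "lc_v_um3": lc_v,
            "lc_st": lc_st,
            "lc_dt_ob": lc_dt_ob,
            "n_lacunae": len(all_lacs),
            "n_canals": len(seg.canals()),
            "bone_volume_mm3": bv,
        }
    )
    row.name = specimen
    return row
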