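"""Phase segmentation and pore labeling of cortical-bone volumes.

Splits a grayscale volume into background, calcified bone and intra-cortical
pores, then labels pore connected components and classifies them into canals
and osteocyte lacunae by volume.  Pores are defined as non-bone voxels that
are enclosed by the bone shell: each Z-slice of the bone mask is hole-filled
in 2D (so the medullary bore and intra-cortical cavities count as "inside"),
and pore = filled − bone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .phantom import BACKGROUND, BONE, CANAL, LACUNA, VoxelVolume

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class PoreComponent:
    id: int
    cls: str  # "canal" | "lacuna" | "speckle"
    voxels: np.ndarray  # (n, 3) int voxel indices (z, y, x)
    border_touching: bool

    @property
    def voxel_count(self) -> int:
        return len(self.voxels)


@dataclass
class PhaseSegmentation:
    """Per-voxel phase labels plus (after labeling) classified pore objects."""

    phase_labels: np.ndarray
    voxel_size_um: float
    components: list[PoreComponent] = field(default_factory=list)
    discarded_voxels: int = 0

    @property
    def bone_voxel_count(self) -> int:
        return int((self.phase_labels == BONE).sum())

    @property
    def bone_volume_mm3(self) -> float:
        return self.bone_voxel_count * (self.voxel_size_um * 1e-3) ** 3

    def lacunae(self, include_border: bool = True) -> list[PoreComponent]:
        return [c for c in self.components
                if c.cls == "lacuna" and (include_border or not c.border_touching)]

    def canals(self) -> list[PoreComponent]:
        return [c for c in self.components if c.cls == "canal"]


def segment_phases(
    volume: VoxelVolume,
    bone_threshold: float | str = "otsu",
    medullary_min_fraction: float = 0.1,
) -> PhaseSegmentation:
    """Threshold bone and recover the enclosed intra-cortical pores.

    ``bone_threshold`` is a fixed grayscale value or ``"otsu"``.  Bone is
    every voxel at or above the threshold; candidate pores are the non-bone
    voxels inside the per-slice hole-filled bone mask.  The medullary cavity
    is itself a hole in every slice, so the largest candidate pore component
    is returned to background when it exceeds ``medullary_min_fraction`` of
    the filled shell volume — intra-cortical canals and lacunae are orders
    of magnitude smaller than the marrow cavity.  Raises if no voxel reaches
    the threshold.
    """
    data = volume.data
    if bone_threshold == "otsu":
        bone_threshold = float(threshold_otsu(data))
    bone = data >= bone_threshold
    if not bone.any():
        raise ValueError("no bone phase found: no voxel at or above the threshold")

    filled = np.empty_like(bone)
    for z in range(bone.shape[0]):  # slice-wise 2D fill; bore is open along Z
        filled[z] = ndimage.binary_fill_holes(bone[z])

    pore = filled & ~bone
    labels, n = ndimage.label(pore, structure=_STRUCT26)
    if n:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        biggest = int(counts.argmax())
        if counts[biggest] > medullary_min_fraction * int(filled.sum()):
            pore &= labels != biggest

    phase = np.full(volume.data.shape, BACKGROUND, dtype=np.uint8)
    phase[bone] = BONE
    phase[pore] = CANAL  # provisional pore label, refined by label_components
    return PhaseSegmentation(phase_labels=phase, voxel_size_um=volume.voxel_size_um)


def label_components(
    seg: PhaseSegmentation,
    lacuna_volume_range_um3: tuple[float, float] = (50 * 1.4**3, 1000 * 1.4**3),
    min_canal_volume_um3: float = 1000 * 1.4**3,
) -> PhaseSegmentation:
    """Label 26-connected pore components and classify them by volume.

    Components with volume inside ``lacuna_volume_range_um3`` become lacunae,
    those at or above ``min_canal_volume_um3`` become canals, anything else
    is discarded as segmentation speckle.  Components touching the volume
    border are flagged; they stay in the counts (their existence is certain)
    but are excluded from shape statistics downstream.
    """
    lo, hi = lacuna_volume_range_um3
    if not (0 <= lo < hi):
        raise ValueError("lacuna volume range must satisfy 0 <= lo < hi")
    if min_canal_volume_um3 < hi:
        raise ValueError("canal volume threshold overlaps the lacuna range")

    pore = np.isin(seg.phase_labels, (CANAL, LACUNA))
    labels, n = ndimage.label(pore, structure=_STRUCT26)
    voxel_vol = seg.voxel_size_um**3
    shape = np.array(pore.shape)

    comps: list[PoreComponent] = []
    discarded = 0
    phase = seg.phase_labels.copy()
    slices = ndimage.find_objects(labels)
    for idx, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        sub = labels[sl] == idx
        coords = np.argwhere(sub) + [s.start for s in sl]
        vol_um3 = len(coords) * voxel_vol
        border = bool((coords == 0).any() or (coords == shape - 1).any())
        if lo <= vol_um3 < hi:
            cls = "lacuna"
            phase[tuple(coords.T)] = LACUNA
        elif vol_um3 >= min_canal_volume_um3:
            cls = "canal"
            phase[tuple(coords.T)] = CANAL
        else:
            discarded += len(coords)  # speckle: stays a pore voxel, no object
            continue
        comps.append(PoreComponent(id=len(comps) + 1, cls=cls, voxels=coords,
                                   border_touching=border))
    return PhaseSegmentation(phase_labels=phase, voxel_size_um=seg.voxel_size_um,
                             components=comps, discarded_voxels=discarded)


def components_table(seg: PhaseSegmentation):
    """Per-component summary as a DataFrame (id, class, voxel_count, border)."""
    import pandas as pd

    return pd.DataFrame(
        [dict(id=c.id, cls=c.cls, voxel_count=c.voxel_count,
              border_touching=c.border_touching) for c in seg.components]
    )
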