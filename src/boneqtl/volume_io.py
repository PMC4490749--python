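"""Reading and writing volumes, label maps and object tables.

Volumes are stored as multi-page TIFF stacks (one page per Z-slice) with the
voxel size recorded in the ImageDescription tag as JSON; ground-truth object
parameters go to a plain CSV next to the label volume.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .phantom import GroundTruth, VoxelVolume


def write_volume(path: str | Path, volume: VoxelVolume) -> None:
    """Write the grayscale stack; with ground truth, also ``*_labels.tif``
    (phase labels), ``*_objects.tif`` (object IDs) and ``*_objects.csv``."""
    path = Path(path)
    meta = json.dumps({"voxel_size_um": volume.voxel_size_um})
    tifffile.imwrite(path, volume.data.astype(np.float32), description=meta)
    if volume.ground_truth is not None:
        gt = volume.ground_truth
        stem = path.with_suffix("")
        tifffile.imwrite(f"{stem}_labels.tif", gt.phase_labels, description=meta)
        tifffile.imwrite(f"{stem}_objects.tif", gt.object_labels.astype(np.int32),
                         description=meta)
        gt.objects.to_csv(f"{stem}_objects.csv", index=False)


def read_volume(path: str | Path) -> VoxelVolume:
    """Read a grayscale TIFF stack written by :func:`write_volume` (ground
    truth files, when present beside it, are loaded too)."""
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray().astype(float)
        desc = tf.pages[0].tags.get("ImageDescription")
        voxel = 1.0
        if desc is not None:
            try:
                voxel = float(json.loads(desc.value).get("voxel_size_um", 1.0))
            except (ValueError, TypeError):
                pass
    stem = path.with_suffix("")
    labels_path = Path(f"{stem}_labels.tif")
    truth = None
    if labels_path.exists():
        phase = tifffile.imread(labels_path)
        objects_vol = tifffile.imread(f"{stem}_objects.tif")
        objects = pd.read_csv(f"{stem}_objects.csv")
        truth = GroundTruth(phase_labels=phase, object_labels=objects_vol,
                            objects=objects, bone_voxel_count=int((phase == 1).sum()))
    return VoxelVolume(data=data, voxel_size_um=voxel, ground_truth=truth,
                       provenance=str(path))
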