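"""Segmentation: phase recovery, component labeling and classification."""

import numpy as np
import pytest

from boneqtl.phantom import BONE, CANAL, LACUNA, PhantomSpec, VoxelVolume, generate_phantom
from boneqtl.segmentation import label_components, segment_phases


def test_noise_free_segmentation_equals_ground_truth(default_phantom, labeled_default):
    gt = default_phantom.ground_truth.phase_labels
    assert np.array_equal(labeled_default.phase_labels, gt)


def test_noisy_otsu_segmentation_agrees_with_truth():
    spec = PhantomSpec(seed=2, noise_sigma=10.0)
    noisy = generate_phantom(spec)
    clean_gt = generate_phantom(PhantomSpec(seed=2)).ground_truth.phase_labels
    seg = segment_phases(noisy, bone_threshold="otsu")
    seg = label_components(seg)
    assert (seg.phase_labels == clean_gt).mean() >= 0.99


def test_all_background_volume_raises():
    vol = VoxelVolume(data=np.zeros((8, 8, 8)), voxel_size_um=1.4)
    with pytest.raises(ValueError, match="no bone"):
        segment_phases(vol, bone_threshold=100)


def test_component_classification_with_large_canals():
    # thick-walled shell whose canals are ~1e4 voxels: the wide lacuna/canal
    # volume ranges separate the two classes by more than an order of magnitude
    spec = PhantomSpec(outer_radius=60, inner_radius=40, height=64,
                       n_lacunae=40, n_canals=2, canal_radius=7.0, seed=4)
    vol = generate_phantom(spec)
    seg = label_components(
        segment_phases(vol, 110),
        lacuna_volume_range_um3=(50 * 1.4**3, 2000 * 1.4**3),
        min_canal_volume_um3=5000 * 1.4**3,
    )
    assert len(seg.lacunae()) == 40
    assert len(seg.canals()) == 2
    canal_vox = seg.canals()[0].voxel_count
    assert canal_vox == pytest.approx(np.pi * 7**2 * 64, rel=0.05)


def test_speckle_discarded_and_pore_conservation():
    data = np.full((20, 40, 40), 20.0)
    yy, xx = np.meshgrid(np.arange(40) + 0.5, np.arange(40) + 0.5, indexing="ij")
    r2 = (yy - 20) ** 2 + (xx - 20) ** 2
    data[:, (r2 <= 18**2) & (r2 > 8**2)] = 200.0
    data[10, 33, 19:22] = 20.0          # 3-voxel speckle mid-wall (r ~ 13)
    data[5:15, 6:9, 18:21] = 20.0       # a 90-voxel lacuna-sized pore mid-wall
    vol = VoxelVolume(data=data, voxel_size_um=1.4)
    seg = label_components(segment_phases(vol, 110))
    assert len(seg.components) == 1
    assert seg.components[0].cls == "lacuna"
    total_pore = int(np.isin(seg.phase_labels, (CANAL, LACUNA)).sum())
    assert seg.components[0].voxel_count + seg.discarded_voxels == total_pore
    assert seg.discarded_voxels == 3


def test_border_touching_lacuna_flagged_and_counted():
    data = np.full((20, 40, 40), 20.0)
    yy, xx = np.meshgrid(np.arange(40) + 0.5, np.arange(40) + 0.5, indexing="ij")
    r2 = (yy - 20) ** 2 + (xx - 20) ** 2
    data[:, (r2 <= 18**2) & (r2 > 8**2)] = 200.0
    data[0:4, 6:10, 18:22] = 20.0       # mid-wall pore clipped by the z=0 face
    data[8:12, 6:10, 18:22] = 20.0      # interior pore, same size
    vol = VoxelVolume(data=data, voxel_size_um=1.4)
    seg = label_components(segment_phases(vol, 110))
    lacs = seg.lacunae()
    assert len(lacs) == 2
    # brute-force border scan as the oracle for the flag
    for c in lacs:
        on_border = bool((c.voxels == 0).any()
                         or (c.voxels == np.array(data.shape) - 1).any())
        assert c.border_touching == on_border
    assert sorted(c.border_touching for c in lacs) == [False, True]
    assert len(seg.lacunae(include_border=False)) == 1


def test_labeling_invariant_to_whole_voxel_translation(default_phantom):
    seg1 = label_components(segment_phases(default_phantom, 110))
    # in-plane shifts within the 3-voxel padding keep every object interior
    shifted = VoxelVolume(data=np.roll(default_phantom.data, (3, -3), axis=(1, 2)),
                          voxel_size_um=default_phantom.voxel_size_um)
    seg2 = label_components(segment_phases(shifted, 110))
    v1 = sorted(c.voxel_count for c in seg1.components)
    v2 = sorted(c.voxel_count for c in seg2.components)
    assert v1 == v2


def test_ground_truth_objects_biject_to_components(default_phantom, labeled_default):
    gt = default_phantom.ground_truth
    assert len(labeled_default.components) == len(gt.objects)
    # each component's voxels carry exactly one ground-truth object id
    for c in labeled_default.components:
        ids = np.unique(gt.object_labels[tuple(c.voxels.T)])
        assert len(ids) == 1 and ids[0] > 0


def test_invalid_volume_ranges_rejected(labeled_default):
    with pytest.raises(ValueError, match="range"):
        label_components(labeled_default, lacuna_volume_range_um3=(100, 50))
    with pytest.raises(ValueError, match="overlaps"):
        label_components(labeled_default, lacuna_volume_range_um3=(50, 5000),
                         min_canal_volume_um3=1000)
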