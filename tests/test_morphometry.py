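"""Morphometry: shape metrics, densities, oblateness, radial thickness."""

import warnings

import numpy as np
import pytest

from boneqtl.morphometry import (assemble_phenotypes, distribution_oblateness,
                                 number_densities, object_shape_metrics,
                                 radial_cortical_thickness)
from boneqtl.phantom import BONE, PhantomSpec, VoxelVolume, generate_phantom
from boneqtl.segmentation import (PhaseSegmentation, PoreComponent,
                                  label_components, segment_phases)
from conftest import digital_ellipsoid, lattice_points


class TestShapeMetrics:
    def test_sphere_is_round(self):
        m = object_shape_metrics(digital_ellipsoid((8, 8, 8)), 1.0)
        assert m.stretch <= 0.05

    def test_prolate_ellipsoid_stretch(self):
        m = object_shape_metrics(digital_ellipsoid((10, 4, 4)), 1.0)
        assert m.stretch == pytest.approx(0.60, abs=0.05)

    def test_volume_is_voxel_count_times_voxel_volume(self):
        comp = PoreComponent(1, "lacuna", np.argwhere(np.ones((10, 10, 10), bool)),
                             False)
        m = object_shape_metrics(comp, 1.4)
        assert m.volume_um3 == pytest.approx(1000 * 1.4**3)
        assert m.volume_um3 == pytest.approx(2744.0)

    def test_single_voxel_degenerate(self):
        comp = PoreComponent(1, "lacuna", np.array([[3, 3, 3]]), False)
        m = object_shape_metrics(comp, 1.4)
        assert m.stretch == 0.0
        assert m.degenerate

    @pytest.mark.parametrize("orientation", [(1, 0, 0), (0, 1, 0), (1, 1, 0),
                                             (1, 1, 1), (2, 1, 3)])
    def test_stretch_invariant_to_rotation(self, orientation):
        m = object_shape_metrics(
            digital_ellipsoid((10, 4, 4), orientation=orientation), 1.0)
        assert m.stretch == pytest.approx(0.60, abs=0.05)

    def test_stretch_invariant_to_isotropic_scaling(self):
        small = object_shape_metrics(digital_ellipsoid((6, 3, 3)), 1.0)
        large = object_shape_metrics(digital_ellipsoid((12, 6, 6)), 1.0)
        assert small.stretch == pytest.approx(large.stretch, abs=0.05)


class TestDensities:
    def test_density_arithmetic(self, labeled_default, default_phantom):
        ca, lc, bv = number_densities(labeled_default)
        gt = default_phantom.ground_truth
        true_bv = gt.bone_voxel_count * (1.4e-3) ** 3
        assert bv == pytest.approx(true_bv, rel=1e-12)
        assert lc == pytest.approx(50 / true_bv, rel=0.02)
        assert ca == pytest.approx(2 / true_bv, rel=0.02)

    def test_zero_canals_zero_density(self):
        spec = PhantomSpec(n_canals=0, n_lacunae=10, seed=6)
        seg = label_components(segment_phases(generate_phantom(spec), 110))
        ca, lc, _ = number_densities(seg)
        assert ca == 0.0
        assert lc > 0

    def test_zero_bone_volume_raises(self):
        seg = PhaseSegmentation(phase_labels=np.zeros((4, 4, 4), np.uint8),
                                voxel_size_um=1.4)
        with pytest.raises(ValueError, match="bone volume"):
            number_densities(seg)


class TestOblateness:
    def test_prolate_spacing_close_in_two_directions(self):
        # close in y and x, far in z: prolate spacing ellipsoid, Ob < 0
        r = distribution_oblateness(lattice_points((10, 2, 2)))
        assert r.value < 0

    def test_oblate_spacing_close_in_one_direction(self):
        r = distribution_oblateness(lattice_points((2, 10, 10)))
        assert r.value > 0

    @pytest.mark.parametrize("n", [6, 8])
    def test_signs_deterministic_across_lattice_sizes(self, n):
        assert distribution_oblateness(lattice_points((10, 2, 2), n)).value < 0
        assert distribution_oblateness(lattice_points((2, 10, 10), n)).value > 0

    def test_cubic_lattice_isotropic(self):
        r = distribution_oblateness(lattice_points((4, 4, 4)))
        assert r.isotropic
        assert r.value == 0.0

    def test_too_few_centroids_undefined(self):
        r = distribution_oblateness(np.random.default_rng(0).normal(size=(5, 3)))
        assert r.value is None


class TestRadialThickness:
    def _cylinder_seg(self, offset=(0.0, 0.0), wedge_deg=None):
        spec = PhantomSpec(n_lacunae=0, n_canals=0, shell_center_offset=offset,
                           height=20, seed=0)
        vol = generate_phantom(spec)
        if wedge_deg is not None:
            side = vol.data.shape[1]
            yy, xx = np.meshgrid(np.arange(side) + 0.5, np.arange(side) + 0.5,
                                 indexing="ij")
            ang = np.degrees(np.arctan2(yy - side / 2, xx - side / 2)) % 360
            vol.data[:, ang < wedge_deg] = 20.0
        return segment_phases(vol, 110), spec

    def test_concentric_cylinder_constant_thickness(self):
        seg, spec = self._cylinder_seg()
        mean, sd = radial_cortical_thickness(seg)
        vox = spec.voxel_size_um
        assert mean == pytest.approx(10 * vox, abs=0.5 * vox)
        assert sd <= 0.5 * vox

    @pytest.mark.parametrize("bins", [16, 90, 360])
    def test_mean_independent_of_bin_count(self, bins):
        seg, spec = self._cylinder_seg()
        mean, _ = radial_cortical_thickness(seg, n_theta_bins=bins)
        assert mean == pytest.approx(10 * spec.voxel_size_um,
                                     abs=0.5 * spec.voxel_size_um)

    def test_eccentric_cylinder_matches_continuous_oracle(self):
        offset = (5.0, 0.0)
        seg, spec = self._cylinder_seg(offset=offset)
        vox = spec.voxel_size_um
        n_bins = 72
        mean, sd, profile = radial_cortical_thickness(seg, n_theta_bins=n_bins,
                                                      return_profile=True)
        assert sd > 1.0 * vox

        # continuous oracle: ray casting against the two circles
        side = seg.phase_labels.shape[1]
        A_o = np.pi * spec.outer_radius**2
        A_i = np.pi * spec.inner_radius**2
        c_out = np.array([side / 2, side / 2])
        c_in = c_out + np.asarray(offset)
        centroid = (A_o * c_out - A_i * c_in) / (A_o - A_i)

        def crossing(center, radius, origin, u):
            d = center - origin
            b = u @ d
            disc = b**2 - d @ d + radius**2
            return b + np.sqrt(disc)

        thetas = (np.arange(n_bins) + 0.5) * 2 * np.pi / n_bins
        per_bin = []
        for t in thetas:
            u = np.array([np.sin(t), np.cos(t)])
            per_bin.append(crossing(c_out, spec.outer_radius, centroid, u)
                           - crossing(c_in, spec.inner_radius, centroid, u))
        oracle = np.asarray(per_bin) * vox
        measured = np.nanmean(profile, axis=0)  # per-angle profile over slices
        assert np.nanmax(np.abs(measured - oracle)) <= 1.0 * vox

    def test_wedge_removed_bins_skipped_with_warning(self):
        seg, spec = self._cylinder_seg(wedge_deg=30)
        with pytest.warns(UserWarning, match="angular bins"):
            mean, _ = radial_cortical_thickness(seg)
        assert mean == pytest.approx(10 * spec.voxel_size_um,
                                     abs=0.5 * spec.voxel_size_um)

    def test_open_shell_errors(self):
        seg, _ = self._cylinder_seg(wedge_deg=300)
        with pytest.raises(ValueError, match="shell not closed"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                radial_cortical_thickness(seg)


class TestAssemble:
    def test_identical_lacunae_have_no_stretch_dispersion(self, labeled_default):
        metrics = [object_shape_metrics(c, 1.4)
                   for c in labeled_default.lacunae(include_border=False)]
        stretches = [m.stretch for m in metrics]
        assert np.std(stretches) < 0.03  # identical shapes, voxelization only

    def test_lacuna_volume_conservation(self, labeled_default):
        row = assemble_phenotypes(labeled_default)
        lacs = labeled_default.lacunae(include_border=False)
        total = sum(c.voxel_count for c in lacs) * 1.4**3
        assert row.lc_v_um3 * len(lacs) == pytest.approx(total, rel=1e-12)

    def test_zero_lacunae_reports_densities_only(self):
        spec = PhantomSpec(n_lacunae=0, n_canals=2, seed=8)
        seg = label_components(segment_phases(generate_phantom(spec), 110))
        row = assemble_phenotypes(seg)
        assert np.isnan(row.lc_v_um3) and np.isnan(row.lc_st)
        assert row.ca_dn_per_mm3 > 0
        assert row.n_lacunae == 0
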