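"""Phantom generator: population sampling, rendering, noise, ground truth."""

import numpy as np
import pytest

from ovamap.phantom import (PackingError, PhantomIntensities, PhantomSpec,
                            TrueFollicle, VolumeCapError, add_noise,
                            build_phantom, render_follicle,
                            sample_follicle_population)
from ovamap.rubric import DEFAULT_RUBRIC
from ovamap.volio import VoxelVolume

SMALL_ORGAN = dict(organ_semi_axes=(350.0, 310.0, 260.0), voxel_size=2.0,
                   vessel_specs=())


class TestSpecValidation:
    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(per_stage_counts={"T5": -1})

    def test_bias_needs_valid_sector(self):
        with pytest.raises(ValueError, match="bias_sector"):
            PhantomSpec(placement_mode="sector_biased", bias_sector="D-IX")

    def test_bias_factor_below_one_rejected(self):
        with pytest.raises(ValueError, match="bias_factor"):
            PhantomSpec(bias_factor=0.5)


class TestSampling:
    def test_zero_counts_give_empty_population(self):
        spec = PhantomSpec(per_stage_counts={})
        assert sample_follicle_population(spec, seed=0) == []

    def test_single_t8_matches_printed_range(self):
        spec = PhantomSpec(per_stage_counts={"T8": 1})
        (f,) = sample_follicle_population(spec, seed=2)
        assert 321.0 - 2 * 21.3 <= f.diameter <= 321.0 + 2 * 21.3
        assert f.n_antra == 1
        assert f.has_zp

    def test_morphology_flags_per_stage(self):
        spec = PhantomSpec(per_stage_counts={"T4": 3, "T5": 3, "T6": 3,
                                             "T7": 3, "T8": 3, "CL": 2})
        pop = sample_follicle_population(spec, seed=4)
        for f in pop:
            assert f.has_zp == (f.stage in ("T5", "T6", "T7", "T8"))
            if f.stage in ("T4", "T5", "CL"):
                assert f.n_antra == 0
            elif f.stage == "T6":
                assert f.n_antra >= 2
            else:
                assert f.n_antra == 1
        # diameters inside each stage's +/-2 SD support
        for f in pop:
            if f.stage == "CL":
                assert 280 <= f.diameter <= 450
            else:
                lo, hi = DEFAULT_RUBRIC.support(f.stage)
                assert lo <= f.diameter <= hi

    def test_deterministic_and_nonoverlapping(self):
        spec = PhantomSpec()
        a = sample_follicle_population(spec, seed=1)
        b = sample_follicle_population(spec, seed=1)
        assert a == b
        centers = np.array([f.center for f in a])
        radii = np.array([f.radius for f in a])
        d = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
        lim = radii[:, None] + radii[None, :]
        np.fill_diagonal(d, np.inf)
        assert (d >= lim).all(), "follicle spheres overlap"

    def test_spheres_inside_organ(self):
        spec = PhantomSpec()
        pop = sample_follicle_population(spec, seed=6)
        semi = np.array(spec.organ_semi_axes)
        off = spec.pad_voxels * spec.voxel_size + semi
        for f in pop:
            c = np.array(f.center) - off
            # conservative containment: centre inside eroded ellipsoid
            assert ((c / (semi - f.radius)) ** 2).sum() <= 1.0 + 1e-9

    def test_cortex_placement_for_early_stages(self):
        spec = PhantomSpec(per_stage_counts={"T4": 30, "T5": 30})
        pop = sample_follicle_population(spec, seed=8)
        semi = np.array(spec.organ_semi_axes)
        off = spec.pad_voxels * spec.voxel_size + semi
        rho = np.array([
            np.sqrt((((np.array(f.center) - off) / semi) ** 2).sum())
            for f in pop
        ])
        assert (rho >= 1 - spec.cortex_fraction - 1e-9).all()

    def test_bias_factor_one_reproduces_homogeneous_exactly(self):
        base = PhantomSpec(per_stage_counts={"T5": 50})
        biased = PhantomSpec(per_stage_counts={"T5": 50},
                             placement_mode="sector_biased",
                             bias_sector="D-I", bias_factor=1.0)
        assert (sample_follicle_population(base, seed=3)
                == sample_follicle_population(biased, seed=3))

    def test_bias_shifts_counts_toward_sector(self):
        biased = PhantomSpec(per_stage_counts={"T5": 400},
                             placement_mode="sector_biased",
                             bias_sector="V-II", bias_factor=4.0)
        pop = sample_follicle_population(biased, seed=5)
        n_biased = sum(f.sector_true == "V-II" for f in pop)
        # homogeneous share would be 1/8; the x4 density target (4/11) is
        # partly eroded by non-overlap saturation at this packing fraction
        assert n_biased / len(pop) > 0.2

    def test_overfull_request_is_refused(self):
        spec = PhantomSpec(organ_semi_axes=(300.0, 300.0, 300.0),
                           per_stage_counts={"CL": 50})
        with pytest.raises(PackingError, match="infeasible"):
            sample_follicle_population(spec, seed=0)

    def test_unplaceable_follicle_names_stage(self):
        # volume budget is fine (19%) but the flat axis cannot hold a T8
        spec = PhantomSpec(organ_semi_axes=(420.0, 380.0, 140.0),
                           per_stage_counts={"T8": 1})
        with pytest.raises(PackingError, match="T8"):
            sample_follicle_population(spec, seed=0)

    def test_homogeneous_sector_counts_calibrated(self):
        """Chi-square homogeneity over 8 sectors rejects at ~5% across seeds."""
        from ovamap.calibration import placement_chisquare_pvalues
        pvals = placement_chisquare_pvalues(
            n_seeds=200, n_follicles=240, seed=5, diameter_scale=0.2)
        rate = float((pvals < 0.05).mean())
        # 99% binomial band around 0.05 at n=200
        half = 2.5758 * np.sqrt(0.05 * 0.95 / 200)
        assert 0.05 - half <= rate <= 0.05 + half


def _follicle(stage, diameter, n_antra=0, frac=0.0, zp=False):
    return TrueFollicle(id=1, stage=stage, center=(0, 0, 0),
                        diameter=diameter, has_zp=zp, n_antra=n_antra,
                        antrum_fraction=frac, sector_true="D-I")


class TestRenderFollicle:
    def test_t5_has_no_antrum_voxels(self):
        patch, mask = render_follicle(_follicle("T5", 89.0, zp=True), 1.5)
        ints = PhantomIntensities()
        assert (patch[mask] == ints.antrum).sum() == 0
        assert (patch[mask] == ints.zp).sum() > 0

    def test_t6_cavities_are_disconnected(self):
        from scipy import ndimage
        f = _follicle("T6", 137.0, n_antra=3, zp=True)
        patch, mask = render_follicle(f, 1.5)
        ints = PhantomIntensities()
        _, n = ndimage.label(patch == ints.antrum)
        assert n == 3

    def test_t8_antrum_is_single_large_cavity(self):
        from scipy import ndimage
        f = _follicle("T8", 321.0, n_antra=1, frac=0.4, zp=True)
        patch, mask = render_follicle(f, 1.5)
        ints = PhantomIntensities()
        antrum = patch == ints.antrum
        _, n = ndimage.label(antrum)
        assert n == 1
        assert antrum.sum() / mask.sum() >= 0.3

    def test_cl_is_homogeneous(self):
        patch, mask = render_follicle(_follicle("CL", 300.0), 1.5)
        ints = PhantomIntensities()
        assert set(np.unique(patch[mask])) == {ints.cl}

    def test_t4_contrast_reduced(self):
        patch4, m4 = render_follicle(_follicle("T4", 53.2), 1.5)
        patch5, m5 = render_follicle(_follicle("T5", 53.2, zp=True), 1.5)
        assert patch4[m4].mean() < patch5[m5].mean()


class TestBuildPhantom:
    def test_empty_spec_gives_organ_only(self):
        spec = PhantomSpec(per_stage_counts={}, **SMALL_ORGAN)
        vol, gt = build_phantom(spec)
        assert gt.label_volume.max() == 0
        ints = spec.intensities
        inside = vol.data[gt.organ_mask]
        assert set(np.unique(inside)) <= {ints.stroma, ints.cortex}

    def test_labels_match_analytic_sphere_volume(self, seg_phantom):
        spec, vol, gt = seg_phantom
        for f in gt.follicles:
            nvox = int((gt.label_volume == f.id).sum())
            analytic = np.pi / 6 * f.diameter**3 / spec.voxel_size**3
            assert abs(nvox - analytic) / analytic < 0.15

    def test_vessel_tube_rendered_dark(self):
        from ovamap.phantom import VesselSpec
        spec = PhantomSpec(
            per_stage_counts={}, organ_semi_axes=(200.0, 180.0, 160.0),
            voxel_size=2.0,
            vessel_specs=(VesselSpec(
                path=((208.0, 188.0, 8.0), (208.0, 188.0, 328.0)),
                diameter=150.0),),
        )
        vol, gt = build_phantom(spec)
        ints = spec.intensities
        n_vessel = int((vol.data == ints.vessel).sum())
        assert n_vessel > 0
        # cross-section area ~ pi r^2 with r = 37.5 voxels
        from ovamap.segment import measure_diameter
        d = measure_diameter(vol.data == ints.vessel, 2.0, "cross_section")
        assert abs(d - 150.0) <= 2 * 2.0

    def test_size_cap_guard(self):
        spec = PhantomSpec(size_cap_voxels=1000)
        with pytest.raises(VolumeCapError, match="cap"):
            build_phantom(spec)


class TestAddNoise:
    def test_zero_sd_identity(self):
        vol = VoxelVolume(np.full((8, 8, 8), 100, dtype=np.uint8), 1.5)
        out = add_noise(vol, 0.0, seed=1)
        assert np.array_equal(out.data, vol.data)

    def test_same_seed_identical(self):
        vol = VoxelVolume(np.full((16, 16, 16), 100, dtype=np.uint8), 1.5)
        a = add_noise(vol, 5.0, seed=42)
        b = add_noise(vol, 5.0, seed=42)
        assert np.array_equal(a.data, b.data)
        c = add_noise(vol, 5.0, seed=43)
        assert not np.array_equal(a.data, c.data)

    def test_sample_sd_matches_requested(self):
        vol = VoxelVolume(np.full((100, 100, 100), 128, dtype=np.uint8), 1.5)
        out = add_noise(vol, 5.0, seed=9)
        sd = out.data.astype(float).std()
        assert 4.5 <= sd <= 5.5  # rounding adds var 1/12; clipping negligible
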