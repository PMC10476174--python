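"""Image-quantification operators on phantoms with known ground truth."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

from embryowet.quantify import (
    LabeledVolume,
    aspect_ratio,
    count_labels,
    diameter_at,
    embryo_length,
    front_speed,
    kymograph_fronts,
    measure_contact_angle,
    middle_axis_length,
    tissue_volume,
)
from embryowet.synthetic import (
    gen_cell_population,
    gen_front_profiles,
    gen_phantom_volume,
    gen_tube_phantom,
)
from embryowet.wetting import ConfinementGeometry, InterfacialTensions, equilibrium_in_cylinder


def render_cylinder_droplet(theta_deg, r=50.0, V=6e5, spacing=(0.3, 0.3, 1.0)):
    delta = -math.cos(math.radians(theta_deg))
    geom = ConfinementGeometry.cylinder(r)
    eq = equilibrium_in_cylinder(V, r, InterfacialTensions.from_delta(delta)).stable
    vol, truth = gen_phantom_volume(eq, geom, spacing=spacing)
    return vol, truth, geom


class TestContactAngle:
    def test_flat_interface(self):
        vol, truth, geom = render_cylinder_droplet(90.0)
        theta, table = measure_contact_angle(vol, geom, center_xy=truth["center_xy_um"])
        assert theta == pytest.approx(90.0, abs=2.0)
        assert table["theta_deg"].notna().sum() >= 3

    def test_rendered_cap_recovery(self):
        vol, truth, geom = render_cylinder_droplet(60.0)
        theta, _ = measure_contact_angle(vol, geom, center_xy=truth["center_xy_um"])
        assert theta == pytest.approx(60.0, abs=5.0)

    def test_top_and_bottom_sides_agree_in_cylinder(self):
        # cylinder caps are symmetric, so both contact lines share the angle
        vol, truth, geom = render_cylinder_droplet(120.0)
        bottom, _ = measure_contact_angle(vol, geom, side="bottom", center_xy=truth["center_xy_um"])
        top, _ = measure_contact_angle(vol, geom, side="top", center_xy=truth["center_xy_um"])
        assert bottom == pytest.approx(120.0, abs=5.0)
        assert top == pytest.approx(120.0, abs=5.0)

    def test_too_few_valid_azimuths_errors(self):
        geom = ConfinementGeometry.cylinder(50.0)
        empty = LabeledVolume(np.zeros((20, 40, 40), dtype=np.uint8), spacing=(1.0, 1.0, 1.0))
        with pytest.raises(ValueError, match="azimuth"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                measure_contact_angle(empty, geom)


class TestMiddleAxis:
    def test_straight_tube_length(self):
        vol, truth = gen_tube_phantom("straight", length_um=150.0, tube_radius_um=12.0)
        axis = middle_axis_length(vol, truth["poles_um"])
        assert axis.arc_length == pytest.approx(150.0, abs=2.0)

    def test_path_stays_on_centerline(self):
        from scipy.spatial import cKDTree

        vol, truth = gen_tube_phantom("straight", length_um=120.0, tube_radius_um=10.0)
        axis = middle_axis_length(vol, truth["poles_um"])
        d, _ = cKDTree(truth["centerline_um"]).query(axis.path_points)
        assert d.max() <= math.sqrt(3.0)  # within one voxel of the true centerline

    def test_arc_length_at_least_pole_distance(self):
        vol, truth = gen_tube_phantom("quarter_torus", bend_radius_um=80.0, tube_radius_um=10.0)
        axis = middle_axis_length(vol, truth["poles_um"])
        pole_dist = np.linalg.norm(truth["poles_um"][1] - truth["poles_um"][0])
        assert axis.arc_length >= pole_dist

    def test_disconnected_poles_raise(self):
        data = np.zeros((40, 11, 11), dtype=np.uint8)
        data[2:10, 4:7, 4:7] = 1
        data[30:38, 4:7, 4:7] = 1
        vol = LabeledVolume(data, spacing=(1.0, 1.0, 1.0))
        with pytest.raises(ValueError, match="not connected"):
            middle_axis_length(vol, [[5.0, 5.0, 5.0], [5.0, 5.0, 35.0]])

    def test_far_pole_rejected(self):
        vol, truth = gen_tube_phantom("straight", length_um=60.0, tube_radius_um=8.0)
        far = truth["poles_um"][0] + np.array([40.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="from the mask"):
            middle_axis_length(vol, [far, truth["poles_um"][1]], snap_radius=5.0)

    def test_spacing_representation_invariance(self):
        vol1, t1 = gen_tube_phantom("straight", length_um=100.0, tube_radius_um=10.0, spacing=(1.0, 1.0, 1.0))
        vol2, t2 = gen_tube_phantom("straight", length_um=100.0, tube_radius_um=10.0, spacing=(0.5, 0.5, 0.5))
        a1 = middle_axis_length(vol1, t1["poles_um"]).arc_length
        a2 = middle_axis_length(vol2, t2["poles_um"]).arc_length
        assert abs(a1 - a2) / a1 < 0.02


class TestDiameter:
    def test_straight_tube_diameter(self):
        vol, truth = gen_tube_phantom("straight", length_um=120.0, tube_radius_um=40.0, spacing=(1, 1, 1))
        axis = middle_axis_length(vol, truth["poles_um"])
        mid = 0.5 * (truth["poles_um"][0] + truth["poles_um"][1])
        d = diameter_at(vol, axis, [mid + [40, 0, 0], mid - [40, 0, 0]])
        assert d == pytest.approx(80.0, abs=2.0)

    def test_tilted_tube_same_diameter(self):
        # 30°-tilted straight tube: orthogonality handling keeps the diameter
        from scipy.spatial import cKDTree

        ang = math.radians(30.0)
        s = np.linspace(0.0, 120.0, 601)
        ctr = np.column_stack([s * math.sin(ang), np.zeros_like(s), s * math.cos(ang)])
        lo = ctr.min(axis=0) - 30.0
        hi = ctr.max(axis=0) + 30.0
        xs = np.arange(lo[0], hi[0], 1.0)
        ys = np.arange(lo[1], hi[1], 1.0)
        zs = np.arange(lo[2], hi[2], 1.0)
        Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij")
        pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
        dist, _ = cKDTree(ctr).query(pts, workers=-1)
        data = (dist.reshape(Z.shape) <= 20.0).astype(np.uint8)
        vol = LabeledVolume(data, spacing=(1.0, 1.0, 1.0))
        poles = [ctr[0] - lo, ctr[-1] - lo]
        axis = middle_axis_length(vol, poles)
        mid = 0.5 * (poles[0] + poles[1])
        d = diameter_at(vol, axis, [mid + [10, 10, 0], mid - [10, 10, 0]])
        assert d == pytest.approx(40.0, rel=0.02)

    def test_elliptical_section_area_equivalent(self):
        # elliptical cylinder a=50, b=40: area-equivalent diameter 2 sqrt(ab)
        a, b, h = 50.0, 40.0, 60.0
        xs = np.arange(-60.0, 60.0, 1.0)
        ys = np.arange(-60.0, 60.0, 1.0)
        zs = np.arange(0.0, h, 1.0)
        ell = ((xs[None, None, :] / a) ** 2 + (ys[None, :, None] / b) ** 2) <= 1.0
        data = np.broadcast_to(ell, (len(zs), len(ys), len(xs))).astype(np.uint8)
        vol = LabeledVolume(data.copy(), spacing=(1.0, 1.0, 1.0))
        poles = [[60.0, 60.0, 0.0], [60.0, 60.0, h - 1.0]]
        axis = middle_axis_length(vol, poles)
        d = diameter_at(vol, axis, [[110.0, 60.0, h / 2], [10.0, 60.0, h / 2]])
        assert d == pytest.approx(2 * math.sqrt(a * b), rel=0.02)


class TestEmbryoLength:
    def make_nuclei(self, rows):
        return pd.DataFrame(rows, columns=["lineage", "x_um", "y_um", "z_um"])

    def test_axial_distance(self):
        n = self.make_nuclei([("TB", 0, 0, 0), ("pTE", 0, 0, 100)])
        assert embryo_length(n) == pytest.approx(100.0)

    def test_lateral_offset_ignored(self):
        n = self.make_nuclei([("TB", 0, 0, 0), ("pTE", 30, 0, 100)])
        assert embryo_length(n) == pytest.approx(100.0)

    def test_matches_brute_force_on_cloud(self, rng):
        pts = rng.uniform(-50, 50, (40, 3))
        lin = np.where(np.arange(40) % 2 == 0, "TB", "pTE")
        n = pd.DataFrame({"lineage": lin, "x_um": pts[:, 0], "y_um": pts[:, 1], "z_um": pts[:, 2]})
        got = embryo_length(n)
        tb = pts[lin == "TB", 2]
        pte = pts[lin == "pTE", 2]
        expect = max(tb.max() - pte.min(), pte.max() - tb.min())
        assert got == pytest.approx(expect)

    def test_missing_lineage(self):
        n = self.make_nuclei([("TB", 0, 0, 0)])
        with pytest.raises(ValueError, match="pTE"):
            embryo_length(n)


class TestKymograph:
    def test_static_front_zero_displacement(self):
        profiles, positions, times, _ = gen_front_profiles(speed_um_per_h=0.0, noise=0.0, seed=1)
        kymo = kymograph_fronts(profiles, positions, times)
        assert np.nanmax(np.abs(kymo["displacement_um"])) < 0.5

    def test_elongation_rate_recovery(self):
        profiles, positions, times, truth = gen_front_profiles(seed=2)
        kymo = kymograph_fronts(profiles, positions, times)
        assert front_speed(kymo) == pytest.approx(truth["speed_um_per_h"], rel=0.05)

    def test_step_noise_robustness(self):
        profiles, positions, times, truth = gen_front_profiles(noise=0.0, seed=3)
        rng = np.random.default_rng(0)
        # isolated impulse corruption (the 3-point median filter's design case)
        spikes = np.zeros(profiles.shape, dtype=bool)
        spikes[..., ::5] = rng.uniform(size=profiles[..., ::5].shape) < 0.15
        noisy = np.where(spikes, rng.uniform(0.0, 1.5, profiles.shape), profiles)
        kymo = kymograph_fronts(noisy, positions, times)
        expected = truth["start_um"] + truth["speed_um_per_h"] * times
        # per-frame tracked front stays near the true edge despite impulses
        assert np.nanmax(np.abs(kymo["front_um"].to_numpy() - expected)) < 2.0


class TestAspectRatio:
    def test_cuboid(self):
        data = np.zeros((30, 30, 30), dtype=np.int32)
        data[5:25, 10:20, 10:20] = 1  # 10x10x20 μm at unit spacing
        df = aspect_ratio(LabeledVolume(data, spacing=(1.0, 1.0, 1.0)))
        assert df.loc[0, "aspect_ratio"] == pytest.approx(0.5)

    def test_sphere(self):
        zs, ys, xs = np.ogrid[:41, :41, :41]
        data = (((zs - 20) ** 2 + (ys - 20) ** 2 + (xs - 20) ** 2) <= 15**2).astype(np.int32)
        df = aspect_ratio(LabeledVolume(data, spacing=(1.0, 1.0, 1.0)))
        assert df.loc[0, "aspect_ratio"] == pytest.approx(1.0, abs=0.05)

    @pytest.mark.parametrize("ratio", [1.2, 0.8, 0.5])
    def test_columnarizing_population(self, ratio):
        vol, truth = gen_cell_population(ratio, n_cells=9)
        df = aspect_ratio(vol)
        assert len(df) == 9
        assert df["aspect_ratio"].mean() == pytest.approx(ratio, rel=0.10)


class TestCountsAndVolumes:
    def test_count_labels(self):
        data = np.zeros((10, 30, 30), dtype=np.int32)
        for lab in range(1, 58):
            data.flat[lab * 31] = lab
        assert count_labels(LabeledVolume(data, spacing=(1, 1, 1))) == 57

    def test_sphere_volume(self):
        r = 20.0
        zs, ys, xs = np.ogrid[:81, :81, :81]
        data = ((((zs - 40) * 0.5) ** 2 + ((ys - 40) * 0.5) ** 2 + ((xs - 40) * 0.5) ** 2) <= r**2)
        vol = LabeledVolume(data.astype(np.uint8), spacing=(0.5, 0.5, 0.5))
        assert tissue_volume(vol) == pytest.approx(4.0 / 3.0 * math.pi * r**3, rel=0.015)

    def test_growth_factor_between_rendered_volumes(self):
        # synthetic epiblast growth: volume ratio 1.78 over 8 h
        from embryowet.synthetic import EPI_GROWTH_RATE_PER_H

        factor = math.exp(EPI_GROWTH_RATE_PER_H * 8.0)
        r1 = 15.0
        r2 = r1 * factor ** (1.0 / 3.0)

        def sphere(r):
            n = int(2 * r / 0.5) + 9
            c = (n - 1) / 2.0
            zs, ys, xs = np.ogrid[:n, :n, :n]
            d = (((zs - c) * 0.5) ** 2 + ((ys - c) * 0.5) ** 2 + ((xs - c) * 0.5) ** 2) <= r**2
            return LabeledVolume(d.astype(np.uint8), spacing=(0.5, 0.5, 0.5))

        ratio = tissue_volume(sphere(r2)) / tissue_volume(sphere(r1))
        assert ratio == pytest.approx(1.78, abs=0.05)


class TestIO:
    def test_tiff_roundtrip(self, tmp_path):
        vol = LabeledVolume(np.arange(24, dtype=np.uint16).reshape(2, 3, 4), spacing=(0.295, 0.295, 1.0))
        path = tmp_path / "vol.tif"
        vol.to_tiff(path)
        back = LabeledVolume.from_tiff(path)
        np.testing.assert_array_equal(back.data, vol.data)
        assert back.spacing == vol.spacing

    def test_h5_roundtrip(self, tmp_path):
        vol = LabeledVolume(np.ones((3, 4, 5), dtype=np.uint8), spacing=(1.0, 1.0, 2.0))
        path = tmp_path / "vol.h5"
        vol.to_h5(path)
        back = LabeledVolume.from_h5(path)
        np.testing.assert_array_equal(back.data, vol.data)
        assert back.spacing == vol.spacing
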