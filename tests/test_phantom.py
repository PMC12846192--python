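"""Simulator: curves, dipole physics, depth observations, augmentation,
datasets."""

import dataclasses

import numpy as np
import pytest

from magwire.geometry import CenterlineCloud
from magwire.phantom import (
    FAMILIES,
    DipoleSource,
    RigidPose,
    Sample,
    SensorFrame,
    ShapeSpec,
    SimulatorConfig,
    augment_sample,
    default_sensor_layout,
    dipole_field,
    generate_curve,
    generate_dataset,
    load_dataset,
    render_guidewire_image,
    save_dataset,
    simulate_relative_depth,
    simulate_sensor_frame,
    split_sizes,
)
from magwire.phantom import _wire_sources


class TestCurves:
    def test_families_produce_expected_turning(self):
        # left bends turn one way, right bends the other, s-shape changes sign
        def turning(pts):
            d = np.diff(pts, axis=0)
            cross = d[:-1, 0] * d[1:, 1] - d[:-1, 1] * d[1:, 0]
            return cross

        base = dict(curvature_scale=1.0, length_mm=80.0, pose=RigidPose(tilt=0.0))
        for fam, sign in [("left_bend", -1.0), ("right_bend", 1.0), ("large_left_curvature", -1.0)]:
            pts = generate_curve(ShapeSpec(fam, **base), seed=3, n_points=64).points
            tr = turning(pts[:, [0, 2]])  # curve lives in the (e_u, e_v) = (x, z) plane
            assert np.all(np.sign(tr) == sign), fam
        tr = turning(generate_curve(ShapeSpec("s_shape", **base), seed=3, n_points=64).points[:, [0, 2]])
        assert (tr[:5] < 0).all() != (tr[-5:] < 0).all()  # sign change along the wire

    def test_uniform_arc_spacing(self):
        c = generate_curve(ShapeSpec("s_shape"), seed=0, n_points=100)
        seg = np.linalg.norm(np.diff(c.points, axis=0), axis=1)
        assert np.ptp(seg) / seg.mean() < 1e-3

    def test_length_approximately_requested(self):
        spec = ShapeSpec("left_bend", length_mm=75.0)
        c = generate_curve(spec, seed=1, n_points=200)
        assert abs(c.total_length() - 75.0) < 0.75

    def test_curve_seeded_reproducible(self):
        a = generate_curve(ShapeSpec("right_bend"), seed=5, n_points=32).points
        b = generate_curve(ShapeSpec("right_bend"), seed=5, n_points=32).points
        assert np.array_equal(a, b)

    def test_unknown_family_raises(self):
        with pytest.raises(ValueError):
            ShapeSpec("zigzag")

    def test_large_left_has_larger_curvature(self):
        def total_turn(pts):
            d = np.diff(pts[:, [0, 2]], axis=0)
            ang = np.arctan2(d[:, 1], d[:, 0])
            return np.abs(np.unwrap(ang)[-1] - ang[0])

        base = dict(curvature_scale=1.0, length_mm=80.0, pose=RigidPose(tilt=0.0))
        small = total_turn(generate_curve(ShapeSpec("left_bend", **base), 2, 64).points)
        big = total_turn(generate_curve(ShapeSpec("large_left_curvature", **base), 2, 64).points)
        assert big > 1.5 * small


class TestDipole:
    def test_inverse_cube_decay(self):
        src = DipoleSource((0.0, 0.0, 0.0), (0.0, 0.0, 0.5))
        dists = np.geomspace(20.0, 400.0, 12)
        mags = [np.linalg.norm(dipole_field(src, (0.0, d / np.sqrt(2), d / np.sqrt(2)))) for d in dists]
        slope = np.polyfit(np.log(dists), np.log(mags), 1)[0]
        assert abs(slope + 3.0) < 1e-6

    def test_on_axis_field_direction_and_value(self):
        # on the moment axis: B = 2 * (mu0/4pi) * m / d^3
        from magwire.phantom import MU0_OVER_4PI_MM_UT

        src = DipoleSource((0.0, 0.0, 0.0), (0.0, 0.0, 0.5))
        B = dipole_field(src, (0.0, 0.0, 100.0))
        assert np.allclose(B[:2], 0.0)
        assert B[2] == pytest.approx(2.0 * MU0_OVER_4PI_MM_UT * 0.5 / 100.0**3)

    def test_equatorial_field_antiparallel_half(self):
        from magwire.phantom import MU0_OVER_4PI_MM_UT

        src = DipoleSource((0.0, 0.0, 0.0), (0.0, 0.0, 0.5))
        B = dipole_field(src, (100.0, 0.0, 0.0))
        assert B[2] == pytest.approx(-MU0_OVER_4PI_MM_UT * 0.5 / 100.0**3)

    def test_zero_moment_rejected(self):
        with pytest.raises(ValueError):
            DipoleSource((0, 0, 0), (0.0, 0.0, 0.0))

    def test_singularity_rejected(self):
        src = DipoleSource((1.0, 2.0, 3.0))
        with pytest.raises(ValueError):
            dipole_field(src, (1.0, 2.0, 3.0))

    def test_superposition(self):
        s1 = DipoleSource((0, 0, 0), (0, 0, 0.3))
        s2 = DipoleSource((10, 0, 0), (0.2, 0, 0))
        layout = default_sensor_layout()
        _, both = simulate_sensor_frame([s1, s2], layout)
        _, a = simulate_sensor_frame([s1], layout)
        _, b = simulate_sensor_frame([s2], layout)
        assert np.allclose(both, a + b, atol=1e-15)

    def test_noise_monte_carlo_converges(self):
        src = DipoleSource((0, 0, 100.0), (0, 0, 0.5))
        layout = default_sensor_layout()
        _, clean = simulate_sensor_frame([src], layout)
        acc = np.zeros_like(clean)
        n = 400
        for s in range(n):
            frame, _ = simulate_sensor_frame([src], layout, noise_sd=0.05, seed=s)
            acc += frame.readings
        err = np.abs(acc / n - clean).max()
        assert err < 0.05 * 4 / np.sqrt(n) * 3  # ~3 sigma of the mean


class TestSensorLayout:
    def test_layout_shape_and_plane(self):
        pos = default_sensor_layout(30.0, 260.0)
        assert pos.shape == (16, 3)
        assert np.all(pos[:, 2] == 260.0)
        assert np.ptp(pos[:, 0]) == pytest.approx(90.0)

    def test_frame_validation(self):
        with pytest.raises(ValueError):
            SensorFrame(np.zeros((15, 3)), np.zeros((15, 3)))

    def test_frame_csv_roundtrip(self, tmp_path):
        src = DipoleSource((5, -3, 120.0), (0.1, 0.2, 0.3))
        frame, _ = simulate_sensor_frame([src], default_sensor_layout(), noise_sd=0.01, seed=1)
        p = tmp_path / "f.csv"
        frame.to_csv(p)
        back = SensorFrame.from_csv(p)
        assert np.allclose(back.positions, frame.positions)
        assert np.allclose(back.readings, frame.readings, rtol=1e-10)


class TestRelativeDepth:
    def test_affine_map_when_clean(self):
        c = generate_curve(ShapeSpec("left_bend"), seed=0, n_points=32)
        z = simulate_relative_depth(c, ambiguity=(1.7, -12.0))
        assert np.allclose(z, 1.7 * c.points[:, 2] - 12.0)

    def test_order_preserved_when_clean(self):
        c = generate_curve(ShapeSpec("s_shape", pose=RigidPose(tilt=0.2)), seed=1, n_points=32)
        z = simulate_relative_depth(c, ambiguity=(0.8, 5.0))
        assert np.array_equal(np.argsort(z), np.argsort(c.points[:, 2]))

    def test_distortion_bounded_and_smooth(self):
        c = generate_curve(ShapeSpec("s_shape", pose=RigidPose(tilt=0.2)), seed=1, n_points=64)
        z = simulate_relative_depth(c, ambiguity=(1.0, 0.0), distortion_rel=0.4, seed=3)
        resid = z - c.points[:, 2]
        assert np.abs(resid).max() <= 0.4 * c.points[:, 2].std() + 1e-9
        # smoothness: consecutive residual differences are small
        assert np.abs(np.diff(resid)).max() < 0.2 * c.points[:, 2].std()

    def test_nonpositive_scale_rejected(self):
        c = generate_curve(ShapeSpec("left_bend"), seed=0, n_points=8)
        with pytest.raises(ValueError):
            simulate_relative_depth(c, ambiguity=(0.0, 0.0))

    def test_seeded_noise_reproducible(self):
        c = generate_curve(ShapeSpec("left_bend"), seed=0, n_points=16)
        a = simulate_relative_depth(c, noise_sd=0.5, seed=9)
        b = simulate_relative_depth(c, noise_sd=0.5, seed=9)
        assert np.array_equal(a, b)


class TestWireSources:
    def test_tangent_alignment_and_grading(self):
        cfg = SimulatorConfig(n_points=64)
        c = generate_curve(ShapeSpec("left_bend"), seed=0, n_points=64)
        sources = _wire_sources(c, cfg)
        assert len(sources) == 3
        mags = [np.linalg.norm(s.moment) for s in sources]
        assert mags == sorted(mags, reverse=True)  # tip strongest
        # moments align with the local tangent
        t0 = c.points[1] - c.points[0]
        cos = np.dot(sources[0].moment, t0) / (np.linalg.norm(sources[0].moment) * np.linalg.norm(t0))
        assert cos > 0.99

    def test_mismatched_config_raises(self):
        cfg = SimulatorConfig(source_fractions=(0.0, 1.0), moment_magnitudes=(1.0,))
        c = generate_curve(ShapeSpec("left_bend"), seed=0, n_points=16)
        with pytest.raises(ValueError):
            _wire_sources(c, cfg)


def _base_sample():
    ds = generate_dataset(1, SimulatorConfig(n_points=32), master_seed=4)
    return ds.samples[0]


class TestAugmentation:
    def test_expansion_count_282_to_1128(self):
        # counting contract on a tiny stand-in: 4 variants per base sample
        smp = _base_sample()
        group = augment_sample(smp, seed=0)
        assert len(group) == 4
        assert 282 * len(group) == 1128

    def test_flip_is_physically_exact(self):
        from magwire.phantom import _flip, simulate_sensor_frame

        smp = _base_sample()
        flipped = _flip(smp)
        # re-simulating the flipped scene's clean field at the flipped
        # sensors reproduces the transformed clean readings exactly
        _, clean = simulate_sensor_frame(flipped.sources, flipped.frame.positions)
        assert np.allclose(clean, flipped.frame_clean, atol=1e-12)

    def test_flip_involution(self):
        from magwire.phantom import _flip

        smp = _base_sample()
        twice = _flip(_flip(smp))
        assert np.array_equal(twice.cloud.points, smp.cloud.points)
        assert np.array_equal(twice.frame.readings, smp.frame.readings)

    def test_rotation_is_physically_exact(self):
        from magwire.phantom import _rotate, simulate_sensor_frame

        smp = _base_sample()
        rot = _rotate(smp, 0.3)
        _, clean = simulate_sensor_frame(rot.sources, rot.frame.positions)
        assert np.allclose(clean, rot.frame_clean, atol=1e-10)

    def test_rotation_preserves_depth(self):
        from magwire.phantom import _rotate

        smp = _base_sample()
        rot = _rotate(smp, 0.4)
        assert np.allclose(rot.cloud.points[:, 2], smp.cloud.points[:, 2])
        assert np.array_equal(rot.z_img, smp.z_img)

    def test_scale_is_physically_exact(self):
        from magwire.phantom import _scale, simulate_sensor_frame

        smp = _base_sample()
        sc = _scale(smp, 1.25)
        _, clean = simulate_sensor_frame(sc.sources, sc.frame.positions)
        assert np.allclose(clean, sc.frame_clean, rtol=1e-12)
        assert np.allclose(sc.cloud.points, 1.25 * smp.cloud.points)
        assert np.allclose(sc.z_img, 1.25 * smp.z_img)

    def test_augment_seeded_reproducible(self):
        smp = _base_sample()
        a = augment_sample(smp, seed=3)
        b = augment_sample(smp, seed=3)
        for x, y in zip(a, b):
            assert np.array_equal(x.frame.readings, y.frame.readings)


class TestDataset:
    def test_split_sizes_721(self):
        assert split_sizes(300) == (210, 60, 30)
        assert split_sizes(1128) == (789, 225, 114)
        n_train, n_val, n_test = split_sizes(10)
        assert n_train + n_val + n_test == 10

    def test_generate_deterministic(self):
        cfg = SimulatorConfig(n_points=16)
        a = generate_dataset(6, cfg, master_seed=2)
        b = generate_dataset(6, cfg, master_seed=2)
        assert a.manifest == b.manifest
        for x, y in zip(a.samples, b.samples):
            assert np.array_equal(x.cloud.points, y.cloud.points)
            assert np.array_equal(x.frame.readings, y.frame.readings)
            assert np.array_equal(x.z_img, y.z_img)

    def test_different_seeds_differ(self):
        cfg = SimulatorConfig(n_points=16)
        a = generate_dataset(3, cfg, master_seed=1)
        b = generate_dataset(3, cfg, master_seed=2)
        assert not np.array_equal(a.samples[0].cloud.points, b.samples[0].cloud.points)

    def test_split_partition(self):
        ds = generate_dataset(20, SimulatorConfig(n_points=8), master_seed=0)
        s = ds.manifest["splits"]
        all_idx = sorted(s["train"] + s["val"] + s["test"])
        assert all_idx == list(range(20))

    def test_augmented_dataset_count(self):
        ds = generate_dataset(5, SimulatorConfig(n_points=8), master_seed=0, augment=True)
        assert len(ds) == 20
        kinds = [r["augmentation"] for r in ds.manifest["samples"]]
        assert kinds[:4] == ["original", "flip", "rotate", "scale"]

    def test_negative_control_fields_uninformative(self):
        cfg = SimulatorConfig(n_points=8, magnetic_informative=False)
        ds = generate_dataset(2, cfg, master_seed=0)
        assert np.all(ds.samples[0].frame_clean == 0.0)

    def test_save_load_roundtrip(self, tmp_path):
        ds = generate_dataset(3, SimulatorConfig(n_points=8), master_seed=1)
        save_dataset(ds, tmp_path / "d")
        back = load_dataset(tmp_path / "d")
        assert len(back) == 3
        assert back.manifest["splits"] == ds.manifest["splits"]
        for x, y in zip(ds.samples, back.samples):
            assert np.allclose(x.cloud.points, y.cloud.points, atol=1e-9)
            assert np.allclose(x.frame.readings, y.frame.readings, rtol=1e-9)

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            generate_dataset(0)
        with pytest.raises(ValueError):
            generate_dataset(1, SimulatorConfig(n_points=1))


class TestRendering:
    def test_rendered_wire_is_dark_on_bright(self):
        from magwire.phantom import default_intrinsics

        ds = generate_dataset(1, SimulatorConfig(n_points=32), master_seed=7)
        img = render_guidewire_image(ds.samples[0].cloud, default_intrinsics(), shape=(512, 512))
        assert img.dtype == np.uint8
        assert (img == 10).sum() > 50  # wire pixels present
        assert np.median(img) == 200  # bright background
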