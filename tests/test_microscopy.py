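"""Full image assembly: modalities, contrast, focus estimation, scanning."""

from dataclasses import replace

import numpy as np
import pytest

from iscatsim.imaging import OpticalTrain, focus_beam
from iscatsim.layers import LayerStack, PlaneWaveSpec, brewster_angle
from iscatsim.materials import air, glass, gold, water
from iscatsim.microscopy import (
    MicroscopeConfig,
    MieSphereSpec,
    PointDipoleSpec,
    add_noise,
    brewster_sweep,
    focus_correlate,
    ipsf,
    iscat_contrast,
    michelson_contrast,
    partial_coherence,
    scan_image,
    simulate_image,
    system_magnification,
)


@pytest.fixture(scope="module")
def au_air_cfg(air_glass, oil_train):
    """55 nm gold sphere in air, 5 nm above glass, 517 nm, 14 deg tilt."""
    ill = PlaneWaveSpec(517.0, 14.0, 0.0, "TM", "up")
    return MicroscopeConfig(
        "iscat", air_glass, ill, oil_train,
        MieSphereSpec((0, 0, 32.5), 55.0, gold()),
        fov_nm=3900, n_pixels=64,
    )


@pytest.fixture(scope="module")
def dipole_cfg(air_glass, oil_train):
    ill = PlaneWaveSpec(517.0, 14.0, 0.0, "TM", "up")
    return MicroscopeConfig(
        "iscat", air_glass, ill, oil_train,
        PointDipoleSpec((0, 0, 30.0), 30.0, gold()),
        fov_nm=3900, n_pixels=64,
    )


class TestSimulateImage:
    def test_no_particle_camera_equals_reference(self, air_glass, oil_train):
        ill = PlaneWaveSpec(517.0, 14.0, 0.0, "TM", "up")
        cfg = MicroscopeConfig(
            "iscat", air_glass, ill, oil_train, None, fov_nm=2000, n_pixels=32
        )
        camera, ref, sca = simulate_image(cfg)
        np.testing.assert_array_equal(camera.intensity, ref.intensity)
        assert np.all(sca.intensity == 0)

    def test_camera_is_coherent_sum(self, au_air_cfg):
        camera, ref, sca = simulate_image(au_air_cfg, 200.0)
        expected = np.sum(np.abs(ref.field + sca.field) ** 2, axis=-1)
        np.testing.assert_allclose(camera.intensity, expected, atol=1e-12)

    def test_modality_illumination_consistency(self, air_glass, oil_train):
        ill_up = PlaneWaveSpec(517.0, 0.0, 0.0, "TM", "up")
        with pytest.raises(ValueError, match="COBRI"):
            MicroscopeConfig("cobri", air_glass, ill_up, oil_train, None)
        ill_dn = PlaneWaveSpec(517.0, 0.0, 0.0, "TM", "down")
        with pytest.raises(ValueError, match="iSCAT"):
            MicroscopeConfig("iscat", air_glass, ill_dn, oil_train, None)

    def test_darkfield_is_scattered_intensity(self, air_glass, oil_train):
        ill = PlaneWaveSpec(517.0, 14.0, 0.0, "TM", "up")
        cfg = MicroscopeConfig(
            "darkfield", air_glass, ill, oil_train,
            MieSphereSpec((0, 0, 32.5), 55.0, gold()), fov_nm=2000, n_pixels=32,
        )
        camera, ref, sca = simulate_image(cfg)
        np.testing.assert_array_equal(camera.intensity, sca.intensity)
        assert ref.power() == 0.0

    def test_cobri_shares_pipeline_with_flipped_direction(self, water_glass, oil_train):
        """COBRI = same code with the illumination rotated 180 deg and the
        transmitted beam as reference."""
        ill = PlaneWaveSpec(520.0, 0.0, 0.0, "TM", "down")
        cfg = MicroscopeConfig(
            "cobri", water_glass, ill, oil_train,
            MieSphereSpec((0, 0, 25.0), 40.0, gold()), fov_nm=2000, n_pixels=32,
        )
        camera, ref, sca = simulate_image(cfg)
        # transmitted reference: |t|^2 of the water->glass interface
        from iscatsim.layers import fresnel

        t = fresnel(water_glass, 0.0, "TM", 520.0, "down")[1]
        assert ref.intensity.mean() == pytest.approx(abs(t) ** 2, rel=1e-6)
        assert sca.power() > 0

    def test_off_axis_fringes_are_directional(self, au_air_cfg):
        """Tilted illumination breaks the x mirror symmetry of the
        defocused interference pattern (fringe directionality)."""
        camera, ref, _ = simulate_image(au_air_cfg, 800.0)
        v = iscat_contrast(camera, ref).values
        asym = np.abs(v - v[:, ::-1]).max() / np.abs(v).max()
        assert asym > 0.2
        cfg0 = replace(
            au_air_cfg, illumination=replace(au_air_cfg.illumination, polar_angle_deg=0.0)
        )
        camera0, ref0, _ = simulate_image(cfg0, 800.0)
        v0 = iscat_contrast(camera0, ref0).values
        asym0 = np.abs(v0 - v0[:, ::-1]).max() / np.abs(v0).max()
        assert asym0 < 1e-8


class TestContrast:
    def test_zero_scattering_zero_contrast(self, air_glass, oil_train):
        ill = PlaneWaveSpec(517.0, 14.0, 0.0, "TM", "up")
        cfg = MicroscopeConfig(
            "iscat", air_glass, ill, oil_train, None, fov_nm=2000, n_pixels=16
        )
        camera, ref, _ = simulate_image(cfg)
        cm = iscat_contrast(camera, ref)
        np.testing.assert_allclose(cm.values, 0.0, atol=1e-14)

    def test_quadrature_phase_leaves_pure_scattering_term(self, au_air_cfg):
        """Where the reference/scattered phase is +/- pi/2 the interference
        term vanishes: contrast = |E_sca|^2 exactly."""
        camera, ref, sca = simulate_image(au_air_cfg, 300.0)
        cm = iscat_contrast(camera, ref)
        quad = np.abs(np.abs(cm.phase) - np.pi / 2) < 0.01
        assert quad.sum() > 10
        np.testing.assert_allclose(
            cm.values[quad], sca.intensity[quad],
            atol=0.03 * np.abs(cm.values).max(),
        )

    def test_contrast_identity_expansion(self, au_air_cfg):
        """camera - |ref|^2 = 2 |ref||sca| cos(phi) + |sca|^2 per pixel."""
        camera, ref, sca = simulate_image(au_air_cfg, -400.0)
        cm = iscat_contrast(camera, ref)
        cross = 2 * np.real(
            np.einsum("yxc,yxc->yx", ref.field, np.conj(sca.field))
        )
        np.testing.assert_allclose(
            cm.values, cross + sca.intensity, atol=1e-10 * np.abs(cm.values).max()
        )
        # and the phase map is consistent with the cross term via the
        # polarization inner product (vector fields: |inner| <= |ref||sca|)
        inner = np.einsum("yxc,yxc->yx", ref.field, np.conj(sca.field))
        np.testing.assert_allclose(
            cross, 2 * np.abs(inner) * np.cos(cm.phase), atol=1e-10 * np.abs(inner).max()
        )

    def test_normalized_variant_rejected_for_dark_reference(self, air_glass, oil_train):
        ill = PlaneWaveSpec(517.0, 14.0, 0.0, "TM", "up")
        cfg = MicroscopeConfig(
            "darkfield", air_glass, ill, oil_train,
            MieSphereSpec((0, 0, 32.5), 55.0, gold()), fov_nm=2000, n_pixels=16,
        )
        camera, ref, _ = simulate_image(cfg)
        with pytest.raises(ValueError, match="dark"):
            iscat_contrast(camera, ref, normalized=True)


class TestIPSF:
    def test_requires_point_dipole(self, au_air_cfg):
        with pytest.raises(ValueError, match="point-dipole"):
            ipsf(au_air_cfg)

    def test_in_focus_on_axis_inversion_symmetry(self, air_glass, oil_train):
        ill = PlaneWaveSpec(517.0, 0.0, 0.0, "TM", "up")
        cfg = MicroscopeConfig(
            "iscat", air_glass, ill, oil_train,
            PointDipoleSpec((0, 0, 30.0), 30.0, gold()), fov_nm=2600, n_pixels=64,
        )
        cm = ipsf(cfg, 0.0)
        v = cm.values
        np.testing.assert_allclose(
            v, v[::-1, ::-1], atol=1e-9 * np.abs(v).max()
        )

    def test_small_mie_sphere_matches_ipsf(self, dipole_cfg):
        """A d <= 20 nm Mie sphere reproduces the point-dipole contrast to
        a couple of percent pixelwise."""
        d = 20.0
        cfg_dip = replace(
            dipole_cfg, scatterer=PointDipoleSpec((0, 0, 30.0), d, gold())
        )
        cfg_mie = replace(
            dipole_cfg, scatterer=MieSphereSpec((0, 0, 30.0), d, gold())
        )
        cm_d = ipsf(cfg_dip, 300.0)
        cam, ref, _ = simulate_image(cfg_mie, 300.0)
        cm_m = iscat_contrast(cam, ref)
        scale = np.abs(cm_d.values).max()
        assert np.abs(cm_m.values - cm_d.values).max() < 0.02 * scale

    def test_defocus_sign_flips_phase_progression(self, dipole_cfg):
        """The radial phase winding of the interference reverses between
        over- and underfocus (conjugate-defocus behaviour)."""
        cm_p = ipsf(dipole_cfg, +600.0)
        cm_m = ipsf(dipole_cfg, -600.0)
        n = dipole_cfg.n_pixels // 2
        prof_p = np.unwrap(cm_p.phase[n, n:])
        prof_m = np.unwrap(cm_m.phase[n, n:])
        slope_p = prof_p[12] - prof_p[2]
        slope_m = prof_m[12] - prof_m[2]
        assert np.sign(slope_p) != np.sign(slope_m)


class TestMichelson:
    def test_constant_image_zero(self):
        assert michelson_contrast(np.ones((8, 8))) == 0.0

    def test_zero_pixel_gives_one(self):
        I = np.ones((8, 8))
        I[3, 3] = 0.0
        assert michelson_contrast(I) == 1.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            michelson_contrast(np.zeros((4, 4)))

    def test_bounded_for_simulated_images(self, au_air_cfg):
        camera, _, _ = simulate_image(au_air_cfg, 500.0)
        m = michelson_contrast(camera)
        assert 0.0 <= m <= 1.0


class TestBrewster:
    @pytest.fixture(scope="class")
    def sweep_cfg(self, water_glass, oil_train):
        ill = PlaneWaveSpec(520.0, 40.0, 0.0, "TM", "up")
        return MicroscopeConfig(
            "iscat", water_glass, ill, oil_train,
            MieSphereSpec((0, 0, 25.0), 40.0, gold()), fov_nm=2600, n_pixels=48,
        )

    def test_te_rejected(self, sweep_cfg):
        cfg = replace(
            sweep_cfg, illumination=replace(sweep_cfg.illumination, polarization="TE")
        )
        with pytest.raises(ValueError, match="TM"):
            brewster_sweep(cfg, [40.0, 42.0])

    def test_reference_vanishes_at_brewster(self, sweep_cfg):
        th_b = brewster_angle(1.5, 1.33)
        for th, ref_power in [(th_b, None), (th_b - 2, None)]:
            cfg = replace(
                sweep_cfg, illumination=replace(sweep_cfg.illumination, polar_angle_deg=th)
            )
            _, ref, _ = simulate_image(cfg)
            if th == th_b:
                p_b = ref.power()
            else:
                p_off = ref.power()
        assert p_b < 1e-8 * p_off

    def test_michelson_peaks_at_brewster(self, sweep_cfg):
        th_b = brewster_angle(1.5, 1.33)
        angles = [th_b - 2, th_b - 1, th_b - 0.3, th_b, th_b + 0.3, th_b + 1, th_b + 2]
        res = brewster_sweep(sweep_cfg, angles)
        mich = [m for _, _, m in res]
        assert angles[int(np.argmax(mich))] == th_b
        # contrast tunes monotonically within +/- 2 deg on each side
        assert mich[0] < mich[1] < mich[2]
        assert mich[4] > mich[5] > mich[6]


class TestFocusCorrelate:
    @pytest.fixture(scope="class")
    def stack14(self, dipole_cfg):
        zs = np.linspace(-1000, 1000, 9)
        imgs = []
        for z in zs:
            cam, ref, _ = simulate_image(dipole_cfg, z)
            imgs.append(cam)
        return zs, imgs

    def test_self_query_exact(self, stack14):
        zs, imgs = stack14
        z_best, corr = focus_correlate(imgs, zs, imgs[6])
        assert z_best == zs[6]
        assert corr[6] == pytest.approx(1.0, abs=1e-12)

    def test_negated_query_anticorrelates(self, stack14):
        zs, imgs = stack14
        _, corr = focus_correlate(imgs, zs, -imgs[3].intensity)
        assert corr[3] == pytest.approx(-1.0, abs=1e-12)

    def test_tie_breaks_toward_smallest_z(self):
        a = np.random.default_rng(0).random((8, 8))
        _, _ = 0, 0
        z, corr = focus_correlate([a, a, a], [500.0, -250.0, 250.0], a)
        assert z == 250.0 or z == -250.0
        assert abs(z) == 250.0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            focus_correlate([np.ones((4, 4))], [0.0], np.ones((4, 4)))

    def test_noise_robust_recovery(self, stack14, rng):
        zs, imgs = stack14
        noisy = add_noise(imgs[2].intensity, "gaussian", level=0.02, seed=7)
        z_best, _ = focus_correlate(imgs, zs, noisy)
        assert z_best == zs[2]

    def test_offaxis_unique_onaxis_two_ridge(self, dipole_cfg):
        """Off-axis stacks correlate uniquely; near-normal incidence shows
        the conjugate-defocus (two-ridge) ambiguity."""
        zs = np.linspace(-1000, 1000, 9)
        anti = {}
        for th in (14.0, -2.0):
            cfg = replace(
                dipole_cfg,
                illumination=replace(dipole_cfg.illumination, polar_angle_deg=th),
            )
            imgs = [simulate_image(cfg, z)[0] for z in zs]
            # every noiseless self-query recovers its own plane
            for j in (1, 4, 7):
                z_best, _ = focus_correlate(imgs, zs, imgs[j])
                assert z_best == zs[j]
            C = np.array(
                [focus_correlate(imgs, zs, imgs[j])[1] for j in range(9)]
            )
            anti[th] = np.mean([C[i, 8 - i] for i in range(9) if i != 4])
        assert anti[-2.0] > 0.1                   # conjugate ridge present
        assert anti[14.0] < 0.05                  # suppressed off axis
        assert anti[-2.0] > 3 * anti[14.0]


class TestPartialCoherence:
    def test_single_wavelength_identity(self, dipole_cfg):
        camera, _, _ = simulate_image(dipole_cfg, 400.0)
        I = partial_coherence(dipole_cfg, [517.0], [1.0], z_foc=400.0)
        np.testing.assert_allclose(I, camera.intensity, atol=1e-14)

    def test_weight_normalization_enforced(self, dipole_cfg):
        with pytest.raises(ValueError, match="sum to 1"):
            partial_coherence(dipole_cfg, [510.0, 520.0], [0.7, 0.7])
        with pytest.raises(ValueError, match="spectrum"):
            partial_coherence(dipole_cfg, [], [])

    def test_bandwidth_reduces_fringe_visibility(self, dipole_cfg):
        """An incoherent spectral sum washes out the large-defocus rings."""
        z = 900.0
        lams = [505.0, 511.0, 517.0, 523.0, 529.0]
        I_co = partial_coherence(dipole_cfg, [517.0], [1.0], z_foc=z)
        I_in = partial_coherence(dipole_cfg, lams, [0.2] * 5, z_foc=z)

        def ring_visibility(I):
            n = I.shape[0] // 2
            prof = I[n, n:]
            outer = prof[18:]
            return (outer.max() - outer.min()) / (outer.max() + outer.min())

        assert ring_visibility(I_in) < ring_visibility(I_co)


class TestScan:
    @pytest.fixture(scope="class")
    def scan_setup(self, water_glass):
        train = OpticalTrain.from_magnification(NA=1.3, n=1.5, magnification=100.0)
        exc = OpticalTrain.from_magnification(NA=1.2, n=1.33, magnification=100.0)
        ill = PlaneWaveSpec(520.0, 0.0, 0.0, "TM", "up")
        beam = focus_beam(
            lambda r, p: np.stack([np.ones_like(r), np.zeros_like(r)], -1),
            exc, 520.0, n_theta=20, n_phi=21,
        )
        return train, ill, beam, water_glass

    def test_empty_sample_constant(self, scan_setup):
        train, ill, beam, stack = scan_setup
        cfg = MicroscopeConfig(
            "iscat", stack, ill, train, None, fov_nm=1500, n_pixels=24
        )
        img = scan_image(cfg, beam, np.array([-300.0, 0.0, 300.0]), np.array([0.0]))
        assert np.abs(img).max() > 0
        assert np.ptp(img) < 1e-12 * np.abs(img).max()

    def test_point_scatterer_peak_at_particle(self, scan_setup):
        train, ill, beam, stack = scan_setup
        cfg = MicroscopeConfig(
            "darkfield", stack, ill, train,
            PointDipoleSpec((120.0, 0.0, 200.0), 30.0, gold()),
            fov_nm=1500, n_pixels=24,
        )
        xs = np.linspace(-360, 360, 7)
        img = scan_image(cfg, beam, xs, np.array([0.0]))
        assert xs[np.argmax(img[0])] == pytest.approx(120.0, abs=1e-9)

    def test_mirror_symmetry(self, scan_setup):
        train, ill, beam, stack = scan_setup
        cfg = MicroscopeConfig(
            "darkfield", stack, ill, train,
            PointDipoleSpec((0.0, 0.0, 200.0), 30.0, gold()),
            fov_nm=1500, n_pixels=24,
        )
        xs = np.linspace(-300, 300, 5)
        img = scan_image(cfg, beam, xs, np.array([0.0]))
        np.testing.assert_allclose(img[0], img[0, ::-1], rtol=1e-6)


class TestSystemMagnification:
    @pytest.mark.parametrize(
        "mag,f3,f4,expected",
        [(40.0, 150.0, 500.0, 133.33), (60.0, 75.0, 200.0, 160.0)],
    )
    def test_rated_setups(self, mag, f3, f4, expected):
        assert system_magnification(mag, (f3, f4)) == pytest.approx(expected, abs=0.005)

    def test_unit_relay(self):
        assert system_magnification(63.0, (180.0, 180.0)) == 63.0

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            system_magnification(-40.0, (150.0, 500.0))
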