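"""Richards-Wolf imaging: magnification, energy, Bessel path, BFP optics."""

import numpy as np
import pytest
from scipy.special import jv

from iscatsim.fields import FarField, PlaneWaveDecomposition, SphereGrid
from iscatsim.imaging import (
    ImageGrid,
    OpticalTrain,
    bfp_attenuator,
    bfp_block,
    bfp_compose,
    bfp_waveplate,
    focus_beam,
    image_farfield,
    image_farfield_bessel,
    image_pwd,
    magnification,
)
from iscatsim.interface import DipoleFarFieldSource

LAM = 517.0
N_OBJ = 1.5
K = 2 * np.pi * N_OBJ / LAM


@pytest.fixture(scope="module")
def dipole_cap(oil_train):
    grid = SphereGrid.cap(oil_train.theta_max, 50, 51, pole="up")
    src = DipoleFarFieldSource([1.0, 0.0, 0.0], K, N_OBJ)
    return FarField.on_grid(grid, src.amplitude(grid.directions), K, N_OBJ)


class TestMagnification:
    def test_unity(self):
        t = OpticalTrain(NA=0.5, n=1.0, n_prime=1.0, f_mm=3.0, f_prime_mm=3.0)
        assert magnification(t) == 1.0

    def test_oil_to_air(self):
        t = OpticalTrain(NA=1.3, n=1.5, n_prime=1.0, f_mm=1.0, f_prime_mm=100.0)
        assert magnification(t) == pytest.approx(150.0)

    def test_na_exceeding_index_rejected(self):
        with pytest.raises(ValueError, match="NA exceeds"):
            OpticalTrain(NA=1.42, n=1.33)


class TestImageFarfield:
    def test_on_axis_emitter_symmetric_image(self, oil_train):
        """A z-dipole at focus images to an inversion-symmetric spot."""
        grid = SphereGrid.cap(oil_train.theta_max, 40, 41, pole="up")
        src = DipoleFarFieldSource([0, 0, 1.0], K, N_OBJ)
        far = FarField.on_grid(grid, src.amplitude(grid.directions), K, N_OBJ)
        img = image_farfield_bessel(far, oil_train, ImageGrid.centered(2000, 64))
        I = img.intensity
        np.testing.assert_allclose(I, I[::-1, ::-1], atol=1e-10 * I.max())

    def test_shift_theorem_subpixel(self, oil_train, dipole_cap):
        delta = 317.0
        g = ImageGrid.centered(4000, 512)
        img = image_farfield_bessel(dipole_cap.shift([delta, 0, 0]), oil_train, g)
        iy, ix = np.unravel_index(np.argmax(img.intensity), img.intensity.shape)
        pix = g.x[1] - g.x[0]
        assert abs(g.x[ix] - delta) <= pix
        assert abs(g.y[iy]) <= pix

    def test_energy_conservation(self, oil_train, dipole_cap):
        """Integrated image intensity equals the collected-cone power."""
        img = image_farfield_bessel(
            dipole_cap, oil_train, ImageGrid.centered(16000, 256)
        )
        P_cone = float(
            np.sum(dipole_cap.weights * np.sum(np.abs(dipole_cap.amplitudes) ** 2, -1))
        )
        assert img.power() == pytest.approx(P_cone, rel=0.01)

    def test_linearity_superposition(self, oil_train, dipole_cap):
        g = ImageGrid.centered(2000, 32)
        src2 = DipoleFarFieldSource([0, 1.0, 0.5], K, N_OBJ)
        far2 = FarField.on_grid(
            dipole_cap.grid, src2.amplitude(dipole_cap.grid.directions), K, N_OBJ
        )
        a = image_farfield_bessel(dipole_cap + far2, oil_train, g)
        b = image_farfield_bessel(dipole_cap, oil_train, g)
        c = image_farfield_bessel(far2, oil_train, g)
        np.testing.assert_allclose(a.field, (b + c).field, atol=1e-12)

    def test_global_phase_drops_out_of_observables(self, oil_train, dipole_cap):
        """Multiplying co-imaged fields by a common phase leaves intensity
        and relative phase unchanged (the arbitrary imaging phase)."""
        g = ImageGrid.centered(2000, 32)
        a = image_farfield_bessel(dipole_cap, oil_train, g)
        b = image_farfield_bessel(dipole_cap * np.exp(0.83j), oil_train, g)
        np.testing.assert_allclose(a.intensity, b.intensity, rtol=1e-12)


class TestBesselPath:
    def test_axisymmetric_low_order_truncation(self, oil_train):
        grid = SphereGrid.cap(oil_train.theta_max, 30, 31, pole="up")
        src = DipoleFarFieldSource([1.0, 0, 0], K, N_OBJ)
        far = FarField.on_grid(grid, src.amplitude(grid.directions), K, N_OBJ)
        g = ImageGrid.centered(3000, 48)
        a = image_farfield_bessel(far, oil_train, g, m_max=2)
        b = image_farfield_bessel(far, oil_train, g)
        np.testing.assert_allclose(a.field, b.field, atol=1e-8 * np.abs(b.field).max())

    def test_m_max_beyond_nyquist_rejected(self, oil_train, dipole_cap):
        with pytest.raises(ValueError, match="Nyquist"):
            image_farfield_bessel(
                dipole_cap, oil_train, ImageGrid.centered(1000, 16), m_max=26
            )

    def test_single_order_radial_profile_is_Jm(self, oil_train):
        """A far field with pure e^{i m phi} azimuthal dependence images to
        a J_m radial profile (analytic azimuthal integration)."""
        m = 3
        grid = SphereGrid.cap(oil_train.theta_max, 60, 41, pole="up")
        th, ph = np.meshgrid(grid.theta, grid.phi, indexing="ij")
        th_hat, ph_hat = grid.unit_vectors()
        amp = np.exp(1j * m * ph)[..., None] * ph_hat     # TE-polarized order m
        far = FarField.on_grid(grid, amp, K, N_OBJ)
        rho = np.linspace(30.0, 1500.0, 40)
        g = ImageGrid(x=rho, y=np.array([0.0]))
        img = image_farfield_bessel(far, oil_train, g)
        # oracle: the TE polarization vector (-sin, cos) splits the order-m
        # pattern into m +/- 1 azimuthal orders; at phi = 0 the y component
        # is a half-sum of the two analytic Bessel kernels
        w = grid.w_cos
        st, ct = np.sin(grid.theta), np.cos(grid.theta)

        def kern(order, r):
            return np.sum(w * np.sqrt(ct) * jv(order, K * r * st))

        expected = np.array(
            [
                1j * K * 0.5 * (1j ** (m + 1) * kern(m + 1, r)
                                + 1j ** (m - 1) * kern(m - 1, r))
                for r in rho
            ]
        )
        np.testing.assert_allclose(img.field[0, :, 1], expected, rtol=1e-6)

    def test_large_radius_artifacts_removed(self, oil_train, dipole_cap):
        """Bessel path at 51 azimuths matches the direct method refined to
        201 azimuths; the direct method at 51 shows percent-level artifacts."""
        g = ImageGrid.centered(16000, 128)
        bess = image_farfield_bessel(dipole_cap, oil_train, g)
        gfine = SphereGrid.cap(oil_train.theta_max, 50, 201, pole="up")
        src = DipoleFarFieldSource([1.0, 0.0, 0.0], K, N_OBJ)
        far_f = FarField.on_grid(gfine, src.amplitude(gfine.directions), K, N_OBJ)
        ref = image_farfield(far_f, oil_train, g)
        rel = np.linalg.norm(bess.intensity - ref.intensity) / np.linalg.norm(
            ref.intensity
        )
        assert rel < 1e-3
        with pytest.warns(UserWarning, match="coarse"):
            direct = image_farfield(dipole_cap, oil_train, g)
        rel_direct = np.linalg.norm(direct.intensity - ref.intensity) / np.linalg.norm(
            ref.intensity
        )
        assert rel_direct > 0.01


class TestImagePWD:
    def test_unit_plane_wave_flat_unit_intensity(self, oil_train):
        pwd = PlaneWaveDecomposition(
            directions=[[0, 0, 1.0]], amplitudes=[[1.0, 0, 0]], k=K, n_medium=N_OBJ
        )
        img = image_pwd(pwd, oil_train, ImageGrid.centered(3000, 32))
        np.testing.assert_allclose(img.intensity, 1.0, atol=1e-8)

    def test_tilted_wave_sine_condition_ramp(self, oil_train):
        th0 = 0.35
        pwd = PlaneWaveDecomposition(
            directions=[[np.sin(th0), 0, np.cos(th0)]],
            amplitudes=[[0, 1.0, 0]],
            k=K,
            n_medium=N_OBJ,
        )
        g = ImageGrid.centered(2000, 64)
        img = image_pwd(pwd, oil_train, g)
        dph = np.unwrap(np.angle(img.field[0, :, 1]))
        slope = (dph[-1] - dph[0]) / (g.x[-1] - g.x[0])
        assert slope == pytest.approx(K * np.sin(th0), rel=1e-9)

    def test_beyond_cone_dropped_with_warning(self, oil_train):
        pwd = PlaneWaveDecomposition(
            directions=[[np.sin(1.3), 0, np.cos(1.3)]],
            amplitudes=[[0, 1.0, 0]],
            k=K,
            n_medium=N_OBJ,
        )
        with pytest.warns(UserWarning, match="dropped"):
            img = image_pwd(pwd, oil_train, ImageGrid.centered(1000, 8))
        assert img.power() == 0.0

    def test_dark_field_block_removes_reference(self):
        train = OpticalTrain.from_magnification(
            NA=1.3, n=1.5, magnification=133.33, bfp=bfp_block(0.1)
        )
        pwd = PlaneWaveDecomposition(
            directions=[[0, 0, 1.0]], amplitudes=[[1.0, 0, 0]], k=K, n_medium=N_OBJ
        )
        img = image_pwd(pwd, train, ImageGrid.centered(1000, 16))
        assert img.power() < 1e-10


class TestBFP:
    def test_double_pass_qwp_is_hwp(self):
        """Quarter-wave plate at 45 deg applied twice rotates x -> y."""
        qwp = bfp_waveplate(np.pi / 2, 45.0)
        double = bfp_compose(qwp, qwp)
        E = np.array([1.0 + 0j, 0.0])
        out = double(np.array(0.1), np.array(0.0), E)
        assert abs(out[0]) < 1e-12
        assert abs(out[1]) == pytest.approx(1.0, abs=1e-12)

    def test_attenuator_scales_intensity_by_t_squared(self, oil_train):
        t = 0.31
        train = OpticalTrain.from_magnification(
            NA=1.3, n=1.5, magnification=133.33, bfp=bfp_attenuator(t)
        )
        pwd = PlaneWaveDecomposition(
            directions=[[0, 0, 1.0]], amplitudes=[[1.0, 0, 0]], k=K, n_medium=N_OBJ
        )
        g = ImageGrid.centered(1000, 8)
        img_att = image_pwd(pwd, train, g)
        img = image_pwd(pwd, oil_train, g)
        np.testing.assert_allclose(img_att.intensity, t**2 * img.intensity, rtol=1e-12)

    def test_zero_radius_block_is_identity(self, oil_train, dipole_cap):
        train = OpticalTrain.from_magnification(
            NA=1.3, n=1.5, magnification=133.33, bfp=bfp_block(0.0, 0.0)
        )
        g = ImageGrid.centered(1000, 16)
        a = image_farfield_bessel(dipole_cap, train, g)
        b = image_farfield_bessel(dipole_cap, oil_train, g)
        # theta = 0 is not on the Gauss grid, so nothing is blocked
        np.testing.assert_allclose(a.field, b.field, atol=1e-14)

    def test_passive_attenuator_bound(self):
        with pytest.raises(ValueError):
            bfp_attenuator(1.2)


class TestFocusBeam:
    def test_low_na_approaches_plane_wave(self):
        train = OpticalTrain(NA=0.01, n=1.0, n_prime=1.0)
        fb = focus_beam(
            lambda r, p: np.stack([np.ones_like(r), np.zeros_like(r)], -1),
            train,
            LAM,
        )
        pts = np.stack(
            [np.linspace(-200, 200, 41), np.zeros(41), np.zeros(41)], -1
        )
        I = np.sum(np.abs(fb.evaluate(pts)) ** 2, -1)
        assert I.max() / I.min() < 1.001

    def test_focal_spot_size_near_scalar_benchmark(self, oil_train):
        fb = focus_beam(
            lambda r, p: np.stack([np.ones_like(r), np.zeros_like(r)], -1),
            oil_train,
            LAM,
        )
        ys = np.linspace(-600, 600, 1201)
        pts = np.stack([np.zeros_like(ys), ys, np.zeros_like(ys)], -1)
        I = np.sum(np.abs(fb.evaluate(pts)) ** 2, -1)
        above = I >= I.max() / 2
        fwhm = ys[above].max() - ys[above].min()
        assert fwhm == pytest.approx(LAM / (2 * 1.3), rel=0.2)

    def test_vectorial_symmetry(self, oil_train):
        fb = focus_beam(
            lambda r, p: np.stack([np.ones_like(r), np.zeros_like(r)], -1),
            oil_train,
            LAM,
        )
        pts = np.array([[0, 300.0, 0], [0, -300.0, 0], [300.0, 0, 0]])
        I = np.sum(np.abs(fb.evaluate(pts)) ** 2, -1)
        assert I[0] == pytest.approx(I[1], rel=1e-10)     # y mirror symmetry
        assert abs(I[2] - I[0]) > 1e-3 * I[0]             # x/y lobes differ
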