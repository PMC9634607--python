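"""Closed-form radial functions against independent numeric oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.optimize import brentq

from shellmap import (
    ShellDecomposition,
    ShellTerm,
    evaluate_decomposition,
    gaussian_g,
    interference_G,
    omega,
    packaged_g_decomposition,
    point_image,
    rescale_to_resolution,
    transfer_disorder,
)


def radial_quadrature_oracle(transform, radii):
    """Inverse 3D radial Fourier transform of an isotropic reciprocal-space
    function: 4*pi int_0^inf s^2 T(s) sinc(2 s r) ds (np.sinc convention)."""
    out = []
    for r in np.atleast_1d(radii):
        val, _ = quad(
            lambda s: 4 * np.pi * s**2 * transform(s) * np.sinc(2 * s * r),
            0, np.inf, limit=400,
        )
        out.append(val)
    return np.array(out)


class TestInterferenceG:
    def test_origin_is_exactly_one(self):
        assert interference_G(0.0) == 1.0

    def test_continuity_at_origin(self):
        assert abs(interference_G(1e-8) - interference_G(0.0)) < 1e-12

    def test_first_zero_matches_tangent_equation(self):
        # smallest positive root of tan(u) = u, u = 2 pi x
        u0 = brentq(lambda u: np.tan(u) - u, np.pi + 0.1, 1.5 * np.pi - 1e-9)
        x0 = u0 / (2 * np.pi)
        assert abs(x0 - 0.7151) < 1e-4
        root = brentq(lambda x: interference_G(x), 0.5, 0.9)
        assert abs(root - x0) < 1e-10

    def test_bounded_by_one(self):
        x = np.linspace(0, 50, 20001)
        assert np.max(np.abs(interference_G(x))) <= 1.0

    def test_matches_reciprocal_ball_fft_oracle(self):
        # 3D FFT of the indicator of the ball |s| <= 1/D, D = 2; the sampled
        # indicator has a jagged boundary, limiting this oracle to about the
        # boundary-voxel fraction (~2e-3 of the peak at this grid)
        D, L, N = 2.0, 64.0, 128
        s1 = np.fft.fftfreq(N, d=L / N)
        SX, SY, SZ = np.meshgrid(s1, s1, s1, indexing="ij")
        ball = ((SX**2 + SY**2 + SZ**2) <= (1 / D) ** 2 + 1e-12).astype(float)
        # sum over s-samples * (1/L^3 spacing in s) -> inverse transform
        kernel = np.fft.fftn(ball).real / L**3
        r_axis = np.arange(N) * (L / N)
        half = N // 2
        prof_fft = kernel[:half, 0, 0]
        prof_closed = point_image(r_axis[:half], D)
        peak = prof_closed[0]
        assert np.max(np.abs(prof_fft - prof_closed)) < 2e-3 * peak

    def test_matches_truncated_synthesis_quadrature(self):
        # precise oracle: 4 pi int_0^{1/D} s^2 sinc(2 s r) ds
        D = 2.0
        r = np.array([0.0, 0.3, 0.7151 * D, 1.8, 2.7, 6.4, 11.0])
        oracle = np.array([
            quad(lambda s: 4 * np.pi * s**2 * np.sinc(2 * s * rv), 0, 1 / D,
                 limit=200)[0]
            for rv in r
        ])
        peak = point_image(0.0, D)
        assert np.max(np.abs(point_image(r, D) - oracle)) < 1e-9 * peak

    def test_first_ripple_is_negative(self):
        # between the first and second zeros of G
        x = np.linspace(0.72, 1.22, 200)
        assert np.all(interference_G(x) <= 0)

    def test_negative_argument_rejected(self):
        with pytest.raises(ValueError):
            interference_G(-0.1)


class TestGaussian:
    def test_unit_integral(self):
        for B in (2.0, 15.0, 80.0):
            val, _ = quad(lambda r: 4 * np.pi * r**2 * gaussian_g(r, B), 0, np.inf)
            assert abs(val - 1.0) < 1e-9

    def test_reciprocal_transform_convention(self):
        # forward radial FT of g(r;B) must be exp(-B s^2/4)
        B = 12.0
        for s in (0.05, 0.2, 0.5):
            val, _ = quad(
                lambda r: 4 * np.pi * r**2 * gaussian_g(r, B) * np.sinc(2 * s * r),
                0, np.inf,
            )
            assert abs(val - np.exp(-B * s**2 / 4)) < 1e-9

    def test_convolution_adds_parameters(self):
        # g(B1) * g(B2) = g(B1+B2), via the quadrature oracle on the product
        # of transforms (independent of the real-space closed form)
        B1, B2 = 7.0, 18.0
        r = np.array([0.0, 0.4, 1.0, 2.5])
        conv = radial_quadrature_oracle(
            lambda s: np.exp(-(B1 + B2) * s**2 / 4), r
        )
        np.testing.assert_allclose(conv, gaussian_g(r, B1 + B2), rtol=1e-6)

    def test_invalid_B(self):
        with pytest.raises(ValueError):
            gaussian_g(1.0, 0.0)


class TestOmega:
    def test_gaussian_limit(self):
        for r in (0.0, 0.5, 1.0):
            assert abs(omega(r, 1e-6, 2.0) - gaussian_g(r, 2.0)) < 1e-8

    def test_matches_blurred_shell_oracle(self):
        # reciprocal space: a unit shell of radius mu transforms to
        # sinc(2 mu s); blurring multiplies by exp(-nu s^2/4)
        mu, nu = 3.0, 2.0
        r = np.linspace(0.0, 6.0, 13)
        oracle = radial_quadrature_oracle(
            lambda s: np.sinc(2 * mu * s) * np.exp(-nu * s**2 / 4), r
        )
        peak = np.max(np.abs(oracle))
        assert np.max(np.abs(omega(r, mu, nu) - oracle)) < 1e-6 * peak

    @pytest.mark.parametrize("mu,nu", [(0.873, 4.819), (0.0, 1.0), (5.0, 0.5),
                                       (10.0, 12.0), (2.2, 7.7)])
    def test_unit_integral(self, mu, nu):
        val, _ = quad(
            lambda r: 4 * np.pi * r**2 * omega(r, mu, nu), 0, mu + 40,
            limit=400,
        )
        assert abs(val - 1.0) < 1e-6

    @pytest.mark.parametrize("mu,nu,B", [(0.0, 3.0, 5.0), (1.5, 2.0, 10.0),
                                         (3.0, 1.0, 25.0), (6.0, 4.0, 2.0),
                                         (9.978, 0.811, 60.0)])
    def test_disorder_transfer_semigroup(self, mu, nu, B):
        # Omega(mu, nu) * g(B) = Omega(mu, nu + B), against the quadrature
        # oracle applied to the product of reciprocal transforms
        r = np.array([0.0, 0.5 * mu + 0.2, mu, mu + 1.0, mu + 3.0])
        oracle = radial_quadrature_oracle(
            lambda s: np.sinc(2 * mu * s) * np.exp(-(nu + B) * s**2 / 4), r
        )
        direct = omega(r, mu, nu + B)
        peak = np.max(np.abs(direct))
        # the oscillatory quadrature carries ~1e-9 absolute noise
        assert np.max(np.abs(direct - oracle)) < max(1e-8 * peak, 2e-9)

    @given(
        mu=st.floats(0.0, 10.0),
        nu=st.floats(0.5, 12.0),
        r=st.floats(0.0, 30.0),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_nonnegative_and_finite(self, mu, nu, r):
        v = omega(r, mu, nu)
        assert np.isfinite(v)
        assert v >= -1e-300

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            omega(1.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            omega(1.0, -0.5, 1.0)


class TestTransferAndRescale:
    def test_transfer_identity_at_zero(self):
        dec = packaged_g_decomposition()
        assert transfer_disorder(dec, 0.0) is dec

    def test_transfer_shifts_nu_only(self):
        dec = packaged_g_decomposition()
        out = transfer_disorder(dec, 10.0)
        t0 = out.terms[0]
        assert (t0.mu, t0.nu, t0.kappa) == (0.000, 20.131, 0.693)
        assert all(
            a.mu == b.mu and a.kappa == b.kappa and b.nu == a.nu + 10.0
            for a, b in zip(dec.terms, out.terms)
        )

    def test_transfer_rejects_deblurring(self):
        with pytest.raises(ValueError):
            transfer_disorder(packaged_g_decomposition(), -1.0)

    def test_rescale_unit_resolution_matches_point_image(self, g_fit21):
        r = np.linspace(0.0, 9.5, 400)
        dec = rescale_to_resolution(g_fit21, 1.0)
        np.testing.assert_allclose(
            evaluate_decomposition(dec, r),
            point_image(r, 1.0),
            atol=1.2 * g_fit21.max_error * point_image(0.0, 1.0),
        )

    def test_rescale_reproduces_point_image_at_d2(self, g_fit21):
        r = np.linspace(0.0, 10.0, 500)
        dec = rescale_to_resolution(g_fit21, 2.0)
        err = np.abs(evaluate_decomposition(dec, r) - point_image(r, 2.0))
        assert err.max() <= 1.2 * g_fit21.max_error * point_image(0.0, 2.0)

    def test_rescale_scales_first_zero(self, g_fit21):
        r = np.linspace(0.2, 6.0, 5801)
        zeros = {}
        for D in (2.0, 4.0):
            v = evaluate_decomposition(rescale_to_resolution(g_fit21, D), r)
            i = np.where(np.diff(np.sign(v)))[0][0]
            zeros[D] = r[i]
        assert abs(zeros[4.0] - 2 * zeros[2.0]) < 2 * (r[1] - r[0])

    def test_point_image_origin_value(self):
        assert abs(point_image(0.0, 1.0) - 4 * np.pi / 3) < 1e-12
        assert abs(point_image(0.0, 2.0) - 4 * np.pi / 3 / 8) < 1e-12


class TestShellTermValidation:
    def test_invariants(self):
        with pytest.raises(ValueError):
            ShellTerm(mu=1.0, nu=0.0, kappa=1.0)
        with pytest.raises(ValueError):
            ShellTerm(mu=-1.0, nu=1.0, kappa=1.0)
        # negative kappa is legitimate (ripples alternate sign)
        ShellTerm(mu=1.0, nu=1.0, kappa=-0.5)

    def test_decomposition_invariants(self):
        t = ShellTerm(0.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            ShellDecomposition((t,), domain_radius=0.0)
        d = ShellDecomposition((t, t), domain_radius=1.0)
        assert d.n_terms == 2
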