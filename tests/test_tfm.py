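"""Forward/inverse elasticity, regularization selection and PIV."""

import numpy as np
import pytest

from conftest import rel_l2, smooth_balanced_field
from wfm.codec_metrics import rotate_field_90
from wfm.core_io import Grid2D, ScalarImage, VectorField2D, fill_invalid
from wfm.tfm import (
    ElasticSubstrate,
    TikhonovConfig,
    forward_displacement,
    fourier_kernel,
    greens_tensor,
    piv_displacement,
    select_lambda_gcv,
    select_lambda_lcurve,
    solve_traction_fttc,
)

SUB = ElasticSubstrate()  # E = 5400 Pa, nu = 0.5


def direct_summation_displacement(traction, substrate=SUB, quad=8):
    """Brute-force evaluation of the Boussinesq surface integral.

    Cell-averaged quadrature: the Green's tensor is averaged over `quad`^2
    midpoint sub-cells of each source cell, which handles the integrable
    r = 0 singularity of the self term.
    """
    g = traction.grid
    d = g.pixel_size
    offs = (np.arange(quad) + 0.5) / quad * d - d / 2
    ox, oy = np.meshgrid(offs, offs)
    xx, yy = g.meshgrid()
    nu, E = substrate.nu, substrate.E
    ux = np.zeros(g.shape)
    uy = np.zeros(g.shape)
    for i in range(g.ny):
        for j in range(g.nx):
            rx = xx[i, j] - (xx[..., None, None] + ox)
            ry = yy[i, j] - (yy[..., None, None] + oy)
            rr = np.hypot(rx, ry)
            pref = (1 + nu) / (np.pi * E * rr**3)
            Gxx = (pref * ((1 - nu) * rr**2 + nu * rx**2)).mean(axis=(-2, -1))
            Gyy = (pref * ((1 - nu) * rr**2 + nu * ry**2)).mean(axis=(-2, -1))
            Gxy = (pref * nu * rx * ry).mean(axis=(-2, -1))
            ux[i, j] = np.sum((Gxx * traction.comp_x + Gxy * traction.comp_y)) * d * d
            uy[i, j] = np.sum((Gxy * traction.comp_x + Gyy * traction.comp_y)) * d * d
    return VectorField2D(g, ux, uy, units="um")


class TestGreensTensor:
    def test_unit_separation_along_x(self):
        G = greens_tensor(np.array([1.0, 0.0]))
        assert G[0, 1] == 0.0 and G[1, 0] == 0.0
        assert G[0, 0] == pytest.approx((1 + 0.5) / (np.pi * 5400.0), rel=1e-12)
        assert G[0, 0] == pytest.approx(8.842e-5, abs=2e-8)

    def test_symmetric_and_even(self, rng):
        for _ in range(20):
            r = rng.normal(size=2) * 10
            G = greens_tensor(r)
            np.testing.assert_allclose(G, G.T)
            np.testing.assert_allclose(G, greens_tensor(-r))

    def test_singularity_raises(self):
        with pytest.raises(ZeroDivisionError):
            greens_tensor(np.array([0.0, 0.0]))


class TestFourierKernel:
    def test_zero_mode_is_zero(self, force_grid):
        Gk = fourier_kernel(force_grid)
        np.testing.assert_array_equal(Gk[0, 0], 0.0)

    def test_decays_like_inverse_k(self, force_grid):
        # along the +kx ray the analytic part scales as 1/k
        Gk = fourier_kernel(force_grid, cell_average=False)
        mags = [np.linalg.norm(Gk[0, m]) for m in (2, 4, 8)]
        assert mags[0] / mags[1] == pytest.approx(2.0, rel=0.05)
        assert mags[1] / mags[2] == pytest.approx(2.0, rel=0.05)

    def test_matches_direct_summation_within_2_percent(self, rng):
        grid = Grid2D(nx=8, ny=8, pixel_size=3.44)
        t = smooth_balanced_field(grid, rng, sigma=1.2, mode="constant")
        u_spec = forward_displacement(t, SUB, mode="padded")
        u_direct = direct_summation_displacement(t)
        assert rel_l2(u_spec, u_direct) < 0.02


class TestForwardDisplacement:
    def test_zero_and_linearity(self, force_grid, balanced_field):
        zero = VectorField2D(
            force_grid, np.zeros(force_grid.shape), np.zeros(force_grid.shape)
        )
        u0 = forward_displacement(zero, SUB)
        np.testing.assert_array_equal(u0.comp_x, 0.0)
        u1 = forward_displacement(balanced_field, SUB)
        u2 = forward_displacement(balanced_field * 2.0, SUB)
        np.testing.assert_allclose(u2.comp_x, 2 * u1.comp_x, rtol=1e-10)

    def test_dipole_displacement_points_inward(self, force_grid):
        # centered x-dipole: force spots at +/- 3 nodes pulling toward center
        cx = np.zeros(force_grid.shape)
        cx[13, 9] = 100.0
        cx[13, 16] = -100.0
        t = VectorField2D(force_grid, cx - cx.mean(), np.zeros(force_grid.shape))
        u = forward_displacement(t, SUB, mode="padded")
        assert u.comp_x[13, 9] > 0  # left spot moves right, toward center
        assert u.comp_x[13, 16] < 0  # right spot moves left

    def test_rotation_equivariance(self, balanced_field):
        u_rot = forward_displacement(rotate_field_90(balanced_field), SUB, "periodic")
        rot_u = rotate_field_90(forward_displacement(balanced_field, SUB, "periodic"))
        assert rel_l2(u_rot, rot_u) < 1e-10


class TestSolveFTTC:
    def test_forward_inverse_identity_periodic(self, balanced_field):
        u = forward_displacement(balanced_field, SUB, mode="periodic")
        t = solve_traction_fttc(u, SUB, TikhonovConfig(0.0, "periodic"))
        assert rel_l2(t, balanced_field) < 1e-6

    def test_huge_lambda_kills_traction(self, balanced_field):
        u = forward_displacement(balanced_field, SUB, mode="periodic")
        t = solve_traction_fttc(u, SUB, TikhonovConfig(1e6, "periodic"))
        assert np.abs(t.comp_x).max() < 1e-6 * np.abs(balanced_field.comp_x).max()

    def test_zero_displacement_zero_traction(self, force_grid):
        zero = VectorField2D(
            force_grid, np.zeros(force_grid.shape), np.zeros(force_grid.shape), "um"
        )
        for lam in (0.0, 1e-4):
            for mode in ("periodic", "padded"):
                t = solve_traction_fttc(zero, SUB, TikhonovConfig(lam, mode))
                np.testing.assert_allclose(t.comp_x, 0.0, atol=1e-12)

    def test_zero_net_force_always(self, balanced_field, rng):
        u = forward_displacement(balanced_field, SUB, mode="periodic")
        noisy = u.with_components(
            u.comp_x + rng.normal(0, 0.01, u.comp_x.shape),
            u.comp_y + rng.normal(0, 0.01, u.comp_y.shape),
        )
        for mode in ("periodic", "padded"):
            t = solve_traction_fttc(noisy, SUB, TikhonovConfig(1e-5, mode))
            assert abs(t.comp_x.sum()) < 1e-8 * np.abs(t.comp_x).max()
            assert abs(t.comp_y.sum()) < 1e-8 * np.abs(t.comp_y).max()

    def test_padded_inverse_recovers_aperiodic_forward(self, rng, force_grid):
        t_true = smooth_balanced_field(force_grid, rng, sigma=2.5, mode="constant")
        u = forward_displacement(t_true, SUB, mode="padded")
        t = solve_traction_fttc(u, SUB, TikhonovConfig(0.0, "padded"))
        assert rel_l2(t, t_true) < 0.05

    def test_nan_displacement_rejected(self, force_grid):
        vals = np.zeros(force_grid.shape)
        bad = vals.copy()
        bad[3, 3] = np.nan
        u = VectorField2D(force_grid, bad, vals, "um")
        with pytest.raises(ValueError, match="fill"):
            solve_traction_fttc(u, SUB)


class TestLambdaSelection:
    def test_curve_monotonicity(self, balanced_field):
        u = forward_displacement(balanced_field, SUB, mode="periodic")
        _, curve = select_lambda_lcurve(u, SUB)
        assert np.all(np.diff(curve.residual_norms) >= -1e-8 * curve.residual_norms.max())
        assert np.all(np.diff(curve.solution_norms) <= 1e-8 * curve.solution_norms.max())

    def test_noiseless_choice_in_bottom_decade(self, balanced_field):
        u = forward_displacement(balanced_field, SUB, mode="periodic")
        lam, curve = select_lambda_lcurve(u, SUB)
        assert lam <= curve.lambdas[0] * 10.0

    def test_noisy_choice_within_2x_of_best(self, balanced_field, rng):
        u = forward_displacement(balanced_field, SUB, mode="periodic")
        urms = np.sqrt(np.mean(u.comp_x**2 + u.comp_y**2))
        noisy = u.with_components(
            u.comp_x + rng.normal(0, 0.05 * urms, u.comp_x.shape),
            u.comp_y + rng.normal(0, 0.05 * urms, u.comp_y.shape),
        )
        lam_star, curve = select_lambda_lcurve(noisy, SUB)
        errors = np.array(
            [
                rel_l2(
                    solve_traction_fttc(noisy, SUB, TikhonovConfig(lam, "periodic")),
                    balanced_field,
                )
                for lam in curve.lambdas
            ]
        )
        chosen = errors[curve.chosen_index]
        assert chosen <= 2.0 * errors.min()

    def test_grid_validation(self, balanced_field):
        u = forward_displacement(balanced_field, SUB, mode="periodic")
        with pytest.raises(ValueError):
            select_lambda_lcurve(u, SUB, lambda_grid=np.array([1.0, 2.0, 3.0]))

    def test_gcv_close_to_error_optimal_on_correlated_noise(self, balanced_field, rng):
        from scipy.ndimage import gaussian_filter

        u = forward_displacement(balanced_field, SUB, mode="periodic")
        urms = np.sqrt(np.mean(u.comp_x**2 + u.comp_y**2))
        # spatially correlated error, the regime where the L-curve corner fails
        noise = [
            gaussian_filter(rng.normal(0, 1, u.comp_x.shape), 1.5) for _ in range(2)
        ]
        noisy = u.with_components(
            u.comp_x + 0.08 * urms * noise[0] / np.std(noise[0]),
            u.comp_y + 0.08 * urms * noise[1] / np.std(noise[1]),
        )
        lam_star, lams, scores = select_lambda_gcv(noisy, SUB)
        errors = np.array(
            [
                rel_l2(
                    solve_traction_fttc(noisy, SUB, TikhonovConfig(lam, "periodic")),
                    balanced_field,
                )
                for lam in lams
            ]
        )
        chosen = errors[int(np.argmin(np.abs(lams - lam_star)))]
        assert chosen <= 1.5 * errors.min()


def render_beads(rng, n=1000, size=256, sigma=1.4, shift=(0.0, 0.0)):
    img = np.zeros((size, size))
    xs = rng.uniform(0, size, n) + shift[0]
    ys = rng.uniform(0, size, n) + shift[1]
    half = int(np.ceil(4 * sigma))
    for x, y in zip(xs, ys):
        cx, cy = int(round(x)), int(round(y))
        x0, x1 = max(cx - half, 0), min(cx + half + 1, size)
        y0, y1 = max(cy - half, 0), min(cy + half + 1, size)
        if x0 >= x1 or y0 >= y1:
            continue
        gx = np.arange(x0, x1) - x
        gy = np.arange(y0, y1) - y
        img[y0:y1, x0:x1] += np.exp(-(gy[:, None] ** 2 + gx[None, :] ** 2) / (2 * sigma**2))
    return img


class TestPIV:
    def test_identical_images_zero_field(self, rng):
        img = ScalarImage(Grid2D(128, 128, 0.5), render_beads(rng, 400, 128))
        field = piv_displacement(img, img, 32, 16)
        np.testing.assert_allclose(field.comp_x, 0.0, atol=1e-6)
        np.testing.assert_allclose(field.comp_y, 0.0, atol=1e-6)

    def test_integer_cyclic_shift_recovered(self, rng):
        vals = render_beads(rng, 400, 128)
        grid = Grid2D(128, 128, 0.5)
        shifted = np.roll(vals, 3, axis=1)  # 3 px along +x
        ref_img, def_img = ScalarImage(grid, vals), ScalarImage(grid, shifted)
        # single pass carries the classic loss-of-pairs bias toward zero
        # (windows lose 3 columns of matched content); within 0.2 px
        single = piv_displacement(ref_img, def_img, 32, 16)
        assert np.nanmean(single.comp_x) == pytest.approx(3 * 0.5, abs=0.2 * 0.5)
        # the image-deformation pass removes that bias
        refined = piv_displacement(ref_img, def_img, 32, 16, passes=3)
        assert np.nanmean(refined.comp_x) == pytest.approx(3 * 0.5, abs=0.05 * 0.5)
        assert np.nanmean(np.abs(refined.comp_y)) < 0.05

    def test_subpixel_shift_within_02_px(self):
        rng1 = np.random.default_rng(7)
        rng2 = np.random.default_rng(7)
        ref = render_beads(rng1, 1200, 256)
        deformed = render_beads(rng2, 1200, 256, shift=(2.5, 0.0))
        grid = Grid2D(256, 256, 1.0)
        field = piv_displacement(ScalarImage(grid, ref), ScalarImage(grid, deformed), 32, 16)
        assert abs(np.nanmean(field.comp_x) - 2.5) < 0.2

    def test_featureless_window_flagged_nan(self, rng):
        vals = render_beads(rng, 300, 128)
        vals[:40, :40] = 0.0  # dead corner
        grid = Grid2D(128, 128, 1.0)
        img = ScalarImage(grid, vals)
        field = piv_displacement(img, img, 32, 32)
        assert np.isnan(field.comp_x[0, 0])
        assert np.isfinite(field.comp_x[2:, 2:]).all()

    def test_parameter_validation(self, rng):
        img = ScalarImage(Grid2D(64, 64), render_beads(rng, 100, 64))
        with pytest.raises(ValueError):
            piv_displacement(img, img, window=8, step=4)
        with pytest.raises(ValueError):
            piv_displacement(img, img, window=32, step=64)
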