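"""Forward and inverse traction force microscopy on an elastic half-space.

The substrate is a linear-elastic, isotropic half-space.  A surface
traction field t produces surface displacements through the Boussinesq
convolution

    u(x) = integral_S G(x - y) t(y) dS(y),

with the in-plane 2x2 Green's tensor

    G(r) = (1 + nu) / (pi E r^3) * [[(1-nu) r^2 + nu r_x^2,  nu r_x r_y],
                                    [nu r_x r_y,  (1-nu) r^2 + nu r_y^2]].

Because the convolution diagonalizes per wavevector, the inverse problem
(Fourier-transform traction cytometry, FTTC) is a family of independent
2x2 solves; ill-posedness at high |k| is damped by Tikhonov
regularization,

    t~ = (G~^T G~ + lambda^2 I)^(-1) G~^T u~,

with lambda chosen at the corner of the L-curve.  The k = 0 mode is
zeroed in both directions: an adherent cell exerts no net traction, and
rigid translation of the substrate is unobservable.

A block-wise normalized-cross-correlation PIV estimator recovers the
displacement field from reference/deformed bead-image pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core_io import Grid2D, ScalarImage, VectorField2D, same_grid


@dataclass(frozen=True)
class ElasticSubstrate:
    """Elastic half-space: Young's modulus E (Pa) and Poisson's ratio nu."""

    E: float = 5400.0
    nu: float = 0.5

    def __post_init__(self) -> None:
        if not self.E > 0:
            raise ValueError(f"E must be positive, got {self.E}")
        if not 0.0 <= self.nu <= 0.5:
            raise ValueError(f"nu must lie in [0, 0.5], got {self.nu}")


@dataclass(frozen=True)
class TikhonovConfig:
    """Regularization settings for the FTTC solve.

    lambda_reg is applied squared, as the damping term lambda^2 I; the
    L-curve scan runs over lambda_grid (strictly increasing).
    """

    lambda_reg: float = 0.0
    mode: str = "padded"
    lambda_grid: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.lambda_reg < 0:
            raise ValueError(f"lambda_reg must be >= 0, got {self.lambda_reg}")
        if self.mode not in ("periodic", "padded"):
            raise ValueError(f"mode must be 'periodic' or 'padded', got {self.mode!r}")
        if self.lambda_grid is not None:
            lg = np.asarray(self.lambda_grid, dtype=float)
            if lg.ndim != 1 or len(lg) < 2 or np.any(np.diff(lg) <= 0) or np.any(lg <= 0):
                raise ValueError("lambda_grid must be 1-D, positive, strictly increasing")
            object.__setattr__(self, "lambda_grid", lg)


@dataclass(frozen=True)
class LCurve:
    """Residual/solution-norm trade-off of a Tikhonov lambda scan."""

    lambdas: np.ndarray
    residual_norms: np.ndarray
    solution_norms: np.ndarray
    chosen_index: int

    @property
    def lambda_star(self) -> float:
        return float(self.lambdas[self.chosen_index])


def greens_tensor(r, substrate: ElasticSubstrate = ElasticSubstrate()) -> np.ndarray:
    """Boussinesq in-plane Green's tensor at separation r (micrometres).

    Symmetric 2x2, units um / (Pa um^2): contract with traction (Pa) and a
    surface element (um^2) to get displacement (um).  Singular at r = 0;
    quadrature callers must average over the source cell instead.
    """
    r = np.asarray(r, dtype=float)
    rx, ry = r[..., 0], r[..., 1]
    rr = np.hypot(rx, ry)
    if np.any(rr == 0):
        raise ZeroDivisionError(
            "Green's tensor is singular at r = 0; use the Fourier kernel or "
            "cell-averaged quadrature for the self term"
        )
    nu, E = substrate.nu, substrate.E
    pref = (1.0 + nu) / (np.pi * E * rr**3)
    G = np.empty(rr.shape + (2, 2))
    G[..., 0, 0] = pref * ((1 - nu) * rr**2 + nu * rx**2)
    G[..., 1, 1] = pref * ((1 - nu) * rr**2 + nu * ry**2)
    G[..., 0, 1] = G[..., 1, 0] = pref * nu * rx * ry
    return G


def fourier_kernel(
    grid: Grid2D,
    substrate: ElasticSubstrate = ElasticSubstrate(),
    cell_average: bool = True,
) -> np.ndarray:
    """Half-space kernel G~(k) on the discrete wavevector lattice.

    Shape (ny, nx, 2, 2), the analytic transform of the real-space tensor:

        G~(k) = 2 (1+nu) / (E k^3) * [[(1-nu) k^2 + nu k_y^2, -nu k_x k_y],
                                      [-nu k_x k_y, (1-nu) k^2 + nu k_x^2]]

    With ``cell_average`` (default) the kernel carries an extra separable
    sinc factor, the transform of a pixel-sized boxcar: traction is then
    treated as piecewise constant over grid cells, which matches the
    cell-averaged quadrature of the real-space operator.  The k = 0 entry
    is set to zero (zero-mean traction convention).  Entries decay as
    1/|k| up to the bounded cell factor.
    """
    d = grid.pixel_size
    kx = 2 * np.pi * np.fft.fftfreq(grid.nx, d=d)
    ky = 2 * np.pi * np.fft.fftfreq(grid.ny, d=d)
    KX, KY = np.meshgrid(kx, ky)
    K = np.hypot(KX, KY)
    K[0, 0] = 1.0  # placeholder, zeroed below
    nu, E = substrate.nu, substrate.E
    pref = 2.0 * (1.0 + nu) / (E * K**3)
    Gk = np.empty(K.shape + (2, 2))
    Gk[..., 0, 0] = pref * ((1 - nu) * K**2 + nu * KY**2)
    Gk[..., 1, 1] = pref * ((1 - nu) * K**2 + nu * KX**2)
    Gk[..., 0, 1] = Gk[..., 1, 0] = -pref * nu * KX * KY
    if cell_average:
        s = np.sinc(KX * d / (2 * np.pi)) * np.sinc(KY * d / (2 * np.pi))
        Gk *= s[..., None, None]
    Gk[0, 0] = 0.0
    return Gk


def _fft_field(cx: np.ndarray, cy: np.ndarray) -> np.ndarray:
    return np.stack([np.fft.fft2(cx), np.fft.fft2(cy)], axis=-1)


#: zero-padding factor per axis for the aperiodic ('padded') mode; x4 keeps
#: wrap-around images far enough that their dipole far field is negligible
def _pad_factor() -> int:
    return 4


def forward_displacement(
    traction: VectorField2D,
    substrate: ElasticSubstrate = ElasticSubstrate(),
    mode: str = "padded",
) -> VectorField2D:
    """Displacement field produced by a traction field (Boussinesq forward map).

    ``periodic`` evaluates the cyclic spectral convolution and is the exact
    inverse pair of :func:`solve_traction_fttc`; ``padded`` zero-pads by a
    factor 4 per axis to suppress wrap-around, approximating an isolated
    cell on an infinite substrate.
    """
    if mode not in ("periodic", "padded"):
        raise ValueError(f"mode must be 'periodic' or 'padded', got {mode!r}")
    g = traction.grid
    cx, cy = traction.comp_x, traction.comp_y
    if not (np.all(np.isfinite(cx)) and np.all(np.isfinite(cy))):
        raise ValueError("traction field contains non-finite values")
    if mode == "padded":
        f = _pad_factor()
        work = Grid2D(nx=f * g.nx, ny=f * g.ny, pixel_size=g.pixel_size)
        px = np.zeros(work.shape)
        py = np.zeros(work.shape)
        px[: g.ny, : g.nx] = cx
        py[: g.ny, : g.nx] = cy
    else:
        work, px, py = g, cx, cy
    Gk = fourier_kernel(work, substrate)
    T = _fft_field(px, py)
    U = np.einsum("...ij,...j->...i", Gk, T)
    ux = np.fft.ifft2(U[..., 0]).real
    uy = np.fft.ifft2(U[..., 1]).real
    if mode == "padded":
        ux, uy = ux[: g.ny, : g.nx], uy[: g.ny, : g.nx]
    return VectorField2D(g, ux, uy, units="um")


def _tikhonov_solve_k(Gk: np.ndarray, U: np.ndarray, lam: float) -> np.ndarray:
    """Per-wavevector (G^T G + lambda^2 I)^(-1) G^T u~ for symmetric real G."""
    GtG = np.einsum("...ji,...jk->...ik", Gk, Gk)
    A = GtG + (lam**2) * np.eye(2)
    rhs = np.einsum("...ji,...j->...i", Gk, U)
    det = A[..., 0, 0] * A[..., 1, 1] - A[..., 0, 1] * A[..., 1, 0]
    singular = np.abs(det) < 1e-300
    if np.any(singular[1:]) or (lam == 0 and np.any(singular.ravel()[1:])):
        # only possible for degenerate nu -> pseudo-inverse fallback
        warnings.warn("near-singular per-k system; falling back to pseudo-inverse")
        T = np.zeros_like(rhs)
        flat_A = A.reshape(-1, 2, 2)
        flat_r = rhs.reshape(-1, 2)
        for idx in range(flat_A.shape[0]):
            T.reshape(-1, 2)[idx] = np.linalg.pinv(flat_A[idx]) @ flat_r[idx]
        return T
    det = np.where(np.abs(det) < 1e-300, 1.0, det)
    inv = np.empty_like(A)
    inv[..., 0, 0] = A[..., 1, 1] / det
    inv[..., 1, 1] = A[..., 0, 0] / det
    inv[..., 0, 1] = -A[..., 0, 1] / det
    inv[..., 1, 0] = -A[..., 1, 0] / det
    return np.einsum("...ij,...j->...i", inv, rhs)


def solve_traction_fttc(
    displacement: VectorField2D,
    substrate: ElasticSubstrate = ElasticSubstrate(),
    config: TikhonovConfig = TikhonovConfig(mode="periodic"),
) -> VectorField2D:
    """Invert displacement to traction by Tikhonov-regularized FTTC.

    ``periodic`` mode is the closed-form per-wavevector solve
    (G~^T G~ + lambda^2 I)^(-1) G~^T u~, the exact inverse of the periodic
    forward map.  ``padded`` mode minimizes the same Tikhonov objective but
    under the aperiodic (zero-padded) convolution operator, with the
    traction constrained to the observed window; the normal equations are
    solved by conjugate gradients.  This removes the boundary artefacts of
    inverting windowed displacement data periodically.

    The k = 0 traction is zeroed (periodic) or the mean subtracted
    (padded), so the output always sums to the zero vector (zero net
    force).  NaN-flagged displacement nodes must be filled (see
    :func:`wfm.core_io.fill_invalid`) before inversion.
    """
    g = displacement.grid
    ux, uy = displacement.comp_x, displacement.comp_y
    if not (np.all(np.isfinite(ux)) and np.all(np.isfinite(uy))):
        raise ValueError("displacement contains NaN; fill invalid nodes first")
    if config.mode == "padded":
        return _solve_padded_cg(displacement, substrate, config.lambda_reg)
    Gk = fourier_kernel(g, substrate)
    U = _fft_field(ux, uy)
    T = _tikhonov_solve_k(Gk, U, config.lambda_reg)
    T[0, 0] = 0.0
    tx = np.fft.ifft2(T[..., 0]).real
    ty = np.fft.ifft2(T[..., 1]).real
    return VectorField2D(g, tx, ty, units="Pa")


def _solve_padded_cg(
    displacement: VectorField2D,
    substrate: ElasticSubstrate,
    lam: float,
    n_iter: int = 120,
    tol: float = 1e-12,
) -> VectorField2D:
    """Support-constrained Tikhonov solve with the aperiodic padded operator."""
    g = displacement.grid
    f = _pad_factor()
    work = Grid2D(nx=f * g.nx, ny=f * g.ny, pixel_size=g.pixel_size)
    Gk = fourier_kernel(work, substrate)

    def apply_G(tx: np.ndarray, ty: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        px = np.zeros(work.shape)
        py = np.zeros(work.shape)
        px[: g.ny, : g.nx] = tx
        py[: g.ny, : g.nx] = ty
        T = _fft_field(px, py)
        U = np.einsum("...ij,...j->...i", Gk, T)
        return (
            np.fft.ifft2(U[..., 0]).real[: g.ny, : g.nx],
            np.fft.ifft2(U[..., 1]).real[: g.ny, : g.nx],
        )

    # the kernel is real and symmetric with G(-r) = G(r), so the adjoint of
    # (pad -> convolve -> crop) is the same map
    b = np.stack(apply_G(displacement.comp_x, displacement.comp_y))

    def normal_op(v: np.ndarray) -> np.ndarray:
        gx, gy = apply_G(v[0], v[1])
        hx, hy = apply_G(gx, gy)
        return np.stack([hx, hy]) + lam**2 * v

    x = np.zeros_like(b)
    r = b - normal_op(x)
    p = r.copy()
    rs = float(np.sum(r * r))
    b2 = float(np.sum(b * b))
    for _ in range(n_iter):
        Ap = normal_op(p)
        denom = float(np.sum(p * Ap))
        if denom <= 0:
            break
        alpha = rs / denom
        x += alpha * p
        r -= alpha * Ap
        rs_new = float(np.sum(r * r))
        if rs_new < tol * b2:
            break
        p = r + (rs_new / rs) * p
        rs = rs_new
    tx = x[0] - x[0].mean()
    ty = x[1] - x[1].mean()
    return VectorField2D(g, tx, ty, units="Pa")


def select_lambda_lcurve(
    displacement: VectorField2D,
    substrate: ElasticSubstrate = ElasticSubstrate(),
    lambda_grid: np.ndarray | None = None,
    mode: str = "periodic",
) -> tuple[float, LCurve]:
    """Pick the Tikhonov parameter at the L-curve corner.

    Scans ``lambda_grid`` (default: 40 log-spaced points over 5 decades
    around the smallest nonzero singular value of the spectral kernel) and
    records the residual norm ||G t~ - u~|| and solution norm ||t~|| per
    lambda.  Because the discrete FTTC system is square and invertible,
    the residual has no noise floor: an (almost) exact fit is always
    possible, so the classic two-branch L geometry degenerates.  The
    corner is therefore found on the pruned curve (residuals above 1e-3 of
    their maximum, discarding the machine-fit branch) as the maximum
    curvature of an axis-normalized spline-smoothed log-log curve,
    cross-checked against generalized cross-validation: when GCV prefers
    (nearly) no damping the corner is spurious and the GCV choice is
    returned, and the corner is never allowed below the GCV optimum.
    """
    g = displacement.grid
    Gk = fourier_kernel(g, substrate)
    U = _fft_field(displacement.comp_x, displacement.comp_y)
    if lambda_grid is None:
        sv = np.linalg.svd(Gk.reshape(-1, 2, 2), compute_uv=False)
        sv_min = sv[1:].min()  # skip the zeroed k = 0 block
        lambda_grid = np.geomspace(1e-3, 1e2, 40) * sv_min
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if len(lambda_grid) < 5 or lambda_grid[-1] / lambda_grid[0] < 1e3:
        raise ValueError("lambda_grid needs >= 5 points spanning >= 3 decades")

    residuals = np.empty(len(lambda_grid))
    solutions = np.empty(len(lambda_grid))
    for i, lam in enumerate(lambda_grid):
        T = _tikhonov_solve_k(Gk, U, lam)
        T[0, 0] = 0.0
        R = np.einsum("...ij,...j->...i", Gk, T) - U
        R[0, 0] = 0.0
        residuals[i] = np.linalg.norm(R)
        solutions[i] = np.linalg.norm(T)
    tol = 1e-8
    if np.any(np.diff(residuals) < -tol * residuals.max()) or np.any(
        np.diff(solutions) > tol * solutions.max()
    ):
        raise RuntimeError(
            "L-curve monotonicity violated (residuals must not decrease, "
            "solution norms must not increase with lambda); numerical failure"
        )
    _, _, gcv_scores = select_lambda_gcv(displacement, substrate, lambda_grid)
    idx = _lcurve_corner(
        lambda_grid, residuals, solutions, gcv_idx=int(np.argmin(gcv_scores))
    )
    curve = LCurve(lambda_grid, residuals, solutions, idx)
    return curve.lambda_star, curve


def _lcurve_corner(
    lambdas: np.ndarray,
    residuals: np.ndarray,
    solutions: np.ndarray,
    gcv_idx: int | None = None,
    prune: float = 1e-3,
    benign_factor: float = 1.05,
) -> int:
    """Corner of a (possibly degenerate) discrete L-curve; see selector doc."""
    keep = residuals >= prune * residuals.max()
    lo = int(np.argmax(keep))
    # benign amplification: when cross-validation is happiest with (nearly)
    # no damping, lambda -> 0 amplifies nothing and the corner is spurious
    if gcv_idx is not None and lambdas[gcv_idx] <= lambdas[0] * 10.0:
        return gcv_idx
    x = np.log10(np.maximum(residuals[lo:], 1e-300))
    y = np.log10(np.maximum(solutions[lo:], 1e-300))
    t = np.log10(lambdas[lo:])
    xs = (x - x.min()) / max(x.max() - x.min(), 1e-12)
    ys = (y - y.min()) / max(y.max() - y.min(), 1e-12)
    idx = None
    if len(t) >= 5:
        try:
            from scipy.interpolate import UnivariateSpline

            sx = UnivariateSpline(t, xs, k=3, s=len(t) * 1e-4)
            sy = UnivariateSpline(t, ys, k=3, s=len(t) * 1e-4)
            d1x, d1y = sx.derivative(1)(t), sy.derivative(1)(t)
            d2x, d2y = sx.derivative(2)(t), sy.derivative(2)(t)
            kappa = np.abs(d1x * d2y - d1y * d2x) / np.maximum(
                (d1x**2 + d1y**2) ** 1.5, 1e-30
            )
            kappa[0] = kappa[-1] = 0.0
            if np.any(kappa > 0):
                idx = lo + int(np.argmax(kappa))
        except Exception:
            idx = None
    if idx is None:
        # triangle rule: farthest point from the chord between the endpoints
        chord = np.array([xs[-1] - xs[0], ys[-1] - ys[0]])
        nrm = np.linalg.norm(chord)
        chord = chord / (nrm if nrm > 0 else 1.0)
        dist = np.abs((xs - xs[0]) * chord[1] - (ys - ys[0]) * chord[0])
        idx = lo + int(np.argmax(dist))
    # local descend: prefer less damping while the solution norm stays flat
    eta_corner = solutions[idx]
    while idx > 0 and solutions[idx - 1] <= benign_factor * eta_corner:
        idx -= 1
    if gcv_idx is not None and idx < gcv_idx:
        # never damp less than cross-validation asks for
        idx = gcv_idx
    return idx


# ---------------------------------------------------------------------------
# particle image velocimetry

def _subpixel_offset(c_m: float, c_0: float, c_p: float) -> float:
    """Three-point Gaussian peak fit; parabolic fallback for non-positive lobes."""
    if c_m > 0 and c_0 > 0 and c_p > 0 and (c_0 >= c_m and c_0 >= c_p):
        lm, l0, lp = np.log(c_m), np.log(c_0), np.log(c_p)
        denom = 2 * lm - 4 * l0 + 2 * lp
        if denom != 0:
            return float(np.clip((lm - lp) / denom, -1.0, 1.0))
    denom = 2 * c_m - 4 * c_0 + 2 * c_p
    if denom != 0:
        return float(np.clip((c_m - c_p) / denom, -1.0, 1.0))
    return 0.0


def piv_displacement(
    img_ref: ScalarImage,
    img_def: ScalarImage,
    window: int = 32,
    step: int = 16,
    passes: int = 1,
) -> VectorField2D:
    """Block-wise normalized cross-correlation displacement estimate.

    Windows of ``window`` pixels are correlated cyclically in Fourier space
    and the peak refined by a three-point Gaussian fit, giving sub-pixel
    displacements (micrometres) on a grid of spacing ``step * pixel_size``.
    Windows with near-zero intensity variance yield NaN (flagged invalid).

    ``passes > 1`` enables iterative image-deformation refinement: the
    deformed image is warped back by the current estimate and the residual
    shift re-measured, which reduces the gradient-attenuation bias of
    single-pass correlation when the displacement varies within a window.
    """
    grid = same_grid(img_ref, img_def)
    if window < 16:
        raise ValueError(f"window must be >= 16 px, got {window}")
    if step > window:
        raise ValueError(f"step ({step}) must not exceed window ({window})")
    if passes < 1:
        raise ValueError(f"passes must be >= 1, got {passes}")
    pv = _piv_single_pass(img_ref, img_def, window, step)
    for _ in range(passes - 1):
        pv = _piv_deform_pass(img_ref, img_def, pv, window, step)
    return pv


def _piv_single_pass(
    img_ref: ScalarImage, img_def: ScalarImage, window: int, step: int
) -> VectorField2D:
    grid = img_ref.grid
    a_full, b_full = img_ref.values, img_def.values
    r_starts = np.arange(0, grid.ny - window + 1, step)
    c_starts = np.arange(0, grid.nx - window + 1, step)
    if len(r_starts) < 2 or len(c_starts) < 2:
        raise ValueError("images too small for the requested window/step")
    ux = np.full((len(r_starts), len(c_starts)), np.nan)
    uy = np.full_like(ux, np.nan)
    for ri, r0 in enumerate(r_starts):
        for ci, c0 in enumerate(c_starts):
            a = a_full[r0 : r0 + window, c0 : c0 + window]
            b = b_full[r0 : r0 + window, c0 : c0 + window]
            a = a - a.mean()
            b = b - b.mean()
            sa, sb = np.linalg.norm(a), np.linalg.norm(b)
            if sa < 1e-10 or sb < 1e-10:
                continue
            cc = np.fft.ifft2(np.fft.fft2(b) * np.conj(np.fft.fft2(a))).real
            cc /= sa * sb
            peak = np.unravel_index(np.argmax(cc), cc.shape)
            py, px = peak
            # cyclic neighbours for the sub-pixel fit
            dy = _subpixel_offset(
                cc[(py - 1) % window, px], cc[py, px], cc[(py + 1) % window, px]
            )
            dx = _subpixel_offset(
                cc[py, (px - 1) % window], cc[py, px], cc[py, (px + 1) % window]
            )
            sy = py if py <= window // 2 else py - window
            sx = px if px <= window // 2 else px - window
            ux[ri, ci] = (sx + dx) * grid.pixel_size
            uy[ri, ci] = (sy + dy) * grid.pixel_size
    out_grid = Grid2D(
        nx=len(c_starts),
        ny=len(r_starts),
        pixel_size=step * grid.pixel_size,
        origin=(
            grid.origin[0] + (window - 1) / 2 * grid.pixel_size,
            grid.origin[1] + (window - 1) / 2 * grid.pixel_size,
        ),
    )
    return VectorField2D(out_grid, ux, uy, units="um")


def _piv_deform_pass(
    img_ref: ScalarImage,
    img_def: ScalarImage,
    estimate: VectorField2D,
    window: int,
    step: int,
) -> VectorField2D:
    """One image-deformation refinement: warp, re-correlate, accumulate."""
    from scipy.interpolate import RegularGridInterpolator
    from scipy.ndimage import map_coordinates

    from .core_io import fill_invalid

    grid = img_ref.grid
    est = fill_invalid(estimate)
    gy, gx = np.mgrid[0 : grid.ny, 0 : grid.nx].astype(float)
    pts = np.column_stack(
        [(grid.origin[1] + gy.ravel() * grid.pixel_size),
         (grid.origin[0] + gx.ravel() * grid.pixel_size)]
    )
    itp_x = RegularGridInterpolator(
        (est.grid.y, est.grid.x), est.comp_x, bounds_error=False, fill_value=None
    )
    itp_y = RegularGridInterpolator(
        (est.grid.y, est.grid.x), est.comp_y, bounds_error=False, fill_value=None
    )
    dx = itp_x(pts).reshape(grid.shape) / grid.pixel_size
    dy = itp_y(pts).reshape(grid.shape) / grid.pixel_size
    warped = map_coordinates(img_def.values, [gy + dy, gx + dx], order=3, mode="nearest")
    resid = _piv_single_pass(img_ref, ScalarImage(grid, warped), window, step)
    base_x, base_y = _sample_field(est, resid.grid)
    return VectorField2D(
        resid.grid,
        np.where(np.isfinite(resid.comp_x), resid.comp_x, 0.0) + base_x,
        np.where(np.isfinite(resid.comp_y), resid.comp_y, 0.0) + base_y,
        units="um",
    )


def _sample_field(field: VectorField2D, grid: Grid2D) -> tuple[np.ndarray, np.ndarray]:
    from scipy.interpolate import RegularGridInterpolator

    yy, xx = np.meshgrid(grid.y, grid.x, indexing="ij")
    pts = np.column_stack([yy.ravel(), xx.ravel()])
    out = []
    for comp in (field.comp_x, field.comp_y):
        itp = RegularGridInterpolator(
            (field.grid.y, field.grid.x), comp, bounds_error=False, fill_value=None
        )
        out.append(itp(pts).reshape(grid.shape))
    return out[0], out[1]


def select_lambda_gcv(
    displacement: VectorField2D,
    substrate: ElasticSubstrate = ElasticSubstrate(),
    lambda_grid: np.ndarray | None = None,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Pick the Tikhonov parameter by generalized cross-validation.

    GCV minimizes ||residual||^2 / (effective residual degrees of
    freedom)^2 over the lambda grid, computed in closed form from the
    per-wavevector eigenvalues of the spectral kernel.  Unlike the L-curve
    corner it remains well behaved when the displacement errors are
    spatially correlated (e.g. PIV window averaging), which makes it the
    selector used by the bead-image pipeline.  Returns
    ``(lambda_star, lambdas, scores)``.
    """
    g = displacement.grid
    Gk = fourier_kernel(g, substrate)
    U = _fft_field(displacement.comp_x, displacement.comp_y)
    w, V = np.linalg.eigh(Gk.reshape(-1, 2, 2))
    coef = np.einsum("nij,ni->nj", V, U.reshape(-1, 2).conj()).conj()
    sv = np.abs(w)
    if lambda_grid is None:
        sv_min = sv[sv > 0].min()
        lambda_grid = np.geomspace(1e-3, 1e2, 40) * sv_min
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    scores = np.empty(len(lambda_grid))
    for i, lam in enumerate(lambda_grid):
        infl = w**2 / (w**2 + lam**2)
        res2 = np.sum(np.abs(coef * (1.0 - infl)) ** 2)
        dof = max(coef.size - np.sum(infl), 1e-9)
        scores[i] = res2 / dof**2
    idx = int(np.argmin(scores))
    return float(lambda_grid[idx]), lambda_grid, scores


def traction_from_bead_images(
    img_ref: ScalarImage,
    img_def: ScalarImage,
    force_grid: Grid2D,
    substrate: ElasticSubstrate = ElasticSubstrate(),
    window: int = 32,
    step: int = 16,
    passes: int = 3,
    lambda_reg: float | None = None,
    mode: str = "padded",
) -> VectorField2D:
    """Full inverse pipeline: multi-pass PIV -> resample -> Tikhonov FTTC.

    ``lambda_reg=None`` selects the parameter by GCV on the resampled
    displacement field.
    """
    from .core_io import fill_invalid, resample_field

    pv = fill_invalid(piv_displacement(img_ref, img_def, window, step, passes=passes))
    rs = resample_field(pv, force_grid)
    if lambda_reg is None:
        lambda_reg, _, _ = select_lambda_gcv(rs, substrate)
    return solve_traction_fttc(rs, substrate, TikhonovConfig(lambda_reg, mode))
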