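"""Wrinkle geometry and traction statistics of single cells.

Traction side: the mean traction f_bar averages per-node force norms; the
force-weighted stress tensor

    S_ij = 1/(2M) sum_m { n_j(x_m, x_0) f_i(x_m) + n_i(x_m, x_0) f_j(x_m) }

(n the unit vector from the image center x_0 to node x_m) is diagonalized
to get the principal traction direction phi_s, the principal traction f_p
(negative = contractile) and the isotropy I = |f_p / f_p_min|.

Wrinkle side: length is the pixel count of the skeletonized mask, the
principal wrinkle direction phi_w comes from the orientation of maximum
power in the 2-D FFT (wrinkles run perpendicular to their wavevector), and
the topology is summarized by counting connected wrinkle regions.

All angles are axial quantities in degrees, in [0, 180), measured
counter-clockwise from +x in the y-up physical frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import label as cc_label, perimeter_crofton, regionprops
from skimage.morphology import skeletonize

from .core_io import BinaryMask, ScalarImage, VectorField2D

#: isotropy / degeneracy tolerance for near-zero second eigenvalues
_EIG_TOL = 1e-9


@dataclass(frozen=True)
class StressSummary:
    """Per-cell traction scalars."""

    mean_traction: float          # Pa
    S: np.ndarray                 # symmetric 2x2, Pa (image-frame components)
    phi_s: float                  # principal direction, deg in [0, 180)
    f_p: float                    # principal traction, Pa (signed)
    f_p_min: float                # second eigenvalue, Pa
    isotropy: float               # |f_p / f_p_min|, NaN when undefined
    degenerate: bool = False      # eigenvalues (near-)equal: phi_s arbitrary


@dataclass(frozen=True)
class WrinkleSummary:
    """Per-cell wrinkle geometry scalars."""

    length_px: int
    length_um: float
    phi_w: float                  # deg in [0, 180), NaN when undefined
    n_components: int
    topology_label: str           # 'clustered' | 'dispersed'


def mean_traction(traction: VectorField2D) -> float:
    """Mean of the per-node traction norms, f_bar = (1/M) sum |f_m|, Pa."""
    mag = traction.magnitude
    if mag.size == 0:
        raise ValueError("empty traction field")
    return float(mag.mean())


def stress_tensor(
    traction: VectorField2D, center: np.ndarray | None = None
) -> np.ndarray:
    """Force-weighted symmetric stress tensor of a traction field, Pa.

    ``center`` defaults to the grid center x_0.  Nodes coinciding with the
    center (where n is undefined) are skipped; components are in the image
    frame (the y-flip to the physical frame happens in
    :func:`principal_traction`).
    """
    g = traction.grid
    if center is None:
        center = g.center
    xx, yy = g.meshgrid()
    rx = xx - center[0]
    ry = yy - center[1]
    rr = np.hypot(rx, ry)
    keep = rr > 0
    if not keep.any():
        raise ValueError("all nodes coincide with the center; geometry degenerate")
    nx_, ny_ = rx[keep] / rr[keep], ry[keep] / rr[keep]
    fx, fy = traction.comp_x[keep], traction.comp_y[keep]
    M = traction.comp_x.size  # normalization uses the full node count
    S = np.empty((2, 2))
    S[0, 0] = np.sum(nx_ * fx) / M
    S[1, 1] = np.sum(ny_ * fy) / M
    S[0, 1] = S[1, 0] = np.sum(nx_ * fy + ny_ * fx) / (2 * M)
    return S


def principal_traction(S: np.ndarray) -> tuple[float, float, float, float]:
    """Diagonalize a stress tensor: (phi_s, f_p, f_p_min, isotropy).

    f_p is the eigenvalue of largest absolute value (negative for a
    contractile cell), phi_s the physical-frame angle of its eigenvector
    folded into [0, 180).  Isotropy I = |f_p / f_p_min| is NaN when the
    second eigenvalue is numerically zero.  For a degenerate (isotropic)
    tensor phi_s is reported as 0.
    """
    S = np.asarray(S, dtype=float)
    if S.shape != (2, 2) or not np.allclose(S, S.T, atol=1e-9 * max(1.0, np.abs(S).max())):
        raise ValueError("S must be a symmetric 2x2 tensor")
    # image frame -> y-up physical frame: similarity with diag(1, -1)
    S_phys = S * np.array([[1.0, -1.0], [-1.0, 1.0]])
    evals, evecs = np.linalg.eigh(S_phys)
    order = np.argsort(np.abs(evals))[::-1]
    f_p, f_p_min = float(evals[order[0]]), float(evals[order[1]])
    scale = max(np.abs(f_p), _EIG_TOL)
    degenerate = np.isclose(f_p, f_p_min, rtol=1e-9, atol=_EIG_TOL * scale)
    if degenerate:
        phi_s = 0.0
    else:
        vx, vy = evecs[:, order[0]]
        phi_s = float(np.degrees(np.arctan2(vy, vx)) % 180.0)
        if np.isclose(phi_s, 180.0):
            phi_s = 0.0
    if np.abs(f_p_min) < _EIG_TOL * scale:
        iso = float("nan")
    else:
        iso = abs(f_p / f_p_min)
    return phi_s, f_p, f_p_min, iso


def stress_summary(
    traction: VectorField2D, center: np.ndarray | None = None
) -> StressSummary:
    """Mean traction plus the full principal decomposition of one field."""
    S = stress_tensor(traction, center)
    phi_s, f_p, f_p_min, iso = principal_traction(S)
    degenerate = np.isclose(f_p, f_p_min, rtol=1e-9, atol=_EIG_TOL)
    return StressSummary(
        mean_traction=mean_traction(traction),
        S=S,
        phi_s=phi_s,
        f_p=f_p,
        f_p_min=f_p_min,
        isotropy=iso,
        degenerate=bool(degenerate),
    )


def wrinkle_length(mask: BinaryMask) -> tuple[int, BinaryMask]:
    """Skeleton pixel count of a wrinkle mask (and the skeleton itself)."""
    skel = skeletonize(mask.values.astype(bool))
    return int(skel.sum()), BinaryMask(mask.grid, skel)


def wrinkle_direction_fft(
    image: ScalarImage | BinaryMask,
    bin_deg: float = 2.0,
    min_foreground_px: int = 10,
    low_k_cycles: float = 6.0,
    anisotropy_min: float = 1.5,
) -> float:
    """Principal wrinkle direction from the 2-D power spectrum, degrees.

    The image is Hann-windowed; power below ``low_k_cycles`` cycles/image
    (incl. DC) is masked to suppress cell-outline leakage; the remaining
    power is summed in ``bin_deg``-wide axial orientation bins and phi_w is
    the argmax orientation rotated by 90 degrees (wrinkle ridges run
    perpendicular to their wavevector).  Returns NaN when the foreground is
    below ``min_foreground_px`` or the spectrum is isotropic
    (max/median bin power < ``anisotropy_min``).
    """
    vals = np.asarray(image.values, dtype=float)
    if isinstance(image, BinaryMask):
        foreground = int(vals.sum())
    else:
        foreground = int(np.sum(vals > vals.mean()))
    if foreground < min_foreground_px:
        return float("nan")
    ny, nx = vals.shape
    win = np.outer(np.hanning(ny), np.hanning(nx))
    F = np.fft.fftshift(np.fft.fft2((vals - vals.mean()) * win))
    power = np.abs(F) ** 2
    fy = np.fft.fftshift(np.fft.fftfreq(ny)) * ny   # cycles per image
    fx = np.fft.fftshift(np.fft.fftfreq(nx)) * nx
    KX, KY = np.meshgrid(fx, fy)
    kmag = np.hypot(KX, KY)
    # inscribed disk only: every orientation then samples equal k-support,
    # otherwise the lattice corners bias the histogram toward the diagonals
    keep = (kmag >= low_k_cycles) & (kmag <= min(nx, ny) / 2)
    # orientation of the wavevector in the y-up physical frame, axial
    theta = np.degrees(np.arctan2(-KY, KX)) % 180.0
    nbins = int(round(180.0 / bin_deg))
    bins = np.minimum((theta[keep] / bin_deg).astype(int), nbins - 1)
    hist = np.bincount(bins, weights=power[keep], minlength=nbins)
    counts = np.bincount(bins, minlength=nbins)
    hist = np.where(counts > 0, hist / np.maximum(counts, 1), 0.0)
    # circular smoothing stabilizes the argmax against bin-level speckle
    kern = np.ones(5) / 5.0
    hist = np.convolve(np.concatenate([hist[-2:], hist, hist[:2]]), kern, "valid")
    med = np.median(hist)
    if med <= 0 or hist.max() / med < anisotropy_min:
        return float("nan")
    k_dir = (np.argmax(hist) + 0.5) * bin_deg
    return float((k_dir + 90.0) % 180.0)


def angle_difference(phi_a: float, phi_b: float) -> float:
    """Axial difference of two direction angles, degrees in [0, 90]."""
    if not (np.isfinite(phi_a) and np.isfinite(phi_b)):
        return float("nan")
    d = abs(phi_a % 180.0 - phi_b % 180.0)
    return float(min(d, 180.0 - d))


def wrinkle_topology(mask: BinaryMask, min_region_px: int = 20) -> tuple[int, str]:
    """Count 8-connected wrinkle regions of at least ``min_region_px`` pixels.

    One region (or none) is labelled 'clustered', several 'dispersed'.
    """
    lab = cc_label(mask.values, connectivity=2)
    sizes = np.bincount(lab.ravel())[1:]
    n = int(np.sum(sizes >= min_region_px))
    return n, ("clustered" if n <= 1 else "dispersed")


def cell_morphometrics(cell_mask: BinaryMask) -> tuple[float, float]:
    """(area in um^2, roundness 4 pi A / P^2) of a single-component mask."""
    lab = cc_label(cell_mask.values, connectivity=2)
    n = lab.max()
    if n == 0:
        raise ValueError("empty cell mask")
    if n > 1:
        raise ValueError(f"cell mask has {n} components; expected exactly 1")
    props = regionprops(lab)[0]
    ps = cell_mask.grid.pixel_size
    area_um2 = props.area * ps**2
    perim = perimeter_crofton(lab > 0, directions=4) * ps
    if perim <= 0:
        raise ValueError("degenerate mask perimeter")
    roundness = min(4.0 * np.pi * area_um2 / perim**2, 1.0)
    return float(area_um2), float(roundness)
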