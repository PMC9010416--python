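"""Synthetic contractile cells: paired traction fields, bead images and wrinkles.

Emulates the measurement scenario end-to-end without any experimental
data: a contractile adherent cell is modelled as a set of inward-pointing
force dipoles anchored at adhesion sites on an elliptical outline, on the
standard 26 x 26 force grid at 3.44 um spacing.  Every sampled traction
field is exactly force- and torque-balanced.  From the traction field the
generator renders

* reference/deformed fluorescent-bead image pairs (through the Boussinesq
  forward map), the input of the PIV + FTTC chain;
* binary wrinkle masks and pseudo-micrographs: sinusoidal ridges drawn
  perpendicular to the local force axis, spaced by the bilayer buckling
  wavelength, with total ridge length proportional to the local force
  magnitude and no ridges below the ~10 Pa extinction floor;
* rotation-augmented (image, traction) training datasets with a manifest.

Magnitudes default to mean tractions of a few tens of Pa (peak scale
50-300 Pa), the range observed for contractile smooth-muscle cells on
~5 kPa substrates.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.ndimage import gaussian_filter

from .core_io import BinaryMask, Grid2D, ScalarImage, VectorField2D, write_field, write_image
from .codec_metrics import rotate_field_90, rotate_image_90, rotate_mask_90
from .tfm import ElasticSubstrate, forward_displacement
from .wrinkle_mechanics import BilayerSubstrate

#: standard force observation grid
FORCE_GRID = Grid2D(nx=26, ny=26, pixel_size=3.44)

#: default bilayer consistent with the ~3 um wavelengths seen on
#: plasma-oxidized PDMS: stiffness ratio 300, skin thickness 0.1 um
DEFAULT_BILAYER = BilayerSubstrate(E_m=5400.0, E_p=300.0 * 5400.0, h=0.1)


@dataclass(frozen=True)
class SyntheticCellSpec:
    """Parameters of the synthetic-cell population.

    Ranges are sampled per cell from the spec's seeded generator.
    """

    n_adhesions: tuple[int, int] = (6, 16)
    cell_radius: float = 20.0             # um, mean outline radius
    traction_scale: tuple[float, float] = (50.0, 300.0)  # Pa, peak spot magnitude
    adhesion_spot_sigma: float = 5.0      # um, Gaussian adhesion footprint
    noise_sd_displacement: float = 0.02   # um, added to bead displacements
    bead_density: float = 0.4             # beads per um^2
    wrinkle_floor: float = 10.0           # Pa, extinction threshold
    ridge_length_per_pa: float = 0.05     # um of ridge per Pa per node
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.cell_radius, self.adhesion_spot_sigma, self.bead_density) <= 0:
            raise ValueError("all scales must be positive")
        if self.wrinkle_floor <= 0 or self.ridge_length_per_pa <= 0:
            raise ValueError("all scales must be positive")

    def rng(self, *streams: int) -> np.random.Generator:
        """Named child generator so sub-steps reproduce independently."""
        return np.random.default_rng([self.seed, *streams])


def sample_traction(
    spec: SyntheticCellSpec,
    grid: Grid2D = FORCE_GRID,
    cell_index: int = 0,
    traction_scale: float | None = None,
) -> VectorField2D:
    """Draw one balanced contractile traction field (Pa).

    Adhesion spots sit on a randomly oriented elliptical outline and pull
    inward toward the cell center; each spot is a Gaussian of footprint
    ``adhesion_spot_sigma``.  The field is then projected to zero net
    torque and zero net force (residuals < 1e-9 of the scale).
    """
    rng = spec.rng(1, cell_index)
    scale = (
        float(traction_scale)
        if traction_scale is not None
        else float(rng.uniform(*spec.traction_scale))
    )
    n_adh = int(rng.integers(spec.n_adhesions[0], spec.n_adhesions[1] + 1))
    center = grid.center + rng.uniform(-3.0, 3.0, size=2)
    a = spec.cell_radius * rng.uniform(0.7, 1.1)
    b = a * rng.uniform(0.45, 0.85)
    tilt = rng.uniform(0, np.pi)
    ct, st = np.cos(tilt), np.sin(tilt)

    xx, yy = grid.meshgrid()
    fx = np.zeros(grid.shape)
    fy = np.zeros(grid.shape)
    angles = np.sort(rng.uniform(0, 2 * np.pi, size=n_adh))
    for ang in angles:
        ex, ey = a * np.cos(ang), b * np.sin(ang)
        px = center[0] + ct * ex - st * ey
        py = center[1] + st * ex + ct * ey
        dx, dy = center[0] - px, center[1] - py
        norm = np.hypot(dx, dy)
        if norm == 0:
            continue
        ux, uy = dx / norm, dy / norm
        # small tangential jitter keeps the dipoles from being perfectly radial
        jitter = rng.normal(0, 0.15)
        ux, uy = ux - jitter * uy, uy + jitter * ux
        # stress fibres run along the long axis of a spindle-shaped cell, so
        # adhesions near the poles pull hardest
        polar_weight = 0.35 + 0.65 * np.cos(ang) ** 2
        mag = scale * polar_weight * rng.uniform(0.4, 1.0)
        w = np.exp(
            -((xx - px) ** 2 + (yy - py) ** 2) / (2 * spec.adhesion_spot_sigma**2)
        )
        fx += mag * ux * w
        fy += mag * uy * w

    # exact balance: project out rigid rotation (torque), then the mean (force)
    rx = xx - grid.center[0]
    ry = yy - grid.center[1]
    torque = np.sum(rx * fy - ry * fx)
    wnorm = np.sum(rx**2 + ry**2)
    fx += torque / wnorm * ry
    fy -= torque / wnorm * rx
    fx -= fx.mean()
    fy -= fy.mean()
    return VectorField2D(grid, fx, fy, units="Pa")


# ---------------------------------------------------------------------------
# bead images

def _render_beads(
    grid: Grid2D, pos_x: np.ndarray, pos_y: np.ndarray, amp: np.ndarray, sigma_px: float
) -> np.ndarray:
    """Accumulate Gaussian point-spread spots at sub-pixel positions."""
    img = np.zeros(grid.shape)
    half = int(np.ceil(4 * sigma_px))
    px = pos_x / grid.pixel_size
    py = pos_y / grid.pixel_size
    for x, y, A in zip(px, py, amp):
        cx, cy = int(round(x)), int(round(y))
        x0, x1 = max(cx - half, 0), min(cx + half + 1, grid.nx)
        y0, y1 = max(cy - half, 0), min(cy + half + 1, grid.ny)
        if x0 >= x1 or y0 >= y1:
            continue
        gx = np.arange(x0, x1) - x
        gy = np.arange(y0, y1) - y
        img[y0:y1, x0:x1] += A * np.exp(
            -(gy[:, None] ** 2 + gx[None, :] ** 2) / (2 * sigma_px**2)
        )
    return img


def render_bead_images(
    traction: VectorField2D,
    substrate: ElasticSubstrate = ElasticSubstrate(),
    spec: SyntheticCellSpec = SyntheticCellSpec(),
    upsample: int = 8,
    psf_sigma_px: float = 1.3,
    image_noise_sd: float = 0.0,
    piv_window: int = 32,
) -> tuple[ScalarImage, ScalarImage, VectorField2D]:
    """Reference and deformed bead images plus the true displacement field.

    Beads are scattered uniformly at ``bead_density`` on a grid ``upsample``
    times finer than the force grid; the deformed image warps each bead by
    the Boussinesq forward displacement interpolated to its position (plus
    ``noise_sd_displacement`` jitter).  A warning is raised when the bead
    count per PIV window falls below 10.
    """
    rng = spec.rng(2)
    g = traction.grid
    img_grid = Grid2D(
        nx=g.nx * upsample, ny=g.ny * upsample, pixel_size=g.pixel_size / upsample
    )
    extent_x = img_grid.nx * img_grid.pixel_size
    extent_y = img_grid.ny * img_grid.pixel_size
    n_beads = int(spec.bead_density * extent_x * extent_y)
    per_window = spec.bead_density * (piv_window * img_grid.pixel_size) ** 2
    if per_window < 10:
        warnings.warn(
            f"~{per_window:.1f} beads per {piv_window}-px PIV window (< 10); "
            "displacement estimates will be unreliable"
        )
    pos_x = rng.uniform(0, extent_x, n_beads)
    pos_y = rng.uniform(0, extent_y, n_beads)
    amp = rng.uniform(0.5, 1.0, n_beads)

    disp = forward_displacement(traction, substrate, mode="padded")
    itp_x = RegularGridInterpolator(
        (g.y, g.x), disp.comp_x, bounds_error=False, fill_value=0.0
    )
    itp_y = RegularGridInterpolator(
        (g.y, g.x), disp.comp_y, bounds_error=False, fill_value=0.0
    )
    pts = np.column_stack([pos_y, pos_x])
    dx = itp_x(pts) + rng.normal(0, spec.noise_sd_displacement, n_beads)
    dy = itp_y(pts) + rng.normal(0, spec.noise_sd_displacement, n_beads)

    ref = _render_beads(img_grid, pos_x, pos_y, amp, psf_sigma_px)
    deformed = _render_beads(img_grid, pos_x + dx, pos_y + dy, amp, psf_sigma_px)
    if image_noise_sd > 0:
        ref = ref + rng.normal(0, image_noise_sd, ref.shape)
        deformed = deformed + rng.normal(0, image_noise_sd, deformed.shape)
    return (
        ScalarImage(img_grid, ref),
        ScalarImage(img_grid, deformed),
        disp,
    )


# ---------------------------------------------------------------------------
# wrinkles

def render_wrinkles(
    traction: VectorField2D,
    bilayer: BilayerSubstrate = DEFAULT_BILAYER,
    grid: Grid2D | None = None,
    spec: SyntheticCellSpec = SyntheticCellSpec(),
) -> tuple[BinaryMask, ScalarImage]:
    """Draw the wrinkle pattern a traction field would produce.

    The traction is smoothed; wherever the local force magnitude exceeds
    ``wrinkle_floor`` a ridge segment is drawn through the node,
    perpendicular to the local force axis, its length
    ``ridge_length_per_pa * |f|`` — so total ridge length grows linearly
    with the force.  Segments snap to phase lines spaced by the bilayer
    buckling wavelength along the force direction.  When the image-mean
    traction is below the floor the mask is empty (wrinkle extinction).
    The pseudo-micrograph adds a soft cell body and shot-like noise on top
    of the ridges.
    """
    g = traction.grid
    if grid is None:
        grid = Grid2D(nx=g.nx * 4, ny=g.ny * 4, pixel_size=g.pixel_size / 4)
    wavelength = bilayer.wavelength
    rng = spec.rng(3)

    extinct = float(traction.magnitude.mean()) < spec.wrinkle_floor
    mag = np.hypot(
        gaussian_filter(traction.comp_x, 0.8), gaussian_filter(traction.comp_y, 0.8)
    )
    if extinct:
        mag = np.zeros_like(mag)
    # the ridge orientation field is smoothed harder than the magnitude so
    # that nearby segments stay parallel and resolve into clean stripes
    dir_x = gaussian_filter(traction.comp_x, 2.0)
    dir_y = gaussian_filter(traction.comp_y, 2.0)
    dir_n = np.hypot(dir_x, dir_y)
    seg_cap = 2.0 * wavelength  # longer ridges split onto adjacent phase lines
    canvas = np.zeros(grid.shape, dtype=bool)
    xx, yy = g.meshgrid()
    for i in range(g.ny):
        for j in range(g.nx):
            m = mag[i, j]
            if m <= spec.wrinkle_floor or dir_n[i, j] == 0:
                continue
            ex = dir_x[i, j] / dir_n[i, j]
            ey = dir_y[i, j] / dir_n[i, j]
            # snap the segment center to the nearest buckling phase line
            s = xx[i, j] * ex + yy[i, j] * ey
            shift = np.round(s / wavelength) * wavelength - s
            cx = xx[i, j] + shift * ex
            cy = yy[i, j] + shift * ey
            total = spec.ridge_length_per_pa * m
            n_seg = max(1, int(np.ceil(total / seg_cap)))
            half = 0.5 * total / n_seg
            for r in range(n_seg):
                off = (r - (n_seg - 1) / 2) * wavelength
                _draw_segment(
                    canvas, grid, cx + off * ex, cy + off * ey, -ey, ex, half
                )
    mask = BinaryMask(grid, canvas)

    body = np.zeros(grid.shape)
    gx, gy = grid.meshgrid()
    cxy = g.center
    r2 = (gx - cxy[0]) ** 2 + (gy - cxy[1]) ** 2
    body = 60.0 * np.exp(-r2 / (2 * (0.8 * spec.cell_radius) ** 2))
    micro = body + 140.0 * canvas + rng.normal(0, 4.0, grid.shape)
    micro = np.clip(micro, 0, 255)
    return mask, ScalarImage(grid, micro)


def _draw_segment(canvas, grid, cx, cy, ux, uy, half_len):
    """Rasterize a centered segment (physical um coords) onto a boolean canvas."""
    from skimage.draw import line

    p0 = ((cx - ux * half_len) / grid.pixel_size, (cy - uy * half_len) / grid.pixel_size)
    p1 = ((cx + ux * half_len) / grid.pixel_size, (cy + uy * half_len) / grid.pixel_size)
    r0, c0 = int(round(p0[1])), int(round(p0[0]))
    r1, c1 = int(round(p1[1])), int(round(p1[0]))
    rr, cc = line(r0, c0, r1, c1)
    keep = (rr >= 0) & (rr < grid.ny) & (cc >= 0) & (cc < grid.nx)
    canvas[rr[keep], cc[keep]] = True


# ---------------------------------------------------------------------------
# datasets

def build_dataset(
    n_cells: int,
    spec: SyntheticCellSpec,
    out_dir: str,
    image_size: int = 64,
    input_kind: str = "wrinkle_mask",
    test_fraction: float = 0.1,
    bilayer: BilayerSubstrate = DEFAULT_BILAYER,
) -> dict:
    """Write an augmented (input image, traction) dataset and its manifest.

    Each of the ``n_cells`` base cells is rotated by 0/90/180/270 degrees
    (force components co-rotated), so the manifest lists exactly
    ``4 * n_cells`` pairs.  The train/test split is drawn per *base cell*
    from the dataset seed so augmented copies never straddle the split.
    """
    if input_kind not in ("wrinkle_mask", "micrograph"):
        raise ValueError(f"unknown input_kind {input_kind!r}")
    os.makedirs(out_dir, exist_ok=True)
    img_grid = Grid2D(
        nx=image_size,
        ny=image_size,
        pixel_size=FORCE_GRID.nx * FORCE_GRID.pixel_size / image_size,
    )
    split_rng = spec.rng(4)
    n_test = int(round(test_fraction * n_cells))
    test_ids = set(split_rng.choice(n_cells, size=n_test, replace=False).tolist())

    pairs = []
    for idx in range(n_cells):
        traction = sample_traction(spec, cell_index=idx)
        mask, micro = render_wrinkles(traction, bilayer, grid=img_grid, spec=spec)
        image = ScalarImage(img_grid, mask.values * 255.0) if input_kind == "wrinkle_mask" else micro
        split = "test" if idx in test_ids else "train"
        img, tr = image, traction
        for k in range(4):
            img_path = os.path.join(out_dir, f"cell{idx:04d}_rot{k}.tif")
            tr_path = os.path.join(out_dir, f"cell{idx:04d}_rot{k}_traction.csv")
            write_image(img, img_path)
            write_field(tr, tr_path)
            pairs.append(
                {
                    "id": f"cell{idx:04d}_rot{k}",
                    "base": idx,
                    "rot_k": k,
                    "image": os.path.basename(img_path),
                    "traction": os.path.basename(tr_path),
                    "split": split,
                }
            )
            img = rotate_image_90(img)
            tr = rotate_field_90(tr)
    manifest = {
        "seed": spec.seed,
        "n_base": n_cells,
        "n_pairs": len(pairs),
        "input_kind": input_kind,
        "image_size": image_size,
        "pixel_size_um": img_grid.pixel_size,
        "force_grid": {"nx": FORCE_GRID.nx, "ny": FORCE_GRID.ny, "spacing_um": FORCE_GRID.pixel_size},
        "pairs": pairs,
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
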