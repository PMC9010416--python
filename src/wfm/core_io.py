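"""Grids, images, masks and vector fields shared by every pipeline stage.

Conventions
-----------
Arrays are row-major in image convention: index ``[i, j]`` is row ``i``
(increasing downward) and column ``j``.  Grid nodes sit at pixel centers,
node ``(0, 0)`` at physical ``(0, 0)`` micrometres.  Angles are reported in
degrees, counter-clockwise from the +x axis in a y-up physical frame; the
single y-flip this requires is applied inside the angle-producing
operations, never here.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import imageio.v3 as iio
import tifffile
import yaml


class GridMismatchError(ValueError):
    """Two inputs of an operation live on different grids."""


class FieldParseError(ValueError):
    """A delimited-text vector-field file is malformed."""


@dataclass(frozen=True)
class Grid2D:
    """Regular pixel grid with square pixels.

    Parameters
    ----------
    nx, ny : int
        Number of columns and rows (both at least 2).
    pixel_size : float
        Node spacing in micrometres.
    """

    nx: int
    ny: int
    pixel_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.nx < 2 or self.ny < 2:
            raise ValueError(f"grid needs nx, ny >= 2, got {self.nx}x{self.ny}")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")
        object.__setattr__(self, "origin", (float(self.origin[0]), float(self.origin[1])))

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    @property
    def x(self) -> np.ndarray:
        """Physical x of each column, micrometres."""
        return self.origin[0] + np.arange(self.nx) * self.pixel_size

    @property
    def y(self) -> np.ndarray:
        """Physical y of each row (image convention, downward), micrometres."""
        return self.origin[1] + np.arange(self.ny) * self.pixel_size

    @property
    def center(self) -> np.ndarray:
        """Grid center origin + ((nx-1)/2, (ny-1)/2) * pixel_size, micrometres."""
        return np.array(
            [
                self.origin[0] + (self.nx - 1) / 2 * self.pixel_size,
                self.origin[1] + (self.ny - 1) / 2 * self.pixel_size,
            ]
        )

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.x, self.y)


def _check_shape(grid: Grid2D, values: np.ndarray, what: str) -> np.ndarray:
    values = np.asarray(values)
    if values.shape != grid.shape:
        raise GridMismatchError(
            f"{what} shape {values.shape} does not match grid {grid.shape}"
        )
    return values


@dataclass(frozen=True)
class ScalarImage:
    """Grayscale raster (micrograph or encoded-force image) on a pixel grid."""

    grid: Grid2D
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = _check_shape(self.grid, self.values, "image").astype(float)
        if not np.all(np.isfinite(v)):
            raise ValueError("image intensities must be finite")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class BinaryMask:
    """{0, 1} raster, e.g. extracted wrinkles or a cell outline."""

    grid: Grid2D
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = _check_shape(self.grid, self.values, "mask")
        v = (np.asarray(v) != 0).astype(np.uint8)
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class VectorField2D:
    """Two-component field on a regular grid.

    The central currency of the pipeline: displacement fields carry
    ``units='um'``, traction fields ``units='Pa'``.  NaN marks a node
    flagged invalid by an estimator (e.g. a featureless PIV window);
    infinities are always rejected.
    """

    grid: Grid2D
    comp_x: np.ndarray = field(repr=False)
    comp_y: np.ndarray = field(repr=False)
    units: str = "Pa"

    def __post_init__(self) -> None:
        cx = _check_shape(self.grid, self.comp_x, "comp_x").astype(float)
        cy = _check_shape(self.grid, self.comp_y, "comp_y").astype(float)
        if np.any(np.isinf(cx)) or np.any(np.isinf(cy)):
            raise ValueError("field components must not be infinite")
        object.__setattr__(self, "comp_x", cx)
        object.__setattr__(self, "comp_y", cy)

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.comp_x, self.comp_y)

    def with_components(self, cx: np.ndarray, cy: np.ndarray) -> "VectorField2D":
        return VectorField2D(self.grid, cx, cy, self.units)

    def __mul__(self, c: float) -> "VectorField2D":
        return self.with_components(self.comp_x * c, self.comp_y * c)

    __rmul__ = __mul__


def same_grid(*objs) -> Grid2D:
    """Return the common grid of the arguments or raise GridMismatchError."""
    grids = [o.grid for o in objs]
    g0 = grids[0]
    for g in grids[1:]:
        if g != g0:
            raise GridMismatchError(f"grid mismatch: {g} vs {g0}")
    return g0


# ---------------------------------------------------------------------------
# raster I/O

def read_image(path: str, pixel_size: float | None = None) -> ScalarImage:
    """Read a single-channel TIFF or PNG as a ScalarImage.

    ``pixel_size`` falls back to TIFF resolution metadata when present,
    else 1.0 um.  Intensities are returned exactly as stored (no rescaling).
    """
    if not os.path.exists(path):
        raise IOError(f"image file not found: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend specific
        raise IOError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim == 3:
        if arr.shape[2] in (3, 4) and np.all(arr[..., 0] == arr[..., 1]):
            arr = arr[..., 0]
        else:
            raise ValueError(f"multi-channel image without conversion rule: {path}")
    if pixel_size is None:
        pixel_size = _tiff_pixel_size(path) or 1.0
    ny, nx = arr.shape
    return ScalarImage(Grid2D(nx=nx, ny=ny, pixel_size=pixel_size), arr.astype(float))


def _tiff_pixel_size(path: str) -> float | None:
    if not path.lower().endswith((".tif", ".tiff")):
        return None
    try:
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            res = page.tags.get("XResolution")
            if res is None:
                return None
            num, den = res.value
            if num == 0:
                return None
            return den / num  # pixels per unit -> unit per pixel
    except Exception:
        return None


def write_image(image: ScalarImage | BinaryMask, path: str) -> None:
    """Write an image or mask as TIFF/PNG, preserving integer dtypes.

    TIFF output embeds the pixel size as resolution metadata so that
    :func:`read_image` recovers the physical grid.
    """
    arr = image.values
    if isinstance(image, BinaryMask):
        arr = (arr * 255).astype(np.uint8)
    elif np.issubdtype(arr.dtype, np.floating):
        if np.allclose(arr, np.round(arr)) and arr.min() >= 0:
            arr = arr.astype(np.uint16 if arr.max() > 255 else np.uint8)
    if path.lower().endswith((".tif", ".tiff")):
        ps = image.grid.pixel_size
        tifffile.imwrite(path, arr, resolution=(1.0 / ps, 1.0 / ps))
    else:
        iio.imwrite(path, arr)


def read_mask(path: str, pixel_size: float | None = None) -> BinaryMask:
    img = read_image(path, pixel_size=pixel_size)
    return BinaryMask(img.grid, img.values > 0)


# ---------------------------------------------------------------------------
# vector-field I/O: delimited text with an explicit units comment

_FIELD_HEADER = ["x_um", "y_um", "cx", "cy"]


def write_field(field2d: VectorField2D, path: str) -> None:
    """Write a field as CSV with columns x_um, y_um, cx, cy.

    A ``# units: ...`` comment line records whether the components are
    displacements (um) or tractions (Pa); ``# pixel_size_um`` makes the
    round trip exact.
    """
    g = field2d.grid
    xx, yy = g.meshgrid()
    table = np.column_stack(
        [xx.ravel(), yy.ravel(), field2d.comp_x.ravel(), field2d.comp_y.ravel()]
    )
    with open(path, "w") as fh:
        fh.write(f"# units: {field2d.units}\n")
        fh.write(f"# pixel_size_um: {g.pixel_size!r}\n")
        fh.write(f"# shape: {g.ny} {g.nx}\n")
        fh.write(",".join(_FIELD_HEADER) + "\n")
        np.savetxt(fh, table, delimiter=",", fmt="%.17g")


def read_field(path: str) -> VectorField2D:
    """Read a field written by :func:`write_field` (comma or tab delimited)."""
    units = "Pa"
    pixel_size = None
    shape = None
    data_lines: list[tuple[int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("units:"):
                    units = body.split(":", 1)[1].strip()
                elif body.startswith("pixel_size_um:"):
                    pixel_size = float(body.split(":", 1)[1])
                elif body.startswith("shape:"):
                    shape = tuple(int(t) for t in body.split(":", 1)[1].split())
                continue
            data_lines.append((lineno, line))
    if not data_lines:
        raise FieldParseError(f"{path}: no data rows")
    delim = "\t" if "\t" in data_lines[0][1] else ","
    header_line, header = data_lines[0]
    cols = [c.strip() for c in header.split(delim)]
    if cols != _FIELD_HEADER:
        raise FieldParseError(
            f"{path}:{header_line}: expected header {_FIELD_HEADER}, got {cols}"
        )
    rows = []
    for lineno, line in data_lines[1:]:
        parts = line.split(delim)
        if len(parts) != 4:
            raise FieldParseError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
        try:
            rows.append([float(p) for p in parts])
        except ValueError as exc:
            raise FieldParseError(f"{path}:{lineno}: {exc}") from exc
    table = np.asarray(rows)
    if shape is None:
        ny = len(np.unique(table[:, 1]))
        nx = len(np.unique(table[:, 0]))
        shape = (ny, nx)
    ny, nx = shape
    if ny * nx != len(table):
        raise FieldParseError(f"{path}: {len(table)} rows do not fill a {ny}x{nx} grid")
    if pixel_size is None:
        xs = np.unique(table[:, 0])
        pixel_size = float(xs[1] - xs[0]) if len(xs) > 1 else 1.0
    grid = Grid2D(nx=nx, ny=ny, pixel_size=pixel_size)
    cx = table[:, 2].reshape(ny, nx)
    cy = table[:, 3].reshape(ny, nx)
    return VectorField2D(grid, cx, cy, units=units)


# ---------------------------------------------------------------------------
# configuration

DEFAULT_CONFIG: dict = {
    "pixel_size": 1.0,        # um per pixel for raw micrographs
    "force_grid_spacing": 3.44,  # um, force observation-point spacing
    "E": 5400.0,              # Pa, substrate Young's modulus
    "nu": 0.5,                # Poisson's ratio (incompressible)
    "codec": {"a": 81.2, "b": 50.0, "I_mid": 127.5},
    "training": {
        "image_size": 256,
        "epochs": 100,
        "batch_size": 1,
        "learning_rate": 2e-4,
        "adam_beta1": 0.5,
        "adam_beta2": 0.9,
        "lambda_l1": 100.0,
    },
}


def load_config(path: str | None = None) -> dict:
    """Load a YAML config merged over the package defaults."""
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    return cfg


def fill_invalid(field2d: VectorField2D) -> VectorField2D:
    """Replace NaN-flagged nodes by nearest-neighbour values (no-op if none)."""
    from scipy.interpolate import NearestNDInterpolator

    bad = ~(np.isfinite(field2d.comp_x) & np.isfinite(field2d.comp_y))
    if not bad.any():
        return field2d
    if bad.all():
        raise ValueError("every node is flagged invalid; nothing to interpolate from")
    yy, xx = np.mgrid[0 : field2d.grid.ny, 0 : field2d.grid.nx]
    pts = np.column_stack([yy[~bad], xx[~bad]])
    out = []
    for comp in (field2d.comp_x, field2d.comp_y):
        itp = NearestNDInterpolator(pts, comp[~bad])
        filled = comp.copy()
        filled[bad] = itp(np.column_stack([yy[bad], xx[bad]]))
        out.append(filled)
    return field2d.with_components(out[0], out[1])


def resample_field(field2d: VectorField2D, grid: Grid2D) -> VectorField2D:
    """Bilinearly interpolate a field onto another grid (same physical frame)."""
    from scipy.interpolate import RegularGridInterpolator

    g = field2d.grid
    pts_y, pts_x = np.meshgrid(grid.y, grid.x, indexing="ij")
    pts = np.column_stack([pts_y.ravel(), pts_x.ravel()])
    out = []
    for comp in (field2d.comp_x, field2d.comp_y):
        itp = RegularGridInterpolator(
            (g.y, g.x), comp, bounds_error=False, fill_value=None
        )
        out.append(itp(pts).reshape(grid.shape))
    return VectorField2D(grid, out[0], out[1], units=field2d.units)
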