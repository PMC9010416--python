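"""Force <-> grayscale codec and the traction-error metrics.

A single force component ``f_d`` (d = x, y) maps to an 8-bit-range
intensity through a bounded arctangent,

    I(f_d) = a * arctan(f_d / b) + I_mid,

so that the unbounded traction axis compresses smoothly into [0, 255]
around the mid gray.  The translator network evaluates one axis at a
time; the second axis is obtained by rotating the input image 90 degrees,
which swaps the roles of f_x and f_y.

Prediction quality is scored with magnitude and direction errors weighted
by the true force magnitude (w_m = f_m_true / f_bar), so that strong
vectors dominate the score, plus a pooled Pearson correlation R over both
components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import BinaryMask, ScalarImage, VectorField2D, same_grid


@dataclass(frozen=True)
class CodecParams:
    """Coefficients of the arctangent force codec.

    a : intensity scale; b : force scale in Pa; I_mid : mid intensity.
    """

    a: float = 81.2
    b: float = 50.0
    I_mid: float = 127.5

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValueError(f"a and b must be positive, got a={self.a}, b={self.b}")

    @property
    def intensity_bounds(self) -> tuple[float, float]:
        """Open interval of decodable intensities (the arctan asymptotes)."""
        half = self.a * np.pi / 2.0
        return (self.I_mid - half, self.I_mid + half)


@dataclass(frozen=True)
class ErrorReport:
    """Weighted magnitude error, direction error, correlation and maps."""

    eps_f: float
    eps_theta: float
    R: float
    magnitude_error_map: np.ndarray
    angle_error_map: np.ndarray

    def as_dict(self) -> dict:
        return {
            "eps_f": float(self.eps_f),
            "eps_theta_deg": float(self.eps_theta),
            "R": float(self.R),
        }


def encode_force(
    f_d: np.ndarray | float, params: CodecParams = CodecParams(), quantize: bool = False
) -> np.ndarray | float:
    """Encode force components (Pa) as intensities.

    With ``quantize`` the result is clamped to [0, 255] and rounded half-up
    to integers, emulating an 8-bit image.
    """
    intensity = params.a * np.arctan(np.asarray(f_d, dtype=float) / params.b) + params.I_mid
    if quantize:
        intensity = np.clip(np.floor(intensity + 0.5), 0.0, 255.0)
    if np.ndim(f_d) == 0:
        return float(intensity)
    return intensity


def decode_force(
    intensity: np.ndarray | float,
    params: CodecParams = CodecParams(),
    clip: bool = False,
) -> np.ndarray | float:
    """Invert the codec: f_d = b * tan((I - I_mid) / a).

    Intensities at or beyond the arctan asymptotes are not decodable; they
    raise unless ``clip`` is set, in which case they are pulled just inside
    the open interval (half a quantization step from the bound).
    """
    lo, hi = params.intensity_bounds
    arr = np.asarray(intensity, dtype=float)
    if clip:
        arr = np.clip(arr, lo + 0.5, hi - 0.5)
    elif np.any(arr <= lo) or np.any(arr >= hi):
        raise ValueError(
            f"intensity outside decodable open interval ({lo:.3f}, {hi:.3f}); "
            "the codec saturates at the arctan asymptotes"
        )
    out = params.b * np.tan((arr - params.I_mid) / params.a)
    if np.ndim(intensity) == 0:
        return float(out)
    return out


def n_saturated(intensity: np.ndarray, params: CodecParams = CodecParams()) -> int:
    """Count pixels at or beyond the decodable bounds (clipped on decode)."""
    lo, hi = params.intensity_bounds
    arr = np.asarray(intensity, dtype=float)
    return int(np.sum((arr <= lo + 0.5) | (arr >= hi - 0.5)))


# ---------------------------------------------------------------------------
# 90-degree rotations (exact on square grids)
#
# Arrays rotate with np.rot90(..., k=-1); in the y-up physical frame this is
# a counter-clockwise quarter turn, under which vector components co-rotate
# as (f_x, f_y) -> (-f_y, f_x).

def rotate_image_90(image: ScalarImage) -> ScalarImage:
    _require_square(image)
    return ScalarImage(image.grid, np.rot90(image.values, k=-1))


def rotate_mask_90(mask: BinaryMask) -> BinaryMask:
    _require_square(mask)
    return BinaryMask(mask.grid, np.rot90(mask.values, k=-1))


def rotate_field_90(field: VectorField2D) -> VectorField2D:
    """Quarter-turn a field, co-rotating the vector components."""
    _require_square(field)
    cx = -np.rot90(field.comp_y, k=-1)
    cy = np.rot90(field.comp_x, k=-1)
    return field.with_components(cx, cy)


def _require_square(obj) -> None:
    if obj.grid.nx != obj.grid.ny:
        raise ValueError(
            f"90-degree rotation requires a square grid, got {obj.grid.shape}"
        )


def axis_split_rotate(
    input_image: ScalarImage,
    traction: VectorField2D,
    params: CodecParams = CodecParams(),
    quantize: bool = True,
) -> tuple[tuple[ScalarImage, ScalarImage], tuple[ScalarImage, ScalarImage]]:
    """Build the two single-axis training pairs from one (image, traction) set.

    Pair 1 is ``(image, encoded f_x map)``.  Pair 2 rotates the image a
    quarter turn and encodes the x-component of the equally rotated traction
    field, which is derived from f_y — so one single-axis network sees both
    force components.
    """
    _require_square(input_image)
    _require_square(traction)
    fx_img = ScalarImage(
        traction.grid, encode_force(traction.comp_x, params, quantize=quantize)
    )
    rot_img = rotate_image_90(input_image)
    rot_traction = rotate_field_90(traction)
    fy_img = ScalarImage(
        traction.grid, encode_force(rot_traction.comp_x, params, quantize=quantize)
    )
    return (input_image, fx_img), (rot_img, fy_img)


# ---------------------------------------------------------------------------
# error metrics

def _weights(true: VectorField2D) -> tuple[np.ndarray, float]:
    mag_true = true.magnitude
    f_bar = float(mag_true.mean())
    if f_bar <= 0:
        raise ValueError("mean true traction is zero; weighted errors undefined")
    return mag_true / f_bar, f_bar


def force_magnitude_error(pred: VectorField2D, true: VectorField2D) -> float:
    """Magnitude-weighted relative force error.

    The per-node relative error |Δf|/f_true carries weight w = f_true/f_bar,
    so the true magnitude cancels and the sum reduces to the singularity-free
    form sum|Δf| / (M * f_bar); zero-force nodes contribute |Δf|/f_bar.
    Returned as a fraction (0.38 means 38%).
    """
    same_grid(pred, true)
    _, f_bar = _weights(true)
    diff = np.abs(pred.magnitude - true.magnitude)
    return float(diff.mean() / f_bar)


def force_angle_error(
    pred: VectorField2D, true: VectorField2D, wrap: bool = True
) -> float:
    """Magnitude-weighted mean direction error in degrees.

    Directions come from the full-quadrant arctangent; per-node differences
    are wrapped to [0, 180] by default (``wrap=False`` keeps the raw
    principal-value difference of theta = arctan(f_y/f_x), which is
    quadrant-ambiguous).
    """
    same_grid(pred, true)
    w, _ = _weights(true)
    if wrap:
        th_p = np.degrees(np.arctan2(pred.comp_y, pred.comp_x))
        th_t = np.degrees(np.arctan2(true.comp_y, true.comp_x))
        d = np.abs(th_p - th_t) % 360.0
        d = np.where(d > 180.0, 360.0 - d, d)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            th_p = np.degrees(np.arctan(pred.comp_y / pred.comp_x))
            th_t = np.degrees(np.arctan(true.comp_y / true.comp_x))
        d = np.abs(np.nan_to_num(th_p) - np.nan_to_num(th_t))
    return float(np.mean(d * w))


def correlation_r(pred: VectorField2D, true: VectorField2D) -> float:
    """Pearson correlation over the pooled f_x and f_y of all nodes."""
    same_grid(pred, true)
    p = np.concatenate([pred.comp_x.ravel(), pred.comp_y.ravel()])
    t = np.concatenate([true.comp_x.ravel(), true.comp_y.ravel()])
    if p.size < 6:
        raise ValueError("correlation needs at least 3 nodes")
    if np.std(p) == 0 or np.std(t) == 0:
        return float("nan")
    return float(np.corrcoef(p, t)[0, 1])


def error_report(pred: VectorField2D, true: VectorField2D) -> ErrorReport:
    """All three metrics plus per-node error maps in one report."""
    same_grid(pred, true)
    w, f_bar = _weights(true)
    mag_map = np.abs(pred.magnitude - true.magnitude) / f_bar
    th_p = np.degrees(np.arctan2(pred.comp_y, pred.comp_x))
    th_t = np.degrees(np.arctan2(true.comp_y, true.comp_x))
    d = np.abs(th_p - th_t) % 360.0
    ang_map = np.where(d > 180.0, 360.0 - d, d) * w
    return ErrorReport(
        eps_f=force_magnitude_error(pred, true),
        eps_theta=force_angle_error(pred, true),
        R=correlation_r(pred, true),
        magnitude_error_map=mag_map,
        angle_error_map=ang_map,
    )
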