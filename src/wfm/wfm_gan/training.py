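"""Training loop, objective, checkpointing and traction prediction.

The objective is the conditional-adversarial-plus-L1 loss

    L(G, D) = E[log D(x, y)] + E[log(1 - D(x, G(x)))] + lambda * L1(y, G(x)),

maximized over the discriminator and minimized over the generator
(lambda = 100 by default, so the generator is L1-dominated regression
sharpened by the patch discriminator).  The baseline model kind trains
the identical generator with the adversarial terms disabled.

The translator predicts one force axis at a time: f_x from the image as
given, f_y from the 90-degree-rotated image (components co-rotate), both
decoded through the arctangent force codec and block-averaged down to the
force observation grid.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from ..codec_metrics import (
    CodecParams,
    decode_force,
    encode_force,
    error_report,
    rotate_image_90,
)
from ..core_io import Grid2D, ScalarImage, VectorField2D, read_image, read_field
from .models import GANConfig, UNetGenerator, build_discriminator, build_generator
from .nn import Adam, F32

_EPS_P = 1e-7  # probability clamp inside the log terms


def gan_objective(
    d_real: np.ndarray,
    d_fake: np.ndarray,
    y: np.ndarray,
    g_x: np.ndarray,
    lambda_l1: float = 100.0,
) -> tuple[float, float]:
    """Scalar (discriminator, generator) losses of the pix2pix objective.

    The discriminator ascends E[log D(x,y)] + E[log(1 - D(x,G(x)))]
    (returned negated, as a loss to minimize); the generator descends
    E[log(1 - D(x,G(x)))] + lambda * L1(y, G(x)).
    """
    dr = np.clip(d_real, _EPS_P, 1.0 - _EPS_P)
    df = np.clip(d_fake, _EPS_P, 1.0 - _EPS_P)
    loss_d = -float(np.mean(np.log(dr)) + np.mean(np.log(1.0 - df)))
    l1 = float(np.mean(np.abs(y - g_x)))
    loss_g = float(np.mean(np.log(1.0 - df))) + lambda_l1 * l1
    return loss_d, loss_g


@dataclass
class TrainedTranslator:
    """Opaque handle to a fitted generator.

    Serializable to a single ``.npz`` archive (parameters + config
    snapshot + per-epoch loss history); predictions are deterministic for
    fixed parameters and input.
    """

    generator: UNetGenerator
    config: GANConfig
    model_kind: str
    history: dict = field(default_factory=dict)
    input_kind: str = "wrinkle_mask"

    def save(self, path: str) -> None:
        arrays = {
            f"p{i}": p.value for i, p in enumerate(self.generator.params())
        }
        meta = {
            "config": {
                k: getattr(self.config, k)
                for k in (
                    "image_size",
                    "epochs",
                    "batch_size",
                    "learning_rate",
                    "adam_beta1",
                    "adam_beta2",
                    "lambda_l1",
                    "base_width",
                    "seed",
                    "device",
                )
            },
            "model_kind": self.model_kind,
            "history": self.history,
            "input_kind": self.input_kind,
        }
        np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str) -> "TrainedTranslator":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            config = GANConfig(**meta["config"])
            gen = build_generator(config)
            for i, p in enumerate(gen.params()):
                p.value[...] = data[f"p{i}"]
        return cls(
            generator=gen,
            config=config,
            model_kind=meta["model_kind"],
            history=meta["history"],
            input_kind=meta.get("input_kind", "wrinkle_mask"),
        )


# ---------------------------------------------------------------------------
# dataset plumbing

def _nn_upsample_to(arr: np.ndarray, size: int) -> np.ndarray:
    """Nearest-neighbour upsample an (ny, nx) array to (size, size)."""
    ny, nx = arr.shape
    iy = np.floor(np.arange(size) * ny / size).astype(int)
    ix = np.floor(np.arange(size) * nx / size).astype(int)
    return arr[np.ix_(iy, ix)]


def block_average_to(arr: np.ndarray, ny: int, nx: int) -> np.ndarray:
    """Average image pixels over the blocks that map to each force node."""
    size_y, size_x = arr.shape
    iy = np.floor(np.arange(size_y) * ny / size_y).astype(int)
    ix = np.floor(np.arange(size_x) * nx / size_x).astype(int)
    out = np.zeros((ny, nx))
    cnt = np.zeros((ny, nx))
    np.add.at(out, (iy[:, None], ix[None, :]), arr)
    np.add.at(cnt, (iy[:, None], ix[None, :]), 1.0)
    return out / cnt


def _norm_image(values: np.ndarray) -> np.ndarray:
    """Map 8-bit intensities to [-1, 1]."""
    return (values.astype(F32) / 127.5) - 1.0


def load_training_arrays(
    manifest: dict | str,
    config: GANConfig,
    codec: CodecParams = CodecParams(),
    split: str = "train",
) -> tuple[np.ndarray, np.ndarray, list[dict]]:
    """Assemble single-axis (input, target) tensors from a dataset manifest.

    Each manifest pair yields two samples via the axis trick: (image,
    encoded f_x) and (image rotated 90 degrees, encoded f_x of the
    co-rotated field).  Returns float32 NCHW arrays in [-1, 1] and the
    manifest entries used.
    """
    if isinstance(manifest, str):
        base = os.path.dirname(manifest)
        with open(manifest) as fh:
            manifest = json.load(fh)
    else:
        base = manifest.get("_dir", ".")
    entries = [p for p in manifest["pairs"] if p["split"] == split]
    if not entries:
        raise ValueError(f"manifest has no pairs in split {split!r}")
    from ..codec_metrics import axis_split_rotate

    xs, ys = [], []
    size = config.image_size
    for entry in entries:
        img = read_image(os.path.join(base, entry["image"]))
        traction = read_field(os.path.join(base, entry["traction"]))
        (img1, f1), (img2, f2) = axis_split_rotate(img, traction, codec, quantize=False)
        for im, fm in ((img1, f1), (img2, f2)):
            vals = im.values
            if vals.shape != (size, size):
                vals = _nn_upsample_to(vals, size)
            xs.append(_norm_image(vals))
            ys.append(_norm_image(_nn_upsample_to(fm.values, size)))
    x = np.stack(xs)[:, None]
    y = np.stack(ys)[:, None]
    return x.astype(F32), y.astype(F32), entries


# ---------------------------------------------------------------------------
# training

def train(
    manifest: dict | str,
    config: GANConfig,
    model_kind: str = "gan",
    codec: CodecParams = CodecParams(),
    checkpoint_dir: str | None = None,
    checkpoint_every: int = 0,
    log=None,
) -> TrainedTranslator:
    """Fit the translator on the manifest's training split.

    ``model_kind='gan'`` alternates discriminator/generator updates with
    the full objective; ``'cnn_baseline'`` runs the identical generator
    with the adversarial terms disabled (pure L1 regression).  Fully
    seeded: the same config and data reproduce the same loss trajectory.
    """
    if model_kind not in ("gan", "cnn_baseline"):
        raise ValueError(f"unknown model_kind {model_kind!r}")
    x, y, entries = load_training_arrays(manifest, config, codec, split="train")
    n = len(x)
    rng = np.random.default_rng(config.seed)
    G = build_generator(config, np.random.default_rng(config.seed + 10))
    opt_g = Adam(
        G.params(), config.learning_rate, config.adam_beta1, config.adam_beta2
    )
    adversarial = model_kind == "gan"
    if adversarial:
        D = build_discriminator(config, np.random.default_rng(config.seed + 11))
        opt_d = Adam(
            D.params(), config.learning_rate, config.adam_beta1, config.adam_beta2
        )
    history = {"loss_d": [], "loss_g_adv": [], "loss_g_l1": []}
    bs = config.batch_size
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        ep_d, ep_adv, ep_l1 = [], [], []
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            xb, yb = x[idx], y[idx]
            g_out, g_tape = G.forward(xb)
            m = float(np.prod(g_out.shape))
            dL1 = np.sign(g_out - yb).astype(F32) / m
            l1 = float(np.mean(np.abs(g_out - yb)))
            if adversarial:
                real_pair = np.concatenate([xb, yb], axis=1)
                fake_pair = np.concatenate([xb, g_out], axis=1)
                d_real, tape_r = D.forward(real_pair)
                d_fake, tape_f = D.forward(fake_pair)
                loss_d, loss_g = gan_objective(
                    d_real, d_fake, yb, g_out, config.lambda_l1
                )
                mr = float(np.prod(d_real.shape))
                dr = np.clip(d_real, _EPS_P, 1 - _EPS_P)
                df = np.clip(d_fake, _EPS_P, 1 - _EPS_P)
                # discriminator ascent on log dr + log(1-df)
                opt_d.zero_grad()
                D.backward((-1.0 / (dr * mr)).astype(F32), tape_r)
                D.backward((1.0 / ((1.0 - df) * mr)).astype(F32), tape_f)
                # generator descent: d/dG [log(1-df)] through D, plus lambda L1
                opt_g.zero_grad()
                for p in D.params():
                    p.grad[...] = 0.0  # discard G-pass gradients w.r.t. D
                dfake_in = D.backward((-1.0 / ((1.0 - df) * mr)).astype(F32), tape_f)
                dG = dfake_in[:, xb.shape[1] :] + config.lambda_l1 * dL1
                G.backward(dG.astype(F32), g_tape)
                opt_d.step()
                opt_g.step()
                ep_d.append(loss_d)
                ep_adv.append(float(np.mean(np.log(1.0 - df))))
            else:
                opt_g.zero_grad()
                G.backward((config.lambda_l1 * dL1).astype(F32), g_tape)
                opt_g.step()
                ep_d.append(0.0)
                ep_adv.append(0.0)
            if not np.isfinite(l1):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, step {start // bs}"
                )
            ep_l1.append(l1)
        history["loss_d"].append(float(np.mean(ep_d)))
        history["loss_g_adv"].append(float(np.mean(ep_adv)))
        history["loss_g_l1"].append(float(np.mean(ep_l1)))
        if log is not None:
            log(
                f"epoch {epoch + 1}/{config.epochs}: "
                f"L1={history['loss_g_l1'][-1]:.4f} D={history['loss_d'][-1]:.4f}"
            )
        if checkpoint_dir and checkpoint_every and (epoch + 1) % checkpoint_every == 0:
            model = TrainedTranslator(G, config, model_kind, history)
            os.makedirs(checkpoint_dir, exist_ok=True)
            model.save(os.path.join(checkpoint_dir, f"checkpoint_ep{epoch + 1}.npz"))
    return TrainedTranslator(G, config, model_kind, history)


# ---------------------------------------------------------------------------
# prediction

def predict_traction(
    model: TrainedTranslator,
    image: ScalarImage,
    codec: CodecParams = CodecParams(),
    force_grid: Grid2D | None = None,
    generator_fn=None,
) -> VectorField2D:
    """Translate an input image into a traction field (Pa).

    The generator runs on the image for f_x and on the 90-degree-rotated
    image for f_y (inverse-rotating that result); both maps are decoded
    through the codec (saturated intensities clipped) and block-averaged
    onto the force grid (default 26 x 26 at 3.44 um).
    """
    if force_grid is None:
        force_grid = Grid2D(nx=26, ny=26, pixel_size=3.44)
    size = model.config.image_size
    vals = image.values
    if vals.shape != (size, size):
        if vals.shape[0] != vals.shape[1]:
            raise ValueError(f"square input required, got {vals.shape}")
        vals = _nn_upsample_to(vals, size)
        image = ScalarImage(Grid2D(size, size, image.grid.pixel_size), vals)

    if generator_fn is None:
        def generator_fn(arr: np.ndarray) -> np.ndarray:
            out, _ = model.generator.forward(arr[None, None].astype(F32))
            return out[0, 0]

    out_x = generator_fn(_norm_image(image.values))
    rot = rotate_image_90(image)
    out_rot = generator_fn(_norm_image(rot.values))
    # predicted map for the rotated frame is the x-component of the rotated
    # field; un-rotate to recover f_y: cy = -rot90(cx_rotated, k=+1)
    int_x = (np.asarray(out_x, dtype=float) + 1.0) * 127.5
    int_rot = (np.asarray(out_rot, dtype=float) + 1.0) * 127.5
    fx_img = decode_force(int_x, codec, clip=True)
    f_rot_img = decode_force(int_rot, codec, clip=True)
    fx = block_average_to(fx_img, force_grid.ny, force_grid.nx)
    f_rot = block_average_to(f_rot_img, force_grid.ny, force_grid.nx)
    # un-rotate on the force grid, where the quarter turn is exact (the
    # uneven nearest-neighbour pixel blocks do not commute with rotation)
    fy = -np.rot90(f_rot, k=1)
    return VectorField2D(force_grid, fx, fy, units="Pa")


def evaluate_translator(
    model: TrainedTranslator,
    manifest: dict | str,
    codec: CodecParams = CodecParams(),
    split: str = "test",
) -> dict:
    """Predict every test pair and pool the three error metrics.

    Returns eps_f, eps_theta (deg), R plus the held-out generator L1, in
    one JSON-ready dict mirroring the baseline-vs-GAN comparison layout.
    """
    if isinstance(manifest, str):
        base = os.path.dirname(manifest)
        with open(manifest) as fh:
            manifest = json.load(fh)
    else:
        base = manifest.get("_dir", ".")
    entries = [p for p in manifest["pairs"] if p["split"] == split and p["rot_k"] == 0]
    if not entries:
        raise ValueError(f"no split={split!r} pairs in manifest")
    size = model.config.image_size
    preds, trues = [], []
    l1s = []
    for entry in entries:
        img = read_image(os.path.join(base, entry["image"]))
        true = read_field(os.path.join(base, entry["traction"]))
        pred = predict_traction(model, img, codec, force_grid=true.grid)
        preds.append(pred)
        trues.append(true)
        target = _norm_image(_nn_upsample_to(encode_force(true.comp_x, codec), size))
        vals = img.values if img.values.shape == (size, size) else _nn_upsample_to(img.values, size)
        out, _ = model.generator.forward(_norm_image(vals)[None, None])
        l1s.append(float(np.mean(np.abs(out[0, 0] - target))))
    pooled_pred = VectorField2D(
        Grid2D(trues[0].grid.nx, trues[0].grid.ny * len(trues), trues[0].grid.pixel_size),
        np.concatenate([p.comp_x for p in preds]),
        np.concatenate([p.comp_y for p in preds]),
        units="Pa",
    )
    pooled_true = pooled_pred.with_components(
        np.concatenate([t.comp_x for t in trues]),
        np.concatenate([t.comp_y for t in trues]),
    )
    rep = error_report(pooled_pred, pooled_true)
    return {
        "model_kind": model.model_kind,
        "n_test_cells": len(entries),
        "eps_f": rep.eps_f,
        "eps_theta_deg": rep.eps_theta,
        "R": rep.R,
        "held_out_l1": float(np.mean(l1s)),
    }
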