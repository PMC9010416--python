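"""Translator architectures: U-Net generator and patch discriminator.

The generator is an encoder–decoder with skip connections: stride-2 4x4
convolutions down to a bottleneck (depth log2(image_size) - 2, so a
64-px desk-scale image gets 4 levels and a 256-px image 6), then
nearest-neighbour upsampling + 3x3 convolution back up, concatenating the
mirror encoder feature map at each level.  The bounded tanh output is
rescaled to the 8-bit intensity range of the force codec.

The discriminator is Markovian (PatchGAN): it scores overlapping local
patches of the 2-channel (input image, force image) concatenation rather
than the whole image, producing a grid of real/fake probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (
    Conv2d,
    InstanceNorm,
    Layer,
    LeakyReLU,
    ReLU,
    Sequential,
    Sigmoid,
    Tanh,
    Upsample2x,
)


@dataclass(frozen=True)
class GANConfig:
    """Training hyperparameters of the translator.

    Defaults follow the pix2pix-style recipe: 100 epochs at batch size 1,
    Adam with learning rate 2e-4, beta1 = 0.5, beta2 = 0.9, and L1 weight
    lambda = 100.  ``image_size`` 256 for full-scale work, 64 for the
    desk-scale configuration exercised by the tests.
    """

    image_size: int = 256
    epochs: int = 100
    batch_size: int = 1
    learning_rate: float = 2e-4
    adam_beta1: float = 0.5
    adam_beta2: float = 0.9
    lambda_l1: float = 100.0
    base_width: int = 16
    seed: int = 0
    device: str = "cpu"

    def __post_init__(self) -> None:
        size = self.image_size
        if size < 32 or (size & (size - 1)) != 0:
            raise ValueError(f"image_size must be a power of 2 >= 32, got {size}")
        for name in ("epochs", "batch_size", "learning_rate", "lambda_l1", "base_width"):
            if getattr(self, name) <= 0 and name != "lambda_l1":
                raise ValueError(f"{name} must be positive")
        if self.lambda_l1 < 0:
            raise ValueError("lambda_l1 must be >= 0")

    @property
    def depth(self) -> int:
        return int(np.log2(self.image_size)) - 2


class UNetGenerator(Layer):
    """1-channel image in [-1, 1] -> 1-channel encoded-force image in [-1, 1]."""

    def __init__(self, config: GANConfig, rng: np.random.Generator):
        w = config.base_width
        depth = config.depth
        widths = [min(w * 2**i, 4 * w) for i in range(depth)]
        self.down: list[Sequential] = []
        cin = 1
        for i, cw in enumerate(widths):
            layers = [Conv2d(cin, cw, k=4, stride=2, pad=1, rng=rng)]
            if i > 0:
                layers.append(InstanceNorm(cw))
            layers.append(LeakyReLU(0.2))
            self.down.append(Sequential(*layers))
            cin = cw
        self.up: list[Sequential] = []
        for i in reversed(range(depth)):
            cout = widths[i - 1] if i > 0 else w
            cin_up = widths[i] + (widths[i] if i < depth - 1 else 0)
            # decoder level i consumes [upsampled previous, encoder skip i]
            self.up.append(
                Sequential(
                    Upsample2x(),
                    Conv2d(cin_up, cout, k=3, stride=1, pad=1, rng=rng),
                    InstanceNorm(cout),
                    ReLU(),
                )
            )
        self.head = Sequential(Conv2d(w, 1, k=3, stride=1, pad=1, rng=rng), Tanh())
        self.depth = depth

    def params(self):
        ps = []
        for blk in (*self.down, *self.up, self.head):
            ps.extend(blk.params())
        return ps

    def forward(self, x):
        skips = []
        tapes_d = []
        for blk in self.down:
            x, t = blk.forward(x)
            skips.append(x)
            tapes_d.append(t)
        tapes_u = []
        concat_c = []
        for j, blk in enumerate(self.up):
            level = self.depth - 1 - j
            if j == 0:
                inp = x  # bottleneck feature map, no partner to concatenate
                concat_c.append(0)
            else:
                concat_c.append(x.shape[1])
                inp = np.concatenate([x, skips[level]], axis=1)
            x, t = blk.forward(inp)
            tapes_u.append(t)
        y, t_head = self.head.forward(x)
        return y, (tapes_d, tapes_u, t_head, concat_c)

    def backward(self, dy, tape):
        tapes_d, tapes_u, t_head, concat_c = tape
        dx = self.head.backward(dy, t_head)
        dskips: list = [None] * self.depth
        for j in reversed(range(len(self.up))):
            level = self.depth - 1 - j
            dinp = self.up[j].backward(dx, tapes_u[j])
            if j == 0:
                dskips[self.depth - 1] = (
                    dinp
                    if dskips[self.depth - 1] is None
                    else dskips[self.depth - 1] + dinp
                )
            else:
                c = concat_c[j]
                dx = dinp[:, :c]
                add = dinp[:, c:]
                dskips[level] = add if dskips[level] is None else dskips[level] + add
        # propagate through the encoder, folding in the skip gradients
        g = dskips[self.depth - 1]
        for i in reversed(range(self.depth)):
            g = self.down[i].backward(g, tapes_d[i])
            if i > 0 and dskips[i - 1] is not None:
                g = g + dskips[i - 1]
        return g


class PatchDiscriminator(Sequential):
    """2-channel (input, force) pair -> grid of patch real/fake scores."""

    def __init__(self, config: GANConfig, rng: np.random.Generator):
        w = config.base_width
        n_strided = 2 if config.image_size <= 64 else 3
        layers: list[Layer] = []
        cin = 2
        cw = w
        for i in range(n_strided):
            layers.append(Conv2d(cin, cw, k=4, stride=2, pad=1, rng=rng))
            if i > 0:
                layers.append(InstanceNorm(cw))
            layers.append(LeakyReLU(0.2))
            cin, cw = cw, min(2 * cw, 4 * w)
        layers.append(Conv2d(cin, cw, k=4, stride=1, pad=1, rng=rng))
        layers.append(InstanceNorm(cw))
        layers.append(LeakyReLU(0.2))
        layers.append(Conv2d(cw, 1, k=4, stride=1, pad=1, rng=rng))
        layers.append(Sigmoid())
        super().__init__(*layers)


def build_generator(config: GANConfig, rng: np.random.Generator | None = None) -> UNetGenerator:
    """U-Net generator at the configured size (fresh seeded parameters)."""
    if config.image_size < 2 ** (config.depth + 2):
        raise ValueError("image_size below architecture minimum")
    rng = rng or np.random.default_rng(config.seed)
    return UNetGenerator(config, rng)


def build_discriminator(
    config: GANConfig, rng: np.random.Generator | None = None
) -> PatchDiscriminator:
    """Patch discriminator matched to the configured image size."""
    rng = rng or np.random.default_rng(config.seed + 1)
    return PatchDiscriminator(config, rng)
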