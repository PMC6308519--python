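"""Context-encoder generator and discriminator builders.

The generator is an asymmetric auto-encoder: four stride-2 3x3 conv stages
(depths 2, 4, 8, 16, leaky rectifier slope 0.2, batch-norm momentum 0.8,
dropout 0.5 on the last stage) encode the full masked sinogram; a
channel-wise fully-connected bottleneck maps the encoded features to the
decoder seed whose spatial dims are the masked-region dims / 16; four
conv + 2x-upsample stages (depths 16, 8, 4, 2, plain rectifiers) and a
final tanh conv emit only the masked region, in (-1, 1).

The discriminator is a three-stage conv stack (first two stride 2) over the
region, flattened into a single sigmoid unit.

For the full-size 544 x 448 sinogram profile the encoder bottleneck is
34 x 28, the decoder seed 34 x 17 and the predicted band 544 x 272.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .layers import (
    BatchNorm2D,
    ChannelwiseDense,
    Conv2D,
    Dense,
    Dropout,
    Flatten,
    LeakyReLU,
    ReLU,
    Sequential,
    Tanh,
    Upsample2x,
    sigmoid,
)

__all__ = [
    "CEArchitectureSpec",
    "Generator",
    "Discriminator",
    "build_generator",
    "build_discriminator",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class CEArchitectureSpec:
    """Shape and width configuration of the context-encoder GAN.

    Dims are given as (bins, angles); both must divide by 16 (four 2x
    halvings).  ``region_angles`` is the height of the predicted band.
    The ``paper`` preset is the full-size profile (544 x 448 input,
    272-row band, discriminator widths 64/128/128); the ``desk`` preset
    (176 x 112 input, 80-row band, slimmer discriminator) trains in
    minutes on one CPU.
    """

    input_bins: int = 176
    input_angles: int = 112
    region_angles: int = 80
    enc_depths: tuple[int, ...] = (2, 4, 8, 16)
    dec_depths: tuple[int, ...] = (16, 8, 4, 2)
    disc_depths: tuple[int, ...] = (8, 16, 16)
    leaky_slope: float = 0.2
    bn_momentum: float = 0.8
    dropout: float = 0.5

    def __post_init__(self) -> None:
        for name, v in (
            ("input_bins", self.input_bins),
            ("input_angles", self.input_angles),
            ("region_angles", self.region_angles),
        ):
            if v % 16 != 0:
                raise ValueError(f"{name} ({v}) must be divisible by 16")
        if self.region_angles > self.input_angles:
            raise ValueError("region cannot exceed the input")

    @classmethod
    def paper(cls) -> "CEArchitectureSpec":
        return cls(input_bins=544, input_angles=448, region_angles=272,
                   disc_depths=(64, 128, 128))

    @classmethod
    def desk(cls) -> "CEArchitectureSpec":
        return cls()

    @property
    def bottleneck_hw(self) -> tuple[int, int]:
        """Encoder output spatial dims (angles/16, bins/16)."""
        return (self.input_angles // 16, self.input_bins // 16)

    @property
    def seed_hw(self) -> tuple[int, int]:
        """Decoder seed spatial dims (region/16, bins/16)."""
        return (self.region_angles // 16, self.input_bins // 16)

    @property
    def region_hw(self) -> tuple[int, int]:
        return (self.region_angles, self.input_bins)


class Generator:
    """Masked sinogram (N, 1, angles, bins) -> region (N, 1, region, bins)."""

    def __init__(self, spec: CEArchitectureSpec, rng: np.random.Generator):
        self.spec = spec
        layers = []
        c_in = 1
        for i, d in enumerate(spec.enc_depths):
            layers += [
                Conv2D(c_in, d, rng, stride=2),
                LeakyReLU(spec.leaky_slope),
                BatchNorm2D(d, spec.bn_momentum),
            ]
            if i == len(spec.enc_depths) - 1 and spec.dropout > 0:
                layers.append(Dropout(spec.dropout, rng))
            c_in = d
        layers.append(
            ChannelwiseDense(c_in, spec.bottleneck_hw, spec.seed_hw, rng)
        )
        for d in spec.dec_depths:
            layers += [
                Conv2D(c_in, d, rng, stride=1),
                Upsample2x(),
                ReLU(),
                BatchNorm2D(d, spec.bn_momentum),
            ]
            c_in = d
        layers += [Conv2D(c_in, 1, rng, stride=1), Tanh()]
        self.net = Sequential(layers)
        # assert the shape algebra once at build time
        probe = np.zeros((1, 1, spec.input_angles, spec.input_bins), np.float32)
        out = self.net.forward(probe, train=False)
        if out.shape[2:] != spec.region_hw:
            raise AssertionError(
                f"decoder emits {out.shape[2:]}, expected {spec.region_hw}"
            )

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        return self.net.forward(x.astype(np.float32), train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.net.backward(dy.astype(np.float32))

    def n_params(self) -> int:
        return self.net.n_params()

    def layer_shapes(self) -> list[tuple[str, tuple[int, ...]]]:
        """Per-layer output shapes for a single-sample forward pass."""
        x = np.zeros((1, 1, self.spec.input_angles, self.spec.input_bins), np.float32)
        shapes = []
        for layer in self.net.layers:
            x = layer.forward(x, train=False)
            shapes.append((type(layer).__name__, x.shape[1:]))
        return shapes


class Discriminator:
    """Region (N, 1, region, bins) -> probability the region is real."""

    def __init__(self, spec: CEArchitectureSpec, rng: np.random.Generator):
        self.spec = spec
        layers = []
        c_in = 1
        for i, d in enumerate(spec.disc_depths):
            stride = 2 if i < 2 else 1
            layers += [
                Conv2D(c_in, d, rng, stride=stride),
                LeakyReLU(spec.leaky_slope),
                BatchNorm2D(d, spec.bn_momentum),
            ]
            c_in = d
        h = -(-spec.region_angles // 4)
        w = -(-spec.input_bins // 4)
        layers += [Flatten(), Dense(c_in * h * w, 1, rng)]
        self.net = Sequential(layers)

    def logits(self, x: np.ndarray, train: bool) -> np.ndarray:
        return self.net.forward(x.astype(np.float32), train).ravel()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Probabilities in (0, 1)."""
        return sigmoid(self.logits(x, train))

    def backward_from_logits(self, dlogits: np.ndarray) -> np.ndarray:
        return self.net.backward(dlogits.reshape(-1, 1).astype(np.float32))

    def n_params(self) -> int:
        return self.net.n_params()


def build_generator(spec: CEArchitectureSpec, seed: int = 0) -> Generator:
    """Construct a generator with seeded weight initialisation."""
    return Generator(spec, np.random.default_rng(seed))


def build_discriminator(spec: CEArchitectureSpec, seed: int = 0) -> Discriminator:
    return Discriminator(spec, np.random.default_rng(seed))


def save_model(path: str | Path, gen: Generator, disc: Discriminator | None = None,
               extra: dict | None = None) -> None:
    """Serialise weights (npz) alongside an architecture JSON."""
    path = Path(path)
    arrays = {f"g{i}": a for i, a in enumerate(gen.net.state_arrays())}
    if disc is not None:
        arrays.update({f"d{i}": a for i, a in enumerate(disc.net.state_arrays())})
    np.savez_compressed(path.with_suffix(".npz"), **arrays)
    meta = {"arch": asdict(gen.spec), "has_discriminator": disc is not None}
    if extra:
        meta["extra"] = extra
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_model(path: str | Path) -> tuple[Generator, Discriminator | None]:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    arch = meta["arch"]
    arch["enc_depths"] = tuple(arch["enc_depths"])
    arch["dec_depths"] = tuple(arch["dec_depths"])
    arch["disc_depths"] = tuple(arch["disc_depths"])
    spec = CEArchitectureSpec(**arch)
    gen = build_generator(spec)
    disc = build_discriminator(spec) if meta["has_discriminator"] else None
    with np.load(path.with_suffix(".npz")) as data:
        for i, a in enumerate(gen.net.state_arrays()):
            a[...] = data[f"g{i}"]
        if disc is not None:
            for i, a in enumerate(disc.net.state_arrays()):
                a[...] = data[f"d{i}"]
    return gen, disc
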