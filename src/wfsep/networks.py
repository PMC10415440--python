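"""Water-fat separation network architectures.

Two variants share one encoder design — four Conv2D blocks (each: two 3x3
convolutions, ReLU then batch normalisation after each) with channel widths
72/144/288/576 at full scale, 2x2 max pooling between blocks, and a
bottleneck block twice the last width (1152 channels at input_size/16, i.e.
12x12 for 192x192 inputs):

* ``MDWFNet`` — the multi-decoder variant: three independent decoders map
  the shared latent features to (i) the 2-channel magnitude water/fat pair,
  (ii) the normalised R2* map and (iii) the normalised field map.  The
  field-map decoder inserts a spatial self-attention block right after the
  first upsampling from the latent space (input_size/8 resolution), letting
  it relate distant image regions — the mechanism aimed at suppressing
  water-fat swap artifacts.
* ``UNet`` — the single-decoder comparator emitting one 4-channel output
  (water, fat, R2*, field map).

Decoder stages mirror the encoder: 2x2 transposed-convolution upsampling,
concatenation with the equal-shape encoder features, then the same Conv2D
block.  Output heads are 1x1 convolutions with ReLU on water/fat
(non-negative magnitudes), sigmoid on R2*/200 in [0,1], and a linear head
on the signed field map.  Inputs are real/imaginary echo pairs: 2 x n_echoes
channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import tensor as T
from .signal_model import EchoSeries, ValidationError
from .tensor import Module, Tensor

__all__ = [
    "NetworkConfig",
    "NetworkOutputs",
    "MDWFNet",
    "UNet",
    "build_mdwf_net",
    "build_unet",
    "pack_input",
    "unpack_input",
    "bottleneck_shape",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters.

    The defaults are the full-scale configuration; reduced desk-scale
    variants shrink ``input_size`` and the filter schedule but keep the
    structure (four pooling stages, bottleneck = 2x last encoder width).
    """

    input_size: int = 192
    n_echoes: int = 3
    encoder_filters: tuple[int, int, int, int] = (72, 144, 288, 576)
    bottleneck_filters: int = 1152
    attention_in_fieldmap_decoder: bool = True
    variant: str = "mdwf"

    def __post_init__(self) -> None:
        if self.input_size % 16 != 0 or self.input_size < 16:
            raise ValidationError("input_size must be divisible by 16 (four pooling stages)")
        if len(self.encoder_filters) != 4:
            raise ValidationError("encoder_filters must list exactly 4 widths")
        if any(b <= a for a, b in zip(self.encoder_filters, self.encoder_filters[1:])):
            raise ValidationError("encoder_filters must be strictly increasing")
        if self.bottleneck_filters < 1 or self.n_echoes < 1:
            raise ValidationError("bottleneck_filters and n_echoes must be positive")
        if self.variant not in ("mdwf", "unet"):
            raise ValidationError("variant must be 'mdwf' or 'unet'")

    @property
    def in_channels(self) -> int:
        return 2 * self.n_echoes


def bottleneck_shape(config: NetworkConfig) -> tuple[int, int, int]:
    """(channels, height, width) of the latent space: closed-form arithmetic."""
    side = config.input_size // 16
    return (config.bottleneck_filters, side, side)


class ConvBlock(Module):
    """Two 3x3 convolutions, each followed by ReLU then batch normalisation."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        self.conv1 = T.Conv2d(in_ch, out_ch, 3, rng)
        self.bn1 = T.BatchNorm2d(out_ch)
        self.conv2 = T.Conv2d(out_ch, out_ch, 3, rng)
        self.bn2 = T.BatchNorm2d(out_ch)

    def __call__(self, x: Tensor) -> Tensor:
        x = self.bn1(T.relu(self.conv1(x)))
        return self.bn2(T.relu(self.conv2(x)))


class Encoder(Module):
    def __init__(self, config: NetworkConfig, rng: np.random.Generator):
        chans = [config.in_channels, *config.encoder_filters]
        self.blocks = [ConvBlock(a, b, rng) for a, b in zip(chans, chans[1:])]
        self.bottleneck = ConvBlock(config.encoder_filters[-1], config.bottleneck_filters, rng)

    def __call__(self, x: Tensor) -> tuple[Tensor, list[Tensor]]:
        skips = []
        for block in self.blocks:
            x = block(x)
            skips.append(x)
            x = T.maxpool2x2(x)
        return self.bottleneck(x), skips


class Decoder(Module):
    """Mirror of the encoder: upsample, concatenate the skip, convolve.

    ``attention=True`` inserts a self-attention block after the first
    upsampling from the latent space.  The head is a 1x1 convolution with
    the requested output activation ('relu', 'sigmoid' or 'linear').
    """

    def __init__(
        self,
        config: NetworkConfig,
        out_channels: int,
        activation: str,
        rng: np.random.Generator,
        attention: bool = False,
    ):
        widths = list(config.encoder_filters)[::-1]  # e.g. [576, 288, 144, 72]
        in_ch = config.bottleneck_filters
        self.upconvs = []
        self.blocks = []
        for w in widths:
            self.upconvs.append(T.ConvTranspose2d(in_ch, w, rng))
            self.blocks.append(ConvBlock(2 * w, w, rng))
            in_ch = w
        self.attention = T.SelfAttention2d(widths[0], rng) if attention else None
        self.head = T.Conv2d(widths[-1], out_channels, 1, rng)
        if activation not in ("relu", "sigmoid", "linear"):
            raise ValidationError(f"unknown output activation {activation!r}")
        self.activation = activation

    def __call__(self, latent: Tensor, skips: list[Tensor]) -> Tensor:
        x = latent
        for i, (up, block) in enumerate(zip(self.upconvs, self.blocks)):
            x = up(x)
            if i == 0 and self.attention is not None:
                x = self.attention(x)
            skip = skips[-(i + 1)]
            if x.shape[2:] != skip.shape[2:]:  # structural guarantee, not data-dependent
                raise ValidationError("skip connection spatial shapes differ")
            x = T.concat([x, skip], axis=1)
            x = block(x)
        x = self.head(x)
        if self.activation == "relu":
            return T.relu(x)
        if self.activation == "sigmoid":
            return T.sigmoid(x)
        return x


@dataclass
class NetworkOutputs:
    """Denormalisable network outputs in NCHW numpy form.

    ``waterfat`` holds non-negative magnitude water/fat channels;
    ``r2star_norm`` is R2*/200 in [0, 1]; ``fieldmap_norm`` is the signed
    field map divided by 400 Hz.
    """

    waterfat: np.ndarray
    r2star_norm: np.ndarray
    fieldmap_norm: np.ndarray

    def stacked(self) -> np.ndarray:
        """(B, 4, H, W) channel order: water, fat, R2*, field map."""
        return np.concatenate([self.waterfat, self.r2star_norm, self.fieldmap_norm], axis=1)


class MDWFNet(Module):
    """Multi-decoder water-fat separation network."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        self.encoder = Encoder(config, rng)
        self.dec_waterfat = Decoder(config, 2, "relu", rng)
        self.dec_r2star = Decoder(config, 1, "sigmoid", rng)
        self.dec_fieldmap = Decoder(
            config, 1, "linear", rng, attention=config.attention_in_fieldmap_decoder
        )
        self.last_bottleneck_shape: "tuple[int, ...] | None" = None

    def forward_tensors(self, x: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        latent, skips = self.encoder(x)
        self.last_bottleneck_shape = latent.shape[1:]
        return (
            self.dec_waterfat(latent, skips),
            self.dec_r2star(latent, skips),
            self.dec_fieldmap(latent, skips),
        )

    def __call__(self, x) -> NetworkOutputs:
        wf, r2, fm = self.forward_tensors(x if isinstance(x, Tensor) else Tensor(x))
        return NetworkOutputs(wf.data, r2.data, fm.data)


class UNet(Module):
    """Single-decoder comparator producing the same four output maps."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        self.encoder = Encoder(config, rng)
        # one shared decoder trunk ending in three activation-specific heads
        # (together a 4-channel output: water, fat, R2*, field map)
        self.decoder = Decoder(config, 2, "relu", rng)
        self.head_r2star = T.Conv2d(config.encoder_filters[0], 1, 1, rng)
        self.head_fieldmap = T.Conv2d(config.encoder_filters[0], 1, 1, rng)
        self.last_bottleneck_shape: "tuple[int, ...] | None" = None

    def forward_tensors(self, x: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        latent, skips = self.encoder(x)
        self.last_bottleneck_shape = latent.shape[1:]
        feat = latent
        for i, (up, block) in enumerate(zip(self.decoder.upconvs, self.decoder.blocks)):
            feat = up(feat)
            skip = skips[-(i + 1)]
            feat = T.concat([feat, skip], axis=1)
            feat = block(feat)
        wf = T.relu(self.decoder.head(feat))
        r2 = T.sigmoid(self.head_r2star(feat))
        fm = self.head_fieldmap(feat)
        return wf, r2, fm

    def __call__(self, x) -> NetworkOutputs:
        wf, r2, fm = self.forward_tensors(x if isinstance(x, Tensor) else Tensor(x))
        return NetworkOutputs(wf.data, r2.data, fm.data)


def build_mdwf_net(config: NetworkConfig, seed: int = 0) -> MDWFNet:
    return MDWFNet(config, seed=seed)


def build_unet(config: NetworkConfig, seed: int = 0) -> UNet:
    if config.variant != "unet":
        config = NetworkConfig(
            input_size=config.input_size,
            n_echoes=config.n_echoes,
            encoder_filters=config.encoder_filters,
            bottleneck_filters=config.bottleneck_filters,
            attention_in_fieldmap_decoder=False,
            variant="unet",
        )
    return UNet(config, seed=seed)


def pack_input(echoes: EchoSeries) -> np.ndarray:
    """Interleave real/imaginary echo components into (H, W, 2*n_echoes).

    Channel order: [Re(e1), Im(e1), Re(e2), Im(e2), ...] — real parts on
    even channel indices, imaginary parts on odd indices.
    """
    n, h, w = echoes.data.shape
    out = np.empty((h, w, 2 * n), dtype=np.float64)
    for e in range(n):
        out[:, :, 2 * e] = echoes.data[e].real
        out[:, :, 2 * e + 1] = echoes.data[e].imag
    return out


def save_model(model, stem) -> None:
    """Persist weights (npz) plus a JSON manifest holding the NetworkConfig."""
    import json
    from dataclasses import asdict
    from pathlib import Path

    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    np.savez(str(stem) + ".npz", **model.state_dict())
    manifest = {"network_config": asdict(model.config)}
    stem.with_suffix(".json").write_text(json.dumps(manifest, indent=2))


def load_model(stem):
    """Rebuild a network from a manifest + weights pair written by save_model."""
    import json
    from pathlib import Path

    stem = Path(stem)
    manifest = json.loads(stem.with_suffix(".json").read_text())
    cfg_d = dict(manifest["network_config"])
    cfg_d["encoder_filters"] = tuple(cfg_d["encoder_filters"])
    config = NetworkConfig(**cfg_d)
    model = MDWFNet(config) if config.variant == "mdwf" else UNet(config)
    with np.load(str(stem) + ".npz") as state:
        model.load_state_dict(dict(state))
    model.eval()
    return model


def unpack_input(packed: np.ndarray) -> np.ndarray:
    """Inverse of :func:`pack_input`: (H, W, 2n) -> complex (n, H, W)."""
    packed = np.asarray(packed)
    if packed.ndim != 3 or packed.shape[2] % 2 != 0:
        raise ValidationError("packed input must be (H, W, 2*n_echoes)")
    n = packed.shape[2] // 2
    re = np.moveaxis(packed[:, :, 0::2], -1, 0)
    im = np.moveaxis(packed[:, :, 1::2], -1, 0)
    return re + 1j * im
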