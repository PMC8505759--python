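"""Encoder-decoder (U-Net) networks built from the numpy layer library.

The plane networks are shallow U-Nets: ``depth`` resolution levels with two
conv+BN+ReLU blocks per level, 2x max-pool downsampling, up-convolutions,
skip concatenations and a final 1x1 convolution producing per-class logits
(softmax applied at the loss/inference boundary).  The same code builds the
3D variant by setting ``ndim=3``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .layers import BatchNorm, Conv, ConvTranspose, MaxPool, Param, ReLU

__all__ = ["UNetConfig", "UNet", "build_unet", "build_3d_unet", "build_2d_axial"]

#: classic U-Net depth used for the volumetric baseline
CLASSIC_3D_DEPTH = 4


@dataclass(frozen=True)
class UNetConfig:
    """Architecture hyperparameters of one network.

    ``first_kernel`` is 5 for the sagittal/coronal planes (larger receptive
    field in the first layer) and 3 for the axial plane and the 3D baseline.
    """

    depth: int = 3
    base_channels: int = 64
    first_kernel: int = 3
    in_channels: int = 2
    out_classes: int = 2

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.base_channels < 2:
            raise ValueError("base_channels must be >= 2")
        if self.out_classes != 2:
            raise ValueError("out_classes must be 2 (background, WMH)")
        if self.first_kernel % 2 == 0:
            raise ValueError("first_kernel must be odd")


class _ConvBlock:
    """(conv -> BN -> ReLU) x 2; the first conv may use a larger kernel."""

    def __init__(self, cin: int, cout: int, ndim: int, rng: np.random.Generator,
                 first_kernel: int = 3):
        self.layers = [
            Conv(cin, cout, first_kernel, ndim, rng),
            BatchNorm(cout, ndim),
            ReLU(),
            Conv(cout, cout, 3, ndim, rng),
            BatchNorm(cout, ndim),
            ReLU(),
        ]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]


class UNet:
    """U-Net over ``ndim`` spatial dimensions with per-class logit output."""

    def __init__(self, config: UNetConfig, ndim: int = 2, seed: int = 0):
        self.config = config
        self.ndim = ndim
        rng = np.random.default_rng(seed)
        ch = [config.base_channels * 2**i for i in range(config.depth)]
        self.channels = ch

        self.encoders: list[_ConvBlock] = []
        cin = config.in_channels
        for level, c in enumerate(ch[:-1]):
            fk = config.first_kernel if level == 0 else 3
            self.encoders.append(_ConvBlock(cin, c, ndim, rng, first_kernel=fk))
            cin = c
        self.pools = [MaxPool(ndim) for _ in ch[:-1]]
        bottom_fk = config.first_kernel if config.depth == 1 else 3
        self.bottleneck = _ConvBlock(cin, ch[-1], ndim, rng, first_kernel=bottom_fk)

        self.upconvs: list[ConvTranspose] = []
        self.decoders: list[_ConvBlock] = []
        for c_hi, c_lo in zip(ch[::-1][:-1], ch[::-1][1:]):
            self.upconvs.append(ConvTranspose(c_hi, c_lo, ndim, rng))
            self.decoders.append(_ConvBlock(2 * c_lo, c_lo, ndim, rng))
        self.final = Conv(ch[0], config.out_classes, 1, ndim, rng)

    # -- execution -----------------------------------------------------
    def _check_input(self, x: np.ndarray) -> None:
        if x.ndim != 2 + self.ndim or x.shape[1] != self.config.in_channels:
            raise ValueError(
                f"expected input (N, {self.config.in_channels}, *spatial) with "
                f"{self.ndim} spatial dims, got {x.shape}"
            )
        stride = 2 ** (self.config.depth - 1)
        for s in x.shape[2:]:
            if s % stride:
                raise ValueError(
                    f"spatial size {x.shape[2:]} not divisible by the total "
                    f"downsampling stride {stride}"
                )

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """Return per-class logits with the same spatial shape as the input."""
        self._check_input(x)
        x = np.ascontiguousarray(x, dtype=np.float32)
        skips = []
        for enc, pool in zip(self.encoders, self.pools):
            x = enc.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        x = self.bottleneck.forward(x, train)
        self._skip_channels = []
        for up, dec, skip in zip(self.upconvs, self.decoders, reversed(skips)):
            x = up.forward(x, train)
            self._skip_channels.append(skip.shape[1])
            x = np.concatenate([skip, x], axis=1)
            x = dec.forward(x, train)
        return self.final.forward(x, train)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        d = self.final.backward(dlogits)
        dskips = []
        for up, dec, c_skip in zip(
            reversed(self.upconvs), reversed(self.decoders), reversed(self._skip_channels)
        ):
            d = dec.backward(d)
            dskip, dx = d[:, :c_skip], d[:, c_skip:]
            dskips.append(dskip)
            d = up.backward(np.ascontiguousarray(dx))
        d = self.bottleneck.backward(d)
        for enc, pool, dskip in zip(
            reversed(self.encoders), reversed(self.pools), reversed(dskips)
        ):
            d = pool.backward(d)
            d = enc.backward(d + dskip)
        return d

    def predict_logits(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x, train=False)

    # -- parameters ----------------------------------------------------
    def blocks(self) -> list:
        return self.encoders + [self.bottleneck] + self.upconvs + self.decoders + [self.final]

    def parameters(self) -> list[Param]:
        out = []
        for block in self.blocks():
            out.extend(block.params())
        return out

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    # -- (de)serialisation ---------------------------------------------
    def _stateful(self) -> list:
        out = []
        for block in self.blocks():
            layers = block.layers if isinstance(block, _ConvBlock) else [block]
            out.extend(layers)
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self._stateful()):
            for p in layer.params():
                state[f"layer{i}.{p.name}"] = p.value.copy()
            if isinstance(layer, BatchNorm):
                state[f"layer{i}.running_mean"] = layer.running_mean.copy()
                state[f"layer{i}.running_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self._stateful()):
            for p in layer.params():
                key = f"layer{i}.{p.name}"
                if p.value.shape != state[key].shape:
                    raise ValueError(f"shape mismatch for {key}")
                p.value[...] = state[key]
            if isinstance(layer, BatchNorm):
                layer.running_mean[...] = state[f"layer{i}.running_mean"]
                layer.running_var[...] = state[f"layer{i}.running_var"]

    def save(self, path: str | Path) -> None:
        """Checkpoint weights (.npz) with a JSON sidecar recording the config."""
        path = Path(path)
        np.savez(path, **self.state_dict())
        sidecar = path.with_suffix(".json")
        sidecar.write_text(
            json.dumps({"config": asdict(self.config), "ndim": self.ndim}, indent=2)
        )

    @classmethod
    def load(cls, path: str | Path) -> "UNet":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        net = cls(UNetConfig(**meta["config"]), ndim=meta["ndim"])
        with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as data:
            net.load_state_dict(dict(data))
        return net


def build_unet(config: UNetConfig, seed: int = 0) -> UNet:
    """A per-plane 2D U-Net."""
    return UNet(config, ndim=2, seed=seed)


def build_2d_axial(config: UNetConfig, seed: int = 0) -> UNet:
    """Single-plane (axial-only) 2D baseline: same architecture, one plane."""
    return UNet(config, ndim=2, seed=seed)


def build_3d_unet(config: UNetConfig | None = None, base_channels: int = 64,
                  depth: int = CLASSIC_3D_DEPTH, seed: int = 0) -> UNet:
    """The volumetric baseline: a classic-depth 3D U-Net.

    By default this follows the standard 3D U-Net layout with 4 resolution
    levels (the depth-trimming of the plane networks is specific to the 2D
    design); pass ``config`` to override.
    """
    if config is None:
        config = UNetConfig(depth=depth, base_channels=base_channels, first_kernel=3)
    return UNet(config, ndim=3, seed=seed)
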