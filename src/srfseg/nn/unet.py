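"""Configurable 3D U-Net over two-channel (CT, PET) patches.

Encoder-decoder with ``levels`` resolution scales: channels double per
level, each block is two 3x3x3 same-padding convolutions with instance
normalization and ReLU, downsampling by 2x2x2 max pooling, upsampling by
2x2x2 transposed convolution with skip concatenation. Scores are raw
(unnormalized); softmax lives in the loss and in inference decoding. With
deep supervision a 1x1x1 score head is attached to the decoder output at
every scale (the coarsest head sits on the bottleneck).

Input intensities may optionally be rescaled by fixed affine factors
(HU/100, SUV/10, on by default) to balance the two channels.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from ..errors import ConfigError, ContractError, DataError
from .layers import Conv3d, ConvTranspose2, InstanceNorm3d, MaxPool2, ReLU

__all__ = ["NetworkConfig", "UNet3D", "build_unet", "save_model", "load_model"]

HU_SCALE = 0.01  # fixed affine input rescale for the CT channel
SUV_SCALE = 0.1  # and for the PET channel


@dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    ``levels`` counts resolution scales (4 for the full-size profile, 2 for
    the desk profile); ``base_channels`` is the feature width at full
    resolution and doubles per level.
    """

    levels: int = 4
    base_channels: int = 16
    in_channels: int = 2
    out_classes: int = 3
    deep_supervision: bool = True
    rescale_input: bool = True

    def __post_init__(self):
        if self.levels < 2:
            raise ConfigError("levels must be >= 2")
        if self.base_channels < 1:
            raise ConfigError("base_channels must be >= 1")
        if self.in_channels != 2 or self.out_classes != 3:
            raise ConfigError("this model is fixed at 2 input channels and 3 classes")

    @property
    def divisor(self) -> int:
        return 2 ** (self.levels - 1)


class _Block:
    """conv-norm-relu twice."""

    def __init__(self, cin: int, cout: int, rng, first: bool = False):
        self.layers = [
            Conv3d(cin, cout, 3, rng, needs_input_grad=not first),
            InstanceNorm3d(cout), ReLU(),
            Conv3d(cout, cout, 3, rng), InstanceNorm3d(cout), ReLU(),
        ]

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class UNet3D:
    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        self.seed = int(seed)
        self.spacing: tuple[float, float, float] = (2.73, 2.73, 2.79)
        self.patch_edge: int = 0  # set by training; 0 = full-volume inference
        rng = np.random.default_rng(seed)
        L, B = config.levels, config.base_channels
        ch = [B * 2**l for l in range(L)]
        self.enc = [
            _Block(config.in_channels if l == 0 else ch[l - 1], ch[l], rng, first=(l == 0))
            for l in range(L - 1)
        ]
        self.pools = [MaxPool2() for _ in range(L - 1)]
        self.bottom = _Block(ch[L - 2], ch[L - 1], rng)
        self.ups = [ConvTranspose2(ch[l + 1], ch[l], rng) for l in range(L - 1)]
        self.dec = [_Block(2 * ch[l], ch[l], rng) for l in range(L - 1)]
        self.head = Conv3d(ch[0], 3, 1, rng)
        self.aux_heads = []
        if config.deep_supervision:
            # one head per coarser scale: decoder outputs at scales 1..L-2, bottleneck at L-1
            self.aux_heads = [Conv3d(ch[s], 3, 1, rng) for s in range(1, L)]

    # -- parameter plumbing ------------------------------------------------
    def _blocks(self):
        out = []
        for b in self.enc:
            out += b.layers
        out += self.bottom.layers
        out += self.ups
        for b in self.dec:
            out += b.layers
        out.append(self.head)
        out += self.aux_heads
        return out

    def param_items(self):
        items = []
        for layer in self._blocks():
            items += layer.param_items()
        return items

    def zero_grad(self):
        for layer in self._blocks():
            layer.zero_grad()

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {
            f"p{i}_{key}": params[key]
            for i, (params, _, key) in enumerate(self.param_items())
        }

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, (params, _, key) in enumerate(self.param_items()):
            arr = arrays[f"p{i}_{key}"]
            if arr.shape != params[key].shape:
                raise ContractError(f"checkpoint shape mismatch for p{i}_{key}")
            params[key] = arr.astype(np.float32)
        # re-point layer params (dict entries were replaced in place above)

    @property
    def divisor(self) -> int:
        return self.config.divisor

    # -- forward / backward ------------------------------------------------
    def _check_shape(self, x):
        d = self.divisor
        if any(s % d for s in x.shape[2:]):
            raise ContractError(
                f"spatial shape {x.shape[2:]} must be divisible by {d} "
                f"(2^(levels-1) with levels={self.config.levels})"
            )

    def forward(self, x: np.ndarray) -> list[np.ndarray]:
        """Return score maps per scale, finest first (length 1 without
        deep supervision). Input is (N, 2, D, H, W); scores are
        (N, 3, ...) per scale. Internally everything runs channels-last."""
        x = np.asarray(x, dtype=np.float32)
        self._check_shape(x)
        if self.config.rescale_input:
            x = x * np.array([HU_SCALE, SUV_SCALE], dtype=np.float32)[None, :, None, None, None]
        h = np.ascontiguousarray(x.transpose(0, 2, 3, 4, 1))
        skips = []
        for block, pool in zip(self.enc, self.pools):
            h = block.forward(h)
            skips.append(h)
            h = pool.forward(h)
        h = self.bottom.forward(h)
        L = self.config.levels
        dec_feats = {L - 1: h}
        for l in range(L - 2, -1, -1):
            u = self.ups[l].forward(h)
            c = np.concatenate([u, skips[l]], axis=-1)
            h = self.dec[l].forward(c)
            dec_feats[l] = h
        self._skip_channels = [s.shape[-1] for s in skips]
        scores = [self.head.forward(dec_feats[0])]
        if self.config.deep_supervision:
            for s, head in enumerate(self.aux_heads, start=1):
                scores.append(head.forward(dec_feats[s]))
        return [np.ascontiguousarray(s.transpose(0, 4, 1, 2, 3)) for s in scores]

    def backward(self, dscores: list[np.ndarray]) -> None:
        """Accumulate parameter gradients for the last forward pass."""
        L = self.config.levels
        dscores = [
            np.ascontiguousarray(np.asarray(g, dtype=np.float32).transpose(0, 2, 3, 4, 1))
            for g in dscores
        ]
        aux = {}
        if self.config.deep_supervision and len(dscores) > 1:
            for s, head in enumerate(self.aux_heads, start=1):
                aux[s] = head.backward(dscores[s])
        d_h = self.head.backward(dscores[0])
        d_enc = [None] * (L - 1)
        for l in range(0, L - 1):
            dc = self.dec[l].backward(d_h)
            cu = dc.shape[-1] - self._skip_channels[l]
            du, dskip = dc[..., :cu], dc[..., cu:]
            d_enc[l] = dskip
            d_h = self.ups[l].backward(np.ascontiguousarray(du))
            if (l + 1) in aux:
                d_h = d_h + aux[l + 1]
        d = self.bottom.backward(d_h)
        for l in range(L - 2, -1, -1):
            d = self.pools[l].backward(d)
            d = d + d_enc[l]
            d = self.enc[l].backward(d)

    # -- inference ---------------------------------------------------------
    def predict(self, x: np.ndarray) -> np.ndarray:
        """Full-resolution class scores for one 2-channel patch (2, D, H, W)."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[0] != 2:
            raise ContractError(f"predict expects (2, D, H, W), got {x.shape}")
        if not np.all(np.isfinite(x)):
            raise DataError("predict input contains non-finite values")
        return self.forward(x[None])[0][0].astype(np.float64)


def build_unet(config: NetworkConfig, seed: int = 0) -> UNet3D:
    """Construct a seeded, deterministically initialized U-Net."""
    return UNet3D(config, seed=seed)


def save_model(model: UNet3D, path) -> None:
    """Save config + parameters + seed + grid metadata as a single .npz."""
    meta = {
        "config": asdict(model.config),
        "seed": model.seed,
        "spacing": list(model.spacing),
        "patch_edge": model.patch_edge,
        "format_version": 1,
    }
    np.savez_compressed(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                        **model.state_arrays())


def load_model(path) -> UNet3D:
    with np.load(path) as zf:
        meta = json.loads(bytes(zf["__meta__"]).decode())
        arrays = {k: zf[k] for k in zf.files if k != "__meta__"}
    model = UNet3D(NetworkConfig(**meta["config"]), seed=meta.get("seed", 0))
    model.spacing = tuple(meta.get("spacing", (2.73, 2.73, 2.79)))
    model.patch_edge = int(meta.get("patch_edge", 0))
    model.load_state_arrays(arrays)
    return model
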