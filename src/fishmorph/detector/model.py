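"""Stacked-hourglass heatmap network and its training configuration.

The architecture follows the stacked-hourglass design for keypoint
localization: residual blocks arranged in a symmetric encoder-decoder
("hourglass") whose order is its nesting depth — each level pools by 2,
recurses, upsamples by 2 and merges with a skip branch at the same scale.
Two hourglass modules are stacked by default, each emitting a full heatmap
set (intermediate supervision); the loss is the MSE against the encoded
ground-truth heatmaps summed over stacks.  Optimization uses Adam at the
reference learning rate 1e-3.

The sizes are free parameters.  The reference setup uses full-resolution
camera images; the desk-scale default trains 64x64 inputs against 16x16
heatmaps (upscale factor 4) so the whole loop runs on one CPU.  Checkpoints
are plain ``.npz`` archives of the parameter arrays plus the JSON-encoded
config.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .autodiff import Tensor, add, conv2d, maxpool2, relu, upsample2

__all__ = ["DetectorConfig", "ConfigError", "StackedHourglass", "Adam", "build_model",
           "save_checkpoint", "load_checkpoint"]


class ConfigError(ValueError):
    """Raised for inconsistent detector configuration."""


@dataclass(frozen=True)
class DetectorConfig:
    """Architecture and training hyperparameters of one view's detector.

    ``upscale_factor`` (input/heatmap resolution ratio) is derived, not set;
    decoded keypoint coordinates are argmax positions multiplied by it.
    """

    num_keypoints: int = 10          # 10 side-view / 9 top-view landmarks
    input_size: int = 64             # square input resolution, px
    heatmap_size: int = 16           # square heatmap resolution, px
    num_stacks: int = 2              # stacked hourglass modules
    hourglass_order: int = 4         # nesting depth of each hourglass
    num_features: int = 16           # channels inside the hourglasses
    gaussian_sigma: float = 2.0      # ground-truth bump width, heatmap px
    learning_rate: float = 1e-3      # Adam initial learning rate

    def __post_init__(self) -> None:
        if self.input_size % self.heatmap_size != 0:
            raise ConfigError(
                f"input size {self.input_size} not divisible by heatmap size {self.heatmap_size}"
            )
        ratio = self.input_size // self.heatmap_size
        if ratio & (ratio - 1) != 0:
            raise ConfigError(f"input/heatmap ratio {ratio} must be a power of two")
        if self.heatmap_size < 2 ** self.hourglass_order:
            raise ConfigError(
                f"heatmap size {self.heatmap_size} too small for order "
                f"{self.hourglass_order} (needs >= {2 ** self.hourglass_order})"
            )
        for name in ("num_keypoints", "num_stacks", "hourglass_order", "num_features"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.gaussian_sigma <= 0 or self.learning_rate <= 0:
            raise ConfigError("gaussian_sigma and learning_rate must be positive")

    @property
    def upscale_factor(self) -> int:
        return self.input_size // self.heatmap_size


class _Conv:
    """Convolution layer owning its weight/bias parameters."""

    def __init__(self, rng, c_in, c_out, k=3, pad=None, stride=1, scale=None, dtype=np.float32):
        pad = (k // 2) if pad is None else pad
        fan_in = c_in * k * k
        scale = np.sqrt(2.0 / fan_in) if scale is None else scale
        self.w = Tensor(rng.normal(0.0, scale, size=(c_out, c_in, k, k)).astype(dtype),
                        requires_grad=True)
        self.b = Tensor(np.zeros(c_out, dtype=dtype), requires_grad=True)
        self.stride, self.pad = stride, pad

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, stride=self.stride, pad=self.pad)

    def params(self):
        return [self.w, self.b]


class _ResBlock:
    """Two 3x3 convolutions with an identity shortcut: x + f(x).

    The branch's second convolution is zero-initialized so every block (and
    hence the whole unnormalized network) starts as the identity; without
    this, stacked residual branches compound activation variance and the
    early optimization is erratic.
    """

    def __init__(self, rng, channels, dtype=np.float32):
        self.c1 = _Conv(rng, channels, channels, dtype=dtype)
        self.c2 = _Conv(rng, channels, channels, scale=0.0, dtype=dtype)

    def __call__(self, x: Tensor) -> Tensor:
        return relu(add(x, self.c2(relu(self.c1(x)))))

    def params(self):
        return self.c1.params() + self.c2.params()


class _Hourglass:
    """Order-n recursive encoder-decoder with per-scale skip branches."""

    def __init__(self, rng, order, channels, dtype=np.float32):
        self.skip = _ResBlock(rng, channels, dtype)
        self.down = _ResBlock(rng, channels, dtype)
        self.inner = (
            _Hourglass(rng, order - 1, channels, dtype) if order > 1 else _ResBlock(rng, channels, dtype)
        )
        self.up = _ResBlock(rng, channels, dtype)

    def __call__(self, x: Tensor) -> Tensor:
        branch = self.skip(x)
        low = self.down(maxpool2(x))
        low = self.inner(low)
        return add(branch, upsample2(self.up(low)))

    def params(self):
        return self.skip.params() + self.down.params() + self.inner.params() + self.up.params()


class StackedHourglass:
    """The full model: stem to heatmap resolution, then stacked hourglasses.

    Calling the model on an image batch (N, 1, S, S) returns one heatmap
    tensor (N, K, H, H) per stack; the last one is the inference output.
    """

    def __init__(self, config: DetectorConfig, seed: int = 0, dtype=np.float32):
        self.config = config
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        c = config.num_features
        n_pools = int(np.log2(config.upscale_factor))

        self.stem: list = [_Conv(rng, 1, c, dtype=dtype)]
        self.stem_pools = n_pools
        for _ in range(n_pools):
            self.stem.append(_ResBlock(rng, c, dtype))

        self.hourglasses = []
        self.heads = []
        self.merges = []
        for s in range(config.num_stacks):
            self.hourglasses.append(_Hourglass(rng, config.hourglass_order, c, dtype))
            # Small-scale head init keeps initial heatmaps near zero.
            self.heads.append(_Conv(rng, c, config.num_keypoints, k=1, pad=0, scale=1e-3, dtype=dtype))
            if s < config.num_stacks - 1:
                self.merges.append(
                    (_ResBlock(rng, c, dtype), _Conv(rng, config.num_keypoints, c, k=1, pad=0, dtype=dtype))
                )

    def params(self) -> list[Tensor]:
        out = []
        for layer in self.stem:
            out += layer.params()
        for hg, head in zip(self.hourglasses, self.heads):
            out += hg.params() + head.params()
        for res, back in self.merges:
            out += res.params() + back.params()
        return out

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.params())

    def __call__(self, images: np.ndarray) -> list[Tensor]:
        cfg = self.config
        if images.ndim != 4 or images.shape[1] != 1 or images.shape[2:] != (cfg.input_size,) * 2:
            raise ConfigError(
                f"expected images (N, 1, {cfg.input_size}, {cfg.input_size}), got {images.shape}"
            )
        x = Tensor(images.astype(self.dtype, copy=False))
        x = relu(self.stem[0](x))
        for block in self.stem[1:]:
            x = block(maxpool2(x))
        outputs: list[Tensor] = []
        for s, (hg, head) in enumerate(zip(self.hourglasses, self.heads)):
            y = hg(x)
            hm = head(y)
            outputs.append(hm)
            if s < len(self.merges):
                res, back = self.merges[s]
                x = add(x, add(res(y), back(hm)))
        return outputs

    def predict(self, images: np.ndarray) -> np.ndarray:
        """Final-stack heatmaps as a plain array (N, K, H, H)."""
        return self(images)[-1].data


def build_model(config: DetectorConfig, seed: int = 0) -> StackedHourglass:
    """Construct a randomly initialized model for the given configuration."""
    return StackedHourglass(config, seed=seed)


class Adam:
    """Adam optimizer over a parameter list (beta1=0.9, beta2=0.999)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            m_hat = self.m[i] / (1 - self.b1 ** self.t)
            v_hat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= (self.lr * m_hat / (np.sqrt(v_hat) + self.eps)).astype(p.data.dtype)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def save_checkpoint(model: StackedHourglass, path: str | Path, extra: dict | None = None) -> None:
    """Serialize parameters + config to a ``.npz`` archive."""
    arrays = {f"param_{i}": p.data for i, p in enumerate(model.params())}
    meta = {"config": asdict(model.config)}
    if extra:
        meta["extra"] = extra
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> StackedHourglass:
    """Rebuild a model from a checkpoint written by :func:`save_checkpoint`."""
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["meta"]).decode())
        config = DetectorConfig(**meta["config"])
        model = StackedHourglass(config, seed=0)
        params = model.params()
        for i, p in enumerate(params):
            stored = npz[f"param_{i}"]
            if stored.shape != p.data.shape:
                raise ConfigError(f"checkpoint parameter {i} shape mismatch")
            p.data = stored.astype(p.data.dtype)
    return model
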