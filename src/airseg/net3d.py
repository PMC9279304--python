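"""3D U-Net for the coarse and fine segmentation stages.

Both stages use the same encoder-decoder architecture with skip connections
by channel concatenation; they differ only in the number of input channels.
The coarse stage sees the single intensity channel; the fine stage sees the
intensity channel plus the C coarse-hint probability channels, so
``in_channels = num_classes + 1``.

The network maps an ``in_channels x d x h x w`` patch to a
``num_classes x d x h x w`` score map of the same spatial shape; spatial
dims must be divisible by ``2**(depth - 1)``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .volumes import NUM_CLASSES


@dataclass
class ModelConfig:
    """Architecture hyperparameters for one stage.

    ``base_channels`` is the width of the first encoder level; widths double
    at each deeper level.  ``depth`` counts encoder levels (>= 2).
    """

    stage: str  # "coarse" | "fine"
    num_classes: int = NUM_CLASSES
    base_channels: int = 8
    depth: int = 3

    def __post_init__(self):
        if self.stage not in ("coarse", "fine"):
            raise ValueError(f"stage must be 'coarse' or 'fine', got {self.stage!r}")
        if self.depth < 2:
            raise ValueError("depth must be >= 2")

    @property
    def in_channels(self) -> int:
        # coarse: intensity only; fine: intensity + one hint channel per class
        return 1 if self.stage == "coarse" else self.num_classes + 1

    @property
    def divisor(self) -> int:
        return 2 ** (self.depth - 1)


class UNet3D:
    """Encoder-decoder segmentation network on single samples (C, D, H, W)."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator | int = 0):
        if isinstance(rng, (int, np.integer)):
            rng = np.random.default_rng(rng)
        self.cfg = cfg
        widths = [cfg.base_channels * 2**i for i in range(cfg.depth)]
        self.enc = []
        cin = cfg.in_channels
        for wdt in widths:
            self.enc.append(nn.ConvBlock(cin, wdt, rng))
            cin = wdt
        self.pools = [nn.MaxPool2() for _ in range(cfg.depth - 1)]
        # up-convolutions halve the channel width before skip concatenation
        self.ups = []
        self.dec = []
        for i in reversed(range(cfg.depth - 1)):
            self.ups.append(nn.ConvTranspose2x(widths[i + 1], widths[i], rng))
            self.dec.append(nn.ConvBlock(2 * widths[i], widths[i], rng))
        self.head = nn.Conv3d(widths[0], cfg.num_classes, 1, rng)

    # -- parameters ---------------------------------------------------------
    def parameters(self) -> list[nn.Param]:
        ps = []
        for block in [*self.enc, *self.ups, *self.dec, self.head]:
            ps.extend(block.parameters())
        return ps

    # -- forward / backward -------------------------------------------------
    def _check_input(self, x: np.ndarray):
        if x.ndim != 4 or x.shape[0] != self.cfg.in_channels:
            raise ValueError(
                f"expected input ({self.cfg.in_channels}, d, h, w), got {x.shape}")
        div = self.cfg.divisor
        if any(s % div for s in x.shape[1:]):
            raise ValueError(
                f"spatial dims {x.shape[1:]} must be divisible by {div}")

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Return class scores (logits) of shape (num_classes, d, h, w)."""
        x = np.asarray(x, dtype=np.float32)
        self._check_input(x)
        skips = []
        for i, block in enumerate(self.enc):
            x = block.forward(x)
            if i < len(self.pools):
                skips.append(x)
                x = self.pools[i].forward(x)
        self._skip_channels = [s.shape[0] for s in skips]
        for j, block in enumerate(self.dec):
            x = self.ups[j].forward(x)
            x = block.forward(np.concatenate([x, skips.pop()], axis=0))
        return self.head.forward(x)

    def backward(self, grad_scores: np.ndarray) -> None:
        """Accumulate parameter gradients from a loss gradient w.r.t. scores."""
        g = self.head.backward(grad_scores.astype(np.float32))
        skip_grads = []
        for j, block in enumerate(reversed(self.dec)):
            jj = len(self.dec) - 1 - j
            g = block.backward(g)
            c_up = g.shape[0] - self._skip_channels[j]
            skip_grads.append(g[c_up:])
            g = self.ups[jj].backward(g[:c_up])
        for i, block in enumerate(reversed(self.enc)):
            ii = len(self.enc) - 1 - i
            if ii < len(self.pools):
                g = self.pools[ii].backward(g)
                g = g + skip_grads[ii]
            g = block.backward(g, need_input_grad=ii > 0)

    def predict_probs(self, x: np.ndarray) -> np.ndarray:
        """Softmax class probabilities for one input sample."""
        return nn.Softmax.forward(self.forward(x))

    # -- checkpointing ------------------------------------------------------
    def state_arrays(self) -> list[np.ndarray]:
        return [p.value for p in self.parameters()]

    def load_state(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("checkpoint parameter count mismatch")
        for p, a in zip(params, arrays):
            if p.value.shape != a.shape:
                raise ValueError("checkpoint parameter shape mismatch")
            p.value = np.asarray(a, dtype=np.float32).copy()


def save_checkpoint(path, model: UNet3D, metadata: dict | None = None) -> None:
    """Serialize parameters + config (+ optional training metadata) as .npz."""
    arrays = {f"param_{i}": a for i, a in enumerate(model.state_arrays())}
    meta = dict(metadata or {})
    meta["model_config"] = asdict(model.cfg)
    np.savez(str(path), __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> tuple[UNet3D, dict]:
    """Rebuild a model from a checkpoint; returns (model, metadata)."""
    with np.load(str(path)) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        n = sum(1 for k in z.files if k.startswith("param_"))
        arrays = [z[f"param_{i}"] for i in range(n)]
    cfg = ModelConfig(**meta.pop("model_config"))
    model = UNet3D(cfg, rng=0)
    model.load_state(arrays)
    return model, meta


def build_model(cfg: ModelConfig, rng: np.random.Generator | int = 0) -> UNet3D:
    """Construct a stage network from its configuration."""
    return UNet3D(cfg, rng)
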