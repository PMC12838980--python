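"""Dual-attention CNN for 5-level facial pain intensity classification.

Architecture
------------
Four 3x3 conv blocks (Conv -> BatchNorm -> ReLU, 2x2 max-pool after blocks
1-3) take a normalized 64x64x3 face to a C_final x 8 x 8 feature map F.
Two attention stages refine it:

* **Multi-head spatial attention** — each of K heads computes a per-pixel
  gate ``A_i = sigmoid(conv1x1(relu(conv1x1(F))))`` and the refined map is
  the unweighted sum ``F' = sum_i A_i * F``. With all head weights at zero
  every gate is 0.5, so ``F' = K/2 * F`` — the documented baseline.
* **Triple-pooling channel attention** — per-channel average, max and
  population standard deviation of F' are concatenated into a descriptor
  ``z`` (order [avg | max | std]) and passed through a two-layer
  squeeze-and-excitation network ``s = sigmoid(W2 relu(W1 z))`` with
  reduction ratio r; ``F'' = s * F'``.

The classifier flattens F'' (8192 values under the default channel plan)
into FC(256) and FC(128) blocks with batch norm, ReLU and dropout, then a
linear layer produces 5 logits. Both attention stages can be switched off
independently, which yields the attention-free baseline CNN used in
ablation grids; output shapes are unchanged.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .autodiff import Tensor, concat, maxpool2d
from .nn import BatchNorm, Conv2d, Dropout, Linear, Module

__all__ = [
    "ModelConfig", "SpatialAttention", "ChannelAttention", "DualAttentionCNN",
    "spatial_attention", "triple_pool", "channel_attention",
    "save_checkpoint", "load_checkpoint",
]

STD_EPS = 1e-6  # inside the sqrt of std-pooling, for gradients at zero variance


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    The default channel plan 32-64-128-128 with pooling after the first
    three blocks maps a 64x64 input to a 128x8x8 tensor, whose flattened
    length is 8192.
    """

    input_size: int = 64
    channels: tuple[int, ...] = (32, 64, 128, 128)
    pool_blocks: tuple[int, ...] = (0, 1, 2)   # block indices followed by 2x2 pool
    spatial_heads: int = 4
    channel_reduction: int = 8
    fc_sizes: tuple[int, int] = (256, 128)
    dropout: float = 0.5
    n_classes: int = 5
    use_spatial_attention: bool = True
    use_channel_attention: bool = True
    use_std_pool: bool = True
    global_avg_pool: bool = False  # replace flatten by GAP over 8x8

    def __post_init__(self):
        if self.spatial_heads < 1:
            raise ValueError("spatial_heads must be >= 1")
        if self.channel_reduction < 1:
            raise ValueError("channel_reduction must be >= 1")

    @property
    def final_spatial(self) -> int:
        return self.input_size // (2 ** len(self.pool_blocks))

    @property
    def flatten_length(self) -> int:
        if self.global_avg_pool:
            return self.channels[-1]
        return self.channels[-1] * self.final_spatial ** 2

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for key in ("channels", "pool_blocks", "fc_sizes"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


# ---------------------------------------------------------------------------
# attention blocks
# ---------------------------------------------------------------------------

class SpatialAttention(Module):
    """K independent heads of conv1x1 -> ReLU -> conv1x1 -> sigmoid gates."""

    def __init__(self, channels: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if n_heads < 1:
            raise ValueError("n_heads must be >= 1")
        self.n_heads = n_heads
        hidden = max(channels // 8, 8)
        self.heads = []
        for i in range(n_heads):
            reduce = Conv2d(channels, hidden, 1, rng, padding=0)
            gate = Conv2d(hidden, 1, 1, rng, padding=0)
            setattr(self, f"head{i}_reduce", reduce)
            setattr(self, f"head{i}_gate", gate)
            self.heads.append((reduce, gate))

    def forward(self, f: Tensor) -> tuple[Tensor, list[Tensor]]:
        maps = []
        refined = None
        for reduce, gate in self.heads:
            a = gate(reduce(f).relu()).sigmoid()  # (N,1,H,W)
            maps.append(a)
            term = a * f
            refined = term if refined is None else refined + term
        return refined, maps


class ChannelAttention(Module):
    """Triple-pooling descriptor + two-layer excitation gate."""

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator,
                 use_std_pool: bool = True):
        super().__init__()
        self.use_std_pool = use_std_pool
        n_pools = 3 if use_std_pool else 2
        hidden = max(int(np.ceil(channels / reduction)), 1)
        self.fc1 = Linear(n_pools * channels, hidden, rng)
        self.fc2 = Linear(hidden, channels, rng)

    def descriptor(self, f: Tensor) -> Tensor:
        n, c = f.shape[0], f.shape[1]
        flat = f.reshape(n, c, -1)
        avg = flat.mean(axis=2)
        mx = flat.max(axis=2)
        parts = [avg, mx]
        if self.use_std_pool:
            var = ((flat - avg.reshape(n, c, 1)) ** 2).mean(axis=2)
            parts.append((var + STD_EPS).sqrt())
        return concat(parts, axis=1)

    def forward(self, f: Tensor) -> tuple[Tensor, Tensor]:
        z = self.descriptor(f)
        s = self.fc2(self.fc1(z).relu()).sigmoid()  # (N,C)
        n, c = s.shape
        return f * s.reshape(n, c, 1, 1), s


# ---------------------------------------------------------------------------
# functional forms (single feature map, no batch axis) — the library surface
# used by tests and by anyone poking at a standalone tensor
# ---------------------------------------------------------------------------

def spatial_attention(f: np.ndarray, weights: list[dict[str, np.ndarray]]
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Apply multi-head spatial attention to a single CxHxW map.

    ``weights`` holds per-head dicts with keys ``w1, b1, w2, b2`` where
    ``w1`` is (hidden, C, 1, 1) and ``w2`` is (1, hidden, 1, 1). Returns
    the refined map F' = sum_i A_i * F and the stacked maps (K,H,W).
    """
    if len(weights) < 1:
        raise ValueError("need at least one attention head")
    f = np.asarray(f, dtype=np.float64)
    c, h, w = f.shape
    refined = np.zeros_like(f)
    maps = np.empty((len(weights), h, w))
    for i, head in enumerate(weights):
        hid = np.einsum("kc,chw->khw", head["w1"][:, :, 0, 0], f)
        hid += head["b1"][:, None, None]
        np.maximum(hid, 0.0, out=hid)
        pre = np.einsum("ok,khw->ohw", head["w2"][:, :, 0, 0], hid)[0]
        pre += head["b2"][0]
        a = 1.0 / (1.0 + np.exp(-pre))
        maps[i] = a
        refined += a[None] * f
    return refined, maps


def triple_pool(f: np.ndarray) -> np.ndarray:
    """Per-channel [avg | max | std] descriptor of a CxHxW map.

    Standard deviation is the population (ddof=0) statistic.
    """
    f = np.asarray(f, dtype=np.float64)
    flat = f.reshape(f.shape[0], -1)
    return np.concatenate([flat.mean(axis=1), flat.max(axis=1), flat.std(axis=1)])


def channel_attention(f: np.ndarray, w1: np.ndarray, b1: np.ndarray,
                      w2: np.ndarray, b2: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    """SE-style gate from the triple-pooled descriptor of a CxHxW map.

    ``w1``: (hidden, 3C), ``w2``: (C, hidden). Returns (F'', s).
    """
    f = np.asarray(f, dtype=np.float64)
    z = triple_pool(f)
    if w1.shape[1] != z.size:
        raise ValueError(f"w1 expects descriptor length {w1.shape[1]}, got {z.size}")
    if w2.shape[1] != w1.shape[0]:
        raise ValueError("w2 inner dimension must match w1 output")
    hidden = np.maximum(w1 @ z + b1, 0.0)
    s = 1.0 / (1.0 + np.exp(-(w2 @ hidden + b2)))
    return s[:, None, None] * f, s


# ---------------------------------------------------------------------------
# the full network
# ---------------------------------------------------------------------------

class DualAttentionCNN(Module):
    def __init__(self, config: ModelConfig, rng: np.random.Generator | int = 0):
        super().__init__()
        if isinstance(rng, (int, np.integer)):
            rng = np.random.default_rng(int(rng))
        self.config = config
        in_ch = 3
        self.blocks = []
        for bi, out_ch in enumerate(config.channels):
            conv = Conv2d(in_ch, out_ch, 3, rng, padding=1)
            bn = BatchNorm(out_ch, spatial=True)
            setattr(self, f"conv{bi}", conv)
            setattr(self, f"bn{bi}", bn)
            self.blocks.append((conv, bn, bi in config.pool_blocks))
            in_ch = out_ch
        c_final = config.channels[-1]
        if config.use_spatial_attention:
            self.spatial = SpatialAttention(c_final, config.spatial_heads, rng)
        if config.use_channel_attention:
            self.channel = ChannelAttention(c_final, config.channel_reduction, rng,
                                            use_std_pool=config.use_std_pool)
        flat = config.flatten_length
        f1, f2 = config.fc_sizes
        self.fc1 = Linear(flat, f1, rng)
        self.fc_bn1 = BatchNorm(f1, spatial=False)
        self.fc2 = Linear(f1, f2, rng)
        self.fc_bn2 = BatchNorm(f2, spatial=False)
        self.head = Linear(f2, config.n_classes, rng)
        self.drop = Dropout(config.dropout)

    def forward(self, x: Tensor, rng: np.random.Generator | None = None,
                return_intermediates: bool = False):
        """Map a (N,3,64,64) normalized batch to (N,5) logits.

        With ``return_intermediates`` also returns a dict holding the
        attention outputs and the pre-flatten feature map (used by the
        explainability module).
        """
        if x.ndim != 4 or x.shape[1] != 3 or x.shape[2] != self.config.input_size:
            raise ValueError(f"expected (N,3,{self.config.input_size},"
                             f"{self.config.input_size}) input, got {x.shape}")
        for conv, bn, pooled in self.blocks:
            x = bn(conv(x)).relu()
            if pooled:
                x = maxpool2d(x, 2)
        inter: dict[str, object] = {"backbone": x}
        if self.config.use_spatial_attention:
            x, maps = self.spatial(x)
            inter["spatial_maps"] = maps
        if self.config.use_channel_attention:
            x, gates = self.channel(x)
            inter["channel_gates"] = gates
        inter["features"] = x  # F'' — Grad-CAM target layer
        n = x.shape[0]
        if self.config.global_avg_pool:
            flat = x.reshape(n, x.shape[1], -1).mean(axis=2)
        else:
            flat = x.reshape(n, -1)
        h = self.drop(self.fc_bn1(self.fc1(flat)).relu(), rng)
        h = self.drop(self.fc_bn2(self.fc2(h)).relu(), rng)
        logits = self.head(h)
        if return_intermediates:
            return logits, inter
        return logits

    def predict_proba(self, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Softmax class probabilities for a (N,3,H,W) array, eval mode."""
        self.eval()
        out = []
        for i in range(0, len(images), batch_size):
            logits = self.forward(Tensor(images[i:i + batch_size])).data
            logits = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(logits)
            out.append(e / e.sum(axis=1, keepdims=True))
        return np.concatenate(out, axis=0)

    def summary(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "flatten_length": self.config.flatten_length,
            "n_parameters": int(sum(p.data.size for p in self.parameters())),
        }


def save_checkpoint(model: DualAttentionCNN, path: str | Path,
                    extra: dict | None = None) -> None:
    """Serialize weights + config (+ optional training metadata) to one file."""
    payload = {
        "config": model.config.to_dict(),
        "state": model.state_dict(),
        "extra": extra or {},
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)
    path.with_suffix(".json").write_text(
        json.dumps({"config": payload["config"], "extra": payload["extra"]},
                   indent=2, default=str))


def load_checkpoint(path: str | Path) -> tuple[DualAttentionCNN, dict]:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    model = DualAttentionCNN(ModelConfig.from_dict(payload["config"]))
    model.load_state_dict(payload["state"])
    return model, payload.get("extra", {})
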