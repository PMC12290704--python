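"""The trainable attention model.

A 3D U-Net consumes the stacked (fixed, moving) image pair and emits three
per-voxel logit maps; a SoftMax with a large temperature (tau = 100 by
default) converts them into near-binary shrink / expand / background
assignment maps.  With tau = 100, a pre-SoftMax logit gap of 0.06 already
yields a winning-channel probability of 1 / (1 + 2 e^{-tau g}) >= 0.995, so
trained maps behave like masks while remaining differentiable.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass

import numpy as np

from .grids import AttentionMaps, ScalarVolume, _require_same_grid
from .nn import UNet3D

__all__ = ["AttentionNetConfig", "AttentionNet", "softmax_temperature",
           "softmax_temperature_backward"]


@dataclass(frozen=True)
class AttentionNetConfig:
    depth: int = 3
    base_channels: int = 8
    softmax_temperature: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.softmax_temperature <= 0:
            raise ValueError("softmax temperature must be positive")


def softmax_temperature(logits: np.ndarray, tau: float) -> np.ndarray:
    """SoftMax over axis 0 of tau-scaled logits (numerically stable)."""
    z = tau * logits.astype(np.float64)
    z -= z.max(axis=0, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=0, keepdims=True)


def softmax_temperature_backward(
    probs: np.ndarray, dprobs: np.ndarray, tau: float
) -> np.ndarray:
    """Gradient wrt logits given grad wrt probabilities."""
    inner = (dprobs * probs).sum(axis=0, keepdims=True)
    return tau * probs * (dprobs - inner)


def zscore(values: np.ndarray) -> np.ndarray:
    std = values.std()
    if std == 0:
        return np.zeros_like(values)
    return (values - values.mean()) / std


class AttentionNet:
    """U-Net + temperature SoftMax, producing AttentionMaps for a scan pair."""

    def __init__(self, config: AttentionNetConfig | None = None):
        self.config = config or AttentionNetConfig()
        self.unet = UNet3D(
            in_channels=2,
            out_channels=3,
            depth=self.config.depth,
            base_channels=self.config.base_channels,
            seed=self.config.seed,
        )

    # -- inference -------------------------------------------------------
    def forward_probs(
        self, fixed_values: np.ndarray, moving_values: np.ndarray, normalize: bool = True
    ) -> np.ndarray:
        """Probability maps (3, D, H, W); shape must divide 2^(depth-1)."""
        if normalize:
            fixed_values = zscore(fixed_values)
            moving_values = zscore(moving_values)
        x = np.stack([fixed_values, moving_values], axis=0)
        logits = self.unet.forward(x)
        return softmax_temperature(logits, self.config.softmax_temperature)

    def forward(
        self, fixed: ScalarVolume, moving: ScalarVolume, normalize: bool = True
    ) -> AttentionMaps:
        """Run the attention model on a co-registered pair.

        Shapes not divisible by the U-Net's pooling factor are symmetrically
        zero-padded for the forward pass and cropped back afterwards.
        """
        _require_same_grid(fixed.grid, moving.grid, "attention forward")
        factor = 2 ** (self.config.depth - 1)
        shape = fixed.grid.shape
        pads = [(-s) % factor for s in shape]
        fv, mv = fixed.values, moving.values
        if normalize:
            fv, mv = zscore(fv), zscore(mv)
        if any(pads):
            pad_spec = [(p // 2, p - p // 2) for p in pads]
            fv = np.pad(fv, pad_spec)
            mv = np.pad(mv, pad_spec)
        probs = self.forward_probs(fv, mv, normalize=False)
        if any(pads):
            sl = tuple(
                slice(p // 2, p // 2 + s) for p, s in zip(pads, shape)
            )
            probs = probs[(slice(None), *sl)]
            probs = probs / probs.sum(axis=0, keepdims=True)
        return AttentionMaps(fixed.grid, probs)

    # -- persistence -----------------------------------------------------
    def save(self, path: str | os.PathLike) -> None:
        state = self.unet.state_dict()
        state["__config__"] = np.frombuffer(
            json.dumps(dataclasses.asdict(self.config)).encode(), dtype=np.uint8
        )
        np.savez(os.fspath(path), **state)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "AttentionNet":
        with np.load(os.fspath(path)) as data:
            cfg = AttentionNetConfig(
                **json.loads(bytes(data["__config__"].tobytes()).decode())
            )
            net = cls(cfg)
            net.unet.load_state_dict(
                {k: data[k] for k in data.files if k != "__config__"}
            )
        return net
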