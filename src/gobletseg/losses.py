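"""Segmentation losses: soft dice, focal, their weighted combination, BCE.

All losses accept either an autodiff ``Tensor`` (gradients flow) or a plain
ndarray (a float is effectively returned via a constant Tensor). The soft
dice is computed over flattened pixels of the whole batch; focal and BCE
are pixel means. Probabilities are clamped to ``[clamp, 1-clamp]`` inside
focal/BCE for numerical stability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn.autodiff import Tensor

__all__ = ["LossConfig", "dice_loss", "focal_loss", "combined_loss", "bce_loss"]

_CLAMP = 1e-7


@dataclass(frozen=True)
class LossConfig:
    """Weights and shape parameters of the compound loss.

    Defaults follow the training protocol: dice and focal combined with
    weights 0.7 / 0.3; focal focusing parameter gamma = 2 and class weight
    alpha = 0.25 (the focal-loss reference defaults).
    """

    dice_weight: float = 0.7
    focal_weight: float = 0.3
    focal_gamma: float = 2.0
    focal_alpha: float = 0.25
    smooth_eps: float = 1e-6

    def __post_init__(self) -> None:
        if self.focal_gamma < 0:
            raise ValueError("focal_gamma must be >= 0")
        if not (0 < self.focal_alpha < 1):
            raise ValueError("focal_alpha must be in (0, 1)")
        if self.smooth_eps <= 0:
            raise ValueError("smooth_eps must be positive")


def _pair(prob, mask) -> tuple[Tensor, np.ndarray]:
    p = prob if isinstance(prob, Tensor) else Tensor(prob)
    g = np.asarray(mask, dtype=np.float64)
    if g.shape != p.data.shape:
        raise ValueError(f"shape mismatch: prob {p.data.shape} vs mask {g.shape}")
    return p, g


def dice_loss(prob, mask, eps: float = 1e-6) -> Tensor:
    """1 - (2*sum(p*g) + eps) / (sum(p) + sum(g) + eps), in [0, 1]."""
    p, g = _pair(prob, mask)
    inter = (p * g).sum()
    denom = p.sum() + float(g.sum()) + eps
    return 1.0 - (2.0 * inter + eps) / denom


def focal_loss(prob, mask, gamma: float = 2.0, alpha: float = 0.25) -> Tensor:
    """Pixel-mean focal loss; at gamma=0, alpha=0.5 equals 0.5 * BCE."""
    p, g = _pair(prob, mask)
    p = p.clip(_CLAMP, 1.0 - _CLAMP)
    q = 1.0 - p
    pos = q.pow_const(gamma) * p.log() * (-alpha)
    neg = p.pow_const(gamma) * q.log() * (-(1.0 - alpha))
    return (pos * g + neg * (1.0 - g)).mean()


def combined_loss(prob, mask, cfg: LossConfig | None = None) -> Tensor:
    cfg = cfg or LossConfig()
    d = dice_loss(prob, mask, cfg.smooth_eps)
    f = focal_loss(prob, mask, cfg.focal_gamma, cfg.focal_alpha)
    return cfg.dice_weight * d + cfg.focal_weight * f


def bce_loss(prob, mask) -> Tensor:
    """Pixel-mean binary cross-entropy (the baseline U-Net's loss)."""
    p, g = _pair(prob, mask)
    p = p.clip(_CLAMP, 1.0 - _CLAMP)
    return -(p.log() * g + (1.0 - p).log() * (1.0 - g)).mean()
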