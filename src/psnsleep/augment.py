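"""Positive-pair construction blocks.

A positive pair is two views of (assumed) the same underlying content.  Five
constructions are provided behind one registry: the time shift block (adjacent
30-s epochs, justified by sleep-stage continuity), mixup, additive Gaussian
noise, random masking, pointwise scaling, and the identity block ``none``.
All blocks preserve array shape; the anchor is always the raw batch and the
view its augmented copy (for ``time_shift`` the view is the next epoch).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import EpochedRecording

KINDS = ("none", "time_shift", "mixup", "gaussian", "random_mask", "scaling")


@dataclass(frozen=True)
class AugmentationConfig:
    kind: str = "time_shift"
    gamma: float = 0.4           # mixup mixing ratio
    noise_sigma: float = 0.1     # Gaussian noise std (on unit-variance input)
    n_masked: int = 100          # zeroed sample points per epoch
    scale_sigma: float = 0.1     # spread of the scaling factors around 1
    per_epoch_scale: bool = False  # one factor per epoch instead of per point
    seed: int = 0

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown augmentation kind {self.kind!r}; expected one of {KINDS}")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma outside [0, 1]: {self.gamma}")
        if self.noise_sigma < 0 or self.scale_sigma < 0:
            raise ValueError("noise_sigma and scale_sigma must be >= 0")
        if self.n_masked < 0:
            raise ValueError(f"n_masked must be >= 0: {self.n_masked}")


@dataclass(frozen=True)
class PositivePairBatch:
    """Anchor/view arrays fed to the two Siamese branches; identical shapes."""

    anchor: np.ndarray
    view: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.anchor, dtype=np.float64)
        v = np.asarray(self.view, dtype=np.float64)
        if a.shape != v.shape:
            raise ValueError(f"anchor/view shape mismatch: {a.shape} vs {v.shape}")
        if a.ndim != 2:
            raise ValueError(f"pair batch must be 2-D (batch x samples), got {a.shape}")
        object.__setattr__(self, "anchor", a)
        object.__setattr__(self, "view", v)

    def __len__(self) -> int:
        return self.anchor.shape[0]


def _as_rng(rng_state) -> np.random.Generator:
    if isinstance(rng_state, np.random.Generator):
        return rng_state
    return np.random.default_rng(rng_state)


def mixup(batch: np.ndarray, gamma: float, rng_state) -> np.ndarray:
    """Row i -> (1 - gamma) * x_i + gamma * x_k, partner k drawn uniformly, k != i."""
    batch = np.asarray(batch, dtype=np.float64)
    B = batch.shape[0]
    if B < 2:
        raise ValueError("mixup needs a batch of at least 2 (a distinct partner per row)")
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"gamma outside [0, 1]: {gamma}")
    rng = _as_rng(rng_state)
    # uniform over the batch excluding the row itself
    partners = (np.arange(B) + rng.integers(1, B, size=B)) % B
    return (1.0 - gamma) * batch + gamma * batch[partners]


def gaussian(batch: np.ndarray, noise_sigma: float, rng_state) -> np.ndarray:
    """Superimpose i.i.d. Normal(0, noise_sigma^2) noise directly (no mixing ratio)."""
    batch = np.asarray(batch, dtype=np.float64)
    if noise_sigma < 0:
        raise ValueError(f"noise_sigma must be >= 0: {noise_sigma}")
    if noise_sigma == 0:
        return batch.copy()
    rng = _as_rng(rng_state)
    return batch + rng.normal(0.0, noise_sigma, size=batch.shape)


def random_mask(batch: np.ndarray, n_masked: int, rng_state) -> np.ndarray:
    """Zero exactly ``n_masked`` distinct sample points per row (patch = one point)."""
    batch = np.asarray(batch, dtype=np.float64)
    B, S = batch.shape
    if not 0 <= n_masked <= S:
        raise ValueError(f"n_masked {n_masked} outside [0, {S}]")
    out = batch.copy()
    if n_masked == 0:
        return out
    rng = _as_rng(rng_state)
    for i in range(B):
        idx = rng.choice(S, size=n_masked, replace=False)
        out[i, idx] = 0.0
    return out


def scaling(batch: np.ndarray, scale_sigma: float, rng_state,
            per_epoch: bool = False) -> np.ndarray:
    """Multiply by random factors rho ~ Normal(1, scale_sigma^2).

    Per sample point by default; ``per_epoch=True`` draws one factor per row.
    """
    batch = np.asarray(batch, dtype=np.float64)
    if scale_sigma < 0:
        raise ValueError(f"scale_sigma must be >= 0: {scale_sigma}")
    if scale_sigma == 0:
        return batch.copy()
    rng = _as_rng(rng_state)
    shape = (batch.shape[0], 1) if per_epoch else batch.shape
    return batch * rng.normal(1.0, scale_sigma, size=shape)


def time_shift_pairs(recording: EpochedRecording | np.ndarray) -> PositivePairBatch:
    """Pair each epoch t with its successor t+1; the final epoch has none.

    Stage transitions are deliberately NOT filtered out: under realistic
    continuity the fraction of cross-stage pairs is small and ignoring them
    is part of the method's assumption.
    """
    epochs = recording.signal if isinstance(recording, EpochedRecording) else np.asarray(recording)
    if epochs.shape[0] < 2:
        raise ValueError("time shift needs at least 2 epochs")
    return PositivePairBatch(anchor=epochs[:-1].copy(), view=epochs[1:].copy())


def make_pairs(data: EpochedRecording | np.ndarray, config: AugmentationConfig,
               rng_state=None) -> PositivePairBatch:
    """Dispatch to the configured block; anchor = raw, view = augmented."""
    rng = _as_rng(config.seed if rng_state is None else rng_state)
    if config.kind == "time_shift":
        return time_shift_pairs(data)
    batch = data.signal if isinstance(data, EpochedRecording) else np.asarray(data, dtype=np.float64)
    if config.kind == "none":
        view = batch.copy()
    elif config.kind == "mixup":
        view = mixup(batch, config.gamma, rng)
    elif config.kind == "gaussian":
        view = gaussian(batch, config.noise_sigma, rng)
    elif config.kind == "random_mask":
        view = random_mask(batch, config.n_masked, rng)
    elif config.kind == "scaling":
        view = scaling(batch, config.scale_sigma, rng, per_epoch=config.per_epoch_scale)
    else:  # pragma: no cover - guarded by AugmentationConfig
        raise ValueError(f"unknown augmentation kind {config.kind!r}")
    return PositivePairBatch(anchor=batch.copy(), view=view)
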