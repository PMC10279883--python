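"""Representation extractor: dual-filter CNN branches summed, then a GRU.

One 30-s epoch enters as a (batch, samples) array.  Two convolutional
branches — one with a short first-layer kernel (~ half the sampling rate,
capturing high-frequency content) and one with a long kernel (~ four times
the sampling rate, capturing slow rhythms) — produce time-frequency feature
maps that are merged by elementwise summation.  Both branches share the
same stride/pool schedule (with 'same' padding), so their output shapes
match by construction and the sum is well defined.  A GRU then consumes
the feature sequence; its final hidden state is the representation c_t.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn
from .nn.tensor import Tensor


@dataclass(frozen=True)
class EncoderConfig:
    sampling_rate: int = 100
    epoch_seconds: int = 30
    small_kernel: int | None = None   # default sampling_rate // 2
    large_kernel: int | None = None   # default sampling_rate * 4
    branch_channels: tuple[int, ...] = (32, 32, 32)  # conv channels per layer
    conv_strides: tuple[int, ...] = (6, 1, 1)
    pool_sizes: tuple[int, ...] = (4, 4, 2)
    later_kernel: int = 8             # kernel for layers after the first
    activation: str = "relu"
    gru_hidden: int = 960
    representation_dim: int = 960
    dropout: float = 0.0
    merge: str = "sum"                # "sum" per the model definition; "concat" escape hatch
    seed: int = 0

    def __post_init__(self):
        if self.activation != "relu":
            raise ValueError("only relu activation is supported")
        if self.merge not in ("sum", "concat"):
            raise ValueError(f"merge must be 'sum' or 'concat': {self.merge!r}")
        n = len(self.branch_channels)
        if not (len(self.conv_strides) == len(self.pool_sizes) == n):
            raise ValueError("branch_channels, conv_strides and pool_sizes must have equal length")
        if self.representation_dim != self.gru_hidden:
            raise ValueError(
                f"representation_dim ({self.representation_dim}) must equal the GRU "
                f"hidden size ({self.gru_hidden}); the representation is the final hidden state")

    @property
    def epoch_samples(self) -> int:
        return self.sampling_rate * self.epoch_seconds

    @property
    def small_kernel_(self) -> int:
        return self.small_kernel if self.small_kernel is not None else self.sampling_rate // 2

    @property
    def large_kernel_(self) -> int:
        return self.large_kernel if self.large_kernel is not None else self.sampling_rate * 4

    @property
    def n_conv_layers(self) -> int:
        return len(self.branch_channels)

    def feature_length(self) -> int:
        """Time steps T seen by the GRU, from the stride/pool arithmetic."""
        L = self.epoch_samples
        for stride, pool in zip(self.conv_strides, self.pool_sizes):
            L = -(-L // stride)   # 'same' conv: ceil(L / stride)
            L = L // pool         # non-overlapping max pool
        return L

    def feature_channels(self) -> int:
        return self.branch_channels[-1] * (2 if self.merge == "concat" else 1)


def tiny_config(seed: int = 0, gru_hidden: int = 32) -> EncoderConfig:
    """Desk-scale preset for tests and smoke runs (2 conv layers, 8 channels)."""
    return EncoderConfig(
        sampling_rate=100, small_kernel=25, large_kernel=200,
        branch_channels=(8, 8), conv_strides=(50, 1), pool_sizes=(2, 2),
        later_kernel=5, gru_hidden=gru_hidden, representation_dim=gru_hidden,
        seed=seed)


def default_config(seed: int = 0, sampling_rate: int = 100) -> EncoderConfig:
    """Full-scale preset: 960-d representation matching the projection width."""
    return EncoderConfig(sampling_rate=sampling_rate, seed=seed)


class _Branch(nn.Module):
    def __init__(self, cfg: EncoderConfig, first_kernel: int, rng: np.random.Generator):
        super().__init__()
        layers: list[nn.Module] = []
        in_ch = 1
        for i, (ch, stride, pool) in enumerate(
                zip(cfg.branch_channels, cfg.conv_strides, cfg.pool_sizes)):
            kernel = first_kernel if i == 0 else cfg.later_kernel
            layers.append(nn.Conv1d(in_ch, ch, kernel, stride, rng))
            layers.append(nn.ReLU())
            if cfg.dropout > 0:
                layers.append(nn.Dropout(cfg.dropout, np.random.default_rng(rng.integers(2**31))))
            if pool > 1:
                layers.append(nn.MaxPool1d(pool))
            in_ch = ch
        self.net = nn.Sequential(*layers)

    def forward(self, x: Tensor) -> Tensor:
        return self.net(x)


class Encoder(nn.Module):
    """The sub-model f_theta mapping (B, S) epochs to (B, d) representations."""

    def __init__(self, config: EncoderConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.small = _Branch(config, config.small_kernel_, rng)
        self.large = _Branch(config, config.large_kernel_, rng)
        self.gru = nn.GRU(config.feature_channels(), config.gru_hidden, rng)

    def cnn_features(self, x: Tensor | np.ndarray) -> Tensor:
        """Merged time-frequency features, shape (B, T, F)."""
        if not isinstance(x, Tensor):
            x = Tensor(x)
        if x.ndim != 2:
            raise ValueError(f"expected (batch, samples), got shape {x.shape}")
        B, S = x.shape
        if S != self.config.epoch_samples:
            raise ValueError(
                f"epoch length {S} != sampling_rate * epoch_seconds = {self.config.epoch_samples}")
        x3 = x.reshape(B, 1, S)
        zs = self.small(x3)
        zl = self.large(x3)
        if zs.shape != zl.shape:  # cannot happen with shared stride schedule
            raise ValueError(f"branch shape mismatch: {zs.shape} vs {zl.shape}")
        if self.config.merge == "sum":
            z = zs + zl
        else:
            B_, C, T = zs.shape
            z = Tensor._result(
                np.concatenate([zs.data, zl.data], axis=1), (zs, zl),
                _concat_backward(zs, zl, C))
        return z.transpose(0, 2, 1)  # (B, T, F)

    def forward(self, x: Tensor | np.ndarray) -> Tensor:
        z = self.cnn_features(x)
        c = self.gru(z)
        if not np.isfinite(c.data).all():
            raise FloatingPointError("non-finite values in the representation")
        return c

    encode = forward

    # -- checkpointing ----------------------------------------------------
    def save(self, path: str | Path):
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez(path.with_suffix(".npz"), **self.state_dict())
        path.with_suffix(".json").write_text(json.dumps(asdict(self.config), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "Encoder":
        path = Path(path)
        cfg_raw = json.loads(path.with_suffix(".json").read_text())
        for key in ("branch_channels", "conv_strides", "pool_sizes"):
            cfg_raw[key] = tuple(cfg_raw[key])
        enc = cls(EncoderConfig(**cfg_raw))
        with np.load(path.with_suffix(".npz")) as npz:
            enc.load_state_dict({k: npz[k] for k in npz.files})
        return enc


def _concat_backward(zs: Tensor, zl: Tensor, C: int):
    def backward(g):
        if zs.requires_grad:
            zs._accum(g[:, :C, :])
        if zl.requires_grad:
            zl._accum(g[:, C:, :])
    return backward


def parameter_count(config: EncoderConfig) -> int:
    """Closed-form parameter count of the encoder as a function of its config."""
    total = 0
    for first_kernel in (config.small_kernel_, config.large_kernel_):
        in_ch = 1
        for i, ch in enumerate(config.branch_channels):
            kernel = first_kernel if i == 0 else config.later_kernel
            total += ch * in_ch * kernel + ch
            in_ch = ch
    F, H = config.feature_channels(), config.gru_hidden
    total += 3 * (F * H + H * H + H)
    return total
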