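"""Neural-network building blocks over the tensor engine.

Parameters are named through attribute paths (``layer0.weight`` ...) so
state dicts serialize to flat ``name -> array`` maps.
"""

from __future__ import annotations

import math

import numpy as np

from .tensor import Tensor, conv1d, max_pool1d


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Minimal container: parameter discovery, state dicts, train/eval mode."""

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield prefix + name, value
        for cname, child in self._children():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        own = dict(self.named_parameters())
        missing = sorted(set(own) - set(state))
        unexpected = sorted(set(state) - set(own))
        if missing or unexpected:
            raise ValueError(
                f"state dict mismatch: missing={missing}, unexpected={unexpected}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()
        return self


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        bound = math.sqrt(6.0 / (in_features + out_features))  # Glorot uniform
        self.weight = Parameter(rng.uniform(-bound, bound, size=(in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv1d(Module):
    """1-D convolution with 'same'-style padding: out length = ceil(L / stride)."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int, rng: np.random.Generator):
        super().__init__()
        scale = math.sqrt(2.0 / (in_channels * kernel))  # He init for ReLU nets
        self.weight = Parameter(rng.normal(0.0, scale, size=(out_channels, in_channels, kernel)))
        self.bias = Parameter(np.zeros(out_channels))
        self.kernel = kernel
        self.stride = stride

    def forward(self, x: Tensor) -> Tensor:
        L = x.shape[-1]
        out_len = -(-L // self.stride)
        total = max((out_len - 1) * self.stride + self.kernel - L, 0)
        return conv1d(x, self.weight, self.bias, stride=self.stride,
                      padding=(total // 2, total - total // 2))


class MaxPool1d(Module):
    def __init__(self, kernel: int):
        super().__init__()
        self.kernel = kernel

    def forward(self, x: Tensor) -> Tensor:
        return max_pool1d(x, self.kernel)


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator | None = None):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1): {p}")
        self.p = p
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class BatchNorm1d(Module):
    """Batch normalization over (batch, features); always uses batch statistics.

    Both Siamese branches run in training mode inside a step, and the
    representation path downstream of the encoder contains no BN, so running
    averages are unnecessary.
    """

    def __init__(self, num_features: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=0, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=0, keepdims=True)
        inv = (var + self.eps) ** -0.5
        return centered * inv * self.gamma + self.beta


class GRU(Module):
    """Gated recurrent unit consuming (B, T, F); returns the final hidden state.

    Gate arithmetic follows the standard formulation
    z = sigma(x W_z + h U_z + b_z), r = sigma(x W_r + h U_r + b_r),
    n = tanh(x W_n + (r * h) U_n + b_n), h' = (1 - z) * n + z * h,
    with the initial hidden state fixed at zero.
    """

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator):
        super().__init__()
        k = 1.0 / math.sqrt(hidden_size)
        def u(shape):
            return Parameter(rng.uniform(-k, k, size=shape))
        self.w_z, self.u_z, self.b_z = u((input_size, hidden_size)), u((hidden_size, hidden_size)), Parameter(np.zeros(hidden_size))
        self.w_r, self.u_r, self.b_r = u((input_size, hidden_size)), u((hidden_size, hidden_size)), Parameter(np.zeros(hidden_size))
        self.w_n, self.u_n, self.b_n = u((input_size, hidden_size)), u((hidden_size, hidden_size)), Parameter(np.zeros(hidden_size))
        self.hidden_size = hidden_size

    def forward(self, x: Tensor, return_sequence: bool = False):
        B, T, _ = x.shape
        h = Tensor(np.zeros((B, self.hidden_size)))
        states = []
        for t in range(T):
            xt = x[:, t, :]
            z = (xt @ self.w_z + h @ self.u_z + self.b_z).sigmoid()
            r = (xt @ self.w_r + h @ self.u_r + self.b_r).sigmoid()
            n = (xt @ self.w_n + (r * h) @ self.u_n + self.b_n).tanh()
            h = (1.0 - z) * n + z * h
            if return_sequence:
                states.append(h)
        return states if return_sequence else h
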