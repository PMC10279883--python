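"""Online/target Siamese training without negative samples.

Two branches share the encoder + projection architecture.  The online
branch (parameters theta) additionally carries a prediction head and is
trained by gradient descent; the target branch (parameters epsilon) is an
exponential moving average of the online branch,

    epsilon <- tau * epsilon + (1 - tau) * theta,

updated after every optimizer step and never touched by gradients.  The
loss is the mean squared error between the L2-normalized online prediction
and the L2-normalized target projection — algebraically 2 - 2 cos(q, a) —
symmetrized by swapping which branch sees the anchor and which the view.
The predictor asymmetry plus the stop-gradient on the target branch is what
prevents the collapse to a constant representation.

Note on tau: the default decay rate is 0.1, so the target tracks the online
network within a few steps.  BYOL-style methods usually run tau >= 0.99;
0.1 makes the scheme closer to a stop-gradient Siamese network with a
slightly lagged target.  The knob is exposed in :class:`TrainConfig`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .nn.tensor import Tensor, no_grad
from .augment import AugmentationConfig, PositivePairBatch, make_pairs, time_shift_pairs
from .data import EpochedRecording
from .encoder import Encoder, EncoderConfig, default_config

_NORM_GUARD = 1e-12


class ProjectionHead(nn.Module):
    """g: Linear -> BatchNorm -> ReLU -> Linear, all layers ``dim`` wide."""

    def __init__(self, dim: int, rng: np.random.Generator):
        super().__init__()
        self.fc1 = nn.Linear(dim, dim, rng)
        self.bn = nn.BatchNorm1d(dim)
        self.fc2 = nn.Linear(dim, dim, rng)

    def forward(self, x):
        return self.fc2(self.bn(self.fc1(x)).relu())


class PredictionHead(nn.Module):
    """p: two affine layers, online branch only.

    As specified the two stacked affine layers carry no intermediate
    nonlinearity (so the head is effectively one affine map); set
    ``activation='relu'`` for a non-degenerate variant.
    """

    def __init__(self, dim: int, rng: np.random.Generator, activation: str | None = None):
        super().__init__()
        if activation not in (None, "relu"):
            raise ValueError(f"unsupported predictor activation: {activation!r}")
        self.fc1 = nn.Linear(dim, dim, rng)
        self.fc2 = nn.Linear(dim, dim, rng)
        self.activation = activation

    def forward(self, x):
        h = self.fc1(x)
        if self.activation == "relu":
            h = h.relu()
        return self.fc2(h)


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 32
    epochs: int = 200
    learning_rate: float = 1e-4
    tau: float = 0.1
    seed: int = 2022
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)
    encoder: EncoderConfig = field(default_factory=default_config)
    predictor_activation: str | None = None

    def __post_init__(self):
        if not 0.0 <= self.tau <= 1.0:
            raise ValueError(f"tau outside [0, 1]: {self.tau}")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2")


class SiameseState:
    """All mutable training state: both branches, optimizer, step counter, log."""

    def __init__(self, config: TrainConfig):
        self.config = config
        enc_cfg = replace(config.encoder, seed=config.seed)
        rng = np.random.default_rng(config.seed + 1)
        dim = enc_cfg.representation_dim
        self.online_encoder = Encoder(enc_cfg)
        self.online_projection = ProjectionHead(dim, rng)
        self.online_predictor = PredictionHead(dim, rng, config.predictor_activation)
        # target = structural copy of the online branch minus the predictor,
        # initialized as an exact parameter copy
        self.target_encoder = Encoder(enc_cfg)
        self.target_encoder.load_state_dict(self.online_encoder.state_dict())
        self.target_projection = ProjectionHead(dim, np.random.default_rng(0))
        self.target_projection.load_state_dict(self.online_projection.state_dict())
        for p in self.target_parameters():
            p.requires_grad = False
        self.tau = config.tau
        self.optimizer = nn.Adam(self.online_parameters(), lr=config.learning_rate)
        self.step = 0
        self.history: list[dict] = []

    def online_parameters(self):
        return (self.online_encoder.parameters() + self.online_projection.parameters()
                + self.online_predictor.parameters())

    def target_parameters(self):
        return self.target_encoder.parameters() + self.target_projection.parameters()


def init_state(config: TrainConfig) -> SiameseState:
    return SiameseState(config)


def project_and_predict(c, branch: str, state: SiameseState,
                        with_prediction: bool | None = None):
    """Run representations through the branch's head stack.

    Online: p(g(c)); target: g(c).  Requesting the predictor on the target
    branch is a contract violation (the target branch has none).
    """
    if branch not in ("online", "target"):
        raise ValueError(f"branch must be 'online' or 'target': {branch!r}")
    if branch == "target" and with_prediction:
        raise ValueError("the target branch has no prediction head")
    if not isinstance(c, Tensor):
        c = Tensor(c)
    if branch == "online":
        a = state.online_projection(c)
        if with_prediction is False:
            return a
        return state.online_predictor(a)
    return state.target_projection(c)


def _l2_normalize(a: Tensor) -> Tensor:
    sq = (a * a).sum(axis=1, keepdims=True)
    if float(np.min(sq.data)) < _NORM_GUARD ** 2:
        warnings.warn("zero-norm row in pair loss; norm guarded at 1e-12",
                      RuntimeWarning, stacklevel=3)
    return a * ((sq + _NORM_GUARD ** 2) ** -0.5)


def _pair_loss_t(a_pred: Tensor, a_target: Tensor) -> Tensor:
    if a_pred.shape != a_target.shape:
        raise ValueError(f"shape mismatch: {a_pred.shape} vs {a_target.shape}")
    diff = _l2_normalize(a_pred) - _l2_normalize(a_target)
    return (diff * diff).sum(axis=1).mean()


def pair_loss(a_pred: np.ndarray, a_target: np.ndarray) -> float:
    """Batch-averaged ||a_pred_bar - a_target_bar||^2 = 2 - 2 cos(a_pred, a_target).

    Both arguments are row-wise L2-normalized first, so the value lies in
    [0, 4] and is invariant to positive rescaling of either argument.
    """
    a = np.atleast_2d(np.asarray(a_pred, dtype=np.float64))
    b = np.atleast_2d(np.asarray(a_target, dtype=np.float64))
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values in pair_loss inputs")
    with no_grad():
        return _pair_loss_t(Tensor(a), Tensor(b)).item()


def _online_forward(x: np.ndarray, state: SiameseState) -> tuple[Tensor, Tensor]:
    c = state.online_encoder(Tensor(x))
    return state.online_predictor(state.online_projection(c)), c


def _target_forward(x: np.ndarray, state: SiameseState) -> Tensor:
    with no_grad():
        return state.target_projection(state.target_encoder(Tensor(x)))


def symmetric_loss(x: np.ndarray, x_view: np.ndarray, state: SiameseState) -> float:
    """L = (pair_loss(online(x), target(x')) + pair_loss(online(x'), target(x))) / 2."""
    loss, _ = _symmetric_loss_graph(x, x_view, state)
    return loss.item()


def _symmetric_loss_graph(x: np.ndarray, x_view: np.ndarray, state: SiameseState
                          ) -> tuple[Tensor, float]:
    q1, c1 = _online_forward(x, state)
    q2, _ = _online_forward(x_view, state)
    t1 = _target_forward(x_view, state)
    t2 = _target_forward(x, state)
    loss = (_pair_loss_t(q1, t1) + _pair_loss_t(q2, t2)) * 0.5
    rep_std = float(c1.data.std(axis=0).mean())
    return loss, rep_std


def ema_update(state: SiameseState) -> SiameseState:
    """epsilon <- tau * epsilon + (1 - tau) * theta, elementwise, in place."""
    tau = state.tau
    for online_mod, target_mod in (
            (state.online_encoder, state.target_encoder),
            (state.online_projection, state.target_projection)):
        theta = dict(online_mod.named_parameters())
        eps = dict(target_mod.named_parameters())
        if set(theta) != set(eps):
            raise ValueError(
                f"online/target structure mismatch: {sorted(set(theta) ^ set(eps))}")
        for name, p in eps.items():
            p.data = tau * p.data + (1.0 - tau) * theta[name].data
    return state


def train_step(pair_batch: PositivePairBatch, state: SiameseState) -> tuple[SiameseState, float]:
    """One optimization step: loss, Adam on theta only, then the EMA update."""
    state.optimizer.zero_grad()
    loss, rep_std = _symmetric_loss_graph(pair_batch.anchor, pair_batch.view, state)
    value = loss.item()
    if not np.isfinite(value):
        raise FloatingPointError(f"non-finite loss {value} at step {state.step}")
    loss.backward()
    state.optimizer.step()
    ema_update(state)
    state.step += 1
    state.history.append({"step": state.step, "loss": value, "rep_std": rep_std})
    return state, value


def _collect_pairs(recordings: list[EpochedRecording | np.ndarray],
                   kind: str) -> tuple[np.ndarray, np.ndarray | None]:
    """Stack training material: (anchors, views) for time_shift, else (epochs, None)."""
    if kind == "time_shift":
        anchors, views = [], []
        for rec in recordings:
            pairs = time_shift_pairs(rec)
            anchors.append(pairs.anchor)
            views.append(pairs.view)
        return np.concatenate(anchors), np.concatenate(views)
    stacks = [rec.signal if isinstance(rec, EpochedRecording) else np.asarray(rec)
              for rec in recordings]
    return np.concatenate(stacks), None


def pretrain(recordings: list[EpochedRecording | np.ndarray], config: TrainConfig,
             state: SiameseState | None = None) -> tuple[Encoder, list[dict]]:
    """Self-supervised pretraining; returns the ONLINE encoder and the loss history.

    ``recordings`` are expected to be normalized already (augmentation acts on
    standardized signals).  Each training epoch shuffles the pool of pairs /
    epochs and iterates batches of ``batch_size``; a trailing partial batch is
    dropped so every step sees a full batch (mixup and batch norm both want
    one).  Deterministic given ``config.seed``.
    """
    if not recordings:
        raise ValueError("empty dataset")
    anchors, views = _collect_pairs(recordings, config.augmentation.kind)
    n = anchors.shape[0]
    if n < config.batch_size:
        raise ValueError(f"{n} training pairs < batch_size {config.batch_size}")
    if state is None:
        state = init_state(config)
    shuffle_rng = np.random.default_rng(config.seed + 2)
    augment_rng = np.random.default_rng(config.seed + 3)
    bs = config.batch_size
    for _epoch in range(config.epochs):
        order = shuffle_rng.permutation(n)
        for start in range(0, n - bs + 1, bs):
            idx = order[start:start + bs]
            if views is not None:
                batch = PositivePairBatch(anchor=anchors[idx], view=views[idx])
            else:
                batch = make_pairs(anchors[idx], config.augmentation, augment_rng)
            state, _ = train_step(batch, state)
    return state.online_encoder, state.history
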