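"""Frozen-encoder evaluation: linear probing, k-fold CV, ablations.

Representation quality is measured by freezing the pretrained encoder,
extracting one representation per 30-s epoch, and training only a small
classifier on top (optionally preceded by a 5-step sequence GRU that sees
the causal window of representations ending at the epoch being scored).
The probe is trained with cross-entropy to the final configured epoch —
no early stopping or best-epoch selection — and each fold's last-epoch
predictions are what gets scored.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, replace, asdict

import numpy as np
import pandas as pd

from . import nn
from .nn.tensor import Tensor, no_grad
from .data import EpochedRecording, Hypnogram, N_STAGES, normalize
from .encoder import Encoder
from .metrics import ConfusionMatrix, EvalMetrics, confusion_matrix, metrics_from_confusion
from .siamese import TrainConfig, pretrain


@dataclass(frozen=True)
class ProbeConfig:
    use_sequence_net: bool = True
    sequence_length: int = 5
    sequence_gru_units: int = 64
    classifier_hidden: int = 64
    learning_rate: float = 1e-4
    epochs: int = 200
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self):
        if self.sequence_length < 1:
            raise ValueError("sequence_length must be >= 1")


class ProbeNet(nn.Module):
    """Optional sequence GRU followed by a two-layer classifier ending in 5 logits."""

    def __init__(self, input_dim: int, config: ProbeConfig):
        super().__init__()
        rng = np.random.default_rng(config.seed)
        self.config = config
        clf_in = input_dim
        if config.use_sequence_net:
            self.gru = nn.GRU(input_dim, config.sequence_gru_units, rng)
            clf_in = config.sequence_gru_units
        self.fc1 = nn.Linear(clf_in, config.classifier_hidden, rng)
        self.fc2 = nn.Linear(config.classifier_hidden, N_STAGES, rng)

    def forward(self, x: Tensor) -> Tensor:
        """x: (B, L, d) windows when the sequence net is on, else (B, d)."""
        if self.config.use_sequence_net:
            x = self.gru(x)
        return self.fc2(self.fc1(x).relu())


def extract_representations(encoder: Encoder, data, batch_size: int = 256) -> np.ndarray:
    """Inference-mode forward pass; the encoder is read-only here.

    ``data`` is a (n_epochs, samples) array, an :class:`EpochedRecording`,
    or a list of either (concatenated in order).
    """
    if isinstance(data, (EpochedRecording, np.ndarray)):
        data = [data]
    arrays = [d.signal if isinstance(d, EpochedRecording) else np.asarray(d) for d in data]
    epochs = np.concatenate(arrays)
    encoder.eval()
    out = []
    with no_grad():
        for start in range(0, epochs.shape[0], batch_size):
            out.append(encoder(epochs[start:start + batch_size]).data)
    encoder.train()
    return np.concatenate(out)


def _window_indices(lengths: list[int], L: int) -> np.ndarray:
    """Causal windows of length L per recording; edges left-padded by repetition."""
    chunks = []
    offset = 0
    for n in lengths:
        base = np.arange(n)
        win = np.stack([np.clip(base - (L - 1 - j), 0, n - 1) for j in range(L)], axis=1)
        chunks.append(win + offset)
        offset += n
    return np.concatenate(chunks)


def _probe_inputs(representations: np.ndarray, config: ProbeConfig,
                  recording_lengths: list[int] | None):
    n = representations.shape[0]
    lengths = recording_lengths if recording_lengths is not None else [n]
    if sum(lengths) != n:
        raise ValueError(f"recording_lengths sum {sum(lengths)} != n representations {n}")
    if not config.use_sequence_net:
        return representations, list(range(len(lengths)))
    keep, chunks, offset = [], [], 0
    for i, ln in enumerate(lengths):
        if ln < config.sequence_length:
            warnings.warn(f"recording {i} has {ln} epochs < sequence_length "
                          f"{config.sequence_length}; skipped", RuntimeWarning, stacklevel=3)
        else:
            keep.append(i)
            chunks.append((offset, ln))
        offset += ln
    if not chunks:
        raise ValueError("no recording long enough for the sequence window")
    idx = _window_indices([ln for _, ln in chunks], config.sequence_length)
    # remap window indices into the full representation array
    remap = np.concatenate([np.arange(off, off + ln) for off, ln in chunks])
    return representations[remap[idx]], keep


def _cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    shift = Tensor(logits.data.max(axis=1, keepdims=True))  # constant, no grad
    z = logits - shift
    lse = z.exp().sum(axis=1, keepdims=True).log()
    onehot = np.zeros(logits.shape)
    onehot[np.arange(labels.size), labels] = 1.0
    picked = (z * Tensor(onehot)).sum(axis=1, keepdims=True)
    return (lse - picked).mean()


def train_probe(representations: np.ndarray, labels, config: ProbeConfig,
                recording_lengths: list[int] | None = None) -> ProbeNet:
    """Train the classifier (encoder untouched); Adam + cross-entropy, seeded."""
    y = labels.stages if isinstance(labels, Hypnogram) else np.asarray(labels, dtype=np.int64)
    if y.shape[0] != representations.shape[0]:
        raise ValueError("representations and labels are not aligned")
    inputs, kept = _probe_inputs(representations, config, recording_lengths)
    if recording_lengths is not None and config.use_sequence_net:
        mask = np.concatenate([
            np.full(ln, i in kept)
            for i, ln in enumerate(recording_lengths)])
        y = y[mask]
    probe = ProbeNet(representations.shape[1], config)
    optimizer = nn.Adam(probe.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    n, bs = inputs.shape[0], config.batch_size
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            optimizer.zero_grad()
            loss = _cross_entropy(probe(Tensor(inputs[idx])), y[idx])
            loss.backward()
            optimizer.step()
    return probe


def predict_probe(probe: ProbeNet, representations: np.ndarray,
                  recording_lengths: list[int] | None = None) -> np.ndarray:
    inputs, _ = _probe_inputs(representations, probe.config, recording_lengths)
    probe.eval()
    preds = []
    with no_grad():
        for start in range(0, inputs.shape[0], 512):
            preds.append(probe(Tensor(inputs[start:start + 512])).data.argmax(axis=1))
    probe.train()
    return np.concatenate(preds)


def kfold_split(n_units: int, k: int = 10, seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Partition unit indices into k disjoint parts; fold i tests part i, trains the rest."""
    if n_units < k:
        raise ValueError(f"cannot split {n_units} units into {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_units)
    parts = np.array_split(order, k)
    folds = []
    for i in range(k):
        test = np.sort(parts[i])
        train = np.sort(np.concatenate([parts[j] for j in range(k) if j != i]))
        folds.append((train, test))
    return folds


@dataclass(frozen=True)
class CrossValidationResult:
    fold_metrics: list[EvalMetrics]
    pooled_confusion: ConfusionMatrix
    pooled_metrics: EvalMetrics

    def fold_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"fold": i, "accuracy": m.accuracy, "macro_f1": m.macro_f1, "kappa": m.kappa}
            for i, m in enumerate(self.fold_metrics)])


def _evaluate_fold(train_subjects, test_subjects, train_config: TrainConfig,
                   probe_config: ProbeConfig) -> ConfusionMatrix:
    norm_train = [normalize(rec)[0] for rec, _ in train_subjects]
    norm_test = [normalize(rec)[0] for rec, _ in test_subjects]
    encoder, _ = pretrain(norm_train, train_config)
    train_reps = extract_representations(encoder, norm_train)
    test_reps = extract_representations(encoder, norm_test)
    train_labels = np.concatenate([h.stages for _, h in train_subjects])
    test_labels = np.concatenate([h.stages for _, h in test_subjects])
    probe = train_probe(train_reps, train_labels, probe_config,
                        recording_lengths=[r.n_epochs for r in norm_train])
    preds = predict_probe(probe, test_reps,
                          recording_lengths=[r.n_epochs for r in norm_test])
    return confusion_matrix(test_labels, preds)


def cross_validate(dataset: list[tuple[EpochedRecording, Hypnogram]],
                   train_config: TrainConfig, probe_config: ProbeConfig,
                   k: int = 10, split_unit: str = "subject") -> CrossValidationResult:
    """Per fold: pretrain on the training part, probe, score the held-out part.

    ``split_unit='subject'`` (default) guarantees no subject contributes to
    both sides of any fold.  ``'epoch'`` splits the pooled epochs instead,
    for parity with evaluation protocols whose splitting unit is unreported;
    it can leak subject identity and is not the default.
    """
    if split_unit == "subject":
        folds = kfold_split(len(dataset), k, seed=train_config.seed)
        get = lambda idx: [dataset[i] for i in idx]
    elif split_unit == "epoch":
        all_rec = np.concatenate([r.signal for r, _ in dataset])
        all_lab = np.concatenate([h.stages for _, h in dataset])
        sr = dataset[0][0].sampling_rate
        folds = kfold_split(all_rec.shape[0], k, seed=train_config.seed)
        def get(idx):
            rec = EpochedRecording(signal=all_rec[idx], sampling_rate=sr,
                                   epoch_seconds=dataset[0][0].epoch_seconds)
            return [(rec, Hypnogram(stages=all_lab[idx]))]
    else:
        raise ValueError(f"split_unit must be 'subject' or 'epoch': {split_unit!r}")

    fold_cms = []
    for i, (train_idx, test_idx) in enumerate(folds):
        try:
            fold_cms.append(_evaluate_fold(get(train_idx), get(test_idx),
                                           train_config, probe_config))
        except Exception as exc:
            raise RuntimeError(f"fold {i} failed: {exc}") from exc
    pooled = fold_cms[0]
    for cm in fold_cms[1:]:
        pooled = pooled + cm
    return CrossValidationResult(
        fold_metrics=[metrics_from_confusion(cm) for cm in fold_cms],
        pooled_confusion=pooled,
        pooled_metrics=metrics_from_confusion(pooled))


def _config_fingerprint(train_config: TrainConfig, probe_config: ProbeConfig) -> str:
    blob = json.dumps({
        "train": {**asdict(train_config), "augmentation": None},
        "probe": asdict(probe_config)}, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def ablation_run(dataset: list[tuple[EpochedRecording, Hypnogram]],
                 augmentations: list[str], train_config: TrainConfig,
                 probe_config: ProbeConfig, n_test_subjects: int | None = None
                 ) -> pd.DataFrame:
    """One row per augmentation block, all other settings identical.

    The sequence net is disabled (representations go straight to the
    classifier) so the comparison reflects the representations themselves.
    Subjects are split once into train/test (last ``n_test_subjects`` held
    out) and the same split is reused for every row.
    """
    probe_config = replace(probe_config, use_sequence_net=False)
    n_test = n_test_subjects or max(1, len(dataset) // 3)
    if n_test >= len(dataset):
        raise ValueError("n_test_subjects must leave at least one training subject")
    train_subjects, test_subjects = dataset[:-n_test], dataset[-n_test:]
    rows = []
    for kind in augmentations:
        cfg = replace(train_config,
                      augmentation=replace(train_config.augmentation, kind=kind))
        cm = _evaluate_fold(train_subjects, test_subjects, cfg, probe_config)
        m = metrics_from_confusion(cm)
        rows.append({"augmentation": kind, "accuracy": m.accuracy,
                     "macro_f1": m.macro_f1, "kappa": m.kappa,
                     "config_hash": _config_fingerprint(cfg, probe_config)})
    return pd.DataFrame(rows)
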