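"""scikit-learn estimator facades.

:class:`SiamesePretrainer` is a transformer: ``fit`` runs the
self-supervised Siamese pretraining on unlabeled epochs, ``transform``
maps epochs to frozen-encoder representations.  :class:`SleepStageProbe`
is a classifier over those representations.  Chained in a sklearn
``Pipeline`` they reproduce the full pretrain-then-probe protocol.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin

from .augment import AugmentationConfig
from .data import EpochedRecording, normalize
from .encoder import default_config, tiny_config
from .evaluate import ProbeConfig, extract_representations, predict_probe, train_probe
from .siamese import TrainConfig, pretrain


def _as_recordings(X, sampling_rate: int) -> list[EpochedRecording]:
    if isinstance(X, EpochedRecording):
        return [X]
    if isinstance(X, np.ndarray):
        return [EpochedRecording(signal=X, sampling_rate=sampling_rate,
                                 epoch_seconds=X.shape[1] // sampling_rate)]
    out = []
    for item in X:
        out.extend(_as_recordings(item, sampling_rate))
    return out


class SiamesePretrainer(TransformerMixin, BaseEstimator):
    """Self-supervised representation learner for epoched single-channel EEG.

    Parameters
    ----------
    preset : {'tiny', 'full'}
        Encoder size. 'tiny' (2 conv layers, 8 channels, 32-d representation)
        is desk-scale; 'full' is the 960-d configuration.
    augment : str
        Positive-pair block: one of none, time_shift, mixup, gaussian,
        random_mask, scaling.
    epochs : int
        Pretraining passes over the pair pool.
    tau : float
        Target decay rate of the EMA update.
    """

    def __init__(self, preset: str = "tiny", augment: str = "time_shift",
                 gamma: float = 0.4, noise_sigma: float = 0.1, n_masked: int = 100,
                 scale_sigma: float = 0.1, epochs: int = 5, batch_size: int = 32,
                 learning_rate: float = 1e-4, tau: float = 0.1, seed: int = 2022,
                 sampling_rate: int = 100, normalize_scope: str = "per_epoch"):
        self.preset = preset
        self.augment = augment
        self.gamma = gamma
        self.noise_sigma = noise_sigma
        self.n_masked = n_masked
        self.scale_sigma = scale_sigma
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.tau = tau
        self.seed = seed
        self.sampling_rate = sampling_rate
        self.normalize_scope = normalize_scope

    def _train_config(self) -> TrainConfig:
        if self.preset == "tiny":
            enc = tiny_config(seed=self.seed)
            enc = replace(enc, sampling_rate=self.sampling_rate)
        elif self.preset == "full":
            enc = default_config(seed=self.seed, sampling_rate=self.sampling_rate)
        else:
            raise ValueError(f"preset must be 'tiny' or 'full': {self.preset!r}")
        aug = AugmentationConfig(kind=self.augment, gamma=self.gamma,
                                 noise_sigma=self.noise_sigma, n_masked=self.n_masked,
                                 scale_sigma=self.scale_sigma, seed=self.seed)
        return TrainConfig(batch_size=self.batch_size, epochs=self.epochs,
                           learning_rate=self.learning_rate, tau=self.tau,
                           seed=self.seed, augmentation=aug, encoder=enc)

    def _normalized(self, X) -> list[EpochedRecording]:
        return [normalize(rec, scope=self.normalize_scope)[0]
                for rec in _as_recordings(X, self.sampling_rate)]

    def fit(self, X, y=None):
        recs = self._normalized(X)
        self.n_features_in_ = recs[0].epoch_samples
        self.encoder_, self.history_ = pretrain(recs, self._train_config())
        self.loss_curve_ = [h["loss"] for h in self.history_]
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "encoder_"):
            raise RuntimeError("SiamesePretrainer is not fitted")
        return extract_representations(self.encoder_, self._normalized(X))


class SleepStageProbe(ClassifierMixin, BaseEstimator):
    """Frozen-representation sleep-stage classifier (the linear-evaluation probe)."""

    def __init__(self, use_sequence_net: bool = True, sequence_length: int = 5,
                 sequence_gru_units: int = 64, classifier_hidden: int = 64,
                 learning_rate: float = 1e-4, epochs: int = 200,
                 batch_size: int = 32, seed: int = 0):
        self.use_sequence_net = use_sequence_net
        self.sequence_length = sequence_length
        self.sequence_gru_units = sequence_gru_units
        self.classifier_hidden = classifier_hidden
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.seed = seed

    def _probe_config(self) -> ProbeConfig:
        return ProbeConfig(
            use_sequence_net=self.use_sequence_net, sequence_length=self.sequence_length,
            sequence_gru_units=self.sequence_gru_units,
            classifier_hidden=self.classifier_hidden, learning_rate=self.learning_rate,
            epochs=self.epochs, batch_size=self.batch_size, seed=self.seed)

    def fit(self, X, y, recording_lengths=None):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.int64)
        self.classes_ = np.arange(5)
        self.n_features_in_ = X.shape[1]
        self.probe_ = train_probe(X, y, self._probe_config(),
                                  recording_lengths=recording_lengths)
        return self

    def predict(self, X, recording_lengths=None) -> np.ndarray:
        if not hasattr(self, "probe_"):
            raise RuntimeError("SleepStageProbe is not fitted")
        return predict_probe(self.probe_, np.asarray(X, dtype=np.float64),
                             recording_lengths=recording_lengths)
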