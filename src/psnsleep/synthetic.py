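"""Hypnogram-structured synthetic polysomnography.

Real overnight sleep shows strong stage continuity: the hypnogram is made
of long runs of a single stage, which is exactly what justifies treating
adjacent 30-s epochs as positive pairs.  The generator reproduces that
structure with a first-order Markov chain (stay with probability
``self_transition_prob``, otherwise jump uniformly to one of the other four
stages) and gives each stage a distinct spectral signature: a sum of
sinusoids at stage-specific frequencies with random phase per epoch, plus
white noise.  Adjacent same-stage epochs are therefore similar in spectrum
but not identical in waveform.

This is a caricature of EEG, not a biophysical model — no K-complexes,
spindle morphology or 1/f background — but it gives downstream code a
dataset whose stages are learnable and whose adjacency statistics are
known in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import EpochedRecording, Hypnogram, N_STAGES, StageLabel


@dataclass(frozen=True)
class StageSignalTemplate:
    """Spectral recipe for one stage: (center frequency Hz, amplitude) pairs + noise."""

    stage: StageLabel
    oscillation_bands: tuple[tuple[float, float], ...]
    noise_amplitude: float = 0.5


def default_templates() -> tuple[StageSignalTemplate, ...]:
    """Well-separated stage signatures loosely echoing real EEG rhythms:

    W alpha-like 10 Hz, N1 theta-like 6 Hz, N2 spindle-band 13 Hz,
    N3 high-amplitude slow 1 Hz, REM mixed 6 + 2.5 Hz.
    """
    return (
        StageSignalTemplate(StageLabel.W, ((10.0, 1.0),)),
        StageSignalTemplate(StageLabel.N1, ((6.0, 1.0),)),
        StageSignalTemplate(StageLabel.N2, ((13.0, 1.0),)),
        StageSignalTemplate(StageLabel.N3, ((1.0, 2.5),)),
        StageSignalTemplate(StageLabel.REM, ((6.0, 0.8), (2.5, 0.8))),
    )


@dataclass(frozen=True)
class SyntheticConfig:
    n_epochs: int = 1000
    sampling_rate: int = 100
    epoch_seconds: int = 30
    self_transition_prob: float = 0.9
    initial_distribution: tuple[float, ...] = (0.2, 0.2, 0.2, 0.2, 0.2)
    templates: tuple[StageSignalTemplate, ...] = field(default_factory=default_templates)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.self_transition_prob <= 1.0:
            raise ValueError(f"self_transition_prob outside [0, 1]: {self.self_transition_prob}")
        init = np.asarray(self.initial_distribution, dtype=float)
        if init.size != N_STAGES or abs(init.sum() - 1.0) > 1e-9 or (init < 0).any():
            raise ValueError("initial_distribution must be 5 non-negative probabilities summing to 1")
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")
        stages = {t.stage for t in self.templates}
        if stages != set(StageLabel):
            raise ValueError(f"templates must cover all 5 stages, got {sorted(stages)}")
        nyquist = self.sampling_rate / 2.0
        for t in self.templates:
            for freq, _amp in t.oscillation_bands:
                if not 0.0 < freq < nyquist:
                    raise ValueError(
                        f"template frequency {freq} Hz outside (0, Nyquist={nyquist}) "
                        f"for stage {t.stage.name}")


def generate_hypnogram(config: SyntheticConfig) -> Hypnogram:
    """Sample the stage sequence from the symmetric-escape Markov chain."""
    rng = np.random.default_rng(config.seed)
    p_stay = config.self_transition_prob
    stages = np.empty(config.n_epochs, dtype=np.int64)
    stages[0] = rng.choice(N_STAGES, p=np.asarray(config.initial_distribution))
    for t in range(1, config.n_epochs):
        if rng.random() < p_stay:
            stages[t] = stages[t - 1]
        else:
            step = rng.integers(1, N_STAGES)  # uniform over the other 4 stages
            stages[t] = (stages[t - 1] + step) % N_STAGES
    return Hypnogram(stages=stages)


def generate_signal(hypnogram: Hypnogram, config: SyntheticConfig) -> EpochedRecording:
    """Render each epoch from its stage template: sinusoids with random phase + noise."""
    rng = np.random.default_rng(config.seed + 1)
    per_epoch = config.sampling_rate * config.epoch_seconds
    t = np.arange(per_epoch) / config.sampling_rate
    by_stage = {tpl.stage: tpl for tpl in config.templates}
    signal = np.empty((len(hypnogram), per_epoch))
    for i, stage in enumerate(hypnogram.stages):
        tpl = by_stage[StageLabel(stage)]
        epoch = np.zeros(per_epoch)
        for freq, amp in tpl.oscillation_bands:
            phase = rng.uniform(0.0, 2.0 * np.pi)
            epoch += amp * np.sin(2.0 * np.pi * freq * t + phase)
        if tpl.noise_amplitude > 0:
            epoch += tpl.noise_amplitude * rng.standard_normal(per_epoch)
        signal[i] = epoch
    return EpochedRecording(signal=signal, sampling_rate=config.sampling_rate,
                            epoch_seconds=config.epoch_seconds, channel="synthetic")


def generate_subject(config: SyntheticConfig, subject_id: str = "S000"
                     ) -> tuple[EpochedRecording, Hypnogram]:
    hyp = generate_hypnogram(config)
    rec = generate_signal(hyp, config)
    rec = EpochedRecording(signal=rec.signal, sampling_rate=rec.sampling_rate,
                           epoch_seconds=rec.epoch_seconds, channel=rec.channel,
                           subject_id=subject_id)
    return rec, hyp


def generate_dataset(config: SyntheticConfig, n_subjects: int
                     ) -> list[tuple[EpochedRecording, Hypnogram]]:
    """Independent subjects with derived seeds (base seed + 1000 * subject index)."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    subjects = []
    for i in range(n_subjects):
        cfg = SyntheticConfig(
            n_epochs=config.n_epochs, sampling_rate=config.sampling_rate,
            epoch_seconds=config.epoch_seconds,
            self_transition_prob=config.self_transition_prob,
            initial_distribution=config.initial_distribution,
            templates=config.templates, seed=config.seed + 1000 * i)
        subjects.append(generate_subject(cfg, subject_id=f"S{i:03d}"))
    return subjects
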