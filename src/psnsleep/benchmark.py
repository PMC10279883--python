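"""Desk-scale representation-quality benchmark on synthetic sleep data.

The study conditions: 10 synthetic subjects of 200 epochs each at 100 Hz
with stage continuity p_stay = 0.9 and the default spectral templates.
The last 3 subjects are held out; the encoder (tiny preset) is pretrained
on the remaining 7 and a linear probe (no sequence net) is trained on the
frozen representations.  Three conditions are compared:

* ``time_shift`` — pretraining with adjacent-epoch positive pairs,
* ``none``       — pretraining with the identity augmentation,
* ``random_encoder`` — no pretraining at all (frozen random initialization).

Held-out probe accuracy orders these conditions the way the augmentation
ablation on real data does: the identity block is the weakest and the time
shift block the strongest, with chance at 0.2 for five balanced stages.
"""

from __future__ import annotations

import numpy as np

from .augment import AugmentationConfig
from .data import normalize
from .encoder import Encoder, tiny_config
from .evaluate import ProbeConfig, extract_representations, predict_probe, train_probe
from .siamese import TrainConfig, pretrain
from .synthetic import SyntheticConfig, generate_dataset

CONDITIONS = ("time_shift", "none", "random_encoder")


def probe_comparison(seed: int, n_subjects: int = 10, n_epochs: int = 200,
                     p_stay: float = 0.9, n_test_subjects: int = 3,
                     pretrain_epochs: int = 5, probe_epochs: int = 50
                     ) -> dict[str, float]:
    """Held-out probe accuracy per condition; deterministic given ``seed``."""
    dataset = generate_dataset(
        SyntheticConfig(n_epochs=n_epochs, self_transition_prob=p_stay, seed=seed),
        n_subjects)
    train, test = dataset[:-n_test_subjects], dataset[-n_test_subjects:]
    norm_train = [normalize(rec)[0] for rec, _ in train]
    norm_test = [normalize(rec)[0] for rec, _ in test]
    y_train = np.concatenate([h.stages for _, h in train])
    y_test = np.concatenate([h.stages for _, h in test])
    probe_cfg = ProbeConfig(use_sequence_net=False, epochs=probe_epochs, seed=seed)

    results: dict[str, float] = {}
    for condition in CONDITIONS:
        if condition == "random_encoder":
            encoder = Encoder(tiny_config(seed=seed))
        else:
            cfg = TrainConfig(
                batch_size=32, epochs=pretrain_epochs, seed=seed,
                encoder=tiny_config(seed=seed),
                augmentation=AugmentationConfig(kind=condition, seed=seed))
            encoder, _ = pretrain(norm_train, cfg)
        reps_train = extract_representations(encoder, norm_train)
        reps_test = extract_representations(encoder, norm_test)
        probe = train_probe(reps_train, y_train, probe_cfg)
        preds = predict_probe(probe, reps_test)
        results[condition] = float((preds == y_test).mean())
    return results
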