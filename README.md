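# psnsleep

Self-supervised representation learning for single-channel EEG sleep
staging, using **only positive sample pairs** — no negative samples, no
memory banks.

Sleep staging assigns each 30-second epoch of an overnight EEG to one of
the five AASM stages (W, N1, N2, N3, REM). Labeling requires trained
experts, so methods that learn useful representations from *unlabeled*
recordings are attractive. `psnsleep` implements PSNSleep, a BYOL-style
Siamese scheme for exactly that setting, for researchers working on
sleep-EEG representation learning who want a self-contained, fully
deterministic reference implementation with a synthetic data generator so
every stage of the pipeline is testable without downloading PSG datasets.

## The method

Two branches share an encoder + projection architecture:

* **Online branch** (parameters θ): encoder f_θ → projection g_θ →
  prediction p_θ, trained by Adam.
* **Target branch** (parameters ε): encoder f_ε → projection g_ε, never
  touched by gradients; after every step it follows the EMA update
  ε ← τ·ε + (1 − τ)·θ with decay rate τ = 0.1.

The encoder is two CNN branches (a short first-layer kernel ≈ fs/2 for
fast rhythms, a long one ≈ 4·fs for slow waves) merged by elementwise sum,
followed by a GRU whose final hidden state is the representation c_t.

A positive pair (x, x′) is two views of the same content. The headline
construction is the **time shift** block: epoch t and epoch t+1 form a
pair, justified by sleep-stage continuity (adjacent epochs almost always
share a stage). Mixup (x̃ᵢ = (1−γ)xᵢ + γx_k, γ = 0.4), additive Gaussian
noise, random masking and pointwise scaling are provided as alternatives,
plus the identity block for ablations.

The loss is the symmetrized, L2-normalized MSE

L = ½·[ ‖p̄_θ(g_θ(f_θ(x))) − ḡ_ε(f_ε(x′))‖² + (x ↔ x′) ],
  each term = 2 − 2·cos(prediction, target projection) ∈ [0, 4].

Representation quality is measured by **linear evaluation**: freeze the
online encoder, extract one representation per epoch, train only a small
classifier (optionally preceded by a 5-step sequence GRU), and report
accuracy, macro-F1 (MF1) and Cohen's κ from the pooled confusion matrix of
a 10-fold cross-validation.

## Worked example

Score a 5×5 confusion matrix (here, the packaged reference matrix from
the method's Sleep-EDF evaluation):

```bash
psnsleep metrics --confusion src/psnsleep/reference/sleep_edf_confusion.csv
```

```
            W      N1      N2      N3     REM      PR      RC      F1
    W    6912     445     136      28     213   80.23   89.37   84.56
   N1     585     993     566      15     625   35.98   35.67   35.82
   N2     603     500   15192     598     777   87.15   85.98   86.56
   N3     157       5     672    4856       6   88.27   85.25   86.74
  REM     358     817     867       4    5670   77.77   73.48   75.56
accuracy 0.808  MF1 0.738  kappa 0.737  (N = 41600)
```

Rows are true stages, columns predictions; PR/RC/F1 are per-stage
precision, recall and F1 in percent. The summary line gives overall
accuracy (trace/N), macro-F1 and chance-corrected agreement κ.

Run the pipeline end to end on synthetic data (a first-order Markov
hypnogram with stay-probability 0.9 and stage-specific spectral
templates):

```python
import psnsleep as ps

res = ps.probe_comparison(seed=1)
print(res)
# {'time_shift': 0.5567, 'none': 0.485, 'random_encoder': 0.5133}
```

Held-out probe accuracy (chance = 0.2) is highest for time-shift
pretraining, above both the identity-augmentation run and a frozen
randomly initialized encoder — the same ordering the augmentation
ablation shows on real data. The sklearn-style estimators compose with
pipelines:

```python
from sklearn.pipeline import Pipeline

pipe = Pipeline([
    ("pretrain", ps.SiamesePretrainer(preset="tiny", augment="time_shift", epochs=5)),
    ("probe", ps.SleepStageProbe(use_sequence_net=False, epochs=50)),
])
```

The CLI mirrors the library: `psnsleep generate | pretrain | evaluate |
ablate | metrics`, each run directory holding a `manifest.json` from which
the run can be reproduced bit-for-bit.

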