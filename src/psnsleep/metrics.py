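"""Sleep-staging evaluation metrics derived from a 5x5 confusion matrix.

Convention throughout: rows are the true stage, columns the predicted
stage, both in the fixed order W, N1, N2, N3, REM.  From the counts we
derive overall accuracy (trace / N), per-class precision, recall and F1,
their unweighted mean MF1, and Cohen's kappa computed from the pooled
matrix.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from .data import N_STAGES, STAGE_NAMES


@dataclass(frozen=True)
class ConfusionMatrix:
    counts: np.ndarray  # (5, 5) non-negative integers, rows = true

    def __post_init__(self):
        arr = np.asarray(self.counts)
        if arr.shape != (N_STAGES, N_STAGES):
            raise ValueError(f"confusion matrix must be 5x5, got {arr.shape}")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("confusion matrix entries must be integral")
            arr = np.round(arr).astype(np.int64)
        if (arr < 0).any():
            raise ValueError("confusion matrix entries must be non-negative")
        object.__setattr__(self, "counts", arr.astype(np.int64))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.counts + other.counts)


@dataclass(frozen=True)
class EvalMetrics:
    accuracy: float
    per_class: dict[str, tuple[float, float, float]]  # stage -> (PR, RC, F1) in percent
    macro_f1: float
    kappa: float


def confusion_matrix(y_true, y_pred) -> ConfusionMatrix:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be equal-length 1-D sequences")
    for name, arr in (("y_true", y_true), ("y_pred", y_pred)):
        if arr.size and (arr.min() < 0 or arr.max() >= N_STAGES):
            raise ValueError(f"{name} contains labels outside the 5-class set")
    return ConfusionMatrix(_sk_confusion(y_true, y_pred, labels=range(N_STAGES)))


def metrics_from_confusion(cm: ConfusionMatrix) -> EvalMetrics:
    """acc = trace/N; per-class PR/RC/F1; MF1 = mean F1; kappa from the matrix.

    A class with an empty row or column contributes PR = RC = F1 = 0 with a
    warning (it cannot be scored).
    """
    counts = cm.counts.astype(np.float64)
    n = counts.sum()
    if n <= 0:
        raise ValueError("empty confusion matrix")
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    tp = np.diag(counts)
    accuracy = tp.sum() / n

    per_class: dict[str, tuple[float, float, float]] = {}
    f1s = []
    for c, name in enumerate(STAGE_NAMES):
        if row[c] == 0 or col[c] == 0:
            warnings.warn(f"stage {name} has no {'true' if row[c] == 0 else 'predicted'} "
                          "examples; its PR/RC/F1 are reported as 0", RuntimeWarning,
                          stacklevel=2)
            pr = rc = f1 = 0.0
        else:
            pr = tp[c] / col[c]
            rc = tp[c] / row[c]
            f1 = 0.0 if pr + rc == 0 else 2.0 * pr * rc / (pr + rc)
        per_class[name] = (100.0 * pr, 100.0 * rc, 100.0 * f1)
        f1s.append(f1)

    p_e = float((row * col).sum()) / (n * n)
    kappa = 1.0 if p_e == 1.0 else (accuracy - p_e) / (1.0 - p_e)
    return EvalMetrics(accuracy=float(accuracy), per_class=per_class,
                       macro_f1=float(np.mean(f1s)), kappa=float(kappa))


# --------------------------------------------------------------------------
# CSV exchange format: header row of stage names, 5 rows of 5 integer counts

def read_confusion_csv(path: str | Path) -> ConfusionMatrix:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise ValueError(f"empty confusion CSV: {path}")
    header = [h.strip() for h in rows[0]]
    data_rows = rows[1:] if header[-N_STAGES:] == list(STAGE_NAMES) else rows
    counts = []
    for r in data_rows:
        cells = [c for c in r if c.strip() != ""]
        counts.append([int(c.replace(",", "")) for c in cells[-N_STAGES:]])
    return ConfusionMatrix(np.asarray(counts))


def write_confusion_csv(cm: ConfusionMatrix, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["stage", *STAGE_NAMES])
        for name, row in zip(STAGE_NAMES, cm.counts):
            writer.writerow([name, *row.tolist()])


def load_reference_confusion(dataset: str) -> ConfusionMatrix:
    """Packaged reference confusion matrices from the published PSNSleep
    evaluations: ``"sleep-edf"`` (Fpz-Cz, 100 Hz) or ``"isruc"`` (F3-A2, 200 Hz)."""
    key = dataset.lower().replace("_", "-")
    files = {"sleep-edf": "sleep_edf_confusion.csv", "isruc": "isruc_confusion.csv"}
    if key not in files:
        raise ValueError(f"unknown reference dataset {dataset!r}; expected {sorted(files)}")
    ref = resources.files("psnsleep.reference") / files[key]
    with resources.as_file(ref) as p:
        return read_confusion_csv(p)


def format_report(cm: ConfusionMatrix, metrics: EvalMetrics | None = None) -> str:
    """Human-readable report: counts plus per-class PR/RC/F1 and the summary line."""
    if metrics is None:
        metrics = metrics_from_confusion(cm)
    lines = [f"{'':>5}" + "".join(f"{s:>8}" for s in STAGE_NAMES)
             + f"{'PR':>8}{'RC':>8}{'F1':>8}"]
    for name, row in zip(STAGE_NAMES, cm.counts):
        pr, rc, f1 = metrics.per_class[name]
        lines.append(f"{name:>5}" + "".join(f"{v:>8d}" for v in row)
                     + f"{pr:>8.2f}{rc:>8.2f}{f1:>8.2f}")
    lines.append(f"accuracy {metrics.accuracy:.3f}  MF1 {metrics.macro_f1:.3f}  "
                 f"kappa {metrics.kappa:.3f}  (N = {cm.total})")
    return "\n".join(lines)
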