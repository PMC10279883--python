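"""Core containers and I/O for epoched single-channel EEG.

The unit of all processing is the 30-second sleep epoch.  A recording is a
2-D array of shape (n_epochs, epoch_samples); stage labels follow the AASM
five-class convention W, N1, N2, N3, REM with the fixed integer encoding
0-4 in that order.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, replace
from enum import IntEnum
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

#: guard substituted for a zero standard deviation during normalization
EPS_NORM = 1e-8


class StageLabel(IntEnum):
    """AASM sleep stages with the package-wide integer encoding."""

    W = 0
    N1 = 1
    N2 = 2
    N3 = 3
    REM = 4


STAGE_NAMES: tuple[str, ...] = tuple(s.name for s in StageLabel)
N_STAGES = len(StageLabel)


@dataclass(frozen=True)
class Hypnogram:
    """Per-epoch stage labels over a night."""

    stages: np.ndarray  # int array, values in 0..4

    def __post_init__(self):
        arr = np.asarray(self.stages, dtype=np.int64)
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError("hypnogram must be a non-empty 1-D label sequence")
        if arr.min() < 0 or arr.max() >= N_STAGES:
            bad = sorted(set(arr[(arr < 0) | (arr >= N_STAGES)].tolist()))
            raise ValueError(f"stage labels outside the 5-class set: {bad}")
        object.__setattr__(self, "stages", arr)

    def __len__(self) -> int:
        return int(self.stages.size)

    def names(self) -> list[str]:
        return [STAGE_NAMES[s] for s in self.stages]


@dataclass(frozen=True)
class EpochedRecording:
    """Single-channel EEG segmented into fixed-length epochs."""

    signal: np.ndarray  # (n_epochs, epoch_samples)
    sampling_rate: int
    epoch_seconds: int = 30
    channel: str = ""
    subject_id: str = ""

    def __post_init__(self):
        sig = np.asarray(self.signal, dtype=np.float64)
        if sig.ndim != 2 or sig.shape[0] < 1:
            raise ValueError(f"signal must be 2-D (epochs x samples), got shape {sig.shape}")
        if not np.isfinite(sig).all():
            raise ValueError("signal contains non-finite values")
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be positive, got {self.sampling_rate}")
        expected = self.sampling_rate * self.epoch_seconds
        if sig.shape[1] != expected:
            raise ValueError(
                f"epoch length {sig.shape[1]} != sampling_rate * epoch_seconds = {expected}")
        object.__setattr__(self, "signal", sig)

    @property
    def n_epochs(self) -> int:
        return self.signal.shape[0]

    @property
    def epoch_samples(self) -> int:
        return self.signal.shape[1]


@dataclass(frozen=True)
class NormalizationParams:
    mu: np.ndarray
    sigma: np.ndarray
    scope: str  # "per_epoch" | "per_recording"


def normalize(recording: EpochedRecording, scope: str = "per_epoch"
              ) -> tuple[EpochedRecording, NormalizationParams]:
    """Zero-mean / unit-variance standardization, (x - mu) / sigma.

    ``scope`` chooses the unit over which the statistics are computed:
    each 30-s epoch independently (default) or the whole recording.
    Population standard deviation is used, so the operation is exactly
    idempotent.  A constant unit (sigma == 0) is standardized with the
    guard ``EPS_NORM`` and a warning, yielding all zeros.
    """
    x = recording.signal
    if scope == "per_epoch":
        mu = x.mean(axis=1, keepdims=True)
        sigma = x.std(axis=1, keepdims=True)
    elif scope == "per_recording":
        mu = np.full((1, 1), x.mean())
        sigma = np.full((1, 1), x.std())
    else:
        raise ValueError(f"unknown normalization scope: {scope!r}")
    n_zero = int((sigma == 0).sum())
    if n_zero:
        warnings.warn(
            f"{n_zero} constant normalization unit(s); sigma replaced by {EPS_NORM}",
            RuntimeWarning, stacklevel=2)
        sigma = np.where(sigma == 0, EPS_NORM, sigma)
    out = replace(recording, signal=(x - mu) / sigma)
    return out, NormalizationParams(mu=mu.squeeze(), sigma=sigma.squeeze(), scope=scope)


def segment_continuous(samples: np.ndarray, sampling_rate: int, epoch_seconds: int = 30,
                       **meta) -> EpochedRecording:
    """Cut a continuous 1-D channel into fixed epochs; a trailing partial epoch is dropped."""
    samples = np.asarray(samples, dtype=np.float64).ravel()
    per_epoch = sampling_rate * epoch_seconds
    n_full, remainder = divmod(samples.size, per_epoch)
    if n_full < 1:
        raise ValueError(
            f"continuous signal of {samples.size} samples is shorter than one "
            f"{epoch_seconds}-s epoch ({per_epoch} samples)")
    if remainder:
        logger.info("dropping trailing partial epoch of %d samples", remainder)
    sig = samples[:n_full * per_epoch].reshape(n_full, per_epoch)
    return EpochedRecording(signal=sig, sampling_rate=sampling_rate,
                            epoch_seconds=epoch_seconds, **meta)


# --------------------------------------------------------------------------
# File formats: npz_bundle (lossless), csv_bundle (inspectable), edf (read only)

_FORMATS = ("npz_bundle", "csv_bundle", "edf")


def _sidecar(recording: EpochedRecording) -> dict:
    return {
        "sampling_rate": int(recording.sampling_rate),
        "epoch_seconds": int(recording.epoch_seconds),
        "channel": recording.channel,
        "subject_id": recording.subject_id,
    }


def write_recording(recording: EpochedRecording, hypnogram: Hypnogram | None,
                    path: str | Path, format: str = "npz_bundle") -> None:
    """Write a recording (and optional hypnogram) as a bundle at ``path``.

    ``path`` is the bundle stem: ``<path>.npz`` + ``<path>.json`` for the
    binary bundle, ``<path>.csv`` (+ ``<path>.labels.csv``) + ``<path>.json``
    for the CSV bundle.  EDF writing is unsupported.
    """
    if format not in ("npz_bundle", "csv_bundle"):
        raise ValueError(f"unsupported write format: {format!r}")
    if hypnogram is not None and len(hypnogram) != recording.n_epochs:
        raise ValueError(
            f"hypnogram length {len(hypnogram)} != n_epochs {recording.n_epochs}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "npz_bundle":
        arrays = {"signal": recording.signal}
        if hypnogram is not None:
            arrays["stages"] = hypnogram.stages
        np.savez(path.with_suffix(".npz"), **arrays)
    else:
        np.savetxt(path.with_suffix(".csv"), recording.signal, delimiter=",")
        if hypnogram is not None:
            np.savetxt(path.with_suffix(".labels.csv"), hypnogram.stages[:, None],
                       fmt="%d", delimiter=",")
    path.with_suffix(".json").write_text(json.dumps(_sidecar(recording), indent=2))


def read_recording(path: str | Path, format: str = "npz_bundle", channel: str | None = None
                   ) -> tuple[EpochedRecording, Hypnogram | None]:
    """Read a recording bundle; returns (recording, hypnogram-or-None).

    For ``edf`` the named ``channel`` is extracted and re-segmented into
    30-s epochs (no labels; EDF+ annotation scoring is out of scope).
    """
    if format not in _FORMATS:
        raise ValueError(f"unknown format: {format!r}; expected one of {_FORMATS}")
    path = Path(path)
    if format == "edf":
        return _read_edf(path, channel), None
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    try:
        meta = json.loads(sidecar_path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed sidecar {sidecar_path}: {exc}") from exc
    for key in ("sampling_rate", "epoch_seconds"):
        if key not in meta:
            raise ValueError(f"sidecar {sidecar_path} missing field {key!r}")
    stages = None
    if format == "npz_bundle":
        with np.load(path.with_suffix(".npz")) as npz:
            if "signal" not in npz:
                raise ValueError(f"bundle {path} missing array 'signal'")
            signal = npz["signal"]
            if "stages" in npz:
                stages = npz["stages"]
    else:
        signal = np.loadtxt(path.with_suffix(".csv"), delimiter=",", ndmin=2)
        labels_path = path.with_suffix(".labels.csv")
        if labels_path.exists():
            stages = np.loadtxt(labels_path, delimiter=",", dtype=np.int64, ndmin=1)
    recording = EpochedRecording(
        signal=signal, sampling_rate=int(meta["sampling_rate"]),
        epoch_seconds=int(meta["epoch_seconds"]),
        channel=meta.get("channel", ""), subject_id=meta.get("subject_id", ""))
    hypnogram = None
    if stages is not None:
        if len(stages) != recording.n_epochs:
            raise ValueError(
                f"stage labels ({len(stages)}) do not match epochs ({recording.n_epochs})")
        hypnogram = Hypnogram(stages=np.asarray(stages).ravel())
    return recording, hypnogram


def _read_edf(path: Path, channel: str | None) -> EpochedRecording:
    import mne  # deferred: EDF support only

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    if channel is None:
        channel = raw.ch_names[0]
    if channel not in raw.ch_names:
        raise ValueError(f"channel {channel!r} not in EDF (available: {raw.ch_names})")
    sfreq = raw.info["sfreq"]
    if abs(sfreq - round(sfreq)) > 1e-9:
        raise ValueError(f"non-integer sampling rate {sfreq} unsupported")
    samples = raw.get_data(picks=[channel])[0]
    return segment_continuous(samples, sampling_rate=int(round(sfreq)),
                              channel=channel, subject_id=path.stem)
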