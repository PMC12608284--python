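"""EEG preprocessing: channel selection, filtering, epoching, artifact
rejection and per-epoch standardization.

The pipeline order is select -> filter -> epoch -> reject -> standardize.
Filtering is zero-phase (forward-backward) windowed-sinc FIR band-pass with
an optional IIR notch; epoching uses fixed windows with fractional overlap;
artifact rejection is a peak-to-peak amplitude threshold with a pluggable
rejector seam; standardization z-scores each channel of each epoch.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .synthetic import RawRecording

logger = logging.getLogger(__name__)

__all__ = [
    "BandSpec",
    "BANDS",
    "EpochSet",
    "PipelineOrderError",
    "select_channels",
    "filter_recording",
    "epoch_recording",
    "reject_artifacts",
    "standardize",
    "concat_epochs",
]

#: Classical EEG frequency bands (Hz) plus the broadband analysis range.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 40.0),
    "broadband": (1.0, 40.0),
}

# 10-20 naming dialects: the older temporal labels and their modern synonyms.
_CHANNEL_SYNONYMS = {"T7": "T3", "T8": "T4", "P7": "T5", "P8": "T6"}


class PipelineOrderError(RuntimeError):
    """Raised when preprocessing stages are applied in an invalid order."""


@dataclass(frozen=True)
class BandSpec:
    name: str
    low: float
    high: float

    @classmethod
    def named(cls, name: str) -> "BandSpec":
        if name not in BANDS:
            raise ValueError(f"unknown band {name!r}; choose from {sorted(BANDS)}")
        return cls(name, *BANDS[name])

    def validate(self, sampling_rate: float) -> None:
        nyq = sampling_rate / 2.0
        if not (0 < self.low < self.high):
            raise ValueError(f"band {self.name}: need 0 < low < high")
        if self.high >= nyq:
            raise ValueError(
                f"band {self.name}: high edge {self.high} Hz >= Nyquist {nyq} Hz"
            )


@dataclass
class EpochSet:
    """Fixed-length epochs with aligned labels, subjects and demographics.

    ``data`` is (n_epochs, n_channels, n_samples); ``labels`` are 1 for MDD
    and 0 for HC; ``demographics`` carries one row per epoch (its subject's
    profile fields).
    """

    data: np.ndarray
    sampling_rate: float
    channel_names: tuple[str, ...]
    labels: np.ndarray
    subject_ids: np.ndarray
    demographics: pd.DataFrame
    stages: list[str] = field(default_factory=list)
    rejection_log: dict | None = None
    # window geometry (samples); lets fold construction reason about how
    # many neighbouring epochs share samples when windows overlap
    window_samples: int | None = None
    step_samples: int | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        self.subject_ids = np.asarray(self.subject_ids)
        n = self.data.shape[0]
        if self.data.ndim != 3:
            raise ValueError("epoch data must be (n_epochs, n_channels, n_samples)")
        if len(self.labels) != n or len(self.subject_ids) != n or len(self.demographics) != n:
            raise ValueError("labels/subject_ids/demographics must align with epochs")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    def subset(self, idx: np.ndarray) -> "EpochSet":
        return EpochSet(
            data=self.data[idx],
            sampling_rate=self.sampling_rate,
            channel_names=self.channel_names,
            labels=self.labels[idx],
            subject_ids=self.subject_ids[idx],
            demographics=self.demographics.iloc[np.atleast_1d(idx)].reset_index(drop=True),
            stages=list(self.stages),
            window_samples=self.window_samples,
            step_samples=self.step_samples,
        )


def _canonical(name: str) -> str:
    name = name.strip()
    return _CHANNEL_SYNONYMS.get(name, name)


def select_channels(rec: RawRecording, names: list[str]) -> RawRecording:
    """Subset and reorder channels; 10-20 synonym dialects (T3/T7 etc.) match."""
    lookup = {_canonical(n): i for i, n in enumerate(rec.channel_names)}
    rows = []
    for name in names:
        key = _canonical(name)
        if key not in lookup:
            raise KeyError(f"channel {name!r} not present in recording")
        rows.append(lookup[key])
    out = RawRecording(
        data=rec.data[rows].copy(),
        channel_names=tuple(names),
        sampling_rate=rec.sampling_rate,
        profile=rec.profile,
        history=rec.history + [f"select:{len(names)}ch"],
    )
    return out


def _fir_bandpass(band: BandSpec, sampling_rate: float) -> np.ndarray:
    # Windowed-sinc (Hamming) design; transition width tied to the low edge
    # so a 1 Hz edge at 250 Hz still has a usable roll-off (~0.1 dB ripple).
    transition = min(band.low, 2.0)
    numtaps = int(math.ceil(3.3 * sampling_rate / transition))
    numtaps |= 1  # odd length -> exactly linear phase, integer group delay
    return signal.firwin(numtaps, [band.low, band.high],
                         pass_zero=False, fs=sampling_rate)


def filter_recording(rec: RawRecording, band: BandSpec,
                     notch_hz: float | None = None) -> RawRecording:
    """Zero-phase band-pass (and optional notch) filtering.

    The FIR band-pass is applied forward-backward, so the pass band is
    amplitude-preserving with zero phase distortion; the notch is a
    forward-backward IIR notch (Q=30).
    """
    band.validate(rec.sampling_rate)
    data = rec.data
    if notch_hz is not None:
        if notch_hz >= rec.sampling_rate / 2:
            raise ValueError("notch frequency must be below Nyquist")
        b, a = signal.iirnotch(notch_hz, Q=30.0, fs=rec.sampling_rate)
        data = signal.filtfilt(b, a, data, axis=-1)
    taps = _fir_bandpass(band, rec.sampling_rate)
    padlen = min(3 * len(taps), data.shape[-1] - 1)
    data = signal.filtfilt(taps, [1.0], data, axis=-1, padlen=padlen)
    return RawRecording(
        data=data,
        channel_names=rec.channel_names,
        sampling_rate=rec.sampling_rate,
        profile=rec.profile,
        history=rec.history + [f"filter:{band.name}" + (f"+notch{notch_hz:g}" if notch_hz else "")],
    )


def epoch_recording(rec: RawRecording, window: float = 4.0,
                    overlap: float = 0.75) -> EpochSet:
    """Slice a recording into fixed windows with fractional overlap.

    The step is ``round(window_samples * (1 - overlap))`` samples; epoch
    count is ``floor((n - W) / S) + 1``.
    """
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    w = int(round(window * rec.sampling_rate))
    if w < 1 or w > rec.n_samples:
        raise ValueError(
            f"window of {w} samples invalid for recording of {rec.n_samples}"
        )
    step = max(1, int(round(w * (1.0 - overlap))))
    n_epochs = (rec.n_samples - w) // step + 1
    starts = np.arange(n_epochs) * step
    data = np.stack([rec.data[:, s: s + w] for s in starts])
    p = rec.profile
    demographics = pd.DataFrame(
        {
            "subject_id": [p.subject_id] * n_epochs,
            "label": [p.label] * n_epochs,
            "age": [p.age] * n_epochs,
            "sex": [p.sex] * n_epochs,
            "education_years": [p.education_years] * n_epochs,
        }
    )
    return EpochSet(
        data=data,
        sampling_rate=rec.sampling_rate,
        channel_names=rec.channel_names,
        labels=np.full(n_epochs, 1 if p.label == "MDD" else 0, dtype=np.int64),
        subject_ids=np.array([p.subject_id] * n_epochs),
        demographics=demographics,
        stages=rec.history + ["epoch"],
        window_samples=w,
        step_samples=step,
    )


def concat_epochs(epoch_sets: list[EpochSet]) -> EpochSet:
    """Stack per-subject epoch sets into one cohort-level set."""
    first = epoch_sets[0]
    for es in epoch_sets[1:]:
        if es.channel_names != first.channel_names:
            raise ValueError("channel layouts differ between epoch sets")
        if es.sampling_rate != first.sampling_rate:
            raise ValueError("sampling rates differ between epoch sets")
    return EpochSet(
        data=np.concatenate([es.data for es in epoch_sets]),
        sampling_rate=first.sampling_rate,
        channel_names=first.channel_names,
        labels=np.concatenate([es.labels for es in epoch_sets]),
        subject_ids=np.concatenate([es.subject_ids for es in epoch_sets]),
        demographics=pd.concat([es.demographics for es in epoch_sets],
                               ignore_index=True),
        stages=list(first.stages),
        window_samples=first.window_samples,
        step_samples=first.step_samples,
    )


def ptp_rejector(data: np.ndarray, threshold: float) -> np.ndarray:
    """Default rejector: epoch survives if every channel's peak-to-peak
    amplitude stays below ``threshold`` (µV)."""
    ptp = data.max(axis=-1) - data.min(axis=-1)
    return (ptp < threshold).all(axis=-1)


def reject_artifacts(epochs: EpochSet, ptp_threshold: float,
                     rejector=None) -> EpochSet:
    """Drop artifact epochs; by amplitude threshold unless a custom rejector
    callable (the seam for plugging in a published rejection tool) is given."""
    if "standardize" in epochs.stages:
        raise PipelineOrderError(
            "artifact rejection must run before standardization: "
            "z-scored epochs have no amplitude scale left to threshold"
        )
    if ptp_threshold <= 0:
        raise ValueError("ptp_threshold must be positive")
    keep = (rejector(epochs.data) if rejector is not None
            else ptp_rejector(epochs.data, ptp_threshold))
    keep = np.asarray(keep, dtype=bool)
    n_dropped = int((~keep).sum())
    if keep.sum() == 0:
        raise ValueError("all epochs rejected; downstream stages need at least one")
    out = epochs.subset(np.flatnonzero(keep))
    out.stages = epochs.stages + ["reject"]
    out.rejection_log = {
        "n_in": epochs.n_epochs,
        "n_rejected": n_dropped,
        "threshold_uv": ptp_threshold,
        "rejected_indices": np.flatnonzero(~keep).tolist(),
    }
    if n_dropped:
        logger.info("rejected %d/%d epochs (ptp >= %g µV)",
                    n_dropped, epochs.n_epochs, ptp_threshold)
    return out


def standardize(epochs: EpochSet, on_constant: str = "drop") -> EpochSet:
    """Z-score each channel of each epoch (mean 0, sd 1 over its samples).

    Epochs containing a constant channel (sd = 0) are dropped and logged by
    default; ``on_constant='error'`` raises instead.
    """
    if on_constant not in ("drop", "error"):
        raise ValueError("on_constant must be 'drop' or 'error'")
    sd = epochs.data.std(axis=-1, keepdims=True)
    degenerate = (sd == 0).any(axis=(1, 2))
    if degenerate.any():
        if on_constant == "error":
            raise ValueError(
                f"{int(degenerate.sum())} epoch(s) contain a constant channel"
            )
        logger.info("dropping %d epoch(s) with constant channels",
                    int(degenerate.sum()))
    keep = np.flatnonzero(~degenerate)
    if keep.size == 0:
        raise ValueError("no epochs left after dropping constant channels")
    sub = epochs.subset(keep)
    mu = sub.data.mean(axis=-1, keepdims=True)
    sd = sub.data.std(axis=-1, keepdims=True)
    sub.data = (sub.data - mu) / sd
    sub.stages = epochs.stages + ["standardize"]
    return sub
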