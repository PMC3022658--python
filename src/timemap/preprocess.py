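"""Epoch-level EEG preprocessing: artifact rejection, averaging, filtering,
re-referencing.

The pipeline turns epoched single-trial EEG into per-condition evoked
potentials (EPs):

1. amplitude-criterion epoch rejection (any sample on any channel beyond
   +-100 uV) — the automated replacement for visual inspection,
2. averaging of correct trials,
3. zero-phase 1-40 Hz band-pass (second-order Butterworth, forward-backward),
4. recalculation against the average reference.

The epoch window convention is half-open [0, 800) ms with 0-based sample
indexing, so 800 ms at 2048 Hz is exactly 1638 samples.  Every step appends
to a provenance log so an evoked's history is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
from scipy import signal

__all__ = [
    "Evoked",
    "EpochSet",
    "RejectionLog",
    "reject_epochs",
    "bandpass",
    "average_reference",
    "average_epochs",
    "downsample",
    "preprocess_epochs",
    "n_samples_for_window",
]


def n_samples_for_window(tmin_ms: float, tmax_ms: float, sfreq: float) -> int:
    """Sample count of the half-open window [tmin, tmax) ms."""
    return int(np.floor((tmax_ms - tmin_ms) * sfreq / 1000.0 + 1e-9))


@dataclass(frozen=True)
class Evoked:
    """Average-referenced (or raw) evoked potential: channels x samples, uV."""

    data: np.ndarray
    sfreq: float
    condition: str = ""
    subject: str = ""
    reference: str = "recording"
    log: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim != 2:
            raise ValueError("Evoked data must be channels x samples")
        if self.sfreq <= 0:
            raise ValueError("sampling rate must be positive")
        object.__setattr__(self, "data", arr)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) * 1000.0 / self.sfreq


@dataclass(frozen=True)
class EpochSet:
    """Single-trial epochs: epochs x channels x samples, uV."""

    data: np.ndarray
    sfreq: float
    condition: str = ""
    subject: str = ""
    correct: np.ndarray | None = None
    log: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim != 3:
            raise ValueError("EpochSet data must be epochs x channels x samples")
        if self.sfreq <= 0:
            raise ValueError("sampling rate must be positive")
        object.__setattr__(self, "data", arr)
        if self.correct is not None:
            corr = np.asarray(self.correct, dtype=bool)
            if corr.shape != (arr.shape[0],):
                raise ValueError("correct flags must match epoch count")
            object.__setattr__(self, "correct", corr)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]


class RejectionLog(NamedTuple):
    rejected: tuple[int, ...]  # epoch indices
    channels: dict[int, tuple[int, ...]]  # epoch -> offending channel indices
    threshold_uv: float


def reject_epochs(
    epochs: EpochSet, threshold_uv: float = 100.0
) -> tuple[EpochSet, RejectionLog]:
    """Drop epochs where any channel exceeds +-threshold at any sample."""
    if threshold_uv <= 0:
        raise ValueError("rejection threshold must be positive")
    over = np.abs(epochs.data) > threshold_uv
    bad_epochs = np.where(over.any(axis=(1, 2)))[0]
    if len(bad_epochs) == epochs.n_epochs:
        raise ValueError("all epochs exceed the rejection threshold")
    channels = {
        int(e): tuple(int(c) for c in np.where(over[e].any(axis=1))[0])
        for e in bad_epochs
    }
    keep = np.setdiff1d(np.arange(epochs.n_epochs), bad_epochs)
    kept = replace(
        epochs,
        data=epochs.data[keep],
        correct=None if epochs.correct is None else epochs.correct[keep],
        log=epochs.log
        + (f"reject_epochs(threshold={threshold_uv}uV): dropped {len(bad_epochs)}",),
    )
    return kept, RejectionLog(tuple(int(e) for e in bad_epochs), channels, threshold_uv)


def bandpass(x, low: float = 1.0, high: float = 40.0, order: int = 2):
    """Zero-phase Butterworth band-pass along the time axis.

    Applied forward-backward (sosfiltfilt), so the effective attenuation is
    the squared magnitude response of the ``order``-order design.  Accepts
    Evoked or EpochSet and returns the same type.
    """
    nyq = x.sfreq / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(
            f"band ({low}, {high}) Hz invalid for Nyquist {nyq} Hz"
        )
    sos = signal.butter(order, [low, high], btype="bandpass", fs=x.sfreq, output="sos")
    filtered = signal.sosfiltfilt(sos, x.data, axis=-1)
    return replace(
        x, data=filtered, log=x.log + (f"bandpass({low}-{high}Hz, order={order})",)
    )


def average_reference(x):
    """Subtract the instantaneous mean across channels at every sample."""
    if x.data.shape[-2] < 2:
        raise ValueError("average reference requires >= 2 channels")
    data = x.data - x.data.mean(axis=-2, keepdims=True)
    kwargs = {"reference": "average"} if isinstance(x, Evoked) else {}
    return replace(x, data=data, log=x.log + ("average_reference",), **kwargs)


def average_epochs(epochs: EpochSet, correct_only: bool = True) -> Evoked:
    """Sample-wise mean over (correct) epochs -> Evoked."""
    if correct_only and epochs.correct is not None:
        mask = epochs.correct
    else:
        mask = np.ones(epochs.n_epochs, dtype=bool)
    if not mask.any():
        raise ValueError("no qualifying epochs to average")
    return Evoked(
        data=epochs.data[mask].mean(axis=0),
        sfreq=epochs.sfreq,
        condition=epochs.condition,
        subject=epochs.subject,
        reference="recording",
        log=epochs.log + (f"average_epochs(n={int(mask.sum())}, correct_only={correct_only})",),
    )


def downsample(x, factor: int):
    """Integer-factor, anti-aliased (zero-phase IIR) downsampling along time.

    Off by default in the pipeline; useful to trade temporal resolution for
    speed.  Accepts Evoked or EpochSet and returns the same type with
    ``sfreq`` divided by ``factor``.
    """
    factor = int(factor)
    if factor < 1:
        raise ValueError("downsampling factor must be >= 1")
    if factor == 1:
        return x
    data = signal.decimate(x.data, factor, axis=-1, zero_phase=True)
    return replace(
        x, data=data, sfreq=x.sfreq / factor, log=x.log + (f"downsample(x{factor})",)
    )


def preprocess_epochs(
    epochs: EpochSet,
    threshold_uv: float = 100.0,
    low: float = 1.0,
    high: float = 40.0,
    correct_only: bool = True,
) -> tuple[Evoked, RejectionLog]:
    """Full chain: reject -> average (correct trials) -> band-pass -> average
    reference.  Rejection runs on the unfiltered epochs because the amplitude
    criterion is defined on recorded voltages."""
    kept, log = reject_epochs(epochs, threshold_uv)
    evoked = average_epochs(kept, correct_only=correct_only)
    evoked = bandpass(evoked, low, high)
    evoked = average_reference(evoked)
    return evoked, log
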