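"""Raw-EEG conditioning: bandpass filtering and artifact-free segment selection.

The analysis pipeline works on a fixed-length artifact-free segment (default
120 s) assembled from consecutive non-overlapping 10 s epochs.  An epoch is
rejected if any channel exceeds an amplitude threshold or if any channel is
flat (near-zero standard deviation).  Rejected epochs may be skipped: the
selected segment need not be contiguous in original recording time, because
each 10 s tract is windowed independently by the spectral stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime

import numpy as np
from scipy import signal

#: 10-20 montage used throughout: the 19-electrode clinical set.
MONTAGE_10_20 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "T3", "C3", "Cz",
    "C4", "T4", "T5", "P3", "Pz", "P4", "T6", "O1", "O2",
)

#: Epoch length (s) used both for artifact rejection and for Welch tracts.
EPOCH_SECONDS = 10.0

#: Default rejection thresholds (µV); overridable everywhere they are used.
DEFAULT_AMP_THRESH_UV = 100.0
DEFAULT_FLAT_SD_THRESH_UV = 0.1

#: Default bandpass design: 0.5–40 Hz, 2nd-order Butterworth, zero-phase.
DEFAULT_BANDPASS = (0.5, 40.0)
DEFAULT_FILTER_ORDER = 2


class InsufficientCleanDataError(RuntimeError):
    """Raised when a recording does not contain enough clean epochs."""


@dataclass(frozen=True)
class EEGRecording:
    """Multichannel scalp EEG in microvolts.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Per-channel time series in µV.
    fs : float
        Sampling rate in Hz.
    channel_labels : tuple of str
        Ordered 10-20 electrode names, one per row of ``samples``.
    start_time : datetime, optional
        Recording start, if known.
    onset_to_eeg_min : float, optional
        Minutes from symptom onset to EEG acquisition (provenance metadata).
    """

    samples: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]
    start_time: datetime | None = None
    onset_to_eeg_min: float | None = None

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 2:
            raise ValueError("samples must be a 2-D (n_channels, n_samples) array")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "channel_labels", tuple(self.channel_labels))
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if len(self.channel_labels) != samples.shape[0]:
            raise ValueError(
                f"{samples.shape[0]} channels but "
                f"{len(self.channel_labels)} labels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class EpochVerdict:
    """Outcome of the artifact test for one 10 s epoch."""

    index: int
    passed: bool
    reason: str  # "" when passed


@dataclass(frozen=True)
class CleanSegment:
    """Concatenation of the clean 10 s epochs selected for analysis."""

    samples: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]
    epoch_indices: tuple[int, ...]
    rejection_log: tuple[EpochVerdict, ...] = field(default=())

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        object.__setattr__(self, "channel_labels", tuple(self.channel_labels))
        object.__setattr__(self, "epoch_indices", tuple(self.epoch_indices))
        object.__setattr__(self, "rejection_log", tuple(self.rejection_log))

    @property
    def duration_s(self) -> float:
        return self.samples.shape[1] / self.fs

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]


def bandpass_filter(
    rec: EEGRecording,
    low: float = DEFAULT_BANDPASS[0],
    high: float = DEFAULT_BANDPASS[1],
    order: int = DEFAULT_FILTER_ORDER,
) -> EEGRecording:
    """Zero-phase Butterworth bandpass of every channel.

    The filter is designed at the stated ``order`` and applied forward and
    backward (``filtfilt``), so the effective magnitude response is squared.
    Defaults follow standard clinical QEEG practice: 0.5–40 Hz, 2nd order.
    """
    nyquist = rec.fs / 2.0
    if not 0 < low < high:
        raise ValueError(f"need 0 < low < high, got low={low}, high={high}")
    if high >= nyquist:
        raise ValueError(
            f"upper edge {high} Hz must be below the Nyquist frequency "
            f"{nyquist} Hz"
        )
    sos = signal.butter(order, (low, high), btype="bandpass", fs=rec.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.samples, axis=1)
    return EEGRecording(
        samples=filtered,
        fs=rec.fs,
        channel_labels=rec.channel_labels,
        start_time=rec.start_time,
        onset_to_eeg_min=rec.onset_to_eeg_min,
    )


def epoch_is_clean(
    epoch: np.ndarray,
    fs: float,
    amp_thresh: float = DEFAULT_AMP_THRESH_UV,
    flat_sd_thresh: float = DEFAULT_FLAT_SD_THRESH_UV,
) -> tuple[bool, str]:
    """Artifact test for a single (n_channels, 10 s × fs) epoch.

    Fails when any channel exceeds ``±amp_thresh`` µV (transient / movement
    artifact) or when any channel's standard deviation falls below
    ``flat_sd_thresh`` µV (flatline / detached electrode).

    Returns
    -------
    (passed, reason)
        ``reason`` is ``""`` when the epoch passes, otherwise names the
        failing test and channel index.
    """
    epoch = np.asarray(epoch, dtype=float)
    expected = int(round(EPOCH_SECONDS * fs))
    if epoch.ndim != 2 or epoch.shape[1] != expected:
        raise ValueError(
            f"epoch must have {expected} samples per channel "
            f"({EPOCH_SECONDS:g} s at {fs:g} Hz), got shape {epoch.shape}"
        )
    amps = np.max(np.abs(epoch), axis=1)
    over = np.nonzero(amps > amp_thresh)[0]
    if over.size:
        ch = int(over[0])
        return False, f"amplitude: channel {ch} reached {amps[ch]:.1f} µV"
    sds = np.std(epoch, axis=1)
    flat = np.nonzero(sds < flat_sd_thresh)[0]
    if flat.size:
        ch = int(flat[0])
        return False, f"flatline: channel {ch} SD {sds[ch]:.4f} µV"
    return True, ""


def select_clean_segment(
    rec: EEGRecording,
    target_s: float = 120.0,
    amp_thresh: float = DEFAULT_AMP_THRESH_UV,
    flat_sd_thresh: float = DEFAULT_FLAT_SD_THRESH_UV,
) -> CleanSegment:
    """First-fit selection of ``target_s`` seconds of artifact-free EEG.

    The recording is partitioned into consecutive non-overlapping 10 s
    epochs; each is tested with :func:`epoch_is_clean`; the first
    ``target_s / 10`` passing epochs are concatenated in temporal order.
    The verdict for every scanned epoch is kept in ``rejection_log``.

    Raises
    ------
    InsufficientCleanDataError
        If fewer clean epochs exist than required, naming the shortfall.
    """
    if target_s <= 0 or target_s % EPOCH_SECONDS:
        raise ValueError(f"target_s must be a positive multiple of {EPOCH_SECONDS:g} s")
    if rec.duration_s < target_s:
        raise InsufficientCleanDataError(
            f"recording lasts {rec.duration_s:.1f} s, shorter than the "
            f"requested {target_s:g} s segment"
        )
    samples_per_epoch = int(round(EPOCH_SECONDS * rec.fs))
    n_epochs = rec.n_samples // samples_per_epoch
    needed = int(round(target_s / EPOCH_SECONDS))

    log: list[EpochVerdict] = []
    kept: list[int] = []
    for i in range(n_epochs):
        sl = rec.samples[:, i * samples_per_epoch : (i + 1) * samples_per_epoch]
        passed, reason = epoch_is_clean(sl, rec.fs, amp_thresh, flat_sd_thresh)
        log.append(EpochVerdict(index=i, passed=passed, reason=reason))
        if passed:
            kept.append(i)
            if len(kept) == needed:
                break
    if len(kept) < needed:
        raise InsufficientCleanDataError(
            f"insufficient clean data: needed {needed} clean 10 s epochs, "
            f"found {len(kept)} in {n_epochs} available"
        )
    chunks = [
        rec.samples[:, i * samples_per_epoch : (i + 1) * samples_per_epoch]
        for i in kept
    ]
    return CleanSegment(
        samples=np.concatenate(chunks, axis=1),
        fs=rec.fs,
        channel_labels=rec.channel_labels,
        epoch_indices=tuple(kept),
        rejection_log=tuple(log),
    )
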