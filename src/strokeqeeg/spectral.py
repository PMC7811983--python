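"""Spectral QEEG biomarkers: relative band powers, DAR, and DTABR.

Pipeline: Welch PSD on non-overlapping Hann-tapered 10 s tracts → absolute
band powers (rectangular integration over bins whose centre falls in the
band) → normalisation by total 1–30 Hz power → delta/alpha ratio (DAR) and
(delta+theta)/(alpha+beta) ratio (DTABR) → arithmetic mean over electrodes.

Band-edge convention: the canonical bands delta [1,4), theta [4,8),
alpha [8,13), beta [13,30) share endpoints, so bins are assigned half-open
on their centre frequency.  This makes the four bands tile the 1–30 Hz
normalisation range with no gap or double counting, and the four relative
powers sum to exactly one on every channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .preprocess import CleanSegment


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band ``[f_low, f_high)`` (optionally closed above)."""

    name: str
    f_low: float
    f_high: float
    include_upper: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.f_low < self.f_high:
            raise ValueError(f"invalid band edges [{self.f_low}, {self.f_high})")

    def bin_mask(self, freqs: np.ndarray) -> np.ndarray:
        mask = (freqs >= self.f_low) & (freqs < self.f_high)
        if self.include_upper:
            mask |= np.isclose(freqs, self.f_high)
        return mask


DELTA = BandDefinition("delta", 1.0, 4.0)
THETA = BandDefinition("theta", 4.0, 8.0)
ALPHA = BandDefinition("alpha", 8.0, 13.0)
BETA = BandDefinition("beta", 13.0, 30.0)
DEFAULT_BANDS: tuple[BandDefinition, ...] = (DELTA, THETA, ALPHA, BETA)
BAND_NAMES = tuple(b.name for b in DEFAULT_BANDS)

#: Default Welch tract length in seconds (0.1 Hz resolution).
DEFAULT_TRACT_S = 10.0


class DegenerateChannelError(ValueError):
    """A channel with no spectral power where positive power is required."""


@dataclass(frozen=True)
class SpectrumEstimate:
    """Welch PSD per channel, density-scaled (µV²/Hz)."""

    freqs: np.ndarray
    psd: np.ndarray  # (n_channels, n_freqs)
    resolution: float
    n_tracts: int
    channel_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "freqs", np.asarray(self.freqs, dtype=float))
        psd = np.atleast_2d(np.asarray(self.psd, dtype=float))
        object.__setattr__(self, "psd", psd)
        object.__setattr__(self, "channel_labels", tuple(self.channel_labels))
        if np.any(psd < 0):
            raise ValueError("PSD must be non-negative")
        if psd.shape != (len(self.channel_labels), self.freqs.size):
            raise ValueError("psd shape inconsistent with labels/freqs")


@dataclass(frozen=True)
class QEEGFeatures:
    """Per-channel QEEG biomarkers (fractions are relative to 1–30 Hz power)."""

    channel_labels: tuple[str, ...]
    rel_delta: np.ndarray
    rel_theta: np.ndarray
    rel_alpha: np.ndarray
    rel_beta: np.ndarray
    dar: np.ndarray
    dtabr: np.ndarray
    #: absolute µV² band powers, retained for audit: {band: (n_channels,)}
    abs_power: dict[str, np.ndarray]

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)


@dataclass(frozen=True)
class ScalpFeatures:
    """The six scalp-averaged biomarkers (arithmetic mean over electrodes)."""

    rel_delta: float
    rel_theta: float
    rel_alpha: float
    rel_beta: float
    dar: float
    dtabr: float

    def as_dict(self) -> dict[str, float]:
        return {
            "rel_delta": self.rel_delta,
            "rel_theta": self.rel_theta,
            "rel_alpha": self.rel_alpha,
            "rel_beta": self.rel_beta,
            "dar": self.dar,
            "dtabr": self.dtabr,
        }


def welch_psd(
    seg: CleanSegment,
    tract_s: float = DEFAULT_TRACT_S,
    window: str = "hann",
) -> SpectrumEstimate:
    """Welch periodogram: mean of tapered modified periodograms over
    non-overlapping ``tract_s`` tracts, density scaling.

    With the density convention the integral of the PSD over frequency
    approximates the signal variance (Parseval), which the tests assert.
    """
    nperseg = int(round(tract_s * seg.fs))
    n = seg.samples.shape[1]
    if n < nperseg:
        raise ValueError(
            f"segment of {n / seg.fs:.1f} s is shorter than one "
            f"{tract_s:g} s tract"
        )
    if n % nperseg:
        raise ValueError(
            f"segment duration {n / seg.fs:.1f} s is not a multiple of the "
            f"tract length {tract_s:g} s"
        )
    freqs, psd = signal.welch(
        seg.samples,
        fs=seg.fs,
        window=window,
        nperseg=nperseg,
        noverlap=0,
        detrend="constant",
        scaling="density",
        axis=1,
    )
    return SpectrumEstimate(
        freqs=freqs,
        psd=psd,
        resolution=seg.fs / nperseg,
        n_tracts=n // nperseg,
        channel_labels=seg.channel_labels,
    )


def band_power(spec: SpectrumEstimate, band: BandDefinition) -> np.ndarray:
    """Absolute power (µV²) per channel: rectangular sum of PSD × bin width
    over the bins whose centre lies in the band."""
    f_max = spec.freqs[-1]
    if band.f_low > f_max or band.f_high > f_max + spec.resolution / 2:
        raise ValueError(
            f"band {band.name} [{band.f_low}, {band.f_high}) exceeds the "
            f"spectral range 0–{f_max:g} Hz"
        )
    mask = band.bin_mask(spec.freqs)
    return spec.psd[:, mask].sum(axis=1) * spec.resolution


def relative_powers(
    spec: SpectrumEstimate,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
) -> dict[str, np.ndarray]:
    """Band powers normalised by each channel's total power over the bands'
    union (the 1–30 Hz range for the default bands)."""
    absolute = {b.name: band_power(spec, b) for b in bands}
    total = np.sum(list(absolute.values()), axis=0)
    bad = np.nonzero(total <= 0)[0]
    if bad.size:
        labels = [spec.channel_labels[i] for i in bad]
        raise DegenerateChannelError(
            f"zero total band power on channel(s) {labels}; relative powers "
            "undefined"
        )
    return {name: p / total for name, p in absolute.items()}


def band_ratios(
    delta: np.ndarray | float,
    theta: np.ndarray | float,
    alpha: np.ndarray | float,
    beta: np.ndarray | float,
) -> tuple[np.ndarray, np.ndarray]:
    """DAR = delta/alpha and DTABR = (delta+theta)/(alpha+beta).

    Accepts absolute or relative powers: the 1–30 Hz normalisation cancels
    in both ratios, so the result is identical either way.
    """
    delta, theta = np.asarray(delta, float), np.asarray(theta, float)
    alpha, beta = np.asarray(alpha, float), np.asarray(beta, float)
    if np.any(alpha <= 0):
        ch = int(np.atleast_1d(alpha <= 0).nonzero()[0][0])
        raise ZeroDivisionError(f"zero alpha power on channel index {ch}: DAR undefined")
    ab = alpha + beta
    if np.any(ab <= 0):
        ch = int(np.atleast_1d(ab <= 0).nonzero()[0][0])
        raise ZeroDivisionError(
            f"zero alpha+beta power on channel index {ch}: DTABR undefined"
        )
    return delta / alpha, (delta + theta) / ab


def compute_ratios(powers: dict[str, np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """DAR and DTABR per channel from a {band: power} mapping (absolute or
    relative powers — the ratios are invariant to the normalisation)."""
    return band_ratios(
        powers["delta"], powers["theta"], powers["alpha"], powers["beta"]
    )


def extract_features(
    seg: CleanSegment,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    tract_s: float = DEFAULT_TRACT_S,
    window: str = "hann",
) -> QEEGFeatures:
    """Full per-channel biomarker extraction from a clean segment."""
    spec = welch_psd(seg, tract_s=tract_s, window=window)
    absolute = {b.name: band_power(spec, b) for b in bands}
    rel = relative_powers(spec, bands)
    dar, dtabr = compute_ratios(rel)
    return QEEGFeatures(
        channel_labels=seg.channel_labels,
        rel_delta=rel["delta"],
        rel_theta=rel["theta"],
        rel_alpha=rel["alpha"],
        rel_beta=rel["beta"],
        dar=dar,
        dtabr=dtabr,
        abs_power=absolute,
    )


def scalp_average(
    features: QEEGFeatures, method: str = "mean_of_ratios"
) -> ScalpFeatures:
    """Average the six biomarkers over all electrodes.

    ``method="mean_of_ratios"`` (default): every parameter, DAR and DTABR
    included, is the arithmetic mean of its per-channel values — the averaged
    DAR is the mean of per-channel ratios, not the ratio of mean powers.
    ``method="ratio_of_means"`` recomputes the ratios from the channel-mean
    relative powers instead; kept for comparison with that alternative
    reading.
    """
    if features.n_channels < 1:
        raise ValueError("no channels to average")
    means = {
        name: float(np.mean(getattr(features, name)))
        for name in ("rel_delta", "rel_theta", "rel_alpha", "rel_beta")
    }
    if method == "mean_of_ratios":
        dar = float(np.mean(features.dar))
        dtabr = float(np.mean(features.dtabr))
    elif method == "ratio_of_means":
        dar_a, dtabr_a = band_ratios(
            means["rel_delta"], means["rel_theta"],
            means["rel_alpha"], means["rel_beta"],
        )
        dar, dtabr = float(dar_a), float(dtabr_a)
    else:
        raise ValueError(f"unknown averaging method {method!r}")
    return ScalpFeatures(dar=dar, dtabr=dtabr, **means)
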