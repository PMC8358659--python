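"""Per-channel EEG feature extraction: PSD, DE, FD and MAV.

Each extractor maps one multichannel epoch to 10 values per channel:

* **PSD** — periodogram band power in the five canonical EEG bands
  (delta 1-4, theta 4-8, alpha 8-13, beta 13-30, gamma 30-45 Hz) on each
  of two equal half-windows (5 bands x 2 segments = 10).
* **DE** — differential entropy ``1/2 ln(2*pi*e*sigma^2)`` of the
  band-filtered signal under a Gaussian assumption, same band x segment
  layout as PSD.
* **FD** — Higuchi fractal dimension on each of 10 equal temporal
  sub-windows; values live in [1, 2] up to estimation noise.
* **MAV** — mean absolute value on each of 10 equal temporal sub-windows.

Band filtering for DE is a zero-phase Butterworth band-pass (order-2
sections run forward and backward, i.e. effective 4th order). Periodograms
are mean-removed and Hann-windowed to limit leakage.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import signal

from .domain import LabeledDomain
from .errors import ConfigError, DegenerateInputError, InputError

__all__ = [
    "DEFAULT_BANDS",
    "Epoch",
    "FeatureConfig",
    "extract_mav",
    "extract_psd",
    "extract_de",
    "extract_fd",
    "featurize_domain",
    "gaussian_differential_entropy",
    "higuchi_fd",
]

#: Canonical EEG bands (Hz): delta, theta, alpha, beta, gamma.
DEFAULT_BANDS: Tuple[Tuple[float, float], ...] = (
    (1.0, 4.0),
    (4.0, 8.0),
    (8.0, 13.0),
    (13.0, 30.0),
    (30.0, 45.0),
)

FEATURE_TYPES = ("psd", "de", "fd", "mav")


@dataclass
class Epoch:
    """One windowed multichannel recording.

    ``signal`` is ``channels x timepoints`` (microvolts), all finite;
    ``label`` is an optional integer class.
    """

    signal: np.ndarray
    sampling_rate: float
    label: Optional[int] = None

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        if not np.all(np.isfinite(self.signal)):
            raise InputError("epoch signal contains non-finite values")
        if self.sampling_rate <= 0:
            raise InputError(f"sampling_rate must be positive, got {self.sampling_rate}")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_times(self) -> int:
        return self.signal.shape[1]


@dataclass(frozen=True)
class FeatureConfig:
    """Configuration of one feature extractor.

    Parameters
    ----------
    feature_type
        One of ``"psd"``, ``"de"``, ``"fd"``, ``"mav"``.
    bands
        Non-overlapping ascending (low, high) Hz intervals; used by PSD
        and DE. The default five bands with ``n_segments=2`` give the
        standard 10 values per channel.
    n_segments
        Temporal segments for PSD/DE (default 2 half-windows).
    n_subwindows
        Temporal sub-windows for MAV/FD (default 10).
    fd_kmax
        Maximum delay of the Higuchi estimator.
    de_floor
        Replacement value for the differential entropy of a zero-variance
        segment (which is -inf); a warning is emitted when used.
    """

    feature_type: str
    bands: Tuple[Tuple[float, float], ...] = DEFAULT_BANDS
    n_segments: int = 2
    n_subwindows: int = 10
    fd_kmax: int = 8
    de_floor: float = -20.0

    def __post_init__(self) -> None:
        if self.feature_type not in FEATURE_TYPES:
            raise ConfigError(
                f"feature_type must be one of {FEATURE_TYPES}, got {self.feature_type!r}"
            )
        if self.n_segments < 1:
            raise ConfigError("n_segments must be >= 1")
        if self.n_subwindows < 1:
            raise ConfigError("n_subwindows must be >= 1")
        if self.fd_kmax < 2:
            raise ConfigError("fd_kmax must be >= 2")
        prev_high = -np.inf
        for low, high in self.bands:
            if not (0 <= low < high):
                raise ConfigError(f"invalid band ({low}, {high})")
            if low < prev_high:
                raise ConfigError("bands must be non-overlapping and ascending")
            prev_high = high

    @property
    def dim_per_channel(self) -> int:
        if self.feature_type in ("psd", "de"):
            return len(self.bands) * self.n_segments
        return self.n_subwindows


def _check_bands_vs_nyquist(cfg: FeatureConfig, fs: float) -> None:
    nyq = fs / 2.0
    for low, high in cfg.bands:
        if high >= nyq:
            raise ConfigError(
                f"band edge {high} Hz >= Nyquist frequency {nyq} Hz "
                f"(sampling rate {fs} Hz)"
            )


def _split(x: np.ndarray, parts: int) -> list[np.ndarray]:
    # as-equal-as-possible contiguous split (first windows one sample
    # longer when the length is not divisible)
    return np.array_split(x, parts)


def gaussian_differential_entropy(variance: float) -> float:
    """Closed-form differential entropy ``1/2 ln(2*pi*e*sigma^2)`` of a
    Gaussian with the given variance."""
    if variance <= 0:
        return -math.inf
    return 0.5 * math.log(2.0 * math.pi * math.e * variance)


def higuchi_fd(x: np.ndarray, kmax: int) -> float:
    """Higuchi fractal dimension of a 1-D series.

    Builds ``k``-decimated curve lengths ``L(k)`` for ``k = 1..kmax`` and
    returns the slope of ``ln L(k)`` against ``ln(1/k)`` (so a smooth
    curve gives ~1 and white noise ~2). A constant series has zero
    curve length at every scale; the dimension of a point is returned
    (1.0) with a warning.
    """
    x = np.asarray(x, dtype=float).ravel()
    N = x.size
    if N < kmax + 1:
        raise DegenerateInputError(
            f"series of length {N} too short for Higuchi kmax={kmax}"
        )
    ks = np.arange(1, kmax + 1)
    L = np.empty(kmax)
    for idx, k in enumerate(ks):
        Lm = []
        for m in range(k):
            n_i = (N - 1 - m) // k
            if n_i < 1:
                continue
            diffs = np.abs(np.diff(x[m::k]))[:n_i]
            # normalization maps the decimated length back to the full
            # sampling interval
            Lm.append(diffs.sum() * (N - 1) / (n_i * k) / k)
        L[idx] = np.mean(Lm)
    if np.all(L == 0):
        warnings.warn(
            "constant signal: all Higuchi curve lengths are zero; returning 1.0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 1.0
    # zero lengths at individual scales would break the log fit
    valid = L > 0
    slope = np.polyfit(np.log(1.0 / ks[valid]), np.log(L[valid]), 1)[0]
    return float(slope)


def extract_mav(epoch: Epoch, cfg: FeatureConfig) -> np.ndarray:
    """Mean absolute value over ``n_subwindows`` contiguous sub-windows.

    Returns ``channels x n_subwindows`` (10 per channel by default).
    """
    if cfg.feature_type != "mav":
        raise ConfigError(f"expected feature_type 'mav', got {cfg.feature_type!r}")
    if epoch.n_times < cfg.n_subwindows:
        raise DegenerateInputError(
            f"{epoch.n_times} timepoints cannot be split into "
            f"{cfg.n_subwindows} sub-windows"
        )
    out = np.empty((epoch.n_channels, cfg.n_subwindows))
    for ch in range(epoch.n_channels):
        for w, seg in enumerate(_split(epoch.signal[ch], cfg.n_subwindows)):
            out[ch, w] = np.mean(np.abs(seg))
    return out


def extract_psd(epoch: Epoch, cfg: FeatureConfig) -> np.ndarray:
    """Band power per (segment, band) from a Hann-windowed periodogram.

    Each channel is split into ``n_segments`` equal windows; on each, a
    mean-removed periodogram is integrated over every configured band.
    Output is ``channels x (bands * segments)``, segment-major (all bands
    of segment 0, then all bands of segment 1, ...). Values are
    nonnegative.
    """
    if cfg.feature_type != "psd":
        raise ConfigError(f"expected feature_type 'psd', got {cfg.feature_type!r}")
    _check_bands_vs_nyquist(cfg, epoch.sampling_rate)
    out = np.empty((epoch.n_channels, cfg.dim_per_channel))
    for ch in range(epoch.n_channels):
        col = 0
        for seg in _split(epoch.signal[ch], cfg.n_segments):
            if seg.size < 8:
                raise DegenerateInputError("PSD segment shorter than 8 samples")
            freqs, pxx = signal.periodogram(
                seg, fs=epoch.sampling_rate, window="hann", detrend="constant"
            )
            df = freqs[1] - freqs[0]
            for low, high in cfg.bands:
                sel = (freqs >= low) & (freqs < high)
                out[ch, col] = pxx[sel].sum() * df
                col += 1
    return out


def extract_de(epoch: Epoch, cfg: FeatureConfig) -> np.ndarray:
    """Differential entropy per (segment, band) under a Gaussian model.

    Each segment is band-pass filtered (zero-phase Butterworth) and the
    filtered variance ``sigma^2`` plugged into ``1/2 ln(2*pi*e*sigma^2)``.
    Zero-variance segments are floored at ``cfg.de_floor`` with a warning.
    Layout matches :func:`extract_psd`.
    """
    if cfg.feature_type != "de":
        raise ConfigError(f"expected feature_type 'de', got {cfg.feature_type!r}")
    _check_bands_vs_nyquist(cfg, epoch.sampling_rate)
    sos = {
        band: signal.butter(
            2, band, btype="bandpass", fs=epoch.sampling_rate, output="sos"
        )
        for band in cfg.bands
    }
    out = np.empty((epoch.n_channels, cfg.dim_per_channel))
    for ch in range(epoch.n_channels):
        col = 0
        for seg in _split(epoch.signal[ch], cfg.n_segments):
            for band in cfg.bands:
                padlen = 3 * (2 * 2 + 1)  # sosfiltfilt default for 2 sections
                if seg.size <= padlen:
                    raise DegenerateInputError(
                        f"DE segment of {seg.size} samples too short for "
                        f"zero-phase filtering (needs > {padlen})"
                    )
                filtered = signal.sosfiltfilt(sos[band], seg)
                var = float(np.var(filtered))
                de = gaussian_differential_entropy(var)
                if not np.isfinite(de):
                    warnings.warn(
                        f"zero-variance segment in band {band}; flooring DE at "
                        f"{cfg.de_floor}",
                        RuntimeWarning,
                        stacklevel=2,
                    )
                    de = cfg.de_floor
                out[ch, col] = de
                col += 1
    return out


def extract_fd(epoch: Epoch, cfg: FeatureConfig) -> np.ndarray:
    """Higuchi fractal dimension over ``n_subwindows`` sub-windows."""
    if cfg.feature_type != "fd":
        raise ConfigError(f"expected feature_type 'fd', got {cfg.feature_type!r}")
    if epoch.n_times // cfg.n_subwindows < cfg.fd_kmax + 1:
        raise DegenerateInputError(
            f"sub-windows of ~{epoch.n_times // cfg.n_subwindows} samples are "
            f"shorter than fd_kmax+1 = {cfg.fd_kmax + 1}"
        )
    out = np.empty((epoch.n_channels, cfg.n_subwindows))
    for ch in range(epoch.n_channels):
        for w, seg in enumerate(_split(epoch.signal[ch], cfg.n_subwindows)):
            out[ch, w] = higuchi_fd(seg, cfg.fd_kmax)
    return out


_EXTRACTORS = {
    "mav": extract_mav,
    "psd": extract_psd,
    "de": extract_de,
    "fd": extract_fd,
}


def extract(epoch: Epoch, cfg: FeatureConfig) -> np.ndarray:
    """Dispatch to the extractor named by ``cfg.feature_type``."""
    return _EXTRACTORS[cfg.feature_type](epoch, cfg)


def featurize_domain(epochs: Sequence[Epoch], cfg: FeatureConfig) -> LabeledDomain:
    """Extract features from every epoch into one labeled feature matrix.

    The matrix has ``d = dim_per_channel * channels`` rows (channel-major:
    channel 0's values first) and one column per epoch. All epochs must
    share channel count and sampling rate and carry labels.
    """
    if len(epochs) == 0:
        raise InputError("no epochs given")
    ref = epochs[0]
    cols, labels = [], []
    for i, ep in enumerate(epochs):
        if ep.n_channels != ref.n_channels or ep.sampling_rate != ref.sampling_rate:
            raise InputError(
                f"epoch {i} has {ep.n_channels} channels @ {ep.sampling_rate} Hz, "
                f"expected {ref.n_channels} @ {ref.sampling_rate} Hz"
            )
        if ep.label is None:
            raise InputError(f"epoch {i} has no label")
        cols.append(extract(ep, cfg).ravel())  # channel-major
        labels.append(ep.label)
    return LabeledDomain(np.column_stack(cols), np.asarray(labels))
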