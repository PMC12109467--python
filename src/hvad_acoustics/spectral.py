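"""Spectral feature extraction for rotary-pump acoustic signatures.

A centrifugal pump rotating at *r* rpm produces an acoustic fundamental at
FF = r/60 Hz with harmonics at integer multiples; the 4-bladed HVAD
impeller additionally accents multiples of 4·FF. This module turns a raw
acceleration time series into the normalized harmonic-power signature used
for classification: estimate the one-sided PSD, integrate it over a 1 Hz
window centered on each of the first 12 harmonics, convert to dB and shift
so the 12 powers sum to 0 dB (unit total on the linear scale). The 0 dB
normalization removes the unknown amplitude calibration of the sensor
chain, so signatures from different recordings are directly comparable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .cohort import HARMONIC_COLUMNS, HarmonicProfile, Recording

__all__ = [
    "SpectralEstimate",
    "HarmonicSet",
    "DB_FLOOR_LINEAR",
    "compute_periodogram",
    "compute_welch",
    "fundamental_from_rpm",
    "detect_fundamental",
    "harmonic_power",
    "extract_profile",
    "normalize_profile",
]

log = logging.getLogger(__name__)

#: Linear powers are clipped here before dB conversion to avoid -inf.
DB_FLOOR_LINEAR = 1e-12


@dataclass(frozen=True)
class SpectralEstimate:
    """One-sided PSD on an ascending frequency grid starting at 0 Hz."""

    freqs: np.ndarray
    psd: np.ndarray  # power per Hz
    bin_width: float  # Hz
    method: str  # estimator provenance, e.g. "periodogram(boxcar)"

    def __post_init__(self) -> None:
        if self.freqs.shape != self.psd.shape:
            raise ValueError("freqs and psd must have equal length")

    def total_power(self) -> float:
        """Integrated power, Sum psd * bin_width (≈ time-domain variance)."""
        return float(np.sum(self.psd) * self.bin_width)


@dataclass(frozen=True)
class HarmonicSet:
    """The harmonic frequencies n*ff, n = 1..n_harmonics, to integrate over."""

    ff: float  # fundamental, Hz
    n_harmonics: int = 12
    window_width: float = 1.0  # Hz

    def __post_init__(self) -> None:
        if self.ff <= 0:
            raise ValueError("ff must be positive")

    @property
    def centers(self) -> np.ndarray:
        return self.ff * np.arange(1, self.n_harmonics + 1)


def compute_periodogram(rec: Recording, window: str = "boxcar") -> SpectralEstimate:
    """Full-record periodogram PSD (bin width = sampling_rate / n_samples).

    The rectangular (boxcar) window matches the plain periodogram default;
    a Hann window is available for sidelobe suppression.
    """
    if rec.samples.size < 2:
        raise ValueError("recording must contain at least 2 samples")
    freqs, psd = signal.periodogram(rec.samples, fs=rec.sampling_rate,
                                    window=window, detrend=False)
    return SpectralEstimate(freqs=freqs, psd=psd,
                            bin_width=rec.sampling_rate / rec.samples.size,
                            method=f"periodogram({window})")


def compute_welch(rec: Recording, segment_seconds: float = 1.0,
                  overlap_fraction: float = 0.5,
                  window: str = "hann") -> SpectralEstimate:
    """Welch-averaged PSD (default 1 s Hann segments with 50% overlap).

    Averaging shortened, overlapped segments trades frequency resolution
    (bin width 1/segment_seconds) for a lower-variance estimate; used for
    visualization, while feature extraction defaults to the periodogram.
    """
    nperseg = int(round(segment_seconds * rec.sampling_rate))
    if nperseg < 2 or nperseg > rec.samples.size:
        raise ValueError(
            f"segment of {segment_seconds} s ({nperseg} samples) does not fit "
            f"a record of {rec.samples.size} samples")
    noverlap = int(round(overlap_fraction * nperseg))
    freqs, psd = signal.welch(rec.samples, fs=rec.sampling_rate, window=window,
                              nperseg=nperseg, noverlap=noverlap, detrend=False)
    return SpectralEstimate(freqs=freqs, psd=psd, bin_width=1.0 / segment_seconds,
                            method=f"welch({window},{segment_seconds}s,"
                                   f"{overlap_fraction:g})")


def fundamental_from_rpm(pump_speed: float) -> float:
    """Pump fundamental frequency in Hz from the set speed in rpm (rpm/60)."""
    if pump_speed <= 0:
        raise ValueError("pump_speed must be positive")
    return pump_speed / 60.0


def detect_fundamental(spec: SpectralEstimate,
                       search_band: tuple[float, float] = (35.0, 55.0)) -> float:
    """Locate the fundamental as the PSD peak inside ``search_band``.

    The peak bin is refined by parabolic interpolation over the three bins
    around it. Intended as a fallback when the pump set speed is not
    recorded; HVAD speeds of 2100-3300 rpm put FF in 35-55 Hz. A warning is
    issued when the peak rises less than 3x above the band's median PSD
    (no clear rotor line; the returned value is then unreliable).
    """
    lo, hi = search_band
    mask = (spec.freqs >= lo) & (spec.freqs <= hi)
    if not mask.any():
        raise ValueError(f"search band {search_band} contains no spectrum bins")
    idx = np.flatnonzero(mask)
    band_psd = spec.psd[idx]
    peak_local = int(np.argmax(band_psd))
    i = idx[peak_local]
    median = float(np.median(band_psd))
    if median > 0 and band_psd[peak_local] < 3.0 * median:
        warnings.warn(
            f"low-confidence fundamental: peak {band_psd[peak_local]:.3g} "
            f"< 3 x band median {median:.3g}", stacklevel=2)
    # parabolic refinement on log power where the three bins allow it
    if 0 < i < spec.freqs.size - 1:
        y0, y1, y2 = spec.psd[i - 1], spec.psd[i], spec.psd[i + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom != 0:
            delta = 0.5 * (y0 - y2) / denom
            delta = float(np.clip(delta, -0.5, 0.5))
            return float(spec.freqs[i] + delta * (spec.freqs[1] - spec.freqs[0]))
    return float(spec.freqs[i])


def harmonic_power(spec: SpectralEstimate, center: float,
                   width: float = 1.0) -> float:
    """Area under the PSD in the closed interval [center-w/2, center+w/2].

    Trapezoidal integration over the bins whose frequency lies in the
    interval; on the fine full-record periodogram grid the quadrature
    choice matters only at the 0.01 dB level.
    """
    lo, hi = center - width / 2.0, center + width / 2.0
    if lo < spec.freqs[0] or hi > spec.freqs[-1]:
        raise ValueError(
            f"window [{lo:.3f}, {hi:.3f}] Hz outside spectrum range "
            f"[{spec.freqs[0]:.3f}, {spec.freqs[-1]:.3f}] Hz")
    mask = (spec.freqs >= lo) & (spec.freqs <= hi)
    n_bins = int(mask.sum())
    if n_bins == 0:
        return 0.0
    if n_bins == 1:
        # coarse grid (e.g. 1 Hz Welch bins): one density value covers the window
        return float(spec.psd[mask][0] * width)
    return float(np.trapezoid(spec.psd[mask], spec.freqs[mask]))


def normalize_profile(powers_db: np.ndarray | list[float]) -> np.ndarray:
    """Shift dB powers so their linearized sum equals 1 (0 dB total).

    Idempotent; invariant to any uniform gain applied before conversion.
    """
    p = np.asarray(powers_db, dtype=float)
    linear = 10.0 ** (p / 10.0)
    total = linear.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError("cannot normalize: no finite harmonic power")
    return p - 10.0 * np.log10(total)


def extract_profile(rec: Recording, ff: float, n_harmonics: int = 12,
                    window_width: float = 1.0,
                    estimator: str = "periodogram") -> HarmonicProfile:
    """Reduce a recording to its normalized harmonic-power signature.

    Integrates the PSD (periodogram by default, Welch optional) over a
    1 Hz window at each of n*ff, n = 1..n_harmonics, converts to dB with a
    1e-12 linear floor, and normalizes to a 0 dB sum. The outcome label is
    left unset.
    """
    harmonics = HarmonicSet(ff=ff, n_harmonics=n_harmonics,
                            window_width=window_width)
    nyquist = rec.sampling_rate / 2.0
    if harmonics.centers[-1] + window_width / 2.0 >= nyquist:
        raise ValueError(
            f"harmonic {n_harmonics} x {ff:.2f} Hz exceeds Nyquist {nyquist:.1f} Hz")
    if estimator == "periodogram":
        spec = compute_periodogram(rec)
    elif estimator == "welch":
        spec = compute_welch(rec)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    powers = np.array([harmonic_power(spec, c, window_width)
                       for c in harmonics.centers])
    clipped = np.maximum(powers, DB_FLOOR_LINEAR)
    if (powers < DB_FLOOR_LINEAR).any():
        log.debug("clipped %d harmonic power(s) at linear floor %g",
                  int((powers < DB_FLOOR_LINEAR).sum()), DB_FLOOR_LINEAR)
    powers_db = normalize_profile(10.0 * np.log10(clipped))
    if n_harmonics == 12:
        log.debug("extracted profile %s", dict(zip(HARMONIC_COLUMNS, powers_db)))
    return HarmonicProfile(patient_id=rec.patient_id,
                           power_db=tuple(float(v) for v in powers_db),
                           outcome=None)
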