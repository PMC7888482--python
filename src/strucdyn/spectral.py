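"""Fourier power spectra and spectrum-derived summary statistics.

All statistics operate on the variance-normalized one-sided periodogram, in
which total power sums to one, so band powers are relative (unitless)
fractions.  The central statistic is relative low-frequency power (RLFP):
the proportion of power in the lowest 20% of frequencies, which at
TR = 0.72 s and N = 1200 samples corresponds to f < 0.14 Hz.  fALFF
(relative power in 0.01-0.08 Hz) and the log-log spectral slope are provided
as companion timescale-related statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PowerSpectrum",
    "FrequencyBand",
    "periodogram",
    "band_power",
    "rlfp",
    "rlfp_from_spectrum",
    "falff",
    "five_band_powers",
    "band_upper_edges_hz",
    "loglog_slope",
]


@dataclass(frozen=True)
class FrequencyBand:
    """Half-open frequency interval [f_lo, f_hi) in Hz."""

    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0 <= self.f_lo < self.f_hi):
            raise ValueError(f"invalid band [{self.f_lo}, {self.f_hi})")


@dataclass
class PowerSpectrum:
    """One-sided relative power spectrum on the grid f_k = k / (N * tr).

    ``power`` sums to one; the DC bin is included (its power is ~0 for
    mean-removed input).
    """

    freqs: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.shape != self.power.shape or self.freqs.ndim != 1:
            raise ValueError("freqs and power must be 1-D arrays of equal length")
        if self.freqs[0] != 0 or np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must start at 0 and be strictly increasing")
        if np.any(self.power < -1e-12):
            raise ValueError("power must be nonnegative")
        if abs(self.power.sum() - 1.0) > 1e-9:
            raise ValueError("relative power must sum to 1")

    @property
    def nyquist(self) -> float:
        return float(self.freqs[-1])

    @property
    def n_bins(self) -> int:
        return self.freqs.size


def periodogram(ts: np.ndarray, tr: float) -> PowerSpectrum:
    """Plain (untapered) periodogram, renormalized to unit total power.

    The input is expected to be detrended and z-scored; a warning is issued
    when the mean is visibly nonzero.  The absolute scale of the series does
    not matter because the spectrum is renormalized.
    """
    x = np.asarray(ts, dtype=float)
    if x.size < 16:
        raise ValueError("periodogram needs at least 16 samples")
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot compute the spectrum of a constant series")
    if abs(x.mean()) > 1e-4 * sd:  # threshold tolerates TSV-rounded z-scores
        warnings.warn(
            "periodogram input does not look detrended/z-scored "
            "(nonzero mean); relative band powers include a DC contribution",
            UserWarning,
            stacklevel=2,
        )
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(x.size, d=tr)
    return PowerSpectrum(freqs, spec / spec.sum())


def band_power(spec: PowerSpectrum, band: FrequencyBand) -> float:
    """Sum of relative power over bins with f_lo <= f < f_hi.

    As a convenience for bands closing exactly at the Nyquist frequency,
    a band whose upper edge equals Nyquist includes the Nyquist bin (so a
    band covering the whole axis returns 1).
    """
    if band.f_hi > spec.nyquist + 1e-12:
        raise ValueError(
            f"band upper edge {band.f_hi} exceeds Nyquist {spec.nyquist:.4g}"
        )
    mask = (spec.freqs >= band.f_lo) & (spec.freqs < band.f_hi)
    if np.isclose(band.f_hi, spec.nyquist):
        mask |= np.isclose(spec.freqs, spec.nyquist)
    if not mask.any():
        raise ValueError(f"band [{band.f_lo}, {band.f_hi}) contains no frequency bins")
    return float(spec.power[mask].sum())


def _low_band_top_bin(n_timepoints: int, fraction: float) -> int:
    """Index of the highest bin inside the lowest ``fraction`` of frequencies.

    Implemented by bin count, k <= floor(fraction * N/2); at TR = 0.72 s and
    N = 1200 this places the RLFP edge at bin 120 (0.139 Hz, printing as
    0.14 Hz).
    """
    return int(np.floor(fraction * (n_timepoints // 2)))


def rlfp_from_spectrum(spec: PowerSpectrum, n_timepoints: int, fraction: float = 0.2) -> float:
    top = _low_band_top_bin(n_timepoints, fraction)
    return float(spec.power[: top + 1].sum())


def rlfp(ts: np.ndarray, tr: float, fraction: float = 0.2) -> float:
    """Relative low-frequency power: fraction of power in the lowest
    ``fraction`` of frequencies (DC bin included)."""
    x = np.asarray(ts, dtype=float)
    return rlfp_from_spectrum(periodogram(x, tr), x.size, fraction)


def falff(ts: np.ndarray, tr: float) -> float:
    """Fractional amplitude of low-frequency fluctuations: relative power in
    [0.01, 0.08) Hz."""
    if 0.5 / tr <= 0.08:
        raise ValueError("Nyquist frequency must exceed 0.08 Hz for fALFF")
    return band_power(periodogram(ts, tr), FrequencyBand(0.01, 0.08))


def _band_bin_edges(n_timepoints: int, fraction: float) -> list[int]:
    m = n_timepoints // 2
    n_bands = int(round(1.0 / fraction))
    return [int(np.floor(j * fraction * m)) for j in range(n_bands + 1)]


def five_band_powers(spec: PowerSpectrum, n_timepoints: int, fraction: float = 0.2) -> np.ndarray:
    """Powers of the equal-width 20% frequency bands (a partition of the axis).

    Band 1 spans bins 0..k1 (the DC bin belongs to the lowest band); band j
    spans bins (k_{j-1}, k_j].  The returned powers sum to one.
    """
    edges = _band_bin_edges(n_timepoints, fraction)
    out = [float(spec.power[: edges[1] + 1].sum())]
    for j in range(1, len(edges) - 1):
        out.append(float(spec.power[edges[j] + 1 : edges[j + 1] + 1].sum()))
    return np.asarray(out)


def band_upper_edges_hz(n_timepoints: int, tr: float, fraction: float = 0.2) -> np.ndarray:
    """Upper edge frequency of each equal-width band, in Hz."""
    edges = _band_bin_edges(n_timepoints, fraction)
    return np.asarray([k / (n_timepoints * tr) for k in edges[1:]])


def loglog_slope(spec: PowerSpectrum) -> float:
    """Power-law exponent of the spectrum: least-squares slope of
    log10(power) on log10(frequency).

    Fitted over the middle 50% of positive-frequency bins (the lowest and
    highest quarter, by bin index, are excluded); zero-power bins inside the
    window are dropped.
    """
    m = spec.n_bins - 1  # positive-frequency bins 1..m
    idx = np.arange(1, m + 1)
    window = idx[m // 4 : (3 * m) // 4]
    usable = window[spec.power[window] > 0]
    n_dropped = window.size - usable.size
    if usable.size < 3:
        raise ValueError(
            f"loglog_slope needs >= 3 usable bins, got {usable.size} "
            f"({n_dropped} zero-power bins excluded)"
        )
    if n_dropped:
        warnings.warn(
            f"loglog_slope excluded {n_dropped} zero-power bins", UserWarning,
            stacklevel=2,
        )
    coeffs = np.polyfit(np.log10(spec.freqs[usable]), np.log10(spec.power[usable]), 1)
    return float(coeffs[0])
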