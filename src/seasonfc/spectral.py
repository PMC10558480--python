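"""Welch power spectra and fractional amplitude of low-frequency fluctuations.

fALFF is the fraction of the power above 0.01 Hz that falls in the
0.01–0.08 Hz low-frequency band. Spectra are estimated on
normalized but *unfiltered* signals — bandpass filtering would empty the
denominator band and push every fALFF toward 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .signal import RegionTimeSeries, normalize_unit_variance

#: fALFF numerator band (Hz) and the lower edge of the denominator band.
FALFF_BAND = (0.01, 0.08)
FALFF_DENOM_LOW = 0.01


@dataclass(frozen=True)
class WelchParams:
    """Welch estimator settings.

    Defaults mirror the common pwelch convention: the signal is split into
    ``n_segments`` Hamming-tapered segments with 50% overlap and the
    windowed periodograms are averaged.
    """

    n_segments: int = 8
    overlap_fraction: float = 0.5
    window: str = "hamming"

    def __post_init__(self) -> None:
        if self.n_segments < 1:
            raise ValueError("n_segments must be >= 1")
        if not (0.0 <= self.overlap_fraction < 1.0):
            raise ValueError("overlap_fraction must be in [0, 1)")

    def segment_length(self, n_samples: int) -> int:
        # k segments with overlap v cover nperseg * (k(1-v) + v) samples
        nperseg = int(np.floor(n_samples / (self.n_segments * (1 - self.overlap_fraction) + self.overlap_fraction)))
        if nperseg < 8:
            raise ValueError(
                f"signal of {n_samples} samples is too short for {self.n_segments} "
                f"segments (segment length {nperseg} < 8)"
            )
        return nperseg


@dataclass
class PowerSpectrum:
    """One-sided power spectral density on a uniform grid up to Nyquist."""

    frequencies_hz: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        self.frequencies_hz = np.asarray(self.frequencies_hz, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.frequencies_hz.shape != self.power.shape:
            raise ValueError("frequency and power grids differ in length")
        if np.any(np.diff(self.frequencies_hz) <= 0):
            raise ValueError("frequency grid must be strictly ascending")
        if np.any(self.power < 0):
            raise ValueError("power must be nonnegative")


def _welch_raw(x: np.ndarray, tr_seconds: float, params: WelchParams):
    n = x.shape[-1]
    nperseg = params.segment_length(n)
    noverlap = int(np.floor(nperseg * params.overlap_fraction))
    window = "boxcar" if params.window in ("rect", "rectangular") else params.window
    return sps.welch(
        x,
        fs=1.0 / tr_seconds,
        window=window,
        nperseg=nperseg,
        noverlap=noverlap,
        detrend=False,
        scaling="density",
        axis=-1,
    )


def welch_psd(signal: np.ndarray, tr_seconds: float, params: WelchParams | None = None) -> PowerSpectrum:
    """Welch PSD of a single region time series.

    Satisfies Parseval in expectation: ``sum(power) * Δf`` approximates the
    signal variance.
    """
    params = params or WelchParams()
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("welch_psd expects a single 1-D time series")
    params.segment_length(x.size)  # raises for too-short signals
    f, p = _welch_raw(x, tr_seconds, params)
    return PowerSpectrum(f, p)


def welch_psd_matrix(series: RegionTimeSeries, params: WelchParams | None = None):
    """Vectorized Welch PSD of every region column.

    Returns ``(frequencies, power)`` with power shaped regions × frequencies.
    """
    params = params or WelchParams()
    f, p = _welch_raw(series.values.T, series.tr_seconds, params)
    return f, p


def falff_array(
    frequencies_hz: np.ndarray,
    power: np.ndarray,
    band_low: float = FALFF_BAND[0],
    band_high: float = FALFF_BAND[1],
    denom_low: float = FALFF_DENOM_LOW,
) -> np.ndarray:
    """fALFF over the last axis of a stack of spectra sharing one grid."""
    f = np.asarray(frequencies_hz, dtype=float)
    p = np.asarray(power, dtype=float)
    eps = 1e-12
    num_mask = (f >= band_low - eps) & (f <= band_high + eps)
    den_mask = f > denom_low + eps
    if not den_mask.any():
        raise ValueError("frequency grid has no bins above the denominator edge")
    denom = p[..., den_mask].sum(axis=-1)
    if np.any(denom <= 0):
        raise ValueError("zero power above the denominator edge; fALFF undefined")
    if not num_mask.any():
        return np.zeros_like(denom)
    return p[..., num_mask].sum(axis=-1) / denom


def falff(
    spectrum: PowerSpectrum,
    band_low: float = FALFF_BAND[0],
    band_high: float = FALFF_BAND[1],
    denom_low: float = FALFF_DENOM_LOW,
) -> float:
    """Fractional amplitude of low-frequency fluctuations.

    Band-total power over bins with ``band_low <= f <= band_high`` divided
    by band-total power over bins with ``f > denom_low`` (strict, up to
    Nyquist). Totals rather than per-bin means are used so the ratio is the
    fraction of above-0.01 Hz power residing in the low-frequency band and
    lies in [0, 1]; a flat spectrum gives the bin-count ratio, roughly
    (0.08 − 0.01)/(Nyquist − 0.01).
    """
    return float(
        falff_array(spectrum.frequencies_hz, spectrum.power, band_low, band_high, denom_low)
    )


def flat_spectrum_falff(
    n_samples: int,
    tr_seconds: float,
    params: WelchParams | None = None,
    band_low: float = FALFF_BAND[0],
    band_high: float = FALFF_BAND[1],
    denom_low: float = FALFF_DENOM_LOW,
) -> float:
    """Analytic fALFF of an exactly flat spectrum on the implemented grid.

    With equal power in every bin the band-total ratio reduces to the
    ratio of bin counts — approximately (0.08−0.01)/(Nyquist−0.01). Serves
    as a closed-form oracle for white-noise input.
    """
    params = params or WelchParams()
    nperseg = params.segment_length(n_samples)
    f = np.fft.rfftfreq(nperseg, d=tr_seconds)
    eps = 1e-12
    n_num = int(np.count_nonzero((f >= band_low - eps) & (f <= band_high + eps)))
    n_den = int(np.count_nonzero(f > denom_low + eps))
    return n_num / n_den


def region_falff(series: RegionTimeSeries, params: WelchParams | None = None) -> np.ndarray:
    """Per-region fALFF of a subject's (normalized, unfiltered) series."""
    series = normalize_unit_variance(series)
    f, p = welch_psd_matrix(series, params)
    return falff_array(f, p)


def mean_tissue_falff(subject, tissue: str, params: WelchParams | None = None) -> float:
    """Unweighted mean fALFF over a subject's GM or WM regions.

    ``subject`` may be a cohort subject record or a bare
    :class:`~seasonfc.signal.RegionTimeSeries`.
    """
    series: RegionTimeSeries = getattr(subject, "series", subject)
    sub = series.select_tissue(tissue)
    return float(region_falff(sub, params).mean())


def group_mean_spectrum(cohort, season: str, tissue: str, params: WelchParams | None = None) -> PowerSpectrum:
    """Season-group mean spectrum: average over regions, then over subjects."""
    members = [s for s in cohort.subjects if s.season == season]
    if not members:
        raise ValueError(f"no subjects acquired in season {season!r}")
    per_subject = []
    freqs = None
    for subj in members:
        sub = normalize_unit_variance(subj.series.select_tissue(tissue))
        f, p = welch_psd_matrix(sub, params)
        if freqs is None:
            freqs = f
        elif f.shape != freqs.shape or not np.allclose(f, freqs):
            raise ValueError("subjects have incompatible frequency grids")
        per_subject.append(p.mean(axis=0))
    return PowerSpectrum(freqs, np.mean(per_subject, axis=0))
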