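"""Time-series preparation for region-averaged BOLD signals.

Functional-connectivity inputs are bandpass filtered (0.01–0.1 Hz by
convention for resting-state BOLD) and normalized to zero mean / unit
variance; spectral inputs are normalized but *not* filtered, because
fractional power measures need the full spectrum in the denominator.
Nuisance covariates (sex) are regressed out of derived measures, not of
raw time series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as sps

logger = logging.getLogger("seasonfc")

TISSUES = ("GM", "WM")


@dataclass
class RegionTimeSeries:
    """A timepoints × regions matrix of region-averaged BOLD signals.

    Parameters
    ----------
    values
        Real matrix, one column per region, one row per timepoint (TR).
    tr_seconds
        Sampling interval in seconds.
    region_labels
        Unique region names, one per column.
    tissue
        Tissue class per region, each ``"GM"`` or ``"WM"``.
    """

    values: np.ndarray
    tr_seconds: float
    region_labels: list[str] = field(default_factory=list)
    tissue: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D timepoints × regions matrix")
        n_regions = self.values.shape[1]
        if not self.region_labels:
            self.region_labels = [f"region_{i:03d}" for i in range(n_regions)]
        if not self.tissue:
            self.tissue = ["GM"] * n_regions
        if len(self.region_labels) != n_regions or len(self.tissue) != n_regions:
            raise ValueError("region_labels/tissue length must match the number of columns")
        if len(set(self.region_labels)) != n_regions:
            raise ValueError("region labels must be unique")
        bad = sorted(set(self.tissue) - set(TISSUES))
        if bad:
            raise ValueError(f"unknown tissue classes {bad}; expected GM or WM")
        if not (self.tr_seconds > 0):
            raise ValueError("tr_seconds must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contain non-finite values")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    @property
    def nyquist_hz(self) -> float:
        return 1.0 / (2.0 * self.tr_seconds)

    def select_tissue(self, tissue: str) -> "RegionTimeSeries":
        """Return the sub-series restricted to one tissue class."""
        if tissue not in TISSUES:
            raise ValueError(f"unknown tissue {tissue!r}")
        idx = [i for i, t in enumerate(self.tissue) if t == tissue]
        if not idx:
            raise ValueError(f"no regions of tissue {tissue}")
        return RegionTimeSeries(
            self.values[:, idx],
            self.tr_seconds,
            [self.region_labels[i] for i in idx],
            [self.tissue[i] for i in idx],
        )


def _butter_sos(low_hz: float, high_hz: float, fs: float, order: int = 4):
    return sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")


def _sosfiltfilt(sos, x: np.ndarray, axis: int) -> np.ndarray:
    # clamp reflect-padding for very short series so the filter still applies
    default_pad = 3 * (2 * sos.shape[0] + 1)
    padlen = min(default_pad, x.shape[axis] - 1)
    return sps.sosfiltfilt(sos, x, axis=axis, padlen=padlen)


def bandpass_filter(
    series: RegionTimeSeries,
    low_hz: float = 0.01,
    high_hz: float = 0.1,
    order: int = 4,
) -> RegionTimeSeries:
    """Zero-phase Butterworth bandpass of every region column.

    A 4th-order Butterworth filter applied forward-backward
    (``sosfiltfilt``) so no phase shift can distort the correlation
    structure between regions. Band edges must lie strictly inside
    (0, Nyquist).
    """
    nyq = series.nyquist_hz
    if not (0.0 < low_hz < high_hz < nyq):
        raise ValueError(
            f"band edges must satisfy 0 < low < high < Nyquist ({nyq:.4f} Hz); "
            f"got [{low_hz}, {high_hz}]"
        )
    sos = _butter_sos(low_hz, high_hz, fs=1.0 / series.tr_seconds, order=order)
    filtered = _sosfiltfilt(sos, series.values, axis=0)
    return replace(series, values=filtered)


def bandpass_white_noise(
    rng: np.random.Generator,
    shape: tuple[int, ...],
    tr_seconds: float,
    low_hz: float,
    high_hz: float,
    order: int = 4,
) -> np.ndarray:
    """Band-limited Gaussian noise, unit variance per trace after filtering.

    Filtering is applied along the last axis. Used by the cohort simulator
    for its shared low-frequency latent signals.
    """
    x = rng.standard_normal(shape)
    sos = _butter_sos(low_hz, high_hz, fs=1.0 / tr_seconds, order=order)
    x = _sosfiltfilt(sos, x, axis=-1)
    sd = x.std(axis=-1, keepdims=True, ddof=1)
    sd[sd == 0] = 1.0
    return (x - x.mean(axis=-1, keepdims=True)) / sd


def normalize_unit_variance(series: RegionTimeSeries) -> RegionTimeSeries:
    """Demean each region and scale to unit sample variance (ddof=1)."""
    mean = series.values.mean(axis=0)
    sd = series.values.std(axis=0, ddof=1)
    flat = np.flatnonzero((sd == 0) | (np.ptp(series.values, axis=0) == 0))
    if flat.size:
        names = [series.region_labels[i] for i in flat[:5]]
        raise ValueError(f"constant region signal(s), cannot normalize: {names}")
    return replace(series, values=(series.values - mean) / sd)


def region_average(
    voxel_series: np.ndarray,
    membership: Sequence[str],
    tr_seconds: float,
    tissue_of: Mapping[str, str] | None = None,
) -> RegionTimeSeries:
    """Average voxel columns into region columns.

    Parameters
    ----------
    voxel_series
        timepoints × voxels matrix.
    membership
        Region label for every voxel column, in column order. Regions appear
        in the output in order of first appearance.
    tissue_of
        Optional mapping from region label to tissue class; every region
        label must be present when given. Defaults to GM for all regions.
    """
    voxel_series = np.asarray(voxel_series, dtype=float)
    if voxel_series.ndim != 2:
        raise ValueError("voxel_series must be 2-D")
    if len(membership) != voxel_series.shape[1]:
        raise ValueError("membership must label every voxel column")
    labels: list[str] = []
    for lab in membership:
        if lab not in labels:
            labels.append(lab)
    cols = []
    for lab in labels:
        idx = [i for i, m in enumerate(membership) if m == lab]
        if not idx:  # pragma: no cover - unreachable by construction
            raise ValueError(f"region {lab!r} has no member voxels")
        cols.append(voxel_series[:, idx].mean(axis=1))
    if tissue_of is not None:
        missing = [lab for lab in labels if lab not in tissue_of]
        if missing:
            raise ValueError(f"no tissue class for region(s) {missing}")
        tissue = [tissue_of[lab] for lab in labels]
    else:
        tissue = ["GM"] * len(labels)
    return RegionTimeSeries(np.column_stack(cols), tr_seconds, labels, tissue)


def residualize_on_covariate(values: np.ndarray, covariate: np.ndarray) -> np.ndarray:
    """OLS residuals of ``values`` on [covariate, intercept], grand mean restored.

    The output has the same mean as the input and is orthogonal to the
    centered covariate; applying the operation twice is a no-op.
    """
    y = np.asarray(values, dtype=float)
    x = np.asarray(covariate, dtype=float)
    if y.shape[0] != x.shape[0]:
        raise ValueError("values and covariate lengths differ")
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant; nothing to regress out")
    X = np.column_stack([x, np.ones_like(x)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return resid + y.mean(axis=0)
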