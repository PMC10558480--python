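"""Pearson functional-connectivity matrices and Fisher-Z summaries.

FC between two region sets is the sample Pearson correlation of their
(filtered, normalized) time courses. Matrices are Fisher-Z transformed
element-wise and summarized as means of |Z| — globally, per functional
network (GM columns partitioned into networks), and per GM region averaged
over WM bundles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .signal import RegionTimeSeries

logger = logging.getLogger("seasonfc")

#: |r| is clipped here before arctanh so duplicate/self regions cannot
#: produce infinite Z-scores.
FISHER_CLIP = 1.0 - 1e-7


@dataclass
class FCMatrix:
    """Labeled Pearson-correlation matrix between two region sets."""

    values: np.ndarray
    row_labels: list[str]
    col_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("matrix shape does not match label counts")
        if np.any(np.abs(self.values) > 1 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")

    @property
    def is_within_set(self) -> bool:
        return self.row_labels == self.col_labels


@dataclass
class ZMatrix:
    """Element-wise Fisher Z (arctanh) transform of an FCMatrix."""

    values: np.ndarray
    row_labels: list[str]
    col_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("matrix shape does not match label counts")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("Z matrix contains non-finite values")

    @property
    def is_within_set(self) -> bool:
        return self.row_labels == self.col_labels


def _standardize_columns(series: RegionTimeSeries) -> np.ndarray:
    x = series.values
    sd = x.std(axis=0, ddof=1)
    flat = np.flatnonzero((sd == 0) | (np.ptp(x, axis=0) == 0))
    if flat.size:
        names = [series.region_labels[i] for i in flat[:5]]
        raise ValueError(f"constant region signal(s), correlation undefined: {names}")
    return (x - x.mean(axis=0)) / sd


def pearson_fc(series_a: RegionTimeSeries, series_b: RegionTimeSeries) -> FCMatrix:
    """Pearson correlation of every region in ``series_a`` with every region
    in ``series_b``.

    When both arguments are the same set of regions the result is
    symmetrized and given an exact unit diagonal.
    """
    if series_a.n_timepoints != series_b.n_timepoints:
        raise ValueError("time series must have equal numbers of timepoints")
    za = _standardize_columns(series_a)
    zb = _standardize_columns(series_b)
    r = za.T @ zb / (series_a.n_timepoints - 1)
    np.clip(r, -1.0, 1.0, out=r)
    same = series_a.region_labels == series_b.region_labels
    if same:
        r = (r + r.T) / 2.0
        np.fill_diagonal(r, 1.0)
    return FCMatrix(r, list(series_a.region_labels), list(series_b.region_labels))


def fisher_z(fc: FCMatrix, clip: float = FISHER_CLIP) -> ZMatrix:
    """arctanh of each correlation, with |r| clipped to ``clip`` first."""
    r = fc.values
    n_clipped = int(np.count_nonzero(np.abs(r) > clip))
    if n_clipped:
        logger.info("fisher_z: clipped %d element(s) with |r| > %g", n_clipped, clip)
    z = np.arctanh(np.clip(r, -clip, clip))
    return ZMatrix(z, list(fc.row_labels), list(fc.col_labels))


def _included_values(z: ZMatrix, exclude_diagonal: bool | None) -> np.ndarray:
    if exclude_diagonal is None:
        exclude_diagonal = z.is_within_set
    if exclude_diagonal:
        if z.values.shape[0] != z.values.shape[1]:
            raise ValueError("diagonal exclusion requires a square matrix")
        iu = np.triu_indices(z.values.shape[0], k=1)
        vals = z.values[iu]
    else:
        vals = z.values.ravel()
    if vals.size == 0:
        raise ValueError("no matrix elements left to average")
    return vals


def mean_abs_z(z: ZMatrix, exclude_diagonal: bool | None = None) -> float:
    """Mean of |Z| over the matrix elements.

    For within-tissue (square, same-label) matrices the unit diagonal and
    the duplicate lower triangle are excluded by default; cross-tissue
    matrices average all elements.
    """
    return float(np.abs(_included_values(z, exclude_diagonal)).mean())


def network_mean_fc(z: ZMatrix, network_map: Mapping[str, str]) -> dict[str, float]:
    """Mean |Z| of each functional-network submatrix of a WM × GM Z-matrix.

    GM columns are partitioned by ``network_map`` (GM region label →
    network name); each network's summary is the mean of |Z| over all WM
    rows and that network's GM columns.
    """
    unmapped = [lab for lab in z.col_labels if lab not in network_map]
    if unmapped:
        raise ValueError(f"GM region(s) without network assignment: {unmapped[:5]}")
    networks = sorted(set(network_map[lab] for lab in z.col_labels))
    out: dict[str, float] = {}
    for net in networks:
        cols = [j for j, lab in enumerate(z.col_labels) if network_map[lab] == net]
        if not cols:  # pragma: no cover - excluded by construction
            raise ValueError(f"network {net!r} has no GM regions")
        out[net] = float(np.abs(z.values[:, cols]).mean())
    return out


def wm_averaged_fc_per_gm(z: ZMatrix) -> pd.Series:
    """Per-GM-region mean |Z| over all WM rows (tabular connectivity map)."""
    if z.values.size == 0:
        raise ValueError("empty Z matrix")
    return pd.Series(np.abs(z.values).mean(axis=0), index=list(z.col_labels), name="wm_mean_abs_z")
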