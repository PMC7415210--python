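"""Sliding-window functional connectivity.

Builds per-participant series of windowed Pearson correlation matrices
from ROI (region-of-interest) time series, the substrate for state
clustering and temporal-variability analysis. Windows are rectangular
(no taper), indexed 0-based and half-open: window ``i`` covers time
points ``[i*step, i*step + window_length)``. No Fisher z-transform is
applied anywhere; all downstream computation operates on raw
correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RoiTimeSeries",
    "WindowParams",
    "WindowedFCSeries",
    "load_roi_timeseries",
    "sliding_window_fc",
    "n_windows",
    "vectorize_upper",
    "devectorize_upper",
]


@dataclass
class RoiTimeSeries:
    """One participant's signal matrix, time points x regions."""

    participant_id: str
    data: np.ndarray  # (T, p), float
    region_labels: list[str]
    tr: float = 3.0  # repetition time, seconds

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time series must be a 2-D (time x regions) array")
        if self.data.shape[1] < 2:
            raise ValueError("need at least 2 regions")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time series contains non-finite values")
        if len(self.region_labels) != self.data.shape[1]:
            raise ValueError("region label count does not match data columns")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class WindowParams:
    """Sliding-window geometry in units of TRs.

    Defaults follow the common resting-state choice of a 10-TR window
    (30 s at TR = 3 s) advanced by a single TR.
    """

    window_length: int = 10
    step: int = 1

    def __post_init__(self) -> None:
        if not (1 <= self.step <= self.window_length):
            raise ValueError("require 1 <= step <= window_length")

    def duration_seconds(self, tr: float) -> float:
        return self.window_length * tr


@dataclass
class WindowedFCSeries:
    """Ordered windowed correlation matrices for one participant.

    ``matrices`` has shape (n_windows, p, p); each slice is symmetric
    with unit diagonal. ``zero_variance`` lists (window_index,
    region_index) pairs whose segment had zero variance; their
    correlations were set to 0 rather than NaN so downstream clustering
    stays total.
    """

    participant_id: str
    matrices: np.ndarray
    window_starts: np.ndarray
    params: WindowParams
    region_labels: list[str] = field(default_factory=list)
    zero_variance: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_windows(self) -> int:
        return self.matrices.shape[0]

    @property
    def n_regions(self) -> int:
        return self.matrices.shape[1]

    def edge_vectors(self) -> np.ndarray:
        """Stack of strict-upper-triangle edge vectors, (n_windows, p*(p-1)/2)."""
        p = self.n_regions
        iu = np.triu_indices(p, k=1)
        return self.matrices[:, iu[0], iu[1]]


def load_roi_timeseries(
    path,
    participant_id: str | None = None,
    tr: float = 3.0,
) -> RoiTimeSeries:
    """Load one participant's TSV (header of region labels, numeric body).

    Raises ``ValueError`` naming the offending line for ragged rows,
    non-numeric cells, or duplicate region labels. Constant
    (zero-variance) region columns are flagged with a warning but kept.
    """
    path = str(path)
    with open(path) as fh:
        labels = fh.readline().rstrip("\n").split("\t")
    if len(set(labels)) != len(labels):
        dupes = sorted({c for c in labels if labels.count(c) > 1})
        raise ValueError(f"{path}: duplicate region labels {dupes}")
    try:
        # round_trip parser: values survive write/read bit-exactly
        df = pd.read_csv(path, sep="\t", header=0, float_precision="round_trip")
    except pd.errors.ParserError as exc:  # ragged rows
        raise ValueError(f"{path}: malformed TSV ({exc})") from exc
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = pd.to_numeric(df[col], errors="coerce")
            row = int(np.flatnonzero(bad.isna().to_numpy())[0])
            # +2: header line plus 1-based numbering
            raise ValueError(
                f"{path}: non-numeric cell in column '{col}' at line {row + 2}"
            )
    values = df.to_numpy(float)
    const = [labels[j] for j in range(values.shape[1]) if np.ptp(values[:, j]) == 0]
    if const:
        warnings.warn(
            f"{path}: constant (zero-variance) region columns: {const}",
            stacklevel=2,
        )
    if participant_id is None:
        import os

        participant_id = os.path.splitext(os.path.basename(path))[0]
    return RoiTimeSeries(participant_id, values, labels, tr=tr)


def n_windows(n_timepoints: int, params: WindowParams) -> int:
    """floor((T - window_length)/step) + 1."""
    if n_timepoints < params.window_length:
        raise ValueError("time series shorter than window length")
    return (n_timepoints - params.window_length) // params.step + 1


def sliding_window_fc(ts: RoiTimeSeries, params: WindowParams | None = None) -> WindowedFCSeries:
    """Pearson correlation matrix in each sliding window.

    Zero-variance segments yield 0-valued correlations for the affected
    region in that window, with a (window, region) flag recorded.
    """
    if params is None:
        params = WindowParams()
    T, p = ts.data.shape
    nw = n_windows(T, params)
    starts = np.arange(nw) * params.step
    mats = np.empty((nw, p, p))
    flags: list[tuple[int, int]] = []
    wl = params.window_length
    for i, s in enumerate(starts):
        seg = ts.data[s : s + wl]
        centered = seg - seg.mean(axis=0)
        sd = centered.std(axis=0, ddof=1)
        zero = sd == 0
        safe_sd = np.where(zero, 1.0, sd)
        z = centered / safe_sd
        c = (z.T @ z) / (wl - 1)
        np.clip(c, -1.0, 1.0, out=c)
        if zero.any():
            for k in np.flatnonzero(zero):
                c[k, :] = 0.0
                c[:, k] = 0.0
                flags.append((i, int(k)))
        np.fill_diagonal(c, 1.0)
        mats[i] = (c + c.T) / 2
    return WindowedFCSeries(
        participant_id=ts.participant_id,
        matrices=mats,
        window_starts=starts,
        params=params,
        region_labels=list(ts.region_labels),
        zero_variance=flags,
    )


def vectorize_upper(matrix: np.ndarray) -> np.ndarray:
    """Strict upper triangle, row-major: length p*(p-1)/2."""
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("input must be a square matrix")
    iu = np.triu_indices(matrix.shape[0], k=1)
    return matrix[iu]


def devectorize_upper(vector: np.ndarray) -> np.ndarray:
    """Inverse of :func:`vectorize_upper`; unit diagonal restored."""
    vector = np.asarray(vector)
    m = vector.size
    # p*(p-1)/2 = m
    p = int(round((1 + np.sqrt(1 + 8 * m)) / 2))
    if p * (p - 1) // 2 != m:
        raise ValueError(f"vector length {m} is not a triangular number")
    out = np.eye(p)
    iu = np.triu_indices(p, k=1)
    out[iu] = vector
    out[(iu[1], iu[0])] = vector
    return out
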