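"""ROI time series, temporal cleaning and edge-level functional connectivity.

The temporal pipeline mirrors standard resting-state practice: linear
detrending, nuisance regression against motion / tissue / spike confounds,
and band-pass filtering, applied in that fixed order.  Functional
connectivity is the Pearson correlation between every pair of ROI time
series; the strict upper triangle of the correlation matrix, flattened
row-major, is the canonical edge vector (4005 edges for the 90-region
AAL cortical/subcortical parcellation).

Edge indexing convention
------------------------
Edge ``k`` runs over ROI pairs ``(i, j)`` with ``i < j`` in row-major order
of the strict upper triangle: ``(0,1), (0,2), ..., (0,n-1), (1,2), ...``.
Indices are 0-based in code; reports use 1-based ``edge_0001`` style names.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as _signal

logger = logging.getLogger(__name__)

CONFOUND_ROLES = ("motion", "motion_derivative", "csf", "wm", "spike")

__all__ = [
    "ROITimeSeries",
    "ConfoundSet",
    "ConnectivityMatrix",
    "EdgeTable",
    "n_edges",
    "edge_pair_to_index",
    "edge_index_to_pair",
    "clean_timeseries",
    "extract_roi_series",
    "correlation_matrix",
    "vectorize_edges",
    "unvectorize_edges",
]


# ---------------------------------------------------------------------------
# edge indexing


def n_edges(n_roi: int) -> int:
    """Number of distinct ROI pairs (upper-triangle edges) for ``n_roi`` regions."""
    return n_roi * (n_roi - 1) // 2


def edge_pair_to_index(i: int, j: int, n_roi: int) -> int:
    """Canonical edge index of ROI pair ``(i, j)``, ``0 <= i < j < n_roi``."""
    if not (0 <= i < j < n_roi):
        raise ValueError(f"invalid ROI pair ({i}, {j}) for n_roi={n_roi}")
    return i * (2 * n_roi - i - 1) // 2 + (j - i - 1)


def edge_index_to_pair(k: int, n_roi: int) -> tuple[int, int]:
    """Inverse of :func:`edge_pair_to_index`.

    Round-trips with :func:`vectorize_edges` for every valid ``k``.
    """
    m = n_edges(n_roi)
    if not 0 <= k < m:
        raise ValueError(f"edge index {k} out of range for n_roi={n_roi} ({m} edges)")
    # solve for the row: edges in rows < i total i*(2n-i-1)/2
    i = int((2 * n_roi - 1 - math.sqrt((2 * n_roi - 1) ** 2 - 8 * k)) // 2)
    # guard against float slop at row boundaries
    while i * (2 * n_roi - i - 1) // 2 > k:
        i -= 1
    while (i + 1) * (2 * n_roi - i - 2) // 2 <= k:
        i += 1
    j = i + 1 + (k - i * (2 * n_roi - i - 1) // 2)
    return i, j


# ---------------------------------------------------------------------------
# containers


@dataclass
class ROITimeSeries:
    """A (time x ROI) matrix of BOLD signals with the sampling interval.

    Parameters
    ----------
    values : ndarray, shape (n_timepoints, n_roi)
    tr : float
        Repetition time (sampling interval) in seconds.
    roi_names : sequence of str
        Unique region names, one per column.
    """

    values: np.ndarray
    tr: float
    roi_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (time x ROI) array")
        if self.values.shape[0] < 2:
            raise ValueError("need at least 2 timepoints")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contain non-finite values")
        self.roi_names = [str(r) for r in self.roi_names]
        if len(self.roi_names) != self.values.shape[1]:
            raise ValueError("roi_names length does not match column count")
        if len(set(self.roi_names)) != len(self.roi_names):
            raise ValueError("roi_names must be unique")
        if self.tr <= 0:
            raise ValueError("tr must be positive (seconds)")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_roi(self) -> int:
        return self.values.shape[1]

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, columns=self.roi_names).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str | Path, tr: float) -> "ROITimeSeries":
        df = pd.read_csv(path, sep="\t")
        return cls(df.to_numpy(float), tr=tr, roi_names=list(df.columns))


@dataclass
class ConfoundSet:
    """Nuisance regressors with per-column roles.

    Roles are drawn from ``motion``, ``motion_derivative``, ``csf``, ``wm``
    and ``spike``; spike columns are 0/1 scan indicators (scrubbing).
    """

    values: np.ndarray
    roles: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (time x confound)")
        self.roles = [str(r) for r in self.roles]
        if len(self.roles) != self.values.shape[1]:
            raise ValueError("one role per confound column required")
        bad = set(self.roles) - set(CONFOUND_ROLES)
        if bad:
            raise ValueError(f"unknown confound roles: {sorted(bad)}")
        for c, role in enumerate(self.roles):
            if role == "spike":
                col = self.values[:, c]
                if not np.all(np.isin(col, (0.0, 1.0))):
                    raise ValueError(f"spike column {c} is not a 0/1 indicator")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    def to_tsv(self, path: str | Path) -> None:
        cols = [f"{role}_{c:02d}" for c, role in enumerate(self.roles)]
        df = pd.DataFrame(self.values, columns=cols)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ConfoundSet":
        df = pd.read_csv(path, sep="\t")
        roles = ["_".join(c.split("_")[:-1]) for c in df.columns]
        return cls(df.to_numpy(float), roles=roles)


@dataclass
class ConnectivityMatrix:
    """Symmetric ROI x ROI Pearson correlation matrix with unit diagonal."""

    values: np.ndarray
    roi_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.ndim != 2 or self.values.shape[1] != n:
            raise ValueError("connectivity matrix must be square")
        if np.max(np.abs(self.values - self.values.T)) > 1e-8:
            raise ValueError("connectivity matrix is not symmetric")
        if np.max(np.abs(np.diag(self.values) - 1.0)) > 1e-8:
            raise ValueError("connectivity matrix diagonal must be 1")
        if np.max(np.abs(self.values)) > 1.0 + 1e-8:
            raise ValueError("correlations must lie in [-1, 1]")
        if len(self.roi_names) != n:
            raise ValueError("roi_names length mismatch")

    @property
    def n_roi(self) -> int:
        return self.values.shape[0]


@dataclass
class EdgeTable:
    """Subjects x edges feature table with binary group labels.

    ``labels`` are 0 for controls and 1 for patients; columns follow the
    canonical upper-triangle edge order for ``n_roi`` regions.
    """

    values: np.ndarray
    labels: np.ndarray
    n_roi: int
    subject_ids: list[str] = field(default_factory=list)
    roi_names: list[str] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (subjects x edges)")
        if self.values.shape[1] != n_edges(self.n_roi):
            raise ValueError(
                f"expected {n_edges(self.n_roi)} edges for n_roi={self.n_roi}, "
                f"got {self.values.shape[1]}"
            )
        if self.labels.shape != (self.values.shape[0],):
            raise ValueError("one label per subject required")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be 0 (control) or 1 (patient)")
        if len(np.unique(self.labels)) < 2:
            raise ValueError("labels must contain both classes")
        if not self.subject_ids:
            self.subject_ids = [f"sub-{i + 1:03d}" for i in range(len(self.labels))]
        if len(self.subject_ids) != len(self.labels):
            raise ValueError("subject_ids length mismatch")
        if self.roi_names is not None and len(self.roi_names) != self.n_roi:
            raise ValueError("roi_names length mismatch")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_edges(self) -> int:
        return self.values.shape[1]

    def edge_pairs(self) -> list[tuple[int, int]]:
        iu = np.triu_indices(self.n_roi, k=1)
        return list(zip(iu[0].tolist(), iu[1].tolist()))

    def edge_name(self, k: int) -> str:
        """Human-readable ROI-pair name of edge ``k``."""
        i, j = edge_index_to_pair(k, self.n_roi)
        names = self.roi_names or [f"ROI_{r + 1:03d}" for r in range(self.n_roi)]
        return f"{names[i]} -- {names[j]}"

    # ---- I/O ------------------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        width = max(4, len(str(self.n_edges)))
        cols = [f"edge_{k + 1:0{width}d}" for k in range(self.n_edges)]
        df = pd.DataFrame(self.values, columns=cols)
        df.insert(0, "label", self.labels)
        df.insert(0, "subject_id", self.subject_ids)
        return df

    def to_csv(self, path: str | Path, sidecar: bool = True) -> None:
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        if sidecar:
            side = {
                "n_roi": self.n_roi,
                "roi_names": self.roi_names,
                "edges": [list(p) for p in self.edge_pairs()],
                "meta": _jsonable(self.meta),
            }
            path.with_suffix(".json").write_text(json.dumps(side))

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        n_roi: int | None = None,
        label_col: str = "label",
        subject_col: str = "subject_id",
        roi_names: list[str] | None = None,
    ) -> "EdgeTable":
        edge_cols = [c for c in df.columns if c.startswith("edge_")]
        if not edge_cols:
            raise ValueError("no edge_* columns found")
        if n_roi is None:
            m = len(edge_cols)
            n_roi = int(round((1 + math.sqrt(1 + 8 * m)) / 2))
        ids = (
            [str(s) for s in df[subject_col]] if subject_col in df.columns else []
        )
        return cls(
            df[edge_cols].to_numpy(float),
            labels=df[label_col].to_numpy(int),
            n_roi=n_roi,
            subject_ids=ids,
            roi_names=roi_names,
        )

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "EdgeTable":
        path = Path(path)
        table = cls.from_dataframe(pd.read_csv(path), **kwargs)
        side = path.with_suffix(".json")
        if side.exists():
            info = json.loads(side.read_text())
            table.roi_names = info.get("roi_names")
            table.meta = info.get("meta", {})
        return table

    @classmethod
    def from_timeseries(
        cls,
        series: Sequence[ROITimeSeries],
        labels: Sequence[int],
        subject_ids: Sequence[str] | None = None,
        fisher_z: bool = False,
    ) -> "EdgeTable":
        """Build the feature table from per-subject ROI time series.

        ``fisher_z`` applies arctanh to the correlations; off by default
        (raw Pearson r is the edge feature).
        """
        if len(series) != len(labels):
            raise ValueError("one label per subject required")
        rows = []
        for ts in series:
            vec, _ = vectorize_edges(correlation_matrix(ts))
            if fisher_z:
                vec = np.arctanh(np.clip(vec, -1 + 1e-12, 1 - 1e-12))
            rows.append(vec)
        return cls(
            np.vstack(rows),
            labels=np.asarray(labels, int),
            n_roi=series[0].n_roi,
            subject_ids=list(subject_ids) if subject_ids else [],
            roi_names=list(series[0].roi_names),
        )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


# ---------------------------------------------------------------------------
# operations


def clean_timeseries(
    ts: ROITimeSeries,
    confounds: ConfoundSet | None = None,
    band: tuple[float, float] = (0.01, 0.1),
) -> ROITimeSeries:
    """Detrend, regress out confounds, then band-pass filter each ROI series.

    The order is fixed: (1) linear detrending, (2) least-squares
    residualization against all confound columns plus an intercept,
    (3) zero-phase band-pass filtering (second-order Butterworth applied
    forward-backward) within ``band`` Hz.

    Raises if the band lies outside (0, Nyquist).  A rank-deficient
    confound matrix is used as-is through a minimum-norm least-squares
    fit (collinear columns contribute nothing extra) with a logged warning.
    """
    low, high = band
    nyquist = 1.0 / (2.0 * ts.tr)
    if not (0.0 < low < high < nyquist):
        raise ValueError(
            f"band {band} Hz must satisfy 0 < low < high < Nyquist ({nyquist:g} Hz)"
        )
    x = _signal.detrend(ts.values, axis=0, type="linear")
    if confounds is not None and confounds.values.shape[1] > 0:
        if confounds.n_timepoints != ts.n_timepoints:
            raise ValueError("confound rows must match time-series rows")
        # keep the linear trend in the design so the projection is exact for
        # confounds that were not themselves detrended
        trend = np.linspace(-1.0, 1.0, ts.n_timepoints)
        design = np.column_stack(
            [np.ones(ts.n_timepoints), trend, confounds.values]
        )
        rank = np.linalg.matrix_rank(design)
        if rank < design.shape[1]:
            logger.warning(
                "confound matrix is rank deficient (%d/%d); collinear columns "
                "carry no additional variance",
                rank,
                design.shape[1],
            )
        beta, *_ = np.linalg.lstsq(design, x, rcond=None)
        x = x - design @ beta
    sos = _signal.butter(2, [low, high], btype="bandpass", fs=1.0 / ts.tr, output="sos")
    x = _signal.sosfiltfilt(sos, x, axis=0)
    return ROITimeSeries(np.ascontiguousarray(x), tr=ts.tr, roi_names=ts.roi_names)


def extract_roi_series(
    unit_values: np.ndarray,
    unit_to_roi: Sequence[str],
    tr: float,
    roi_order: Sequence[str] | None = None,
) -> ROITimeSeries:
    """Average unit (voxel) series into ROI series.

    Each ROI column is the unweighted mean over all units carrying its
    label; ROI order follows ``roi_order`` (the atlas order) when given,
    otherwise first appearance.  An ROI in ``roi_order`` with no units is
    an error naming that ROI.
    """
    unit_values = np.asarray(unit_values, dtype=float)
    labels = [str(u) for u in unit_to_roi]
    if unit_values.shape[1] != len(labels):
        raise ValueError("one ROI label per unit column required")
    if roi_order is None:
        roi_order = list(dict.fromkeys(labels))
    else:
        roi_order = [str(r) for r in roi_order]
        unknown = set(labels) - set(roi_order)
        if unknown:
            raise ValueError(f"unit labels not in atlas: {sorted(unknown)}")
    cols = []
    for roi in roi_order:
        members = [c for c, lab in enumerate(labels) if lab == roi]
        if not members:
            raise ValueError(f"ROI '{roi}' has no units")
        cols.append(unit_values[:, members].mean(axis=1))
    return ROITimeSeries(np.column_stack(cols), tr=tr, roi_names=list(roi_order))


def correlation_matrix(ts: ROITimeSeries) -> ConnectivityMatrix:
    """Pearson correlation between every pair of ROI series."""
    sd = ts.values.std(axis=0)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(
            f"zero-variance ROI series: {[ts.roi_names[i] for i in zero]}"
        )
    r = np.corrcoef(ts.values, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(r, roi_names=ts.roi_names)


def vectorize_edges(
    m: ConnectivityMatrix | np.ndarray,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Flatten the strict upper triangle into the canonical edge vector.

    Returns the edge vector and the edge map (list of ROI pairs, position
    ``k`` holding the pair of edge ``k``).
    """
    values = m.values if isinstance(m, ConnectivityMatrix) else np.asarray(m, float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("square matrix required")
    if np.max(np.abs(values - values.T)) > 1e-8:
        raise ValueError("matrix is asymmetric beyond tolerance 1e-8")
    iu = np.triu_indices(values.shape[0], k=1)
    return values[iu].copy(), list(zip(iu[0].tolist(), iu[1].tolist()))


def unvectorize_edges(vec: np.ndarray, n_roi: int, diagonal: float = 1.0) -> np.ndarray:
    """Rebuild the symmetric matrix from a canonical edge vector."""
    vec = np.asarray(vec, dtype=float)
    if vec.shape != (n_edges(n_roi),):
        raise ValueError(f"expected {n_edges(n_roi)} edges for n_roi={n_roi}")
    out = np.full((n_roi, n_roi), diagonal, dtype=float)
    iu = np.triu_indices(n_roi, k=1)
    out[iu] = vec
    out[(iu[1], iu[0])] = vec
    return out
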