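"""Two-group synthetic resting-state datasets with known discriminative edges.

Two generation routes share one :class:`SyntheticSpec`:

* the **time-series route** draws per-subject ROI series from group-specific
  correlation matrices in which a sparse set of planted "signal" edges
  differs between groups by ``delta``, and feeds the real connectivity
  pipeline;
* the **direct edge-table route** draws Fisher-z-scale Gaussian edge values
  and shifts the signal edges by ``effect_size_d`` standard deviations
  between groups — fast fixtures with exact ground truth.

Defaults emulate the study scale every downstream default assumes: 39
patients vs 30 controls, 90 ROIs (4005 edges), 205 timepoints at TR = 2 s,
and 5 signal edges.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .connectivity import (
    ConfoundSet,
    EdgeTable,
    ROITimeSeries,
    edge_pair_to_index,
    n_edges,
)

__all__ = [
    "SyntheticSpec",
    "make_group_covariances",
    "simulate_roi_timeseries",
    "simulate_edge_table",
    "simulate_confounds",
    "simulate_cohort_timeseries",
    "write_dataset",
]

#: between-subject SD of edge values on the Fisher-z scale (direct route)
EDGE_SD = 0.2


@dataclass
class SyntheticSpec:
    """Parameters of a simulated two-group cohort.

    ``delta`` is the planted correlation difference (group1 − group0) at
    each signal edge on the time-series route; ``effect_size_d`` is the
    standardized mean difference (Cohen's d) at each signal edge on the
    direct edge-table route.
    """

    n_roi: int = 90
    n_group0: int = 30  # controls
    n_group1: int = 39  # patients
    n_timepoints: int = 205
    tr: float = 2.0
    signal_edges: list[tuple[int, int]] | None = None
    n_signal: int = 5
    delta: float = 0.3
    effect_size_d: float = 1.5
    base_rank: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_roi", "n_group0", "n_group1", "n_timepoints", "n_signal"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.base_rank < 1:
            raise ValueError("base_rank must be >= 1")
        if self.signal_edges is None:
            self.signal_edges = self._draw_signal_edges()
        self.signal_edges = [(int(i), int(j)) for i, j in self.signal_edges]
        seen = set()
        for i, j in self.signal_edges:
            if not (0 <= i < j < self.n_roi):
                raise ValueError(f"signal edge ({i}, {j}) is not a valid pair (i<j)")
            if (i, j) in seen:
                raise ValueError(f"duplicate signal edge ({i}, {j})")
            seen.add((i, j))

    def _draw_signal_edges(self) -> list[tuple[int, int]]:
        rng = np.random.default_rng([17, self.seed])
        chosen: set[tuple[int, int]] = set()
        while len(chosen) < self.n_signal:
            i, j = sorted(rng.choice(self.n_roi, size=2, replace=False).tolist())
            chosen.add((int(i), int(j)))
        return sorted(chosen)

    @property
    def n_subjects(self) -> int:
        return self.n_group0 + self.n_group1

    @property
    def signal_edge_indices(self) -> list[int]:
        """Canonical edge indices of the planted signal edges."""
        return [edge_pair_to_index(i, j, self.n_roi) for i, j in self.signal_edges]


def _nearest_correlation(m: np.ndarray, eig_floor: float = 1e-6) -> np.ndarray:
    """Clip eigenvalues at ``eig_floor`` and re-normalize to unit diagonal."""
    w, v = np.linalg.eigh((m + m.T) / 2.0)
    w = np.clip(w, eig_floor, None)
    s = (v * w) @ v.T
    d = np.sqrt(np.diag(s))
    s = s / np.outer(d, d)
    s = (s + s.T) / 2.0
    np.fill_diagonal(s, 1.0)
    return s


def make_group_covariances(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """Correlation matrices for the two groups with planted edge differences.

    The shared background is a low-rank factor model plus a diagonal,
    normalized to a correlation matrix.  At each signal edge ``(i, j)`` the
    groups are pushed apart symmetrically: group 0 gets ``r − delta/2`` and
    group 1 gets ``r + delta/2``.  Positive definiteness is restored by
    eigenvalue clipping followed by re-normalization, which perturbs the
    planted difference by at most ~0.02.
    """
    rng = np.random.default_rng([29, spec.seed])
    loadings = rng.normal(0.0, np.sqrt(0.3 / spec.base_rank), (spec.n_roi, spec.base_rank))
    cov = loadings @ loadings.T
    cov[np.diag_indices_from(cov)] += 0.7
    d = np.sqrt(np.diag(cov))
    base = cov / np.outer(d, d)

    g0, g1 = base.copy(), base.copy()
    for i, j in spec.signal_edges:
        r = base[i, j]
        lo, hi = r - spec.delta / 2.0, r + spec.delta / 2.0
        if max(abs(lo), abs(hi)) >= 0.999:
            raise ValueError(
                f"cannot plant delta={spec.delta} on edge ({i}, {j}): base "
                f"correlation {r:.3f} pushed outside (-1, 1)"
            )
        g0[i, j] = g0[j, i] = lo
        g1[i, j] = g1[j, i] = hi

    g0, g1 = _nearest_correlation(g0), _nearest_correlation(g1)
    diff = np.array([g1[i, j] - g0[i, j] for i, j in spec.signal_edges])
    if np.max(np.abs(diff - spec.delta)) > 0.02:
        raise ValueError(
            "positive-definite repair moved a planted difference by more than "
            "0.02; reduce delta or the background correlation level"
        )
    return g0, g1


def simulate_roi_timeseries(
    cov: np.ndarray,
    n_timepoints: int,
    tr: float,
    seed: int,
    roi_names: list[str] | None = None,
) -> ROITimeSeries:
    """Zero-mean Gaussian ROI series with the given correlation structure."""
    cov = np.asarray(cov, dtype=float)
    if np.max(np.abs(cov - cov.T)) > 1e-10:
        raise ValueError("covariance must be symmetric")
    w = np.linalg.eigvalsh(cov)
    if w.min() <= 0:
        raise ValueError("covariance must be positive definite")
    chol = np.linalg.cholesky(cov)
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_timepoints, cov.shape[0])) @ chol.T
    names = roi_names or [f"ROI_{r + 1:03d}" for r in range(cov.shape[0])]
    return ROITimeSeries(x, tr=tr, roi_names=names)


def simulate_cohort_timeseries(
    spec: SyntheticSpec,
) -> tuple[list[ROITimeSeries], np.ndarray, list[str]]:
    """Per-subject ROI series for the whole cohort (controls first).

    Returns the series list, the 0/1 label vector and subject ids.
    """
    g0, g1 = make_group_covariances(spec)
    ss = np.random.SeedSequence([31, spec.seed])
    seeds = [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(spec.n_subjects)]
    names = [f"ROI_{r + 1:03d}" for r in range(spec.n_roi)]
    series, labels, ids = [], [], []
    for s in range(spec.n_subjects):
        grp = 0 if s < spec.n_group0 else 1
        cov = g0 if grp == 0 else g1
        series.append(
            simulate_roi_timeseries(cov, spec.n_timepoints, spec.tr, seeds[s], names)
        )
        labels.append(grp)
        ids.append(f"sub-{s + 1:03d}")
    return series, np.asarray(labels, int), ids


def simulate_edge_table(spec: SyntheticSpec) -> EdgeTable:
    """Direct Gaussian edge-table simulation with planted effect sizes.

    Edge values are Fisher-z-scale Gaussians with per-edge baseline means
    shared by the groups and between-subject SD :data:`EDGE_SD`.  Each
    signal edge separates the groups by ``effect_size_d`` SDs, with the
    sign alternating across signal edges (both group1>group0 and
    group1<group0 directions occur).  Ground truth lands in
    ``table.meta``.
    """
    rng = np.random.default_rng([41, spec.seed])
    m = n_edges(spec.n_roi)
    mu = rng.normal(0.2, 0.1, m)
    values = mu + rng.normal(0.0, EDGE_SD, (spec.n_subjects, m))
    labels = np.r_[np.zeros(spec.n_group0, int), np.ones(spec.n_group1, int)]
    directions = []
    for rank, k in enumerate(spec.signal_edge_indices):
        sign = 1.0 if rank % 2 == 0 else -1.0
        shift = sign * spec.effect_size_d * EDGE_SD
        values[labels == 1, k] += shift / 2.0
        values[labels == 0, k] -= shift / 2.0
        directions.append(int(sign))
    return EdgeTable(
        values,
        labels=labels,
        n_roi=spec.n_roi,
        roi_names=[f"ROI_{r + 1:03d}" for r in range(spec.n_roi)],
        meta={
            "signal_edges": [list(p) for p in spec.signal_edges],
            "signal_edge_indices": spec.signal_edge_indices,
            "signal_directions": directions,
            "effect_size_d": spec.effect_size_d,
            "seed": spec.seed,
        },
    )


def simulate_confounds(
    n_timepoints: int,
    n_motion: int = 6,
    spike_rate: float = 0.02,
    seed: int = 0,
) -> ConfoundSet:
    """Motion random walks + derivatives, CSF/WM averages and spike indicators.

    Each spike column marks exactly one scan (sums to 1); the expected spike
    count is ``spike_rate * n_timepoints``.
    """
    if n_motion < 0:
        raise ValueError("n_motion must be >= 0")
    if not 0 <= spike_rate < 1:
        raise ValueError("spike_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    cols, roles = [], []
    motion = np.cumsum(rng.normal(0.0, 0.02, (n_timepoints, n_motion)), axis=0)
    for c in range(n_motion):
        cols.append(motion[:, c])
        roles.append("motion")
    for c in range(n_motion):
        deriv = np.r_[0.0, np.diff(motion[:, c])]
        cols.append(deriv)
        roles.append("motion_derivative")
    for role in ("csf", "wm"):
        cols.append(rng.normal(0.0, 1.0, n_timepoints))
        roles.append(role)
    spike_at = np.flatnonzero(rng.random(n_timepoints) < spike_rate)
    for t in spike_at:
        ind = np.zeros(n_timepoints)
        ind[t] = 1.0
        cols.append(ind)
        roles.append("spike")
    values = np.column_stack(cols) if cols else np.empty((n_timepoints, 0))
    return ConfoundSet(values, roles=roles)


def write_dataset(spec: SyntheticSpec, out_dir: str | Path, timeseries: bool = False) -> None:
    """Write a synthetic dataset (edge table + ground truth, optionally series)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = simulate_edge_table(spec)
    table.to_csv(out / "edges.csv")
    truth = {
        "signal_edges": [list(p) for p in spec.signal_edges],
        "signal_edge_indices": spec.signal_edge_indices,
        "spec": {
            "n_roi": spec.n_roi,
            "n_group0": spec.n_group0,
            "n_group1": spec.n_group1,
            "n_timepoints": spec.n_timepoints,
            "tr": spec.tr,
            "delta": spec.delta,
            "effect_size_d": spec.effect_size_d,
            "base_rank": spec.base_rank,
        },
        "seed": spec.seed,
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    if timeseries:
        series_dir = out / "timeseries"
        series_dir.mkdir(exist_ok=True)
        series, labels, ids = simulate_cohort_timeseries(spec)
        for ts, sid in zip(series, ids):
            ts.to_tsv(series_dir / f"{sid}.tsv")
        conf_dir = out / "confounds"
        conf_dir.mkdir(exist_ok=True)
        ss = np.random.SeedSequence([43, spec.seed])
        for sid, child in zip(ids, ss.spawn(len(ids))):
            conf = simulate_confounds(
                spec.n_timepoints, seed=int(child.generate_state(1)[0] % 2**31)
            )
            conf.to_tsv(conf_dir / f"{sid}.tsv")
        import pandas as pd

        pd.DataFrame({"subject_id": ids, "label": labels}).to_csv(
            out / "participants.tsv", sep="\t", index=False
        )
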