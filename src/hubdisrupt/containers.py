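"""Core in-memory containers for the network pipeline.

All matrices are plain ``numpy`` arrays wrapped in light dataclasses that
carry region labels and enforce the structural invariants each stage relies
on (symmetry, zero diagonals, finite entries).  Regions are indexed 0-based
internally; label files carry the atlas 1-based numbering alongside the
abbreviations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

NODAL_METRIC_NAMES = ("degree", "clustering", "betweenness", "local_efficiency")

_SYM_TOL = 1e-10


def _check_labels(values: np.ndarray, labels: list[str]) -> list[str]:
    if labels is None:
        return [f"R{i + 1:03d}" for i in range(values.shape[0])]
    labels = [str(x) for x in labels]
    if len(labels) != values.shape[0]:
        raise ValueError(
            f"{len(labels)} region labels for {values.shape[0]} regions"
        )
    return labels


@dataclass
class TimeSeriesMatrix:
    """One subject's ROI signals, shaped (n_regions, n_timepoints)."""

    values: np.ndarray
    region_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time series must be a 2-D regions x time matrix")
        n_regions, n_time = self.values.shape
        if n_regions < 2:
            raise ValueError("need at least 2 regions")
        if n_time < 3:
            raise ValueError("need at least 3 time points")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains non-finite entries")
        self.region_labels = _check_labels(self.values, self.region_labels)

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


@dataclass
class ConnectivityMatrix:
    """Symmetric region x region weight matrix.

    ``kind`` tracks the processing stage: ``raw_r`` (Pearson r, unit
    diagonal), ``cleaned`` (negatives and diagonal zeroed) or ``fisher_z``
    (arctanh-transformed cleaned weights).
    """

    values: np.ndarray
    kind: str = "raw_r"
    region_labels: list[str] | None = None

    _KINDS = ("raw_r", "cleaned", "fisher_z")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in self._KINDS:
            raise ValueError(f"kind must be one of {self._KINDS}, got {self.kind!r}")
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("connectivity matrix contains non-finite entries")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("connectivity matrix must be symmetric")
        if self.kind in ("cleaned", "fisher_z"):
            if np.any(np.diag(self.values) != 0):
                raise ValueError(f"kind={self.kind} requires a zero diagonal")
            if np.any(self.values < 0):
                raise ValueError(f"kind={self.kind} requires non-negative entries")
        self.region_labels = _check_labels(self.values, self.region_labels)

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.region_labels,
                            columns=self.region_labels)


@dataclass
class BinaryNetwork:
    """Unweighted, undirected network at a given edge sparsity."""

    adjacency: np.ndarray
    sparsity: float
    region_labels: list[str] | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        if np.any(a != a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if not (0 < self.sparsity <= 1):
            raise ValueError("sparsity must lie in (0, 1]")
        self.adjacency = a.astype(np.int8)
        self.region_labels = _check_labels(self.adjacency, self.region_labels)

    @property
    def n_regions(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


@dataclass
class GlobalMetrics:
    """Whole-network scalars for one subject-network."""

    L: float                         # characteristic path length (edges)
    E_glob: float                    # global efficiency, in [0, 1]
    C: float                         # mean clustering coefficient, in [0, 1]
    n_regions: int
    connected_pair_fraction: float   # fraction of node pairs with finite distance

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"L": self.L, "E_glob": self.E_glob, "C": self.C,
              "n_regions": self.n_regions,
              "connected_pair_fraction": self.connected_pair_fraction}]
        )


@dataclass
class NodalMetrics:
    """Per-region metric vectors for one subject-network."""

    degree: np.ndarray
    clustering: np.ndarray
    betweenness: np.ndarray
    local_efficiency: np.ndarray
    region_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.degree = np.asarray(self.degree, dtype=float)
        self.clustering = np.asarray(self.clustering, dtype=float)
        self.betweenness = np.asarray(self.betweenness, dtype=float)
        self.local_efficiency = np.asarray(self.local_efficiency, dtype=float)
        n = self.degree.shape[0]
        for name in ("clustering", "betweenness", "local_efficiency"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"{name} has wrong shape")
        self.region_labels = _check_labels(self.degree[:, None], self.region_labels)

    def get(self, metric_name: str) -> np.ndarray:
        if metric_name not in NODAL_METRIC_NAMES:
            raise ValueError(
                f"unknown metric {metric_name!r}; expected one of {NODAL_METRIC_NAMES}"
            )
        return getattr(self, metric_name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"degree": self.degree, "clustering": self.clustering,
             "betweenness": self.betweenness,
             "local_efficiency": self.local_efficiency},
            index=self.region_labels,
        )
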