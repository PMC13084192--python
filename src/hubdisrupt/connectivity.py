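"""From one subject's ROI time series to a sparsity-thresholded binary network.

The stages are applied in a fixed order: Pearson correlation between every
pair of regional BOLD signals, removal of negative weights and
self-connections (negative functional connectivity has no agreed biological
reading, so it is discarded rather than modeled), a Fisher r-to-z transform
to normalise the weight distribution, and binarisation by sparsity: the
strongest fraction ``s`` of possible connections becomes edges, so every
subject's network has exactly the same edge count.

Binarisation is invariant to any strictly monotone reweighting, so thresholding
raw r or Fisher-z weights gives the same network; the pipeline thresholds z
weights and the invariance is covered by tests.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import BinaryNetwork, ConnectivityMatrix, TimeSeriesMatrix

log = logging.getLogger(__name__)

# arctanh diverges at r = 1; duplicate ROIs (exact copies) are clipped here.
FISHER_CLIP = 1.0 - 1e-7


def pearson_connectivity(ts: TimeSeriesMatrix) -> ConnectivityMatrix:
    """Pairwise Pearson correlation of regional time series.

    Returns a ``raw_r`` connectivity matrix: symmetric with unit diagonal.
    A region with zero variance has no defined correlation and is an error.
    """
    sd = ts.values.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(
            f"region(s) {dead.tolist()} have zero variance; "
            "Pearson correlation is undefined"
        )
    r = np.corrcoef(ts.values)
    # corrcoef can stray by ~1e-16 outside [-1, 1]
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(r, kind="raw_r", region_labels=ts.region_labels)


def clean_matrix(w: ConnectivityMatrix) -> ConnectivityMatrix:
    """Zero out negative weights and the diagonal; keep positive weights as-is.

    Idempotent: cleaning a cleaned matrix changes nothing.
    """
    if w.kind not in ("raw_r", "cleaned"):
        raise ValueError(f"clean_matrix expects kind raw_r, got {w.kind!r}")
    v = w.values.copy()
    v[v < 0] = 0.0
    np.fill_diagonal(v, 0.0)
    return ConnectivityMatrix(v, kind="cleaned", region_labels=w.region_labels)


def fisher_z(w: ConnectivityMatrix) -> ConnectivityMatrix:
    """Entry-wise Fisher transform z = arctanh(r) of a cleaned matrix.

    Zeros map to zeros and the transform is strictly increasing on (0, 1),
    so edge rankings are preserved.  Entries at or above the clip bound
    (exact unit correlations from duplicated signals) are clipped, not
    rejected, and a warning is logged.
    """
    if w.kind != "cleaned":
        raise ValueError(f"fisher_z expects kind cleaned, got {w.kind!r}")
    v = w.values
    n_clipped = int(np.count_nonzero(v >= FISHER_CLIP))
    if n_clipped:
        log.warning("fisher_z: clipped %d entries at r >= %g", n_clipped, FISHER_CLIP)
    z = np.arctanh(np.minimum(v, FISHER_CLIP))
    return ConnectivityMatrix(z, kind="fisher_z", region_labels=w.region_labels)


def binarize_by_sparsity(w: ConnectivityMatrix, s: float) -> BinaryNetwork:
    """Keep the K = floor(s * N(N-1)/2) strongest connections as edges.

    Flooring never exceeds the requested retained fraction.  Ties at the
    K-th weight are broken deterministically by (descending weight,
    ascending row, ascending column) so repeated runs are bit-identical.
    """
    if not (0 < s <= 1):
        raise ValueError(f"sparsity must lie in (0, 1], got {s}")
    n = w.n_regions
    rows, cols = np.triu_indices(n, k=1)
    weights = w.values[rows, cols]
    k = math.floor(s * n * (n - 1) / 2)
    adj = np.zeros((n, n), dtype=np.int8)
    if k > 0:
        # primary key last in lexsort: descending weight, then row, then col
        order = np.lexsort((cols, rows, -weights))[:k]
        adj[rows[order], cols[order]] = 1
        adj |= adj.T
    return BinaryNetwork(adj, sparsity=s, region_labels=w.region_labels)


def network_from_timeseries(ts: TimeSeriesMatrix, s: float) -> BinaryNetwork:
    """Full per-subject chain: correlate, clean, Fisher-z, binarize."""
    return binarize_by_sparsity(fisher_z(clean_matrix(pearson_connectivity(ts))), s)


# ---------------------------------------------------------------------------
# file I/O

def read_timeseries(
    path: str | Path,
    region_labels: list[str] | None = None,
    orientation: str = "auto",
    sep: str = "\t",
) -> TimeSeriesMatrix:
    """Read a delimited regions x time table (no header by default).

    ``orientation`` is ``"regions_rows"``, ``"regions_cols"`` or ``"auto"``.
    Auto-detection matches the row/column count against the label list when
    one is given; otherwise the smaller dimension is taken as regions (an
    fMRI session retains far more time points than atlas parcels).
    """
    df = pd.read_csv(path, sep=sep, header=None)
    if df.iloc[0].apply(lambda x: isinstance(x, str)).all():
        # header row of region abbreviations => columns are regions
        df = pd.read_csv(path, sep=sep)
        values = df.to_numpy(dtype=float).T
        labels = region_labels if region_labels is not None else list(df.columns)
        return TimeSeriesMatrix(values, labels)
    values = df.to_numpy(dtype=float)
    if orientation == "auto":
        if region_labels is not None:
            if values.shape[0] == len(region_labels):
                pass
            elif values.shape[1] == len(region_labels):
                values = values.T
            else:
                raise ValueError(
                    f"{path}: neither dimension {values.shape} matches "
                    f"{len(region_labels)} region labels"
                )
        elif values.shape[1] < values.shape[0]:
            values = values.T
    elif orientation == "regions_cols":
        values = values.T
    elif orientation != "regions_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    return TimeSeriesMatrix(values, region_labels)


def write_matrix_tsv(w: ConnectivityMatrix, path: str | Path) -> None:
    """Write a connectivity matrix as TSV with a region-label header."""
    w.to_frame().to_csv(path, sep="\t", float_format="%.10g")


def write_edge_list(net: BinaryNetwork, path: str | Path) -> None:
    """Export adjacency as a three-column edge list (region_a, region_b, 1)."""
    rows, cols = np.triu_indices(net.n_regions, k=1)
    keep = net.adjacency[rows, cols] == 1
    labels = net.region_labels
    with open(path, "w") as fh:
        for i, j in zip(rows[keep], cols[keep]):
            fh.write(f"{labels[i]}\t{labels[j]}\t1\n")
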