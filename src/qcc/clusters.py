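"""Threshold-based cluster calling and cluster-level concordance.

A cluster (peak) is a maximal run of at least ``min_run`` consecutive
probes whose values lie strictly above an empirical quantile threshold —
a deliberately simple caller, so that the comparison of probe-level and
cluster-level reproducibility is not confounded by peak-caller behavior.
Cluster-level concordance between two replicates is the Pearson
correlation of their 0/1 cluster-membership vectors (the phi coefficient
of the 2x2 probe overlap table), scanned over a grid of quantile
thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .corestats import PairedReplicates
from .exceptions import DataError, ParameterError, UndefinedCorrelationError

__all__ = [
    "ClusterCallConfig",
    "ConcordanceCurve",
    "call_clusters",
    "binary_concordance",
    "concordance_curve",
    "DEFAULT_THRESHOLD_GRID",
]

#: default quantile grid scanned by :func:`concordance_curve`
DEFAULT_THRESHOLD_GRID = np.round(np.arange(0.80, 0.9951, 0.005), 4)


@dataclass(frozen=True)
class ClusterCallConfig:
    """Quantile threshold and minimum run length for cluster calling.

    ``min_run=4`` consecutive probes corresponds to roughly 150 bp at the
    50-bp median probe spacing of the arrays this models.
    """

    quantile_threshold: float
    min_run: int = 4

    def __post_init__(self) -> None:
        if not 0.0 < self.quantile_threshold < 1.0:
            raise ParameterError(
                f"quantile_threshold must lie in (0, 1), got {self.quantile_threshold}"
            )
        if self.min_run < 1:
            raise ParameterError(f"min_run must be >= 1, got {self.min_run}")


@dataclass(frozen=True)
class ConcordanceCurve:
    """Cluster-level concordance as a function of the quantile threshold.

    ``correlations`` holds NaN where the concordance is undefined (no
    clusters called in a replicate); ``defined`` flags the valid entries.
    ``max_correlation`` is the maximum over defined entries and
    ``argmax_threshold`` the threshold attaining it.
    """

    thresholds: np.ndarray
    correlations: np.ndarray
    defined: np.ndarray
    max_correlation: float
    argmax_threshold: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "concordance": self.correlations,
                "defined": self.defined,
            }
        )


def _runs(high: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as 0-based half-open (start, end) pairs."""
    edges = np.flatnonzero(np.diff(np.concatenate(([0], high.view(np.int8), [0]))))
    return list(zip(edges[::2].tolist(), edges[1::2].tolist()))


def call_clusters(
    values: np.ndarray, config: ClusterCallConfig
) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Call clusters on one probe track given in genomic order.

    Probes strictly above the empirical ``quantile_threshold`` quantile
    (linear-interpolation definition) are "high"; maximal runs of at
    least ``min_run`` consecutive high probes become clusters.  Returns
    the cluster intervals as 0-based half-open probe-index pairs and the
    boolean membership mask marking exactly the probes inside called
    clusters.  Strict comparison means constant data yield no clusters.
    The track must be a single contiguous probe vector: split by
    chromosome upstream so runs never span chromosomes.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise DataError("cannot call clusters on an empty track")
    if values.size < config.min_run:
        raise DataError(
            f"track has {values.size} probes, fewer than min_run={config.min_run}"
        )
    threshold = float(np.quantile(values, config.quantile_threshold))
    high = values > threshold
    intervals = [
        (s, e) for s, e in _runs(high) if e - s >= config.min_run
    ]
    mask = np.zeros(values.size, dtype=bool)
    for s, e in intervals:
        mask[s:e] = True
    return intervals, mask


def binary_concordance(mask_x: np.ndarray, mask_y: np.ndarray) -> float:
    """Pearson correlation of two 0/1 cluster-membership vectors.

    Computed as the phi coefficient of the 2x2 overlap table

        phi = (n11*n00 - n10*n01) / sqrt(n1. * n0. * n.1 * n.0)

    which equals the Pearson correlation of the binary vectors.

    Raises
    ------
    UndefinedCorrelationError
        If either mask is constant (all zeros or all ones).
    """
    mx = np.asarray(mask_x, dtype=bool)
    my = np.asarray(mask_y, dtype=bool)
    if mx.shape != my.shape or mx.ndim != 1:
        raise DataError("masks must be one-dimensional and equal-length")
    n = mx.size
    n11 = int(np.count_nonzero(mx & my))
    n10 = int(np.count_nonzero(mx & ~my))
    n01 = int(np.count_nonzero(~mx & my))
    n00 = n - n11 - n10 - n01
    r1, r0 = n11 + n10, n01 + n00
    c1, c0 = n11 + n01, n10 + n00
    if r1 == 0 or r0 == 0 or c1 == 0 or c0 == 0:
        raise UndefinedCorrelationError(
            "cluster concordance undefined: a membership mask is constant"
        )
    return (n11 * n00 - n10 * n01) / math.sqrt(float(r1 * r0) * float(c1 * c0))


def concordance_curve(
    pair: PairedReplicates,
    threshold_grid: np.ndarray | None = None,
    min_run: int = 4,
) -> ConcordanceCurve:
    """Cluster-level concordance of a replicate pair across thresholds.

    At each quantile threshold, clusters are called independently in each
    replicate and the binary concordance of the two membership masks is
    recorded.  Thresholds where either replicate yields no clusters are
    flagged undefined and excluded from the maximum.
    """
    grid = DEFAULT_THRESHOLD_GRID if threshold_grid is None else np.asarray(
        threshold_grid, dtype=np.float64
    )
    if grid.size == 0 or np.any(grid <= 0.0) or np.any(grid >= 1.0):
        raise ParameterError("threshold grid must be non-empty and inside (0, 1)")
    correlations = np.full(grid.size, np.nan)
    for i, q in enumerate(grid):
        cfg = ClusterCallConfig(quantile_threshold=float(q), min_run=min_run)
        _, mask_x = call_clusters(pair.values_x, cfg)
        _, mask_y = call_clusters(pair.values_y, cfg)
        try:
            correlations[i] = binary_concordance(mask_x, mask_y)
        except UndefinedCorrelationError:
            pass  # flagged as undefined (NaN), not silently dropped
    defined = np.isfinite(correlations)
    if not defined.any():
        raise UndefinedCorrelationError(
            "cluster concordance undefined at every threshold in the grid"
        )
    imax = int(np.nanargmax(correlations))
    return ConcordanceCurve(
        thresholds=grid,
        correlations=correlations,
        defined=defined,
        max_correlation=float(correlations[imax]),
        argmax_threshold=float(grid[imax]),
    )
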