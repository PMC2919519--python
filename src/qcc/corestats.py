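"""Correlation statistics for replicate probe tracks.

Implements the standard Pearson and Spearman correlation coefficients and
the quantized correlation coefficient (QCC).  QCC discretizes each
replicate into ``B0`` equal-count quantile bins and then greedily merges
adjacent bins — the same bin-index pair in *both* replicates — whenever
the merge increases the Pearson correlation of the bin labels.  Because
background probes on a two-color tiling array are numerous and scatter
symmetrically around zero, the greedy loop collapses them into one large
bin, removing most of their contribution to the statistic; the result is
far less sensitive to the fraction of probes carrying signal than the raw
Pearson or Spearman coefficients.

The merging loop never rescans the probe vectors: it maintains the joint
B x B contingency table of bin labels and evaluates every candidate merge
from integer suffix sums of that table.  All covariance and variance
terms are exact integers, so results are deterministic and exactly
symmetric under swapping the two replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.stats

from .exceptions import DataError, ParameterError, QCCError, UndefinedCorrelationError

__all__ = [
    "PairedReplicates",
    "QuantizationState",
    "QCCResult",
    "pearson_correlation",
    "spearman_correlation",
    "quantize_equal_count",
    "joint_contingency",
    "pearson_from_contingency",
    "initial_quantization",
    "evaluate_merge_candidates",
    "qcc",
    "analytic_expected_pcc",
]

#: absolute improvement below this counts as "no longer improves", and
#: candidates within this of the best are tied (lowest index wins).
IMPROVEMENT_TOL = 1e-12


@dataclass(frozen=True)
class PairedReplicates:
    """Two aligned, equal-length probe-signal vectors.

    Parameters
    ----------
    values_x, values_y
        Probe signals (e.g. log-ratios) of replicate 1 and replicate 2,
        in the same probe order.  Must be finite and of equal length
        ``n >= 2``; pairing and filtering of missing probes happens
        upstream in :mod:`qcc.tracks_io`.
    probe_keys
        Optional ordered probe identifiers (coordinates or IDs) carried
        through from I/O, one per probe.
    """

    values_x: np.ndarray
    values_y: np.ndarray
    probe_keys: Sequence | None = None

    def __post_init__(self) -> None:
        x = np.ascontiguousarray(self.values_x, dtype=np.float64)
        y = np.ascontiguousarray(self.values_y, dtype=np.float64)
        if x.ndim != 1 or y.ndim != 1:
            raise DataError("replicate value vectors must be one-dimensional")
        if x.size != y.size:
            raise DataError(
                f"replicates differ in length: {x.size} vs {y.size}"
            )
        if x.size < 2:
            raise DataError("need at least two paired probes")
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise DataError("replicate values must be finite (filter upstream)")
        if self.probe_keys is not None and len(self.probe_keys) != x.size:
            raise DataError("probe_keys length must match the value vectors")
        object.__setattr__(self, "values_x", x)
        object.__setattr__(self, "values_y", y)

    @property
    def n(self) -> int:
        """Number of paired probes."""
        return self.values_x.size

    def swapped(self) -> "PairedReplicates":
        """The same pair with the two replicates exchanged."""
        return PairedReplicates(self.values_y, self.values_x, self.probe_keys)


@dataclass
class QuantizationState:
    """Bin structure shared by both replicates during quantize-and-merge.

    ``boundaries_x``/``boundaries_y`` are the rank cut positions: bin ``k``
    (1-based) holds the probes whose ranks fall in
    ``(boundaries[k-1], boundaries[k]]``.  Under joint merging the two
    boundary lists evolve identically; both are kept so each replicate's
    bin structure is explicit.
    """

    B: int
    initial_bins_B0: int
    boundaries_x: list[int]
    boundaries_y: list[int]
    labels_x: np.ndarray
    labels_y: np.ndarray
    joint_counts: np.ndarray
    current_pcc: float

    @property
    def n(self) -> int:
        return int(self.joint_counts.sum())


@dataclass(frozen=True)
class QCCResult:
    """Outcome of the quantize-and-merge procedure.

    ``merge_trace`` records each accepted merge as ``(bin index k,
    correlation after merging bins k and k+1)``; its correlations are
    strictly increasing.  ``qcc`` equals the last trace entry, or
    ``initial_pcc_quantized`` when no merge improved the correlation.
    """

    qcc: float
    initial_pcc_quantized: float
    merge_trace: list[tuple[int, float]]
    final_state: QuantizationState
    raw_pcc: float
    spearman: float
    n_probes: int
    initial_bins: int


# ---------------------------------------------------------------------------
# plain correlations
# ---------------------------------------------------------------------------


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    vx = float(xc @ xc)
    vy = float(yc @ yc)
    if vx <= 0.0 or vy <= 0.0:
        raise UndefinedCorrelationError(
            "Pearson correlation undefined: an input vector is constant"
        )
    return float(np.clip((xc @ yc) / math.sqrt(vx * vy), -1.0, 1.0))


def pearson_correlation(pair: PairedReplicates) -> float:
    """Sample Pearson correlation of the two replicates.

    Raises
    ------
    UndefinedCorrelationError
        If either vector is constant.
    """
    return _pearson(pair.values_x, pair.values_y)


def spearman_correlation(pair: PairedReplicates) -> float:
    """Spearman correlation: Pearson applied to average ranks.

    Ties receive average (midrank) ranks, the standard convention.
    Invariant under strictly increasing transforms of either input.
    """
    rx = scipy.stats.rankdata(pair.values_x, method="average")
    ry = scipy.stats.rankdata(pair.values_y, method="average")
    return _pearson(rx, ry)


# ---------------------------------------------------------------------------
# quantization and the contingency table
# ---------------------------------------------------------------------------


def _rank_cuts(n: int, n_bins: int) -> np.ndarray:
    """Cut positions: bin k spans ranks (cuts[k-1], cuts[k]], cuts[k] = ceil(k*n/B)."""
    k = np.arange(n_bins + 1, dtype=np.int64)
    return (k * n + n_bins - 1) // n_bins


def quantize_equal_count(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Assign each value an equal-count quantile bin label in ``1..n_bins``.

    Bin 1 holds the smallest values.  Bin sizes differ by at most one
    probe when ``n_bins`` does not divide ``n`` (bin ``k`` spans ranks
    ``(ceil((k-1)*n/B), ceil(k*n/B)]``).  Ties are broken by stable input
    order, so tied values straddling a cut are split deterministically;
    this guarantees the equal-size property on data with ties, which
    tiling arrays routinely produce.
    """
    values = np.asarray(values, dtype=np.float64)
    n = values.size
    if n_bins < 2:
        raise ParameterError(f"n_bins must be >= 2, got {n_bins}")
    if n_bins > n:
        raise ParameterError(f"n_bins={n_bins} exceeds the number of probes n={n}")
    order = np.argsort(values, kind="stable")
    cuts = _rank_cuts(n, n_bins)
    # rank j (1-based) -> smallest k with cuts[k] >= j
    label_of_rank = np.searchsorted(cuts, np.arange(1, n + 1), side="left")
    labels = np.empty(n, dtype=np.int64)
    labels[order] = label_of_rank
    return labels


def joint_contingency(
    labels_x: np.ndarray, labels_y: np.ndarray, B: int
) -> np.ndarray:
    """B x B table with entry (a, b) = #{i : labels_x[i]=a, labels_y[i]=b}."""
    lx = np.asarray(labels_x, dtype=np.int64)
    ly = np.asarray(labels_y, dtype=np.int64)
    if lx.shape != ly.shape or lx.ndim != 1:
        raise DataError("label vectors must be one-dimensional and equal-length")
    for name, l in (("labels_x", lx), ("labels_y", ly)):
        if l.size and (l.min() < 1 or l.max() > B):
            raise DataError(f"{name} contains labels outside 1..{B}")
    flat = (lx - 1) * B + (ly - 1)
    return np.bincount(flat, minlength=B * B).reshape(B, B)


def _table_moments(table: np.ndarray) -> tuple[int, int, int, int, int, int]:
    """Exact integer moments (n, Sx, Sy, Sxx, Syy, Sxy) of the label pair."""
    B = table.shape[0]
    v = np.arange(1, B + 1, dtype=np.int64)
    r = table.sum(axis=1)
    c = table.sum(axis=0)
    n = int(table.sum())
    sx = int(v @ r)
    sy = int(v @ c)
    sxx = int((v * v) @ r)
    syy = int((v * v) @ c)
    sxy = int(v @ table @ v)
    return n, sx, sy, sxx, syy, sxy


def _corr_from_moments(n, sx, sy, sxx, syy, sxy) -> float:
    cov = n * sxy - sx * sy
    vx = n * sxx - sx * sx
    vy = n * syy - sy * sy
    if vx <= 0 or vy <= 0:
        raise UndefinedCorrelationError(
            "correlation undefined: a margin has zero variance"
        )
    return float(cov) / math.sqrt(float(vx) * float(vy))


def pearson_from_contingency(table: np.ndarray) -> float:
    """Pearson correlation of the integer label vectors summarized by ``table``.

    Exactly equals :func:`pearson_correlation` applied to the expanded
    label vectors, at a cost independent of ``n``.  All moments are exact
    integers.

    Raises
    ------
    UndefinedCorrelationError
        If either marginal is concentrated in a single bin.
    """
    table = np.asarray(table, dtype=np.int64)
    if table.ndim != 2 or table.shape[0] != table.shape[1]:
        raise DataError("contingency table must be square")
    if table.sum() < 2:
        raise DataError("contingency table must hold at least two observations")
    return _corr_from_moments(*_table_moments(table))


def initial_quantization(
    pair: PairedReplicates, initial_bins: int
) -> QuantizationState:
    """Quantize both replicates into ``initial_bins`` equal-count bins."""
    if not (2 <= initial_bins <= pair.n):
        raise ParameterError(
            f"initial_bins must satisfy 2 <= B0 <= n={pair.n}, got {initial_bins}"
        )
    lx = quantize_equal_count(pair.values_x, initial_bins)
    ly = quantize_equal_count(pair.values_y, initial_bins)
    table = joint_contingency(lx, ly, initial_bins)
    cuts = _rank_cuts(pair.n, initial_bins).tolist()
    return QuantizationState(
        B=initial_bins,
        initial_bins_B0=initial_bins,
        boundaries_x=list(cuts),
        boundaries_y=list(cuts),
        labels_x=lx,
        labels_y=ly,
        joint_counts=table,
        current_pcc=pearson_from_contingency(table),
    )


# ---------------------------------------------------------------------------
# merge candidates
# ---------------------------------------------------------------------------


def _candidate_correlations(table: np.ndarray) -> np.ndarray:
    """Correlation after merging bins (k, k+1), for every k in 1..B-1.

    Vectorized over candidates via integer suffix sums: merging bins k and
    k+1 relabels every bin above k down by one, so each moment of the
    merged configuration is the original moment minus a suffix sum.
    Returns an array of length B-1 (index k-1 = candidate k); entries are
    NaN where the merged configuration has zero variance on a margin.
    """
    table = np.asarray(table, dtype=np.int64)
    B = table.shape[0]
    v = np.arange(1, B + 1, dtype=np.int64)
    r = table.sum(axis=1)
    c = table.sum(axis=0)
    n, sx, sy, sxx, syy, sxy = _table_moments(table)

    def suffix(a: np.ndarray) -> np.ndarray:
        return np.cumsum(a[::-1])[::-1]

    # candidate k decrements the label of every row/column with 0-index >= k
    tr = suffix(r)[1:]                    # sum of row counts over bins > k
    tc = suffix(c)[1:]
    ur = suffix(v * r)[1:]                # label-weighted row suffix
    uc = suffix(v * c)[1:]
    p = suffix(table @ v)[1:]             # sum_{a>k, b} v_b N_ab
    q = suffix(v @ table)[1:]             # sum_{a, b>k} v_a N_ab
    w2 = table[::-1, ::-1].cumsum(axis=0).cumsum(axis=1)[::-1, ::-1]
    w = np.diagonal(w2)[1:].copy()        # sum_{a>k, b>k} N_ab

    sx_k = sx - tr
    sy_k = sy - tc
    sxx_k = sxx - 2 * ur + tr
    syy_k = syy - 2 * uc + tc
    sxy_k = sxy - p - q + w

    cov = n * sxy_k - sx_k * sy_k
    vx = n * sxx_k - sx_k * sx_k
    vy = n * syy_k - sy_k * sy_k
    valid = (vx > 0) & (vy > 0)
    out = np.full(B - 1, np.nan)
    np.divide(
        cov.astype(np.float64),
        np.sqrt(vx.astype(np.float64) * vy.astype(np.float64)),
        out=out,
        where=valid,
    )
    return out


def evaluate_merge_candidates(
    state: QuantizationState,
) -> list[tuple[int, float]]:
    """All B-1 candidate merges of state and the correlation each yields.

    Candidate ``k`` merges bins ``k`` and ``k+1`` in *both* replicates.
    Returns ``(k, correlation)`` pairs; a candidate whose merged
    configuration is constant on either margin carries NaN (invalid).
    With fewer than three bins there are no candidates (merging from two
    bins would leave a constant vector) and the list is empty.
    """
    if state.B < 3:
        return []
    corr = _candidate_correlations(state.joint_counts)
    return [(k + 1, float(corr[k])) for k in range(state.B - 1)]


def _merge_table(table: np.ndarray, k: int) -> np.ndarray:
    """Contingency table after merging bins k and k+1 (1-based) on both axes."""
    i = k - 1
    t = table.copy()
    t[i] += t[i + 1]
    t = np.delete(t, i + 1, axis=0)
    t[:, i] += t[:, i + 1]
    return np.delete(t, i + 1, axis=1)


def _select_candidate(corr: np.ndarray, current: float) -> int | None:
    """Index (1-based) of the accepted merge, or None to stop.

    The best candidate must exceed the current correlation by more than
    ``IMPROVEMENT_TOL``; candidates within ``IMPROVEMENT_TOL`` of the best
    are tied and the lowest bin index wins.
    """
    if np.all(np.isnan(corr)):
        return None
    best = float(np.nanmax(corr))
    if best <= current + IMPROVEMENT_TOL:
        return None
    tied = np.flatnonzero(~np.isnan(corr) & (corr >= best - IMPROVEMENT_TOL))
    return int(tied[0]) + 1


def qcc(pair: PairedReplicates, initial_bins: int = 100) -> QCCResult:
    """Quantized correlation coefficient of two replicate tracks.

    Both replicates are quantized into ``initial_bins`` equal-count bins;
    then, repeatedly, the single adjacent-bin merge (applied to the same
    bin indices in both replicates) that most improves the Pearson
    correlation of the bin labels is accepted, until no candidate strictly
    improves it or only two bins remain.  ``initial_bins=100`` is
    sufficient for stability except at very high SNR with very low
    coverage, where it can be raised.

    Returns a :class:`QCCResult` carrying the statistic, the full merge
    trace, the final bin structure, and the raw Pearson and Spearman
    coefficients of the same pair for comparison.
    """
    state = initial_quantization(pair, initial_bins)
    initial_pcc = state.current_pcc
    raw_pcc = pearson_correlation(pair)
    spearman = spearman_correlation(pair)

    table = state.joint_counts
    cuts = list(state.boundaries_x)
    merge_map = np.arange(1, initial_bins + 1, dtype=np.int64)
    current = initial_pcc
    B = initial_bins
    trace: list[tuple[int, float]] = []
    evaluations = 0
    eval_cap = initial_bins * (initial_bins - 1) // 2

    while B >= 3:
        corr = _candidate_correlations(table)
        evaluations += B - 1
        if evaluations > eval_cap:  # pragma: no cover - termination guard
            raise QCCError(
                "merge loop exceeded the B0(B0-1)/2 candidate-evaluation bound"
            )
        k = _select_candidate(corr, current)
        if k is None:
            break
        table = _merge_table(table, k)
        current = float(corr[k - 1])
        trace.append((k, current))
        merge_map[merge_map > k] -= 1
        del cuts[k]
        B -= 1

    final_state = QuantizationState(
        B=B,
        initial_bins_B0=initial_bins,
        boundaries_x=list(cuts),
        boundaries_y=list(cuts),
        labels_x=merge_map[state.labels_x - 1],
        labels_y=merge_map[state.labels_y - 1],
        joint_counts=table,
        current_pcc=current,
    )
    return QCCResult(
        qcc=current,
        initial_pcc_quantized=initial_pcc,
        merge_trace=trace,
        final_state=final_state,
        raw_pcc=raw_pcc,
        spearman=spearman,
        n_probes=pair.n,
        initial_bins=initial_bins,
    )


# ---------------------------------------------------------------------------
# closed-form oracle for the simulation model
# ---------------------------------------------------------------------------


def analytic_expected_pcc(coverage: float, snr: float, noise_sd: float = 1.0) -> float:
    """Population Pearson correlation of the two-group simulation model.

    A fraction ``coverage`` of probes has underlying mean ``snr * noise_sd``
    in both replicates, the rest mean zero, and each replicate adds
    independent Gaussian noise of s.d. ``noise_sd``.  The between-probe
    variance of the shared mean is ``p(1-p)(S*sigma)^2``, so

        rho = p(1-p) S^2 / (p(1-p) S^2 + 1),

    independent of ``sigma`` because the SNR is expressed in noise-s.d.
    units.  Zero at ``p = 0`` or ``p = 1`` (no between-probe signal
    variance).
    """
    if not 0.0 <= coverage <= 1.0:
        raise ParameterError(f"coverage must lie in [0, 1], got {coverage}")
    if snr < 0.0:
        raise ParameterError(f"snr must be >= 0, got {snr}")
    if noise_sd <= 0.0:
        raise ParameterError(f"noise_sd must be > 0, got {noise_sd}")
    mu = snr * noise_sd
    signal_var = coverage * (1.0 - coverage) * mu * mu
    return signal_var / (signal_var + noise_sd * noise_sd)
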