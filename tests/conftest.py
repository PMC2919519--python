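"""Shared fixtures and independent reference implementations.

The reference implementations here deliberately avoid the package's fast
code paths: quantization assigns labels by looping over sorted blocks,
contingency tables are counted with nested loops, and the greedy merge
reference relabels the full probe vectors and recomputes the Pearson
correlation with :func:`numpy.corrcoef` at every candidate.  They exist
to cross-check the contingency-table shortcuts, not to share code with
them.
"""

from __future__ import annotations

import math

import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


# ---------------------------------------------------------------------------
# naive references
# ---------------------------------------------------------------------------


def naive_quantize(values, n_bins):
    """Equal-count quantile labels via an explicit loop over rank blocks."""
    values = np.asarray(values, dtype=float)
    n = values.size
    order = np.argsort(values, kind="stable")
    labels = np.empty(n, dtype=int)
    for k in range(1, n_bins + 1):
        lo = math.ceil((k - 1) * n / n_bins)
        hi = math.ceil(k * n / n_bins)
        labels[order[lo:hi]] = k
    return labels


def naive_contingency(labels_x, labels_y, B):
    """O(n * B^2) nested-loop counting."""
    table = np.zeros((B, B), dtype=int)
    for a in range(1, B + 1):
        for b in range(1, B + 1):
            table[a - 1, b - 1] = int(
                np.sum((np.asarray(labels_x) == a) & (np.asarray(labels_y) == b))
            )
    return table


def expand_table(table):
    """Label vectors whose joint counts reproduce ``table``."""
    xs, ys = [], []
    B = table.shape[0]
    for a in range(B):
        for b in range(B):
            xs.extend([a + 1] * int(table[a, b]))
            ys.extend([b + 1] * int(table[a, b]))
    return np.array(xs, dtype=float), np.array(ys, dtype=float)


def naive_greedy_qcc(x, y, initial_bins, tol=1e-12):
    """Greedy quantize-and-merge that recomputes Pearson from full vectors.

    Same contract as the fast implementation (joint merges, lowest-index
    tie break, strict improvement beyond ``tol``) but every candidate
    correlation comes from ``np.corrcoef`` on relabeled n-length vectors.
    Returns (final correlation, merge trace, initial quantized Pearson).
    """
    lx = naive_quantize(x, initial_bins).astype(float)
    ly = naive_quantize(y, initial_bins).astype(float)
    current = float(np.corrcoef(lx, ly)[0, 1])
    initial = current
    trace = []
    B = initial_bins
    while B >= 3:
        cands = np.full(B - 1, np.nan)
        for k in range(1, B):
            nlx = np.where(lx > k, lx - 1, lx)
            nly = np.where(ly > k, ly - 1, ly)
            if nlx.std() == 0 or nly.std() == 0:
                continue
            cands[k - 1] = np.corrcoef(nlx, nly)[0, 1]
        if np.all(np.isnan(cands)):
            break
        best = float(np.nanmax(cands))
        if best <= current + tol:
            break
        k = int(np.flatnonzero(~np.isnan(cands) & (cands >= best - tol))[0]) + 1
        lx = np.where(lx > k, lx - 1, lx)
        ly = np.where(ly > k, ly - 1, ly)
        current = float(cands[k - 1])
        trace.append((k, current))
        B -= 1
    return current, trace, initial


def random_pair(rng, n, rho=0.5):
    """A correlated Gaussian pair for randomized cross-checks."""
    x = rng.normal(size=n)
    y = rho * x + math.sqrt(1 - rho**2) * rng.normal(size=n)
    return x, y
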