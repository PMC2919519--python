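"""Synthetic ChIP-chip replicate generation and parameter sweeps.

The simulator emulates a two-color tiling-array experiment in its two
governing parameters: signal coverage (the fraction of probes at truly
bound positions) and the signal-to-noise ratio (the bound probes' mean
enrichment in units of the noise standard deviation).  The same probes
carry signal in both replicates — the replicates measure the same
underlying binding — and each replicate adds its own independent Gaussian
noise to every probe.  A clustered variant places the signal in
fixed-width runs of consecutive probes so that peak calling has a ground
truth.

Sweeps over coverage or over the initial bin count summarize the mean and
95% confidence interval of the Pearson, Spearman, and quantized
correlation coefficients per grid cell.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .corestats import (
    PairedReplicates,
    pearson_correlation,
    qcc,
    spearman_correlation,
)
from .exceptions import ParameterError

__all__ = [
    "SimulationConfig",
    "SweepResult",
    "simulate_replicate_pair",
    "simulate_clustered_pair",
    "coverage_sweep",
    "bin_sweep",
    "plot_sweep",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated replicate pair.

    ``n_probes`` defaults to 300,000, the scale of the NimbleGen tiling
    arrays the model emulates.  ``snr`` is the signal probes' mean in
    units of ``noise_sd``; ``coverage`` is the fraction of probes given
    that mean.  ``seed`` feeds a fresh :func:`numpy.random.default_rng`
    stream (any value accepted there, including a ``SeedSequence``).
    """

    n_probes: int = 300_000
    coverage: float = 0.05
    snr: float = 3.0
    noise_sd: float = 1.0
    seed: object = None

    def __post_init__(self) -> None:
        if self.n_probes < 2:
            raise ParameterError(f"n_probes must be >= 2, got {self.n_probes}")
        if not 0.0 <= self.coverage <= 1.0:
            raise ParameterError(f"coverage must lie in [0, 1], got {self.coverage}")
        if self.snr < 0.0:
            raise ParameterError(f"snr must be >= 0, got {self.snr}")
        if self.noise_sd <= 0.0:
            raise ParameterError(f"noise_sd must be > 0, got {self.noise_sd}")


@dataclass(frozen=True)
class SweepResult:
    """Per-cell summary of a parameter sweep.

    ``table`` holds one row per grid cell with the mean and 95% CI
    half-width (``1.96 * sd / sqrt(reps)``) of each statistic; ``params``
    records the full configuration for provenance.
    """

    table: pd.DataFrame
    reps: int
    params: dict

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def simulate_replicate_pair(
    config: SimulationConfig,
) -> tuple[PairedReplicates, np.ndarray]:
    """One replicate pair plus the boolean signal mask.

    Exactly ``floor(coverage * n_probes)`` probes receive the underlying
    mean ``snr * noise_sd`` in both replicates; every probe then gets
    independent ``N(0, noise_sd^2)`` noise per replicate.  The signal
    block occupies the first probes of the vector — placement is
    irrelevant to every statistic computed on the pair (the clustered
    simulator provides positional structure).  Seeded runs are
    bit-reproducible.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_probes
    n_signal = int(math.floor(config.coverage * n))
    mask = np.zeros(n, dtype=bool)
    mask[:n_signal] = True
    base = np.where(mask, config.snr * config.noise_sd, 0.0)
    x = base + rng.normal(0.0, config.noise_sd, size=n)
    y = base + rng.normal(0.0, config.noise_sd, size=n)
    return PairedReplicates(x, y), mask


def simulate_clustered_pair(
    n_probes: int,
    n_clusters: int,
    snr: float,
    cluster_size: int = 5,
    noise_sd: float = 1.0,
    seed: object = None,
) -> tuple[PairedReplicates, list[tuple[int, int]], np.ndarray]:
    """Replicate pair whose signal sits in fixed-width probe runs.

    ``n_clusters`` non-overlapping runs of ``cluster_size`` consecutive
    probes carry mean ``snr * noise_sd`` in both replicates; consecutive
    clusters are separated by at least one background probe.  Probe order
    represents genomic order.  Placement is uniform over the feasible
    arrangements via gap allocation (no rejection sampling).

    Returns the pair, the true cluster intervals as 0-based half-open
    ``(start, end)`` probe-index pairs, and the boolean signal mask.
    """
    if n_probes < 2:
        raise ParameterError(f"n_probes must be >= 2, got {n_probes}")
    if n_clusters < 0 or cluster_size < 1:
        raise ParameterError("n_clusters must be >= 0 and cluster_size >= 1")
    if snr < 0.0 or noise_sd <= 0.0:
        raise ParameterError("need snr >= 0 and noise_sd > 0")
    if n_clusters * (cluster_size + 1) > n_probes:
        raise ParameterError(
            f"cannot place {n_clusters} clusters of {cluster_size} probes "
            f"with >=1 probe gaps in {n_probes} probes"
        )
    rng = np.random.default_rng(seed)
    mask = np.zeros(n_probes, dtype=bool)
    intervals: list[tuple[int, int]] = []
    if n_clusters > 0:
        # distribute the free slack uniformly over the n_clusters+1 gaps;
        # interior gaps get a mandatory extra probe of separation
        free = n_probes - n_clusters * cluster_size - (n_clusters - 1)
        extra = rng.multinomial(free, np.full(n_clusters + 1, 1.0 / (n_clusters + 1)))
        pos = 0
        for i in range(n_clusters):
            pos += int(extra[i]) + (1 if i > 0 else 0)
            intervals.append((pos, pos + cluster_size))
            mask[pos : pos + cluster_size] = True
            pos += cluster_size
    base = np.where(mask, snr * noise_sd, 0.0)
    x = base + rng.normal(0.0, noise_sd, size=n_probes)
    y = base + rng.normal(0.0, noise_sd, size=n_probes)
    return PairedReplicates(x, y), intervals, mask


def _ci95(values: np.ndarray) -> float:
    if values.size < 2:
        raise ParameterError("confidence interval needs reps >= 2")
    return 1.96 * float(np.std(values, ddof=1)) / math.sqrt(values.size)


def _child_seeds(seed, count: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(count)


def coverage_sweep(
    snr_list: Sequence[float],
    coverage_grid: Sequence[float],
    reps: int = 100,
    initial_bins: int = 100,
    base_config: SimulationConfig | None = None,
    seed: object = None,
) -> SweepResult:
    """Mean +/- CI of Pearson, Spearman, and QCC over a coverage grid.

    For each ``(snr, coverage)`` cell, ``reps`` replicate pairs are
    simulated from child streams of ``seed`` (so cells are independent
    and the whole sweep is deterministic given ``seed``).
    """
    if reps < 2:
        raise ParameterError(f"reps must be >= 2, got {reps}")
    base = base_config or SimulationConfig()
    cells = [(s, c) for s in snr_list for c in coverage_grid]
    seeds = _child_seeds(seed, len(cells) * reps)
    rows = []
    for idx, (snr, coverage) in enumerate(cells):
        stats = {"pearson": [], "spearman": [], "qcc": []}
        for r in range(reps):
            cfg = dataclasses.replace(
                base, snr=snr, coverage=coverage, seed=seeds[idx * reps + r]
            )
            pair, _ = simulate_replicate_pair(cfg)
            res = qcc(pair, initial_bins=initial_bins)
            stats["pearson"].append(res.raw_pcc)
            stats["spearman"].append(res.spearman)
            stats["qcc"].append(res.qcc)
        row = {"snr": snr, "coverage": coverage, "reps": reps}
        for name, vals in stats.items():
            vals = np.asarray(vals)
            row[f"{name}_mean"] = float(vals.mean())
            row[f"{name}_ci95"] = _ci95(vals)
        rows.append(row)
    params = {
        "snr_list": list(snr_list),
        "coverage_grid": list(coverage_grid),
        "reps": reps,
        "initial_bins": initial_bins,
        "n_probes": base.n_probes,
        "noise_sd": base.noise_sd,
        "seed": repr(seed),
    }
    return SweepResult(table=pd.DataFrame(rows), reps=reps, params=params)


def bin_sweep(
    initial_bins_grid: Sequence[int],
    snr: float,
    coverage: float,
    reps: int = 100,
    base_config: SimulationConfig | None = None,
    seed: object = None,
) -> SweepResult:
    """Mean +/- CI of QCC as a function of the initial bin count.

    The same ``reps`` simulated pairs are scored at every ``B0`` in the
    grid (a paired design), so differences between bin counts are not
    confounded by simulation noise.  Deterministic given ``seed``.
    """
    if reps < 2:
        raise ParameterError(f"reps must be >= 2, got {reps}")
    grid = [int(b) for b in initial_bins_grid]
    if min(grid) < 2:
        raise ParameterError("every initial bin count must be >= 2")
    base = base_config or SimulationConfig()
    if max(grid) > base.n_probes:
        raise ParameterError(
            f"initial bins {max(grid)} exceeds n_probes={base.n_probes}"
        )
    seeds = _child_seeds(seed, reps)
    pairs = []
    for r in range(reps):
        cfg = dataclasses.replace(base, snr=snr, coverage=coverage, seed=seeds[r])
        pair, _ = simulate_replicate_pair(cfg)
        pairs.append(pair)
    rows = []
    for b0 in grid:
        vals = np.asarray([qcc(p, initial_bins=b0).qcc for p in pairs])
        rows.append(
            {
                "initial_bins": b0,
                "reps": reps,
                "qcc_mean": float(vals.mean()),
                "qcc_ci95": _ci95(vals),
            }
        )
    params = {
        "initial_bins_grid": grid,
        "snr": snr,
        "coverage": coverage,
        "reps": reps,
        "n_probes": base.n_probes,
        "noise_sd": base.noise_sd,
        "seed": repr(seed),
    }
    return SweepResult(table=pd.DataFrame(rows), reps=reps, params=params)


def plot_sweep(result: SweepResult, path, x: str | None = None) -> None:
    """Render a sweep as statistic-vs-axis curves with 95% CI error bars."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = result.table
    if x is None:
        x = "coverage" if "coverage" in table.columns else "initial_bins"
    stats = sorted(
        c[: -len("_mean")] for c in table.columns if c.endswith("_mean")
    )
    fig, ax = plt.subplots(figsize=(6, 4))
    groups = table.groupby("snr") if "snr" in table.columns else [(None, table)]
    for snr, sub in groups:
        for stat in stats:
            label = stat if snr is None else f"{stat} (SNR {snr:g})"
            ax.errorbar(
                sub[x],
                sub[f"{stat}_mean"],
                yerr=sub[f"{stat}_ci95"],
                marker="o",
                capsize=3,
                label=label,
            )
    ax.set_xlabel(x.replace("_", " "))
    ax.set_ylabel("correlation")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
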