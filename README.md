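# qcc — signal-robust reproducibility statistics for replicate tiling-array tracks

ChIP-chip experiments (chromatin immunoprecipitation hybridized to tiling
microarrays) are run in replicates, and a correlation coefficient between
the replicate probe tracks is the usual quality check. The raw Pearson
correlation is a poor yardstick for this: on two-color arrays most probes
are background log-ratios scattering around zero, and their sheer number
makes the coefficient depend on *how much* signal the experiment has, not
only on how reproducible that signal is. Two replicate pairs with the same
signal-to-noise ratio can score 0.30 or 0.59 depending solely on whether
5% or 20% of probes are bound.

This package implements the **quantized correlation coefficient (QCC)**,
a statistic designed for exactly this situation, together with the
simulation machinery and cluster-level concordance procedure used to
characterize it. It is aimed at anyone doing quality control of replicate
genome-wide array measurements — ChIP-chip first, but equally array CGH or
expression data where most of the genome is background.

## The statistic

For replicate vectors \(x_i, y_i\), \(i = 1,\dots,n\):

1. **Quantize.** Each replicate is independently binned into \(B_0\)
   equal-count quantile bins (default \(B_0 = 100\)); probe values are
   replaced by bin labels \(1,\dots,B_0\), label 1 for the smallest values.
2. **Merge.** Of the \(B-1\) ways to merge two adjacent bins (the same
   bin-index pair in both replicates), apply the one that most increases
   the Pearson correlation of the label vectors.
3. **Repeat** until no merge improves the correlation (or two bins remain).
   The maximized label correlation is the QCC.

The noisy background bins — labels shuffled between replicates — are the
ones whose merging raises the correlation, so the loop collapses the
background into one large group and the statistic focuses on the
reproducibility of the signal quantiles. Like the Spearman coefficient
(to which QCC reduces before any merge, up to binning), it depends only
on ranks and is invariant under strictly increasing transforms of either
replicate. The merge loop evaluates at most \(B_0(B_0-1)/2\) candidates,
each in \(O(B)\)–\(O(B^2)\) from the joint label contingency table, so the
cost after quantization is independent of \(n\).

Also included:

- a replicate-pair simulator with two parameters, signal coverage \(p\)
  and SNR \(S\) (signal mean in noise-s.d. units), plus a clustered
  variant with fixed-width 5-probe signal runs and a closed-form expected
  Pearson correlation \(p(1-p)S^2 / (p(1-p)S^2 + 1)\) for calibration;
- coverage and bin-count sweeps with 95% confidence intervals;
- a simple cluster caller (runs of ≥ 4 consecutive probes above a quantile
  threshold) and the phi-coefficient concordance of the resulting binary
  membership masks, scanned over a threshold grid;
- bedGraph / TSV track reading, exact coordinate- or probe-id-based
  replicate alignment, and BED export of called clusters;
- a `qcc` command-line tool (`correlate`, `simulate`, `sweep`, `clusters`).

## Worked example

```python
from qcc import SimulationConfig, simulate_replicate_pair, qcc

cfg = SimulationConfig(n_probes=300_000, coverage=0.05, snr=3.0, seed=0)
pair, _ = simulate_replicate_pair(cfg)
res = qcc(pair, initial_bins=100)
print(f"Pearson  (raw)    {res.raw_pcc:.3f}")
print(f"Spearman          {res.spearman:.3f}")
print(f"QCC               {res.qcc:.3f}")
print(f"final bins        {res.final_state.B}  (from B0={res.initial_bins}, {len(res.merge_trace)} merges)")
```

prints

```
Pearson  (raw)    0.296
Spearman          0.128
QCC               0.645
final bins        7  (from B0=100, 93 merges)
```

Two replicates at SNR 3 with 5% of 300,000 probes bound correlate at only
0.30 probe-by-probe (and 0.13 on ranks) because 285,000 background probes
dominate; after quantization and 93 greedy merges the background occupies
a single large bin and the label correlation settles at 0.645. Rerunning
the same experiment with 20% coverage (same SNR, `coverage=0.20`) moves
the raw Pearson to 0.588 — nearly double — while the QCC moves only to
0.766: the statistic tracks data quality rather than signal quantity.

The same numbers come out of the CLI on files on disk:

```sh
qcc simulate --coverage 0.05 --snr 3 --seed 0 --out-dir sim/
qcc correlate sim/replicate1.bedgraph sim/replicate2.bedgraph
```

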