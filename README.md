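# dynconn

Sliding-window dynamic functional connectivity analysis for node (ROI)
signal time-series, built around the relationship between the temporal
**mean** and **variance** of edge correlation trajectories.

## The problem

In static functional connectivity, an edge between two brain regions is
declared relevant when the correlation of their signals is large. In the
*dynamic* case — correlations estimated in a sliding window — there are two
defensible notions of relevance at a time-point:

* **magnitude-based**: the windowed correlation `r_e(t)` exceeds a global
  cutoff `c`;
* **variance-based**: `r_e(t)` exceeds that edge's own temporal mean plus
  `k` standard deviations, `r_e(t) > μ_e + k·σ_e`.

Whether these two strategies agree depends on how the per-edge mean `μ_e`
and variance `σ²_e` scale against each other across edges. Classical
mean–variance scaling (Taylor's law) would make variance grow with the
mean and the strategies redundant. For correlation time-series the
opposite holds — `ρ_Spearman(μ_e, σ²_e) < 0` — partly because a bounded
variable near its ceiling has little room to fluctuate
(`σ²_e ≤ (1 − μ_e)(1 + μ_e)` for `r ∈ [−1, 1]`). Consequently
magnitude-based selection emphasizes high-mean, low-variance
within-network edges (segregation), while variance-based selection
emphasizes low-mean, high-variance between-network edges (integration).

`dynconn` implements the full pipeline: windowed Spearman/Pearson edge
correlation (stride 1 sample, `W = T − w + 1` windows), per-edge
mean/variance summaries averaged across subjects, the rank-correlation
scaling test, both binarization strategies with overlap diagnostics, the
within/between-network variance contrast (paired two-tailed t-test), and a
synthetic cohort generator with closed-form ground truth so every stage is
testable without imaging data. Real ROI tables (TSV/CSV, one row per
node) and node-partition files are consumed directly.

## The synthetic cohort

Node `i` in network block `k` is generated as

    x_i(t) = a_k(t)·g_k(t) + b(t)·h(t) + sqrt(1 − a_k(t)² − b(t)²)·ε_i(t)

with independent unit-variance latents (optionally bandpass-filtered to
0.008–0.1 Hz), so the instantaneous correlation is exactly
`a_k(t)² + b(t)²` within block `k` and `b(t)²` between blocks. Defaults
(constant `a = 0.8`, `b(t) = 0.3 + 0.2·sin(2πt/200)`, 20 subjects, 40
nodes in 4 blocks, 240 samples at TR = 2 s) put within-block edges in the
high-mean/low-variance regime and between-block edges in the opposite one.

## Worked example

```python
from dynconn import (BlockCohortSpec, generate_cohort,
                     sliding_window_correlation, summarize_edges,
                     group_average, mean_variance_scaling, variance_contrast)

cohort = generate_cohort(BlockCohortSpec(seed=7))
summaries = [summarize_edges(sliding_window_correlation(s, 45, "spearman"))
             for s in cohort.subjects]
group = group_average(summaries)
scaling = mean_variance_scaling(group)
contrast = variance_contrast(summaries, cohort.partition)
print(f"mean-variance scaling: rho = {scaling.rho:.4f} (p = {scaling.p_value:.3g})")
print(f"within-network mean variance:  {contrast.within_mean_variance.mean():.4f}")
print(f"between-network mean variance: {contrast.between_mean_variance.mean():.4f}")
print(f"paired t = {contrast.t_statistic:.2f} (p = {contrast.p_value:.3g})")
```

prints

```
mean-variance scaling: rho = -0.5444 (p = 2.1e-61)
within-network mean variance:  0.0203
between-network mean variance: 0.0502
paired t = -21.78 (p = 6.75e-15)
```

The negative rho says high-mean edges fluctuate less; the contrast shows
between-network edges carrying roughly 2.5x the temporal variance of
within-network edges, so the two thresholding strategies select largely
disjoint sets of edge events.

The same analysis is scriptable from the shell:

```
dynconn simulate --subjects 20 --nodes 40 --blocks 4 --seed 7 --out cohort/
dynconn connect  --in cohort/ --window-seconds 90 --tr 2 --out edges/
dynconn stats    --edges edges/ --out stats/
dynconn rsn      --summaries stats/ --partition cohort/partition.tsv --out contrast.json
dynconn run      --seed 7 --out full_run/      # everything, with a manifest
dynconn sweep    --seed 7 --out sweep/         # 50/90/130 s x spearman/pearson
```

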