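# Methods

## Sliding-window edge correlation

A window of `w` samples is slid one sample at a time over the `N × T`
node-signal matrix; window `t` covers samples `[t, t + w)` and its value is
indexed by the window's first sample, giving exactly `W = T − w + 1`
windows (a window starting later would run off the series). For each
window the correlation of every unordered node pair is computed — Spearman
by default (ranks within the window segment, average ranks on ties, then
product-moment on the ranks), which is robust to outliers at the short
window lengths typical of this analysis; Pearson is available for
robustness checks. Storage is edge-major (`E × W`, upper-triangle
row-major, `i < j`): per-edge statistics are then contiguous and memory is
half the node × node × time cube; `EdgeSeries.matrix_at(t)` reconstructs
the symmetric matrix view when needed.

A window in which a node's segment is constant has no defined correlation;
such cells are stored as NaN, counted, logged, and excluded from all
downstream summaries (an edge must retain at least 2 usable windows or it
is an error). Window lengths are specified in seconds and must be an exact
multiple of the sampling interval — no silent rounding.

## Edge summaries and the scaling test

Per subject, each edge's trajectory is reduced to its arithmetic mean and
unbiased (n − 1) sample variance; the unbiased estimator is the safer
choice for the modest window counts involved, and the bounded-variable
variance bound is corrected accordingly: every output must satisfy
`σ²_e ≤ (1 − μ_e)(1 + μ_e) · n/(n − 1)` (the Bhatia–Davis bound for a
variable in [−1, 1]), which the test suite asserts on all runs.

The order of operations is: summarize per subject → average means and
variances element-wise across subjects → rank-correlate the group-level
mean vector against the variance vector once across edges. The p-value
uses the two-sided t-approximation with `E − 2` degrees of freedom,
appropriate for the large edge counts this is used at; an exact
permutation p-value (all `E!` orderings) is available for `E ≤ 9`.
Pooling subject-level points instead of averaging first is possible by
passing per-subject summaries straight to the scaling test, but the
group-average reading is the primary interface.

## Thresholding strategies

Both strategies use strict inequality, which makes the zero-variance edge
unambiguous (a constant edge is never "unusually high"). Thresholds apply
to signed correlations by default, with an absolute-value option. The
defining algebraic contrast — adding a constant to one edge's trajectory
changes its magnitude raster but leaves its variance raster bit-identical —
is asserted exactly in the tests, as is nestedness of presence sets under
rising cutoffs. The demo cutoff set {0.3, 0.2, 0.15} and `k = 1` reproduce
the qualitative worked-example pattern: the high-steady edge is present
only at its peaks at 0.3 and throughout below its minimum, the
low-fluctuating edge (range −0.2..0.2, span 0.4) is invisible to any
cutoff ≥ 0.2, and the variance strategy isolates both edges' peaks, in
anti-phase. For a pure sinusoid sampled densely over full periods the
`k = 1` exceedance fraction has the closed form 1/4 (the SD of a sinusoid
is `A/√2`, and `sin θ > 1/√2` on a quarter of the cycle), which anchors
the variance-threshold tests.

The worked-example pair itself is under-determined in its source material;
this package fixes S1 at mean 0.26 / amplitude 0.05 and S2 at mean 0 /
amplitude 0.2 in anti-phase, values chosen so the pattern above holds for
the caption cutoffs; both are configurable.

## Network contrast

Edges are classified within/between by label equality of their endpoints.
Per subject, each class's edge variances are averaged with equal weight
per edge (no per-network size normalization), and the per-subject
(within, between) pairs are compared with a **paired** two-tailed t-test —
both class means come from the same subject, making pairing the natural
design; an unpaired variant is exposed behind a flag. Two degenerate
paired cases are distinguished: identical classes in every subject (no
effect: t = 0, p = 1) and a constant nonzero difference (zero variance of
differences: flagged `degenerate`, NaN statistics, rather than an infinite
t). The variance-matrix view orders nodes by network in first-appearance
order of the partition file — deterministic without hidden sorting.

## Synthetic cohort: what it emulates and what it does not

The generator targets the *statistical* structure the pipeline is
sensitive to: block-organized nodes whose within-block correlation is high
and steady while the between-block correlation is low and slowly
fluctuating, with BOLD-like slow autocorrelation obtained by
bandpass-filtering white latents (default 0.008–0.1 Hz, second-order
Butterworth, forward-backward, re-standardized; defaults: TR = 2 s,
T = 240, 20 subjects, 40 nodes in 4 equal blocks, `a = 0.8`,
`b(t) = 0.3 + 0.2 sin(2πt/200)`). The mixture construction makes the
instantaneous correlation available in closed form, which is what the
recovery and tracking tests check against. Each subject draws from a
deterministic substream of a single seed (`SeedSequence.spawn`), so
cohorts are bit-reproducible and per-subject reproducible independent of
cohort size. Output series are re-standardized per node; correlation is
scale-free, so this affects nothing downstream while making the
unit-variance contract exact.

Not modelled: hemodynamic response convolution, head motion,
physiological noise, spatial structure, or negative between-network
coupling. Passing tests therefore demonstrate that the *estimators and
contrasts* behave correctly on data with the designed covariance
structure; they do not certify behaviour under realistic fMRI artifacts.

## Benchmark design choices

* **Designed-effect cohort** (scaling sign, network contrast): the
  defaults above. The negative scaling and the contrast direction are
  consequences of the construction — within-block edges sit near the
  correlation ceiling with small estimator noise, between-block edges sit
  low with both trajectory variance and large estimator noise — and are
  required to be sign-stable across windows of 50/90/130 s and both
  correlation coefficients.
* **Recovery benchmark** (windowed correlation vs ground truth, MAE
  ≤ 0.10): coupling dynamics much slower than the window (period 200
  samples ≥ 4w) so the window-averaged truth is meaningful; **white**
  latents, because the sampling error of a windowed correlation scales as
  `(1 − ρ²)/√(w−1)` only for serially uncorrelated samples — band-limited
  latents cut the effective sample count per 45-sample window to roughly
  `2·B·w·TR ≈ 17` and roughly double the error, which is a property of
  windowed correlation on smooth signals, not an estimator defect; and
  two equal blocks of 20 nodes, balancing high-correlation (precise) and
  low-correlation (noisy, MAE ≈ 0.12 each) edges so the benchmark probes
  both regimes. Predicted MAE under these conditions is ≈ 0.085; the
  suite asserts ≤ 0.10.
* **Problem sizes**: unit tests run on 3–12-node fixtures; cohort-level
  tests use the 40-node defaults, for which the full sweep completes in
  seconds. The 264-node bookkeeping (34 716 edges, 196 windows) is
  verified combinatorially and on a thin 3-node series of the same
  length.

## Numerical notes

* Correlations are clipped to [−1, 1] after `corrcoef` to remove
  last-ulp excursions, so range invariants hold exactly.
* Sample variances of floating-constant series can be ~1e−32 rather than
  0; thresholding uses strict inequalities so this cannot create spurious
  presences.
* File round-trips are value-exact: floats are written with 17
  significant digits and parsed with round-trip precision.
* The pipeline manifest hashes every written artifact (SHA-256) plus the
  canonical config JSON; identical config + seed reproduces identical
  hashes, which the suite asserts.
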