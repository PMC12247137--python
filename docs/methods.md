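# Methods

This note documents the models, defaults and design choices behind
`somatomode`, in the spirit of a statistical-methods appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Calcium arm

### ΔF/F0 and activation calling

Fluorescence traces are normalized per neuron as
ΔF/F0 = (F_t − F0)/F0 × 100 %, with F0 the mean over the first 60 s of the
recording. The baseline window must be stimulus-free; recordings whose
first epoch starts before 60 s are rejected rather than silently
re-windowed, because a contaminated F0 biases every downstream call. By
construction the mean ΔF/F0 over the baseline window is exactly zero
(tested to 1e-9).

The activation statistic is the **maximum** ΔF/F0 inside an epoch's
analysis window, thresholded inclusively at 20 %. A transient criterion on
a time series is conventionally its peak; a sustained-mean alternative
would interact badly with short (10-s) mechanical stimuli. Window choices:

* mechanical: onset → offset + 10 s decay margin (configurable). The decay
  margin accommodates indicator kinetics slower than the stimulus.
* chemical: onset + 60 s → onset + 11 min. The first minute after an
  injection is excluded because the mechanical act of injecting produces
  artifactual signal; the caller will therefore never score an excursion
  confined to that minute.

Percentages (overlap shares, activated fractions) are rounded
half-away-from-zero to one decimal, the convention that matches all
published-style figures this pipeline reproduces (e.g. 198/530 → 37.358 →
37.4). Unrounded overlap shares sum to 100 exactly; the rounded triple may
sum to 99.8–100.2.

The activated-fraction denominator (all detectable neurons, including
constitutively fluorescent ones that never respond) is not derivable from
response calls, so it is an explicit input (`n_detectable`).

Amplitude comparisons use Student's pooled-variance unpaired *t* test
(two-sided), with Welch's variant behind `equal_var=False`. Degenerate
zero-variance-equal-mean inputs report t = 0, p = 1.

### Synthetic recordings

The generator plants one responder class per neuron — both / only-A /
only-B / none over a pain stimulus A and an itch stimulus B — and builds
traces as `baseline × (1 + ΔF/F0_planted/100) + N(0, noise_sd)`:

* **Kernel.** Mechanical transients use a double exponential
  `exp(−t/τ_decay) − exp(−t/τ_rise)` with τ_rise = 0.2 s, τ_decay = 1.5 s,
  an adequate stand-in for slow, high-sensitivity GCaMP6s kinetics; both
  taus are config fields, since indicator kinetics are a simulator choice,
  not a measured fact. Kernels are normalized by their *sampled* maximum so
  a planted responder's noiseless peak equals its configured amplitude
  exactly.
* **Chemical responses** are a single sustained window:
  `(1 − exp(−t/30 s)) · exp(−t/240 s)` starting 90 s post injection, so the
  response peak (~156 s post injection) falls inside the analysis window
  and after the excluded minute. An optional injection-artifact spike 2 s
  after injection, applied to every neuron, exercises the exclusion rule.
* **Amplitudes** are planted per class × stimulus, with dual-responsive
  neurons given larger defaults (80/60 %) than single-sensory neurons
  (45/40 %). The multisensory amplitude advantage is planted, not emergent:
  the phenomenon is an observation about real neurons, and the generator
  only needs to reproduce it for the statistics to be testable.
* **Noise** is additive i.i.d. Gaussian on fluorescence (default sd 2 a.u.
  against baseline 100), the simplest model sufficient to stress a
  threshold criterion; shot noise, drift and motion artifacts are out of
  scope. At the default level the 20 % threshold sits 10 noise-sd above a
  silent neuron, so class recovery is exact; tests also probe sd 5 (z = 4),
  where miscalls are rare but nonzero, against binomial envelopes.
* **Defaults.** 5 Hz sampling, 640-s mechanical session with two 10-s
  stimuli 5 min apart (preventing sensitization carry-over motivates the
  spacing), 3240-s chemical session with injections ≥ 40 min apart. Frame
  rate and durations are testability choices. Default class fractions
  anchor on the mechanical-overlap field (198/293/39 responders) plus a
  non-responder pool sized so pinch activates 44.1 % of 1113 detectable
  neurons. The published per-stimulus activated fractions and the published
  overlap counts are mutually inconsistent for any single population (they
  come from different fields of view), so the generator favors the overlap
  counts; the emergent brush fraction is then 21.3 %.

Output is a pure function of the config, including its seed.

## Transcriptomic arm

### QC

Cells are retained with **> 500** detected genes and mitochondrial UMI rate
**< 20 %**, both strict, computed on the full matrix; mitochondrial genes
(`mt-` prefix, mouse convention) are then removed from the retained matrix.
A missing mito annotation degrades gracefully (warning, rate treated as 0)
rather than failing, since non-10x matrices often lack the flag.

### Positivity thresholding

Per gene, the "maximum" level is the mean of the **top three per-cell**
values; the threshold is 5 % of it; positivity is strictly greater-than.
Reading "top three" as cells (not genes) follows the cited
fraction-of-positive-cells method; the alternative literal reading is
dimensionally meaningless for a per-gene threshold. Consequences of these
choices, all tested: an all-zero gene has fraction 0; genes with fewer than
three expressing cells include zeros in the top-3 mean (no special-casing);
per-gene rescaling leaves calls unchanged (the rule is scale-invariant per
gene); raising the threshold fraction never increases any fraction.

Thresholding operates on per-cell depth-normalized linear expression
(counts per 10,000) by default. The source method's expression scale is
unstated; cp10k makes thresholds comparable across cells of different
depth, and the choice is exposed (`normalize=False` for raw counts).

Classification over {Mrgpra3, Nmb} (itch) and {Tac1, Calca} (pain) uses the
classified set — cells positive for ≥ 1 of the four markers — as the
denominator for class percentages, and all cells for per-marker fractions;
both are reported. On the 420/146/405 fixture the dual-class share computes
to 405/971 = 41.7 %; the figure this arithmetic mirrors prints 41.6 %, an
internal rounding inconsistency in the source, and this package reports the
computed value.

### Differential expression

Normalization for testing is cp10k (rank tests are invariant to the log1p
that is conventionally applied on top). SCTransform-style variance
stabilization is deliberately not reimplemented; it is a packaged method
out of scope here, and the rank-sum test depends only on within-cell depth
normalization.

The two-sided Wilcoxon rank-sum p-value is computed by **exact enumeration
of all C(n, n_a) group assignments on midranks** when both groups have ≤ 8
cells (this handles ties exactly; the usual exact distribution does not),
vectorized over genes; otherwise by the tie-corrected normal approximation.
Fold change is `log2((mean_A + 1e-9)/(mean_B + 1e-9))` on linear normalized
expression — well-defined at zero means, close to common practice. The
`passes` flag is raw `P < 0.05 AND log2FC > 0.25 AND max(pct_1, pct_2) >
0.1`; the fold-change filter is positive-only by default (the marker-style
usage), with `absolute_lfc=True` for two-sided screening.
Benjamini–Hochberg q-values are emitted as an extra column but do not
enter the flag, matching the raw-P convention of the procedure being
reproduced. Per-cluster positive markers keep only genes with log2FC > 0.1
in the cluster (only-positive); per-class condition contrasts (CCI or AEW
vs control) skip class × condition cells that do not exist, with a warning.

### Synthetic counts

Gene-wise negative binomial with per-cell lognormal library factors
(σ = 0.25), thinned by mean-dependent dropout `P(drop) = exp(−1.2 μ²)`
(sparse measurements vanish often, well-expressed ones essentially never).
Six samples — two each of control, CCI and AEW — with 400 cells each.

* **Classes and markers.** Cells are itch-only / pain-only / dual /
  marker-negative with fractions 420:146:405:271 over 1242 (the
  control-group arithmetic of the classification this emulates). Within
  marker-competent cells, per-marker expression probabilities (Mrgpra3
  0.065, Nmb 0.995, Tac1 0.655, Calca 0.826) are set so marginal
  prevalences approximate 4.3/66.1/29.1/36.7 % of all cells; competent
  cells falling through both draws are assigned the prevalent marker of the
  pair. Expressing cells draw NB(mean 20, size 4); non-expressing cells
  have leak mean 0.005, which single stray counts keep below the learned
  thresholds.
* **Background genes.** 3000 genes with means LogNormal(ln 5, 0.5) and
  size 10 (UMI counts are near-Poisson). This deliberately models only the
  moderately-to-well expressed gene complement that the rank test and the
  min.pct filter actually act on; the near-silent majority of a real matrix
  is not emulated in bulk (the dropout model and marker leak cover the
  sparse regime). The choice keeps every background gene informative, so
  the null p-value distribution is close to uniform and planted effects are
  the only structured signal.
* **Condition effects.** 100 planted genes (50 up in CCI, 50 up in AEW,
  log2FC 1.5 at base mean 5), optionally class-restricted. At these sizes
  the DE arm recovers plants with sensitivity ≥ 0.9 and empirical FDR
  ≤ 0.1 at 500 cells per condition, and its null p < 0.05 rate stays inside
  the 99 % binomial band around 0.05 — both verified per seed in the tests,
  not assumed.
* **Low-quality cells.** 5 % of cells get library scale 0.05 on nuclear
  genes and 4 on mito genes, so both QC rules (genes detected and mito
  rate) have real work to do; healthy cells sit near 7 % mito.
* **Fixture builder.** `make_fixture_classes` produces a minimal
  deterministic matrix (markers at a fixed level plus an *Actb*
  housekeeping column so every cell has a nonzero library) in which the
  classifier recovers requested class counts exactly — the vehicle for
  printed-total arithmetic like 420/146/405 over 971.

Not simulated in either generator: ambient RNA, doublets, batch effects,
read-level data, ROI segmentation, motion. Passing tests demonstrate the
correctness and calibration of the *procedures* under the stated noise
models — not that real recordings or libraries satisfy those models.

## Numerical conventions

* Rounding of reported percentages: half-away-from-zero, one decimal.
* SEM with n = 1 is undefined; reported as 0 by convention (flagged in the
  API docs) so population traces remain plottable.
* Empty responder unions are reported with `defined=False` and None
  percentages, never a division by zero.
* Degenerate all-tied genes in the asymptotic Wilcoxon branch get p = 1
  (no evidence), keeping them out of every pass list.
* p-values are clipped away from 0 at the smallest positive float only to
  keep downstream log transforms finite.

## Problem sizes

Defaults are desk-scale: 1113-neuron mechanical fields at 5 Hz for ~11 min,
232-neuron chemical fields for 54 min, 2400-cell × 3017-gene matrices. A
full two-arm analysis, the test suite, and the acceptance script each run
in well under a minute to a few minutes on a single CPU.

## Known limitations

* The 20 % criterion is applied to the peak statistic; if a sustained-mean
  reading of the criterion were intended, activated fractions would drop
  for brief transients. The statistic is isolated in
  `StimulusResponseCaller.decision_function` and easy to swap.
* The positivity scale (raw vs normalized vs variance-stabilized) is a
  genuine unknown of the source procedure; cp10k is the default, and
  results at other scales can differ for genes whose top-3 cells have
  atypical depth.
* The generators plant effects rather than derive them from mechanism;
  recovery tests validate the estimators, not biology.
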