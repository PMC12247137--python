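# somatomode

Analysis toolkit for classifying dorsal root ganglion (DRG) sensory neurons
as pain-, itch-, or dual-responsive, from two complementary kinds of
evidence:

1. **In vivo two-photon calcium imaging** — per-neuron fluorescence traces
   under mechanical (pinch/brush) or chemical (formalin/chloroquine)
   stimulation of the hind paw, analyzed as ΔF/F0 transients;
2. **Single-cell RNA sequencing** — gene × cell UMI count matrices, analyzed
   with a fraction-of-positive-cells marker threshold over the itch markers
   *Mrgpra3* and *Nmb* and the pain markers *Tac1* and *Calca*.

It is aimed at sensory-neuroscience groups who want the two bespoke
procedures — transient-based activation calling and top-3/5% marker
thresholding — as tested, reusable library code rather than one-off
analysis scripts. Because raw imaging stacks and sequencing runs are rarely
shareable, both arms ship with synthetic-data generators that plant known
responder classes and marker structure, so every statistic the package
computes can be checked against ground truth.

## The core procedures

**Calcium arm.** For neuron *i* with fluorescence *F_t*,

    ΔF/F0 = (F_t − F0) / F0 × 100 %,   F0 = mean of F_t over the first 60 s

with the baseline window required to be stimulus-free. A neuron is *activated*
by a stimulus when its peak ΔF/F0 inside the stimulus analysis window is
**≥ 20 %** (inclusive). Mechanical windows run from stimulus onset to offset
plus a 10-s decay margin; chemical windows run from 1 min after injection
(excluding the injection artifact) to 11 min after injection. Responder
overlap between a pain and an itch stimulus is summarized Euler-style
(both / only-A / only-B over the responder union), and population peak
amplitudes are compared with an unpaired Student's *t* test (mean ± SEM).

**Transcriptomic arm.** Cells pass QC with > 500 detected genes and a
mitochondrial UMI rate < 20 % (mitochondrial genes are then dropped). For
each gene, the "maximum" expression is the mean of its top three per-cell
values (counts per 10,000); the positivity threshold is **5 %** of that
maximum, and a cell is positive when it exceeds the threshold strictly.
Neurons positive for ≥ 1 of the four markers are classified as

* itch — (*Mrgpra3*⁺ or *Nmb*⁺) and no pain marker,
* pain — (*Tac1*⁺ or *Calca*⁺) and no itch marker,
* itch/pain — at least one marker of each modality.

Differential expression uses the two-sided Wilcoxon rank-sum test (exact
enumeration for groups of ≤ 8 cells, tie-corrected normal approximation
otherwise) with the conventional filters *P* < 0.05, log2 fold change
> 0.25, and min.pct > 0.1.

The two classification steps are sklearn-style estimators
(`DeltaFOverF`, `StimulusResponseCaller`, `MarkerPositivityClassifier`)
that compose in a `sklearn.pipeline.Pipeline`; module-level functions wrap
them for everyday use.

## Worked example

```python
from somatomode import (
    CalciumSimConfig, generate_recording, compute_dff, call_responses,
    summarize_overlap, compare_amplitudes,
    TranscriptomeSimConfig, generate_counts, qc_filter, classify_neurons,
)

# --- calcium arm: 200 neurons, planted 50 dual / 80 pinch-only / 20 brush-only
cfg = CalciumSimConfig(
    n_neurons=200,
    class_counts={"both": 50, "only_a": 80, "only_b": 20, "none": 50},
    seed=1,
)
rec, truth = generate_recording(cfg)
calls = call_responses(compute_dff(rec), rec.epochs)
ov = summarize_overlap(calls, "pinch", "brush")
print(ov.n_both, ov.n_only_a, ov.n_only_b, ov.pct_both)
# 50 80 20 33.3        <- planted counts recovered; 50/150 = 33.3 %

peaks = calls.calls.query("stimulus == 'pinch'").set_index("neuron_id").peak_dff
res = compare_amplitudes(
    peaks[list(truth.ids_of_class("both"))],
    peaks[list(truth.ids_of_class("only_a"))],
)
print(f"{res.mean_a:.1f}±{res.sem_a:.1f} vs {res.mean_b:.1f}±{res.sem_b:.1f} {res.stars}")
# 80.5±0.2 vs 45.6±0.2 ***   <- dual-responsive neurons respond more strongly

# --- transcriptomic arm: 2400 simulated cells across control/CCI/AEW samples
adata, _ = generate_counts(TranscriptomeSimConfig(seed=1))
filtered, qc = qc_filter(adata)
print(qc.n_cells_before, "->", qc.n_cells_after)
# 2400 -> 2274          <- planted low-quality cells removed by the QC rules
assign = classify_neurons(filtered)
print(assign.counts, assign.percentages)
# {'itch': 762, 'pain': 289, 'itch_pain': 705}
# {'itch': 43.4, 'pain': 16.5, 'itch_pain': 40.1}
```

The first block shows activation calling recovering the planted responder
structure exactly and the planted multisensory amplitude advantage being
highly significant; the second shows QC, thresholding and classification
recovering the planted marker-class mix of the generator.

A CLI wraps the same pipelines
(`somatomode sim-calcium / calcium-analyze / sim-counts / classify / de /
run-all`); every run writes its tables plus a JSON manifest of inputs,
thresholds and seeds, and reruns with the same config are byte-identical.

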