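# Methods

This package re-implements, as tested code on synthetic data, an analysis
pipeline for a six-icon RSVP ERP speller: per-subject CNN decoding of
target icons from stimulus-locked EEG, followed by an interpretability
analysis of the learned convolutional filters and a group-level comparison
between high-performing (H) and low-performing / "illiterate" (L) subjects.
The human EEG behind the original cohort was never deposited, so the
simulator below defines the study conditions; the published per-subject
summary table ships with the package as worked-example input for the metric
identities and the cohort split.

## Paradigm and data model

Six icons are presented one at a time (RSVP) in random order, 20
presentations per icon per trial, ISI 300 ms; one icon per trial is the
target, each icon is targeted twice per 12-trial session.  EEG is recorded
from 11 electrodes of the 10/20 system (F3, Fz, F4, C3, Cz, C4, P3, Pz, P4,
O1, O2) at 256 Hz.  An epoch is the 300-sample (~1.17 s) window after a
stimulus onset; epochs therefore overlap later stimuli, and the simulator
deliberately does **not** model that overlap (each epoch is independent).
Epoch tables are tab-delimited text (one row per epoch-channel, columns
`s000..s299` in µV) with a flat `key=value` sidecar carrying the sampling
rate and channel order.

## Synthetic subjects

A subject is a `SubjectProfile`: a list of positive ERP components
(Gaussian bumps in time, each with a per-channel gain pattern normalised to
max 1), a noise model, and two single-trial variability parameters.

* **H-like** subjects carry P300/P500/P700 components at 0.30/0.50/0.70 s.
  P300/P500 are sharp (σ = 0.05 s) with parietal/occipital-dominant
  topographies; P700 is broad (σ = 0.15 s) and fronto-central.  One
  component per subject, drawn uniformly, is amplitude-boosted ×1.6 and is
  that subject's *dominant* component (the spread of reported per-subject
  peak times motivates per-subject dominance rather than a fixed hierarchy).
  Latency jitter across epochs is small (σ = 0.02 s) and 85–95% of trials
  are attended.
* **L-like** subjects carry a single broad fronto-central P700 only.  Its
  latency fluctuates strongly across epochs (σ = 0.15 s) and only 40–60% of
  trials are attended: in a lapsed trial the target is still labelled target
  but its epochs contain no ERP.  These two mechanisms — latency
  instability and attentional lapses — are the standard account of ERP
  speller illiteracy; amplitude alone cannot produce it here, because
  20-fold averaging over 11 channels makes even weak stationary components
  decodable.

Base peak amplitude is 5 µV; noise is an equal mix of 1/f-shaped and white
noise scaled to exactly 10 µV RMS per channel per epoch.  Per-subject
jitter: latencies ±0.02 s, amplitudes and widths ±20%, topography gains
±10% (renormalised).  All parameters are drawn once per subject from the
profile seed; every epoch, schedule and lapse draw descends from explicit
`SeedSequence`s, so identical seeds give bit-identical datasets.

The simulator does not model volume conduction, ocular/muscle artifacts,
inter-session drift, or stimulus overlap.  Passing tests on this generator
therefore demonstrate correctness of the pipeline and recoverability of the
injected structure — not performance on real EEG.

## Input construction

CNN inputs are per-icon averages: repetitions of an icon within a trial are
averaged in non-overlapping groups of *k*, then the three frontal rows are
copied below the two occipital rows ("frontal wrap"), giving 14×300
matrices whose 6-row spatial filter can also span the occipital–frontal
seam.  Training uses k = 5 (4 target + 20 non-target inputs per trial, 288
per session): enough inputs per subject while denoising single epochs.
Trial decoding always uses the full k = 20 average per icon — detection is
a trial-level property.  No filtering, re-referencing or baseline
correction is applied (an optional per-channel baseline flag exists, off by
default).

## Network and training

Architecture (input 14×300): 6×20 valid convolution (8 filters) → ReLU →
2×2 max-pool → 1×12 valid convolution (9 filters, ~100 ms window) → ReLU →
1×10 max-pool → dense 128 (ReLU, dropout 0.5) → dense 2 → softmax.  The
first output element scores target affiliation.  Pooling is non-overlapping
with floor-division boundaries, so the realised shape chain is
9×281 → 4×140 → 4×129 → 4×12.  Filter counts, the dense width and the
dropout rate are free parameters with the defaults above.

Training minimises 2-class cross-entropy with Adam (lr 1e-3, β = 0.9/0.999)
for a fixed number of minibatch steps: 2000 at batch 16 in the `desk`
profile (under a minute per subject on one CPU), 10,000 at batch 32 in the
`full` profile.  The implementation is plain numpy with analytic
gradients, verified against central-difference numerical gradients at 1e-4
relative tolerance.  The training set is shuffled once and iterated in
contiguous minibatches from a seeded per-pass offset; this keeps the
precomputed first-layer patch matrix sliceable without per-iteration
gathers, which dominates the step cost otherwise.  Weight init (He normal),
the stratified validation split (25%), shuffling and dropout masks all
derive from one spec seed.  Because the oddball ratio is 1:5,
inverse-frequency class weights are applied to the loss **by default**; a
flag restores the unweighted loss, which collapses weak-signal subjects to
the majority (all-negative) prediction.  Training/validation correct-rate
((TP+TN)/total) and FP/FN rates are recorded every 100 steps.

## Decoding and metrics

Each icon input gets a binary label (positive iff target score >
non-target score; exact ties are negative).  Per trial: a unique positive
icon is selected directly; several positives → the positive icon with the
greatest target score; none → the greatest target score among all six.
Exact argmax ties resolve to the lowest icon index.  A trial's ERP counts
as detected when the true target icon was labelled positive; subjects with
detection rate > 50% form group H, the rest (including exactly 50%) group
L.

Per-subject metrics: trial accuracy (selected = true target); sensitivity,
precision and F1 over per-icon binary decisions of the decoded session;
AUC via the Mann-Whitney rank statistic (mid-ranks for ties) over per-icon
target scores; and the two feature-map statistics below.  Group differences
use classic equal-variance one-way ANOVA (two groups).  Report tables round
to 3 decimals, half away from zero.

## Feature-map statistics

The trained network is probed with the subject's wrapped grand-average
target ERP.  Post-ReLU conv maps are extracted per filter (L1: 9×281, L2:
4×129).  Time is assigned to columns through the cumulative receptive-field
geometry — conv widths 20 and 12, pool widths 2 and 10 give (jump, size) of
(1, 20), (2, 21), (2, 43), (20, 61) after the four stages — using column
*centers*, which are unbiased for symmetric peaks.  The mapping is verified
by a brute-force dependency trace (perturb one input sample, observe which
columns change).

* **PSNR** of a map: `10·log10(max(v)² / Σv²)` — peak power over total map
  power.  This form is computable from a map alone, is 0 dB for perfectly
  concentrated maps and increasingly negative for diffuse ones, matching
  the all-negative published PSNR column and its "high weight ⇒ greater
  PSNR" reading.  (An image-codec PSNR needs a reference image and cannot
  be negative; no reference is available, so that variant is
  underdetermined and deliberately not reproduced.)  The subject value is
  the mean over L1 filters; all-zero maps are skipped as missing.
* **PeT**: average the L2 maps across filters, collapse rows by the mean,
  return the receptive-field center time of the maximum column.  Row
  collapse by mean (not max) matches the averaging character of the
  statistic.

## Problem sizes and numerical choices

The test-suite cohort is 10 H-like + 10 L-like subjects at desk scale
(2000 iterations, one training and one decoded session each), the size at
which the group-level contrasts stabilise while the whole suite stays in
the tens of minutes on one CPU; the acceptance script uses a 5+5 cohort
for the same reason.  Network arithmetic runs in float32 (float64 for the
gradient check); softmax and all metric computations are float64.
Degenerate cases are explicit: all-zero maps → missing PSNR/PeT;
zero-denominator rates → missing, never 0; single-class AUC → missing;
zero-variance-equal-mean ANOVA → F = 0, p = 1.  Exact softmax score ties
label negative; argmax ties select the lowest icon index.

## Known limitations

* The generator's phenotypes are stylised; real illiteracy involves richer
  nonstationarity (drift, artifacts, habituation) than lapses + jitter.
* Per-icon sensitivity/precision depend on the decode-time labelling of
  k = 20 averages; the original analysis granularity is not stated and
  other choices (single-epoch labelling) change those columns.
* The published group-level learning-curve claim that the false-positive
  rate rises to 1 for L subjects while the false-negative rate falls to 0
  could not be reproduced by any honest training regime tried here
  (unweighted training collapses weak subjects to all-negative — the
  mirror image; balanced weighting keeps FP near 0 while FN stays high).
  The pipeline records the full learning history so the comparison is
  explicit, and the corresponding acceptance check is expected to fail;
  notably the source material itself states both "FP becomes 1" and "FP
  remains close to 0" in different sections.
* With ~1/3 of H-like subjects dominated by the broad P700, PeT recovery
  error is bimodal: sharp-dominant subjects recover within one or two map
  columns, broad-dominant ones can land on a neighbouring component.
  Median error over a cohort is the stable summary, and that is what is
  asserted.
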