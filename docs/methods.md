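# Methods

## The detection problem

Backscatter flow cytometry (BSFC) streams five synchronized voltage channels
at 60 kHz while whole blood flows at 55.6 mm s⁻¹ through a 30 × 30 μm²
channel crossed by a 5 μm illumination slit: three elastic-scatter channels
(405, 488, 633 nm), a green-fluorescence ground-truth channel (525 nm, from
GFP-expressing spiked clusters), and a red autofluorescence channel (670 nm).
Circulating tumor cell clusters (CTCCs, ≥ 2 cells) are the rare positive
class; everything else that scatters — white blood cells, debris, clots — is
a non-cluster (NC) event. Recordings are processed as independent 90-second
segments.

## Transit physics and the width gate

An object of length `L` crossing the slit of width `s` at speed `v` produces
a pulse of base width `(L + s)/v · f_s` samples. At the instrument defaults a
15 μm cell (large single cell) transits in ~21.6 samples; a two-cell 26 μm
cluster in ~33.5. The multicellular gate is derived exactly as the
instrument's analysis does: the maximum single-cell transit (21.6, taken
conservatively as 22 whole samples) times an FWHM/width fraction of 0.75,
rounded half-up — 17 samples. Events with equalized FWHM below 17 are
discarded as single cells.

Rendered pulses in the simulator are flat-topped (Tukey window, taper
fraction 0.5): a plateau while the object fully covers the slit with
raised-cosine ramps as it enters and leaves. This shape is what makes the
0.75 FWHM/width relationship hold on a linear-amplitude trace (a Gaussian
would give ~0.37); on the quadratic T² trace it gives ~0.68. With these
fractions the gate-equivalent object length is ~16 μm on a linear trace —
just above the single-cell range, just below the two-cell cluster range —
which is precisely the discrimination the gate is meant to deliver.

## ROI detection

Per segment, on the scatter channels only:

1. **Clot handling.** A clot is declared when the sample standard deviation
   of the cumulative (summed) scatter signal exceeds 1.75 V (strict
   inequality; equivalently variance > 3.06 V²). Correction subtracts a
   centered 500-sample moving average (edge-truncated) from each channel and
   re-adds the subtracted baseline's mean, preserving the global mean to
   < 1e-6 V; the pass repeats until σ < 1.75 V, capped at three iterations to
   avoid an infinite loop on noise that a moving average cannot remove.
2. **Band-pass.** 2nd-order Butterworth, 50–10 000 Hz, applied zero-phase
   (forward–backward) so peak apexes stay aligned with the raw trace that
   the ±49-sample feature windows are cut from. The pad length is set to
   three settling times of the 50 Hz edge; scipy's default is far shorter
   and leaves boundary transients.
3. **Normalization.** Optional day-power divisor first, then per-segment
   min–max to [0, 1] per channel (constant channels are zeroed with a
   warning). Order fixed as power-correct → min–max.
4. **Anomaly trace.** PCA is fit per segment on the n×3 observation matrix;
   T² at each sample is Σ score²/λ over the retained components (default 2,
   configurable; with all 3 retained T² equals the squared Mahalanobis
   distance, which is the oracle-checked mode). Zero-variance components are
   excluded with a warning.
5. **Event extraction.** Contiguous runs with T² > 10 (an absolute,
   dimensionless empirical threshold) become event ranges; within a range
   only the tallest local maximum is kept — a multi-peaked range is one
   cluster event. Events overlapping the first/last 3 · f_s/50 samples
   (~60 ms) are dropped: reflection padding inflates variance there and
   fabricates wide runs at segment boundaries.
6. **Width measurement.** The event waveform is the run on the
   Mahalanobis-distance trace (√T², linear in pulse amplitude — half-maximum
   on the squared trace would mean 2^−1/2 of peak amplitude and lets noise
   dips truncate the measurement). Geometric height equalization rescales
   every local maximum (strictly greater than both neighbors; plateaus take
   the leftmost sample) to one and divides in-between samples by the
   straight line joining the original heights, so lower shoulder peaks no
   longer shrink the apparent width; FWHM is the ≥ 0.5 run containing the
   apex with sub-sample interpolation at the crossings, rounded to nearest,
   clipped to the run length (and flagged) when no crossing lies inside.
7. **Gate.** FWHM < 17 removed; the gate is inclusive at 17.

The fluorescence ground-truth channel passes through the same
filter → threshold → extraction → equalized-FWHM chain with an amplitude
threshold in place of T²: 5 × a robust baseline σ (median absolute
deviation based). Five σ sits at the top of the 3–5 σ range used by
earlier intensity-threshold detectors; at 3 σ a 90-s noise trace yields
thousands of spurious one-sample crossings that would contaminate the
ground-truth labels.

## Labeling and features

A scatter ROI is labeled CTCC iff its FWHM is strictly greater than 17 and
it overlaps a fluorescence ROI, or an overlapping fluorescence ROI has FWHM
strictly greater than 17; otherwise NC. (The detection gate is inclusive at
17 while the label rule is strict, so an event at exactly 17 samples with
co-located fluorescence of ≤ 17 samples is retained but labeled NC — an
intentional edge case that follows both rules literally.) Matching is any
index-range overlap (ranges half-open, 0-based); apex-distance matching
(≤ 25 samples) is available but off by default.

Feature vectors use the *raw* channels: each scatter channel is z-scored
over its segment (degenerate zero-σ channels contribute zeros), a ±49-sample
window around the apex is cut (edge-padded with the boundary value), and the
three 99-sample windows are concatenated in 405/488/633 order — 297 values.
Class imbalance is preserved; it is the loss's job.

Splits are always by experimental day: a fixed test set (default ≈ 32 % of
days) and rotating train/validation folds of the remainder (validation
≈ 21 % of the train+val days; with 34 days this is the 11/18/5 layout and
five folds). Per-segment z-scoring (rather than per-recording) was chosen
for locality; it also makes features invariant to the day-power scale.

## Classifier and cascade

The network is six (convolution → ReLU → max-pool) blocks with channel
widths 8-16-32-32-32-32 and kernel 3 (the architecture details beyond
"six conv + pool blocks, an extra pool, a dense head" are free choices and
configurable), an additional max-pool, and a single-logit dense head:
297 → 2 positions × 32 channels → 1 score. It is implemented directly in
numpy (im2col convolutions, gradient-checked against finite differences)
and trains with Adam at 1e-3 for at most 15 epochs, early-stopping when
validation F1 (ties broken by lower validation loss) fails to improve for
7 epochs, restoring the best-validation weights. Everything is
deterministic given the seed.

The loss is `loss_mix · weighted-BCE + (1 − loss_mix) · (1 − TI)^γ` with the
Tversky index computed on soft scores over the batch,
TI = ΣTP/(ΣTP + α ΣFN + β ΣFP). Defaults α = 0.7, β = 0.3, γ = 0.75 (the
focal-Tversky literature defaults), mix 0.5; the positive class weight
defaults to N_neg/N_pos of the stage's training set. At mix 1 the loss
reduces exactly to weighted BCE, at 0 to focal Tversky (limit-checked).

The cascade trains up to ten networks: stage k+1's training set is stage
k's training-set TP ∪ FP ∪ FN (true negatives dropped), so the set shrinks
and its positive fraction can only rise; a stage whose surviving set is
single-class truncates the cascade with a warning (a perfect stage does
this immediately). At evaluation each example is re-scored from its
features at every stage (threshold 0.5 throughout) and only predicted
positives advance, so the predicted-positive set weakly shrinks with
depth — the mechanism behind purity rising and sensitivity falling as
stages are added. An audit records the stage at which each rejected
example was dropped.

## Rare-event statistics

- `poisson_min_events(p, x)`: a sample must contain n = x/p events to
  detect an average of x at per-event probability p (n·p = x exactly;
  ceiling for presentation).
- `blood_volume_and_time`: volume = n/concentration, time =
  volume/throughput; at p = 0.353, 0.4–0.5 clusters · mL⁻¹ and 3 μL · min⁻¹
  this gives ~2.83 clusters, 5.7–7.1 mL and up to ~39 h.
- `theoretical_cv(μ) = 100/√μ`, the Poisson counting floor; extra variance
  sources combine as σ²(x+y) = σ²x + σ²y + 2 cov (signed covariance,
  floored at 0 with a warning). The volume-variability term is estimated
  from the empirical variance of per-replicate NC counts scaled to the
  cluster rate; its covariance with counting noise defaults to 0.
- `spiking_subsample`: for a target of k clusters, the prefix of the
  time-ordered event stream up to and including the k-th ground-truth
  cluster, with every earlier NC event — emulating stopping the recording
  once the desired spike count has been seen. Subsets are nested by
  construction.
- `cv_study`: observed %CV of a counting model across replicate streams per
  target vs the Poisson floor. An ideal detector on Poisson-replicated
  spikes must sit inside the chi-square sampling band of the theoretical
  value — the "no variability added by the model" check.

## The simulator: what it emulates and what it does not

Emulated: per-channel Gaussian baselines at the measured variances
(0.169/0.452/0.511 V²); Poisson event counts at configured per-minute rates;
transit-width pulse physics; cluster size categories (two-cell 26 μm;
3–6 cells 35–60 μm; 6+ cells 65–100 μm); a co-located fluorescence pulse for
every cluster; lognormal per-event amplitude scatter (σ = 0.25) and
per-day power factors (σ = 0.1); slow random-walk clot drift scaled to push
the cumulative σ past 1.75 V; optional shoulder sub-peaks; optional
autofluorescent WBC-like confounders (default off) with a spectral tilt
toward the red channels, widths spanning the gate (10–35 μm so some pass it
and supply NC training examples), and green amplitude (0.02 V) below
ground-truth significance.

Amplitude scales are free parameters (no published amplitude statistics
exist): single-cell means (1.8, 2.4, 2.4) V and cluster means
(3.0, 3.5, 3.6) V were fixed once so that the 405 nm channel has the highest
signal-to-background ratio and event apexes clear the T² = 10 threshold by
an order of magnitude at realistic SNR, while baseline samples stay below it
with chi-square tail probability ~0.7 %.

Not emulated: optics/point-spread behavior, red-blood-cell-resolved
scattering, non-Gaussian detector noise, cell orientation effects, or any
real inter-day biology. Passing tests therefore demonstrate that the
algorithms are implemented correctly and behave as designed under the
modeled physics — not that the real-data performance figures transfer.

## Problem sizes used by the test suite

The end-to-end check trains on 10 simulated days of 2 × 40-second segments
(cluster rates cycling 0.5–4.5 min⁻¹ across days, confounders at 24 min⁻¹)
with a 3-stage cascade on a reduced 6-epoch schedule — small enough for a
single CPU, large enough that stage-1 training errors survive and later
cascade stages actually form; detected-vs-true per-day counts must correlate
at r > 0.9. Detection recovery (≥ 95 % of gate-length clusters) and the
zero-ROI noise check run on separate 20–30-second segments. The %CV study
uses 220 event-level replicate streams per target {5, 10, 30, 50, 100} with
the variance-ratio test at family α = 0.01 (Bonferroni across targets).

## Known limitations

- The T² threshold (10) is treated as an absolute dimensionless value, as
  used; no per-segment calibration procedure is defined.
- Equalization is exactly idempotent only while re-division cannot move a
  local maximum across a sample boundary; steep peak-to-peak lines over wide
  peaks can shift an apex by one sample.
- The boundary guard discards events within ~60 ms of segment edges;
  streamed acquisitions lose those events to segmentation in any case.
- The numpy network trains comfortably at 10²–10⁵ examples; it is not meant
  for GPU-scale data.
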