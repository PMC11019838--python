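# deeppeak

Label-free detection of **circulating tumor cell clusters (CTCCs)** in
multi-channel **backscatter flow cytometry (BSFC)** voltage traces.

CTCCs are rare (well under one per mL of blood) but carry a far higher
metastatic risk than single circulating tumor cells. BSFC records elastic
backscatter from whole blood flowing through a microfluidic channel on three
wavelengths (405/488/633 nm) at 60 kHz, plus a green-fluorescence channel
(525 nm) that serves only as ground truth for GFP-expressing spiked clusters —
never as a classifier input. The analysis problem is finding a handful of
cluster transits per hour inside millions of samples of blood-scatter
baseline.

This package implements the two-stage detection pipeline, the rare-event
statistics around it, and a synthetic trace simulator so every stage is
testable without instrument data:

1. **ROI detection** (`deeppeak.roi_detect`) — per 1.5-minute segment:
   blood-clot baseline correction (iterative 500-point moving-average
   subtraction while the cumulative-scatter σ exceeds 1.75 V), zero-phase
   2nd-order Butterworth band-pass (50–10 000 Hz), per-segment min–max
   normalization, then an anomaly trace: each time sample is a 3-feature
   observation scored by Hotelling's

   $$T^2_t = \sum_{k} \frac{s_{t,k}^2}{\lambda_k}$$

   over the retained principal components (scores $s$, component variances
   $\lambda$). Contiguous runs with $T^2 > 10$ become candidate events;
   after geometric height equalization (local maxima rescaled to 1,
   in-between samples divided by the peak-to-peak line) events narrower than
   **17 samples FWHM** — the transit width of the largest single cell — are
   removed.
2. **ROI classification** (`deeppeak.classify`) — a small 1-D CNN (six
   convolution + max-pool blocks, an extra pool, a sigmoid head) on 297-point
   feature vectors (±49 samples of z-scored raw signal around the peak,
   concatenated across the three scatter channels), trained with a weighted
   binary cross-entropy mixed with the focal Tversky loss
   $(1 - \mathrm{TI})^\gamma$, $\mathrm{TI} = TP/(TP + \alpha FN + \beta FP)$.
   Up to ten networks form a **cascade**: each stage retrains on the previous
   stage's TP ∪ FP ∪ FN, and at evaluation only predicted positives advance —
   purity rises with depth while sensitivity falls. Estimators follow
   scikit-learn conventions (`PeakCNNClassifier`, `CascadeClassifier`).
3. **Statistics** (`deeppeak.evaluate`) — purity/sensitivity/specificity/F1,
   false-alarm rate (FP · min⁻¹) on unspiked blood, net two-stage performance,
   Poisson blood-volume planning ($x = n\,p$), and observed-vs-theoretical
   coefficient of variation ($\%CV = 100/\sqrt{\mu}$) with the fixed-count
   spiking subsample procedure.
4. **Simulation** (`deeppeak.simulate`) — transit-time physics
   (width = (length + slit)/speed × rate, so a 15 μm cell spans ~21.6
   samples), measured baseline variances (0.169/0.452/0.511 V²), co-located
   fluorescence pulses for clusters, clot drift, day-to-day power variation,
   and optional autofluorescent confounders.

## Worked example

```python
from deeppeak import (SimConfig, simulate_day, detect_segment, detect_gfp_rois,
                      poisson_min_events, blood_volume_and_time, theoretical_cv,
                      default_width_gate, volumetric_throughput)
from deeppeak.featurize import examples_from_segment

cfg = SimConfig(segment_duration=20.0, single_cell_rate=20.0, ctcc_rate=9.0)
segments, truth = simulate_day(cfg, n_segments=1, seed=101)
rois, clot = detect_segment(segments[0])
gfp = detect_gfp_rois(segments[0])
examples = examples_from_segment(segments[0], rois, gfp)

print(f"width gate: {default_width_gate()} samples")
print(f"injected clusters: {(truth['kind'] == 'ctcc').sum()}, "
      f"retained ROIs: {len(rois)}, labeled clusters: {(examples['label'] == 1).sum()}")
for r in rois[:3]:
    print(f"  ROI @ {r.peak_index}: T2 {r.peak_t2:.0f}, FWHM {r.fwhm_samples} samples")

plan = poisson_min_events(0.353)
vol = blood_volume_and_time(plan.n, (0.4, 0.5), volumetric_throughput(30, 30, 55.6))
print(f"clusters needed for one detection at p=0.353: {plan.n_rounded}")
print(f"blood volume: {vol.volume_ml[0]:.1f}-{vol.volume_ml[1]:.1f} mL, "
      f"time: {vol.time_hours[0]:.0f}-{vol.time_hours[1]:.0f} h")
```

prints

```
width gate: 17 samples
injected clusters: 4, retained ROIs: 4, labeled clusters: 4
  ROI @ 647848: T2 453, FWHM 25 samples
  ROI @ 973064: T2 519, FWHM 25 samples
  ROI @ 1087293: T2 163, FWHM 25 samples
clusters needed for one detection at p=0.353: 3
blood volume: 5.7-7.1 mL, time: 31-39 h
```

All four injected clusters in 20 s of simulated whole-blood signal survive
the anomaly threshold and the 17-sample width gate (two-cell clusters of
26 μm transit in ~33 samples, FWHM 25); the ~20 single cells do not. At a
net detection sensitivity of 35.3 %, about 3 clusters must be present to
detect one — at 0.4–0.5 clusters · mL⁻¹ that means processing 5.7–7.1 mL of
blood, 31–39 h at the 3 μL · min⁻¹ channel throughput.

## Command line

```bash
deeppeak simulate --out day0/ --n-segments 2 --seed 1   # synthetic segments + truth
deeppeak segment long_trace.csv --duration 90 --out segs/
deeppeak detect segs/segment000.csv --out peaks.csv     # clot report + peak table
deeppeak validate-config pipeline.yaml
deeppeak run pipeline.yaml --out run/                   # simulate -> ... -> report.json
deeppeak evaluate --pred predictions.csv --minutes 175 --out report.json
```

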