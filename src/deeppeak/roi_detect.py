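"""Region-of-interest detection for BSFC traces.

The detection chain turns a five-channel segment into candidate
multicellular events:

1. clot detection/correction — if the cumulative (summed) scatter signal
   shows excess baseline variance, a 500-point moving-average baseline is
   iteratively removed (the global mean is preserved);
2. band-pass filtering — second-order Butterworth, 50-10000 Hz, applied
   zero-phase so peak locations are not shifted;
3. per-segment min-max normalization of each scatter channel (after the
   day-power correction);
4. an anomaly trace — each time sample is a 3-feature observation;
   principal components are fit on the segment and Hotelling's T^2
   (sum over retained components of score^2 / component variance)
   measures its distance from the centroid; with all components retained
   this equals the squared Mahalanobis distance;
5. peak extraction — contiguous runs with T^2 above an empirical
   threshold of 10 become event ranges, one event per range;
6. geometric height equalization + FWHM — local maxima are rescaled to
   one and in-between points divided by the peak-to-peak line, so
   shouldered peaks yield a representative FWHM;
7. the multicellular width gate — events narrower than 17 points FWHM
   are removed (single cells transit in at most ~22 samples).

The green-fluorescence channel goes through the same filter ->
threshold -> extraction -> FWHM chain (with an amplitude threshold in
place of T^2) to produce ground-truth ROIs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .trace_io import GFP_CHANNEL, SCATTER_CHANNELS, SchemaError, TraceSegment


@dataclass
class DetectionParams:
    """Thresholds and filter settings for ROI detection (defaults per the method)."""

    clot_std_threshold: float = 1.75        # V, on the cumulative scatter signal
    clot_variance_threshold: float = 3.06   # V^2, triggers baseline correction
    moving_average_window: int = 500        # samples
    max_clot_iterations: int = 3
    butterworth_order: int = 2
    band: tuple[float, float] = (50.0, 10_000.0)  # Hz
    t2_threshold: float = 10.0
    min_fwhm: int = 17                      # samples, inclusive gate
    n_principal_components: int = 2
    gfp_threshold_sigma: float = 5.0        # amplitude threshold, x baseline std

    def __post_init__(self) -> None:
        lo, hi = self.band
        if not 0 < lo < hi:
            raise ValueError("band must satisfy 0 < low < high")
        for name in ("clot_std_threshold", "clot_variance_threshold", "t2_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ClotReport:
    detected: bool
    initial_std: float
    final_std: float
    iterations: int


@dataclass
class RoiEvent:
    """One detected peak: range, apex, equalized width and anomaly score."""

    segment_id: int
    start_index: int
    peak_index: int
    end_index: int          # half-open
    fwhm_samples: int
    peak_intensity: float
    peak_t2: float = np.nan
    channel_group: str = "scatter_cumulative"
    fwhm_clipped: bool = False  # no half-max crossing inside the ROI

    def __post_init__(self) -> None:
        if not self.start_index <= self.peak_index < self.end_index:
            raise ValueError("require start <= peak < end")


def cumulative_scatter(segment: TraceSegment) -> np.ndarray:
    """Sum of the three scatter channels (the cumulative scattering signal)."""
    return segment.scatter_matrix().sum(axis=1)


def detect_clot(cumulative: np.ndarray, params: DetectionParams | None = None) -> bool:
    """A clot is present iff the cumulative signal's sample std exceeds 1.75 V."""
    params = params or DetectionParams()
    if len(cumulative) < 2:
        raise ValueError("need at least 2 samples")
    return float(np.std(cumulative, ddof=1)) > params.clot_std_threshold


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge truncation (shorter windows at edges)."""
    kernel = np.ones(window)
    sums = np.convolve(x, kernel, mode="same")
    counts = np.convolve(np.ones_like(x), kernel, mode="same")
    return sums / counts


def correct_clot(
    segment: TraceSegment, params: DetectionParams | None = None
) -> tuple[TraceSegment, ClotReport]:
    """Remove clot baseline drift from the scatter channels.

    When the cumulative variance exceeds the clot threshold (3.06 V^2),
    each scatter channel has its centered 500-sample moving average
    subtracted and its pre-subtraction mean added back, preserving the
    global mean.  The pass repeats until the cumulative std falls below
    1.75 V, up to three times (a hard cap preventing an infinite loop on
    noisy data).  Clean segments are returned unchanged.
    """
    params = params or DetectionParams()
    window = params.moving_average_window
    if segment.n_samples <= window:
        warnings.warn(
            f"segment ({segment.n_samples} samples) shorter than the "
            f"{window}-sample baseline window; window shrunk to fit"
        )
        window = max(2, segment.n_samples - 1)
    cum = cumulative_scatter(segment)
    initial_std = float(np.std(cum, ddof=1))
    if initial_std**2 <= params.clot_variance_threshold:
        return segment, ClotReport(False, initial_std, initial_std, 0)

    out = segment.copy()
    iterations = 0
    std = initial_std
    while std > params.clot_std_threshold and iterations < params.max_clot_iterations:
        for name in SCATTER_CHANNELS:
            x = out.channels[name]
            baseline = _moving_average(x, window)
            # re-adding the subtracted baseline's own mean keeps the global
            # mean exactly (it equals the channel mean up to edge truncation)
            out.channels[name] = x - baseline + baseline.mean()
        iterations += 1
        std = float(np.std(cumulative_scatter(out), ddof=1))
    return out, ClotReport(True, initial_std, std, iterations)


def bandpass_filter(
    segment: TraceSegment, params: DetectionParams | None = None
) -> TraceSegment:
    """Band-pass the scatter channels (2nd-order Butterworth, zero-phase).

    Zero-phase (forward-backward) application keeps peak apexes aligned
    with the raw trace, which the +-49-sample feature windows rely on.
    """
    params = params or DetectionParams()
    lo, hi = params.band
    nyquist = segment.sample_rate / 2.0
    if hi >= nyquist:
        raise ValueError(
            f"band high ({hi} Hz) must be below the Nyquist frequency ({nyquist} Hz)"
        )
    sos = signal.butter(
        params.butterworth_order, [lo, hi], btype="bandpass", fs=segment.sample_rate,
        output="sos",
    )
    # the 50 Hz low cut has a ~20 ms settling time; scipy's default filtfilt
    # padding is far shorter and leaves edge transients that masquerade as
    # wide anomaly runs at the segment boundaries
    padlen = min(segment.n_samples - 1, int(3 * segment.sample_rate / lo))
    out = segment.copy()
    for name in SCATTER_CHANNELS:
        out.channels[name] = signal.sosfiltfilt(sos, out.channels[name], padlen=padlen)
    return out


def filter_channel(
    x: np.ndarray, sample_rate: float, params: DetectionParams | None = None
) -> np.ndarray:
    """Band-pass a single channel with the same zero-phase Butterworth."""
    params = params or DetectionParams()
    sos = signal.butter(
        params.butterworth_order, list(params.band), btype="bandpass",
        fs=sample_rate, output="sos",
    )
    padlen = min(len(x) - 1, int(3 * sample_rate / params.band[0]))
    return signal.sosfiltfilt(sos, x, padlen=padlen)


def normalize_segment(
    segment: TraceSegment, day_power_reference: float | None = None
) -> TraceSegment:
    """Map each scatter channel to [0, 1] (min -> 0, max -> 1).

    An optional per-day power scale is divided out first (it does not
    change the min-max result but keeps intermediate traces comparable
    across days).  A constant channel cannot be normalized and is set to
    zero with a warning.
    """
    out = segment.copy()
    for name in SCATTER_CHANNELS:
        x = out.channels[name]
        if day_power_reference:
            x = x / day_power_reference
        lo, hi = x.min(), x.max()
        if hi == lo:
            warnings.warn(f"channel {name} is constant; normalized to 0")
            out.channels[name] = np.zeros_like(x)
        else:
            out.channels[name] = (x - lo) / (hi - lo)
    return out


def hotelling_t2_trace(
    segment: TraceSegment, params: DetectionParams | None = None
) -> np.ndarray:
    """Hotelling's T^2 anomaly trace from the three scatter channels.

    Each time sample is a 3-feature observation.  Principal components
    are estimated on this segment's observations; T^2 at each sample is
    the sum over the retained components of score^2 / component variance.
    With all three components retained this equals the squared
    Mahalanobis distance of the observation from the centroid.
    """
    params = params or DetectionParams()
    X = segment.scatter_matrix()
    Xc = X - X.mean(axis=0)
    n = X.shape[0]
    # SVD-based PCA: component variances are s^2/(n-1)
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    variances = s**2 / (n - 1)
    k = min(params.n_principal_components, 3)
    t2 = np.zeros(n)
    used = 0
    for j in range(3):
        if used >= k:
            break
        if variances[j] <= np.finfo(float).eps * max(variances[0], 1.0):
            warnings.warn(f"principal component {j} has zero variance; excluded")
            continue
        score = Xc @ Vt[j]
        t2 += score**2 / variances[j]
        used += 1
    return t2


def find_rois(
    t2: np.ndarray, params: DetectionParams | None = None, segment_id: int = 0,
    channel_group: str = "scatter_cumulative",
) -> list[RoiEvent]:
    """Extract one event per contiguous supra-threshold run of the anomaly trace.

    Within a run only the tallest local maximum is kept as the event's
    apex — a range with several local peaks is a single cluster event,
    not several.  Events are returned un-gated, without FWHM (set to the
    run length as a placeholder; see :func:`characterize_rois`).
    """
    params = params or DetectionParams()
    if np.any(t2 < 0):
        raise ValueError("anomaly trace must be non-negative")
    above = t2 > params.t2_threshold
    if not above.any():
        return []
    padded = np.concatenate(([False], above, [False]))
    d = np.diff(padded.astype(np.int8))
    run_starts = np.flatnonzero(d == 1)
    run_ends = np.flatnonzero(d == -1)
    events = []
    for s, e in zip(run_starts, run_ends):
        peak = s + int(np.argmax(t2[s:e]))
        events.append(
            RoiEvent(
                segment_id=segment_id, start_index=int(s), peak_index=peak,
                end_index=int(e), fwhm_samples=max(1, e - s),
                peak_intensity=float(t2[peak]), peak_t2=float(t2[peak]),
                channel_group=channel_group,
            )
        )
    return events


def _local_maxima(w: np.ndarray) -> np.ndarray:
    """Indices of local maxima: strictly greater than both neighbors.

    Plateaus take the leftmost sample; boundary samples qualify when
    they exceed their single neighbor.  Falls back to the global argmax
    if no sample qualifies (e.g. a monotone ramp).
    """
    n = len(w)
    if n == 1:
        return np.array([0])
    maxima = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and w[j + 1] == w[i]:
            j += 1
        left_ok = i == 0 or w[i] > w[i - 1]
        right_ok = j == n - 1 or w[i] > w[j + 1]
        if left_ok and right_ok and not (i == 0 and j == n - 1):
            maxima.append(i)
        i = j + 1
    if not maxima:
        return np.array([int(np.argmax(w))])
    return np.asarray(maxima)


def equalize_heights(waveform: np.ndarray) -> np.ndarray:
    """Geometric height equalization of an ROI waveform.

    Every local maximum is rescaled to one; points between consecutive
    maxima are divided by the straight line joining the original maxima
    heights; points outside the first/last maximum are divided by that
    maximum's height.  A single-maximum ROI is simply divided by its
    peak height.  Idempotent up to floating-point tolerance.
    """
    w = np.asarray(waveform, dtype=float)
    if np.all(w == 0):
        warnings.warn("all-zero ROI; equalization skipped")
        return w.copy()
    peaks = _local_maxima(w)
    heights = w[peaks]
    divisor = np.empty_like(w)
    divisor[: peaks[0] + 1] = heights[0]
    divisor[peaks[-1] :] = heights[-1]
    for (p0, p1), (h0, h1) in zip(zip(peaks[:-1], peaks[1:]), zip(heights[:-1], heights[1:])):
        span = p1 - p0
        divisor[p0 : p1 + 1] = h0 + (h1 - h0) * np.arange(span + 1) / span
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(divisor != 0, w / divisor, 0.0)
    return out


def measure_fwhm(
    equalized: np.ndarray, peak_index: int, full_output: bool = False
) -> int | tuple[int, bool]:
    """FWHM (integer samples) of an equalized waveform around its apex.

    Measures the length of the half-maximum (>= 0.5) run containing
    ``peak_index``, with sub-sample linear interpolation at the two
    crossings, rounded to the nearest integer.  When a crossing falls
    outside the ROI the width is clipped to the ROI length and flagged
    (``full_output=True`` returns ``(fwhm, clipped)``).
    """
    w = np.asarray(equalized, dtype=float)
    n = len(w)
    if not 0 <= peak_index < n:
        raise ValueError("peak_index outside waveform")
    half = 0.5
    clipped = False
    # left crossing
    i = peak_index
    while i > 0 and w[i - 1] >= half:
        i -= 1
    if i == 0 and w[0] >= half:
        left = 0.0
        clipped = True
    else:
        left = (i - 1) + (half - w[i - 1]) / (w[i] - w[i - 1])
    # right crossing
    j = peak_index
    while j < n - 1 and w[j + 1] >= half:
        j += 1
    if j == n - 1 and w[n - 1] >= half:
        right = float(n - 1)
        clipped = True
    else:
        right = j + (half - w[j]) / (w[j + 1] - w[j])
    if clipped and left == 0.0 and right == float(n - 1):
        fwhm = n
    else:
        fwhm = max(1, int(np.floor(right - left + 0.5)))
    if full_output:
        return fwhm, clipped
    return fwhm


def characterize_rois(
    trace: np.ndarray, events: list[RoiEvent]
) -> list[RoiEvent]:
    """Equalize each event range and measure its FWHM on the source trace."""
    out = []
    for ev in events:
        roi = trace[ev.start_index : ev.end_index]
        eq = equalize_heights(roi)
        fwhm, clip = measure_fwhm(eq, ev.peak_index - ev.start_index, full_output=True)
        out.append(replace(ev, fwhm_samples=fwhm, fwhm_clipped=clip))
    return out


def width_gate(
    events: list[RoiEvent], params: DetectionParams | None = None
) -> list[RoiEvent]:
    """Retain events at or above the multicellular FWHM gate (17 samples).

    Peaks *less than* the gate are removed, so the gate is inclusive.
    A pure filter: output is a subset of input; idempotent.
    """
    params = params or DetectionParams()
    return [ev for ev in events if ev.fwhm_samples >= params.min_fwhm]


def _drop_boundary_events(
    events: list[RoiEvent], segment: TraceSegment, params: DetectionParams
) -> list[RoiEvent]:
    """Discard events overlapping the filter settling zone at segment edges.

    Zero-phase filtering extends the trace by reflection, which inflates
    the local variance within roughly one low-cut settling time of each
    boundary and fakes wide anomaly runs there.  The guard is 3 settling
    times of the band's low edge (3 * f_s / f_low samples, 60 ms at the
    defaults) — events split across segment boundaries are not usable
    anyway.
    """
    guard = int(3 * segment.sample_rate / params.band[0])
    n = segment.n_samples
    if 2 * guard >= n:
        return events
    return [e for e in events if e.start_index >= guard and e.end_index <= n - guard]


def detect_gfp_rois(
    segment: TraceSegment, params: DetectionParams | None = None
) -> list[RoiEvent]:
    """Ground-truth ROIs from the green-fluorescence channel.

    The fluorescence channel is a single series, so an amplitude
    threshold (``gfp_threshold_sigma`` x a robust baseline std, estimated
    by the median absolute deviation) stands in for the multivariate
    T^2 threshold; the rest of the chain (filter -> runs -> equalized
    FWHM) is identical.  Events are returned un-gated: the labeling rule
    applies its own width test.
    """
    params = params or DetectionParams()
    if GFP_CHANNEL not in segment.channels:
        raise SchemaError("green-fluorescence channel absent")
    x = filter_channel(segment.channels[GFP_CHANNEL], segment.sample_rate, params)
    mad = np.median(np.abs(x - np.median(x)))
    sigma = 1.4826 * mad if mad > 0 else x.std()
    if sigma == 0:
        return []
    thr = params.gfp_threshold_sigma * sigma
    padded = np.concatenate(([False], x > thr, [False]))
    d = np.diff(padded.astype(np.int8))
    run_starts = np.flatnonzero(d == 1)
    run_ends = np.flatnonzero(d == -1)
    events = []
    for s, e in zip(run_starts, run_ends):
        peak = s + int(np.argmax(x[s:e]))
        events.append(
            RoiEvent(
                segment_id=segment.segment_id, start_index=int(s), peak_index=peak,
                end_index=int(e), fwhm_samples=max(1, e - s),
                peak_intensity=float(x[peak]), channel_group="gfp",
            )
        )
    return _drop_boundary_events(characterize_rois(x, events), segment, params)


def detect_segment(
    segment: TraceSegment,
    params: DetectionParams | None = None,
    day_power_reference: float | None = None,
) -> tuple[list[RoiEvent], ClotReport]:
    """Run the full scatter-channel detection chain on one segment.

    Returns the gate-surviving scatter ROIs and the clot report.
    """
    params = params or DetectionParams()
    corrected, clot_report = correct_clot(segment, params)
    filtered = bandpass_filter(corrected, params)
    normalized = normalize_segment(filtered, day_power_reference)
    t2 = hotelling_t2_trace(normalized, params)
    events = find_rois(t2, params, segment_id=segment.segment_id)
    events = _drop_boundary_events(events, segment, params)
    # widths are measured on the Mahalanobis-distance trace (sqrt of T^2):
    # thresholding is unchanged (monotone transform) but the distance is
    # linear in peak amplitude, so half-maximum has its usual meaning and
    # noise dips between plateau maxima stay shallow after equalization
    events = characterize_rois(np.sqrt(t2), events)
    return width_gate(events, params), clot_report
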