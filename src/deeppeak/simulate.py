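"""Synthetic backscatter flow cytometry (BSFC) trace generation.

Generates multi-channel voltage recordings with known ground truth that
statistically emulate the acquisition used for label-free detection of
circulating tumor cell clusters (CTCCs): Gaussian baselines with the
measured per-channel variances, transit-time peak physics for single
cells and clusters, a co-located green-fluorescence pulse for every
spiked cluster, blood-clot baseline drift, day-to-day laser-power
variation, and optional autofluorescent confounder events.

Transit model
-------------
An object of physical length ``L`` crossing an illumination slit of
width ``s`` at flow speed ``v`` occupies the slit for ``(L + s) / v``
seconds, i.e. ``(L + s) / v * f_s`` samples at sample rate ``f_s``.
A 15 um cell at 55.6 mm/s and 60 kHz therefore spans ~21.6 samples,
which is why single cells measure 21-22 points in width while clusters
are wider.  Rendered pulses are flat-topped (Tukey, taper fraction 0.5):
smooth, unimodal, zero at the base, with a plateau while the object
fully covers the slit.  Their FWHM is 0.75 x the base width on a
linear-amplitude trace — the conservative FWHM/width relationship the
detection gate is derived from — and ~0.68 x the base width on the
quadratic Hotelling T^2 trace the detector actually thresholds.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trace_io import (
    GFP_CHANNEL,
    RED_CHANNEL,
    SCATTER_CHANNELS,
    TraceSegment,
)


class GenerationError(RuntimeError):
    """A configured event cannot be hosted by the requested segment."""


def transit_width_points(
    object_length: float, slit_width: float, flow_speed: float, sample_rate: float
) -> float:
    """Width (in samples, unrounded) of the transit of an object across the slit.

    Parameters
    ----------
    object_length, slit_width : um
    flow_speed : mm/s
    sample_rate : samples/s

    The object occupies the slit from the moment its leading edge enters
    until its trailing edge leaves, a path of ``object_length + slit_width``
    micrometers.  ``object_length`` may be 0 (point object -> slit-only
    transit); all other arguments must be positive.
    """
    if object_length < 0:
        raise ValueError("object_length must be >= 0")
    for name, v in (
        ("slit_width", slit_width),
        ("flow_speed", flow_speed),
        ("sample_rate", sample_rate),
    ):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    path_um = object_length + slit_width
    return path_um * 1e-3 / flow_speed * sample_rate


def fwhm_gate_from_transit(max_transit: float, fwhm_fraction: float = 0.75) -> int:
    """FWHM gate (integer samples) from a maximum single-cell transit width.

    Multiplies the full transit width by a conservative FWHM/width
    fraction and rounds half-up: a 22-sample maximum transit at fraction
    0.75 gives the 17-point multicellular gate.
    """
    if max_transit <= 0:
        raise ValueError("max_transit must be positive")
    if not 0 < fwhm_fraction <= 1:
        raise ValueError("fwhm_fraction must be in (0, 1]")
    return int(math.floor(fwhm_fraction * max_transit + 0.5))


def default_width_gate(
    cell_length: float = 15.0,
    slit_width: float = 5.0,
    flow_speed: float = 55.6,
    sample_rate: float = 60_000.0,
    fwhm_fraction: float = 0.75,
) -> int:
    """The multicellular FWHM gate for the default acquisition (17 samples).

    The single-cell transit width is rounded up to whole samples before
    applying the FWHM fraction, reflecting the *maximum* time a large
    single cell can occupy the slit (21.6 -> 22 samples -> gate 17).
    """
    transit = transit_width_points(cell_length, slit_width, flow_speed, sample_rate)
    return fwhm_gate_from_transit(math.ceil(transit), fwhm_fraction)


def volumetric_throughput(
    channel_width: float, channel_height: float, flow_speed: float
) -> float:
    """Volumetric throughput (uL/min) of a rectangular microfluidic channel.

    ``channel_width`` and ``channel_height`` in um, ``flow_speed`` in mm/s.
    The 30 x 30 um^2 channel at 55.6 mm/s processes ~3 uL/min.
    """
    for name, v in (
        ("channel_width", channel_width),
        ("channel_height", channel_height),
        ("flow_speed", flow_speed),
    ):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    # um^2 * (mm/s = 1e3 um/s) -> um^3/s; 1 uL = 1e9 um^3; per minute x60
    return channel_width * channel_height * flow_speed * 1e3 * 60.0 / 1e9


#: FWHM / base-width of the rendered flat-top pulse on a linear trace
LINEAR_FWHM_FRACTION = 0.75
#: the same ratio on the quadratic T^2 trace (half-max at amplitude 2^-1/4)
T2_FWHM_FRACTION = 0.5 + float(np.arccos(2.0 ** -0.25)) / np.pi


def gate_equivalent_length(
    min_fwhm: int = 17,
    slit_width: float = 5.0,
    flow_speed: float = 55.6,
    sample_rate: float = 60_000.0,
    pulse_fwhm_fraction: float = LINEAR_FWHM_FRACTION,
) -> float:
    """Physical length (um) whose rendered pulse FWHM equals the width gate.

    Rendered pulses have FWHM = ``pulse_fwhm_fraction`` x base width:
    0.75 on any linear-amplitude trace (including the Mahalanobis
    distance the detector measures widths on), ~0.68 on the squared
    (T^2) trace.  An object passes the gate when its transit width is at
    least ``min_fwhm / pulse_fwhm_fraction`` samples.
    """
    transit_needed = min_fwhm / pulse_fwhm_fraction
    return transit_needed / sample_rate * flow_speed * 1e3 - slit_width


@dataclass
class SizeCategory:
    """One bin of the cluster cell-count distribution, mapped to physical length."""

    probability: float
    min_length_um: float
    max_length_um: float


@dataclass
class SimConfig:
    """Acquisition and event-rate parameters for the synthetic generator.

    Defaults mirror the instrument: 60 kHz sampling, 90 s segments,
    55.6 mm/s flow through a 5 um slit, and per-channel baseline
    variances of 0.169 / 0.452 / 0.511 V^2 for the 405 / 488 / 633 nm
    scatter channels.  Event rates are per minute of recording; the clot
    rate is per hour.
    """

    sample_rate: float = 60_000.0
    segment_duration: float = 90.0
    flow_speed: float = 55.6
    slit_width: float = 5.0
    channel_baseline_variance: tuple[float, float, float] = (0.169, 0.452, 0.511)
    single_cell_rate: float = 30.0
    ctcc_rate: float = 2.0
    ctcc_size_distribution: tuple[SizeCategory, ...] = (
        SizeCategory(0.55, 26.0, 26.0),   # two-cell clusters
        SizeCategory(0.35, 35.0, 60.0),   # 3-6 cells
        SizeCategory(0.10, 65.0, 100.0),  # 6+ cells
    )
    single_cell_length: tuple[float, float] = (12.0, 1.5)  # mean, sd (um), clipped 8-15
    # per-channel mean peak amplitudes (V); 405 nm has the highest
    # signal-to-background ratio relative to its baseline noise
    single_cell_amplitude: tuple[float, float, float] = (1.8, 2.4, 2.4)
    ctcc_amplitude: tuple[float, float, float] = (3.0, 3.5, 3.6)
    confounder_amplitude: tuple[float, float, float] = (1.0, 2.2, 3.0)
    amplitude_sigma: float = 0.25  # lognormal spread of per-event amplitude
    gfp_amplitude: float = 1.5
    gfp_baseline_std: float = 0.03
    red_baseline_std: float = 0.05
    clot_rate: float = 0.5  # events/hour
    clot_drift_amplitude: float = 3.0  # std (V) of the cumulative-signal drift
    power_scale_sigma: float = 0.1  # lognormal day-to-day power factor
    autofluor_confounder_rate: float = 0.0  # events/min; off by default
    confounder_length_range: tuple[float, float] = (10.0, 35.0)
    confounder_green_amplitude: float = 0.02
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("single_cell_rate", "ctcc_rate", "clot_rate", "autofluor_confounder_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if any(v <= 0 for v in self.channel_baseline_variance):
            raise ValueError("baseline variances must be positive")
        total = sum(c.probability for c in self.ctcc_size_distribution)
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"ctcc size distribution sums to {total}, expected 1")


TRUTH_COLUMNS = [
    "event_id",
    "kind",
    "segment_id",
    "start_index",
    "end_index",
    "physical_length_um",
    "has_gfp",
]


def _hann_pulse(base_width: float, n: int, center: float) -> np.ndarray:
    """Raised-cosine lobe of the given base width centered at ``center`` samples."""
    t = np.arange(n) - center
    x = np.zeros(n)
    inside = np.abs(t) <= base_width / 2
    x[inside] = np.cos(np.pi * t[inside] / base_width) ** 2
    return x


def _tukey_pulse(base_width: float, n: int, center: float) -> np.ndarray:
    """Flat-top pulse: unit plateau over the central half of the base width,
    raised-cosine tapers over the outer quarters (Tukey, taper fraction 0.5)."""
    t = np.abs(np.arange(n) - center)
    x = np.zeros(n)
    plateau = base_width / 4.0
    x[t <= plateau] = 1.0
    taper = (t > plateau) & (t <= base_width / 2.0)
    x[taper] = np.cos(np.pi * (t[taper] - plateau) / (base_width / 2.0)) ** 2
    return x


def render_peak(
    kind: str,
    length_um: float,
    amplitudes: np.ndarray | tuple[float, ...],
    shoulder: float | None = None,
    *,
    slit_width: float = 5.0,
    flow_speed: float = 55.6,
    sample_rate: float = 60_000.0,
) -> np.ndarray:
    """Render one transit pulse, per channel.

    Returns an ``(n_samples, n_channels)`` array whose base width equals
    the transit width of ``length_um``.  ``shoulder``, if given, is the
    relative amplitude (0-1) of a lower sub-peak attached next to the
    main lobe, emulating clusters whose cells scatter unevenly; such
    peaks show two local maxima and an artificially narrow naive FWHM.
    """
    if length_um <= 0:
        raise ValueError("length_um must be positive")
    amplitudes = np.asarray(amplitudes, dtype=float)
    if np.any(amplitudes < 0):
        raise ValueError("amplitudes must be >= 0")
    base = transit_width_points(length_um, slit_width, flow_speed, sample_rate)
    n = max(3, int(round(base)))
    center = (n - 1) / 2
    if shoulder is None:
        pulse = _tukey_pulse(base, n, center)
    else:
        if not 0 < shoulder < 1:
            raise ValueError("shoulder amplitude fraction must be in (0, 1)")
        # main lobe on the leading side, lower shoulder lobe overlapping its
        # trailing edge; the offsets keep two distinct local maxima while the
        # naive FWHM (half the *main* lobe) stays well below the equalized one
        main = _hann_pulse(0.70 * base, n, center - 0.17 * base)
        sub = shoulder * _hann_pulse(0.50 * base, n, center + 0.22 * base)
        pulse = main + sub
        pulse /= pulse.max()
    return np.outer(pulse, amplitudes)


def _draw_ctcc_length(config: SimConfig, rng: np.random.Generator) -> float:
    probs = [c.probability for c in config.ctcc_size_distribution]
    cat = config.ctcc_size_distribution[rng.choice(len(probs), p=probs)]
    return float(rng.uniform(cat.min_length_um, cat.max_length_um))


def _place_events(
    n_events: int, widths: list[int], n_samples: int, rng: np.random.Generator, kind: str
) -> list[int]:
    """Draw non-overlapping start positions (uniform); error if unhostable."""
    starts: list[int] = []
    occupied: list[tuple[int, int]] = []
    for w in widths:
        if w >= n_samples:
            raise GenerationError(
                f"segment of {n_samples} samples too short to host a {kind} event "
                f"of {w} samples"
            )
        placed = False
        for _ in range(200):
            s = int(rng.integers(0, n_samples - w))
            if all(s + w <= a or s >= b for a, b in occupied):
                occupied.append((s, s + w))
                starts.append(s)
                placed = True
                break
        if not placed:
            warnings.warn(f"could not place a {kind} event without overlap; dropped")
            starts.append(-1)
    return starts


def _clot_drift(n: int, target_std: float, rng: np.random.Generator) -> np.ndarray:
    """Low-frequency random-walk baseline drift with the requested std."""
    walk = np.cumsum(rng.standard_normal(n))
    # smooth with a long moving average to kill high-frequency content
    win = max(3, min(n // 10, 5000))
    kernel = np.ones(win) / win
    smooth = np.convolve(walk, kernel, mode="same")
    sd = smooth.std()
    if sd == 0:
        return np.zeros(n)
    return smooth / sd * target_std


def simulate_day(
    config: SimConfig, n_segments: int = 1, seed: int | None = None, day_id: int = 0
) -> tuple[list[TraceSegment], pd.DataFrame]:
    """Simulate one experimental day: segments plus a ground-truth table.

    Every cluster event places correlated scatter pulses on all three
    scatter channels and a co-located green-fluorescence pulse of the
    same transit width (``has_gfp`` true); single cells and confounders
    have no (or only weak) green signal.  A per-day multiplicative power
    factor scales all scatter channels.  Identical ``(config, seed)``
    reproduces identical output bit-for-bit.
    """
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    rng = np.random.default_rng(config.rng_seed if seed is None else seed)
    power = float(np.exp(rng.normal(0.0, config.power_scale_sigma)))
    n = int(round(config.sample_rate * config.segment_duration))
    duration_min = config.segment_duration / 60.0
    baseline_std = np.sqrt(np.asarray(config.channel_baseline_variance))

    segments: list[TraceSegment] = []
    truth_rows: list[dict] = []
    event_id = 0
    for seg_id in range(n_segments):
        scatter = rng.standard_normal((n, 3)) * baseline_std
        gfp = rng.standard_normal(n) * config.gfp_baseline_std
        red = rng.standard_normal(n) * config.red_baseline_std

        specs: list[tuple[str, float, np.ndarray, float]] = []
        for _ in range(rng.poisson(config.single_cell_rate * duration_min)):
            length = float(
                np.clip(rng.normal(*config.single_cell_length), 8.0, 15.0)
            )
            specs.append(("single_cell", length, np.asarray(config.single_cell_amplitude), 0.0))
        for _ in range(rng.poisson(config.ctcc_rate * duration_min)):
            length = _draw_ctcc_length(config, rng)
            specs.append(("ctcc", length, np.asarray(config.ctcc_amplitude), config.gfp_amplitude))
        for _ in range(rng.poisson(config.autofluor_confounder_rate * duration_min)):
            length = float(rng.uniform(*config.confounder_length_range))
            specs.append(
                ("confounder", length, np.asarray(config.confounder_amplitude),
                 config.confounder_green_amplitude)
            )

        widths = [
            max(3, int(round(transit_width_points(
                length, config.slit_width, config.flow_speed, config.sample_rate
            ))))
            for _, length, _, _ in specs
        ]
        starts = _place_events(len(specs), widths, n, rng, "cellular")
        for (kind, length, amp3, gfp_amp), w, s in zip(specs, widths, starts):
            if s < 0:
                continue
            scale = float(np.exp(rng.normal(0.0, config.amplitude_sigma)))
            pulse = render_peak(
                kind, length, amp3 * scale,
                slit_width=config.slit_width, flow_speed=config.flow_speed,
                sample_rate=config.sample_rate,
            )
            m = pulse.shape[0]
            scatter[s : s + m] += pulse
            if gfp_amp > 0:
                gfp[s : s + m] += pulse[:, 0] / pulse[:, 0].max() * gfp_amp * scale
            truth_rows.append(
                dict(
                    event_id=event_id, kind=kind, segment_id=seg_id,
                    start_index=s, end_index=s + m,
                    physical_length_um=length, has_gfp=kind == "ctcc",
                )
            )
            event_id += 1

        n_clots = rng.poisson(config.clot_rate / 60.0 * duration_min)
        if n_clots > 0:
            drift = _clot_drift(n, config.clot_drift_amplitude, rng)
            scatter += drift[:, None] / 3.0
            truth_rows.append(
                dict(
                    event_id=event_id, kind="clot", segment_id=seg_id,
                    start_index=0, end_index=n,
                    physical_length_um=np.nan, has_gfp=False,
                )
            )
            event_id += 1

        scatter *= power
        channels = {
            SCATTER_CHANNELS[0]: scatter[:, 0],
            SCATTER_CHANNELS[1]: scatter[:, 1],
            SCATTER_CHANNELS[2]: scatter[:, 2],
            GFP_CHANNEL: gfp,
            RED_CHANNEL: red,
        }
        segments.append(
            TraceSegment(
                channels=channels, sample_rate=config.sample_rate,
                segment_id=seg_id, day_id=day_id,
                start_time=seg_id * config.segment_duration,
            )
        )

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    if len(truth) == 0:
        truth = truth.astype(
            {"event_id": "int64", "segment_id": "int64",
             "start_index": "int64", "end_index": "int64", "has_gfp": "bool"},
            errors="ignore",
        )
    return segments, truth


def simulate_event_stream(
    ctcc_mean: float,
    nc_mean: float,
    duration_min: float = 60.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Event-level (traceless) stream: Poisson counts, uniform event times.

    Used by the counting-statistics machinery, where only the ordered
    sequence of labeled events matters, not the voltage traces.  Returns
    a DataFrame sorted by ``time_min`` with a binary ``label`` column
    (1 = cluster, 0 = NC).
    """
    rng = np.random.default_rng(seed)
    n_pos = rng.poisson(ctcc_mean)
    n_neg = rng.poisson(nc_mean)
    times = np.concatenate([
        rng.uniform(0, duration_min, n_pos),
        rng.uniform(0, duration_min, n_neg),
    ])
    labels = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)])
    order = np.argsort(times, kind="stable")
    return pd.DataFrame({"time_min": times[order], "label": labels[order]}).reset_index(
        drop=True
    )
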