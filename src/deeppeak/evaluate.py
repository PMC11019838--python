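"""Performance metrics and rare-event counting statistics.

Covers the confusion-matrix metrics (purity/precision, sensitivity,
specificity, accuracy, F1), the false-alarm rate on negative-control
blood, net two-stage performance, Poisson blood-volume planning, and
the observed-vs-theoretical coefficient-of-variation (%CV) analysis
with the fixed-count spiking subsample procedure.

Rare-event planning: to detect an average of ``x`` events at detection
probability ``p``, a sample must contain ``n = x / p`` events; the
required blood volume is ``n / concentration`` and the processing time
``volume / throughput``.  Poisson counting sets a floor on run-to-run
variability: %CV = 100 * sqrt(mu) / mu = 100 / sqrt(mu) for a mean
count ``mu``; extra variance sources combine as
``var(x + y) = var(x) + var(y) + 2 cov(x, y)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    """Confusion-derived metrics; a metric with an undefined denominator is None."""

    purity: float | None
    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    f1: float | None
    far: float | None = None  # events/min, filled by the caller when known
    pcc: float | None = None


@dataclass
class PoissonPlan:
    """Blood-volume plan for detecting ``x`` events at probability ``p``."""

    x: float
    p: float
    n: float                    # required events in the sample, x / p
    n_rounded: int              # ceiling for presentation
    concentration: tuple[float, float] | None = None  # clusters/mL (low, high)
    volume_ml: tuple[float, float] | None = None
    time_hours: tuple[float, float] | None = None


@dataclass
class CVReport:
    target: float
    mu: float                   # mean detected count across replicates
    observed_cv: float          # %
    theoretical_cv: float       # %, Poisson floor at the target
    count_variance: float
    volume_variance: float = 0.0
    combined_variance: float = 0.0


def confusion(true_labels, predicted_labels) -> ConfusionCounts:
    """2x2 tally with the cluster class (1) as positive."""
    y = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {p.shape}")
    return ConfusionCounts(
        tp=int(np.sum((p == 1) & (y == 1))),
        fp=int(np.sum((p == 1) & (y == 0))),
        tn=int(np.sum((p == 0) & (y == 0))),
        fn=int(np.sum((p == 0) & (y == 1))),
    )


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def core_metrics(c: ConfusionCounts) -> MetricsReport:
    """Purity, sensitivity, specificity, accuracy and F1 from counts.

    Undefined denominators yield None rather than 0; F1 is 0 when
    purity + sensitivity = 0.
    """
    purity = _ratio(c.tp, c.tp + c.fp)
    sensitivity = _ratio(c.tp, c.tp + c.fn)
    specificity = _ratio(c.tn, c.tn + c.fp)
    accuracy = _ratio(c.tp + c.tn, c.total)
    if purity is None or sensitivity is None:
        f1 = None
    elif purity + sensitivity == 0:
        f1 = 0.0
    else:
        f1 = 2 * purity * sensitivity / (purity + sensitivity)
    return MetricsReport(purity, sensitivity, specificity, accuracy, f1)


def f1_score(purity: float, sensitivity: float) -> float:
    """Harmonic mean of purity and sensitivity (0 when both are 0)."""
    if purity + sensitivity == 0:
        return 0.0
    return 2 * purity * sensitivity / (purity + sensitivity)


def false_alarm_rate(fp_count: int, minutes: float) -> float:
    """False positives per minute of negative-control data."""
    if minutes <= 0:
        raise ValueError("minutes must be positive")
    if fp_count < 0:
        raise ValueError("fp_count must be non-negative")
    return fp_count / minutes


def net_sensitivity(detection_sensitivity: float, classification_sensitivity: float) -> float:
    """Net two-stage sensitivity: the product of the stage sensitivities."""
    for v in (detection_sensitivity, classification_sensitivity):
        if not 0 <= v <= 1:
            raise ValueError("sensitivities must be in [0, 1]")
    return detection_sensitivity * classification_sensitivity


def net_specificity(tn_detect: int, tn_class: int, fp_final: int) -> float | None:
    """Net specificity from the NC events rejected by either stage.

    TN_total = TN_detect + TN_class; net specificity =
    TN_total / (TN_total + FP_final).  None when all counts are zero.
    """
    if min(tn_detect, tn_class, fp_final) < 0:
        raise ValueError("counts must be non-negative")
    tn_total = tn_detect + tn_class
    return _ratio(tn_total, tn_total + fp_final)


def pearson_correlation(detected_counts, true_counts) -> float | None:
    """Product-moment correlation between detected and expected counts."""
    x = np.asarray(detected_counts, dtype=float)
    y = np.asarray(true_counts, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired units")
    if x.std() == 0 or y.std() == 0:
        warnings.warn("zero variance in one series; correlation undefined")
        return None
    return float(np.corrcoef(x, y)[0, 1])


def poisson_min_events(p: float, x: float = 1.0) -> PoissonPlan:
    """Events needed in a sample to detect an average of ``x`` at probability ``p``.

    n = x / p exactly (so n * p = x pre-rounding); the presentation
    value is the ceiling.  At the model's net sensitivity of ~0.353,
    detecting one cluster needs ~3 present.
    """
    if not 0 < p <= 1:
        raise ValueError("p must be in (0, 1]")
    if x <= 0:
        raise ValueError("x must be positive")
    n = x / p
    return PoissonPlan(x=x, p=p, n=n, n_rounded=int(np.ceil(n - 1e-12)))


def blood_volume_and_time(
    n: float,
    concentration_range: tuple[float, float],
    throughput_ul_min: float,
) -> PoissonPlan:
    """Blood volume (mL) and processing time (h) to contain ``n`` clusters.

    ``concentration_range`` is (low, high) clusters/mL; the low
    concentration gives the larger required volume.  Returns unrounded
    values; presentation rounding is left to the caller.
    """
    lo, hi = concentration_range
    if lo <= 0 or hi <= 0 or throughput_ul_min <= 0:
        raise ValueError("concentrations and throughput must be positive")
    vol = (n / hi, n / lo)  # mL, (smaller, larger)
    time_h = tuple(v * 1e3 / throughput_ul_min / 60.0 for v in vol)
    return PoissonPlan(
        x=np.nan, p=np.nan, n=n, n_rounded=int(np.ceil(n - 1e-12)),
        concentration=(lo, hi), volume_ml=vol, time_hours=time_h,
    )


def theoretical_cv(mu: float) -> float:
    """Poisson counting %CV: 100 * sqrt(mu) / mu."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    return 100.0 * np.sqrt(mu) / mu


def combined_variance(var_x: float, var_y: float, cov_xy: float = 0.0) -> float:
    """var(x + y) = var(x) + var(y) + 2 cov(x, y), floored at zero."""
    if var_x < 0 or var_y < 0:
        raise ValueError("variances must be non-negative")
    total = var_x + var_y + 2.0 * cov_xy
    if total < 0:
        warnings.warn("combined variance numerically negative; floored at 0")
        return 0.0
    return total


def spiking_subsample(
    events: pd.DataFrame,
    target_ctcc_counts: tuple[int, ...] = (5, 10, 30, 50, 100),
    label_column: str = "label",
) -> dict[int, pd.DataFrame]:
    """Fixed-count subsets of a time-ordered event stream.

    For each target ``k``, returns the prefix of the stream up to and
    including the k-th ground-truth cluster — every NC event recorded
    before that moment is included, mimicking truncating the recording
    once the desired spike count has been observed.  Subsets are nested.
    Targets beyond the number of available clusters are dropped with a
    warning.
    """
    labels = events[label_column].to_numpy(dtype=int)
    cum_pos = np.cumsum(labels == 1)
    n_pos = int(cum_pos[-1]) if len(cum_pos) else 0
    out: dict[int, pd.DataFrame] = {}
    for k in sorted(target_ctcc_counts):
        if k == 0:
            out[k] = events.iloc[0:0]
            continue
        if k > n_pos:
            warnings.warn(
                f"stream holds only {n_pos} clusters; target {k} dropped"
            )
            continue
        cut = int(np.searchsorted(cum_pos, k)) + 1
        out[k] = events.iloc[:cut]
    return out


def cv_report(
    detected_counts, target: float, volume_counts=None
) -> CVReport:
    """Observed vs theoretical %CV of detected counts across replicates.

    ``volume_counts`` (optional) are per-replicate NC-event counts used
    to estimate the volume-variability term: their variance is scaled to
    the cluster rate (target / mean NC count) and combined with the
    Poisson counting variance (covariance taken as 0).
    """
    counts = np.asarray(detected_counts, dtype=float)
    if len(counts) < 3:
        raise ValueError("need >= 3 replicates")
    mu = float(counts.mean())
    count_var = float(counts.var(ddof=1))
    observed = 100.0 * np.sqrt(count_var) / mu if mu > 0 else 0.0
    vol_var = 0.0
    if volume_counts is not None:
        vol = np.asarray(volume_counts, dtype=float)
        if vol.mean() > 0:
            vol_var = float(vol.var(ddof=1)) * (target / vol.mean()) ** 2
    combined = combined_variance(target, vol_var)
    return CVReport(
        target=target, mu=mu, observed_cv=float(observed),
        theoretical_cv=theoretical_cv(target), count_variance=count_var,
        volume_variance=vol_var, combined_variance=combined,
    )


def cv_study(
    count_fn,
    replicates_by_target: dict[int, list[pd.DataFrame]],
    include_volume_term: bool = False,
) -> list[CVReport]:
    """%CV analysis of a counting model over replicate event streams.

    ``count_fn(stream) -> int`` is the model's detected-cluster count
    for one replicate stream (an ideal detector simply counts the
    ground-truth labels).  For each target the observed %CV across its
    replicates is compared with the Poisson floor 100/sqrt(target).
    """
    reports = []
    for target in sorted(replicates_by_target):
        reps = replicates_by_target[target]
        if len(reps) < 3:
            raise ValueError(f"target {target}: need >= 3 replicates")
        counts = [count_fn(r) for r in reps]
        vols = None
        if include_volume_term:
            vols = [int((r["label"] == 0).sum()) for r in reps]
        reports.append(cv_report(counts, target, volume_counts=vols))
    return reports
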