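"""Feature vectors, ground-truth labeling, and day-wise dataset splits.

Classifier inputs are 297-point vectors built from the *raw* (unfiltered)
scatter channels: each channel is z-scored over its segment, a window of
+-49 samples around the peak is extracted (99 values), and the three
windows are concatenated in 405 / 488 / 633 nm order (features 1-99,
100-198, 199-297).  The filtered trace is used only for ROI finding.

Labels come from the green-fluorescence (GFLR) ground-truth channel: a
scatter ROI is a cluster (CTCC) if it is wider than the 17-point gate in
the cumulative scatter trace *and* matches a fluorescence ROI, or if its
matching fluorescence ROI is itself wider than 17 points; otherwise it
is a non-cluster (NC) event.  Splits are always by experimental day,
never by event, so no day leaks between train, validation and test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .roi_detect import RoiEvent
from .trace_io import SCATTER_CHANNELS, TraceSegment

N_FEATURES = 297
HALF_WINDOW = 49

LABEL_CTCC = 1
LABEL_NC = 0


def build_feature_vector(segment: TraceSegment, peak_index: int) -> np.ndarray:
    """The 297-point z-scored scatter window around one peak.

    Windows crossing a segment boundary are edge-padded with the
    boundary value; a zero-variance channel contributes 99 zeros.
    """
    n = segment.n_samples
    if not 0 <= peak_index < n:
        raise ValueError(f"peak_index {peak_index} outside segment of {n} samples")
    parts = []
    for name in SCATTER_CHANNELS:
        x = segment.channels[name]
        std = x.std()
        if std == 0:
            warnings.warn(f"channel {name} has zero variance; features set to 0")
            parts.append(np.zeros(2 * HALF_WINDOW + 1))
            continue
        z = (x - x.mean()) / std
        lo, hi = peak_index - HALF_WINDOW, peak_index + HALF_WINDOW + 1
        window = z[max(lo, 0) : min(hi, n)]
        if lo < 0:
            window = np.concatenate([np.full(-lo, z[0]), window])
        if hi > n:
            window = np.concatenate([window, np.full(hi - n, z[-1])])
        parts.append(window)
    return np.concatenate(parts)


def _overlaps(a: RoiEvent, b: RoiEvent) -> bool:
    return a.start_index < b.end_index and b.start_index < a.end_index


def _centers_close(a: RoiEvent, b: RoiEvent, max_distance: int) -> bool:
    return abs(a.peak_index - b.peak_index) <= max_distance


def label_events(
    scatter_rois: list[RoiEvent],
    gfp_rois: list[RoiEvent],
    min_fwhm: int = 17,
    match: str = "overlap",
    max_center_distance: int = 25,
) -> list[int]:
    """Assign CTCC/NC labels to scatter ROIs against fluorescence ROIs.

    A scatter ROI is labeled CTCC iff its FWHM is strictly greater than
    the gate and it matches a fluorescence ROI, or a matching
    fluorescence ROI has FWHM strictly greater than the gate.  Matching
    is any index-range overlap by default (``match='center'`` uses
    apex distance instead).  Depends only on (FWHM, overlap) pairs, so
    it is insensitive to the ordering of either list.
    """
    if match not in ("overlap", "center"):
        raise ValueError("match must be 'overlap' or 'center'")
    labels = []
    for sroi in scatter_rois:
        if match == "overlap":
            matched = [g for g in gfp_rois if _overlaps(sroi, g)]
        else:
            matched = [g for g in gfp_rois if _centers_close(sroi, g, max_center_distance)]
        is_ctcc = bool(matched) and (
            sroi.fwhm_samples > min_fwhm
            or any(g.fwhm_samples > min_fwhm for g in matched)
        )
        labels.append(LABEL_CTCC if is_ctcc else LABEL_NC)
    return labels


@dataclass(frozen=True)
class DatasetSplit:
    """One train/validation partition plus the shared held-out test days."""

    fold_id: int
    train_days: tuple[int, ...]
    val_days: tuple[int, ...]
    test_days: tuple[int, ...]


def make_splits(
    day_ids: list[int],
    test_fraction: float = 11 / 34,
    n_folds: int = 5,
    val_fraction: float = 0.21,
    seed: int = 0,
) -> list[DatasetSplit]:
    """Day-wise splits: one fixed test set plus rotating train/val folds.

    With 34 days at the default fractions this yields an 11-day test set
    and five folds of 18 training / 5 validation days.  Validation
    windows rotate through the shuffled train+val days with evenly
    spaced offsets, so each fold partitions those days into train | val.
    Deterministic given the seed.
    """
    days = list(dict.fromkeys(day_ids))
    if len(days) < 3:
        raise ValueError("need at least 3 days to split")
    rng = np.random.default_rng(seed)
    order = [days[i] for i in rng.permutation(len(days))]
    n_test = int(round(test_fraction * len(days)))
    n_test = min(max(n_test, 1), len(days) - 2)
    test = tuple(sorted(order[:n_test]))
    trainval = order[n_test:]
    m = len(trainval)
    n_val = max(1, int(round(val_fraction * m)))
    if m - n_val < 1 or n_folds > m:
        raise ValueError(
            f"too few days ({m} after the test split) for {n_folds} folds "
            f"with {n_val} validation days"
        )
    splits = []
    for k in range(n_folds):
        off = int(round(k * m / n_folds))
        off = min(off, m - n_val)
        val = trainval[off : off + n_val]
        train = [d for d in trainval if d not in val]
        splits.append(
            DatasetSplit(
                fold_id=k, train_days=tuple(sorted(train)),
                val_days=tuple(sorted(val)), test_days=test,
            )
        )
    return splits


def examples_from_segment(
    segment: TraceSegment,
    scatter_rois: list[RoiEvent],
    gfp_rois: list[RoiEvent],
    min_fwhm: int = 17,
) -> pd.DataFrame:
    """Feature-vector rows plus labels and provenance for one segment.

    Class imbalance is preserved as-is: imbalance is handled by the
    classifier's loss, not by resampling the data.
    """
    labels = label_events(scatter_rois, gfp_rois, min_fwhm=min_fwhm)
    rows = []
    for roi, label in zip(scatter_rois, labels):
        feats = build_feature_vector(segment, roi.peak_index)
        row = {f"f{i + 1}": feats[i] for i in range(N_FEATURES)}
        row.update(
            label=label, day_id=segment.day_id, segment_id=segment.segment_id,
            peak_index=roi.peak_index, fwhm_samples=roi.fwhm_samples,
        )
        rows.append(row)
    cols = [f"f{i + 1}" for i in range(N_FEATURES)] + [
        "label", "day_id", "segment_id", "peak_index", "fwhm_samples",
    ]
    return pd.DataFrame(rows, columns=cols)


def feature_matrix(examples: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """(X, y) arrays from an examples table."""
    cols = [f"f{i + 1}" for i in range(N_FEATURES)]
    return examples[cols].to_numpy(dtype=float), examples["label"].to_numpy(dtype=int)
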