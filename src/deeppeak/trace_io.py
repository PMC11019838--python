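"""Reading, writing and segmenting multi-channel voltage traces.

The acquisition chain stores five synchronized channels sampled at 60 kHz
as delimited text: three elastic-scatter channels (405/488/633 nm), one
green exogenous-fluorescence ground-truth channel (525 nm) and one red
autofluorescence channel (670 nm).  Long recordings are split into
1.5-minute analysis segments that are processed independently.

Index convention: all sample positions are 0-based and ranges are
half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

SCATTER_CHANNELS = ("scatter405", "scatter488", "scatter633")
GFP_CHANNEL = "gfp525"
RED_CHANNEL = "red670"
ALL_CHANNELS = SCATTER_CHANNELS + (GFP_CHANNEL, RED_CHANNEL)

#: precision used when writing traces as text (significant digits)
TEXT_PRECISION = 6

PEAK_TABLE_COLUMNS = [
    "segment_id",
    "channel_group",
    "peak_index",
    "start_index",
    "end_index",
    "fwhm_samples",
    "peak_intensity",
    "t2_score",
]


class SchemaError(ValueError):
    """A file or table does not have the expected columns/channels."""


class TraceParseError(ValueError):
    """A trace file contains malformed rows."""


@dataclass
class TraceRecord:
    """A continuous multi-channel recording (not yet segmented).

    ``channels`` maps channel name to a 1-D float array; all present
    channels have equal length.  ``missing_channels`` lists optional
    channels that were absent from the source file (they are flagged,
    never fabricated).
    """

    channels: dict[str, np.ndarray]
    sample_rate: float = 60_000.0
    day_id: int = 0
    missing_channels: tuple[str, ...] = ()

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))


@dataclass
class TraceSegment:
    """A fixed-rate block of synchronized voltage channels.

    This is the object all signal processing acts on.  The last segment
    of a stream may be shorter than the nominal duration; it is kept and
    flagged ``partial``.
    """

    channels: dict[str, np.ndarray]
    sample_rate: float
    segment_id: int = 0
    day_id: int = 0
    start_time: float = 0.0
    partial: bool = False
    missing_channels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) > 1:
            raise SchemaError(f"channels have unequal lengths: {sorted(lengths)}")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    def scatter_matrix(self) -> np.ndarray:
        """Stack the three scatter channels as an (n_samples, 3) matrix."""
        missing = [c for c in SCATTER_CHANNELS if c not in self.channels]
        if missing:
            raise SchemaError(f"missing mandatory scatter channels: {missing}")
        return np.column_stack([self.channels[c] for c in SCATTER_CHANNELS])

    def copy(self) -> "TraceSegment":
        return TraceSegment(
            channels={k: v.copy() for k, v in self.channels.items()},
            sample_rate=self.sample_rate,
            segment_id=self.segment_id,
            day_id=self.day_id,
            start_time=self.start_time,
            partial=self.partial,
            missing_channels=self.missing_channels,
        )


def write_trace_csv(record: TraceRecord | TraceSegment, path: str | Path) -> None:
    """Write a trace as CSV: one column per channel, one row per sample."""
    path = Path(path)
    df = pd.DataFrame({k: v for k, v in record.channels.items()})
    df.to_csv(path, index=False, float_format=f"%.{TEXT_PRECISION}g")


def read_trace_csv(
    path: str | Path, sample_rate: float = 60_000.0, day_id: int = 0
) -> TraceRecord:
    """Read a continuous multi-channel record from a delimited text file.

    Channels are matched by header name, never by position.  The three
    scatter channels are mandatory; fluorescence channels are optional
    and flagged as missing when absent.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:  # pragma: no cover - message passthrough
        raise TraceParseError(f"malformed trace file {path}: {exc}") from exc
    missing_scatter = [c for c in SCATTER_CHANNELS if c not in df.columns]
    if missing_scatter:
        raise SchemaError(
            f"{path}: missing mandatory scatter channels {missing_scatter}; "
            f"found columns {list(df.columns)}"
        )
    # malformed (non-numeric) rows are reported with their line number
    channels: dict[str, np.ndarray] = {}
    for name in ALL_CHANNELS:
        if name not in df.columns:
            continue
        col = pd.to_numeric(df[name], errors="coerce").to_numpy(dtype=float)
        bad = np.flatnonzero(np.isnan(col) & df[name].notna().to_numpy())
        if bad.size:
            raise TraceParseError(
                f"{path}: non-numeric value in column {name!r} at data line {bad[0] + 2}"
            )
        channels[name] = col
    missing = tuple(c for c in ALL_CHANNELS if c not in channels)
    return TraceRecord(
        channels=channels, sample_rate=sample_rate, day_id=day_id, missing_channels=missing
    )


def segment_stream(
    record: TraceRecord, segment_duration: float = 90.0
) -> list[TraceSegment]:
    """Split a continuous record into consecutive non-overlapping segments.

    Concatenating the returned segments restores the record exactly (the
    split is a partition: no sample duplicated or dropped).  A final
    partial segment is retained and flagged.
    """
    n = record.n_samples
    if n == 0:
        raise ValueError("record is empty")
    seg_len = int(round(segment_duration * record.sample_rate))
    if seg_len <= 0:
        raise ValueError("segment_duration too short for the sample rate")
    segments: list[TraceSegment] = []
    for seg_id, start in enumerate(range(0, n, seg_len)):
        end = min(start + seg_len, n)
        segments.append(
            TraceSegment(
                channels={k: v[start:end] for k, v in record.channels.items()},
                sample_rate=record.sample_rate,
                segment_id=seg_id,
                day_id=record.day_id,
                start_time=start / record.sample_rate,
                partial=(end - start) < seg_len,
                missing_channels=record.missing_channels,
            )
        )
    return segments


def new_peak_table(rows: list[dict] | None = None) -> pd.DataFrame:
    """An empty (or row-initialized) peak-characteristics table."""
    df = pd.DataFrame(rows if rows else [], columns=PEAK_TABLE_COLUMNS)
    return df.astype(
        {
            "segment_id": "int64",
            "channel_group": "object",
            "peak_index": "int64",
            "start_index": "int64",
            "end_index": "int64",
            "fwhm_samples": "int64",
            "peak_intensity": "float64",
            "t2_score": "float64",
        }
    )


def write_peak_table(table: pd.DataFrame, path: str | Path) -> None:
    """Persist a peak table as CSV with a stable column order.

    A header comment documents the 0-based, half-open index convention.
    """
    missing = [c for c in PEAK_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"peak table missing columns: {missing}")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# indices are 0-based; ranges are half-open [start_index, end_index)\n")
        table[PEAK_TABLE_COLUMNS].to_csv(fh, index=False, float_format="%.10g")


def read_peak_table(path: str | Path) -> pd.DataFrame:
    """Read a peak table written by :func:`write_peak_table`."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in PEAK_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: peak table missing columns {missing}")
    if len(df) == 0:
        return new_peak_table()
    out = df[PEAK_TABLE_COLUMNS].copy()
    for col in ("segment_id", "peak_index", "start_index", "end_index", "fwhm_samples"):
        out[col] = out[col].astype("int64")
    return out
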