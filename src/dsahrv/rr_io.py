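"""Reading and writing RR-interval segments.

An RR interval is the time between two consecutive R-waves (heartbeats)
of an ECG, expressed here in seconds.  Segments are the unit of analysis:
each carries an id, an ordered list of RR intervals, and an optional
rhythm label (``SR`` for sinus rhythm, ``PAF`` for paroxysmal atrial
fibrillation).

The on-disk format is a flat CSV with header ``segment_id,rr_seconds``
and an optional ``label`` column; a separate two-column manifest
(``segment_id,label``) can attach or override labels.  R-peak sample
indices plus a sampling rate can be converted to RR intervals with
:func:`rr_from_rpeaks`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RPeakSeries",
    "RRSeries",
    "rr_from_rpeaks",
    "read_rr_csv",
    "write_rr_csv",
    "read_manifest",
    "attach_labels",
    "write_feature_table",
    "read_feature_table",
]

VALID_LABELS = ("SR", "PAF", "unlabeled")


@dataclass
class RPeakSeries:
    """R-wave sample indices for one ECG segment.

    ``peaks`` are strictly increasing integer sample indices; ``fs`` is
    the sampling rate in Hz.  A segment of N+1 R-waves yields N RR
    intervals.
    """

    segment_id: str
    peaks: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.peaks = np.asarray(self.peaks)
        if self.fs <= 0:
            raise ValueError("invalid sampling rate: fs must be > 0")
        if self.peaks.size < 2:
            raise ValueError("insufficient peaks: need at least 2 R-waves")
        if np.any(np.diff(self.peaks) <= 0):
            raise ValueError("unsorted annotation: peaks must be strictly increasing")


@dataclass
class RRSeries:
    """One labeled segment of RR intervals in seconds."""

    segment_id: str
    rr: np.ndarray
    label: str = "unlabeled"

    def __post_init__(self) -> None:
        self.rr = np.asarray(self.rr, dtype=float)
        if self.rr.size and np.any(self.rr <= 0):
            raise ValueError("invalid RR value: intervals must be > 0")
        if self.label not in VALID_LABELS:
            raise ValueError(f"unknown label {self.label!r}; expected one of {VALID_LABELS}")

    @property
    def n(self) -> int:
        """Number of intervals N."""
        return int(self.rr.size)


def rr_from_rpeaks(peaks: RPeakSeries, label: str = "unlabeled") -> RRSeries:
    """Derive RR intervals (seconds) from R-peak sample indices.

    r_j = (R_{j+1} - R_j) / fs, giving N intervals from N+1 peaks.
    """
    rr = np.diff(peaks.peaks.astype(float)) / peaks.fs
    return RRSeries(segment_id=peaks.segment_id, rr=rr, label=label)


def read_rr_csv(path: str | Path) -> list[RRSeries]:
    """Read segments from an RR CSV (``segment_id,rr_seconds[,label]``).

    One :class:`RRSeries` per distinct segment id, preserving row order
    within a segment.  Raises ``ValueError`` on missing columns or
    non-positive / non-numeric RR values (reporting the offending row).
    """
    df = pd.read_csv(path, dtype={"segment_id": str}, float_precision="round_trip")
    required = {"segment_id", "rr_seconds"}
    if not required.issubset(df.columns):
        missing = sorted(required - set(df.columns))
        raise ValueError(f"malformed input: missing columns {missing}")
    rr_num = pd.to_numeric(df["rr_seconds"], errors="coerce")
    bad = rr_num.isna() | (rr_num <= 0)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
        raise ValueError(f"invalid RR value at line {row}: RR must be numeric and > 0")
    df = df.assign(rr_seconds=rr_num)

    has_label = "label" in df.columns
    out: list[RRSeries] = []
    for seg_id, grp in df.groupby("segment_id", sort=False):
        label = "unlabeled"
        if has_label:
            labels = grp["label"].dropna().unique()
            if len(labels) > 1:
                raise ValueError(f"malformed input: conflicting labels for segment {seg_id!r}")
            if len(labels) == 1:
                label = str(labels[0])
        out.append(RRSeries(segment_id=str(seg_id), rr=grp["rr_seconds"].to_numpy(), label=label))
    return out


def write_rr_csv(segments: Iterable[RRSeries], path: str | Path, include_label: bool = True) -> None:
    """Write segments to the RR CSV format (inverse of :func:`read_rr_csv`)."""
    rows = []
    for seg in segments:
        for r in seg.rr:
            row = {"segment_id": seg.segment_id, "rr_seconds": r}
            if include_label:
                row["label"] = seg.label
            rows.append(row)
    cols = ["segment_id", "rr_seconds"] + (["label"] if include_label else [])
    # %.17g round-trips float64 exactly
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False, float_format="%.17g")


def read_manifest(path: str | Path) -> dict[str, str]:
    """Read a ``segment_id,label`` manifest into a mapping."""
    df = pd.read_csv(path, dtype=str)
    if not {"segment_id", "label"}.issubset(df.columns):
        raise ValueError("malformed input: manifest needs segment_id and label columns")
    return dict(zip(df["segment_id"], df["label"]))


def attach_labels(segments: Sequence[RRSeries], manifest: dict[str, str]) -> list[RRSeries]:
    """Return segments relabeled from a manifest (ids absent keep their label)."""
    return [
        RRSeries(s.segment_id, s.rr, manifest.get(s.segment_id, s.label))
        for s in segments
    ]


def write_feature_table(features: Sequence, path: str | Path) -> None:
    """Write a flat per-segment feature table.

    One row per segment: ``segment_id, label, V, W, max_cooccurrence``
    followed by the flattened transition-probability cells ``p0..p{V^W-1}``
    in row-major order.  All vectors must share one (V, W) setting so the
    table has rectangular shape.
    """
    features = list(features)
    if not features:
        pd.DataFrame(columns=["segment_id", "label", "V", "W", "max_cooccurrence"]).to_csv(
            path, index=False
        )
        return
    dim = features[0].values.size
    if any(fv.values.size != dim for fv in features):
        raise ValueError("inconsistent feature dimensions: vectors differ in length")
    rows = []
    for fv in features:
        row = {
            "segment_id": fv.segment_id,
            "label": fv.label,
            "V": fv.V,
            "W": fv.W,
            "max_cooccurrence": fv.max_cooccurrence,
        }
        row.update({f"p{i}": v for i, v in enumerate(fv.values)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature table written by :func:`write_feature_table`."""
    df = pd.read_csv(path, dtype={"segment_id": str}, float_precision="round_trip")
    required = {"segment_id", "label", "V", "W", "max_cooccurrence"}
    if not required.issubset(df.columns):
        raise ValueError("malformed input: not a feature table")
    return df
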