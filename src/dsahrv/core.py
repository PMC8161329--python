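"""The dynamic symbolic assignment (DSA) transform.

RR intervals are discretized against a *dynamic* threshold list derived
from the segment's own mean interval r̄: with relative step t (default
0.05) and an odd vocabulary size V, the V−1 thresholds are

    T = { r̄·(1 − t·(1+k)), r̄·(1 + t·(1+k)) : k = 0 … (V−3)/2 },

sorted ascending — e.g. V=5 gives 0.90 r̄, 0.95 r̄, 1.05 r̄, 1.10 r̄.
Each interval r_j is then mapped to symbol v_i (rendered 'a', 'b', …)
via the half-open rule T_{i−1} ≤ r_j < T_i, with implicit outer bounds
T_0 = 0 and T_V = +∞ so every positive value receives exactly one
symbol.  Because the thresholds scale with the mean, the symbolization
is invariant to rescaling the series — no fixed amplitude breakpoints
are involved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rr_io import RRSeries

__all__ = [
    "ThresholdList",
    "SymbolSequence",
    "mean_rr",
    "build_thresholds",
    "symbolize",
    "dsa_transform",
]

MAX_VOCAB = 25  # symbols render as lowercase letters 'a'..'y'


@dataclass
class ThresholdList:
    """Ordered dynamic thresholds T_1 < … < T_{V−1} for one segment."""

    thresholds: np.ndarray
    V: int
    t: float
    mean_rr: float

    @property
    def k_max(self) -> int:
        """Largest step index k used: (V−3)/2."""
        return (self.V - 3) // 2


@dataclass
class SymbolSequence:
    """A discretized RR segment: symbol indices in [0, V) plus rendering."""

    indices: np.ndarray  # 0-based bin indices
    V: int
    segment_id: str = ""
    label: str = "unlabeled"

    @property
    def symbols(self) -> str:
        """The sequence rendered as lowercase letters."""
        return "".join(chr(ord("a") + i) for i in self.indices)

    def __len__(self) -> int:
        return int(self.indices.size)


def mean_rr(rr: RRSeries | np.ndarray) -> float:
    """Arithmetic mean interval r̄ of a non-empty segment, in seconds."""
    values = rr.rr if isinstance(rr, RRSeries) else np.asarray(rr, dtype=float)
    if values.size == 0:
        raise ValueError("empty RR series")
    return float(values.mean())


def build_thresholds(mean: float, V: int, t: float = 0.05) -> ThresholdList:
    """Build the V−1 dynamic thresholds around a segment mean.

    Parameters
    ----------
    mean : mean RR interval in seconds (> 0).
    V : vocabulary size; odd, 3 ≤ V ≤ 25.  Oddness keeps the list
        symmetric about the mean with a middle bin containing it.
    t : relative step between adjacent thresholds (default 0.05).
    """
    if mean <= 0:
        raise ValueError("invalid mean: must be > 0")
    if V % 2 == 0:
        raise ValueError("vocabulary size must be odd")
    if not 3 <= V <= MAX_VOCAB:
        raise ValueError(f"vocabulary size must be in [3, {MAX_VOCAB}]")
    if t <= 0:
        raise ValueError("relative step t must be > 0")
    offsets = t * (1 + np.arange((V - 1) // 2))
    th = mean * np.sort(np.concatenate([1.0 - offsets, 1.0 + offsets]))
    if th[0] <= 0:
        raise ValueError("threshold underflow: t too large for this vocabulary size")
    return ThresholdList(thresholds=th, V=V, t=t, mean_rr=mean)


def symbolize(rr: RRSeries, th: ThresholdList) -> SymbolSequence:
    """Map each interval to its bin under T_{i−1} ≤ r < T_i.

    Values below the lowest threshold get the first symbol, values at or
    above the highest get the last; a value exactly equal to a threshold
    falls in the upper bin (the half-open convention).
    """
    if rr.n == 0:
        raise ValueError("empty RR series")
    idx = np.searchsorted(th.thresholds, rr.rr, side="right")
    return SymbolSequence(indices=idx, V=th.V, segment_id=rr.segment_id, label=rr.label)


def dsa_transform(
    rr: RRSeries, V: int, t: float = 0.05, mean: float | None = None
) -> SymbolSequence:
    """Full DSA transform: segment mean → dynamic thresholds → symbols.

    Thresholds are computed from the segment's own mean, which is what
    makes the assignment dynamic; pass ``mean`` to pin an external
    reference mean instead (for experimentation only).
    """
    m = mean_rr(rr) if mean is None else mean
    return symbolize(rr, build_thresholds(m, V, t))


def write_symbol_file(sequences, path) -> None:
    """Write symbol sequences as ``segment_id<TAB>label<TAB>symbols`` lines."""
    with open(path, "w", encoding="utf-8") as fh:
        for seq in sequences:
            fh.write(f"{seq.segment_id}\t{seq.label}\t{seq.symbols}\n")


def read_symbol_file(path, V: int) -> list[SymbolSequence]:
    """Read sequences written by :func:`write_symbol_file`."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            seg_id, label, symbols = line.rstrip("\n").split("\t")
            idx = np.array([ord(c) - ord("a") for c in symbols])
            out.append(SymbolSequence(indices=idx, V=V, segment_id=seg_id, label=label))
    return out
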