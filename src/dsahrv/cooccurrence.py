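"""Co-occurrence pattern-transition matrices and the derived features.

A window of total length W slides over a symbol sequence with stride 1;
the first W−1 symbols form the row pattern and the final symbol the
column.  Rows enumerate all V^(W−1) patterns in lexicographic order
(never-observed patterns keep zero rows), so sequences of any length
share one feature space of fixed dimension V^W.

Counts are normalized *globally* — each cell is divided by the total
number of windows, len(D) − W + 1 — so the probability matrix P is a
joint distribution over (pattern, symbol), not a per-row conditional
Markov matrix.  Row-major flattening of P gives the feature vector P→;
its largest entry, the *max co-occurrence*, is high for regular rhythms
(one dominant transition) and low for irregular ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd

from .core import SymbolSequence

__all__ = [
    "TransitionMatrix",
    "FeatureVector",
    "count_transitions",
    "transition_probabilities",
    "flatten",
    "max_cooccurrence",
    "export_heatmap_matrix",
    "read_heatmap_matrix",
]

MIN_WORD, MAX_WORD = 2, 5


def _pattern_labels(V: int, length: int) -> list[str]:
    alphabet = [chr(ord("a") + i) for i in range(V)]
    return ["".join(p) for p in product(alphabet, repeat=length)]


@dataclass
class TransitionMatrix:
    """Transition counts M (and probabilities P once normalized)."""

    counts: np.ndarray  # shape (V**(W-1), V), integer
    V: int
    W: int
    segment_id: str = ""
    label: str = "unlabeled"
    probs: np.ndarray | None = None

    @property
    def total(self) -> int:
        """Number of windows counted: len(D) − W + 1 for a single sequence."""
        return int(self.counts.sum())

    @property
    def row_labels(self) -> list[str]:
        return _pattern_labels(self.V, self.W - 1)

    @property
    def col_labels(self) -> list[str]:
        return _pattern_labels(self.V, 1)


@dataclass
class FeatureVector:
    """Row-major flattening P→ of a probability matrix, length V^W."""

    values: np.ndarray
    V: int
    W: int
    segment_id: str = ""
    label: str = "unlabeled"

    @property
    def max_cooccurrence(self) -> float:
        if self.values.size == 0:
            raise ValueError("empty feature vector")
        return float(self.values.max())


def count_transitions(D: SymbolSequence, W: int, max_word: int = MAX_WORD) -> TransitionMatrix:
    """Count pattern→symbol transitions with an overlapping length-W window."""
    if not MIN_WORD <= W <= max_word:
        raise ValueError(f"unsupported word size: W must be in [{MIN_WORD}, {max_word}]")
    n = len(D)
    if n < W:
        raise ValueError("sequence too short for word size")
    V = D.V
    counts = np.zeros((V ** (W - 1), V), dtype=np.int64)
    idx = D.indices
    # base-V encoding of the (W-1)-symbol row pattern
    powers = V ** np.arange(W - 2, -1, -1)
    windows = np.lib.stride_tricks.sliding_window_view(idx, W)
    rows = windows[:, :-1] @ powers
    cols = windows[:, -1]
    np.add.at(counts, (rows, cols), 1)
    return TransitionMatrix(counts=counts, V=V, W=W, segment_id=D.segment_id, label=D.label)


def transition_probabilities(M: TransitionMatrix) -> TransitionMatrix:
    """Fill ``probs`` by dividing every cell by the grand total of counts."""
    total = M.total
    if total == 0:
        raise ValueError("no transitions to normalize")
    M.probs = M.counts / total
    return M


def flatten(M: TransitionMatrix) -> FeatureVector:
    """Concatenate the probability rows into the single vector P→."""
    if M.probs is None:
        raise ValueError("normalize before flattening")
    return FeatureVector(
        values=M.probs.ravel().copy(),
        V=M.V,
        W=M.W,
        segment_id=M.segment_id,
        label=M.label,
    )


def max_cooccurrence(fv: FeatureVector) -> float:
    """The largest cell of P→ — the scalar DSA feature."""
    return fv.max_cooccurrence


def features_from_sequence(D: SymbolSequence, W: int) -> FeatureVector:
    """Convenience chain: count → normalize → flatten."""
    return flatten(transition_probabilities(count_transitions(D, W)))


def export_heatmap_matrix(M: TransitionMatrix, path: str | Path) -> None:
    """Write the probability matrix as a labeled CSV grid.

    Rows are the (W−1)-symbol patterns in lexicographic order, columns
    the following symbol — the layout used for transition heatmaps.
    """
    if M.probs is None:
        raise ValueError("normalize before flattening")
    df = pd.DataFrame(M.probs, index=M.row_labels, columns=M.col_labels)
    df.to_csv(path, index_label="pattern")


def read_heatmap_matrix(path: str | Path) -> pd.DataFrame:
    """Read a grid written by :func:`export_heatmap_matrix`."""
    return pd.read_csv(path, index_col="pattern")
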