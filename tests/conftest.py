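import numpy as np
import pytest

from dsahrv.core import SymbolSequence
from dsahrv.synthetic import SynthConfig


def sequence_from_string(text: str, V: int, segment_id: str = "seq", label: str = "unlabeled"):
    idx = np.array([ord(c) - ord("a") for c in text])
    return SymbolSequence(indices=idx, V=V, segment_id=segment_id, label=label)


@pytest.fixture
def example_sequence():
    """The three-symbol sequence used throughout the worked derivations."""
    return sequence_from_string("aabcbbbcbcbbbababc", V=3)


@pytest.fixture
def small_synth_cfg():
    """Short segments, few per class — enough to exercise every stage."""
    return SynthConfig(n_per_class=8, duration_s=30.0, seed=7)
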