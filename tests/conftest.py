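import numpy as np
import pytest

from meh.patterns import PatternCounts, Window, as_pattern_counts


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_counts(rng, w=4, max_depth=50, min_depth=2):
    """A random window's pattern counts (uniform patterns, random depth)."""
    depth = int(rng.integers(min_depth, max_depth + 1))
    alphabet = [format(i, f"0{w}b") for i in range(2**w)]
    counts = {}
    for idx in rng.integers(0, 2**w, size=depth):
        pat = alphabet[idx]
        counts[pat] = counts.get(pat, 0) + 1
    return as_pattern_counts(counts)


@pytest.fixture
def window_cg4():
    return Window(chrom="chr1", context="CG", strand="+", sites=(10, 14, 20, 27))


@pytest.fixture
def two_pattern_counts(window_cg4):
    return PatternCounts(window_cg4, {"0000": 2, "1111": 2})
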