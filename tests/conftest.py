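import numpy as np
import pytest

import otsp


@pytest.fixture(scope="session")
def library():
    """Full 260-template barcode library (20 V x 13 J)."""
    return otsp.generate_barcode_library(seed=101)


@pytest.fixture(scope="session")
def small_library():
    """A 4 V x 3 J library for fast classification tests."""
    return otsp.generate_barcode_library(seed=102, n_v=4, n_j=3)


@pytest.fixture(scope="session")
def bias_model():
    return otsp.make_bias_model(seed=202)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])


# ---------------------------------------------------------------------------
# independent Levenshtein oracle (pure-Python dynamic programming), used to
# cross-check the edlib-based matcher

def levenshtein(a: str, b: str) -> int:
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def oracle_min_window_distance(sequence: str, barcode: str) -> int:
    """Min edit distance between the barcode and any substring (free-start,
    free-end semi-global DP)."""
    m = len(barcode)
    prev = [0] * (len(sequence) + 1)  # row 0: window may start anywhere
    for i in range(1, m + 1):
        cur = [i] + [0] * len(sequence)
        for j in range(1, len(sequence) + 1):
            cost = barcode[i - 1] != sequence[j - 1]
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
        prev = cur
    return min(prev)


def oracle_leftmost_start(sequence: str, barcode: str, k: int):
    """Smallest window start whose distance to the barcode is <= k, by
    exhaustive enumeration of starts and window lengths."""
    m = len(barcode)
    for s in range(len(sequence)):
        for length in range(max(0, m - k), min(len(sequence) - s, m + k) + 1):
            if levenshtein(barcode, sequence[s : s + length]) <= k:
                return s
    return None
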