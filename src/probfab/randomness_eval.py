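"""Entropy estimation and randomness testing for binary streams.

A source is *random* when every output sequence is equally likely —
its per-symbol Shannon block entropy

    H_n = -(1/n) * sum_seq p(seq) * log2 p(seq)

is maximal (1 bit/symbol for binary) for every block size n, with the
entropy rate defined as the large-n limit of H_n. A source with
0 < H < 1 is *probabilistic*: genuinely stochastic but biased, exactly
what a Bernoulli unit tuned away from p = 1/2 produces. H = 0 is
deterministic.

Block entropies use the plug-in estimator over overlapping n-blocks,
guarded against undersampling (at least 5 * 2^n observed blocks are
required before a value is reported). The randomness-test battery is a
two-test subset of the standard NIST SP 800-22 suite — the monobit
frequency test and the runs test — scored, as suites are, by the
proportion of subsequences passing at the 1% significance level, with
a proportion above 0.93 counting as a pass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import erfc

from .circuit_rng import BitStream

__all__ = [
    "UndersampledError",
    "EntropyEstimate",
    "TestResult",
    "block_entropy",
    "entropy_profile",
    "classify_source",
    "monobit_test",
    "runs_test",
    "nist_subset",
    "PASS_P_VALUE",
    "PASS_PROPORTION",
]

#: Per-sequence significance level: a subsequence passes when p >= 0.01.
PASS_P_VALUE = 0.01
#: Suite-level criterion: a test passes when > 93% of subsequences pass.
PASS_PROPORTION = 0.93


class UndersampledError(ValueError):
    """Raised when a stream is too short to estimate a block entropy."""


def _as_bits(bits: BitStream | np.ndarray) -> np.ndarray:
    arr = bits.bits if isinstance(bits, BitStream) else np.asarray(bits, dtype=np.uint8)
    return arr


def block_entropy(bits: BitStream | np.ndarray, n: int) -> float:
    """Plug-in per-symbol entropy of overlapping n-blocks, in bits/symbol.

    Bounded by [0, 1] for a binary stream. Raises
    :class:`UndersampledError` unless at least ``5 * 2**n`` overlapping
    blocks are available, the usual guard against the downward bias of the
    plug-in estimator on sparse histograms.
    """
    if n < 1:
        raise ValueError("block size must be >= 1")
    arr = _as_bits(bits)
    n_blocks = arr.size - n + 1
    if n_blocks < 5 * 2**n:
        raise UndersampledError(
            f"need at least {5 * 2**n} overlapping {n}-blocks, have {max(n_blocks, 0)}"
        )
    # encode each overlapping block as an integer word
    windows = np.lib.stride_tricks.sliding_window_view(arr, n)
    words = windows @ (1 << np.arange(n - 1, -1, -1)).astype(np.int64)
    counts = np.bincount(words, minlength=2**n)
    p = counts[counts > 0] / n_blocks
    return float(-(p * np.log2(p)).sum() / n)


@dataclass(frozen=True)
class EntropyEstimate:
    """Block entropies H_n over a range of block sizes."""

    block_sizes: tuple[int, ...]
    h_n: tuple[float, ...]
    sample_counts: tuple[int, ...]

    @property
    def h1(self) -> float:
        return self.h_n[self.block_sizes.index(1)]


def entropy_profile(bits: BitStream | np.ndarray, max_n: int) -> EntropyEstimate:
    """Estimate H_n for n = 1 .. max_n, stopping where data run out."""
    arr = _as_bits(bits)
    sizes, values, counts = [], [], []
    for n in range(1, max_n + 1):
        try:
            h = block_entropy(arr, n)
        except UndersampledError:
            break
        sizes.append(n)
        values.append(h)
        counts.append(arr.size - n + 1)
    if not sizes:
        raise UndersampledError("stream too short for even the 1-block entropy")
    return EntropyEstimate(tuple(sizes), tuple(values), tuple(counts))


def classify_source(est: EntropyEstimate, tolerance: float = 0.05) -> str:
    """Label a source random / probabilistic / deterministic from H_1.

    Random sources sit at the entropy ceiling (H_1 within ``tolerance`` of
    1 bit), deterministic ones at the floor (within ``tolerance`` of 0);
    anything between is probabilistic — stochastic with a controlled bias.
    """
    h1 = est.h1
    if h1 >= 1.0 - tolerance:
        return "random"
    if h1 <= tolerance:
        return "deterministic"
    return "probabilistic"


# ---------------------------------------------------------------------------
# NIST-style tests
# ---------------------------------------------------------------------------


def monobit_test(bits: BitStream | np.ndarray) -> tuple[float, float]:
    """Frequency (monobit) test: (statistic, p-value).

    The statistic is |sum of +-1 bits| / sqrt(n); under the fair-coin null
    it is half-normal and the p-value is erfc(stat / sqrt(2)).
    """
    arr = _as_bits(bits)
    if arr.size == 0:
        raise ValueError("empty stream")
    s = abs(int(arr.sum()) * 2 - arr.size) / math.sqrt(arr.size)
    return s, float(erfc(s / math.sqrt(2.0)))


def runs_test(bits: BitStream | np.ndarray) -> tuple[float, float]:
    """Runs test: (statistic, p-value).

    Counts maximal runs of identical bits and compares with the
    expectation 2 n pi (1 - pi) under independence, where pi is the
    ones fraction. Following the standard battery, the test short-circuits
    to p = 0 when the ones fraction itself is already implausible
    (|pi - 1/2| >= 2 / sqrt(n)).
    """
    arr = _as_bits(bits)
    n = arr.size
    if n < 2:
        raise ValueError("stream too short for the runs test")
    pi = float(arr.mean())
    if abs(pi - 0.5) >= 2.0 / math.sqrt(n):
        return math.inf, 0.0
    v = int((arr[1:] != arr[:-1]).sum()) + 1
    num = abs(v - 2.0 * n * pi * (1.0 - pi))
    den = 2.0 * math.sqrt(2.0 * n) * pi * (1.0 - pi)
    stat = num / den
    return stat, float(erfc(stat))


_TESTS = {"monobit": monobit_test, "runs": runs_test}


@dataclass(frozen=True)
class TestResult:
    """Outcome of one randomness test applied across m subsequences."""

    test_name: str
    statistic: float  # statistic on the full stream
    p_value: float  # p-value on the full stream
    proportion_score: float  # fraction of subsequences with p >= 0.01
    passed: bool  # proportion_score > 0.93

    def as_dict(self) -> dict:
        return {
            "test": self.test_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "proportion_score": self.proportion_score,
            "passed": self.passed,
        }


def nist_subset(
    bits: BitStream | np.ndarray,
    subsequences: int = 100,
    tests: tuple[str, ...] = ("monobit", "runs"),
) -> list[TestResult]:
    """Score a stream on the monobit and runs tests, suite style.

    The stream is split into ``subsequences`` equal contiguous pieces of
    at least 1000 bits each; every test yields a p-value per piece and the
    suite-level score is the proportion of pieces at or above the 1%
    level. A score above 0.93 is a pass.
    """
    arr = _as_bits(bits)
    m = subsequences
    if m < 1:
        raise ValueError("need at least one subsequence")
    if arr.size < m * 1000:
        raise ValueError(
            f"stream of {arr.size} bits too short for {m} subsequences of >= 1000 bits"
        )
    piece_len = arr.size // m
    results = []
    for name in tests:
        try:
            fn = _TESTS[name]
        except KeyError:
            raise ValueError(f"unknown test {name!r}") from None
        stat, p_full = fn(arr)
        p_vals = [fn(arr[i * piece_len : (i + 1) * piece_len])[1] for i in range(m)]
        proportion = sum(p >= PASS_P_VALUE for p in p_vals) / m
        results.append(
            TestResult(
                test_name=name,
                statistic=stat,
                p_value=p_full,
                proportion_score=proportion,
                passed=proportion > PASS_PROPORTION,
            )
        )
    return results
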