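"""From Bernoulli bits to distributions.

An array of N parallel Bernoulli units feeding a priority encoder yields,
in a single read-out, the index of the first successful trial — a
Geometric(p) variate:

    Pr(X = k) = (1 - p)^(k - 1) * p,    k = 1, 2, ...

Scaling the trial index by a time quantum dt with the per-trial success
probability set to p = 1 - exp(-rate * dt) makes K * dt a quantized
exponential waiting time whose cumulative distribution agrees with
Exponential(rate) exactly at every grid point k * dt; as rate * dt -> 0
the quantized law converges to the continuous exponential.

The software baseline generates exponentials the classical way: a
Lehmer/Park–Miller minimal-standard congruential generator produces a
uniform U and the inverse transform E = -ln(U) / rate maps it to an
exponential. Arbitrary target distributions are reached by feeding
unbiased (p = 1/2) bits as a binary fraction through a monotone
inverse-CDF transfer function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .chaos_rng import ChaosMap, iterate_map
from .circuit_rng import BitStream

__all__ = [
    "PriorityEncoder",
    "geometric_pmf",
    "first_success_index",
    "sample_geometric_encoder",
    "ExponentialSampler",
    "sample_exponential_hw",
    "LCG_MODULUS",
    "LcgState",
    "lcg_uniform",
    "sample_exponential_sw",
    "TransferFunction",
    "sample_arbitrary",
    "SoftwareBackend",
    "HardwareBackend",
    "ChaosBackend",
    "make_backend",
]


@dataclass(frozen=True)
class PriorityEncoder:
    """Priority encoder over a bank of parallel Bernoulli trials.

    ``width`` is the number of physical trials read out per clock.
    ``overflow_policy`` governs an all-zero read-out: ``"chain"`` issues
    further clocks until a success appears (the total index is then exactly
    geometric, by memorylessness), ``"saturate"`` reports the width itself,
    truncating the tail and biasing the distribution by at most
    ``(1 - p) ** width``.
    """

    width: int = 32
    overflow_policy: str = "chain"

    def __post_init__(self) -> None:
        if self.width < 1:
            raise ValueError("encoder width must be >= 1")
        if self.overflow_policy not in ("chain", "saturate"):
            raise ValueError(f"unknown overflow_policy {self.overflow_policy!r}")

    def saturate_bias(self, p: float) -> float:
        """Upper bound on total-variation bias in saturate mode."""
        return (1.0 - p) ** self.width


def geometric_pmf(k: int, p: float) -> float:
    """Probability that the first Bernoulli success occurs on trial ``k``."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p must be in (0, 1], got {p}")
    return (1.0 - p) ** (k - 1) * p


def first_success_index(bits: BitStream | np.ndarray, encoder: PriorityEncoder) -> int | None:
    """1-based index of the first 1 in a width-sized read-out, or None.

    Models one clock of the encoder: priority runs top-to-bottom, so the
    earliest asserted input wins. An all-zero word returns None (the
    overflow signal); policy handling is the caller's concern.
    """
    arr = bits.bits if isinstance(bits, BitStream) else np.asarray(bits)
    if arr.size != encoder.width:
        raise ValueError(
            f"read-out length {arr.size} does not match encoder width {encoder.width}"
        )
    hits = np.flatnonzero(arr)
    return int(hits[0]) + 1 if hits.size else None


def sample_geometric_encoder(
    p: float,
    encoder: PriorityEncoder,
    rng: np.random.Generator,
    size: int = 1,
) -> np.ndarray:
    """Draw trial-to-first-success counts through the bit-level encoder.

    Simulates the actual hardware path: banks of ``width`` Bernoulli bits
    are generated and priority-encoded; in chain mode additional banks are
    clocked for draws that overflowed, accumulating the offset. Vectorised
    over draws for speed, but every bit the hardware would produce is
    actually sampled.
    """
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p must be in (0, 1], got {p}")
    if size < 0:
        raise ValueError("size must be non-negative")
    out = np.zeros(size, dtype=np.int64)
    active = np.arange(size)
    offset = 0
    while active.size:
        bank = rng.random((active.size, encoder.width)) < p
        found = bank.any(axis=1)
        idx = bank.argmax(axis=1) + 1  # 1-based within this bank
        out[active[found]] = offset + idx[found]
        if encoder.overflow_policy == "saturate":
            out[active[~found]] = offset + encoder.width
            break
        active = active[~found]
        offset += encoder.width
    return out


@dataclass
class ExponentialSampler:
    """Exponential waiting-time generator backed by the Bernoulli encoder.

    Attributes
    ----------
    rate : float
        Target exponential rate (1/time).
    quantum : float
        Hardware time quantum dt; one encoder trial corresponds to one
        quantum of elapsed time.
    encoder : PriorityEncoder
        Read-out stage.
    mode : str
        ``"quantized"`` (default) returns K * dt exactly as the hardware
        would; ``"dequantized"`` subtracts a uniform sub-quantum offset,
        (K - U) * dt, smoothing the staircase CDF onto the continuous
        exponential (an approximation of the physical read-out, labelled
        as such).
    """

    rate: float
    quantum: float
    encoder: PriorityEncoder = field(default_factory=PriorityEncoder)
    mode: str = "quantized"

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.quantum <= 0:
            raise ValueError("quantum must be positive")
        if self.mode not in ("quantized", "dequantized"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def p(self) -> float:
        """Per-trial success probability 1 - exp(-rate * quantum)."""
        return -math.expm1(-self.rate * self.quantum)

    @property
    def saturate_bias(self) -> float:
        """Distributional bias bound if the encoder saturates instead of chaining."""
        return self.encoder.saturate_bias(self.p)

    def ks_bound(self) -> float:
        """Analytic sup-distance between the quantized law and Exponential(rate).

        With p = 1 - exp(-rate * dt) the quantized CDF coincides with the
        exponential CDF at every grid point, so the Kolmogorov–Smirnov
        distance is the largest within-cell increment of the exponential,
        attained on the first cell: 1 - exp(-rate * dt) = p.
        """
        return self.p

    def sample(self, rng: np.random.Generator, size: int = 1) -> np.ndarray:
        """Draw waiting times through the encoder path."""
        k = sample_geometric_encoder(self.p, self.encoder, rng, size=size)
        tau = k.astype(float) * self.quantum
        if self.mode == "dequantized":
            tau -= rng.random(size) * self.quantum
        return tau


def sample_exponential_hw(sampler: ExponentialSampler, seed: int, size: int = 1) -> np.ndarray:
    """Seeded convenience wrapper around :meth:`ExponentialSampler.sample`."""
    return sampler.sample(np.random.default_rng(seed), size=size)


# ---------------------------------------------------------------------------
# Software baseline: Lehmer minimal-standard generator + inverse transform
# ---------------------------------------------------------------------------

LCG_MODULUS = 2**31 - 1  # Mersenne prime modulus of the minimal standard


@dataclass(frozen=True)
class LcgState:
    """State of the Park–Miller minimal-standard congruential generator."""

    state: int
    multiplier: int = 16807

    def __post_init__(self) -> None:
        if not 1 <= self.state <= LCG_MODULUS - 1:
            raise ValueError(f"state must lie in [1, {LCG_MODULUS - 1}]")


def lcg_uniform(state: LcgState) -> tuple[LcgState, float]:
    """One step of ``s' = (a * s) mod (2^31 - 1)``; returns (s', s'/m).

    The output lies strictly inside (0, 1): the state never reaches 0 (the
    modulus is prime and the multiplier a primitive root) and never equals
    the modulus.
    """
    nxt = (state.multiplier * state.state) % LCG_MODULUS
    return LcgState(nxt, state.multiplier), nxt / LCG_MODULUS


def sample_exponential_sw(rate: float, state: LcgState) -> tuple[LcgState, float]:
    """Inverse-transform exponential draw, E = -ln(U) / rate."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    state, u = lcg_uniform(state)
    return state, -math.log(u) / rate


# ---------------------------------------------------------------------------
# Arbitrary distributions from unbiased bits
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TransferFunction:
    """Monotone inverse-CDF mapping unbiased bits to a target distribution.

    ``bit_depth`` unbiased bits form a binary fraction u in [0, 1) which is
    pushed through ``inverse_cdf``; the draw then follows the target law up
    to 2^-bit_depth uniform discretisation.
    """

    inverse_cdf: Callable[[float], float]
    bit_depth: int = 32

    def __post_init__(self) -> None:
        if self.bit_depth < 1:
            raise ValueError("bit_depth must be >= 1")


def sample_arbitrary(tf: TransferFunction, bits: BitStream | np.ndarray) -> float:
    """Map one word of unbiased bits through the transfer function."""
    arr = bits.bits if isinstance(bits, BitStream) else np.asarray(bits)
    if arr.size != tf.bit_depth:
        raise ValueError(
            f"got {arr.size} bits for a transfer function of depth {tf.bit_depth}"
        )
    u = float(np.dot(arr, 0.5 ** np.arange(1, tf.bit_depth + 1)))
    return tf.inverse_cdf(u)


# ---------------------------------------------------------------------------
# Exponential backends for the stochastic simulator
# ---------------------------------------------------------------------------


class SoftwareBackend:
    """Classical software path: minimal-standard uniform + Eq.-style inverse transform."""

    name = "software"

    def __init__(self, seed: int, multiplier: int = 16807):
        # spread the user seed over the full state space [1, m-1]; naive
        # small seeds start the recurrence at tiny states whose first
        # uniform is near zero, which would bias the first waiting time
        s = int(np.random.SeedSequence(seed).generate_state(1)[0]) % (LCG_MODULUS - 1) + 1
        self._state = LcgState(s, multiplier)

    def sample_times(self, rates: np.ndarray) -> np.ndarray:
        rates = np.asarray(rates, dtype=float)
        out = np.empty(rates.size)
        for i, a in enumerate(rates.flat):
            self._state, out[i] = sample_exponential_sw(a, self._state)
        return out


class HardwareBackend:
    """Encoder path: one shared time quantum per draw set, one geometric per rate.

    The quantum is chosen per call as ``dt = q / max(rates)`` so the
    fastest reaction sees success probability about q per trial; all rates
    share the same dt, emulating a single hardware clock. Overflow events
    (chained extra clocks) are counted for auditability.
    """

    name = "hardware"

    def __init__(
        self,
        seed: int,
        quantum_factor: float = 0.01,
        encoder: PriorityEncoder | None = None,
        mode: str = "quantized",
    ):
        if quantum_factor <= 0:
            raise ValueError("quantum_factor must be positive")
        self.quantum_factor = quantum_factor
        self.encoder = encoder or PriorityEncoder()
        self.mode = mode
        self.overflow_count = 0
        self._rng = np.random.default_rng(seed)

    def sample_times(self, rates: np.ndarray) -> np.ndarray:
        rates = np.asarray(rates, dtype=float)
        dt = self.quantum_factor / rates.max()
        out = np.empty(rates.size)
        for i, a in enumerate(rates.flat):
            sampler = ExponentialSampler(
                rate=a, quantum=dt, encoder=self.encoder, mode=self.mode
            )
            k = sample_geometric_encoder(sampler.p, self.encoder, self._rng, size=1)[0]
            if k > self.encoder.width:
                self.overflow_count += 1
            tau = k * dt
            if self.mode == "dequantized":
                tau -= self._rng.random() * dt
            out[i] = tau
        return out


class ChaosBackend:
    """Chaos-map path: thresholded orbit bits form uniforms, then inverse transform.

    Each draw consumes ``bit_depth`` bits from the logistic orbit
    (threshold 1/2, balanced under the invariant density) to build a
    binary-fraction uniform. Successive orbit bits are weakly correlated,
    so this source is probabilistic rather than ideal-random; it exists to
    emulate the temperature-invariant alternative, not to beat it.
    """

    name = "chaos"

    def __init__(self, x0: float = 0.6180339887498949, control: float = 4.0, bit_depth: int = 32):
        self._map = ChaosMap(family="logistic", control=control, state=x0)
        self.bit_depth = bit_depth
        self._weights = 0.5 ** np.arange(1, bit_depth + 1)

    def sample_times(self, rates: np.ndarray) -> np.ndarray:
        rates = np.asarray(rates, dtype=float)
        out = np.empty(rates.size)
        for i, a in enumerate(rates.flat):
            orbit = iterate_map(self._map, self.bit_depth)
            u = float(np.dot(orbit > 0.5, self._weights))
            out[i] = -math.log1p(-u) / a  # -ln(1-u), u in [0, 1)
        return out


def make_backend(name: str, seed: int, quantum_factor: float = 0.01, **kwargs):
    """Construct an exponential backend by name (software/hardware/chaos)."""
    if name == "software":
        return SoftwareBackend(seed, **kwargs)
    if name == "hardware":
        return HardwareBackend(seed, quantum_factor=quantum_factor, **kwargs)
    if name == "chaos":
        # derive a reproducible interior starting point from the seed
        x0 = (np.random.default_rng(seed).random() * 0.96) + 0.02
        return ChaosBackend(x0=x0, **kwargs)
    raise ValueError(f"unknown backend {name!r}")
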