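"""Statistical emulation of a thermal-noise Bernoulli bit generator.

The physical device traps Johnson noise on a capacitor (RMS voltage
``sqrt(kT/C)``), amplifies it through a chain of OTAs and compares the
amplified signal against a user-selectable "Probability Select" voltage.
The comparator emits a digital 1 whenever the instantaneous noise voltage
exceeds the threshold, so the success probability of the resulting
Bernoulli trial is the upper-tail mass of a Gaussian centred at the
post-amplifier operating point.

This module models that chain statistically: the amplified noise is an
untruncated Gaussian with standard deviation ``gain_total * sqrt(kT/C)``
(the supply rails are retained only as metadata for digital thresholding —
with realistic gains the clipped tail mass is negligible), and a seeded
pseudo-random generator stands in for the physical noise so every sampling
operation is reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "BOLTZMANN",
    "NoiseModel",
    "BernoulliUnit",
    "BitStream",
    "thermal_rms",
    "supply_to_noise_sigmas",
    "success_probability",
    "calibrate_threshold",
    "sample_bits",
]

#: Boltzmann constant (CODATA 2018 exact value), J/K.
BOLTZMANN = 1.380649e-23


def thermal_rms(temperature: float, capacitance: float) -> float:
    """RMS voltage of thermal (Johnson) noise on a capacitor, ``sqrt(kT/C)``.

    Parameters
    ----------
    temperature : float
        Absolute temperature in kelvin. Must be positive.
    capacitance : float
        Load capacitance in farad. Must be positive.

    Returns
    -------
    float
        RMS noise voltage in volts. Increasing in T, decreasing in C.
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    if capacitance <= 0:
        raise ValueError(f"capacitance must be positive, got {capacitance}")
    return math.sqrt(BOLTZMANN * temperature / capacitance)


def supply_to_noise_sigmas(
    supply: float, temperature: float = 300.0, capacitance: float = 500e-15
) -> float:
    """How many raw-noise standard deviations fit between 0 V and the supply.

    Expresses the supply voltage as a multiple of the *unamplified* thermal
    RMS level — the figure of merit showing why amplification is needed
    before a comparator can see the noise (a 100 mV supply sits roughly
    1000 sigma above a 100 uV noise floor).
    """
    if supply <= 0:
        raise ValueError("supply must be positive")
    return supply / thermal_rms(temperature, capacitance)


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian thermal-noise source with its amplifier chain and rails.

    Attributes
    ----------
    temperature : float
        Kelvin; defaults to room temperature.
    capacitance : float
        Farad; default 500 fF, a typical on-fabric capacitor value.
    gain_total : float
        Product of the OTA amplifier gains applied to the raw noise.
    mean_level : float
        Post-amplifier DC operating point (volts); the comparator sees a
        Gaussian centred here.
    supply_high, supply_low : float
        Rails (V_dd, V_ss); retained for digital interpretation only.
    """

    temperature: float = 300.0
    capacitance: float = 500e-15
    gain_total: float = 2500.0
    mean_level: float = 1.2
    supply_high: float = 2.4
    supply_low: float = 0.0

    def __post_init__(self) -> None:
        if self.temperature <= 0 or self.capacitance <= 0:
            raise ValueError("temperature and capacitance must be positive")
        if self.gain_total <= 0:
            raise ValueError("gain_total must be positive")
        if self.supply_high <= self.supply_low:
            raise ValueError("supply_high must exceed supply_low")

    @property
    def raw_rms(self) -> float:
        """Unamplified RMS noise voltage sqrt(kT/C), volts."""
        return thermal_rms(self.temperature, self.capacitance)

    @property
    def sigma(self) -> float:
        """Amplified noise standard deviation seen by the comparator, volts."""
        return self.gain_total * self.raw_rms


@dataclass(frozen=True)
class BernoulliUnit:
    """One comparator-backed Bernoulli trial generator.

    ``threshold`` is the Probability Select voltage; the derived success
    probability ``p`` is the Gaussian upper-tail mass above it.
    """

    noise: NoiseModel = field(default_factory=NoiseModel)
    threshold: float = 1.2

    @property
    def p(self) -> float:
        return success_probability(self)


def success_probability(unit: BernoulliUnit) -> float:
    """Probability that the amplified noise exceeds the comparator threshold.

    The integral of the noise density from the threshold voltage up to the
    positive rail, evaluated on the untruncated Gaussian model (the mass
    beyond the rails is negligible for any realistic gain).
    """
    z = (unit.threshold - unit.noise.mean_level) / unit.noise.sigma
    return float(stats.norm.sf(z))


def calibrate_threshold(p_target: float, noise: NoiseModel) -> float:
    """Threshold voltage producing a requested success probability.

    Inverts :func:`success_probability`: returns the Probability Select
    level t with ``P(noise sample > t) == p_target``.

    Raises
    ------
    ValueError
        If ``p_target`` is not strictly inside (0, 1).
    """
    if not 0.0 < p_target < 1.0:
        raise ValueError(f"p_target must be in (0, 1), got {p_target}")
    return noise.mean_level + noise.sigma * float(stats.norm.isf(p_target))


@dataclass(frozen=True)
class BitStream:
    """An ordered 0/1 sequence with provenance (source label and seed)."""

    bits: np.ndarray
    seed: int | None = None
    source_label: str = ""
    p: float | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.bits, dtype=np.uint8)
        if arr.ndim != 1:
            raise ValueError("bits must be one-dimensional")
        if arr.size and not np.isin(arr, (0, 1)).all():
            raise ValueError("bits must contain only 0 and 1")
        object.__setattr__(self, "bits", arr)

    def __len__(self) -> int:
        return int(self.bits.size)

    def ones_fraction(self) -> float:
        return float(self.bits.mean()) if len(self) else math.nan

    def write(self, path) -> None:
        """Write ASCII bitstream: header line, then 80 bits per line."""
        with open(path, "w") as fh:
            seed = -1 if self.seed is None else self.seed
            p = math.nan if self.p is None else self.p
            fh.write(f"# source={self.source_label} seed={seed} p={p}\n")
            text = "".join("1" if b else "0" for b in self.bits)
            for i in range(0, len(text), 80):
                fh.write(text[i : i + 80] + "\n")

    @classmethod
    def read(cls, path) -> "BitStream":
        with open(path) as fh:
            lines = fh.read().splitlines()
        label, seed, p = "", None, None
        body = lines
        if lines and lines[0].startswith("#"):
            body = lines[1:]
            for token in lines[0].lstrip("# ").split():
                key, _, val = token.partition("=")
                if key == "source":
                    label = val
                elif key == "seed":
                    seed = None if val == "-1" else int(val)
                elif key == "p":
                    p = None if val == "nan" else float(val)
        chars = "".join(body)
        if chars and set(chars) - {"0", "1"}:
            raise ValueError("bitstream file contains characters other than 0/1")
        bits = np.frombuffer(chars.encode(), dtype=np.uint8) - ord("0")
        return cls(bits=bits, seed=seed, source_label=label, p=p)


def sample_bits(unit: BernoulliUnit, n: int, seed: int) -> BitStream:
    """Draw ``n`` independent comparator outputs from a Bernoulli unit.

    Each draw samples the amplified Gaussian noise and emits 1 iff the
    sample strictly exceeds the threshold (equality, a measure-zero event,
    emits 0). Identical (unit, n, seed) always reproduce the same stream.
    """
    if n < 0:
        raise ValueError(f"n must be non-negative, got {n}")
    rng = np.random.default_rng(seed)
    noise = rng.normal(unit.noise.mean_level, unit.noise.sigma, size=n)
    bits = (noise > unit.threshold).astype(np.uint8)
    return BitStream(bits=bits, seed=seed, source_label="circuit", p=unit.p)
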