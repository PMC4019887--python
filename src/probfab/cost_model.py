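"""Computational-step accounting for the stochastic simulation loop.

Costs are counted in abstract computational steps (clock cycles of a
modern general-purpose CPU for the software path, fabric clocks for the
emulated analog path). The software cost of one exponential variate is
the classical inverse-transform chain — an 88-step congruential uniform
draw, a 136-step natural logarithm, a 5-step floating multiply and a
32-step floating divide, 261 steps in total — while the Bernoulli-array
+ priority-encoder path produces the same variate in 2 steps.

The per-iteration breakdown of the simulation loop, for r reaction
channels and delta parallel functional units, is

    (1) initialise               1
    (2) propensities             5 r / delta
    (3) generate waiting times   r * (cost per exponential variate)
    (4) find the minimum         (r - 1) / delta
    (5) state update             (r - 1) / delta
    (6) loop branch              1

Step (3) dominates: at delta = 2 it takes at least 98% of each software
iteration, which is what makes hardware variate generation worth having.
Intermediate values are kept as exact rationals so fractional per-unit
costs never accumulate rounding error.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

__all__ = [
    "OpCosts",
    "StepBreakdown",
    "exp_variate_cost",
    "iteration_breakdown",
    "step3_fraction",
    "generator_speedup",
    "projected_speedup",
    "exact_speedup",
    "round_sig",
]

STEP_LABELS = (
    "initialize",
    "propensities",
    "waiting_times",
    "find_minimum",
    "update",
    "loop",
)


@dataclass(frozen=True)
class OpCosts:
    """Per-operation step costs (CPU cycles / fabric clocks)."""

    load: int = 1
    fpmul: int = 5
    fpdiv: int = 32
    natural_log: int = 136
    uniform_draw: int = 88
    compare: int = 1
    add: int = 1
    hw_bernoulli_array: int = 1
    hw_priority_encode: int = 1

    def __post_init__(self) -> None:
        for name, value in vars(self).items():
            if value < 0:
                raise ValueError(f"cost {name} must be >= 0")


def exp_variate_cost(costs: OpCosts = OpCosts(), backend: str = "software") -> int:
    """Steps to produce one exponential variate on the given backend.

    Software: uniform draw + ln + multiply + divide (261 with defaults).
    Hardware: clock the Bernoulli array, then priority-encode (2 steps).
    """
    if backend == "software":
        return costs.uniform_draw + costs.natural_log + costs.fpmul + costs.fpdiv
    if backend == "hardware":
        return costs.hw_bernoulli_array + costs.hw_priority_encode
    raise ValueError(f"unknown backend {backend!r}")


@dataclass(frozen=True)
class StepBreakdown:
    """Exact per-iteration step counts for the six algorithmic stages."""

    r: int
    delta: int
    backend: str
    steps: tuple[Fraction, ...]

    @property
    def total(self) -> Fraction:
        return sum(self.steps, Fraction(0))

    @property
    def step3_fraction(self) -> Fraction:
        return self.steps[2] / self.total

    def as_dict(self) -> dict:
        return {
            "r": self.r,
            "delta": self.delta,
            "backend": self.backend,
            **{label: float(s) for label, s in zip(STEP_LABELS, self.steps)},
            "total": float(self.total),
            "step3_fraction": float(self.step3_fraction),
        }

    def as_table(self) -> str:
        width = max(len(lbl) for lbl in STEP_LABELS)
        lines = [f"iteration breakdown (r={self.r}, delta={self.delta}, {self.backend})"]
        for i, (label, s) in enumerate(zip(STEP_LABELS, self.steps), start=1):
            lines.append(f"  ({i}) {label:<{width}}  {float(s):>12.4f}")
        lines.append(f"  total {float(self.total):.4f}")
        lines.append(f"  waiting-time share {float(self.step3_fraction):.4%}")
        return "\n".join(lines)


def iteration_breakdown(
    r: int, delta: int, backend: str = "software", costs: OpCosts = OpCosts()
) -> StepBreakdown:
    """Step counts of one simulation-loop iteration, kept as exact rationals."""
    if r < 1 or delta < 1:
        raise ValueError("r and delta must be >= 1")
    gen = exp_variate_cost(costs, backend)
    steps = (
        Fraction(costs.load),
        Fraction(costs.fpmul * r, delta),
        Fraction(gen * r),
        Fraction(costs.compare * (r - 1), delta),
        Fraction(costs.add * (r - 1), delta),
        Fraction(1),
    )
    return StepBreakdown(r=r, delta=delta, backend=backend, steps=steps)


def step3_fraction(r: int, delta: int, costs: OpCosts = OpCosts()) -> float:
    """Share of a software iteration spent generating waiting times."""
    return float(iteration_breakdown(r, delta, "software", costs).step3_fraction)


def round_sig(x: float | Fraction, sig: int) -> float:
    """Round to ``sig`` significant figures, half away from zero, exactly.

    Operates on exact rationals so borderline halves (e.g. 130.5 at two
    significant figures) round the way decimal arithmetic would, not the
    way binary floats happen to fall.
    """
    if sig < 1:
        raise ValueError("sig must be >= 1")
    q = Fraction(x)
    if q == 0:
        return 0.0
    sign = 1 if q > 0 else -1
    q = abs(q)
    # decimal exponent: largest e with 10^e <= q
    e = 0
    probe = q
    while probe >= 10:
        probe /= 10
        e += 1
    while probe < 1:
        probe *= 10
        e -= 1
    scale = Fraction(10) ** (e - sig + 1)
    units = q / scale
    floor_units = units.numerator // units.denominator
    remainder = units - floor_units
    if remainder * 2 >= 1:
        floor_units += 1
    return float(sign * floor_units * scale)


def generator_speedup(costs: OpCosts = OpCosts(), sig: int = 2) -> float:
    """Hardware-over-software fold change for one exponential variate.

    The ratio of per-variate costs (261 / 2 = 130.5 with defaults),
    reported to ``sig`` significant figures as a headline factor.
    """
    ratio = Fraction(exp_variate_cost(costs, "software"), exp_variate_cost(costs, "hardware"))
    return round_sig(ratio, sig)


def projected_speedup(
    r: int = 10, delta: int = 2, costs: OpCosts = OpCosts()
) -> int:
    """Projected whole-trajectory fold speed-up from hardware variates.

    Composes the two headline figures the way they are naturally quoted:
    the generator fold change at two significant figures, discounted by
    the waiting-time share of the loop truncated to whole percent
    (>= 98% at delta = 2 for every r), then rounded to the nearest
    integer. With the default costs this gives 130 * 0.98 -> 127.
    """
    ratio = generator_speedup(costs)
    share = iteration_breakdown(r, delta, "software", costs).step3_fraction
    share_pct = Fraction(int(share * 100), 100)  # truncate to whole percent
    projected = Fraction(ratio) * share_pct
    return int(projected + Fraction(1, 2))


def exact_speedup(r: int, delta: int, costs: OpCosts = OpCosts()) -> float:
    """Exact Amdahl-style fold change: software total over hardware total.

    Equals 1 / ((1 - f) + f / s) with f the software waiting-time share
    and s the per-variate cost ratio; reported unrounded for comparison
    with the headline projection.
    """
    sw = iteration_breakdown(r, delta, "software", costs).total
    hw = iteration_breakdown(r, delta, "hardware", costs).total
    return float(sw / hw)
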