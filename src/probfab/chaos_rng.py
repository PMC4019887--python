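"""Temperature-invariant random source: an iterated 1-D chaotic map.

Thermal-noise generators drift with ambient temperature; a chaos circuit —
a nonlinear map iterated through a sample-and-hold loop — gives a
probabilistic source whose statistics do not depend on temperature. The
published nine-transistor circuit realises a unimodal map y(x) whose shape
is tuned by a control voltage; its exact algebraic form is not reproduced
here, so the map family is pluggable. The default is the logistic map
``x <- c * x * (1 - x)``: at c = 4 it is chaotic on [0, 1] with the known
arcsine (Beta(1/2, 1/2)) invariant density, which makes its long-run
statistics exactly testable.

Bits are extracted by thresholding the held value; at the invariant
density's median the long-run bit frequency is 1/2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .circuit_rng import BitStream

__all__ = ["MAP_FAMILIES", "register_map", "ChaosMap", "iterate_map", "chaos_bits"]

# family name -> (update function f(x, control), admissible control interval)
MAP_FAMILIES: dict[str, tuple[Callable[[float, float], float], tuple[float, float]]] = {
    "logistic": (lambda x, c: c * x * (1.0 - x), (0.0, 4.0)),
    # tent map included as a second built-in family; control is the peak slope
    "tent": (lambda x, c: c * min(x, 1.0 - x), (0.0, 2.0)),
}


def register_map(
    name: str,
    update: Callable[[float, float], float],
    control_range: tuple[float, float],
) -> None:
    """Register a custom map family (e.g. a measured circuit transfer curve)."""
    MAP_FAMILIES[name] = (update, control_range)


@dataclass
class ChaosMap:
    """A 1-D chaotic map with control parameter and current state in [0, 1].

    ``control`` plays the role of the circuit's control voltage: it selects
    one member of the unimodal family and thereby the statistics of the
    generated sequence.
    """

    family: str = "logistic"
    control: float = 4.0
    state: float = 0.6180339887498949  # irrational default avoids short cycles

    def __post_init__(self) -> None:
        if self.family not in MAP_FAMILIES:
            raise ValueError(f"unknown map family {self.family!r}")
        lo, hi = MAP_FAMILIES[self.family][1]
        if not lo <= self.control <= hi:
            raise ValueError(
                f"control {self.control} outside admissible range [{lo}, {hi}]"
            )
        if not 0.0 <= self.state <= 1.0:
            raise ValueError(f"state {self.state} outside the unit interval")

    def curve(self, x: np.ndarray) -> np.ndarray:
        """Evaluate the map transfer function y(x) on an array (no state change)."""
        f = MAP_FAMILIES[self.family][0]
        return np.array([f(float(xi), self.control) for xi in np.asarray(x, float)])


def iterate_map(cmap: ChaosMap, n: int) -> np.ndarray:
    """Iterate the map ``n`` times, returning the orbit x_1 .. x_n.

    The map's ``state`` advances to the final orbit point, so successive
    calls continue the same trajectory (sample-and-hold behaviour).
    Deterministic given (family, control, initial state).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    f = MAP_FAMILIES[cmap.family][0]
    orbit = np.empty(n)
    x = cmap.state
    for i in range(n):
        x = f(x, cmap.control)
        if not 0.0 <= x <= 1.0:
            raise ValueError(
                f"orbit left the unit interval at step {i} (x={x}); "
                "check control parameter"
            )
        orbit[i] = x
    cmap.state = x
    return orbit


def chaos_bits(cmap: ChaosMap, n: int, threshold: float = 0.5) -> BitStream:
    """Extract ``n`` bits by thresholding successive held orbit values.

    Bit i is 1 iff orbit value i strictly exceeds ``threshold``. For the
    logistic map at control 4 the invariant density is symmetric about 1/2,
    so threshold 0.5 yields asymptotically balanced bits.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    if n == 0:
        bits = np.empty(0, dtype=np.uint8)
    else:
        bits = (iterate_map(cmap, n) > threshold).astype(np.uint8)
    label = f"chaos:{cmap.family}(control={cmap.control:g})"
    return BitStream(bits=bits, seed=None, source_label=label)
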