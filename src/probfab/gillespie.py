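"""Stochastic simulation of mass-action reaction networks.

Implements the first-reaction variant of the stochastic simulation
algorithm: per event, each reaction i draws a candidate waiting time from
Exponential(a_i) — where a_i is its mass-action propensity at the current
molecule counts — and the reaction with the least time fires. The
exponential draws come from a pluggable backend: the classical software
path (congruential uniform + inverse transform), the emulated Bernoulli
encoder path, or the chaos-map path.

The equivalent direct variant (one total time ~ Exponential(sum a_i), the
reaction chosen with probability a_i / sum a_i) is provided as a
cross-validation oracle, along with the governing probability forms — the
no-event survival P0(tau) = exp(-sum(alpha) * tau) and the joint density
P(tau, mu) = alpha_mu * P0(tau) — and the deterministic mean-field ODE
limit to which the stochastic trajectories converge at large copy
numbers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .variate_gen import HardwareBackend, make_backend

__all__ = [
    "Reaction",
    "ReactionNetwork",
    "SystemState",
    "Trajectory",
    "SimConfig",
    "ExtinctionError",
    "propensity",
    "step_first_reaction",
    "step_direct",
    "simulate",
    "p0_no_update",
    "joint_density",
    "ode_limit",
]

logger = logging.getLogger(__name__)


class ExtinctionError(RuntimeError):
    """Raised by single-step functions when every propensity is zero."""


@dataclass(frozen=True)
class Reaction:
    """One mass-action reaction channel.

    ``rate_constant`` is the stochastic rate constant c (units depend on
    the reaction order); ``reactants`` and ``products`` map species names
    to non-negative stoichiometric counts. Total reactant order is limited
    to two (zeroth- through bimolecular channels).
    """

    name: str
    rate_constant: float
    reactants: Mapping[str, int]
    products: Mapping[str, int]

    def __post_init__(self) -> None:
        if self.rate_constant < 0:
            raise ValueError(f"rate constant of {self.name!r} must be >= 0")
        for side, coeffs in (("reactants", self.reactants), ("products", self.products)):
            for sp, nu in coeffs.items():
                if not isinstance(nu, int) or nu < 0:
                    raise ValueError(
                        f"{side} stoichiometry of {self.name!r} must be "
                        f"non-negative integers, got {sp}:{nu}"
                    )
        if self.order > 2:
            raise ValueError(
                f"reaction {self.name!r} has order {self.order}; at most "
                "bimolecular channels are supported"
            )

    @property
    def order(self) -> int:
        return sum(self.reactants.values())

    @property
    def state_change(self) -> dict[str, int]:
        """Net change per species (products minus reactants)."""
        delta = dict.fromkeys({*self.reactants, *self.products}, 0)
        for sp, nu in self.products.items():
            delta[sp] += nu
        for sp, nu in self.reactants.items():
            delta[sp] -= nu
        return delta


@dataclass
class ReactionNetwork:
    """Species with initial integer counts plus a list of reaction channels."""

    species: Sequence[str]
    initial_counts: Mapping[str, int]
    reactions: Sequence[Reaction]

    def __post_init__(self) -> None:
        if len(set(self.species)) != len(self.species):
            raise ValueError("duplicate species names")
        if not self.reactions:
            raise ValueError("network must contain at least one reaction")
        for sp in self.species:
            n = self.initial_counts.get(sp, 0)
            if not isinstance(n, int) or n < 0:
                raise ValueError(f"initial count of {sp!r} must be a non-negative integer")
        known = set(self.species)
        for rxn in self.reactions:
            missing = ({*rxn.reactants, *rxn.products}) - known
            if missing:
                raise ValueError(
                    f"reaction {rxn.name!r} references unknown species {sorted(missing)}"
                )
        self._index = {sp: i for i, sp in enumerate(self.species)}
        # per-reaction compiled views for the simulation fast path
        self._delta = np.zeros((len(self.reactions), len(self.species)), dtype=np.int64)
        self._react = []
        for j, rxn in enumerate(self.reactions):
            for sp, d in rxn.state_change.items():
                self._delta[j, self._index[sp]] = d
            self._react.append(
                [(self._index[sp], nu) for sp, nu in rxn.reactants.items()]
            )

    @property
    def n_species(self) -> int:
        return len(self.species)

    def initial_state(self) -> "SystemState":
        return SystemState(
            counts={sp: int(self.initial_counts.get(sp, 0)) for sp in self.species},
            time=0.0,
        )

    def counts_vector(self, counts: Mapping[str, int]) -> np.ndarray:
        return np.array([counts.get(sp, 0) for sp in self.species], dtype=np.int64)

    def propensities(self, x: np.ndarray) -> np.ndarray:
        """Vector of mass-action propensities at integer counts ``x``."""
        a = np.empty(len(self.reactions))
        for j, rxn in enumerate(self.reactions):
            a[j] = _mass_action(rxn.rate_constant, self._react[j], x)
        return a


def _mass_action(c: float, reactants: list[tuple[int, int]], x: np.ndarray) -> float:
    """Combinatorial mass-action propensity on integer counts."""
    a = c
    for idx, nu in reactants:
        n = x[idx]
        if nu == 1:
            a *= n
        else:  # nu == 2, distinct unordered pairs
            a *= n * (n - 1) / 2.0
        if a == 0.0:
            return 0.0
    return a if a > 0.0 else 0.0


@dataclass
class SystemState:
    """Molecule counts and the current simulation time."""

    counts: dict[str, int]
    time: float = 0.0

    def __post_init__(self) -> None:
        for sp, n in self.counts.items():
            if n < 0:
                raise ValueError(f"negative count for species {sp!r}")


def propensity(reaction: Reaction, state: SystemState | Mapping[str, int]) -> float:
    """Mass-action propensity of one reaction at the given counts.

    Zeroth order: c. First order A -> .: c * X_A. Bimolecular A + B -> .:
    c * X_A * X_B. Dimerisation 2A -> .: c * X_A * (X_A - 1) / 2 (number
    of distinct unordered pairs). Zero whenever reactants are insufficient.
    """
    counts = state.counts if isinstance(state, SystemState) else state
    a = reaction.rate_constant
    for sp, nu in reaction.reactants.items():
        n = counts.get(sp, 0)
        if nu == 1:
            a *= n
        elif nu == 2:
            a *= n * (n - 1) / 2.0
        else:  # unreachable: order capped at 2 in Reaction
            raise ValueError("unsupported stoichiometry")
    return a if a > 0.0 else 0.0


def step_first_reaction(
    network: ReactionNetwork, state: SystemState, rng_backend
) -> tuple[int, float]:
    """One first-reaction step: draw tau_i ~ Exp(a_i) per channel, fire the min.

    Returns (reaction index, waiting time). Ties — a measure-zero event in
    exact arithmetic — resolve to the lowest index. Raises
    :class:`ExtinctionError` when no channel can fire.
    """
    x = network.counts_vector(state.counts)
    a = network.propensities(x)
    live = a > 0
    if not live.any():
        raise ExtinctionError("all propensities are zero")
    taus = np.full(a.size, np.inf)
    taus[live] = rng_backend.sample_times(a[live])
    mu = int(taus.argmin())  # argmin takes the first minimum: lowest index
    return mu, float(taus[mu])


def step_direct(
    network: ReactionNetwork, state: SystemState, rng_backend
) -> tuple[int, float]:
    """One direct-method step: tau ~ Exp(sum a), mu with probability a_mu / sum a.

    Distributionally equivalent to :func:`step_first_reaction`; kept as an
    independent cross-check of the first-reaction sampler.
    """
    x = network.counts_vector(state.counts)
    a = network.propensities(x)
    total = a.sum()
    if total <= 0:
        raise ExtinctionError("all propensities are zero")
    tau = float(rng_backend.sample_times(np.array([total]))[0])
    # select the channel from a uniform derived from one more exponential draw:
    # U = 1 - exp(-E) is uniform when E ~ Exp(1)
    u = -math.expm1(-float(rng_backend.sample_times(np.array([1.0]))[0]))
    mu = int(np.searchsorted(np.cumsum(a) / total, u, side="right"))
    mu = min(mu, a.size - 1)
    return mu, tau


@dataclass
class Trajectory:
    """Event history of one stochastic run: (time, counts) plus fired labels."""

    species: Sequence[str]
    times: list[float] = field(default_factory=list)
    counts: list[tuple[int, ...]] = field(default_factory=list)
    reactions: list[str] = field(default_factory=list)  # "" for the initial record

    def __len__(self) -> int:
        return len(self.times)

    @property
    def n_events(self) -> int:
        return max(len(self.times) - 1, 0)

    def record(self, time: float, counts: np.ndarray, reaction: str) -> None:
        if self.times and time <= self.times[-1]:
            raise ValueError("event times must be strictly increasing")
        self.times.append(float(time))
        self.counts.append(tuple(int(c) for c in counts))
        self.reactions.append(reaction)

    def state_at(self, t: float) -> dict[str, int]:
        """Counts in force at time t (the last event at or before t)."""
        if not self.times or t < self.times[0]:
            raise ValueError("time precedes the first record")
        i = int(np.searchsorted(self.times, t, side="right")) - 1
        return dict(zip(self.species, self.counts[i]))

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.counts, columns=list(self.species))
        df.insert(0, "time", self.times)
        df["reaction"] = self.reactions
        return df


@dataclass
class SimConfig:
    """Run configuration: stopping rules, seed, and exponential backend."""

    t_end: float | None = None
    max_events: int | None = None
    seed: int = 0
    backend: str = "software"
    quantum_factor: float = 0.01
    hw_mode: str = "quantized"

    def __post_init__(self) -> None:
        if self.t_end is None and self.max_events is None:
            raise ValueError("set t_end and/or max_events")
        if self.t_end is not None and self.t_end <= 0:
            raise ValueError("t_end must be positive")
        if self.max_events is not None and self.max_events < 0:
            raise ValueError("max_events must be non-negative")


def simulate(network: ReactionNetwork, config: SimConfig) -> Trajectory:
    """Run the first-reaction stochastic simulation to the stopping rule.

    The trajectory starts with the initial record at t = 0 and gains one
    record per executed reaction event. The run halts at ``t_end`` (an
    event that would land beyond it is discarded), at ``max_events``, or at
    extinction (no channel can fire). Fully reproducible given the seed.
    """
    kwargs = {"mode": config.hw_mode} if config.backend == "hardware" else {}
    backend = make_backend(config.backend, config.seed, config.quantum_factor, **kwargs)
    traj = Trajectory(species=list(network.species))
    x = network.counts_vector(network.initial_counts)
    t = 0.0
    traj.record(t, x, "")
    events = 0
    while True:
        if config.max_events is not None and events >= config.max_events:
            break
        a = network.propensities(x)
        live = a > 0
        if not live.any():
            logger.debug("extinction at t=%g after %d events", t, events)
            break
        taus = np.full(a.size, np.inf)
        taus[live] = backend.sample_times(a[live])
        mu = int(taus.argmin())
        t_next = t + float(taus[mu])
        if config.t_end is not None and t_next > config.t_end:
            break
        x = x + network._delta[mu]
        if (x < 0).any():  # propensity zero-guard makes this unreachable
            raise AssertionError("negative molecule count after update")
        t = t_next
        traj.record(t, x, network.reactions[mu].name)
        events += 1
    if isinstance(backend, HardwareBackend):
        logger.info(
            "backend=hardware quantum_factor=%g width=%d overflows=%d events=%d",
            config.quantum_factor,
            backend.encoder.width,
            backend.overflow_count,
            events,
        )
    else:
        logger.info("backend=%s events=%d", config.backend, events)
    return traj


# ---------------------------------------------------------------------------
# Governing probability forms and the deterministic limit
# ---------------------------------------------------------------------------


def p0_no_update(total_alpha: float, tau: float) -> float:
    """Probability that no state update occurs within a window of length tau.

    ``exp(-total_alpha * tau)`` — the survival function of the first event
    when updates arrive with total rate ``total_alpha``.
    """
    if total_alpha < 0 or tau < 0:
        raise ValueError("total_alpha and tau must be non-negative")
    return math.exp(-total_alpha * tau)


def joint_density(tau: float, mu: int, alphas: Sequence[float]) -> float:
    """Joint density that the next update is to channel mu after delay tau.

    ``alpha_mu * exp(-sum(alphas) * tau)``; integrating over tau >= 0 and
    summing over channels gives total probability one.
    """
    alphas = np.asarray(alphas, dtype=float)
    if (alphas < 0).any():
        raise ValueError("alphas must be non-negative")
    if not 0 <= mu < alphas.size:
        raise IndexError(f"channel index {mu} out of range")
    if tau < 0:
        raise ValueError("tau must be non-negative")
    return float(alphas[mu] * math.exp(-alphas.sum() * tau))


def ode_limit(
    network: ReactionNetwork,
    t_grid: Sequence[float],
    max_step: float = 1e-3,
) -> np.ndarray:
    """Deterministic mean-field limit integrated on a fixed-step RK4 scheme.

    Solves ``dx/dt = sum_mu nu_mu * a_mu(x)`` on continuous counts, using
    the same stochastic rate constants and combinatorial propensity forms
    as the jump process (exact correspondence for networks of order <= 1;
    the standard mean-field approximation for bimolecular channels).
    Returns an array of shape (len(t_grid), n_species).

    Raises
    ------
    RuntimeError
        If the integration drives a count negative (step size too large
        for the network's stiffness).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 1 or t_grid[0] != 0.0:
        raise ValueError("t_grid must be 1-D and start at 0")
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")

    delta = network._delta.astype(float)

    def deriv(x: np.ndarray) -> np.ndarray:
        a = np.empty(len(network.reactions))
        for j in range(len(network.reactions)):
            v = network.reactions[j].rate_constant
            for idx, nu in network._react[j]:
                v *= x[idx] if nu == 1 else x[idx] * (x[idx] - 1) / 2.0
            a[j] = v
        return a @ delta

    x = network.counts_vector(network.initial_counts).astype(float)
    out = np.empty((t_grid.size, x.size))
    out[0] = x
    for i in range(1, t_grid.size):
        span = t_grid[i] - t_grid[i - 1]
        n_sub = max(1, int(math.ceil(span / max_step)))
        h = span / n_sub
        for _ in range(n_sub):
            k1 = deriv(x)
            k2 = deriv(x + 0.5 * h * k1)
            k3 = deriv(x + 0.5 * h * k2)
            k4 = deriv(x + h * k3)
            x = x + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if (x < -1e-9).any():
            raise RuntimeError(
                "integration produced negative counts; reduce max_step"
            )
        out[i] = x
    return out
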