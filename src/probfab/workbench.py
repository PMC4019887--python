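"""File I/O, fixture networks and run plumbing.

Reaction networks travel as a small JSON dialect::

    {"species":  [{"name": "A", "init": 100}],
     "reactions": [{"name": "R1", "rate_constant": 1.0,
                    "reactants": {"A": 1}, "products": {}}]}

Trajectories are written as TSV with a ``time`` column, one column per
species and a trailing ``reaction`` column naming the fired channel.
Canonical fixture networks (irreversible decay, birth–death,
Lotka–Volterra predator–prey, and seeded random mass-action networks)
are generated programmatically so no external data are needed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .gillespie import Reaction, ReactionNetwork, Trajectory

__all__ = [
    "NetworkSchemaError",
    "UnknownSpeciesError",
    "NegativeCountError",
    "FixtureSpec",
    "network_from_dict",
    "network_to_dict",
    "load_network",
    "dump_network",
    "write_trajectory",
    "generate_fixture",
]


class NetworkSchemaError(ValueError):
    """Malformed network document (bad keys, types or structure)."""


class UnknownSpeciesError(NetworkSchemaError):
    """A reaction references a species that is not declared."""


class NegativeCountError(NetworkSchemaError):
    """A species is declared with a negative initial count."""


_TOP_KEYS = {"species", "reactions"}
_SPECIES_KEYS = {"name", "init"}
_REACTION_KEYS = {"name", "rate_constant", "reactants", "products"}


def network_from_dict(doc: dict) -> ReactionNetwork:
    """Validate a network document and build the in-memory network."""
    if not isinstance(doc, dict):
        raise NetworkSchemaError("network document must be a JSON object")
    unknown = set(doc) - _TOP_KEYS
    if unknown:
        raise NetworkSchemaError(f"unknown top-level keys {sorted(unknown)}")
    if "species" not in doc or "reactions" not in doc:
        raise NetworkSchemaError("document needs 'species' and 'reactions' lists")

    species, init = [], {}
    for entry in doc["species"]:
        if not isinstance(entry, dict) or set(entry) - _SPECIES_KEYS or "name" not in entry:
            raise NetworkSchemaError(f"bad species entry {entry!r}")
        name = entry["name"]
        count = entry.get("init", 0)
        if not isinstance(count, int) or isinstance(count, bool):
            raise NetworkSchemaError(f"initial count of {name!r} must be an integer")
        if count < 0:
            raise NegativeCountError(f"initial count of {name!r} is negative")
        species.append(name)
        init[name] = count

    known = set(species)
    reactions = []
    for entry in doc["reactions"]:
        if not isinstance(entry, dict) or set(entry) - _REACTION_KEYS:
            raise NetworkSchemaError(f"bad reaction entry {entry!r}")
        for key in ("name", "rate_constant"):
            if key not in entry:
                raise NetworkSchemaError(f"reaction entry missing {key!r}")
        for side in ("reactants", "products"):
            for sp, nu in entry.get(side, {}).items():
                if sp not in known:
                    raise UnknownSpeciesError(
                        f"reaction {entry['name']!r} references undeclared species {sp!r}"
                    )
                if not isinstance(nu, int) or isinstance(nu, bool) or nu < 0:
                    raise NetworkSchemaError(
                        f"stoichiometry {sp}:{nu!r} in {entry['name']!r} must be a "
                        "non-negative integer"
                    )
        reactions.append(
            Reaction(
                name=entry["name"],
                rate_constant=float(entry["rate_constant"]),
                reactants=dict(entry.get("reactants", {})),
                products=dict(entry.get("products", {})),
            )
        )
    try:
        return ReactionNetwork(species=species, initial_counts=init, reactions=reactions)
    except ValueError as exc:
        raise NetworkSchemaError(str(exc)) from exc


def network_to_dict(network: ReactionNetwork) -> dict:
    return {
        "species": [
            {"name": sp, "init": int(network.initial_counts.get(sp, 0))}
            for sp in network.species
        ],
        "reactions": [
            {
                "name": rxn.name,
                "rate_constant": rxn.rate_constant,
                "reactants": dict(rxn.reactants),
                "products": dict(rxn.products),
            }
            for rxn in network.reactions
        ],
    }


def load_network(path) -> ReactionNetwork:
    """Load and validate a network JSON file."""
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise NetworkSchemaError(f"malformed JSON in {path}: {exc}") from exc
    return network_from_dict(doc)


def dump_network(network: ReactionNetwork, path) -> None:
    with open(path, "w") as fh:
        json.dump(network_to_dict(network), fh, indent=1)
        fh.write("\n")


def write_trajectory(traj: Trajectory, path, record_every: int = 1) -> None:
    """Write a trajectory as TSV, optionally thinned.

    Thinning keeps every ``record_every``-th event record but always
    retains the initial record and the final one.
    """
    if record_every < 1:
        raise ValueError("record_every must be >= 1")
    n = len(traj)
    keep = list(range(0, n, record_every))
    if keep and keep[-1] != n - 1:
        keep.append(n - 1)
    with open(path, "w") as fh:
        fh.write("time\t" + "\t".join(traj.species) + "\treaction\n")
        for i in keep:
            row = "\t".join(str(c) for c in traj.counts[i])
            fh.write(f"{traj.times[i]:.10g}\t{row}\t{traj.reactions[i]}\n")


@dataclass(frozen=True)
class FixtureSpec:
    """Request for one of the canonical fixture networks."""

    name: str
    parameters: dict = field(default_factory=dict)
    seed: int = 0


def generate_fixture(spec: FixtureSpec) -> ReactionNetwork:
    """Build a canonical network: decay, birthdeath, lotka or random.

    decay
        A -> 0 with c = 1 from 100 molecules (exponential mean decay).
    birthdeath
        0 -> A at rate b = 10, A -> 0 with c = 1; the stationary law of A
        is Poisson(b / c).
    lotka
        The classic predator–prey set X -> 2X, X + Y -> 2Y, Y -> 0.
    random
        A seeded mass-action network with ``size`` species and ``2 * size``
        reactions of order <= 2; identical seeds give identical networks.
    """
    p = dict(spec.parameters)
    if spec.name == "decay":
        c = float(p.pop("c", 1.0))
        x0 = int(p.pop("x0", 100))
        _reject_extra(spec.name, p)
        return ReactionNetwork(
            species=["A"],
            initial_counts={"A": x0},
            reactions=[Reaction("decay", c, {"A": 1}, {})],
        )
    if spec.name == "birthdeath":
        b = float(p.pop("b", 10.0))
        c = float(p.pop("c", 1.0))
        x0 = int(p.pop("x0", 0))
        _reject_extra(spec.name, p)
        return ReactionNetwork(
            species=["A"],
            initial_counts={"A": x0},
            reactions=[
                Reaction("birth", b, {}, {"A": 1}),
                Reaction("death", c, {"A": 1}, {}),
            ],
        )
    if spec.name == "lotka":
        c1 = float(p.pop("c1", 10.0))
        c2 = float(p.pop("c2", 0.01))
        c3 = float(p.pop("c3", 10.0))
        x0 = int(p.pop("x0", 1000))
        y0 = int(p.pop("y0", 1000))
        _reject_extra(spec.name, p)
        return ReactionNetwork(
            species=["X", "Y"],
            initial_counts={"X": x0, "Y": y0},
            reactions=[
                Reaction("prey_birth", c1, {"X": 1}, {"X": 2}),
                Reaction("predation", c2, {"X": 1, "Y": 1}, {"Y": 2}),
                Reaction("predator_death", c3, {"Y": 1}, {}),
            ],
        )
    if spec.name == "random":
        size = int(p.pop("size", 4))
        _reject_extra(spec.name, p)
        return _random_network(size, spec.seed)
    raise ValueError(f"unknown fixture {spec.name!r}")


def _reject_extra(name: str, leftover: dict) -> None:
    if leftover:
        raise ValueError(f"unknown parameters for fixture {name!r}: {sorted(leftover)}")


def _random_network(size: int, seed: int) -> ReactionNetwork:
    if size < 1:
        raise ValueError("size must be >= 1")
    rng = np.random.default_rng(seed)
    species = [f"S{i}" for i in range(size)]
    init = {sp: int(rng.integers(10, 200)) for sp in species}
    reactions = []
    for j in range(2 * size):
        order = int(rng.integers(0, 3))
        chosen = list(rng.choice(size, size=order, replace=True))
        reactants: dict[str, int] = {}
        for idx in chosen:
            reactants[species[idx]] = reactants.get(species[idx], 0) + 1
        n_prod = int(rng.integers(0, 3))
        products: dict[str, int] = {}
        for idx in rng.choice(size, size=n_prod, replace=True):
            products[species[idx]] = products.get(species[idx], 0) + 1
        c = float(10.0 ** rng.uniform(-2, 1))
        if order == 2:
            c /= 100.0  # keep bimolecular channels from dominating
        reactions.append(Reaction(f"R{j}", c, reactants, products))
    return ReactionNetwork(species=species, initial_counts=init, reactions=reactions)
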