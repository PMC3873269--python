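"""Reaction network of the Bcl-2 protein family and its rate parameters.

The model describes the 16 Bcl-2 family proteins (6 anti-apoptotic guardians,
6 BH3-only enablers, 2 BH3-only activators, 2 multidomain effectors), the
activated effector forms aBax/aBak, and every bound pair the interaction
table admits.  Reaction kinds:

* ``catalytic_activation`` — an activator (tBid, Bim) converts an effector
  into its activated form, itself unchanged (irreversible).
* ``reversible_binding`` — heterodimerization of an anti-apoptotic protein
  with a pro-apoptotic partner; forward rate is one of the affinity classes
  ``ks`` (strong), ``ki`` (intermediate), ``kw`` (weak); reverse rate ``km``.
* ``reversible_dimerization`` — activated effectors pair into the three MAC
  dimers aBax~aBax, aBak~aBak, aBax~aBak (forward ``kd``, reverse ``km``).
* ``production`` — zeroth-order synthesis of each of the 16 proteins, rate
  ``kp<Name>``.  These 16 rates are the model's independent inputs.
* ``degradation`` — a single catch-all entry: first-order loss at ``kdeg``
  of every species, complexes included (a complex degrades whole; neither
  partner is returned to its free pool).

Abundances are molecules per abstract reaction volume, with the convention
1 nM = 600 molecules.  Time is measured in hours.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import yaml

__all__ = [
    "SpeciesSpec",
    "ReactionRule",
    "ReactionNetwork",
    "RateParams",
    "build_default_network",
    "default_rate_params",
    "build_toy_network",
    "stoichiometry",
    "initial_state",
    "load_network",
    "save_network",
    "COMPLEX_SEPARATOR",
]

COMPLEX_SEPARATOR = "~"

GROUPS = frozenset(
    {
        "antiapoptotic",
        "enabler",
        "activator",
        "effector",
        "activated_effector",
        "complex",
    }
)

REACTION_KINDS = frozenset(
    {
        "catalytic_activation",
        "reversible_binding",
        "reversible_dimerization",
        "production",
        "degradation",
    }
)

#: Canonical input order of the 16 production-rate parameters.
PRODUCTION_PARAMS = (
    "kpMcl1",
    "kpA1",
    "kpBclXl",
    "kpBcl2",
    "kpBclw",
    "kpBclB",
    "kpHrk",
    "kpBik",
    "kptBid",
    "kpPuma",
    "kpBim",
    "kpBad",
    "kpBmf",
    "kpNoxa",
    "kpBax",
    "kpBak",
)

#: Weak-class bound pairs present in the reaction table but not in the
#: qualitative interaction table (Bcl-2 with Hrk and Bik).  The pairwise
#: cross-check treats these as documented extras rather than errors.
INTERACTION_TABLE_EXTRAS = frozenset({("Bcl2", "Hrk"), ("Bcl2", "Bik")})


class NetworkError(ValueError):
    """Structural problem in a reaction network definition."""


class ParameterError(ValueError):
    """Invalid rate-parameter set."""


@dataclass(frozen=True)
class SpeciesSpec:
    """One chemical species: a free protein, an activated effector or a complex."""

    name: str
    group: str
    production_param: str | None = None

    @property
    def produced(self) -> bool:
        return self.production_param is not None

    @property
    def is_complex(self) -> bool:
        return COMPLEX_SEPARATOR in self.name

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise NetworkError(f"unknown species group {self.group!r} for {self.name!r}")
        if (self.group == "complex") != self.is_complex:
            raise NetworkError(
                f"species {self.name!r}: group 'complex' must coincide with a "
                f"bound-pair name containing {COMPLEX_SEPARATOR!r}"
            )
        if self.produced and self.is_complex:
            raise NetworkError(f"complex species {self.name!r} cannot be produced")


@dataclass(frozen=True)
class ReactionRule:
    """One reaction entry (reversible entries expand to two flux channels)."""

    kind: str
    reactants: tuple[str, ...]
    products: tuple[str, ...]
    forward_rate: str
    reverse_rate: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "reactants", tuple(self.reactants))
        object.__setattr__(self, "products", tuple(self.products))
        if self.kind not in REACTION_KINDS:
            raise NetworkError(f"unknown reaction kind {self.kind!r}")
        if self.kind == "catalytic_activation":
            if len(self.reactants) != 2 or len(self.products) != 2:
                raise NetworkError("catalytic activation needs two reactants and two products")
            if self.reactants[0] != self.products[0]:
                raise NetworkError("catalyst must appear unchanged on both sides")
            if self.reverse_rate is not None:
                raise NetworkError("catalytic activation is irreversible")
        elif self.kind == "reversible_binding":
            if len(self.reactants) != 2 or len(set(self.reactants)) != 2:
                raise NetworkError("binding needs two distinct reactants")
            if len(self.products) != 1 or self.reverse_rate is None:
                raise NetworkError("binding needs one complex product and a reverse rate")
        elif self.kind == "reversible_dimerization":
            if len(self.reactants) != 2 or len(self.products) != 1 or self.reverse_rate is None:
                raise NetworkError("dimerization needs two reactants, one product, a reverse rate")
        elif self.kind == "production":
            if self.reactants or len(self.products) != 1:
                raise NetworkError("production has no reactants and one product")
        elif self.kind == "degradation":
            if self.reactants or self.products:
                raise NetworkError(
                    "degradation is the catch-all entry: no explicit reactants/products"
                )

    @property
    def is_reversible(self) -> bool:
        return self.reverse_rate is not None


@dataclass(frozen=True)
class ReactionNetwork:
    """Validated, ordered species list plus reaction rules."""

    species: tuple[SpeciesSpec, ...]
    reactions: tuple[ReactionRule, ...]
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", tuple(self.species))
        object.__setattr__(self, "reactions", tuple(self.reactions))
        self._validate()

    # -- queries -------------------------------------------------------
    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species)

    def index(self, name: str) -> int:
        try:
            return self.species_names.index(name)
        except ValueError:
            raise NetworkError(f"unknown species {name!r}") from None

    def species_by_group(self, group: str) -> tuple[str, ...]:
        return tuple(s.name for s in self.species if s.group == group)

    @property
    def produced_species(self) -> tuple[SpeciesSpec, ...]:
        return tuple(s for s in self.species if s.produced)

    def binding_pairs(self) -> set[tuple[str, str]]:
        """Unordered partner pairs of every reversible binding reaction."""
        return {
            (r.reactants[0], r.reactants[1])
            for r in self.reactions
            if r.kind == "reversible_binding"
        }

    # -- validation ----------------------------------------------------
    def _validate(self) -> None:
        names = self.species_names
        if len(set(names)) != len(names):
            raise NetworkError("duplicate species names")
        known = set(names)
        referenced: set[str] = set()
        n_degradation = 0
        for r in self.reactions:
            for s in (*r.reactants, *r.products):
                if s not in known:
                    raise NetworkError(f"reaction references unknown species {s!r}")
                referenced.add(s)
            if r.kind == "degradation":
                n_degradation += 1
            if r.kind == "production":
                spec = self.species[self.index(r.products[0])]
                if spec.production_param != r.forward_rate:
                    raise NetworkError(
                        f"production of {spec.name!r} uses rate {r.forward_rate!r} but the "
                        f"species declares {spec.production_param!r}"
                    )
        if n_degradation != 1:
            raise NetworkError("exactly one catch-all degradation entry is required")
        produced_by_rule = {
            r.products[0] for r in self.reactions if r.kind == "production"
        }
        declared = {s.name for s in self.produced_species}
        if produced_by_rule != declared:
            raise NetworkError(
                "species with a production_param must match production reactions exactly"
            )
        # The catch-all degradation touches every species, so a species is an
        # orphan only if nothing but degradation involves it.
        orphans = known - referenced - declared
        if orphans:
            raise NetworkError(f"orphan species never referenced by any reaction: {sorted(orphans)}")

    def check_interaction_table(
        self, table_pairs: Iterable[tuple[str, str]], extras: Iterable[tuple[str, str]] = ()
    ) -> None:
        """Cross-check binding reactions against a qualitative interaction table.

        ``table_pairs`` are (anti-apoptotic, partner) pairs with effectors
        given by their activated forms.  ``extras`` lists pairs present in
        the reaction table only, tolerated with documentation.
        """
        model = self.binding_pairs()
        table = set(table_pairs)
        extra = set(extras)
        missing = table - model
        surplus = model - table - extra
        if missing or surplus:
            raise NetworkError(
                f"interaction-table mismatch: missing={sorted(missing)} surplus={sorted(surplus)}"
            )

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        species = []
        for s in self.species:
            entry: dict = {"name": s.name, "group": s.group}
            if s.production_param:
                entry["production_param"] = s.production_param
            species.append(entry)
        reactions = []
        for r in self.reactions:
            entry = {
                "kind": r.kind,
                "reactants": list(r.reactants),
                "products": list(r.products),
                "forward_rate": r.forward_rate,
            }
            if r.reverse_rate:
                entry["reverse_rate"] = r.reverse_rate
            reactions.append(entry)
        return {"metadata": dict(self.metadata), "species": species, "reactions": reactions}

    @classmethod
    def from_dict(cls, doc: Mapping) -> "ReactionNetwork":
        species = tuple(
            SpeciesSpec(
                name=e["name"],
                group=e["group"],
                production_param=e.get("production_param"),
            )
            for e in doc["species"]
        )
        reactions = tuple(
            ReactionRule(
                kind=e["kind"],
                reactants=tuple(e.get("reactants", ())),
                products=tuple(e.get("products", ())),
                forward_rate=e["forward_rate"],
                reverse_rate=e.get("reverse_rate"),
            )
            for e in doc["reactions"]
        )
        return cls(species=species, reactions=reactions, metadata=doc.get("metadata", {}))


@dataclass(frozen=True)
class RateParams:
    """Named nonnegative rate constants.

    Units: second-order rates (binding, dimerization, activation) in
    molecule^-1 h^-1, first-order rates (unbinding ``km``, degradation
    ``kdeg``) in h^-1, production rates in molecules h^-1, all in the
    abstract reaction volume where 1 nM = 600 molecules.
    """

    values: Mapping[str, float]
    time_unit: str = "hour"
    molecules_per_nM: float = 600.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", dict(self.values))
        for name, v in self.values.items():
            if not (v >= 0.0) or not math.isfinite(v):
                raise ParameterError(f"rate {name!r} must be finite and >= 0, got {v}")
        if "kdeg" in self.values and self.values["kdeg"] <= 0:
            raise ParameterError("kdeg must be positive")
        classes = [self.values.get(k) for k in ("ks", "ki", "kw")]
        if all(c is not None for c in classes) and not (classes[0] > classes[1] > classes[2]):
            raise ParameterError("affinity classes must satisfy ks > ki > kw")

    def __getitem__(self, name: str) -> float:
        try:
            return self.values[name]
        except KeyError:
            raise ParameterError(f"unknown rate parameter {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self.values

    def updated(self, **overrides: float) -> "RateParams":
        unknown = set(overrides) - set(self.values)
        if unknown:
            raise ParameterError(f"unknown rate parameters: {sorted(unknown)}")
        merged = dict(self.values)
        merged.update(overrides)
        return replace(self, values=merged)

    def production_rates(self, names: Iterable[str] = PRODUCTION_PARAMS) -> dict[str, float]:
        return {k: self.values[k] for k in names}


# ---------------------------------------------------------------------------
# default model
# ---------------------------------------------------------------------------

_DEFAULT_NETWORK_RESOURCE = "bcl2_family.yaml"

#: Degradation rate implementing the ~10 h protein half-life, h^-1.
KDEG_DEFAULT = math.log(2.0) / 10.0

# Kinetic defaults are calibrated estimates (the model's literature sources
# give affinity classes, not printed constants): the strong/intermediate/weak
# on-rate classes keep their 1:10:100 ratio, and the absolute scale is set so
# that sequestration quenches free activators much faster than turnover
# (ks * [guardian pool] >> kdeg), which is what gives the toggle its two
# branches at the ~10^2-molecule abundances the production rates imply.
KINETIC_DEFAULTS = {
    "ks": 0.5,  # strong binding on-rate, molecule^-1 h^-1
    "ki": 0.05,  # intermediate
    "kw": 0.005,  # weak
    "ka": 0.5,  # catalytic activation efficiency, molecule^-1 h^-1
    "kd": 0.5,  # effector dimerization, molecule^-1 h^-1
    "km": 0.2,  # complex dissociation, h^-1
    "kdeg": KDEG_DEFAULT,
}

#: Production rates (molecules h^-1): activators 0.1, enablers 1.0,
#: anti-apoptotic proteins 10.0, effectors 60.0.
PRODUCTION_DEFAULTS = {
    "kpMcl1": 10.0,
    "kpA1": 10.0,
    "kpBclXl": 10.0,
    "kpBcl2": 10.0,
    "kpBclw": 10.0,
    "kpBclB": 10.0,
    "kpHrk": 1.0,
    "kpBik": 1.0,
    "kptBid": 0.1,
    "kpPuma": 1.0,
    "kpBim": 0.1,
    "kpBad": 1.0,
    "kpBmf": 1.0,
    "kpNoxa": 1.0,
    "kpBax": 60.0,
    "kpBak": 60.0,
}


def build_default_network() -> ReactionNetwork:
    """Load the canonical 59-species, 62-entry Bcl-2 family network."""
    ref = resources.files("bclswitch").joinpath(f"data/{_DEFAULT_NETWORK_RESOURCE}")
    with ref.open("r") as fh:
        doc = yaml.safe_load(fh)
    return ReactionNetwork.from_dict(doc)


def default_rate_params(**overrides: float) -> RateParams:
    """Default kinetic constants and production rates, override by keyword."""
    values = {**KINETIC_DEFAULTS, **PRODUCTION_DEFAULTS}
    params = RateParams(values=values)
    return params.updated(**overrides) if overrides else params


def load_network(path) -> ReactionNetwork:
    with open(path, "r") as fh:
        return ReactionNetwork.from_dict(yaml.safe_load(fh))


def save_network(net: ReactionNetwork, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(net.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# stoichiometry and initial conditions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Channel:
    """One irreversible mass-action flux: rate * prod(reactant abundances)."""

    rate_name: str
    reactant_indices: tuple[int, ...]
    column: int


def expand_channels(net: ReactionNetwork) -> list[Channel]:
    """Flux channels of the network: reversible entries give two channels,
    the catch-all degradation one channel per species."""
    channels: list[Channel] = []
    col = 0

    def add(rate_name: str, reactants: tuple[int, ...]) -> None:
        nonlocal col
        channels.append(Channel(rate_name, reactants, col))
        col += 1

    idx = {s.name: i for i, s in enumerate(net.species)}
    for r in net.reactions:
        if r.kind == "degradation":
            for s in net.species:
                add(r.forward_rate, (idx[s.name],))
        else:
            add(r.forward_rate, tuple(idx[s] for s in r.reactants))
            if r.is_reversible:
                add(r.reverse_rate, tuple(idx[s] for s in r.products))
    return channels


def stoichiometry(net: ReactionNetwork) -> np.ndarray:
    """Net species change per flux channel, shape (n_species, n_channels)."""
    idx = {s.name: i for i, s in enumerate(net.species)}
    channels = expand_channels(net)
    S = np.zeros((len(net.species), len(channels)))
    col = 0
    for r in net.reactions:
        if r.kind == "degradation":
            for s in net.species:
                S[idx[s.name], col] -= 1.0
                col += 1
            continue
        for s in r.reactants:
            S[idx[s], col] -= 1.0
        for s in r.products:
            S[idx[s], col] += 1.0
        col += 1
        if r.is_reversible:
            for s in r.products:
                S[idx[s], col] -= 1.0
            for s in r.reactants:
                S[idx[s], col] += 1.0
            col += 1
    assert col == len(channels)
    return S


def initial_state(net: ReactionNetwork, params: RateParams) -> np.ndarray:
    """Pre-stimulus abundances: kp/kdeg for produced species, zero otherwise.

    Each synthesized protein starts at the level balancing its production
    against first-order degradation; activated effectors and all complexes
    start empty.
    """
    kdeg = params["kdeg"]
    if kdeg <= 0:
        raise ParameterError("kdeg must be positive to balance production")
    x0 = np.zeros(len(net.species))
    for i, s in enumerate(net.species):
        if s.produced:
            x0[i] = params[s.production_param] / kdeg
    return x0


def monomer_weights(net: ReactionNetwork) -> np.ndarray:
    """Monomer content per species (2 for bound pairs, else 1).

    Every non-production, non-degradation reaction conserves this weighted
    total, so at steady state sum(w*x) = sum(kp)/kdeg.
    """
    return np.array([2.0 if s.is_complex else 1.0 for s in net.species])


# ---------------------------------------------------------------------------
# toy networks with closed-form steady states (test oracles)
# ---------------------------------------------------------------------------

TOY_KINDS = ("production_degradation", "single_binding", "activation_dimerization")


def build_toy_network(kind: str) -> tuple[ReactionNetwork, RateParams]:
    """Tiny networks whose steady states are known in closed form."""
    if kind == "production_degradation":
        net = ReactionNetwork(
            species=(SpeciesSpec("A", "enabler", production_param="kpA"),),
            reactions=(
                ReactionRule("production", (), ("A",), "kpA"),
                ReactionRule("degradation", (), (), "kdeg"),
            ),
            metadata={"name": "toy_production_degradation"},
        )
        params = RateParams({"kpA": 5.0, "kdeg": 0.1})
    elif kind == "single_binding":
        net = ReactionNetwork(
            species=(
                SpeciesSpec("A", "antiapoptotic", production_param="kpA"),
                SpeciesSpec("B", "enabler", production_param="kpB"),
                SpeciesSpec("A~B", "complex"),
            ),
            reactions=(
                ReactionRule("reversible_binding", ("A", "B"), ("A~B",), "kf", "km"),
                ReactionRule("production", (), ("A",), "kpA"),
                ReactionRule("production", (), ("B",), "kpB"),
                ReactionRule("degradation", (), (), "kdeg"),
            ),
            metadata={"name": "toy_single_binding"},
        )
        params = RateParams({"kf": 0.01, "km": 0.5, "kpA": 4.0, "kpB": 2.0, "kdeg": 0.1})
    elif kind == "activation_dimerization":
        net = ReactionNetwork(
            species=(
                SpeciesSpec("T", "activator", production_param="kpT"),
                SpeciesSpec("B", "effector", production_param="kpB"),
                SpeciesSpec("aB", "activated_effector"),
                SpeciesSpec("aB~aB", "complex"),
            ),
            reactions=(
                ReactionRule("catalytic_activation", ("T", "B"), ("T", "aB"), "ka"),
                ReactionRule("reversible_dimerization", ("aB", "aB"), ("aB~aB",), "kd", "km"),
                ReactionRule("production", (), ("T",), "kpT"),
                ReactionRule("production", (), ("B",), "kpB"),
                ReactionRule("degradation", (), (), "kdeg"),
            ),
            metadata={"name": "toy_activation_dimerization"},
        )
        params = RateParams(
            {"ka": 0.02, "kd": 0.05, "km": 0.5, "kpT": 1.0, "kpB": 6.0, "kdeg": 0.1}
        )
    else:
        raise NetworkError(f"unknown toy network kind {kind!r}; choose from {TOY_KINDS}")
    return net, params
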