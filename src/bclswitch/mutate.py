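"""Random topology mutation of the Bcl-2 network.

A mutation adds a non-existing or deletes an existing interaction of one of
two kinds: an inhibitory binding between an anti-apoptotic protein and a
pro-apoptotic partner (a BH3-only protein or an activated effector), or a
catalytic activation of an effector by an activator.  Group-level structure
is preserved: every anti-apoptotic protein keeps at least one inhibitory
edge and every effector keeps at least one activation edge.  Production,
degradation and the effector dimerizations (the MAC readout itself) are
never touched.  Added bindings get the strong class ks (reverse km) by
default; added activations get ka.

The alternative-models experiment repeats the Monte-Carlo response analysis
on a panel of mutated networks and scores how well each model's response
classes cluster in the stimulus PC plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .montecarlo import MonteCarloResult, run_monte_carlo
from .network import (
    COMPLEX_SEPARATOR,
    RateParams,
    ReactionNetwork,
    ReactionRule,
    SpeciesSpec,
)
from .patterns import normalize_stimuli, principal_components, separability_score

__all__ = [
    "TopologyMutation",
    "MutationError",
    "candidate_edges",
    "mutate_topology",
    "revert_mutations",
    "alternative_model_experiment",
    "AlternativeModelRun",
]

_PRO_GROUPS = ("enabler", "activator", "activated_effector")


class MutationError(RuntimeError):
    pass


@dataclass(frozen=True)
class TopologyMutation:
    action: str  # "add" | "delete"
    edge_kind: str  # "inhibitory_binding" | "activation"
    partner_a: str  # anti-apoptotic protein, or the activator
    partner_b: str  # pro-apoptotic partner, or the effector
    forward_rate: str = "ks"
    reverse_rate: str | None = "km"

    def __post_init__(self) -> None:
        if self.action not in ("add", "delete"):
            raise MutationError(f"unknown action {self.action!r}")
        if self.edge_kind not in ("inhibitory_binding", "activation"):
            raise MutationError(f"unknown edge kind {self.edge_kind!r}")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.partner_a, self.partner_b)


def _binding_rules(net: ReactionNetwork) -> dict[tuple[str, str], ReactionRule]:
    return {
        (r.reactants[0], r.reactants[1]): r
        for r in net.reactions
        if r.kind == "reversible_binding"
    }


def _activation_rules(net: ReactionNetwork) -> dict[tuple[str, str], ReactionRule]:
    return {
        (r.reactants[0], r.reactants[1]): r
        for r in net.reactions
        if r.kind == "catalytic_activation"
    }


def _activated_form(effector: str) -> str:
    return "a" + effector


def candidate_edges(
    net: ReactionNetwork,
) -> tuple[list[TopologyMutation], list[TopologyMutation]]:
    """(addable, deletable) mutations for the current network."""
    anti = net.species_by_group("antiapoptotic")
    pro = [s for g in _PRO_GROUPS for s in net.species_by_group(g)]
    activators = net.species_by_group("activator")
    effectors = net.species_by_group("effector")
    bindings = _binding_rules(net)
    activations = _activation_rules(net)

    addable: list[TopologyMutation] = []
    for a in anti:
        for b in pro:
            if (a, b) not in bindings:
                addable.append(TopologyMutation("add", "inhibitory_binding", a, b))
    for act in activators:
        for eff in effectors:
            if (act, eff) not in activations:
                addable.append(
                    TopologyMutation(
                        "add", "activation", act, eff, forward_rate="ka", reverse_rate=None
                    )
                )

    deletable: list[TopologyMutation] = []
    for (a, b), rule in bindings.items():
        deletable.append(
            TopologyMutation(
                "delete",
                "inhibitory_binding",
                a,
                b,
                forward_rate=rule.forward_rate,
                reverse_rate=rule.reverse_rate,
            )
        )
    for (act, eff), rule in activations.items():
        deletable.append(
            TopologyMutation(
                "delete", "activation", act, eff, forward_rate=rule.forward_rate,
                reverse_rate=None,
            )
        )
    return addable, deletable


def _apply(net: ReactionNetwork, mut: TopologyMutation) -> ReactionNetwork:
    species = list(net.species)
    reactions = list(net.reactions)
    if mut.edge_kind == "inhibitory_binding":
        complex_name = f"{mut.partner_a}{COMPLEX_SEPARATOR}{mut.partner_b}"
        if mut.action == "add":
            if complex_name not in net.species_names:
                species.append(SpeciesSpec(complex_name, "complex"))
            reactions.append(
                ReactionRule(
                    "reversible_binding",
                    (mut.partner_a, mut.partner_b),
                    (complex_name,),
                    mut.forward_rate,
                    mut.reverse_rate,
                )
            )
        else:
            rule = _binding_rules(net).get(mut.pair)
            if rule is None:
                raise MutationError(f"no binding {mut.pair} to delete")
            reactions.remove(rule)
            # drop the complex species if nothing else references it
            still_used = any(
                complex_name in (*r.reactants, *r.products)
                for r in reactions
                if r.kind != "degradation"
            )
            if not still_used:
                species = [s for s in species if s.name != complex_name]
    else:  # activation
        aform = _activated_form(mut.partner_b)
        if mut.action == "add":
            reactions.append(
                ReactionRule(
                    "catalytic_activation",
                    (mut.partner_a, mut.partner_b),
                    (mut.partner_a, aform),
                    mut.forward_rate,
                )
            )
        else:
            rule = _activation_rules(net).get(mut.pair)
            if rule is None:
                raise MutationError(f"no activation {mut.pair} to delete")
            reactions.remove(rule)
    meta = dict(net.metadata)
    applied = meta.get("mutations_applied", 0)
    meta["mutations_applied"] = applied + 1
    return ReactionNetwork(species=tuple(species), reactions=tuple(reactions), metadata=meta)


def _group_consistent(net: ReactionNetwork) -> bool:
    bindings = _binding_rules(net)
    activations = _activation_rules(net)
    for a in net.species_by_group("antiapoptotic"):
        if not any(pa == a for pa, _ in bindings):
            return False
    for eff in net.species_by_group("effector"):
        if not any(pe == eff for _, pe in activations):
            return False
    return True


def mutate_topology(
    net: ReactionNetwork,
    n_mutations: int,
    rng: np.random.Generator | int | None = None,
    max_retries: int = 1000,
) -> tuple[ReactionNetwork, list[TopologyMutation]]:
    """Apply ``n_mutations`` distinct random mutations under the constraints.

    Candidates are recomputed after every step; a draw that would break
    group consistency, or undo an earlier mutation, is resampled.  The
    symmetric difference between the mutated and original reaction sets has
    size exactly ``n_mutations``.
    """
    if n_mutations < 1:
        raise MutationError("n_mutations must be >= 1")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    current = net
    applied: list[TopologyMutation] = []
    touched: set[tuple[str, str, str]] = set()
    retries = 0
    while len(applied) < n_mutations:
        addable, deletable = candidate_edges(current)
        pool = addable + deletable
        mut = pool[int(rng.integers(len(pool)))]
        key = (mut.edge_kind, mut.partner_a, mut.partner_b)
        candidate_net = None
        if key not in touched:
            candidate_net = _apply(current, mut)
            if not _group_consistent(candidate_net):
                candidate_net = None
        if candidate_net is None:
            retries += 1
            if retries > max_retries:
                raise MutationError(
                    f"could not find {n_mutations} feasible mutations "
                    f"after {max_retries} retries"
                )
            continue
        current = candidate_net
        applied.append(mut)
        touched.add(key)
    return current, applied


def revert_mutations(
    net: ReactionNetwork, mutations: list[TopologyMutation]
) -> ReactionNetwork:
    """Undo recorded mutations in reverse order (bookkeeping inverse)."""
    current = net
    for mut in reversed(mutations):
        inverse = TopologyMutation(
            action="delete" if mut.action == "add" else "add",
            edge_kind=mut.edge_kind,
            partner_a=mut.partner_a,
            partner_b=mut.partner_b,
            forward_rate=mut.forward_rate,
            reverse_rate=mut.reverse_rate,
        )
        current = _apply(current, inverse)
    meta = dict(current.metadata)
    meta.pop("mutations_applied", None)
    return ReactionNetwork(
        species=current.species, reactions=current.reactions, metadata=meta
    )


@dataclass
class AlternativeModelRun:
    network: ReactionNetwork
    mutations: list[TopologyMutation]
    mc: MonteCarloResult
    separability: float | None
    silhouette: float | None = None


def _pattern_scores(mc: MonteCarloResult, seed: int) -> tuple[float, float] | None:
    labels = np.asarray(mc.labels)
    if len(np.unique(labels)) < 2:
        return None
    pca = principal_components(normalize_stimuli(mc.stimuli))
    return separability_score(pca.plane, labels, seed=seed, with_silhouette=True)


def alternative_model_experiment(
    net: ReactionNetwork,
    params: RateParams,
    n_models: int = 10,
    n_mutations: int = 5,
    n_iterations: int = 1000,
    q_interval: tuple[float, float] = (0.1, 10.0),
    sampling: str = "log",
    seed: int = 0,
    default_mc: MonteCarloResult | None = None,
) -> tuple[AlternativeModelRun, list[AlternativeModelRun]]:
    """Monte-Carlo + pattern analysis for the default and mutated networks.

    Returns ``(default_run, mutant_runs)``.  Each mutated model gets its
    own bimodal threshold; a model without one is reported with
    ``mc.threshold is None`` and median-based labels.
    """
    seeds = np.random.SeedSequence(seed).spawn(n_models + 1)
    mc_seed = int(seeds[0].generate_state(1)[0] % (2**31))
    if default_mc is None:
        default_mc = run_monte_carlo(
            net,
            params,
            n_iterations,
            q_interval=q_interval,
            sampling=sampling,
            seed=mc_seed,
        )
    default_scores = _pattern_scores(default_mc, seed=seed)
    default_run = AlternativeModelRun(
        network=net,
        mutations=[],
        mc=default_mc,
        separability=None if default_scores is None else default_scores[0],
        silhouette=None if default_scores is None else default_scores[1],
    )
    runs: list[AlternativeModelRun] = []
    for k in range(n_models):
        sub_rng = np.random.default_rng(seeds[k + 1])
        mutated, muts = mutate_topology(net, n_mutations, rng=sub_rng)
        sub_seed = int(seeds[k + 1].generate_state(2)[1] % (2**31))
        mc = run_monte_carlo(
            mutated,
            params,
            n_iterations,
            q_interval=q_interval,
            sampling=sampling,
            seed=sub_seed,
        )
        scores = _pattern_scores(mc, seed=seed)
        runs.append(
            AlternativeModelRun(
                network=mutated,
                mutations=muts,
                mc=mc,
                separability=None if scores is None else scores[0],
                silhouette=None if scores is None else scores[1],
            )
        )
    return default_run, runs
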