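"""Structure of the default Bcl-2 network and the toy fixtures."""

import math

import numpy as np
import pytest

from bclswitch.network import (
    INTERACTION_TABLE_EXTRAS,
    NetworkError,
    ParameterError,
    RateParams,
    ReactionNetwork,
    ReactionRule,
    SpeciesSpec,
    build_default_network,
    build_toy_network,
    default_rate_params,
    initial_state,
    load_network,
    monomer_weights,
    save_network,
    stoichiometry,
    expand_channels,
)

#: Qualitative interaction table: anti-apoptotic protein -> partners it
#: binds and inhibits (effectors via their activated forms).
BINDS_AND_INHIBITS = {
    "Mcl1": ["Noxa", "Bim", "Puma", "aBax", "aBak"],
    "Bcl2": ["Bad", "Bim", "Puma", "Bmf", "aBax"],
    "A1": ["Noxa", "Bim", "Puma", "tBid", "Hrk", "Bik", "aBax", "aBak"],
    "BclXl": ["Bad", "Bim", "Puma", "tBid", "Hrk", "Bmf", "Bik", "aBak", "aBax"],
    "Bclw": ["Bad", "Bim", "Puma", "tBid", "Hrk", "Bmf", "Bik", "aBax"],
    "BclB": ["aBax"],
}


class TestDefaultNetwork:
    def test_counts(self, net):
        assert len(net.reactions) == 62
        assert len(net.species) == 59
        assert len(net.produced_species) == 16
        assert len(net.species_by_group("complex")) == 41

    def test_reaction_7_is_mcl1_noxa_intermediate(self, net):
        r = net.reactions[6]
        assert r.kind == "reversible_binding"
        assert set(r.reactants) == {"Mcl1", "Noxa"}
        assert r.products == ("Mcl1~Noxa",)
        assert r.forward_rate == "ki"
        assert r.reverse_rate == "km"

    @pytest.mark.parametrize(
        "row, partners, rate",
        [
            (4, ("Mcl1", "Puma"), "ks"),
            (12, ("A1", "Noxa"), "kw"),
            (24, ("Bcl2", "Bad"), "ki"),
            (38, ("BclXl", "aBak"), "ks"),
            (42, ("aBax", "aBax"), "kd"),
        ],
    )
    def test_rate_class_spot_checks(self, net, row, partners, rate):
        r = net.reactions[row]
        assert r.reactants == partners
        assert r.forward_rate == rate

    def test_catalytic_activations_are_irreversible(self, net):
        cats = [r for r in net.reactions if r.kind == "catalytic_activation"]
        assert len(cats) == 4
        assert all(r.reverse_rate is None and r.forward_rate == "ka" for r in cats)
        assert {r.reactants[0] for r in cats} == {"tBid", "Bim"}

    def test_interaction_table_consistency(self, net):
        pairs = [(a, b) for a, bs in BINDS_AND_INHIBITS.items() for b in bs]
        net.check_interaction_table(pairs, extras=INTERACTION_TABLE_EXTRAS)
        # without the two documented weak-class extras the check must fail
        with pytest.raises(NetworkError, match="surplus"):
            net.check_interaction_table(pairs)

    def test_degradation_covers_every_species_once(self, net):
        channels = expand_channels(net)
        deg = [c for c in channels if c.rate_name == "kdeg"]
        assert len(deg) == len(net.species)
        assert sorted(c.reactant_indices[0] for c in deg) == list(range(len(net.species)))

    def test_serialization_round_trip(self, net, tmp_path):
        path = tmp_path / "net.yaml"
        save_network(net, path)
        again = load_network(path)
        assert again.species == net.species  # order preserved
        assert again.reactions == net.reactions

    def test_deterministic_build(self, net):
        assert build_default_network().species_names == net.species_names


class TestRateParams:
    def test_defaults_match_production_table(self, params):
        assert params["kpBax"] == 60.0
        assert params["kpBak"] == 60.0
        assert params["kptBid"] == 0.1
        assert params["kpBim"] == 0.1
        for name in ("kpHrk", "kpBik", "kpPuma", "kpBad", "kpBmf", "kpNoxa"):
            assert params[name] == 1.0
        for name in ("kpMcl1", "kpA1", "kpBclXl", "kpBcl2", "kpBclw", "kpBclB"):
            assert params[name] == 10.0
        assert params["kdeg"] == pytest.approx(math.log(2) / 10.0)

    def test_affinity_class_ordering(self, params):
        assert params["ks"] > params["ki"] > params["kw"]

    def test_invalid_params_rejected(self):
        with pytest.raises(ParameterError):
            RateParams({"kdeg": 0.0})
        with pytest.raises(ParameterError):
            RateParams({"ks": 1.0, "ki": 2.0, "kw": 0.1})
        with pytest.raises(ParameterError):
            default_rate_params(kpBok=1.0)

    def test_updated_is_functional(self, params):
        p2 = params.updated(kptBid=0.2)
        assert p2["kptBid"] == 0.2
        assert params["kptBid"] == 0.1


class TestStoichiometry:
    def test_production_channel(self, net):
        S = stoichiometry(net)
        channels = expand_channels(net)
        j = next(i for i, c in enumerate(channels) if c.rate_name == "kpBax")
        col = S[:, j]
        assert col[net.index("Bax")] == 1.0
        assert np.count_nonzero(col) == 1

    def test_binding_channel(self, net):
        S = stoichiometry(net)
        channels = expand_channels(net)
        i_m, i_n, i_c = (net.index(s) for s in ("Mcl1", "Noxa", "Mcl1~Noxa"))
        j = next(
            i
            for i, c in enumerate(channels)
            if c.rate_name == "ki" and set(c.reactant_indices) == {i_m, i_n}
        )
        assert (S[i_m, j], S[i_n, j], S[i_c, j]) == (-1.0, -1.0, 1.0)

    def test_catalytic_channel_leaves_catalyst_unchanged(self, net):
        S = stoichiometry(net)
        channels = expand_channels(net)
        i_t, i_b, i_a = (net.index(s) for s in ("tBid", "Bax", "aBax"))
        j = next(
            i
            for i, c in enumerate(channels)
            if c.rate_name == "ka" and c.reactant_indices == (i_t, i_b)
        )
        assert S[i_t, j] == 0.0
        assert S[i_b, j] == -1.0
        assert S[i_a, j] == 1.0

    def test_monomer_conservation_structure(self, net):
        """Every non-production, non-degradation column conserves monomers."""
        S = stoichiometry(net)
        channels = expand_channels(net)
        w = monomer_weights(net)
        for j, c in enumerate(channels):
            if c.rate_name.startswith("kp") or c.rate_name == "kdeg":
                continue
            assert w @ S[:, j] == pytest.approx(0.0)


class TestInitialState:
    def test_balances_production_and_degradation(self, net, params):
        x0 = initial_state(net, params)
        kdeg = params["kdeg"]
        assert x0[net.index("Bax")] == pytest.approx(60.0 / kdeg)
        assert x0[net.index("Bax")] == pytest.approx(865.617, rel=1e-4)
        for s in net.species:
            if s.is_complex or s.group == "activated_effector":
                assert x0[net.index(s.name)] == 0.0

    def test_zero_kdeg_rejected(self, net):
        with pytest.raises(ParameterError):
            RateParams({"kdeg": 0.0, "kpBax": 1.0})


class TestToyNetworks:
    @pytest.mark.parametrize(
        "kind", ["production_degradation", "single_binding", "activation_dimerization"]
    )
    def test_toys_validate(self, kind):
        toy, toy_params = build_toy_network(kind)
        assert isinstance(toy, ReactionNetwork)
        assert len(toy.species) <= 4

    def test_unknown_kind(self):
        with pytest.raises(NetworkError):
            build_toy_network("frobnicate")


class TestValidation:
    def test_orphan_species_rejected(self):
        with pytest.raises(NetworkError, match="orphan"):
            ReactionNetwork(
                species=(
                    SpeciesSpec("A", "enabler", production_param="kpA"),
                    SpeciesSpec("Ghost", "enabler"),
                ),
                reactions=(
                    ReactionRule("production", (), ("A",), "kpA"),
                    ReactionRule("degradation", (), (), "kdeg"),
                ),
            )

    def test_unknown_species_in_reaction_rejected(self):
        with pytest.raises(NetworkError, match="unknown species"):
            ReactionNetwork(
                species=(SpeciesSpec("A", "enabler", production_param="kpA"),),
                reactions=(
                    ReactionRule("production", (), ("A",), "kpA"),
                    ReactionRule("reversible_binding", ("A", "B"), ("A~B",), "ks", "km"),
                    ReactionRule("degradation", (), (), "kdeg"),
                ),
            )

    def test_catalyst_must_be_unchanged(self):
        with pytest.raises(NetworkError, match="catalyst"):
            ReactionRule("catalytic_activation", ("T", "B"), ("B", "aB"), "ka")
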