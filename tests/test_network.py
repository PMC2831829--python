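"""Reaction network: mass-action kinetics, moiety bookkeeping, variants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from casprd.config import network_from_parameters
from casprd.network import (
    ConfigurationError,
    ProteinSpecies,
    Reaction,
    ReactionNetwork,
    ScenarioVariant,
    apply_variant,
    build_reference_network,
    mass_action_rates,
)


def brute_force_rates(network, conc):
    """Independent per-reaction loop: rate vector = Σ net-stoich × velocity."""
    conc = np.asarray(conc, dtype=float)
    idx = {name: i for i, name in enumerate(network.species_names)}
    phi = 1.0
    u, v = (conc[idx[n]] for n in network.substrate_pair)
    if u + v > 0:
        phi = u / (u + v)
    out = np.zeros(network.n_species)
    for rxn in network.reactions:
        vel = rxn.rate_constant
        for name, stoich in rxn.reactants:
            vel *= conc[idx[name]] ** stoich
        if rxn.tag in ("synthesis", "turnover", "ubiquitin_degradation"):
            vel *= phi
        for name, stoich in rxn.reactants:
            out[idx[name]] -= stoich * vel
        for name, stoich in rxn.products:
            out[idx[name]] += stoich * vel
    return out


class TestMassAction:
    def test_bimolecular_example(self):
        """A + B → C at k: d[C]/dt = k[A][B], reactants consumed equally."""
        net = ReactionNetwork(
            species=(
                ProteinSpecies("A", 30.0, 1.0),
                ProteinSpecies("B", 30.0, 2.0),
                ProteinSpecies("C", 60.0),
                ProteinSpecies("substrate", 50.0, 1.0),
                ProteinSpecies("substrate_cleaved", 25.0),
            ),
            reactions=(Reaction((("A", 1), ("B", 1)), (("C", 1),), 1.3, "xiap_binding"),),
        )
        rates = mass_action_rates(net, net.initial_concentrations())
        k = 1.3
        expected = {"A": -2 * k, "B": -2 * k, "C": 2 * k}
        for name, want in expected.items():
            assert rates[net.species_index(name)] == pytest.approx(want)

    def test_zero_state_zero_rates(self, reference_network):
        """No zeroth-order input at zero state... except synthesis reactions,
        so drop them first."""
        net = reference_network.with_reactions(
            r for r in reference_network.reactions if r.tag != "synthesis"
        )
        rates = mass_action_rates(net, np.zeros(net.n_species))
        assert np.all(rates == 0.0)

    def test_negative_concentration_rejected(self, reference_network):
        conc = reference_network.initial_concentrations()
        conc[0] = -0.5
        with pytest.raises(ValueError, match="negative concentration"):
            mass_action_rates(reference_network, conc)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_oracle(self, reference_network, seed):
        """Vectorised rates equal an independent per-reaction loop."""
        rng = np.random.default_rng(seed)
        conc = rng.uniform(0.0, 1.0, reference_network.n_species)
        got = mass_action_rates(reference_network, conc)
        want = brute_force_rates(reference_network, conc)
        np.testing.assert_allclose(got, want, rtol=1e-12, atol=1e-15)

    def test_vectorised_over_nodes(self, reference_network):
        rng = np.random.default_rng(7)
        conc = rng.uniform(0.0, 1.0, (5, reference_network.n_species))
        got = reference_network.reaction_velocities(conc)
        for i in range(5):
            np.testing.assert_allclose(
                got[i], reference_network.reaction_velocities(conc[i])
            )


class TestReferenceNetwork:
    def test_required_reaction_tags_present(self, reference_network):
        tags = {r.tag for r in reference_network.reactions}
        assert {"c3_feedback_on_c9", "c3_autoprocessing"} <= tags
        assert {"xiap_binding", "xiap_cleavage", "smac_binding"} <= tags
        assert {"ubiquitin_degradation", "synthesis", "turnover"} <= tags

    def test_missing_rate_constant_names_tag(self, reference_params):
        import copy

        params = copy.deepcopy(reference_params)
        del params["reactions"][0]["k"]
        tag = params["reactions"][0]["tag"]
        with pytest.raises(ConfigurationError, match=tag):
            network_from_parameters(params)

    def test_unknown_species_in_reaction_rejected(self):
        with pytest.raises(ConfigurationError, match="unknown species"):
            ReactionNetwork(
                species=(
                    ProteinSpecies("substrate", 50.0, 1.0),
                    ProteinSpecies("substrate_cleaved", 25.0),
                ),
                reactions=(Reaction((("ghost", 1),), (), 1.0, "turnover"),),
            )

    def test_xiap_moiety_conserved_without_degradation(self, toy_binding_network):
        """Pure binding/unbinding conserves the bound+free moiety: integrate
        the toy network (synthesis/turnover removed) and track A + C."""
        from casprd.solver import simulate_local_ode

        net = toy_binding_network.with_reactions(
            r
            for r in toy_binding_network.reactions
            if r.tag not in ("synthesis", "turnover")
        )
        course = simulate_local_ode(net, [], t_end=50.0, save_interval=1.0)
        moiety = course.get("A")[0] + course.get("C")[0]
        np.testing.assert_allclose(moiety, moiety[0], rtol=1e-6)

    def test_caspase3_moiety_conserved_in_reference(
        self, reference_network, wave_inputs
    ):
        """Total caspase-3 across pro/active/inhibitor-bound forms is constant
        once synthesis, turnover and degradation are disabled."""
        from casprd.solver import simulate_local_ode

        net = reference_network.with_reactions(
            r
            for r in reference_network.reactions
            if r.tag not in ("synthesis", "turnover", "ubiquitin_degradation")
        )
        course = simulate_local_ode(net, wave_inputs, t_end=900.0, save_interval=5.0)
        moiety = sum(
            course.get(n)[0]
            for n in ("casp3_pro", "casp3", "xiap_casp3", "bir12_casp3")
        )
        np.testing.assert_allclose(moiety, moiety[0], rtol=1e-5)

    def test_no_substrate_no_cleavage(self, reference_params, wave_inputs):
        import copy

        from casprd.solver import simulate_local_ode

        params = copy.deepcopy(reference_params)
        for sp in params["species"]:
            if sp["name"] == "substrate":
                sp["init_uM"] = 0.0
        net = build_reference_network(params)
        course = simulate_local_ode(net, wave_inputs, t_end=900.0, save_interval=5.0)
        assert np.all(course.get("substrate_cleaved") == 0.0)


class TestVariants:
    def test_knockout_removes_exactly_tagged_reactions(self, reference_network):
        n_feedback = len(reference_network.reactions_tagged("c3_feedback_on_c9"))
        assert n_feedback > 0
        knocked = apply_variant(reference_network, "no_c3_to_c9_feedback")
        assert len(knocked.reactions) == len(reference_network.reactions) - n_feedback
        survivors = set(knocked.reactions)
        assert survivors == {
            r for r in reference_network.reactions if r.tag != "c3_feedback_on_c9"
        }

    def test_knockout_idempotent(self, reference_network):
        once = apply_variant(reference_network, "no_c3_autoprocessing")
        twice = apply_variant(once, "no_c3_autoprocessing")
        assert once.reactions == twice.reactions

    def test_rate_scale_multiplies_every_constant(self, reference_network):
        scaled = apply_variant(reference_network, "rate_scale:10")
        for before, after in zip(reference_network.reactions, scaled.reactions):
            assert after.rate_constant == pytest.approx(10.0 * before.rate_constant)
            assert after.tag == before.tag

    def test_immobile_apoptosome_targets_only_flagged_species(self, reference_network):
        frozen = apply_variant(reference_network, "immobile_apoptosome")
        for before, after in zip(reference_network.species, frozen.species):
            if before.apoptosome_containing:
                assert not after.diffusible
            else:
                assert after.diffusible == before.diffusible
        D = dict(zip(frozen.species_names, frozen.diffusivities()))
        assert D["smac"] > 0 and D["casp3"] > 0
        assert D["apop_pc9"] == 0.0 and D["xiap_apop_c9"] == 0.0

    def test_diffusivity_scale_recorded_not_structural(self, reference_network):
        scaled = apply_variant(reference_network, "diffusivity_scale:100")
        assert scaled.diffusivity_scale == pytest.approx(100.0)
        assert scaled.reactions == reference_network.reactions
        np.testing.assert_allclose(
            scaled.diffusivities(), reference_network.diffusivities() / 100.0
        )

    def test_original_network_unmodified(self, reference_network):
        before = (reference_network.reactions, reference_network.species)
        apply_variant(reference_network, ["no_c3_autoprocessing", "rate_scale:10"])
        assert (reference_network.reactions, reference_network.species) == before

    def test_unknown_variant_rejected(self):
        with pytest.raises(ConfigurationError, match="unknown variant"):
            ScenarioVariant.parse("teleport_smac")
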