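"""Reaction-network data model and the two circuit builders."""

import numpy as np
import pytest

from litrswitch.derive import DerivedRateSet
from litrswitch.network import (GenericGeneRates, LITRConfig, ReactionDef,
                                ReactionNetwork, SpeciesDef,
                                build_generic_network, build_litr_network,
                                concentration_to_count,
                                count_to_concentration,
                                mass_action_propensity)


class TestUnits:
    @pytest.mark.parametrize("nm, vol, count", [
        (0.0, 1.0, 0),
        (30.0, 1.0, 18),    # the free-RNAp working concentration
        (20.0, 1.0, 12),
        (1000.0, 1.0, 602),
    ])
    def test_concentration_to_count(self, nm, vol, count):
        assert concentration_to_count(nm, vol) == count

    def test_round_trip_within_rounding(self):
        for nm in (0.0, 5.0, 30.0, 250.0, 1e4):
            n = concentration_to_count(nm, 1.0)
            back = count_to_concentration(n, 1.0)
            assert abs(back - nm) <= 0.5 / 0.6022 + 1e-9

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            concentration_to_count(-1.0, 1.0)


class TestPropensity:
    def test_homodimerization_needs_two_molecules(self):
        rxn = ReactionDef({"A": 2}, {"A2": 1}, 0.5, "um3_per_second")
        assert mass_action_propensity(rxn, {"A": 1}, 1.0) == 0.0
        assert mass_action_propensity(rxn, {"A": 4}, 1.0) == \
            pytest.approx(0.5 * 4 * 3 / 2)

    def test_bimolecular_scales_with_inverse_volume(self):
        rxn = ReactionDef({"A": 1, "B": 1}, {"C": 1}, 0.1, "um3_per_second")
        assert mass_action_propensity(rxn, {"A": 2, "B": 3}, 1.0) == \
            pytest.approx(0.6)
        assert mass_action_propensity(rxn, {"A": 2, "B": 3}, 2.0) == \
            pytest.approx(0.3)

    def test_first_order_dilution_rate(self):
        rxn = ReactionDef({"P": 1}, {}, 3.9e-4, "per_second")
        assert mass_action_propensity(rxn, {"P": 1000}, 1.0) == \
            pytest.approx(0.39)

    def test_order_above_two_rejected(self):
        with pytest.raises(ValueError):
            ReactionDef({"A": 3}, {}, 1.0, "per_second")

    def test_negative_counts_rejected(self):
        rxn = ReactionDef({"A": 1}, {}, 1.0, "per_second")
        with pytest.raises(ValueError):
            mass_action_propensity(rxn, {"A": -1}, 1.0)


class TestNetworkModel:
    def test_duplicate_species_rejected(self):
        with pytest.raises(ValueError):
            ReactionNetwork([SpeciesDef("A"), SpeciesDef("A")], [])

    def test_undeclared_species_rejected(self):
        with pytest.raises(ValueError, match="undeclared"):
            ReactionNetwork([SpeciesDef("A")],
                            [ReactionDef({"A": 1}, {"B": 1}, 1.0)])

    def test_constant_species_have_zero_net_stoichiometry(self):
        net = ReactionNetwork(
            [SpeciesDef("A", 5), SpeciesDef("R", 10, constant=True)],
            [ReactionDef({"A": 1, "R": 1}, {"A": 2, "R": 1}, 1.0,
                         "um3_per_second")])
        compiled = net.compile()
        assert compiled.net[0, net.species_index("R")] == 0
        assert compiled.net[0, net.species_index("A")] == 1

    def test_text_and_json_round_trip(self, litr_net_plain):
        for encode, decode in ((ReactionNetwork.to_text,
                                ReactionNetwork.from_text),
                               (ReactionNetwork.to_json,
                                ReactionNetwork.from_json)):
            clone = decode(encode(litr_net_plain))
            assert clone.species_names == litr_net_plain.species_names
            assert len(clone.reactions) == len(litr_net_plain.reactions)
            a, b = clone.compile(), litr_net_plain.compile()
            assert np.array_equal(a.net, b.net)
            assert np.allclose(a.rate_eff, b.rate_eff)
            assert np.array_equal(a.initial, b.initial)


class TestGenericBuilder:
    def test_twenty_dynamic_species_plus_constant_rnap(self):
        net = build_generic_network(GenericGeneRates.example(),
                                    GenericGeneRates.example())
        assert net.n_dynamic_species() == 20
        assert [s.name for s in net.species if s.constant] == ["R"]

    def test_promoter_copy_conserved_by_every_reaction(self):
        net = build_generic_network(GenericGeneRates.example(),
                                    GenericGeneRates.example())
        compiled = net.compile()
        assert np.array_equal(compiled.cons_matrix @ compiled.initial,
                              compiled.cons_totals)
        # each reaction's net stoichiometry is orthogonal to each law
        assert np.all(compiled.net @ compiled.cons_matrix.T == 0)

    def test_dimer_degradation_rate_is_monomer_rate_over_sigma(self):
        g = GenericGeneRates.example()
        net = build_generic_network(g, g)
        rates = [r.rate_constant for r in net.reactions
                 if r.source_row == "gamma_p/sigma"]
        assert rates == [pytest.approx(g.gamma_p / g.sigma)] * 2

    def test_missing_rate_constant_names_the_reaction_row(self):
        import dataclasses
        with pytest.raises(ValueError, match="dimerization"):
            dataclasses.replace(GenericGeneRates.example(), k1=0.0)


class TestLITRBuilder:
    def test_species_counts(self, litr_net_plain):
        assert litr_net_plain.metadata["species_count_dynamic"] == 27
        assert litr_net_plain.metadata["species_count_total"] == 30

    def test_without_inducers_every_inducer_propensity_vanishes(self,
                                                                litr_net_plain):
        compiled = litr_net_plain.compile()
        state = compiled.initial.copy()
        # put molecules everywhere so only the zero inducer count can gate
        state[~compiled.is_constant] = 50
        for j, rxn in enumerate(litr_net_plain.reactions):
            if any(s in ("I_l", "I_t") for s in rxn.reactants):
                a = mass_action_propensity(
                    rxn, dict(zip(litr_net_plain.species_names, state)),
                    litr_net_plain.volume)
                assert a == 0.0

    def test_second_operator_site_binding_is_200_fold_accelerated(self,
                                                                  litr_net_plain):
        rates = DerivedRateSet.default()
        row = [r for r in litr_net_plain.reactions
               if r.source_row == "200*k_l3"]
        assert len(row) == 1
        assert row[0].rate_constant == pytest.approx(200 * rates["k_l3"]) \
            == pytest.approx(0.6)

    def test_promoter_copies_conserved_by_every_reaction(self):
        net = build_litr_network(LITRConfig(n_lacI=3, n_tetR=5,
                                            iptg=100.0, dox=10.0))
        compiled = net.compile()
        assert np.all(compiled.net @ compiled.cons_matrix.T == 0)
        assert list(compiled.cons_totals) == [5, 3]

    def test_irreversible_displacements_have_no_reverse_entry(self,
                                                              litr_net_plain):
        # inducer-driven release of a repressor from the DNA is one-way:
        # the exact reverse of each displacement reaction must not exist
        pairs = {(frozenset(r.reactants.items()), frozenset(r.products.items()))
                 for r in litr_net_plain.reactions}
        displacements = [r for r in litr_net_plain.reactions
                         if set(r.reactants) & {"I_l", "I_t"}
                         and set(r.products) & {"D_l", "D_t", "d1TetR2"}]
        assert len(displacements) == 4
        for r in displacements:
            reverse = (frozenset(r.products.items()),
                       frozenset(r.reactants.items()))
            assert reverse not in pairs, r.label

    def test_manifest_cross_references_every_reaction(self, litr_net_plain):
        manifest = litr_net_plain.metadata["manifest"]
        assert len(manifest) == len(litr_net_plain.reactions)
        symbols = set(DerivedRateSet.default().entries)
        for entry in manifest:
            base = entry["source_row"].split("*")[-1]
            assert base in symbols or base == "gamma_p", entry

    def test_inducer_reservoirs_are_chemostatted(self):
        net = build_litr_network(LITRConfig(1, 1, iptg=500.0, dox=50.0))
        compiled = net.compile()
        for name, expect in (("I_l", 301), ("I_t", 30), ("R", 18)):
            i = net.species_index(name)
            assert compiled.is_constant[i]
            assert compiled.initial[i] == expect
            assert np.all(compiled.net[:, i] == 0)

    def test_o1_operator_override_changes_only_laci_dna_unbinding(self):
        weak = build_litr_network(LITRConfig(1, 1, 0, 0),
                                  laci_operator_q_l3=5.4e-5)
        base = build_litr_network(LITRConfig(1, 1, 0, 0))
        diffs = [(a.label, a.rate_constant, b.rate_constant)
                 for a, b in zip(weak.reactions, base.reactions)
                 if a.rate_constant != b.rate_constant]
        assert diffs and all(b == 5.4e-7 and a == 5.4e-5
                             for _, a, b in diffs)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            LITRConfig(n_lacI=-1, n_tetR=1)
        with pytest.raises(ValueError):
            LITRConfig(n_lacI=1, n_tetR=1, iptg=-5.0)
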