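"""Rate laws, RHS assembly, conserved moieties and serialization."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from minicoag.kinetics import (
    MassActionReaction,
    MichaelisMentenReaction,
    NetworkConfigError,
    ReactionNetwork,
    SpeciesSpec,
    build_rhs,
    conservation_laws,
    mass_action_flux,
    michaelis_menten_flux,
    network_from_text,
    network_to_text,
)
from minicoag.models import DEFAULT_PARAMETERS, minimal_model, reference_model


def _state(network, **conc):
    y = network.initial_state() * 0.0
    for name, value in conc.items():
        y[network.index(name)] = value
    return y


class TestMassActionFlux:
    def test_thrombin_inactivation_flux(self):
        """Bimolecular TH + AT inactivation at plasma-scale concentrations."""
        net = reference_model()
        rxn = net.reactions[29]  # TH + AT -> INACT, kf = 7.1
        assert rxn.kf == 7.1
        y = _state(net, TH=1.0e-3, AT=3.4e-3)
        assert mass_action_flux(rxn, y, net) == pytest.approx(2.414e-5, rel=1e-12)

    def test_zero_reactant_annihilates_forward_term(self):
        net = reference_model()
        y = _state(net, AT=3.4e-3)  # TH = 0
        assert mass_action_flux(net.reactions[29], y, net) == 0.0

    def test_detailed_balance_gives_zero_net_flux(self):
        net = reference_model()
        rxn = net.reactions[0]  # TF + FVII <-> TF-FVII, kf 3.2e3, kb 3.1e-3
        # choose concentrations with kf*[TF][FVII] = kb*[TF-FVII]
        tf, fvii = 1e-6, 1e-6
        complex_ = rxn.kf * tf * fvii / rxn.kb
        y = _state(net, TF=tf, FVII=fvii, **{"TF-FVII": complex_})
        assert mass_action_flux(rxn, y, net) == pytest.approx(0.0, abs=1e-18)

    @given(
        kf=st.floats(1e-3, 1e3),
        kb=st.one_of(st.none(), st.floats(1e-3, 1e3)),
        conc=st.lists(st.floats(0, 1e-2), min_size=4, max_size=4),
    )
    def test_flux_matches_term_by_term_oracle(self, kf, kb, conc):
        """Vectorised flux equals brute-force enumeration of powers."""
        species = tuple(SpeciesSpec(n) for n in "ABCD")
        rxn = MassActionReaction(reactants={"A": 1, "B": 1},
                                 products={"C": 1, "D": 1}, kf=kf, kb=kb)
        net = ReactionNetwork(species, (rxn,))
        y = np.array(conc)

        expected = kf
        for sp in ("A", "B"):
            expected *= y[net.index(sp)]
        if kb is not None:
            back = kb
            for sp in ("C", "D"):
                back *= y[net.index(sp)]
            expected -= back
        assert mass_action_flux(rxn, y, net) == pytest.approx(expected, rel=1e-12, abs=1e-300)
        # and the compiled RHS must route the same flux through stoichiometry
        dy = build_rhs(net)(y)
        assert dy[net.index("A")] == pytest.approx(-expected, rel=1e-12, abs=1e-300)
        assert dy[net.index("C")] == pytest.approx(expected, rel=1e-12, abs=1e-300)


class TestMichaelisMentenFlux:
    def test_half_saturation_identity(self):
        net = minimal_model()
        rxn = net.reactions[0]
        y = _state(net, X=rxn.KM, TF=2.5e-8)
        expected = rxn.kcat * 2.5e-8 / 2.0
        assert michaelis_menten_flux(rxn, y, net) == pytest.approx(expected, rel=1e-12)

    def test_zero_substrate_gives_zero_flux(self):
        net = minimal_model()
        y = _state(net, TF=2.5e-8)
        assert michaelis_menten_flux(net.reactions[0], y, net) == 0.0

    def test_prothrombin_cleavage_flux(self):
        """Tenase-catalysed thrombin production at literature constants."""
        net = minimal_model(DEFAULT_PARAMETERS)
        rxn = net.reactions[1]  # PT -> TH catalysed by Xa-Va
        y = _state(net, PT=1.4e-3, **{"Xa-Va": 1.0e-5})
        expected = 8e-2 * 1e-5 * 1.4e-3 / (1e-3 + 1.4e-3)
        assert expected == pytest.approx(4.667e-7, rel=1e-3)
        assert michaelis_menten_flux(rxn, y, net) == pytest.approx(expected, rel=1e-12)


class TestBuildRhs:
    def test_minimal_model_initial_rates(self):
        """At t=0 only the TF-driven activation of X is active."""
        net = minimal_model(DEFAULT_PARAMETERS)
        dy = build_rhs(net)(net.initial_state())
        expected = 5e-2 * 2.5e-8 * 1.6e-4 / (1e-4 + 1.6e-4)
        assert expected == pytest.approx(7.69e-10, rel=1e-3)
        assert dy[net.index("Xa-Va")] == pytest.approx(expected, rel=1e-12)
        assert dy[net.index("X")] == pytest.approx(-expected, rel=1e-12)
        assert dy[net.index("TH")] == 0.0
        assert dy[net.index("TF")] == 0.0

    def test_all_zero_state_gives_zero_rates(self):
        for net in (minimal_model(), reference_model()):
            dy = build_rhs(net)(np.zeros(net.n_species))
            assert np.all(dy == 0.0)

    @pytest.mark.parametrize("factory", [minimal_model, reference_model])
    def test_conserved_vectors_annihilate_rates(self, factory):
        """Every conservation vector is orthogonal to the rate vector."""
        net = factory()
        rhs = build_rhs(net)
        laws = conservation_laws(net)
        assert laws, "expected at least one conserved combination"
        rng = np.random.default_rng(0)
        scale = np.maximum(net.initial_state(), 1e-6)
        for _ in range(20):
            y = rng.random(net.n_species) * scale
            dy = rhs(y)
            for w in laws:
                assert abs(w @ dy) <= 1e-12 * max(1.0, np.max(np.abs(w * dy)) * net.n_species)

    def test_irreversible_fluxes_nonnegative_on_nonnegative_state(self):
        net = reference_model()
        rng = np.random.default_rng(1)
        for _ in range(10):
            y = rng.random(net.n_species) * 1e-3
            for rxn in net.reactions:
                if isinstance(rxn, MassActionReaction) and not rxn.reversible:
                    assert mass_action_flux(rxn, y, net) >= 0.0


class TestConservationLaws:
    def test_minimal_model_conserved_moieties(self):
        """PT+TH+INACT, AT+INACT, X+V+XaVa and TF itself are conserved."""
        net = minimal_model()
        basis = np.array(conservation_laws(net))
        assert len(basis) == 4

        def in_span(w):
            coeffs, res, *_ = np.linalg.lstsq(basis.T, w, rcond=None)
            return np.allclose(basis.T @ coeffs, w, atol=1e-10)

        names = net.species_names
        for members in (("PT", "TH", "INACT"), ("AT", "INACT"),
                        ("X", "V", "Xa-Va"), ("TF",)):
            w = np.array([1.0 if n in members else 0.0 for n in names])
            assert in_span(w), f"{members} not conserved"

    def test_single_irreversible_conversion(self):
        net = ReactionNetwork(
            (SpeciesSpec("A", 1.0), SpeciesSpec("B")),
            (MassActionReaction(reactants={"A": 1}, products={"B": 1}, kf=1.0),),
        )
        (w,) = conservation_laws(net)
        assert np.allclose(w / w[0], [1.0, 1.0])

    def test_reference_model_tf_not_conserved(self):
        """TF–VIIa + AT routing to INACT destroys the bare-TF moiety."""
        net = reference_model()
        basis = np.array(conservation_laws(net))
        w_tf = np.zeros(net.n_species)
        w_tf[net.index("TF")] = 1.0
        coeffs, *_ = np.linalg.lstsq(basis.T, w_tf, rcond=None)
        assert not np.allclose(basis.T @ coeffs, w_tf, atol=1e-8)


class TestValidation:
    def test_unknown_species_rejected(self):
        with pytest.raises(NetworkConfigError, match="undeclared"):
            ReactionNetwork(
                (SpeciesSpec("A"),),
                (MassActionReaction(reactants={"A": 1}, products={"Z": 1}, kf=1.0),),
            )

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(NetworkConfigError):
            MassActionReaction(reactants={"A": 1}, products={"B": 1}, kf=-1.0)
        with pytest.raises(NetworkConfigError):
            MichaelisMentenReaction(substrate="A", enzyme="E", products={"B": 1},
                                    kcat=1.0, KM=0.0)

    def test_stoichiometry_above_one_rejected(self):
        with pytest.raises(NetworkConfigError, match="stoichiometry"):
            MassActionReaction(reactants={"A": 2}, products={"B": 1}, kf=1.0)

    def test_negative_initial_concentration_rejected(self):
        with pytest.raises(NetworkConfigError):
            SpeciesSpec("A", initial_concentration=-1e-9)

    def test_duplicate_species_rejected(self):
        with pytest.raises(NetworkConfigError, match="duplicate"):
            ReactionNetwork((SpeciesSpec("A"), SpeciesSpec("A")), ())


class TestSerialization:
    @pytest.mark.parametrize("factory", [minimal_model, reference_model])
    def test_round_trip_is_lossless(self, factory):
        net = factory()
        text = network_to_text(net)
        back = network_from_text(text)
        assert back == net
        assert network_to_text(back) == text
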