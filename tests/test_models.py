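import math

import pytest
import yaml
from hypothesis import given, settings
from hypothesis import strategies as st

import polexo as px
from polexo.models import (
    InvalidParameterError,
    MismatchExtensionKinetics,
    ProofreadingParams,
    Reaction,
    SchemeError,
    Species,
    build_fate_scheme,
    scheme_from_dict,
    scheme_to_dict,
)


class TestProofreadingScheme:
    def test_single_mismatch_structure(self, single_mismatch_scheme):
        scheme = single_mismatch_scheme
        assert len(scheme.species) == 6
        assert len(scheme.reactions) == 9
        k_minus3 = next(r for r in scheme.reactions if r.label == "k-3")
        assert k_minus3.rate_constant == pytest.approx(2.9 / 0.061)
        assert k_minus3.rate_constant == pytest.approx(47.5, abs=0.05)

    def test_no_inhibited_branch_when_absent(self):
        params = px.get_fixture("excision_20C", "4").proofreading_params()
        assert not params.ed_i_present
        scheme = px.build_proofreading_scheme(params, 1.0, 0.25)
        assert "ED_I" not in scheme.species_names
        assert not any(r.label in ("k4", "k-4") for r in scheme.reactions)

    def test_symmetric_transfer_identity(self):
        params = ProofreadingParams(k2=1.0, k3=10.0, K3=1.0)
        assert params.k_minus3 == pytest.approx(10.0)

    def test_missing_K3_rejected(self):
        with pytest.raises(InvalidParameterError):
            ProofreadingParams(k2=1.0, k3=1.0, K3=None)

    def test_negative_concentration_rejected(self):
        params = ProofreadingParams(k2=1.0, k3=1.0, K3=0.5)
        with pytest.raises(SchemeError):
            px.build_proofreading_scheme(params, -1.0, 0.25)

    def test_initial_material_free(self, single_mismatch_scheme):
        ic = single_mismatch_scheme.initial_conditions
        assert set(ic) == {"E", "D"}
        assert ic["E"] == 1.0 and ic["D"] == 0.25

    def test_lone_k4_rejected(self):
        with pytest.raises(InvalidParameterError):
            ProofreadingParams(k2=1.0, k3=1.0, K3=0.5, k4=1.0)

    def test_deterministic_rebuild(self):
        params = px.get_fixture("excision_20C", "1").proofreading_params()
        a = px.build_proofreading_scheme(params, 1.0, 0.25)
        b = px.build_proofreading_scheme(params, 1.0, 0.25)
        assert a.species == b.species
        assert a.reactions == b.reactions
        assert a.initial_conditions == b.initial_conditions


class TestExtensionScheme:
    def test_fraction_primed_n3(self):
        params = px.get_fixture("buried_extension_20C", "n-3").extension_params()
        assert params.fraction_primed == pytest.approx(0.82 / 2.28, rel=1e-12)
        assert params.fraction_primed == pytest.approx(0.36, abs=0.01)

    def test_fraction_primed_n10(self):
        params = px.get_fixture("buried_extension_20C", "n-10").extension_params()
        assert params.fraction_primed == pytest.approx(1.5 / 1.54, rel=1e-12)
        assert 0.97 < params.fraction_primed < 0.98

    def test_pre_equilibration_flag(self, extension_n3_scheme):
        assert extension_n3_scheme.pre_equilibration_disabled == ("k_pol",)

    def test_zero_kpol_never_extends(self):
        import numpy as np

        params = px.ExtensionParams(k1_prime=1.0, k_minus1_prime=2.0, k_pol=0.0)
        scheme = px.build_extension_scheme(params, 0.2, 0.075)
        times = np.geomspace(1e-3, 100.0, 10)
        series = px.integrate(scheme, px.default_protocol(scheme, 100.0), times)
        assert series["XP"].max() < 1e-12


class TestMismatchExtensionKinetics:
    def test_exactly_one_representation(self):
        with pytest.raises(InvalidParameterError):
            MismatchExtensionKinetics(kcat=0.025, Km=87.0, kcat_over_Km_limit=0.1)
        with pytest.raises(InvalidParameterError):
            MismatchExtensionKinetics()

    def test_saturating_rate_is_kcat(self):
        mk = MismatchExtensionKinetics(kcat=0.025, Km=87.0)
        assert mk.first_order_rate(None) == 0.025

    def test_limit_rate_scales_with_dntp(self):
        mk = MismatchExtensionKinetics(kcat_over_Km_limit=0.1)
        assert mk.first_order_rate(1000.0) == pytest.approx(1e-4)

    def test_limit_requires_concentration(self):
        mk = MismatchExtensionKinetics(kcat_over_Km_limit=0.1)
        with pytest.raises(InvalidParameterError):
            mk.first_order_rate(None)


class TestFateScheme:
    def _n0_n1(self):
        cat = px.fixtures()
        return (
            cat[("buried_excision_20C", "n-0")].proofreading_params(),
            cat[("buried_excision_20C", "n-1")].proofreading_params(),
        )

    def test_competing_extension_branch(self):
        n0, n1 = self._n0_n1()
        scheme = build_fate_scheme(
            n0,
            n1,
            MismatchExtensionKinetics(kcat=0.025, Km=87.0),
            MismatchExtensionKinetics(kcat_over_Km_limit=0.1),
        )
        ext0 = next(r for r in scheme.reactions if r.label == "k_ext[n0]")
        assert ext0.rate_constant == pytest.approx(0.025)
        ext1 = next(r for r in scheme.reactions if r.label == "k_ext[n1]")
        assert ext1.rate_constant == pytest.approx(1e-4)

    def test_zero_extension_single_absorbing_state(self):
        n0, n1 = self._n0_n1()
        scheme = build_fate_scheme(
            n0,
            n1,
            MismatchExtensionKinetics(kcat_over_Km_limit=0.0),
            MismatchExtensionKinetics(kcat_over_Km_limit=0.0),
        )
        assert scheme.species_by_role("absorbing-product") == ["excised"]

    def test_unresolvable_extension_rate(self):
        n0, n1 = self._n0_n1()
        with pytest.raises(InvalidParameterError):
            build_fate_scheme(
                n0,
                n1,
                MismatchExtensionKinetics(kcat_over_Km_limit=0.1),
                MismatchExtensionKinetics(kcat_over_Km_limit=0.1),
                dntp_conc_n0=None,  # limit without a concentration
                dntp_conc_n1=None,
            )


class TestStoichiometryAudit:
    def test_all_catalogue_excision_rows_audit(self, catalogue):
        for (table, row), fx in catalogue.items():
            if not table.startswith(("excision", "buried_excision")):
                continue
            scheme = px.build_proofreading_scheme(fx.proofreading_params(), 1.0, 0.25)
            scheme.audit_stoichiometry()  # raises on violation

    def test_unbalanced_reaction_rejected(self):
        with pytest.raises(SchemeError):
            px.KineticScheme(
                species=[Species("D", "free-dna"), Species("P", "absorbing-product")],
                reactions=[Reaction(("D",), ("P", "P"), 1.0, "k")],
                initial_conditions={"D": 1.0},
                dna_moiety={"D": 1, "P": 1},
                enzyme_moiety={},
            )

    def test_undeclared_species_rejected(self):
        with pytest.raises(SchemeError):
            px.KineticScheme(
                species=[Species("D", "free-dna")],
                reactions=[Reaction(("D",), ("Q",), 1.0, "k")],
                initial_conditions={"D": 1.0},
            )


@given(
    k3=st.floats(0.01, 100),
    K3=st.floats(1e-3, 10),
    k2=st.floats(0.1, 500),
)
@settings(max_examples=30, deadline=None)
def test_k_minus3_ratio_property(k3, K3, k2):
    params = ProofreadingParams(k2=k2, k3=k3, K3=K3)
    scheme = px.build_proofreading_scheme(params, 1.0, 0.25)
    k3_rxn = next(r for r in scheme.reactions if r.label == "k3")
    km3_rxn = next(r for r in scheme.reactions if r.label == "k-3")
    assert km3_rxn.rate_constant == k3_rxn.rate_constant / K3


def test_scheme_yaml_round_trip(single_mismatch_scheme):
    data = scheme_to_dict(single_mismatch_scheme)
    text = yaml.safe_dump(data)
    restored = scheme_from_dict(yaml.safe_load(text))
    assert restored.species == single_mismatch_scheme.species
    assert restored.reactions == single_mismatch_scheme.reactions
    assert restored.initial_conditions == single_mismatch_scheme.initial_conditions
    assert restored.dna_moiety == single_mismatch_scheme.dna_moiety
    assert (
        restored.pre_equilibration_disabled
        == single_mismatch_scheme.pre_equilibration_disabled
    )


def test_reaction_unit_tags():
    bi = Reaction(("E", "D"), ("ED",), 300.0, "k1")
    uni = Reaction(("ED",), ("E", "D"), 0.2, "k-1")
    assert bi.unit == "uM-1.s-1"
    assert uni.unit == "s-1"
    with pytest.raises(SchemeError):
        Reaction(("E",), ("ED",), -1.0, "bad")
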