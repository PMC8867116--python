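import math

import numpy as np
import pytest

import polexo as px
from polexo import engine
from polexo.models import KineticScheme, Reaction, Species


def _remaining(scheme, series):
    absorbing = set(scheme.species_by_role("absorbing-product"))
    return sum(
        series[n] for n, w in scheme.dna_moiety.items() if w and n not in absorbing
    )


class TestIntegrate:
    def test_zero_rates_constant(self):
        scheme = KineticScheme(
            species=[Species("D", "free-dna"), Species("P", "absorbing-product")],
            reactions=[Reaction(("D",), ("P",), 0.0, "k")],
            initial_conditions={"D": 0.7},
            dna_moiety={"D": 1, "P": 1},
        )
        times = np.linspace(0, 5, 7)
        series = px.integrate(scheme, px.Protocol([px.Phase(5.0)]), times)
        assert np.allclose(series["D"], 0.7, rtol=0, atol=1e-12)
        assert np.allclose(series["P"], 0.0, atol=1e-12)

    def test_pseudo_first_order_binding(self):
        # E >> D: [D](t) = D0 exp(-k1 E0 t)
        scheme = KineticScheme(
            species=[
                Species("E", "free-enzyme"),
                Species("D", "free-dna"),
                Species("ED", "complex"),
            ],
            reactions=[Reaction(("E", "D"), ("ED",), 300.0, "k1")],
            initial_conditions={"E": 10.0, "D": 0.01},
            dna_moiety={"D": 1, "ED": 1},
            enzyme_moiety={"E": 1, "ED": 1},
        )
        series = px.integrate(scheme, px.Protocol([px.Phase(0.002)]), np.array([1e-3]))
        expected = 0.01 * math.exp(-3.0)  # 4.98e-4; E depletion shifts it ~0.2%
        assert series["D"][0] == pytest.approx(expected, rel=2.5e-3)

    def test_biphasic_decay_fast_amplitude(self, single_mismatch_scheme):
        # fast phase carries ~k2/(k1+k2) = 5.75% of the DNA (binding flux
        # oracle); by 20 ms the fast phase is complete and the slow phase has
        # barely started, so 90-96% of the primer remains
        times = np.array([0.02])
        series = px.integrate(
            single_mismatch_scheme, px.Protocol([px.Phase(0.02)]), times
        )
        remaining = _remaining(single_mismatch_scheme, series)[0] / 0.25
        assert 0.90 < remaining < 0.96

    def test_non_monotonic_times_rejected(self, decay_scheme):
        with pytest.raises(ValueError):
            px.integrate(decay_scheme, px.Protocol([px.Phase(1.0)]), np.array([0.5, 0.2]))

    def test_times_beyond_protocol_rejected(self, decay_scheme):
        with pytest.raises(ValueError):
            px.integrate(decay_scheme, px.Protocol([px.Phase(1.0)]), np.array([0.5, 2.0]))

    def test_mass_conservation(self, single_mismatch_scheme):
        times = np.geomspace(1e-3, 10, 30)
        series = px.integrate(
            single_mismatch_scheme, px.default_protocol(single_mismatch_scheme, 10.0), times
        )
        total = sum(series[n] for n in ("D", "ED_p", "ED_x", "ED_I", "P"))
        assert np.max(np.abs(total - 0.25)) < 1e-6 * 0.25

    def test_tolerance_convergence(self, single_mismatch_scheme, monkeypatch):
        times = np.geomspace(1e-3, 10, 15)
        proto = px.default_protocol(single_mismatch_scheme, 10.0)
        coarse = px.integrate(single_mismatch_scheme, proto, times)
        monkeypatch.setattr(engine, "RTOL", engine.RTOL / 2)
        monkeypatch.setattr(engine, "ATOL", engine.ATOL / 2)
        fine = px.integrate(single_mismatch_scheme, proto, times)
        rem_c = _remaining(single_mismatch_scheme, coarse)
        rem_f = _remaining(single_mismatch_scheme, fine)
        assert np.max(np.abs(rem_c - rem_f) / np.maximum(rem_f, 1e-9)) < 1e-4


class TestProtocol:
    def test_single_equilibrium_phase_only(self):
        with pytest.raises(ValueError):
            px.Protocol([px.Phase("to-equilibrium"), px.Phase("to-equilibrium")])
        with pytest.raises(ValueError):
            px.Protocol([px.Phase(1.0), px.Phase("to-equilibrium")])

    def test_pre_equilibration_reaches_equilibrium(self, extension_n3_scheme):
        # at t=0 of the timed phase the two-state split must match
        # k1'/(k1'+k-1') and be stationary under the disabled scheme
        times = np.array([0.0])
        series = px.integrate(
            extension_n3_scheme, px.default_protocol(extension_n3_scheme, 1.0), times
        )
        total = 0.075
        primed = 0.82 / (0.82 + 1.46)
        assert series["ED_p"][0] / total == pytest.approx(primed, abs=1e-6)
        assert series["XP"][0] == pytest.approx(0.0, abs=1e-9)

    def test_injection_adds_material(self, decay_scheme):
        proto = px.Protocol([px.Phase(1.0, injections={"D": 1.0})])
        series = px.integrate(decay_scheme, proto, np.array([0.0]))
        assert series["D"][0] == pytest.approx(2.0)


class TestObserve:
    def test_initial_remaining_equals_total_dna(self, single_mismatch_scheme):
        times = np.array([0.0, 1e-3])
        series = px.integrate(
            single_mismatch_scheme, px.Protocol([px.Phase(1e-3)]), times
        )
        tc = px.observe(single_mismatch_scheme, series, "remaining-starting-primer", times)
        assert tc.values[0] == pytest.approx(0.25, rel=1e-9)

    def test_remaining_reaches_zero_without_inhibited_state(self):
        params = px.get_fixture("excision_20C", "4").proofreading_params()
        scheme = px.build_proofreading_scheme(params, 1.0, 0.25)
        times = np.array([50.0])
        series = px.integrate(scheme, px.Protocol([px.Phase(50.0)]), times)
        tc = px.observe(scheme, series, "remaining-starting-primer", times)
        assert tc.values[-1] < 1e-6

    def test_extension_drains_to_product(self, extension_n3_scheme):
        times = np.array([60.0])
        series = px.integrate(
            extension_n3_scheme, px.default_protocol(extension_n3_scheme, 60.0), times
        )
        tc = px.observe(extension_n3_scheme, series, "extended-product", times)
        assert tc.values[-1] == pytest.approx(0.075, rel=1e-4)

    def test_unknown_observable(self, extension_n3_scheme):
        with pytest.raises(ValueError):
            px.observe(extension_n3_scheme, {}, "no-such-observable", [0.0])


class TestTimeCourse:
    def test_validation(self):
        with pytest.raises(ValueError):
            px.TimeCourse("s", "20", np.array([0.0, 0.0]), np.array([1.0, 1.0]), "remaining-starting-primer")
        with pytest.raises(ValueError):
            px.TimeCourse("s", "20", np.array([0.0, 1.0]), np.array([1.0, -0.1]), "remaining-starting-primer")

    def test_round_trip(self, tmp_path):
        tcs = [
            px.TimeCourse("a", "20", np.array([0.1, 1.0]), np.array([0.2, 0.1]),
                          "remaining-starting-primer", replicate=0),
            px.TimeCourse("a", "20", np.array([0.1, 1.0]), np.array([0.21, 0.09]),
                          "remaining-starting-primer", replicate=1),
        ]
        path = tmp_path / "tc.tsv"
        px.write_timecourses(path, tcs)
        back = px.read_timecourses(path)
        assert len(back) == 2
        for orig, rest in zip(tcs, back):
            assert rest.substrate_id == orig.substrate_id
            assert rest.replicate == orig.replicate
            np.testing.assert_allclose(rest.times, orig.times)
            np.testing.assert_allclose(rest.values, orig.values)


class TestGillespie:
    def test_exponential_decay_single_molecule(self, decay_scheme):
        # one molecule decaying at k=2: P(survive to t) = exp(-2t)
        times = np.array([0.5])
        mean = px.gillespie_oracle(
            decay_scheme, px.Protocol([px.Phase(0.5)]), times,
            n_molecules=1, n_runs=4000, seed=7,
        )
        p = math.exp(-1.0)
        se = math.sqrt(p * (1 - p) / 4000)
        assert abs(mean["D"][0] - p) < 3 * se

    def test_zero_rates_constant(self):
        scheme = KineticScheme(
            species=[Species("D", "free-dna"), Species("P", "absorbing-product")],
            reactions=[Reaction(("D",), ("P",), 0.0, "k")],
            initial_conditions={"D": 1.0},
            dna_moiety={"D": 1, "P": 1},
        )
        times = np.array([0.1, 1.0])
        mean = px.gillespie_oracle(scheme, px.Protocol([px.Phase(1.0)]), times,
                                   n_molecules=50, n_runs=10, seed=0)
        assert np.allclose(mean["D"], 1.0)

    def test_seed_reproducible(self, decay_scheme):
        times = np.array([0.2, 0.7])
        a = px.gillespie_oracle(decay_scheme, px.Protocol([px.Phase(1.0)]), times,
                                n_molecules=20, n_runs=50, seed=42)
        b = px.gillespie_oracle(decay_scheme, px.Protocol([px.Phase(1.0)]), times,
                                n_molecules=20, n_runs=50, seed=42)
        for k in a:
            np.testing.assert_array_equal(a[k], b[k])

    def test_matches_ode_mean(self, single_mismatch_scheme):
        # batch means against the ODE solution, within 3x the empirical
        # Monte-Carlo standard error at every output time
        times = np.geomspace(1e-2, 5.0, 6)
        proto = px.default_protocol(single_mismatch_scheme, 5.0)
        ode = px.integrate(single_mismatch_scheme, proto, times)
        rem_ode = _remaining(single_mismatch_scheme, ode)
        batches = []
        for s in range(8):
            g = px.gillespie_oracle(single_mismatch_scheme, proto, times,
                                    n_molecules=500, n_runs=50, seed=100 + s)
            batches.append(_remaining(single_mismatch_scheme, g))
        batches = np.array(batches)
        mean = batches.mean(axis=0)
        se = batches.std(axis=0, ddof=1) / math.sqrt(len(batches))
        z = np.abs(mean - rem_ode) / np.maximum(se, 1e-12)
        assert np.all(z < 3.0), f"z-scores {z}"
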