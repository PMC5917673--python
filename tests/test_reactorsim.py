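import math

import numpy as np
import pytest

from protoforge.errors import InvariantError
from protoforge.kinetics import AVOGADRO, KineticParameters, RateLaw
from protoforge.netio import NetworkModel, Reaction, Species
from protoforge.reactorsim import (CalibrationCurve, MembraneSpec,
                                   ProtosensorModel, Reservoir,
                                   calibrate_signal, evaluate_truth_table,
                                   membrane_rate, signal_to_noise_db,
                                   simulate_ode, simulate_ssa, transfer_map)


class TestMembraneRate:
    def test_equilibrium_flux_is_zero(self):
        spec = MembraneSpec(permeability={"S": 2.0})
        assert membrane_rate(spec, "S", 1e-3, 1e-3, 10.0) == 0.0

    def test_fick_arithmetic(self):
        # 6/d * P * dC: 0.6/s * 1 mM = 0.6 mM/s
        spec = MembraneSpec(permeability={"S": 1.0}, pore_scale=1.0)
        assert membrane_rate(spec, "S", 1e-3, 0.0, 10.0) == \
            pytest.approx(6e-4)

    def test_antisymmetry(self):
        spec = MembraneSpec(permeability={"S": 3.0}, pore_scale=2.0)
        assert membrane_rate(spec, "S", 2e-3, 5e-4, 10.0) == \
            pytest.approx(-membrane_rate(spec, "S", 5e-4, 2e-3, 10.0))

    def test_retained_species_zero_flux(self):
        spec = MembraneSpec(permeability={})
        assert membrane_rate(spec, "E", 1e-3, 0.0, 10.0) == 0.0

    def test_enzyme_permeability_rejected(self, tiny_network):
        kin = KineticParameters(laws={"R1": RateLaw(
            mechanism="mm_uni", kcat=1.0, Km_map={"S": 1e-6})})
        with pytest.raises(InvariantError):
            ProtosensorModel(network=tiny_network, kinetics=kin,
                             membrane=MembraneSpec(permeability={"E": 1.0}))


class TestSimulateOde:
    def test_inert_model_stays_constant(self, tiny_network):
        kin = KineticParameters(laws={"R1": RateLaw(
            mechanism="mm_uni", kcat=1.0, Km_map={"S": 1e-6})})
        model = ProtosensorModel(network=tiny_network, kinetics=kin,
                                 membrane=None,
                                 interior_initial={"S": 1e-4})  # no enzyme
        trace = simulate_ode(model, 600.0, dt_out=60.0)
        assert np.allclose(trace.concentrations["S"], 1e-4)
        assert np.allclose(trace.concentrations["P"], 0.0)

    def test_zero_order_regime_slope(self, tiny_network):
        # S0 = 100*Km: early product slope ~ kcat*E0 within 2%
        kin = KineticParameters(laws={"R1": RateLaw(
            mechanism="mm_uni", kcat=5.0, Km_map={"S": 1e-6})})
        model = ProtosensorModel(network=tiny_network, kinetics=kin,
                                 interior_initial={"S": 1e-4, "E": 1e-9})
        trace = simulate_ode(model, 10.0, dt_out=1.0)
        slope = (trace.concentrations["P"][5] -
                 trace.concentrations["P"][1]) / 4.0
        assert slope == pytest.approx(5.0 * 1e-9, rel=0.02)

    def test_transport_time_constant(self, uptake_model_factory):
        # inert permeable species: gap shrinks by e^-1 per tau = d/(6 P)
        model = uptake_model_factory(permeability=1.0, e_conc=0.0,
                                     s_out=1e-3)
        tau = 10.0 / 6.0
        trace = simulate_ode(model, 5 * tau, dt_out=tau / 10)
        s = trace.concentrations["S"]
        i = int(round(tau / (tau / 10)))
        assert s[i] == pytest.approx(1e-3 * (1 - math.exp(-1)), rel=1e-3)
        assert np.all(np.diff(s) > -1e-15)  # monotone approach

    def test_finite_reservoir_mass_balance(self, uptake_model_factory):
        model = uptake_model_factory(permeability=1.0, e_conc=0.0,
                                     s_out=1e-3)
        model = ProtosensorModel(
            network=model.network, kinetics=model.kinetics,
            membrane=model.membrane, diameter_um=10.0,
            interior_initial={}, exterior={"S": 1e-3},
            reservoir=Reservoir(mode="finite", volume_L=model.volume_L))
        # equal volumes: equilibrium splits the gradient in half
        trace = simulate_ode(model, 60.0, dt_out=5.0)
        assert trace.final("S") == pytest.approx(5e-4, rel=1e-3)


class TestSimulateSsa:
    def test_zero_propensity_trace_constant(self, tiny_network):
        kin = KineticParameters(laws={"R1": RateLaw(
            mechanism="mm_uni", kcat=1.0, Km_map={"S": 1e-6})})
        model = ProtosensorModel(network=tiny_network, kinetics=kin,
                                 interior_initial={"S": 1e-9})  # no enzyme
        trace = simulate_ssa(model, 100.0, seed=0, dt_out=10.0)
        assert np.all(trace.concentrations["S"] ==
                      trace.concentrations["S"][0])

    def test_seed_reproducibility(self, uptake_model_factory):
        model = uptake_model_factory()
        a = simulate_ssa(model, 100.0, seed=7, dt_out=10.0)
        b = simulate_ssa(model, 100.0, seed=7, dt_out=10.0)
        c = simulate_ssa(model, 100.0, seed=8, dt_out=10.0)
        assert np.array_equal(a.concentrations["P"], b.concentrations["P"])
        assert not np.array_equal(a.concentrations["P"],
                                  c.concentrations["P"])

    def test_pure_birth_poisson_mean(self):
        # S -> S + P at rate k*n_S: P(t) ~ Poisson(k*n_S*t)
        net = NetworkModel(
            species=[Species(id="S"), Species(id="P")],
            reactions=[Reaction(id="b", substrates=[("S", 1)],
                                products=[("S", 1), ("P", 1)])])
        kin = KineticParameters(laws={"b": RateLaw(mechanism="mass_action",
                                                   k=0.05)})
        model = ProtosensorModel(network=net, kinetics=kin)
        nav = AVOGADRO * model.volume_L
        model = model.with_overrides(interior={"S": 100 / nav})
        t_end, lam = 50.0, 0.05 * 100 * 50.0
        counts = [simulate_ssa(model, t_end, seed=s, dt_out=t_end
                               ).concentrations["P"][-1] * nav
                  for s in range(200)]
        se = math.sqrt(lam / 200)
        assert abs(np.mean(counts) - lam) < 3 * se

    def test_count_conservation_of_carrier_pair(self):
        """NAD+ + NADH exactly constant in counts along an SSA trace."""
        net = NetworkModel(
            species=[Species(id="S"), Species(id="NAD+"), Species(id="NADH"),
                     Species(id="Q"), Species(id="X"), Species(id="Y"),
                     Species(id="E1", role="enzyme"),
                     Species(id="E2", role="enzyme")],
            reactions=[
                Reaction(id="r1", substrates=[("S", 1), ("NAD+", 1)],
                         products=[("Q", 1), ("NADH", 1)], enzyme="E1"),
                Reaction(id="r2", substrates=[("NADH", 1), ("X", 1)],
                         products=[("NAD+", 1), ("Y", 1)], enzyme="E2")])
        kin = KineticParameters(laws={
            "r1": RateLaw(mechanism="ordered_bibi", kcat=5.0,
                          Km_map={"S": 1e-7, "NAD+": 1e-7}, Kia=1e-7),
            "r2": RateLaw(mechanism="pingpong_bibi", kcat=5.0,
                          Km_map={"NADH": 1e-7, "X": 1e-7})})
        model = ProtosensorModel(
            network=net, kinetics=kin,
            membrane=MembraneSpec(permeability={"S": 0.2}),
            interior_initial={"E1": 2e-9, "E2": 2e-9, "NAD+": 3e-8,
                              "X": 5e-8},
            exterior={"S": 2e-8})
        nav = AVOGADRO * model.volume_L
        trace = simulate_ssa(model, 200.0, seed=3, dt_out=10.0)
        total = np.round((trace.concentrations["NAD+"] +
                          trace.concentrations["NADH"]) * nav)
        assert np.all(total == total[0])
        assert trace.concentrations["NADH"].max() > 0  # cycling happened


class TestTruthTable:
    def or_model(self):
        net = NetworkModel(
            species=[Species(id="A"), Species(id="B"), Species(id="P"),
                     Species(id="E1", role="enzyme"),
                     Species(id="E2", role="enzyme")],
            reactions=[
                Reaction(id="ra", substrates=[("A", 1)], products=[("P", 1)],
                         enzyme="E1"),
                Reaction(id="rb", substrates=[("B", 1)], products=[("P", 1)],
                         enzyme="E2")])
        kin = KineticParameters(laws={
            "ra": RateLaw(mechanism="mm_uni", kcat=10.0, Km_map={"A": 1e-4}),
            "rb": RateLaw(mechanism="mm_uni", kcat=10.0, Km_map={"B": 1e-4})})
        return ProtosensorModel(
            network=net, kinetics=kin,
            membrane=MembraneSpec(permeability={"A": 1.0, "B": 1.0}),
            interior_initial={"E1": 1e-8, "E2": 1e-8}, exterior={})

    def test_toy_or_circuit_truth_table(self):
        obs = evaluate_truth_table(
            self.or_model(), input_levels={"A": 1e-4, "B": 1e-4},
            output_thresholds={"P": (1e-5, 1e-6)}, t_read=600.0)
        assert obs.rows == {(0, 0): (0,), (0, 1): (1,), (1, 0): (1,),
                            (1, 1): (1,)}
        assert obs.indeterminate_rows() == []
        assert all(m["P"] >= 0 for m in obs.margins.values())

    def test_all_off_row_is_zero_with_no_driving_substrate(self):
        obs = evaluate_truth_table(
            self.or_model(), input_levels={"A": 1e-4, "B": 1e-4},
            output_thresholds={"P": (1e-5, 1e-6)}, t_read=60.0)
        assert obs.readouts[(0, 0)]["P"] == 0.0

    def test_batch_equals_encapsulated_for_fast_transport(self):
        """pore_scale -> large removes the membrane bottleneck."""
        model = self.or_model()
        fast = ProtosensorModel(
            network=model.network, kinetics=model.kinetics,
            membrane=MembraneSpec(permeability={"A": 1.0, "B": 1.0},
                                  pore_scale=1e4),
            interior_initial=model.interior_initial, exterior={})
        kwargs = dict(input_levels={"A": 1e-3, "B": 1e-3},
                      output_thresholds={"P": (1e-5, 1e-6)}, t_read=300.0)
        enc = evaluate_truth_table(fast, mode="encapsulated", **kwargs)
        bat = evaluate_truth_table(fast, mode="batch", **kwargs)
        for bits in enc.rows:
            a, b = enc.readouts[bits]["P"], bat.readouts[bits]["P"]
            assert a == pytest.approx(b, rel=0.05, abs=1e-9)

    def test_indeterminate_reported_not_rounded(self):
        model = self.or_model()
        # thresholds bracketing the actual readout force an indeterminate bit
        obs = evaluate_truth_table(
            model, input_levels={"A": 1e-4, "B": 1e-4},
            output_thresholds={"P": (1e2, 1e-12)}, t_read=600.0)
        assert (1, 1) in obs.indeterminate_rows()

    def test_threshold_ordering_enforced(self):
        with pytest.raises(InvariantError):
            evaluate_truth_table(self.or_model(), {"A": 1e-4, "B": 1e-4},
                                 {"P": (1e-6, 1e-5)})


class TestTransferMap:
    def test_single_point_equals_seeded_ssa(self, uptake_model_factory):
        model = uptake_model_factory()
        tm = transfer_map(model, {"S": np.array([2e-8])}, ("P",),
                          t_read=100.0, n_traj=1, base_seed=5, dt_out=100.0)
        ref = simulate_ssa(model.with_overrides(exterior={"S": 2e-8}),
                          100.0, seed=5, dt_out=100.0)
        assert tm.outputs["P"][0] == pytest.approx(ref.final("P"))

    def test_ode_rows_monotone_in_driving_input(self):
        model = TestTruthTable().or_model()
        grids = {"A": np.logspace(-6, -3, 5), "B": np.array([0.0, 1e-4])}
        tm = transfer_map(model, grids, ("P",), t_read=300.0, method="ode",
                          dt_out=50.0)
        arr = tm.outputs["P"]
        assert arr.shape == (5, 2)
        assert np.all(np.diff(arr, axis=0) >= -1e-15)

    def test_default_five_trajectories(self, uptake_model_factory):
        tm = transfer_map(uptake_model_factory(), {"S": np.array([2e-8])},
                          ("P",), t_read=50.0, dt_out=50.0)
        assert tm.n_traj == 5


class TestCalibrationAndSnr:
    def test_offset_at_zero_concentration(self):
        curve = CalibrationCurve("X", "absorbance", "340", gain=2.0,
                                 offset=0.05)
        assert calibrate_signal(curve, 0.0) == 0.05

    def test_identity_curve(self):
        curve = CalibrationCurve("X", "fluorescence", "488", gain=1.0)
        assert calibrate_signal(curve, 0.37) == 0.37

    def test_beer_lambert_nadh_gain(self):
        # 6.22e3 AU/M * 100 uM = 0.622 AU (configured gain constant)
        curve = CalibrationCurve("NADH", "absorbance", "340", gain=6.22e3)
        assert calibrate_signal(curve, 1e-4) == pytest.approx(0.622)

    def test_snr_closed_forms(self):
        rng = np.random.default_rng(0)
        off = rng.normal(0.0, 1.0, 4000)
        on10 = rng.normal(10.0, 1.0, 4000)
        assert signal_to_noise_db(on10, off) == pytest.approx(20.0, abs=0.3)
        on1 = rng.normal(1.0, 1.0, 4000)
        assert signal_to_noise_db(on1, off) == pytest.approx(0.0, abs=0.5)

    def test_equal_means_sentinel(self):
        assert signal_to_noise_db([1.0, 2.0], [2.0, 1.0]) == -math.inf

    def test_insufficient_replicates(self):
        with pytest.raises(InvariantError):
            signal_to_noise_db([1.0], [0.0, 0.1])
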