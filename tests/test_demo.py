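"""Plant, controller, testbench tools, and the sequential reference loop."""

import numpy as np
import pytest

from cosimloop.protocol import ConfigError
from cosimloop.demo import (
    SETPOINT,
    U_MAX,
    U_MIN,
    DemoError,
    EnergyAccumulator,
    LinearCardiacPM,
    MPCConfig,
    MPCController,
    build_demo_graph,
    generate_stable_system,
    knob_testbench_step,
    make_demo_system,
    mpc_control_step,
    power_meter_step,
    sequential_reference_sim,
    steady_state,
    stimulation_energy,
    trajectory_max_diff,
)
from cosimloop.graph import assign_ports


def _scalar_pm(a=0.5, b=1.0, c=1.0, d=0.0):
    """1-state, 1-input, 2-output plant (second output mirrors the first)."""
    return LinearCardiacPM([[a]], [[b]], [[c], [c]], [[d], [d]], [0.0])


class TestPlant:
    def test_hand_iterated_geometric_convergence(self):
        # a=0.5, b=c=1, d=0, u=1: outputs 0, 1, 1.5, 1.75, ... -> 2
        pm = _scalar_pm()
        outs = [pm.step([1.0])[0] for _ in range(4)]
        assert outs == [0.0, 1.0, 1.5, 1.75]
        assert steady_state(_scalar_pm(), [1.0])[0] == pytest.approx(2.0)

    def test_memoryless_and_zero_input_limits(self):
        pm = _scalar_pm(a=0.0, d=0.25)
        # A = 0: gain is C B + D
        assert np.allclose(steady_state(pm, [2.0]), (1.0 * 1.0 + 0.25) * 2.0)
        assert np.allclose(steady_state(pm, [0.0]), 0.0)

    def test_first_output_comes_from_pre_update_state(self):
        pm = LinearCardiacPM(np.zeros((2, 2)), np.eye(2)[:, :1],
                             np.eye(2), np.zeros((2, 1)), np.zeros(2))
        first = pm.step([3.0])
        second = pm.step([0.0])
        assert np.allclose(first, 0.0)  # D=0, x0=0
        assert np.allclose(second, [3.0, 0.0])  # C B u from the recursion

    def test_unstable_system_has_no_steady_state(self):
        pm = _scalar_pm(a=1.5)
        with pytest.raises(DemoError, match="unstable"):
            steady_state(pm, [1.0])

    def test_dimension_mismatch_is_an_error(self):
        with pytest.raises(DemoError):
            LinearCardiacPM(np.eye(2), np.ones((3, 1)), np.ones((2, 2)),
                            np.zeros((2, 1)), np.zeros(2))
        with pytest.raises(DemoError):
            _scalar_pm().step([1.0, 2.0])

    def test_constant_input_reaches_closed_form_limit(self):
        for seed in (0, 1, 2):
            pm = generate_stable_system(seed)
            u = np.linspace(1.0, 2.0, 6)
            target = steady_state(pm, u)
            for _ in range(500):
                ym = pm.step(u)
            assert np.max(np.abs(ym - target)) < 1e-9


class TestGenerator:
    def test_same_seed_same_system(self):
        a, b = generate_stable_system(7), generate_stable_system(7)
        assert np.array_equal(a.A, b.A) and np.array_equal(a.D, b.D)

    def test_spectral_radius_and_gain_rank_across_seeds(self):
        for seed in range(100):
            m = generate_stable_system(seed)
            assert max(abs(np.linalg.eigvals(m.A))) <= 0.9 + 1e-12
            assert np.linalg.matrix_rank(m.dc_gain()) == 2

    def test_tiny_state_dimension_rejected(self):
        with pytest.raises(DemoError):
            generate_stable_system(0, n=1)

    def test_demo_system_setpoint_is_exactly_reachable(self, demo_system):
        u_mid = (np.array(U_MIN) + np.array(U_MAX)) / 2
        assert np.allclose(demo_system.dc_gain() @ u_mid, SETPOINT)


class TestController:
    def test_fully_pinned_box_returns_the_pin(self, demo_system):
        u0 = tuple(np.full(6, 3.0))
        cfg = MPCConfig(u_min=u0, u_max=u0)
        ctl = MPCController(cfg, demo_system)
        for ym in ([0.0, 0.0], [50.0, 100.0]):
            assert np.array_equal(ctl.step(ym), np.array(u0))

    def test_partially_pinned_components_stay_pinned(self, demo_system):
        u_min = list(U_MIN)
        u_max = list(U_MAX)
        u_min[2] = u_max[2] = 7.5
        cfg = MPCConfig(u_min=tuple(u_min), u_max=tuple(u_max))
        traj = sequential_reference_sim(demo_system, cfg, 20)
        assert np.all(traj["u"][:, 2] == 7.5)

    def test_infeasible_box_rejected(self):
        with pytest.raises(ConfigError):
            MPCConfig(u_min=(1.0,) * 6, u_max=(0.0,) * 6)

    def test_state_estimate_follows_model_recursion(self, demo_system, mpc_config):
        x = np.zeros(demo_system.A.shape[0])
        u, x_next = mpc_control_step(mpc_config, demo_system, x, [0.0, 0.0],
                                     np.zeros(6))
        assert np.allclose(x_next, demo_system.A @ x + demo_system.B @ u)
        assert np.all(u >= np.array(U_MIN)) and np.all(u <= np.array(U_MAX))

    def test_tracks_a_reachable_setpoint(self, demo_system, mpc_config):
        traj = sequential_reference_sim(demo_system, mpc_config, 100)
        err = np.abs(traj["ym"][-1] - np.array(SETPOINT)) / np.array(SETPOINT)
        assert np.all(err < 0.01)


class TestPowerMeter:
    def test_printed_formula(self):
        acc = EnergyAccumulator()
        u, ym = [10.0, 2.0, 5.0, 1.0, 0.0, 0.0], [100.0, 60.0]
        ru, rym, acc = power_meter_step(u, ym, acc)
        assert acc.energy == pytest.approx(25.0)  # period 1.0 x (20 + 5 + 0)
        assert ru is u and rym is ym  # pass-through, untouched

    def test_zero_heart_rate_accumulates_nothing(self):
        acc = EnergyAccumulator(energy=5.0)
        power_meter_step([10.0] * 6, [100.0, 0.0], acc)
        assert acc.energy == 5.0

    def test_zero_stimulation_accumulates_nothing(self):
        acc = EnergyAccumulator()
        power_meter_step([0.0] * 6, [100.0, 300.0], acc)
        assert acc.energy == 0.0

    def test_meter_does_not_perturb_the_loop(self, demo_system, mpc_config):
        plain = sequential_reference_sim(demo_system, mpc_config, 30)
        metered = sequential_reference_sim(demo_system, mpc_config, 30, meter=True)
        assert trajectory_max_diff(plain, metered) == 0.0
        # energy at beat t pairs ym_t with the input the plant consumed
        u_consumed = np.vstack([np.zeros(6), metered["u"][:-1]])
        assert metered["energy"][-1] == pytest.approx(
            stimulation_energy(u_consumed, metered["ym"]), rel=1e-12)


class TestKnob:
    RULE = {"output": 0, "op": ">", "threshold": 100.0,
            "if_true": [0.5], "if_false": [1.0]}

    def test_threshold_rule_selects_branch(self):
        assert knob_testbench_step([120.0, 300.0], self.RULE) == [0.5]
        assert knob_testbench_step([80.0, 300.0], self.RULE) == [1.0]

    def test_malformed_rule_is_a_config_error(self):
        with pytest.raises(ConfigError):
            knob_testbench_step([1.0, 2.0], {"op": "~", "output": 0,
                                             "threshold": 0, "if_true": [1],
                                             "if_false": [1]})
        with pytest.raises(ConfigError):
            knob_testbench_step([1.0], {"op": ">"})

    def test_knob_change_is_causal(self, demo_system, mpc_config):
        base = sequential_reference_sim(demo_system, mpc_config, 40)
        toggled = sequential_reference_sim(
            demo_system, mpc_config, 40,
            knob_schedule=lambda t: 0.5 if t >= 20 else 1.0)
        for key in ("u", "ym"):
            assert np.array_equal(base[key][:19], toggled[key][:19])
        assert not np.array_equal(base["ym"][19], toggled["ym"][19])

    def test_default_knob_equals_knob_free(self, demo_system, mpc_config):
        base = sequential_reference_sim(demo_system, mpc_config, 30)
        defaulted = sequential_reference_sim(demo_system, mpc_config, 30,
                                             knob_schedule=lambda t: 1.0)
        assert trajectory_max_diff(base, defaulted) == 0.0


class TestSequentialReference:
    def test_single_beat(self, demo_system, mpc_config):
        traj = sequential_reference_sim(demo_system, mpc_config, 1)
        assert traj["t"].shape == (1,)
        # first output is from x0=0 and u=0; u is the MPC response to it
        fresh = MPCController(mpc_config, demo_system)
        assert np.array_equal(traj["u"][0], fresh.step(traj["ym"][0]))

    def test_inputs_respect_the_box_throughout(self, demo_system, mpc_config):
        traj = sequential_reference_sim(demo_system, mpc_config, 60)
        assert np.all(traj["u"] >= np.array(U_MIN) - 1e-12)
        assert np.all(traj["u"] <= np.array(U_MAX) + 1e-12)

    def test_beats_must_be_positive(self, demo_system, mpc_config):
        with pytest.raises(DemoError):
            sequential_reference_sim(demo_system, mpc_config, 0)


class TestDemoTopologies:
    def test_four_node_port_numbering_matches_convention(self):
        ports = assign_ports(build_demo_graph("null"))
        assert ports["CZ"].oport == {"VCZ": 1, "VOUT": 2}
        assert ports["CZ"].iport == {"VPZ": 1, "VIN": 2}

    def test_meter_graph_is_a_single_cycle_through_the_meter(self):
        g = build_demo_graph("meter")
        ports = assign_ports(g)
        assert set(ports["XZ"].iport) == {"VC", "VP"}
        assert set(ports["XZ"].oport) == {"VXP", "VXC"}

    def test_unknown_topology_rejected(self):
        with pytest.raises(DemoError):
            build_demo_graph("moebius")
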