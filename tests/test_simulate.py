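"""Expression model, equilibrium solver, readout and truth-table prediction."""

from __future__ import annotations

import math

import numpy as np
import pytest

from ribologic.compile import LogicSpec, compile_gate, logic_functions
from ribologic.design import DesignConfig, preset
from ribologic.simulate import (
    Binding,
    ExpressionParams,
    calibrate_threshold,
    dose_grid,
    simulate_condition,
    solve_equilibrium,
    transcription_levels,
    truth_table,
    two_species_closed_form,
)

from .conftest import compile_wired

PARAMS = ExpressionParams()


class TestTranscription:
    def test_no_inducer_gives_leak(self, xor_netlist):
        levels = transcription_levels(xor_netlist, {}, PARAMS)
        for sp in xor_netlist.triggers:
            assert levels[sp.name] == pytest.approx(3.0 * PARAMS.leak_fraction)
        for sp in xor_netlist.antisenses:
            assert levels[sp.name] == pytest.approx(9.0 * PARAMS.leak_fraction)

    def test_saturating_inducer(self, xor_netlist):
        levels = transcription_levels(xor_netlist, {"IPTG": 1e9, "aTc": 1e9}, PARAMS)
        for sp in xor_netlist.triggers:
            assert levels[sp.name] == pytest.approx(3.0, rel=1e-6)

    def test_single_inducer_drives_cross_wired_pair(self, xor_netlist):
        levels = transcription_levels(xor_netlist, {"IPTG": 1.0}, PARAMS)
        high = {n for n, v in levels.items() if v > 1.0}
        # IPTG (lac) drives trigger 1 and the other arm's antisense 2
        assert high == {"T1", "A2"}

    def test_negative_concentration_rejected(self, xor_netlist):
        with pytest.raises(ValueError):
            transcription_levels(xor_netlist, {"IPTG": -1.0}, PARAMS)


class TestEquilibriumSolver:
    def test_matches_two_species_closed_form_sweep(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            s0, t0 = rng.uniform(0.01, 20, size=2)
            K = 10 ** rng.uniform(-3, 6)
            state = solve_equilibrium({"S": s0, "T": t0}, [Binding("S", "T", K)])
            expected = two_species_closed_form(s0, t0, K)
            assert state.complexes[("S", "T")] == pytest.approx(expected, rel=1e-6)
            assert state.conservation_residual() < 1e-9

    def test_zero_K_leaves_species_free(self):
        totals = {"S": 2.0, "T": 3.0, "A": 1.0}
        state = solve_equilibrium(totals, [Binding("S", "T", 0.0)])
        assert state.free == pytest.approx(totals)
        assert state.complexes[("S", "T")] == 0.0

    def test_strong_antisense_outcompetes_switch(self):
        # K_TA >> K_ST with antisense in excess: almost no triggered switch
        state = solve_equilibrium(
            {"S": 1.0, "T": 3.0, "A": 9.0},
            [Binding("S", "T", 5.0), Binding("T", "A", 5000.0)],
        )
        assert state.complexes[("S", "T")] / 1.0 < 0.05

    def test_conservation_on_random_competition_networks(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n_s, n_t, n_a = rng.integers(1, 4, size=3)
            totals = {}
            bindings = []
            for i in range(n_s):
                totals[f"S{i}"] = float(rng.uniform(0, 10))
            for i in range(n_t):
                totals[f"T{i}"] = float(rng.uniform(0, 10))
                for j in range(n_s):
                    bindings.append(Binding(f"S{j}", f"T{i}", float(10 ** rng.uniform(-2, 5))))
            for i in range(n_a):
                totals[f"A{i}"] = float(rng.uniform(0, 10))
                for j in range(n_t):
                    bindings.append(Binding(f"T{j}", f"A{i}", float(10 ** rng.uniform(-2, 5))))
            state = solve_equilibrium(totals, bindings)
            assert state.conservation_residual() < 1e-9

    def test_unknown_species_in_binding(self):
        with pytest.raises(ValueError):
            solve_equilibrium({"S": 1.0}, [Binding("S", "ghost", 1.0)])


class TestReadout:
    def test_no_triggers_gives_basal(self, xor_netlist, model):
        state, levels = simulate_condition(xor_netlist, {}, PARAMS, model)
        # leak-level triggers are further captured by leak-level antisense
        assert levels["green"] < PARAMS.reporter_basal + 0.1 * PARAMS.reporter_gain

    def test_or_switch_one_sensor_saturates_output(self, xor_netlist, model):
        _, on = simulate_condition(xor_netlist, {"IPTG": 1e9}, PARAMS, model)
        _, both = simulate_condition(xor_netlist, {"IPTG": 1e9, "aTc": 0.0}, PARAMS, model)
        assert on["green"] == pytest.approx(both["green"], rel=1e-9)
        assert on["green"] > 0.8 * PARAMS.reporter_gain

    def test_and_part_needs_both_triggers(self, library2, model):
        _, net = compile_wired("AND", library2)
        _, one = simulate_condition(net, {"IPTG": 1.0}, PARAMS, model)
        _, both = simulate_condition(net, {"IPTG": 1.0, "aTc": 1.0}, PARAMS, model)
        thr = calibrate_threshold(net, PARAMS, model)
        assert one["green"] < thr < both["green"]


class TestTruthTables:
    @pytest.mark.parametrize("circuit", ["XOR", "NAND", "HALF_ADDER",
                                         "HALF_SUBTRACTOR", "FEYNMAN"])
    def test_boolean_calls_match_logic(self, circuit, circuit_suite, model):
        spec, net = circuit_suite[circuit]
        table = truth_table(net, PARAMS, model=model)
        fns = logic_functions(spec)
        for row in table.rows:
            for channel, fn in fns.items():
                assert row.calls[channel] == fn(*map(bool, row.inputs)), (
                    circuit, row.inputs, channel, row.levels,
                )

    def test_nand_is_on_with_no_inputs(self, circuit_suite, model):
        _, net = circuit_suite["NAND"]
        table = truth_table(net, PARAMS, model=model)
        assert table.calls("green")[(0, 0)] is True
        assert table.calls("green")[(1, 1)] is False

    def test_feynman_map_is_bijective(self, circuit_suite, model):
        _, net = circuit_suite["FEYNMAN"]
        table = truth_table(net, PARAMS, model=model)
        images = {tuple(r.calls[ch] for ch in table.channels) for r in table.rows}
        assert len(images) == 4

    def test_unwired_netlist_rejected(self, library2):
        net = compile_gate(LogicSpec("XOR"), library2, rng_seed=1)
        with pytest.raises(ValueError, match="wire_inducers"):
            truth_table(net, PARAMS)


class TestAntisenseMechanism:
    def test_triggered_fraction_monotone_in_antisense(self):
        """More cognate antisense can only repress, never activate."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            K_st = float(10 ** rng.uniform(-1, 4))
            K_ta = float(10 ** rng.uniform(-1, 5))
            s0, t0 = rng.uniform(0.1, 10, size=2)
            prev = math.inf
            for a0 in (0.0, 0.5, 2.0, 8.0, 32.0):
                state = solve_equilibrium(
                    {"S": float(s0), "T": float(t0), "A": float(a0)},
                    [Binding("S", "T", K_st), Binding("T", "A", K_ta)],
                )
                frac = state.complexes[("S", "T")] / s0
                assert frac <= prev + 1e-9
                prev = frac

    def test_weak_antisense_raises_nimply_leakage(self, library2, model):
        """A bulged (weaker) antisense represses less: the repressed state of
        the NIMPLY gate leaks more than with the full-match antisense."""
        trigger_cfg = preset("optimized")["trigger"]

        def repressed_level(anti_bulge: str) -> float:
            cfg = {
                "trigger": trigger_cfg,
                "antisense": DesignConfig(
                    overhang_mode="five_prime_only", bulge=anti_bulge
                ),
            }
            _, net = compile_wired("NIMPLY", library2, cfg=cfg)
            # repressed state: trigger and antisense both induced
            _, levels = simulate_condition(net, {"IPTG": 1.0, "aTc": 1.0}, PARAMS, model)
            return levels["green"]

        assert repressed_level("single_nt") >= repressed_level("none")


class TestDoseGrid:
    def test_single_point_off(self, xor_netlist, model):
        frame = dose_grid(xor_netlist, {"IPTG": [0.0], "aTc": [0.0]}, PARAMS, model)
        assert frame.shape == (1, 1)
        thr = calibrate_threshold(xor_netlist, PARAMS, model)
        assert frame.iloc[0, 0] < thr

    def test_near_symmetry_under_input_swap(self, xor_netlist, model):
        grid = [0.0, 0.5, 1.0]
        frame = dose_grid(xor_netlist, {"IPTG": grid, "aTc": grid}, PARAMS, model)
        asym = np.abs(frame.to_numpy() - frame.to_numpy().T)
        scale = frame.to_numpy().max()
        assert asym.max() / scale < 0.05

    def test_digital_xor_surface(self, xor_netlist, model):
        grid = [0.0, 0.25, 0.5, 1.0]
        frame = dose_grid(xor_netlist, {"IPTG": grid, "aTc": grid}, PARAMS, model).to_numpy()
        corners = max(frame[0, 0], frame[-1, -1])
        edges = max(frame[0, -1], frame[-1, 0])
        assert edges / corners >= PARAMS.digitality_ratio

    def test_empty_grid_rejected(self, xor_netlist):
        with pytest.raises(ValueError):
            dose_grid(xor_netlist, {"IPTG": []}, PARAMS)
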