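"""Gate compilation: architectures, wiring, plasmids, symbolic logic, JSON."""

from __future__ import annotations

import pytest

from ribologic.compile import (
    CompileError,
    LogicSpec,
    assign_plasmids,
    compile_circuit,
    compile_gate,
    logic_functions,
    netlist_from_dict,
    netlist_to_dict,
    screen_netlist,
    symbolic_truth_table,
    wire_inducers,
)
from ribologic.parts import ConcatenatedSwitch


class TestGateArchitectures:
    def test_xor_netlist_shape(self, library2):
        net = compile_gate(LogicSpec("XOR"), library2, rng_seed=1)
        (csw,) = net.switches
        assert isinstance(csw, ConcatenatedSwitch)
        assert len(csw.sensors) == 2
        assert len(csw.linker_between_sensors) == 9
        assert len(net.triggers) == 2 and len(net.antisenses) == 2
        assert len(net.activation_edges()) == 2
        assert len(net.annihilation_edges()) == 2

    def test_or_gate_has_no_antisense(self, library2):
        net = compile_gate(LogicSpec("OR"), library2, rng_seed=1)
        assert net.antisenses == []
        (csw,) = net.switches
        assert csw.combine == "or"
        assert len(csw.linker_between_sensors) == 9

    def test_nimply_edge_counts(self, library2):
        net = compile_gate(LogicSpec("NIMPLY"), library2, rng_seed=1)
        assert len(net.activation_edges()) == 1
        assert len(net.annihilation_edges()) == 1

    def test_and_gate_is_two_sensor_all_required(self, library2):
        net = compile_gate(LogicSpec("AND"), library2, rng_seed=1)
        (csw,) = net.switches
        assert csw.combine == "and"
        assert net.antisenses == []

    def test_half_adder_and_subtractor_share_green_subnetlist(self, library4):
        ha = compile_circuit(LogicSpec("HALF_ADDER"), library4, rng_seed=1)
        hs = compile_circuit(LogicSpec("HALF_SUBTRACTOR"), library4, rng_seed=1)

        def green_part(net):
            switches = [s for s in net.switches if net.reporters[s.name] == "green"]
            trig_names = {
                e.source for e in net.activation_edges()
                if e.target in {s.name for s in switches}
            }
            trigs = [t for t in net.triggers if t.name in trig_names]
            antis = [a for a in net.antisenses if a.target_trigger in trig_names]
            return switches, trigs, antis

        assert green_part(ha) == green_part(hs)

    def test_feynman_buffer_arm_is_bare(self, library4):
        net = compile_circuit(LogicSpec("FEYNMAN"), library4, rng_seed=1)
        red_switches = {s.name for s in net.switches if net.reporters[s.name] == "red"}
        red_triggers = [
            net.trigger(e.source) for e in net.activation_edges() if e.target in red_switches
        ]
        (t3,) = red_triggers
        assert t3.overhang5 == "" and t3.overhang3 == "" and t3.bulges == ()
        assert all(a.target_trigger != t3.name for a in net.antisenses)

    def test_insufficient_library(self, library2):
        with pytest.raises(CompileError, match="orthogonal switches"):
            compile_circuit(LogicSpec("HALF_ADDER"), library2, rng_seed=1)

    def test_reporter_collision(self):
        with pytest.raises(CompileError, match="collision"):
            LogicSpec("HALF_ADDER", outputs=("green", "green"))

    def test_compilation_deterministic(self, library4):
        a = compile_circuit(LogicSpec("FEYNMAN"), library4, rng_seed=3)
        b = compile_circuit(LogicSpec("FEYNMAN"), library4, rng_seed=3)
        assert netlist_to_dict(a) == netlist_to_dict(b)


class TestWiring:
    def test_canonical_xor_operator_layout(self, library2):
        net = compile_gate(LogicSpec("XOR"), library2, rng_seed=1)
        wire_inducers(net, {"IPTG": "A", "aTc": "B"})
        ops = {sp.name: sp.operator for sp in net.triggers + net.antisenses}
        assert ops == {"T1": "lac", "A2": "lac", "T2": "tet", "A1": "tet"}
        assert net.inducer_map == {"IPTG": "lac", "aTc": "tet"}

    def test_nand_triggers_constitutive(self, library2):
        net = compile_gate(LogicSpec("NAND"), library2, rng_seed=1)
        wire_inducers(net, {"IPTG": "A", "aTc": "B"})
        assert all(t.operator == "constitutive" for t in net.triggers)
        assert {a.operator for a in net.antisenses} == {"lac", "tet"}

    def test_buffer_wires_single_trigger(self, library2):
        net = compile_gate(LogicSpec("BUFFER", inputs=("IPTG",)), library2, rng_seed=1)
        wire_inducers(net, {"IPTG": "A"})
        (t,) = net.triggers
        assert t.operator == "lac"
        assert net.antisenses == []

    def test_mapping_arity_mismatch(self, library2):
        net = compile_gate(LogicSpec("XOR"), library2, rng_seed=1)
        with pytest.raises(CompileError, match="mapping covers"):
            wire_inducers(net, {"IPTG": "A"})


class TestPlasmids:
    def test_default_levels(self, library2):
        net = compile_gate(LogicSpec("XOR"), library2, rng_seed=1)
        assign_plasmids(net)
        levels = net.plasmids
        assert levels[net.switches[0].name] == "low"
        assert all(levels[t.name] == "medium" for t in net.triggers)
        assert all(levels[a.name] == "high" for a in net.antisenses)

    def test_or_gate_uses_no_high_copy(self, library2):
        net = compile_gate(LogicSpec("OR"), library2, rng_seed=1)
        assign_plasmids(net)
        assert "high" not in net.plasmids.values()

    def test_overrides_exact(self, library2):
        net = compile_gate(LogicSpec("XOR"), library2, rng_seed=1)
        assign_plasmids(net, overrides={"T1": "high"})
        assert net.plasmids["T1"] == "high"

    def test_unknown_override_rejected(self, library2):
        net = compile_gate(LogicSpec("XOR"), library2, rng_seed=1)
        with pytest.raises(CompileError, match="unknown species"):
            assign_plasmids(net, overrides={"nope": "low"})


class TestSymbolicLogic:
    @pytest.mark.parametrize(
        "circuit", ["BUFFER", "NOT", "OR", "AND", "NIMPLY", "XOR", "NAND",
                    "HALF_ADDER", "HALF_SUBTRACTOR", "FEYNMAN"]
    )
    def test_edges_alone_reproduce_boolean_function(self, circuit, library4):
        inputs = ("IPTG",) if circuit in ("BUFFER", "NOT") else ("IPTG", "aTc")
        spec = LogicSpec(circuit, inputs=inputs)
        net = compile_circuit(spec, library4, rng_seed=1)
        fns = logic_functions(spec)
        table = symbolic_truth_table(net)
        for combo, outputs in table.items():
            for channel, fn in fns.items():
                assert outputs[channel] == fn(*map(bool, combo)), (circuit, combo, channel)

    def test_feynman_is_a_bijection(self, library4):
        net = compile_circuit(LogicSpec("FEYNMAN"), library4, rng_seed=1)
        table = symbolic_truth_table(net)
        images = {tuple(row.values()) for row in table.values()}
        assert len(images) == 4  # one-to-one over all four input rows


class TestScreenAndSerialization:
    def test_compiled_xor_screen_clean(self, library2):
        net = compile_gate(LogicSpec("XOR"), library2, rng_seed=1)
        assert screen_netlist(net).ok

    def test_netlist_json_roundtrip(self, circuit_suite):
        for _, net in circuit_suite.values():
            back = netlist_from_dict(netlist_to_dict(net))
            assert netlist_to_dict(back) == netlist_to_dict(net)
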