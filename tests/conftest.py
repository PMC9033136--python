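from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ribologic.compile import LogicSpec, assign_plasmids, compile_circuit, wire_inducers
from ribologic.fixtures import FixtureSpec, make_switch_library
from ribologic.fold import EnergyModel
from ribologic.parts import SwitchPart
from ribologic.seqs import reverse_complement

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

INDUCER_MAP = {"IPTG": "A", "aTc": "B"}


@pytest.fixture(scope="session")
def model() -> EnergyModel:
    return EnergyModel()


@pytest.fixture(scope="session")
def library2():
    """Two orthogonal fixture switches (enough for XOR/OR/NAND)."""
    return make_switch_library(FixtureSpec(n_switches=2, seed=1))


@pytest.fixture(scope="session")
def library4():
    """Four orthogonal fixture switches (enough for the half adder)."""
    return make_switch_library(FixtureSpec(n_switches=4, seed=1))


def compile_wired(circuit: str, library, rng_seed: int = 1, **kwargs):
    """Compile, wire inducers and assign plasmids in one step."""
    spec = LogicSpec(circuit)
    net = compile_circuit(spec, library, rng_seed=rng_seed, **kwargs)
    mapping = dict(INDUCER_MAP) if len(spec.bits) == 2 else {"IPTG": "A"}
    wire_inducers(net, mapping)
    assign_plasmids(net)
    return spec, net


@pytest.fixture(scope="session")
def xor_netlist(library2):
    return compile_wired("XOR", library2)[1]


@pytest.fixture(scope="session")
def circuit_suite(library4):
    """All five headline circuits compiled over the same library."""
    return {
        circ: compile_wired(circ, library4)
        for circ in ("XOR", "NAND", "HALF_ADDER", "HALF_SUBTRACTOR", "FEYNMAN")
    }


@pytest.fixture()
def toy_switch() -> SwitchPart:
    """A small deterministic hand-built switch (not from the generator)."""
    rng = np.random.default_rng(7)
    toehold = "".join(rng.choice(list("ACGU"), 12))
    stem_bottom = "".join(rng.choice(list("ACGU"), 18))
    return SwitchPart(
        name="toy",
        toehold_seq=toehold,
        stem_bottom=stem_bottom,
        stem_top=reverse_complement(stem_bottom),
        loop_seq="ACAGGAGGACA",
        start_codon_offset=0,
        linker_seq="AUGACAACAACAACAACAACA",
    )
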