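"""Compile logic functions into toehold-switch circuit netlists.

Gate architectures:

* ``NIMPLY`` (A AND NOT B) — one switch, a trigger carrying input A, and an
  antisense RNA carrying input B that annihilates the trigger.
* ``OR`` — two orthogonal sensors concatenated with a 9-nt linker ahead of
  one reporter; either trigger activates output.
* ``XOR`` — (A NIMPLY B) OR (B NIMPLY A): the concatenated switch plus two
  triggers and two antisenses, cross-wired so each inducer drives one
  gate's trigger and the other gate's antisense.
* ``NAND`` — the XOR netlist with both triggers made constitutive: output
  is now ON in the no-input case and OFF only when both antisenses fire.
* ``AND`` — a black-box two-sensor part standing in for a library
  split-trigger AND switch; both triggers must bind.
* ``HALF_ADDER`` = XOR (SUM) + AND (CARRY); ``HALF_SUBTRACTOR`` = XOR
  (DIFFERENCE) + NIMPLY (BORROW, computed as B-AND-NOT-A for A - B);
  ``FEYNMAN`` = XOR (Q) + BUFFER (P = A), a reversible controlled-NOT.

The compiler records the *logical* wiring (which input bit drives which
species) at compile time; :func:`wire_inducers` then binds inducers to
operators (IPTG -> lac, aTc -> tet) and :func:`assign_plasmids` sets copy
levels (switches low, triggers medium, antisenses high).
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
import pathlib
from dataclasses import dataclass, replace

import numpy as np

from .design import DesignConfig, preset
from .fold import (
    DEFAULT_MODEL,
    CrosstalkResult,
    EnergyModel,
    accessibility,
    crosstalk_matrix,
    duplex_energy,
)
from .parts import (
    AntisenseRNA,
    CircuitNetlist,
    ConcatenatedSwitch,
    Edge,
    SwitchPart,
    TriggerRNA,
)
from . import design as _design

logger = logging.getLogger("ribologic")

__all__ = [
    "LogicSpec",
    "CompileError",
    "compile_gate",
    "compile_circuit",
    "wire_inducers",
    "assign_plasmids",
    "logic_functions",
    "evaluate_symbolic",
    "screen_netlist",
    "netlist_to_dict",
    "netlist_from_dict",
    "save_netlist",
    "load_netlist",
]

SINGLE_GATES = ("BUFFER", "NOT", "OR", "AND", "NIMPLY", "XOR", "NAND")
COMPOSITE_GATES = ("HALF_ADDER", "HALF_SUBTRACTOR", "FEYNMAN")
CIRCUITS = SINGLE_GATES + COMPOSITE_GATES

#: switches consumed per gate (sensor domains drawn from the library)
_SWITCHES_NEEDED = {
    "BUFFER": 1, "NOT": 1, "NIMPLY": 1, "OR": 2, "AND": 2, "XOR": 2, "NAND": 2,
    "HALF_ADDER": 4, "HALF_SUBTRACTOR": 3, "FEYNMAN": 3,
}

_ARITY = {"BUFFER": 1, "NOT": 1}  # all other circuits take two inputs

#: known inducer -> operator pairings; unknown inducers get operators in order
INDUCER_OPERATORS = {"IPTG": "lac", "aTc": "tet"}
_OPERATOR_POOL = ("lac", "tet")


class CompileError(ValueError):
    """Compilation cannot proceed (missing parts, bad wiring, collisions)."""


@dataclass(frozen=True)
class LogicSpec:
    """What to build: a named circuit, its inducer inputs, its reporters."""

    circuit: str
    inputs: tuple[str, ...] = ("IPTG", "aTc")
    outputs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        name = self.circuit.upper()
        object.__setattr__(self, "circuit", name)
        if name not in CIRCUITS:
            raise CompileError(f"unknown circuit {self.circuit!r}; known: {CIRCUITS}")
        arity = _ARITY.get(name, 2)
        if len(self.inputs) != arity:
            raise CompileError(
                f"{name} takes {arity} input(s), got {len(self.inputs)}"
            )
        n_out = 2 if name in COMPOSITE_GATES else 1
        outs = self.outputs or (("green", "red")[:n_out])
        if len(outs) != n_out:
            raise CompileError(f"{name} has {n_out} output(s), got {len(outs)}")
        if len(set(outs)) != len(outs):
            raise CompileError(f"reporter collision: channels {outs} must be distinct")
        object.__setattr__(self, "outputs", tuple(outs))

    @property
    def bits(self) -> tuple[str, ...]:
        """Logical bit names, one per input, in input order."""
        return ("A", "B")[: len(self.inputs)]


# ---------------------------------------------------------------------------
# truth functions (ground truth the compiled netlists must reproduce)


def logic_functions(spec: LogicSpec):
    """Map each output channel to its Boolean function of the input bits."""
    c = spec.circuit
    fns = {
        "BUFFER": {0: lambda a: a},
        "NOT": {0: lambda a: not a},
        "OR": {0: lambda a, b: a or b},
        "AND": {0: lambda a, b: a and b},
        "NIMPLY": {0: lambda a, b: a and not b},
        "XOR": {0: lambda a, b: a != b},
        "NAND": {0: lambda a, b: not (a and b)},
        # composite: first channel is the XOR-computed bit
        "HALF_ADDER": {0: lambda a, b: a != b, 1: lambda a, b: a and b},      # SUM, CARRY
        "HALF_SUBTRACTOR": {0: lambda a, b: a != b, 1: lambda a, b: (not a) and b},  # DIFF, BORROW
        "FEYNMAN": {0: lambda a, b: a != b, 1: lambda a, b: a},               # Q, P
    }[c]
    return {spec.outputs[k]: fn for k, fn in fns.items()}


# ---------------------------------------------------------------------------
# linker search


def _design_linker(
    sensors: list[SwitchPart],
    rng: np.random.Generator,
    model: EnergyModel,
    length: int = 9,
    min_accessibility: float = 0.5,
    max_iter: int = 200,
) -> str:
    """A short inter-sensor linker that stays mostly unpaired in the
    concatenated switch MFE."""
    joined_left = sensors[0].seq
    joined_right = "".join(s.seq for s in sensors[1:])
    best, best_acc = None, -1.0
    for _ in range(max_iter):
        cand = _design._draw(rng, length)
        full = joined_left + cand + joined_right
        region = (len(joined_left), len(joined_left) + length)
        acc = accessibility(full, region, model)
        if acc > best_acc:
            best, best_acc = cand, acc
        if acc >= min_accessibility:
            return cand
    raise CompileError(
        f"no {length}-nt linker reached accessibility {min_accessibility} "
        f"(best {best_acc:.2f}: {best})"
    )


# ---------------------------------------------------------------------------
# gate builders


def _resolve_cfgs(cfg, rng_seed: int) -> dict[str, DesignConfig]:
    if isinstance(cfg, str):
        return preset(cfg, rng_seed=rng_seed)
    if isinstance(cfg, DesignConfig):
        return {"trigger": cfg, "antisense": cfg}
    return dict(cfg)


@dataclass
class _Builder:
    """Accumulates species while compiling one or more sub-gates."""

    library: list[SwitchPart]
    cfgs: dict[str, DesignConfig]
    model: EnergyModel
    rng: np.random.Generator
    next_switch: int = 0
    n_trig: int = 0
    n_anti: int = 0
    derived: list[TriggerRNA] = dataclasses.field(default_factory=list)

    def take_switches(self, n: int, circuit: str) -> list[SwitchPart]:
        if self.next_switch + n > len(self.library):
            raise CompileError(
                f"{circuit}: needs {self.next_switch + n} orthogonal switches, "
                f"library holds {len(self.library)}"
            )
        out = self.library[self.next_switch : self.next_switch + n]
        self.next_switch += n
        return out

    def trigger(self, sw: SwitchPart, bit: str, cfg: DesignConfig | None = None) -> TriggerRNA:
        self.n_trig += 1
        # a later antisense carries the reverse complement of its trigger's
        # overhangs; keeping new overhangs away from those complements
        # suppresses antisense-vs-non-cognate-trigger crosstalk across arms
        t = _design.derive_trigger(
            sw, cfg or self.cfgs["trigger"], self.model, name=f"T{self.n_trig}"
        )
        t = replace(t, operator="constitutive" if bit == "const" else "none")
        self.derived.append(t)
        return t

    def antisense(self, trig: TriggerRNA) -> AntisenseRNA:
        self.n_anti += 1
        return _design.derive_antisense(
            trig, self.cfgs["antisense"], self.model, name=f"A{self.n_anti}"
        )


def _build_gate(
    b: _Builder,
    circuit: str,
    bits: tuple[str, ...],
    channel: str,
    net: CircuitNetlist,
) -> None:
    """Append one gate's species and edges to ``net``.

    ``bits`` carries the logical input of each gate terminal (for the
    two-input gates, ``bits[0]`` is the first NIMPLY arm's trigger).
    """
    bare = DesignConfig(overhang_mode="none", bulge="none")

    if circuit in ("BUFFER", "NOT"):
        (sw,) = b.take_switches(1, circuit)
        sw = replace(sw, reporter=channel)
        bit = bits[0]
        if circuit == "BUFFER":
            # Feynman-style BUFFER arm: bare trigger, no antisense
            t = b.trigger(sw, bit, cfg=bare)
            net.switches.append(sw)
            net.triggers.append(t)
            net.edges.append(Edge("activates", t.name, sw.name, sensor=sw.name))
            net.input_bits[t.name] = bit
        else:  # NOT = NIMPLY with a constitutive trigger
            t = b.trigger(sw, "const")
            a = b.antisense(t)
            net.switches.append(sw)
            net.triggers.append(t)
            net.antisenses.append(a)
            net.edges.append(Edge("activates", t.name, sw.name, sensor=sw.name))
            net.edges.append(Edge("annihilates", a.name, t.name))
            net.input_bits[t.name] = "const"
            net.input_bits[a.name] = bit
        net.reporters[sw.name] = channel
        return

    if circuit == "NIMPLY":
        (sw,) = b.take_switches(1, circuit)
        sw = replace(sw, reporter=channel)
        t = b.trigger(sw, bits[0])
        a = b.antisense(t)
        net.switches.append(sw)
        net.triggers.append(t)
        net.antisenses.append(a)
        net.edges.append(Edge("activates", t.name, sw.name, sensor=sw.name))
        net.edges.append(Edge("annihilates", a.name, t.name))
        net.input_bits[t.name] = bits[0]
        net.input_bits[a.name] = bits[1]
        net.reporters[sw.name] = channel
        return

    if circuit in ("OR", "AND", "XOR", "NAND"):
        s1, s2 = b.take_switches(2, circuit)
        combine = "and" if circuit == "AND" else "or"
        linker = _design_linker([s1, s2], b.rng, b.model)
        gate_name = f"{circuit}_{channel}"
        csw = ConcatenatedSwitch(
            name=gate_name, sensors=(s1, s2),
            linker_between_sensors=linker, reporter=channel, combine=combine,
        )
        t1 = b.trigger(s1, bits[0])
        t2 = b.trigger(s2, bits[1])
        net.switches.append(csw)
        net.triggers.extend([t1, t2])
        net.edges.append(Edge("activates", t1.name, gate_name, sensor=s1.name))
        net.edges.append(Edge("activates", t2.name, gate_name, sensor=s2.name))
        net.reporters[gate_name] = channel
        if circuit in ("XOR", "NAND"):
            a1 = b.antisense(t1)
            a2 = b.antisense(t2)
            net.antisenses.extend([a1, a2])
            net.edges.append(Edge("annihilates", a1.name, t1.name))
            net.edges.append(Edge("annihilates", a2.name, t2.name))
            if circuit == "NAND":
                # constitutive triggers; antisenses keep the XOR cross-wiring
                t1 = replace(t1, operator="constitutive")
                t2 = replace(t2, operator="constitutive")
                net.triggers[-2:] = [t1, t2]
                net.input_bits[t1.name] = "const"
                net.input_bits[t2.name] = "const"
            else:
                net.input_bits[t1.name] = bits[0]
                net.input_bits[t2.name] = bits[1]
            # input i drives trigger_i and the *other* arm's antisense
            net.input_bits[a2.name] = bits[0]
            net.input_bits[a1.name] = bits[1]
        else:
            net.input_bits[t1.name] = bits[0]
            net.input_bits[t2.name] = bits[1]
        return

    raise CompileError(f"cannot build {circuit!r} as a sub-gate")  # pragma: no cover


#: deterministic stream offsets for design retries (see _with_retries)
_RETRY_STRIDE = 7919
_MAX_ATTEMPTS = 5


def _shift_cfgs(cfgs: dict[str, DesignConfig], offset: int) -> dict[str, DesignConfig]:
    return {k: replace(c, rng_seed=c.rng_seed + offset) for k, c in cfgs.items()}


def _with_retries(build, spec: LogicSpec, model: EnergyModel):
    """Run ``build(attempt)`` until the design succeeds and screens clean.

    Sequence design is stochastic: occasionally two independently drawn
    overhangs collide (an antisense then cross-reacts with the other arm's
    trigger) or a search stalls.  A fresh deterministic stream nearly
    always resolves it; after the retry budget the last netlist is
    returned with a logged warning (flags are advisory), while a final
    failed search propagates.
    """
    last_exc: Exception | None = None
    for attempt in range(_MAX_ATTEMPTS):
        try:
            net = build(attempt)
        except _design.DesignSearchError as exc:
            last_exc = exc
            continue
        screen = screen_netlist(net, model)
        if screen.ok:
            return net
        if attempt == _MAX_ATTEMPTS - 1:
            logger.warning(
                "%s: crosstalk flags persist after %d attempts: %s",
                spec.circuit, _MAX_ATTEMPTS, screen.flagged_pairs(),
            )
            return net
    raise CompileError(
        f"{spec.circuit}: sequence design failed after {_MAX_ATTEMPTS} attempts"
    ) from last_exc


def compile_gate(
    spec: LogicSpec,
    library: list[SwitchPart],
    cfg="optimized",
    model: EnergyModel = DEFAULT_MODEL,
    rng_seed: int = 0,
) -> CircuitNetlist:
    """Compile a single gate into a netlist.

    ``cfg`` is a preset name (``initial`` / ``optimized``), one
    :class:`~ribologic.design.DesignConfig` for both roles, or a dict with
    ``trigger`` and ``antisense`` entries.  Compilation is deterministic
    given the library order and ``rng_seed``.
    """
    if spec.circuit in COMPOSITE_GATES:
        return compile_circuit(spec, library, cfg, model, rng_seed)

    def build(attempt: int) -> CircuitNetlist:
        offset = attempt * _RETRY_STRIDE
        cfgs = _shift_cfgs(_resolve_cfgs(cfg, rng_seed), offset)
        b = _Builder(
            library=list(library), cfgs=cfgs, model=model,
            rng=np.random.default_rng(rng_seed + offset),
        )
        net = CircuitNetlist(name=spec.circuit, inputs=list(spec.bits))
        _build_gate(b, spec.circuit, spec.bits, spec.outputs[0], net)
        net.validate()
        return net

    return _with_retries(build, spec, model)


def compile_circuit(
    spec: LogicSpec,
    library: list[SwitchPart],
    cfg="optimized",
    model: EnergyModel = DEFAULT_MODEL,
    rng_seed: int = 0,
    *,
    buffer_switch_index: int | None = None,
) -> CircuitNetlist:
    """Compile a two-output circuit (half adder/subtractor, Feynman gate).

    Both sub-gates share the same inducer inputs; the XOR sub-gate reports
    on the first output channel.  ``buffer_switch_index`` optionally picks
    which library switch hosts the Feynman BUFFER arm (default: the switch
    after the two XOR sensors, i.e. the third orthogonal part).
    """
    if spec.circuit in SINGLE_GATES:
        return compile_gate(spec, library, cfg, model, rng_seed)
    library = list(library)
    if buffer_switch_index is not None:
        if spec.circuit != "FEYNMAN":
            raise CompileError("buffer_switch_index only applies to the Feynman gate")
        lib = list(library)
        third = lib.pop(buffer_switch_index)
        library = lib[:2] + [third] + lib[2:]
    need = _SWITCHES_NEEDED[spec.circuit]
    if len(library) < need:
        raise CompileError(
            f"{spec.circuit}: needs {need} orthogonal switches, library holds {len(library)}"
        )

    def build(attempt: int) -> CircuitNetlist:
        offset = attempt * _RETRY_STRIDE
        cfgs = _shift_cfgs(_resolve_cfgs(cfg, rng_seed), offset)
        b = _Builder(
            library=library, cfgs=cfgs, model=model,
            rng=np.random.default_rng(rng_seed + offset),
        )
        net = CircuitNetlist(name=spec.circuit, inputs=list(spec.bits))
        ch1, ch2 = spec.outputs
        a_bit, b_bit = spec.bits
        _build_gate(b, "XOR", (a_bit, b_bit), ch1, net)
        if spec.circuit == "HALF_ADDER":
            _build_gate(b, "AND", (a_bit, b_bit), ch2, net)
        elif spec.circuit == "HALF_SUBTRACTOR":
            # BORROW for A - B is (NOT A) AND B, i.e. B NIMPLY A
            _build_gate(b, "NIMPLY", (b_bit, a_bit), ch2, net)
        else:  # FEYNMAN: P = A via a BUFFER arm with a bare trigger
            _build_gate(b, "BUFFER", (a_bit,), ch2, net)
        net.validate()
        return net

    return _with_retries(build, spec, model)


# ---------------------------------------------------------------------------
# wiring and plasmids


def wire_inducers(netlist: CircuitNetlist, mapping: dict[str, str]) -> CircuitNetlist:
    """Bind chemical inducers to operators on the compiled species.

    ``mapping`` sends each inducer to the input bit it carries (e.g.
    ``{"IPTG": "A", "aTc": "B"}``).  Every species whose recorded input bit
    matches gets that inducer's operator; for an XOR this reproduces the
    canonical wiring (Lac operator on T1 and A2, Tet operator on T2 and A1).
    Constitutive species are left untouched.
    """
    bits_needed = {b for b in netlist.input_bits.values() if b != "const"}
    if set(mapping.values()) != bits_needed:
        raise CompileError(
            f"inducer mapping covers bits {sorted(set(mapping.values()))}, "
            f"netlist needs {sorted(bits_needed)}"
        )
    pool = [op for op in _OPERATOR_POOL]
    inducer_op: dict[str, str] = {}
    for ind in mapping:
        if ind in INDUCER_OPERATORS:
            inducer_op[ind] = INDUCER_OPERATORS[ind]
            if INDUCER_OPERATORS[ind] in pool:
                pool.remove(INDUCER_OPERATORS[ind])
    for ind in mapping:
        if ind not in inducer_op:
            if not pool:
                raise CompileError("more inducers than available operators")
            inducer_op[ind] = pool.pop(0)

    bit_op = {mapping[ind]: op for ind, op in inducer_op.items()}

    def rewire(species):
        bit = netlist.input_bits.get(species.name)
        if bit in (None, "const"):
            return species
        return replace(species, operator=bit_op[bit])

    netlist.triggers = [rewire(t) for t in netlist.triggers]
    netlist.antisenses = [rewire(a) for a in netlist.antisenses]
    netlist.inducer_map = dict(inducer_op)
    netlist.validate()
    return netlist


DEFAULT_COPY_LEVELS = {"switch": "low", "trigger": "medium", "antisense": "high"}


def assign_plasmids(
    netlist: CircuitNetlist, overrides: dict[str, str] | None = None
) -> CircuitNetlist:
    """Assign copy levels: switches low, triggers medium, antisenses high.

    ``overrides`` maps species names to explicit levels.
    """
    plasmids: dict[str, str] = {}
    for sw in netlist.switches:
        plasmids[sw.name] = DEFAULT_COPY_LEVELS["switch"]
    for t in netlist.triggers:
        plasmids[t.name] = DEFAULT_COPY_LEVELS["trigger"]
    for a in netlist.antisenses:
        plasmids[a.name] = DEFAULT_COPY_LEVELS["antisense"]
    if overrides:
        unknown = set(overrides) - set(plasmids)
        if unknown:
            raise CompileError(f"plasmid overrides for unknown species {sorted(unknown)}")
        plasmids.update(overrides)
    netlist.plasmids = plasmids
    netlist.validate()
    return netlist


# ---------------------------------------------------------------------------
# symbolic evaluation (edges only, no thermodynamics)


def evaluate_symbolic(netlist: CircuitNetlist, assignment: dict[str, bool]) -> dict[str, bool]:
    """Evaluate the netlist as pure Boolean logic over its edges.

    A trigger is active when its input bit is on (constitutive counts as
    on) and no induced antisense annihilates it; a sensor is triggered by
    any active cognate trigger; OR switches fire on any sensor, AND
    switches only when all sensors fire.  Returns channel -> bool.
    """

    def bit_on(name: str) -> bool:
        bit = netlist.input_bits.get(name, "const")
        return True if bit == "const" else bool(assignment[bit])

    annihilators: dict[str, list[str]] = {}
    for e in netlist.annihilation_edges():
        annihilators.setdefault(e.target, []).append(e.source)

    def trigger_active(tname: str) -> bool:
        if not bit_on(tname):
            return False
        return not any(bit_on(a) for a in annihilators.get(tname, []))

    sensor_inputs: dict[tuple[str, str], list[str]] = {}
    for e in netlist.activation_edges():
        sensor_inputs.setdefault((e.target, e.sensor or e.target), []).append(e.source)

    out: dict[str, bool] = {}
    for sw in netlist.switches:
        sensors = (
            sw.sensor_names if isinstance(sw, ConcatenatedSwitch) else (sw.name,)
        )
        fired = [
            any(trigger_active(t) for t in sensor_inputs.get((sw.name, sn), []))
            for sn in sensors
        ]
        combine = sw.combine if isinstance(sw, ConcatenatedSwitch) else "or"
        val = all(fired) if combine == "and" else any(fired)
        out[netlist.reporters[sw.name]] = val
    return out


def symbolic_truth_table(netlist: CircuitNetlist) -> dict[tuple[int, ...], dict[str, bool]]:
    """All 2^n symbolic rows, keyed by the input-bit tuple in netlist order."""
    rows = {}
    for combo in itertools.product((0, 1), repeat=len(netlist.inputs)):
        assignment = dict(zip(netlist.inputs, (bool(v) for v in combo)))
        rows[combo] = evaluate_symbolic(netlist, assignment)
    return rows


# ---------------------------------------------------------------------------
# crosstalk screening


def screen_netlist(
    netlist: CircuitNetlist,
    model: EnergyModel = DEFAULT_MODEL,
    threshold: float | None = None,
    relative_margin: float = 0.5,
) -> CrosstalkResult:
    """Pairwise duplex screen of the compiled species.

    Rows are the input species (triggers, antisenses); columns are their
    potential partners (switch sensing domains and triggers).  Cognate
    pairs — a trigger with its own sensor's switch, an antisense with its
    declared trigger or its own arm's switch — are exempt.  The duplex
    score deliberately ignores that a closed hairpin occludes its stem, so
    antisense-vs-own-switch is architectural, not crosstalk.

    With no absolute ``threshold``, the flag bar is *relative*: a
    non-cognate interaction is flagged when its magnitude comes within
    ``relative_margin`` of the weakest cognate duplex — orthogonality is
    about the separation between intended and unintended binding, and
    full-length species (45-80 nt) inevitably share short pairing runs.
    """
    sensors = netlist.sensors()
    switch_cols = [(f"{own}:{s.name}", s.sensing_seq) for own, s in sensors]
    trig_cols = [(t.name, t.seq) for t in netlist.triggers]
    rows = [(t.name, t.seq) for t in netlist.triggers] + [
        (a.name, a.seq) for a in netlist.antisenses
    ]
    functional: set[tuple[str, str]] = set()  # intended duplexes (the floor)
    cognate: set[tuple[str, str]] = set()     # exempt from flagging
    trig_sensor: dict[str, str] = {}
    for e in netlist.activation_edges():
        col = f"{e.target}:{e.sensor or e.target}"
        functional.add((e.source, col))
        trig_sensor[e.source] = col
    for e in netlist.annihilation_edges():
        functional.add((e.source, e.target))
        # the antisense inherits its trigger's switch as architectural
        if e.target in trig_sensor:
            cognate.add((e.source, trig_sensor[e.target]))
    cognate |= functional
    for t in netlist.triggers:  # self columns
        cognate.add((t.name, t.name))
    if threshold is None:
        seq_of = dict(rows) | dict(switch_cols) | dict(trig_cols)
        floor = min(
            abs(duplex_energy(seq_of[rn], seq_of[cn], model).energy)
            for rn, cn in functional
        )
        threshold = relative_margin * floor
    return crosstalk_matrix(
        rows, switch_cols + trig_cols, model, threshold=threshold, cognate=cognate
    )


# ---------------------------------------------------------------------------
# netlist JSON schema


def _part_dict(p) -> dict:
    if isinstance(p, ConcatenatedSwitch):
        return {
            "type": "concatenated_switch",
            "name": p.name,
            "sensors": [_part_dict(s) for s in p.sensors],
            "linker_between_sensors": p.linker_between_sensors,
            "reporter": p.reporter,
            "combine": p.combine,
        }
    d = dataclasses.asdict(p)
    d["type"] = {
        SwitchPart: "switch", TriggerRNA: "trigger", AntisenseRNA: "antisense"
    }[type(p)]
    if "bulges" in d:
        d["bulges"] = [[pos, base] for pos, base in d["bulges"]]
    return d


def _part_from_dict(d: dict):
    d = dict(d)
    kind = d.pop("type")
    if kind == "concatenated_switch":
        d["sensors"] = tuple(_part_from_dict(s) for s in d["sensors"])
        return ConcatenatedSwitch(**d)
    cls = {"switch": SwitchPart, "trigger": TriggerRNA, "antisense": AntisenseRNA}[kind]
    if "bulges" in d:
        d["bulges"] = tuple((int(p), b) for p, b in d["bulges"])
    return cls(**d)


def netlist_to_dict(netlist: CircuitNetlist) -> dict:
    return {
        "name": netlist.name,
        "switches": [_part_dict(s) for s in netlist.switches],
        "triggers": [_part_dict(t) for t in netlist.triggers],
        "antisenses": [_part_dict(a) for a in netlist.antisenses],
        "edges": [dataclasses.asdict(e) for e in netlist.edges],
        "plasmids": netlist.plasmids,
        "inducer_map": netlist.inducer_map,
        "reporters": netlist.reporters,
        "inputs": netlist.inputs,
        "input_bits": netlist.input_bits,
    }


def netlist_from_dict(d: dict) -> CircuitNetlist:
    net = CircuitNetlist(
        name=d["name"],
        switches=[_part_from_dict(s) for s in d["switches"]],
        triggers=[_part_from_dict(t) for t in d["triggers"]],
        antisenses=[_part_from_dict(a) for a in d["antisenses"]],
        edges=[Edge(**e) for e in d["edges"]],
        plasmids=dict(d.get("plasmids", {})),
        inducer_map=dict(d.get("inducer_map", {})),
        reporters=dict(d.get("reporters", {})),
        inputs=list(d.get("inputs", [])),
        input_bits=dict(d.get("input_bits", {})),
    )
    net.validate()
    return net


def save_netlist(netlist: CircuitNetlist, path: str | pathlib.Path) -> None:
    pathlib.Path(path).write_text(json.dumps(netlist_to_dict(netlist), indent=2))


def load_netlist(path: str | pathlib.Path) -> CircuitNetlist:
    return netlist_from_dict(json.loads(pathlib.Path(path).read_text()))
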