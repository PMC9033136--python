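"""Domain types for toehold-switch circuit parts and their file formats.

A toehold switch is written 5'->3' as::

    toehold | stem_bottom | loop (RBS) | stem_top | linker (start codon) ...

The hairpin (stem_bottom paired to stem_top) sequesters the ribosome binding
site and start codon; the single-stranded toehold plus stem_bottom form the
sensing domain a trigger RNA recognises.  Trigger and antisense RNAs are a
core complementarity domain decorated with optional 5'/3' overhangs and
single-nucleotide bulges at the overhang/core junctions.

Part libraries round-trip through FASTA with ``key=value`` header tokens
(optionally supplemented by a YAML sidecar); expression cassettes can be
exported as GenBank flat files with promoter/operator/part features.
"""

from __future__ import annotations

import pathlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .seqs import clean_rna, reverse_complement

__all__ = [
    "SwitchPart",
    "TriggerRNA",
    "AntisenseRNA",
    "ConcatenatedSwitch",
    "Edge",
    "CircuitNetlist",
    "ValidationCheck",
    "ValidationReport",
    "validate_switch",
    "assemble_sequence",
    "disassemble_sequence",
    "load_part_library",
    "write_part_library",
    "export_cassettes_genbank",
]

OPERATORS = ("lac", "tet", "none", "constitutive")
COPY_LEVELS = ("low", "medium", "high")

DEFAULT_RBS = "AGGAGG"


class PartParseError(ValueError):
    """A part record could not be parsed or is missing required metadata."""


# ---------------------------------------------------------------------------
# assembly of overhang / bulge / core sequences


def assemble_sequence(
    overhang5: str,
    core_seq: str,
    overhang3: str,
    bulges: Sequence[tuple[int, str]] = (),
) -> str:
    """Build the full strand: overhangs flanking the core, with bulge
    nucleotides inserted at their (0-based) positions in the final sequence.

    Positions refer to the assembled string, so the inverse operation
    (:func:`disassemble_sequence`) is exact.
    """
    base = overhang5 + core_seq + overhang3
    out = list(base)
    for pos, nt in sorted(bulges):
        if not (0 <= pos <= len(out)):
            raise ValueError(f"bulge position {pos} outside sequence of length {len(out)}")
        out.insert(pos, nt)
    return "".join(out)


def disassemble_sequence(
    full: str,
    len5: int,
    core_len: int,
    bulge_positions: Sequence[int],
) -> tuple[str, str, str, list[tuple[int, str]]]:
    """Inverse of :func:`assemble_sequence`; returns (o5, core, o3, bulges)."""
    positions = sorted(bulge_positions)
    chars = list(full)
    bulges: list[tuple[int, str]] = []
    for pos in reversed(positions):
        bulges.append((pos, chars.pop(pos)))
    bulges.reverse()
    rest = "".join(chars)
    o5 = rest[:len5]
    core = rest[len5 : len5 + core_len]
    o3 = rest[len5 + core_len :]
    return o5, core, o3, bulges


# ---------------------------------------------------------------------------
# part types


@dataclass(frozen=True)
class SwitchPart:
    """One toehold-switch sensor: hairpin sequestering RBS and start codon."""

    name: str
    toehold_seq: str
    stem_top: str
    stem_bottom: str
    loop_seq: str
    start_codon_offset: int
    linker_seq: str
    reporter: str = "green"
    rbs: str = DEFAULT_RBS

    def __post_init__(self) -> None:
        for fname in ("toehold_seq", "stem_top", "stem_bottom", "loop_seq", "linker_seq"):
            object.__setattr__(
                self, fname, clean_rna(getattr(self, fname), name=f"{self.name}.{fname}")
            )
        if min(len(self.toehold_seq), len(self.stem_top), len(self.stem_bottom),
               len(self.loop_seq), len(self.linker_seq)) == 0:
            raise ValueError(f"{self.name}: all switch segments must be non-empty")

    @property
    def seq(self) -> str:
        """Full switch RNA, 5'->3'."""
        return (
            self.toehold_seq + self.stem_bottom + self.loop_seq
            + self.stem_top + self.linker_seq
        )

    @property
    def sensing_seq(self) -> str:
        """The domain a cognate trigger is complementary to."""
        return self.toehold_seq + self.stem_bottom

    def segment_bounds(self) -> dict[str, tuple[int, int]]:
        t = len(self.toehold_seq)
        sb = t + len(self.stem_bottom)
        lp = sb + len(self.loop_seq)
        st = lp + len(self.stem_top)
        return {
            "toehold": (0, t),
            "stem_bottom": (t, sb),
            "loop": (sb, lp),
            "stem_top": (lp, st),
            "linker": (st, len(self.seq)),
        }

    def target_pairs(self) -> frozenset[tuple[int, int]]:
        """Declared hairpin: stem_bottom base-paired to stem_top, rest open."""
        b = self.segment_bounds()
        b0, b1 = b["stem_bottom"]
        t0, t1 = b["stem_top"]
        n = min(b1 - b0, t1 - t0)
        return frozenset((b0 + k, t1 - 1 - k) for k in range(n))


@dataclass(frozen=True)
class _InputRNA:
    """Shared shape of trigger and antisense RNAs (core + overhangs + bulges)."""

    name: str
    core_seq: str
    overhang5: str = ""
    overhang3: str = ""
    bulges: tuple[tuple[int, str], ...] = ()
    operator: str = "none"

    def __post_init__(self) -> None:
        object.__setattr__(self, "core_seq", clean_rna(self.core_seq, name=f"{self.name}.core"))
        for fname in ("overhang5", "overhang3"):
            val = getattr(self, fname)
            if val:
                object.__setattr__(self, fname, clean_rna(val, name=f"{self.name}.{fname}"))
        object.__setattr__(
            self,
            "bulges",
            tuple(sorted((int(p), clean_rna(b, name=f"{self.name}.bulge")) for p, b in self.bulges)),
        )
        if self.operator not in OPERATORS:
            raise ValueError(f"{self.name}: unknown operator {self.operator!r}")
        self.seq  # assembles; raises on inconsistent bulge positions

    @property
    def seq(self) -> str:
        return assemble_sequence(self.overhang5, self.core_seq, self.overhang3, self.bulges)

    def disassemble(self) -> tuple[str, str, str, list[tuple[int, str]]]:
        return disassemble_sequence(
            self.seq, len(self.overhang5), len(self.core_seq), [p for p, _ in self.bulges]
        )


@dataclass(frozen=True)
class TriggerRNA(_InputRNA):
    """Trans-acting activator: core complementary to a switch sensing domain."""


@dataclass(frozen=True)
class AntisenseRNA(_InputRNA):
    """Trigger-annihilating RNA: core complementary to a trigger core.

    An empty ``bulges`` tuple is the "full match" design (no bulge), which
    binds its trigger with the most favourable duplex energy.
    """

    target_trigger: str = ""

    def __post_init__(self) -> None:
        super().__post_init__()
        if not self.target_trigger:
            raise ValueError(f"{self.name}: antisense must declare its target trigger")


@dataclass(frozen=True)
class ConcatenatedSwitch:
    """Several sensor domains joined by a short linker ahead of one reporter.

    ``combine='or'`` is the concatenated OR architecture (any sensor
    triggered gives output); ``combine='and'`` models a split-trigger AND
    part as a black-box two-sensor gate (both sensors must be triggered).
    """

    name: str
    sensors: tuple[SwitchPart, ...]
    linker_between_sensors: str
    reporter: str = "green"
    combine: str = "or"

    def __post_init__(self) -> None:
        if len(self.sensors) < 2:
            raise ValueError(f"{self.name}: a concatenated switch needs >= 2 sensors")
        object.__setattr__(self, "sensors", tuple(self.sensors))
        object.__setattr__(
            self,
            "linker_between_sensors",
            clean_rna(self.linker_between_sensors, name=f"{self.name}.linker"),
        )
        if self.combine not in ("or", "and"):
            raise ValueError(f"{self.name}: combine must be 'or' or 'and'")

    @property
    def seq(self) -> str:
        return self.linker_between_sensors.join(s.seq for s in self.sensors)

    @property
    def sensor_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.sensors)


SwitchLike = Union[SwitchPart, ConcatenatedSwitch]
Part = Union[SwitchPart, TriggerRNA, AntisenseRNA]


# ---------------------------------------------------------------------------
# netlist


@dataclass(frozen=True)
class Edge:
    """Typed interaction: trigger activates a switch sensor, or antisense
    annihilates a trigger."""

    kind: str  # "activates" | "annihilates"
    source: str
    target: str  # switch name for activation, trigger name for annihilation
    sensor: str | None = None  # sensor domain within the target switch

    def __post_init__(self) -> None:
        if self.kind not in ("activates", "annihilates"):
            raise ValueError(f"unknown edge kind {self.kind!r}")


@dataclass
class CircuitNetlist:
    """Species plus typed interaction edges, copy levels, operator wiring and
    reporter channels — everything the simulator needs."""

    name: str
    switches: list[SwitchLike] = field(default_factory=list)
    triggers: list[TriggerRNA] = field(default_factory=list)
    antisenses: list[AntisenseRNA] = field(default_factory=list)
    edges: list[Edge] = field(default_factory=list)
    plasmids: dict[str, str] = field(default_factory=dict)
    inducer_map: dict[str, str] = field(default_factory=dict)
    reporters: dict[str, str] = field(default_factory=dict)
    #: ordered logical input bit names, e.g. ["A", "B"]
    inputs: list[str] = field(default_factory=list)
    #: which input bit drives each trigger/antisense ("const" = constitutive)
    input_bits: dict[str, str] = field(default_factory=dict)

    # -- lookups ----------------------------------------------------------
    def switch(self, name: str) -> SwitchLike:
        return self._by_name(self.switches, name)

    def trigger(self, name: str) -> TriggerRNA:
        return self._by_name(self.triggers, name)

    def antisense(self, name: str) -> AntisenseRNA:
        return self._by_name(self.antisenses, name)

    @staticmethod
    def _by_name(pool, name):
        for p in pool:
            if p.name == name:
                return p
        raise KeyError(name)

    def species_names(self) -> list[str]:
        return (
            [s.name for s in self.switches]
            + [t.name for t in self.triggers]
            + [a.name for a in self.antisenses]
        )

    def sensors(self) -> list[tuple[str, SwitchPart]]:
        """(owning-switch name, sensor part) for every sensor domain."""
        out: list[tuple[str, SwitchPart]] = []
        for sw in self.switches:
            if isinstance(sw, ConcatenatedSwitch):
                out.extend((sw.name, s) for s in sw.sensors)
            else:
                out.append((sw.name, sw))
        return out

    def activation_edges(self) -> list[Edge]:
        return [e for e in self.edges if e.kind == "activates"]

    def annihilation_edges(self) -> list[Edge]:
        return [e for e in self.edges if e.kind == "annihilates"]

    def validate(self) -> None:
        names = set(self.species_names())
        sensor_names = {s.name for _, s in self.sensors()}
        trig_names = {t.name for t in self.triggers}
        for e in self.edges:
            if e.source not in names:
                raise ValueError(f"edge source {e.source!r} not in netlist")
            if e.kind == "activates":
                if e.target not in {sw.name for sw in self.switches}:
                    raise ValueError(f"activation target {e.target!r} is not a switch")
                if e.sensor is not None and e.sensor not in sensor_names:
                    raise ValueError(f"unknown sensor domain {e.sensor!r}")
            else:
                if e.target not in trig_names:
                    raise ValueError(f"annihilation target {e.target!r} is not a trigger")
                a = self.antisense(e.source)
                if a.target_trigger != e.target:
                    raise ValueError(
                        f"{a.name} annihilates {e.target} but is declared against "
                        f"{a.target_trigger}"
                    )
        for sp in self.plasmids.values():
            if sp not in COPY_LEVELS:
                raise ValueError(f"unknown copy level {sp!r}")


# ---------------------------------------------------------------------------
# validation report


@dataclass(frozen=True)
class ValidationCheck:
    name: str
    passed: bool
    detail: str = ""


@dataclass(frozen=True)
class ValidationReport:
    part: str
    checks: tuple[ValidationCheck, ...]

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def failures(self) -> list[ValidationCheck]:
        return [c for c in self.checks if not c.passed]


@dataclass(frozen=True)
class ValidationConfig:
    rbs: str = DEFAULT_RBS
    allowed_stem_mismatches: int = 0


def validate_switch(
    part: SwitchPart, config: ValidationConfig | None = None
) -> ValidationReport:
    """Check the structural invariants of a switch part.

    The report carries one entry per invariant: stem complementarity (up to
    the configured number of designed mismatches), exactly one RBS motif in
    the loop, and a single-stranded toehold in the declared hairpin target.
    """
    cfg = config or ValidationConfig()
    checks: list[ValidationCheck] = []

    top_rc = reverse_complement(part.stem_bottom)
    if len(part.stem_top) != len(part.stem_bottom):
        checks.append(
            ValidationCheck(
                "stem_complementarity", False,
                f"stem lengths differ ({len(part.stem_top)} vs {len(part.stem_bottom)})",
            )
        )
    else:
        mism = sum(1 for a, b in zip(part.stem_top, top_rc) if a != b)
        checks.append(
            ValidationCheck(
                "stem_complementarity",
                mism <= cfg.allowed_stem_mismatches,
                f"{mism} mismatch(es), {cfg.allowed_stem_mismatches} allowed",
            )
        )

    n_rbs = part.loop_seq.count(cfg.rbs)
    checks.append(
        ValidationCheck("rbs_single_copy", n_rbs == 1, f"found {n_rbs}x {cfg.rbs!r} in loop")
    )

    th_end = len(part.toehold_seq)
    paired_in_target = {i for ij in part.target_pairs() for i in ij}
    toehold_free = all(i not in paired_in_target for i in range(th_end))
    checks.append(
        ValidationCheck("toehold_single_stranded", toehold_free, "declared target structure")
    )

    return ValidationReport(part=part.name, checks=tuple(checks))


# ---------------------------------------------------------------------------
# FASTA round-trip

_ROLE_FIELDS = {
    "switch": ("toehold_len", "stem_len", "loop_len", "start_codon_offset", "reporter", "rbs"),
    "trigger": ("o5_len", "o3_len", "core_len", "bulges", "operator"),
    "antisense": ("o5_len", "o3_len", "core_len", "bulges", "operator", "target"),
}


def _header_tokens(description: str) -> dict[str, str]:
    toks = {}
    for tok in description.split()[1:]:
        if "=" in tok:
            k, v = tok.split("=", 1)
            toks[k] = v
    return toks


def _fmt_bulges(bulges: Iterable[tuple[int, str]]) -> str:
    items = [f"{p}:{b}" for p, b in bulges]
    return ",".join(items) if items else "-"


def _parse_bulges(text: str) -> list[tuple[int, str]]:
    if text in ("-", ""):
        return []
    out = []
    for item in text.split(","):
        p, b = item.split(":")
        out.append((int(p), b))
    return out


def part_to_record(part: Part) -> SeqRecord:
    if isinstance(part, SwitchPart):
        meta = (
            f"role=switch toehold_len={len(part.toehold_seq)} "
            f"stem_len={len(part.stem_top)} loop_len={len(part.loop_seq)} "
            f"start_codon_offset={part.start_codon_offset} reporter={part.reporter} "
            f"rbs={part.rbs}"
        )
    elif isinstance(part, AntisenseRNA):
        meta = (
            f"role=antisense o5_len={len(part.overhang5)} o3_len={len(part.overhang3)} "
            f"core_len={len(part.core_seq)} bulges={_fmt_bulges(part.bulges)} "
            f"operator={part.operator} target={part.target_trigger}"
        )
    elif isinstance(part, TriggerRNA):
        meta = (
            f"role=trigger o5_len={len(part.overhang5)} o3_len={len(part.overhang3)} "
            f"core_len={len(part.core_seq)} bulges={_fmt_bulges(part.bulges)} "
            f"operator={part.operator}"
        )
    else:
        raise TypeError(f"cannot serialize {type(part).__name__}")
    return SeqRecord(Seq(part.seq), id=part.name, description=f"{part.name} {meta}")


def record_to_part(record: SeqRecord, sidecar: dict | None = None) -> Part:
    name = record.id
    meta = _header_tokens(record.description)
    if sidecar and name in sidecar:
        merged = {str(k): str(v) for k, v in sidecar[name].items()}
        merged.update(meta)  # header wins over sidecar
        meta = merged
    role = meta.get("role")
    if role is None:
        raise PartParseError(f"record {name!r}: missing role annotation")
    if role not in _ROLE_FIELDS:
        raise PartParseError(f"record {name!r}: unknown role {role!r}")
    seq = clean_rna(str(record.seq), name=name)

    try:
        if role == "switch":
            tl = int(meta["toehold_len"])
            sl = int(meta["stem_len"])
            ll = int(meta["loop_len"])
            toehold = seq[:tl]
            stem_bottom = seq[tl : tl + sl]
            loop = seq[tl + sl : tl + sl + ll]
            stem_top = seq[tl + sl + ll : tl + 2 * sl + ll]
            linker = seq[tl + 2 * sl + ll :]
            return SwitchPart(
                name=name,
                toehold_seq=toehold,
                stem_bottom=stem_bottom,
                loop_seq=loop,
                stem_top=stem_top,
                start_codon_offset=int(meta.get("start_codon_offset", 0)),
                linker_seq=linker,
                reporter=meta.get("reporter", "green"),
                rbs=meta.get("rbs", DEFAULT_RBS),
            )
        o5l = int(meta["o5_len"])
        corel = int(meta["core_len"])
        bulges = _parse_bulges(meta.get("bulges", "-"))
        o5, core, o3, bl = disassemble_sequence(seq, o5l, corel, [p for p, _ in bulges])
        for (p, b_expect), (_, b_got) in zip(sorted(bulges), bl):
            if b_expect != b_got:
                raise PartParseError(
                    f"record {name!r}: bulge base mismatch at position {p}"
                )
        common = dict(
            name=name, core_seq=core, overhang5=o5, overhang3=o3,
            bulges=tuple(bl), operator=meta.get("operator", "none"),
        )
        if role == "trigger":
            return TriggerRNA(**common)
        return AntisenseRNA(target_trigger=meta.get("target", ""), **common)
    except PartParseError:
        raise
    except (KeyError, ValueError, IndexError) as exc:
        raise PartParseError(f"record {name!r}: {exc}") from exc


def load_part_library(path: str | pathlib.Path) -> list[Part]:
    """Read a FASTA part library (with key=value headers and an optional
    ``<path>.yaml`` metadata sidecar) into validated typed parts."""
    path = pathlib.Path(path)
    sidecar = None
    sc_path = path.with_suffix(path.suffix + ".yaml")
    if sc_path.exists():
        sidecar = yaml.safe_load(sc_path.read_text()) or {}
    parts = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts.append(record_to_part(rec, sidecar))
    if not parts:
        raise PartParseError(f"{path}: no FASTA records found")
    return parts


def write_part_library(parts: Iterable[Part], path: str | pathlib.Path) -> None:
    records = [part_to_record(p) for p in parts]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GenBank cassette export

_OPERATOR_NOTE = {"lac": "Lac operator", "tet": "Tet operator",
                  "constitutive": "constitutive (no operator)", "none": "unregulated"}


def _cassette_record(species_name: str, seq: str, operator: str, kind: str) -> SeqRecord:
    # expression cassettes live on DNA plasmids: back-transcribe for GenBank
    dna = seq.replace("U", "T")
    promoter = "TAATACGACTCACTATAGGG"  # T7 promoter + G-start
    full = promoter + dna
    rec = SeqRecord(Seq(full), id=species_name, name=species_name[:16],
                    description=f"{kind} expression cassette")
    rec.annotations["molecule_type"] = "DNA"
    rec.features.append(
        SeqFeature(FeatureLocation(0, len(promoter)), type="promoter",
                   qualifiers={"label": ["T7 promoter"]})
    )
    rec.features.append(
        SeqFeature(FeatureLocation(len(promoter), len(full)), type="misc_RNA",
                   qualifiers={"label": [f"{species_name} ({kind})"],
                               "note": [_OPERATOR_NOTE.get(operator, operator)]})
    )
    return rec


def export_cassettes_genbank(netlist: CircuitNetlist, path: str | pathlib.Path) -> None:
    """Write one annotated GenBank record per expression cassette."""
    records = []
    for sw in netlist.switches:
        records.append(_cassette_record(sw.name, sw.seq, "none", "switch"))
    for t in netlist.triggers:
        records.append(_cassette_record(t.name, t.seq, t.operator, "trigger"))
    for a in netlist.antisenses:
        records.append(_cassette_record(a.name, a.seq, a.operator, "antisense"))
    SeqIO.write(records, str(path), "genbank")
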