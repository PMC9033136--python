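"""Part types, validation, FASTA/YAML round trips, GenBank export."""

from __future__ import annotations

import dataclasses

import pytest
import yaml
from Bio import SeqIO
from hypothesis import given, strategies as st

from ribologic.fixtures import FixtureSpec, make_switch_library
from ribologic.parts import (
    AntisenseRNA,
    CircuitNetlist,
    Edge,
    PartParseError,
    SwitchPart,
    TriggerRNA,
    assemble_sequence,
    disassemble_sequence,
    export_cassettes_genbank,
    load_part_library,
    validate_switch,
    write_part_library,
)
from ribologic.seqs import AlphabetError, reverse_complement


def trigger_example() -> TriggerRNA:
    return TriggerRNA(
        name="T1",
        core_seq="GGAUCCGAUAGCUAGCAUGCGAUCAAGGCC",
        overhang5="ACACAACCA",
        overhang3="CCAACACAC",
        bulges=((9, "A"), (40, "C")),
        operator="lac",
    )


class TestAssembly:
    @given(
        st.text(alphabet="ACGU", max_size=10),
        st.text(alphabet="ACGU", min_size=1, max_size=20),
        st.text(alphabet="ACGU", max_size=10),
        st.lists(st.sampled_from("ACGU"), max_size=3),
    )
    def test_bijection(self, o5, core, o3, bulge_bases):
        # junction-style bulges: one after the 5' overhang, rest at the end
        positions = sorted(
            {min(len(o5) + k, len(o5) + len(core) + len(o3) + k) for k in range(len(bulge_bases))}
        )
        bulges = list(zip(positions, bulge_bases))
        full = assemble_sequence(o5, core, o3, bulges)
        assert len(full) == len(o5) + len(core) + len(o3) + len(bulges)
        got = disassemble_sequence(full, len(o5), len(core), positions)
        assert got == (o5, core, o3, bulges)

    def test_out_of_range_bulge(self):
        with pytest.raises(ValueError):
            assemble_sequence("", "ACGU", "", [(9, "A")])


class TestSwitchValidation:
    def test_fixture_switch_passes(self, library2):
        for sw in library2:
            report = validate_switch(sw)
            assert report.passed, report.failures()

    def test_reversed_stem_fails(self, toy_switch):
        # reverse (not complement) of the bottom strand breaks pairing
        broken = dataclasses.replace(toy_switch, stem_top=toy_switch.stem_bottom[::-1])
        report = validate_switch(broken)
        failed = {c.name for c in report.failures()}
        assert "stem_complementarity" in failed

    def test_duplicated_rbs_fails(self, toy_switch):
        doubled = dataclasses.replace(toy_switch, loop_seq="AGGAGGAGGAGG")
        report = validate_switch(doubled)
        assert {c.name for c in report.failures()} == {"rbs_single_copy"}

    def test_generator_validator_consistency(self):
        """Every part the fixtures generator emits must validate cleanly."""
        count = 0
        for seed in range(25):
            lib = make_switch_library(
                FixtureSpec(n_switches=4, seed=seed, screen_designability=False)
            )
            for sw in lib:
                assert validate_switch(sw).passed
                count += 1
        assert count >= 100


class TestPartTypes:
    def test_dna_transliterated(self):
        sw = SwitchPart(
            name="dna",
            toehold_seq="ACGTACGTACGT",
            stem_bottom="ACGTACGTACGTACGTAC",
            stem_top=reverse_complement("ACGUACGUACGUACGUAC"),
            loop_seq="ACAGGAGGACA",
            start_codon_offset=0,
            linker_seq="ATGACAACAACA",
        )
        assert "T" not in sw.seq and "U" in sw.seq

    def test_alphabet_violation(self):
        with pytest.raises(AlphabetError):
            TriggerRNA(name="bad", core_seq="ACGX")

    def test_antisense_requires_target(self):
        with pytest.raises(ValueError):
            AntisenseRNA(name="A1", core_seq="ACGU")

    def test_bulge_positions_roundtrip_through_seq(self):
        t = trigger_example()
        o5, core, o3, bulges = t.disassemble()
        assert (o5, core, o3, tuple(bulges)) == (
            t.overhang5, t.core_seq, t.overhang3, t.bulges
        )


class TestLibraryIO:
    def test_roundtrip_all_part_types(self, tmp_path, library2):
        trig = trigger_example()
        anti = AntisenseRNA(
            name="A1",
            core_seq=reverse_complement(trig.core_seq),
            overhang5="CACACAACA",
            target_trigger="T1",
            operator="tet",
        )
        parts = list(library2) + [trig, anti]
        path = tmp_path / "lib.fasta"
        write_part_library(parts, path)
        back = load_part_library(path)
        assert back == parts  # dataclass equality: every field bit-exact

    def test_yaml_sidecar_supplies_metadata(self, tmp_path):
        trig = trigger_example()
        path = tmp_path / "lib.fasta"
        # strip header metadata down to the name, move it to the sidecar
        write_part_library([trig], path)
        rec = next(SeqIO.parse(str(path), "fasta"))
        meta = dict(tok.split("=") for tok in rec.description.split()[1:])
        path.write_text(f">{trig.name}\n{trig.seq}\n")
        sidecar = {trig.name: meta}
        (tmp_path / "lib.fasta.yaml").write_text(yaml.safe_dump(sidecar))
        assert load_part_library(path) == [trig]

    def test_missing_role_is_parse_error(self, tmp_path):
        path = tmp_path / "bad.fasta"
        path.write_text(">nameless\nACGUACGU\n")
        with pytest.raises(PartParseError, match="role"):
            load_part_library(path)

    def test_bad_alphabet_is_named_in_error(self, tmp_path):
        path = tmp_path / "bad.fasta"
        path.write_text(">weird role=trigger o5_len=0 o3_len=0 core_len=8 operator=none\nACGXACGU\n")
        with pytest.raises((PartParseError, AlphabetError), match="weird"):
            load_part_library(path)

    def test_genbank_export(self, tmp_path, xor_netlist):
        path = tmp_path / "cassettes.gb"
        export_cassettes_genbank(xor_netlist, path)
        records = list(SeqIO.parse(str(path), "genbank"))
        assert len(records) == 1 + 2 + 2  # switch + triggers + antisenses
        for rec in records:
            types = [f.type for f in rec.features]
            assert "promoter" in types and "misc_RNA" in types


class TestNetlistValidation:
    def test_unknown_edge_source(self, xor_netlist):
        net = CircuitNetlist(
            name="bad",
            switches=list(xor_netlist.switches),
            triggers=list(xor_netlist.triggers),
            antisenses=list(xor_netlist.antisenses),
            edges=[Edge("activates", "ghost", xor_netlist.switches[0].name)],
        )
        with pytest.raises(ValueError, match="ghost"):
            net.validate()

    def test_antisense_against_undeclared_trigger(self, xor_netlist):
        a1 = xor_netlist.antisenses[0]
        wrong_target = next(
            t.name for t in xor_netlist.triggers if t.name != a1.target_trigger
        )
        net = CircuitNetlist(
            name="bad",
            switches=list(xor_netlist.switches),
            triggers=list(xor_netlist.triggers),
            antisenses=list(xor_netlist.antisenses),
            edges=[Edge("annihilates", a1.name, wrong_target)],
        )
        with pytest.raises(ValueError, match="declared against"):
            net.validate()
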