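# ribologic

Design toolkit and simulator for **RNA-only logic circuits built from
toehold switches**. A toehold switch is a riboregulator whose hairpin
sequesters the ribosome binding site and start codon; a complementary
*trigger* RNA opens it (translation ON), and an *antisense* RNA
complementary to the trigger annihilates it (back to OFF). From these
three species the package compiles Boolean and arithmetic circuits the
way a synthetic biologist would wire them in *E. coli*:

- **NIMPLY** (A AND NOT B): one switch + trigger(A) + antisense(B);
- **OR / XOR**: two orthogonal sensor domains concatenated with a 9-nt
  linker ahead of one reporter; for XOR, each chemical inducer drives one
  arm's trigger *and* the other arm's antisense (IPTG → Lac operator on
  T1 and A2; aTc → Tet operator on T2 and A1);
- **NAND**: the XOR netlist with constitutive trigger promoters;
- **half adder** (SUM = XOR, CARRY = AND), **half subtractor**
  (DIFFERENCE = XOR, BORROW = NIMPLY) and the reversible **Feynman /
  controlled-NOT gate** (P = A, Q = A XOR B) on dual reporters.

The package covers the whole desk workflow: part modelling and FASTA/
GenBank I/O (`ribologic.parts`), trigger/antisense sequence design with
the overhang and bulge rules (`ribologic.design`) — 15-nt single-stranded
overhangs supply the thermodynamic driving force that lets the antisense
out-compete the switch for the trigger, and single-nucleotide junction
bulges interrupt long double-stranded RNA (an RNase III substrate) —
in-silico screening for structure defects, overhang accessibility and
crosstalk (`ribologic.fold`, an internal Nussinov-with-stacking engine),
circuit compilation and inducer wiring (`ribologic.compile`), and truth
table / dose-response prediction with a competitive-hybridization
equilibrium model (`ribologic.simulate`). `ribologic.fixtures` generates
synthetic orthogonal switch libraries so everything is testable without
proprietary part sequences. Energies are model units for rank-ordering
designs, not kcal/mol; see `docs/methods.md` for the model and all
constants.

## Worked example

```python
from ribologic import (FixtureSpec, make_switch_library, LogicSpec,
                       compile_gate, wire_inducers, assign_plasmids, truth_table)

lib = make_switch_library(FixtureSpec(n_switches=2, seed=1))
net = compile_gate(LogicSpec("XOR"), lib, rng_seed=1)
wire_inducers(net, {"IPTG": "A", "aTc": "B"})
assign_plasmids(net)                     # switch: low, triggers: medium, antisenses: high
table = truth_table(net)
print(f"threshold = {table.threshold:.2f}")
print(table.to_frame()[["A", "B", "green_level", "green_call"]].round(2))
```

prints

```
threshold = 21.72
 A  B  green_level  green_call
 0  0         3.38           0
 0  1        85.83           1
 1  0        85.02           1
 1  1         4.62           0
```

The operators land on the canonical cross-wiring
(`{'T1': 'lac', 'A2': 'lac', 'T2': 'tet', 'A1': 'tet'}`): with one
inducer present, that arm's trigger is made while the *other* arm's
trigger is silenced by its induced antisense, so the reporter is high;
with both inducers, both antisenses fire and the output collapses —
XOR. Levels are arbitrary reporter units (basal 1, gain 100); the call
threshold is the geometric mean of a reference BUFFER gate's ON and OFF
levels.

The same workflow is available from the shell:

```bash
ribologic fixtures --n 2 --seed 1 -o lib.fasta
ribologic compile --circuit xor --library lib.fasta --map IPTG=A,aTc=B -o net.json
ribologic screen --netlist net.json -o screen.csv
ribologic simulate --netlist net.json --grid "IPTG=0,0.25,0.5,1 aTc=0,0.25,0.5,1" -o grid.csv
```

## Acceptance script

`scripts/acceptance.py` re-runs the whole pipeline from scratch: it
generates a fresh orthogonal library, compiles XOR, NAND, half adder,
half subtractor and the Feynman gate, wires inducers and plasmid copy
levels, screens every netlist for crosstalk, predicts all 20 truth-table
rows and the XOR inducer dose surface, and writes the results JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
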