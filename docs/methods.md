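# Methods

`ribologic` models RNA-only logic gates built from three kinds of
trans-acting RNA: **toehold switches** (hairpins whose stem sequesters the
ribosome binding site and start codon), **trigger RNAs** (linear RNAs
complementary to a switch's toehold + stem-bottom "sensing domain"; binding
opens the hairpin and restores translation), and **antisense RNAs** (RNAs
complementary to a trigger; hybridization annihilates the trigger and
returns the switch to OFF). A trigger alone implements BUFFER logic; a
trigger plus an antisense implements NIMPLY (A AND NOT B); two orthogonal
NIMPLY arms reading out through one concatenated switch implement XOR;
XOR combined with AND, NIMPLY or BUFFER yields a half adder, half
subtractor, or Feynman (controlled-NOT) gate.

## Energy model and folding engine

All structure and hybridization scores come from a deliberately small
thermodynamic stand-in, not a nearest-neighbour parameter set. Energies
are in arbitrary "units", not kcal/mol; the model's job is to rank-order
designs, and every constant is configurable through `EnergyModel`:

| parameter | default | meaning |
|---|---|---|
| `pair_energy` | GC −3, AU −2, GU −1 | per base pair |
| `stack_bonus` | −0.5 | per pair stacked directly on another |
| `bulge_penalty` | +3 | per unpaired interior nucleotide in a duplex |
| `min_loop` | 3 nt | minimum hairpin loop |
| `duplex_init` | +2 | cost of bringing two strands together |

`fold_mfe` is a Nussinov-style interval dynamic program extended with the
stacking term; `duplex_energy` is an antiparallel alignment DP over purely
intermolecular pairs with stacking and interior-loop terms. Both are exact
under the model — the test suite checks them against exhaustive
enumeration on hundreds of short random instances — and deterministic
(ties prefer pairing the smallest 5' index with its smallest admissible
partner). Ensemble defect is approximated by the per-base distance between
the MFE structure and the design target; no partition function is
computed. Pseudoknots, temperature dependence and kinetics are out of
scope.

A consequence of the per-nucleotide bulge penalty: a single-nucleotide
bulge costs +3 plus a lost stack, so a full-match duplex always beats its
bulged counterpart by ≥ 3.5 units — the model's version of the bulge
acting as an energy barrier, and the reason bulges also break the long
double-stranded runs that `long_duplex_check` flags as RNase III
substrates (default `max_stem` 20 bp; the threshold is a chosen constant,
the design intent is only "no long uninterrupted dsRNA").

## Design rules

A trigger core is the reverse complement of toehold + stem-bottom (12 + 18
nt with the default geometry, so 30 nt). Overhangs (default 15 nt) extend
the ends; the junction bulge base is chosen as the alphabetically first
base that cannot pair — Watson-Crick or GU wobble — with the nucleotide it
faces across the cognate duplex (the partner of the neighbouring core
base). The antisense core reverse-complements the trigger core, and the
antisense overhangs reverse-complement the trigger overhangs: the extra
antisense–trigger pairing beyond what the switch can reach is the
thermodynamic driving force that tips the competition. Two presets bundle
the two design generations: `initial` (15-nt overhangs on both ends,
junction bulges everywhere) and `optimized` (trigger 3'-only overhang,
antisense 5'-only overhang, bulge-free "full-match" antisense), the
latter reflecting which variants performed best.

Overhang sequences are found by seeded multi-start search: rejection
sampling over several base-composition profiles, then hill climbing that
mutates overhang bases which come out paired in the predicted MFE. A
candidate is accepted when ≥ 80% of its bases are unpaired in the MFE of
the assembled molecule (`accessibility_threshold`, configurable) and its
duplex energy against every avoid-list sequence stays within the
crosstalk bound (default 6 units, meant for short elements). The search is
deterministic per seed and raises a `DesignSearchError` carrying the best
candidate when the budget (default 10 000 structure evaluations) runs out.

## Compilation, wiring, copy levels

The compiler records, for every trigger and antisense, which logical input
bit drives it; `wire_inducers` then binds inducers to operators (IPTG →
lac, aTc → tet) so that for an XOR each input induces one arm's trigger
and the *other* arm's antisense — the canonical cross-wiring. NAND is the
XOR netlist with both triggers made constitutive. The AND part is modelled
as a black-box two-sensor switch requiring both triggers (its split-trigger
internals are not designed here). Concatenated sensors are joined by a
9-nt linker searched for ≥ 50% accessibility in the assembled switch.
`assign_plasmids` applies the low/medium/high copy convention (switch 1×,
trigger 3×, antisense 9× relative transcript abundance by default). The
half subtractor computes A − B with BORROW = (NOT A) AND B; the Feynman
gate reuses the half-subtractor layout with a bare (overhang-free) trigger
on the BUFFER arm, and which library switch hosts that arm is exposed as
`buffer_switch_index`.

Compilation is deterministic given library order and seed. Because
overhang draws are independent across arms, two arms occasionally collide
(an antisense would cross-react with the other arm's trigger); the
compiler then re-derives with a deterministically shifted stream (up to 5
attempts) before accepting a flagged design with a warning.

## Crosstalk screening

`crosstalk_matrix` flags any non-cognate pair whose duplex magnitude
exceeds an absolute threshold. At the whole-species level
(`screen_netlist`) the default bar is *relative*: a non-cognate
interaction is flagged when it comes within 0.5× of the weakest intended
duplex. Full-length species (45–80 nt) under this energy model always
share short chained pairing runs worth −10 to −25 units, so no useful
absolute bar exists; orthogonality is the separation between intended
(≈ −85 to −155) and unintended binding. Antisense-vs-own-switch pairs are
exempt by construction: the antisense contains the stem-bottom sequence,
and a two-strand duplex score cannot see that the closed hairpin occludes
it — a known limitation of screening without intramolecular competition.

## Equilibrium simulation

Per input condition: transcript abundance = copy scale × (leak + (1 −
leak)·Hill(c)), with Hill K 0.25 (relative units), coefficient 2 and leak
0.02 — invented, documented constants with no claim of matching cellular
numbers. The arabinose-induced T7 polymerase is a global on/off master
switch, default on. All declared interactions then equilibrate as
simultaneous bimolecular bindings (S + T ⇌ S·T, T + A ⇌ T·A) with
K = exp(−ΔG / 30). Trigger–sensor ΔG subtracts the hairpin stem energy
(the trigger must open the stem), trigger–antisense ΔG does not — that
asymmetry, plus the overhang pairing, is why the induced antisense wins.
The scale 30 places cognate binding in the strong regime (K·total ≈ 10–60)
while leak-level triggers stay sub-saturating. The solver is a damped
fixed-point iteration on the free concentrations, checked against the
closed-form two-species quadratic and required to conserve mass to 1e−9
relative. Equilibrium subsumes both proposed antisense mechanisms (strand
displacement of the bound trigger vs. capture of the free trigger): they
share a final state, so the model is agnostic about the pathway.

Readout: reporter level = basal + gain × (fraction of switch molecules
with ≥ 1 triggered sensor) for OR-type switches, or all sensors for AND
parts, treating sensors as independent sites. Boolean calls threshold at
the geometric mean of a reference BUFFER gate's ON and OFF levels
(computed from the netlist's own first activation edge); an absolute
override is available. The digitality of the XOR dose surface is
summarized by max(single-inducer edges) / max(corners) with a default
acceptance ratio of 3.

## Synthetic libraries (what a green test does and does not establish)

`make_switch_library` generates stand-ins for published orthogonal switch
collections; the real part sequences are not reproduced. Domains are drawn
so that 5-mer vocabularies are disjoint across the library (bounding
Watson-Crick complementary runs between any trigger and any non-cognate
sensing domain at 4 bp), energy-screened to keep non-cognate duplexes
weaker than 15 units, and screened for overhang designability (a core
that buries every candidate overhang is rejected — the generator's
counterpart of keeping only workable design candidates). Loops carry the
RBS exactly once by construction (A/C flanks cannot recreate the G-rich
motif). Decoy RNAs are searched the same way against the whole library.

Green tests on these libraries establish that the *pipeline logic* —
design rules, netlist wiring, competitive equilibrium, thresholding — is
internally consistent under the stated energy model. They do not
establish anything about real cellular behaviour: no RNA degradation,
ribosome traffic, transcriptional context or measured fold-changes are
modelled, and published in-vivo fluorescence ratios are explicitly not
reproduction targets.

## Numerical choices and degenerate inputs

Zero-length overhangs return the empty string; `expand_loop(switch, 0)` is
the identity; empty accessibility regions, empty species lists, negative
concentrations and non-ACGU characters raise immediately with the
offending name. DNA input (T) is transliterated to RNA with a logged
notice. All coordinates are 0-based half-open; all sequences 5'→3'.
Floating-point boundaries in the accessibility acceptance test are guarded
(15 × 0.2 is not exactly 3). Solver non-convergence raises with the
residual rather than returning a partial state.
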