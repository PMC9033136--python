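"""Synthetic orthogonal switch libraries and decoy RNAs.

Real part libraries come from published collections of characterized
toehold switches; their exact sequences are not bundled here.  This module
generates structurally faithful stand-ins so the whole pipeline — design,
compilation, screening, simulation — is exercisable without external data.

Orthogonality scheme ``disjoint-kmer``: every sensing domain is drawn so
that its k-mer vocabulary (default k=5) is disjoint from every other
domain's, within and across parts.  Because a complementary run between
trigger_i and domain_j corresponds exactly to a common substring of
domain_i and domain_j, disjoint 5-mer vocabularies cap Watson-Crick
complementary runs at 4 bp; candidates are additionally verified against
the energy model so chained short runs stay under the crosstalk threshold.
``random-screened`` drops the k-mer guarantee and relies on the energy
screen alone (a stress test for the screening machinery).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import DesignSearchError, generate_overhang
from .fold import DEFAULT_MODEL, EnergyModel, duplex_energy
from .parts import DEFAULT_RBS, SwitchPart
from .seqs import reverse_complement

__all__ = ["FixtureSpec", "GenerationError", "DecoyRNA", "make_switch_library", "make_decoy"]


class GenerationError(RuntimeError):
    """The sampler could not satisfy the orthogonality constraints."""


@dataclass(frozen=True)
class FixtureSpec:
    """Shape and determinism knobs of a synthetic library.

    The default geometry (12-nt toehold, 18-bp stem, 11-nt loop carrying
    the RBS, 21-nt post-stem linker) follows the second-generation switch
    template; ``crosstalk_threshold`` is the orthogonality bar in energy
    units — non-cognate trigger/switch duplexes must stay weaker than this
    (cognate duplexes score around -85 to -95 under the default model).
    """

    n_switches: int = 3
    toehold_len: int = 12
    stem_len: int = 18
    loop_len: int = 11
    linker_len: int = 21
    orthogonality_scheme: str = "disjoint-kmer"
    seed: int = 0
    crosstalk_threshold: float = 15.0
    kmer: int = 5
    max_iter: int = 50_000
    rbs: str = DEFAULT_RBS
    #: reject domains whose trigger cannot carry an accessible 15-nt
    #: overhang on either end — mirrors selecting designable candidates
    screen_designability: bool = True

    def __post_init__(self) -> None:
        if self.n_switches < 1:
            raise ValueError("n_switches must be >= 1")
        if self.orthogonality_scheme not in ("disjoint-kmer", "random-screened"):
            raise ValueError(f"unknown scheme {self.orthogonality_scheme!r}")
        if self.loop_len < len(self.rbs):
            raise ValueError("loop too short to hold the RBS motif")
        if self.toehold_len < 1 or self.stem_len < 4 or self.linker_len < 4:
            raise ValueError("segment lengths outside template bounds")


_BASES = np.array(list("ACGU"))
_AC = np.array(list("AC"))


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _make_loop(spec: FixtureSpec, rng: np.random.Generator) -> str:
    """Loop of the requested length containing the RBS exactly once.

    A/C flanks cannot recreate the G-rich RBS motif, so single occurrence
    is guaranteed by construction.
    """
    pad = spec.loop_len - len(spec.rbs)
    left = "".join(rng.choice(_AC, pad // 2))
    right = "".join(rng.choice(_AC, pad - pad // 2))
    return left + spec.rbs + right


def _make_linker(spec: FixtureSpec, rng: np.random.Generator) -> str:
    # post-stem region: start codon first, A/C filler after
    return "AUG" + "".join(rng.choice(_AC, spec.linker_len - 3))


def _designable(domain: str, model: EnergyModel, rng: np.random.Generator) -> bool:
    """Can this domain's trigger carry accessible overhangs on both ends?

    Some cores pair any appended 15-mer well enough to bury it; such parts
    would fail downstream trigger design, so they are rejected here — the
    in-silico counterpart of keeping only the best design candidates.
    """
    core = reverse_complement(domain)
    for side in ("3", "5"):
        try:
            generate_overhang(15, core, model, rng, side=side, max_iter=1_500)
        except DesignSearchError:
            return False
    return True


def make_switch_library(
    spec: FixtureSpec = FixtureSpec(),
    model: EnergyModel = DEFAULT_MODEL,
) -> list[SwitchPart]:
    """Generate ``n_switches`` mutually orthogonal switch parts.

    Deterministic per seed.  Every part passes
    :func:`ribologic.parts.validate_switch`, and every non-cognate
    trigger-sensing-domain duplex is weaker than ``crosstalk_threshold``.
    """
    rng = np.random.default_rng(spec.seed)
    domain_len = spec.toehold_len + spec.stem_len
    domains: list[str] = []
    used_kmers: set[str] = set()

    attempts = 0
    while len(domains) < spec.n_switches:
        attempts += 1
        if attempts > spec.max_iter:
            raise GenerationError(
                f"could not find {spec.n_switches} orthogonal domains within "
                f"{spec.max_iter} draws at threshold {spec.crosstalk_threshold}; "
                "widen the threshold, shorten the domains, or spread the "
                "alphabet (fewer switches per library)"
            )
        cand = "".join(rng.choice(_BASES, domain_len))
        if spec.orthogonality_scheme == "disjoint-kmer":
            kms = _kmers(cand, spec.kmer)
            if len(kms) != domain_len - spec.kmer + 1:  # internal repeat
                continue
            if kms & used_kmers:
                continue
        trig = reverse_complement(cand)
        ok = True
        for d in domains:
            if abs(duplex_energy(trig, d, model).energy) > spec.crosstalk_threshold:
                ok = False
                break
            if abs(duplex_energy(reverse_complement(d), cand, model).energy) > spec.crosstalk_threshold:
                ok = False
                break
        if not ok:
            continue
        if spec.screen_designability and not _designable(cand, model, rng):
            continue
        domains.append(cand)
        if spec.orthogonality_scheme == "disjoint-kmer":
            used_kmers |= _kmers(cand, spec.kmer)

    parts = []
    for k, dom in enumerate(domains, start=1):
        toehold = dom[: spec.toehold_len]
        stem_bottom = dom[spec.toehold_len :]
        parts.append(
            SwitchPart(
                name=f"sw{k}",
                toehold_seq=toehold,
                stem_bottom=stem_bottom,
                stem_top=reverse_complement(stem_bottom),
                loop_seq=_make_loop(spec, rng),
                start_codon_offset=0,
                linker_seq=_make_linker(spec, rng),
                rbs=spec.rbs,
            )
        )
    return parts


@dataclass(frozen=True)
class DecoyRNA:
    """An RNA that interacts with nothing in a library (negative control)."""

    name: str
    seq: str


def make_decoy(
    library: list,
    seed: int = 0,
    model: EnergyModel = DEFAULT_MODEL,
    *,
    length: int = 30,
    threshold: float = 15.0,
    max_iter: int = 5_000,
) -> DecoyRNA:
    """Search for a decoy whose duplex energy against every library species
    (switches, triggers, antisenses alike) stays weaker than ``threshold``.

    A/C-rich draws keep candidates unstructured and weakly pairing.
    """
    if not library:
        raise ValueError("library must be non-empty")
    if length < 1:
        raise ValueError("decoy length must be >= 1")
    rng = np.random.default_rng(seed)
    targets = [p.seq for p in library]
    best, best_worst = None, float("inf")
    for _ in range(max_iter):
        cand = "".join(rng.choice(_BASES, length, p=[0.45, 0.45, 0.05, 0.05]))
        worst = max(abs(duplex_energy(cand, t, model).energy) for t in targets)
        if worst < best_worst:
            best, best_worst = cand, worst
        if worst <= threshold:
            return DecoyRNA(name="decoy", seq=cand)
    raise GenerationError(
        f"no decoy of length {length} stayed under |dG| <= {threshold} "
        f"against all {len(targets)} species (best worst-case {best_worst:.1f}: {best})"
    )
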