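"""Independent brute-force oracles for the folding and duplex engines.

These enumerate every admissible structure/pairing explicitly and score it
with the same closed-form energy functions the engine documents; they share
no code path with the dynamic programs they check.
"""

from __future__ import annotations

from ribologic.fold import EnergyModel, duplex_pair_energy, structure_energy


def enumerate_structures(seq: str, model: EnergyModel):
    """All pseudoknot-free structures of ``seq`` respecting min_loop."""

    def rec(positions: tuple[int, ...]):
        if not positions:
            yield frozenset()
            return
        i = positions[0]
        yield from rec(positions[1:])  # i unpaired
        for jx in range(1, len(positions)):
            j = positions[jx]
            if j - i > model.min_loop and model.pair(seq[i], seq[j]) is not None:
                inner = positions[1:jx]
                outer = positions[jx + 1 :]
                for s_in in rec(inner):
                    for s_out in rec(outer):
                        yield s_in | s_out | {(i, j)}

    yield from rec(tuple(range(len(seq))))


def brute_force_mfe(seq: str, model: EnergyModel) -> float:
    best = 0.0
    for struct in enumerate_structures(seq, model):
        if struct:
            best = min(best, structure_energy(seq, struct, model))
    return best


def brute_force_duplex(a: str, b: str, model: EnergyModel) -> float:
    """Minimum over all antiparallel intermolecular pairings (monotone
    matchings of positions in ``a`` against decreasing positions in ``b``)."""
    best = 0.0

    def rec(i: int, j_max: int, pairs: list[tuple[int, int]]):
        nonlocal best
        if pairs:
            best = min(best, duplex_pair_energy(a, b, pairs, model))
        if i >= len(a):
            return
        rec(i + 1, j_max, pairs)
        for j in range(j_max):
            if model.pair(a[i], b[j]) is not None:
                rec(i + 1, j, pairs + [(i, j)])

    rec(0, len(b), [])
    return best
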