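"""Internal RNA structure and hybridization engine.

This is a deliberately lightweight thermodynamic stand-in for a full
nearest-neighbour package: secondary structures are scored with per-pair
energies (GC/AU/GU), a bonus for stacked adjacent pairs, and a per-nucleotide
penalty for interior bulges in duplexes.  Energies are in arbitrary "units",
not kcal/mol; the model is meant to rank-order designs (is the toehold open,
does the antisense out-compete the switch, is there crosstalk), not to
reproduce measured free energies.

Two optimizers are provided:

* :func:`fold_mfe` — single-strand minimum-energy nested structure via
  Nussinov-style dynamic programming extended with stacking terms.
* :func:`duplex_energy` — best purely intermolecular pairing of two strands
  (an antiparallel alignment), with stacking and interior-bulge terms.

Both are exact under the model; tests compare them against exhaustive
enumeration on short sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .seqs import AlphabetError, RNA_ALPHABET

__all__ = [
    "EnergyModel",
    "SecondaryStructure",
    "DuplexResult",
    "DuplexRun",
    "CrosstalkResult",
    "fold_mfe",
    "duplex_energy",
    "defect_score",
    "accessibility",
    "paired_fraction",
    "crosstalk_matrix",
    "long_duplex_check",
]


@dataclass(frozen=True)
class EnergyModel:
    """Pairing/stacking/loop parameters for folding and hybridization.

    Attributes
    ----------
    pair_energy:
        Energy per base pair by pair class (``GC``, ``AU``, ``GU``); all < 0.
    stack_bonus:
        Extra energy for each pair stacked directly on another (< 0 favours
        helices over isolated pairs).
    bulge_penalty:
        Penalty per unpaired interior nucleotide inside a duplex (>= 0);
        this is what makes a single-nucleotide bulge an energy barrier.
    min_loop:
        Minimum number of unpaired nucleotides closed by a hairpin pair.
    duplex_init:
        Initiation cost for bringing two strands together (>= 0).
    """

    pair_energy: dict[str, float] = field(
        default_factory=lambda: {"GC": -3.0, "AU": -2.0, "GU": -1.0}
    )
    stack_bonus: float = -0.5
    bulge_penalty: float = 3.0
    min_loop: int = 3
    duplex_init: float = 2.0

    def __post_init__(self) -> None:
        if any(v >= 0 for v in self.pair_energy.values()):
            raise ValueError("pair energies must be negative")
        if self.bulge_penalty < 0 or self.duplex_init < 0:
            raise ValueError("penalties must be non-negative")
        if self.min_loop < 3:
            raise ValueError("min_loop must be >= 3")

    def pair(self, a: str, b: str) -> float | None:
        """Energy of pairing bases ``a`` and ``b``; None if they cannot pair."""
        key = "".join(sorted((a, b)))
        if key in ("CG", "GC"):
            return self.pair_energy["GC"]
        if key in ("AU", "UA"):
            return self.pair_energy["AU"]
        if key in ("GU", "UG"):
            return self.pair_energy["GU"]
        return None


DEFAULT_MODEL = EnergyModel()


@dataclass(frozen=True)
class SecondaryStructure:
    """A pseudoknot-free set of base pairs ``(i, j)`` with ``i < j``."""

    length: int
    pairs: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        seen: set[int] = set()
        plist = sorted(self.pairs)
        for i, j in plist:
            if not (0 <= i < j < self.length):
                raise ValueError(f"pair {(i, j)} out of range for length {self.length}")
            if i in seen or j in seen:
                raise ValueError(f"base in more than one pair near {(i, j)}")
            seen.update((i, j))
        for i, j in plist:
            for k, l in plist:
                if i < k < j < l:
                    raise ValueError(f"pseudoknot: {(i, j)} crosses {(k, l)}")

    def partner(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for i, j in self.pairs:
            out[i] = j
            out[j] = i
        return out

    def dot_bracket(self) -> str:
        chars = ["."] * self.length
        for i, j in self.pairs:
            chars[i] = "("
            chars[j] = ")"
        return "".join(chars)

    def __len__(self) -> int:
        return self.length


def _check_seq(seq: str, name: str = "sequence") -> None:
    if not seq:
        raise ValueError(f"{name} is empty")
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise AlphabetError(f"{name}: invalid characters {sorted(bad)}")


def structure_energy(seq: str, pairs: Iterable[tuple[int, int]], model: EnergyModel) -> float:
    """Score a nested structure: pair terms plus stacking of adjacent pairs."""
    pset = set(pairs)
    total = 0.0
    for i, j in pset:
        e = model.pair(seq[i], seq[j])
        if e is None:
            raise ValueError(f"bases {i},{j} cannot pair")
        total += e
        if (i + 1, j - 1) in pset:
            total += model.stack_bonus
    return total


def fold_mfe(seq: str, model: EnergyModel = DEFAULT_MODEL) -> tuple[SecondaryStructure, float]:
    """Minimum-energy nested secondary structure of a single strand.

    Dynamic programming over intervals; ties broken toward pairing the
    smallest 5' index with the smallest admissible partner, so results are
    deterministic.  Sequences with no admissible pair return the open chain
    at energy 0.
    """
    _check_seq(seq)
    n = len(seq)
    NEG = float("-inf")

    # V[i][j]: best energy with (i, j) paired; W[i][j]: best over interval.
    V = [[NEG] * n for _ in range(n)]
    W = [[0.0] * (n + 1) for _ in range(n + 1)]

    def w(i: int, j: int) -> float:
        return W[i][j + 1] if i <= j else 0.0

    for span in range(model.min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            pe = model.pair(seq[i], seq[j])
            if pe is not None:
                best = w(i + 1, j - 1)
                if V[i + 1][j - 1] != NEG:
                    best = min(best, V[i + 1][j - 1] + model.stack_bonus)
                V[i][j] = pe + best
            # W recurrence
            best = w(i + 1, j)
            for k in range(i + model.min_loop + 1, j + 1):
                if V[i][k] != NEG:
                    cand = V[i][k] + w(k + 1, j)
                    if cand < best:
                        best = cand
            W[i][j + 1] = best

    pairs: set[tuple[int, int]] = set()

    def trace_w(i: int, j: int) -> None:
        while i <= j:
            target = w(i, j)
            chosen = False
            if target < -1e-12:
                for k in range(i + model.min_loop + 1, j + 1):
                    if V[i][k] != NEG and abs(V[i][k] + w(k + 1, j) - target) < 1e-9:
                        trace_v(i, k)
                        i = k + 1
                        chosen = True
                        break
            if not chosen:
                i += 1

    def trace_v(i: int, j: int) -> None:
        pairs.add((i, j))
        pe = model.pair(seq[i], seq[j])
        assert pe is not None
        inner = V[i][j] - pe
        if (
            i + 1 <= j - 1
            and V[i + 1][j - 1] != NEG
            and abs(V[i + 1][j - 1] + model.stack_bonus - inner) < 1e-12
            and V[i + 1][j - 1] + model.stack_bonus <= w(i + 1, j - 1) + 1e-12
        ):
            trace_v(i + 1, j - 1)
        else:
            trace_w(i + 1, j - 1)

    energy = w(0, n - 1)
    if energy < 0:
        trace_w(0, n - 1)
    struct = SecondaryStructure(length=n, pairs=frozenset(pairs))
    # traceback must reproduce the DP optimum
    assert abs(structure_energy(seq, struct.pairs, model) - energy) < 1e-9
    return struct, energy


@dataclass(frozen=True)
class DuplexResult:
    """Best intermolecular pairing of two strands.

    ``pairs`` holds (i, j): position i of strand A pairs position j of
    strand B, antiparallel (i increasing, j decreasing).
    """

    pairs: tuple[tuple[int, int], ...]
    energy: float

    def __iter__(self):  # allow  (pairs, energy) unpacking
        yield self.pairs
        yield self.energy


def duplex_pair_energy(
    a: str, b: str, pairs: Sequence[tuple[int, int]], model: EnergyModel
) -> float:
    """Score an explicit intermolecular pairing (oracle-friendly closed form)."""
    if not pairs:
        return 0.0
    total = model.duplex_init
    prev = None
    for i, j in sorted(pairs):
        e = model.pair(a[i], b[j])
        if e is None:
            raise ValueError(f"bases a[{i}]={a[i]}, b[{j}]={b[j]} cannot pair")
        total += e
        if prev is not None:
            pi, pj = prev
            if j >= pj:
                raise ValueError("pairs must be antiparallel (j strictly decreasing)")
            if i == pi + 1 and j == pj - 1:
                total += model.stack_bonus
            else:
                total += model.bulge_penalty * ((i - pi - 1) + (pj - j - 1))
        prev = (i, j)
    return total


def duplex_energy(
    a: str, b: str, model: EnergyModel = DEFAULT_MODEL
) -> DuplexResult:
    """Best purely intermolecular pairing energy of strands ``a`` and ``b``.

    The optimum includes the initiation cost ``duplex_init``, per-pair and
    stacking terms, and ``bulge_penalty`` per unpaired interior nucleotide.
    If no pairing beats the open state, the empty duplex (energy 0) is
    returned — weak partners simply do not hybridize.
    """
    _check_seq(a, "a")
    _check_seq(b, "b")
    n, m = len(a), len(b)
    INF = float("inf")

    # M[i][j]: best pairing-set energy (no init) whose last pair is (i, j).
    # H[i][j]: min over p<=i, q>=j of M[p][q] + bulge*((i-p)+(q-j)).
    M = [[INF] * m for _ in range(n)]
    H = [[INF] * m for _ in range(n)]
    back: dict[tuple[int, int], tuple[str, tuple[int, int] | None]] = {}
    hback: dict[tuple[int, int], str] = {}
    bp = model.bulge_penalty

    for i in range(n):
        for j in range(m - 1, -1, -1):
            pe = model.pair(a[i], b[j])
            if pe is not None:
                best, how = 0.0, ("start", None)
                if i > 0 and j < m - 1:
                    if M[i - 1][j + 1] + model.stack_bonus < best - 1e-12:
                        best = M[i - 1][j + 1] + model.stack_bonus
                        how = ("stack", (i - 1, j + 1))
                    if H[i - 1][j + 1] < best - 1e-12:
                        best = H[i - 1][j + 1]
                        how = ("loop", (i - 1, j + 1))
                M[i][j] = pe + best
                back[(i, j)] = how
            # H recurrence (after M[i][j] is known)
            cands = [(M[i][j], "here")]
            if i > 0:
                cands.append((H[i - 1][j] + bp, "up"))
            if j < m - 1:
                cands.append((H[i][j + 1] + bp, "right"))
            hbest, hhow = min(cands, key=lambda t: t[0])
            H[i][j] = hbest
            hback[(i, j)] = hhow

    best_e, best_ij = INF, None
    for i in range(n):
        for j in range(m):
            if M[i][j] < best_e - 1e-12:
                best_e, best_ij = M[i][j], (i, j)

    if best_ij is None or best_e + model.duplex_init >= -1e-12:
        return DuplexResult(pairs=(), energy=0.0)

    # traceback
    pairs: list[tuple[int, int]] = []
    ij: tuple[int, int] | None = best_ij
    while ij is not None:
        pairs.append(ij)
        how, prev = back[ij]
        if how == "start":
            ij = None
        elif how == "stack":
            ij = prev
        else:  # interior loop: walk H pointers to the contributing M cell
            hi, hj = prev  # type: ignore[misc]
            while hback[(hi, hj)] != "here":
                if hback[(hi, hj)] == "up":
                    hi -= 1
                else:
                    hj += 1
            ij = (hi, hj)
    pairs.sort()
    energy = best_e + model.duplex_init
    assert abs(duplex_pair_energy(a, b, pairs, model) - energy) < 1e-9
    return DuplexResult(pairs=tuple(pairs), energy=energy)


def paired_fraction(seq: str, model: EnergyModel = DEFAULT_MODEL) -> float:
    struct, _ = fold_mfe(seq, model)
    return 2 * len(struct.pairs) / len(seq)


def defect_score(
    seq: str, target: SecondaryStructure, model: EnergyModel = DEFAULT_MODEL
) -> float:
    """Normalized per-base distance between the MFE structure and a target.

    A base counts as defective when its pairing status (partner index, or
    unpaired) differs between prediction and target; the score is the
    defective fraction, in [0, 1].  0 means the MFE structure equals the
    target exactly; this is a cheap surrogate for a full ensemble defect.
    """
    if target.length != len(seq):
        raise ValueError("target length does not match sequence")
    mfe, _ = fold_mfe(seq, model)
    got = mfe.partner()
    want = target.partner()
    bad = sum(1 for i in range(len(seq)) if got.get(i) != want.get(i))
    return bad / len(seq)


def accessibility(
    seq: str, region: tuple[int, int], model: EnergyModel = DEFAULT_MODEL
) -> float:
    """Fraction of bases in ``region`` (0-based, half-open) unpaired at MFE."""
    start, end = region
    if not (0 <= start < end <= len(seq)):
        raise ValueError(f"empty or out-of-range region {region} for length {len(seq)}")
    struct, _ = fold_mfe(seq, model)
    partner = struct.partner()
    unpaired = sum(1 for i in range(start, end) if i not in partner)
    return unpaired / (end - start)


@dataclass
class CrosstalkResult:
    """Pairwise duplex energies with orthogonality flags.

    ``flags`` marks non-cognate pairs whose interaction magnitude exceeds
    the threshold; cognate pairs are exempt by definition.
    """

    energies: pd.DataFrame
    flags: pd.DataFrame
    threshold: float

    @property
    def ok(self) -> bool:
        return not self.flags.to_numpy().any()

    def flagged_pairs(self) -> list[tuple[str, str]]:
        out = []
        for an in self.flags.index:
            for bn in self.flags.columns:
                if self.flags.at[an, bn]:
                    out.append((an, bn))
        return out


def _named(species: Sequence) -> list[tuple[str, str]]:
    out = []
    for k, sp in enumerate(species):
        if isinstance(sp, str):
            out.append((f"sp{k}", sp))
        elif isinstance(sp, tuple):
            out.append((sp[0], sp[1]))
        else:  # objects with .name / .seq (parts types)
            out.append((sp.name, sp.seq))
    return out


def crosstalk_matrix(
    species_a: Sequence,
    species_b: Sequence,
    model: EnergyModel = DEFAULT_MODEL,
    threshold: float = 6.0,
    cognate: set[tuple[str, str]] | None = None,
) -> CrosstalkResult:
    """All-against-all duplex energies between two species lists.

    Species may be raw strings, ``(name, seq)`` tuples, or objects exposing
    ``.name``/``.seq``.  ``cognate`` names the intended interactions (by
    name pair); when omitted, same-index pairs are treated as cognate.
    A non-cognate pair is flagged when ``|energy| > threshold``.
    """
    if not species_a or not species_b:
        raise ValueError("species lists must be non-empty")
    na = _named(species_a)
    nb = _named(species_b)
    if cognate is None:
        cognate = {
            (na[k][0], nb[k][0]) for k in range(min(len(na), len(nb)))
        }
    idx = [n for n, _ in na]
    cols = [n for n, _ in nb]
    energies = pd.DataFrame(0.0, index=idx, columns=cols)
    flags = pd.DataFrame(False, index=idx, columns=cols)
    for an, aseq in na:
        for bn, bseq in nb:
            e = duplex_energy(aseq, bseq, model).energy
            energies.at[an, bn] = e
            if (an, bn) not in cognate and abs(e) > threshold:
                flags.at[an, bn] = True
    return CrosstalkResult(energies=energies, flags=flags, threshold=threshold)


@dataclass(frozen=True)
class DuplexRun:
    """A contiguous stretch of stacked intermolecular pairs."""

    length: int
    a_start: int
    a_end: int  # half-open
    b_start: int
    b_end: int  # half-open


def duplex_runs(pairs: Sequence[tuple[int, int]]) -> list[DuplexRun]:
    """Maximal runs of contiguous (stacked) pairs in an antiparallel duplex."""
    runs: list[DuplexRun] = []
    spairs = sorted(pairs)
    k = 0
    while k < len(spairs):
        start = k
        while (
            k + 1 < len(spairs)
            and spairs[k + 1][0] == spairs[k][0] + 1
            and spairs[k + 1][1] == spairs[k][1] - 1
        ):
            k += 1
        i0, j0 = spairs[start]
        i1, j1 = spairs[k]
        runs.append(
            DuplexRun(
                length=k - start + 1,
                a_start=i0,
                a_end=i1 + 1,
                b_start=j1,
                b_end=j0 + 1,
            )
        )
        k += 1
    return runs


def long_duplex_check(
    a: str,
    b: str,
    model: EnergyModel = DEFAULT_MODEL,
    max_stem: int = 20,
) -> list[DuplexRun]:
    """Flag contiguous duplex stretches long enough to attract RNase III.

    Long uninterrupted double-stranded RNA is a degradation substrate in
    E. coli; designs avoid it by interrupting duplexes with bulges.  Returns
    the runs in the optimal duplex longer than ``max_stem`` base pairs
    (empty list = pass); a bulge breaks a run.
    """
    res = duplex_energy(a, b, model)
    return [r for r in duplex_runs(res.pairs) if r.length > max_stem]
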