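"""Derive trigger and antisense RNAs from switch parts.

The design rules implemented here:

* a trigger core is the reverse complement of the switch sensing domain
  (toehold + stem-bottom), so trigger binding opens the hairpin;
* an antisense core is the reverse complement of its trigger core;
* single-stranded overhangs (default 15 nt) extend either or both ends and
  supply the thermodynamic driving force that lets the antisense out-compete
  the switch for the trigger;
* an optional single-nucleotide bulge sits at each overhang/core junction —
  it interrupts the long double-stranded region (an RNase III substrate)
  and acts as an energy barrier to strand displacement.

Two named presets capture the two design generations: ``initial`` puts
overhangs on both ends with junction bulges on triggers and antisenses;
``optimized`` uses a 3'-only trigger overhang and a 5'-only, bulge-free
("full match") antisense overhang, which showed the best performance.

Overhang sequences are found by seeded rejection sampling, scored first for
accessibility (the overhang must stay single-stranded in the predicted MFE
of the assembled molecule) and then for crosstalk against an avoid-list.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .fold import DEFAULT_MODEL, EnergyModel, duplex_energy, fold_mfe
from .parts import AntisenseRNA, SwitchPart, TriggerRNA
from .seqs import nonpairing_base, reverse_complement

__all__ = [
    "DesignConfig",
    "DesignSearchError",
    "preset",
    "derive_trigger",
    "derive_antisense",
    "generate_overhang",
    "expand_loop",
]

OVERHANG_MODES = ("both", "five_prime_only", "three_prime_only", "none")


class DesignSearchError(RuntimeError):
    """Sequence search exhausted its iteration budget.

    Carries the best candidate seen so far (``best`` / ``best_score``) so a
    caller can inspect how close the search got.
    """

    def __init__(self, message: str, best: str | None = None, best_score: float | None = None):
        super().__init__(message)
        self.best = best
        self.best_score = best_score


@dataclass(frozen=True)
class DesignConfig:
    """Knobs of the overhang/bulge/loop design space.

    ``overhang_mode`` places the extended overhang(s); ``bulge`` controls the
    single-nucleotide junction bulge; ``loop_expansion`` lengthens the switch
    hairpin loop before triggers are derived.  Thresholds govern the
    rejection-sampling search for overhang sequences.
    """

    overhang_mode: str = "both"
    overhang_len: int = 15
    bulge: str = "single_nt"  # or "none"
    loop_expansion: int = 0
    rng_seed: int = 0
    accessibility_threshold: float = 0.8
    crosstalk_threshold: float = 6.0
    max_iter: int = 10_000

    def __post_init__(self) -> None:
        if self.overhang_mode not in OVERHANG_MODES:
            raise ValueError(f"unknown overhang_mode {self.overhang_mode!r}")
        if self.bulge not in ("single_nt", "none"):
            raise ValueError(f"unknown bulge mode {self.bulge!r}")
        if self.overhang_len < 0 or self.loop_expansion < 0:
            raise ValueError("overhang_len and loop_expansion must be >= 0")

    @property
    def has5(self) -> bool:
        return self.overhang_mode in ("both", "five_prime_only") and self.overhang_len > 0

    @property
    def has3(self) -> bool:
        return self.overhang_mode in ("both", "three_prime_only") and self.overhang_len > 0


def preset(name: str, rng_seed: int = 0) -> dict[str, DesignConfig]:
    """Named design generations: ``initial`` or ``optimized``.

    Returns configs keyed ``trigger`` and ``antisense``.
    """
    if name == "initial":
        return {
            "trigger": DesignConfig(overhang_mode="both", bulge="single_nt", rng_seed=rng_seed),
            "antisense": DesignConfig(overhang_mode="both", bulge="single_nt", rng_seed=rng_seed),
        }
    if name == "optimized":
        return {
            "trigger": DesignConfig(
                overhang_mode="three_prime_only", bulge="single_nt", rng_seed=rng_seed
            ),
            "antisense": DesignConfig(
                overhang_mode="five_prime_only", bulge="none", rng_seed=rng_seed
            ),
        }
    raise ValueError(f"unknown preset {name!r} (expected 'initial' or 'optimized')")


# A/C-biased draws: A and C cannot pair with each other, so candidates start
# out unstructured and usually clear the accessibility screen quickly.  The
# search rotates through several compositions because the best choice
# depends on the context sequence (an A/C overhang is useless next to a
# G/U-rich core stretch).
_BASES = np.array(list("ACGU"))
_WEIGHTS = np.array([0.4, 0.4, 0.1, 0.1])
_PROFILES = (
    np.array([0.40, 0.40, 0.10, 0.10]),  # A/C-rich
    np.array([0.25, 0.25, 0.25, 0.25]),  # uniform
    np.array([0.40, 0.10, 0.40, 0.10]),  # A/G-rich
    np.array([0.10, 0.40, 0.10, 0.40]),  # C/U-rich
    np.array([0.10, 0.10, 0.40, 0.40]),  # G/U-rich
)


def _draw(rng: np.random.Generator, length: int, profile: int = 0) -> str:
    return "".join(rng.choice(_BASES, size=length, p=_PROFILES[profile % len(_PROFILES)]))


def generate_overhang(
    length: int,
    context: str,
    model: EnergyModel = DEFAULT_MODEL,
    seed: int | np.random.Generator = 0,
    *,
    side: str = "5",
    avoid: tuple[str, ...] = (),
    accessibility_threshold: float = 0.8,
    crosstalk_threshold: float = 6.0,
    max_iter: int = 10_000,
) -> str:
    """Search for an overhang that stays single-stranded next to ``context``.

    A candidate is accepted when, in the MFE structure of the assembled
    molecule (overhang attached on ``side`` of ``context``), at least
    ``accessibility_threshold`` of its bases are unpaired, and its duplex
    energy against every avoid-list sequence has magnitude at most
    ``crosstalk_threshold``.  Deterministic for a fixed seed.

    The search is rejection sampling over several base compositions,
    followed by hill climbing on a combined objective (paired overhang
    bases plus avoid-list energy excess); a stalled climb restarts from
    fresh draws.  If no candidate satisfies both constraints within the
    budget a :class:`DesignSearchError` carries the best sequence found.
    """
    if length < 0:
        raise ValueError("length must be >= 0")
    if length == 0:
        return ""
    if side not in ("5", "3"):
        raise ValueError("side must be '5' or '3'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def crosstalk_excess(cand: str) -> float:
        return sum(
            max(0.0, abs(duplex_energy(cand, other, model).energy) - crosstalk_threshold)
            for other in avoid
        )

    def assemble(cand: str) -> tuple[str, tuple[int, int]]:
        if side == "5":
            return cand + context, (0, length)
        return context + cand, (len(context), len(context) + length)

    def paired_positions(cand: str) -> list[int]:
        assembled, (lo, hi) = assemble(cand)
        partner = fold_mfe(assembled, model)[0].partner()
        return [i - lo for i in range(lo, hi) if i in partner]

    # accept npaired <= floor(length * (1 - threshold)), guarding the
    # floating-point boundary (15 * 0.2 is not exactly 3.0)
    max_paired = int(length * (1 - accessibility_threshold) + 1e-9)

    def score(cand: str) -> tuple[float, int, float]:
        """(combined objective, paired count, crosstalk excess)."""
        npaired = len(paired_positions(cand)) if context else 0
        excess = crosstalk_excess(cand)
        return npaired + excess, npaired, excess

    def accepted(npaired: int, excess: float) -> bool:
        return npaired <= max_paired and excess == 0.0

    # multi-start: random draws over all compositions, then a hill climb
    # mutating paired (or, failing that, random) overhang bases.  Folding
    # dominates the cost, so the budget counts structure evaluations.
    n_random = 12 * len(_PROFILES)
    stall_limit = 250
    budget = max_iter
    best, best_obj = None, float("inf")
    while budget > 0:
        round_best, round_obj, round_paired = None, float("inf"), length + 1
        for it in range(min(n_random, budget)):
            budget -= 1
            cand = _draw(rng, length, profile=it % len(_PROFILES))
            obj, npaired, excess = score(cand)
            if accepted(npaired, excess):
                return cand
            if obj < round_obj:
                round_best, round_obj, round_paired = cand, obj, npaired
        cur, cur_obj = round_best, round_obj
        stall = 0
        while budget > 0 and stall < stall_limit and cur is not None:
            budget -= 1
            stall += 1
            pos_list = paired_positions(cur) if context else []
            if not pos_list or rng.random() < 0.3:
                pos_list = [int(rng.integers(length))]
            pos = int(rng.choice(pos_list))
            new_base = str(rng.choice(_BASES))
            cand = cur[:pos] + new_base + cur[pos + 1 :]
            if cand == cur:
                continue
            obj, npaired, excess = score(cand)
            if accepted(npaired, excess):
                return cand
            if obj <= cur_obj:  # plateau moves allowed
                cur, cur_obj = cand, obj
            if obj < round_obj:
                round_best, round_obj, round_paired = cand, obj, npaired
                stall = 0
        if round_obj < best_obj:
            best, best_obj = round_best, round_obj
    raise DesignSearchError(
        f"no overhang of length {length} met accessibility >= "
        f"{accessibility_threshold} and the avoid-list bound within "
        f"{max_iter} evaluations",
        best=best,
        best_score=best_obj,
    )


def _junction_bulges(
    core: str, facing_of_core_start: str, facing_of_core_end: str,
    has5: bool, has3: bool, o5_len: int,
) -> tuple[tuple[int, str], ...]:
    """Bulge bases for the present overhang/core junctions.

    The bulge base is chosen so it cannot pair (Watson-Crick or GU wobble)
    with the nucleotide it faces across the cognate duplex — the partner of
    the neighbouring core base; ties go to the alphabetically first base.
    Positions are absolute indices into the assembled full sequence.
    """
    bulges: list[tuple[int, str]] = []
    pos5 = o5_len
    if has5:
        bulges.append((pos5, nonpairing_base(facing_of_core_start)))
    if has3:
        pos3 = o5_len + (1 if has5 else 0) + len(core)
        bulges.append((pos3, nonpairing_base(facing_of_core_end)))
    return tuple(bulges)


def derive_trigger(
    switch: SwitchPart,
    cfg: DesignConfig = DesignConfig(),
    model: EnergyModel = DEFAULT_MODEL,
    *,
    name: str | None = None,
    avoid: tuple[str, ...] = (),
) -> TriggerRNA:
    """Design the trigger RNA for a switch.

    The core is the reverse complement of toehold + stem-bottom; overhangs
    and junction bulges are attached per ``cfg``.  The returned trigger is
    checked to open the full sensing domain in the predicted trigger-switch
    duplex.
    """
    core = reverse_complement(switch.sensing_seq)
    rng = np.random.default_rng(cfg.rng_seed)
    o5 = o3 = ""
    if cfg.has5:
        o5 = generate_overhang(
            cfg.overhang_len, core, model, rng, side="5", avoid=avoid,
            accessibility_threshold=cfg.accessibility_threshold,
            crosstalk_threshold=cfg.crosstalk_threshold, max_iter=cfg.max_iter,
        )
    if cfg.has3:
        o3 = generate_overhang(
            cfg.overhang_len, o5 + core, model, rng, side="3", avoid=avoid,
            accessibility_threshold=cfg.accessibility_threshold,
            crosstalk_threshold=cfg.crosstalk_threshold, max_iter=cfg.max_iter,
        )
    bulges: tuple[tuple[int, str], ...] = ()
    if cfg.bulge == "single_nt":
        # partner of core[0] is the sensing domain's 3' base, and vice versa
        sensing = switch.sensing_seq
        bulges = _junction_bulges(core, sensing[-1], sensing[0], cfg.has5, cfg.has3, len(o5))
    trig = TriggerRNA(
        name=name or f"{switch.name}_trigger",
        core_seq=core,
        overhang5=o5,
        overhang3=o3,
        bulges=bulges,
    )
    _check_opens_sensing(trig, switch, model)
    return trig


def _check_opens_sensing(trig: TriggerRNA, switch: SwitchPart, model: EnergyModel) -> None:
    res = duplex_energy(trig.seq, switch.seq, model)
    sensing_len = len(switch.sensing_seq)
    covered = {j for _, j in res.pairs if j < sensing_len}
    if len(covered) < sensing_len:
        raise DesignSearchError(
            f"{trig.name}: trigger-switch duplex leaves "
            f"{sensing_len - len(covered)} sensing bases unopened"
        )


def derive_antisense(
    trigger: TriggerRNA,
    cfg: DesignConfig = DesignConfig(overhang_mode="five_prime_only", bulge="none"),
    model: EnergyModel = DEFAULT_MODEL,
    *,
    name: str | None = None,
    avoid: tuple[str, ...] = (),
) -> AntisenseRNA:
    """Design the antisense RNA that annihilates ``trigger``.

    The core reverse-complements the trigger core, so the antisense covers
    everything the switch could bind.  Antisense overhangs are the reverse
    complements of the trigger's overhangs (5' antisense overhang pairs the
    trigger's 3' overhang and vice versa): the extra pairing beyond the
    switch-binding core is exactly the thermodynamic driving force that
    tips the equilibrium toward trigger-antisense binding.  Where the
    trigger has no overhang to match, a neutral single-stranded overhang is
    searched for instead (it contributes no driving force).

    ``bulge='none'`` is the full-match design; ``bulge='single_nt'`` places
    a non-pairing nucleotide at each overhang/core junction.
    """
    core = reverse_complement(trigger.core_seq)
    rng = np.random.default_rng(cfg.rng_seed + 1)
    o5 = o3 = ""
    complementary = False
    if cfg.has5:
        if trigger.overhang3:
            # pairs the trigger bases immediately 3' of its core
            o5 = reverse_complement(trigger.overhang3[: cfg.overhang_len])
            complementary = True
        else:
            o5 = generate_overhang(
                cfg.overhang_len, core, model, rng, side="5", avoid=avoid,
                accessibility_threshold=cfg.accessibility_threshold,
                crosstalk_threshold=cfg.crosstalk_threshold, max_iter=cfg.max_iter,
            )
    if cfg.has3:
        if trigger.overhang5:
            # pairs the trigger bases immediately 5' of its core
            o3 = reverse_complement(trigger.overhang5[-cfg.overhang_len :])
            complementary = True
        else:
            o3 = generate_overhang(
                cfg.overhang_len, o5 + core, model, rng, side="3", avoid=avoid,
                accessibility_threshold=cfg.accessibility_threshold,
                crosstalk_threshold=cfg.crosstalk_threshold, max_iter=cfg.max_iter,
            )
    bulges: tuple[tuple[int, str], ...] = ()
    if cfg.bulge == "single_nt":
        tcore = trigger.core_seq
        bulges = _junction_bulges(core, tcore[-1], tcore[0], cfg.has5, cfg.has3, len(o5))
    anti = AntisenseRNA(
        name=name or f"{trigger.name}_anti",
        core_seq=core,
        overhang5=o5,
        overhang3=o3,
        bulges=bulges,
        target_trigger=trigger.name,
    )
    if complementary:
        e_full = duplex_energy(trigger.seq, anti.seq, model).energy
        e_core = duplex_energy(trigger.core_seq, core, model).energy
        if not e_full < e_core:
            raise DesignSearchError(
                f"{anti.name}: overhangs provide no thermodynamic driving force "
                f"({e_full:.2f} vs core-only {e_core:.2f})"
            )
    return anti


def expand_loop(
    switch: SwitchPart,
    delta: int,
    seed: int = 0,
    model: EnergyModel = DEFAULT_MODEL,
    *,
    max_iter: int = 10_000,
) -> SwitchPart:
    """Lengthen the hairpin loop by ``delta`` nt without disturbing the stem.

    Bases are inserted at the 3' end of the loop (after the RBS) and a
    candidate is accepted only if the predicted MFE keeps the same number of
    stem pairs and the RBS still occurs exactly once.  ``delta=0`` returns
    the input unchanged.
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    if delta == 0:
        return switch
    rng = np.random.default_rng(seed)
    base_struct, _ = fold_mfe(switch.seq, model)
    base_stem = len(base_struct.pairs)

    best, best_score = None, -1
    for _ in range(max_iter):
        ins = _draw(rng, delta)
        new_loop = switch.loop_seq + ins
        cand = replace(switch, loop_seq=new_loop)
        if cand.loop_seq.count(switch.rbs) != 1:
            continue
        struct, _ = fold_mfe(cand.seq, model)
        score = -abs(len(struct.pairs) - base_stem)
        if score > best_score:
            best, best_score = cand, score
        if len(struct.pairs) == base_stem:
            return cand
    raise DesignSearchError(
        f"could not expand loop by {delta} nt without changing the stem",
        best=best.loop_seq if best else None,
        best_score=float(best_score),
    )
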