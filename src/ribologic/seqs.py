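"""Small RNA-sequence helpers shared across the package.

All sequences are stored 5'->3' over the RNA alphabet {A, C, G, U};
coordinates are 0-based, half-open.  DNA input (containing T) is
transliterated to RNA on ingestion.
"""

from __future__ import annotations

import logging

logger = logging.getLogger("ribologic")

RNA_ALPHABET = frozenset("ACGU")

_COMPLEMENT = str.maketrans("ACGU", "UGCA")

#: Watson-Crick partners (used for bulge-base selection and validation).
WC_PARTNER = {"A": "U", "U": "A", "G": "C", "C": "G"}

#: Bases b such that (base, b) can pair under the energy model (WC or GU wobble).
PAIRING_PARTNERS = {
    "A": frozenset("U"),
    "U": frozenset("AG"),
    "G": frozenset("CU"),
    "C": frozenset("G"),
}


class AlphabetError(ValueError):
    """Sequence contains characters outside {A, C, G, U}."""


def clean_rna(seq: str, *, name: str = "sequence") -> str:
    """Uppercase, transliterate DNA T->U, and validate the alphabet.

    Raises :class:`AlphabetError` naming the offending record on failure.
    """
    s = seq.strip().upper().replace(" ", "")
    if "T" in s:
        logger.info("%s: DNA input transliterated to RNA (T -> U)", name)
        s = s.replace("T", "U")
    bad = set(s) - RNA_ALPHABET
    if bad:
        raise AlphabetError(
            f"{name}: invalid characters {sorted(bad)} (expected A/C/G/U)"
        )
    return s


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def can_pair(a: str, b: str) -> bool:
    """True if bases ``a`` and ``b`` form a WC or GU wobble pair."""
    return b in PAIRING_PARTNERS.get(a, frozenset())


def is_wc_pair(a: str, b: str) -> bool:
    return WC_PARTNER.get(a) == b


def nonpairing_base(facing: str) -> str:
    """The alphabetically first base that cannot pair (WC or GU) with ``facing``.

    Used to choose bulge-nucleotide identities: a bulge must stay unpaired
    opposite the base it faces in the cognate duplex.
    """
    for b in "ACGU":
        if not can_pair(b, facing):
            return b
    raise ValueError(f"no non-pairing base for {facing!r}")  # pragma: no cover
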