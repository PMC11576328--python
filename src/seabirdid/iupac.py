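"""IUPAC nucleotide codes and primer-aware sequence comparison.

Degenerate primers use the standard IUPAC ambiguity alphabet plus inosine
('I'), a synthetic base that pairs with all four nucleotides and is common
in broad-range metazoan primers.
"""

from __future__ import annotations

# Base sets for each IUPAC code. 'I' (inosine) is valid in primers only.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
    "I": frozenset("ACGT"),
}

#: Characters allowed in a stored (unaligned) reference or query sequence.
SEQUENCE_ALPHABET = frozenset("ACGTRYSWKMBDHVN")

#: Characters allowed in a primer (sequence alphabet + inosine).
PRIMER_ALPHABET = frozenset(IUPAC_SETS)

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N", "I": "I",
    "-": "-",
}


def reverse_complement(seq: str) -> str:
    """Reverse-complement a sequence over the full ambiguity alphabet."""
    try:
        return "".join(_COMPLEMENT[c] for c in reversed(seq.upper()))
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"cannot complement character {exc.args[0]!r}") from exc


def codes_match(primer_code: str, template_code: str) -> bool:
    """True if a primer position can pair with a template position.

    Both sides may be ambiguity codes; they match when their base sets
    intersect ('I' and 'N' therefore match anything).
    """
    a = IUPAC_SETS.get(primer_code)
    b = IUPAC_SETS.get(template_code)
    if a is None or b is None:
        return False
    return not a.isdisjoint(b)


def count_mismatches(primer: str, window: str) -> int:
    """Number of positions where a primer cannot pair with a template window."""
    if len(primer) != len(window):
        raise ValueError("primer and window lengths differ")
    return sum(not codes_match(p, t) for p, t in zip(primer, window))
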