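"""IUPAC nucleotide ambiguity codes and the set algebra used for consensus
merging.

Every code denotes a non-empty subset of {A, C, G, T}; merging two observed
characters means taking the union of their sets and mapping back to the
minimal code containing it.  This is the semantics used when overlapping
contigs of one diploid individual disagree: both alleles are retained
(e.g. A + G -> R), never voted away.
"""

from __future__ import annotations

CODE_TO_SET: dict[str, frozenset[str]] = {
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
}

SET_TO_CODE: dict[frozenset[str], str] = {s: c for c, s in CODE_TO_SET.items()}

#: Complement map over the full ambiguity alphabet (R={A,G} -> Y={T,C}, etc.).
COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

UNAMBIGUOUS = frozenset("ACGT")


def expand(code: str) -> frozenset[str]:
    """Base set denoted by a single IUPAC code (case-insensitive)."""
    try:
        return CODE_TO_SET[code.upper()]
    except KeyError:
        raise ValueError(f"not an IUPAC nucleotide code: {code!r}") from None


def code_for(bases: frozenset[str] | set[str]) -> str:
    """Minimal IUPAC code for a non-empty subset of {A,C,G,T}."""
    try:
        return SET_TO_CODE[frozenset(bases)]
    except KeyError:
        raise ValueError(f"not a valid base set: {sorted(bases)!r}") from None


def merge_codes(*codes: str) -> str:
    """Union-merge IUPAC codes: merge_codes('A','G') == 'R'."""
    if not codes:
        raise ValueError("need at least one code to merge")
    union: frozenset[str] = frozenset()
    for c in codes:
        union = union | expand(c)
    return code_for(union)


def reverse_complement(seq: str) -> str:
    """Reverse complement over the full IUPAC alphabet."""
    try:
        return "".join(COMPLEMENT[c.upper()] for c in reversed(seq))
    except KeyError as exc:
        raise ValueError(f"non-IUPAC character in sequence: {exc}") from None


def is_valid_sequence(seq: str) -> bool:
    return all(c.upper() in CODE_TO_SET for c in seq)
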