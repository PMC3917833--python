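"""Nucleotide alphabet utilities: IUPAC ambiguity sets, bitmasks, complements.

Ambiguity codes are handled by the Cornish-Bowden convention throughout the
package: a code denoting a set S contributes fractionally (1/|S|) to counts,
and matches a primer base iff that base is a member of S.
"""

from __future__ import annotations

from functools import reduce

#: IUPAC nucleotide codes mapped to the set of unambiguous bases they denote.
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
}

GAP = "-"
BASES = "ACGT"

#: 4-bit encoding (A=1, C=2, G=4, T=8); ambiguity codes OR their members.
_BASE_BITS = {"A": 1, "C": 2, "G": 4, "T": 8}
IUPAC_BITS: dict[str, int] = {
    code: reduce(lambda acc, b: acc | _BASE_BITS[b], members, 0)
    for code, members in IUPAC_SETS.items()
}
IUPAC_BITS[GAP] = 0

_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N", GAP: GAP,
}


def is_unambiguous(seq: str) -> bool:
    """True if *seq* contains only A, C, G, T."""
    return all(c in _BASE_BITS for c in seq)


def complement(base: str) -> str:
    return _COMPLEMENT[base]


def reverse_complement(seq: str) -> str:
    """Reverse complement, preserving IUPAC ambiguity codes."""
    try:
        return "".join(_COMPLEMENT[c] for c in reversed(seq))
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"not a nucleotide symbol: {exc.args[0]!r}") from exc


def normalize_symbol(c: str) -> str:
    """Uppercase, U -> T, '.' -> '-'; reject anything non-IUPAC."""
    c = c.upper()
    if c == "U":
        return "T"
    if c == ".":
        return GAP
    if c not in _COMPLEMENT:
        raise ValueError(f"invalid nucleotide symbol: {c!r}")
    return c


def normalize_sequence(seq: str) -> str:
    """Apply :func:`normalize_symbol` to every character."""
    up = seq.upper().replace("U", "T").replace(".", GAP)
    for c in up:
        if c not in _COMPLEMENT:
            raise ValueError(f"invalid nucleotide symbol: {c!r}")
    return up
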