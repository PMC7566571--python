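"""Small RNA-alphabet helpers shared across modules.

All sequences are handled internally as uppercase RNA (A/C/G/U); DNA input
(T) is accepted everywhere and normalised on entry.
"""

from __future__ import annotations

RNA_ALPHABET = frozenset("ACGU")

_RC_TABLE = str.maketrans("ACGU", "UGCA")


def normalize_rna(seq: str) -> str:
    """Uppercase a sequence and convert T to U; reject non-ACGU characters."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - RNA_ALPHABET
    if bad:
        raise ValueError(f"non-ACGU/T characters in sequence: {sorted(bad)}")
    return s


def revcomp_rna(seq: str) -> str:
    """Reverse complement of an RNA string (A<->U, C<->G)."""
    return normalize_rna(seq).translate(_RC_TABLE)[::-1]
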