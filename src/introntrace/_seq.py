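"""Codon-level helpers shared across modules.

Thin wrappers around Biopython's codon tables; kept as plain dict lookups so
the tight loops in the spliced aligner avoid per-call object construction.
"""
from __future__ import annotations

from functools import lru_cache

from Bio.Data import CodonTable

from .errors import ValidationError

DNA_ALPHABET = frozenset("ACGT")


@lru_cache(maxsize=None)
def codon_map(table_id: int = 1) -> dict[str, str]:
    """Codon -> amino acid map for an NCBI translation table; stops map to '*'."""
    tab = CodonTable.unambiguous_dna_by_id[table_id]
    m = dict(tab.forward_table)
    for c in tab.stop_codons:
        m[c] = "*"
    return m


@lru_cache(maxsize=None)
def synonymous_codons(table_id: int = 1) -> dict[str, tuple[str, ...]]:
    """Amino acid -> sorted tuple of its codons (stops excluded)."""
    out: dict[str, list[str]] = {}
    for codon, aa in codon_map(table_id).items():
        if aa == "*":
            continue
        out.setdefault(aa, []).append(codon)
    return {aa: tuple(sorted(cs)) for aa, cs in out.items()}


def translate(seq: str, table_id: int = 1) -> str:
    """Translate an in-frame DNA string; trailing partial codon is dropped.

    Unknown codons translate to 'X' (never raises on content so the aligner
    can scan arbitrary frames).
    """
    m = codon_map(table_id)
    return "".join(
        m.get(seq[i : i + 3], "X") for i in range(0, len(seq) - len(seq) % 3, 3)
    )


def check_dna(seq: str, what: str = "sequence") -> None:
    """Reject empty or non-ACGT sequences with a clear error."""
    if not seq:
        raise ValidationError(f"{what} is empty")
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValidationError(
            f"{what} contains characters outside A/C/G/T: {sorted(bad)}"
        )
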