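"""Splice-site context extraction, proto-splice-site scanning, codon usage.

The proto-splice consensus used throughout is (C|A)AG immediately upstream of
the insertion point and (A|G) immediately downstream, evaluated on the
spliced (exonic) coding sequence.
"""
from __future__ import annotations

from collections.abc import Iterable
from dataclasses import dataclass

from ._seq import check_dna, codon_map
from .errors import ValidationError
from .intron_mapping import GeneStructure, IntronPosition

UPSTREAM_TRIS = ("AAG", "CAG")
DOWNSTREAM_NTS = ("A", "G")


@dataclass(frozen=True)
class SpliceSiteContext:
    """Exonic context of an intron insertion point."""

    upstream_tri: str  # last 3 exonic nt before the intron
    downstream_nt: str  # first exonic nt after the intron

    def __post_init__(self) -> None:
        check_dna(self.upstream_tri, "upstream_tri")
        check_dna(self.downstream_nt, "downstream_nt")
        if len(self.upstream_tri) != 3 or len(self.downstream_nt) != 1:
            raise ValidationError("context must be 3 nt + 1 nt")


def extract_context(
    gene: GeneStructure, cds: str, intron: IntronPosition
) -> SpliceSiteContext:
    """Context at ``intron`` on the spliced CDS of ``gene``.

    Raises when the intron sits closer than 3 nt to the CDS start (no full
    upstream triplet exists) or at/after the CDS end.
    """
    if len(cds) != gene.cds_len:
        raise ValidationError(
            f"cds length {len(cds)} != cds_len {gene.cds_len} of {gene.gene_id!r}"
        )
    o = intron.cds_offset
    if o < 3:
        raise ValidationError(f"truncated context: cds_offset {o} < 3")
    if o >= len(cds):
        raise ValidationError(f"cds_offset {o} out of range")
    return SpliceSiteContext(upstream_tri=cds[o - 3 : o], downstream_nt=cds[o])


def is_proto_splice(ctx: SpliceSiteContext) -> bool:
    """True iff the context matches (C|A)AG - (A|G)."""
    return ctx.upstream_tri in UPSTREAM_TRIS and ctx.downstream_nt in DOWNSTREAM_NTS


def scan_proto_splice_sites(cds: str) -> list[int]:
    """All cds offsets (3 <= o < len) whose context passes :func:`is_proto_splice`."""
    check_dna(cds, "cds")
    return [
        o
        for o in range(3, len(cds))
        if cds[o - 3 : o] in UPSTREAM_TRIS and cds[o] in DOWNSTREAM_NTS
    ]


def codon_usage(
    cds_set: Iterable[str],
    compartment: str = "nuclear",
    amino_acids: Iterable[str] | None = None,
    table_id: int = 1,
) -> dict[str, dict[str, float]]:
    """Per-amino-acid codon fractions over a set of in-frame CDS.

    Amino acids with zero observed codons are absent from the result. The
    translation table is configurable for organellar input; stop codons are
    never counted.
    """
    wanted = set(amino_acids) if amino_acids is not None else None
    cmap = codon_map(table_id)
    counts: dict[str, dict[str, int]] = {}
    for cds in cds_set:
        check_dna(cds, "cds")
        if len(cds) % 3:
            raise ValidationError(f"cds length {len(cds)} not divisible by 3")
        for i in range(0, len(cds), 3):
            codon = cds[i : i + 3]
            aa = cmap.get(codon, "X")
            if aa in ("*", "X"):
                continue
            if wanted is not None and aa not in wanted:
                continue
            counts.setdefault(aa, {}).setdefault(codon, 0)
            counts[aa][codon] += 1
    table: dict[str, dict[str, float]] = {}
    for aa in sorted(counts):
        total = sum(counts[aa].values())
        table[aa] = {c: n / total for c, n in sorted(counts[aa].items())}
    return table


def context_table(
    genes_with_cds: Iterable[tuple[GeneStructure, str]],
) -> list[dict]:
    """Per-intron context rows with proto-splice flags (report helper)."""
    rows = []
    for gene, cds in genes_with_cds:
        for intron in gene.introns:
            try:
                ctx = extract_context(gene, cds, intron)
            except ValidationError:
                rows.append(
                    {
                        "gene_id": gene.gene_id,
                        "species_id": gene.species_id,
                        "cds_offset": intron.cds_offset,
                        "phase": intron.phase,
                        "upstream_tri": "",
                        "downstream_nt": "",
                        "proto_splice": False,
                    }
                )
                continue
            rows.append(
                {
                    "gene_id": gene.gene_id,
                    "species_id": gene.species_id,
                    "cds_offset": intron.cds_offset,
                    "phase": intron.phase,
                    "upstream_tri": ctx.upstream_tri,
                    "downstream_nt": ctx.downstream_nt,
                    "proto_splice": is_proto_splice(ctx),
                }
            )
    return rows
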