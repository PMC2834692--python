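"""Intron-position identification from protein/genomic-locus pairs.

The aligner is a deterministic seed-and-chain spliced aligner: exact
amino-acid k-mer seeds against the three forward-frame translations of the
locus, extended to maximal exact diagonal runs, chained by dynamic
programming with zero gap cost. Inter-block gaps are then screened as intron
candidates with three filters, applied in order:

1. LENGTH   — the gap must be longer than 20 nt (strict),
2. SITE     — it must start with GT and end with AG,
3. JUNCTION — the 18 exonic nt around the junction (9 + 9, spliced) must
              translate to the corresponding residues of the query protein.

Candidate boundaries may slide within +/-12 nt when the slid placement
yields an identical spliced sequence; the smallest such shift that passes
all filters wins (ties broken leftmost).

Coordinates are 0-based half-open throughout; only ``anchor_residue`` is
1-based.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from ._seq import check_dna, translate
from .errors import (
    InternalConsistencyError,
    MalformedChainError,
    NoSplicedAlignmentError,
    ValidationError,
)

MIN_INTRON_LENGTH = 21  # "longer than 20 nucleotides", strict
SHIFT_WINDOW = 12  # max boundary slide (nt) for canonical-site rescue
JUNCTION_FLANK = 9  # exonic nt examined on each side of a junction

REASON_LENGTH = "LENGTH"
REASON_SITE = "SITE"
REASON_JUNCTION = "JUNCTION"


@dataclass(frozen=True)
class GenomicLocus:
    """A genomic sequence holding the (possibly intron-containing) gene."""

    locus_id: str
    sequence: str
    species_id: str = ""

    def __post_init__(self) -> None:
        check_dna(self.sequence, f"locus {self.locus_id!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AlignmentBlock:
    """An ungapped protein-to-genome match (one exon piece).

    ``p_*`` are protein residue indices, ``g_*`` genomic nt indices; both
    0-based half-open, with 3 * protein span == genomic span.
    """

    p_start: int
    p_end: int
    g_start: int
    g_end: int

    def __post_init__(self) -> None:
        if not (self.p_end > self.p_start and self.g_end > self.g_start):
            raise ValidationError(f"empty or inverted block {self}")
        if 3 * (self.p_end - self.p_start) != self.g_end - self.g_start:
            raise ValidationError(f"block spans out of 3:1 ratio: {self}")

    @property
    def n_residues(self) -> int:
        return self.p_end - self.p_start


@dataclass(frozen=True)
class IntronPosition:
    """An accepted intron, located on the coding sequence and the locus."""

    cds_offset: int  # coding nt preceding the intron
    phase: int  # cds_offset mod 3
    anchor_residue: int  # 1-based protein index
    g_start: int
    g_end: int
    donor: str
    acceptor: str

    def __post_init__(self) -> None:
        if self.phase != self.cds_offset % 3:
            raise ValidationError(
                f"phase {self.phase} != cds_offset {self.cds_offset} mod 3"
            )
        if self.anchor_residue != self.cds_offset // 3 + 1:
            raise ValidationError(
                f"anchor_residue {self.anchor_residue} inconsistent with "
                f"cds_offset {self.cds_offset}"
            )

    @property
    def length(self) -> int:
        return self.g_end - self.g_start


@dataclass(frozen=True)
class RejectedCandidate:
    """A screened gap that failed a filter; ``reason`` names the first failure."""

    g_start: int
    g_end: int
    reason: str


@dataclass
class GeneStructure:
    """A protein together with its ordered intron positions on the CDS."""

    gene_id: str
    species_id: str
    compartment: str  # "nuclear" | "mitochondrial"
    protein: str
    introns: list[IntronPosition] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.compartment not in ("nuclear", "mitochondrial"):
            raise ValidationError(f"bad compartment {self.compartment!r}")
        offsets = [i.cds_offset for i in self.introns]
        if offsets != sorted(set(offsets)):
            raise ValidationError(
                f"intron cds_offsets not strictly increasing for {self.gene_id}"
            )
        for i in self.introns:
            if not (0 < i.cds_offset < self.cds_len):
                raise ValidationError(
                    f"cds_offset {i.cds_offset} outside (0, {self.cds_len})"
                )

    @property
    def cds_len(self) -> int:
        """Coding length in nt, stop codon excluded."""
        return 3 * len(self.protein)

    @property
    def n_introns(self) -> int:
        return len(self.introns)

    def phases(self) -> list[int]:
        return [i.phase for i in self.introns]


@dataclass
class ChainResult:
    """Outcome of :func:`spliced_align`."""

    blocks: list[AlignmentBlock]
    coverage: float  # fraction of protein residues covered
    ambiguous: bool  # another equal-score chain existed (tie-broken leftmost)

    def __iter__(self):
        return iter(self.blocks)


@dataclass
class MappingResult:
    """Outcome of :func:`structure_from_alignment`."""

    structure: GeneStructure
    rejected: list[RejectedCandidate]
    chain: ChainResult


# ---------------------------------------------------------------------------
# spliced alignment
# ---------------------------------------------------------------------------


def _candidate_blocks(protein: str, locus: GenomicLocus, seed_k: int) -> list[AlignmentBlock]:
    """Maximal exact diagonal runs found from k-mer seeds, all three frames."""
    seq = locus.sequence
    frames = [translate(seq[f:]) for f in range(3)]
    index: dict[str, list[tuple[int, int]]] = {}
    for f, fr in enumerate(frames):
        for j in range(len(fr) - seed_k + 1):
            index.setdefault(fr[j : j + seed_k], []).append((f, j))

    seen: set[tuple[int, int, int]] = set()  # (frame, p_start, g_aa_start)
    blocks: list[AlignmentBlock] = []
    for i in range(len(protein) - seed_k + 1):
        for f, j in index.get(protein[i : i + seed_k], ()):
            fr = frames[f]
            # extend left
            pi, fj = i, j
            while pi > 0 and fj > 0 and protein[pi - 1] == fr[fj - 1]:
                pi -= 1
                fj -= 1
            key = (f, pi, fj)
            if key in seen:
                continue
            seen.add(key)
            # extend right
            pe, fe = i + seed_k, j + seed_k
            while pe < len(protein) and fe < len(fr) and protein[pe] == fr[fe]:
                pe += 1
                fe += 1
            blocks.append(
                AlignmentBlock(pi, pe, f + 3 * fj, f + 3 * fe)
            )
    blocks.sort(key=lambda b: (b.g_start, b.p_start, b.g_end))
    return blocks


def _link_gain(a: AlignmentBlock, b: AlignmentBlock) -> int | None:
    """Residues ``b`` adds after chain ``...a``; None if incompatible.

    ``b`` may be trimmed at its head to remove protein overlap with ``a``;
    the trimmed block must retain residues and start after ``a`` genomically.
    """
    trim = max(0, a.p_end - b.p_start)
    if b.p_end - b.p_start <= trim:
        return None
    if b.g_start + 3 * trim <= a.g_end:
        return None
    return b.p_end - (b.p_start + trim)


def spliced_align(
    protein: str,
    locus: GenomicLocus,
    seed_k: int = 6,
    min_coverage: float = 0.9,
) -> ChainResult:
    """Chain exact-match blocks to cover the protein on the locus.

    Raises :class:`NoSplicedAlignmentError` when no chain covers at least
    ``min_coverage`` of the protein.
    """
    if len(protein) < seed_k:
        raise ValidationError(
            f"protein shorter ({len(protein)}) than seed length {seed_k}"
        )
    blocks = _candidate_blocks(protein, locus, seed_k)
    if not blocks:
        raise NoSplicedAlignmentError(
            f"no seed matches for protein on locus {locus.locus_id!r}"
        )

    n = len(blocks)
    score = [b.n_residues for b in blocks]
    pred = [-1] * n
    tied = [False] * n
    for i in range(n):
        bi = blocks[i]
        for j in range(i):
            g = _link_gain(blocks[j], bi)
            if g is None:
                continue
            s = score[j] + g
            if s > score[i]:
                score[i] = s
                pred[i] = j
                tied[i] = tied[j]
            elif s == score[i] and (pred[i] != j):
                tied[i] = True

    best = max(range(n), key=lambda i: (score[i], -blocks[i].g_start))
    best_score = score[best]
    ambiguous = tied[best] or sum(1 for i in range(n) if score[i] == best_score) > 1

    chain_rev = []
    i = best
    while i != -1:
        chain_rev.append(blocks[i])
        i = pred[i]
    chain = list(reversed(chain_rev))

    # trim protein overlaps introduced by chaining
    trimmed: list[AlignmentBlock] = []
    for b in chain:
        if trimmed and b.p_start < trimmed[-1].p_end:
            cut = trimmed[-1].p_end - b.p_start
            b = AlignmentBlock(b.p_start + cut, b.p_end, b.g_start + 3 * cut, b.g_end)
        trimmed.append(b)

    coverage = best_score / len(protein)
    if coverage < min_coverage:
        raise NoSplicedAlignmentError(
            f"best chain covers {coverage:.2%} of protein "
            f"(< {min_coverage:.2%}) on locus {locus.locus_id!r}"
        )
    return ChainResult(trimmed, coverage, ambiguous)


# ---------------------------------------------------------------------------
# intron identification
# ---------------------------------------------------------------------------


def _check_chain(blocks: list[AlignmentBlock]) -> list[AlignmentBlock]:
    chain = sorted(blocks, key=lambda b: b.g_start)
    for a, b in zip(chain, chain[1:]):
        if b.p_start < a.p_end or b.g_start < a.g_end:
            raise MalformedChainError(f"blocks overlap: {a} then {b}")
        if b.g_start == a.g_end:
            raise MalformedChainError(f"gap of length <= 0 between {a} and {b}")
    return chain


def verify_junction(
    locus: GenomicLocus,
    g_start: int,
    g_end: int,
    cds_offset: int,
    protein: str,
    upstream_exon_start: int,
    downstream_exon_end: int,
) -> bool:
    """Translate the spliced 9+9-nt window around a candidate junction.

    Returns True iff the codon-aligned translation of the window equals the
    corresponding residues of ``protein``. Windows are truncated where fewer
    than 9 contiguous exonic nt exist on a side.
    """
    seq = locus.sequence
    cds_len = 3 * len(protein)
    if not (0 < cds_offset < cds_len):
        return False

    up = min(JUNCTION_FLANK, g_start - upstream_exon_start, cds_offset)
    start = cds_offset - up
    start += (-start) % 3  # snap to codon boundary
    up = cds_offset - start

    down = min(JUNCTION_FLANK, downstream_exon_end - g_end, cds_len - cds_offset)
    end = cds_offset + down
    end -= end % 3
    down = end - cds_offset

    if end <= start:
        return False
    window = seq[g_start - up : g_start] + seq[g_end : g_end + down]
    if len(window) % 3 != 0:
        raise InternalConsistencyError(
            f"junction window length {len(window)} not codon-aligned"
        )
    return translate(window) == protein[start // 3 : end // 3]


def _gap_candidates(
    seq: str,
    a: AlignmentBlock,
    b: AlignmentBlock,
    shift_window: int,
) -> list[tuple[int, int, int, int]]:
    """Enumerate (g_start, g_end, cds_offset_extra, shift) intron placements.

    With d protein residues unaccounted between the blocks, every placement
    has fixed length ``gs - ge - 3d``; the donor may sit anywhere in the
    nominal window [ge, ge + 3d] (splitting the 3d coding nt between the
    exons) extended by ``shift_window`` nt on both sides to absorb block
    boundaries that overshot into the intron (identical-translation runs).
    Sorted by (shift outside the nominal window, leftmost donor) — the
    acceptance preference order; downstream filters (GT..AG + junction
    translation) decide which placement is real.
    """
    ge, gs = a.g_end, b.g_start
    d = b.p_start - a.p_end
    length = gs - ge - 3 * d
    if length <= 0:
        return []
    out = []
    for A in range(ge - shift_window, ge + 3 * d + shift_window + 1):
        B = A + length
        if A <= a.g_start or B >= b.g_end:
            continue
        shift = max(0, ge - A, A - (ge + 3 * d))
        out.append((A, B, A - ge, shift))
    out.sort(key=lambda t: (t[3], t[0]))
    return out


def identify_introns(
    blocks: list[AlignmentBlock] | ChainResult,
    locus: GenomicLocus,
    protein: str,
    min_length: int = MIN_INTRON_LENGTH,
    shift_window: int = SHIFT_WINDOW,
) -> tuple[list[IntronPosition], list[RejectedCandidate]]:
    """Screen inter-block gaps against the three acceptance filters.

    Returns accepted introns plus a rejection log naming, for each failed
    gap, the first filter it failed (LENGTH, SITE or JUNCTION).
    """
    if isinstance(blocks, ChainResult):
        blocks = blocks.blocks
    chain = _check_chain(blocks)
    seq = locus.sequence
    accepted: list[IntronPosition] = []
    rejected: list[RejectedCandidate] = []

    prev_exon_start = max(0, chain[0].g_start - 3 * chain[0].p_start)
    for a, b in zip(chain, chain[1:]):
        found = None
        for A, B, extra, _shift in _gap_candidates(seq, a, b, shift_window):
            cds_offset = 3 * a.p_end + extra
            if not (0 < cds_offset < 3 * len(protein)):
                continue
            if B - A < min_length:
                continue
            if seq[A : A + 2] != "GT" or seq[B - 2 : B] != "AG":
                continue
            if not verify_junction(
                locus, A, B, cds_offset, protein, prev_exon_start, b.g_end
            ):
                continue
            found = (A, B, cds_offset)
            break
        if found is not None:
            A, B, cds_offset = found
            accepted.append(
                IntronPosition(
                    cds_offset=cds_offset,
                    phase=cds_offset % 3,
                    anchor_residue=cds_offset // 3 + 1,
                    g_start=A,
                    g_end=B,
                    donor=seq[A : A + 2],
                    acceptor=seq[B - 2 : B],
                )
            )
            prev_exon_start = B
        else:
            # report against the unshifted, donor-side-minimal placement
            A, B = a.g_end, b.g_start - 3 * (b.p_start - a.p_end)
            if B <= A:
                B = b.g_start
            if B - A < min_length:
                reason = REASON_LENGTH
            elif seq[A : A + 2] != "GT" or seq[B - 2 : B] != "AG":
                reason = REASON_SITE
            else:
                reason = REASON_JUNCTION
            rejected.append(RejectedCandidate(A, B, reason))
            prev_exon_start = b.g_start  # be permissive about the next window
    return accepted, rejected


def structure_from_alignment(
    protein: str,
    locus: GenomicLocus,
    gene_id: str = "",
    species_id: str | None = None,
    compartment: str = "nuclear",
    seed_k: int = 6,
    min_coverage: float = 0.9,
    min_length: int = MIN_INTRON_LENGTH,
    shift_window: int = SHIFT_WINDOW,
) -> MappingResult:
    """Align, screen gaps, and assemble a :class:`GeneStructure`.

    Deterministic for fixed inputs and parameters; alignment and filter
    errors propagate.
    """
    chain = spliced_align(protein, locus, seed_k=seed_k, min_coverage=min_coverage)
    introns, rejected = identify_introns(
        chain, locus, protein, min_length=min_length, shift_window=shift_window
    )
    structure = GeneStructure(
        gene_id=gene_id or locus.locus_id,
        species_id=locus.species_id if species_id is None else species_id,
        compartment=compartment,
        protein=protein,
        introns=introns,
    )
    return MappingResult(structure=structure, rejected=rejected, chain=chain)
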