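"""Intron positions on protein alignments: occurrence matrices, shared-position
tables between taxonomic groups, conserved-block restriction, and the
independent- vs single-transfer sharing comparison.

A *position* is an (alignment column, phase) pair — phase equality makes the
comparison nucleotide-exact. A position is shared between two groups when at
least one sequence in each carries an intron there; it is group-specific
when exactly one group carries it.
"""
from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .intron_mapping import GeneStructure

VARIANT_ALL = "all_columns"
VARIANT_BLOCKS = "conserved_blocks"


@dataclass
class ProteinAlignment:
    """A protein multiple alignment; rows keyed by sequence id."""

    family_id: str
    rows: dict[str, str]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValidationError(f"alignment {self.family_id!r} has no rows")
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) != 1:
            raise ValidationError(
                f"alignment {self.family_id!r} rows differ in length: {sorted(lengths)}"
            )

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values())))

    def ungapped(self, seq_id: str) -> str:
        return self.rows[seq_id].replace("-", "")

    def residue_to_column(self, seq_id: str) -> list[int]:
        """1-based alignment column of each residue (index 0 = residue 1)."""
        return [i + 1 for i, ch in enumerate(self.rows[seq_id]) if ch != "-"]


@dataclass(frozen=True)
class IntronOccurrence:
    seq_id: str
    column: int  # 1-based alignment column of the anchor residue
    phase: int


@dataclass
class IntronOccurrenceMatrix:
    """Presence/absence of introns keyed by (sequence, column, phase)."""

    family_id: str
    entries: frozenset[IntronOccurrence]

    def positions(self) -> set[tuple[int, int]]:
        return {(e.column, e.phase) for e in self.entries}

    def carriers(self, column: int, phase: int) -> set[str]:
        return {
            e.seq_id for e in self.entries if e.column == column and e.phase == phase
        }


@dataclass(frozen=True)
class ConservedBlock:
    """A high-identity, low-gap run of alignment columns (1-based, inclusive)."""

    col_start: int
    col_end: int
    mean_identity: float
    max_gap_fraction: float

    def __contains__(self, column: int) -> bool:
        return self.col_start <= column <= self.col_end


@dataclass
class SharedPositionTable:
    """Group-by-group shared-position counts (the published tables' shape)."""

    groups: list[str]
    diagonal: dict[str, int]  # group -> group-specific position count
    pair_counts: dict[frozenset, int]  # {g_i, g_j} -> shared count
    total_positions: int  # distinct (column, phase) positions
    n_shared_distinct: int  # distinct positions seen in >= 2 groups
    variant: str = VARIANT_ALL
    pair_percentages: dict[frozenset, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.pair_percentages and self.total_positions:
            self.pair_percentages = {
                k: 100.0 * v / self.total_positions
                for k, v in self.pair_counts.items()
            }

    def shared(self, g1: str, g2: str) -> int:
        return self.pair_counts.get(frozenset((g1, g2)), 0)


def map_introns_to_alignment(
    alignment: ProteinAlignment, structures: Iterable[GeneStructure]
) -> IntronOccurrenceMatrix:
    """One entry per intron at the alignment column of its anchor residue.

    Each structure's protein must equal its ungapped alignment row.
    """
    entries = []
    for s in structures:
        row_id = _row_id_for(alignment, s)
        if alignment.ungapped(row_id) != s.protein:
            raise ValidationError(
                f"sequence {row_id!r}: protein does not match its ungapped "
                f"alignment row in family {alignment.family_id!r}"
            )
        col_of = alignment.residue_to_column(row_id)
        for intron in s.introns:
            entries.append(
                IntronOccurrence(
                    seq_id=row_id,
                    column=col_of[intron.anchor_residue - 1],
                    phase=intron.phase,
                )
            )
    return IntronOccurrenceMatrix(
        family_id=alignment.family_id, entries=frozenset(entries)
    )


def _row_id_for(alignment: ProteinAlignment, s: GeneStructure) -> str:
    for candidate in (
        f"{s.gene_id}|{s.species_id}",
        s.gene_id,
        s.species_id,
    ):
        if candidate in alignment.rows:
            return candidate
    raise ValidationError(
        f"no alignment row for gene {s.gene_id!r} / species {s.species_id!r} "
        f"in family {alignment.family_id!r}"
    )


def find_shared_positions(
    matrix: IntronOccurrenceMatrix,
    grouping: Mapping[str, str],
    variant: str = VARIANT_ALL,
    groups: Iterable[str] | None = None,
) -> SharedPositionTable:
    """Count group-specific and pairwise-shared positions.

    ``grouping`` maps sequence ids to group names. A position carried by more
    than two groups contributes to every carrying pair but counts once in the
    distinct-shared total. Percentages use the total number of distinct
    positions as denominator.
    """
    if not grouping:
        raise ValidationError("empty grouping")
    for e in matrix.entries:
        if e.seq_id not in grouping:
            raise ValidationError(f"sequence {e.seq_id!r} has no group assignment")

    pos_groups: dict[tuple[int, int], set[str]] = {}
    for e in matrix.entries:
        pos_groups.setdefault((e.column, e.phase), set()).add(grouping[e.seq_id])

    group_list = sorted(groups) if groups is not None else sorted(set(grouping.values()))
    diagonal = {g: 0 for g in group_list}
    pair_counts: dict[frozenset, int] = {}
    n_shared = 0
    for gs in pos_groups.values():
        if len(gs) == 1:
            diagonal[next(iter(gs))] += 1
        else:
            n_shared += 1
            for g1 in gs:
                for g2 in gs:
                    if g1 < g2:
                        key = frozenset((g1, g2))
                        pair_counts[key] = pair_counts.get(key, 0) + 1
    return SharedPositionTable(
        groups=group_list,
        diagonal=diagonal,
        pair_counts=pair_counts,
        total_positions=len(pos_groups),
        n_shared_distinct=n_shared,
        variant=variant,
    )


def detect_conserved_blocks(
    alignment: ProteinAlignment,
    window: int = 10,
    min_identity: float = 0.5,
    max_gap_fraction: float = 0.1,
    min_length: int = 8,
) -> list[ConservedBlock]:
    """Windowed identity/gap heuristic standing in for a block-finding tool.

    A column passes when its gap fraction is <= ``max_gap_fraction`` and the
    mean pairwise identity over the centred ``window`` columns is >=
    ``min_identity``; maximal runs of >= ``min_length`` passing columns
    become blocks.
    """
    ids = sorted(alignment.rows)
    mat = np.array([list(alignment.rows[i]) for i in ids])
    n_rows, n_cols = mat.shape
    gaps = mat == "-"
    gap_frac = gaps.mean(axis=0)

    col_identity = np.zeros(n_cols)
    for c in range(n_cols):
        col = mat[~gaps[:, c], c]
        m = len(col)
        if m < 2:
            col_identity[c] = 0.0
            continue
        _, counts = np.unique(col, return_counts=True)
        same = (counts * (counts - 1) // 2).sum()
        col_identity[c] = same / (m * (m - 1) / 2)

    half = window // 2
    passing = np.zeros(n_cols, dtype=bool)
    for c in range(n_cols):
        lo = max(0, c - half)
        hi = min(n_cols, c + half + (window % 2))
        win_mean = col_identity[lo:hi].mean()
        passing[c] = gap_frac[c] <= max_gap_fraction and win_mean >= min_identity

    blocks: list[ConservedBlock] = []
    c = 0
    while c < n_cols:
        if not passing[c]:
            c += 1
            continue
        start = c
        while c < n_cols and passing[c]:
            c += 1
        if c - start >= min_length:
            blocks.append(
                ConservedBlock(
                    col_start=start + 1,
                    col_end=c,
                    mean_identity=float(col_identity[start:c].mean()),
                    max_gap_fraction=float(gap_frac[start:c].max()),
                )
            )
    return blocks


def restrict_to_blocks(
    matrix: IntronOccurrenceMatrix, blocks: Iterable[ConservedBlock]
) -> IntronOccurrenceMatrix:
    """Keep only occurrences whose column lies inside a conserved block."""
    blocks = list(blocks)
    kept = frozenset(
        e for e in matrix.entries if any(e.column in b for b in blocks)
    )
    return IntronOccurrenceMatrix(family_id=matrix.family_id, entries=kept)


def shared_positions_in_blocks(
    matrix: IntronOccurrenceMatrix,
    grouping: Mapping[str, str],
    blocks: Iterable[ConservedBlock],
    groups: Iterable[str] | None = None,
) -> SharedPositionTable:
    """The conserved-blocks variant of :func:`find_shared_positions`."""
    return find_shared_positions(
        restrict_to_blocks(matrix, blocks),
        grouping,
        variant=VARIANT_BLOCKS,
        groups=groups,
    )


@dataclass
class TransferClassComparison:
    """Sharing between two focal groups, split by transfer history class."""

    focal_groups: tuple[str, str]
    pct_independent: float | None
    pct_single: float | None
    shared_independent: int
    total_independent: int
    shared_single: int
    total_single: int

    @property
    def ratio(self) -> float | None:
        if not self.pct_independent or not self.pct_single:
            return None
        return self.pct_independent / self.pct_single


def compare_transfer_classes(
    matrices: Mapping[str, IntronOccurrenceMatrix],
    n_events: Mapping[str, int],
    grouping: Mapping[str, str],
    focal_groups: tuple[str, str],
) -> TransferClassComparison:
    """Shared-position percentage between the focal groups, per transfer class.

    Genes with >= 2 events form the independent class; genes with exactly 1
    the single class. For each class the percentage is 100 x (positions
    shared between the focal groups, summed over the class's genes) / (total
    distinct positions over the class's genes). Empty classes (or classes
    with zero positions) report ``None``.
    """
    g1, g2 = focal_groups
    sums = {"independent": [0, 0], "single": [0, 0]}  # [shared, total]
    seen = {"independent": False, "single": False}
    for gene_id, matrix in matrices.items():
        ev = n_events.get(gene_id)
        if ev is None or ev < 1:
            continue
        cls = "independent" if ev >= 2 else "single"
        seen[cls] = True
        table = find_shared_positions(matrix, grouping)
        sums[cls][0] += table.shared(g1, g2)
        sums[cls][1] += table.total_positions

    def pct(cls: str) -> float | None:
        if not seen[cls] or sums[cls][1] == 0:
            return None
        return 100.0 * sums[cls][0] / sums[cls][1]

    return TransferClassComparison(
        focal_groups=focal_groups,
        pct_independent=pct("independent"),
        pct_single=pct("single"),
        shared_independent=sums["independent"][0],
        total_independent=sums["independent"][1],
        shared_single=sums["single"][0],
        total_single=sums["single"][1],
    )
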