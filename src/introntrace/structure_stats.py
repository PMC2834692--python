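"""Gene-structure summary statistics: density, phase distribution, exon symmetry."""
from __future__ import annotations

from collections.abc import Callable, Iterable
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .intron_mapping import GeneStructure


@dataclass
class StructureStats:
    """Pooled statistics over a collection of gene structures.

    ``density`` is introns per kb of coding sequence pooled over the
    collection; ``symmetry_counts[a][b]`` counts internal exons whose
    upstream intron has phase ``a`` and downstream intron phase ``b``.
    """

    n_genes: int
    n_introns: int
    total_cds_len: int
    density: float
    phase_counts: tuple[int, int, int]
    phase_fractions: tuple[float, float, float] | None
    symmetry_counts: np.ndarray  # 3x3 int matrix
    symmetric_fraction: float | None

    def __post_init__(self) -> None:
        assert sum(self.phase_counts) == self.n_introns
        assert self.symmetry_counts.shape == (3, 3)


def intron_density(gene: GeneStructure) -> float:
    """Introns per 1 kb of coding sequence (stop codon excluded)."""
    if gene.cds_len == 0:
        raise ValidationError(f"gene {gene.gene_id!r} has empty coding sequence")
    return 1000.0 * gene.n_introns / gene.cds_len


def phase_distribution(
    genes: Iterable[GeneStructure],
) -> tuple[tuple[int, int, int], tuple[float, float, float] | None]:
    """Counts and fractions of phase 0/1/2 introns over the collection.

    Fractions are ``None`` when there are no introns.
    """
    counts = [0, 0, 0]
    for g in genes:
        for p in g.phases():
            counts[p] += 1
    total = sum(counts)
    fractions = tuple(c / total for c in counts) if total else None
    return (counts[0], counts[1], counts[2]), fractions


def exon_symmetry(
    genes: Iterable[GeneStructure],
) -> tuple[np.ndarray, float | None]:
    """Classify internal exons by flanking intron phases.

    Every exon flanked by two introns contributes one count to class
    (upstream phase, downstream phase); terminal exons are excluded.
    Symmetric classes are 0-0, 1-1 and 2-2.
    """
    m = np.zeros((3, 3), dtype=int)
    for g in genes:
        ph = g.phases()
        for a, b in zip(ph, ph[1:]):
            m[a, b] += 1
    total = int(m.sum())
    frac = float(np.trace(m)) / total if total else None
    return m, frac


def compute_stats(genes: Iterable[GeneStructure]) -> StructureStats:
    genes = list(genes)
    phase_counts, phase_fractions = phase_distribution(genes)
    sym, sym_frac = exon_symmetry(genes)
    n_introns = sum(g.n_introns for g in genes)
    total_cds = sum(g.cds_len for g in genes)
    density = 1000.0 * n_introns / total_cds if total_cds else 0.0
    return StructureStats(
        n_genes=len(genes),
        n_introns=n_introns,
        total_cds_len=total_cds,
        density=density,
        phase_counts=phase_counts,
        phase_fractions=phase_fractions,
        symmetry_counts=sym,
        symmetric_fraction=sym_frac,
    )


def grouped_stats(
    genes: Iterable[GeneStructure],
    key: Callable[[GeneStructure], str] = lambda g: g.species_id,
) -> dict[str, StructureStats]:
    """Same statistics aggregated per group (e.g. per species)."""
    buckets: dict[str, list[GeneStructure]] = {}
    for g in genes:
        buckets.setdefault(key(g), []).append(g)
    return {k: compute_stats(v) for k, v in sorted(buckets.items())}
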