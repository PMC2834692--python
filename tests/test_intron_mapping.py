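import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from introntrace._seq import translate
from introntrace.errors import (
    MalformedChainError,
    NoSplicedAlignmentError,
    ValidationError,
)
from introntrace.intron_mapping import (
    AlignmentBlock,
    GenomicLocus,
    IntronPosition,
    identify_introns,
    spliced_align,
    structure_from_alignment,
    verify_junction,
)

from helpers import build_locus, chain_score_oracle, make_intron, random_cds


def test_locus_rejects_bad_alphabet():
    with pytest.raises(ValidationError):
        GenomicLocus("x", "ACGTN")
    with pytest.raises(ValidationError):
        GenomicLocus("x", "")


def test_block_invariants():
    with pytest.raises(ValidationError):
        AlignmentBlock(0, 1, 0, 4)  # not 3:1
    with pytest.raises(ValidationError):
        AlignmentBlock(2, 2, 0, 0)  # empty


def test_intron_position_phase_anchor_consistency():
    with pytest.raises(ValidationError):
        IntronPosition(12, 1, 5, 0, 30, "GT", "AG")  # phase != offset mod 3
    with pytest.raises(ValidationError):
        IntronPosition(12, 0, 4, 0, 30, "GT", "AG")  # anchor != 12//3 + 1
    ip = IntronPosition(13, 1, 5, 0, 30, "GT", "AG")
    assert ip.length == 30


class TestSplicedAlign:
    def test_identity_single_block(self, rng):
        cds = random_cds(rng, 60)
        protein = translate(cds)
        res = spliced_align(protein, GenomicLocus("g", cds))
        assert len(res.blocks) == 1
        b = res.blocks[0]
        assert (b.p_start, b.p_end, b.g_start, b.g_end) == (0, 60, 0, 180)
        assert res.coverage == 1.0

    def test_two_exon_gene_matches_chain_oracle(self, rng):
        # exon1 30 nt, 100-nt canonical intron, exon2 45 nt
        cds = random_cds(rng, 25)
        locus = GenomicLocus("g", build_locus(cds, [(30, make_intron(rng, 100))]))
        protein = translate(cds)
        res = spliced_align(protein, locus)
        assert len(res.blocks) >= 2
        covered = sum(b.n_residues for b in res.blocks)
        from introntrace.intron_mapping import _candidate_blocks

        blocks = _candidate_blocks(protein, locus, seed_k=6)
        assert covered == chain_score_oracle(blocks)
        assert covered == len(protein)

    def test_unrelated_sequences_raise(self):
        # empirical over seeded random pairs: chance full-coverage chains
        # essentially never occur
        for seed in range(10):
            r = np.random.default_rng(seed)
            protein = "".join(
                "ACDEFGHIKLMNPQRSTVWY"[i] for i in r.integers(0, 20, 100)
            )
            dna = "".join("ACGT"[i] for i in r.integers(0, 4, 2000))
            with pytest.raises(NoSplicedAlignmentError):
                spliced_align(protein, GenomicLocus("g", dna))

    def test_protein_shorter_than_seed(self):
        with pytest.raises(ValidationError):
            spliced_align("MK", GenomicLocus("g", "ATGAAA"))

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 10_000), st.integers(1, 4))
    def test_chain_dp_equals_oracle_on_random_multi_exon_genes(self, seed, n_introns):
        r = np.random.default_rng(seed)
        cds = random_cds(r, 40)
        offsets = sorted({3 * int(i) for i in r.integers(7, 33, n_introns)})
        locus = GenomicLocus(
            "g",
            build_locus(cds, [(o, make_intron(r, int(r.integers(30, 90)))) for o in offsets]),
        )
        protein = translate(cds)
        from introntrace.intron_mapping import _candidate_blocks

        blocks = _candidate_blocks(protein, locus, seed_k=6)
        if len(blocks) > 12:
            return
        res = spliced_align(protein, locus, min_coverage=0.0)
        assert sum(b.n_residues for b in res.blocks) == chain_score_oracle(blocks)


class TestIdentifyIntrons:
    def _gene(self, rng, n_codons=60, introns=()):
        cds = random_cds(rng, n_codons)
        locus = GenomicLocus("g", build_locus(cds, list(introns)))
        return cds, locus, translate(cds)

    def test_gap_of_exactly_20_rejected_length(self, rng):
        cds, locus, protein = self._gene(rng, introns=[(60, make_intron(rng, 20))])
        res = spliced_align(protein, locus)
        accepted, rejected = identify_introns(res, locus, protein)
        assert accepted == []
        assert [r.reason for r in rejected] == ["LENGTH"]

    def test_gap_of_21_accepted(self, rng):
        cds, locus, protein = self._gene(rng, introns=[(60, make_intron(rng, 21))])
        res = spliced_align(protein, locus)
        accepted, rejected = identify_introns(res, locus, protein)
        assert [(i.cds_offset, i.phase) for i in accepted] == [(60, 0)]
        assert rejected == []

    def test_gc_donor_rejected_site(self, rng):
        intron = make_intron(rng, 80, donor="GC")
        cds, locus, protein = self._gene(rng, introns=[(60, intron)])
        res = spliced_align(protein, locus)
        accepted, rejected = identify_introns(res, locus, protein)
        assert accepted == []
        assert [r.reason for r in rejected] == ["SITE"]

    def test_planted_intron_after_nt_12(self, rng):
        cds = random_cds(rng, 40)
        intron = make_intron(rng, 50)
        locus = GenomicLocus("g", build_locus(cds, [(12, intron)]))
        protein = translate(cds)
        blocks = [AlignmentBlock(0, 4, 0, 12), AlignmentBlock(4, 40, 62, 170)]
        accepted, rejected = identify_introns(blocks, locus, protein)
        assert len(accepted) == 1
        i = accepted[0]
        assert (i.cds_offset, i.phase, i.anchor_residue) == (12, 0, 5)
        assert rejected == []

    def test_overlapping_blocks_malformed(self, rng):
        cds, locus, protein = self._gene(rng)
        blocks = [AlignmentBlock(0, 10, 0, 30), AlignmentBlock(10, 20, 30, 60)]
        with pytest.raises(MalformedChainError):
            identify_introns(blocks, locus, protein)

    def test_phase1_and_phase2_recovery(self, rng):
        for offset in (61, 62, 100, 101):
            cds = random_cds(rng, 60)
            locus = GenomicLocus("g", build_locus(cds, [(offset, make_intron(rng, 70))]))
            protein = translate(cds)
            res = spliced_align(protein, locus)
            accepted, rejected = identify_introns(res, locus, protein)
            assert [(i.cds_offset, i.phase) for i in accepted] == [
                (offset, offset % 3)
            ], (offset, rejected)

    def test_filter_monotonicity_relaxing_length_only_adds(self, rng):
        introns = [(45, make_intron(rng, 25)), (105, make_intron(rng, 80))]
        cds, locus, protein = self._gene(rng, introns=introns)
        res = spliced_align(protein, locus)
        strict, _ = identify_introns(res, locus, protein, min_length=30)
        relaxed, _ = identify_introns(res, locus, protein, min_length=21)
        strict_set = {(i.cds_offset, i.phase) for i in strict}
        relaxed_set = {(i.cds_offset, i.phase) for i in relaxed}
        assert strict_set <= relaxed_set
        assert len(relaxed) == 2 and len(strict) == 1


class TestVerifyJunction:
    def _setup(self, rng, offset=60):
        cds = random_cds(rng, 40)
        intron = make_intron(rng, 60)
        locus = GenomicLocus("g", build_locus(cds, [(offset, intron)]))
        return cds, locus, translate(cds), offset, offset + 60

    def test_identity_true(self, rng):
        cds, locus, protein, a, b = self._setup(rng)
        assert verify_junction(locus, a, b, 60, protein, 0, len(locus))

    def test_single_mismatch_false(self, rng):
        cds, locus, protein, a, b = self._setup(rng)
        mutated = list(protein)
        mutated[20] = "W" if mutated[20] != "W" else "Y"  # residue right after
        assert not verify_junction(locus, a, b, 60, "".join(mutated), 0, len(locus))

    def test_phase1_split_codon_reassembled(self, rng):
        # hand-checked: intron after coding nt 61 splits codon 20 (0-based)
        cds, locus, protein, a, b = (None,) * 5
        cds = random_cds(rng, 40)
        locus = GenomicLocus("g", build_locus(cds, [(61, make_intron(rng, 60))]))
        protein = translate(cds)
        assert verify_junction(locus, 61, 121, 61, protein, 0, len(locus))
        bad = list(protein)
        bad[20] = "W" if bad[20] != "W" else "Y"
        assert not verify_junction(locus, 61, 121, 61, "".join(bad), 0, len(locus))


class TestStructureFromAlignment:
    def test_intronless_gene_empty_list(self, rng):
        cds = random_cds(rng, 80)
        res = structure_from_alignment(translate(cds), GenomicLocus("g", cds))
        assert res.structure.introns == []
        assert res.rejected == []

    def test_noncanonical_donor_in_rejection_log(self, rng):
        cds = random_cds(rng, 80)
        introns = [(60, make_intron(rng, 90, donor="GC")), (150, make_intron(rng, 90))]
        locus = GenomicLocus("g", build_locus(cds, introns))
        res = structure_from_alignment(translate(cds), locus)
        assert [(i.cds_offset, i.phase) for i in res.structure.introns] == [(150, 0)]
        assert [r.reason for r in res.rejected] == ["SITE"]

    def test_phase_anchor_invariant_on_outputs(self, small_study):
        for fam in small_study.families:
            for sp, s in fam.structures.items():
                res = structure_from_alignment(s.protein, fam.loci[sp])
                for i in res.structure.introns:
                    assert i.phase == i.cds_offset % 3
                    assert i.anchor_residue == i.cds_offset // 3 + 1

    def test_roundtrip_against_simulator_truth(self, small_study):
        for fam in small_study.families:
            for sp, s in fam.structures.items():
                res = structure_from_alignment(s.protein, fam.loci[sp])
                assert [(i.cds_offset, i.phase) for i in res.structure.introns] == [
                    (i.cds_offset, i.phase) for i in s.introns
                ]
                assert res.rejected == []
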