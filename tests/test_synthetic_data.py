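import dataclasses
import itertools
import math

import numpy as np
import pytest

from introntrace._seq import translate
from introntrace.errors import ConfigError
from introntrace.synthetic_data import (
    SimulationConfig,
    config_with,
    emit_genomic,
    evolve_introns,
    legal_gain_offsets,
    simulate_family,
    simulate_study,
    splice,
)
from introntrace.transfer_timing import SpeciesTree

from helpers import random_cds


class TestConfig:
    def test_seed_mandatory(self):
        with pytest.raises(TypeError):
            SimulationConfig()

    def test_min_intron_length_over_20_enforced(self):
        with pytest.raises(ConfigError):
            SimulationConfig(seed=1, intron_length=(20, 100))

    def test_bad_site_model(self):
        with pytest.raises(ConfigError):
            SimulationConfig(seed=1, site_model="magnetic")


class TestEvolveIntrons:
    def test_poisson_gain_mean(self, rng):
        cfg = SimulationConfig(
            seed=1, gain_rate=2.0, loss_rate=0.0,
            min_intron_spacing=0, min_terminal_exon=0,
        )
        cds = random_cds(rng, 400)  # 1200 nt; lambda*L/1000*t = 4 at t ~ 1.667
        t = 4 / (2.0 * 1.2)
        total = 0
        reps = 3000
        for _ in range(reps):
            introns, gained, _ = evolve_introns([], cds, t, cfg, rng)
            total += len(gained)
        mean = total / reps
        sigma = math.sqrt(4 / reps)
        assert abs(mean - 4) < 3.5 * sigma + 0.05  # small thinning deficit

    def test_all_lost_at_huge_loss_rate(self, rng):
        cfg = SimulationConfig(seed=1, gain_rate=0.0, loss_rate=1e9)
        introns = [(30, 0, 0), (61, 1, 1)]
        out, gained, lost = evolve_introns(introns, random_cds(rng, 100), 1.0, cfg, rng)
        assert out == [] and gained == [] and len(lost) == 2

    def test_zero_rates_identity(self, rng):
        cfg = SimulationConfig(seed=1, gain_rate=0.0, loss_rate=0.0)
        introns = [(33, 0, 0)]
        out, gained, lost = evolve_introns(introns, random_cds(rng, 100), 5.0, cfg, rng)
        assert out == introns and not gained and not lost

    def test_phase_weights_recovered(self, rng):
        cfg = SimulationConfig(
            seed=1, gain_rate=8.0, loss_rate=0.0,
            min_intron_spacing=0, min_terminal_exon=0,
        )
        cds = random_cds(rng, 500)
        counts = [0, 0, 0]
        while sum(counts) < 2500:
            _, gained, _ = evolve_introns([], cds, 1.0, cfg, rng)
            for _, p, _ in gained:
                counts[p] += 1
        n = sum(counts)
        for k, expect in enumerate((0.5, 0.3, 0.2)):
            sigma = math.sqrt(expect * (1 - expect) / n)
            assert abs(counts[k] / n - expect) < 3.5 * sigma

    def test_targeted_mode_hits_proto_sites_only(self, rng):
        cfg = SimulationConfig(
            seed=1, gain_rate=20.0, loss_rate=0.0,
            site_model="proto_splice_targeted",
            min_intron_spacing=0, min_terminal_exon=0,
        )
        cds = random_cds(rng, 300)
        legal = set(legal_gain_offsets(cds, cfg))
        _, gained, _ = evolve_introns([], cds, 2.0, cfg, rng)
        assert gained and all(o in legal for o, _, _ in gained)


class TestEmitGenomic:
    def test_no_introns_locus_equals_cds(self, rng):
        cfg = SimulationConfig(seed=1)
        cds = random_cds(rng, 60)
        locus, positions = emit_genomic(cds, [], cfg, rng)
        assert locus.sequence == cds and positions == []

    def test_single_intron_geometry(self, rng):
        cfg = SimulationConfig(seed=1, intron_length=(100, 100))
        cds = random_cds(rng, 60)
        locus, positions = emit_genomic(cds, [(12, 0, 0)], cfg, rng)
        assert len(locus.sequence) == len(cds) + 100
        assert locus.sequence[12:14] == "GT"
        assert locus.sequence[110:112] == "AG"
        assert positions[0].g_start == 12 and positions[0].g_end == 112

    def test_roundtrip_many_random_structures(self, rng):
        cfg = SimulationConfig(seed=1, intron_length=(60, 200))
        for _ in range(200):
            cds = random_cds(rng, int(rng.integers(50, 150)))
            offsets = sorted(
                {int(o) for o in rng.integers(30, len(cds) - 30, rng.integers(0, 5))}
            )
            introns = [(o, o % 3, k) for k, o in enumerate(offsets)]
            locus, positions = emit_genomic(cds, introns, cfg, rng)
            assert splice(locus.sequence, positions) == cds

    def test_min_length_config_error(self, rng):
        bad = SimulationConfig(seed=1)
        bad.intron_length = (10, 50)  # bypass constructor validation
        with pytest.raises(ConfigError):
            emit_genomic(random_cds(rng, 50), [(30, 0, 0)], bad, rng)


class TestSimulateFamily:
    def test_lambda_zero_all_intron_free(self):
        cfg = SimulationConfig(seed=5, gain_rate=0.0, n_genes=2)
        fam = simulate_family(cfg, "geneA")
        assert all(s.n_introns == 0 for s in fam.structures.values())

    def test_determinism_same_seed(self):
        cfg = SimulationConfig(seed=9)
        f1 = simulate_family(cfg, "geneA")
        f2 = simulate_family(cfg, "geneA")
        assert f1.cds == f2.cds
        assert f1.transfer_branches == f2.transfer_branches
        assert {
            sp: [(i.cds_offset, i.g_start, i.g_end) for i in s.introns]
            for sp, s in f1.structures.items()
        } == {
            sp: [(i.cds_offset, i.g_start, i.g_end) for i in s.introns]
            for sp, s in f2.structures.items()
        }
        assert f1.alignment.rows == f2.alignment.rows

    def test_no_intron_in_mitochondrial_gene_or_above_transfer(self, small_study):
        tree = small_study.tree
        for fam in small_study.families:
            transfer_nodes = [tree.by_branch[b] for b in fam.transfer_branches]
            for sp, s in fam.structures.items():
                if s.compartment == "mitochondrial":
                    assert s.n_introns == 0
                    assert fam.loci[sp].sequence == fam.cds[sp]
            for ev in fam.events:
                node = tree.by_branch[ev.branch]
                assert any(
                    node is t or tree.is_ancestor(t, node) for t in transfer_nodes
                ), (fam.gene_id, ev)

    def test_every_intron_traces_to_one_event(self, small_study):
        for fam in small_study.families:
            event_ids = {e.event_id for e in fam.events}
            for sp, evs in fam.intron_events.items():
                assert len(evs) == fam.structures[sp].n_introns
                assert set(evs) <= event_ids

    def test_explicit_transfer_branches(self):
        cfg = SimulationConfig(seed=3, transfers={"geneA": ["cre", "dre+hsa"]})
        fam = simulate_family(cfg, "geneA")
        assert fam.transfer_branches == ["cre", "dre+hsa"]
        nuclear = {sp for sp, st in fam.true_states.items() if st == "N"}
        assert nuclear == {"cre", "dre", "hsa"}

    def test_unknown_transfer_branch_error(self):
        cfg = SimulationConfig(seed=3, transfers={"geneA": ["nope"]})
        with pytest.raises(ConfigError):
            simulate_family(cfg, "geneA")

    def test_true_alignment_rows_ungap_to_proteins(self, small_study):
        for fam in small_study.families:
            for sp, s in fam.structures.items():
                row = fam.alignment.rows[f"{fam.gene_id}|{sp}"]
                assert row.replace("-", "") == s.protein

    def test_descent_parallel_labels_partition(self, small_study):
        for fam in small_study.families:
            carried = set()
            for sp, s in fam.structures.items():
                col_of = fam.alignment.residue_to_column(f"{fam.gene_id}|{sp}")
                for i in s.introns:
                    carried.add((col_of[i.anchor_residue - 1], i.phase))
            assert set(fam.position_labels) == carried
            assert set(fam.position_labels.values()) <= {
                "unique", "descent", "parallel",
            }


class TestIndels:
    def test_insertion_creates_gap_columns(self):
        cfg = SimulationConfig(
            seed=21, indel_mode="simple", indel_rate=0.6, n_genes=1,
            gain_rate=1.0,
        )
        fam = simulate_family(cfg, "geneA")
        lengths = {len(r.replace("-", "")) for r in fam.alignment.rows.values()}
        rows = fam.alignment.rows
        if len(lengths) > 1:  # at least one insertion happened
            assert any("-" in r for r in rows.values())
        for sp, s in fam.structures.items():
            assert rows[f"geneA|{sp}"].replace("-", "") == s.protein

    def test_roundtrip_still_exact_with_indels(self):
        from introntrace.intron_mapping import structure_from_alignment

        cfg = SimulationConfig(
            seed=22, indel_mode="simple", indel_rate=0.4, n_genes=1
        )
        fam = simulate_family(cfg, "geneA")
        for sp, s in fam.structures.items():
            res = structure_from_alignment(s.protein, fam.loci[sp])
            assert [(i.cds_offset, i.phase) for i in res.structure.introns] == [
                (i.cds_offset, i.phase) for i in s.introns
            ]


def test_study_determinism_and_shape():
    cfg = SimulationConfig(seed=4, n_genes=3)
    s1, s2 = simulate_study(cfg), simulate_study(cfg)
    assert [f.gene_id for f in s1.families] == ["gene000", "gene001", "gene002"]
    for f1, f2 in zip(s1.families, s2.families):
        assert f1.cds == f2.cds and f1.localization == f2.localization
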