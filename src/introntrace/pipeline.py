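"""End-to-end orchestration: simulate -> map -> stats -> timing -> shared ->
context, with a reconciled run report.

Stages communicate through plain files in the output directory, so each stage
is also usable on externally supplied inputs with the same formats:

* ``proteins.fasta`` / ``loci.fasta`` / ``cds.fasta`` — ids ``gene|species``
* ``localization.tsv`` — gene_id, species_id, state (M/N/U)
* ``grouping.tsv`` — species_id, group
* ``tree.nwk`` — rooted newick, multifurcations allowed
* ``alignments/<gene>.afa`` — aligned FASTA per family
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import io_utils, shared_positions, splice_context, structure_stats
from .errors import IntronTraceError, NoSplicedAlignmentError, ValidationError
from .intron_mapping import (
    GeneStructure,
    IntronPosition,
    structure_from_alignment,
)
from .shared_positions import ProteinAlignment
from .synthetic_data import SimulationConfig, StudyTruth, simulate_study
from .transfer_timing import (
    GeneLocalization,
    SpeciesTree,
    annotate_events_newick,
    find_independent_transfers,
    infer_transfers,
    rank_transfer_times,
)

log = logging.getLogger("introntrace")

ALL_STAGES = ("simulate", "map", "stats", "timing", "shared", "context")


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    simulation: dict = field(default_factory=dict)  # SimulationConfig overrides
    input_dir: str | None = None  # read inputs here instead of simulating
    mapping: dict = field(default_factory=dict)  # structure_from_alignment kwargs
    blocks: dict = field(default_factory=dict)  # detect_conserved_blocks kwargs
    focal_groups: tuple[str, str] = ("green_alga", "animals")

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValidationError(f"unknown stages: {sorted(unknown)}")


def _structure_to_dict(s: GeneStructure) -> dict:
    return {
        "gene_id": s.gene_id,
        "species_id": s.species_id,
        "compartment": s.compartment,
        "protein": s.protein,
        "introns": [dataclasses.asdict(i) for i in s.introns],
    }


def structure_from_dict(d: dict) -> GeneStructure:
    return GeneStructure(
        gene_id=d["gene_id"],
        species_id=d["species_id"],
        compartment=d["compartment"],
        protein=d["protein"],
        introns=[IntronPosition(**i) for i in d["introns"]],
    )


def write_simulation(truth: StudyTruth, out: Path) -> None:
    """Emit every simulator artifact as plain-text files."""
    proteins, loci, cds, loc_rows = {}, {}, {}, []
    truth_obj = {"families": {}}
    for fam in truth.families:
        for sp in sorted(fam.structures):
            sid = f"{fam.gene_id}|{sp}"
            proteins[sid] = fam.structures[sp].protein
            loci[sid] = fam.loci[sp].sequence
            cds[sid] = fam.cds[sp]
            loc_rows.append(
                {
                    "gene_id": fam.gene_id,
                    "species_id": sp,
                    "state": fam.localization[sp],
                }
            )
        io_utils.write_fasta(
            out / "alignments" / f"{fam.gene_id}.afa", dict(sorted(fam.alignment.rows.items()))
        )
        truth_obj["families"][fam.gene_id] = {
            "transfer_branches": fam.transfer_branches,
            "true_states": fam.true_states,
            "structures": {
                sp: _structure_to_dict(s) for sp, s in sorted(fam.structures.items())
            },
            "events": [dataclasses.asdict(e) for e in fam.events],
            "position_labels": {
                f"{c}:{p}": lab for (c, p), lab in sorted(fam.position_labels.items())
            },
        }
    io_utils.write_fasta(out / "proteins.fasta", dict(sorted(proteins.items())))
    io_utils.write_fasta(out / "loci.fasta", dict(sorted(loci.items())))
    io_utils.write_fasta(out / "cds.fasta", dict(sorted(cds.items())))
    io_utils.write_tsv(
        out / "localization.tsv", loc_rows, ["gene_id", "species_id", "state"]
    )
    (out / "tree.nwk").write_text(truth.config.tree_newick + "\n")
    io_utils.write_tsv(
        out / "grouping.tsv",
        [
            {"species_id": sp, "group": g}
            for sp, g in sorted(truth.config.groups.items())
        ],
        ["species_id", "group"],
    )
    io_utils.write_json(out / "truth.json", truth_obj)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages in dependency order; returns the run report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": dataclasses.asdict(config), "stages": {}}
    data_dir = Path(config.input_dir) if config.input_dir else out

    if "simulate" in config.stages:
        sim_cfg = SimulationConfig.from_dict({"seed": config.seed, **config.simulation})
        truth = simulate_study(sim_cfg)
        write_simulation(truth, out)
        data_dir = out
        report["stages"]["simulate"] = {
            "n_genes": len(truth.families),
            "n_species": len(truth.tree.leaf_names),
            "n_events": sum(len(f.events) for f in truth.families),
        }
        log.info("simulate: %s", report["stages"]["simulate"])

    structures: list[GeneStructure] = []
    if "map" in config.stages:
        proteins = io_utils.read_fasta(data_dir / "proteins.fasta")
        loci = io_utils.read_fasta(data_dir / "loci.fasta")
        missing = sorted(set(proteins) - set(loci))
        if missing:
            raise ValidationError(f"loci missing for sequences: {missing[:5]}")
        intron_rows, reject_rows = [], []
        n_failed = 0
        from .intron_mapping import GenomicLocus

        for sid in sorted(proteins):
            gene_id, species_id = io_utils.split_seq_id(sid)
            locus = GenomicLocus(sid, loci[sid], species_id)
            try:
                res = structure_from_alignment(
                    proteins[sid], locus, gene_id=gene_id,
                    species_id=species_id, **config.mapping,
                )
            except NoSplicedAlignmentError:
                n_failed += 1
                continue
            structures.append(res.structure)
            for i in res.structure.introns:
                intron_rows.append(
                    {
                        "gene_id": gene_id,
                        "species_id": species_id,
                        "cds_offset": i.cds_offset,
                        "phase": i.phase,
                        "anchor_residue": i.anchor_residue,
                        "intron_length": i.length,
                        "donor": i.donor,
                        "acceptor": i.acceptor,
                    }
                )
            for r in res.rejected:
                reject_rows.append(
                    {
                        "gene_id": gene_id,
                        "species_id": species_id,
                        "g_start": r.g_start,
                        "g_end": r.g_end,
                        "reason": r.reason,
                    }
                )
        io_utils.write_tsv(
            out / "introns.tsv",
            intron_rows,
            [
                "gene_id", "species_id", "cds_offset", "phase",
                "anchor_residue", "intron_length", "donor", "acceptor",
            ],
        )
        io_utils.write_tsv(
            out / "rejections.tsv",
            reject_rows,
            ["gene_id", "species_id", "g_start", "g_end", "reason"],
        )
        io_utils.write_json(
            out / "structures.json", [_structure_to_dict(s) for s in structures]
        )
        n_candidates = len(intron_rows) + len(reject_rows)
        report["stages"]["map"] = {
            "sequences": len(proteins),
            "unaligned": n_failed,
            "candidates": n_candidates,
            "accepted": len(intron_rows),
            "rejected": len(reject_rows),
        }
        assert (
            report["stages"]["map"]["accepted"]
            + report["stages"]["map"]["rejected"]
            == n_candidates
        )
        log.info("map: %s", report["stages"]["map"])

    if "stats" in config.stages:
        if not structures:
            structures = [
                structure_from_dict(d)
                for d in io_utils.read_json(out / "structures.json")
            ]
        per_gene = [
            {
                "gene_id": s.gene_id,
                "species_id": s.species_id,
                "n_introns": s.n_introns,
                "cds_len": s.cds_len,
                "density": structure_stats.intron_density(s),
            }
            for s in structures
        ]
        io_utils.write_tsv(
            out / "gene_stats.tsv",
            per_gene,
            ["gene_id", "species_id", "n_introns", "cds_len", "density"],
        )
        pooled = structure_stats.compute_stats(structures)
        by_species = structure_stats.grouped_stats(structures)
        stats_obj = {"pooled": _stats_to_dict(pooled)}
        stats_obj["per_species"] = {
            sp: _stats_to_dict(st) for sp, st in by_species.items()
        }
        io_utils.write_json(out / "structure_stats.json", stats_obj)
        report["stages"]["stats"] = {
            "n_genes": pooled.n_genes,
            "n_introns": pooled.n_introns,
            "density": pooled.density,
        }

    scenarios = {}
    if "timing" in config.stages:
        tree = SpeciesTree.from_newick((data_dir / "tree.nwk").read_text())
        loc = io_utils.read_localization_tsv(data_dir / "localization.tsv")
        for gene_id in sorted(loc):
            scenarios[gene_id] = infer_transfers(
                tree, GeneLocalization(gene_id, loc[gene_id])
            )
        io_utils.write_json(
            out / "scenarios.json",
            {
                g: {
                    "transfer_branches": sorted(s.transfer_branches),
                    "n_events": s.n_events,
                    "resolved": s.resolved,
                    "alternatives": [sorted(a) for a in s.alternatives],
                }
                for g, s in scenarios.items()
            },
        )
        independent = find_independent_transfers(scenarios)
        io_utils.write_tsv(
            out / "independent_transfers.tsv",
            [
                {
                    "gene_id": r["gene_id"],
                    "n_events": r["n_events"],
                    "lineages": ";".join(r["lineages"]),
                    "resolved": r["resolved"],
                }
                for r in independent
            ],
            ["gene_id", "n_events", "lineages", "resolved"],
        )
        (out / "tree_with_events.nwk").write_text(
            annotate_events_newick(tree, scenarios) + "\n"
        )
        rank_transfer_times(scenarios, tree)  # constructed for side-effect-free validation
        report["stages"]["timing"] = {
            "genes": len(scenarios),
            "independent": len(independent),
            "unresolved": sum(1 for s in scenarios.values() if not s.resolved),
        }

    if "shared" in config.stages:
        if not structures:
            structures = [
                structure_from_dict(d)
                for d in io_utils.read_json(out / "structures.json")
            ]
        grouping_sp = io_utils.read_grouping_tsv(data_dir / "grouping.tsv")
        by_gene: dict[str, list[GeneStructure]] = {}
        for s in structures:
            by_gene.setdefault(s.gene_id, []).append(s)
        table_rows, detail_rows = [], []
        matrices = {}
        n_specific = n_shared = n_total = 0
        for gene_id in sorted(by_gene):
            afa = data_dir / "alignments" / f"{gene_id}.afa"
            aln = ProteinAlignment(gene_id, io_utils.read_fasta(afa))
            matrix = shared_positions.map_introns_to_alignment(aln, by_gene[gene_id])
            matrices[gene_id] = matrix
            grouping = {
                sid: grouping_sp[io_utils.split_seq_id(sid)[1]]
                for sid in aln.rows
            }
            blocks = shared_positions.detect_conserved_blocks(aln, **config.blocks)
            for variant, table in (
                ("all_columns", shared_positions.find_shared_positions(matrix, grouping)),
                (
                    "conserved_blocks",
                    shared_positions.shared_positions_in_blocks(
                        matrix, grouping, blocks
                    ),
                ),
            ):
                for g in table.groups:
                    table_rows.append(
                        {
                            "gene_id": gene_id,
                            "variant": variant,
                            "group_1": g,
                            "group_2": g,
                            "count": table.diagonal[g],
                            "percent": "",
                        }
                    )
                for pair, count in sorted(
                    table.pair_counts.items(), key=lambda kv: sorted(kv[0])
                ):
                    g1, g2 = sorted(pair)
                    table_rows.append(
                        {
                            "gene_id": gene_id,
                            "variant": variant,
                            "group_1": g1,
                            "group_2": g2,
                            "count": count,
                            "percent": table.pair_percentages[pair],
                        }
                    )
                if variant == "all_columns":
                    n_specific += sum(table.diagonal.values())
                    n_shared += table.n_shared_distinct
                    n_total += table.total_positions
            for col, phase in sorted(matrix.positions()):
                carriers = sorted(matrix.carriers(col, phase))
                detail_rows.append(
                    {
                        "gene_id": gene_id,
                        "column": col,
                        "phase": phase,
                        "carriers": ";".join(carriers),
                        "groups": ";".join(sorted({grouping[c] for c in carriers})),
                        "in_block": any(col in b for b in blocks),
                    }
                )
        assert n_specific + n_shared == n_total  # conservation of positions
        io_utils.write_tsv(
            out / "shared_positions.tsv",
            table_rows,
            ["gene_id", "variant", "group_1", "group_2", "count", "percent"],
        )
        io_utils.write_tsv(
            out / "position_detail.tsv",
            detail_rows,
            ["gene_id", "column", "phase", "carriers", "groups", "in_block"],
        )
        report["stages"]["shared"] = {
            "families": len(by_gene),
            "positions": n_total,
            "specific": n_specific,
            "shared": n_shared,
        }
        if scenarios:
            comp = shared_positions.compare_transfer_classes(
                matrices,
                {g: s.n_events for g, s in scenarios.items()},
                {
                    f"{s.gene_id}|{s.species_id}": grouping_sp[s.species_id]
                    for s in structures
                },
                config.focal_groups,
            )
            io_utils.write_json(
                out / "transfer_class_comparison.json",
                {
                    "focal_groups": list(comp.focal_groups),
                    "pct_independent": comp.pct_independent,
                    "pct_single": comp.pct_single,
                    "ratio": comp.ratio,
                    "shared_independent": comp.shared_independent,
                    "total_independent": comp.total_independent,
                    "shared_single": comp.shared_single,
                    "total_single": comp.total_single,
                },
            )

    if "context" in config.stages:
        if not structures:
            structures = [
                structure_from_dict(d)
                for d in io_utils.read_json(out / "structures.json")
            ]
        cds_map = io_utils.read_fasta(data_dir / "cds.fasta")
        pairs = [
            (s, cds_map[f"{s.gene_id}|{s.species_id}"])
            for s in structures
            if f"{s.gene_id}|{s.species_id}" in cds_map
        ]
        rows = splice_context.context_table(pairs)
        io_utils.write_tsv(
            out / "splice_context.tsv",
            rows,
            [
                "gene_id", "species_id", "cds_offset", "phase",
                "upstream_tri", "downstream_nt", "proto_splice",
            ],
        )
        usage_rows = []
        for compartment in ("nuclear", "mitochondrial"):
            cset = [c for s, c in pairs if s.compartment == compartment]
            if not cset:
                continue
            for aa, codons in splice_context.codon_usage(cset, compartment).items():
                for codon, frac in codons.items():
                    usage_rows.append(
                        {
                            "compartment": compartment,
                            "amino_acid": aa,
                            "codon": codon,
                            "fraction": frac,
                        }
                    )
        io_utils.write_tsv(
            out / "codon_usage.tsv",
            usage_rows,
            ["compartment", "amino_acid", "codon", "fraction"],
        )
        report["stages"]["context"] = {
            "introns": len(rows),
            "proto_splice": sum(1 for r in rows if r["proto_splice"]),
        }

    # truth comparison when a truth log is available
    truth_path = data_dir / "truth.json"
    if truth_path.exists() and structures:
        truth_obj = io_utils.read_json(truth_path)
        true_set, found_set = set(), set()
        for gene_id, fam in truth_obj["families"].items():
            for sp, sd in fam["structures"].items():
                for i in sd["introns"]:
                    true_set.add((gene_id, sp, i["cds_offset"], i["phase"]))
        for s in structures:
            for i in s.introns:
                found_set.add((s.gene_id, s.species_id, i.cds_offset, i.phase))
        tp = len(true_set & found_set)
        report["truth_comparison"] = {
            "true_introns": len(true_set),
            "recovered": tp,
            "recall": tp / len(true_set) if true_set else 1.0,
            "false_positives": len(found_set - true_set),
        }

    io_utils.write_json(out / "report.json", report)
    return report


def _stats_to_dict(st: structure_stats.StructureStats) -> dict:
    return {
        "n_genes": st.n_genes,
        "n_introns": st.n_introns,
        "total_cds_len": st.total_cds_len,
        "density": st.density,
        "phase_counts": list(st.phase_counts),
        "phase_fractions": list(st.phase_fractions) if st.phase_fractions else None,
        "symmetry_counts": st.symmetry_counts.tolist(),
        "symmetric_fraction": st.symmetric_fraction,
    }
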