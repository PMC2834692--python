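# introntrace

Toolkit for studying spliceosomal intron gain in genes transferred from the
mitochondrion to the nucleus. Because such genes were intron-less at the
moment of transfer, every intron they carry today was gained afterwards —
which makes them a natural experiment for intron evolution. The package
implements the full analysis chain plus a simulator that generates gene
families with known ground truth:

1. **intron_mapping** — a deterministic seed-and-chain spliced aligner maps a
   protein onto its genomic locus; inter-block gaps are screened as introns
   (length > 20 nt, canonical GT..AG, and an 18-nt translated junction
   check), yielding intron positions and phases.
2. **structure_stats** — intron density (introns/kb CDS), phase
   distribution, and exon-symmetry classes for internal exons.
3. **transfer_timing** — irreversible (Dollo-style) parsimony placement of
   transfer events on a rooted species tree from per-species localization
   states (M/N/U), with enumeration of equally parsimonious alternatives,
   detection of independently transferred genes, and relative timing.
4. **shared_positions** — maps introns onto protein alignments, counts
   group-specific and shared (column, phase) positions, restricts to
   conserved blocks, and compares sharing between independently- and
   singly-transferred genes.
5. **splice_context** — proto-splice-site contexts ((C|A)AG - (A|G)) and
   compartment-resolved codon usage (e.g. the Gln CAA/CAG contrast).
6. **synthetic_data** — simulates families on a species tree with sampled
   transfer branches, Poisson intron gain (uniform or proto-splice-targeted
   sites, configurable phase weights), exponential loss, compartment codon
   usage, and full event-level ground truth (descent vs parallel labels).
7. **pipeline / cli** — orchestration, plain-text file adapters, reconciled
   run reports.

## CLI

```bash
# generate a synthetic study (writes FASTA/TSV/newick/truth.json)
introntrace simulate --out out/ --seed 1

# or run everything end to end: simulate -> map -> stats -> timing -> shared -> context
introntrace run --out out/ --seed 1

# individual stages on existing inputs
introntrace map-introns --input-dir data/ --out out/
introntrace timing      --input-dir data/ --out out/
```

Sequence ids follow the `gene_id|species_id` convention in all FASTA files.
Expected inputs per stage: `proteins.fasta` + `loci.fasta` (map),
`tree.nwk` + `localization.tsv` (timing), `alignments/<gene>.afa` +
`grouping.tsv` (shared), `cds.fasta` (context). Outputs include per-gene
intron tables with a rejection log (reason codes LENGTH/SITE/JUNCTION),
scenario JSON, shared-position tables in two variants (all columns /
conserved blocks), codon-usage and splice-context TSVs, and `report.json`
with reconciled counts. Runs are byte-identical under a fixed seed.

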