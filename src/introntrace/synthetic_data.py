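"""Ground-truth simulator: gene families evolving on a rooted species tree
with irreversible mitochondrion-to-nucleus transfers, post-transfer intron
gain/loss, compartment-specific codon usage and optional simple insertions.

Mechanics per gene: the root sequence is mitochondrial-encoded; a transfer
event on a branch switches the lineage to nuclear (once, irreversibly) and
resamples codons synonymously from the nuclear usage table. Introns evolve
only at/below a transfer: gains arrive as a Poisson process (rate
``gain_rate`` per kb of CDS per unit branch length), sites drawn uniformly
over legal offsets or over proto-splice sites in targeted mode; existing
introns are lost with probability 1 - exp(-loss_rate * t). Gains landing on
an occupied or too-close site are discarded (Poisson thinning), which keeps
per-site occupancy analytically tractable.

Every extant intron traces to exactly one recorded gain event, which is what
lets shared positions be labelled shared-by-descent (one event) versus
parallel (several events).
"""
from __future__ import annotations

import itertools
import math
from collections.abc import Mapping
from dataclasses import dataclass, field, replace

import numpy as np

from ._seq import synonymous_codons, translate
from .errors import ConfigError, ValidationError
from .intron_mapping import GeneStructure, GenomicLocus, IntronPosition
from .shared_positions import ProteinAlignment
from .splice_context import scan_proto_splice_sites
from .transfer_timing import SpeciesTree, TreeNode

AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: 12-leaf preset mimicking the animals/fungi + plants/green-alga + protists
#: layout of the study tree (root multifurcation).
PRESET_TREE = (
    "((((hsa:0.20,dre:0.25):0.30,(dme:0.35,cel:0.40):0.25):0.20,"
    "((sce:0.30,spo:0.30):0.20,afu:0.40):0.30):0.20,"
    "((ath:0.20,osa:0.20):0.20,cre:0.45):0.25,"
    "(ddi:0.50,pfa:0.55):0.20):0.0;"
)

PRESET_GROUPS = {
    "hsa": "animals",
    "dre": "animals",
    "dme": "animals",
    "cel": "animals",
    "sce": "fungi",
    "spo": "fungi",
    "afu": "fungi",
    "ath": "plants",
    "osa": "plants",
    "cre": "green_alga",
    "ddi": "protists",
    "pfa": "protists",
}

SITE_MODELS = ("uniform", "proto_splice_targeted")
INDEL_MODES = ("none", "simple")


def default_codon_usage() -> dict[str, dict[str, dict[str, float]]]:
    """Uniform synonymous usage except glutamine: CAG-rich nuclear, CAA-rich
    mitochondrial (the published contrast)."""
    base: dict[str, dict[str, float]] = {}
    for aa, codons in synonymous_codons().items():
        base[aa] = {c: 1.0 / len(codons) for c in codons}
    nuclear = {aa: dict(ws) for aa, ws in base.items()}
    mito = {aa: dict(ws) for aa, ws in base.items()}
    nuclear["Q"] = {"CAA": 0.1, "CAG": 0.9}
    mito["Q"] = {"CAA": 0.9, "CAG": 0.1}
    return {"nuclear": nuclear, "mitochondrial": mito}


@dataclass
class SimulationConfig:
    """All simulator knobs; ``seed`` is mandatory."""

    seed: int
    tree_newick: str = PRESET_TREE
    groups: dict[str, str] = field(default_factory=lambda: dict(PRESET_GROUPS))
    n_genes: int = 20
    protein_length: tuple[int, int] = (150, 250)
    transfer_prob: float = 0.2  # per still-mitochondrial branch (root included)
    transfers: dict[str, list[str]] | None = None  # explicit branch labels per gene
    gain_rate: float = 2.0  # gains per kb CDS per unit branch length
    loss_rate: float = 0.1
    phase_weights: tuple[float, float, float] = (5.0, 3.0, 2.0)
    site_model: str = "uniform"
    intron_length: tuple[int, int] = (60, 500)
    min_intron_spacing: int = 30  # nt between intron offsets (0 disables)
    min_terminal_exon: int = 30  # nt of CDS kept intron-free at each end
    subst_prob: float = 0.02  # per residue per unit branch length
    codon_usage: dict[str, dict[str, dict[str, float]]] = field(
        default_factory=default_codon_usage
    )
    indel_mode: str = "none"
    indel_rate: float = 0.0  # insertions per gene per unit branch length
    prob_unknown: float = 0.0  # mask a leaf's localization to U

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if self.site_model not in SITE_MODELS:
            raise ConfigError(f"site_model must be one of {SITE_MODELS}")
        if self.indel_mode not in INDEL_MODES:
            raise ConfigError(f"indel_mode must be one of {INDEL_MODES}")
        if self.intron_length[0] <= 20:
            raise ConfigError(
                "minimum intron length must exceed 20 nt (the acceptance "
                "filter would reject every simulated intron)"
            )
        if self.intron_length[0] > self.intron_length[1]:
            raise ConfigError("intron_length range inverted")
        if min(self.phase_weights) < 0 or sum(self.phase_weights) <= 0:
            raise ConfigError("phase weights must be non-negative, sum > 0")
        if self.gain_rate < 0 or self.loss_rate < 0 or self.subst_prob < 0:
            raise ConfigError("rates must be >= 0")
        if not 0 <= self.transfer_prob <= 1 or not 0 <= self.prob_unknown <= 1:
            raise ConfigError("probabilities must lie in [0, 1]")

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        for key in ("protein_length", "phase_weights", "intron_length"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class GainEvent:
    """One intron-gain event on a branch; the unit of descent tracking."""

    event_id: int
    gene_id: str
    branch: str  # branch label (sorted leaf names)
    site_id: int  # anchor residue's site id
    phase: int


@dataclass
class FamilyTruth:
    """Everything the simulator knows about one gene family."""

    gene_id: str
    transfer_branches: list[str]
    structures: dict[str, GeneStructure]  # species -> structure
    loci: dict[str, GenomicLocus]
    cds: dict[str, str]
    alignment: ProteinAlignment
    localization: dict[str, str]  # observed states (may contain U)
    true_states: dict[str, str]  # actual states (M / N only)
    events: list[GainEvent]
    # (alignment column, phase) -> "descent" | "parallel" | "unique"
    position_labels: dict[tuple[int, int], str]
    intron_events: dict[str, list[int]]  # species -> event_id per intron, in order


@dataclass
class StudyTruth:
    config: SimulationConfig
    tree: SpeciesTree
    families: list[FamilyTruth]


# ---------------------------------------------------------------------------
# per-branch intron dynamics (offset-based core, reused by tests directly)
# ---------------------------------------------------------------------------


def legal_gain_offsets(cds: str, config: SimulationConfig) -> list[int]:
    """Offsets where a gain may land under the configured site model,
    before occupancy/spacing thinning."""
    lo = max(1, config.min_terminal_exon)
    hi = len(cds) - max(1, config.min_terminal_exon)
    if config.site_model == "proto_splice_targeted":
        return [o for o in scan_proto_splice_sites(cds) if lo <= o <= hi]
    return list(range(lo, hi + 1))


def evolve_introns(
    introns: list[tuple[int, int, int]],
    cds: str,
    branch_length: float,
    config: SimulationConfig,
    rng: np.random.Generator,
    event_ids: itertools.count | None = None,
) -> tuple[list[tuple[int, int, int]], list[tuple[int, int, int]], list[tuple[int, int, int]]]:
    """One branch of intron dynamics on a CDS.

    ``introns`` are (cds_offset, phase, event_id) records. Returns
    (surviving + gained records sorted by offset, gained, lost). Gains whose
    drawn site is occupied or violates spacing are discarded (thinning).
    """
    if event_ids is None:
        event_ids = itertools.count(0)
    p_loss = 1.0 - math.exp(-config.loss_rate * branch_length)
    survivors, lost = [], []
    for rec in introns:
        (lost if rng.random() < p_loss else survivors).append(rec)

    n_gains = rng.poisson(config.gain_rate * len(cds) / 1000.0 * branch_length)
    offsets = {o for o, _, _ in survivors}
    weights = np.asarray(config.phase_weights, dtype=float)
    weights = weights / weights.sum()
    legal = legal_gain_offsets(cds, config)
    gained = []
    n_res = len(cds) // 3
    for _ in range(n_gains):
        if config.site_model == "proto_splice_targeted":
            if not legal:
                continue
            o = int(legal[rng.integers(len(legal))])
        else:
            phase = int(rng.choice(3, p=weights))
            if phase == 0:
                idx = int(rng.integers(1, n_res))
            else:
                idx = int(rng.integers(0, n_res))
            o = 3 * idx + phase
            if not (config.min_terminal_exon <= o <= len(cds) - config.min_terminal_exon):
                continue
            if not (0 < o < len(cds)):
                continue
        if o in offsets:
            continue
        if config.min_intron_spacing and any(
            abs(o - other) < config.min_intron_spacing for other in offsets
        ):
            continue
        offsets.add(o)
        gained.append((o, o % 3, next(event_ids)))

    merged = sorted(survivors + gained)
    return merged, gained, lost


def _scrub(intron: list[str], window: int = 14) -> None:
    """Remove alternative GT donors near the 5' end and AG acceptors near the
    3' end so boundary-rescue shifts cannot find a second canonical placement."""
    n = len(intron)
    for i in range(1, min(window, n - 2)):
        if intron[i] == "G" and intron[i + 1] == "T":
            intron[i + 1] = "C"
    for j in range(max(2, n - window), n - 2):
        if intron[j] == "A" and intron[j + 1] == "G":
            intron[j] = "C"


def emit_genomic(
    cds: str,
    introns: list[tuple[int, int, int]],
    config: SimulationConfig,
    rng: np.random.Generator,
    locus_id: str = "",
    species_id: str = "",
) -> tuple[GenomicLocus, list[IntronPosition]]:
    """Insert canonical GT..AG introns into a CDS at their offsets.

    Splicing the returned locus with the returned positions reproduces the
    CDS exactly (round-trip invariant).
    """
    lo, hi = config.intron_length
    if lo <= 20:
        raise ConfigError("configured minimum intron length must exceed 20 nt")
    parts = []
    positions = []
    prev = 0
    shift = 0
    for offset, phase, _event in sorted(introns):
        if not (0 < offset < len(cds)):
            raise ValidationError(f"intron offset {offset} outside CDS")
        length = int(rng.integers(lo, hi + 1))
        interior = [
            "ACGT"[int(c)] for c in rng.integers(0, 4, size=length - 4)
        ]
        _scrub(interior)
        parts.append(cds[prev:offset])
        parts.append("GT" + "".join(interior) + "AG")
        g_start = offset + shift
        positions.append(
            IntronPosition(
                cds_offset=offset,
                phase=phase,
                anchor_residue=offset // 3 + 1,
                g_start=g_start,
                g_end=g_start + length,
                donor="GT",
                acceptor="AG",
            )
        )
        shift += length
        prev = offset
    parts.append(cds[prev:])
    locus = GenomicLocus(
        locus_id=locus_id or "locus",
        sequence="".join(parts),
        species_id=species_id,
    )
    return locus, positions


def splice(locus_sequence: str, positions: list[IntronPosition]) -> str:
    """Remove the intron spans from a locus (truth-side round-trip check)."""
    out = []
    prev = 0
    for p in sorted(positions, key=lambda p: p.g_start):
        out.append(locus_sequence[prev : p.g_start])
        prev = p.g_end
    out.append(locus_sequence[prev:])
    return "".join(out)


# ---------------------------------------------------------------------------
# whole-family simulation
# ---------------------------------------------------------------------------


@dataclass
class _Lineage:
    sites: list[int]
    codons: list[str]
    compartment: str  # "mitochondrial" | "nuclear"
    introns: list[tuple[int, int, int]]  # (anchor site_id, phase, event_id)


def _draw_codon(aa: str, usage: dict[str, dict[str, float]], rng) -> str:
    ws = usage.get(aa)
    if not ws:
        ws = {c: 1.0 for c in synonymous_codons()[aa]}
    codons = sorted(ws)
    p = np.array([ws[c] for c in codons], dtype=float)
    return codons[int(rng.choice(len(codons), p=p / p.sum()))]


def _cds_of(lin: _Lineage) -> str:
    return "".join(lin.codons)


def _offset_records(lin: _Lineage) -> list[tuple[int, int, int]]:
    idx = {s: i for i, s in enumerate(lin.sites)}
    recs = []
    for site, phase, event in lin.introns:
        recs.append((3 * idx[site] + phase, phase, event))
    return sorted(recs)


def simulate_family(
    config: SimulationConfig,
    gene_id: str,
    tree: SpeciesTree | None = None,
    rng: np.random.Generator | None = None,
) -> FamilyTruth:
    """Evolve one gene family down the tree and emit its full ground truth."""
    if tree is None:
        tree = SpeciesTree.from_newick(config.tree_newick)
    if rng is None:
        rng = np.random.default_rng([config.seed, _stable_hash(gene_id)])

    usage = config.codon_usage
    n_res = int(rng.integers(config.protein_length[0], config.protein_length[1] + 1))
    root_aas = [AA20[int(i)] for i in rng.integers(0, len(AA20), size=n_res)]
    root = _Lineage(
        sites=list(range(n_res)),
        codons=[_draw_codon(aa, usage["mitochondrial"], rng) for aa in root_aas],
        compartment="mitochondrial",
        introns=[],
    )
    site_counter = itertools.count(n_res)
    event_counter = itertools.count(0)
    master: list[int] = list(range(n_res))

    if config.transfers is not None:
        planned = set(config.transfers.get(gene_id, []))
        known = {n.branch_label for n in tree.nodes}
        bad = planned - known
        if bad:
            raise ConfigError(f"unknown transfer branches for {gene_id!r}: {sorted(bad)}")
    else:
        planned = None

    events: list[GainEvent] = []
    transfer_branches: list[str] = []
    leaves: dict[str, _Lineage] = {}

    def walk(node: TreeNode, lin: _Lineage) -> None:
        lin = _Lineage(
            sites=list(lin.sites),
            codons=list(lin.codons),
            compartment=lin.compartment,
            introns=list(lin.introns),
        )
        t = node.length
        # 1) transfer?
        if lin.compartment == "mitochondrial":
            hit = (
                node.branch_label in planned
                if planned is not None
                else rng.random() < config.transfer_prob
            )
            if hit:
                lin.compartment = "nuclear"
                transfer_branches.append(node.branch_label)
                lin.codons = [
                    _draw_codon(translate(c), usage["nuclear"], rng)
                    for c in lin.codons
                ]
        # 2) substitutions
        if config.subst_prob > 0 and t > 0:
            p_sub = 1.0 - math.exp(-config.subst_prob * t)
            comp_usage = usage[lin.compartment]
            for i in range(len(lin.codons)):
                if rng.random() < p_sub:
                    old = translate(lin.codons[i])
                    choices = AA20.replace(old, "")
                    new = choices[int(rng.integers(len(choices)))]
                    lin.codons[i] = _draw_codon(new, comp_usage, rng)
        # 3) insertions (simple indel mode)
        if config.indel_mode == "simple" and config.indel_rate > 0 and t > 0:
            for _ in range(int(rng.poisson(config.indel_rate * t))):
                k = int(rng.integers(1, 4))
                j = int(rng.integers(0, len(lin.sites) + 1))
                new_ids = [next(site_counter) for _ in range(k)]
                new_codons = [
                    _draw_codon(
                        AA20[int(rng.integers(len(AA20)))],
                        usage[lin.compartment],
                        rng,
                    )
                    for _ in range(k)
                ]
                anchor_pos = (
                    master.index(lin.sites[j - 1]) + 1 if j > 0
                    else master.index(lin.sites[0])
                )
                master[anchor_pos:anchor_pos] = new_ids
                lin.sites[j:j] = new_ids
                lin.codons[j:j] = new_codons
        # 4) intron dynamics (nuclear lineages only)
        if lin.compartment == "nuclear" and t > 0:
            cds = _cds_of(lin)
            recs = _offset_records(lin)
            merged, gained, _lost = evolve_introns(
                recs, cds, t, config, rng, event_ids=event_counter
            )
            lost_events = {e for _, _, e in _lost}
            lin.introns = [r for r in lin.introns if r[2] not in lost_events]
            for o, phase, event_id in gained:
                site = lin.sites[o // 3]
                lin.introns.append((site, phase, event_id))
                events.append(
                    GainEvent(
                        event_id=event_id,
                        gene_id=gene_id,
                        branch=node.branch_label,
                        site_id=site,
                        phase=phase,
                    )
                )
        if node.is_leaf:
            leaves[node.label] = lin
        else:
            for child in node.children:
                walk(child, lin)

    walk(tree.root, root)

    # emit per-leaf artifacts
    structures: dict[str, GeneStructure] = {}
    loci: dict[str, GenomicLocus] = {}
    cds_map: dict[str, str] = {}
    true_states: dict[str, str] = {}
    observed: dict[str, str] = {}
    intron_events: dict[str, list[int]] = {}
    rows: dict[str, str] = {}
    master_pos = {s: i for i, s in enumerate(master)}

    for species in sorted(leaves):
        lin = leaves[species]
        cds = _cds_of(lin)
        recs = _offset_records(lin)
        locus, positions = emit_genomic(
            cds,
            recs,
            config,
            rng,
            locus_id=f"{gene_id}|{species}",
            species_id=species,
        )
        structures[species] = GeneStructure(
            gene_id=gene_id,
            species_id=species,
            compartment=lin.compartment,
            protein=translate(cds),
            introns=positions,
        )
        loci[species] = locus
        cds_map[species] = cds
        state = "N" if lin.compartment == "nuclear" else "M"
        true_states[species] = state
        observed[species] = (
            "U" if rng.random() < config.prob_unknown else state
        )
        intron_events[species] = [e for _, _, e in recs]
        row = ["-"] * len(master)
        for site, codon in zip(lin.sites, lin.codons):
            row[master_pos[site]] = translate(codon)
        rows[f"{gene_id}|{species}"] = "".join(row)

    alignment = ProteinAlignment(family_id=gene_id, rows=rows)

    # descent / parallel labels over (column, phase) positions
    pos_events: dict[tuple[int, int], set[int]] = {}
    pos_carriers: dict[tuple[int, int], int] = {}
    event_by_id = {e.event_id: e for e in events}
    for species, lin in leaves.items():
        for site, phase, event_id in lin.introns:
            key = (master_pos[site] + 1, phase)
            pos_events.setdefault(key, set()).add(event_id)
            pos_carriers[key] = pos_carriers.get(key, 0) + 1
    position_labels = {}
    for key, evs in pos_events.items():
        if pos_carriers[key] == 1:
            position_labels[key] = "unique"
        elif len(evs) == 1:
            position_labels[key] = "descent"
        else:
            position_labels[key] = "parallel"
    del event_by_id

    return FamilyTruth(
        gene_id=gene_id,
        transfer_branches=sorted(transfer_branches),
        structures=structures,
        loci=loci,
        cds=cds_map,
        alignment=alignment,
        localization=observed,
        true_states=true_states,
        events=events,
        position_labels=position_labels,
        intron_events=intron_events,
    )


def _stable_hash(s: str) -> int:
    """Deterministic small hash for per-gene rng streams (not security)."""
    h = 0
    for ch in s:
        h = (h * 131 + ord(ch)) % (2**31 - 1)
    return h


def simulate_study(config: SimulationConfig) -> StudyTruth:
    """Simulate ``n_genes`` independent families on one tree."""
    tree = SpeciesTree.from_newick(config.tree_newick)
    missing = set(config.groups) - tree.leaf_names
    extra = tree.leaf_names - set(config.groups)
    if extra:
        raise ConfigError(f"tree leaves without group assignment: {sorted(extra)}")
    del missing  # groups covering extra species are harmless
    families = [
        simulate_family(config, f"gene{i:03d}", tree=tree)
        for i in range(config.n_genes)
    ]
    return StudyTruth(config=config, tree=tree, families=families)


def make_alignment(truth: FamilyTruth) -> ProteinAlignment:
    """The true homology alignment of a simulated family."""
    return truth.alignment


def config_with(config: SimulationConfig, **overrides) -> SimulationConfig:
    """Functional update helper (dataclasses.replace with validation rerun)."""
    return replace(config, **overrides)
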