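"""Hand-construction utilities and independent oracles used across the suite.

The oracles deliberately avoid the package's algorithms: exhaustive
enumeration for chain scores and transfer scenarios, regex scanning for
proto-splice sites, and naive all-pairs counting for shared positions.
"""
from __future__ import annotations

import itertools
import re

import numpy as np

from introntrace._seq import codon_map, synonymous_codons
from introntrace.transfer_timing import SpeciesTree, TreeNode

# --- sequence builders ------------------------------------------------------

_NONSTOP = sorted(
    c for c, aa in codon_map().items() if aa != "*"
)


def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    return "".join(_NONSTOP[int(i)] for i in rng.integers(0, len(_NONSTOP), n_codons))


def make_intron(rng: np.random.Generator, length: int, donor="GT", acceptor="AG") -> str:
    """Canonical intron with interior scrubbed of decoy GT/AG near the ends."""
    interior = ["ACGT"[int(c)] for c in rng.integers(0, 4, size=length - 4)]
    for i in range(0, min(14, len(interior) - 1)):
        if interior[i] == "G" and interior[i + 1] == "T":
            interior[i + 1] = "C"
    for j in range(max(0, len(interior) - 15), len(interior) - 1):
        if interior[j] == "A" and interior[j + 1] == "G":
            interior[j] = "C"
    return donor + "".join(interior) + acceptor


def build_locus(cds: str, introns: list[tuple[int, str]]) -> str:
    """Insert intron sequences at the given cds offsets."""
    parts, prev = [], 0
    for offset, seq in sorted(introns):
        parts.append(cds[prev:offset])
        parts.append(seq)
        prev = offset
    parts.append(cds[prev:])
    return "".join(parts)


# --- chain-score oracle -----------------------------------------------------


def chain_score_oracle(blocks) -> int:
    """Max protein residues coverable by any colinear chain (exhaustive).

    Chains walk blocks in genomic order; a block may be head-trimmed to
    remove protein overlap with the chain so far, and must then still start
    after the previous block genomically (gap >= 1).
    """
    best = 0
    order = sorted(range(len(blocks)), key=lambda i: blocks[i].g_start)

    def walk(pos: int, p_end: int, g_end: int, score: int) -> None:
        nonlocal best
        best = max(best, score)
        for k in range(pos, len(order)):
            b = blocks[order[k]]
            trim = max(0, p_end - b.p_start)
            if b.p_end - b.p_start <= trim:
                continue
            if b.g_start + 3 * trim <= g_end:
                continue
            walk(k + 1, b.p_end, b.g_end, score + b.p_end - (b.p_start + trim))

    walk(0, -(10**9), -(10**9), 0)
    return best


# --- transfer-scenario oracle ----------------------------------------------


def transfer_oracle(tree: SpeciesTree, states: dict[str, str]):
    """All minimal transfer-branch sets by exhaustive search.

    A branch set is valid iff it is an antichain, no chosen branch has an M
    leaf below it, and every N leaf lies below exactly one chosen branch.
    Returns (min_event_count, list of minimal frozensets of branch labels);
    (0, [frozenset()]) when no N leaf exists.
    """
    leaves = {n.label: n for n in tree.nodes if n.is_leaf}
    n_leaves = [leaves[s] for s, st in states.items() if st == "N" and s in leaves]
    eligible = [
        n
        for n in tree.nodes
        if not any(states.get(s) == "M" for s in n.leaf_set)
        and any(states.get(s) == "N" for s in n.leaf_set)
    ]
    if not n_leaves:
        return 0, [frozenset()]

    def below(leaf: TreeNode, branch: TreeNode) -> bool:
        return leaf is branch or tree.is_ancestor(branch, leaf)

    for k in range(1, len(eligible) + 1):
        found = []
        for combo in itertools.combinations(eligible, k):
            ok = all(
                not (a is b or tree.is_ancestor(a, b) or tree.is_ancestor(b, a))
                for a, b in itertools.combinations(combo, 2)
            )
            if not ok:
                continue
            if all(sum(below(nl, br) for br in combo) == 1 for nl in n_leaves):
                found.append(frozenset(br.branch_label for br in combo))
        if found:
            return k, found
    raise AssertionError("no valid scenario found")  # pragma: no cover


def all_rooted_trees(leaves: tuple[str, ...]):
    """All rooted multifurcating tree shapes over the given labelled leaves,
    as newick strings."""
    if len(leaves) == 1:
        yield leaves[0]
        return
    for parts in _set_partitions(list(leaves)):
        if len(parts) < 2:
            continue
        for combo in itertools.product(*(all_rooted_trees(tuple(p)) for p in parts)):
            yield "(" + ",".join(sorted(combo)) + ")"


def _set_partitions(items: list):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def random_tree_newick(rng: np.random.Generator, n_leaves: int) -> str:
    """A random rooted shape (binary or multifurcating) on n labelled leaves."""
    names = [f"s{i}" for i in range(n_leaves)]

    def build(group: list[str]) -> str:
        if len(group) == 1:
            return group[0]
        k = int(rng.integers(2, min(4, len(group)) + 1))
        idx = np.arange(len(group))
        rng.shuffle(idx)
        shuffled = [group[i] for i in idx]
        parts = [[] for _ in range(k)]
        for j, name in enumerate(shuffled):
            parts[j % k].append(name)
        return "(" + ",".join(build(p) for p in parts) + ")"

    return build(names) + ";"


# --- shared-position oracle -------------------------------------------------


def naive_shared_counts(entries, grouping):
    """Naive per-(column, phase) classification by scanning all entries.

    Returns (diagonal dict, pair dict, total distinct, distinct shared).
    """
    positions = sorted({(e.column, e.phase) for e in entries})
    groups = sorted(set(grouping.values()))
    diagonal = {g: 0 for g in groups}
    pairs: dict[frozenset, int] = {}
    n_shared = 0
    for col, phase in positions:
        present = sorted(
            {
                grouping[e.seq_id]
                for e in entries
                if e.column == col and e.phase == phase
            }
        )
        if len(present) == 1:
            diagonal[present[0]] += 1
            continue
        n_shared += 1
        for g1, g2 in itertools.combinations(present, 2):
            key = frozenset((g1, g2))
            pairs[key] = pairs.get(key, 0) + 1
    return diagonal, pairs, len(positions), n_shared


# --- proto-splice regex oracle ---------------------------------------------

_PROTO_RE = re.compile(r"(?=[CA]AG[AG])")


def regex_proto_offsets(cds: str) -> list[int]:
    return [m.start() + 3 for m in _PROTO_RE.finditer(cds) if m.start() + 3 >= 3]
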