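"""Parsimony placement and relative timing of organelle-to-nucleus transfers.

Model: every gene starts in the mitochondrial genome at the root (state M).
A transfer event on a branch switches the whole subtree below it to nuclear
(state N), irreversibly — so the event branches of any one gene form an
antichain, and a leaf observed N must have exactly one event on its root
path while a leaf observed M must have none. Leaves in state U (unknown or
absent) are unconstrained.

The minimal scenario is unique as a *count*: it consists of the maximal
M-free subtrees that contain at least one N leaf. When U leaves leave slack
(an event could slide down toward the N leaves it covers without changing
the count), all equally parsimonious branch sets are enumerated and the
scenario is flagged unresolved; the canonical placement is the most
rootward one.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import dendropy

from .errors import DegenerateScenarioError, ValidationError

STATES = ("M", "N", "U")

MAX_ALTERNATIVES = 256  # cap on fully enumerated alternative scenarios


@dataclass
class TreeNode:
    """Node of a rooted species tree; the node identifies the branch above it."""

    label: str
    children: list["TreeNode"] = field(default_factory=list)
    parent: "TreeNode | None" = None
    length: float = 1.0  # length of the branch above this node
    leaf_set: frozenset[str] = frozenset()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def branch_label(self) -> str:
        """Stable branch identifier: sorted leaf names under the branch."""
        return "+".join(sorted(self.leaf_set))

    def __hash__(self) -> int:  # identity-based; nodes are unique objects
        return id(self)

    def __repr__(self) -> str:
        return f"TreeNode({self.branch_label})"


class SpeciesTree:
    """Rooted species tree (multifurcations allowed) with labelled branches."""

    def __init__(self, root: TreeNode):
        self.root = root
        self.nodes: list[TreeNode] = []
        self._collect(root)
        leaves = [n.label for n in self.nodes if n.is_leaf]
        if len(set(leaves)) != len(leaves):
            raise ValidationError("duplicate species ids in tree leaves")
        self.leaf_names = set(leaves)
        self.by_branch = {n.branch_label: n for n in self.nodes}

    def _collect(self, node: TreeNode) -> None:
        # postorder; also fills leaf sets
        for c in node.children:
            c.parent = node
            self._collect(c)
        node.leaf_set = (
            frozenset([node.label])
            if node.is_leaf
            else frozenset().union(*(c.leaf_set for c in node.children))
        )
        self.nodes.append(node)

    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesTree":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", suppress_internal_node_taxa=True
        )

        def build(dnode) -> TreeNode:
            label = ""
            if dnode.taxon is not None:
                label = dnode.taxon.label
            elif dnode.label:
                label = dnode.label
            length = dnode.edge.length
            if length is None:
                length = 0.0 if dnode.parent_node is None else 1.0
            return TreeNode(
                label=label,
                children=[build(c) for c in dnode.child_nodes()],
                length=float(length),
            )

        return cls(build(tree.seed_node))

    def is_ancestor(self, a: TreeNode, b: TreeNode) -> bool:
        """True iff ``a`` is a proper ancestor of ``b``."""
        p = b.parent
        while p is not None:
            if p is a:
                return True
            p = p.parent
        return False

    def depth(self, node: TreeNode) -> int:
        d = 0
        p = node.parent
        while p is not None:
            d += 1
            p = p.parent
        return d

    def leaf(self, species_id: str) -> TreeNode:
        for n in self.nodes:
            if n.is_leaf and n.label == species_id:
                return n
        raise ValidationError(f"species {species_id!r} not a leaf of the tree")


@dataclass
class GeneLocalization:
    """Observed compartment state per species for one gene."""

    gene_id: str
    states: dict[str, str]  # species -> M | N | U

    def __post_init__(self) -> None:
        for sp, st in self.states.items():
            if st not in STATES:
                raise ValidationError(
                    f"gene {self.gene_id!r}, species {sp!r}: bad state {st!r}"
                )
        if all(st == "U" for st in self.states.values()):
            raise ValidationError(
                f"gene {self.gene_id!r} has no informative (non-U) state"
            )


@dataclass
class TransferScenario:
    """Parsimony-minimal transfer placement for one gene."""

    gene_id: str
    transfer_branches: frozenset[str]  # canonical (most rootward) placement
    n_events: int
    resolved: bool
    alternatives: list[frozenset[str]]  # all minimal branch sets, canonical first
    unmapped_species: tuple[str, ...] = ()

    @property
    def independent(self) -> bool:
        return self.n_events >= 2


def infer_transfers(
    tree: SpeciesTree, loc: GeneLocalization
) -> TransferScenario:
    """Minimal irreversible-transfer scenario explaining the leaf states.

    Species in ``loc`` absent from the tree are reported in
    ``unmapped_species``; tree leaves absent from ``loc`` are treated as U.
    """
    unmapped = tuple(sorted(set(loc.states) - tree.leaf_names))
    states = {
        n: loc.states.get(n.label, "U") for n in tree.nodes if n.is_leaf
    }
    if all(st != "N" for st in states.values()) and all(
        st != "M" for st in states.values()
    ):
        raise DegenerateScenarioError(
            f"gene {loc.gene_id!r}: no informative leaf mapped to the tree"
        )

    has_m: dict[TreeNode, bool] = {}
    has_n: dict[TreeNode, bool] = {}
    for n in tree.nodes:  # postorder
        if n.is_leaf:
            has_m[n] = states[n] == "M"
            has_n[n] = states[n] == "N"
        else:
            has_m[n] = any(has_m[c] for c in n.children)
            has_n[n] = any(has_n[c] for c in n.children)

    # canonical events: maximal M-free subtrees containing at least one N leaf
    events: list[TreeNode] = []
    for n in tree.nodes:
        if has_m[n] or not has_n[n]:
            continue
        if n.parent is None or has_m[n.parent]:
            events.append(n)

    # per-event slack: the event may sit anywhere on the path from the
    # canonical node down to the LCA of the N leaves it covers
    per_event_options: list[list[TreeNode]] = []
    for v in events:
        chain = [v]
        cur = v
        while True:
            n_children = [c for c in cur.children if has_n[c]]
            if len(n_children) != 1:
                break
            cur = n_children[0]
            chain.append(cur)
        per_event_options.append(chain)

    n_alt = 1
    for chain in per_event_options:
        n_alt *= len(chain)
    resolved = n_alt == 1

    alternatives: list[frozenset[str]] = []
    if n_alt <= MAX_ALTERNATIVES:
        for combo in itertools.product(*per_event_options):
            alternatives.append(frozenset(n.branch_label for n in combo))
    else:  # keep the canonical one; the count is still reported via resolved
        alternatives.append(frozenset(v.branch_label for v in events))

    canonical = frozenset(v.branch_label for v in events)
    # canonical first, rest in sorted order for determinism
    rest = sorted((a for a in alternatives if a != canonical), key=sorted)
    return TransferScenario(
        gene_id=loc.gene_id,
        transfer_branches=canonical,
        n_events=len(events),
        resolved=resolved,
        alternatives=[canonical] + rest,
        unmapped_species=unmapped,
    )


def find_independent_transfers(
    scenarios: dict[str, TransferScenario],
) -> list[dict]:
    """Genes with >= 2 inferred events, as table rows (gene x lineages)."""
    rows = []
    for gene_id in sorted(scenarios):
        s = scenarios[gene_id]
        if s.n_events >= 2:
            rows.append(
                {
                    "gene_id": gene_id,
                    "n_events": s.n_events,
                    "lineages": sorted(s.transfer_branches),
                    "resolved": s.resolved,
                }
            )
    return rows


@dataclass
class TransferRanking:
    """Relative-timing view over many genes' canonical scenarios."""

    tree: SpeciesTree
    events: list[tuple[str, str]]  # (gene_id, branch_label)

    def compare(self, a: tuple[str, str], b: tuple[str, str]) -> str:
        """'more_ancient', 'more_recent', 'equal' or 'incomparable' for a vs b."""
        na = self.tree.by_branch[a[1]]
        nb = self.tree.by_branch[b[1]]
        if na is nb:
            return "equal"
        if self.tree.is_ancestor(na, nb):
            return "more_ancient"
        if self.tree.is_ancestor(nb, na):
            return "more_recent"
        return "incomparable"

    def classes_for(self, species_id: str) -> list[tuple[int, list[str]]]:
        """Genes with an event on the species' root path, binned by depth.

        Returned as (depth, gene ids) pairs ordered root-first; smaller
        depth = relatively more ancient transfer.
        """
        leaf = self.tree.leaf(species_id)
        path = set()
        n: TreeNode | None = leaf
        while n is not None:
            path.add(n)
            n = n.parent
        bins: dict[int, list[str]] = {}
        for gene_id, branch in self.events:
            node = self.tree.by_branch[branch]
            if node in path:
                bins.setdefault(self.tree.depth(node), []).append(gene_id)
        return [(d, sorted(g)) for d, g in sorted(bins.items())]


def rank_transfer_times(
    scenarios: dict[str, TransferScenario], tree: SpeciesTree
) -> TransferRanking:
    """Partial order of canonical events by ancestor-descendant relations."""
    events = [
        (gene_id, branch)
        for gene_id in sorted(scenarios)
        for branch in sorted(scenarios[gene_id].transfer_branches)
    ]
    return TransferRanking(tree=tree, events=events)


def annotate_events_newick(
    tree: SpeciesTree, scenarios: dict[str, TransferScenario]
) -> str:
    """Newick string with per-branch transfer labels (gene lists)."""
    by_branch: dict[str, list[str]] = {}
    for gene_id in sorted(scenarios):
        for b in scenarios[gene_id].transfer_branches:
            by_branch.setdefault(b, []).append(gene_id)

    def fmt(node: TreeNode) -> str:
        genes = by_branch.get(node.branch_label, [])
        tag = ("|EGT:" + ",".join(genes)) if genes else ""
        if node.is_leaf:
            return node.label + tag
        inner = ",".join(fmt(c) for c in node.children)
        return f"({inner}){node.label}{tag}"

    return fmt(tree.root) + ";"
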