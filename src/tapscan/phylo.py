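"""Ancestral TAP family counts by asymmetric Wagner parsimony.

Given a rooted species tree and a family-by-species matrix of nonnegative
copy numbers, each family's ancestral counts are reconstructed by minimising

    sum over branches of  g * max(0, c_child - c_parent)
                        + l * max(0, c_parent - c_child)

where ``g`` and ``l`` are the per-unit gain and loss penalties (asymmetric
Wagner parsimony; branch lengths play no role).  The reconstruction is a
two-pass dynamic program over the bounded state space ``0..max(leaf
counts)``: for positive penalties the per-branch cost is monotone in the
distance between parent and child states, so an optimal ancestral count
never exceeds the largest leaf count (any larger state could be lowered to
the maximum leaf count without increasing any branch cost).  Co-optimal
states are resolved to the smallest count in a root-to-leaf pass, biasing
against inferring unobserved ancestral copies.

Each branch change is then classified: *gain* (0 -> >0), *loss* (>0 -> 0),
*expansion* (increase with both ends >= 1), *contraction* (decrease with
both ends >= 1), or *none*.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "WagnerConfig",
    "BranchEvent",
    "EventTable",
    "parse_newick",
    "load_newick",
    "prune_tree_to_species",
    "read_count_matrix",
    "wagner_reconstruct",
    "classify_branch_events",
    "summarize_events",
]

EVENT_KINDS = ("gain", "loss", "expansion", "contraction")


@dataclass(frozen=True)
class WagnerConfig:
    """Penalties of the asymmetric Wagner parsimony.

    ``gain_penalty`` is the cost per unit increase along a branch,
    ``loss_penalty`` per unit decrease.  Equal penalties recover classic
    (symmetric) Wagner parsimony.  ``tie_rule`` currently supports only
    ``smallest_count``.
    """

    gain_penalty: float = 1.0
    loss_penalty: float = 1.0
    tie_rule: str = "smallest_count"

    def __post_init__(self) -> None:
        if not (self.gain_penalty > 0 and self.loss_penalty > 0):
            raise ValueError("penalties must be positive")
        if self.tie_rule != "smallest_count":
            raise ValueError(f"unknown tie rule {self.tie_rule!r}")


# ---------------------------------------------------------------------------
# tree I/O

def parse_newick(text: str) -> dendropy.Tree:
    """Parse a rooted Newick tree; polytomies allowed, branch lengths ignored.

    Raises ``ValueError`` on malformed Newick or duplicate leaf labels.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise ValueError(f"malformed Newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise ValueError(f"duplicate leaf labels: {', '.join(sorted(dupes))}")
    tree.is_rooted = True
    return tree


def load_newick(path) -> dendropy.Tree:
    with open(path, encoding="utf-8") as fh:
        return parse_newick(fh.read())


def prune_tree_to_species(
    tree: dendropy.Tree,
    species: Iterable[str],
    mapping: Optional[Mapping[str, str]] = None,
) -> dendropy.Tree:
    """Minimal subtree spanning the requested species; unary nodes suppressed.

    ``mapping`` resolves species absent from the tree onto the leaf that
    stands in for them (the closest sampled relative); the pruned tree's
    leaves are relabelled back to the requested names.  The mapping must not
    send two requested species to the same leaf.
    """
    requested = sorted(set(species))
    mapping = dict(mapping or {})
    target_of = {sp: mapping.get(sp, sp) for sp in requested}
    targets = list(target_of.values())
    if len(set(targets)) != len(targets):
        collide = sorted({t for t in targets if targets.count(t) > 1})
        raise ValueError(f"mapping sends multiple species to the same leaf: {collide}")
    leaf_labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = sorted(set(targets) - leaf_labels)
    if missing:
        raise ValueError(f"species not found in tree: {', '.join(missing)}")
    pruned = tree.extract_tree_with_taxa_labels(labels=targets)
    pruned.is_rooted = True
    pruned.suppress_unifurcations()
    back = {leaf_label: sp for sp, leaf_label in target_of.items()}
    for leaf in pruned.leaf_node_iter():
        leaf.taxon.label = back[leaf.taxon.label]
    return pruned


def read_count_matrix(source) -> pd.DataFrame:
    """Read a family-by-species count matrix (TSV, families as rows).

    Validates unique labels and nonnegative integer counts.
    """
    if isinstance(source, str) and "\t" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source, sep="\t", index_col=0)
    if df.index.duplicated().any() or df.columns.duplicated().any():
        raise ValueError("duplicate family or species labels in count matrix")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number) or (values < 0).any():
        raise ValueError("counts must be nonnegative numbers")
    if not np.array_equal(values, values.astype(int)):
        raise ValueError("counts must be integers")
    return df.astype(int)


# ---------------------------------------------------------------------------
# reconstruction

def _branch_cost_matrix(n_states: int, cfg: WagnerConfig) -> np.ndarray:
    states = np.arange(n_states)
    diff = states[None, :] - states[:, None]  # child - parent
    return cfg.gain_penalty * np.maximum(diff, 0) + cfg.loss_penalty * np.maximum(-diff, 0)


def wagner_reconstruct(
    tree: dendropy.Tree,
    leaf_counts: Mapping[str, int],
    cfg: WagnerConfig = WagnerConfig(),
) -> tuple[dict[dendropy.Node, int], float]:
    """Minimum-cost ancestral counts for one family.

    Returns (per-node counts keyed by tree node, total cost).  Every leaf
    label must have a count.  Among co-optimal reconstructions the smallest
    count is chosen at each node in the root-to-leaf pass.
    """
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label not in leaf_counts:
            raise KeyError(f"no count for leaf {leaf.taxon.label!r}")
    max_count = max((leaf_counts[l.taxon.label] for l in tree.leaf_node_iter()), default=0)
    n_states = max_count + 1
    cost_m = _branch_cost_matrix(n_states, cfg)

    # bottom-up: minimal subtree cost per (node, ancestral state)
    subtree_cost: dict[dendropy.Node, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            c = np.full(n_states, np.inf)
            c[leaf_counts[node.taxon.label]] = 0.0
        else:
            c = np.zeros(n_states)
            for child in node.child_nodes():
                # cost of branch to child plus child's subtree, minimised over
                # the child's state, for every parent state
                c += (cost_m + subtree_cost[child][None, :]).min(axis=1)
        subtree_cost[node] = c

    root = tree.seed_node
    total = float(subtree_cost[root].min())
    counts: dict[dendropy.Node, int] = {}
    # top-down: smallest co-optimal state
    counts[root] = int(np.argmin(subtree_cost[root]))  # argmin takes first (= smallest)
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        p = counts[node.parent_node]
        counts[node] = int(np.argmin(cost_m[p, :] + subtree_cost[node]))
    return counts, total


def classify_branch_events(parent_count: int, child_count: int) -> str:
    """Label one branch change: gain / loss / expansion / contraction / none."""
    if parent_count == child_count:
        return "none"
    if parent_count == 0:
        return "gain"
    if child_count == 0:
        return "loss"
    return "expansion" if child_count > parent_count else "contraction"


# ---------------------------------------------------------------------------
# per-family summary

@dataclass(frozen=True)
class BranchEvent:
    """One non-trivial change of one family on the branch leading to ``node``."""

    node: str
    family: str
    event: str
    parent_count: int
    child_count: int


@dataclass
class EventTable:
    """Branch events plus per-node and grand totals across families."""

    events: list[BranchEvent]
    node_totals: pd.DataFrame  # nodes x event kinds
    grand_totals: dict[str, int]
    ancestral_counts: pd.DataFrame  # families x node labels


def _ensure_node_labels(tree: dendropy.Tree) -> None:
    """Give unlabelled internal nodes stable preorder labels N1, N2, ..."""
    taken = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    taken |= {n.label for n in tree.preorder_internal_node_iter() if n.label}
    i = 0
    for node in tree.preorder_internal_node_iter():
        if not node.label:
            i += 1
            while f"N{i}" in taken:
                i += 1
            node.label = f"N{i}"


def _node_label(node: dendropy.Node) -> str:
    return node.taxon.label if node.is_leaf() else node.label


def summarize_events(
    tree: dendropy.Tree,
    matrix: pd.DataFrame,
    cfg: WagnerConfig = WagnerConfig(),
    mapping: Optional[Mapping[str, str]] = None,
) -> EventTable:
    """Reconstruct every family on the tree and classify all branch changes.

    ``matrix`` is families x species; the tree is pruned to the matrix's
    species first (``mapping`` resolves species onto stand-in leaves).
    Totals are per node (events on the branch leading to that node) and
    grand totals across the whole tree.
    """
    tree = prune_tree_to_species(tree, matrix.columns, mapping=mapping)
    _ensure_node_labels(tree)
    node_order = [_node_label(n) for n in tree.preorder_node_iter()]

    events: list[BranchEvent] = []
    totals = pd.DataFrame(0, index=node_order, columns=list(EVENT_KINDS))
    ancestral = pd.DataFrame(0, index=matrix.index, columns=node_order)
    for family in matrix.index:
        leaf_counts = matrix.loc[family].to_dict()
        counts, _ = wagner_reconstruct(tree, leaf_counts, cfg)
        for node in tree.preorder_node_iter():
            ancestral.loc[family, _node_label(node)] = counts[node]
            if node.parent_node is None:
                continue
            ev = classify_branch_events(counts[node.parent_node], counts[node])
            if ev != "none":
                label = _node_label(node)
                events.append(
                    BranchEvent(
                        node=label,
                        family=family,
                        event=ev,
                        parent_count=counts[node.parent_node],
                        child_count=counts[node],
                    )
                )
                totals.loc[label, ev] += 1
    grand = {ev: int(totals[ev].sum()) for ev in EVENT_KINDS}
    return EventTable(
        events=events,
        node_totals=totals,
        grand_totals=grand,
        ancestral_counts=ancestral,
    )
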