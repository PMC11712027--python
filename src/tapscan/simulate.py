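"""Deterministic fixture generators.

Two families of fixtures make the whole pipeline testable without any
external data:

* synthetic rule sets plus domtblout text with *planted* family memberships
  (members get every required domain at GA + margin with full profile
  coverage; decoys sit below the gathering threshold or below the coverage
  cutoff), together with a truth table of intent;
* family-count matrices evolved along a tree under a simple per-branch
  event process (gain / loss / expansion / contraction, at most one sampled
  event per branch per family) with the full history recorded.

All generators are byte-deterministic under a fixed seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional

import dendropy
import numpy as np
import pandas as pd

from .phylo import classify_branch_events
from .rules import (
    DEFAULT_COVERAGE_CUTOFF,
    DomainProfileMeta,
    FamilyRule,
    ProfileOrigin,
    RuleSet,
    TapClass,
)

__all__ = [
    "PlantedTruth",
    "SimulatedHistory",
    "gen_toy_ruleset",
    "gen_domtblout",
    "gen_count_evolution",
]


@dataclass
class PlantedTruth:
    """Intent behind a generated domtblout: per-sequence planted family
    (None for decoys) and per-(sequence, profile) filter-pass intent."""

    seed: int
    intended_family: dict[str, Optional[str]] = field(default_factory=dict)
    intended_label: dict[str, Optional[str]] = field(default_factory=dict)
    filter_pass: dict[tuple[str, str], bool] = field(default_factory=dict)


@dataclass
class SimulatedHistory:
    """True per-node counts and per-branch events of a count simulation."""

    seed: int
    tree: dendropy.Tree
    node_counts: dict[str, dict[str, int]]  # family -> node label -> count
    events: list[tuple[str, str, str, int, int]]  # (family, node, event, parent, child)

    def event_totals(self) -> dict[str, int]:
        totals = {"gain": 0, "loss": 0, "expansion": 0, "contraction": 0}
        for _, _, ev, _, _ in self.events:
            totals[ev] += 1
        return totals


# ---------------------------------------------------------------------------
# rule-set generator

def gen_toy_ruleset(
    n_families: int, with_subfamilies: bool = False, seed: int = 0
) -> RuleSet:
    """A valid synthetic rule set exercising every rule feature.

    Families use disjoint domain pools, so a planted member of one family can
    never satisfy another top-level family's clauses (membership recovery is
    well-posed).  Depending on the seed, individual families get one-of-two
    clauses, forbidden domains, best-of pairs, merge outputs, and (when
    ``with_subfamilies`` is set) child rules adding a specific domain.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    rng = random.Random(seed)
    rules: dict[str, FamilyRule] = {}
    profiles: dict[str, DomainProfileMeta] = {}
    dom_counter = 0

    def new_domain() -> str:
        nonlocal dom_counter
        dom_counter += 1
        name = f"D{dom_counter:03d}"
        profiles[name] = DomainProfileMeta(
            profile_name=name,
            profile_length=rng.randrange(60, 240, 10),
            ga_threshold=round(rng.uniform(18.0, 35.0), 1),
            coverage_cutoff=rng.choice([DEFAULT_COVERAGE_CUTOFF, 0.5, 0.8]),
            origin=rng.choice(list(ProfileOrigin)),
        )
        return name

    for i in range(1, n_families + 1):
        fam = f"F{i:02d}"
        clauses = []
        n_clauses = rng.choice([1, 1, 2])
        best_of: list[tuple[str, str]] = []
        for _ in range(n_clauses):
            if rng.random() < 0.3:
                a, b = new_domain(), new_domain()
                clauses.append(frozenset({a, b}))
                if rng.random() < 0.5:
                    best_of.append((a, b))
            else:
                clauses.append(frozenset({new_domain()}))
        forbidden = frozenset({new_domain()}) if rng.random() < 0.3 else frozenset()
        output = fam
        if rng.random() < 0.15 and i > 1:
            # merge: report under the previous family's output label
            output = rules[f"F{i - 1:02d}"].output_family
        rules[fam] = FamilyRule(
            family_id=fam,
            tap_class=rng.choice(list(TapClass)),
            required_clauses=tuple(clauses),
            forbidden=forbidden,
            best_of=tuple(best_of),
            output_family=output,
        )
        if with_subfamilies and rng.random() < 0.4:
            sub = f"{fam}s"
            rules[sub] = FamilyRule(
                family_id=sub,
                tap_class=rules[fam].tap_class,
                required_clauses=rules[fam].required_clauses
                + (frozenset({new_domain()}),),
                forbidden=forbidden,
                best_of=tuple(best_of),
                parent_family=fam,
            )
    return RuleSet(rules=rules, profiles=profiles, version_tag=f"toy-{seed}")


# ---------------------------------------------------------------------------
# domtblout generator

_DOMTBLOUT_HEADER = (
    "#                                                                            --- full sequence --- -------------- this domain -------------   hmm coord   ali coord   env coord\n"
    "# target name        accession   tlen query name           accession   qlen   E-value  score  bias   #  of  c-Evalue  i-Evalue  score  bias  from    to  from    to  from    to  acc description of target\n"
    "#------------------- ---------- ----- -------------------- ---------- ----- --------- ------ ----- --- --- --------- --------- ------ ----- ----- ----- ----- ----- ----- ----- ---- ---------------------\n"
)


def _row(seq: str, seqlen: int, dom: str, domlen: int, score: float,
         hmm_from: int, hmm_to: int, acc: float) -> str:
    span = hmm_to - hmm_from + 1
    ali_to = min(span, seqlen)
    cols = [
        seq, "-", str(seqlen), dom, "-", str(domlen),
        "1e-20", f"{score:.1f}", "0.1",
        "1", "1", "1e-20", "1e-20", f"{score:.1f}", "0.1",
        str(hmm_from), str(hmm_to), "1", str(ali_to), "1", str(min(span + 4, seqlen)),
        f"{acc:.2f}", "planted",
    ]
    return " ".join(cols) + "\n"


def gen_domtblout(
    rs: RuleSet, n_seqs: int, margin: float, seed: int = 0,
    decoy_fraction: float = 0.4,
) -> tuple[str, PlantedTruth]:
    """Domtblout text with planted memberships and decoys.

    Members receive one domain hit per required clause (best-of pairs plant
    the first member) with sequence bit score GA + ``margin`` and full
    profile span.  Decoys receive either a score GA - ``margin`` or a span
    strictly below the coverage cutoff.  The truth table records the planted
    family (and output label) per sequence and the intended filter outcome
    per (sequence, profile).
    """
    if margin <= 0:
        raise ValueError("margin must be positive")
    rng = random.Random(seed)
    truth = PlantedTruth(seed=seed)
    lines = [_DOMTBLOUT_HEADER]
    fam_ids = sorted(rs.rules)
    for i in range(1, n_seqs + 1):
        seq = f"SEQ{i:05d}"
        seqlen = rng.randrange(200, 900)
        if not fam_ids or rng.random() < decoy_fraction:
            truth.intended_family[seq] = None
            truth.intended_label[seq] = None
            dom = rng.choice(sorted(rs.profiles)) if rs.profiles else None
            if dom is None:
                continue
            meta = rs.profiles[dom]
            if rng.random() < 0.5:  # below GA
                lines.append(_row(seq, seqlen, dom, meta.profile_length,
                                  meta.ga_threshold - margin,
                                  1, meta.profile_length, 0.9))
            else:  # above GA but below the coverage cutoff
                span = max(1, int(meta.profile_length * meta.coverage_cutoff) - 2)
                lines.append(_row(seq, seqlen, dom, meta.profile_length,
                                  meta.ga_threshold + margin, 1, span, 0.9))
            truth.filter_pass[(seq, dom)] = False
        else:
            fam = rng.choice(fam_ids)
            rule = rs.rules[fam]
            truth.intended_family[seq] = fam
            truth.intended_label[seq] = rule.output_family
            suppressed = {b for _, b in rule.best_of}
            planted: set[str] = set()
            for clause in rule.required_clauses:
                preferred = sorted(clause - suppressed) or sorted(clause)
                dom = preferred[0]
                if dom in planted:
                    continue
                planted.add(dom)
                meta = rs.profiles[dom]
                lines.append(_row(seq, seqlen, dom, meta.profile_length,
                                  meta.ga_threshold + margin,
                                  1, meta.profile_length, 0.95))
                truth.filter_pass[(seq, dom)] = True
    return "".join(lines), truth


# ---------------------------------------------------------------------------
# count evolution

def gen_count_evolution(
    tree: dendropy.Tree,
    root_count: int,
    p_gain: float,
    p_loss: float,
    p_expand: float,
    p_contract: float,
    seed: int = 0,
    n_families: int = 1,
    max_events_per_family: Optional[int] = None,
) -> tuple[pd.DataFrame, SimulatedHistory]:
    """Evolve family counts root-to-leaves with at most one event per branch.

    On every branch one of gain (0 -> 1), loss (c -> 0), expansion (c -> c+1)
    or contraction (c -> c-1, staying >= 1) is sampled with the given
    probabilities (their sum must be <= 1); an event inapplicable to the
    parent count is skipped.  ``max_events_per_family`` optionally caps the
    number of events a family accumulates across the whole tree — with a cap
    of 1, parsimony provably recovers the history exactly, which is the
    regime the recovery tests use.

    Returns the leaf count matrix (families x species) and the full history.
    """
    probs = [p_gain, p_loss, p_expand, p_contract]
    if any(not (0 <= p <= 1) for p in probs):
        raise ValueError("probabilities must be in [0, 1]")
    if sum(probs) > 1:
        raise ValueError("event probabilities sum to more than 1 on a branch")
    if root_count < 0:
        raise ValueError("root_count must be nonnegative")
    rng = random.Random(seed)

    from .phylo import _ensure_node_labels, _node_label  # stable node labels

    _ensure_node_labels(tree)
    leaf_labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    node_counts: dict[str, dict[str, int]] = {}
    events: list[tuple[str, str, str, int, int]] = []
    rows = []
    for fi in range(1, n_families + 1):
        family = f"FAM{fi:03d}"
        counts: dict[dendropy.Node, int] = {}
        n_events = 0
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                counts[node] = root_count
                continue
            parent = counts[node.parent_node]
            child = parent
            u = rng.random()
            choice = None
            acc = 0.0
            for name, p in zip(("gain", "loss", "expansion", "contraction"), probs):
                acc += p
                if u < acc:
                    choice = name
                    break
            if max_events_per_family is not None and n_events >= max_events_per_family:
                choice = None
            if choice == "gain" and parent == 0:
                child = 1
            elif choice == "loss" and parent > 0:
                child = 0
            elif choice == "expansion" and parent >= 1:
                child = parent + 1
            elif choice == "contraction" and parent >= 2:
                child = parent - 1
            counts[node] = child
            if child != parent:
                events.append(
                    (family, _node_label(node),
                     classify_branch_events(parent, child), parent, child)
                )
                n_events += 1
        node_counts[family] = {_node_label(n): c for n, c in counts.items()}
        rows.append([node_counts[family][l] for l in leaf_labels])
    matrix = pd.DataFrame(
        rows, index=[f"FAM{fi:03d}" for fi in range(1, n_families + 1)],
        columns=leaf_labels, dtype=int,
    )
    history = SimulatedHistory(seed=seed, tree=tree, node_counts=node_counts, events=events)
    return matrix, history
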