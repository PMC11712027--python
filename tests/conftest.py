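"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
from typing import Iterable, Mapping

import pytest

from tapscan.hmmer import DomainHit
from tapscan.rules import RuleSet, load_builtin_ruleset


@pytest.fixture(scope="session")
def builtin_rs() -> RuleSet:
    return load_builtin_ruleset()


# ---------------------------------------------------------------------------
# hit construction helpers

def make_hit(
    seq_id: str,
    profile: str,
    profile_length: int,
    score: float = 50.0,
    hmm_from: int = 1,
    hmm_to: int | None = None,
    seq_length: int = 500,
    acc: float = 0.95,
    dom_index: int = 1,
) -> DomainHit:
    hmm_to = profile_length if hmm_to is None else hmm_to
    span = hmm_to - hmm_from + 1
    return DomainHit(
        seq_id=seq_id,
        seq_length=seq_length,
        profile_name=profile,
        profile_length=profile_length,
        seq_evalue=1e-20,
        seq_bitscore=score,
        dom_index=dom_index,
        dom_bitscore=score,
        hmm_from=hmm_from,
        hmm_to=hmm_to,
        ali_from=1,
        ali_to=min(span, seq_length),
        env_from=1,
        env_to=min(span + 2, seq_length),
        acc=acc,
    )


def hits_from_detected(
    rs: RuleSet, seq_id: str, detected: Mapping[str, float]
) -> list[DomainHit]:
    """Full-coverage hits realizing a detected-domain -> score map."""
    return [
        make_hit(seq_id, dom, rs.profiles[dom].profile_length, score)
        for dom, score in sorted(detected.items())
    ]


# ---------------------------------------------------------------------------
# brute-force rule evaluation (oracle for the classifier)

def brute_force_families(rs: RuleSet, detected: Mapping[str, float]) -> set[tuple[str, str | None]]:
    """Directly evaluate every rule, then reduce each lineage to its deepest
    match.  Returns {(output_family, subfamily-or-None)}."""
    matched = []
    for rule in rs.rules.values():
        det = dict(detected)
        for a, b in rule.best_of:
            if a in det and b in det:
                if det[b] > det[a]:
                    del det[a]
                else:
                    del det[b]
        if any(f in det for f in rule.forbidden):
            continue
        if all(any(d in det for d in clause) for clause in rule.required_clauses):
            matched.append(rule)
    by_root: dict[str, list] = {}
    for rule in matched:
        by_root.setdefault(rs.root_family(rule.family_id), []).append(rule)
    out = set()
    for group in by_root.values():
        best = max(group, key=lambda r: (rs.rule_depth(r.family_id), r.family_id))
        out.add(
            (best.output_family, best.family_id if best.parent_family else None)
        )
    return out


# ---------------------------------------------------------------------------
# exhaustive Wagner parsimony (oracle for the DP)

def enumerate_tree_shapes(n_leaves: int) -> list[str]:
    """All rooted multifurcating tree shapes with exactly ``n_leaves`` leaves,
    as Newick strings with leaves labelled L1..Ln in left-to-right order."""

    def shapes(n: int) -> list:
        if n == 1:
            return ["leaf"]
        out = []
        for parts in _partitions(n):
            for combo in itertools.product(*(shapes(p) for p in parts)):
                out.append(list(combo))
        # deduplicate by canonical form
        uniq = {}
        for s in out:
            uniq[_canon(s)] = s
        return list(uniq.values())

    def _partitions(n: int):
        # partitions of n into >=2 parts, non-increasing
        def rec(n, maxp):
            if n == 0:
                yield ()
                return
            for p in range(min(n, maxp), 0, -1):
                for rest in rec(n - p, p):
                    yield (p,) + rest
        return [p for p in rec(n, n - 1) if len(p) >= 2]

    def _canon(s):
        if s == "leaf":
            return "L"
        return "(" + ",".join(sorted(_canon(c) for c in s)) + ")"

    def to_newick(s, counter):
        if s == "leaf":
            counter[0] += 1
            return f"L{counter[0]}"
        return "(" + ",".join(to_newick(c, counter) for c in s) + ")"

    return [to_newick(s, [0]) + ";" for s in shapes(n_leaves)]


def exhaustive_wagner(tree, leaf_counts, gain_penalty, loss_penalty):
    """Minimum reconstruction cost by enumerating every ancestral assignment
    over states 0..max(leaf counts)."""
    nodes = list(tree.preorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    max_c = max(leaf_counts.values(), default=0)

    def branch_cost(p, c):
        d = c - p
        return gain_penalty * d if d > 0 else loss_penalty * (-d)

    best = float("inf")
    for assign in itertools.product(range(max_c + 1), repeat=len(internal)):
        state = dict(zip(internal, assign))
        for n in nodes:
            if n.is_leaf():
                state[n] = leaf_counts[n.taxon.label]
        cost = sum(
            branch_cost(state[n.parent_node], state[n])
            for n in nodes
            if n.parent_node is not None
        )
        best = min(best, cost)
    return best


def bruteforce_coverage(intervals: Iterable[tuple[int, int]], length: int) -> float:
    """Per-position interval-union coverage oracle."""
    covered = set()
    for a, b in intervals:
        covered.update(range(a, b + 1))
    return len(covered) / length
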