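"""The TAP classification engine.

Maps GA- and coverage-filtered domain hits to TAP family assignments.  Per
sequence the engine builds the set of detected domains (best full-sequence
bit score per profile), resolves any best-of pairs, and evaluates every
family rule.  Among matching rules that are related through the subfamily
graph the deepest (most specific) rule wins and provides the subfamily
label; matches in unrelated rule lineages each yield their own assignment.
Merge rules (e.g. bZIP1/bZIP2/bZIPCDD/bZIPAUREO) report under their shared
output label.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .hmmer import DomainHit, profile_coverage
from .rules import FamilyRule, RuleSet, family_catalog

__all__ = [
    "SequenceAssignment",
    "ClassificationResult",
    "detected_domains",
    "resolve_best_of",
    "evaluate_rule",
    "classify_sequences",
    "write_outputs",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SequenceAssignment:
    """One sequence assigned to one output family.

    ``supporting_domains`` lists (domain, best sequence bit score, coverage)
    for every detected domain that appears in the matched rule's required
    clauses.  ``subfamily`` is set when the matched rule is a subfamily; the
    ``family`` label is always the rule's output label (merges applied).
    """

    seq_id: str
    family: str
    subfamily: Optional[str] = None
    supporting_domains: tuple[tuple[str, float, float], ...] = ()


@dataclass
class ClassificationResult:
    assignments: list[SequenceAssignment]
    family_counts: dict[str, int]
    unassigned: list[str]


def detected_domains(
    hits_for_seq: Sequence[DomainHit],
) -> dict[str, tuple[float, float]]:
    """Map each detected profile to (best sequence bit score, union coverage).

    Input hits must already be GA- and coverage-filtered and belong to one
    sequence.
    """
    by_profile: dict[str, list[DomainHit]] = {}
    for h in hits_for_seq:
        by_profile.setdefault(h.profile_name, []).append(h)
    return {
        name: (max(h.seq_bitscore for h in group), profile_coverage(group))
        for name, group in by_profile.items()
    }


def resolve_best_of(
    detected: Mapping[str, tuple[float, float]],
    pair: tuple[str, str],
) -> dict[str, tuple[float, float]]:
    """Suppress the lower-scoring member of a best-of pair.

    When both members are detected only the better one stays in consideration
    for the current rule; an exact score tie keeps the first element of the
    ordered pair.  With zero or one member detected the map is unchanged.
    """
    a, b = pair
    out = dict(detected)
    if a in out and b in out:
        # tie -> first element wins, so b is dropped on equality
        loser = a if out[a][0] < out[b][0] else b
        del out[loser]
    return out


def evaluate_rule(
    rule: FamilyRule,
    detected: Mapping[str, tuple[float, float]],
) -> tuple[bool, list[str]]:
    """Evaluate one rule against a best-of-resolved detected-domain map.

    Returns (matched, witness) where the witness lists one satisfying domain
    per required clause.  A rule matches iff every required clause has at
    least one detected member and no forbidden domain is detected.
    """
    if any(dom in detected for dom in rule.forbidden):
        return False, []
    witness: list[str] = []
    for clause in rule.required_clauses:
        present = sorted(d for d in clause if d in detected)
        if not present:
            return False, []
        witness.append(max(present, key=lambda d: (detected[d][0], d)))
    return True, witness


def _match_rules(
    rs: RuleSet, detected: Mapping[str, tuple[float, float]]
) -> list[FamilyRule]:
    matched = []
    for rule in rs.rules.values():
        resolved = dict(detected)
        for pair in rule.best_of:
            resolved = resolve_best_of(resolved, pair)
        ok, _ = evaluate_rule(rule, resolved)
        if ok:
            matched.append(rule)
    return matched


def _most_specific(rs: RuleSet, matched: Sequence[FamilyRule]) -> list[FamilyRule]:
    """Per rule lineage keep only the deepest matching rule.

    Rules are grouped by their top-level ancestor; within a group the rule
    with the greatest subfamily depth wins (alphabetical family_id breaks
    exact-depth ties deterministically).
    """
    by_root: dict[str, list[FamilyRule]] = {}
    for rule in matched:
        by_root.setdefault(rs.root_family(rule.family_id), []).append(rule)
    winners = []
    for root in sorted(by_root):
        group = by_root[root]
        winners.append(
            max(group, key=lambda r: (rs.rule_depth(r.family_id), r.family_id))
        )
    return winners


def classify_sequences(
    hits: Sequence[DomainHit],
    rs: RuleSet,
    sequence_universe: Optional[Iterable[str]] = None,
) -> ClassificationResult:
    """Classify sequences from filtered domain hits.

    ``sequence_universe`` optionally enumerates all searched sequences (e.g.
    from the FASTA), so sequences with no surviving hit appear in
    ``unassigned``; by default the universe is the set of sequences with at
    least one hit.  A sequence matching several unrelated families receives
    one assignment per family (and a warning).
    """
    by_seq: dict[str, list[DomainHit]] = {}
    for h in hits:
        by_seq.setdefault(h.seq_id, []).append(h)
    universe = sorted(set(sequence_universe) | by_seq.keys()) if sequence_universe is not None else sorted(by_seq)

    assignments: list[SequenceAssignment] = []
    unassigned: list[str] = []
    for seq_id in universe:
        detected = detected_domains(by_seq.get(seq_id, []))
        winners = _most_specific(rs, _match_rules(rs, detected))
        if not winners:
            unassigned.append(seq_id)
            continue
        if len({r.output_family for r in winners}) > 1:
            warnings.warn(
                f"sequence {seq_id!r} matches multiple unrelated families: "
                + ", ".join(sorted(r.output_family for r in winners)),
                stacklevel=2,
            )
        for rule in winners:
            support = tuple(
                (dom, detected[dom][0], detected[dom][1])
                for dom in sorted(detected)
                if dom in rule.required_domains
            )
            assignments.append(
                SequenceAssignment(
                    seq_id=seq_id,
                    family=rule.output_family,
                    subfamily=rule.family_id if rule.parent_family is not None else None,
                    supporting_domains=support,
                )
            )

    counts: dict[str, int] = {}
    for fam in sorted({a.family for a in assignments}):
        counts[fam] = len({a.seq_id for a in assignments if a.family == fam})
    return ClassificationResult(
        assignments=assignments, family_counts=counts, unassigned=unassigned
    )


# ---------------------------------------------------------------------------
# output files

def _fmt_domains(support: tuple[tuple[str, float, float], ...]) -> str:
    return ";".join(f"{d}:{s:g}:{c:.3f}" for d, s, c in support)


def write_outputs(result: ClassificationResult, rs: RuleSet, destination: str | Path) -> list[Path]:
    """Write the three classification outputs into ``destination``.

    * ``output1.tsv`` — one row per assignment: sequence, family, domain
      evidence (domain:bitscore:coverage);
    * ``output2.tsv`` — count of distinct sequences per output family over
      the full catalog, zero rows included;
    * ``output3.tsv`` — output 1 plus the subfamily column.

    Rows are ordered by (family, seq_id); output is byte-deterministic.
    """
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    ordered = sorted(result.assignments, key=lambda a: (a.family, a.seq_id))

    out1 = dest / "output1.tsv"
    with out1.open("w", encoding="utf-8") as fh:
        fh.write("seq_id\tfamily\tdomains\n")
        for a in ordered:
            fh.write(f"{a.seq_id}\t{a.family}\t{_fmt_domains(a.supporting_domains)}\n")

    labels, _ = family_catalog(rs)
    out2 = dest / "output2.tsv"
    with out2.open("w", encoding="utf-8") as fh:
        fh.write("family\tcount\n")
        for fam in labels:
            fh.write(f"{fam}\t{result.family_counts.get(fam, 0)}\n")

    out3 = dest / "output3.tsv"
    with out3.open("w", encoding="utf-8") as fh:
        fh.write("seq_id\tfamily\tsubfamily\tdomains\n")
        for a in ordered:
            sub = a.subfamily if a.subfamily is not None else "-"
            fh.write(
                f"{a.seq_id}\t{a.family}\t{sub}\t{_fmt_domains(a.supporting_domains)}\n"
            )
    return [out1, out2, out3]
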