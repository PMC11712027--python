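"""HMMER3 ``--domtblout`` parsing and the two hit filters.

Classification operates on hmmsearch per-domain table rows.  Two filters are
applied before any rule is evaluated:

* the *gathering threshold* (GA): a hit is kept only if its full-sequence
  bit score is at least the profile's reference score — values equal to the
  threshold pass, only strictly lower scores are discarded;
* the *coverage cutoff*: for each (sequence, profile) pair, the fraction of
  the profile's match states covered by the union of its domain alignments
  must reach the profile's cutoff (default 0.75), otherwise the whole group
  is discarded.

Both filters are per-group predicates, hence idempotent and commuting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence, TextIO

from .rules import RuleSet

__all__ = [
    "DomainHit",
    "DomtbloutError",
    "parse_domtblout",
    "filter_by_ga",
    "profile_coverage",
    "filter_by_coverage",
    "score_ordered_report",
]


class DomtbloutError(ValueError):
    """Malformed domtblout row; carries the 1-based line number."""

    def __init__(self, message: str, line: int):
        self.line = line
        super().__init__(f"line {line}: {message}")


@dataclass(frozen=True)
class DomainHit:
    """One domain row of a ``--domtblout`` table (1-based inclusive coordinates)."""

    seq_id: str
    seq_length: int
    profile_name: str
    profile_length: int
    seq_evalue: float
    seq_bitscore: float
    dom_index: int
    dom_bitscore: float
    hmm_from: int
    hmm_to: int
    ali_from: int
    ali_to: int
    env_from: int
    env_to: int
    acc: float

    def __post_init__(self) -> None:
        if not (1 <= self.hmm_from <= self.hmm_to <= self.profile_length):
            raise ValueError(
                f"{self.seq_id}/{self.profile_name}: hmm coordinates "
                f"{self.hmm_from}-{self.hmm_to} outside 1-{self.profile_length}"
            )
        if not (1 <= self.ali_from <= self.ali_to <= self.seq_length):
            raise ValueError(
                f"{self.seq_id}/{self.profile_name}: alignment coordinates "
                f"{self.ali_from}-{self.ali_to} outside 1-{self.seq_length}"
            )
        if self.env_from > self.env_to:
            raise ValueError(f"{self.seq_id}/{self.profile_name}: envelope reversed")
        if not (0.0 <= self.acc <= 1.0):
            raise ValueError(f"{self.seq_id}/{self.profile_name}: acc outside [0, 1]")


# domtblout columns (0-based) -> constructor fields
_N_COLUMNS = 22


def parse_domtblout(stream: str | TextIO) -> list[DomainHit]:
    """Parse domtblout text into :class:`DomainHit` records.

    Accepts a string or a text file object.  Comment lines (``#``) are
    skipped; each data row must have the 22 fixed whitespace-delimited
    columns (a free-text description may follow).  Raises
    :class:`DomtbloutError` naming the offending line on malformed rows.
    """
    if hasattr(stream, "read"):
        text = stream.read()
    else:
        text = stream
    hits: list[DomainHit] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split()
        if len(cols) < _N_COLUMNS:
            raise DomtbloutError(
                f"expected at least {_N_COLUMNS} columns, got {len(cols)}", lineno
            )
        try:
            hit = DomainHit(
                seq_id=cols[0],
                seq_length=int(cols[2]),
                profile_name=cols[3],
                profile_length=int(cols[5]),
                seq_evalue=float(cols[6]),
                seq_bitscore=float(cols[7]),
                dom_index=int(cols[9]),
                dom_bitscore=float(cols[13]),
                hmm_from=int(cols[15]),
                hmm_to=int(cols[16]),
                ali_from=int(cols[17]),
                ali_to=int(cols[18]),
                env_from=int(cols[19]),
                env_to=int(cols[20]),
                acc=float(cols[21]),
            )
        except ValueError as exc:
            raise DomtbloutError(str(exc), lineno) from exc
        hits.append(hit)
    return hits


def _profile_meta(hit: DomainHit, rs: RuleSet):
    try:
        return rs.profiles[hit.profile_name]
    except KeyError:
        raise KeyError(
            f"hit {hit.seq_id}: profile {hit.profile_name!r} not in rule set"
        ) from None


def filter_by_ga(hits: Sequence[DomainHit], rs: RuleSet) -> list[DomainHit]:
    """Keep hits whose full-sequence bit score reaches the profile's GA threshold.

    Boundary semantics: a score exactly equal to the threshold is retained.
    Order is preserved.  Raises ``KeyError`` for profiles unknown to ``rs``.
    """
    return [h for h in hits if h.seq_bitscore >= _profile_meta(h, rs).ga_threshold]


def profile_coverage(
    hits: Sequence[DomainHit], mode: Literal["union", "best"] = "union"
) -> float:
    """Fraction of the profile's match states covered by a group of hits.

    All hits must share seq_id, profile_name and profile_length.  ``union``
    merges the [hmm_from, hmm_to] intervals of all domain rows; ``best``
    uses the single longest interval only.
    """
    if not hits:
        raise ValueError("profile_coverage of an empty hit group")
    keys = {(h.seq_id, h.profile_name, h.profile_length) for h in hits}
    if len(keys) != 1:
        raise ValueError(f"hits span multiple (sequence, profile) groups: {sorted(keys)}")
    length = hits[0].profile_length
    intervals = sorted((h.hmm_from, h.hmm_to) for h in hits)
    if mode == "best":
        covered = max(b - a + 1 for a, b in intervals)
        return covered / length
    covered = 0
    cur_from, cur_to = intervals[0]
    for a, b in intervals[1:]:
        if a > cur_to + 1:
            covered += cur_to - cur_from + 1
            cur_from, cur_to = a, b
        else:
            cur_to = max(cur_to, b)
    covered += cur_to - cur_from + 1
    return covered / length


def filter_by_coverage(
    hits: Sequence[DomainHit],
    rs: RuleSet,
    mode: Literal["union", "best"] = "union",
) -> list[DomainHit]:
    """Keep (sequence, profile) groups whose coverage reaches the profile cutoff.

    Groups exactly at the cutoff are retained; kept groups keep all member
    hits, and input order is preserved.
    """
    groups: dict[tuple[str, str], list[DomainHit]] = {}
    for h in hits:
        _profile_meta(h, rs)
        groups.setdefault((h.seq_id, h.profile_name), []).append(h)
    keep: set[tuple[str, str]] = set()
    for key, group in groups.items():
        cutoff = rs.profiles[key[1]].coverage_cutoff
        if profile_coverage(group, mode=mode) >= cutoff:
            keep.add(key)
    return [h for h in hits if (h.seq_id, h.profile_name) in keep]


def score_ordered_report(hits: Sequence[DomainHit]) -> str:
    """TSV report of hits sorted by sequence bit score (descending).

    Ties are broken by sequence id (ascending).  Used when curating gathering
    thresholds: the score at which the domain motif starts to deviate from
    the top-scoring sequences becomes the GA threshold.  Includes the ``acc``
    (mean posterior alignment accuracy) column to aid that judgement.
    """
    header = "\t".join(
        ["seq_id", "profile", "seq_bitscore", "seq_evalue", "dom_bitscore",
         "hmm_from", "hmm_to", "acc"]
    )
    rows = [header]
    for h in sorted(hits, key=lambda h: (-h.seq_bitscore, h.seq_id)):
        rows.append(
            "\t".join(
                [h.seq_id, h.profile_name, format(h.seq_bitscore, "g"),
                 format(h.seq_evalue, "g"), format(h.dom_bitscore, "g"),
                 str(h.hmm_from), str(h.hmm_to), format(h.acc, "g")]
            )
        )
    return "\n".join(rows) + "\n"
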