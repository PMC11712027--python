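"""Two-group TAP family-size comparisons with a normality gate.

For every family (and for per-species totals) the copy numbers of the two
species groups are compared with a two-sided two-sample test.  The test is
chosen per family by Shapiro-Wilk: when both samples are compatible with
normality (p > 0.05 in each) a Welch t-test is used, otherwise the Wilcoxon
rank-sum test.  Family-level p-values are corrected with the
Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupComparison",
    "choose_test",
    "compare_groups",
    "bh_adjust",
    "SHAPIRO_ALPHA",
]

#: Level of the Shapiro-Wilk gate: normality is rejected when p <= 0.05.
SHAPIRO_ALPHA = 0.05

TOTAL_LABEL = "total"


@dataclass(frozen=True)
class GroupComparison:
    label: str  # family name or "total"
    group_a: str
    group_b: str
    test_used: str  # "t_test" | "wilcoxon"
    statistic: float
    p_value: float
    p_adjusted: float


def choose_test(sample_a: Sequence[float], sample_b: Sequence[float]) -> str:
    """Pick ``t_test`` or ``wilcoxon`` via the Shapiro-Wilk normality gate.

    ``t_test`` is chosen iff neither sample rejects normality at
    p <= 0.05.  Constant samples (zero variance, where Shapiro-Wilk is
    undefined) gate to ``wilcoxon``.  Requires at least 3 values per sample.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each sample needs at least 3 values for the normality gate")
    for s in (a, b):
        if np.ptp(s) == 0:
            return "wilcoxon"
        if sps.shapiro(s).pvalue <= SHAPIRO_ALPHA:
            return "wilcoxon"
    return "t_test"


def _two_sample(sample_a, sample_b, test: str) -> tuple[float, float]:
    if test == "t_test":
        res = sps.ttest_ind(sample_a, sample_b, equal_var=False)
    else:
        # exact null distribution for small tie-free samples, otherwise the
        # tie- and continuity-corrected normal approximation
        res = sps.mannwhitneyu(sample_a, sample_b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def compare_groups(
    matrix: pd.DataFrame,
    grouping: Mapping[str, str],
    include_total: bool = True,
) -> list[GroupComparison]:
    """Compare family sizes between exactly two species groups.

    ``matrix`` is families x species; ``grouping`` maps species to group
    labels (exactly two groups, each with >= 3 species; species without a
    group are ignored).  Returns one comparison per family — BH-adjusted
    over the family set — plus one unadjusted comparison of the per-species
    TAP totals when ``include_total`` is set.
    """
    members: dict[str, list[str]] = {}
    for sp in matrix.columns:
        if sp in grouping:
            members.setdefault(grouping[sp], []).append(sp)
    groups = sorted(members)
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    ga, gb = groups
    if len(members[ga]) < 3 or len(members[gb]) < 3:
        raise ValueError("each group needs at least 3 species")

    rows: list[tuple[str, str, float, float]] = []
    for family in matrix.index:
        a = matrix.loc[family, members[ga]].to_numpy(dtype=float)
        b = matrix.loc[family, members[gb]].to_numpy(dtype=float)
        test = choose_test(a, b)
        stat, p = _two_sample(a, b, test)
        rows.append((family, test, stat, p))

    adjusted = bh_adjust([r[3] for r in rows])
    out = [
        GroupComparison(
            label=family, group_a=ga, group_b=gb, test_used=test,
            statistic=stat, p_value=p, p_adjusted=float(p_adj),
        )
        for (family, test, stat, p), p_adj in zip(rows, adjusted)
    ]

    if include_total:
        ta = matrix[members[ga]].sum(axis=0).to_numpy(dtype=float)
        tb = matrix[members[gb]].sum(axis=0).to_numpy(dtype=float)
        test = choose_test(ta, tb)
        stat, p = _two_sample(ta, tb, test)
        out.append(
            GroupComparison(
                label=TOTAL_LABEL, group_a=ga, group_b=gb, test_used=test,
                statistic=stat, p_value=p, p_adjusted=p,
            )
        )
    return out
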