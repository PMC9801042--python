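"""Polyploid (wheat-style) homoeolog analytics.

Assigns precursors to subgenomes from chromosome-name patterns, groups
homologous mature sequences by single-linkage clustering under a small
edit distance, classifies groups into A:B:D copy-number configurations,
and provides the triad fraction, a chi-square subgenome-bias test, and
ternary expression coordinates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import edlib
import numpy as np
from scipy import stats

DEFAULT_LABELS = ("A", "B", "D")
UNPLACED = "unplaced"


def assign_subgenome(
    chrom: str,
    patterns: Optional[Dict[str, str]] = None,
    labels: Sequence[str] = DEFAULT_LABELS,
) -> str:
    """Subgenome label for a chromosome name.

    The default rule is the wheat convention: the trailing letter of names
    like ``1A``..``7D`` (also matching ``chr3B``).  A pattern map of
    label -> regex overrides it; the first matching label wins.
    """
    if patterns is None:
        patterns = {lab: rf"^(chr)?[0-9]+{lab}$" for lab in labels}
    for lab, pat in patterns.items():
        if re.match(pat, chrom):
            return lab
    return UNPLACED


@dataclass
class HomologGroup:
    group_id: str
    members: List[Tuple[str, str]]  # (member id, subgenome label)
    configuration: str = ""

    def label_counts(self, labels: Sequence[str] = DEFAULT_LABELS) -> Dict[str, int]:
        counts = {lab: 0 for lab in labels}
        for _, lab in self.members:
            if lab in counts:
                counts[lab] += 1
        return counts

    @property
    def is_triad(self) -> bool:
        return self.configuration == "1:1:1"


def _edit_distance(a: str, b: str, k: int) -> int:
    res = edlib.align(a, b, mode="NW", task="distance", k=k)
    return res["editDistance"]  # -1 when > k


def group_homologs(
    matures: Sequence[Tuple[str, str, str]],
    max_distance: int = 2,
    labels: Sequence[str] = DEFAULT_LABELS,
) -> List[HomologGroup]:
    """Single-linkage clustering of (id, sequence, subgenome) triples.

    Two members join when their mature sequences are within
    ``max_distance`` edits.  Group ids come from the lexicographically
    smallest member id, making the partition independent of input order.
    """
    if not matures:
        raise ValueError("no mature sequences to group")
    items = sorted(matures, key=lambda t: (t[0], t[1]))
    n = len(items)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    # bucket by length to skip impossible pairs (length diff > max_distance)
    by_len: Dict[int, List[int]] = {}
    for i, (_, seq, _) in enumerate(items):
        by_len.setdefault(len(seq), []).append(i)
    lengths = sorted(by_len)
    for li, la in enumerate(lengths):
        cand_idx = []
        for lb in lengths[li:]:
            if lb - la > max_distance:
                break
            cand_idx.extend(by_len[lb])
        for ii, i in enumerate(by_len[la]):
            for j in cand_idx:
                if j <= i:
                    continue
                if items[i][1] == items[j][1] or _edit_distance(
                    items[i][1], items[j][1], max_distance
                ) >= 0:
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[max(ri, rj)] = min(ri, rj)

    clusters: Dict[int, List[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    groups: List[HomologGroup] = []
    for root in clusters:
        member_idx = clusters[root]
        members = sorted((items[i][0], items[i][2]) for i in member_idx)
        gid = members[0][0]
        g = HomologGroup(group_id=gid, members=members)
        g.configuration = classify_configuration(g, labels=labels)
        groups.append(g)
    groups.sort(key=lambda g: g.group_id)
    return groups


def classify_configuration(
    group: HomologGroup, labels: Sequence[str] = DEFAULT_LABELS
) -> str:
    """Per-subgenome copy-count signature ("a:b:d") or "others".

    "others" covers any group with more than one copy on some subgenome or
    with unplaced members; unplaced members are excluded from the digits
    but keep the group in the "others" class.
    """
    counts = group.label_counts(labels)
    n_unplaced = sum(1 for _, lab in group.members if lab not in labels)
    if n_unplaced > 0 or any(c > 1 for c in counts.values()):
        return "others"
    return ":".join(str(counts[lab]) for lab in labels)


def configuration_tally(groups: Sequence[HomologGroup]) -> Dict[str, int]:
    tally: Dict[str, int] = {}
    for g in groups:
        tally[g.configuration] = tally.get(g.configuration, 0) + 1
    return tally


def triad_fraction(groups: Sequence[HomologGroup]) -> float:
    """Fraction of homolog groups that are 1:1:1 triads."""
    if not groups:
        raise ValueError("no homolog groups")
    return sum(1 for g in groups if g.is_triad) / len(groups)


@dataclass
class Chi2Result:
    statistic: float
    df: int
    p_value: float


def subgenome_bias_test(
    counts: Sequence[int], expected: Optional[Sequence[float]] = None
) -> Chi2Result:
    """Goodness-of-fit chi-square of per-subgenome precursor counts.

    Expected counts are equal by default (no continuity correction);
    supply ``expected`` for subgenome-size-proportional expectations.
    """
    obs = np.asarray(counts, dtype=float)
    if len(obs) < 2:
        raise ValueError("need at least two subgenome labels")
    if obs.sum() <= 0:
        raise ValueError("zero total count")
    if expected is not None:
        exp = np.asarray(expected, dtype=float)
        exp = exp / exp.sum() * obs.sum()
    else:
        exp = None
    stat, p = stats.chisquare(obs, f_exp=exp)
    return Chi2Result(statistic=float(stat), df=len(obs) - 1, p_value=float(p))


@dataclass
class TernaryPoint:
    a: float
    b: float
    d: float
    defined: bool = True

    def as_tuple(self) -> Tuple[float, float, float]:
        return (self.a, self.b, self.d)


def ternary_coordinates(expr: Sequence[float]) -> TernaryPoint:
    """Normalize (a, b, d) expression to shares summing to 1.

    A zero total yields an undefined point (flagged, components NaN-free
    zeros) rather than an error, so whole tables can be mapped."""
    a, b, d = (float(x) for x in expr)
    total = a + b + d
    if min(a, b, d) < 0:
        raise ValueError("expression values must be >= 0")
    if total == 0:
        return TernaryPoint(0.0, 0.0, 0.0, defined=False)
    return TernaryPoint(a / total, b / total, d / total)
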