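"""Hairpin folding, duplex geometry, processing precision, and features.

The default folding engine is a deterministic weighted base-pair
maximization (Nussinov-style dynamic program) over nested pairings with a
minimum hairpin-loop size.  Pair weights play the role of a toy energy
model (GC -3, AU -2, GU -1 by default), so the reported "energy" is the
sum of pair weights of the optimal structure; AMFE normalizes it per
100 nt.  A thermodynamic folder can be plugged in by supplying a
dot-bracket string and energy directly via :func:`structure_from_dotbracket`
(Vienna convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import MatureRecord, PrecursorRecord, normalize_rna
from .srna import ReadStack

_ALPHABET = set("ACGU")


@dataclass
class FoldParams:
    """Pair weights (<= 0) and minimum hairpin loop size for the folder."""

    gc: float = -3.0
    au: float = -2.0
    gu: float = -1.0
    min_loop: int = 3

    def __post_init__(self) -> None:
        if self.gc > 0 or self.au > 0 or self.gu > 0:
            raise ValueError("pair weights must be <= 0")
        if self.min_loop < 3:
            raise ValueError("min_loop must be >= 3")

    def weight(self, a: str, b: str) -> Optional[float]:
        pair = a + b
        if pair in ("GC", "CG"):
            return self.gc
        if pair in ("AU", "UA"):
            return self.au
        if pair in ("GU", "UG"):
            return self.gu
        return None


DEFAULT_FOLD_PARAMS = FoldParams()


@dataclass
class SecondaryStructure:
    """Dot-bracket + symmetric pair table + energy."""

    dotbracket: str
    pairs: Dict[int, int]
    energy: float

    def __post_init__(self) -> None:
        for i, j in self.pairs.items():
            if self.pairs.get(j) != i:
                raise ValueError("pair table is not symmetric")

    def __len__(self) -> int:
        return len(self.dotbracket)

    def partner(self, i: int) -> Optional[int]:
        return self.pairs.get(i)

    @property
    def paired_fraction(self) -> float:
        return len(self.pairs) / len(self.dotbracket) if self.dotbracket else 0.0


def _pairs_from_dotbracket(db: str) -> Dict[int, int]:
    stack: List[int] = []
    pairs: Dict[int, int] = {}
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced dot-bracket at position {i}")
            j = stack.pop()
            pairs[i] = j
            pairs[j] = i
        elif c != ".":
            raise ValueError(f"invalid dot-bracket character {c!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket: unclosed '('")
    return pairs


def structure_from_dotbracket(
    db: str, seq: Optional[str] = None, energy: Optional[float] = None,
    params: FoldParams = DEFAULT_FOLD_PARAMS,
) -> SecondaryStructure:
    """Accept an externally supplied dot-bracket verbatim.

    When no energy is given it is computed from the pair table under the
    active toy weights (requires the sequence).
    """
    pairs = _pairs_from_dotbracket(db)
    if energy is None:
        if seq is None:
            raise ValueError("need a sequence to score a bare dot-bracket")
        seq = normalize_rna(seq)
        energy = 0.0
        for i, j in pairs.items():
            if i < j:
                w = params.weight(seq[i], seq[j])
                energy += w if w is not None else 0.0
    return SecondaryStructure(dotbracket=db, pairs=pairs, energy=energy)


def fold_hairpin(seq: str, params: FoldParams = DEFAULT_FOLD_PARAMS) -> SecondaryStructure:
    """Minimum-energy nested structure by weighted base-pair maximization.

    Deterministic traceback: pairing i is preferred over leaving i
    unpaired on ties, and the smallest bifurcation point wins.
    """
    seq = normalize_rna(seq)
    if set(seq) - _ALPHABET:
        raise ValueError(f"non-ACGU(T) characters in sequence: {set(seq) - _ALPHABET}")
    n = len(seq)
    if n < params.min_loop + 2:
        raise ValueError(f"sequence shorter than min_loop + 2 = {params.min_loop + 2}")

    # weight matrix; +inf marks unpairable
    idx = np.frombuffer(seq.encode(), dtype=np.uint8)
    codes = np.zeros(n, dtype=np.int8)
    for base, c in zip("ACGU", range(4)):
        codes[idx == ord(base)] = c
    wtab = np.full((4, 4), np.inf)
    for (a, b), w in (
        (("G", "C"), params.gc), (("C", "G"), params.gc),
        (("A", "U"), params.au), (("U", "A"), params.au),
        (("G", "U"), params.gu), (("U", "G"), params.gu),
    ):
        wtab["ACGU".index(a), "ACGU".index(b)] = w
    W = wtab[np.ix_(codes, codes)]  # W[i, k] = weight of pair (i, k) or inf

    INF = np.inf
    E = np.zeros((n + 1, n + 1))  # E[i][j] over half-open window [i, j)
    for span in range(2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span  # exclusive
            best = E[i + 1][j]  # i unpaired
            ks = np.arange(i + params.min_loop + 1, j)
            if len(ks):
                cand = W[i, ks] + E[i + 1, ks] + E[ks + 1, j]
                kbest = cand.min()
                if kbest < best:
                    best = kbest
            E[i][j] = best

    # traceback: prefer pairing, then smaller bifurcation point
    pairs: Dict[int, int] = {}
    stack = [(0, n)]
    while stack:
        i, j = stack.pop()
        if j - i < 2:
            continue
        target = E[i][j]
        chosen = None
        for k in range(i + params.min_loop + 1, j):
            w = W[i, k]
            if w < INF and w + E[i + 1][k] + E[k + 1][j] == target:
                chosen = k
                break
        if chosen is not None and W[i, chosen] < 0:
            pairs[i] = chosen
            pairs[chosen] = i
            stack.append((i + 1, chosen))
            stack.append((chosen + 1, j))
        else:
            stack.append((i + 1, j))

    db = "".join(
        "(" if i in pairs and pairs[i] > i else ")" if i in pairs else "."
        for i in range(n)
    )
    return SecondaryStructure(dotbracket=db, pairs=pairs, energy=float(E[0][n]))


def amfe(energy: float, length: int) -> float:
    """Adjusted (length-normalized) minimal free energy per 100 nt."""
    if length <= 0:
        raise ValueError("length must be positive")
    return energy / length * 100.0


# ---------------------------------------------------------------------------
# Duplex geometry
# ---------------------------------------------------------------------------

@dataclass
class DuplexStats:
    """Geometry of the mature/star duplex under canonical Dicer processing."""

    mismatches: int
    asym_bulge_nt: int
    overhang_3p_5arm: int
    overhang_3p_3arm: int
    star_offset: int
    star_length: int

    @property
    def star_end(self) -> int:
        return self.star_offset + self.star_length


def _mature_arm(structure: SecondaryStructure, mature: MatureRecord) -> str:
    """Which arm the mature sits on; error when it straddles the loop."""
    partners = [structure.partner(i) for i in range(mature.offset, mature.end)]
    partners = [p for p in partners if p is not None]
    if not partners:
        raise ValueError("loop-spanning mature: no paired positions")
    above = [p for p in partners if p >= mature.end]
    below = [p for p in partners if p < mature.offset]
    inside = [p for p in partners if mature.offset <= p < mature.end]
    if inside or (above and below):
        raise ValueError("loop-spanning mature")
    return "5p" if above else "3p"


def extract_duplex(structure: SecondaryStructure, mature: MatureRecord) -> DuplexStats:
    """Infer the star under 2-nt 3' overhang geometry and score the duplex.

    The star spans the partners of the mature shifted to leave 2-nt 3'
    overhangs on both strands; bulged (unpaired) anchor positions are
    skipped inward when locating the star ends.  Mismatches count mature
    positions (excluding the mature's own 2-nt 3' overhang) that are
    unpaired or paired outside the star.  ``asym_bulge_nt`` totals the nt
    imbalance of interior loops between the two strands of the duplex.
    """
    _mature_arm(structure, mature)  # raises for loop-spanning matures
    n = len(structure)
    m0, m1 = mature.offset, mature.end  # half-open

    # anchor positions for star inference (skip unpaired anchors inward)
    def paired_from(pos: int, step: int, lo: int, hi: int) -> Optional[Tuple[int, int]]:
        skipped = 0
        while lo <= pos < hi:
            p = structure.partner(pos)
            if p is not None:
                return pos, skipped
            pos += step
            skipped += 1
        return None

    a_hi = paired_from(m0, +1, m0, m1)  # anchor for star 3' end
    a_lo = paired_from(m1 - 3, -1, m0, m1)  # anchor for star 5' end
    if a_hi is None or a_lo is None:
        raise ValueError("mature has no paired positions for star inference")
    q1, skip1 = a_hi
    q2, skip2 = a_lo
    star_hi = structure.partner(q1) + 2 + skip1  # inclusive 3' end of star
    star_lo = structure.partner(q2) - skip2
    star_lo = max(0, star_lo)
    star_hi = min(n - 1, star_hi)
    if star_lo > star_hi:
        star_lo, star_hi = star_hi, star_lo
    star_offset, star_end = star_lo, star_hi + 1

    # mismatches over the duplex-facing part of the mature
    mismatches = 0
    for i in range(m0, m1 - 2):
        p = structure.partner(i)
        if p is None or not (star_offset <= p < star_end):
            mismatches += 1

    # interior-loop asymmetry between consecutive paired mature positions
    paired_pos = [i for i in range(m0, m1) if structure.partner(i) is not None
                  and star_offset <= structure.partner(i) < star_end]
    asym = 0
    for a, b in zip(paired_pos, paired_pos[1:]):
        gap_m = b - a - 1
        gap_s = abs(structure.partner(a) - structure.partner(b)) - 1
        asym += abs(gap_m - gap_s)

    # 3' overhangs measured from the pair table
    if m0 < star_offset:  # mature on 5' arm
        five = (m0, m1)
        three = (star_offset, star_end)
    else:
        five = (star_offset, star_end)
        three = (m0, m1)

    def first_paired(lo: int, hi: int) -> Optional[int]:
        for i in range(lo, hi):
            if structure.partner(i) is not None:
                return i
        return None

    def last_paired(lo: int, hi: int) -> Optional[int]:
        for i in range(hi - 1, lo - 1, -1):
            if structure.partner(i) is not None:
                return i
        return None

    o3 = o5 = 0
    fp = first_paired(*five)
    if fp is not None:
        o3 = (three[1] - 1 - structure.partner(fp)) - (fp - five[0])
    lp = last_paired(*five)
    if lp is not None:
        o5 = (five[1] - 1 - lp) - (structure.partner(lp) - three[0])

    return DuplexStats(
        mismatches=mismatches,
        asym_bulge_nt=asym,
        overhang_3p_5arm=max(0, o5),
        overhang_3p_3arm=max(0, o3),
        star_offset=star_offset,
        star_length=star_end - star_offset,
    )


def infer_star(structure: SecondaryStructure, mature: MatureRecord) -> Tuple[int, int]:
    """(offset, length) of the inferred star for a mature."""
    d = extract_duplex(structure, mature)
    return d.star_offset, d.star_length


# ---------------------------------------------------------------------------
# Processing precision
# ---------------------------------------------------------------------------

def precision_of_processing(
    stack: ReadStack,
    matures: Sequence[MatureRecord],
    star: Optional[Tuple[int, int]] = None,
    tol: int = 1,
) -> float:
    """Fraction of stacked read counts whose 5' and 3' ends both fall
    within +/- ``tol`` nt of an annotated mature or inferred star end."""
    if not stack.entries:
        raise ValueError("no read support: empty stack")
    refs: List[Tuple[int, int]] = [(m.offset, m.end) for m in matures]
    if star is not None:
        refs.append((star[0], star[0] + star[1]))
    if not refs:
        raise ValueError("no reference mature/star coordinates")
    total = precise = 0
    for offset, length, count, _sample in stack.entries:
        total += count
        end = offset + length
        if any(abs(offset - s) <= tol and abs(end - e) <= tol for s, e in refs):
            precise += count
    return precise / total


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------

def _kmer_names(k: int) -> List[str]:
    names = [""]
    for _ in range(k):
        names = [n + b for n in names for b in "ACGU"]
    return names


@dataclass
class FeatureRegistry:
    """Versioned, ordered feature-name registry.

    Sequence family: mono/di/tri-nucleotide frequencies (4 + 16 + 64),
    GC content, precursor and mature lengths.  Structure family: paired
    fraction, MFE, AMFE, stem length, loop size, duplex statistics, and a
    per-position pairing profile binned to ``n_profile_bins``.  Expression
    family: max TPM, mean TPM, breadth (zeros when no evidence).
    """

    kmer_max: int = 3
    n_profile_bins: int = 20
    include_expression: bool = True
    version: str = "default-1"

    def names(self) -> List[str]:
        out: List[str] = []
        for k in range(1, self.kmer_max + 1):
            out += [f"freq_{m}" for m in _kmer_names(k)]
        out += ["gc_content", "precursor_len", "mature_len"]
        out += [
            "paired_fraction", "mfe", "amfe", "stem_len", "loop_size",
            "duplex_mismatches", "duplex_asym_bulge_nt",
            "overhang_3p_5arm", "overhang_3p_3arm",
        ]
        out += [f"pairing_bin_{i:02d}" for i in range(self.n_profile_bins)]
        if self.include_expression:
            out += ["tpm_max", "tpm_mean", "breadth"]
        return out


DEFAULT_REGISTRY = FeatureRegistry()


def _stem_and_loop(structure: SecondaryStructure) -> Tuple[int, int]:
    """Stem length = number of pairs; loop size = smallest enclosed gap."""
    n_pairs = len(structure.pairs) // 2
    if n_pairs == 0:
        return 0, len(structure)
    inner = min(
        (j - i - 1) for i, j in structure.pairs.items() if i < j
    )
    return n_pairs, inner


def extract_features(
    record: PrecursorRecord,
    structure: SecondaryStructure,
    duplex: Optional[DuplexStats] = None,
    expression: Optional[Dict[str, float]] = None,
    registry: FeatureRegistry = DEFAULT_REGISTRY,
) -> "pd.Series":
    """Deterministic feature vector per the active registry."""
    import pandas as pd

    seq = record.sequence
    n = len(seq)
    values: Dict[str, float] = {}
    for k in range(1, registry.kmer_max + 1):
        counts = {m: 0 for m in _kmer_names(k)}
        denom = max(1, n - k + 1)
        for i in range(n - k + 1):
            counts[seq[i : i + k]] = counts.get(seq[i : i + k], 0) + 1
        for m in _kmer_names(k):
            values[f"freq_{m}"] = counts[m] / denom
    values["gc_content"] = (seq.count("G") + seq.count("C")) / n
    values["precursor_len"] = float(n)
    pm = record.primary_mature()
    values["mature_len"] = float(pm.length) if pm else 0.0

    values["paired_fraction"] = structure.paired_fraction
    values["mfe"] = structure.energy
    values["amfe"] = amfe(structure.energy, n)
    stem, loop = _stem_and_loop(structure)
    values["stem_len"] = float(stem)
    values["loop_size"] = float(loop)
    if duplex is not None:
        values["duplex_mismatches"] = float(duplex.mismatches)
        values["duplex_asym_bulge_nt"] = float(duplex.asym_bulge_nt)
        values["overhang_3p_5arm"] = float(duplex.overhang_3p_5arm)
        values["overhang_3p_3arm"] = float(duplex.overhang_3p_3arm)
    else:  # no resolvable duplex: fail-worst sentinel values, kept finite
        values["duplex_mismatches"] = float(pm.length if pm else n)
        values["duplex_asym_bulge_nt"] = float(n)
        values["overhang_3p_5arm"] = 0.0
        values["overhang_3p_3arm"] = 0.0

    paired = np.array([1.0 if i in structure.pairs else 0.0 for i in range(n)])
    bins = np.array_split(paired, registry.n_profile_bins)
    for i, b in enumerate(bins):
        values[f"pairing_bin_{i:02d}"] = float(b.mean()) if len(b) else 0.0

    if registry.include_expression:
        expression = expression or {}
        values["tpm_max"] = float(expression.get("tpm_max", 0.0))
        values["tpm_mean"] = float(expression.get("tpm_mean", 0.0))
        values["breadth"] = float(expression.get("breadth", 0.0))

    s = pd.Series(values).reindex(registry.names())
    if s.isna().any():
        raise ValueError(f"registry mismatch: missing {list(s[s.isna()].index)}")
    return s
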