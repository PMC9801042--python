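"""Compilation of candidate miRNA precursors from heterogeneous sources.

Aggregates per-source annotations (GFF3 + genome, or bare precursor
sequences located by mismatch-tolerant search), merges loci that
reciprocally overlap on the same strand, and applies a uniform naming
scheme in which database-derived names take precedence and novel loci
receive ``<prefix>-MIR_N<k><letter>`` style names.
"""

from __future__ import annotations

import re
from collections import defaultdict
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import gffutils
import numpy as np
from Bio import SeqIO

from .core import GenomicInterval, MatureRecord, PrecursorRecord, normalize_rna, revcomp_rna

PRECURSOR_TYPE = "miRNA_primary_transcript"
MATURE_TYPE = "miRNA"


# ---------------------------------------------------------------------------
# FASTA / GFF3 input
# ---------------------------------------------------------------------------

def load_fasta(path: str) -> Dict[str, str]:
    """Read a FASTA file into a dict of uppercase sequences (DNA or RNA)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def _extract_transcribed(genome: Dict[str, str], iv: GenomicInterval) -> str:
    if iv.chrom not in genome:
        raise ValueError(f"chromosome {iv.chrom!r} absent from genome FASTA")
    contig = genome[iv.chrom]
    if iv.end > len(contig):
        raise ValueError(
            f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds contig length {len(contig)}"
        )
    sub = contig[iv.start : iv.end]
    if iv.strand == "-":
        return revcomp_rna(sub)
    return normalize_rna(sub)


def _feature_name(feat) -> str:
    for key in ("Name", "ID"):
        if key in feat.attributes:
            return feat.attributes[key][0]
    return f"{feat.featuretype}:{feat.seqid}:{feat.start}-{feat.end}"


def parse_annotation_source(
    gff3_path: str,
    genome: Dict[str, str],
    source_tag: str = "annotated",
    precursor_type: str = PRECURSOR_TYPE,
    mature_type: str = MATURE_TYPE,
) -> List[PrecursorRecord]:
    """Parse one annotation source into precursor records.

    Mature features are nested under the precursor that contains them by
    coordinate (same chrom and strand); a mature contained by no precursor
    is an error naming the offending feature.  Minus-strand sequences are
    stored reverse-complemented so records carry the transcribed strand.
    """
    db = gffutils.create_db(
        gff3_path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    records: List[PrecursorRecord] = []
    intervals: List[Tuple[GenomicInterval, PrecursorRecord]] = []
    for feat in db.features_of_type(precursor_type, order_by=("seqid", "start")):
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        seq = _extract_transcribed(genome, iv)
        rec = PrecursorRecord(
            id=_feature_name(feat), sequence=seq, sources={source_tag}, interval=iv
        )
        records.append(rec)
        intervals.append((iv, rec))

    for feat in db.features_of_type(mature_type, order_by=("seqid", "start")):
        m_iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        host = None
        for iv, rec in intervals:
            if iv.strand == m_iv.strand and iv.contains(m_iv):
                host = (iv, rec)
                break
        if host is None:
            raise ValueError(
                f"mature feature {_feature_name(feat)} at "
                f"{m_iv.chrom}:{m_iv.start}-{m_iv.end}({m_iv.strand}) is not "
                "contained in any precursor"
            )
        iv, rec = host
        offset = m_iv.start - iv.start if iv.strand == "+" else iv.end - m_iv.end
        length = len(m_iv)
        mature = MatureRecord(
            name=_feature_name(feat),
            arm="unknown",
            offset=offset,
            length=length,
            sequence=rec.sequence[offset : offset + length],
        )
        rec.add_mature(mature)
    return records


# ---------------------------------------------------------------------------
# Mismatch-tolerant location of coordinate-free precursors
# ---------------------------------------------------------------------------

def _to_dna_bytes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().replace("U", "T").encode(), dtype=np.uint8)


def locate_precursor(
    seq: str, genome: Dict[str, str], max_mismatch: int = 2
) -> List[GenomicInterval]:
    """All genome positions (both strands) matching *seq* with at most
    ``max_mismatch`` substitutions, ordered by (chrom, start, strand).

    Substitutions only — indel-tolerant alignment is out of scope.  An
    empty list marks the precursor as unlocated downstream.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    queries = {"+": _to_dna_bytes(seq), "-": _to_dna_bytes(revcomp_rna(seq))}
    L = len(seq)
    hits: List[GenomicInterval] = []
    for chrom in sorted(genome):
        contig = _to_dna_bytes(genome[chrom])
        if len(contig) < L:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(contig, L)
        for strand, q in queries.items():
            mism = (windows != q).sum(axis=1)
            for start in np.flatnonzero(mism <= max_mismatch):
                hits.append(GenomicInterval(chrom, int(start), int(start) + L, strand))
    hits.sort(key=lambda iv: (iv.chrom, iv.start, iv.strand))
    return hits


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

class SourceCatalog(dict):
    """source tag -> set of precursor ids, with Venn-style region counts."""

    def region_counts(self) -> Dict[Tuple[str, ...], int]:
        return source_region_counts(self)


def _mature_key_on(rep: PrecursorRecord, rec: PrecursorRecord, m: MatureRecord):
    """Re-express a mature onto the representative's coordinates; None if outside."""
    if rec.interval is None or rep.interval is None:
        return (m.offset, m.length)
    if rec.interval.strand == "+":
        g_start = rec.interval.start + m.offset
    else:
        g_start = rec.interval.end - m.offset - m.length
    if rep.interval.strand == "+":
        new_off = g_start - rep.interval.start
    else:
        new_off = rep.interval.end - (g_start + m.length)
    if new_off < 0 or new_off + m.length > len(rep.sequence):
        return None
    return (new_off, m.length)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def aggregate_candidates(
    record_sets: Sequence[Tuple[str, Sequence[PrecursorRecord]]],
    min_overlap_fraction: float = 0.5,
) -> Tuple[List[PrecursorRecord], SourceCatalog]:
    """Merge same-strand precursors that reciprocally overlap.

    Records sharing >= ``min_overlap_fraction`` reciprocal overlap (single
    linkage) collapse to one record whose sources is the union and whose
    matures are deduplicated by (offset, length) on the representative
    (longest) member.  Unlocated records pass through, deduplicated by
    exact sequence.  The result is independent of input order.
    """
    located: List[Tuple[str, PrecursorRecord]] = []
    unlocated: List[Tuple[str, PrecursorRecord]] = []
    for tag, recs in record_sets:
        for rec in recs:
            rec = PrecursorRecord(
                id=rec.id,
                sequence=rec.sequence,
                sources=set(rec.sources) | {tag},
                interval=rec.interval,
                matures=list(rec.matures),
            )
            (located if rec.interval is not None else unlocated).append((tag, rec))

    located.sort(
        key=lambda tr: (
            tr[1].interval.chrom,
            tr[1].interval.start,
            tr[1].interval.end,
            tr[1].interval.strand,
            tr[1].id,
        )
    )
    uf = _UnionFind(len(located))
    for i in range(len(located)):
        iv_i = located[i][1].interval
        for j in range(i + 1, len(located)):
            iv_j = located[j][1].interval
            if iv_j.chrom != iv_i.chrom or iv_j.start >= iv_i.end:
                break
            if iv_j.strand != iv_i.strand:
                continue
            if iv_i.reciprocal_overlap(iv_j) >= min_overlap_fraction:
                uf.union(i, j)

    clusters: Dict[int, List[Tuple[str, PrecursorRecord]]] = defaultdict(list)
    for i, item in enumerate(located):
        clusters[uf.find(i)].append(item)

    merged: List[PrecursorRecord] = []
    for root in sorted(clusters):
        members = clusters[root]
        rep = min(
            (rec for _, rec in members),
            key=lambda r: (-len(r.sequence), r.interval.start, r.id),
        )
        sources = set().union(*(rec.sources for _, rec in members))
        mature_keys = {}
        for _, rec in members:
            for m in rec.matures:
                key = _mature_key_on(rep, rec, m)
                if key is not None and key not in mature_keys:
                    mature_keys[key] = m.name
        matures = [
            MatureRecord(
                name=mature_keys[(off, ln)],
                arm="unknown",
                offset=off,
                length=ln,
                sequence=rep.sequence[off : off + ln],
            )
            for off, ln in sorted(mature_keys)
        ]
        out = PrecursorRecord(
            id=rep.id, sequence=rep.sequence, sources=sources, interval=rep.interval
        )
        for m in matures:
            out.add_mature(m)
        merged.append(out)

    # unlocated singletons: deduplicate by exact sequence
    by_seq: Dict[str, PrecursorRecord] = {}
    for _, rec in sorted(unlocated, key=lambda tr: (tr[1].sequence, tr[1].id)):
        if rec.sequence in by_seq:
            prev = by_seq[rec.sequence]
            prev.sources |= rec.sources
            seen = {(m.offset, m.length) for m in prev.matures}
            for m in rec.matures:
                if (m.offset, m.length) not in seen:
                    prev.add_mature(m)
                    seen.add((m.offset, m.length))
        else:
            by_seq[rec.sequence] = PrecursorRecord(
                id=rec.id,
                sequence=rec.sequence,
                sources=set(rec.sources),
                interval=None,
                matures=list(rec.matures),
            )
    merged.extend(by_seq[s] for s in sorted(by_seq))

    catalog = SourceCatalog()
    for rec in merged:
        for src in rec.sources:
            catalog.setdefault(src, set()).add(rec.id)
    return merged, catalog


def source_region_counts(catalog: Dict[str, set]) -> Dict[Tuple[str, ...], int]:
    """Venn-region counts: one count per nonempty source-membership pattern."""
    if not catalog:
        raise ValueError("catalog must contain at least one source")
    membership: Dict[str, set] = defaultdict(set)
    for src, ids in catalog.items():
        for i in ids:
            membership[i].add(src)
    counts: Dict[Tuple[str, ...], int] = defaultdict(int)
    for srcs in membership.values():
        counts[tuple(sorted(srcs))] += 1
    return dict(counts)


# ---------------------------------------------------------------------------
# Uniform naming
# ---------------------------------------------------------------------------

_LETTERS = "abcdefghijklmnopqrstuvwxyz"


def _member_letter(i: int) -> str:
    """a, b, ..., z, aa, ab, ... for family members."""
    out = ""
    i += 1
    while i > 0:
        i, r = divmod(i - 1, 26)
        out = _LETTERS[r] + out
    return out


def assign_uniform_names(
    records: Sequence[PrecursorRecord],
    species_prefix: str,
    novel_source: str = "predicted",
) -> List[PrecursorRecord]:
    """Apply the uniform naming scheme in place.

    Records carrying a database name (any source other than the novel tag)
    keep it.  Novel loci are numbered in genomic order and named
    ``<prefix>-MIR_N<k><letter>``; identical-sequence siblings (multiple
    genome hits) share ``k`` and differ by letter.  Matures get ``-5p`` /
    ``-3p`` suffixes.  Duplicate resulting names raise.
    """
    if not re.fullmatch(r"[a-z]{3}", species_prefix):
        raise ValueError("species_prefix must be a lowercase 3-letter code")

    novel = [r for r in records if r.sources == {novel_source}]
    order_key = lambda r: (
        (0, r.interval.chrom, r.interval.start) if r.interval else (1, r.sequence, 0)
    )
    families: Dict[str, List[PrecursorRecord]] = {}
    for rec in sorted(novel, key=order_key):
        families.setdefault(rec.sequence, []).append(rec)

    k = 0
    seen_first: List[str] = []
    for rec in sorted(novel, key=order_key):
        if rec.sequence in seen_first:
            continue
        seen_first.append(rec.sequence)
        k += 1
        for member_i, member in enumerate(families[rec.sequence]):
            member.id = f"{species_prefix}-MIR_N{k}{_member_letter(member_i)}"
            stem = f"{species_prefix}-miR_N{k}{_member_letter(member_i)}"
            for m in member.matures:
                if m.arm == "unknown":
                    m.arm = member.infer_arm(m)
                m.name = f"{stem}-{m.arm}"

    names = [r.id for r in records]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise ValueError(f"duplicate precursor names after assignment: {sorted(dupes)}")
    return list(records)


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def write_gff3(records: Iterable[PrecursorRecord], path: str) -> None:
    """Write located records as GFF3 (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in records:
            if rec.interval is None:
                continue
            iv = rec.interval
            fh.write(
                f"{iv.chrom}\tmircurate\t{PRECURSOR_TYPE}\t{iv.start + 1}\t{iv.end}\t."
                f"\t{iv.strand}\t.\tID={rec.id};Name={rec.id};"
                f"sources={','.join(sorted(rec.sources))}\n"
            )
            for m in sorted(rec.matures, key=lambda m: m.offset):
                if iv.strand == "+":
                    g_start = iv.start + m.offset
                else:
                    g_start = iv.end - m.offset - m.length
                fh.write(
                    f"{iv.chrom}\tmircurate\t{MATURE_TYPE}\t{g_start + 1}\t"
                    f"{g_start + m.length}\t.\t{iv.strand}\t.\t"
                    f"ID={m.name};Name={m.name};Derives_from={rec.id}\n"
                )


def write_fasta(records: Iterable[PrecursorRecord], path: str, matures: bool = False) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if matures:
                for m in sorted(rec.matures, key=lambda m: m.offset):
                    fh.write(f">{m.name}\n{m.sequence}\n")
            else:
                fh.write(f">{rec.id}\n{rec.sequence}\n")


def write_catalog_tsv(catalog: SourceCatalog, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("source\tprecursor_id\n")
        for src in sorted(catalog):
            for pid in sorted(catalog[src]):
                fh.write(f"{src}\t{pid}\n")
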