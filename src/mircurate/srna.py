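"""Aligned sRNA reads -> read stacks, TPM matrices, breadth, de-novo loci.

Reads use the collapsed representation standard in sRNA work: one entry
per unique (sequence, placement, sample) with a multiplicity count.  SAM
input is parsed with pysam (count recovered from the ``_xN`` name suffix
written by common collapsers, default 1); a 6-column TSV dialect
(sample, chrom, start, end, strand, count) is accepted for
dependency-free round trips.  Multi-mapped reads count fully at each
placement up to a configurable cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd
import pysam

from .core import GenomicInterval, PrecursorRecord, normalize_rna, revcomp_rna

DEFAULT_MAX_PLACEMENTS = 20


@dataclass
class AlignedRead:
    """One collapsed sRNA read placement."""

    interval: GenomicInterval
    count: int
    sample: str
    sequence: Optional[str] = None  # transcribed-strand RNA, when known

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("read count must be >= 1")
        if self.sequence is not None:
            self.sequence = normalize_rna(self.sequence)
            if len(self.sequence) != len(self.interval):
                raise ValueError(
                    f"sequence length {len(self.sequence)} != interval length "
                    f"{len(self.interval)}"
                )


@dataclass
class ReadStack:
    """Per-precursor read evidence in precursor coordinates."""

    precursor_id: str
    precursor_length: int
    entries: List[Tuple[int, int, int, str]] = field(default_factory=list)
    # entries: (offset, length, count, sample), unique by (offset, length, sample)

    @property
    def total_count(self) -> int:
        return sum(e[2] for e in self.entries)

    def samples(self) -> set:
        return {e[3] for e in self.entries}


# ---------------------------------------------------------------------------
# Input
# ---------------------------------------------------------------------------

def _count_from_name(name: str) -> int:
    if "_x" in name:
        tail = name.rsplit("_x", 1)[1]
        if tail.isdigit():
            return int(tail)
    return 1


def read_sam(
    path: str,
    sample: Optional[str] = None,
    max_placements: int = DEFAULT_MAX_PLACEMENTS,
) -> List[AlignedRead]:
    """Parse mapped, unspliced alignments from a SAM file.

    The sample id defaults to the first read group ID in the header, else
    the file stem.  Placements beyond ``max_placements`` per read name are
    dropped.
    """
    reads: List[AlignedRead] = []
    placements: Dict[str, int] = {}
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        if sample is None:
            rgs = sam.header.get("RG", [])
            sample = rgs[0]["ID"] if rgs else path.rsplit("/", 1)[-1].split(".")[0]
        for aln in sam:
            if aln.is_unmapped or aln.cigartuples is None:
                continue
            if any(op not in (0, 7, 8) for op, _ in aln.cigartuples):
                continue  # unspliced, ungapped only
            placements[aln.query_name] = placements.get(aln.query_name, 0) + 1
            if placements[aln.query_name] > max_placements:
                continue
            strand = "-" if aln.is_reverse else "+"
            iv = GenomicInterval(
                aln.reference_name, aln.reference_start, aln.reference_end, strand
            )
            seq = aln.query_sequence
            if seq is not None and strand == "-":
                seq = revcomp_rna(seq)
            rg = aln.get_tag("RG") if aln.has_tag("RG") else sample
            reads.append(
                AlignedRead(
                    interval=iv,
                    count=_count_from_name(aln.query_name),
                    sample=rg,
                    sequence=seq,
                )
            )
    return reads


def read_alignment_tsv(path: str, genome: Optional[Dict[str, str]] = None) -> List[AlignedRead]:
    """Parse the 6-column dialect: sample, chrom, start, end, strand, count."""
    df = pd.read_csv(
        path,
        sep="\t",
        names=["sample", "chrom", "start", "end", "strand", "count"],
        dtype={"sample": str, "chrom": str},
        comment="#",
    )
    reads = []
    for row in df.itertuples(index=False):
        iv = GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand)
        seq = None
        if genome is not None and iv.chrom in genome:
            sub = genome[iv.chrom][iv.start : iv.end]
            seq = revcomp_rna(sub) if iv.strand == "-" else normalize_rna(sub)
        reads.append(AlignedRead(interval=iv, count=int(row.count), sample=row.sample, sequence=seq))
    return reads


def write_alignment_tsv(reads: Iterable[AlignedRead], path: str) -> None:
    with open(path, "w") as fh:
        for r in sorted(
            reads, key=lambda r: (r.sample, r.interval.chrom, r.interval.start,
                                  r.interval.end, r.interval.strand)
        ):
            iv = r.interval
            fh.write(f"{r.sample}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\t{r.count}\n")


def write_sam(reads: Iterable[AlignedRead], genome: Dict[str, str], path: str) -> None:
    """Write collapsed reads as plain-text SAM with counts in ``_xN`` names."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": len(genome[c])} for c in sorted(genome)],
        "RG": [],
    }
    ordered = sorted(
        reads, key=lambda r: (r.sample, r.interval.chrom, r.interval.start,
                              r.interval.end, r.interval.strand)
    )
    samples = sorted({r.sample for r in ordered})
    header["RG"] = [{"ID": s} for s in samples]
    tids = {c: i for i, c in enumerate(sorted(genome))}
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for i, r in enumerate(ordered):
            iv = r.interval
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"{r.sample}.r{i}_x{r.count}"
            a.flag = 16 if iv.strand == "-" else 0
            a.reference_id = tids[iv.chrom]
            a.reference_start = iv.start
            a.mapping_quality = 255
            a.cigarstring = f"{len(iv)}M"
            seq = r.sequence
            if seq is None:
                sub = genome[iv.chrom][iv.start : iv.end]
                seq = revcomp_rna(sub) if iv.strand == "-" else normalize_rna(sub)
            # SAM stores the forward-genome-strand sequence, DNA alphabet
            fwd = revcomp_rna(seq) if iv.strand == "-" else seq
            a.query_sequence = fwd.replace("U", "T")
            a.set_tag("RG", r.sample)
            out.write(a)


# ---------------------------------------------------------------------------
# Read stacks
# ---------------------------------------------------------------------------

def build_read_stack(reads: Sequence[AlignedRead], precursor: PrecursorRecord) -> ReadStack:
    """Collect reads fully contained in the precursor on its strand,
    re-expressed in precursor (transcribed-strand) coordinates."""
    if precursor.interval is None:
        raise ValueError(f"precursor {precursor.id} is unlocated; cannot build stack")
    iv = precursor.interval
    agg: Dict[Tuple[int, int, str], int] = {}
    for r in reads:
        riv = r.interval
        if riv.strand != iv.strand or not iv.contains(riv):
            continue
        if iv.strand == "+":
            offset = riv.start - iv.start
        else:
            offset = iv.end - riv.end
        key = (offset, len(riv), r.sample)
        agg[key] = agg.get(key, 0) + r.count
    entries = [(o, l, c, s) for (o, l, s), c in sorted(agg.items())]
    return ReadStack(precursor_id=precursor.id, precursor_length=len(precursor), entries=entries)


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def library_stats(reads: Sequence[AlignedRead]) -> Dict[str, int]:
    """Total mapped read count per sample (the TPM denominator)."""
    totals: Dict[str, int] = {}
    for r in reads:
        totals[r.sample] = totals.get(r.sample, 0) + r.count
    return totals


def compute_tpm(counts: pd.DataFrame, stats: Dict[str, int]) -> pd.DataFrame:
    """TPM(e, s) = count(e, s) / total(s) * 1e6.

    ``counts`` is entities x samples; every sample column must have a
    positive library total.
    """
    for s in counts.columns:
        if s not in stats:
            raise ValueError(f"sample {s!r} missing from library stats")
        if stats[s] <= 0:
            raise ValueError(f"sample {s!r} has zero mapped reads")
    totals = pd.Series({s: float(stats[s]) for s in counts.columns})
    return counts.astype(float).div(totals, axis=1) * 1e6


def expression_breadth(
    matrix: pd.DataFrame, tpm_min: float = 1.0, frac_min: float = 0.5
) -> pd.DataFrame:
    """Fraction of samples at or above ``tpm_min``; broad when strictly
    greater than ``frac_min`` (e.g. >=1 TPM in more than half of samples)."""
    if matrix.shape[1] == 0:
        raise ValueError("expression matrix has no samples")
    breadth = (matrix >= tpm_min).sum(axis=1) / matrix.shape[1]
    return pd.DataFrame({"breadth": breadth, "broad": breadth > frac_min})


def stack_counts(
    stacks: Sequence[ReadStack], samples: Sequence[str]
) -> pd.DataFrame:
    """Per-precursor x sample raw count table from read stacks."""
    data = {pid: {} for pid in (st.precursor_id for st in stacks)}
    for st in stacks:
        for _, _, c, s in st.entries:
            data[st.precursor_id][s] = data[st.precursor_id].get(s, 0) + c
    df = pd.DataFrame.from_dict(data, orient="index").reindex(columns=list(samples))
    return df.fillna(0).astype(int)


# ---------------------------------------------------------------------------
# De-novo locus discovery (read-cluster stage)
# ---------------------------------------------------------------------------

def discover_loci(
    reads: Sequence[AlignedRead],
    genome: Dict[str, str],
    max_gap: int = 200,
    flank: int = 100,
    max_locus_len: int = 300,
    source_tag: str = "predicted",
) -> List[PrecursorRecord]:
    """Cluster same-strand reads into candidate precursor loci.

    Reads within ``max_gap`` nt on the same chrom/strand form a cluster;
    clusters longer than ``max_locus_len`` are discarded, the rest are
    extended by ``flank`` nt each side (clipped to the contig) and excised
    as candidate precursors from the transcribed strand.  The most
    abundant read in each cluster is recorded as a provisional mature.
    """
    by_key: Dict[Tuple[str, str], List[AlignedRead]] = {}
    for r in reads:
        by_key.setdefault((r.interval.chrom, r.interval.strand), []).append(r)

    candidates: List[PrecursorRecord] = []
    n = 0
    for (chrom, strand) in sorted(by_key):
        group = sorted(by_key[(chrom, strand)], key=lambda r: (r.interval.start, r.interval.end))
        cluster: List[AlignedRead] = []
        cluster_end = -1

        def flush() -> None:
            nonlocal n
            if not cluster:
                return
            c_start = min(r.interval.start for r in cluster)
            c_end = max(r.interval.end for r in cluster)
            if c_end - c_start > max_locus_len:
                return
            start = max(0, c_start - flank)
            end = min(len(genome[chrom]), c_end + flank)
            iv = GenomicInterval(chrom, start, end, strand)
            n += 1
            rec = PrecursorRecord(
                id=f"locus_{chrom}_{start}_{end}_{strand.replace('-', 'm').replace('+', 'p')}",
                sequence=(
                    revcomp_rna(genome[chrom][start:end])
                    if strand == "-"
                    else normalize_rna(genome[chrom][start:end])
                ),
                sources={source_tag},
                interval=iv,
            )
            # provisional mature: most abundant read placement
            tally: Dict[Tuple[int, int], int] = {}
            for r in cluster:
                riv = r.interval
                off = riv.start - start if strand == "+" else end - riv.end
                tally[(off, len(riv))] = tally.get((off, len(riv)), 0) + r.count
            (off, ln), _ = max(tally.items(), key=lambda kv: (kv[1], -kv[0][0]))
            from .core import MatureRecord

            rec.add_mature(
                MatureRecord(
                    name=f"{rec.id}_m",
                    arm="unknown",
                    offset=off,
                    length=ln,
                    sequence=rec.sequence[off : off + ln],
                )
            )
            candidates.append(rec)

        for r in group:
            if cluster and r.interval.start - cluster_end > max_gap:
                flush()
                cluster = []
            cluster.append(r)
            cluster_end = max(cluster_end, r.interval.end)
        flush()
    return candidates
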