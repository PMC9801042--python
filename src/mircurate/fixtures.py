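"""Synthetic genomes, annotations, and multi-sample sRNA alignments with
known truth, so every pipeline stage is testable without external data.

True loci are planted perfect hairpins (stem + loop + reverse-complement
stem) with the mature on the 5' arm and the star at the canonical
2-nt-overhang partner position.  Decoys are dinucleotide-shuffled copies
of true hairpins placed on separate contigs: composition is preserved,
structure is destroyed, and (by default) they receive no reads.  All
randomness flows from the single config seed; equal configs give
byte-identical bundles.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import GenomicInterval, MatureRecord, PrecursorRecord, revcomp_rna
from .srna import AlignedRead, write_alignment_tsv, write_sam

BASES = "ACGU"


@dataclass
class FixtureConfig:
    seed: int = 42
    n_true: int = 50
    n_decoys: int = 50
    stem_len: int = 30
    loop_len: int = 8
    mature_len: int = 21
    depth: int = 50
    precision: float = 0.95
    isoform_rates: Dict[str, float] = field(
        default_factory=lambda: {"add5": 0.01, "sub5": 0.01, "add3": 0.01, "sub3": 0.01}
    )
    n_samples: int = 4
    arm_switch_fraction: float = 0.2
    arm_dominance: float = 0.8  # canonical-read share of the dominant arm
    flank_len: int = 150
    decoy_depth: int = 0  # uniform noise reads per decoy locus (0 = none)
    subgenome_labels: Optional[Sequence[str]] = None  # e.g. ("A", "B", "D")

    def __post_init__(self) -> None:
        if not (0 < self.precision <= 1):
            raise ValueError("precision must be in (0, 1]")
        if self.stem_len < self.mature_len:
            raise ValueError("stem_len must be >= mature_len")
        iso_sum = sum(self.isoform_rates.values())
        if any(not 0 <= p <= 1 for p in self.isoform_rates.values()) or iso_sum > 1:
            raise ValueError("isoform rates must be probabilities summing to <= 1")
        if self.precision + iso_sum > 1:
            raise ValueError("precision + isoform rates exceed 1")
        if not (0 <= self.arm_switch_fraction <= 1):
            raise ValueError("arm_switch_fraction must be in [0, 1]")

    @property
    def precursor_len(self) -> int:
        return 2 * self.stem_len + self.loop_len

    def samples(self) -> List[str]:
        return [f"s{i:02d}" for i in range(self.n_samples)]


@dataclass
class TruthLocus:
    locus_id: str
    interval: GenomicInterval
    precursor_seq: str
    mature_offset: int
    mature_len: int
    star_offset: int
    star_len: int
    is_decoy: bool
    precision: float
    arm_switch: bool = False
    dominant_arm: Dict[str, str] = field(default_factory=dict)  # sample -> 5p/3p


@dataclass
class FixtureBundle:
    config: FixtureConfig
    genome: Dict[str, str]
    truth: List[TruthLocus]
    reads: List[AlignedRead]

    def true_loci(self) -> List[TruthLocus]:
        return [t for t in self.truth if not t.is_decoy]

    def decoy_loci(self) -> List[TruthLocus]:
        return [t for t in self.truth if t.is_decoy]

    def records(self) -> List[PrecursorRecord]:
        """Truth loci as precursor records (annotated truth; decoys predicted)."""
        out = []
        for t in self.truth:
            rec = PrecursorRecord(
                id=t.locus_id,
                sequence=t.precursor_seq,
                sources={"predicted" if t.is_decoy else "annotated"},
                interval=t.interval,
            )
            rec.add_mature(
                MatureRecord(
                    name=f"{t.locus_id}-m",
                    arm="unknown",
                    offset=t.mature_offset,
                    length=t.mature_len,
                    sequence=t.precursor_seq[t.mature_offset : t.mature_offset + t.mature_len],
                )
            )
            out.append(rec)
        return out


def random_rna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(BASES), size=n))


def plant_hairpin(
    rng: np.random.Generator, cfg: FixtureConfig, max_tries: int = 50
) -> Tuple[str, int, int, int]:
    """One perfect hairpin: returns (sequence, mature_offset, star_offset,
    star_len).  The mature sits on the 5' arm; the star is its canonical
    partner leaving 2-nt 3' overhangs on both strands.

    Random stems occasionally admit an equal-energy alternative fold that
    breaks the planted duplex (internal self-complementarity), so draws
    are rejected until the folded structure reproduces the planted
    geometry exactly — the generator's contract is a *perfect* hairpin.
    """
    from .core import MatureRecord
    from .hairpin import extract_duplex, fold_hairpin

    last = None
    for _ in range(max_tries):
        stem = random_rna(rng, cfg.stem_len)
        loop = random_rna(rng, cfg.loop_len)
        seq = stem + loop + revcomp_rna(stem)
        n = len(seq)
        lo, hi = 2, cfg.stem_len - cfg.mature_len  # mature and star inside the stem
        m0 = int(rng.integers(lo, hi + 1))
        m1 = m0 + cfg.mature_len
        star_offset = n + 2 - m1
        star_len = cfg.mature_len
        last = (seq, m0, star_offset, star_len)
        try:
            st = fold_hairpin(seq)
            d = extract_duplex(
                st,
                MatureRecord("m", "unknown", m0, cfg.mature_len, seq[m0:m1]),
            )
        except ValueError:
            continue
        if (
            d.mismatches == 0
            and d.asym_bulge_nt == 0
            and (d.overhang_3p_5arm, d.overhang_3p_3arm) == (2, 2)
            and (d.star_offset, d.star_length) == (star_offset, star_len)
        ):
            return last
    return last


def dinucleotide_shuffle(seq: str, rng: np.random.Generator, max_tries: int = 10000) -> str:
    """Shuffle preserving dinucleotide counts (random Eulerian walk on the
    dinucleotide multigraph, retried until the walk covers every edge)."""
    if len(seq) <= 2:
        return seq
    for _ in range(max_tries):
        edges: Dict[str, List[str]] = {}
        for a, b in zip(seq, seq[1:]):
            edges.setdefault(a, []).append(b)
        for a in edges:
            rng.shuffle(edges[a])
        walk = [seq[0]]
        node = seq[0]
        n_edges = len(seq) - 1
        for _step in range(n_edges):
            nxt_list = edges.get(node)
            if not nxt_list:
                break
            node = nxt_list.pop()
            walk.append(node)
        if len(walk) == len(seq):
            return "".join(walk)
    # extremely unlikely fallback: plain shuffle
    chars = list(seq)
    rng.shuffle(chars)
    return "".join(chars)


def _contig_name(i: int, is_decoy: bool, cfg: FixtureConfig) -> str:
    if cfg.subgenome_labels:
        lab = cfg.subgenome_labels[i % len(cfg.subgenome_labels)]
        base = (i // len(cfg.subgenome_labels)) + 1
        return f"{base + (1000 if is_decoy else 0)}{lab}"
    return f"ctg_{'d' if is_decoy else 't'}{i:03d}"


def generate_bundle(cfg: FixtureConfig) -> FixtureBundle:
    """Genome + truth + reads under a single seed."""
    rng = np.random.default_rng(cfg.seed)
    truth: List[TruthLocus] = []
    genome: Dict[str, str] = {}
    samples = cfg.samples()
    n_switch = int(round(cfg.arm_switch_fraction * cfg.n_true))
    switch_idx = set(
        rng.choice(cfg.n_true, size=n_switch, replace=False).tolist()
    ) if n_switch else set()

    hairpins: List[str] = []
    for i in range(cfg.n_true):
        seq, m0, s0, sl = plant_hairpin(rng, cfg)
        hairpins.append(seq)
        strand = "+" if rng.random() < 0.5 else "-"
        left = random_rna(rng, cfg.flank_len)
        right = random_rna(rng, cfg.flank_len)
        placed = seq if strand == "+" else revcomp_rna(seq)
        contig = (left + placed + right).replace("U", "T")
        chrom = _contig_name(i, False, cfg)
        genome[chrom] = contig
        iv = GenomicInterval(chrom, cfg.flank_len, cfg.flank_len + len(seq), strand)
        dom = "5p" if rng.random() < 0.5 else "3p"
        flip = {"5p": "3p", "3p": "5p"}
        dominant = {
            s: (flip[dom] if (i in switch_idx and k >= len(samples) // 2) else dom)
            for k, s in enumerate(samples)
        }
        truth.append(
            TruthLocus(
                locus_id=f"true_{i:03d}",
                interval=iv,
                precursor_seq=seq,
                mature_offset=m0,
                mature_len=cfg.mature_len,
                star_offset=s0,
                star_len=sl,
                is_decoy=False,
                precision=cfg.precision,
                arm_switch=i in switch_idx,
                dominant_arm=dominant,
            )
        )

    for i in range(cfg.n_decoys):
        src = hairpins[i % len(hairpins)] if hairpins else random_rna(rng, cfg.precursor_len)
        seq = dinucleotide_shuffle(src, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        left = random_rna(rng, cfg.flank_len)
        right = random_rna(rng, cfg.flank_len)
        placed = seq if strand == "+" else revcomp_rna(seq)
        chrom = _contig_name(i, True, cfg)
        genome[chrom] = (left + placed + right).replace("U", "T")
        iv = GenomicInterval(chrom, cfg.flank_len, cfg.flank_len + len(seq), strand)
        m0 = 2  # nominal mature placement; decoys carry no real processing signal
        truth.append(
            TruthLocus(
                locus_id=f"decoy_{i:03d}",
                interval=iv,
                precursor_seq=seq,
                mature_offset=m0,
                mature_len=cfg.mature_len,
                star_offset=len(seq) + 2 - (m0 + cfg.mature_len),
                star_len=cfg.mature_len,
                is_decoy=True,
                precision=0.0,
            )
        )

    reads = simulate_reads(truth, cfg, rng)
    return FixtureBundle(config=cfg, genome=genome, truth=truth, reads=reads)


def _draw_read(
    rng: np.random.Generator,
    locus: TruthLocus,
    cfg: FixtureConfig,
    sample: str,
) -> Tuple[int, int]:
    """(offset, length) of one simulated read in precursor coordinates."""
    n = len(locus.precursor_seq)
    m0, mlen = locus.mature_offset, locus.mature_len
    m1 = m0 + mlen
    s0, slen = locus.star_offset, locus.star_len
    s1 = s0 + slen
    canonical = ((m0, m1), (s0, s1))

    iso_classes = list(cfg.isoform_rates)
    probs = [cfg.precision] + [cfg.isoform_rates[c] for c in iso_classes]
    probs.append(max(0.0, 1.0 - sum(probs)))
    choice = rng.choice(len(probs), p=np.array(probs) / sum(probs))

    dom = locus.dominant_arm.get(sample, "5p")
    mature_is_5p = (m0 + m1) / 2 < n / 2
    p_mature = cfg.arm_dominance if (dom == "5p") == mature_is_5p else 1 - cfg.arm_dominance

    if choice == 0:  # canonical read at mature or star
        a, b = canonical[0 if rng.random() < p_mature else 1]
        return a, b - a
    if choice <= len(iso_classes):  # isomiR off the mature
        cls = iso_classes[choice - 1]
        shift = int(rng.integers(1, 3))
        o, e = m0, m1
        if cls == "add5":
            o = max(0, m0 - shift)
        elif cls == "sub5":
            o = m0 + shift
        elif cls == "add3":
            e = min(n, m1 + shift)
        else:  # sub3
            e = m1 - shift
        return o, e - o
    # uniform background, rejected away from canonical ends (+/-2 nt)
    for _ in range(100):
        length = int(rng.integers(20, 25))
        if n - length <= 0:
            continue
        o = int(rng.integers(0, n - length + 1))
        e = o + length
        if all(abs(o - a) > 2 or abs(e - b) > 2 for a, b in canonical):
            return o, length
    return 0, min(20, n)


def simulate_reads(
    truth: Sequence[TruthLocus], cfg: FixtureConfig, rng: np.random.Generator
) -> List[AlignedRead]:
    """Multi-sample collapsed reads per locus, respecting planted precision,
    isoform rates, and per-sample arm dominance.  Decoys get ``decoy_depth``
    uniform reads (none by default)."""
    reads: List[AlignedRead] = []
    samples = cfg.samples()
    for locus in truth:
        depth = cfg.decoy_depth if locus.is_decoy else cfg.depth
        if depth <= 0:
            continue
        n = len(locus.precursor_seq)
        iv = locus.interval
        for sample in samples:
            # Poisson sequencing-depth noise around the configured mean
            n_reads = int(rng.poisson(depth))
            tally: Dict[Tuple[int, int], int] = {}
            for _ in range(n_reads):
                if locus.is_decoy:
                    length = int(rng.integers(20, 25))
                    o = int(rng.integers(0, n - length + 1))
                else:
                    o, length = _draw_read(rng, locus, cfg, sample)
                tally[(o, length)] = tally.get((o, length), 0) + 1
            for (o, length), count in sorted(tally.items()):
                if iv.strand == "+":
                    g0 = iv.start + o
                else:
                    g0 = iv.end - o - length
                reads.append(
                    AlignedRead(
                        interval=GenomicInterval(iv.chrom, g0, g0 + length, iv.strand),
                        count=count,
                        sample=sample,
                        sequence=locus.precursor_seq[o : o + length],
                    )
                )
    return reads


# ---------------------------------------------------------------------------
# On-disk bundle
# ---------------------------------------------------------------------------

def write_bundle(bundle: FixtureBundle, outdir: str, sam: bool = True) -> Dict[str, str]:
    """Write genome FASTA, truth annotation GFF3s, alignments, and the
    truth table.  GFF3 coordinates are 1-based inclusive on disk; reads
    come out both as SAM and as the 6-column TSV dialect."""
    from .annotation import write_gff3

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "genome": os.path.join(outdir, "genome.fa"),
        "annotated_gff3": os.path.join(outdir, "annotated.gff3"),
        "decoys_gff3": os.path.join(outdir, "decoys.gff3"),
        "reads_tsv": os.path.join(outdir, "reads.tsv"),
        "truth": os.path.join(outdir, "truth.tsv"),
    }
    with open(paths["genome"], "w") as fh:
        for chrom in sorted(bundle.genome):
            fh.write(f">{chrom}\n{bundle.genome[chrom]}\n")
    records = bundle.records()
    write_gff3([r for r in records if r.id.startswith("true_")], paths["annotated_gff3"])
    write_gff3([r for r in records if r.id.startswith("decoy_")], paths["decoys_gff3"])
    write_alignment_tsv(bundle.reads, paths["reads_tsv"])
    if sam:
        paths["reads_sam"] = os.path.join(outdir, "reads.sam")
        write_sam(bundle.reads, bundle.genome, paths["reads_sam"])
    with open(paths["truth"], "w") as fh:
        fh.write(
            "locus_id\tchrom\tstart\tend\tstrand\tis_decoy\tmature_offset\t"
            "mature_len\tstar_offset\tstar_len\tprecision\tarm_switch\tdominant_arms\n"
        )
        for t in bundle.truth:
            doms = ",".join(f"{s}:{a}" for s, a in sorted(t.dominant_arm.items()))
            iv = t.interval
            fh.write(
                f"{t.locus_id}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\t"
                f"{int(t.is_decoy)}\t{t.mature_offset}\t{t.mature_len}\t"
                f"{t.star_offset}\t{t.star_len}\t{t.precision}\t{int(t.arm_switch)}\t{doms}\n"
            )
    return paths
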