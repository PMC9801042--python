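"""Core domain types shared across the toolkit.

Coordinates are 0-based half-open internally; GFF3 I/O converts to and
from the 1-based inclusive convention on disk.  All stored RNA sequences
use U (input FASTA/SAM may use T); minus-strand sequences are stored as
the transcribed strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

_RNA_COMPLEMENT = str.maketrans("ACGUNacgun", "UGCANugcan")

VALID_STRANDS = ("+", "-")


def normalize_rna(seq: str) -> str:
    """Uppercase and convert T to U."""
    return seq.upper().replace("T", "U")


def revcomp_rna(seq: str) -> str:
    """Reverse complement of an RNA string (A<->U, G<->C)."""
    return normalize_rna(seq).translate(_RNA_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval with strand.

    ``start`` is 0-based inclusive, ``end`` exclusive.
    """

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        """True when *other* lies fully inside this interval on the same chrom."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def reciprocal_overlap(self, other: "GenomicInterval") -> float:
        """Smaller of the two mutual overlap fractions (0 when disjoint)."""
        ov = self.overlap_len(other)
        if ov == 0:
            return 0.0
        return min(ov / len(self), ov / len(other))


@dataclass
class MatureRecord:
    """A mature miRNA located on its precursor.

    ``offset`` is the 0-based start on the precursor (transcribed-strand
    coordinates); ``sequence`` must equal the precursor subsequence at
    ``[offset, offset + length)``.
    """

    name: str
    arm: str  # one of "5p", "3p", "unknown"
    offset: int
    length: int
    sequence: str

    def __post_init__(self) -> None:
        if self.arm not in ("5p", "3p", "unknown"):
            raise ValueError(f"invalid arm {self.arm!r}")
        if self.offset < 0 or self.length <= 0:
            raise ValueError("mature offset/length must be non-negative/positive")
        self.sequence = normalize_rna(self.sequence)

    @property
    def end(self) -> int:
        return self.offset + self.length

    def validate_against(self, precursor_seq: str) -> None:
        if self.end > len(precursor_seq):
            raise ValueError(
                f"mature {self.name} [{self.offset},{self.end}) exceeds "
                f"precursor length {len(precursor_seq)}"
            )
        sub = precursor_seq[self.offset : self.end]
        if normalize_rna(sub) != self.sequence:
            raise ValueError(
                f"mature {self.name} sequence does not match precursor "
                f"subsequence at [{self.offset},{self.end})"
            )


@dataclass
class PrecursorRecord:
    """A candidate hairpin locus with provenance and mature arms."""

    id: str
    sequence: str
    sources: set = field(default_factory=set)
    interval: Optional[GenomicInterval] = None
    matures: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = normalize_rna(self.sequence)
        if not self.sequence:
            raise ValueError(f"precursor {self.id}: empty sequence")
        if not self.sources:
            raise ValueError(f"precursor {self.id}: sources must be nonempty")
        for m in self.matures:
            m.validate_against(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)

    def infer_arm(self, mature: MatureRecord) -> str:
        """5p/3p by which half of the precursor the mature midpoint falls in."""
        mid = mature.offset + mature.length / 2
        return "5p" if mid < len(self.sequence) / 2 else "3p"

    def add_mature(self, mature: MatureRecord) -> None:
        mature.validate_against(self.sequence)
        if mature.arm == "unknown":
            mature.arm = self.infer_arm(mature)
        self.matures.append(mature)

    def primary_mature(self) -> Optional[MatureRecord]:
        """First mature by precursor position, or None when unannotated."""
        if not self.matures:
            return None
        return min(self.matures, key=lambda m: (m.offset, m.length, m.name))
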