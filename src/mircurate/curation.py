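"""Curation-ready analytics: isomiR classes, arm switching, genomic
context, and the deterministic summary/report export.

isomiR classes follow the template-variant nomenclature: add5/sub5 are
5' template addition/deletion relative to the annotated mature, add3/sub3
the 3' analogues.  Non-templated tailing is out of scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .annotation import write_fasta, write_gff3
from .core import GenomicInterval, MatureRecord, PrecursorRecord

ISOFORM_CLASSES = ("add5", "sub5", "add3", "sub3")

DEFAULT_CONTEXT_PRECEDENCE = ("TE", "lncRNA", "intron", "exon", "miRNA")


@dataclass
class IsoformCall:
    add5: int = 0
    sub5: int = 0
    add3: int = 0
    sub3: int = 0

    def __post_init__(self) -> None:
        if min(self.add5, self.sub5, self.add3, self.sub3) < 0:
            raise ValueError("isoform amounts must be >= 0")
        if self.add5 and self.sub5:
            raise ValueError("add5 and sub5 cannot both be nonzero")
        if self.add3 and self.sub3:
            raise ValueError("add3 and sub3 cannot both be nonzero")

    @property
    def canonical(self) -> bool:
        return self.add5 == self.sub5 == self.add3 == self.sub3 == 0

    def label(self) -> str:
        if self.canonical:
            return "canonical"
        parts = [f"{c}:{getattr(self, c)}" for c in ISOFORM_CLASSES if getattr(self, c)]
        return ",".join(parts)


def classify_isoform(offset: int, length: int, mature: MatureRecord) -> IsoformCall:
    """Classify one stack entry against its mature by end-coordinate shifts."""
    read_end = offset + length
    return IsoformCall(
        add5=max(0, mature.offset - offset),
        sub5=max(0, offset - mature.offset),
        add3=max(0, read_end - mature.end),
        sub3=max(0, mature.end - read_end),
    )


def isoform_tally(
    stack_entries: Sequence[Tuple[int, int, int, str]],
    mature: MatureRecord,
    precursor_length: Optional[int] = None,
    same_arm_window: Optional[int] = None,
) -> Dict[str, int]:
    """Read-count tally per isoform class for entries on the mature's arm.

    A read belongs to the mature's arm when its 5' end falls in the same
    precursor half (requires ``precursor_length``); alternatively an
    explicit ``same_arm_window`` around the mature 5' end can be given.
    Other-arm reads (e.g. star products) are skipped, not misclassified
    as extreme end variants.
    """
    if precursor_length is None and same_arm_window is None:
        raise ValueError("need precursor_length or same_arm_window")

    def same_arm(offset: int) -> bool:
        if precursor_length is not None:
            half = precursor_length / 2
            return (offset < half) == (mature.offset < half)
        return abs(offset - mature.offset) <= same_arm_window

    tally = {c: 0 for c in ("canonical",) + ISOFORM_CLASSES}
    for offset, length, count, _sample in stack_entries:
        if not same_arm(offset):
            continue
        call = classify_isoform(offset, length, mature)
        if call.canonical:
            tally["canonical"] += count
        else:
            for c in ISOFORM_CLASSES:
                if getattr(call, c):
                    tally[c] += count
    return tally


# ---------------------------------------------------------------------------
# Arm expression and arm switching
# ---------------------------------------------------------------------------

@dataclass
class ArmSwitchEvent:
    precursor_id: str
    samples_5p_dominant: List[str]
    samples_3p_dominant: List[str]
    max_ratio_5p: float
    max_ratio_3p: float


def detect_arm_switching(
    arm: pd.DataFrame, floor: float = 1.0, ratio_min: float = 2.0
) -> List[ArmSwitchEvent]:
    """Find precursors whose dominant arm flips between samples.

    ``arm`` is indexed by (precursor id, sample) with columns ``tpm_5p``
    and ``tpm_3p``.  An event requires some sample where 5p dominates by
    >= ``ratio_min`` and another where 3p does, with both arms >= ``floor``
    in each implicated sample.
    """
    events: List[ArmSwitchEvent] = []
    for pid, sub in arm.groupby(level=0, sort=True):
        sub = sub.droplevel(0)
        if len(sub) < 2:
            continue
        ok = (sub["tpm_5p"] >= floor) & (sub["tpm_3p"] >= floor)
        d5 = ok & (sub["tpm_5p"] >= ratio_min * sub["tpm_3p"])
        d3 = ok & (sub["tpm_3p"] >= ratio_min * sub["tpm_5p"])
        if d5.any() and d3.any():
            events.append(
                ArmSwitchEvent(
                    precursor_id=pid,
                    samples_5p_dominant=sorted(sub.index[d5]),
                    samples_3p_dominant=sorted(sub.index[d3]),
                    max_ratio_5p=float((sub.loc[d5, "tpm_5p"] / sub.loc[d5, "tpm_3p"]).max()),
                    max_ratio_3p=float((sub.loc[d3, "tpm_3p"] / sub.loc[d3, "tpm_5p"]).max()),
                )
            )
    return events


# ---------------------------------------------------------------------------
# Genomic context
# ---------------------------------------------------------------------------

@dataclass
class GenomicContext:
    label: str
    overlap_fraction: float


def genomic_context(
    interval: GenomicInterval,
    features: Sequence[Tuple[GenomicInterval, str]],
    precedence: Sequence[str] = DEFAULT_CONTEXT_PRECEDENCE,
    min_fraction: float = 0.5,
) -> GenomicContext:
    """Highest-precedence feature label covering >= ``min_fraction`` of the
    precursor; "intergenic" when none qualifies.  TE subclasses (labels
    starting with "TE") inherit the precedence of "TE"."""
    rank = {label: i for i, label in enumerate(precedence)}
    best: Optional[Tuple[int, float, str]] = None
    for fiv, label in features:
        frac = interval.overlap_len(fiv) / len(interval)
        if frac < min_fraction:
            continue
        base = "TE" if label.startswith("TE") else label
        if base not in rank:
            continue
        key = (rank[base], -frac, label)
        if best is None or key < (best[0], -best[1], best[2]):
            best = (rank[base], frac, label)
    if best is None:
        return GenomicContext(label="intergenic", overlap_fraction=0.0)
    return GenomicContext(label=best[2], overlap_fraction=best[1])


def context_features_from_gff3(
    path: str,
    type_map: Optional[Dict[str, str]] = None,
) -> List[Tuple[GenomicInterval, str]]:
    """Load (interval, label) context features from a genome GFF3.

    ``type_map`` maps GFF3 feature types to context labels; the default
    covers exon/intron/lncRNA and common TE types (TIR, Helitron, LINE,
    LTR become TE subclasses).
    """
    import gffutils

    type_map = type_map or {
        "exon": "exon",
        "intron": "intron",
        "lnc_RNA": "lncRNA",
        "lncRNA": "lncRNA",
        "transposable_element": "TE",
        "TIR_transposon": "TE:TIR",
        "helitron": "TE:Helitron",
        "LINE_element": "TE:LINE",
        "LTR_retrotransposon": "TE:LTR",
    }
    db = gffutils.create_db(
        path, dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    out: List[Tuple[GenomicInterval, str]] = []
    for feat in db.all_features(order_by=("seqid", "start")):
        if feat.featuretype in type_map:
            strand = feat.strand if feat.strand in ("+", "-") else "+"
            out.append(
                (GenomicInterval(feat.seqid, feat.start - 1, feat.end, strand),
                 type_map[feat.featuretype])
            )
    return out


# ---------------------------------------------------------------------------
# Summary and report export
# ---------------------------------------------------------------------------

def build_summary(
    records: Sequence[PrecursorRecord],
    selection: pd.DataFrame,
    structures: Dict[str, "SecondaryStructure"],
    stacks: Optional[Dict[str, "ReadStack"]] = None,
    expression: Optional[pd.DataFrame] = None,
    breadth: Optional[pd.DataFrame] = None,
    contexts: Optional[Dict[str, GenomicContext]] = None,
    arm_events: Optional[Sequence[ArmSwitchEvent]] = None,
    removed_ids: Iterable[str] = (),
) -> Tuple[pd.DataFrame, Dict[str, dict]]:
    """One curation row per retained candidate plus per-candidate reports.

    Inputs are keyed by a common id set; orphan ids in ``selection`` raise.
    ``removed_ids`` drops curated-away candidates; regeneration from the
    same inputs is deterministic.
    """
    from .hairpin import amfe

    rec_ids = {r.id for r in records}
    orphans = sorted(set(selection.index) - rec_ids)
    if orphans:
        raise ValueError(f"selection contains unknown candidate ids: {orphans[:5]}")
    removed = set(removed_ids)
    stacks = stacks or {}
    contexts = contexts or {}
    arm_counts: Dict[str, int] = {}
    for ev in arm_events or ():
        arm_counts[ev.precursor_id] = arm_counts.get(ev.precursor_id, 0) + 1

    rows = []
    reports: Dict[str, dict] = {}
    for rec in sorted(records, key=lambda r: r.id):
        if rec.id in removed or rec.id not in selection.index:
            continue
        st = structures[rec.id]
        sel = selection.loc[rec.id]
        pm = rec.primary_mature()
        stack = stacks.get(rec.id)
        tally = (
            isoform_tally(stack.entries, pm, precursor_length=len(rec))
            if stack is not None and pm is not None
            else {c: 0 for c in ("canonical",) + ISOFORM_CLASSES}
        )
        iv = rec.interval
        ctx = contexts.get(rec.id)
        row = {
            "id": rec.id,
            "chrom": iv.chrom if iv else ".",
            "start": iv.start if iv else -1,
            "end": iv.end if iv else -1,
            "strand": iv.strand if iv else ".",
            "sources": ",".join(sorted(rec.sources)),
            "precursor_len": len(rec),
            "mature_len": pm.length if pm else 0,
            "mfe": st.energy,
            "amfe": amfe(st.energy, len(rec)),
            "ht_pass": bool(sel["ht_pass"]),
            "svm_pass": bool(sel["svm_pass"]),
            "svm_score": float(sel["svm_score"]),
            "selected": bool(sel["selected"]),
            "breadth": float(breadth.loc[rec.id, "breadth"])
            if breadth is not None and rec.id in breadth.index
            else 0.0,
            "context": ctx.label if ctx else "NA",
            "arm_switch_events": arm_counts.get(rec.id, 0),
        }
        row.update({f"iso_{k}": v for k, v in tally.items()})
        rows.append(row)
        reports[rec.id] = {
            **row,
            "dotbracket": st.dotbracket,
            "sequence": rec.sequence,
            "matures": [
                {"name": m.name, "arm": m.arm, "offset": m.offset, "length": m.length}
                for m in sorted(rec.matures, key=lambda m: m.offset)
            ],
            "read_stack": [
                {"offset": o, "length": l, "count": c, "sample": s}
                for o, l, c, s in (stack.entries if stack else [])
            ],
        }
    summary = pd.DataFrame(rows).set_index("id") if rows else pd.DataFrame()
    return summary, reports


def render_stack_text(stack: "ReadStack", width: Optional[int] = None) -> str:
    """Plain-text read-stack layout (one aligned row per entry)."""
    width = width or stack.precursor_length
    lines = [f"# {stack.precursor_id} ({stack.precursor_length} nt)"]
    for offset, length, count, sample in stack.entries:
        bar = "." * offset + "=" * length
        bar = bar.ljust(width, ".")[:width]
        lines.append(f"{bar} x{count} [{sample}]")
    return "\n".join(lines) + "\n"


def export_curated(
    records: Sequence[PrecursorRecord],
    summary: pd.DataFrame,
    reports: Dict[str, dict],
    outdir: str,
    stacks: Optional[Dict[str, "ReadStack"]] = None,
) -> None:
    """Write the curated annotation: TSV summary, GFF3, FASTA (precursors
    and matures), and per-candidate markdown + JSON reports."""
    import os

    os.makedirs(outdir, exist_ok=True)
    os.makedirs(os.path.join(outdir, "reports"), exist_ok=True)
    kept = [r for r in records if r.id in summary.index]
    summary.sort_index().to_csv(os.path.join(outdir, "summary.tsv"), sep="\t")
    write_gff3(kept, os.path.join(outdir, "annotation.gff3"))
    write_fasta(kept, os.path.join(outdir, "precursors.fa"))
    write_fasta(kept, os.path.join(outdir, "matures.fa"), matures=True)
    stacks = stacks or {}
    for pid in sorted(reports):
        rep = reports[pid]
        with open(os.path.join(outdir, "reports", f"{pid}.json"), "w") as fh:
            json.dump(rep, fh, indent=1, sort_keys=True)
        md = [
            f"# {pid}",
            "",
            f"- location: {rep['chrom']}:{rep['start']}-{rep['end']}({rep['strand']})",
            f"- sources: {rep['sources']}",
            f"- MFE: {rep['mfe']:.2f}  AMFE: {rep['amfe']:.2f}",
            f"- selected: {rep['selected']} (criteria: {rep['ht_pass']}, svm: {rep['svm_pass']})",
            "",
            "```",
            rep["sequence"],
            rep["dotbracket"],
            "```",
        ]
        if pid in stacks:
            md += ["", "```", render_stack_text(stacks[pid]).rstrip(), "```"]
        with open(os.path.join(outdir, "reports", f"{pid}.md"), "w") as fh:
            fh.write("\n".join(md) + "\n")
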