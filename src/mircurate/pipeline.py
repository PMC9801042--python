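"""End-to-end orchestration: fold candidates, attach read evidence,
extract features, and run both selection routes.

This is the glue the CLI and the tests share; each step simply calls the
corresponding module function.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .core import PrecursorRecord
from .hairpin import (
    DEFAULT_FOLD_PARAMS,
    DEFAULT_REGISTRY,
    FeatureRegistry,
    FoldParams,
    SecondaryStructure,
    extract_duplex,
    extract_features,
)
from .selection import (
    CandidateBundle,
    CriteriaResult,
    CriteriaThresholds,
    apply_criteria,
    fit_one_class,
    score_candidates,
    select_final,
)
from .srna import (
    AlignedRead,
    ReadStack,
    build_read_stack,
    compute_tpm,
    expression_breadth,
    library_stats,
    stack_counts,
)


@dataclass
class EvaluatedCandidates:
    bundles: Dict[str, CandidateBundle]
    features: pd.DataFrame  # candidates x registry features
    criteria: Dict[str, CriteriaResult]
    tpm: Optional[pd.DataFrame] = None
    breadth: Optional[pd.DataFrame] = None

    @property
    def structures(self) -> Dict[str, SecondaryStructure]:
        return {pid: b.structure for pid, b in self.bundles.items()}

    @property
    def stacks(self) -> Dict[str, ReadStack]:
        return {pid: b.stack for pid, b in self.bundles.items() if b.stack is not None}


def evaluate_candidates(
    records: Sequence[PrecursorRecord],
    reads: Sequence[AlignedRead] = (),
    fold_params: FoldParams = DEFAULT_FOLD_PARAMS,
    thresholds: CriteriaThresholds = CriteriaThresholds(),
    registry: FeatureRegistry = DEFAULT_REGISTRY,
    tpm_min: float = 1.0,
    frac_min: float = 0.5,
) -> EvaluatedCandidates:
    """Fold every candidate, attach read stacks and expression, and
    evaluate the high-throughput criteria and feature vectors."""
    from .hairpin import fold_hairpin

    reads = list(reads)
    samples = sorted({r.sample for r in reads})
    totals = library_stats(reads)

    bundles: Dict[str, CandidateBundle] = {}
    stacks: List[ReadStack] = []
    for rec in records:
        structure = fold_hairpin(rec.sequence, fold_params)
        pm = rec.primary_mature()
        duplex = None
        if pm is not None:
            try:
                duplex = extract_duplex(structure, pm)
            except ValueError:
                duplex = None
        stack = None
        if rec.interval is not None and reads:
            stack = build_read_stack(reads, rec)
            stacks.append(stack)
        bundles[rec.id] = CandidateBundle(
            record=rec, structure=structure, duplex=duplex, stack=stack
        )

    tpm = breadth = None
    if stacks and samples:
        counts = stack_counts(stacks, samples)
        tpm = compute_tpm(counts, totals)
        breadth = expression_breadth(tpm, tpm_min=tpm_min, frac_min=frac_min)

    criteria: Dict[str, CriteriaResult] = {}
    feat_rows = {}
    for pid, bundle in bundles.items():
        expr = None
        if tpm is not None and pid in tpm.index:
            row = tpm.loc[pid]
            expr = {
                "tpm_max": float(row.max()),
                "tpm_mean": float(row.mean()),
                "breadth": float(breadth.loc[pid, "breadth"]),
            }
        bundle.expression = expr
        criteria[pid] = apply_criteria(bundle, thresholds)
        feat_rows[pid] = extract_features(
            bundle.record, bundle.structure, bundle.duplex, expr, registry
        )

    features = pd.DataFrame(feat_rows).T.reindex(columns=registry.names())
    features = features.loc[sorted(features.index)]
    return EvaluatedCandidates(
        bundles=bundles, features=features, criteria=criteria, tpm=tpm, breadth=breadth
    )


def run_selection(
    evaluated: EvaluatedCandidates,
    training_ids: Sequence[str],
    nu: float = 0.05,
    gamma: Optional[float] = None,
    mode: str = "union",
) -> pd.DataFrame:
    """Train the one-class SVM on the annotated positives and combine the
    two routes into the final selection table."""
    train = evaluated.features.loc[sorted(set(training_ids))]
    model = fit_one_class(train, nu=nu, gamma=gamma)
    svm = score_candidates(model, evaluated.features)
    return select_final(evaluated.criteria, svm, mode=mode)


def arm_expression_table(
    evaluated: EvaluatedCandidates, tol: int = 1
) -> pd.DataFrame:
    """Per-(precursor, sample) TPM of the 5p and 3p products.

    Reads are assigned to an arm by which half of the precursor their
    midpoint falls in; counts are scaled by the library totals recovered
    from the stacks."""
    rows = []
    totals: Dict[str, int] = {}
    for b in evaluated.bundles.values():
        if b.stack is None:
            continue
        for _o, _l, c, s in b.stack.entries:
            totals[s] = totals.get(s, 0) + c
    for pid, b in sorted(evaluated.bundles.items()):
        if b.stack is None or not b.stack.entries:
            continue
        n = len(b.record)
        per_sample: Dict[str, Dict[str, int]] = {}
        for o, l, c, s in b.stack.entries:
            arm = "tpm_5p" if o + l / 2 < n / 2 else "tpm_3p"
            per_sample.setdefault(s, {"tpm_5p": 0, "tpm_3p": 0})
            per_sample[s][arm] += c
        for s, vals in sorted(per_sample.items()):
            rows.append(
                {
                    "precursor_id": pid,
                    "sample": s,
                    "tpm_5p": vals["tpm_5p"] / totals[s] * 1e6,
                    "tpm_3p": vals["tpm_3p"] / totals[s] * 1e6,
                }
            )
    if not rows:
        return pd.DataFrame(columns=["tpm_5p", "tpm_3p"])
    return pd.DataFrame(rows).set_index(["precursor_id", "sample"])
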