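"""High-throughput criteria and one-class SVM candidate selection.

The criteria encode the consensus rules for calling plant miRNAs from
sRNA-Seq evidence (duplex geometry, processing precision, replication);
every threshold is configurable.  The novelty detector is a one-class
SVM (RBF kernel) trained on annotated positives only, with nu bounding
the training-outlier fraction; features are standardized with statistics
learned from the training set.  The final set is the union of the two
routes by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.svm import OneClassSVM

from .core import PrecursorRecord
from .hairpin import DuplexStats, SecondaryStructure, precision_of_processing
from .srna import ReadStack


@dataclass
class CriteriaThresholds:
    """Defaults encode consensus plant miRNA annotation criteria."""

    mature_len_min: int = 20
    mature_len_max: int = 24
    max_precursor_len: int = 300
    max_mismatches: int = 5
    max_asym_bulge: int = 3
    overhang: int = 2
    overhang_tol: int = 1
    min_precision: float = 0.75
    min_libraries: int = 2
    require_star_or_replication: bool = True
    precision_tol: int = 1

    def __post_init__(self) -> None:
        if not (0 < self.min_precision <= 1):
            raise ValueError("min_precision must be in (0, 1]")
        for name in ("mature_len_min", "mature_len_max", "max_precursor_len",
                     "overhang", "min_libraries"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class CriteriaResult:
    rules: Dict[str, bool]

    @property
    def passed(self) -> bool:
        return all(self.rules.values())

    def failed_rules(self) -> List[str]:
        return [k for k, v in self.rules.items() if not v]


@dataclass
class CandidateBundle:
    """Everything the criteria need to judge one precursor."""

    record: PrecursorRecord
    structure: SecondaryStructure
    duplex: Optional[DuplexStats] = None
    stack: Optional[ReadStack] = None
    expression: Optional[Dict[str, float]] = None  # tpm_max / tpm_mean / breadth


def apply_criteria(
    bundle: CandidateBundle, t: CriteriaThresholds = CriteriaThresholds()
) -> CriteriaResult:
    """Evaluate every rule independently; missing read evidence fails the
    evidence-dependent rules (closed-world) rather than erroring."""
    rec, duplex, stack = bundle.record, bundle.duplex, bundle.stack
    rules: Dict[str, bool] = {}

    pm = rec.primary_mature()
    rules["mature_len"] = (
        pm is not None and t.mature_len_min <= pm.length <= t.mature_len_max
    )
    rules["precursor_len"] = len(rec) <= t.max_precursor_len

    if duplex is not None:
        rules["duplex_mismatches"] = duplex.mismatches <= t.max_mismatches
        rules["asym_bulge"] = duplex.asym_bulge_nt <= t.max_asym_bulge
        ok5 = abs(duplex.overhang_3p_5arm - t.overhang) <= t.overhang_tol
        ok3 = abs(duplex.overhang_3p_3arm - t.overhang) <= t.overhang_tol
        rules["overhangs"] = ok5 and ok3
    else:
        rules["duplex_mismatches"] = False
        rules["asym_bulge"] = False
        rules["overhangs"] = False

    has_reads = stack is not None and bool(stack.entries)
    star = (duplex.star_offset, duplex.star_length) if duplex is not None else None
    if has_reads and pm is not None:
        prec = precision_of_processing(stack, rec.matures, star=star, tol=t.precision_tol)
        rules["precision"] = prec >= t.min_precision
    else:
        rules["precision"] = False

    n_libs = len(stack.samples()) if has_reads else 0
    rules["libraries"] = n_libs >= t.min_libraries

    if t.require_star_or_replication:
        star_seen = False
        replicated_samples: set = set()
        if has_reads:
            for offset, length, _count, sample in stack.entries:
                end = offset + length
                if star is not None and (
                    abs(offset - star[0]) <= t.precision_tol
                    and abs(end - (star[0] + star[1])) <= t.precision_tol
                ):
                    star_seen = True
                if pm is not None and (
                    abs(offset - pm.offset) <= t.precision_tol
                    and abs(end - pm.end) <= t.precision_tol
                ):
                    replicated_samples.add(sample)
        rules["star_or_replication"] = star_seen or len(replicated_samples) >= t.min_libraries

    return CriteriaResult(rules=rules)


# ---------------------------------------------------------------------------
# One-class SVM
# ---------------------------------------------------------------------------

@dataclass
class OneClassModel:
    svm: OneClassSVM
    feature_names: List[str]
    center: pd.Series
    scale: pd.Series
    dropped: List[str] = field(default_factory=list)
    nu: float = 0.05
    gamma: float = 0.0
    threshold: float = 0.0


def _standardize(df: pd.DataFrame, center: pd.Series, scale: pd.Series) -> np.ndarray:
    return ((df[center.index] - center) / scale).to_numpy(dtype=float)


def fit_one_class(
    train: pd.DataFrame,
    nu: float = 0.05,
    gamma: Optional[float] = None,
    threshold: float = 0.0,
) -> OneClassModel:
    """Fit the novelty detector on annotated-positive feature vectors.

    Features are standardized with center/scale learned from the training
    set only; zero-variance features are dropped with a warning and
    recorded in the model metadata.  The training inlier fraction is
    approximately 1 - nu.
    """
    if not (0 < nu < 1):
        raise ValueError("nu must be in (0, 1)")
    if len(train) < 10:
        raise ValueError("need at least 10 training vectors")
    center = train.mean(axis=0)
    scale = train.std(axis=0, ddof=0)
    dropped = list(scale.index[scale == 0])
    if dropped:
        warnings.warn(f"dropping zero-variance features: {dropped}", stacklevel=2)
    kept = scale.index[scale > 0]
    if gamma is None:
        gamma = 1.0 / len(kept)  # variance ~1 after standardization
    X = _standardize(train, center[kept], scale[kept])
    svm = OneClassSVM(nu=nu, kernel="rbf", gamma=gamma)
    svm.fit(X)
    return OneClassModel(
        svm=svm,
        feature_names=list(train.columns),
        center=center[kept],
        scale=scale[kept],
        dropped=dropped,
        nu=nu,
        gamma=gamma,
        threshold=threshold,
    )


def score_candidates(model: OneClassModel, vectors: pd.DataFrame) -> pd.DataFrame:
    """Score candidates with a fitted model.

    Returns a frame indexed like ``vectors`` with columns ``score`` and
    ``svm_pass`` (score >= model threshold).  The vectors must come from
    the same feature registry as the training set.
    """
    if list(vectors.columns) != model.feature_names:
        raise ValueError(
            "feature registry mismatch between model and candidate vectors"
        )
    X = _standardize(vectors, model.center, model.scale)
    scores = model.svm.decision_function(X)
    return pd.DataFrame(
        {"score": scores, "svm_pass": scores >= model.threshold}, index=vectors.index
    )


# ---------------------------------------------------------------------------
# Final selection
# ---------------------------------------------------------------------------

SELECTION_MODES = ("union", "intersection", "ht_only", "svm_only")


def select_final(
    ht: Dict[str, CriteriaResult],
    svm: pd.DataFrame,
    mode: str = "union",
) -> pd.DataFrame:
    """Combine the two selection routes.

    Returns a frame indexed by candidate id with columns ht_pass,
    svm_pass, svm_score, selected.  The id sets must be identical.
    """
    if mode not in SELECTION_MODES:
        raise ValueError(f"mode must be one of {SELECTION_MODES}")
    ht_ids, svm_ids = set(ht), set(svm.index)
    if ht_ids != svm_ids:
        raise ValueError(
            f"id mismatch: {sorted(ht_ids ^ svm_ids)[:5]} differ between routes"
        )
    ids = sorted(ht_ids)
    ht_pass = pd.Series({i: ht[i].passed for i in ids})
    svm_pass = svm.loc[ids, "svm_pass"].astype(bool)
    if mode == "union":
        selected = ht_pass | svm_pass
    elif mode == "intersection":
        selected = ht_pass & svm_pass
    elif mode == "ht_only":
        selected = ht_pass
    else:
        selected = svm_pass
    return pd.DataFrame(
        {
            "ht_pass": ht_pass,
            "svm_pass": svm_pass,
            "svm_score": svm.loc[ids, "score"],
            "selected": selected,
        }
    )
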