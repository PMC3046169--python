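"""Feature-set construction and the constrained subset search.

The baseline classifier uses the features whose absolute correlation
with observed ddG exceeds a floor (default 0.2). The Arg/Glu specialist
classifiers are chosen from an ensemble of small models: every subset of
3 or 4 baseline features that contains no pair of highly correlated
(redundant) features, optionally extended by one extra term (for Arg,
the intra-molecular Coulomb energy). Each candidate is trained on all
mutations — there are too few Arg or Glu examples to train on them
alone — with hyper-parameters chosen by pooled inner-CV F1 over all
mutations; the winner is the candidate with the best inner-CV F1
restricted to the target amino acid.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .energetics import FEATURE_NAMES
from .evaluation import ClassificationCounts, precision_recall_f1
from .models import TrainingConfig, train_linear_svm

DEFAULT_R_MIN = 0.2  # baseline inclusion floor on |corr(feature, ddG)|
DEFAULT_R_MAX = 0.8  # redundancy ceiling on |corr(feature, feature)|


@dataclass(frozen=True)
class SubsetCandidate:
    """One evaluated feature subset with its inner-CV result."""

    feature_ids: tuple[str, ...]
    inner_f1: float  # pooled inner-CV F1 on the target amino acid
    C: float
    class_weight: float


def baseline_feature_set(
    corr: pd.Series, r_min: float = DEFAULT_R_MIN
) -> tuple[str, ...]:
    """Features with |corr(feature, ddG)| > r_min, in canonical order."""
    chosen = tuple(f for f in FEATURE_NAMES if f in corr.index and abs(corr[f]) > r_min)
    if not chosen:
        raise ValueError(
            f"no feature exceeds |r| > {r_min}; lower r_min or check the data"
        )
    return chosen


def redundancy_pairs(
    corr_matrix: pd.DataFrame, r_max: float = DEFAULT_R_MAX
) -> set[frozenset]:
    """Unordered feature pairs too correlated to appear in one subset."""
    if list(corr_matrix.index) != list(corr_matrix.columns):
        raise ValueError("correlation matrix must be square with matching labels")
    vals = corr_matrix.to_numpy(dtype=float)
    if not np.allclose(vals, vals.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(vals), 1.0, atol=1e-8):
        raise ValueError("correlation matrix must have unit diagonal")
    feats = list(corr_matrix.index)
    return {
        frozenset((feats[i], feats[j]))
        for i, j in combinations(range(len(feats)), 2)
        if abs(vals[i, j]) > r_max
    }


def enumerate_candidate_subsets(
    base: tuple[str, ...],
    excluded: set[frozenset],
    sizes: tuple[int, ...] = (3, 4),
    extra_feature: str | None = None,
) -> list[tuple[str, ...]]:
    """All admissible subsets of the baseline features, canonically ordered.

    A subset is admissible when it contains no excluded (redundant) pair.
    With ``extra_feature`` given, every admissible subset is additionally
    emitted with the extra term appended (deduplicated). Ordering is by
    subset size, then position within the baseline feature order, so the
    selection tie-break (smaller, earlier subset wins) is deterministic.
    """
    if extra_feature is not None and extra_feature in base:
        raise ValueError(f"extra feature {extra_feature!r} already in the base set")

    def admissible(subset: tuple[str, ...]) -> bool:
        return all(
            frozenset(pair) not in excluded for pair in combinations(subset, 2)
        )

    plain = [
        subset
        for size in sorted(sizes)
        for subset in combinations(base, size)
        if admissible(subset)
    ]
    out = list(plain)
    if extra_feature is not None:
        seen = set(out)
        for subset in plain:
            ext = subset + (extra_feature,)
            if ext not in seen:
                out.append(ext)
                seen.add(ext)
    return out


def admissible_subsets(
    base: tuple[str, ...],
    excluded: set[frozenset],
    sizes: tuple[int, ...] = (3, 4),
    extra_feature: str | None = None,
) -> list[tuple[str, ...]]:
    """Candidate subsets with graceful degeneracy handling.

    Like :func:`enumerate_candidate_subsets`, but when the baseline set is
    too small for the requested sizes (or the redundancy constraints rule
    out every combination) the whole baseline set itself is the single
    candidate — a 2-feature baseline still yields a usable specialist.
    """
    usable_sizes = tuple(s for s in sizes if s <= len(base))
    cands = (
        enumerate_candidate_subsets(base, excluded, usable_sizes, extra_feature)
        if usable_sizes else []
    )
    return cands if cands else [tuple(base)]


def pooled_inner_predictions(
    scaled_train: pd.DataFrame,
    inner_folds,
    feature_ids: tuple[str, ...],
    C: float,
    class_weight: float,
    seed: int = 0,
    rows_log: set | None = None,
) -> pd.DataFrame:
    """Pool inner-test predictions over the inner folds.

    ``scaled_train`` must be the standardized outer-training table; every
    inner fold trains on its inner-training clusters and predicts its
    inner-test clusters, so each row is predicted exactly once. Row
    indices touched are added to ``rows_log`` (leakage instrumentation).
    """
    cid = scaled_train["cluster_id"].astype(str)
    pools = []
    for itrain, itest in inner_folds:
        tr = scaled_train[cid.isin(itrain)]
        te = scaled_train[cid.isin(itest)]
        if len(te) == 0:
            continue
        if rows_log is not None:
            rows_log.update(tr.index)
            rows_log.update(te.index)
        model = train_linear_svm(tr, feature_ids, C, class_weight, None, seed)
        s = model.decision_values(te, standardized=True)
        pools.append(pd.DataFrame({
            "label": te["label"].to_numpy(),
            "call": np.where(s > 0, 1, -1),
            "score": s,
            "wt_aa": te["wt_aa"].to_numpy(),
        }, index=te.index))
    if not pools:
        raise ValueError("inner folds produced no test rows")
    return pd.concat(pools)


def _f1(pool: pd.DataFrame) -> float:
    c = ClassificationCounts.from_labels(pool["label"], pool["call"])
    return precision_recall_f1(c)[2]


def select_best_subset(
    scaled_train: pd.DataFrame,
    candidates: list[tuple[str, ...]],
    target_aa: str,
    inner_folds,
    config: TrainingConfig | None = None,
    rows_log: set | None = None,
) -> SubsetCandidate:
    """Choose the subset whose inner-CV F1 on the target amino acid is best.

    Hyper-parameters are optimised per candidate on *all* mutations (the
    target amino acid enters only through the final comparison). Ties go
    to the smaller, canonically earlier subset, i.e. the first maximum in
    candidate order.
    """
    if config is None:
        config = TrainingConfig()
    if not candidates:
        raise ValueError("empty candidate list")
    if not (scaled_train["wt_aa"] == target_aa).any():
        raise ValueError(f"no rows with target amino acid {target_aa!r}")

    best: SubsetCandidate | None = None
    for subset in candidates:
        best_hp = None
        for C in config.C_grid:
            for cw in config.class_weight_grid:
                pool = pooled_inner_predictions(
                    scaled_train, inner_folds, subset, C, cw, config.seed, rows_log
                )
                overall = _f1(pool)
                if best_hp is None or overall > best_hp[0]:
                    best_hp = (overall, C, cw, pool)
        _, C, cw, pool = best_hp
        target_f1 = _f1(pool[pool["wt_aa"] == target_aa])
        if best is None or target_f1 > best.inner_f1:
            best = SubsetCandidate(subset, target_f1, C, cw)
    return best


def selection_report(winners: dict[str, SubsetCandidate]) -> pd.DataFrame:
    """Tabular summary of specialist selection (one row per target type)."""
    return pd.DataFrame(
        [
            {"target_aa": aa, "subset": "+".join(w.feature_ids),
             "inner_f1": w.inner_f1, "C": w.C, "class_weight": w.class_weight}
            for aa, w in winners.items()
        ],
        columns=["target_aa", "subset", "inner_f1", "C", "class_weight"],
    )
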