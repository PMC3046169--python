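"""Homology-cluster-aware nested cross-validation and performance metrics.

Complexes related by homology share a cluster label, and folds are cut
along cluster boundaries so that no homologue of a test complex is ever
seen in training. The outer loop estimates generalization; the inner
loop (run on outer-training clusters only) chooses hyper-parameters and,
in ensemble mode, the specialist feature subsets. Pooled outer-test
predictions yield precision, recall, F1 and the Matthews correlation
coefficient, overall and per amino-acid type.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import LinearModel, TrainingConfig, train_linear_svm
from .features import (
    feature_correlation_matrix,
    feature_ddg_correlation,
    standardize,
)

#: Amino-acid types frequent enough in alanine-scanning compilations to
#: warrant per-type reporting.
FREQUENT_AA = ("R", "N", "D", "E", "K", "W", "Y")

ClusterFold = tuple[frozenset, frozenset]  # (train clusters, test clusters)


@dataclass(frozen=True)
class FoldPlan:
    """Nested fold plan over homology clusters."""

    outer: tuple[ClusterFold, ...]
    inner: tuple[tuple[ClusterFold, ...], ...]  # per outer fold
    k_outer: int
    k_inner: int
    seed: int

    def __post_init__(self) -> None:
        all_test: set = set()
        for train, test in self.outer:
            if train & test:
                raise ValueError("cluster on both sides of an outer fold")
            if all_test & test:
                raise ValueError("cluster in more than one outer test fold")
            all_test |= test
        for fold_inner, (outer_train, outer_test) in zip(self.inner, self.outer):
            for itrain, itest in fold_inner:
                if itrain & itest:
                    raise ValueError("cluster on both sides of an inner fold")
                if (itrain | itest) & outer_test:
                    raise ValueError("outer-test cluster leaked into an inner fold")


def _deal(clusters: list, k: int) -> list[frozenset]:
    return [frozenset(clusters[j::k]) for j in range(k)]


def make_cluster_folds(
    cluster_ids,
    k_outer: int | None = None,
    k_inner: int = 3,
    seed: int = 0,
) -> FoldPlan:
    """Shuffle clusters by seed and deal them round-robin into nested folds.

    ``k_outer=None`` (or equal to the number of clusters) gives
    leave-one-cluster-out. Inner folds are dealt the same way within each
    outer training set, with ``k_inner`` capped at the cluster count.
    """
    unique = sorted({str(c) for c in cluster_ids})
    if len(unique) < 2:
        raise ValueError("need at least 2 homology clusters")
    if k_outer is None:
        k_outer = len(unique)
    if k_outer > len(unique):
        raise ValueError(f"k_outer={k_outer} exceeds {len(unique)} clusters")
    if k_outer < 2 or k_inner < 2:
        raise ValueError("fold counts must be >= 2")

    rng = np.random.default_rng(seed)
    shuffled = [unique[i] for i in rng.permutation(len(unique))]
    outer = []
    for test in _deal(shuffled, k_outer):
        outer.append((frozenset(shuffled) - test, test))

    inner = []
    for j, (train, _test) in enumerate(outer):
        sub_rng = np.random.default_rng([seed, j])
        train_list = sorted(train)
        train_shuffled = [train_list[i] for i in sub_rng.permutation(len(train_list))]
        k_in = min(k_inner, len(train_shuffled))
        if k_in < 2:
            raise ValueError("outer training set has fewer than 2 clusters")
        fold_inner = tuple(
            (frozenset(train_shuffled) - itest, itest)
            for itest in _deal(train_shuffled, k_in)
        )
        inner.append(fold_inner)
    return FoldPlan(tuple(outer), tuple(inner), k_outer, k_inner, seed)


# ---------------------------------------------------------------------------
# Metrics.

@dataclass(frozen=True)
class ClassificationCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @classmethod
    def from_labels(cls, y_true, y_pred) -> "ClassificationCounts":
        t = np.asarray(y_true, dtype=int)
        p = np.asarray(y_pred, dtype=int)
        return cls(
            tp=int(((t == 1) & (p == 1)).sum()),
            fp=int(((t == -1) & (p == 1)).sum()),
            fn=int(((t == 1) & (p == -1)).sum()),
            tn=int(((t == -1) & (p == -1)).sum()),
        )


def precision_recall_f1(c: ClassificationCounts) -> tuple[float, float, float]:
    """Precision, recall and their harmonic mean (zero-denominator -> 0)."""
    p = c.tp / (c.tp + c.fp) if c.tp + c.fp else 0.0
    r = c.tp / (c.tp + c.fn) if c.tp + c.fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


def mcc(c: ClassificationCounts) -> float:
    """Matthews correlation coefficient; 0 when any marginal is empty."""
    denom2 = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    if denom2 == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom2)


def score_ddg_correlation(scores, ddg) -> float:
    """Pearson correlation between decision scores and observed ddG."""
    s = np.asarray(scores, dtype=float)
    d = np.asarray(ddg, dtype=float)
    if s.size < 3:
        raise ValueError("need at least 3 rows for a correlation estimate")
    if s.std() == 0 or d.std() == 0:
        return 0.0
    return float(np.corrcoef(s, d)[0, 1])


@dataclass(frozen=True)
class Metrics:
    counts: ClassificationCounts
    precision: float
    recall: float
    f1: float
    mcc: float
    per_aa: dict = field(default_factory=dict)  # aa -> dict of sub-metrics
    score_ddg_corr: float | None = None

    @classmethod
    def from_predictions(cls, pred: pd.DataFrame) -> "Metrics":
        """Summarise a pooled prediction table (label, call, score, ddg, wt_aa)."""
        counts = ClassificationCounts.from_labels(pred["label"], pred["call"])
        p, r, f1 = precision_recall_f1(counts)
        per_aa = {}
        for aa, grp in pred.groupby("wt_aa"):
            ca = ClassificationCounts.from_labels(grp["label"], grp["call"])
            pa, ra, fa = precision_recall_f1(ca)
            per_aa[aa] = {
                "n": ca.total, "precision": pa, "recall": ra,
                "f1": fa, "mcc": mcc(ca),
            }
        corr = None
        if "ddg" in pred.columns and len(pred) >= 3 and pred["ddg"].notna().all():
            corr = score_ddg_correlation(pred["score"], pred["ddg"])
        return cls(counts, p, r, f1, mcc(counts), per_aa, corr)


# ---------------------------------------------------------------------------
# Nested cross-validation.

@dataclass
class NestedCVResult:
    metrics: Metrics
    predictions: pd.DataFrame  # pooled outer-test predictions
    rows_used_by_fold: list[set]  # training-row indices touched per outer fold
    fold_details: list[dict]  # chosen features/hyper-parameters per fold


def _grid_search(scaled_train, inner_folds, feature_ids, config, rows_log):
    """Best (C, class_weight) by pooled inner-test F1 over all mutations."""
    from .selection import pooled_inner_predictions

    best = None
    for C in config.C_grid:
        for cw in config.class_weight_grid:
            pool = pooled_inner_predictions(
                scaled_train, inner_folds, feature_ids, C, cw, config.seed, rows_log
            )
            c = ClassificationCounts.from_labels(pool["label"], pool["call"])
            f1 = precision_recall_f1(c)[2]
            if best is None or f1 > best[0]:
                best = (f1, C, cw)
    return best[1], best[2], best[0]


def detect_specialist_aas(
    scaled_train, inner_folds, feature_ids, C, class_weight, seed,
    floor: float = 0.35, candidates=FREQUENT_AA,
) -> tuple[str, ...]:
    """Amino acids on which the general model underperforms in training.

    Uses pooled inner-CV predictions (training data only, so the choice
    respects the cross-validation boundary) and flags frequent amino acids
    whose per-type F1 falls below ``floor``.
    """
    from .selection import pooled_inner_predictions

    pool = pooled_inner_predictions(
        scaled_train, inner_folds, feature_ids, C, class_weight, seed, None
    )
    weak = []
    for aa in candidates:
        grp = pool[pool["wt_aa"] == aa]
        if len(grp) == 0:
            continue
        c = ClassificationCounts.from_labels(grp["label"], grp["call"])
        if precision_recall_f1(c)[2] < floor:
            weak.append(aa)
    return tuple(weak)


def training_inner_folds(cluster_ids, k_inner: int = 3, seed: int = 0):
    """Cluster folds over the whole data set, for full-data model fitting."""
    unique = sorted({str(c) for c in cluster_ids})
    if len(unique) < 2:
        raise ValueError("need at least 2 homology clusters")
    rng = np.random.default_rng(seed)
    shuffled = [unique[i] for i in rng.permutation(len(unique))]
    k = min(k_inner, len(shuffled))
    if k < 2:
        raise ValueError("need at least 2 inner folds")
    return tuple(
        (frozenset(shuffled) - test, test) for test in _deal(shuffled, k)
    )


def fit_full_ensemble(
    table: pd.DataFrame,
    config: TrainingConfig | None = None,
    specialist_aas: tuple[str, ...] = ("R", "E"),
    r_min: float = 0.2,
    r_max: float = 0.8,
    subset_sizes: tuple[int, ...] = (3, 4),
    arg_extra_feature: str | None = "coulomb_sc_intra",
    k_inner: int = 3,
):
    """Fit the deployable ensemble on the full data set.

    Selection and hyper-parameter tuning use inner cluster folds only
    (there is no outer test here — this is the model that ships). Returns
    the ensemble and a detail dict mirroring one nested-CV fold record.
    """
    from . import selection as sel
    from .models import HotspotEnsemble

    if config is None:
        config = TrainingConfig()
    scaled, stats = standardize(table)
    inner_folds = training_inner_folds(table["cluster_id"], k_inner, config.seed)
    corr = feature_ddg_correlation(table)
    base = sel.baseline_feature_set(corr, r_min)
    C, cw, inner_f1 = _grid_search(scaled, inner_folds, base, config, None)
    general = train_linear_svm(scaled, base, C, cw, stats, config.seed)
    detail = {"baseline_features": base, "C": C, "class_weight": cw,
              "inner_f1": inner_f1}

    members = {"R": general, "E": general}
    corr_mat = feature_correlation_matrix(table).loc[list(base), list(base)]
    excluded = sel.redundancy_pairs(corr_mat, r_max)
    for aa in specialist_aas:
        extra = arg_extra_feature if aa == "R" else None
        if extra is not None and extra in base:
            extra = None
        cands = sel.admissible_subsets(base, excluded, subset_sizes, extra)
        winner = sel.select_best_subset(scaled, cands, aa, inner_folds, config, None)
        members[aa] = train_linear_svm(
            scaled, winner.feature_ids, winner.C, winner.class_weight,
            stats, config.seed,
        )
        detail[f"subset_{aa}"] = winner.feature_ids
        detail[f"inner_f1_{aa}"] = winner.inner_f1
        detail[f"hyper_{aa}"] = (winner.C, winner.class_weight)
    ensemble = HotspotEnsemble(general=general, arg=members["R"], glu=members["E"])
    return ensemble, detail


def nested_cv(
    table: pd.DataFrame,
    plan: FoldPlan,
    config: TrainingConfig | None = None,
    mode: str = "general",
    specialist_aas: tuple[str, ...] = ("R", "E"),
    r_min: float = 0.2,
    r_max: float = 0.8,
    subset_sizes: tuple[int, ...] = (3, 4),
    arg_extra_feature: str | None = "coulomb_sc_intra",
) -> NestedCVResult:
    """Run the nested cross-validation protocol.

    ``mode="general"`` evaluates the single baseline classifier;
    ``mode="ensemble"`` additionally selects and applies the Arg/Glu
    specialist classifiers (chosen per outer fold using inner folds only).
    With ``specialist_aas=()`` ensemble mode degrades exactly to general
    mode. Each outer fold standardizes on its training rows, chooses the
    baseline feature set from training correlations, grid-searches
    hyper-parameters by pooled inner-test F1, trains on the full outer
    training set and scores the untouched outer test set.
    """
    from . import selection as sel

    if config is None:
        config = TrainingConfig()
    if mode not in ("general", "ensemble"):
        raise ValueError(f"unknown mode {mode!r}")
    clusters = set(table["cluster_id"].astype(str))
    plan_clusters = set().union(*(tr | te for tr, te in plan.outer))
    if clusters != plan_clusters:
        raise ValueError(
            f"cluster mismatch between table ({sorted(clusters)}) "
            f"and plan ({sorted(plan_clusters)})"
        )

    all_pred = []
    rows_used_by_fold: list[set] = []
    fold_details: list[dict] = []
    for j, (train_clusters, test_clusters) in enumerate(plan.outer):
        cid = table["cluster_id"].astype(str)
        train_df = table[cid.isin(train_clusters)]
        test_df = table[cid.isin(test_clusters)]
        if len(test_df) == 0:
            continue
        rows_log: set = set()
        scaled_train, stats = standardize(train_df)
        scaled_test = stats.apply(test_df)
        inner_folds = plan.inner[j]

        corr = feature_ddg_correlation(train_df)
        base = sel.baseline_feature_set(corr, r_min)
        C, cw, inner_f1 = _grid_search(scaled_train, inner_folds, base, config, rows_log)
        general = train_linear_svm(scaled_train, base, C, cw, stats, config.seed)
        rows_log.update(scaled_train.index)

        detail = {"fold": j, "baseline_features": base, "C": C,
                  "class_weight": cw, "inner_f1": inner_f1}
        specialists: dict[str, LinearModel] = {}
        if mode == "ensemble":
            corr_mat = feature_correlation_matrix(train_df).loc[list(base), list(base)]
            excluded = sel.redundancy_pairs(corr_mat, r_max)
            for aa in specialist_aas:
                extra = arg_extra_feature if aa == "R" else None
                if extra is not None and extra in base:
                    extra = None
                cands = sel.admissible_subsets(base, excluded, subset_sizes, extra)
                winner = sel.select_best_subset(
                    scaled_train, cands, aa, inner_folds, config, rows_log
                )
                specialists[aa] = train_linear_svm(
                    scaled_train, winner.feature_ids, winner.C,
                    winner.class_weight, stats, config.seed,
                )
                detail[f"subset_{aa}"] = winner.feature_ids
                detail[f"inner_f1_{aa}"] = winner.inner_f1

        # Score the untouched outer test fold.
        leaked = rows_log & set(test_df.index)
        if leaked:
            raise AssertionError(f"outer-test rows used in training: {sorted(leaked)}")
        scores = general.decision_values(scaled_test, standardized=True)
        codes = test_df["wt_aa"].to_numpy()
        for aa, model in specialists.items():
            mask = codes == aa
            if mask.any():
                scores[mask] = model.decision_values(
                    scaled_test.loc[mask], standardized=True
                )
        fold_pred = test_df[["complex_id", "chain", "resnum", "wt_aa",
                             "ddg", "cluster_id", "label"]].copy()
        fold_pred["score"] = scores
        fold_pred["call"] = np.where(scores > 0, 1, -1)
        fold_pred["outer_fold"] = j
        all_pred.append(fold_pred)
        rows_used_by_fold.append(rows_log)
        fold_details.append(detail)

    predictions = pd.concat(all_pred)
    if predictions[["complex_id", "chain", "resnum"]].duplicated().any():
        raise AssertionError("outer test folds overlap")
    return NestedCVResult(
        metrics=Metrics.from_predictions(predictions),
        predictions=predictions,
        rows_used_by_fold=rows_used_by_fold,
        fold_details=fold_details,
    )
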