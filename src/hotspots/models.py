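"""Linear SVM scoring functions and the hot-spot classifier ensemble.

A fitted model is exported as an explicit weight vector plus decision
threshold over named energy features, so scoring never requires the
training backend: ``s(x) = sum_k w_k x_k - b`` on standardized features,
and a residue is called a hot spot iff ``s > 0`` (strictly).

The ensemble holds three linear models: a general one, and two
specialists applied to arginine and glutamic-acid residues — the amino
acid types on which a single general classifier performs worst, because
their energetics are dominated by a different subset of terms
(long-range charged interactions and hydrogen bonds rather than packing).

Two scikit-learn-style estimators wrap this machinery
(:class:`LinearHotspotSVM`, :class:`HotspotEnsembleClassifier`); the
module-level functions are thin wrappers kept for scripting.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import LinearSVC

from ._topology import MUTABLE_AA, NON_MUTABLE
from .energetics import DEFAULT_SHELL_RADIUS, EnergyConfig, FEATURE_NAMES, energy_vector
from .features import FeatureStats, _is_degenerate_sd, standardize
from .structure import TypedComplex, find_interface_residues

DEFAULT_C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)
DEFAULT_CLASS_WEIGHT_GRID = (1.0, 2.0, 5.0)


@dataclass(frozen=True)
class TrainingConfig:
    """Hyper-parameter grids for the soft-margin linear SVM.

    ``class_weight`` is the cost multiplier on the positive (hot spot)
    class, countering its minority status in alanine-scanning data.
    """

    C_grid: tuple[float, ...] = DEFAULT_C_GRID
    class_weight_grid: tuple[float, ...] = DEFAULT_CLASS_WEIGHT_GRID
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.C_grid or not self.class_weight_grid:
            raise ValueError("hyper-parameter grids must be non-empty")


@dataclass(frozen=True)
class LinearModel:
    """Explicit linear scoring function over named features."""

    feature_ids: tuple[str, ...]
    weights: np.ndarray
    threshold: float
    stats: FeatureStats | None = None  # standardization used at training
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.feature_ids) != len(self.weights):
            raise ValueError("one weight per feature id required")

    def score(self, x: Mapping[str, float] | pd.Series) -> float:
        """s = w . x_standardized - threshold for a single feature vector."""
        try:
            raw = np.array([float(x[f]) for f in self.feature_ids])
        except KeyError as exc:
            raise KeyError(f"feature vector missing component {exc}") from exc
        if self.stats is not None:
            mean = self.stats.mean[list(self.feature_ids)]
            sd = self.stats.sd[list(self.feature_ids)]
            sd = sd.mask(_is_degenerate_sd(sd, mean), 1.0)
            raw = (raw - mean.to_numpy()) / sd.to_numpy()
        return float(self.weights @ raw - self.threshold)

    def decision_values(self, table: pd.DataFrame, standardized: bool = False) -> np.ndarray:
        x = table[list(self.feature_ids)].to_numpy(dtype=float)
        if not standardized and self.stats is not None:
            mean = self.stats.mean[list(self.feature_ids)]
            sd = self.stats.sd[list(self.feature_ids)]
            sd = sd.mask(_is_degenerate_sd(sd, mean), 1.0)
            x = (x - mean.to_numpy()) / sd.to_numpy()
        return x @ self.weights - self.threshold

    # -- human-readable serialization (feature, weight, mean, sd rows) ------

    def to_text(self) -> str:
        buf = io.StringIO()
        for k, v in sorted(self.meta.items()):
            buf.write(f"# {k}={v}\n")
        buf.write("feature\tweight\tmean\tsd\n")
        mean = self.stats.mean if self.stats is not None else None
        sd = self.stats.sd if self.stats is not None else None
        for f, w in zip(self.feature_ids, self.weights):
            m = 0.0 if mean is None else float(mean[f])
            s = 1.0 if sd is None else float(sd[f])
            buf.write(f"{f}\t{float(w)!r}\t{m!r}\t{s!r}\n")
        buf.write(f"__threshold__\t{float(self.threshold)!r}\t0.0\t1.0\n")
        return buf.getvalue()

    @classmethod
    def from_text(cls, text: str) -> "LinearModel":
        meta: dict = {}
        feats, weights, means, sds = [], [], [], []
        threshold = 0.0
        for line in text.splitlines():
            if not line.strip():
                continue
            if line.startswith("#"):
                k, _, v = line[1:].strip().partition("=")
                meta[k.strip()] = v.strip()
                continue
            parts = line.split("\t")
            if parts[0] == "feature":
                continue
            if parts[0] == "__threshold__":
                threshold = float(parts[1])
                continue
            feats.append(parts[0])
            weights.append(float(parts[1]))
            means.append(float(parts[2]))
            sds.append(float(parts[3]))
        stats = FeatureStats(
            mean=pd.Series(means, index=feats), sd=pd.Series(sds, index=feats)
        )
        return cls(tuple(feats), np.array(weights), threshold, stats, meta)


def classify(s: float) -> int:
    """Hot-spot call from a decision score: +1 iff s > 0 (strictly)."""
    return 1 if s > 0 else -1


def train_linear_svm(
    table: pd.DataFrame,
    feature_ids: Iterable[str],
    C: float = 1.0,
    class_weight: float = 1.0,
    stats: FeatureStats | None = None,
    seed: int = 0,
) -> LinearModel:
    """Fit a soft-margin linear SVM (hinge loss, asymmetric class cost).

    ``table`` must already be standardized; ``stats`` (the standardization
    used) is stored on the model so raw feature vectors can be scored later.
    """
    feature_ids = tuple(feature_ids)
    x = table[list(feature_ids)].to_numpy(dtype=float)
    y = table["label"].to_numpy(dtype=int)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite feature values")
    if len(np.unique(y)) < 2:
        raise ValueError("training table contains a single class")
    svc = LinearSVC(
        C=C,
        loss="hinge",
        class_weight={1: class_weight, -1: 1.0},
        tol=1e-5,
        max_iter=50000,
        random_state=seed,
    )
    import warnings
    from sklearn.exceptions import ConvergenceWarning

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        svc.fit(x, y)
    return LinearModel(
        feature_ids=feature_ids,
        weights=svc.coef_.ravel().copy(),
        threshold=float(-svc.intercept_[0]),
        stats=stats,
        meta={"C": C, "class_weight": class_weight},
    )


def score(model: LinearModel, x: Mapping[str, float] | pd.Series) -> float:
    return model.score(x)


@dataclass(frozen=True)
class HotspotEnsemble:
    """General + Arg + Glu linear models with wild-type routing."""

    general: LinearModel
    arg: LinearModel
    glu: LinearModel

    def route(self, wild_type: str) -> LinearModel:
        if wild_type in NON_MUTABLE:
            raise ValueError(f"{wild_type} is not an alanine-scannable residue type")
        if wild_type not in MUTABLE_AA:
            raise ValueError(f"unknown amino-acid code {wild_type!r}")
        if wild_type == "R":
            return self.arg
        if wild_type == "E":
            return self.glu
        return self.general

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, model in (("general", self.general), ("arg", self.arg), ("glu", self.glu)):
            (directory / f"model_{name}.tsv").write_text(model.to_text())

    @classmethod
    def load(cls, directory: str | Path) -> "HotspotEnsemble":
        directory = Path(directory)
        models = {}
        for name in ("general", "arg", "glu"):
            path = directory / f"model_{name}.tsv"
            if not path.exists():
                raise FileNotFoundError(f"missing weight table {path}")
            models[name] = LinearModel.from_text(path.read_text())
        return cls(models["general"], models["arg"], models["glu"])


def route(ensemble: HotspotEnsemble, wild_type: str) -> LinearModel:
    return ensemble.route(wild_type)


def predict_complex(
    ensemble: HotspotEnsemble,
    complex: TypedComplex,
    shell_radius: float = DEFAULT_SHELL_RADIUS,
    contact_cutoff: float = 5.0,
    energy_config: EnergyConfig | None = None,
) -> pd.DataFrame:
    """Score every candidate interface residue of a complex.

    Returns one row per interface residue (chain, resnum, wt_aa, score,
    hotspot_call), sorted by chain then residue number.
    """
    rows = []
    for site in find_interface_residues(complex, contact_cutoff):
        ev = energy_vector(complex, site, shell_radius, energy_config)
        model = ensemble.route(site.wild_type)
        s = model.score(ev)
        rows.append(
            {"chain": site.chain_id, "resnum": site.residue_number,
             "wt_aa": site.wild_type, "score": s, "hotspot_call": classify(s)}
        )
    return pd.DataFrame(rows, columns=["chain", "resnum", "wt_aa", "score", "hotspot_call"])


# ---------------------------------------------------------------------------
# scikit-learn-style estimators.

class LinearHotspotSVM(BaseEstimator, ClassifierMixin):
    """Linear hot-spot classifier over named energy features.

    Standardizes the selected feature columns, fits a soft-margin linear
    SVM with an asymmetric cost on the positive class, and exposes the
    scoring function as explicit ``weights_`` and ``threshold_``.

    Parameters
    ----------
    feature_ids : sequence of str, optional
        Feature columns to use; defaults to all 12 energy features.
    C : float
        Soft-margin penalty.
    class_weight : float
        Cost multiplier for the +1 (hot spot) class.
    seed : int
        Backend RNG seed (liblinear dual coordinate descent).
    """

    def __init__(self, feature_ids=None, C=1.0, class_weight=1.0, seed=0):
        self.feature_ids = feature_ids
        self.C = C
        self.class_weight = class_weight
        self.seed = seed

    def _frame(self, X) -> pd.DataFrame:
        feats = tuple(self.feature_ids) if self.feature_ids is not None else FEATURE_NAMES
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(feats):
            raise ValueError(f"expected {len(feats)} feature columns, got {X.shape[1]}")
        return pd.DataFrame(X, columns=list(feats))

    def fit(self, X, y):
        feats = tuple(self.feature_ids) if self.feature_ids is not None else FEATURE_NAMES
        df = self._frame(X).copy()
        df["label"] = np.asarray(y, dtype=int)
        scaled, stats = standardize(df, "fit", feats)
        self.model_ = train_linear_svm(
            scaled, feats, C=self.C, class_weight=self.class_weight,
            stats=stats, seed=self.seed,
        )
        self.weights_ = self.model_.weights
        self.threshold_ = self.model_.threshold
        self.classes_ = np.array([-1, 1])
        self.n_features_in_ = len(feats)
        return self

    def decision_function(self, X) -> np.ndarray:
        return self.model_.decision_values(self._frame(X))

    def predict(self, X) -> np.ndarray:
        s = self.decision_function(X)
        return np.where(s > 0, 1, -1)


class HotspotEnsembleClassifier(BaseEstimator, ClassifierMixin):
    """Three linear hot-spot classifiers with amino-acid routing.

    Fits a general model on all rows plus Arg and Glu specialists on the
    same rows but restricted to the given feature subsets (the subsets
    themselves are chosen by :func:`hotspots.selection.select_best_subset`).
    Rows are routed at prediction time by wild-type amino acid, supplied
    either as an ``aa`` argument or as a ``wt_aa`` column of ``X``.
    """

    def __init__(self, general_features=None, arg_features=None, glu_features=None,
                 C=1.0, class_weight=1.0, arg_params=None, glu_params=None, seed=0):
        self.general_features = general_features
        self.arg_features = arg_features
        self.glu_features = glu_features
        self.C = C
        self.class_weight = class_weight
        self.arg_params = arg_params  # optional (C, class_weight) overrides
        self.glu_params = glu_params
        self.seed = seed

    def _aa(self, X, aa):
        if aa is not None:
            return np.asarray(aa)
        if isinstance(X, pd.DataFrame) and "wt_aa" in X.columns:
            return X["wt_aa"].to_numpy()
        raise ValueError("amino-acid codes required: pass aa= or a wt_aa column")

    def _fit_member(self, X, y, feats, C, cw):
        est = LinearHotspotSVM(feature_ids=feats, C=C, class_weight=cw, seed=self.seed)
        return est.fit(X, y).model_

    def fit(self, X, y, aa=None):
        self._aa(X, aa)  # validated for contract symmetry with predict
        gen = self._fit_member(X, y, self.general_features, self.C, self.class_weight)
        arg_C, arg_cw = self.arg_params or (self.C, self.class_weight)
        glu_C, glu_cw = self.glu_params or (self.C, self.class_weight)
        arg = self._fit_member(X, y, self.arg_features or self.general_features, arg_C, arg_cw)
        glu = self._fit_member(X, y, self.glu_features or self.general_features, glu_C, glu_cw)
        self.ensemble_ = HotspotEnsemble(general=gen, arg=arg, glu=glu)
        self.classes_ = np.array([-1, 1])
        return self

    def decision_function(self, X, aa=None) -> np.ndarray:
        codes = self._aa(X, aa)
        df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(
            np.asarray(X, dtype=float), columns=list(FEATURE_NAMES)
        )
        out = np.empty(len(df), dtype=float)
        for name, model in (("general", self.ensemble_.general),
                            ("R", self.ensemble_.arg), ("E", self.ensemble_.glu)):
            mask = (codes == name) if name in ("R", "E") else ~np.isin(codes, ("R", "E"))
            if mask.any():
                out[mask] = model.decision_values(df.loc[mask])
        return out

    def predict(self, X, aa=None) -> np.ndarray:
        return np.where(self.decision_function(X, aa) > 0, 1, -1)
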