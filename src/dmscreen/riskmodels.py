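"""Risk scoring: questionnaire point tables and trainable classifiers.

Two families of screening models are supported behind one interface
(``predict_risk(pop) -> scores``, thresholded by the cascade):

* :class:`ScoreTable` — a binned-points questionnaire score (the NCDRS /
  ADART pattern): each item maps a feature into disjoint, exhaustive bins
  carrying non-negative integer points; the total score is compared to a
  recommended cutoff. The published point tables are not reproduced
  here; editable JSON placeholders with the same schema ship with the
  package.
* :class:`RiskModel` — a probabilistic classifier over a feature list,
  one of seven learner kinds (logistic regression, SVM, random forest,
  k-NN, centroid-displacement k-NN, multilayer perceptron, gradient
  boosted trees), trained with fixed sensible defaults and a seed.

Model understanding uses additive per-feature contributions on the
log-odds scale: exact tree-path contributions for the boosted-tree
learner, an exact linear decomposition for logistic regression, and
seeded permutation importance (ranking only) for the rest. A feature's
contribution converts to a relative risk by comparing the sigmoid of the
base-plus-contribution against the sigmoid of the base alone.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from sklearn.compose import ColumnTransformer
from sklearn.ensemble import RandomForestClassifier
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors
from sklearn.neural_network import MLPClassifier
from sklearn.calibration import CalibratedClassifierCV
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import FunctionTransformer, OneHotEncoder, StandardScaler
from sklearn.svm import SVC
from sklearn.base import BaseEstimator, ClassifierMixin
from lightgbm import LGBMClassifier

from .synthpop import PROTECTED_COLUMNS

__all__ = [
    "ScoreTable",
    "RiskModel",
    "ExplanationVector",
    "RiskModelError",
    "LEARNER_KINDS",
    "load_score_table",
    "apply_score_table",
    "impute",
    "fit",
    "cross_validate",
    "rank_features",
    "streamline",
    "explain",
    "contributions_to_rr",
]

log = logging.getLogger("dmscreen")

# sklearn emits this when a ColumnTransformer hands an unnamed array to an
# estimator that saw names at fit time; the columns are positionally identical
warnings.filterwarnings("ignore", message="X does not have valid feature names")

LEARNER_KINDS = ("LOGISTIC", "SVM", "RANDOM_FOREST", "KNN",
                 "CENTROID_DISPLACEMENT_KNN", "NEURAL_NET",
                 "GRADIENT_BOOSTED_TREES")


class RiskModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# score tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoreBin:
    points: int
    lo: float | None = None          # numeric bin: [lo, hi)
    hi: float | None = None
    categories: tuple[str, ...] | None = None  # categorical bin


@dataclass
class ScoreTable:
    """Binned-points risk score with a positivity cutoff (score >= cutoff)."""

    name: str
    items: list[tuple[str, list[ScoreBin]]]
    cutoff: int

    def __post_init__(self) -> None:
        for feature, bins in self.items:
            if not bins:
                raise RiskModelError(f"item {feature!r} has no bins")
            if any(b.points < 0 or int(b.points) != b.points for b in bins):
                raise RiskModelError(f"item {feature!r}: points must be non-negative integers")
            numeric = bins[0].categories is None
            if numeric:
                ordered = sorted(bins, key=lambda b: -np.inf if b.lo is None else b.lo)
                if ordered[0].lo is not None or ordered[-1].hi is not None:
                    raise RiskModelError(
                        f"item {feature!r}: numeric bins must cover the whole line "
                        "(first lo and last hi open)")
                for a, b in zip(ordered, ordered[1:]):
                    if a.hi is None or b.lo is None or a.hi != b.lo:
                        raise RiskModelError(
                            f"item {feature!r}: numeric bins must be contiguous and disjoint")
            else:
                seen: set[str] = set()
                for b in bins:
                    if b.categories is None:
                        raise RiskModelError(f"item {feature!r} mixes bin kinds")
                    dup = seen & set(b.categories)
                    if dup:
                        raise RiskModelError(f"item {feature!r}: categories {dup} in two bins")
                    seen |= set(b.categories)

    # cascade-facing interface -------------------------------------------------
    def predict_risk(self, pop: pd.DataFrame) -> np.ndarray:
        scores, _ = apply_score_table(self, pop)
        return scores.astype(float)

    @classmethod
    def from_dict(cls, d: dict) -> "ScoreTable":
        items = []
        for item in d["items"]:
            bins = [ScoreBin(points=int(b["points"]),
                             lo=b.get("lo"), hi=b.get("hi"),
                             categories=tuple(b["categories"]) if "categories" in b else None)
                    for b in item["bins"]]
            items.append((item["feature"], bins))
        return cls(name=d["name"], items=items, cutoff=int(d["cutoff"]))

    def to_dict(self) -> dict:
        out = {"name": self.name, "cutoff": self.cutoff, "items": []}
        for feature, bins in self.items:
            bd = []
            for b in bins:
                e: dict = {"points": b.points}
                if b.categories is not None:
                    e["categories"] = list(b.categories)
                else:
                    e["lo"], e["hi"] = b.lo, b.hi
                bd.append(e)
            out["items"].append({"feature": feature, "bins": bd})
        return out


def load_score_table(source: str) -> ScoreTable:
    """Load a score table from a JSON path, or one of the shipped
    placeholders by name ('ncdrs_placeholder', 'adart_placeholder')."""
    try:
        text = resources.files("dmscreen.data").joinpath(f"{source}.json").read_text()
    except FileNotFoundError:
        with open(source) as fh:
            text = fh.read()
    return ScoreTable.from_dict(json.loads(text))


def apply_score_table(table: ScoreTable, pop: pd.DataFrame
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Total points per person and positivity flags (score >= cutoff)."""
    n = len(pop)
    total = np.zeros(n, dtype=int)
    for feature, bins in table.items:
        if feature not in pop.columns:
            raise RiskModelError(f"score table {table.name!r} needs feature {feature!r}")
        col = pop[feature]
        if bins[0].categories is None:
            vals = col.to_numpy(dtype=float)
            bad = ~np.isfinite(vals)
            if bad.any():
                raise RiskModelError(
                    f"feature {feature!r}: non-finite value at rows "
                    f"{list(np.flatnonzero(bad)[:5])}")
            ordered = sorted(bins, key=lambda b: -np.inf if b.lo is None else b.lo)
            edges = np.array([b.lo for b in ordered[1:]], dtype=float)
            pts = np.array([b.points for b in ordered])
            total += pts[np.searchsorted(edges, vals, side="right")]
        else:
            mapping = {c: b.points for b in bins for c in (b.categories or ())}
            pts = col.map(mapping)
            if pts.isna().any():
                bad_vals = col[pts.isna()].unique()[:5]
                raise RiskModelError(
                    f"feature {feature!r}: values {list(bad_vals)} outside all bins")
            total += pts.to_numpy(dtype=int)
    return total, total >= table.cutoff


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

def impute(dev: pd.DataFrame, test: pd.DataFrame, seed: int = 0,
           max_missing: float = 0.2) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Complete both tables using models fitted on the development set only.

    Numeric features are filled by an iterative (chained-equations)
    imputer, categorical features by the development-set mode. Columns
    missing ``max_missing`` or more of their development values are
    dropped from both tables with a warning, mirroring the exclusion of
    heavily missing features from analysis. Test-set values never
    influence the imputation model.
    """
    dev, test = dev.copy(), test.copy()
    candidates = [c for c in dev.columns if c not in PROTECTED_COLUMNS]
    dropped = [c for c in candidates if dev[c].isna().mean() >= max_missing]
    if dropped:
        log.warning("impute: dropping columns with >= %d%% missing data: %s",
                    int(max_missing * 100), dropped)
        dev = dev.drop(columns=dropped)
        test = test.drop(columns=[c for c in dropped if c in test.columns])
        candidates = [c for c in candidates if c not in dropped]

    numeric = [c for c in candidates if pd.api.types.is_numeric_dtype(dev[c])]
    categorical = [c for c in candidates if c not in numeric]

    if numeric and (dev[numeric].isna().any().any()
                    or test[numeric].isna().any().any()):
        imp = IterativeImputer(random_state=seed, max_iter=10, sample_posterior=False)
        imp.fit(dev[numeric])
        dev[numeric] = imp.transform(dev[numeric])
        test[numeric] = imp.transform(test[numeric])
    for c in categorical:
        if dev[c].isna().any() or test[c].isna().any():
            mode = dev[c].mode(dropna=True)
            if len(mode) == 0:
                raise RiskModelError(f"column {c!r} has no observed values to impute from")
            dev[c] = dev[c].fillna(mode.iloc[0])
            test[c] = test[c].fillna(mode.iloc[0])
    return dev, test


# ---------------------------------------------------------------------------
# trainable classifiers
# ---------------------------------------------------------------------------

class CentroidDisplacementKNN(BaseEstimator, ClassifierMixin):
    """k-NN variant scoring by displacement from local class centroids.

    Among a query's k nearest neighbours, each class is represented by
    the centroid of its members (falling back to the global class
    centroid when absent); the query is scored by a softmin over its
    distances to the two centroids.
    """

    def __init__(self, n_neighbors: int = 25):
        self.n_neighbors = n_neighbors

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        self.classes_ = np.unique(y)
        self._X, self._y = X, y
        self._global = {c: X[y == c].mean(axis=0) for c in self.classes_}
        self._nn = NearestNeighbors(n_neighbors=min(self.n_neighbors, len(X))).fit(X)
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        _, idx = self._nn.kneighbors(X)
        probs = np.empty((len(X), len(self.classes_)))
        for i, (x, nb) in enumerate(zip(X, idx)):
            d = []
            for c in self.classes_:
                members = nb[self._y[nb] == c]
                centroid = self._X[members].mean(axis=0) if len(members) else self._global[c]
                d.append(np.linalg.norm(x - centroid))
            d = np.asarray(d)
            w = np.exp(-(d - d.min()))
            probs[i] = w / w.sum()
        return probs

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def _make_estimator(learner_kind: str, seed: int):
    if learner_kind == "LOGISTIC":
        return LogisticRegression(max_iter=2000, random_state=seed)
    if learner_kind == "SVM":
        # sigmoid-calibrated margins stand in for the removed probability=True
        return CalibratedClassifierCV(SVC(random_state=seed), ensemble=False)
    if learner_kind == "RANDOM_FOREST":
        return RandomForestClassifier(n_estimators=300, min_samples_leaf=5,
                                      random_state=seed, n_jobs=1)
    if learner_kind == "KNN":
        return KNeighborsClassifier(n_neighbors=25)
    if learner_kind == "CENTROID_DISPLACEMENT_KNN":
        return CentroidDisplacementKNN(n_neighbors=25)
    if learner_kind == "NEURAL_NET":
        return MLPClassifier(hidden_layer_sizes=(32, 16), max_iter=400,
                             random_state=seed)
    if learner_kind == "GRADIENT_BOOSTED_TREES":
        return LGBMClassifier(n_estimators=200, learning_rate=0.05, num_leaves=31,
                              min_child_samples=30, random_state=seed,
                              deterministic=True, force_row_wise=True,
                              n_jobs=1, verbose=-1)
    raise RiskModelError(f"unknown learner kind {learner_kind!r}; "
                         f"expected one of {LEARNER_KINDS}")

#: learners whose features are standardised before fitting
_SCALED = {"LOGISTIC", "SVM", "KNN", "CENTROID_DISPLACEMENT_KNN", "NEURAL_NET"}


@dataclass
class RiskModel:
    """A fitted probabilistic screening classifier."""

    feature_list: list[str]
    learner_kind: str
    pipeline: Pipeline
    base_rate: float
    seed: int
    outcome: str = "dm_status"
    #: transformed-column index -> original feature, for grouping contributions
    _column_map: list[str] = field(default_factory=list, repr=False)

    def predict_risk(self, pop: pd.DataFrame) -> np.ndarray:
        """Predicted probability of the outcome, in [0, 1]."""
        missing = [f for f in self.feature_list if f not in pop.columns]
        if missing:
            raise RiskModelError(f"population lacks model features {missing}")
        X = pop[self.feature_list]
        if X.isna().any().any():
            raise RiskModelError("missing feature values: impute before prediction")
        return self.pipeline.predict_proba(X)[:, 1]


def _build_pipeline(dev: pd.DataFrame, features: list[str],
                    learner_kind: str, seed: int) -> Pipeline:
    categorical = [f for f in features if not pd.api.types.is_numeric_dtype(dev[f])]
    numeric = [f for f in features if f not in categorical]
    transformers = []
    if numeric:
        transformers.append(("num", StandardScaler() if learner_kind in _SCALED
                             else "passthrough", numeric))
    if categorical:
        transformers.append(("cat", OneHotEncoder(drop="first", sparse_output=False,
                                                  handle_unknown="ignore"), categorical))
    pre = ColumnTransformer(transformers, verbose_feature_names_out=False)
    # hand the estimator a bare array so fit and predict agree on naming
    return Pipeline([("pre", pre),
                     ("arr", FunctionTransformer(np.asarray)),
                     ("clf", _make_estimator(learner_kind, seed))])


def _original_feature(transformed_name: str, features: list[str]) -> str:
    # OneHotEncoder emits "<feature>_<level>"; match the longest known prefix
    best = ""
    for f in features:
        if (transformed_name == f or transformed_name.startswith(f + "_")) and len(f) > len(best):
            best = f
    return best or transformed_name


def fit(dev: pd.DataFrame, learner_kind: str, features: list[str],
        seed: int = 0, outcome: str = "dm_status") -> RiskModel:
    """Train one classifier on the development set. Deterministic per seed."""
    if learner_kind not in LEARNER_KINDS:
        raise RiskModelError(f"unknown learner kind {learner_kind!r}")
    missing = [f for f in features if f not in dev.columns]
    if missing:
        raise RiskModelError(f"development set lacks features {missing}")
    if outcome not in dev.columns:
        raise RiskModelError(f"development set lacks outcome column {outcome!r}")
    y = dev[outcome].to_numpy(dtype=bool)
    if y.all() or not y.any():
        raise RiskModelError("development set must contain both classes")
    if dev[features].isna().any().any():
        raise RiskModelError("missing feature values: impute before fitting")
    pipe = _build_pipeline(dev, list(features), learner_kind, seed)
    pipe.fit(dev[features], y.astype(int))
    colnames = list(pipe.named_steps["pre"].get_feature_names_out())
    return RiskModel(feature_list=list(features), learner_kind=learner_kind,
                     pipeline=pipe, base_rate=float(y.mean()), seed=seed,
                     outcome=outcome,
                     _column_map=[_original_feature(c, list(features)) for c in colnames])


def cross_validate(dev: pd.DataFrame, learner_kind: str, features: list[str],
                   k: int = 5, seed: int = 0, outcome: str = "dm_status",
                   n_boot: int = 500) -> dict:
    """Seeded k-fold cross-validation with pooled out-of-fold metrics.

    Rows are randomly partitioned into k near-equal folds; each row is
    validated exactly once. Returns per-fold AUC/auPR, and pooled AUC /
    auPR over the out-of-fold predictions with stratified-bootstrap 95%
    CIs.
    """
    n = len(dev)
    if k < 2:
        raise RiskModelError("k must be at least 2")
    if k > n:
        raise RiskModelError(f"k={k} exceeds the {n} development rows")
    from .metrics import bootstrap_ci  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    folds = np.array_split(rng.permutation(n), k)
    y = dev[outcome].to_numpy(dtype=bool)
    oof = np.full(n, np.nan)
    per_fold = []
    for i, val_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(n), val_idx)
        model = fit(dev.iloc[train_idx], learner_kind, features, seed=seed,
                    outcome=outcome)
        preds = model.predict_risk(dev.iloc[val_idx])
        oof[val_idx] = preds
        yv = y[val_idx]
        row = {"fold": i, "n": len(val_idx)}
        if yv.any() and not yv.all():
            row["auc"] = float(roc_auc_score(yv, preds))
            row["aupr"] = float(average_precision_score(yv, preds))
        per_fold.append(row)
    pooled_auc = float(roc_auc_score(y, oof))
    pooled_aupr = float(average_precision_score(y, oof))
    out = {
        "per_fold": pd.DataFrame(per_fold),
        "pooled_auc": pooled_auc,
        "pooled_aupr": pooled_aupr,
        "oof_predictions": oof,
    }
    if n_boot:
        out["auc_ci95"] = bootstrap_ci(oof, y, lambda s, t: roc_auc_score(t, s),
                                       B=max(n_boot, 100), seed=seed)
        out["aupr_ci95"] = bootstrap_ci(oof, y,
                                        lambda s, t: average_precision_score(t, s),
                                        B=max(n_boot, 100), seed=seed)
    return out


# ---------------------------------------------------------------------------
# explanations and importance
# ---------------------------------------------------------------------------

@dataclass
class ExplanationVector:
    """Additive per-feature contributions on the log-odds scale.

    ``base + sum(phi)`` equals the model's log-odds output for the row.
    """

    features: list[str]
    phi: np.ndarray
    base: float

    @property
    def fx(self) -> float:
        return float(self.base + self.phi.sum())

    def contribution(self, feature: str) -> float:
        try:
            return float(self.phi[self.features.index(feature)])
        except ValueError:
            raise RiskModelError(f"feature {feature!r} not in the explanation") from None


def _group_contributions(raw: np.ndarray, column_map: list[str],
                         features: list[str]) -> np.ndarray:
    """Sum transformed-column contributions back onto original features."""
    out = np.zeros((raw.shape[0], len(features)))
    index = {f: j for j, f in enumerate(features)}
    for col, f in enumerate(column_map):
        out[:, index[f]] += raw[:, col]
    return out


def explain(model: RiskModel, data: pd.DataFrame) -> list[ExplanationVector]:
    """Exact additive explanations for the tree-boosted and logistic learners.

    Tree learner: tree-path (Shapley-style) contributions from the
    booster's native per-feature output decomposition. Logistic
    learner: ``phi_j = beta_j * (x_j - mean_j)`` over the standardised
    design, which is exactly additive. Other learners have no additive
    decomposition here; use :func:`rank_features`.
    """
    if len(data) == 0:
        raise RiskModelError("cannot explain an empty table")
    X = data[model.feature_list]
    Xt = model.pipeline.named_steps["pre"].transform(X)
    clf = model.pipeline.named_steps["clf"]
    if model.learner_kind == "GRADIENT_BOOSTED_TREES":
        contrib = clf.booster_.predict(Xt, pred_contrib=True)
        base = float(contrib[0, -1])
        phi = _group_contributions(contrib[:, :-1], model._column_map,
                                   model.feature_list)
    elif model.learner_kind == "LOGISTIC":
        coef = clf.coef_[0]
        center = getattr(model, "_train_center", None)
        if center is None:
            center = np.zeros(Xt.shape[1])
        raw = coef * (np.asarray(Xt) - center)
        base = float(clf.intercept_[0] + coef @ center)
        phi = _group_contributions(raw, model._column_map, model.feature_list)
    else:
        raise RiskModelError(
            f"learner {model.learner_kind} has no exact additive explanation; "
            "use rank_features (permutation importance) instead")
    if not np.all(np.isfinite(phi)):
        raise RiskModelError("non-finite contribution encountered")
    return [ExplanationVector(features=list(model.feature_list), phi=phi[i], base=base)
            for i in range(len(data))]


def rank_features(model: RiskModel, data: pd.DataFrame,
                  seed: int = 0) -> list[tuple[str, float]]:
    """Features by descending mean absolute contribution over ``data``.

    Uses exact additive contributions where available and seeded
    permutation importance (mean AUC drop over 5 shuffles) otherwise.
    Ties break lexicographically by feature name.
    """
    if len(data) == 0:
        raise RiskModelError("cannot rank features on an empty table")
    try:
        expl = explain(model, data)
        mean_abs = np.abs(np.stack([e.phi for e in expl])).mean(axis=0)
        scores = dict(zip(model.feature_list, mean_abs))
    except RiskModelError:
        if model.outcome not in data.columns:
            raise RiskModelError(
                f"permutation importance needs the outcome column {model.outcome!r}")
        rng = np.random.default_rng(seed)
        y = data[model.outcome].to_numpy(dtype=bool)
        base_auc = roc_auc_score(y, model.predict_risk(data))
        scores = {}
        for f in model.feature_list:
            drops = []
            for _ in range(5):
                shuffled = data.copy()
                shuffled[f] = rng.permutation(shuffled[f].to_numpy())
                drops.append(base_auc - roc_auc_score(y, model.predict_risk(shuffled)))
            scores[f] = abs(float(np.mean(drops)))
    return sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))


def streamline(dev: pd.DataFrame, learner_kind: str = "GRADIENT_BOOSTED_TREES",
               features: list[str] | None = None,
               ks: tuple[int, ...] = (5, 10, 15, 20, 25),
               tolerance: float = 0.005, seed: int = 0,
               outcome: str = "dm_status", k_cv: int = 5,
               n_boot: int = 0) -> tuple[int, RiskModel, pd.DataFrame]:
    """Top-k feature streamlining.

    Features are ranked on a full model fitted to the development set;
    one model per k is cross-validated on the top-k features, and the
    smallest k whose CV AUC is within ``tolerance`` of the best over the
    grid is selected. Returns (chosen k, final model refit on the whole
    development set, per-k AUC/auPR table).
    """
    if not ks:
        raise RiskModelError("ks must be non-empty")
    if list(ks) != sorted(ks):
        raise RiskModelError("ks must be sorted ascending")
    if features is None:
        features = [c for c in dev.columns if c not in PROTECTED_COLUMNS]
    full = fit(dev, learner_kind, features, seed=seed, outcome=outcome)
    ranking = [f for f, _ in rank_features(full, dev, seed=seed)]
    rows = []
    for k in ks:
        top = ranking[:min(k, len(ranking))]
        cv = cross_validate(dev, learner_kind, top, k=k_cv, seed=seed,
                            outcome=outcome, n_boot=n_boot)
        rows.append({"k": k, "n_features": len(top), "auc": cv["pooled_auc"],
                     "aupr": cv["pooled_aupr"]})
    table = pd.DataFrame(rows)
    best = table["auc"].max()
    chosen = int(table.loc[table["auc"] >= best - tolerance, "k"].min())
    model = fit(dev, learner_kind, ranking[:chosen], seed=seed, outcome=outcome)
    return chosen, model, table


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def contributions_to_rr(expl: ExplanationVector, feature: str) -> float:
    """Relative risk implied by one feature's log-odds contribution.

    RR = sigmoid(base + phi_f) / sigmoid(base); above 1 exactly when the
    contribution is positive.
    """
    phi = expl.contribution(feature)
    if not np.isfinite(phi) or not np.isfinite(expl.base):
        raise RiskModelError("non-finite contribution or base value")
    return _sigmoid(expl.base + phi) / _sigmoid(expl.base)
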