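"""Categorical naive Bayes on equal-frequency bins, and the uniform
train/predict contract shared with the comparator classifier families.

The naive Bayes model is categorical: each feature is discretized into
``k`` equal-frequency bins (edges fit on training data only by default),
plus a dedicated missing category, and the class-conditional bin
probabilities are Laplace-smoothed,

    P(bin | class) = (count + alpha) / (n_class + alpha * n_categories).

Prediction multiplies the class prior by the per-feature conditionals (in
log space) and normalizes; exact posterior ties resolve to the negative
class.  Comparators — L2 logistic regression, CART decision tree (Gini),
and a seeded random forest — run on the continuous features (no
discretization) via scikit-learn, with training-median imputation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import AnalysisError
from .featselect import MISSING_BIN, discretize_equal_frequency

FAMILIES = ("naive_bayes", "logistic_regression", "decision_tree", "random_forest")
_ALIASES = {"nb": "naive_bayes", "lr": "logistic_regression",
            "dt": "decision_tree", "rf": "random_forest"}


def canonical_family(name: str) -> str:
    name = _ALIASES.get(name, name)
    if name not in FAMILIES:
        raise ValueError(f"unknown classifier family {name!r}; expected one of {FAMILIES}")
    return name


@dataclass(frozen=True)
class ClassifierSpec:
    """One classifier family with its hyperparameters and RNG seed."""

    family: str
    hyperparameters: Mapping[str, object] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", canonical_family(self.family))


@dataclass
class NBModel:
    """Fitted categorical naive Bayes: priors, bin edges and smoothed tables."""

    classes: np.ndarray                 # sorted; classes[0] is the negative class
    log_prior: np.ndarray               # (2,)
    feature_names: list[str]
    edges: dict[str, np.ndarray]        # internal quantile edges per feature
    log_cond: dict[str, np.ndarray]     # (n_categories, 2) log P(cat | class)
    k_bins: int
    alpha: float

    def n_categories(self, feature: str) -> int:
        return self.log_cond[feature].shape[0]

    def to_dict(self) -> dict:
        """Human-readable serialization (priors, edges, tables) for audit."""
        return {
            "classes": self.classes.tolist(),
            "prior": np.exp(self.log_prior).tolist(),
            "k_bins": self.k_bins,
            "alpha": self.alpha,
            "features": {
                f: {
                    "edges": self.edges[f].tolist(),
                    "P(bin|class)": np.exp(self.log_cond[f]).T.tolist(),
                }
                for f in self.feature_names
            },
        }


def _bin_value(value: float, edges: np.ndarray, n_bins: int) -> int:
    """Bin index under fitted edges; out-of-range clamps, NaN -> missing."""
    if np.isnan(value):
        return n_bins  # the dedicated missing category is the last one
    return int(np.searchsorted(edges, value, side="left"))


def fit_nb(X, y, k_bins: int = 4, alpha: float = 1.0,
           feature_names: Optional[Sequence[str]] = None,
           edges: Optional[Mapping[str, np.ndarray]] = None) -> NBModel:
    """Fit the categorical naive Bayes model on training rows only.

    ``edges`` may be supplied to reuse pre-fit discretization (the leaky
    whole-cohort variant); by default edges come from the training data.
    """
    if isinstance(X, pd.DataFrame):
        feature_names = list(X.columns)
        X = X.to_numpy(float)
    else:
        X = np.asarray(X, float)
        feature_names = list(feature_names) if feature_names is not None else [
            f"x{i}" for i in range(X.shape[1])
        ]
    y = np.asarray(y, bool)
    classes = np.array([False, True])
    n_by_class = np.array([(y == c).sum() for c in classes])
    if (n_by_class < 2).any():
        raise AnalysisError(f"need >= 2 training patients per class, got {n_by_class.tolist()}")
    log_prior = np.log(n_by_class / y.size)

    fit_edges: dict[str, np.ndarray] = {}
    log_cond: dict[str, np.ndarray] = {}
    import warnings

    for j, name in enumerate(feature_names):
        col = X[:, j]
        if edges is not None and name in edges:
            e = np.asarray(edges[name], float)
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                finite = col[~np.isnan(col)]
                if finite.size == 0:
                    e = np.array([])
                else:
                    _, e = discretize_equal_frequency(col, k_bins)
        n_bins = len(e) + 1
        n_cat = n_bins + 1  # + missing category
        labels = np.where(np.isnan(col), n_bins,
                          np.searchsorted(e, col, side="left"))
        counts = np.zeros((n_cat, 2))
        for ci, c in enumerate(classes):
            cat, cnt = np.unique(labels[y == c], return_counts=True)
            counts[cat.astype(int), ci] = cnt
        fit_edges[name] = e
        log_cond[name] = np.log(
            (counts + alpha) / (n_by_class[None, :] + alpha * n_cat)
        )
    return NBModel(classes=classes, log_prior=log_prior,
                   feature_names=feature_names, edges=fit_edges,
                   log_cond=log_cond, k_bins=k_bins, alpha=alpha)


def predict_nb(model: NBModel, x) -> tuple[bool, np.ndarray]:
    """Label and normalized posterior for one feature vector.

    ``x`` is a mapping or sequence aligned with the model's features.
    Posterior ties resolve to the negative class.
    """
    if isinstance(x, (pd.Series, Mapping)):
        try:
            vec = [float(x[f]) for f in model.feature_names]
        except KeyError as exc:
            raise KeyError(f"feature {exc.args[0]!r} absent from input") from exc
    else:
        vec = list(np.asarray(x, float))
        if len(vec) != len(model.feature_names):
            raise ValueError("input length does not match the model's features")
    log_post = model.log_prior.copy()
    for name, v in zip(model.feature_names, vec):
        n_bins = model.n_categories(name) - 1
        cat = _bin_value(v, model.edges[name], n_bins)
        log_post = log_post + model.log_cond[name][cat]
    log_post -= log_post.max()
    post = np.exp(log_post)
    post /= post.sum()
    label = bool(model.classes[1]) if log_post[1] > log_post[0] else bool(model.classes[0])
    return label, post


def fit_predict(spec: ClassifierSpec, X_train, y_train, x_test) -> bool:
    """Uniform contract: train one model, return the label for one test row.

    Naive Bayes consumes the raw (possibly missing) values and discretizes
    internally; the other families receive continuous features with
    training-median imputation.
    """
    if isinstance(X_train, pd.DataFrame):
        feature_names = list(X_train.columns)
        X_train = X_train.to_numpy(float)
    else:
        X_train = np.asarray(X_train, float)
        feature_names = None
    y_train = np.asarray(y_train, bool)
    x_test = np.asarray(
        [x_test[f] for f in feature_names] if isinstance(x_test, (pd.Series, Mapping))
        and feature_names is not None else x_test, float
    ).ravel()

    hp = dict(spec.hyperparameters)
    if spec.family == "naive_bayes":
        model = fit_nb(X_train, y_train, k_bins=int(hp.pop("k_bins", 4)),
                       alpha=float(hp.pop("alpha", 1.0)), feature_names=feature_names,
                       edges=hp.pop("edges", None))
        label, _ = predict_nb(model, x_test)
        return label

    med = np.nanmedian(X_train, axis=0)
    med = np.where(np.isnan(med), 0.0, med)
    Xt = np.where(np.isnan(X_train), med[None, :], X_train)
    xt = np.where(np.isnan(x_test), med, x_test)[None, :]

    if np.unique(y_train).size < 2:
        raise AnalysisError("single-class training target")

    if spec.family == "logistic_regression":
        from sklearn.linear_model import LogisticRegression
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler

        clf = make_pipeline(
            StandardScaler(),
            LogisticRegression(C=float(hp.pop("C", 1.0)), max_iter=2000),  # L2 default
        )
    elif spec.family == "decision_tree":
        from sklearn.tree import DecisionTreeClassifier

        clf = DecisionTreeClassifier(criterion="gini",
                                     max_depth=hp.pop("max_depth", None),
                                     random_state=spec.seed)
    elif spec.family == "random_forest":
        from sklearn.ensemble import RandomForestClassifier

        clf = RandomForestClassifier(
            n_estimators=int(hp.pop("n_estimators", 100)),
            criterion="gini", bootstrap=True, max_features="sqrt",
            random_state=spec.seed,
        )
    else:  # pragma: no cover - guarded by ClassifierSpec
        raise ValueError(f"unknown family {spec.family!r}")
    clf.fit(Xt, y_train)
    return bool(clf.predict(xt)[0])
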