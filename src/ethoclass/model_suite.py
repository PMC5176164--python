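"""Four model families for behaviour classification.

Penalised multinomial logistic regression (the linear baseline), support
vector machines with linear / polynomial / radial / sigmoid kernels,
random forests, and stochastic gradient-boosted trees. Hyperparameter
names follow the R conventions the families are best known under
(cost/gamma/coef0/degree for SVM, n_trees/vars_per_split/min_node_size for
forests, learning_rate/max_depth/n_rounds/subsample for boosting,
mixing/strength for the elastic-net penalty).

Scale-sensitive families (logistic, SVM) standardise continuous predictors
at fit time and store the constants; tree families consume raw features.
SVM multiclass handling is one-vs-one with Platt probability calibration.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

FAMILIES = ("penalised_logistic", "svm", "random_forest", "gbm")
SVM_KERNELS = ("linear", "polynomial", "radial", "sigmoid")

_ALLOWED_PARAMS = {
    "penalised_logistic": {"mixing", "strength", "max_iter"},
    "svm": {"cost", "gamma", "coef0", "degree"},
    "random_forest": {"n_trees", "vars_per_split", "min_node_size"},
    "gbm": {"learning_rate", "max_depth", "n_rounds", "subsample"},
}

_POSITIVE_PARAMS = {"cost", "gamma", "n_trees", "n_rounds", "max_depth", "strength"}


class SchemaError(ValueError):
    """Prediction-time predictor schema does not match training."""


@dataclass(frozen=True)
class ModelConfig:
    family: str
    kernel: str | None = None        # svm only
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; one of {FAMILIES}")
        if self.family == "svm":
            if self.kernel not in SVM_KERNELS:
                raise ValueError(f"svm kernel must be one of {SVM_KERNELS}")
        elif self.kernel is not None:
            raise ValueError("kernel is only meaningful for the svm family")
        unknown = set(self.hyperparameters) - _ALLOWED_PARAMS[self.family]
        if unknown:
            raise ValueError(
                f"unknown hyperparameter(s) {sorted(unknown)} for family "
                f"{self.family!r}; allowed: {sorted(_ALLOWED_PARAMS[self.family])}"
            )
        for name, val in self.hyperparameters.items():
            if name in _POSITIVE_PARAMS and not val > 0:
                raise ValueError(f"{name} must be strictly positive (got {val})")
            if name == "subsample" and not 0 < val <= 1:
                raise ValueError(f"subsample must be in (0, 1] (got {val})")
            if name == "mixing" and not 0 <= val <= 1:
                raise ValueError(f"mixing must be in [0, 1] (got {val})")

    def label(self) -> str:
        return self.family if self.kernel is None else f"{self.family}:{self.kernel}"


@dataclass
class TrainedModel:
    """A fitted classifier plus everything needed to apply it safely."""

    config: ModelConfig
    estimator: object
    schema: list[str]                 # predictor columns, in training order
    classes: tuple[str, ...]
    scaler: StandardScaler | None = None
    class_counts: dict[str, int] = field(default_factory=dict)

    def _check_schema(self, data: pd.DataFrame) -> None:
        have = set(data.columns)
        want = set(self.schema)
        if have >= want:
            return
        raise SchemaError(
            f"predictor schema mismatch; missing: {sorted(want - have)}, "
            f"extra: {sorted(have - want) if have - want else '[]'}"
        )


def _build_estimator(config: ModelConfig):
    hp = config.hyperparameters
    if config.family == "penalised_logistic":
        mixing = float(hp.get("mixing", 0.5))
        strength = float(hp.get("strength", 1e-3))
        return LogisticRegression(
            penalty="elasticnet", solver="saga", l1_ratio=mixing,
            C=1.0 / strength, max_iter=int(hp.get("max_iter", 2000)),
            tol=1e-3, random_state=config.seed,
        )
    if config.family == "svm":
        kernel = {"linear": "linear", "polynomial": "poly",
                  "radial": "rbf", "sigmoid": "sigmoid"}[config.kernel]
        return SVC(
            kernel=kernel, C=float(hp.get("cost", 1.0)),
            gamma=float(hp.get("gamma", 0.01)) if "gamma" in hp else "scale",
            coef0=float(hp.get("coef0", 0.0)), degree=int(hp.get("degree", 3)),
            probability=True, random_state=config.seed, cache_size=500,
        )
    if config.family == "random_forest":
        return RandomForestClassifier(
            n_estimators=int(hp.get("n_trees", 500)),
            max_features=int(hp["vars_per_split"]) if "vars_per_split" in hp else "sqrt",
            min_samples_leaf=int(hp.get("min_node_size", 1)),
            random_state=config.seed, n_jobs=1,
        )
    if config.family == "gbm":
        return XGBClassifier(
            learning_rate=float(hp.get("learning_rate", 0.1)),
            max_depth=int(hp.get("max_depth", 4)),
            n_estimators=int(hp.get("n_rounds", 200)),
            subsample=float(hp.get("subsample", 0.8)),
            tree_method="hist",
            random_state=config.seed, n_jobs=1, verbosity=0,
        )
    raise AssertionError(config.family)


def fit(config: ModelConfig, train: pd.DataFrame, predictors: list[str] | None = None) -> TrainedModel:
    """Fit one model family on a labelled feature table.

    ``predictors`` defaults to every non-metadata column; the label column
    is ``category``. Deterministic given ``config.seed``. Raises on
    single-class input and on non-finite predictor values (naming the
    first offending column).
    """
    from .dataset_builder import predictor_columns

    cols = predictors if predictors is not None else predictor_columns(train)
    X = train[cols].to_numpy(dtype=float)
    y = train["category"].to_numpy(dtype=object)

    classes = tuple(sorted(np.unique(y)))
    if len(classes) < 2:
        raise ValueError(f"training data has a single class {classes}; need >= 2")
    bad = ~np.isfinite(X)
    if bad.any():
        j = int(np.argmax(bad.any(axis=0)))
        raise ValueError(f"non-finite predictor values in column {cols[j]!r}")

    scaler = None
    if config.family in ("penalised_logistic", "svm"):
        scaler = StandardScaler().fit(X)
        X = scaler.transform(X)

    est = _build_estimator(config)
    if config.family == "gbm":
        codes = np.searchsorted(classes, y)
        est.fit(X, codes)
    else:
        est.fit(X, y)
    counts = {c: int((y == c).sum()) for c in classes}
    return TrainedModel(config=config, estimator=est, schema=list(cols),
                        classes=classes, scaler=scaler, class_counts=counts)


def predict(model: TrainedModel, data: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Predict classes and per-class probabilities for a feature table.

    Returns (classes, probabilities); probabilities are non-negative and
    sum to one per row; the predicted class is the argmax, with ties broken
    by the fixed class order.
    """
    if len(data) == 0:
        return (pd.Series([], dtype=object),
                pd.DataFrame(columns=list(model.classes)))
    model._check_schema(data)
    X = data[model.schema].to_numpy(dtype=float)
    if model.scaler is not None:
        X = model.scaler.transform(X)
    proba = model.estimator.predict_proba(X)
    if model.config.family == "gbm":
        order = np.arange(len(model.classes))
    else:
        order = np.array([list(model.estimator.classes_).index(c) for c in model.classes])
    proba = proba[:, order]
    proba = proba / proba.sum(axis=1, keepdims=True)
    pred = np.asarray(model.classes, dtype=object)[np.argmax(proba, axis=1)]
    probs = pd.DataFrame(proba, columns=list(model.classes), index=data.index)
    return pd.Series(pred, index=data.index, name="predicted"), probs


# ---------------------------------------------------------------------------
# grid search with the inner 70/30 split and 10-fold CV
# ---------------------------------------------------------------------------

def _epoch_keys(table: pd.DataFrame) -> np.ndarray:
    """Stable per-row keys so fold assignment is invariant to row order."""
    return np.array(
        [f"{s}:{e}" for s, e in zip(table["subject_id"].astype(str),
                                    table["epoch_index"].astype(int))],
        dtype=object,
    )


@dataclass
class GridSearchResult:
    config: ModelConfig
    cv_accuracy: float            # mean out-of-fold accuracy on the 70% split
    validation_accuracy: float    # accuracy on the 30% split after refit
    trace: list[dict] = field(default_factory=list)


def grid_search(
    grids: dict[str, list[dict]],
    train: pd.DataFrame,
    n_folds: int = 10,
    inner_fraction: float = 0.70,
    seed: int = 0,
    predictors: list[str] | None = None,
) -> dict[str, GridSearchResult]:
    """Select hyperparameters per family.

    The training table is split 70/30 at the epoch level (subjects may
    straddle the split, as when parameters are tuned before the subject-wise
    holdout). Every grid point is scored by 10-fold cross-validation on the
    70% part (mean out-of-fold accuracy); the winner is refit on the full
    70% and reported with its accuracy on the 30% validation part. Fold
    assignment is keyed to stable epoch identifiers, so permuting the rows
    does not change the selected configuration.

    ``grids`` maps a family label (e.g. ``"svm:polynomial"`` or
    ``"random_forest"``) to a list of hyperparameter dicts.
    """
    n = len(train)
    if n_folds > n:
        raise ValueError(f"n_folds={n_folds} exceeds {n} training rows")
    if not grids or any(not pts for pts in grids.values()):
        raise ValueError("every family grid must be non-empty")

    keys = _epoch_keys(train)
    order = np.argsort(keys, kind="stable")
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    perm = order[rng.permutation(n)]
    n_inner = int(round(inner_fraction * n))
    inner_pos, valid_pos = perm[:n_inner], perm[n_inner:]
    inner = train.iloc[inner_pos].reset_index(drop=True)
    valid = train.iloc[valid_pos].reset_index(drop=True)
    folds = np.arange(len(inner)) % n_folds
    folds = folds[rng.permutation(len(inner))]

    results: dict[str, GridSearchResult] = {}
    for label, points in grids.items():
        family, _, kernel = label.partition(":")
        trace = []
        best: tuple[float, ModelConfig] | None = None
        for hp in points:
            config = ModelConfig(family=family, kernel=kernel or None,
                                 hyperparameters=dict(hp), seed=seed)
            accs = []
            for k in range(n_folds):
                tr = inner.loc[folds != k]
                te = inner.loc[folds == k]
                model = fit(config, tr, predictors)
                pred, _ = predict(model, te)
                accs.append(float((pred.to_numpy() == te["category"].to_numpy()).mean()))
            mean_acc = float(np.mean(accs))
            trace.append({"hyperparameters": dict(hp), "cv_accuracy": mean_acc})
            if best is None or mean_acc > best[0]:
                best = (mean_acc, config)
        cv_acc, config = best
        final = fit(config, inner, predictors)
        pred, _ = predict(final, valid)
        val_acc = float((pred.to_numpy() == valid["category"].to_numpy()).mean())
        results[label] = GridSearchResult(config=config, cv_accuracy=cv_acc,
                                          validation_accuracy=val_acc, trace=trace)
    return results


# ---------------------------------------------------------------------------
# grid definitions
# ---------------------------------------------------------------------------

def load_grids(path: str | Path | None = None) -> dict[str, list[dict]]:
    """Load grid definitions from YAML; with no path, the packaged default
    grids (the published best-parameter neighbourhoods for each family)."""
    if path is None:
        text = resources.files("ethoclass.data").joinpath("default_grids.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    return {label: list(points) for label, points in raw["families"].items()}


def fast_grids() -> dict[str, list[dict]]:
    """One compact grid point per family, sized for quick runs on small
    synthetic cohorts; same four families as the full default grids."""
    return {
        "gbm": [{"learning_rate": 0.1, "max_depth": 4, "n_rounds": 150, "subsample": 0.8}],
        "random_forest": [{"n_trees": 200, "vars_per_split": 8, "min_node_size": 1}],
        "penalised_logistic": [{"mixing": 0.5, "strength": 1e-3, "max_iter": 500}],
        "svm:polynomial": [{"degree": 3, "gamma": 0.01, "coef0": 1, "cost": 10}],
    }


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_model(model: TrainedModel, directory: str | Path) -> None:
    """Versioned archive: schema + metadata as JSON, fitted state pickled."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    meta = {
        "format_version": 1,
        "family": model.config.family,
        "kernel": model.config.kernel,
        "hyperparameters": model.config.hyperparameters,
        "seed": model.config.seed,
        "schema": model.schema,
        "classes": list(model.classes),
        "class_counts": model.class_counts,
    }
    (d / "model.json").write_text(json.dumps(meta, indent=2))
    with open(d / "model.pkl", "wb") as fh:
        pickle.dump({"estimator": model.estimator, "scaler": model.scaler}, fh)


def load_model(directory: str | Path) -> TrainedModel:
    d = Path(directory)
    meta = json.loads((d / "model.json").read_text())
    if meta.get("format_version") != 1:
        raise ValueError(f"unsupported model archive version {meta.get('format_version')}")
    with open(d / "model.pkl", "rb") as fh:
        state = pickle.load(fh)
    config = ModelConfig(family=meta["family"], kernel=meta["kernel"],
                         hyperparameters=meta["hyperparameters"], seed=meta["seed"])
    return TrainedModel(config=config, estimator=state["estimator"],
                        schema=meta["schema"], classes=tuple(meta["classes"]),
                        scaler=state["scaler"], class_counts=meta["class_counts"])
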