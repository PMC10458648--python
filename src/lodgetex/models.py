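"""The four lodging classifiers behind one fit/predict/predict_proba contract.

XGBoost is tuned with a sequential Tree-structured Parzen Estimator over
its usual six hyperparameters; the random forest with a grid search under
5-fold cross-validation over six parameters; KNN uses a fixed k = 3 and is
implemented natively (brute-force Euclidean, vote-fraction probabilities,
distance ties to the lowest index); the ANN is a single-hidden-layer ReLU
multilayer perceptron tuned over hidden width and iteration cap.  Features
are standardized (train mean/sd) for the distance- and gradient-based
models (KNN, ANN) only; tree ensembles consume raw features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Any, Mapping

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neural_network import MLPClassifier

from .synth import CLASS_ORDER, FeatureTable

MODEL_TYPES = ("xgboost", "random_forest", "knn", "ann")


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.8
    stratified: bool = True
    seed: int = 0


def split_train_test(
    table: FeatureTable, spec: SplitSpec | None = None
) -> tuple[FeatureTable, FeatureTable]:
    """Stratified, seed-deterministic 80/20 split; per-class proportions are
    within one sample of the target fractions."""
    spec = spec or SplitSpec()
    idx = np.arange(table.n)
    if spec.stratified:
        _, counts = np.unique(table.y, return_counts=True)
        if counts.min() < 2:
            raise ValueError("stratified split needs >= 2 samples per class")
        stratify = table.y
    else:
        stratify = None
    tr, te = train_test_split(
        idx,
        train_size=spec.train_fraction,
        stratify=stratify,
        random_state=spec.seed,
        shuffle=True,
    )
    return table.subset(np.sort(tr)), table.subset(np.sort(te))


def _class_order(labels: np.ndarray) -> list[str]:
    uniq = [str(u) for u in np.unique(labels)]
    if set(uniq) <= set(CLASS_ORDER):
        return [c for c in CLASS_ORDER if c in uniq]
    return sorted(uniq)


class _NativeKNN:
    """Brute-force k-nearest-neighbour classifier.

    Probabilities are neighbour vote fractions; equal distances rank by
    training index (stable sort); a zero-distance neighbour participates
    like any other."""

    def __init__(self, n_neighbors: int = 3):
        self.k = int(n_neighbors)

    def fit(self, X: np.ndarray, y_idx: np.ndarray, n_classes: int) -> "_NativeKNN":
        self.X_ = np.asarray(X, dtype=float)
        self.y_ = np.asarray(y_idx, dtype=int)
        self.n_classes_ = n_classes
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        d = ((X[:, None, :] - self.X_[None, :, :]) ** 2).sum(axis=2)
        k = min(self.k, self.X_.shape[0])
        nn = np.argsort(d, axis=1, kind="stable")[:, :k]
        proba = np.zeros((len(X), self.n_classes_))
        for i in range(len(X)):
            votes = np.bincount(self.y_[nn[i]], minlength=self.n_classes_)
            proba[i] = votes / votes.sum()
        return proba


class _ConstantClassifier:
    """Degenerate one-class training data: predict that class everywhere."""

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return np.ones((len(X), 1))


@dataclass
class TrainedClassifier:
    """Uniform contract over the four model types."""

    model_type: str
    hyperparams: dict[str, Any]
    classes: list[str]
    _backend: Any = field(repr=False)
    _scaler: tuple[np.ndarray, np.ndarray] | None = field(default=None, repr=False)

    def _transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if np.isnan(X).any():
            raise ValueError("NaN in features")
        if self._scaler is not None:
            mean, sd = self._scaler
            if X.shape[1] != len(mean):
                raise ValueError("feature dimension mismatch")
            X = (X - mean) / sd
        return X

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = self._transform(X)
        if self.model_type == "knn":
            p = self._backend.predict_proba(X)
        else:
            p = self._backend.predict_proba(X)
            # backends may drop classes absent from training; re-embed
            if p.shape[1] != len(self.classes):
                full = np.zeros((len(X), len(self.classes)))
                seen = getattr(self._backend, "classes_", np.arange(p.shape[1]))
                for j, c in enumerate(np.asarray(seen, dtype=int)):
                    full[:, c] = p[:, j]
                p = full
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X: np.ndarray) -> np.ndarray:
        proba = self.predict_proba(X)
        return np.array([self.classes[i] for i in proba.argmax(axis=1)])


def _encode(y: np.ndarray, classes: list[str]) -> np.ndarray:
    lut = {c: i for i, c in enumerate(classes)}
    return np.array([lut[str(v)] for v in y], dtype=int)


def fit(
    train: FeatureTable,
    model_type: str,
    hyperparams: Mapping[str, Any] | None = None,
    seed: int = 0,
) -> TrainedClassifier:
    """Fit one of the four classifiers with the given hyperparameters."""
    if model_type not in MODEL_TYPES:
        raise ValueError(f"unknown model type {model_type!r}")
    hp = dict(hyperparams or default_hyperparams(model_type))
    X = np.asarray(train.X, dtype=float)
    if np.isnan(X).any():
        raise ValueError("NaN in features")
    classes = _class_order(train.y)
    y_idx = _encode(train.y, classes)

    scaler = None
    if model_type in ("knn", "ann"):
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        scaler = (mean, sd)
        X = (X - mean) / sd

    if len(classes) == 1:
        backend = _ConstantClassifier()
    elif model_type == "knn":
        backend = _NativeKNN(n_neighbors=int(hp.get("n_neighbors", 3))).fit(
            X, y_idx, len(classes)
        )
    elif model_type == "random_forest":
        backend = RandomForestClassifier(
            n_estimators=int(hp.get("n_estimators", 500)),
            max_depth=hp.get("max_depth"),
            max_features=hp.get("max_features", "sqrt"),
            min_samples_split=int(hp.get("min_samples_split", 2)),
            min_samples_leaf=int(hp.get("min_samples_leaf", 1)),
            bootstrap=bool(hp.get("bootstrap", True)),
            random_state=seed,
            n_jobs=1,
        ).fit(X, y_idx)
    elif model_type == "xgboost":
        from xgboost import XGBClassifier

        backend = XGBClassifier(
            n_estimators=int(hp.get("n_estimators", 200)),
            learning_rate=float(hp.get("learning_rate", 0.1)),
            max_depth=int(hp.get("max_depth", 4)),
            subsample=float(hp.get("subsample", 1.0)),
            colsample_bytree=float(hp.get("colsample_bytree", 1.0)),
            min_child_weight=float(hp.get("min_child_weight", 1.0)),
            objective="multi:softprob",
            tree_method="hist",
            random_state=seed,
            n_jobs=1,
            verbosity=0,
        ).fit(X, y_idx)
    else:  # ann
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence warnings at small caps
            backend = MLPClassifier(
                hidden_layer_sizes=(int(hp.get("hidden_width", 64)),),
                activation="relu",
                max_iter=int(hp.get("max_iter", 400)),
                random_state=seed,
                early_stopping=False,
            ).fit(X, y_idx)

    return TrainedClassifier(
        model_type=model_type,
        hyperparams=hp,
        classes=classes,
        _backend=backend,
        _scaler=scaler,
    )


def default_hyperparams(model_type: str) -> dict[str, Any]:
    return {
        "xgboost": {
            "n_estimators": 200,
            "learning_rate": 0.1,
            "max_depth": 4,
            "subsample": 1.0,
            "colsample_bytree": 1.0,
            "min_child_weight": 1.0,
        },
        "random_forest": {
            "n_estimators": 500,
            "max_depth": None,
            "max_features": "sqrt",
            "min_samples_split": 2,
            "min_samples_leaf": 1,
            "bootstrap": True,
        },
        "knn": {"n_neighbors": 3},
        "ann": {"hidden_width": 64, "max_iter": 400},
    }[model_type]


def _cv_accuracy(
    table: FeatureTable,
    model_type: str,
    hp: Mapping[str, Any],
    seed: int,
    folds: int = 5,
) -> float:
    """Mean stratified k-fold CV accuracy of one hyperparameter point."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for tr, te in skf.split(table.X, table.y):
        model = fit(table.subset(tr), model_type, hp, seed=seed)
        pred = model.predict(table.X[te])
        accs.append(float((pred == table.y[te]).mean()))
    return float(np.mean(accs))


# ---------------------------------------------------------------------------
# hyperparameter search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Dim:
    """One search dimension: uniform / log-uniform / integer interval."""

    lo: float
    hi: float
    kind: str = "uniform"  # uniform | log | int

    def sample(self, rng: np.random.Generator) -> float:
        if self.kind == "log":
            return float(np.exp(rng.uniform(np.log(self.lo), np.log(self.hi))))
        v = rng.uniform(self.lo, self.hi)
        return int(round(v)) if self.kind == "int" else float(v)

    def _to(self, x: float) -> float:
        return np.log(x) if self.kind == "log" else float(x)

    def _back(self, z: float) -> float:
        v = np.exp(z) if self.kind == "log" else z
        v = min(max(v, self.lo), self.hi)
        return int(round(v)) if self.kind == "int" else float(v)

    def width(self) -> float:
        return self._to(self.hi) - self._to(self.lo)


XGB_SPACE: dict[str, _Dim] = {
    "n_estimators": _Dim(50, 300, "int"),
    "learning_rate": _Dim(0.01, 0.3, "log"),
    "max_depth": _Dim(2, 8, "int"),
    "subsample": _Dim(0.5, 1.0),
    "colsample_bytree": _Dim(0.5, 1.0),
    "min_child_weight": _Dim(1.0, 10.0, "log"),
}


def _parzen_logpdf(z: float, centers: list[float], bw: float) -> float:
    c = np.asarray(centers)
    resid = (z - c) / bw
    return float(
        np.log(np.mean(np.exp(-0.5 * resid**2) / (bw * np.sqrt(2 * np.pi))) + 1e-300)
    )


def _tpe_suggest(
    space: Mapping[str, _Dim],
    trials: list[tuple[dict[str, Any], float]],
    rng: np.random.Generator,
    n_startup: int = 5,
    gamma: float = 0.25,
    n_candidates: int = 24,
) -> dict[str, Any]:
    """One Tree-structured Parzen Estimator proposal (maximization).

    Past trials are split at the gamma quantile into good/bad sets; each
    dimension gets 1-D Parzen mixtures l(z) over good and g(z) over bad
    points; candidates are drawn from l and the candidate maximizing
    sum_dims [log l - log g] is returned."""
    if len(trials) < n_startup:
        return {n: d.sample(rng) for n, d in space.items()}
    ordered = sorted(trials, key=lambda t: -t[1])
    n_good = max(2, int(np.ceil(gamma * len(trials))))
    good = [t[0] for t in ordered[:n_good]]
    bad = [t[0] for t in ordered[n_good:]] or good

    best_cand, best_score = None, -np.inf
    for _ in range(n_candidates):
        cand: dict[str, Any] = {}
        score = 0.0
        for name, dim in space.items():
            zg = [dim._to(g[name]) for g in good]
            zb = [dim._to(b[name]) for b in bad]
            bw = max(dim.width() / max(np.sqrt(len(zg)), 1.0), 1e-6)
            center = zg[rng.integers(len(zg))]
            z = rng.normal(center, bw)
            cand[name] = dim._back(z)
            z_used = dim._to(cand[name])
            score += _parzen_logpdf(z_used, zg, bw) - _parzen_logpdf(z_used, zb, bw)
        if score > best_score:
            best_cand, best_score = cand, score
    assert best_cand is not None
    return best_cand


RF_GRID: dict[str, list[Any]] = {
    "n_estimators": [100, 300],
    "max_depth": [None, 10],
    "max_features": ["sqrt", 0.5],
    "min_samples_split": [2, 5],
    "min_samples_leaf": [1, 2],
    "bootstrap": [True, False],
}

ANN_GRID: dict[str, list[Any]] = {
    "hidden_width": [16, 32, 64, 128],
    "max_iter": [200, 400],
}


def _grid_points(grid: Mapping[str, list[Any]]) -> list[dict[str, Any]]:
    names = list(grid)
    return [dict(zip(names, vals)) for vals in product(*(grid[n] for n in names))]


def tune(
    train: FeatureTable,
    model_type: str,
    budget: int = 16,
    seed: int = 0,
    cv_folds: int = 5,
) -> dict[str, Any]:
    """Search hyperparameters for one model type (mean stratified CV accuracy).

    xgboost: TPE over six dimensions, `budget` trials.  random_forest: grid
    search over six parameters (budget-capped, seed-deterministic subset).
    knn: fixed n_neighbors = 3, no search.  ann: grid over hidden width and
    iteration cap, budget-capped."""
    if model_type not in MODEL_TYPES:
        raise ValueError(f"unknown model type {model_type!r}")
    if model_type == "knn":
        return {"n_neighbors": 3}
    if budget < 1:
        raise ValueError("budget must be >= 1")
    rng = np.random.default_rng(seed)

    if model_type == "xgboost":
        trials: list[tuple[dict[str, Any], float]] = []
        for _ in range(budget):
            hp = _tpe_suggest(XGB_SPACE, trials, rng)
            score = _cv_accuracy(train, model_type, hp, seed, folds=cv_folds)
            trials.append((hp, score))
        return max(trials, key=lambda t: t[1])[0]

    grid = RF_GRID if model_type == "random_forest" else ANN_GRID
    points = _grid_points(grid)
    if budget < len(points):
        pick = rng.choice(len(points), size=budget, replace=False)
        points = [points[i] for i in sorted(pick)]
    best_hp, best_score = None, -np.inf
    for hp in points:
        score = _cv_accuracy(train, model_type, hp, seed, folds=cv_folds)
        if score > best_score:
            best_hp, best_score = hp, score
    assert best_hp is not None
    return best_hp
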