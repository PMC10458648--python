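"""Recursive feature elimination ranked by random-forest importance.

At each step the current feature set is scored by stratified 10-fold
cross-validated accuracy of a random forest, a forest is refit on the full
data, and the feature with the lowest Gini importance is dropped (one per
iteration; importance ties break toward the lower column index).

The returned subset is chosen by the one-standard-error rule: the smallest
feature count whose mean CV score is within one standard error (of the
best size's fold scores) of the curve maximum.  A strict arg-max on the
raw curve overfits cross-validation noise — near the top the curve is
flat to within fold-to-fold scatter, so the literal maximum frequently
lands on a set still carrying uninformative features.  Pass
``tolerance=0`` for the strict arg-max (ties toward fewer features).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .synth import FeatureTable


@dataclass
class SelectionResult:
    elimination_order: list[str]  # removed features, worst first
    score_curve: dict[int, float]  # n features kept -> mean CV accuracy
    chosen_features: list[str]
    best_score: float

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "elimination_order": self.elimination_order,
                    "score_curve": {str(k): v for k, v in self.score_curve.items()},
                    "chosen_features": self.chosen_features,
                    "best_score": self.best_score,
                },
                fh,
                indent=2,
            )

    def plot(self, path) -> None:
        """Score-versus-feature-count curve (matplotlib, PNG)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        ks = sorted(self.score_curve)
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(ks, [self.score_curve[k] for k in ks], "o-", color="goldenrod")
        ax.axvline(len(self.chosen_features), ls="--", color="gray")
        ax.set_xlabel("number of features kept")
        ax.set_ylabel("mean CV accuracy")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def rf_rfe(
    table: FeatureTable,
    cv_folds: int = 10,
    seed: int = 0,
    n_trees: int = 500,
    tolerance: float | None = None,
) -> SelectionResult:
    """Random-forest recursive feature elimination with CV scoring.

    ``tolerance`` is the score slack below the curve maximum within which
    a smaller feature set is preferred; ``None`` (default) uses one
    standard error of the best size's fold scores, ``0`` the strict
    arg-max with ties toward fewer features.
    """
    if table.m < 1:
        raise ValueError("no features")
    if len(np.unique(table.y)) < 2:
        raise ValueError("constant labels: nothing to select for")
    if table.n < cv_folds:
        raise ValueError("need at least cv_folds samples")

    active = list(range(table.m))
    names = list(table.feature_names)
    curve: dict[int, float] = {}
    fold_scores: dict[int, np.ndarray] = {}
    eliminated: list[str] = []
    subsets: dict[int, list[int]] = {}

    while active:
        rf = RandomForestClassifier(
            n_estimators=n_trees, random_state=seed, n_jobs=1
        )
        cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        scores = cross_val_score(
            rf, table.X[:, active], table.y, cv=cv, scoring="accuracy", n_jobs=1
        )
        curve[len(active)] = float(scores.mean())
        fold_scores[len(active)] = scores
        subsets[len(active)] = list(active)
        if len(active) == 1:
            break
        rf.fit(table.X[:, active], table.y)
        worst = int(np.argmin(rf.feature_importances_))  # ties -> lowest index
        eliminated.append(names[active[worst]])
        del active[worst]

    best_k = min(
        (k for k in curve), key=lambda k: (-curve[k], k)
    )  # max score, ties toward fewer features
    best_score = curve[best_k]
    if tolerance is None:
        folds = fold_scores[best_k]
        tolerance = float(np.std(folds, ddof=1) / np.sqrt(len(folds)))
    chosen_k = min(
        (k for k in curve if curve[k] >= best_score - tolerance - 1e-12),
        default=best_k,
    )
    return SelectionResult(
        elimination_order=eliminated,
        score_curve=curve,
        chosen_features=[names[i] for i in subsets[chosen_k]],
        best_score=best_score,
    )
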