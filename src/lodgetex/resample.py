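"""Native class-imbalance treatments: SMOTE and its composites.

Implements the SMOTE core (segment interpolation between a minority point
and one of its k minority neighbours), Tomek-link detection, edited
nearest-neighbour (ENN) cleaning, and the five composite plans used in the
lodging study: SMOTE-Tomek, SMOTE-ENN, Borderline-SMOTE (variant 1),
SMOTE-NC and ADASYN.  All oversampling plans equalize minority classes to
the majority count; SMOTE-ENN then edits every class, so its output is
deliberately NOT balanced (the majority can end up smallest).  Synthetic
rows carry provenance "synthetic".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .synth import FeatureTable

METHODS = ("smote_tomek", "smote_enn", "borderline_smote", "smote_nc", "adasyn")


@dataclass(frozen=True)
class ResamplePlan:
    method: str
    k_smote: int = 5
    k_edit: int = 3
    seed: int = 0
    nominal_columns: tuple[int, ...] = ()  # only meaningful for smote_nc

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown resampling method {self.method!r}")
        if self.k_smote < 1 or self.k_edit < 1:
            raise ValueError("neighbor counts must be >= 1")


def _pairwise_sq_dists(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    aa = (A * A).sum(axis=1)[:, None]
    bb = (B * B).sum(axis=1)[None, :]
    return np.maximum(aa + bb - 2.0 * (A @ B.T), 0.0)


def _knn_indices(X: np.ndarray, query: np.ndarray, k: int, exclude_self: bool) -> np.ndarray:
    """Indices (into X) of the k nearest neighbours of each query row.
    Ties broken toward the lowest index via stable argsort."""
    d = _pairwise_sq_dists(query, X)
    if exclude_self:
        # queries are rows of X in the same order
        np.fill_diagonal(d, np.inf)
    order = np.argsort(d, axis=1, kind="stable")
    return order[:, :k]


def smote(
    table: FeatureTable,
    minority_class: str,
    n_new: int,
    k: int = 5,
    seed: int | np.random.Generator = 0,
) -> FeatureTable:
    """Append n_new synthetic rows for one minority class.

    Each synthetic row is x + lambda (y - x) with x a random minority row,
    y one of its k nearest minority neighbours (Euclidean) and
    lambda ~ U[0,1]; k is capped at class size - 1.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_new == 0:
        return table
    idx = np.flatnonzero(table.y == minority_class)
    if len(idx) < 2:
        raise ValueError(
            f"class {minority_class!r} has {len(idx)} sample(s); SMOTE needs >= 2"
        )
    Xm = table.X[idx]
    k = min(k, len(idx) - 1)
    nn = _knn_indices(Xm, Xm, k, exclude_self=True)

    base = rng.integers(0, len(idx), size=n_new)
    pick = rng.integers(0, k, size=n_new)
    lam = rng.uniform(0.0, 1.0, size=n_new)
    x = Xm[base]
    y = Xm[nn[base, pick]]
    new_X = x + lam[:, None] * (y - x)
    return _append(table, new_X, minority_class)


def _append(table: FeatureTable, new_X: np.ndarray, label: str) -> FeatureTable:
    n_new = len(new_X)
    start = int(len(table.y))
    return FeatureTable(
        feature_names=list(table.feature_names),
        X=np.vstack([table.X, new_X]),
        y=np.concatenate([table.y, np.full(n_new, label, dtype=table.y.dtype)]),
        provenance=np.concatenate([table.provenance, np.full(n_new, "synthetic")]),
        ids=np.concatenate(
            [table.ids, np.array([f"syn{start + i:05d}" for i in range(n_new)])]
        ),
    )


def tomek_links(table: FeatureTable) -> list[tuple[int, int]]:
    """All (a, b) index pairs, a < b, of opposite-class mutual nearest
    neighbours.  Distance ties break toward the lowest index."""
    X, y = table.X, table.y
    if len(np.unique(y)) < 2:
        return []
    nn1 = _knn_indices(X, X, 1, exclude_self=True)[:, 0]
    links = []
    for a in range(len(y)):
        b = int(nn1[a])
        if b > a and int(nn1[b]) == a and y[a] != y[b]:
            links.append((a, b))
    return links


def enn_edit(table: FeatureTable, k: int = 3) -> np.ndarray:
    """Indices of samples whose class disagrees with the majority vote of
    their k nearest neighbours (self excluded).  Vote ties keep the sample."""
    X, y = table.X, table.y
    if len(y) <= k:
        raise ValueError("ENN needs more samples than neighbours")
    nn = _knn_indices(X, X, k, exclude_self=True)
    marked = []
    for i in range(len(y)):
        votes = y[nn[i]]
        labels, counts = np.unique(votes, return_counts=True)
        top = counts.max()
        winners = labels[counts == top]
        if len(winners) == 1 and winners[0] != y[i]:
            marked.append(i)
    return np.array(marked, dtype=int)


def _majority_class(table: FeatureTable) -> tuple[str, int]:
    counts = table.class_counts()
    cls = max(counts, key=lambda c: counts[c])
    return cls, counts[cls]


def _smote_equalize(
    table: FeatureTable, k: int, rng: np.random.Generator
) -> FeatureTable:
    """Oversample every minority class up to the majority count."""
    _, target = _majority_class(table)
    out = table
    for cls, cnt in table.class_counts().items():
        if cnt < target:
            out = smote(out, cls, target - cnt, k=k, seed=rng)
    return out


def _borderline_smote(
    table: FeatureTable, k: int, rng: np.random.Generator
) -> FeatureTable:
    """Borderline-SMOTE1: synthesize only from 'danger' minority seeds —
    points with at least half, but not all, of their k whole-data neighbours
    in other classes.  Falls back to all minority points for a class with no
    danger seeds."""
    _, target = _majority_class(table)
    out = table
    nn_all = _knn_indices(table.X, table.X, k, exclude_self=True)
    for cls, cnt in table.class_counts().items():
        if cnt >= target:
            continue
        idx = np.flatnonzero(table.y == cls)
        other = (table.y[nn_all[idx]] != cls).sum(axis=1)
        danger = idx[(other >= k / 2) & (other < k)]
        seeds = danger if len(danger) >= 2 else idx
        out = _smote_from_seeds(out, table, cls, seeds, target - cnt, k, rng)
    return out


def _smote_from_seeds(
    out: FeatureTable,
    original: FeatureTable,
    cls: str,
    seed_idx: np.ndarray,
    n_new: int,
    k: int,
    rng: np.random.Generator,
) -> FeatureTable:
    """SMOTE interpolation anchored at given seed rows, neighbours searched
    among ALL real rows of the class in `original`."""
    if n_new <= 0:
        return out
    cls_idx = np.flatnonzero(original.y == cls)
    Xc = original.X[cls_idx]
    if len(cls_idx) < 2:
        raise ValueError(f"class {cls!r} has fewer than 2 samples")
    kk = min(k, len(cls_idx) - 1)
    Xs = original.X[seed_idx]
    d = _pairwise_sq_dists(Xs, Xc)
    # a seed is its own neighbour at distance 0: mask it out
    for r, s in enumerate(seed_idx):
        hit = np.flatnonzero(cls_idx == s)
        if hit.size:
            d[r, hit[0]] = np.inf
    nn = np.argsort(d, axis=1, kind="stable")[:, :kk]

    base = rng.integers(0, len(seed_idx), size=n_new)
    pick = rng.integers(0, kk, size=n_new)
    lam = rng.uniform(0.0, 1.0, size=n_new)
    x = Xs[base]
    y = Xc[nn[base, pick]]
    return _append(out, x + lam[:, None] * (y - x), cls)


def _adasyn(table: FeatureTable, k: int, rng: np.random.Generator) -> FeatureTable:
    """Synthetic budget per minority point proportional to the fraction of
    other-class points among its k whole-data neighbours; totals chosen to
    approximately equalize each class with the majority."""
    _, target = _majority_class(table)
    out = table
    nn_all = _knn_indices(table.X, table.X, k, exclude_self=True)
    for cls, cnt in table.class_counts().items():
        G = target - cnt
        if G <= 0:
            continue
        idx = np.flatnonzero(table.y == cls)
        r = (table.y[nn_all[idx]] != cls).sum(axis=1).astype(float)
        if r.sum() == 0:
            r = np.ones_like(r)
        r /= r.sum()
        g = np.floor(r * G + 0.5).astype(int)  # per-point budget, ~G total
        cls_idx = np.flatnonzero(table.y == cls)
        Xc = table.X[cls_idx]
        kk = min(k, len(cls_idx) - 1)
        nn_min = _knn_indices(Xc, Xc, kk, exclude_self=True)
        pos_of = {int(v): p for p, v in enumerate(cls_idx)}
        new_rows = []
        for point, budget in zip(idx, g):
            p = pos_of[int(point)]
            for _ in range(int(budget)):
                j = nn_min[p, rng.integers(0, kk)]
                lam = rng.uniform()
                new_rows.append(Xc[p] + lam * (Xc[j] - Xc[p]))
        if new_rows:
            out = _append(out, np.asarray(new_rows), cls)
    return out


def _smote_nc(
    table: FeatureTable,
    k: int,
    rng: np.random.Generator,
    nominal_columns: Sequence[int],
) -> FeatureTable:
    """SMOTE-NC: nominal-feature-aware SMOTE.  Nominal mismatches add the
    squared median-of-continuous-standard-deviations penalty to the distance;
    synthetic nominal values take the mode among the k neighbours; continuous
    values interpolate as in SMOTE.  With no nominal columns this is exactly
    the plain SMOTE equalization (same code path, same draws)."""
    nominal = sorted(set(int(c) for c in nominal_columns))
    if not nominal:
        return _smote_equalize(table, k, rng)

    cont = [c for c in range(table.m) if c not in nominal]
    med_sd = float(np.median(np.std(table.X[:, cont], axis=0))) if cont else 1.0
    penalty = med_sd**2

    _, target = _majority_class(table)
    out = table
    for cls, cnt in table.class_counts().items():
        n_new = target - cnt
        if n_new <= 0:
            continue
        idx = np.flatnonzero(table.y == cls)
        if len(idx) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples")
        Xm = table.X[idx]
        kk = min(k, len(idx) - 1)
        d = _pairwise_sq_dists(Xm[:, cont], Xm[:, cont]) if cont else np.zeros(
            (len(idx), len(idx))
        )
        for c in nominal:
            d += penalty * (Xm[:, c][:, None] != Xm[:, c][None, :])
        np.fill_diagonal(d, np.inf)
        nn = np.argsort(d, axis=1, kind="stable")[:, :kk]

        base = rng.integers(0, len(idx), size=n_new)
        pick = rng.integers(0, kk, size=n_new)
        lam = rng.uniform(0.0, 1.0, size=n_new)
        x = Xm[base]
        y = Xm[nn[base, pick]]
        new_X = x + lam[:, None] * (y - x)
        for c in nominal:
            for r in range(n_new):
                votes = Xm[nn[base[r]], c]
                vals, counts = np.unique(votes, return_counts=True)
                new_X[r, c] = vals[np.argmax(counts)]
        out = _append(out, new_X, cls)
    return out


def apply_resample(table: FeatureTable, plan: ResamplePlan) -> FeatureTable:
    """Apply one of the five imbalance treatments (training data only)."""
    rng = np.random.default_rng(plan.seed)
    if plan.method == "smote_tomek":
        over = _smote_equalize(table, plan.k_smote, rng)
        links = tomek_links(over)
        majority, _ = _majority_class(table)
        drop = {a if over.y[a] == majority else b
                for a, b in links
                if majority in (over.y[a], over.y[b])}
        keep = np.setdiff1d(np.arange(over.n), np.array(sorted(drop), dtype=int))
        return over.subset(keep)
    if plan.method == "smote_enn":
        over = _smote_equalize(table, plan.k_smote, rng)
        marked = enn_edit(over, k=plan.k_edit)
        keep = np.setdiff1d(np.arange(over.n), marked)
        return over.subset(keep)
    if plan.method == "borderline_smote":
        return _borderline_smote(table, plan.k_smote, rng)
    if plan.method == "adasyn":
        return _adasyn(table, plan.k_smote, rng)
    if plan.method == "smote_nc":
        return _smote_nc(table, plan.k_smote, rng, plan.nominal_columns)
    raise ValueError(f"unknown resampling method {plan.method!r}")
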