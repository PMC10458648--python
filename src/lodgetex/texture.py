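"""Gray-level co-occurrence matrices and the 14 Haralick texture features.

A GLCM tallies ordered pairs of quantized gray levels at a fixed pixel
offset, restricted to pixel pairs that both fall inside the canopy mask;
the symmetric form adds the transposed tally.  One matrix is built per
angle (0, 45, 90, 135 degrees at distance d), the matrices are averaged
for rotation robustness, and the 14 classical scalar statistics are
computed from the averaged matrix.

Conventions (documented because Haralick's originals are 1-based):
gray levels are 0-based (0..Ng-1); the sum distribution p_{x+y} is indexed
k = 0..2Ng-2 and the absolute-difference distribution p_{x-y} is indexed
k = 0..Ng-1; logarithms are base 2 with 0·log 0 := 0.  Sum variance uses
f8 = sum entropy as its centring constant, following Haralick's original
definition.  "Variance" centres on the grand mean level mu = sum_i i p_x(i).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .synth import FeatureTable

log = logging.getLogger(__name__)

FEATURE_NAMES: tuple[str, ...] = (
    "angular_second_moment",
    "contrast",
    "correlation",
    "variance",
    "inverse_difference_moment",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "info_measure_I",
    "info_measure_II",
    "max_correlation_coefficient",
)

ANGLES_DEG: tuple[int, ...] = (0, 45, 90, 135)

# row/col steps for each angle at unit distance (image convention: row down)
_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

_VALID_NG = (4, 8, 16, 32, 64)


class DegenerateGLCMError(ValueError):
    """Raised when fewer than two valid pixel pairs exist for the offset."""


def quantize(gray: np.ndarray, levels: int) -> np.ndarray:
    """Equal-width quantization of an 8-bit image to `levels` gray levels:
    level = floor(value * levels / 256), in [0, levels-1]."""
    if levels not in _VALID_NG:
        raise ValueError(f"levels must be one of {_VALID_NG}, got {levels}")
    gray = np.asarray(gray)
    return (gray.astype(np.int64) * levels // 256).astype(np.uint8)


def _xlog2(p: np.ndarray) -> np.ndarray:
    """p * log2(p) with 0 log 0 := 0."""
    out = np.zeros_like(p, dtype=float)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


@dataclass
class GLCMatrix:
    """Normalized (optionally symmetric) co-occurrence matrix with the
    marginal and derived distributions the Haralick statistics need."""

    P: np.ndarray  # Ng x Ng, sums to 1
    levels: int
    distance: int = 1
    angle: float | None = None  # degrees; None for an angle average
    symmetric: bool = True

    px: np.ndarray = field(init=False)
    py: np.ndarray = field(init=False)
    p_sum: np.ndarray = field(init=False)  # p_{x+y}, k = 0..2Ng-2
    p_diff: np.ndarray = field(init=False)  # p_{|x-y|}, k = 0..Ng-1

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        ng = self.levels
        if self.P.shape != (ng, ng):
            raise ValueError("P must be Ng x Ng")
        total = self.P.sum()
        if not np.isclose(total, 1.0, atol=1e-12):
            raise ValueError(f"GLCM must be normalized (sum {total})")
        if (self.P < 0).any():
            raise ValueError("GLCM entries must be non-negative")
        self.px = self.P.sum(axis=1)
        self.py = self.P.sum(axis=0)
        i = np.arange(ng)
        sums = i[:, None] + i[None, :]
        diffs = np.abs(i[:, None] - i[None, :])
        self.p_sum = np.bincount(sums.ravel(), weights=self.P.ravel(), minlength=2 * ng - 1)
        self.p_diff = np.bincount(diffs.ravel(), weights=self.P.ravel(), minlength=ng)

    # -- moments and entropies of the marginals ---------------------------
    @property
    def mu_x(self) -> float:
        return float(np.arange(self.levels) @ self.px)

    @property
    def mu_y(self) -> float:
        return float(np.arange(self.levels) @ self.py)

    @property
    def sigma_x(self) -> float:
        i = np.arange(self.levels)
        return float(np.sqrt(((i - self.mu_x) ** 2) @ self.px))

    @property
    def sigma_y(self) -> float:
        i = np.arange(self.levels)
        return float(np.sqrt(((i - self.mu_y) ** 2) @ self.py))

    @property
    def HX(self) -> float:
        return float(-_xlog2(self.px).sum())

    @property
    def HY(self) -> float:
        return float(-_xlog2(self.py).sum())

    @property
    def HXY1(self) -> float:
        outer = self.px[:, None] * self.py[None, :]
        mask = (self.P > 0) & (outer > 0)
        return float(-(self.P[mask] * np.log2(outer[mask])).sum())

    @property
    def HXY2(self) -> float:
        outer = self.px[:, None] * self.py[None, :]
        return float(-_xlog2(outer).sum())

    def Q(self) -> np.ndarray:
        """Matrix whose second-largest eigenvalue gives the maximal
        correlation coefficient, restricted to levels with nonzero marginals:
        Q(i,j) = sum_k p(i,k) p(j,k) / (p_x(i) p_y(k))."""
        keep = (self.px > 0) & (self.py > 0)
        P = self.P[np.ix_(keep, keep)]
        px = self.px[keep]
        py = self.py[keep]
        return (P / px[:, None]) @ (P / py[None, :]).T


def compute_glcm(
    quantized: np.ndarray,
    mask: np.ndarray | None = None,
    distance: int = 1,
    angle: int = 0,
    symmetric: bool = True,
    normalize: bool = True,
    levels: int | None = None,
) -> GLCMatrix:
    """Count co-occurring level pairs at the given offset, both pixels inside
    the mask; raises DegenerateGLCMError with fewer than two valid pairs.
    `levels` defaults to the smallest standard gray-level count that fits
    the data; pass it explicitly for cross-image comparability."""
    if distance < 1:
        raise ValueError("distance must be >= 1")
    if angle not in _OFFSETS:
        raise ValueError(f"angle must be one of {tuple(_OFFSETS)}")
    q = np.asarray(quantized)
    if levels is None:
        fitting = [ng for ng in _VALID_NG if ng >= int(q.max()) + 1]
        if not fitting:
            raise ValueError(
                f"values up to {int(q.max())} exceed the largest standard "
                f"gray-level count {_VALID_NG[-1]}; quantize the image first"
            )
        levels = fitting[0]
    elif int(q.max()) >= levels:
        raise ValueError("quantized values exceed the stated gray-level count")
    if mask is None:
        mask = np.ones(q.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)

    dr, dc = (_OFFSETS[angle][0] * distance, _OFFSETS[angle][1] * distance)
    h, w = q.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    if r0 >= r1 or c0 >= c1:
        raise DegenerateGLCMError("offset larger than image")

    a = q[r0:r1, c0:c1]
    b = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    valid = mask[r0:r1, c0:c1] & mask[r0 + dr : r1 + dr, c0 + dc : c1 + dc]

    counts = np.zeros((levels, levels), dtype=np.int64)
    np.add.at(counts, (a[valid], b[valid]), 1)
    if symmetric:
        counts = counts + counts.T
    total = counts.sum()
    if total < 2:
        raise DegenerateGLCMError(
            f"only {total} valid pixel pair(s) at distance {distance}, angle {angle}"
        )
    P = counts.astype(float)
    if normalize:
        P /= total
    return GLCMatrix(
        P=P, levels=levels, distance=distance, angle=angle, symmetric=symmetric
    )


def average_glcms(glcms: Sequence[GLCMatrix]) -> GLCMatrix:
    """Element-wise mean of co-occurrence matrices (rotation-robust pooling)."""
    if not glcms:
        raise ValueError("no GLCMs to average")
    levels = {g.levels for g in glcms}
    if len(levels) != 1:
        raise ValueError(f"mixed gray-level counts {sorted(levels)}")
    P = np.mean([g.P for g in glcms], axis=0)
    return GLCMatrix(
        P=P,
        levels=glcms[0].levels,
        distance=glcms[0].distance,
        angle=None,
        symmetric=all(g.symmetric for g in glcms),
    )


@dataclass
class TextureFeatureVector:
    values: dict[str, float]
    degenerate: bool = False  # constant-image correlation degeneracy

    def as_array(self) -> np.ndarray:
        return np.array([self.values[n] for n in FEATURE_NAMES])

    def __getitem__(self, name: str) -> float:
        return self.values[name]


def haralick_features(G: GLCMatrix) -> TextureFeatureVector:
    """All 14 Haralick statistics of one GLCM (see module docstring for the
    indexing and logarithm conventions)."""
    ng = G.levels
    i = np.arange(ng)
    P = G.P
    k_sum = np.arange(2 * ng - 1)
    k_diff = np.arange(ng)

    asm = float((P**2).sum())
    contrast = float((k_diff**2) @ G.p_diff)

    degenerate = False
    sx, sy = G.sigma_x, G.sigma_y
    if sx * sy > 0:
        ij = np.outer(i, i)
        correlation = float(((ij * P).sum() - G.mu_x * G.mu_y) / (sx * sy))
    else:
        correlation = 0.0
        degenerate = True

    mu = G.mu_x  # grand mean level
    variance = float((((i[:, None] - mu) ** 2) * P).sum())
    idm = float((P / (1.0 + (i[:, None] - i[None, :]) ** 2)).sum())

    sum_average = float(k_sum @ G.p_sum)
    sum_entropy = float(-_xlog2(G.p_sum).sum())
    sum_variance = float(((k_sum - sum_entropy) ** 2) @ G.p_sum)

    entropy = float(-_xlog2(P).sum())

    d_mean = float(k_diff @ G.p_diff)
    difference_variance = float((k_diff**2) @ G.p_diff - d_mean**2)
    difference_entropy = float(-_xlog2(G.p_diff).sum())

    hx, hy, hxy1, hxy2 = G.HX, G.HY, G.HXY1, G.HXY2
    denom = max(hx, hy)
    info_I = float((entropy - hxy1) / denom) if denom > 0 else 0.0
    info_II = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    Q = G.Q()
    if Q.shape[0] < 2:
        mcc = 0.0
        degenerate = True
    else:
        eig = np.sort(np.real(np.linalg.eigvals(Q)))[::-1]
        mcc = float(np.sqrt(np.clip(eig[1], 0.0, 1.0)))

    values = dict(
        zip(
            FEATURE_NAMES,
            (
                asm,
                contrast,
                correlation,
                variance,
                idm,
                sum_average,
                sum_variance,
                sum_entropy,
                entropy,
                difference_variance,
                difference_entropy,
                info_I,
                info_II,
                mcc,
            ),
        )
    )
    return TextureFeatureVector(values=values, degenerate=degenerate)


@dataclass(frozen=True)
class GLCMParams:
    """Quantization levels, pixel distance and the angles to average."""

    levels: int = 16
    distance: int = 1
    angles: tuple[int, ...] = ANGLES_DEG


def extract_plot_features(
    roi: np.ndarray,
    mask: np.ndarray | None = None,
    params: GLCMParams | None = None,
) -> TextureFeatureVector:
    """quantize -> one GLCM per angle -> average -> 14 Haralick features."""
    p = params or GLCMParams()
    q = quantize(roi, p.levels)
    glcms = [
        compute_glcm(q, mask=mask, distance=p.distance, angle=a, levels=p.levels)
        for a in p.angles
    ]
    return haralick_features(average_glcms(glcms))


def extract_feature_table(
    rois_masks: Sequence[tuple[str, np.ndarray, np.ndarray | None, str]],
    params: GLCMParams | None = None,
) -> FeatureTable:
    """Feature table for (plot_id, roi, mask, class_label) tuples; plots whose
    GLCM is degenerate (e.g. empty mask) are skipped and logged."""
    ids, rows, labels = [], [], []
    skipped = []
    for plot_id, roi, mask, label in rois_masks:
        try:
            fv = extract_plot_features(roi, mask, params)
        except DegenerateGLCMError as exc:
            skipped.append(plot_id)
            log.warning("skipping plot %s: %s", plot_id, exc)
            continue
        ids.append(plot_id)
        rows.append(fv.as_array())
        labels.append(label)
    if skipped:
        log.info("skipped %d plot(s): %s", len(skipped), skipped)
    if not rows:
        raise ValueError("no plots yielded features")
    return FeatureTable(
        feature_names=list(FEATURE_NAMES),
        X=np.vstack(rows),
        y=np.array(labels),
        provenance=np.full(len(rows), "original"),
        ids=np.array(ids),
    )
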