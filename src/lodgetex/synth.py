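"""Synthetic breeding-field generator.

Emulates an orthomosaic of four-row soybean plots on a soil background, with
four lodging classes (NL < ML < HL < SL) whose canopy texture grows more
heterogeneous with lodging severity: erect canopies image as uniform fine
grain, while lodged canopies show oriented stem streaks and exposed-soil
gaps.  The generator is the testbed for the whole pipeline — no field
dataset is bundled — so its contracts (exact class histograms, seed
determinism, monotone texture heterogeneity) are first-class and tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

CLASS_ORDER: tuple[str, ...] = ("NL", "ML", "HL", "SL")

#: admissible visual lodging scores per class (1–5 scale, 0.5 steps)
SCORE_SETS: dict[str, tuple[float, ...]] = {
    "NL": (1.0, 1.5),
    "ML": (2.0, 2.5),
    "HL": (3.0, 3.5),
    "SL": (4.0, 4.5, 5.0),
}

#: the study's original class counts (1266 plots total)
ORIGINAL_CLASS_COUNTS: dict[str, int] = {"NL": 964, "ML": 206, "HL": 85, "SL": 11}

#: small-scale counts used for quick end-to-end runs; keeps strong imbalance
#: while every class survives a stratified 80/20 split and k-NN oversampling
SMALL_CLASS_COUNTS: dict[str, int] = {"NL": 90, "ML": 22, "HL": 12, "SL": 6}


class InvalidScoreError(ValueError):
    """Lodging score outside the 1–5, 0.5-increment visual scale."""


def score_to_class(score: float) -> str:
    """Map a visual lodging score (1.0–5.0 in 0.5 steps) to its class label.

    NL covers {1.0, 1.5}, ML {2.0, 2.5}, HL {3.0, 3.5}, SL {4.0, 4.5, 5.0}.
    """
    for cls, scores in SCORE_SETS.items():
        if any(abs(score - s) < 1e-9 for s in scores):
            return cls
    raise InvalidScoreError(
        f"score {score!r} is not on the 1-5 scale with 0.5 increments"
    )


@dataclass(frozen=True)
class TextureParams:
    """Per-class appearance parameters for one plot patch.

    canopy_level/soil_level are mean 8-bit intensities; grain_sd is the
    fine-grain noise scale; streak_amp the amplitude of oriented lodging
    streaks; blotch_fraction the expected exposed-soil area fraction.
    """

    canopy_level: float = 170.0
    soil_level: float = 70.0
    grain_sd: float = 4.0
    streak_amp: float = 0.0
    streak_period: float = 8.0
    blotch_fraction: float = 0.0


# heterogeneity strictly increases NL -> SL; soil gaps open up as plants
# fall; canopy intensities stay well above soil so the two-phase
# segmentation separates exposed soil rather than lodging streaks
DEFAULT_TEXTURE_PARAMS: dict[str, TextureParams] = {
    "NL": TextureParams(grain_sd=4.0, streak_amp=0.0, blotch_fraction=0.0),
    "ML": TextureParams(grain_sd=7.0, streak_amp=12.0, blotch_fraction=0.06),
    "HL": TextureParams(grain_sd=10.0, streak_amp=18.0, blotch_fraction=0.16),
    "SL": TextureParams(grain_sd=16.0, streak_amp=25.0, blotch_fraction=0.32),
}


@dataclass(frozen=True)
class PlotRecord:
    """One breeding plot: bounding box (0-based, half-open), score and class."""

    plot_id: str
    bbox: tuple[int, int, int, int]  # row0, col0, row1, col1
    score: float
    lodging_class: str

    def __post_init__(self) -> None:
        if self.lodging_class != score_to_class(self.score):
            raise ValueError(
                f"class {self.lodging_class} inconsistent with score {self.score}"
            )


@dataclass
class FieldConfig:
    """Layout and appearance of a synthetic field image."""

    class_counts: Mapping[str, int] = field(
        default_factory=lambda: dict(ORIGINAL_CLASS_COUNTS)
    )
    plot_shape: tuple[int, int] = (40, 56)  # rows, cols of one plot patch
    gap: int = 12  # inter-plot spacing, pixels
    margin: int = 16  # field border, pixels
    texture_params: Mapping[str, TextureParams] = field(
        default_factory=lambda: dict(DEFAULT_TEXTURE_PARAMS)
    )
    soil_level: float = 70.0
    soil_grain_sd: float = 6.0
    rgb: bool = False  # 3-band mode: green canopy on brown soil
    rng_seed: int = 0

    @property
    def n_plots(self) -> int:
        return int(sum(self.class_counts.values()))

    def validate(self) -> None:
        if any(c < 0 for c in self.class_counts.values()):
            raise ValueError("class counts must be non-negative")
        if self.n_plots == 0:
            raise ValueError("no plots requested")
        if min(self.plot_shape) < 16:
            raise ValueError("plot patches must be at least 16x16")
        unknown = set(self.class_counts) - set(CLASS_ORDER)
        if unknown:
            raise ValueError(f"unknown classes {sorted(unknown)}")


def generate_plot_texture(
    cls: str,
    shape: tuple[int, int],
    seed: int | np.random.Generator,
    params: TextureParams | None = None,
    return_truth: bool = False,
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Render one plot patch (8-bit grayscale) for a lodging class.

    The texture model is additive: canopy base level + Gaussian grain +
    an oriented sinusoidal streak field (lodged stems) with per-patch random
    orientation and phase; exposed-soil blotches are cut in by thresholding
    smoothed noise at the class's blotch fraction.  With all heterogeneity
    parameters at zero the patch is constant.

    With ``return_truth=True`` also returns the boolean canopy mask (True
    where the pixel is canopy rather than exposed soil).
    """
    if cls not in CLASS_ORDER:
        raise ValueError(f"unknown lodging class {cls!r}")
    if min(shape) < 16:
        raise ValueError("patch must be at least 16x16")
    p = params if params is not None else DEFAULT_TEXTURE_PARAMS[cls]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    rows, cols = shape
    img = np.full(shape, p.canopy_level, dtype=float)
    if p.grain_sd > 0:
        img += rng.normal(0.0, p.grain_sd, size=shape)

    if p.streak_amp > 0:
        theta = rng.uniform(0, np.pi)
        phase = rng.uniform(0, 2 * np.pi)
        rr, cc = np.mgrid[0:rows, 0:cols]
        coord = rr * np.cos(theta) + cc * np.sin(theta)
        img += p.streak_amp * np.sin(2 * np.pi * coord / p.streak_period + phase)

    canopy = np.ones(shape, dtype=bool)
    if p.blotch_fraction > 0:
        canopy = ~_blotch_mask(shape, p.blotch_fraction, rng)
        img[~canopy] = p.soil_level + rng.normal(0.0, 5.0, size=int((~canopy).sum()))

    patch = np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)
    return (patch, canopy) if return_truth else patch


def _blotch_mask(
    shape: tuple[int, int], fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Smooth-noise threshold mask covering ~`fraction` of the patch."""
    from scipy.ndimage import gaussian_filter

    noise = gaussian_filter(rng.normal(size=shape), sigma=3.0)
    thresh = np.quantile(noise, 1.0 - fraction)
    return noise > thresh


def _scores_for(cls: str, n: int, rng: np.random.Generator) -> np.ndarray:
    return rng.choice(SCORE_SETS[cls], size=n)


def generate_field(
    config: FieldConfig,
) -> tuple[np.ndarray, list[PlotRecord]]:
    """Generate a field image and its plot records.

    Plots are laid out row-major on a near-square grid with `gap` spacing on
    a soil-textured background; class labels are shuffled across positions.
    Identical config + seed gives bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    n = config.n_plots
    ph, pw = config.plot_shape

    ncols = int(np.ceil(np.sqrt(n)))
    nrows = int(np.ceil(n / ncols))
    H = config.margin * 2 + nrows * ph + (nrows - 1) * config.gap
    W = config.margin * 2 + ncols * pw + (ncols - 1) * config.gap

    soil = config.soil_level + rng.normal(0.0, config.soil_grain_sd, size=(H, W))
    img = np.clip(np.floor(soil + 0.5), 0, 255).astype(np.uint8)

    labels: list[str] = []
    for cls in CLASS_ORDER:
        labels.extend([cls] * int(config.class_counts.get(cls, 0)))
    labels_arr = np.array(labels)
    rng.shuffle(labels_arr)

    records: list[PlotRecord] = []
    for idx, cls in enumerate(labels_arr):
        r, c = divmod(idx, ncols)
        r0 = config.margin + r * (ph + config.gap)
        c0 = config.margin + c * (pw + config.gap)
        patch = generate_plot_texture(
            str(cls), (ph, pw), rng, params=config.texture_params[str(cls)]
        )
        img[r0 : r0 + ph, c0 : c0 + pw] = patch
        score = float(_scores_for(str(cls), 1, rng)[0])
        records.append(
            PlotRecord(
                plot_id=f"plot{idx:04d}",
                bbox=(r0, c0, r0 + ph, c0 + pw),
                score=score,
                lodging_class=str(cls),
            )
        )

    if config.rgb:
        img = _tint_rgb(img, config)
    return img, records


def _tint_rgb(gray: np.ndarray, config: FieldConfig) -> np.ndarray:
    """Map intensity to a green-canopy / brown-soil 3-band image."""
    g = gray.astype(float) / 255.0
    # soil ~ brown (120, 90, 60), canopy ~ green (60, 160, 60); blend on intensity
    t = np.clip((gray.astype(float) - config.soil_level) / 80.0, 0, 1)
    r = (1 - t) * 120 + t * 60 * (g * 2)
    gch = (1 - t) * 90 + t * 200 * g
    b = (1 - t) * 60 + t * 60 * g
    rgb = np.stack([r, gch, b], axis=-1)
    return np.clip(np.floor(rgb + 0.5), 0, 255).astype(np.uint8)


@dataclass
class FeatureTable:
    """n plots x m named features with class labels and provenance flags."""

    feature_names: list[str]
    X: np.ndarray
    y: np.ndarray
    provenance: np.ndarray  # per-row {"original", "synthetic"}
    ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        self.provenance = np.asarray(self.provenance)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        n, m = self.X.shape
        if len(self.feature_names) != m:
            raise ValueError("feature_names length must match X columns")
        if len(self.y) != n or len(self.provenance) != n:
            raise ValueError("y/provenance length must match X rows")
        if np.isnan(self.X).any():
            raise ValueError("missing values in feature matrix")
        if self.ids is None:
            self.ids = np.arange(n)
        else:
            self.ids = np.asarray(self.ids)
            if len(self.ids) != n:
                raise ValueError("ids length must match X rows")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def m(self) -> int:
        return self.X.shape[1]

    def class_counts(self) -> dict[str, int]:
        labels, counts = np.unique(self.y, return_counts=True)
        out = {str(k): int(v) for k, v in zip(labels, counts)}
        ordered = {c: out[c] for c in CLASS_ORDER if c in out}
        ordered.update({k: v for k, v in out.items() if k not in ordered})
        return ordered

    def subset(self, idx: np.ndarray | Sequence[int]) -> "FeatureTable":
        idx = np.asarray(idx)
        return FeatureTable(
            feature_names=list(self.feature_names),
            X=self.X[idx],
            y=self.y[idx],
            provenance=self.provenance[idx],
            ids=self.ids[idx],
        )

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.X, columns=self.feature_names)
        df.insert(0, "plot_id", self.ids)
        df["class"] = self.y
        df["provenance"] = self.provenance
        return df

    @classmethod
    def from_dataframe(cls, df) -> "FeatureTable":
        meta = [c for c in ("plot_id", "score", "class", "provenance") if c in df]
        names = [c for c in df.columns if c not in meta]
        return cls(
            feature_names=names,
            X=df[names].to_numpy(dtype=float),
            y=df["class"].to_numpy(),
            provenance=(
                df["provenance"].to_numpy()
                if "provenance" in df
                else np.full(len(df), "original")
            ),
            ids=df["plot_id"].to_numpy() if "plot_id" in df else None,
        )


def generate_feature_table(
    class_counts: Mapping[str, int],
    class_means: Mapping[str, Sequence[float]],
    class_covs: Mapping[str, np.ndarray],
    seed: int,
    feature_names: Sequence[str] | None = None,
) -> FeatureTable:
    """Draw a class-conditional Gaussian feature table (provenance 'original')."""
    rng = np.random.default_rng(seed)
    dims = {len(np.atleast_1d(v)) for v in class_means.values()}
    if len(dims) != 1:
        raise ValueError("class means must share one dimension")
    m = dims.pop()
    rows, labels = [], []
    for cls in CLASS_ORDER:
        if cls not in class_counts:
            continue
        k = int(class_counts[cls])
        if k == 0:
            continue
        mean = np.atleast_1d(np.asarray(class_means[cls], dtype=float))
        cov = np.atleast_2d(np.asarray(class_covs[cls], dtype=float))
        if cov.shape != (m, m):
            raise ValueError(f"covariance for {cls} must be {m}x{m}")
        rows.append(
            rng.multivariate_normal(mean, cov, size=k)
            if np.any(cov)
            else np.tile(mean, (k, 1))
        )
        labels.extend([cls] * k)
    X = np.vstack(rows)
    names = list(feature_names) if feature_names else [f"f{i}" for i in range(m)]
    return FeatureTable(
        feature_names=names,
        X=X,
        y=np.array(labels),
        provenance=np.full(len(labels), "original"),
    )


def gaussian_table_spec(
    m: int = 12, separation: float = 3.0, scale: float = 1.0
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Convenience class-conditional Gaussian spec: class means march along a
    shared direction `separation` apart (in units of the common sd `scale`)."""
    direction = np.ones(m) / np.sqrt(m)
    means = {
        cls: k * separation * scale * direction for k, cls in enumerate(CLASS_ORDER)
    }
    covs = {cls: (scale**2) * np.eye(m) for cls in CLASS_ORDER}
    return means, covs


def records_to_csv(records: Sequence[PlotRecord], path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "plot_id": r.plot_id,
                "row0": r.bbox[0],
                "col0": r.bbox[1],
                "row1": r.bbox[2],
                "col1": r.bbox[3],
                "score": r.score,
                "class": r.lodging_class,
            }
            for r in records
        ]
    ).to_csv(path, index=False)


def records_from_csv(path) -> list[PlotRecord]:
    import pandas as pd

    df = pd.read_csv(path)
    return [
        PlotRecord(
            plot_id=str(row.plot_id),
            bbox=(int(row.row0), int(row.col0), int(row.row1), int(row.col1)),
            score=float(row.score),
            lodging_class=str(row["class"]),
        )
        for _, row in df.iterrows()
    ]
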