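"""End-to-end orchestration: simulate -> segment -> features -> (select) ->
split -> resample(train) -> tune+fit -> evaluate, with a run directory,
manifest, and reproducible seeds.

Every stage writes its artifact into the run directory (images as PNG,
tables as CSV, reports as JSON); the manifest lists every file with a
checksum plus the seeds and stage timings.  A completed stage is skipped
under ``resume=True`` when its artifact already exists.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics, models, resample, segment, selection, synth, texture
from .synth import SMALL_CLASS_COUNTS, FeatureTable, FieldConfig

log = logging.getLogger(__name__)

FIXTURE_NAMES = ("xgboost", "rf", "knn", "ann")


@dataclass
class RunConfig:
    """Everything one reproducible pipeline run needs."""

    seed: int = 0
    out_dir: str | Path = "runs/run0"
    class_counts: dict[str, int] = field(
        default_factory=lambda: dict(SMALL_CLASS_COUNTS)
    )
    plot_shape: tuple[int, int] = (40, 56)
    segment_params: segment.SegmentParams = field(default_factory=segment.SegmentParams)
    glcm_params: texture.GLCMParams = field(default_factory=texture.GLCMParams)
    run_selection: bool = False
    selection_cv_folds: int = 10
    selection_trees: int = 200
    resample_methods: tuple[str, ...] = resample.METHODS
    model_types: tuple[str, ...] = models.MODEL_TYPES
    tune_budget: int = 6
    tune_cv_folds: int = 3
    train_fraction: float = 0.8
    resume: bool = False

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        if "segment_params" in raw:
            raw["segment_params"] = segment.SegmentParams(**raw["segment_params"])
        if "glcm_params" in raw:
            gp = dict(raw["glcm_params"])
            if "angles" in gp:
                gp["angles"] = tuple(gp["angles"])
            raw["glcm_params"] = texture.GLCMParams(**gp)
        for key in ("plot_shape", "resample_methods", "model_types"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        def _plain(v):
            if isinstance(v, tuple):
                return [_plain(x) for x in v]
            if isinstance(v, dict):
                return {k: _plain(x) for k, x in v.items()}
            return v

        d = {k: _plain(v) for k, v in dataclasses.asdict(self).items()}
        d["out_dir"] = str(self.out_dir)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    (out / "config.json").write_text(json.dumps(config.to_dict(), indent=2))

    def _stage(name: str, artifact: Path, fn):
        if config.resume and artifact.exists():
            log.info("stage %s: resume, artifact %s exists", name, artifact.name)
            return
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        timings[name] = time.perf_counter() - t0
        log.info("stage %s: %.2fs", name, timings[name])

    # -- simulate ----------------------------------------------------------
    field_png = out / "field.png"
    plots_csv = out / "plots.csv"

    def _simulate():
        cfg = FieldConfig(
            class_counts=config.class_counts,
            plot_shape=config.plot_shape,
            rng_seed=config.seed,
        )
        img, records = synth.generate_field(cfg)
        import imageio.v3 as iio

        iio.imwrite(field_png, img)
        synth.records_to_csv(records, plots_csv)

    _stage("simulate", field_png, _simulate)

    # -- segment + features ------------------------------------------------
    features_csv = out / "features.csv"

    def _features():
        import imageio.v3 as iio

        img = iio.imread(field_png)
        if img.ndim == 3:
            img = segment.to_grayscale(img)
        records = synth.records_from_csv(plots_csv)
        items = []
        stats = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", segment.SegmentationWarning)
            for rec in records:
                roi = segment.crop_roi(img, rec.bbox)
                mask = segment.segment_canopy(roi, config.segment_params)
                items.append((rec.plot_id, roi, mask.mask, rec.lodging_class))
                stats.append(
                    {
                        "plot_id": rec.plot_id,
                        "foreground_fraction": mask.foreground_fraction,
                        "n_components": mask.n_components,
                    }
                )
        table = texture.extract_feature_table(items, config.glcm_params)
        df = table.to_dataframe()
        df = df.merge(pd.DataFrame(stats), on="plot_id", how="left")
        df.to_csv(features_csv, index=False)

    _stage("features", features_csv, _features)

    # -- selection ---------------------------------------------------------
    table = FeatureTable.from_dataframe(
        pd.read_csv(features_csv).drop(
            columns=["foreground_fraction", "n_components"]
        )
    )
    selection_json = out / "selection.json"
    if config.run_selection:

        def _select():
            result = selection.rf_rfe(
                table,
                cv_folds=config.selection_cv_folds,
                seed=config.seed,
                n_trees=config.selection_trees,
            )
            result.to_json(selection_json)

        _stage("select", selection_json, _select)
        chosen = json.loads(selection_json.read_text())["chosen_features"]
        keep = [table.feature_names.index(c) for c in chosen]
        table = FeatureTable(
            feature_names=chosen,
            X=table.X[:, keep],
            y=table.y,
            provenance=table.provenance,
            ids=table.ids,
        )

    # -- split / resample / train / evaluate --------------------------------
    train, test = models.split_train_test(
        table, models.SplitSpec(config.train_fraction, True, config.seed)
    )
    assert (test.provenance == "original").all()

    reports = []
    for method in config.resample_methods:
        plan = resample.ResamplePlan(method=method, seed=config.seed)
        balanced = resample.apply_resample(train, plan)
        for model_type in config.model_types:
            report_json = out / f"report_{method}_{model_type}.json"

            def _train_eval(balanced=balanced, model_type=model_type,
                            method=method, report_json=report_json):
                hp = models.tune(
                    balanced,
                    model_type,
                    budget=config.tune_budget,
                    seed=config.seed,
                    cv_folds=config.tune_cv_folds,
                )
                clf = models.fit(balanced, model_type, hp, seed=config.seed)
                pred = clf.predict(test.X)
                proba_full = np.zeros((test.n, len(synth.CLASS_ORDER)))
                proba = clf.predict_proba(test.X)
                for j, c in enumerate(clf.classes):
                    proba_full[:, synth.CLASS_ORDER.index(c)] = proba[:, j]
                report = metrics.evaluate(test.y, pred, proba_full)
                report.meta = {
                    "resample_method": method,
                    "model_type": model_type,
                    "hyperparams": {k: (None if v is None else v)
                                    for k, v in hp.items()},
                    "train_counts": balanced.class_counts(),
                    "seed": config.seed,
                }
                report_json.write_text(json.dumps(report.to_dict(), indent=2))

            _stage(f"train_eval[{method},{model_type}]", report_json, _train_eval)
            reports.append(report_json.name)

    manifest = {
        "seed": config.seed,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "reports": reports,
        "files": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


# ---------------------------------------------------------------------------
# printed-confusion-matrix fixtures
# ---------------------------------------------------------------------------

def fixture_path(name: str) -> Path:
    """Path to a bundled held-out confusion-matrix fixture
    (one of 'xgboost', 'rf', 'knn', 'ann')."""
    if name not in FIXTURE_NAMES:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    return Path(str(resources.files("lodgetex").joinpath(f"data/table2/{name}.csv")))


def load_fixture(name: str) -> metrics.ConfusionMatrix:
    return read_matrix_csv(fixture_path(name))


def read_matrix_csv(path: str | Path) -> metrics.ConfusionMatrix:
    """Read a labelled 4x4 confusion-matrix CSV (rows actual, cols predicted)."""
    df = pd.read_csv(path, comment="#", index_col=0)
    labels = tuple(str(c) for c in df.columns)
    if list(df.index) != list(df.columns):
        raise ValueError("confusion-matrix CSV must have matching row/col labels")
    try:
        C = df.to_numpy(dtype=np.int64)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"malformed confusion-matrix CSV: {exc}") from exc
    return metrics.ConfusionMatrix(C, labels)


def evaluate_fixture(path: str | Path) -> metrics.EvaluationReport:
    """Metrics computed directly from a printed confusion matrix."""
    return metrics.evaluate_matrix(read_matrix_csv(path))
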