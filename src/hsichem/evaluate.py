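"""Experimental designs and metrics for two-variety classification.

Two designs are implemented:

* **grade transfer** — calibrate on all scenes of one size grade and predict
  every grade, probing how well a model trained on one kernel-size
  distribution transfers to the others (3 x 3 train/predict grid);
* **four-way pixel/object** — with an image-level 2:1 calibration/prediction
  split, cross pixel-wise and object-wise spectra for training and
  prediction: pixel->pixel, pixel->object (the pixel-trained model scores
  each object's average preprocessed spectrum), object->pixel and
  object->object, for each classifier family.

Reports carry per-class correct/total counts in the ``correct/total``
fraction style; accuracy is the pooled fraction correct, sensitivity the
per-class accuracy of the positive (first-variety) class and specificity
that of the other class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import (
    KNNConfig,
    RBFNNConfig,
    SVMConfig,
    TrainedClassifier,
    grid_search_svm,
    select_representative_pixels,
    train_knn,
    train_rbfnn,
)
from .cubes import HyperspectralCube, ObjectMask, extract_pixel_spectra
from .preprocess import preprocess_pixels
from .tables import ObjectSpectraTable, PixelSpectraTable

__all__ = [
    "EvaluationReport",
    "ClassifierSpec",
    "fit_classifier",
    "split_scenes",
    "evaluate",
    "run_grade_transfer",
    "GradeTransferResult",
    "run_four_way",
    "FourWayResult",
    "prediction_map",
    "render_prediction_map",
]

FOUR_WAY_MODES = (
    "pixel_to_pixel",
    "pixel_to_object",
    "object_to_pixel",
    "object_to_object",
)


@dataclass
class EvaluationReport:
    """Confusion counts plus the three headline metrics."""

    mode: str
    positive_class: str
    class_counts: dict  # class -> (correct, total)
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.positive_class not in self.class_counts:
            raise ValueError(
                f"positive class {self.positive_class!r} absent from counts"
            )

    @property
    def accuracy(self) -> float:
        """Pooled percent correct (0-100)."""
        correct = sum(c for c, _ in self.class_counts.values())
        total = sum(t for _, t in self.class_counts.values())
        return 100.0 * correct / total

    @property
    def sensitivity(self) -> float:
        c, t = self.class_counts[self.positive_class]
        return c / t

    @property
    def specificity(self) -> float:
        others = [v for k, v in self.class_counts.items() if k != self.positive_class]
        correct = sum(c for c, _ in others)
        total = sum(t for _, t in others)
        return correct / total

    def fractions(self) -> dict:
        return {k: f"{c}/{t}" for k, (c, t) in self.class_counts.items()}

    @staticmethod
    def from_counts(
        class_counts: Mapping, positive_class: str, mode: str = "counts", **params
    ) -> "EvaluationReport":
        return EvaluationReport(
            mode=mode,
            positive_class=positive_class,
            class_counts=dict(class_counts),
            params=dict(params),
        )


@dataclass
class ClassifierSpec:
    """Which model family to fit and with what configuration."""

    kind: str  # svm | knn | rbfnn
    config: SVMConfig | KNNConfig | RBFNNConfig | None = None


def fit_classifier(
    spec: ClassifierSpec, X: np.ndarray, y: np.ndarray, seed: int = 0, **meta
) -> TrainedClassifier:
    if spec.kind == "svm":
        _, _, clf = grid_search_svm(X, y, spec.config, seed=seed, **meta)
        return clf
    if spec.kind == "knn":
        return train_knn(X, y, spec.config, **meta)
    if spec.kind == "rbfnn":
        return train_rbfnn(X, y, spec.config, **meta)
    raise ValueError(f"unknown classifier kind {spec.kind!r}")


def split_scenes(
    scene_meta: pd.DataFrame,
    ratio: tuple[int, int] = (2, 1),
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Image-level calibration/prediction split, stratified by class x grade.

    Per group, ``floor(n * a / (a + b))`` scenes go to calibration.  The
    split is at scene level, so no pixel of a prediction image ever leaks
    into calibration.
    """
    required = {"scene_id", "class", "grade"}
    if not required.issubset(scene_meta.columns):
        raise ValueError(f"scene metadata must have columns {sorted(required)}")
    a, b = ratio
    rng = np.random.default_rng(seed)
    cal: list[str] = []
    pred: list[str] = []
    groups = scene_meta.drop_duplicates("scene_id").groupby(
        ["class", "grade"], sort=True
    )
    for _, grp in groups:
        ids = sorted(grp["scene_id"])
        if len(ids) < 3:
            raise ValueError(
                f"group {tuple(grp.iloc[0][['class', 'grade']])} has only "
                f"{len(ids)} scenes; need at least 3 to split {a}:{b}"
            )
        perm = rng.permutation(len(ids))
        n_cal = int(np.floor(len(ids) * a / (a + b)))
        cal.extend(ids[i] for i in perm[:n_cal])
        pred.extend(ids[i] for i in perm[n_cal:])
    return sorted(cal), sorted(pred)


def evaluate(
    model: TrainedClassifier,
    X: np.ndarray,
    y: Sequence,
    positive_class: str,
    mode: str = "evaluation",
) -> EvaluationReport:
    """Predict and tally per-class correct/total counts."""
    y = np.asarray(y)
    unseen = set(np.unique(y)) - set(model.classes)
    if unseen:
        raise ValueError(f"labels {sorted(unseen)} were never seen in training")
    preds = model.predict(X)
    counts = {}
    for cls in model.classes:
        sel = y == cls
        counts[cls] = (int(np.sum(preds[sel] == cls)), int(np.sum(sel)))
    counts = {k: v for k, v in counts.items() if v[1] > 0 or k == positive_class}
    return EvaluationReport(
        mode=mode,
        positive_class=positive_class,
        class_counts=counts,
        params=dict(model.params),
    )


# ---------------------------------------------------------------------------
# Grade transfer


@dataclass
class GradeTransferResult:
    reports: dict  # (train_grade, predict_grade) -> EvaluationReport
    models: dict  # train_grade -> TrainedClassifier

    def mean_transfer_accuracy(self, train_grade: str) -> float:
        accs = [
            rep.accuracy
            for (tg, pg), rep in self.reports.items()
            if tg == train_grade and pg != train_grade
        ]
        return float(np.mean(accs))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (tg, pg), rep in self.reports.items():
            rows.append(
                {
                    "train_grade": tg,
                    "predict_grade": pg,
                    "set": "calibration" if tg == pg else "prediction",
                    "accuracy": rep.accuracy,
                    "sensitivity": rep.sensitivity,
                    "specificity": rep.specificity,
                    **{f"counts_{k}": v for k, v in rep.fractions().items()},
                }
            )
        return pd.DataFrame(rows)


def run_grade_transfer(
    objects: ObjectSpectraTable,
    band_indices: np.ndarray,
    spec: ClassifierSpec | None = None,
    positive_class: str | None = None,
    seed: int = 0,
) -> GradeTransferResult:
    """Calibrate per grade on object-wise spectra and predict every grade.

    Calibration uses *all* scenes of the training grade (no inner split);
    the own-grade entry of the 3x3 grid is therefore a calibration report.
    """
    spec = spec or ClassifierSpec("svm", SVMConfig())
    grades = sorted(objects.meta["grade"].unique())
    if len(grades) < 3:
        raise ValueError(f"grade transfer needs three grades, found {grades}")
    classes = sorted(objects.meta["class"].unique())
    positive_class = positive_class or classes[0]
    X = objects.spectra[:, band_indices]
    y = objects.meta["class"].to_numpy()
    grade_col = objects.meta["grade"].to_numpy()
    reports, models = {}, {}
    for tg in grades:
        tr = grade_col == tg
        model = fit_classifier(spec, X[tr], y[tr], seed=seed)
        models[tg] = model
        for pg in grades:
            pr = grade_col == pg
            reports[(tg, pg)] = evaluate(
                model,
                X[pr],
                y[pr],
                positive_class,
                mode=f"train {tg} -> predict {pg}",
            )
    return GradeTransferResult(reports=reports, models=models)


# ---------------------------------------------------------------------------
# Four-way pixel/object design


@dataclass
class FourWayResult:
    reports: dict  # (mode, kind) -> {"calibration": report, "prediction": report}
    models: dict  # ("pixel"|"object", kind) -> TrainedClassifier

    def accuracy(self, mode: str, kind: str, subset: str = "prediction") -> float:
        return self.reports[(mode, kind)][subset].accuracy

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (mode, kind), pair in self.reports.items():
            for subset, rep in pair.items():
                rows.append(
                    {
                        "mode": mode,
                        "classifier": kind,
                        "set": subset,
                        "accuracy": rep.accuracy,
                        "sensitivity": rep.sensitivity,
                        "specificity": rep.specificity,
                        **{f"counts_{k}": v for k, v in rep.fractions().items()},
                    }
                )
        return pd.DataFrame(rows)


def _normalise_specs(classifiers) -> dict:
    """Accept {kind: config}, {kind: {"pixel": cfg, "object": cfg}} or None."""
    if classifiers is None:
        classifiers = {
            "svm": SVMConfig(),
            "knn": {"pixel": KNNConfig(k=3), "object": KNNConfig(k=5)},
            "rbfnn": RBFNNConfig(),
        }
    out = {}
    for kind, cfg in classifiers.items():
        if isinstance(cfg, dict):
            out[kind] = {"pixel": cfg.get("pixel"), "object": cfg.get("object")}
        else:
            out[kind] = {"pixel": cfg, "object": cfg}
    return out


def _representative_per_class(
    X: np.ndarray, y: np.ndarray, n_groups: int, seed: int
) -> np.ndarray:
    """k-means representatives selected per variety across all its grades."""
    keep = []
    for i, cls in enumerate(np.unique(y)):
        rows = np.nonzero(y == cls)[0]
        sel = select_representative_pixels(X[rows], n_groups=n_groups, seed=seed + i)
        keep.append(rows[sel.indices])
    return np.concatenate(keep)


def run_four_way(
    pixels: PixelSpectraTable,
    objects: ObjectSpectraTable,
    cal_scenes: Sequence[str],
    pred_scenes: Sequence[str],
    pixel_bands: np.ndarray,
    object_bands: np.ndarray,
    classifiers: Mapping | None = None,
    n_groups: int = 300,
    positive_class: str | None = None,
    seed: int = 0,
) -> FourWayResult:
    """Cross pixel/object training and prediction for each classifier family.

    Pixel-level calibration and prediction sets are both shrunk by
    representative-pixel selection (per variety).  Pixel-trained models score
    object rows on the object's average preprocessed spectrum restricted to
    the pixel-wise effective wavelengths, and vice versa — so the calibration
    columns of pixel->pixel and pixel->object are identical by construction.
    """
    if pixels.stage != "wt+snv" or objects.stage != "wt+snv":
        raise ValueError("four-way evaluation expects preprocessed tables")
    specs = _normalise_specs(classifiers)
    classes = sorted(objects.meta["class"].unique())
    positive_class = positive_class or classes[0]
    pixel_bands = np.asarray(pixel_bands, dtype=int)
    object_bands = np.asarray(object_bands, dtype=int)

    pix_cal_rows = pixels.meta["scene_id"].isin(set(cal_scenes)).to_numpy()
    pix_pred_rows = pixels.meta["scene_id"].isin(set(pred_scenes)).to_numpy()
    obj_cal_rows = objects.meta["scene_id"].isin(set(cal_scenes)).to_numpy()
    obj_pred_rows = objects.meta["scene_id"].isin(set(pred_scenes)).to_numpy()

    yp_all = pixels.meta["class"].to_numpy()
    yo_all = objects.meta["class"].to_numpy()

    # representative pixels, selected on the full spectra then band-sliced
    cal_idx = np.nonzero(pix_cal_rows)[0]
    pred_idx = np.nonzero(pix_pred_rows)[0]
    cal_keep = cal_idx[
        _representative_per_class(
            pixels.spectra[cal_idx], yp_all[cal_idx], n_groups, seed
        )
    ]
    pred_keep = pred_idx[
        _representative_per_class(
            pixels.spectra[pred_idx], yp_all[pred_idx], n_groups, seed + 101
        )
    ]

    Xp_cal = pixels.spectra[np.sort(cal_keep)][:, pixel_bands]
    yp_cal = yp_all[np.sort(cal_keep)]
    Xp_pred = pixels.spectra[np.sort(pred_keep)]
    yp_pred = yp_all[np.sort(pred_keep)]

    Xo_cal = objects.spectra[obj_cal_rows]
    yo_cal = yo_all[obj_cal_rows]
    Xo_pred = objects.spectra[obj_pred_rows]
    yo_pred = yo_all[obj_pred_rows]

    reports, models = {}, {}
    for kind, levels in specs.items():
        pix_model = fit_classifier(
            ClassifierSpec(kind, levels["pixel"]), Xp_cal, yp_cal, seed=seed
        )
        obj_model = fit_classifier(
            ClassifierSpec(kind, levels["object"]),
            Xo_cal[:, object_bands],
            yo_cal,
            seed=seed,
        )
        models[("pixel", kind)] = pix_model
        models[("object", kind)] = obj_model

        pix_cal_rep = evaluate(
            pix_model, Xp_cal, yp_cal, positive_class, mode="pixel calibration"
        )
        obj_cal_rep = evaluate(
            obj_model,
            Xo_cal[:, object_bands],
            yo_cal,
            positive_class,
            mode="object calibration",
        )
        reports[("pixel_to_pixel", kind)] = {
            "calibration": pix_cal_rep,
            "prediction": evaluate(
                pix_model,
                Xp_pred[:, pixel_bands],
                yp_pred,
                positive_class,
                mode="pixel_to_pixel",
            ),
        }
        reports[("pixel_to_object", kind)] = {
            "calibration": pix_cal_rep,
            "prediction": evaluate(
                pix_model,
                Xo_pred[:, pixel_bands],
                yo_pred,
                positive_class,
                mode="pixel_to_object",
            ),
        }
        reports[("object_to_pixel", kind)] = {
            "calibration": obj_cal_rep,
            "prediction": evaluate(
                obj_model,
                Xp_pred[:, object_bands],
                yp_pred,
                positive_class,
                mode="object_to_pixel",
            ),
        }
        reports[("object_to_object", kind)] = {
            "calibration": obj_cal_rep,
            "prediction": evaluate(
                obj_model,
                Xo_pred[:, object_bands],
                yo_pred,
                positive_class,
                mode="object_to_object",
            ),
        }
    return FourWayResult(reports=reports, models=models)


# ---------------------------------------------------------------------------
# Prediction maps


def prediction_map(
    model: TrainedClassifier,
    cube: HyperspectralCube,
    objmask: ObjectMask,
    band_indices: np.ndarray,
    wavelet: str = "db7",
    level: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Classify every ROI pixel and paint the result into a label raster.

    Returns ``(raster, predictions)``: the raster holds 0 for background and
    ``1 + class index`` (in the model's sorted class order) for foreground;
    ``predictions`` are the per-row labels on the extracted pixel table, in
    extraction order, so raster and table agree exactly by construction.
    """
    band_indices = np.asarray(band_indices, dtype=int)
    if model.n_features != len(band_indices):
        raise ValueError(
            f"model expects {model.n_features} features but {len(band_indices)} "
            "bands were given"
        )
    table = extract_pixel_spectra(cube, objmask)
    processed = preprocess_pixels(table, wavelet=wavelet, level=level)
    preds = model.predict(processed.spectra[:, band_indices])
    class_code = {cls: i + 1 for i, cls in enumerate(model.classes)}
    raster = np.zeros(cube.shape[:2], dtype=int)
    rows = processed.meta["row"].to_numpy()
    cols = processed.meta["col"].to_numpy()
    raster[rows, cols] = np.array([class_code[p] for p in preds])
    return raster, preds


def render_prediction_map(
    raster: np.ndarray,
    classes: Sequence[str],
    path: str | Path,
    title: str | None = None,
) -> Path:
    """Save a fixed-palette class map (background black) with a legend."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap
    from matplotlib.patches import Patch

    palette = ["#000000", "#e41a1c", "#377eb8", "#4daf4a", "#984ea3"]
    ncls = len(classes)
    cmap = ListedColormap(palette[: ncls + 1])
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(raster, cmap=cmap, vmin=0, vmax=ncls, interpolation="nearest")
    ax.set_axis_off()
    handles = [
        Patch(color=palette[i + 1], label=str(cls)) for i, cls in enumerate(classes)
    ]
    ax.legend(handles=handles, loc="lower right", fontsize=8)
    if title:
        ax.set_title(title)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path
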