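"""Scene splitting, metric reports, grade transfer, four-way design, maps."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import confusion_matrix

import hsichem as h
from hsichem.classify import KNNConfig, RBFNNConfig, SVMConfig
from hsichem.evaluate import (
    ClassifierSpec,
    EvaluationReport,
    evaluate,
    prediction_map,
    run_four_way,
    run_grade_transfer,
    split_scenes,
)
from hsichem.pipeline import RunConfig, build_tables


def _scene_frame(per_group):
    rows = []
    for cls in "AB":
        for grade in ("Grade1", "Grade2", "Grade3"):
            for i in range(per_group):
                rows.append(
                    {"scene_id": f"{cls}-{grade}-{i:03d}", "class": cls, "grade": grade}
                )
    return pd.DataFrame(rows)


class TestSplitScenes:
    def test_thirty_scenes_split_twenty_ten(self):
        cal, pred = split_scenes(_scene_frame(30), seed=0)
        frame = _scene_frame(30)
        for (cls, grade), grp in frame.groupby(["class", "grade"]):
            ids = set(grp["scene_id"])
            assert len(ids & set(cal)) == 20
            assert len(ids & set(pred)) == 10

    def test_three_scenes_split_two_one(self):
        cal, pred = split_scenes(_scene_frame(3), seed=1)
        assert len(cal) == 12 and len(pred) == 6  # 2/1 per each of 6 groups

    def test_no_scene_in_both_sets(self):
        cal, pred = split_scenes(_scene_frame(6), seed=2)
        assert not set(cal) & set(pred)
        assert len(cal) + len(pred) == 36

    def test_same_seed_same_split(self):
        assert split_scenes(_scene_frame(6), seed=5) == split_scenes(
            _scene_frame(6), seed=5
        )

    def test_too_few_scenes_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            split_scenes(_scene_frame(2), seed=0)


class TestReports:
    def test_all_correct_is_perfect(self):
        rep = EvaluationReport.from_counts(
            {"A": (10, 10), "B": (7, 7)}, positive_class="A"
        )
        assert rep.accuracy == 100.0
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0

    def test_swapping_positive_class_swaps_sensitivity_specificity(self):
        counts = {"A": (8, 10), "B": (6, 7)}
        a = EvaluationReport.from_counts(counts, positive_class="A")
        b = EvaluationReport.from_counts(counts, positive_class="B")
        assert a.sensitivity == b.specificity
        assert a.specificity == b.sensitivity
        assert a.accuracy == b.accuracy

    def test_metrics_match_confusion_matrix_recomputation(self, blobs_model):
        clf, X, y = blobs_model
        rep = evaluate(clf, X, y, positive_class="A")
        preds = clf.predict(X)
        cm = confusion_matrix(y, preds, labels=["A", "B"])
        assert rep.sensitivity == pytest.approx(cm[0, 0] / cm[0].sum())
        assert rep.specificity == pytest.approx(cm[1, 1] / cm[1].sum())
        assert rep.accuracy == pytest.approx(100.0 * np.trace(cm) / cm.sum())

    def test_unseen_label_rejected(self, blobs_model):
        clf, X, _ = blobs_model
        with pytest.raises(ValueError, match="never seen"):
            evaluate(clf, X[:3], np.array(["A", "C", "B"]), positive_class="A")

    def test_fraction_format(self):
        rep = EvaluationReport.from_counts(
            {"A": (665, 665), "B": (245, 246)}, positive_class="A"
        )
        assert rep.fractions() == {"A": "665/665", "B": "245/246"}


@pytest.fixture(scope="module")
def blobs_model():
    rng = np.random.default_rng(0)
    X = np.vstack([rng.normal(0, 1.0, (25, 3)), rng.normal(1.5, 1.0, (25, 3))])
    y = np.array(["A"] * 25 + ["B"] * 25)
    clf = h.train_knn(X, y, KNNConfig(k=3))
    return clf, X, y


class TestGradeTransfer:
    def test_grid_has_nine_entries_and_saturates_without_drift(self, mini_study):
        """With grade-independent signatures a model trained on any grade
        should transfer almost perfectly."""
        _, _, pixels, objects = mini_study
        model = h.pca_fit(objects.spectra, 7)
        sel = h.select_by_pca_loadings(model, n_select=17)
        gt = run_grade_transfer(
            objects, sel.band_indices, ClassifierSpec("svm", SVMConfig(log2_step=2.0)),
            seed=0,
        )
        assert len(gt.reports) == 9
        frame = gt.to_frame()
        assert len(frame) == 9
        assert (frame["accuracy"] >= 95.0).all()

    def test_counts_cover_every_object(self, mini_study):
        _, _, _, objects = mini_study
        model = h.pca_fit(objects.spectra, 7)
        sel = h.select_by_pca_loadings(model, n_select=10)
        gt = run_grade_transfer(
            objects, sel.band_indices, ClassifierSpec("knn", KNNConfig(k=3)), seed=0
        )
        n_g1 = (objects.meta["grade"] == "Grade1").sum()
        rep = gt.reports[("Grade2", "Grade1")]
        assert sum(t for _, t in rep.class_counts.values()) == n_g1


@pytest.fixture(scope="module")
def four_way(mini_study):
    _, _, pixels, objects = mini_study
    scene_meta = pixels.meta[["scene_id", "class", "grade"]].drop_duplicates()
    cal, pred = split_scenes(scene_meta, seed=3)
    pm = h.pca_fit(pixels.spectra, 7)
    om = h.pca_fit(objects.spectra, 7)
    pix_sel = h.select_by_pca_loadings(pm, n_select=17)
    obj_sel = h.select_by_pca_loadings(om, n_select=20)
    classifiers = {
        "svm": SVMConfig(log2_step=2.0),
        "knn": {"pixel": KNNConfig(k=3), "object": KNNConfig(k=5)},
        "rbfnn": RBFNNConfig(),
    }
    return run_four_way(
        pixels,
        objects,
        cal,
        pred,
        pix_sel.band_indices,
        obj_sel.band_indices,
        classifiers=classifiers,
        n_groups=150,
        seed=0,
    )


class TestFourWay:
    def test_twelve_reports(self, four_way):
        assert len(four_way.reports) == 12
        modes = {m for m, _ in four_way.reports}
        assert modes == {
            "pixel_to_pixel",
            "pixel_to_object",
            "object_to_pixel",
            "object_to_object",
        }

    def test_pixel_calibration_metrics_repeat_across_pixel_rows(self, four_way):
        for kind in ("svm", "knn", "rbfnn"):
            a = four_way.reports[("pixel_to_pixel", kind)]["calibration"]
            b = four_way.reports[("pixel_to_object", kind)]["calibration"]
            assert a.class_counts == b.class_counts
            c = four_way.reports[("object_to_pixel", kind)]["calibration"]
            d = four_way.reports[("object_to_object", kind)]["calibration"]
            assert c.class_counts == d.class_counts

    def test_counts_sum_to_evaluated_rows(self, four_way, mini_study):
        _, _, _, objects = mini_study
        for (mode, kind), pair in four_way.reports.items():
            for rep in pair.values():
                total = sum(t for _, t in rep.class_counts.values())
                assert total > 0
        # object prediction rows = objects in prediction scenes
        rep = four_way.reports[("object_to_object", "svm")]["prediction"]
        assert sum(t for _, t in rep.class_counts.values()) == 24  # 6 groups x 1 scene x 4 objects

    def test_zero_variability_study_is_perfectly_classified(self):
        cfg = RunConfig.preset(
            "desk",
            scenes_per_group=3,
            scatter_gain_sd=0.0,
            scatter_offset_sd=0.0,
            noise_sd=0.0,
        )
        scenes = h.generate_study(
            scenes_per_group=3, base_config=cfg.scene_config(), master_seed=8
        )
        pixels, objects = build_tables(scenes, cfg)
        scene_meta = pixels.meta[["scene_id", "class", "grade"]].drop_duplicates()
        cal, pred = split_scenes(scene_meta, seed=0)
        # two distinct spectra only -> centred rank 1
        pm = h.pca_fit(pixels.spectra, 1)
        pix_sel = h.select_by_pca_loadings(pm, n_select=10, n_pcs=1)
        res = run_four_way(
            pixels,
            objects,
            cal,
            pred,
            pix_sel.band_indices,
            pix_sel.band_indices,
            classifiers={"knn": KNNConfig(k=1), "rbfnn": RBFNNConfig()},
            n_groups=50,
            seed=0,
        )
        for pair in res.reports.values():
            for rep in pair.values():
                assert rep.accuracy == 100.0


class TestPredictionMap:
    def test_map_agrees_with_table_and_truth(self, signatures):
        cfg = h.SceneConfig(seed=31)
        scene = h.generate_scene(cfg, signatures, class_assignment=["A", "B", "A", "B"])
        corrected = h.correct_reflectance(scene.raw, scene.refs)
        om = h.label_objects(h.segment_background(corrected))
        table = h.extract_pixel_spectra(corrected, om, "s")
        prep = h.preprocess_pixels(table)
        truth_cls = np.array(
            [
                scene.truth.class_codes[c]
                for c in scene.truth.class_map[
                    prep.meta["row"].to_numpy(), prep.meta["col"].to_numpy()
                ]
            ]
        )
        bands = np.arange(0, 200, 10)
        clf = h.train_knn(prep.spectra[:, bands], truth_cls, KNNConfig(k=3))
        raster, preds = prediction_map(clf, corrected, om, bands)
        # raster agrees with the tabular predictions pixel for pixel
        rows, cols = prep.meta["row"].to_numpy(), prep.meta["col"].to_numpy()
        codes = {cls: i + 1 for i, cls in enumerate(clf.classes)}
        assert np.array_equal(
            raster[rows, cols], np.array([codes[p] for p in preds])
        )
        assert (raster[scene.truth.label_map == 0] == 0).all()
        assert (preds == truth_cls).mean() >= 0.9

    def test_single_object_scene_is_uniformly_labelled(self, signatures):
        cfg = h.SceneConfig(seed=32, n_objects=1, noise_sd=0.0, scatter_gain_sd=0.0,
                            scatter_offset_sd=0.0)
        scene = h.generate_scene(cfg, signatures)
        corrected = h.correct_reflectance(scene.raw, scene.refs)
        om = h.label_objects(h.segment_background(corrected))
        table = h.preprocess_pixels(h.extract_pixel_spectra(corrected, om, "s"))
        bands = np.arange(200)
        clf = h.train_knn(table.spectra, np.array(["A"] * len(table)), KNNConfig(k=1))
        raster, preds = prediction_map(clf, corrected, om, bands)
        assert set(preds) == {"A"}
        assert set(np.unique(raster)) == {0, 1}

    def test_feature_mismatch_rejected(self, signatures, noisy_scene):
        _, scene = noisy_scene
        corrected = h.correct_reflectance(scene.raw, scene.refs)
        om = h.label_objects(h.segment_background(corrected))
        clf = h.train_knn(np.zeros((4, 5)), np.array(["A", "B", "A", "B"]), KNNConfig(k=1))
        with pytest.raises(ValueError, match="features|bands"):
            prediction_map(clf, corrected, om, np.arange(10))
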