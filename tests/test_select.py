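"""PCA/ICA fitting, scores images and effective-wavelength selection."""

import numpy as np
import pytest

import hsichem as h
from hsichem.preprocess import snv, wt_smooth
from hsichem.select import (
    PCAModel,
    ica_fit,
    pca_fit,
    scores_image,
    select_by_ica_weights,
    select_by_pca_loadings,
)


def _random_model(rng, bands, k):
    """Fabricate a valid PCAModel with orthonormal loadings for selector tests."""
    q, _ = np.linalg.qr(rng.normal(size=(bands, k)))
    evr = np.sort(rng.uniform(0.01, 1.0, k))[::-1]
    evr = evr / (evr.sum() * 1.1)
    return PCAModel(
        loadings=q,
        scores=np.zeros((1, k)),
        explained_variance_ratio=evr,
        mean=np.zeros(bands),
    )


def _oracle_pca_rank(loadings, evr, n_pcs, n_select):
    """Independent enumeration of the documented selection rule."""
    score = [
        max(np.sqrt(evr[j]) * abs(loadings[b, j]) for j in range(n_pcs))
        for b in range(loadings.shape[0])
    ]
    bands = len(score)
    peaks = []
    i = 0
    while i < bands:
        j = i
        while j + 1 < bands and score[j + 1] == score[i]:
            j += 1
        if (i == 0 or score[i - 1] < score[i]) and (
            j == bands - 1 or score[j + 1] < score[i]
        ):
            peaks.append(i)
        i = j + 1
    ranked = sorted(peaks, key=lambda b: (-score[b], b))[:n_select]
    if len(ranked) < n_select:
        rest = sorted(
            (b for b in range(bands) if b not in peaks), key=lambda b: (-score[b], b)
        )
        ranked += rest[: n_select - len(ranked)]
    return sorted(ranked)


class TestPCA:
    def test_single_direction_data_has_unit_pc1_ratio(self):
        rng = np.random.default_rng(0)
        direction = rng.normal(size=12)
        X = np.outer(rng.normal(size=40), direction) + 5.0
        model = pca_fit(X, 1)
        assert model.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-10)

    def test_ratios_match_eigendecomposition_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 12))
        model = pca_fit(X, 12)
        cov = np.cov(X, rowvar=False)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        assert np.max(np.abs(model.explained_variance_ratio - eig / eig.sum())) < 1e-8

    def test_loadings_orthonormal_and_reconstruction_exact(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 10))
        model = pca_fit(X, 10)
        assert np.max(np.abs(model.loadings.T @ model.loadings - np.eye(10))) < 1e-8
        recon = model.scores @ model.loadings.T + model.mean
        assert np.max(np.abs(recon - X)) < 1e-8

    def test_row_permutation_changes_loadings_at_most_by_sign(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(25, 8))
        a = pca_fit(X, 3).loadings
        b = pca_fit(X[rng.permutation(25)], 3).loadings
        for j in range(3):
            assert np.allclose(a[:, j], b[:, j], atol=1e-8) or np.allclose(
                a[:, j], -b[:, j], atol=1e-8
            )

    def test_rank_deficient_request_rejected(self):
        rng = np.random.default_rng(4)
        X = np.outer(rng.normal(size=20), rng.normal(size=6))  # rank 1
        with pytest.raises(ValueError, match="rank"):
            pca_fit(X, 4)


class TestScoresImage:
    def test_empty_mask_is_all_nan(self):
        rng = np.random.default_rng(0)
        model = _random_model(rng, 8, 2)
        wl = np.linspace(1000, 1300, 8)
        cube = h.HyperspectralCube(rng.uniform(size=(4, 4, 8)), wl, "corrected")
        om = h.ObjectMask(np.zeros((4, 4), bool), np.zeros((4, 4), int), 0)
        assert np.isnan(scores_image(model, cube, om, pc=1)).all()

    def test_single_pixel_value_is_its_projection(self):
        rng = np.random.default_rng(1)
        model = _random_model(rng, 8, 2)
        wl = np.linspace(1000, 1300, 8)
        data = rng.uniform(size=(4, 4, 8))
        cube = h.HyperspectralCube(data, wl, "corrected")
        labels = np.zeros((4, 4), int)
        labels[1, 2] = 1
        om = h.ObjectMask(labels > 0, labels, 1)
        img = scores_image(model, cube, om, pc=2)
        expected = (data[1, 2] - model.mean) @ model.loadings[:, 1]
        assert img[1, 2] == pytest.approx(expected)
        assert np.isnan(img[0, 0])

    def test_pc_out_of_range_rejected(self):
        model = _random_model(np.random.default_rng(2), 8, 2)
        wl = np.linspace(1000, 1300, 8)
        cube = h.HyperspectralCube(np.zeros((2, 2, 8)), wl, "corrected")
        om = h.ObjectMask(np.zeros((2, 2), bool), np.zeros((2, 2), int), 0)
        with pytest.raises(ValueError, match="pc"):
            scores_image(model, cube, om, pc=3)

    def test_two_class_scene_separates_on_pc1(self, signatures):
        cfg = h.SceneConfig(seed=21)
        scene = h.generate_scene(
            cfg, signatures, class_assignment=["A", "B", "A", "B"]
        )
        corrected = h.correct_reflectance(scene.raw, scene.refs)
        om = h.label_objects(h.segment_background(corrected))
        table = h.extract_pixel_spectra(corrected, om, "s")
        prep = lambda s: snv(wt_smooth(s))
        model = pca_fit(prep(table.spectra), 2)
        img = scores_image(model, corrected, om, pc=1, preprocess=prep)
        cm = scene.truth.class_map
        gap = np.nanmean(img[cm == 1]) - np.nanmean(img[cm == 2])
        assert abs(gap) > 0.5  # classes separate strongly on PC1


class TestPCASelection:
    def test_single_spike_selected_first(self):
        model = _random_model(np.random.default_rng(5), 12, 1)
        loadings = np.zeros((12, 1))
        loadings[7, 0] = 1.0
        model.loadings = loadings
        model.explained_variance_ratio = np.array([0.9])
        sel = select_by_pca_loadings(model, n_select=1, n_pcs=1)
        assert sel.band_indices.tolist() == [7]

    @pytest.mark.parametrize("seed,n_select", [(0, 3), (1, 5), (2, 8), (3, 12)])
    def test_matches_bruteforce_oracle(self, seed, n_select):
        rng = np.random.default_rng(seed)
        model = _random_model(rng, 12, 4)
        sel = select_by_pca_loadings(model, n_select=n_select, n_pcs=4)
        oracle = _oracle_pca_rank(
            model.loadings, model.explained_variance_ratio, 4, n_select
        )
        assert sel.band_indices.tolist() == oracle

    def test_cardinality_uniqueness_and_wavelength_mapping(self, mini_study):
        _, _, pixels, _ = mini_study
        model = pca_fit(pixels.spectra, 7, wavelengths=pixels.wavelengths)
        sel = select_by_pca_loadings(model, n_select=17)
        assert len(sel.band_indices) == 17
        assert len(set(sel.band_indices.tolist())) == 17
        assert np.all(np.diff(sel.band_indices) > 0)
        spacing = np.diff(pixels.wavelengths).max()
        for idx, nm in zip(sel.band_indices, sel.wavelengths):
            assert abs(pixels.wavelengths[idx] - nm) <= spacing

    def test_too_many_bands_rejected(self):
        model = _random_model(np.random.default_rng(6), 12, 2)
        with pytest.raises(ValueError, match="select"):
            select_by_pca_loadings(model, n_select=13, n_pcs=2)


class TestICA:
    def test_same_seed_reproduces_unmixing(self):
        rng = np.random.default_rng(7)
        # non-Gaussian sources: ICA is only identifiable for these
        X = rng.uniform(-1, 1, size=(300, 3)) @ rng.normal(size=(3, 6))
        a = ica_fit(X, 3, seed=5)
        b = ica_fit(X, 3, seed=5)
        assert np.array_equal(a.unmixing, b.unmixing)

    def test_unmixing_reproduces_sources(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(200, 5))
        model = ica_fit(X, 3, seed=1)
        recon = (X - model.mean) @ model.unmixing.T
        assert np.max(np.abs(recon - model.sources)) < 1e-8

    def test_recovers_two_uniform_sources(self):
        rng = np.random.default_rng(9)
        s = rng.uniform(-1, 1, size=(2000, 2))
        A = np.array([[1.0, 0.6], [0.4, 1.0]])
        X = s @ A.T
        model = ica_fit(X, 2, seed=3)
        corr = np.corrcoef(s.T, model.sources.T)[:2, 2:]
        # best assignment up to permutation and sign
        best = max(
            abs(corr[0, 0]) + abs(corr[1, 1]), abs(corr[0, 1]) + abs(corr[1, 0])
        )
        assert best / 2 >= 0.95

    def test_components_beyond_rank_rejected(self):
        rng = np.random.default_rng(10)
        X = np.outer(rng.normal(size=50), rng.normal(size=6))
        with pytest.raises(ValueError, match="rank"):
            ica_fit(X, 3, seed=0)


class TestICASelection:
    def test_trivial_weight_matrix(self):
        from hsichem.select import ICAModel

        model = ICAModel(
            mixing=np.zeros((3, 2)),
            unmixing=np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]),
            sources=np.zeros((1, 2)),
            mean=np.zeros(3),
            n_components=2,
            seed=0,
            n_iter=1,
        )
        sel = select_by_ica_weights(model, n_select=2)
        assert np.allclose(sel.scores, [0.5, 0.5, 0.0])
        assert sel.band_indices.tolist() == [0, 1]

    def test_matches_bruteforce_ranking(self):
        from hsichem.select import ICAModel

        rng = np.random.default_rng(11)
        W = rng.normal(size=(4, 10))
        model = ICAModel(
            mixing=np.zeros((10, 4)),
            unmixing=W,
            sources=np.zeros((1, 4)),
            mean=np.zeros(10),
            n_components=4,
            seed=0,
            n_iter=1,
        )
        sel = select_by_ica_weights(model, n_select=6)
        score = np.abs(W).mean(axis=0)
        oracle = sorted(sorted(range(10), key=lambda b: (-score[b], b))[:6])
        assert sel.band_indices.tolist() == oracle
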