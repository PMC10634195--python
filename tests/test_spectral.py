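"""Normalization, PCA invariants, loading annotation and score-space classing."""

import numpy as np
import pytest

from evlipo.bands import BandTable, default_band_table, default_components
from evlipo.spectral import (
    SpectrumSet,
    annotate_loading,
    classify_events,
    cluster_separation,
    fit_pca,
    normalize_spectra,
    select_region,
)
from evlipo.synth import DEFAULT_CLASSES, make_particle_spectrum

CHOLESTEROL_LINES = (698.0, 1438.0, 2850.0, 2866.0, 2888.0, 2932.0)


def _set(spectra, axis, labels=None):
    spectra = np.asarray(spectra, float)
    labels = np.array(["x"] * len(spectra)) if labels is None else np.asarray(labels)
    return SpectrumSet(spectra=spectra, axis=axis, labels=labels)


@pytest.fixture(scope="module")
def three_class_set():
    """EV / LDL / 50:50 complex event spectra with compositional jitter."""
    rng = np.random.default_rng(2024)
    axis = np.arange(600.0, 1802.0, 2.0)
    comps = default_components(axis)
    spectra, labels = [], []
    for lbl in ("EV", "LDL", "EV-LDL complex"):
        for _ in range(60):
            s = make_particle_spectrum(DEFAULT_CLASSES[lbl], comps, rng, jitter_sd=0.2)
            spectra.append(s + rng.normal(0, 0.01, len(axis)))
            labels.append(lbl)
    return _set(spectra, axis, labels)


class TestNormalization:
    def test_area_normalized_row_integrates_to_one(self):
        axis = np.arange(0.0, 10.0, 1.0)
        out = normalize_spectra(_set([np.ones(10)], axis), "area")
        assert np.trapezoid(out.spectra[0], axis) == pytest.approx(1.0)

    def test_snv_is_idempotent(self, rng):
        axis = np.arange(0.0, 100.0, 1.0)
        s = _set(rng.normal(1, 0.3, (5, 100)), axis)
        once = normalize_spectra(s, "snv")
        twice = normalize_spectra(once, "snv")
        assert np.allclose(once.spectra, twice.spectra)

    def test_area_normalization_is_scale_invariant(self, rng):
        axis = np.arange(0.0, 50.0, 1.0)
        x = rng.uniform(0.5, 2.0, (3, 50))
        a = normalize_spectra(_set(x, axis), "area")
        b = normalize_spectra(_set(7.0 * x, axis), "area")
        assert np.allclose(a.spectra, b.spectra)

    def test_zero_row_error_names_the_row(self, rng):
        axis = np.arange(0.0, 10.0, 1.0)
        x = rng.uniform(0.5, 2.0, (3, 10))
        x[1] = 0.0
        with pytest.raises(ValueError, match=r"\[1\]"):
            normalize_spectra(_set(x, axis), "area")
        with pytest.raises(ValueError, match=r"\[1\]"):
            normalize_spectra(_set(x, axis), "snv")

    def test_unknown_method_rejected(self):
        axis = np.arange(0.0, 10.0, 1.0)
        with pytest.raises(ValueError):
            normalize_spectra(_set([np.ones(10)], axis), "minmax")


class TestPCA:
    def test_identical_spectra_give_zero_scores_and_variance(self):
        axis = np.arange(0.0, 50.0, 1.0)
        model = fit_pca(_set(np.tile(np.sin(axis), (8, 1)), axis), 2)
        assert np.allclose(model.scores, 0.0)
        assert np.allclose(model.explained_variance_ratio, 0.0)

    def test_orthonormal_loadings_centered_scores_ordered_variance(self, rng):
        axis = np.arange(0.0, 80.0, 1.0)
        model = fit_pca(_set(rng.normal(size=(30, 80)), axis), 5)
        gram = model.loadings @ model.loadings.T
        assert np.allclose(gram, np.eye(5), atol=1e-8)
        assert np.allclose(model.scores.mean(axis=0), 0.0, atol=1e-8)
        assert (np.diff(model.explained_variance_ratio) <= 1e-12).all()

    def test_full_rank_reconstruction(self, rng):
        axis = np.arange(0.0, 40.0, 1.0)
        x = rng.normal(size=(10, 40))
        model = fit_pca(_set(x, axis), 10)
        recon = model.scores @ model.loadings + model.mean
        assert np.allclose(recon, x, atol=1e-6)

    def test_two_class_difference_at_1438_dominates_pc1_loading(self, rng):
        """Classes differing only at the 1438 cm^-1 band put the PC1 loading
        extremum within +/- 6 cm^-1 of that band."""
        axis = np.arange(600.0, 1802.0, 2.0)
        band = np.exp(-0.5 * ((axis - 1438.0) / 5.0) ** 2)
        base = np.exp(-0.5 * ((axis - 1000.0) / 30.0) ** 2)
        spectra = [base + (1.0 if i % 2 else 0.2) * band + rng.normal(0, 1e-3, len(axis))
                   for i in range(40)]
        model = fit_pca(_set(spectra, axis), 1)
        peak_wn = axis[np.argmax(np.abs(model.loadings[0]))]
        assert abs(peak_wn - 1438.0) <= 6.0

    def test_canonical_sign_makes_largest_element_positive(self, rng):
        axis = np.arange(0.0, 60.0, 1.0)
        model = fit_pca(_set(rng.normal(size=(20, 60)), axis), 3)
        for row in model.loadings:
            assert row[np.argmax(np.abs(row))] > 0


class TestAnnotation:
    def test_cholesterol_loading_matches_all_six_lines(self):
        from evlipo.bands import RamanBand, default_axis, make_component_spectrum

        axis = default_axis(600.0, 3100.0, 2.0)
        chol = make_component_spectrum(
            "cholesterol", [RamanBand(center=c) for c in CHOLESTEROL_LINES], axis
        )
        # build a rank-1 model whose PC1 loading IS the cholesterol spectrum
        v = chol.intensity / np.linalg.norm(chol.intensity)
        rng = np.random.default_rng(5)
        x = np.outer(rng.normal(size=30), v)
        model = fit_pca(_set(x, axis), 1)
        out = annotate_loading(model, 0, default_band_table(), tolerance=6.0)
        matched = {o["band_wavenumber"] for o in out if o["component"] == "cholesterol"}
        assert set(CHOLESTEROL_LINES) <= matched

    def test_empty_band_table_leaves_all_peaks_unmatched(self, rng):
        axis = np.arange(600.0, 1802.0, 2.0)
        x = np.outer(rng.normal(size=10), np.exp(-0.5 * ((axis - 1000) / 10) ** 2))
        model = fit_pca(_set(x, axis), 1)
        out = annotate_loading(model, 0, BandTable(entries=[]))
        assert out and all(o["component"] == "" for o in out)

    def test_peak_beyond_tolerance_is_unmatched(self, rng):
        axis = np.arange(600.0, 1802.0, 2.0)
        tol = 6.0
        center = 1438.0 + 8.0  # on-grid, just outside tolerance of the 1438 entry
        x = np.outer(rng.normal(size=10), np.exp(-0.5 * ((axis - center) / 5.0) ** 2))
        model = fit_pca(_set(x, axis), 1)
        table = BandTable(entries=[(1438.0, "cholesterol", "")])
        out = annotate_loading(model, 0, table, tolerance=tol)
        peaks_near = [o for o in out if abs(o["wavenumber"] - center) <= 4]
        assert peaks_near and all(o["component"] == "" for o in peaks_near)

    def test_component_index_out_of_range(self, rng):
        axis = np.arange(0.0, 20.0, 1.0)
        model = fit_pca(_set(rng.normal(size=(5, 20)), axis), 2)
        with pytest.raises(ValueError):
            annotate_loading(model, 5, default_band_table())


class TestSeparationAndClassing:
    def test_two_point_masses(self):
        axis = np.arange(0.0, 4.0, 1.0)
        x = np.array([[1, 0, 0, 0]] * 10 + [[-1, 0, 0, 0]] * 10, dtype=float)
        x += np.random.default_rng(0).normal(0, 1e-6, x.shape)
        labels = np.array(["a"] * 10 + ["b"] * 10)
        model = fit_pca(_set(x, axis, labels), 2)
        sep = cluster_separation(model)
        pair = sep["pairs"].iloc[0]
        assert pair["centroid_distance"] == pytest.approx(2.0, abs=1e-4)
        assert pair["silhouette"] > 0.99

    def test_single_label_rejected(self, rng):
        axis = np.arange(0.0, 10.0, 1.0)
        model = fit_pca(_set(rng.normal(size=(6, 10)), axis), 2)
        with pytest.raises(ValueError):
            cluster_separation(model)

    def test_tiny_label_flagged_with_nan_silhouette(self, rng):
        axis = np.arange(0.0, 10.0, 1.0)
        labels = np.array(["a"] * 9 + ["b"])
        model = fit_pca(_set(rng.normal(size=(10, 10)), axis, labels), 2)
        sep = cluster_separation(model)
        assert sep["flagged"] == ["b"]
        assert np.isnan(sep["pairs"].iloc[0]["silhouette"])

    def test_loading_sign_pattern_opposes_triglyceride_and_cholesterol(self, three_class_set):
        """Cholesterol-rich vesicles vs triglyceride-rich LDL put those two
        band families on opposite signs of the PC1 loading."""
        model = fit_pca(normalize_spectra(three_class_set, "snv"), 2)
        out = annotate_loading(model, 0, default_band_table())
        tri = {o["sign"] for o in out if o["component"] == "triglyceride"}
        chol = {o["sign"] for o in out if o["component"] == "cholesterol"}
        assert tri == {1} and chol == {-1}

    def test_complex_class_occupies_positive_quadrant_more_than_ev(self, three_class_set):
        model = fit_pca(normalize_spectra(three_class_set, "snv"), 2)
        sep = cluster_separation(model)
        q = sep["quadrant_fractions"]
        assert q["EV-LDL complex"]["(+,+)"] > q["EV"]["(+,+)"]

    def test_separation_invariant_to_global_scaling_under_snv(self, three_class_set):
        m1 = fit_pca(normalize_spectra(three_class_set, "snv"), 2)
        scaled = SpectrumSet(
            spectra=5.0 * three_class_set.spectra,
            axis=three_class_set.axis,
            labels=three_class_set.labels,
        )
        m2 = fit_pca(normalize_spectra(scaled, "snv"), 2)
        s1 = cluster_separation(m1)["pairs"]["centroid_distance"].to_numpy()
        s2 = cluster_separation(m2)["pairs"]["centroid_distance"].to_numpy()
        assert np.allclose(s1, s2, rtol=1e-8)

    def test_event_at_centroid_gets_that_label(self, three_class_set):
        model = fit_pca(normalize_spectra(three_class_set, "snv"), 2)
        centroid = model.scores[model.labels == "LDL", :2].mean(axis=0)
        pred, conf = classify_events(model, new_scores=centroid[None, :])
        assert pred[0] == "LDL" and conf[0] > 0.34

    def test_equidistant_event_tie_breaks_lexicographically(self):
        axis = np.arange(0.0, 4.0, 1.0)
        x = np.array([[1, 0, 0, 0]] * 5 + [[-1, 0, 0, 0]] * 5, dtype=float)
        labels = np.array(["b"] * 5 + ["a"] * 5)
        model = fit_pca(_set(x, axis, labels), 2)
        pred, conf = classify_events(model, new_scores=np.array([[0.0, 0.0]]))
        assert pred[0] == "a"
        assert conf[0] == pytest.approx(0.5)

    def test_well_separated_classes_classified_accurately(self, three_class_set):
        model = fit_pca(normalize_spectra(three_class_set, "snv"), 2)
        pred, _ = classify_events(model)
        assert (pred == three_class_set.labels).mean() >= 0.95

    def test_dimension_mismatch_rejected(self, three_class_set):
        model = fit_pca(normalize_spectra(three_class_set, "snv"), 2)
        with pytest.raises(ValueError):
            classify_events(model, new_scores=np.zeros((3, 4)))


def test_select_region_restricts_axis(three_class_set):
    sub = select_region(three_class_set, (700.0, 800.0))
    assert sub.axis.min() >= 700.0 and sub.axis.max() <= 800.0
    with pytest.raises(ValueError):
        select_region(three_class_set, (5000.0, 6000.0))
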