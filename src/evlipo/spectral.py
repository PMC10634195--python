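"""PCA-based spectral classing of trapping-event Raman spectra.

Event spectra are normalized, decomposed by PCA, and the loading peaks are
annotated against a chemical band table. Score-space statistics (centroid
distances, silhouettes, sign-quadrant occupancy of the first two components)
quantify how vesicle, lipoprotein and mixture populations separate: a
triglyceride-rich lipoprotein class and a cholesterol-rich vesicle class
produce a first loading whose triglyceride- and cholesterol-band peaks carry
opposite signs, and mixture (complex) particles score between the two.

Loading signs are canonicalized (largest-magnitude element positive) since
PCA eigenvector sign is arbitrary.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.signal import argrelextrema
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .bands import BandTable

__all__ = [
    "SpectrumSet",
    "PCAModel",
    "FINGERPRINT_REGION",
    "HIGH_FREQUENCY_REGION",
    "normalize_spectra",
    "select_region",
    "fit_pca",
    "annotate_loading",
    "cluster_separation",
    "classify_events",
]

FINGERPRINT_REGION = (600.0, 1800.0)
HIGH_FREQUENCY_REGION = (2800.0, 3050.0)


@dataclass
class SpectrumSet:
    """Event spectra (rows) on a shared wavenumber axis with sample labels."""

    spectra: np.ndarray
    axis: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.spectra.ndim != 2:
            raise ValueError("spectra must be a 2-D events x wavenumbers matrix")
        if self.spectra.shape[1] != len(self.axis):
            raise ValueError("spectra column count must equal axis length")
        if len(self.labels) != self.spectra.shape[0]:
            raise ValueError("labels length must equal spectra row count")
        if not np.isfinite(self.spectra).all():
            raise ValueError("spectra contain missing or non-finite values")


@dataclass
class PCAModel:
    mean: np.ndarray
    loadings: np.ndarray  # components x wavenumbers, rows orthonormal
    scores: np.ndarray  # events x components, column means ~ 0
    explained_variance_ratio: np.ndarray
    axis: np.ndarray
    labels: np.ndarray


def select_region(s: SpectrumSet, region: tuple[float, float]) -> SpectrumSet:
    """Restrict a spectrum set to a wavenumber interval (inclusive)."""
    lo, hi = region
    mask = (s.axis >= lo) & (s.axis <= hi)
    if not mask.any():
        raise ValueError(f"region [{lo}, {hi}] cm^-1 selects no wavenumbers")
    return SpectrumSet(spectra=s.spectra[:, mask], axis=s.axis[mask], labels=s.labels)


def normalize_spectra(s: SpectrumSet, method: str = "area") -> SpectrumSet:
    """Row-wise normalization: 'area' (unit integral over the axis),
    'snv' (standard normal variate: mean 0, sd 1), or 'none'."""
    if method == "none":
        return SpectrumSet(spectra=s.spectra.copy(), axis=s.axis, labels=s.labels)
    x = s.spectra
    if method == "area":
        integral = np.trapezoid(x, s.axis, axis=1)
        bad = np.where(np.abs(integral) < 1e-12)[0]
        if bad.size:
            raise ValueError(f"area normalization undefined for zero-integral row(s) {bad.tolist()}")
        out = x / integral[:, None]
    elif method == "snv":
        sd = x.std(axis=1, ddof=0)
        bad = np.where(sd < 1e-12)[0]
        if bad.size:
            raise ValueError(f"SNV normalization undefined for constant row(s) {bad.tolist()}")
        out = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return SpectrumSet(spectra=out, axis=s.axis, labels=s.labels)


def fit_pca(s: SpectrumSet, n_components: int = 2) -> PCAModel:
    """PCA of the spectrum set with canonicalized loading signs.

    Degenerate (zero-variance) input yields all-zero scores and explained
    variance ratios rather than an error.
    """
    n_rows = s.spectra.shape[0]
    if not (1 <= n_components <= n_rows):
        raise ValueError("need rows >= n_components >= 1")
    mean = s.spectra.mean(axis=0)
    centered = s.spectra - mean
    total_var = float((centered**2).sum())
    if total_var < 1e-24:
        k = min(n_components, s.spectra.shape[1])
        loadings = np.zeros((k, s.spectra.shape[1]))
        loadings[np.arange(k), np.arange(k)] = 1.0  # arbitrary orthonormal set
        return PCAModel(
            mean=mean,
            loadings=loadings,
            scores=np.zeros((n_rows, k)),
            explained_variance_ratio=np.zeros(k),
            axis=s.axis,
            labels=s.labels,
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(s.spectra)
    loadings = pca.components_.copy()
    # canonical sign: largest-magnitude loading element positive
    for i in range(loadings.shape[0]):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] = -loadings[i]
            scores[:, i] = -scores[:, i]
    return PCAModel(
        mean=mean,
        loadings=loadings,
        scores=scores,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        axis=s.axis,
        labels=s.labels,
    )


def annotate_loading(
    model: PCAModel,
    component_index: int,
    table: BandTable,
    tolerance: float = 6.0,
    peak_threshold: float = 0.3,
) -> list[dict]:
    """Match loading extrema to chemical band assignments.

    Local extrema with |loading| >= ``peak_threshold`` x the loading's max
    magnitude are matched to the nearest band-table entry within
    ``tolerance`` cm^-1; unmatched peaks carry an empty assignment.
    Returns dicts with wavenumber, sign (+1/-1), loading value, matched
    component and assignment note.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    if not (0 <= component_index < model.loadings.shape[0]):
        raise ValueError(f"component index {component_index} out of range")
    loading = model.loadings[component_index]
    amp = np.abs(loading)
    if amp.max() == 0:
        return []
    cut = peak_threshold * amp.max()
    maxima = argrelextrema(loading, np.greater_equal, order=2)[0]
    minima = argrelextrema(loading, np.less_equal, order=2)[0]
    # plateau guards: drop flat-run duplicates and sub-threshold extrema
    peaks = sorted(
        {int(i) for i in np.concatenate([maxima, minima]) if amp[i] >= cut}
    )
    out = []
    for i in peaks:
        wn = float(model.axis[i])
        entry = table.nearest(wn)
        matched = entry is not None and abs(entry[0] - wn) <= tolerance
        out.append(
            {
                "wavenumber": wn,
                "sign": int(np.sign(loading[i])) or 1,
                "loading": float(loading[i]),
                "component": entry[1] if matched else "",
                "assignment": entry[2] if matched else "",
                "band_wavenumber": float(entry[0]) if matched else np.nan,
            }
        )
    return out


def cluster_separation(model: PCAModel, labels: np.ndarray | None = None) -> dict:
    """Separation statistics on the first two principal-component scores.

    Returns per-label-pair centroid distances and silhouettes, plus, per
    label, the fraction of events in each PC1/PC2 sign quadrant. Labels with
    fewer than 2 events are flagged and excluded from silhouettes.
    """
    labels = model.labels if labels is None else np.asarray(labels)
    if model.scores.shape[1] < 2:
        raise ValueError("cluster separation needs at least two components")
    uniq = sorted(set(labels.tolist()))
    if len(uniq) < 2:
        raise ValueError("need at least two distinct labels")
    xy = model.scores[:, :2]
    flagged = [u for u in uniq if (labels == u).sum() < 2]
    pairs = []
    for a, b in combinations(uniq, 2):
        ma, mb = labels == a, labels == b
        dist = float(np.linalg.norm(xy[ma].mean(axis=0) - xy[mb].mean(axis=0)))
        if a in flagged or b in flagged:
            sil = np.nan
        else:
            sel = ma | mb
            sil = float(silhouette_score(xy[sel], labels[sel]))
        pairs.append({"label_a": a, "label_b": b, "centroid_distance": dist, "silhouette": sil})
    quadrants = {}
    for u in uniq:
        sub = xy[labels == u]
        n = len(sub)
        quadrants[u] = {
            "(+,+)": float(((sub[:, 0] > 0) & (sub[:, 1] > 0)).sum() / n),
            "(+,-)": float(((sub[:, 0] > 0) & (sub[:, 1] <= 0)).sum() / n),
            "(-,+)": float(((sub[:, 0] <= 0) & (sub[:, 1] > 0)).sum() / n),
            "(-,-)": float(((sub[:, 0] <= 0) & (sub[:, 1] <= 0)).sum() / n),
        }
    return {"pairs": pd.DataFrame(pairs), "quadrant_fractions": quadrants, "flagged": flagged}


def classify_events(
    model: PCAModel,
    reference_labels: np.ndarray | None = None,
    new_scores: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-centroid classification in the first two PCs.

    Centroids come from the fitted model's reference labels; ``new_scores``
    defaults to the model's own scores. Confidence is the softmin of
    centroid distances; exact ties resolve to the lexicographically first
    label (with correspondingly split confidence).
    """
    labels = model.labels if reference_labels is None else np.asarray(reference_labels)
    scores = model.scores[:, :2] if new_scores is None else np.asarray(new_scores, dtype=float)
    if scores.ndim != 2 or scores.shape[1] != 2:
        raise ValueError("new_scores must be an (n, 2) array of PC1/PC2 scores")
    uniq = sorted(set(labels.tolist()))
    centroids = np.vstack([model.scores[labels == u, :2].mean(axis=0) for u in uniq])
    d = np.linalg.norm(scores[:, None, :] - centroids[None, :, :], axis=2)
    w = np.exp(-(d - d.min(axis=1, keepdims=True)))
    conf = w / w.sum(axis=1, keepdims=True)
    # argmin takes the first (lexicographically smallest) label on exact ties
    best = d.argmin(axis=1)
    pred = np.array([uniq[i] for i in best], dtype=object)
    return pred, conf[np.arange(len(pred)), best]
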