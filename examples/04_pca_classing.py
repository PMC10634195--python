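"""Separate vesicle, lipoprotein and complex event spectra in PCA space.

Cholesterol-rich vesicles and triglyceride-rich low-density-lipoprotein
particles load the two band families on opposite signs of PC1, so a
vesicle-lipoprotein complex lands between the pure clusters.
"""

import numpy as np

from evlipo import (
    DEFAULT_CLASSES,
    SpectrumSet,
    annotate_loading,
    cluster_separation,
    default_axis,
    default_band_table,
    default_components,
    fit_pca,
    make_particle_spectrum,
    normalize_spectra,
)

axis = default_axis(600.0, 1800.0, 2.0)
components = default_components(axis)
rng = np.random.default_rng(909)

spectra, labels = [], []
for label in ("EV", "LDL", "EV-LDL complex"):
    for _ in range(80):
        s = make_particle_spectrum(DEFAULT_CLASSES[label], components, rng, jitter_sd=0.2)
        spectra.append(s + rng.normal(0, 0.01, len(axis)))
        labels.append(label)

sset = SpectrumSet(spectra=np.array(spectra), axis=axis, labels=np.array(labels))
model = fit_pca(normalize_spectra(sset, "snv"), 2)
print(f"explained variance: PC1 {model.explained_variance_ratio[0]:.2f}, "
      f"PC2 {model.explained_variance_ratio[1]:.2f}")

annotations = annotate_loading(model, 0, default_band_table())
for comp in ("triglyceride", "cholesterol"):
    signs = {a["sign"] for a in annotations if a["component"] == comp}
    print(f"PC1 loading sign of {comp} bands: {signs}")

quadrants = cluster_separation(model)["quadrant_fractions"]
for label in ("EV", "LDL", "EV-LDL complex"):
    print(f"{label:<15s} fraction of events in the (+,+) quadrant: "
          f"{quadrants[label]['(+,+)']:.2f}")
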