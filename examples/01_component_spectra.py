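"""Build the component Raman spectra the synthetic particles are mixed from.

Each lipid or protein component is a sum of Gaussian bands on a shared
wavenumber grid; particle spectra are non-negative mixtures of these.
"""

import numpy as np

from evlipo import default_axis, default_band_table, default_components

axis = default_axis(600.0, 3100.0, 2.0)
components = default_components(axis)

print(f"axis: {axis[0]:.0f}-{axis[-1]:.0f} cm^-1, {len(axis)} points")
for name, comp in sorted(components.items()):
    peak = axis[np.argmax(comp.intensity)]
    print(f"  {name:<13s} max-normalized, strongest band near {peak:.0f} cm^-1")

# the band table maps loading peaks back to molecular assignments
table = default_band_table()
entry = table.nearest(1440.0)
print(f"nearest catalogued band to 1440 cm^-1: {entry[0]:.0f} cm^-1 ({entry[1]})")
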