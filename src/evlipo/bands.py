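"""Raman band models and reference component spectra.

Biological single particles trapped in an optical tweezer produce Raman
spectra that are, to a good approximation, weighted sums of a handful of
component spectra (cholesterol, triglycerides, protein, phospholipid).
Each component is modelled as a sum of Gaussian (optionally Lorentzian)
bands on a wavenumber axis in cm^-1.

The six cholesterol lines (698, 1438, 2850, 2866, 2888, 2932 cm^-1) are
the chemically anchored assignments used throughout; the remaining default
band positions are literature-standard lipid/protein markers and are fully
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RamanBand",
    "ComponentSpectrum",
    "BandTable",
    "DEFAULT_BANDS",
    "default_axis",
    "default_band_table",
    "default_components",
    "make_component_spectrum",
]

# FWHM -> Gaussian sigma
_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class RamanBand:
    """One vibrational band: center (cm^-1), FWHM width (cm^-1), relative amplitude."""

    center: float
    width: float = 12.0
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"band width must be > 0, got {self.width}")
        if self.amplitude < 0:
            raise ValueError(f"band amplitude must be >= 0, got {self.amplitude}")

    def profile(self, axis: np.ndarray, shape: str = "gaussian") -> np.ndarray:
        """Evaluate the band profile on a wavenumber axis."""
        if shape == "gaussian":
            sigma = self.width * _FWHM_TO_SIGMA
            return self.amplitude * np.exp(-0.5 * ((axis - self.center) / sigma) ** 2)
        if shape == "lorentzian":
            hwhm = self.width / 2.0
            return self.amplitude * hwhm**2 / ((axis - self.center) ** 2 + hwhm**2)
        raise ValueError(f"unknown band shape {shape!r}")


@dataclass(frozen=True)
class ComponentSpectrum:
    """A named chemical component evaluated on a shared wavenumber grid."""

    name: str
    bands: tuple[RamanBand, ...]
    axis: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.axis) <= 0):
            raise ValueError("wavenumber axis must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("component intensity must be non-negative everywhere")


@dataclass
class BandTable:
    """Wavenumber -> chemical assignment lookup used to annotate PCA loadings."""

    entries: list[tuple[float, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for wn, _, _ in self.entries:
            if wn <= 0:
                raise ValueError(f"band wavenumber must be positive, got {wn}")

    def nearest(self, wavenumber: float) -> tuple[float, str, str] | None:
        if not self.entries:
            return None
        return min(self.entries, key=lambda e: abs(e[0] - wavenumber))


# Cholesterol positions are the anchored assignments; the rest are standard
# lipid/protein markers.
DEFAULT_BANDS: dict[str, tuple[float, ...]] = {
    "cholesterol": (698.0, 1438.0, 2850.0, 2866.0, 2888.0, 2932.0),
    "triglyceride": (1302.0, 1445.0, 1747.0),
    "protein": (1003.0, 1656.0),
    "phospholipid": (718.0, 1094.0),
}

_ASSIGNMENT_NOTES: dict[str, str] = {
    "cholesterol": "sterol ring / CH2 / CH stretch",
    "triglyceride": "CH2 twist / CH2 bend / C=O ester",
    "protein": "phenylalanine / amide I",
    "phospholipid": "choline / C-C stretch",
}


def default_axis(start: float = 600.0, stop: float = 3100.0, step: float = 2.0) -> np.ndarray:
    """Default wavenumber grid, 600-3100 cm^-1 at 2 cm^-1 spacing."""
    return np.arange(start, stop + step / 2, step)


def make_component_spectrum(
    name: str,
    bands: list[RamanBand] | tuple[RamanBand, ...],
    axis: np.ndarray,
    shape: str = "gaussian",
) -> ComponentSpectrum:
    """Build a component spectrum as a max-normalized sum of band profiles.

    Raises ``ValueError`` naming the offending band if any band center lies
    outside the axis range.
    """
    axis = np.asarray(axis, dtype=float)
    if axis.ndim != 1 or axis.size < 2 or np.any(np.diff(axis) <= 0):
        raise ValueError("axis must be a strictly increasing 1-D grid")
    if not bands:
        raise ValueError("bands must be non-empty")
    lo, hi = axis[0], axis[-1]
    for b in bands:
        if not (lo <= b.center <= hi):
            raise ValueError(
                f"band center {b.center} cm^-1 outside axis range [{lo}, {hi}]"
            )
    intensity = np.zeros_like(axis)
    for b in bands:
        intensity += b.profile(axis, shape=shape)
    peak = intensity.max()
    if peak > 0:
        intensity = intensity / peak
    return ComponentSpectrum(name=name, bands=tuple(bands), axis=axis, intensity=intensity)


def default_band_table() -> BandTable:
    entries = [
        (wn, comp, _ASSIGNMENT_NOTES[comp])
        for comp, positions in DEFAULT_BANDS.items()
        for wn in positions
    ]
    return BandTable(entries=sorted(entries))


def default_components(
    axis: np.ndarray | None = None, shape: str = "gaussian"
) -> dict[str, ComponentSpectrum]:
    """The four default chemical components on a shared axis.

    Bands outside the axis range are dropped (a restricted fingerprint axis
    simply loses the high-frequency lines); a component with no band left on
    the axis is omitted.
    """
    if axis is None:
        axis = default_axis()
    lo, hi = axis[0], axis[-1]
    out = {}
    for name, centers in DEFAULT_BANDS.items():
        bands = [RamanBand(center=c) for c in centers if lo <= c <= hi]
        if bands:
            out[name] = make_component_spectrum(name, bands, axis, shape=shape)
    return out
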