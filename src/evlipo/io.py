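"""Plain-text (CSV) persistence for cycles, event tables and spectra.

Cycle files: column 0 time (s), column 1 Rayleigh (a.u.), remaining columns
Raman intensities with the wavenumber axis declared in the header
(``raman_<wavenumber>``). Event-spectrum matrices share the same header
convention.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .trapping import TraceCycle

__all__ = [
    "write_cycle",
    "read_cycle",
    "write_spectra",
    "read_spectra",
    "cycle_filename",
]


def cycle_filename(sample: int, cycle: int) -> str:
    return f"sample{sample:03d}_cycle{cycle:04d}.csv"


def write_cycle(cycle: TraceCycle, path: str | Path) -> Path:
    path = Path(path)
    cols = {"time_s": cycle.times, "rayleigh_au": cycle.rayleigh}
    for j, wn in enumerate(cycle.axis):
        cols[f"raman_{wn:g}"] = cycle.raman[:, j]
    pd.DataFrame(cols).to_csv(path, index=False)
    return path


def read_cycle(path: str | Path, sample: int = 0, cycle: int = 0) -> TraceCycle:
    df = pd.read_csv(path)
    raman_cols = [c for c in df.columns if c.startswith("raman_")]
    axis = np.array([float(c.split("_", 1)[1]) for c in raman_cols])
    order = np.argsort(axis)
    return TraceCycle(
        times=df["time_s"].to_numpy(),
        rayleigh=df["rayleigh_au"].to_numpy(),
        raman=df[raman_cols].to_numpy()[:, order],
        axis=axis[order],
        sample=sample,
        cycle=cycle,
    )


def write_spectra(spectra: np.ndarray, axis: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(spectra, columns=[f"raman_{wn:g}" for wn in axis]).to_csv(path, index=False)
    return path


def read_spectra(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    axis = np.array([float(c.split("_", 1)[1]) for c in df.columns])
    order = np.argsort(axis)
    return df.to_numpy()[:, order], axis[order]
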