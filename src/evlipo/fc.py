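"""Calibrated fluorescence flow-cytometry quantification over density fractions.

Fluorescence in arbitrary units is converted to ERF/MESF units by an
ordinary least-squares fit of log10(assigned bead value) on log10(measured
bead intensity). Event counts become concentrations of the original
fraction via time-based acquisition (events / (flow rate x time) x dilution;
the reference protocol dilutes 50 uL of each fraction into 950 uL, factor
20). Fractions pool into an LPP-rich window (1.06-1.10 g/cm^3) and an
EV-rich window (1.12-1.16 g/cm^3), both bounds inclusive, with densities
rounded to 2 decimals first (gradient fractions are discrete).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Calibration",
    "FractionSummary",
    "LPP_RICH_WINDOW",
    "EV_RICH_WINDOW",
    "FULL_WINDOW",
    "fit_calibration",
    "apply_calibration",
    "concentration",
    "fraction_summaries",
    "pooled_windows",
    "spike_in_compare",
    "detergent_sensitivity",
]

LPP_RICH_WINDOW = (1.06, 1.10)
EV_RICH_WINDOW = (1.12, 1.16)
FULL_WINDOW = (1.06, 1.16)

#: events/s above which coincident multi-particle detection ("swarming")
#: becomes plausible on this class of instrument
DEFAULT_SWARM_RATE_LIMIT = 10_000.0


@dataclass(frozen=True)
class Calibration:
    """log10-log10 fluorescence calibration: log10(ERF) = slope*log10(au) + intercept."""

    slope: float
    intercept: float
    r_squared: float

    def to_erf(self, fl_au: np.ndarray) -> np.ndarray:
        fl_au = np.asarray(fl_au, dtype=float)
        out = np.zeros_like(fl_au)
        pos = fl_au > 0
        out[pos] = 10.0 ** (self.slope * np.log10(fl_au[pos]) + self.intercept)
        return out  # fl_au == 0 maps to 0 by convention


@dataclass(frozen=True)
class FractionSummary:
    density: float
    n_events: int
    concentration: float
    condition: str = ""

    def __post_init__(self) -> None:
        if self.n_events < 0 or self.concentration < 0:
            raise ValueError("counts and concentrations must be >= 0")


def fit_calibration(beads: pd.DataFrame, force_unit_slope: bool = False) -> Calibration:
    """Least-squares bead regression in log10-log10 space.

    ``beads`` needs columns ``assigned_value`` (ERF/MESF) and
    ``measured_intensity`` (a.u., median of the bead population); at least
    two beads with distinct intensities are required.
    """
    assigned = beads["assigned_value"].to_numpy(dtype=float)
    measured = beads["measured_intensity"].to_numpy(dtype=float)
    if np.any(assigned <= 0) or np.any(measured <= 0):
        raise ValueError("bead values and intensities must be > 0")
    if len(np.unique(measured)) < 2:
        raise ValueError("need >= 2 beads with distinct measured intensities")
    x = np.log10(measured)
    y = np.log10(assigned)
    if force_unit_slope:
        slope = 1.0
        intercept = float(np.mean(y - x))
    else:
        slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return Calibration(slope=float(slope), intercept=float(intercept), r_squared=r2)


def apply_calibration(
    events: pd.DataFrame,
    calibration: Calibration,
    threshold: float = 100.0,
    swarm_rate_limit: float = DEFAULT_SWARM_RATE_LIMIT,
) -> pd.DataFrame:
    """Add calibrated ``fl_erf`` and an inclusive ``above_threshold`` flag.

    Zero fluorescence calibrates to 0 ERF (below any positive threshold).
    Warns when the observed event rate exceeds the swarm-risk limit.
    """
    out = events.copy()
    out["fl_erf"] = calibration.to_erf(out["fl_au"].to_numpy(dtype=float))
    out["above_threshold"] = out["fl_erf"] >= threshold
    if len(out) > 1 and "time" in out.columns:
        span = float(out["time"].max() - out["time"].min())
        if span > 0 and len(out) / span > swarm_rate_limit:
            warnings.warn(
                f"event rate {len(out) / span:.0f}/s exceeds swarm-risk limit "
                f"{swarm_rate_limit:.0f}/s; coincident detection likely",
                stacklevel=2,
            )
    return out


def concentration(
    n_events: int, acquisition_time: float, flow_rate: float, dilution_factor: float = 1.0
) -> float:
    """Time-based particle concentration of the original sample, events/uL."""
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    if acquisition_time <= 0 or flow_rate <= 0 or dilution_factor <= 0:
        raise ValueError("time, flow rate and dilution factor must be > 0")
    return n_events / (flow_rate * acquisition_time) * dilution_factor


def _in_window(density: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    return (density >= lo) & (density <= hi)


def fraction_summaries(
    events: pd.DataFrame,
    acquisition_time: float,
    flow_rate: float,
    dilution_factor: float = 20.0,
    condition: str = "",
) -> pd.DataFrame:
    """Per-density-fraction event counts and concentrations.

    Densities are rounded to 2 decimals before grouping; the returned frame
    has one row per observed fraction.
    """
    density = events["fraction_density"].to_numpy(dtype=float).round(2)
    rows = []
    for dens in sorted(set(density.tolist())):
        n = int((density == dens).sum())
        rows.append(
            {
                "density": dens,
                "n_events": n,
                "concentration": concentration(n, acquisition_time, flow_rate, dilution_factor),
                "condition": condition,
            }
        )
    return pd.DataFrame(rows, columns=["density", "n_events", "concentration", "condition"])


def pooled_windows(
    events: pd.DataFrame,
    acquisition_time: float,
    flow_rate: float,
    dilution_factor: float = 20.0,
    windows: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Pooled counts/concentrations over density windows (bounds inclusive).

    Defaults to the LPP-rich, EV-rich and full windows; events falling in no
    window are pooled as "other" so that window counts (over the disjoint
    LPP/EV/other partition) conserve the total.
    """
    if windows is None:
        windows = {"LPP-rich": LPP_RICH_WINDOW, "EV-rich": EV_RICH_WINDOW, "total": FULL_WINDOW}
    density = events["fraction_density"].to_numpy(dtype=float).round(2)
    rows = []
    claimed = np.zeros(len(density), dtype=bool)
    for name, win in windows.items():
        mask = _in_window(density, win)
        if name != "total":
            claimed |= mask
        n = int(mask.sum())
        rows.append(
            {
                "window": name,
                "low": win[0],
                "high": win[1],
                "n_events": n,
                "concentration": concentration(n, acquisition_time, flow_rate, dilution_factor),
            }
        )
    n_other = int((~claimed).sum())
    rows.append(
        {
            "window": "other",
            "low": np.nan,
            "high": np.nan,
            "n_events": n_other,
            "concentration": concentration(n_other, acquisition_time, flow_rate, dilution_factor),
        }
    )
    return pd.DataFrame(rows)


def spike_in_compare(summary_a: pd.DataFrame, summary_b: pd.DataFrame) -> pd.DataFrame:
    """Per-window fold change (B/A) and absolute difference between two
    pooled-window summaries (e.g., non-spiked control vs LPP-spiked sample).

    A zero-count window in A with events in B is flagged infinite rather
    than erroring; the difference is always reported.
    """
    a = summary_a.set_index("window")
    b = summary_b.set_index("window")
    if sorted(a.index) != sorted(b.index):
        raise ValueError("window sets differ between the two summaries")
    rows = []
    for w in a.index:
        na, nb = float(a.loc[w, "n_events"]), float(b.loc[w, "n_events"])
        if na == 0:
            fold, infinite = (1.0, False) if nb == 0 else (np.inf, True)
        else:
            fold, infinite = nb / na, False
        rows.append(
            {
                "window": w,
                "n_a": na,
                "n_b": nb,
                "fold_change": fold,
                "infinite": infinite,
                "difference": nb - na,
            }
        )
    return pd.DataFrame(rows)


def detergent_sensitivity(pre_counts: dict[str, int], post_counts: dict[str, int]) -> pd.DataFrame:
    """Percent of events lost per gate after detergent (lysis) treatment.

    loss = 100 * (1 - post/pre); a post > pre gate is clipped to 0% with an
    anomaly flag, and pre = 0 is undefined (NaN, flagged).
    """
    if sorted(pre_counts) != sorted(post_counts):
        raise ValueError("pre and post gates must match")
    rows = []
    for gate in sorted(pre_counts):
        pre, post = pre_counts[gate], post_counts[gate]
        if pre < 0 or post < 0:
            raise ValueError("gate counts must be >= 0")
        if pre == 0:
            loss, flag = np.nan, "undefined (pre=0)"
        elif post > pre:
            loss, flag = 0.0, "anomaly (post>pre)"
        else:
            loss, flag = 100.0 * (1.0 - post / pre), ""
        rows.append({"gate": gate, "pre": pre, "post": post, "percent_lost": loss, "flag": flag})
    return pd.DataFrame(rows)
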