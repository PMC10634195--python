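"""Rayleigh-trace computation and trapping-event segmentation.

An optical trap holds at most one particle at a time; a capture shows up as
a step-wise increase of the elastic (Rayleigh) scattering intensity that
persists until the laser is blocked at the end of the acquisition cycle.
This module turns per-cycle Rayleigh/Raman spectral stacks into a table of
trapping events, each with one background-subtracted Raman spectrum.

Step detection uses a two-window mean-difference statistic
``d[i] = mean(x[i:i+w]) - mean(x[i-w:i])`` thresholded at
``max(min_step, k * sigma_hat)`` where ``sigma_hat`` is a robust noise scale
(median absolute deviation of first differences / sqrt(2)); the change point
is refined to the local argmax of ``d``. All indices are 0-based and
intervals half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TraceCycle",
    "TrappingEvent",
    "SegmentationParams",
    "compute_rayleigh_trace",
    "detect_steps",
    "extract_event_spectrum",
    "run_campaign_segmentation",
]


@dataclass
class TraceCycle:
    """One acquisition cycle: a timestamped stack of synchronous spectra."""

    times: np.ndarray  # seconds, strictly increasing
    rayleigh: np.ndarray  # elastic-scatter intensity per spectrum (a.u.)
    raman: np.ndarray  # spectra x wavenumbers (a.u.)
    axis: np.ndarray  # wavenumber grid (cm^-1)
    sample: int = 0
    cycle: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.rayleigh = np.asarray(self.rayleigh, dtype=float)
        self.raman = np.asarray(self.raman, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if len(self.rayleigh) != self.raman.shape[0]:
            raise ValueError("rayleigh length must equal raman row count")
        if self.raman.shape[1] != len(self.axis):
            raise ValueError("raman column count must equal axis length")

    @property
    def n_spectra(self) -> int:
        return len(self.rayleigh)


@dataclass
class TrappingEvent:
    """A detected trapped-particle interval [start_idx, end_idx)."""

    start_idx: int
    end_idx: int
    background_idx: np.ndarray
    step_height: float
    event_spectrum: np.ndarray
    truncated: bool = False
    sample: int = 0
    cycle: int = 0

    def __post_init__(self) -> None:
        if not self.start_idx < self.end_idx:
            raise ValueError("event interval must be non-empty")
        bg = np.asarray(self.background_idx)
        if np.any((bg >= self.start_idx) & (bg < self.end_idx)):
            raise ValueError("background indices must be disjoint from the event interval")


@dataclass
class SegmentationParams:
    min_step: float = 3.0  # a.u., minimum accepted step height
    min_duration: int = 5  # spectra
    k_sigma: float = 5.0  # robust-noise multiplier for the detection threshold
    window: int | None = None  # two-window half width; defaults to min_duration
    merge_gap: int = 3  # events closer than this many spectra are joined
    background_n: int = 20  # pre-event baseline spectra used for subtraction
    rayleigh_window: tuple[float, float] | None = None  # derive trace from spectra


def compute_rayleigh_trace(
    cycle: TraceCycle, window: tuple[float, float] | None = None
) -> np.ndarray:
    """Per-spectrum elastic-scatter scalar series.

    Returns the stored Rayleigh channel, or, when ``window`` is given, the
    mean Raman-stack intensity over that wavenumber interval (used when the
    elastic line is recorded within the spectral axis rather than on a
    separate channel).
    """
    if window is None:
        return cycle.rayleigh.copy()
    lo, hi = window
    if lo >= hi:
        raise ValueError("window must be a non-empty (low, high) wavenumber interval")
    mask = (cycle.axis >= lo) & (cycle.axis <= hi)
    if not mask.any():
        raise ValueError(f"window [{lo}, {hi}] cm^-1 selects no wavenumbers")
    return cycle.raman[:, mask].mean(axis=1)


def _robust_noise_sd(trace: np.ndarray) -> float:
    """Noise sd estimate from the MAD of first differences (step-insensitive)."""
    d = np.diff(trace)
    if len(d) == 0:
        return 0.0
    mad = np.median(np.abs(d - np.median(d)))
    return float(mad * 1.4826 / np.sqrt(2.0))


def detect_steps(
    trace: np.ndarray,
    min_step: float = 3.0,
    min_duration: int = 5,
    k_sigma: float = 5.0,
    window: int | None = None,
    merge_gap: int = 3,
) -> list[tuple[int, int, float]]:
    """Detect step-wise increases; returns sorted (start, end, step_height).

    An interval is reported when its mean level exceeds the preceding
    baseline by at least ``max(min_step, k_sigma * sigma_hat)`` and it lasts
    at least ``min_duration`` spectra. Up- and down-going change points are
    both located so that mid-cycle release (a return to baseline) terminates
    an event; an event still open at trace end is truncated there.
    """
    if min_step <= 0:
        raise ValueError("min_step must be > 0")
    if min_duration < 1:
        raise ValueError("min_duration must be >= 1")
    trace = np.asarray(trace, dtype=float)
    n = len(trace)
    if n < max(min_duration, 2):
        return []
    w = window if window is not None else min_duration
    w = max(1, min(w, n // 2))

    # two-window mean-difference statistic at every candidate change index,
    # with windows shrunk near the trace edges so that early/late captures
    # remain detectable
    cs = np.concatenate([[0.0], np.cumsum(trace)])
    idx = np.arange(1, n)
    before_len = np.minimum(idx, w)
    after_len = np.minimum(n - idx, w)
    before = (cs[idx] - cs[idx - before_len]) / before_len
    after = (cs[idx + after_len] - cs[idx]) / after_len
    d = after - before  # d[j] corresponds to a change at index idx[j]

    # the statistic's noise sd is sigma * sqrt(1/len_before + 1/len_after)
    sigma = _robust_noise_sd(trace)
    threshold = np.maximum(
        min_step, k_sigma * sigma * np.sqrt(1.0 / before_len + 1.0 / after_len)
    )

    # candidate change points: local argmax (resp. argmin) of contiguous
    # super-threshold runs of the statistic
    def _change_points(stat: np.ndarray) -> list[int]:
        above = stat >= threshold
        pts: list[int] = []
        j = 0
        while j < len(stat):
            if above[j]:
                k = j
                while k + 1 < len(stat) and above[k + 1]:
                    k += 1
                pts.append(int(idx[j + int(np.argmax(stat[j : k + 1]))]))
                j = k + 1
            else:
                j += 1
        return pts

    ups = _change_points(d)
    downs = _change_points(-d)

    raw: list[tuple[int, int]] = []
    for s in ups:
        ends = [e for e in downs if e > s]
        e = min(ends) if ends else n
        raw.append((s, e))
    # drop nested duplicates from consecutive up-steps sharing a down-step
    raw = sorted(set(raw))
    merged: list[list[int]] = []
    for s, e in raw:
        if merged and s - merged[-1][1] < merge_gap:
            merged[-1][1] = max(merged[-1][1], e)
        elif merged and s < merged[-1][1]:
            continue  # overlapping (one trapped particle at a time)
        else:
            merged.append([s, e])

    events: list[tuple[int, int, float]] = []
    prev_end = 0
    for s, e in merged:
        if e - s < min_duration:
            prev_end = e
            continue
        # baseline: up to 20 pre-step samples, not crossing the previous event
        b0 = max(prev_end, s - max(w, 20))
        baseline = trace[b0:s]
        height = float(trace[s:e].mean() - (baseline.mean() if len(baseline) else 0.0))
        if height >= min_step:
            events.append((s, e, height))
        prev_end = e
    return events


def extract_event_spectrum(
    cycle: TraceCycle,
    interval: tuple[int, int],
    background_n: int = 20,
    step_height: float | None = None,
) -> TrappingEvent:
    """Background-subtracted mean Raman spectrum of one trapped interval.

    Background is the last ``background_n`` pre-event baseline spectra of the
    same cycle (nearest-in-time, tracking slow drift); if none exist the
    post-release spectra after the event are used instead; with neither a
    ``ValueError`` is raised.
    """
    s, e = interval
    n = cycle.n_spectra
    if not (0 <= s < e <= n):
        raise ValueError(f"invalid event interval [{s}, {e}) for cycle of {n} spectra")
    if s > 0:
        bg_idx = np.arange(max(0, s - background_n), s)
    elif e < n:
        bg_idx = np.arange(e, min(n, e + background_n))
    else:
        raise ValueError("no background spectra available in this cycle")
    event_mean = cycle.raman[s:e].mean(axis=0)
    bg_mean = cycle.raman[bg_idx].mean(axis=0)
    if step_height is None:
        step_height = float(cycle.rayleigh[s:e].mean() - cycle.rayleigh[bg_idx].mean())
    return TrappingEvent(
        start_idx=s,
        end_idx=e,
        background_idx=bg_idx,
        step_height=step_height,
        event_spectrum=event_mean - bg_mean,
        truncated=e == n,
        sample=cycle.sample,
        cycle=cycle.cycle,
    )


def run_campaign_segmentation(
    cycles,
    params: SegmentationParams | None = None,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Segment every cycle of a campaign into one spectrum per event.

    Accepts any iterable of :class:`TraceCycle` (a lazy generator streams
    without materialising the campaign). Returns (event table, event-spectra
    matrix aligned with the table rows, wavenumber axis).
    """
    params = params or SegmentationParams()
    rows: list[dict] = []
    spectra: list[np.ndarray] = []
    axis: np.ndarray | None = None
    for cyc in cycles:
        if axis is None:
            axis = cyc.axis
        elif len(axis) != len(cyc.axis) or not np.allclose(axis, cyc.axis):
            raise ValueError(
                f"wavenumber axis mismatch at sample {cyc.sample} cycle {cyc.cycle}"
            )
        trace = compute_rayleigh_trace(cyc, params.rayleigh_window)
        steps = detect_steps(
            trace,
            min_step=params.min_step,
            min_duration=params.min_duration,
            k_sigma=params.k_sigma,
            window=params.window,
            merge_gap=params.merge_gap,
        )
        for s, e, height in steps:
            ev = extract_event_spectrum(
                cyc, (s, e), background_n=params.background_n, step_height=height
            )
            rows.append(
                {
                    "sample": cyc.sample,
                    "cycle": cyc.cycle,
                    "start": s,
                    "end": e,
                    "step_height": height,
                    "truncated": ev.truncated,
                }
            )
            spectra.append(ev.event_spectrum)
    table = pd.DataFrame(
        rows, columns=["sample", "cycle", "start", "end", "step_height", "truncated"]
    )
    mat = np.vstack(spectra) if spectra else np.empty((0, len(axis) if axis is not None else 0))
    return table, mat, axis if axis is not None else np.empty(0)
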