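"""End-to-end orchestration: simulate -> segment -> pca -> morphometry -> quantify.

A single YAML/JSON-style config drives every stage; all randomness is
spawned from one master seed through named substreams, so a rerun with the
same config produces identical outputs. Stage blocks are optional — a
missing block skips that stage with a warning — and each stage's outputs are
written under the run directory together with a manifest recording the
config hash, seed and package version.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .afm import DEFAULT_PRIORS, PopulationPrior, classify_particles, measure_particles
from .bands import default_axis, default_band_table, default_components
from .fc import apply_calibration, fit_calibration, fraction_summaries, pooled_windows
from .io import cycle_filename, write_cycle, write_spectra
from .spectral import (
    SpectrumSet,
    annotate_loading,
    cluster_separation,
    fit_pca,
    normalize_spectra,
    select_region,
)
from .synth import (
    DEFAULT_CLASSES,
    CampaignConfig,
    generate_afm_particles,
    generate_fc_events,
    simulate_campaign,
)
from .trapping import SegmentationParams, run_campaign_segmentation

__all__ = ["load_config", "run_pipeline"]

logger = logging.getLogger("evlipo")

STAGES = ("simulate", "segment", "pca", "morphometry", "quantify")


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValueError("config must be a mapping")
    return config


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _substream_seed(master_seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _resolve_classes(names_fracs: list) -> list:
    out = []
    for item in names_fracs:
        name, frac = item["class"], float(item["fraction"])
        if name not in DEFAULT_CLASSES:
            raise KeyError(f"unknown particle class {name!r}")
        out.append((DEFAULT_CLASSES[name], frac))
    return out


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Run the configured stages and return the consolidated report.

    A stage failure aborts the run with the failing stage named; outputs of
    already-completed stages are left in place.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master_seed = int(config.get("seed", 0))
    report: dict = {
        "config_hash": _config_hash(config),
        "seed": master_seed,
        "version": __version__,
        "stages": {},
    }
    state: dict = {}

    for stage in STAGES:
        if stage not in config:
            warnings.warn(f"stage {stage!r} missing from config; skipped")
            report["stages"][stage] = {"status": "skipped"}
            continue
        t0 = time.perf_counter()
        logger.info("stage %s: start", stage)
        try:
            summary = _RUNNERS[stage](config[stage], master_seed, out_dir, state)
        except Exception as exc:  # noqa: BLE001 - name the failing stage
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        summary["status"] = "ok"
        summary["elapsed_s"] = round(time.perf_counter() - t0, 3)
        report["stages"][stage] = summary
        logger.info("stage %s: done in %.2fs", stage, summary["elapsed_s"])

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report


def _run_simulate(block: dict, master_seed: int, out_dir: Path, state: dict) -> dict:
    seed = _substream_seed(master_seed, "simulate")
    campaign = CampaignConfig(seed=seed, **block.get("campaign", {}))
    axis_cfg = block.get("axis", {})
    axis = default_axis(**axis_cfg)
    classes = _resolve_classes(
        block.get("classes", [{"class": "EV", "fraction": 0.5}, {"class": "LDL", "fraction": 0.5}])
    )
    cycles, truth = simulate_campaign(campaign, classes, axis=axis)
    cyc_dir = out_dir / "cycles"
    if block.get("write_cycles", False):
        cyc_dir.mkdir(exist_ok=True)
        for c in cycles:
            write_cycle(c, cyc_dir / cycle_filename(c.sample, c.cycle))
    truth.to_csv(out_dir / "ground_truth_events.csv", index=False)
    state["cycles"] = cycles
    state["truth"] = truth
    state["classes"] = classes
    state["axis"] = axis
    return {
        "n_cycles": len(cycles),
        "total_spectra": campaign.total_spectra,
        "cycle_duration_s": round(campaign.cycle_duration, 1),
        "n_true_events": len(truth),
    }


def _run_segment(block: dict, master_seed: int, out_dir: Path, state: dict) -> dict:
    if "cycles" not in state:
        raise ValueError("segment stage requires the simulate stage (or pre-loaded cycles)")
    params = SegmentationParams(**block)
    events, spectra, axis = run_campaign_segmentation(state["cycles"], params)
    events.to_csv(out_dir / "events.csv", index=False)
    write_spectra(spectra, axis, out_dir / "event_spectra.csv")
    state["events"] = events
    state["event_spectra"] = spectra
    return {"n_events": len(events)}


def _run_pca(block: dict, master_seed: int, out_dir: Path, state: dict) -> dict:
    if "events" not in state or len(state["events"]) == 0:
        raise ValueError("pca stage requires segmented event spectra")
    # label each detected event by the true class of its cycle (synthetic runs)
    truth = state["truth"].set_index(["sample", "cycle"])["class"]
    labels = np.array(
        [
            truth.get((r.sample, r.cycle), "unknown")
            for r in state["events"].itertuples()
        ],
        dtype=object,
    )
    sset = SpectrumSet(spectra=state["event_spectra"], axis=state["axis"], labels=labels)
    region = tuple(block.get("region", (600.0, 1800.0)))
    sset = select_region(sset, region)
    sset = normalize_spectra(sset, method=block.get("normalize", "snv"))
    model = fit_pca(sset, n_components=int(block.get("n_components", 2)))
    pd.DataFrame(
        model.scores, columns=[f"PC{i+1}" for i in range(model.scores.shape[1])]
    ).assign(label=labels).to_csv(out_dir / "pca_scores.csv", index=False)
    write_spectra(model.loadings, model.axis, out_dir / "pca_loadings.csv")
    annot = annotate_loading(model, 0, default_band_table(), tolerance=float(block.get("tolerance", 6.0)))
    with open(out_dir / "pc1_annotation.json", "w") as fh:
        json.dump(annot, fh, indent=2)
    summary: dict = {
        "explained_variance_ratio": model.explained_variance_ratio.tolist(),
        "n_annotated_peaks": len(annot),
    }
    if len(set(labels.tolist())) >= 2:
        sep = cluster_separation(model)
        sep["pairs"].to_csv(out_dir / "cluster_separation.csv", index=False)
        summary["quadrant_fractions"] = sep["quadrant_fractions"]
    return summary


def _run_morphometry(block: dict, master_seed: int, out_dir: Path, state: dict) -> dict:
    seed = _substream_seed(master_seed, "morphometry")
    from .synth import EV_MORPHOMETRY, LDL_MORPHOMETRY

    pops = block.get("populations")
    if pops is None:
        populations = [(LDL_MORPHOMETRY, 0.86), (EV_MORPHOMETRY, 0.14)]
    else:
        populations = [
            (PopulationPrior(**{k: v for k, v in p.items() if k != "fraction"}), p["fraction"])
            for p in pops
        ]
    table = generate_afm_particles(
        populations,
        n=int(block.get("n", 10_000)),
        seed=seed,
        noise_sd=float(block.get("noise_sd", 0.0)),
    )
    measured = measure_particles(table)
    labelled, summaries = classify_particles(
        measured, priors=tuple(p for p, _ in populations) or DEFAULT_PRIORS
    )
    labelled.to_csv(out_dir / "morphometry.csv", index=False)
    summaries.to_csv(out_dir / "morphometry_summary.csv", index=False)
    return {
        "n_particles": len(labelled),
        "class_fractions": {
            row["class"]: round(row["fraction"], 4) for _, row in summaries.iterrows()
        },
    }


def _run_quantify(block: dict, master_seed: int, out_dir: Path, state: dict) -> dict:
    seed = _substream_seed(master_seed, "quantify")
    classes = [
        (DEFAULT_CLASSES[item["class"]], int(item["count"]))
        for item in block.get(
            "classes", [{"class": "EV", "count": 2000}, {"class": "LDL", "count": 2000}]
        )
    ]
    events, beads = generate_fc_events(
        classes, threshold=float(block.get("threshold_erf", 100.0)), seed=seed
    )
    cal = fit_calibration(beads)
    events = apply_calibration(events, cal, threshold=float(block.get("threshold_erf", 100.0)))
    kwargs = dict(
        acquisition_time=float(block.get("acquisition_time_s", 30.0)),
        flow_rate=float(block.get("flow_rate_ul_s", 1.0)),
        dilution_factor=float(block.get("dilution_factor", 20.0)),
    )
    fracs = fraction_summaries(events, **kwargs)
    pools = pooled_windows(events, **kwargs)
    events.to_csv(out_dir / "fc_events.csv", index=False)
    fracs.to_csv(out_dir / "fraction_summaries.csv", index=False)
    pools.to_csv(out_dir / "pooled_windows.csv", index=False)
    return {
        "n_events": len(events),
        "calibration": {"slope": cal.slope, "intercept": cal.intercept, "r2": cal.r_squared},
        "pooled": {row["window"]: int(row["n_events"]) for _, row in pools.iterrows()},
    }


_RUNNERS = {
    "simulate": _run_simulate,
    "segment": _run_segment,
    "pca": _run_pca,
    "morphometry": _run_morphometry,
    "quantify": _run_quantify,
}
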