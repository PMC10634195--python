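"""Segment trapping events out of noisy Rayleigh traces.

The detector thresholds a two-window mean-difference statistic against a
robust noise estimate; each accepted event yields one background-subtracted
Raman spectrum (baseline = the last 20 pre-event spectra of the same cycle).
"""

from evlipo import CampaignConfig, default_axis, run_campaign_segmentation, simulate_campaign

axis = default_axis(600.0, 1800.0, 2.0)
config = CampaignConfig(
    spectra_per_cycle=256, cycles_per_sample=50, n_samples=1,
    arrival_rate=0.5, noise_sd=1.0, seed=11,
)
cycles, truth = simulate_campaign(config, axis=axis)
events, spectra, _ = run_campaign_segmentation(cycles)

hits = truth.merge(events, on=["sample", "cycle"], suffixes=("_true", "_det"))
matched = hits[abs(hits["start_true"] - hits["start_det"]) <= 1]
print(f"logged events:   {len(truth)}")
print(f"detected events: {len(events)}")
print(f"recall:    {len(matched) / len(truth):.3f}  (boundary within one spectrum)")
print(f"precision: {len(matched) / len(events):.3f}")
print(f"event spectra matrix: {spectra.shape[0]} events x {spectra.shape[1]} wavenumbers")
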