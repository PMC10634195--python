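"""Simulate a single-particle optical-trapping campaign.

Each 9.7 s acquisition cycle records 256 synchronous Rayleigh/Raman spectra
at 38 ms each; a Poisson-arriving particle produces a step-wise Rayleigh
increase that persists until the laser-block release at cycle end. The
generator streams cycles lazily, so a full-scale campaign never has to fit
in memory.
"""

from evlipo import CampaignConfig, default_axis, simulate_campaign

config = CampaignConfig(
    spectra_per_cycle=256,
    acquisition_time=0.038,
    cycles_per_sample=20,
    n_samples=1,
    arrival_rate=0.5,
    noise_sd=1.0,
    seed=7,
)
print(f"cycle duration: {config.cycle_duration:.1f} s")
print(f"total spectra: {config.total_spectra}")

axis = default_axis(600.0, 1800.0, 2.0)
cycles, truth = simulate_campaign(config, axis=axis)

print(f"simulated {len(cycles)} cycles, {len(truth)} trapping events logged")
first = truth.iloc[0]
print(
    f"first event: sample {first['sample']} cycle {first['cycle']}, "
    f"spectra [{first['start']}, {first['end']}), class {first['class']}, "
    f"step height {first['step_height']:.1f} a.u."
)
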