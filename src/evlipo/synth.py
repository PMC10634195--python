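"""Ground-truthed synthetic inputs for every pipeline stage.

Emulates the particle populations of plasma EV/lipoprotein experiments:

* component Raman spectra (cholesterol / triglyceride / protein /
  phospholipid) and class compositions — vesicles cholesterol- and
  protein-rich, LDL/VLDL/CM increasingly triglyceride-rich, the EV-LDL
  complex a 50:50 blend;
* optical-trapping campaigns (default 256 spectra per 9.7 s cycle at 38 ms
  per spectrum, 100 cycles per sample, 1 s laser-block release gap) with
  Poisson arrivals, at most one trapped particle at a time, the step
  persisting until cycle-end release;
* adsorbed-particle AFM tables via the spherical-cap forward projection;
* flow-cytometry event lists over buoyant-density fractions with lognormal
  fluorescence scaling with particle surface area.

TEM-measured size populations: CM 148.2 +/- 91 nm, VLDL 63.5 +/- 24 nm,
LDL 25.3 +/- 3.4 nm (truncated at zero). All randomness flows from a single
seed through named SeedSequence substreams; identical configs and seeds give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .afm import PopulationPrior, forward_project
from .bands import ComponentSpectrum, default_axis, default_components
from .trapping import TraceCycle

__all__ = [
    "ParticleClassSpec",
    "CampaignConfig",
    "DEFAULT_CLASSES",
    "LDL_MORPHOMETRY",
    "EV_MORPHOMETRY",
    "make_particle_spectrum",
    "sample_diameters",
    "truncated_normal",
    "simulate_campaign",
    "iter_cycles",
    "generate_afm_particles",
    "generate_fc_events",
    "default_bead_table",
    "fit_truncated_normal",
]


@dataclass(frozen=True)
class ParticleClassSpec:
    """Everything the generator needs to emulate one particle class."""

    label: str
    composition: dict[str, float]
    size_mean: float  # nm, solution diameter
    size_sd: float
    density_mean: float  # g/cm^3 buoyant density
    density_sd: float
    morph_ca_mean: float = 90.0  # degrees, adsorbed contact angle
    morph_ca_sd: float = 10.0
    trap_step_mean: float = 10.0  # a.u., Rayleigh step height
    trap_step_sd: float = 2.0

    def __post_init__(self) -> None:
        if not self.composition or sum(self.composition.values()) <= 0:
            raise ValueError("composition weights must sum > 0")
        if any(w < 0 for w in self.composition.values()):
            raise ValueError("composition weights must be >= 0")
        if self.size_mean <= 0:
            raise ValueError("size_mean must be > 0")
        if not (1.00 <= self.density_mean <= 1.30):
            raise ValueError("density_mean must lie within 1.00-1.30 g/cm^3")


def _blend(a: dict[str, float], b: dict[str, float]) -> dict[str, float]:
    keys = set(a) | set(b)
    return {k: 0.5 * a.get(k, 0.0) + 0.5 * b.get(k, 0.0) for k in sorted(keys)}


_EV_COMPOSITION = {"cholesterol": 1.0, "protein": 0.6, "phospholipid": 0.4}
_LDL_COMPOSITION = {"triglyceride": 1.0, "cholesterol": 0.3, "protein": 0.2}

DEFAULT_CLASSES: dict[str, ParticleClassSpec] = {
    "CM": ParticleClassSpec(
        label="CM",
        composition={"triglyceride": 1.5, "cholesterol": 0.1},
        size_mean=148.2,
        size_sd=91.0,
        density_mean=1.06,
        density_sd=0.01,
        morph_ca_mean=71.0,
        morph_ca_sd=8.0,
    ),
    "VLDL": ParticleClassSpec(
        label="VLDL",
        composition={"triglyceride": 1.2, "cholesterol": 0.2, "protein": 0.1},
        size_mean=63.5,
        size_sd=24.0,
        density_mean=1.07,
        density_sd=0.01,
        morph_ca_mean=71.0,
        morph_ca_sd=8.0,
    ),
    "LDL": ParticleClassSpec(
        label="LDL",
        composition=dict(_LDL_COMPOSITION),
        size_mean=25.3,
        size_sd=3.4,
        density_mean=1.08,
        density_sd=0.01,
        morph_ca_mean=71.0,
        morph_ca_sd=8.0,
    ),
    "EV": ParticleClassSpec(
        label="EV",
        composition=dict(_EV_COMPOSITION),
        size_mean=100.0,
        size_sd=35.0,
        density_mean=1.14,
        density_sd=0.012,
        morph_ca_mean=97.0,
        morph_ca_sd=12.0,
    ),
    "EV-LDL complex": ParticleClassSpec(
        label="EV-LDL complex",
        composition=_blend(_EV_COMPOSITION, _LDL_COMPOSITION),
        size_mean=110.0,
        size_sd=35.0,
        density_mean=1.10,
        density_sd=0.015,
        morph_ca_mean=97.0,
        morph_ca_sd=12.0,
    ),
}

# Adsorbed-particle morphometry populations: stiff small lipoproteins vs
# softer vesicles with widely dispersed diameters.
LDL_MORPHOMETRY = PopulationPrior(
    label="LDL", ca_mean=71.0, ca_sd=8.0, d_model="gaussian", d_loc=17.0, d_scale=3.0
)
EV_MORPHOMETRY = PopulationPrior(
    label="EV", ca_mean=97.0, ca_sd=12.0, d_model="uniform", d_loc=30.0, d_scale=130.0
)


@dataclass(frozen=True)
class CampaignConfig:
    """Acquisition geometry and noise of a trapping campaign."""

    spectra_per_cycle: int = 256
    acquisition_time: float = 0.038  # seconds per spectrum
    cycles_per_sample: int = 100
    n_samples: int = 1
    release_gap: float = 1.0  # seconds of laser block between cycles
    arrival_rate: float = 0.5  # expected trapping events per cycle
    noise_sd: float = 1.0  # a.u., additive Gaussian noise
    rayleigh_baseline: float = 50.0  # a.u.
    background_level: float = 0.5  # a.u., Raman background amplitude
    shot_noise: bool = False  # optional Poisson noise mode
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.spectra_per_cycle, self.cycles_per_sample, self.n_samples) < 1:
            raise ValueError("all counts must be >= 1")
        if self.acquisition_time <= 0:
            raise ValueError("acquisition_time must be > 0")
        if self.arrival_rate < 0:
            raise ValueError("arrival_rate must be >= 0")

    @property
    def cycle_duration(self) -> float:
        """Nominal cycle duration in seconds (spectra x acquisition time)."""
        return self.spectra_per_cycle * self.acquisition_time

    @property
    def total_spectra(self) -> int:
        return self.spectra_per_cycle * self.cycles_per_sample * self.n_samples


def make_particle_spectrum(
    spec: ParticleClassSpec,
    components: dict[str, ComponentSpectrum],
    rng: np.random.Generator | int | None = None,
    jitter_sd: float = 0.0,
) -> np.ndarray:
    """Weighted sum of component spectra, with optional per-component
    lognormal brightness jitter (sd in log space)."""
    missing = [k for k in spec.composition if k not in components]
    if missing:
        raise KeyError(f"composition references unknown components: {missing}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    out = None
    for name in sorted(spec.composition):
        w = spec.composition[name]
        if jitter_sd > 0:
            w = w * float(rng.lognormal(mean=0.0, sigma=jitter_sd))
        contrib = w * components[name].intensity
        out = contrib if out is None else out + contrib
    return out


def truncated_normal(
    mean: float,
    sd: float,
    low: float,
    high: float,
    n: int,
    rng: np.random.Generator,
    max_tries: int = 1000,
) -> np.ndarray:
    """Rejection sampling from a Gaussian restricted to (low, high).

    Raises if the acceptance probability is hopeless (mean far outside the
    bounds), rather than looping forever.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if sd == 0:
        if not (low < mean < high):
            raise ValueError(f"degenerate mean {mean} outside ({low}, {high})")
        return np.full(n, mean)
    p_inside = stats.norm.cdf(high, mean, sd) - stats.norm.cdf(low, mean, sd)
    if p_inside < 1e-6:
        raise ValueError(
            f"truncation ({low}, {high}) is incompatible with N({mean}, {sd}^2)"
        )
    out = np.empty(0)
    for _ in range(max_tries):
        need = n - len(out)
        if need <= 0:
            break
        draw = rng.normal(mean, sd, size=max(need * 2, 16))
        out = np.concatenate([out, draw[(draw > low) & (draw < high)]])
    if len(out) < n:
        raise ValueError("rejection sampling failed to converge")
    return out[:n]


def sample_diameters(spec: ParticleClassSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Solution diameters (nm) from the class size population, truncated > 0."""
    return truncated_normal(spec.size_mean, spec.size_sd, 0.0, np.inf, n, rng)


def fit_truncated_normal(
    data: np.ndarray, low: float = 0.0
) -> tuple[float, float, float]:
    """Maximum-likelihood (mu, sigma) of a Gaussian left-truncated at ``low``.

    Corrects the truncation bias of the naive sample mean (relevant for wide
    size populations like chylomicrons, where the positive-diameter cut
    shifts the truncated-sample mean upward). Returns (mu_hat, sigma_hat,
    se_mu) with the standard error taken from the inverse Hessian at the
    optimum.
    """
    from scipy import optimize

    x = np.asarray(data, dtype=float)
    if np.any(x <= low):
        raise ValueError("data must lie strictly above the truncation bound")

    def nll(theta: np.ndarray) -> float:
        mu, log_sigma = theta
        sigma = np.exp(log_sigma)
        z = (x - mu) / sigma
        return float(
            0.5 * np.sum(z**2)
            + len(x) * log_sigma
            + len(x) * stats.norm.logsf((low - mu) / sigma)
        )

    res = optimize.minimize(
        nll, x0=np.array([x.mean(), np.log(x.std())]), method="BFGS"
    )
    mu_hat = float(res.x[0])
    sigma_hat = float(np.exp(res.x[1]))
    se_mu = float(np.sqrt(res.hess_inv[0, 0]))
    return mu_hat, sigma_hat, se_mu


def _background_spectrum(axis: np.ndarray, level: float) -> np.ndarray:
    """Smooth broad fluorescence-like background on the Raman axis."""
    span = axis[-1] - axis[0]
    x = (axis - axis[0]) / span
    return level * (1.0 + 0.5 * np.exp(-0.5 * ((x - 0.3) / 0.25) ** 2) - 0.3 * x)


def iter_cycles(
    config: CampaignConfig,
    classes: list[tuple[ParticleClassSpec, float]] | None = None,
    components: dict[str, ComponentSpectrum] | None = None,
    axis: np.ndarray | None = None,
    event_log: list | None = None,
):
    """Lazily yield the campaign's TraceCycles (one at a time).

    ``event_log``, when supplied, accumulates ground-truth rows
    (sample, cycle, start, end, class, step_height) as cycles are produced.
    """
    if classes is None:
        classes = [(DEFAULT_CLASSES["EV"], 0.5), (DEFAULT_CLASSES["LDL"], 0.5)]
    fractions = np.array([f for _, f in classes], dtype=float)
    if classes and not np.isclose(fractions.sum(), 1.0):
        raise ValueError("class mixing fractions must sum to 1")
    if axis is None:
        axis = default_axis()
    if components is None:
        components = default_components(axis)
    else:
        for c in components.values():
            if len(c.axis) != len(axis) or not np.allclose(c.axis, axis):
                raise ValueError("component axes must match the campaign axis")

    root = np.random.SeedSequence(config.seed)
    n = config.spectra_per_cycle
    background = _background_spectrum(axis, config.background_level)
    cycle_times = np.arange(n) * config.acquisition_time

    for sample in range(config.n_samples):
        for cycle in range(config.cycles_per_sample):
            ss = np.random.SeedSequence(
                entropy=root.entropy, spawn_key=(sample, cycle)
            )
            rng = np.random.default_rng(ss)
            t0 = (sample * config.cycles_per_sample + cycle) * (
                config.cycle_duration + config.release_gap
            )
            rayleigh = np.full(n, config.rayleigh_baseline)
            raman = np.tile(background, (n, 1))
            # Poisson arrivals; the trap holds one particle until cycle-end
            # release, so only the first arrival produces an event.
            n_arrivals = rng.poisson(config.arrival_rate)
            if n_arrivals > 0 and n >= 2:
                arrival_times = np.sort(rng.integers(1, n, size=n_arrivals))
                start = int(arrival_times[0])
                cls = classes[rng.choice(len(classes), p=fractions)][0]
                step = max(
                    float(rng.normal(cls.trap_step_mean, cls.trap_step_sd)),
                    0.1 * cls.trap_step_mean,
                )
                spectrum = make_particle_spectrum(cls, components, rng, jitter_sd=0.1)
                rayleigh[start:] += step
                raman[start:] += spectrum
                if event_log is not None:
                    event_log.append(
                        {
                            "sample": sample,
                            "cycle": cycle,
                            "start": start,
                            "end": n,
                            "class": cls.label,
                            "step_height": step,
                        }
                    )
            if config.noise_sd > 0:
                rayleigh = rayleigh + rng.normal(0, config.noise_sd, size=n)
                raman = raman + rng.normal(0, config.noise_sd, size=raman.shape)
            if config.shot_noise:
                rayleigh = rng.poisson(np.clip(rayleigh, 0, None)).astype(float)
                raman = rng.poisson(np.clip(raman, 0, None)).astype(float)
            yield TraceCycle(
                times=t0 + cycle_times,
                rayleigh=rayleigh,
                raman=raman,
                axis=axis,
                sample=sample,
                cycle=cycle,
            )


def simulate_campaign(
    config: CampaignConfig,
    classes: list[tuple[ParticleClassSpec, float]] | None = None,
    components: dict[str, ComponentSpectrum] | None = None,
    axis: np.ndarray | None = None,
) -> tuple[list[TraceCycle], pd.DataFrame]:
    """Materialise the whole campaign plus its ground-truth event log."""
    log: list[dict] = []
    cycles = list(iter_cycles(config, classes, components, axis, event_log=log))
    truth = pd.DataFrame(
        log, columns=["sample", "cycle", "start", "end", "class", "step_height"]
    )
    return cycles, truth


def generate_afm_particles(
    populations: list[tuple[PopulationPrior, float]],
    n: int,
    seed: int = 0,
    noise_sd: float = 0.0,
) -> pd.DataFrame:
    """Labelled adsorbed-particle table of cap measurements (h_nm, a_nm).

    Draws (D_eq, CA) per class — CA from a Gaussian truncated to (0, 180)
    degrees, D_eq from the class diameter model truncated > 0 — then
    forward-projects each particle to its cap geometry, with optional
    additive Gaussian measurement noise (nm) on h and a.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    fractions = np.array([f for _, f in populations], dtype=float)
    if not np.isclose(fractions.sum(), 1.0):
        raise ValueError("population fractions must sum to 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    which = rng.choice(len(populations), size=n, p=fractions)
    d_eq = np.empty(n)
    ca = np.empty(n)
    labels = np.empty(n, dtype=object)
    for i, (pop, _) in enumerate(populations):
        mask = which == i
        k = int(mask.sum())
        if k == 0:
            continue
        ca[mask] = truncated_normal(pop.ca_mean, pop.ca_sd, 0.0, 180.0, k, rng)
        if pop.d_model == "gaussian":
            d_eq[mask] = truncated_normal(pop.d_loc, pop.d_scale, 0.0, np.inf, k, rng)
        elif pop.d_model == "uniform":
            d_eq[mask] = rng.uniform(pop.d_loc, pop.d_scale, size=k)
        else:
            raise ValueError(f"unknown diameter model {pop.d_model!r}")
        labels[mask] = pop.label
    t = np.tan(np.radians(ca) / 2.0)
    a = d_eq / np.sqrt(2.0 + t * t)
    h = a * t
    if noise_sd > 0:
        h = np.clip(h + rng.normal(0, noise_sd, n), 1e-6, None)
        a = np.clip(a + rng.normal(0, noise_sd, n), 0.0, None)
    return pd.DataFrame(
        {
            "particle_id": np.arange(n),
            "h_nm": h,
            "a_nm": a,
            "cluster_flag": np.zeros(n, dtype=bool),
            "true_class": labels,
            "true_D_eq_nm": d_eq,
            "true_CA_deg": ca,
        }
    )


def default_bead_table() -> pd.DataFrame:
    """Four-point calibration bead set spanning the instrument's dynamic
    range; intensities sit at half the assigned ERF value (slope 1 in
    log-log space, intercept log10(2))."""
    assigned = np.array([1e2, 1e3, 1e4, 1e5])
    return pd.DataFrame(
        {"assigned_value": assigned, "measured_intensity": assigned / 2.0}
    )


def generate_fc_events(
    classes: list[tuple[ParticleClassSpec, int]],
    threshold: float = 100.0,
    beads: pd.DataFrame | None = None,
    seed: int = 0,
    brightness_per_nm2: float = 0.025,
    fl_sigma: float = 0.5,
    condition: str = "sample",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fluorescence-triggered flow-cytometry event list with ground truth.

    Per particle the true fluorescence is lognormal with median proportional
    to surface area (diameter squared), scatter channels increase with size,
    and buoyant density is Gaussian per class (clipped to the physical
    1.00-1.30 g/cm^3 gradient range). Only particles whose calibrated
    fluorescence meets the trigger threshold (inclusive) are emitted.
    """
    # local import avoids a cycle: fc only needs the calibration fit
    from .fc import apply_calibration, fit_calibration

    if not classes:
        raise ValueError("class list must be non-empty")
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if beads is None:
        beads = default_bead_table()
    cal = fit_calibration(beads)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    frames = []
    for spec, count in classes:
        if count < 0:
            raise ValueError("class counts must be >= 0")
        if count == 0:
            continue
        d = sample_diameters(spec, count, rng)
        area = d**2
        fl_au = brightness_per_nm2 * area * rng.lognormal(0.0, fl_sigma, size=count)
        ssc = 0.01 * d**2 * rng.lognormal(0.0, 0.3, size=count)
        rwfsc = 0.02 * d**2 * rng.lognormal(0.0, 0.3, size=count)
        density = np.clip(
            rng.normal(spec.density_mean, spec.density_sd, size=count), 1.00, 1.30
        )
        t = np.sort(rng.uniform(0.0, 30.0, size=count))
        frames.append(
            pd.DataFrame(
                {
                    "fl_au": fl_au,
                    "ssc_au": ssc,
                    "rwfsc_au": rwfsc,
                    "time": t,
                    "fraction_density": density,
                    "condition": condition,
                    "true_class": spec.label,
                    "true_diameter_nm": d,
                }
            )
        )
    events = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=[
            "fl_au", "ssc_au", "rwfsc_au", "time",
            "fraction_density", "condition", "true_class", "true_diameter_nm",
        ]
    )
    events = apply_calibration(events, cal, threshold=threshold)
    emitted = events[events["above_threshold"]].reset_index(drop=True)
    return emitted, beads
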