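# Methods

Models, parameter choices and numerical decisions behind `evlipo`. Symbols:
`h` cap height (nm), `a` cap contact radius (nm), `CA` contact angle (deg),
`D_eq` equivalent free-particle diameter (nm), ERF equivalent reference
fluorophores.

## 1. Raman component model

A molecular component is a sum of Gaussian bands on a shared wavenumber
grid; band widths are full width at half maximum (default 12 cm⁻¹, typical
of condensed-phase lipid bands at a few cm⁻¹ instrument resolution).
Component spectra are max-normalized so mixture weights are directly
comparable. Default band positions (cm⁻¹):

- cholesterol: 698, 1438, 2850, 2866, 2888, 2932
- triglyceride: 1302, 1445, 1747
- protein: 1003, 1656
- phospholipid: 718, 1094

A particle spectrum is a non-negative mixture of component spectra with
per-particle lognormal jitter on the weights (σ_log = 0.1–0.2), modelling
particle-to-particle compositional variation. The default axis is 600–3100
cm⁻¹ at 2 cm⁻¹ spacing, covering both the fingerprint region (600–1800) and
the high-frequency C–H stretch region (2800–3050). Restricting the axis
silently drops bands that fall outside it; a component with no surviving
band is omitted.

The default class compositions place triglyceride-dominant lipoproteins and
cholesterol-dominant vesicles at opposite extremes, and the
vesicle-lipoprotein complex is their 50:50 blend. The triglyceride contrast
between classes is deliberately the largest single contrast, so under the
canonical sign convention (below) lipoproteins land at PC1 > 0
deterministically. This choice was fixed before any classification checks
were run.

## 2. Trapping campaign generator

One acquisition cycle is `spectra_per_cycle` (default 256) spectra at
`acquisition_time` (default 0.038 s) each, i.e. a 9.7 s cycle, followed by a
1 s laser-block release. A campaign is `cycles_per_sample` cycles for each
of `n_samples` samples; at 256 × 100 × 21 this reproduces a realistic
537,600-spectrum campaign. Cycles are generated lazily (`iter_cycles`): a
full-resolution campaign of that size is ≈ 5 GB if materialised, so the
generator streams and the segmentation consumes any iterable.

Within a cycle, particle arrivals are Poisson (`arrival_rate`, default 0.5
per cycle); the trap holds one particle, so the first arrival defines the
event. The event starts at a uniform random spectrum index ≥ 1 and persists
to cycle end (a trapped particle is released only by the laser block). The
Rayleigh trace is a baseline (50 a.u.) plus a class-dependent step
(mean 10, sd 2 a.u.) plus Gaussian noise (`noise_sd`, default 1 a.u., i.e.
signal-to-noise ≈ 10 — a deliberately moderate default so detection is
non-trivial but the ≥ 95 % recall/precision contract is meaningful).
Determinism: each cycle draws from `SeedSequence(entropy,
spawn_key=(sample, cycle))`, so any cycle is reproducible in isolation and
lazy and materialised runs are bit-identical.

## 3. Step detection

For a trace `x[0..n)`, the statistic at candidate change index `i` is the
difference of window means, `d[i] = mean(x[i:i+w⁺]) − mean(x[i−w⁻:i])`,
with `w⁺ = min(w, n−i)`, `w⁻ = min(w, i)`; shrinking windows at the edges
keeps early and late captures detectable. The noise scale is estimated
robustly as `MAD(diff(x))·1.4826/√2`, which is insensitive to the steps
themselves. The per-position threshold is
`max(min_step, k·σ̂·√(1/w⁻ + 1/w⁺))` with `k = 5` (a 5σ point test; with
~255 candidate positions per cycle and 2,100 cycles, the expected number of
Gaussian false positives over a full campaign is ≪ 1). Change points are
the argmax of contiguous super-threshold runs; up-steps open events,
down-steps (mid-cycle release) close them, otherwise events truncate at
cycle end. Events closer than `merge_gap = 3` spectra are joined (a
one-spectrum dip in an otherwise continuous capture is noise, not a
release). `min_duration = 5` spectra (190 ms) rejects transient
passers-by that never settle in the trap and bounds the variance of the
event-mean spectrum. Step height is the event mean minus a baseline of up
to 20 pre-step samples that never crosses the previous event.

Background subtraction uses the last `background_n = 20` pre-event spectra
of the same cycle (nearest in time, tracking slow drift); an event starting
at spectrum 0 falls back to post-release spectra; an event spanning the
whole cycle with no background raises.

## 4. Spectral analysis

Normalization: `area` divides each spectrum by its trapezoidal integral
over the axis; `snv` (standard normal variate) centres and scales each row.
SNV is the default for classing because it removes the multiplicative
intensity variation caused by particle size and trap position while
preserving relative band structure; rows with zero integral or zero
variance are rejected with the offending row indices named. The fingerprint
region (600–1800 cm⁻¹) is the default classing region — it carries the
discriminating triglyceride/cholesterol/protein bands, while the C–H
stretch region is intense but compositionally less specific.

PCA is scikit-learn's full-solver PCA. Canonical orientation: each loading
is flipped so its largest-magnitude element is positive (scores flipped
accordingly), making score signs reproducible across runs and platforms.
Degenerate input (identical spectra) yields zero scores and zero explained
variance rather than noise-determined directions.

Loading annotation finds local extrema of a loading (order-2 relative
extrema, |value| ≥ 30 % of the loading's maximum) and matches each to the
nearest catalogued band within ±6 cm⁻¹ (three grid steps — tight enough to
avoid crosstalk between the 1438 and 1445 cm⁻¹ bands' neighbourhoods while
tolerant of grid discretisation). Classing is nearest-centroid in the first
two score dimensions with a softmin confidence; ties break
lexicographically so results are deterministic.

## 5. AFM morphometry

Spherical-cap model: `CA = 2·arctan(h/a)`; `D_eq = √(h² + 2a²)`. The
latter conserves membrane area between the adsorbed cap and the free
sphere: cap area (spherical surface plus contact disk) is
`π(h² + a²) + πa² = π(h² + 2a²) = πD_eq²`. Area conservation is the
physically motivated choice for membrane-bounded particles (lipid area is
conserved on adsorption; volume is not, since vesicles exchange water).
The forward projection inverts this exactly: `a = D_eq/√(2 + tan²(CA/2))`,
`h = a·tan(CA/2)`, with the `CA = 180°` limit `a = 0, h = D_eq`.

Classification assigns each particle to the population prior with the
highest log-density in `(D_eq, CA)`. Default priors: lipoproteins
`D_eq ~ N(17, 3) nm`, `CA ~ N(71, 8)°`; vesicles `D_eq ~ U(30, 130) nm`,
`CA ~ N(97, 12)°`. The generator draws from the same families, so
round-trip tests check the estimator, not the priors' realism.

## 6. Size populations and truncation

Electron-microscopy-like size distributions are zero-truncated normals
(diameters cannot be negative): LDL 25.3 ± 3.4 nm, VLDL 63.5 ± 24 nm,
chylomicrons 148.2 ± 91 nm, vesicles 100 ± 35 nm. For narrow populations
truncation is negligible and the sample mean is unbiased; for chylomicrons
(σ/μ ≈ 0.6) truncation inflates the sample mean by ≈ 7 %, so
`fit_truncated_normal` maximises the truncated-normal likelihood (BFGS on
the negative log-likelihood with a log-σ parametrisation; the standard
error of μ̂ comes from the inverse Hessian). Tests and the acceptance
script compare the naive mean against the analytic truncated mean and the
MLE against the generating mean, each at 3 standard errors.

## 7. Flow cytometry

Calibration regresses `log10(assigned ERF)` on `log10(measured a.u.)` by
ordinary least squares over a bead dilution series; at least two distinct
intensities are required. The ERF threshold (default 100) is inclusive
(≥). Concentration is `n / (flow_rate · time) · dilution` with a default
dilution factor of 20 (50 µL sample in 950 µL buffer). Density windows are
inclusive on both bounds with densities rounded to two decimals:
lipoprotein-rich 1.06–1.10 g/mL, vesicle-rich 1.12–1.16 g/mL; events in
neither window are pooled as "other" so window counts always conserve the
total. Event rates above 10,000 s⁻¹ raise a swarm warning (coincident
particles defeat single-particle counting). Detergent sensitivity reports
`100·(1 − post/pre)` percent lost, flags post > pre as an anomaly and
pre = 0 as undefined rather than silently clipping.

## 8. Pipeline and reproducibility

The pipeline runs simulate → segment → pca → morphometry → quantify from
one config. All stage randomness derives from a single master seed through
named substreams (`sha256(f"{seed}:{stage}") mod 2³¹`, kept below 2³¹ so
seeds are valid everywhere), so stages are independently reproducible and
adding a stage never perturbs another's draws. Each run writes a manifest
with the config hash, seed, package version and per-stage summaries.
Missing stage blocks are skipped with a warning; a stage failure aborts the
run naming the stage. A thin `evlipo` click CLI wraps the stages for shell
use; everything else is library API.

## 9. Scope and limitations

Everything here is validated against synthetic data from this package's own
generators. Passing tests demonstrate that the inverse analyses are
self-consistent with the stated forward models at the stated noise levels —
they do not demonstrate performance on instrument data, where baselines
drift nonlinearly, noise is non-Gaussian, cosmic-ray spikes occur, and true
band shapes are not Gaussian. Specific simplifications:

- Rayleigh noise is white Gaussian; no 1/f drift, spikes or detector
  saturation.
- Band positions/widths are fixed per component; no temperature or
  environment shifts.
- The trap model holds exactly one particle per cycle; real traps can
  exchange particles mid-cycle.
- AFM measurement noise is optional additive Gaussian on `(h, a)`; tip
  convolution and partial rupture are not modelled.
- Flow-cytometry brightness scales with membrane area only
  (0.025 a.u./nm²); labelling heterogeneity beyond lognormal jitter is not
  modelled.
- Problem sizes used in tests (10⁴ morphometry particles, 10³ size draws,
  ≤ 200 cycles per segmentation test) are package choices balancing
  statistical power against test runtime; the generators scale beyond them.
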