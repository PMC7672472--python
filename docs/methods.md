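# Methods

## The digestion model

The generator produces fluorescence–time trajectories with the structure
the analysis assumes, so every downstream statistic can be validated
against known ground truth.

A well contains one aptamer species (full length N nt, protected-product
length P nt) at ~1 μM with ligand at concentration c μM. Because the
ligand is in large excess in every modeled condition (≥ 25 μM), ligand
depletion is ignored and the equilibrium fraction bound follows the
single-site isotherm

    θ(c) = c / (K_d,app + c),

with θ = 0 for the non-binder sentinel. `fraction_bound` logs a warning
when c is less than ten times the aptamer concentration, the validity
bound of this approximation.

Digestion is phenomenological first-order kinetics. Free aptamer is
digested to completion at rate `k_unprotected` (per minute). A ligand-bound
aptamer is trimmed at the same rate only down to its protected product,
which is subsequently degraded at the much slower `k_leak`. The dye
reports total stainable nucleotides; fluorescence yield is taken
proportional to retained length, the simplest monotone choice consistent
with short products staining poorly, so the protected product carries a
fraction ω = P/N of the intact signal.

Whether bound/unbound interconversion is fast or slow relative to
digestion is not identified by plate data, so both regimes are available:

* **slow exchange** (default; reproduces persistent-product gels): a
  fraction θ of molecules follows the protected pathway,

      F(t) = B + A·[(1−θ)·e^(−k_u t) + θ·(ω + (1−ω)·e^(−k_u t))·e^(−k_leak t)]

* **fast exchange**: a single exponential at the occupancy-weighted rate
  k_eff = (1−θ)·k_u + θ·k_leak.

Both reduce to the same single exponential at θ = 0. The noiseless curve
is non-increasing in t for all valid parameters (k_u > k_leak ≥ 0), and
non-decreasing in θ at every t whenever ω·k_u ≥ k_leak — amply satisfied
by the defaults (0.575·0.03 = 0.017 vs 0.002); outside that corner of
parameter space a large k_leak on a short protected product can transiently
invert the ordering, which is why the property tests pin the realistic
regime.

Observed fluorescence is F·(1+ε) with ε ~ Normal(0, noise_cv) i.i.d. per
read (destructive sampling into a fresh well at each time point makes
reads independent), clipped at zero. Noise is multiplicative with constant
CV, the dominant behavior of plate readers well above the blank; no
additive noise floor is modeled beyond `background`.

### Defaults and why

| parameter | default | rationale |
|---|---|---|
| `k_unprotected` | 0.03 /min | ≈ 93% digestion of free aptamer over the 90-min read window — the control reaches its lowest fluorescence within the window |
| `k_leak` | 0.002 /min | protected product persists over the window (−17% at 90 min) but is gone on the ~14 h scale |
| `amplitude` | 1000 a.u. | arbitrary instrument scale; all statistics are scale-free |
| `background` | 0 a.u. | no blank subtraction is performed anywhere; a nonzero background inflates both AUCs and biases R toward 0 — a known, documented bias source that the user controls |
| `noise_cv` | 0.05 | typical plate-reader replicate scatter; screens use 0.05, calibration experiments 0.02 |
| schedule | 0–90 min, 5-min steps, 1 h pre-incubation | inside the 1.5–4 h windows used across aptamers in the assay family |
| screen | 200 μM ligand, 2 replicates | the screening concentration and replicate count of the candidate-screen design |
| calibration | 0, 25, 50, 100, 200, 400, 800 μM | the dose–response concentration series |

With these defaults and ω = 42/73 (the stem-loop screening library), the
four bundled binders (apparent K_d 10–30 μM) have noiseless resistance
values 0.80–0.89 at 200 μM — binders near R ≈ 1, non-binders at R ≈ 0,
which is the regime the screen is designed to separate.

Randomness: each well draws from
`SeedSequence([master_seed, well_index])`, where `well_index` enumerates
(aptamer, condition with control first, replicate) in panel order. Any
single well is therefore reproducible in isolation, and a full panel is
bit-reproducible for a fixed master seed.

### What the generator does and does not emulate

It reproduces exponential control digestion, concentration-dependent
retention of a protected product, replicate scatter, and ligand-specific
fluorophore artifacts in the strand-displacement channel. It does **not**
model endonucleolytic side products (absorbed into `k_unprotected`, since
the plate statistic only sees total stainable signal), per-nucleotide
stochastic digestion, emission spectra (one channel per read), dye
artifacts in the digestion channel (one ligand is known to attenuate the
staining dye moderately; because the statistic is an AUC ratio this
mostly rescales R rather than flipping calls, and it is left out of the
model), or ligand depletion. Passing tests therefore validate the
statistics and the pipeline, not instrument- or chemistry-specific
effects in real data.

## Statistics

AUC is the composite trapezoid over the recorded grid; irregular grids
are supported, and the t = 0 read is included by default (a flag excludes
it for sensitivity analysis). When ligand and control wells have different
grids, the curves are linearly interpolated onto the overlap of the two
spans and integrated there only — never extrapolated.

R is defined as (AUC₁ − AUC₀)/AUC₀. Replicates are aggregated with a
common denominator: AUC₀ is the mean over control-replicate AUCs; each
ligand replicate gives R_i against that shared denominator; the condition
reports mean ± SD (SD only for n ≥ 2). This is the least-assumptive
scheme when replicate pairing between ligand and control wells is
unknown. Negative R and CR are reported raw with a quality flag, never
clipped, so artifact-like behavior stays visible. CR is computed
ratio-first (`100·(ΔL/ΔT)`) so the reference entry is exactly 100 in
floating point.

An alternative phrasing of the resistance metric as the plain AUC ratio
(without the −1 offset) circulates in descriptions of this assay; this
package implements the difference-over-control form above, which is 0 for
a non-binder.

## Screening and fitting

Binder calling thresholds the replicate-mean R at τ = 0.1 (ties are
binders). The observed clusters sit at 0.8–1 and ~0; τ = 0.1 is far from
both, and is exposed as a flag. Panels mixing screening concentrations
are refused: R is not concentration-standardized across candidates. A
companion z-score (R_mean/R_sd) is reported but does not affect the call,
keeping the headline rule the simple effect-size threshold.

The dose–response fit is bounded least squares (`scipy.optimize.
least_squares`, trust-region reflective) of R(c) = R_max·c/(k_half + c),
initialized at R_max = max(R) and k_half at the first concentration
reaching half of it. Under slow exchange with zero background, the model
R is exactly proportional to θ(c), so the fitted k_half identifies the
generating apparent K_d; with background or fast exchange it remains an
apparent constant. A flat (all ≤ 0) response returns a documented
non-binder sentinel (converged = False, NaN parameters) instead of
raising. Confidence intervals are percentile bootstrap (200 seeded
resamples, stratified by concentration) because replicate counts are far
too small for asymptotics. The fit is scale-equivariant in concentration
units.

## Strand-displacement comparison

The quenched fluorophore–quencher complex emits
F_q = (1 − q)·F_max with quench efficiency q ≥ 0.9 (the optimization
target for the complement strand). A binder displaces the complement by
δ = d_max·c/(k_sd + c); the observed signal is multiplied by the ligand's
`dye_artifact_factor` m (1 = clean, 0.1 = −90% attenuation, 1.3 = +30%
enhancement). F₀ is measured ligand-free and artifact-free. With q = 0.9,
an m = 0.1 attenuation bounds the observed signal by
0.1·(0.1 + 0.9·δ)·F_max ≤ F_q for any δ ≤ 1 — a structural false
negative, matching the observed discordance direction for strongly
attenuating ligands — while m > 1 on a non-binder yields a spurious
positive gain. The digestion channel is blind to these factors, which is
the comparison's point. The displacement constant k_sd is a property of
the ligand–complement competition and is deliberately a single assay
parameter, not derived per-ligand from K_d,app.

## Numerical and I/O choices

Tables are RFC-4180 CSV (UTF-8, "." decimal); readers use round-trip
float parsing so write→read is an exact identity; writers use fixed
column order, stable sorts and write-to-temp-then-rename, so equal inputs
give byte-identical files and failed runs leave no partial output. FASTA
panels default the protected length to N − 5 when the header omits
`protected_length` (the enzyme removes 3–6 nt from the 5′ end before
stalling). Validation is eager: schema errors name the missing column,
data errors name the offending group, and every plate must contain a
ligand-free control for each aptamer measured with ligand.

## Problem sizes

The test suite and the acceptance script use the study-shaped designs
directly: 29 candidates × 2 conditions × 2 replicates for the screen
(100 seeded repeats), 1000 condition/control pairs for the null
calibration, 50 Monte-Carlo repeats × 3 replicates at 7 calibration
concentrations for parameter recovery. The full suite runs in a few
seconds on one CPU.

## Known limitations

- The hyperbolic dose–response assumes protection saturates with
  occupancy; whether real digestion inhibition saturates below full
  protection is absorbed into `k_leak` rather than asserted.
- R depends on the read window: longer windows inflate R for persistent
  products (the AUC ratio grows with T/k_u⁻¹). Comparisons are only
  meaningful within a shared schedule, which the screen enforces.
- Two-site binders are out of scope; the fit is strictly one-site.
- No multiple-testing correction across panels: screening is
  effect-size-based by design.
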