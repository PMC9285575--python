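# Methods

## Scope

`glucocest` implements the quantitative core of dynamic glucose-enhanced
CEST MRI with D-glucose and 3-O-methyl-D-glucose (3OMG): a multi-pool
Bloch–McConnell simulator that generates phantom and in-vivo-like
Z-spectrum stacks with known ground truth, and the voxel-wise analysis
chain (smoothing-spline interpolation, B0 correction, asymmetry saturation
transfer, quality filtering, dynamic ΔST% contrast and group statistics)
that turns such stacks into parametric maps and time courses.

## Spin model

Magnetization of bulk water plus N exchangeable-proton pools evolves under
continuous-wave irradiation according to the Bloch–McConnell equations in
the rotating frame of the saturation pulse, with a star exchange topology:
each solute pool exchanges only with water, with pool-to-water rate
`k_i` and water-to-pool rate `f_i k_i` (detailed balance), where
`f_i = protons_per_molecule × c / 111 M` is the pool's proton fraction.
The augmented linear system (state plus constant drive) is propagated over
the saturation time by a single matrix exponential; this closed form is
exact for constant-coefficient ODEs and is the production path. An
independent cross-check integrates the same operator with an adaptive
stiff solver (LSODA, rtol 1e-9); the two agree to better than 1e-6 in Z.
The trajectory oscillates at the off-resonance precession frequency (kHz)
for the whole 5 s window, which makes time integration expensive
(seconds per offset) — another reason the matrix exponential is the
production path.

Readout is idealized: saturation is a perfect block pulse and the signal
is the water z-magnetization immediately afterwards, normalized by the
signal at the S0 reference offset (−10 ppm). This reflects
centric-encoded single-shot acquisitions, where post-saturation
magnetization dominates image contrast; no k-space or sequence physics is
modelled. When an offset scheme does not include −10 ppm (e.g. the
61-offset ±6 ppm in-vivo scheme), the generators append it as an extra
acquired reference frame.

## Exchange-rate law and agent presets

Hydroxyl-proton exchange is base-catalysed; the package uses

    k(pH) = k_0 + (k_ref − k_0) · 10^(pH − pH_ref)

so `k(pH_ref) = k_ref` and the rate grows one decade per pH unit above the
floor `k_0` (buffer catalysis is folded into `k_0`). Published exchange
rates for these agents vary widely, so the presets are *effective* values
chosen once so that the simulated contrast reproduces the qualitative
behaviour reported for the two molecules, and exposed in configuration:

| agent   | pools | shift (ppm) | protons | k_ref @ pH 7 (s⁻¹) | k_0 (s⁻¹) |
|---------|-------|-------------|---------|--------------------|-----------|
| glucose | 1     | +1.2        | 5       | 4000               | 300       |
| 3OMG    | 1     | +1.2        | 4       | 800                | 60        |
| glucose-3pool | 3 | +0.8/+1.5/+2.9 | 2/2/1 | 6000/3000/1500 | 450/250/120 |

The several-fold rate difference is what flips the pH optimum between the
agents: at 3 μT the labeling-efficiency optimum sits near k ≈ ω₁ ≈ 800
s⁻¹, which glucose reaches only near pH 6.1 (hence rising contrast toward
acidic pH) while 3OMG sits on it at neutral pH (hence a peak near pH 7.0).
Anomer composition (β:α = 64:36 for glucose, 58:42 for 3OMG) is stored;
an optional β/α rate-ratio scaling exists but is off by default because
no quantitative ratio is established.

Water relaxation presets exist per field **and** per medium:
solution-like (phosphate-buffered phantoms; T1/T2 = 3.5/1.2 s at 7 T,
3.0/1.8 s at 3 T) and tissue-like (tumor in vivo; 2.0/0.050 s at 7 T,
1.7/0.070 s at 3 T). The medium split matters: with tissue T1/T2 the
direct-saturation spillover caps asymmetry at a few percent (the in-vivo
ΔST% scale), while solution T1/T2 permits the tens-of-percent in-vitro ST
values. Temperature is carried as metadata (37 °C) but has no independent
effect beyond the chosen rates and relaxation times.

## Synthetic data

**Phantom**: disk-shaped vials (20 mM agent, pH 7.4–6.0) on a zero
background in a 64×64 (default) matrix, each vial voxel carrying the
noise-free Bloch–McConnell spectrum of its pH, plus noise. Ground truth
returned per vial is the *minimum-centred* asymmetry of the noise-free
spectrum — ST is defined on the B0-corrected spectrum whose water minimum
sits at 0 ppm, and even a shift-free CEST spectrum has its continuous
minimum displaced a few 0.001 ppm downfield by the agent resonance, so the
reference value must apply the same centring convention as the analysis.

**B0 corruption**: a low-order random polynomial surface (default ≤ 0.4
ppm peak) resamples each voxel's spectrum by cubic interpolation, as if
the water centre sat at the local shift; the truth map is returned.
Shifts beyond half the sampled offset range are rejected.

**Noise**: Gaussian (default) or Rician magnitude noise with
σ = S0/SNR, where S0 is the median unsaturated signal. Gaussian noise is
clipped at zero since stacks hold magnitude data.

**Dynamic series**: a baseline frame (no agent) plus frames every 6 min.
Tumor voxels (two disk ROIs on the flanks) mix extracellular and
intracellular compartment spectra with volume fractions 0.5/0.5 — the
extracellular fraction includes the vascular space of an aggressive
subcutaneous tumor, and this value sets the absolute ΔST% scale of the
presets (~0.2–1.5 percentage points at 7 T and 3 g/kg, the reported
order of magnitude). Dose maps to peak extracellular concentration as
3 g/kg → 10 mM, 1.5 g/kg → 5 mM (config-exposed; only the ratio matters
for the ordinal comparisons). Two presets encode the headline kinetics:

* `stable` (3OMG-like): constant concentrations and pH after arrival in
  both compartments → flat ground-truth contrast;
* `rising` (glucose-like): constant extracellular concentration, no
  intracellular accumulation (metabolised), extracellular pH drifting
  linearly 7.0 → 6.4 over the observation window (lactate-driven
  acidification) → monotonically rising contrast, because glucose ST
  grows toward acidic pH.

Cohorts add log-normal between-subject uptake-amplitude variability
(σ = 0.15) and per-subject noise (default image SNR 100). What the
generator does **not** emulate: perfusion/arterial-input kinetics,
partial-volume and motion artifacts, semisolid magnetization-transfer
background, B1 inhomogeneity, and k-space acquisition effects. Passing
tests therefore validate the analysis chain against the stated spin
model, not against every property of scanner data.

## Analysis chain

Per stack: (1) foreground segmentation by intensity threshold (default
10% of the 99th-percentile S0); (2) per-voxel smoothing-spline fit of the
Z-spectrum; (3) water centre located on a 0.005 ppm grid within ±1.5 ppm
of nominal zero as the midpoint of the deepest plateau of the smooth
curve — the contiguous region within 5% of the line depth of the minimum.
This reduces to the argmin for a curved line bottom, but stays
well-conditioned when strong saturation flattens the bottom over a few
tenths of a ppm, where a raw argmin is decided by sub-resolution
interpolation wiggles; (4) B0 correction by evaluating the smooth curve at
`offset + centre`, with points outside the sampled support marked missing
rather than extrapolated; (5) ST = (S(−Δ) − S(+Δ))/S0 on the corrected
curve, with S0 the smoothed signal at −10 ppm of the *uncorrected*
spectrum (the convention adopted where the protocol leaves it open) and
Δ = 1.2 ppm by default (0.8 ppm supported for in-vitro glucose); (6) a
quality filter keeping only voxels with R² strictly above 0.97, where R²
compares the smooth curve with the raw samples — noise-dominated spectra
fit poorly under data-driven smoothing and fall below the cut.

Smoothing parameter: for a single voxel the default is
generalized-cross-validation selection (scipy's `make_smoothing_spline`).
For whole stacks, one λ is calibrated per stack by k-fold
cross-validation (five folds, 19-point log grid, 48 sampled foreground
voxels) and reused for every voxel; this is ~20× faster than per-voxel
GCV and behaves identically in the R²-filter sense. Cohort processing
calibrates once on the first subject's baseline frame.

Dynamics: ΔST% = (ST_post − ST_pre)·100 on the intersection of validity
masks; the enhanced fraction is the percentage of tumor-ROI voxels with
ΔST% > 0 (undefined — NaN with a warning — when the ROI misses the valid
mask, never silently 0). Group testing follows the small-animal design:
per-subject ROI means first, then one-way ANOVA across time points and
Dunnett two-sided comparisons of each later frame against the *first
post-injection* frame (the reference used when asking whether contrast
keeps growing after arrival), α = 0.05. Dunnett critical values come from
scipy's numerical multivariate-t implementation; its family-wise type-I
error calibrates to 0.05 within Monte-Carlo error in the package's own
null simulations.

## Numerical choices and edge cases

* Simulated Z is clipped to [0, 1] (round-off only); B1 = 0 gives Z ≡ 1.
* All-constant or non-finite voxel spectra are invalid with R² = 0.
* Voxels whose shifted ±Δ points leave the sampled support are
  invalidated, not extrapolated.
* Every stochastic operation takes an explicit seed; identical seeds give
  byte-identical stacks. No global random state is used.
* Offsets are stored descending (+max → −max) by acquisition convention;
  all offset arithmetic is in labelled ppm, never in indices.

## Problem sizes

Default test and acceptance runs use 24×24–64×64 matrices, 5–7 vials,
five post frames, five subjects per cohort, 200 null replicates for the
stable-condition check and 10⁴ replicates for the family-wise-error
calibration; these sizes reproduce the ordinal and calibration properties
with comfortable Monte-Carlo margins. The solver cross-check uses the
61-offset in-vivo scheme.

## Known limitations

* Exchange rates are effective, ordinal-level calibrations, not fits to
  any measured spectra; absolute ST values depend on them and on the
  water presets.
* Minimum-based water centring carries a small systematic bias (up to
  ~0.02 ppm under strong asymmetric CEST on a saturated flat-bottomed
  line); ground truth applies the same centring convention, and
  WASSR-style reference scans are not modelled.
* No semisolid MT pool, no spillover correction (AREX), no Lorentzian
  decomposition — asymmetry analysis only, as in the emulated protocol.
* The stable/rising uptake presets are two-compartment caricatures meant
  to separate kinetic signatures, not pharmacokinetic models.
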