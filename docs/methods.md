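# Methods

## Model overview

The pipeline simulates a phantom experiment on an energy-discriminating
photon-counting CT system and quantifies how well mixed contrast agents can
be separated. A ray with basis-material areal densities
`a = (a_water, a_iodine, a_gadolinium, a_gold)` (g/cm²) produces expected
counts in detector bin *i*

    λ_i(a) = Σ_{E ∈ bin i} S(E) · exp( − Σ_b a_b (μ/ρ)_b(E) ),

where `S(E)` is the incident fluence per 0.5-keV grid step and `(μ/ρ)_b`
the mass-attenuation curve of basis material *b*. Measured counts are
independent Poisson variates with these means. Decomposition maximises the
Poisson log-likelihood `L(a) = Σ_i [m_i ln λ_i(a) − λ_i(a)]` per ray. The
same `λ(a)` implementation drives simulation and inversion, so estimator
tests isolate estimator behaviour; the *object*, however, contains a
material (the polymer body) that is deliberately **not** in the basis —
exactly as in the physical experiment — which is the main source of the
small residual quantification biases.

## Attenuation data

Per-material tables ship as CSVs of anchor energies (10–150 keV) from
published photon cross-section compilations, with the K edge represented by
a doubled row holding the one-sided limits (iodine 33.2, gadolinium 50.2,
gold 80.7 keV; edge jump ratios 4–5.5×). Queries interpolate log-log within
the edge-delimited segment, so interpolation never bridges an edge; exact
anchor queries return the tabulated value bit-for-bit. Gold's L edges
(11.9–14.4 keV) are smoothed over: they lie below the 30-keV noise
threshold and never influence detected counts. Polyoxymethylene (the
phantom body, density 1.41 g/mL) is composed from H/C/O elemental data.
Solutions use the dilute model `μ_mix = μ_water + Σ_b c_b (μ/ρ)_b`,
neglecting water displacement by the solute (≤1 % at ≤10 mg/mL).

## Tube spectrum and detector

No tube specification (anode, filtration) is available for the physical
prototype, so the spectrum is a deliberately simple, fully configurable
model: Kramers bremsstrahlung fluence `∝ (kVp/E − 1)` filtered by 2.5 mm
aluminium equivalent, cut off at 120 kVp, without characteristic lines.
Spectra are normalised by their photon count above the 30-keV noise
threshold; exposure (the mAs stand-in) is expressed as that unattenuated
counts-per-ray budget N0. The detector applies five ideal rectangular
pulse-height windows `[T_i, T_{i+1})`, the last one ending at the tube
voltage; the published per-study threshold sets are the defaults
(30/51/64/72/85 keV for the gadolinium, iodine and iodine–gadolinium
studies; 30/53/78/83/98 for gold; 30/51/78/83/98 for gold–gadolinium, with
thresholds just below and above the 50.2/80.7-keV edges). Pulse pile-up,
charge sharing, spectral tailing and scatter are out of scope, matching the
effects the original analysis also left unmodelled.

## Phantom and designs

A 13-cm polyoxymethylene cylinder holds 12 holes of 1.5 cm diameter on a
4.5-cm ring (the layout is not published; a single ring is the simplest
non-overlapping arrangement and the ring radius is configurable). Hole 12
is the PBS reference; PBS and tube walls are modelled as water. Three
design sources exist:

* `table1_fixture` — the published concentrations, digit for digit.
* `analytic` — tube concentrations solved against the spectral attenuation
  model (optionally hardened by the mean in-phantom path).
* `generated` (default) — reproduces the original calibration procedure:
  each agent's HU-per-(mg/mL) response is *measured* on noiseless
  conventional images of an unmixed dilution series under the study's
  threshold set, and every tube is solved against that measured response.
  This makes designed mixture tubes reconstruct to the 280-HU target within
  ~1 HU regardless of agent, which pure spectral weighting cannot achieve
  because rays reaching a tube are hardened by the body. Calibration is
  deterministic and cached per threshold set.

Mixture series use the "spiral" fraction grid `f_k = (k−1)/10`: agent 1
decreases while agent 2 increases, endpoints are single-agent tubes, and
every tube hits the common attenuation target. Generated concentration
ranges come out within ~20 % of the published ones (ratios 0.81–1.09),
the difference reflecting the unknown true beam.

## Scan simulation

Parallel-beam, single-slice geometry over 360°; desk-scale defaults of 400
views × 256 detectors across the 16.8-cm field of view and N0 = 1e5
counts/ray keep a full five-study replication around a minute while leaving
ROI statistics ample; the published 2400-view protocol is a configuration
change. The nine-row detector and eight-slice averaging of the physical
protocol are emulated by multiplying the per-ray budget by 8 — statistically
equivalent for uncorrelated counting noise. Line integrals are computed
analytically (chord lengths through body and tube circles), which is exact
for this piecewise-constant phantom; a Radon-transform projector for
arbitrary rasterised maps is provided and cross-checked against the exact
one. Counts are Poisson with one master seed; per-study substreams are
derived deterministically from the study index.

## Maximum-likelihood decomposition

Basis per study: water and iodine always; gadolinium and/or gold when
present (three materials for iodine–gadolinium, four for gold–gadolinium).
A K-edge material is admissible only if its edge lies strictly between two
active thresholds. Per ray, the negative log-likelihood is minimised by
damped Fisher scoring: the Fisher information `Σ_i (m_i/λ_i²) ∂λ_i ∂λ_i` is
positive semidefinite everywhere, which keeps every step a descent
direction — the exact Hessian is indefinite on polymer-only paths and
stalls Newton there — and it coincides with the exact Hessian wherever the
model fits. Iterations are vectorised over all rays with per-ray
backtracking; convergence requires the scale-weighted gradient max-norm
below 1e-6 relative to the ray's total counts (scales: 1 g/cm² for water,
1 mg/cm² for contrast materials), with a 200-iteration cap and a
Nelder–Mead fallback for stragglers. Water is initialised from the
one-parameter water-equivalent fit (the estimator behind the conventional
image); contrast materials start at zero. Estimates are unconstrained:
negative concentrations are legitimate noise excursions and keep the
estimator unbiased. Zero-count rays are flagged non-convergent and left at
zero; `m ln λ` is taken as 0 when `m = 0` and λ is floored at 1e-12.

## Reconstruction and post-processing

Standard 2-D parallel-beam FBP (ramp filter, Hann-apodised by default for
noisy data) replaces the proprietary multi-row algorithm; the
quantification logic is in-plane. Material sinograms (g/cm²) reconstruct
directly to mg/mL; the water-equivalent sinogram reconstructs to relative
water density `d`, with `HU = 1000·(d − 1)`. The reconstruction grid ties
one pixel to one detector element (0.66 mm at desk scale, 0.4 mm when run
with 420 detectors as on the physical grid). Material images are smoothed
with a normalised Gaussian, σ = 2 px. The published description ("a 2-pixel
radius and sigma") is ambiguous between kernel radius and σ; both are
configurable, the default reads σ = 2 px truncated at 2σ. The de-ringing
hook is a no-op by default since the ideal detector produces no rings.

## ROI analysis and statistics

Circular ROIs are seeded at the known hole centres on the conventional
image, refined by a polarity-aware intensity centroid (tubes may be darker
than the surrounding polymer) iterated to a fixed point but capped at 15 %
of the tube radius so the centroid cannot drift into the body, and sized to
60 % of the tube radius (unpublished in the original; 60 % avoids edge and
partial-volume pixels and is configurable). The same ROIs are reused on
every image of a dataset. Statistics are computed on both smoothed and
unsmoothed images; smoothed is reported by default (whether the original
ROI statistics preceded the smoothing is unstated).

Prepared-vs-measured concentrations are fit by OLS (slope, offset, R²,
residual RMSE, t-based 95 % CI of the slope — the published "95 % CI" row
is interpreted as the slope CI). Cross-contamination is the RMSE of the 11
tube-ROI means of an off-target image against its expected constant
(0 mg/mL; 1000 mg/mL for water). CNR is `|mean_tube − mean_PBS| / SD_PBS`
and the CNR slope is the OLS slope of CNR against prepared concentration,
fit with an intercept (a through-origin variant is available; the original
fitting choice is unstated). Reliability between unmixed and mixed
measurements uses the two-way mixed-effects ICC for the mean of k series,
aligned by prepared-concentration rank; the consistency form
`(MS_rows − MS_error)/MS_rows` is the default and the absolute-agreement
form is reported alongside. Gadolinium has k = 3 series, gold and iodine
k = 2 (only one mixture each exists).

## What the generator does and does not emulate

Simulated data carry the study's design logic (equal-attenuation spiral
mixtures, study-specific thresholds, Poisson counting statistics, the
unspanned body material) but an idealised instrument: known spectrum, ideal
bins, no pile-up/charge-sharing/scatter, no detector drift, no rings, exact
geometry. Passing tests therefore demonstrate the correctness of the
estimation and quantification chain and the *qualitative* instrument-
independent findings (equal-HU tubes separate in material images;
four-material decomposition costs CNR roughly two-fold; gadolinium beats
gold in a 120-kVp beam; slight cross-contamination appears where the basis
is largest). They do not certify the absolute slopes/offsets of the
physical scanner, which depend on the proprietary spectrum and detector
response: simulated mixed-series slopes sit near 0.97–1.02 where the
physical system, with real model mismatch, reported 0.81–0.95.

## Numerical choices and limitations

Optical depths are clipped at ±80 before exponentiation (guards optimiser
trial steps; unreachable physically). FBP interior amplitudes are accurate
to ~0.1 %; ROI means inherit ~1 % systematic loss from Gaussian smoothing
near tube rims and the polymer-induced decomposition bias, visible as
unmixed slopes of 0.98–1.01 rather than exactly 1. Noiseless runs replace
Poisson draws by their means (float counts), making round-trip tests
deterministic. Reports serialise to sorted-key JSON without timestamps, so
identical configuration and seed reproduce byte-identical reports. The
fan-beam geometry, helical acquisition, iterative/regularised
reconstruction and detector-response calibration are out of scope.
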