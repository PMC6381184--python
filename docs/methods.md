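# Methods

## Glycan model and nomenclature

A (galacto)mannooligosaccharide is a backbone of n β-1,4-linked mannoses,
numbered 1..n from the reducing end, with a subset of positions carrying
one α-1,6-galactosyl unit each. Only single galactosyl decorations are
modelled; acetylation and glucomannan (glucose backbone units) are out of
scope. Short names are written non-reducing → reducing end (`MGGMM` has
galactosyls at backbone positions 4 and 3); systematic names carry the
positions as superscripts (`α-6^4-6^3-di-galactosyl-mannopentaose`).
Parsing accepts both, plus the `Mn` shorthand, and formatting round-trips
exactly for backbones up to length 12.

With h total hexoses the neutral formula is C(6h)H(10h+2)O(5h+1)
(condensation of h hexoses with loss of h−1 waters). Monoisotopic atomic
masses: C 12.000000, H 1.0078250, O 15.9949146, Na 22.9897693 Da. The
sodium-adduct convention is **neutral mass + Na atomic mass with no
electron-mass subtraction**; this reproduces the conventional sodiated
MALDI reference masses of mannotriose (527.159 Da) and mannotetraose
(689.212 Da) at three decimals. Subtracting the electron mass would lower
both by 0.0005 Da and still round to the same third decimal, so the
simpler convention is used and stated here prominently.

## Isotope envelopes and the two label corrections

Natural envelopes are computed by multiplying per-atom isotope
polynomials (IUPAC abundances; C 1.07% ¹³C, H 0.0115% ²H, O 0.038% ¹⁷O /
0.205% ¹⁸O) over the formula, i.e. an exact convolution over nominal mass
offsets, truncated at cumulative abundance 1−10⁻⁶ and renormalised. The
test suite checks this against an independent exhaustive isotopologue
enumeration to 10⁻⁹.

Peak areas are taken at monoisotopic positions only — no envelope
fitting, centroiding or resolution modelling — matching unit-mass
MALDI-TOF treatment. For a product species the light position is its
sodium-adduct monoisotopic m/z and the heavy position is +2.004246 Da
(the exact ¹⁸O−¹⁶O difference); matching tolerance defaults to 0.3 Da,
and an ambiguous double match is an error rather than a guess.

Two corrections convert raw areas into the true heavy fraction:

1. **M+2 overlap.** The observed heavy monoisotopic area is
   H·a₀ + L·a₂; subtracting light_area·(a₂/a₀) leaves H·a₀. For the
   hexasaccharide-scale species involved, a₂/a₀ ≈ 0.08–0.10, so the
   correction is material. A negative result (possible under noise for
   nearly pure-light samples) is clamped to zero with a warning rather
   than an error. The light area is left untouched: the subtracted signal
   belongs to a different isotopologue of the light species, not to its
   monoisotopic peak, so this step does not conserve the two-peak total.
2. **Incomplete labelling.** With fraction p of the reaction water
   ¹⁸O-enriched (default 0.92), only p of glycon products are heavy:
   heavy_true = heavy/p and light_true = total − heavy_true, conserving
   the total exactly. If heavy/p exceeds the total, the supplied p is
   inconsistent with the data and the correction errors out.

The printed-style ratios ("1:8.9") are formatted from corrected pairs;
this package treats such ratios as post-correction values, the only
reading under which share × heavy-fraction arithmetic reproduces the
companion frequency percentages (0.89 × 8.9/9.9 ≈ 80%).

## Binding modes and frequency inference

A productive mode occupies −1 and +1 simultaneously with a contiguous
placement; for backbone length n in a −N…+P cleft the k_neg range is
max(1, n−P)..min(n−1, N), verified against positional brute force.
Non-productive poses (e.g. a ligand sitting entirely in −4…−2) are not
enumerated. The cleft default is −4…+4 with galactosyl decorations
tolerated in {−3, −2, −1, +1}; decoration tolerance is a hard
include/exclude filter, not an energetic weighting, because no subsite
energies are available — variant enzymes are represented by editing the
cleft geometry or the tolerated set in the configuration.

Products: the glycon fragment (subsites −k..−1) acquires the new heavy
reducing end; decorations travel with their residues. Pair shares are
computed from the molar amount of the smaller product of each
complementary pair, and of the larger product where both are quantified;
the two estimates are averaged when they agree within 5% and rejected
otherwise (chromatographic response differences are the user's
responsibility). A symmetric cleavage (two identical-size halves) has its
doubled molar amount halved. Shares are scale-invariant, so any common
quantification unit works.

Frequencies are reported both as exact fractions and as nearest-integer
percents. The forward simulator draws modes multinomially and heavy
labels binomially (probability p), which makes the
simulate → infer round trip an identity in expectation; at 10⁶ events the
maximum frequency error is below one percentage point.

## Kinetics

* **Michaelis–Menten (polymer substrates, mg/ml).** Unweighted nonlinear
  least squares of V = Vmax·[S]/(K_M+[S]) (lmfit), initialised at
  Vmax₀ = max V and K_M₀ = [S] at half-max by interpolation — robust for
  monotone MM data. kcat = Vmax/[E]; the efficiency standard error is
  propagated from the (Vmax, K_M) covariance. The fit warns when
  max [S] < 2·K_M ("saturation not reached"), the regime where the linear
  estimator below is preferable. The regression is unweighted because no
  weighting scheme is stated for the reference analysis.
* **Linear low-[S] (fallback).** Slope through the origin of V vs [S]
  over points with [S] at or below a configurable fraction (default
  0.25) of the abscissa of the rate maximum, divided by [E]. Returns
  only the efficiency — kcat and K_M are not separable at low [S].
* **Depletion (oligosaccharide substrates, mM).** ln(S₀/Sₜ) regressed on
  t **through the origin** (the model has no intercept: ln(S₀/S₀) = 0 at
  t = 0 exactly), using only points at ≤ 25% conversion, applied
  automatically. Efficiency = slope/[E].

Each fit records its unit system (mg/ml for polymers, mM for
oligosaccharides) and refuses cross-unit efficiency comparison. Activity
conversion: 1 U = 1 µmole reducing ends per minute per µmole enzyme, so
turnover (s⁻¹) = specific activity / 60, displayed at nearest-integer
precision above 10 s⁻¹ and one decimal below. The PAHBAH reducing-end
calibration is an OLS line with monotonicity checks, extrapolation
warnings, and clamping of below-blank signals to zero. Initial rates use
the longest initial window whose linear fit keeps R² ≥ 0.98
(configurable); the window rule is this package's own choice, since no
selection criterion is stated for "the initial linear range".

### Estimator accuracy under the depletion protocol

Under the stated sampling protocol (samples every 5.4 min from 2 to
50 min, [E] = 2 nM, S₀ = 0.1 mM), the ≤25% conversion window contains
only five points, and 2% multiplicative noise on Sₜ translates into
roughly 4% median relative error in the efficiency — commensurate with
the ±6% uncertainty reported for these measurements. Two further points:
the sample nearest the conversion boundary enters the fit only when noise
pushes its measured conversion below the cutoff, a selection effect worth
~1% downward bias at this design. The test suite therefore measures
estimator bias and accuracy on a dense 1-min grid strictly inside the
usable window (bias < 1%, median error < 3%), and exercises the protocol
grid separately in the noise-free recovery checks.

## Synthetic data

The generators emulate the statistical structure the analysis assumes,
not the instruments themselves. Noise is multiplicative log-normal
(mean-preserving, CV-parameterised; default CV 2% — a placeholder, since
real HPAEC/MALDI noise magnitudes are not reported) with an optional
uniform additive baseline on spectra. Spectra place the light envelope at
the sodium-adduct m/z with 1.00336 Da isotopologue spacing and merge
light isotopologues from +2 upward into the shifted heavy envelope, so
the observed heavy monoisotopic area equals H·a₀ + L·a₂ by construction
and zero-noise spectra invert exactly through the two corrections.
Decorated polymers use a two-state Markov decoration process with
transition probabilities tuned to the qualitative patterns of the two
reference galactomannans: guar-like (stationary density 0.5, Gal:Man 1:2,
short clustered runs, default length 900) and locust-bean-like (density
0.25, Gal:Man 1:4, mean bare blocks of ~10 residues, default length
1500). All generators are deterministic under a fixed seed.

What the simulations do **not** capture: chromatographic response-factor
differences between species, MALDI desorption/ionisation bias between
light and heavy species, baseline drift and peak-shape effects,
processive or multi-cleavage digestion (each simulated event is a single
cleavage), and subsite energetics (mode frequencies are inputs, not
predictions). Passing round-trip tests therefore demonstrate correctness
of the inference arithmetic under the stated noise model, not robustness
to these instrument systematics.

## Numerical choices and degenerate inputs

Envelope truncation at cumulative 1−10⁻⁶; frequency vectors validated to
sum to 1 within 10⁻⁹; pair shares to 1 within 10⁻⁶; DE calibration is
piecewise-linear through the (typically four) ladder anchors — too few
for a spline — with linear end-slope extrapolation under a warning, and a
±0.05 DE assignment tolerance chosen to separate the closest reference
species (M2 at 1.87 vs G at 2.10 DE). Degenerate cases error early with
named offending tokens: unparseable species names, missing or ambiguous
peaks, all-zero rate series, fully-converted depletion series,
non-monotone calibration standards.

## Known limitations

* Frequencies for a size pair require a label-pair measurement for one of
  its members; with neither measured the inference refuses rather than
  assuming symmetry.
* The closed-form mode enumeration assumes a single contiguous cleft;
  enzymes with discontinuous subsite usage are not representable.
* The variant with an unprinted label ratio (the W110H −4..+1 mode) can
  only be checked qualitatively; no quantitative target exists for it.
* mzML ingestion is not implemented; peak lists are delimited text (the
  `PeakList` contract would admit an mzML reader without API change).
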