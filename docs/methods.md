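# Methods

This note documents the models, numerical choices and limitations behind
`osteospec`. It states nothing that the test suite or the analysis scripts
do not themselves compute.

## Spectral model and preprocessing

A spectrum is a strictly increasing wavenumber grid (cm⁻¹) with intensities
in arbitrary units. Three modalities are supported — Raman fingerprint
(800–1800 cm⁻¹), Raman high-wavenumber (2700–3800 cm⁻¹) and FTIR
(~800–1800 cm⁻¹) — with tolerant grid bounds so edge channels survive
cropping. Replicate acquisitions of one specimen (three per specimen, the
standard protocol) are resampled to the first replicate's grid and averaged
*before* any ratio is computed; the averaging is recorded in the metadata.
Duplicate wavenumbers in a file (instrument rescans) collapse by the mean.

**Baselines.** Two estimators: a lower-convex-hull ("rubber band")
baseline, the default for Raman and the FTIR background step, and an
iteratively down-weighted polynomial (degree ≤ 5). A corrected spectrum
whose minimum dips below −5 % of its maximum is *reported*, never silently
clamped — deep negative excursions usually mean an artifact the analyst
should see.

**Mie-type scattering correction.** First-order EMSC: the spectrum is
modelled as `a + b·ref + c₁x + c₂x²` (x = scaled wavenumber) and the
correction returns `(s − a − c₁x − c₂x²)/b`, requiring `b > 0` and a
well-conditioned design. Resonant iterative Mie correction is out of scope.
Two practical consequences, both verified on synthetic cohorts:

* EMSC removes background only *relative to its reference*; with the
  spectrum as its own reference it is an exact identity. The fixed FTIR
  pipeline therefore inserts an explicit rubber-band background step after
  the EMSC step.
* A reference averaged over a mixed two-group cohort is hazardous: the
  least-squares polynomial absorbs part of each specimen's deviation from
  the mean *composition*, i.e. exactly the group signal, and biases the
  deconvolved area ratios (on zero-noise synthetic cohorts the WT collagen
  maturity came out at 7.0 against a true 2.9). The cohort runner therefore
  applies EMSC against an external reference only when one is supplied;
  multiplicative scale cancels in every ratio regardless.

**pMMA (embedding resin).** The resin carbonyl band at ~1730 cm⁻¹ is
quantified by a least-squares scale of a resin reference over
1700–1760 cm⁻¹, clipped so the window residual stays non-negative within a
noise allowance (no over-subtraction); a negative optimum returns the
spectrum unchanged with contribution 0 and a warning. The subtracted area
is the numerator of the resin-porosity ratio; its denominator is the raw
phosphate band area on the same pre-normalization intensity scale. The
bundled resin reference is a synthetic two-Gaussian surrogate (1730 strong,
1450 weak) and is user-replaceable by a measured spectrum.

**Normalizations.** FTIR spectra are vector-normalized over the ν₁,ν₃
phosphate band (900–1200 cm⁻¹); high-wavenumber Raman spectra are scaled so
the collagen CH-stretch local maximum near 2940 cm⁻¹ equals 1. Both are
idempotent and make every downstream parameter invariant to global
intensity rescaling (checked end to end over 20 random scale factors).

## Band deconvolution

Subpeak candidates are minima of the Savitzky–Golay second derivative
inside the band, prominence-filtered and required to have genuinely
negative curvature. Candidates seed the fit only when they resolve the full
expected subpeak set; otherwise the template centers stand — mixing
partially resolved candidates into a template destabilizes the area
partition. Template centers: ν₁,ν₃ PO₄ {960, 1030, 1058, 1076, 1096, 1110,
1127} cm⁻¹; amide I {1610, 1630, 1660, 1678, 1690} cm⁻¹ (standard bone
practice); tendon amide I {1610, 1640, 1670, 1690} cm⁻¹.

The fit is bounded nonlinear least squares (scipy trust-region reflective)
over per-peak amplitude ≥ 0, center within seed ± tolerance (±5 cm⁻¹
default, ±3 in the FTIR pipeline — the protocol quotes its positions with
"~"), FWHM within bounds, plus a linear baseline. Shapes are Gaussian by
default with a pseudo-Voigt option (area closed form
`A·FWHM·[η·π/2 + (1−η)·½√(π/ln 2)]`). Initialization is a fixed function of
the seeds and the data; no randomness, and fits are invariant to seed
order. Optimizer failures return `converged=False` rather than raising.
Nearest-subpeak lookups quantize distances to 10⁻⁶ cm⁻¹ so exact ties break
toward the lower wavenumber.

**Conditioning.** The subpeak partition of the phosphate and amide I
envelopes is ill-conditioned: FWHM (~20–28 cm⁻¹) is comparable to the
center spacing, so nearly-degenerate parameter directions are driven by
noise; at the synthetic noise level an unregularized fit occasionally
collapses a small subpeak entirely (recovered acid-phosphate group effect
+417 % against an injected +29 %). Three measures restore stability, all on
the estimator side:

1. **Wide fit windows with explicit neighbours.** The phosphate fit runs
   over 830–1270 cm⁻¹ including the ν₂ carbonate (~871) and amide III
   (~1240) bands as nuisance subpeaks; the amide I fit runs over
   1500–1730 cm⁻¹ including amide II (~1550). Modelling the neighbours
   stops their tails from wobbling the fitted baseline. Integration is then
   restricted to the named bands (900–1200, 1600–1720).
2. **Soft Tikhonov penalties** pulling centers toward their seeds (relative
   weight 0.2) and log-widths toward the template linewidths (0.4), scaled
   by the RMS of the chord-subtracted band signal. Bias introduced is
   common-mode across groups and small (verified ≤ ~0.5 points on recovered
   percent effects at zero noise).
3. Template widths as configuration, like the centers.

With these, across eight independently seeded cohorts the fit-side error of
the recovered group effects is ≈ ±0.2 points (phosphate/amide I), ±0.05
(crystallinity), ±1.7 (acid phosphate, the worst-conditioned pair) and
±0.7 (collagen maturity).

## Material parameters

Tendon Raman ratios use local-maximum intensity picking (halfwidth 5 cm⁻¹)
on rubber-band-corrected spectra — peak picking absorbs small calibration
shifts; the β-sheet fraction is the fitted ~1610 cm⁻¹ subpeak area over the
amide I area. High-wavenumber ratios (3243, 3330, 3457 over 2940 cm⁻¹) are
computed after CH-stretch scaling. Bone FTIR parameters come from the fixed
pipeline EMSC → background → pMMA → vector normalization → band fits;
carbonate/phosphate is reported in both intensity mode (ν₂ CO₃ local max in
850–900 over the 960 local max) and area mode, since the defining phrase
mixes the two. Collagen secondary structure assigns fitted amide I subpeaks
to β-sheet (1605–1635), random coil (1635–1655), helix (1655–1665), turns
(1665–1685) and other (1685–1720) by center; fractions are normalized over
assigned subpeaks and sum to 1.

## Mechanical analysis

Tensile: CSA = mass/(ρ·length) with ρ = 1.12 mg/mm³ (standard tendon
literature value; configurable — the protocol derives CSA from mass and
length but prints no density). Strain is percent of initial length; only
the final monotone ramp to fracture is analyzed (the protocol's
load/hold/unload cycles are segmented off by displacement-direction sign).
The elastic modulus is the maximum least-squares slope over contiguous
windows spanning 20 % of the pre-ultimate strain range — a concrete reading
of "slope of the linear part" — reported per unit fractional strain.
Toughness is the trapezoidal integral of stress over fractional strain to
the failure point.

Bending: stiffness is the same maximum-slope-window estimator on
load–displacement. Failure is the first sustained (3-sample) drop below
90 % of the running maximum, with the running maximum required to exceed
half the global maximum so the noisy toe cannot trigger it; a monotone
curve returns its last point flagged "no failure". Yield uses a 10 %
secant-deviation rule with toe correction: the displacement origin is the
zero-load intercept of the fitted elastic line, and yield is the first
point past the elastic region where the secant from that origin falls below
90 % of stiffness. Without toe correction the criterion is ill-posed — on
any curve with a toe region the raw secant never reaches 90 % of the
elastic slope. A 0.2 %-offset criterion (offset as a fraction of span) is
selectable; both agree within 10 % on smooth synthetic curves, and the
criterion used is recorded in every result. If the curve fails before the
criterion fires, yield is set to the ultimate point and flagged brittle.
Note that the secant yield necessarily lies beyond the elastic–plastic kink
of the synthetic curves, so recovered post-yield-displacement group effects
sit a few points beyond the kink-based ground truth (−76 % vs an injected
−71 % on the bending preset at seed 42) — a property of the yield
definition, not an estimator error; the loads and work integrals are
unaffected.
Work-to-fracture integrates load over displacement to the failure index;
post-yield displacement is failure minus yield displacement (0, flagged,
for brittle failures).

## Statistics

Percent change is 100·(test − reference)/reference, printed to the result
tables' convention (signed, nearest integer percent, one decimal below
10 % magnitude, halves away from zero — 19.5 prints as +20 %). Student's
and Welch's t from summaries reconstruct SD = SEM·√n and defer to
`scipy.stats.ttest_ind_from_stats`; the summary-form pooled t is exactly
the raw-sample t whenever raw samples match the summaries. Mann–Whitney
uses the exact null when min(n₁,n₂) ≤ 8, n₁·n₂ ≤ 100 and there are no ties,
the tie-corrected normal approximation otherwise; raw observations are
required (printed summaries carry no rank information). All p-values are
two-sided. `comparison_table` applies a Shapiro–Wilk pre-screen (α = 0.05,
only when both groups have n ≥ 5) and records, in every row, which test was
used. No multiple-testing correction is applied, matching the reporting
convention the pipeline mirrors. Type-I error of both tests is verified
empirically within [0.03, 0.07] at α = 0.05 over 1000 null simulations.

## Synthetic data: what it emulates, and what not

Generators are pure functions of (recipe, seed); identical inputs give
bit-identical output. Spectra are sums of pseudo-Voigt subpeaks plus a
polynomial baseline, optionally a global multiplicative scale, pMMA
contamination, and white Gaussian noise (0.4 % of the clean maximum for
FTIR, 0.3 %/0.15 % for Raman fingerprint/high-wavenumber); three replicates
per specimen are averaged, as in the acquisition protocol. Mechanical
curves are piecewise: a slope-continuous quadratic toe, a linear elastic
segment, a reduced-slope post-yield segment and instant fracture, with
closed-form truth for modulus, yield, ultimate, toughness and
work-to-fracture. A harder out-of-model FTIR preset
(`paper-bone-ftir-hard`) applies a genuinely multiplicative quadratic
distortion beyond the EMSC model class; it carries no recovery guarantee.

**Calibration.** Cohort presets inject the study's printed effects as
ground truth. Tendon Raman: each specimen's true ratios are drawn around
the printed group means with SD = SEM·√n (the printed dispersions), then
peak amplitudes are calibrated *through the measurement operator itself*
(rubber-band baseline + local-max picking on the clean spectrum) by fixed-
point iteration, so "truth" means what the defined measurement would read
on the noiseless spectrum. Bone FTIR: ratio effects are split symmetrically
between numerator and denominator subpeak areas (×√r and ÷√r), the
phosphate/amide effect is then imposed exactly by a closed-form rescale of
the whole phosphate band, and crystallinity is encoded in the 960 cm⁻¹
linewidth (WT FWHM 20 cm⁻¹). Mechanical presets place group means so the
printed tensile (−60 % modulus, −39 % ultimate stress, +27 % ultimate
strain) and bending (−64/−58/−56/−71 %) effects hold; work-to-fracture is
emergent from the curve construction and lands at the study's −84.4 %.

**Between-specimen variability.** Spectral specimens carry a 10 % CV global
intensity scale (section thickness, focus — cancels in every ratio) plus
2 % CV independent per-subpeak area scatter (1.5 % on the 960 cm⁻¹
linewidth); mechanical parameters carry 3 % CV (4 % on
ultimate-strain/PYD); specimen geometry (mass, length) uses the printed
dispersions. These CVs were set by a power argument: the presets exist to
verify recovery of the injected effects at the study's sample sizes, so the
cohort-level sampling SD of a recovered percent difference (≈ √2·CV/√n)
must sit comfortably below the recovery tolerances; a blanket 5 % CV would
make the tolerance unattainable in distribution at n = 10 per group
regardless of estimator quality. Expected end-to-end precision of a
recovered percent effect (sampling + fit, 1 SD): ≈ 0.9 points
(phosphate/amide I), 0.4 (crystallinity), 2.3 (acid phosphate), 1.6
(collagen maturity), ≈ 2 points for the tensile parameters.

**What passing does not show.** The synthetic spectra are exactly in the
fit's model class (Gaussian subpeaks, polynomial baseline); real spectra
have non-Voigt lineshapes, correlated baselines, cosmic rays and detector
drift, so recovery here bounds estimator noise and protocol consistency,
not real-world accuracy. Absolute levels of some parameters (e.g. the
small GAG and OH-stretch ratios) are biased upward by noise-maximum
picking; group *effects* are much less affected because the bias is
common-mode. Absolute animal-level results of the mirrored study (moduli in
N/mm², BMD, microCT morphometry) depend on its raw measurements, which are
not deposited; they are covered only through synthetic recovery and
printed-summary inference.

## Numerical conventions

Areas are in a.u.·cm⁻¹ by trapezoid above a chord (raw mode) or analytic
subpeak sums (fit mode); mode is recorded. Strain is displayed in percent
but integrated and differentiated as a fraction. Seeds propagate through
`numpy.random.SeedSequence.spawn`, one child per specimen, so cohorts are
reproducible per (preset, seed) and specimens are independent. Degenerate
inputs raise typed errors (`SpectrumError`, `PreprocessError`,
`BandFitError`, `BiomechError`, `StatsError`) with messages naming the
offending quantity.

## Known limitations

* The pMMA scale estimate assumes the tissue contributes little intrinsic
  intensity at 1700–1760 cm⁻¹; a strongly shifted amide I envelope would
  bias it.
* The EMSC implementation is first-order with quadratic wavenumber terms;
  resonant Mie distortion is only approximated (see the hard preset).
* The acid-phosphate area ratio (1127/1096) is the worst-conditioned
  deconvolution output; its recovered group effect carries ≈ ±2.3 points
  (1 SD) under the preset conditions.
* Single-spectrum FTIR analysis (no EMSC reference) relies on the
  rubber-band background, whose chord under broad envelopes biases absolute
  area ratios; cross-specimen comparisons are unaffected because the bias
  is shared.
* Bending "material-level" properties (modulus from beam theory) are out of
  scope; the structural parameters above are what the load–displacement
  curve supports.
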