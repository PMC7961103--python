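# Methods

`pctracer` analyzes dual stable-isotope MALDI mass spectrometry imaging (MSI)
experiments on lung phosphatidylcholine (PC) metabolism: an exogenous,
universally 13C-labeled DPPC tracer (U13C-DPPC, all 40 carbons heavy) marks
instilled therapeutic surfactant and its metabolic products, while injected
*methyl*-D9-choline marks PC newly synthesized through the CDP:choline
(Kennedy) pathway. This note documents the models, parameters, and numerical
choices behind each stage, and what the synthetic phantom does and does not
establish.

## Mass model

All arithmetic reduces to an element/isotope count map. Atomic masses are
CODATA/AME constants collected in one table (`mass.ISOTOPE_MASS`); the heavy
label isotopes 13C and D are first-class symbols so that labeling is a count
transfer (C→13C, H→D) that conserves atoms. A diacyl PC with n acyl carbons
and d double bonds has composition C(n+8) H(2n+16−2d) N O8 P. Singly charged
cations subtract one electron mass; the sodiated PC32:0 ion computes to
m/z 756.55138, in agreement with the customary lock-mass value 756.551374 to
better than 0.01 ppm, which anchors the whole table. Key derived shifts:

- 13C − 12C = 1.0033548 Da, D − 1H = 1.0062768 Da
- D9 label: +9.0564907 Da on any ion of the species
- U13C-DPPC: +40.1341934 Da over DPPC

ppm errors are signed, (observed − theoretical)/theoretical × 1e6, printed at
one decimal; m/z is printed at four decimals.

### Natural-abundance envelopes

Aggregated isotopologue envelopes (M+0, M+1, …) are computed by per-element
polynomial convolution over neutron-shift space, carrying a first moment per
shift so each aggregated peak reports an abundance-weighted mean mass offset.
Fine structure within a nominal shift is deliberately not resolved. Labeled
sites are pure isotopes (no 14C/3H, no residual substitution). The
implementation is verified in tests against a brute-force expansion over all
per-atom isotope assignments on small formulas.

## MS/MS fragment model

Sodiated/potassiated PC precursors are scored by their two diagnostic
headgroup neutral losses — trimethylamine (C3H9N, nominal 59) and
phosphocholine (C5H14NO4P, nominal 183); protonated precursors by the
phosphocholine cation (C5H15NO4P+, nominal 184). Label routing is explicit
per tracer: the nine D9 deuteriums sit on the N-methyls and depart with
either loss; every 13C tracer in scope carries a fully heavy choline, sending
three 13C into trimethylamine (nominal 62) and five into phosphocholine
(nominal 188), with remaining heavy atoms (glycerol + palmitoyl for the 13C24
re-acylation label) retained on the fragment. Unknown tracer names require a
user-supplied routing rather than a guess. A label cancels out of a fragment
m/z exactly when all of its atoms depart with the loss; this holds for both
D9 losses and for the 13C5 phosphocholine loss, but not for the 13C5
trimethylamine loss, which retains two heavy carbons.

Fragment ppm errors are computed against fragments derived from the
*theoretical* precursor m/z. For the sodiated 13C24-PC16:0_20:4 precursor
(theoretical 828.6319) the predicted fragments are 766.5483 and 640.5491;
measured values of 766.5479 and 640.5487 score −0.6 ppm each.

## Image processing

- **Lock-mass recalibration** models drift as proportional (multiplicative):
  the most intense peak within ±20 ppm (default) of the lock m/z defines the
  correction factor applied to the whole axis. Absence of the lock peak is a
  flagged, non-fatal outcome.
- **Peak picking/alignment**: peaks below 0.05% of the dataset base-peak
  intensity are discarded; survivors are clustered greedily, seeding each
  cluster from the most intense unassigned peak and absorbing every
  unassigned peak within 3 ppm of the seed m/z (this seed-order greedy rule
  is the canonical tie-break); consensus m/z is the intensity-weighted mean;
  clusters present in fewer than 0.5% of pixels are dropped. Frequency counts
  nonzero pixels after the intensity filter.
- **Ion images** sum centroid intensities in a symmetric, closed ±ppm window
  (default 3 ppm, matching the alignment tolerance). TIC normalization
  divides by the pixel's total ion current; zero-TIC and spectrum-less grid
  pixels are missing (NaN), never zero.
- **Hotspot removal** clips values above the high quantile (default 99%) of
  valid pixels, computed with linear interpolation between order statistics
  (type 7); the clip state is recorded on the image and a re-clip at the same
  quantile is a no-op, making the operation idempotent. Hotspot removal is a
  visualization step: ratio and regional statistics operate on unclipped
  images, since clipping the bright tail of a high-uptake region would bias
  fold-change estimates downward.
- **Ratio images** are pixelwise quotients with denominator-zero and missing
  pixels propagated as missing; they are invariant to global intensity
  scaling, which is what makes isotopologue ratios robust to section-to-
  section intensity differences.

## Tracer quantification

Incorporation ratios report the mean ± sample SD (n−1) of pixelwise
labeled/unlabeled ratios over a region, excluding zero-denominator pixels.
Regional fold changes are ratios of region means. Remodeling abundances
express each species' intensity as a percentage of an explicit t=0 dose
reference (the normalization behind such references is instrument-specific,
so the reference is an input, not an inference). Group comparison is the
classical pooled-variance two-sample Student's t-test (Welch's form
available via `equal_var=False`), with p-values from the t distribution.

## The lung phantom

The generator emulates the *measured structure* of a lung MSI experiment —
not lung biology — so every pipeline stage can be validated against known
truth:

- **Geometry**: 64×64 pixels at 40 µm (default), a parenchyma background,
  two elliptical bronchiole lumina, and one elliptical surfactant-deposition
  blob. Region shapes are parameterized so tests do not depend on them.
- **Panel**: PC32:0 (dominant, everywhere), PC32:1, PC34:1, PC34:2
  (widespread), PC36:4 and PC38:6 (bronchiole-restricted), each emitted as
  H+/Na+/K+ adducts (0.35 : 1 : 0.45, sodiated dominant) with a 3-peak
  natural envelope.
- **Tracers**: D9-PC32:0 and D9-PC32:1 at 1% of the endogenous pools
  (Kennedy-pathway synthesis); U13C-DPPC at 7.55% of the deposited excess
  DPPC (the Poractant alfa-type dose enrichment; 2.87% models a CHF5633-type
  dose); the 13C24-PC16:0_20:4 re-acylation product at 0.1% of local DPPC,
  absent from bronchioles. The deposition blob raises DPPC 2.5-fold.
- **Noise**: multiplicative log-normal, CV 0.2 per pixel per lipid pool.
  A labeled isotopologue shares its parent pool's factor — isotopologue
  ratios cancel ionization/matrix effects, which is the physical basis of
  ratio imaging — plus an independent CV 0.02 channel jitter. Mass axes
  drift linearly with acquisition index, ±3 ppm by default (±5 ppm in the
  end-to-end recovery test), emulating slow calibration drift.
- **Determinism**: one seeded `numpy` generator drives all randomness; the
  seed is recorded in the dataset metadata.

What passing phantom tests show: the pipeline inverts the distortions the
generator applies (drift, noise, normalization) and recovers configured
fractions/folds within 3 standard errors at realistic abundances (labeled
species at 0.1–1% survive the 0.05%/0.5%/3 ppm picking thresholds). What
they do not show: robustness to matrix clusters, detector saturation,
profile peak shapes, co-isolated isobar fragmentation, or spatial intensity
structure beyond piecewise-constant regions — real data can fail in ways the
phantom cannot expose.

## Problem sizes and degenerate inputs

Tests run the 64×64 phantom (4,096 spectra, ~60–120 peaks each), which keeps
the full suite to a few seconds; the generator scales to larger grids
linearly. Degenerate inputs are explicit errors: empty datasets for peak
picking, all-missing images for clipping, zero denominators for folds and
ratios, label substitutions exceeding available atoms, and profile-mode or
UUID-mismatched imzML files. A pixel-less dataset still writes a valid
header-only imzML.

## Known limitations

Positive-ion, singly charged, diacyl PC only; no negative mode, ether/lyso
species, or other phospholipid classes. No profile-mode centroiding, spatial
segmentation, or kinetic (turnover-rate) modeling. Nominal masses use simple
rounding of the monoisotopic loss mass.
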