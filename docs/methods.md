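# Methods

This note documents the models, defaults and numerical choices behind the
package, and what the synthetic fixtures do and do not establish about real
data.

## Probe design

**Detection sites.** A detection site is a fixed-length window (default 40 nt)
on the target transcript whose two halves abut at a 5'-AG-3' or 5'-TA-3'
dinucleotide, the junction the ligase requires. Coordinates are 1-based
inclusive throughout the public API, so a site written 347–386 spans 40
nucleotides. Which side of the junction dinucleotide ends the 5' half is not
dictated by the chemistry as long as it is applied consistently; here the 5'
half ends with the *first* junction base (…A|G…, …T|A…), a convention isolated
in one helper so it can be swapped. Site enumeration lists every legal window,
tiles them greedily left-to-right without overlap, and, when more than the
requested number survive, subsamples at evenly spaced indices so the chosen
sites spread along the transcript. Sites are never allowed to overlap.

**Thermodynamics.** Binding-arm melting temperatures use the two-state
DNA/DNA nearest-neighbor model with the unified parameter table and a
monovalent-salt entropy correction, evaluated at 0.25 µM total oligo and
50 mM Na⁺ — the defaults of the oligo-analyzer tools probe designers use.
DNA:RNA hybrid parameters are deliberately not used, to reproduce the
DNA:DNA numbers those tools report. Arms start at 20 nt from the junction and
are extended or trimmed one base at a time at their distal ends, within a
12–30 nt window, until each arm's Tm enters 45–65 °C; a site whose arms cannot
reach the window (e.g. boxed in by a transcript end) is flagged and excluded
with a logged reason rather than emitted out of spec.

**Specificity.** A site fails the off-target screen iff any of its k-mers
(default k = 10, i.e. ≥10 shared contiguous nucleotides) occurs exactly in a
non-target transcript. The screen indexes the sense strand only, since probes
hybridize to RNA; an antisense flag exists for BLAST-style parity. The k-mer
index is required by construction (and by test) to agree exactly with naive
substring search. Self-complementarity is scored as the longest common
substring between a sequence and its own reverse complement; panels accept
scores up to 6 by default.

**Oligo assembly.** The eight overhang templates are 11-nt pairs drawn once
from a fixed-seed generator under GC 40–60%, homopolymer ≤ 3, and
pairwise-orthogonality constraints (no shared or cross-complementary ≥8-mer);
laboratories with validated template tables can load their own. Circles are
60 nt — two 11-nt arms reverse-complementary to the cognate overhangs around a
core embedding a 16-nt barcode — and all templates share one common 31-nt
bridge. Imagers are substrings of the circle (the barcode), which guarantees
their reverse complements appear in the tandem-repeat RCA amplicon; the
erasable variant replaces every dT with dU (15–20 nt), the rapid variant is a
10–11 nt stretch. Per-probe working concentration is 100 nM up to five pairs
per target, pro-rated beyond that so the per-target sum is exactly 1000 nM
(ten pairs → twenty H oligos at 50 nM). Targets are routed round-robin to
(cycle, channel) slots with at most five channels per cycle.

## Detection models

**Calibration.** With λ = c·FPKM transcript copies per cell, the fraction of
cells containing at least one copy is 1 − e^(−c·FPKM). The constant c is
fitted from (fpkm, n_cells, n_positive) tables by binomial maximum likelihood
on log c (bounded scalar search, tolerance 1e−10); a least-squares variant on
the fractions is available for comparison. Data in which every point is
saturated at fraction 0 or 1 carry no information about c and raise a
non-identifiability error.

**Efficiency.** Composite and per-site efficiency are the exact pair
E = 1 − (1 − p)^k and p = 1 − (1 − E)^(1/k), computed via expm1/log1p to
avoid cancellation; percentages are reported with half-up rounding.

**Puncta intensities.** Negative binomial parameterized by (mean m,
dispersion r) with variance m + m²/r, so cv = √(m + m²/r)/m. Fitting fixes
the mean at the sample mean, initializes r by method of moments, and refines
it by bounded maximum likelihood (tolerance 1e−6) on rounded intensities.
Zero-variance input returns cv = 0 with dispersion flagged undefined;
under-dispersed input returns the Poisson limit r = ∞. Signal-to-background
is the median punctum peak over the median background pixel, infinite when
the background median is zero.

## Image quantification

Z-stacks are max-projected. Cycles are aligned by integer-pixel phase
correlation of the nuclear-stain channels (the first cycle is the reference);
sub-pixel refinement is out of scope. A flat fiducial or a post-alignment
correlation below 0.2 falls back to the identity offset with a warning.
Nucleus seeds are local maxima of the Gaussian-smoothed nuclear image above an
Otsu threshold (parameter-free default); boundaries grow from the seeds by
watershed on inverted smoothed intensity, constrained to above-threshold
pixels, and are expanded by round(1 µm / pixel size) with nearest-label
assignment of contested pixels — original nucleus pixels are never
reassigned. Defaults: smoothing σ 1 µm, minimum seed separation 4 µm,
expansion 1 µm; the first two are standard starting points for epithelial
nuclei at 0.3–0.7 µm/px and are exposed in every entry point. Intensities are
measured as plain means over each sampling area with no background
subtraction by default. Pixel coordinates are 0-based row-major; physical
units enter only through `pixel_size_um`.

## Classification

Each gene is scaled by 10/max over all cells and fields of view (an all-zero
gene is an error, not a silent skip), then transformed by log10(0.1 + x),
which maps [0, 10] onto [−1, ~1.004]. The log base must be 10 for the stated
−1:1 range to hold. K-means runs in log space with Euclidean distance, 50
restarts and seed 0 by default; k is always user-chosen (10 for the default
8-gene fixture). Hierarchical clustering defaults to average linkage on
Euclidean distances; t-SNE (perplexity 30) is visualization-only and never
feeds classification, and no spatial feature enters any clustering. Marker
rules label clusters by thresholded centroid expression with
precedence = number of markers by default, so a dual-positive rule (e.g. a
Sftpc⁺Scgb1a1⁺ BASC-like rule) dominates the single-positive rules it
overlaps; equal-precedence conflicts raise.

## Synthetic data

The generators define the package's study conditions:

- **Transcriptomes** are uniform random sequences (defaults: 1–2.5 kb),
  scrubbed of accidental ≥10-mer sharing with any target so that *only*
  planted collisions (exact 10-mers copied from a named detection site into a
  named background transcript) fail the screen. Real transcriptomes have
  repeat structure, biased composition and isoforms that this does not
  emulate; the fixtures validate screen logic, not genome-scale specificity
  rates.
- **Calibration curves** draw n_positive ~ Binomial(n_cells, 1 − e^(−c·f))
  on a default grid of 36 log-spaced FPKM values over 0.05–5, emulating a
  36-gene single-cell qPCR panel concentrated where the curve is informative.
- **Tissue fields** default to 512×512 px at 0.5 µm/px, 300 nuclei placed by
  dart-throwing with 8 µm minimum separation, ten equiprobable classes over
  eight genes imaged as two cycles of four channels plus a nuclear stain, and
  a planted (3, −2) px offset on the second cycle. Class expression profiles
  are marker-like rate patterns (one or two high genes at 25 expected puncta,
  others at 0.5), a fixture device rather than a claim about lung biology.
  Puncta are Gaussian spots (σ 1.5 px) with NB amplitudes (mean 150, cv 1.5,
  mid-range of the 1–2 regime); the background level of 1.5 keeps the field
  in the >30-fold signal-to-background regime by construction. Nuclei do not
  overlap, there is no point-spread blur between cells, and offsets are pure
  integer translations — so end-to-end recovery results (exact cell counts,
  exact offsets, ARI ≳ 0.9) demonstrate pipeline correctness under clean
  conditions, not robustness to crowded or aberrated real micrographs.

These sizes keep the full default test suite and the reproduction script in
the tens of seconds on a single core.

## Known limitations

- No secondary-structure or hybridization-kinetics modelling in probe
  design; Tm and exact k-mer identity are the only filters.
- Registration is translation-only; rotation or scale drift between cycles is
  not corrected.
- Segmentation is seeded watershed on the nuclear stain; densely packed or
  overlapping nuclei will merge (two seeds closer than the minimum separation
  merge by design).
- The classifier is plain k-means; it inherits k-means' spherical-cluster
  assumptions in log space.
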