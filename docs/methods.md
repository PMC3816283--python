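# Methods

## Kinetic model

Uptake is modeled as single-compartment unidirectional influx during a
constant-concentration perfusion: the tissue distribution volume
Q\*/C\* (mL/g) grows linearly in perfusion time T with slope K_in and
intercept V₀. The assumptions are (a) negligible backflux over the
perfusion window, (b) constant perfusate concentration, and (c) a
time-invariant vascular space. Linearity over the 30–120 s window is
asserted, not detected; `fit_kin_multipoint` reports r² as a lack-of-fit
diagnostic but does not prune points.

Two estimators are provided and are exactly consistent: on noise-free data
from the uptake line, the single-timepoint formula evaluated with the true
V₀ reproduces the multipoint slope at every timepoint (this is a tested
invariant). Replicate single-timepoint records are converted to K_in per
record and then averaged (mean ± SEM across animals) rather than pooling
Q\* first, matching per-animal reporting with small group sizes. Negative
K_in values (tissue signal below the vascular contribution) are reported
with a `negative_kin` flag, never truncated, so group means stay unbiased.

V₀ precedence when fitting grouped tables: an explicit argument, else the
impermeant-tracer (sucrose) estimate from the same batch, else the
multipoint intercept; the choice is recorded as `v0_source`.

Units: fits are done in mL/g vs s; K_in is reported in µL/s/g (×1000),
V₀ in mL/g. A metamorphic test checks that consistent unit changes of
Q\* and C\* leave K_in unchanged.

## Calibration

Standards are fit by unweighted OLS of intensity-per-gram on nominal
concentration, intercept retained: homogenate autofluorescence and any
non-dark-subtracted camera offset land in the intercept, and no variance
model for the standards is assumed. A through-origin option exists for
cameras with verified dark subtraction. Region mass is
area (µm²) × thickness (µm, default 20) × 10⁻¹² × density (1.04 g/cm³).
Back-calculated concentrations below zero are preserved and flagged;
clamping is left to reporting time. The spiking dilution used when
preparing homogenate standards is treated as already folded into the
nominal concentrations.

## Efflux screen

The passive reference line is OLS of log₁₀ K_in (mL/s/g) on LogD (pH 7.4)
over compounds annotated `passive`. Deviation = predicted − observed
log K_in; a compound ≥ 1.0 log unit below the line is flagged as an efflux
suspect. The 1.0 default separates OLS scatter of passive panels
(typically < 0.5 log units) from genuine efflux substrates, which sit
1–3+ units low; the threshold is configuration, and classification is
monotone in it. The shipped compound panel
(`data/reference_compounds_synthetic.csv`) is synthetic: plausible names
and LogD values with K_in constructed on a reference line, intended as
editable configuration rather than measured truth.

## Image quantification

Pixel model: intensities are point samples at pixel centers, masks are
label images, areas are pixel counts × pixel_size² (no sub-pixel boundary
handling). Vessels are segmented from the endothelial channel by Otsu
threshold (manual override available) and 8-connected component labeling;
components under `min_size_px` (default 10) are dropped and counted.
Per-vessel expression is the plain mean of the target channel over each
labeled region and is invariant to relabeling.

BDT ("brain distant to tumor"), the fold-change denominator, is all tissue
at least `margin_px` (default 50 px) from any lesion pixel, computed by
Euclidean distance transform.

Registration searches integer translations only (same-slice modalities
share orientation and scale once the autoradiograph's block factor is
undone) and maximizes Pearson correlation over the overlapping region,
requiring ≥ 50% overlap; a peak correlation below 0.2 is logged as
unreliable. An FFT phase-correlation implementation serves as an
independent oracle in the tests, never as the implementation.

## Synthetic generator

The generator's defaults encode the study conditions the package targets:
baseline K_in 0.12 µL/s/g with V₀ 0.015 mL/g and C\* 50 µg/mL over
30–120 s; inhibited K_in 2.4 (cyclosporin A) and 2.2 (verapamil) µL/s/g
with n = 4 per group; per-vessel transporter intensity ~22.6 A.U. (normal
brain) vs ~22.9 A.U. (lesion vasculature) with SD ≈ 10.5 A.U. (chosen so
that SEMs of a few tenths of an A.U. arise at realistic vessel counts of
several hundred); passive-tracer lesion folds lognormal around 4.9 and
efflux-substrate folds around 0.98.

Noise models: additive Gaussian on images (camera read noise),
multiplicative CV-parameterized Gaussian on Q\* (inter-animal
variability), additive Gaussian on standards' intensity-per-gram. With
blur and noise at zero, every region statistic equals its configured value
exactly, and the perfusion generator is the exact model the kinetics
module fits — so round-trip tests are exact, not approximate.

Vessels are straight constant-intensity tubes with rejection-sampled
disjoint placement; no vessel-geometry statistics are emulated beyond
count, radius and length ranges, all config-exposed. Lesions are disks;
their masks are carried as ground truth rather than re-segmented, and the
analysis may additionally threshold-detect them (`--masks auto`).
What the generator deliberately does not emulate: histology texture,
vascular network topology, photon-physics camera noise, partial-volume
and section-registration artifacts of real cryosections. Passing
round-trip tests therefore validates the measurement arithmetic, not
robustness to real-tissue nuisance structure.

The autoradiograph is a block-mean downsample (integer factor f) of a
full-resolution activity map; output dimensions are floor(section/f) so
that every coarse pixel is a full-block mean (edge part-blocks would carry
biased means). Coarse ground-truth masks keep only blocks entirely inside
one lesion or entirely in background, which makes lesion/background mean
ratios exact at any factor. A known integer shift (coarse pixels,
background-filled) can be injected for registration exercises.

All randomness flows from one top-level seed through named substreams
(`crc32` of the artifact name mixed into the bit generator's seed
sequence), so generating a new artifact never perturbs an existing one,
and identical configuration + seed yields byte-identical files (writers
embed no timestamps).

## Statistics

The t-test defaults to pooled variance (Welch available as a flag); all
p-values are two-sided. Dunnett's many-to-one procedure computes pooled-
variance t statistics of each treatment against control and compares them
with the (1 − α) quantile of the null max-|t| distribution, obtained by
seeded Monte-Carlo (default 100,000 draws) rather than tables — exact in
the limit for any family size and unbalanced n, cached per configuration.
With one treatment the critical value reduces to the pooled-t quantile
(tested); with k ≥ 2 it is strictly larger (monotone in family size).
scipy's Dunnett implementation is used in the tests as an independent
cross-check of the decisions, not as the implementation.

Simulation sizes used by the test suite — 200 replicate uptake experiments
for parameter-recovery calibration, 5,000 replicate null experiments for
type-I-error checks, 100,000 draws per Dunnett critical value — were
chosen so Monte-Carlo error is comfortably below the tolerances asserted
(e.g. FWER tolerance ±0.01 vs binomial SE ≈ 0.003 at 5,000 reps).

## Report

`analyze_run` assembles a versioned JSON report (schema shipped in
`data/report_schema_v1.json`) with explicit `missing` entries for absent
stages; reports carry seed and configuration but no wall-clock time, so
identical runs are byte-identical. The efflux section substitutes the
run's own fitted baseline K_in for the probe compound before screening.

## Known limitations

- One slice per animal; no serial-section 3-D reconstruction.
- Registration is translation-only; rotation/scale mismatch is out of scope.
- No two-compartment or efflux-rate (k_out) modeling; inhibition is
  summarized as a fold change, not an inhibition constant.
- The passive reference panel is synthetic configuration; conclusions
  about specific compounds require a measured panel.
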