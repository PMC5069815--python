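# Methods

This note documents the models, defaults and numerical choices behind
`hccscreen`, and what the synthetic data does and does not establish.

## The screen being modelled

Two hepatic cell populations are co-cultured in 384-well plates: a malignant
HCC population (Huh7-like) and an immortalized normal hepatocyte population
(Fa2N-4-like). Both grow exponentially, N(t) = N₀·2^(t/T_d), with doubling
times T_d = 23.8 h (HCC) and 43.5 h (hepatocytes). Wells are seeded at
800 HCC + 1500 hepatocytes (a 35:65 premix chosen so neither population is
lost over the assay window), attached for 16 h, exposed to compound for
72 h, then fixed, stained (Hoechst; CHALV1 and AFP immunofluorescence) and
imaged in four fields per well.

Compound action is modelled as an endpoint survival multiplier per
population, the four-parameter logistic (4PL)

    V(c) = bottom + (top − bottom) / (1 + (c / IC50)^h),

in percent viability, applied to the grown count; realized survivor counts
are Poisson. This is deliberately an endpoint model — the screen reads one
timepoint, and modelling kill kinetics would add parameters nothing in the
data could constrain.

## Synthetic data generator

The generator renders what the analysis consumes and records what the
analysis should recover:

- **Geometry.** 512×512 px fields, 16-bit grayscale, nucleus radius
  ~N(6, 1) px (floored at 2 px). Nuclei are Gaussian spots of scale
  σ = r/2 in the Hoechst channel; markers are uniform disks over the cell
  footprint (nucleus dilated by a 4-px ring — a cytoplasm proxy; no
  cytoplasm stain exists in this screen).
- **Intensities.** Log-normal per channel. Defaults: Hoechst median 6000
  (gSD 1.2) for both populations; CHALV1/AFP median 1200 (gSD 1.4) for HCC
  vs 120 (gSD 1.4) for hepatocytes — a ten-fold separation, comfortably
  above the five-fold level at which classification is validated.
- **Noise.** Additive Gaussian read noise (SD 10 counts) over a background
  of 100; optional Poisson photon noise (off by default). No PSF
  convolution, z-blur or photobleaching: the analysis operates on
  segmentable spots, and optical realism would not change what the tests
  can establish.
- **Sampling.** The four fields capture a fraction (default 0.07) of the
  well's cells — a 20× objective sees a small part of a 384-well. At
  control density this is ~280 cells/field, ~1150/well. The default was
  set by a power calculation: the hit rule's tightest margin is the
  hepatocyte arm of a selective compound (~10 percentage points below the
  20 % gate), and with ~430 counted hepatocytes per well that margin is
  ≈3 SD of the duplicate-mean counting noise. Fewer counted cells make the
  screen lose true hits to Poisson noise, which is exactly why the QC rule
  demands >100 cells per well.
- **Placement.** Rejection sampling with minimum centroid separation 1.2×
  the mean nucleus diameter. Fields that cannot hold the requested count
  raise a named error rather than silently overlapping.
- **Determinism.** One run seed; per-well streams derive from a SHA-256
  hash of (seed, plate, well), so any well regenerates bit-identically in
  isolation.
- **Drug library.** A deterministic 43-compound pilot deck: 3 selective
  anti-folate-like compounds (HCC-arm IC50s 0.004074, 2.764 and
  0.0005194 µM; hepatocyte-arm IC50s 0.01518, 23.43 and 0.001688 µM), 12
  pan-cytotoxic, 8 hepatotoxic, 20 inactive, plus DMSO and sorafenib
  controls. The selective compounds' hepatocyte curves carry a high bottom
  plateau (90 % viability): in co-culture the hepatocyte population
  resists these compounds, which is the phenomenon the screen exists to
  detect; a full-kill hepatocyte curve at those monoculture potencies
  would contradict the screen's own outcome.

What the generator does **not** emulate: cell shape beyond disks+rings,
intensity spatial gradients, plate edge effects, focus failures, staining
batch variation, or any optics physics. Tests passing on this data show the
*analysis logic* is correct under the screen's statistical assumptions; they
do not show robustness to those real-world artifacts.

## Segmentation and classification

Nuclei: Gaussian smoothing (σ = 2 px), global Otsu threshold, Euclidean
distance transform, peak seeds (minimum separation 0.8× the expected
radius), watershed, then removal of regions below the area of a disk of
half the expected radius. The Otsu split runs on **log** intensity: nuclei
span a wide dynamic range over a dim background, and a linear-domain split
sits so high that small dim nuclei lose their thresholded area to the
minimum-area filter (measured 1.7 % missed nuclei at 300 cells/field,
versus 0 with the log split). Watershed labels are assigned
deterministically (scan-order seeds), so repeated runs agree exactly.

Per cell, every marker channel is measured as the mean over the nucleus
mask and over the 4-px dilation ring (ring pixels contested between cells
go to the nearest nucleus). **Classification uses the nucleus-mask means.**
The markers cover the whole footprint in this assay, and the nucleus mask
always sits inside it, whereas the ring of a generously segmented nucleus
spills into background and dilutes *both* markers at once for small dim
cells — a correlated error the AND rule cannot absorb (ring-based accuracy
97.8–98.5 % at the 5×/gSD 1.5 validation fixture, nucleus-based 100 %).
Both measurements are still computed and written.

Thresholds come from an Otsu split of the pooled negative-control
log-intensities per marker (≥50 cells required). If the pooled distribution
is unimodal — the histogram valley at the split is not deeper than 0.7× the
smaller mode — the split is meaningless and configured fixed cutoffs are
used instead. A cell is HCC only if *both* markers exceed their cutoffs,
hepatocyte only if both are at or below; single-positive cells are
**ambiguous** and excluded from both population counts. Accuracy is
accordingly scored over classified cells: abstaining on a boundary cell is
the designed behaviour, not an error. Wells with ≤100 cells fail QC and are
excluded from all screen statistics (the inequality is strict: 101 passes,
100 fails).

## Screening statistics

Per population, inhibition = 100·(1 − count / mean negative-control count),
computed per plate and never clipped below zero (stimulation is information).
Plate quality is Z′ = 1 − 3(s_p + s_n)/|m_p − m_n| on per-well HCC counts of
the two control arms (sample SDs, ddof 1); the screen aborts below the
configurable gate (default 0.5), still writing its report. Duplicate wells
are averaged before hit calling; disagreement beyond 30 pp is flagged. The
hit rule is strict on both sides: mean HCC inhibition > 50 **and** mean
hepatocyte inhibition < 20. Compounds with no QC-passing wells are excluded
and logged — with this library that legitimately removes several
pan-cytotoxic compounds whose wells hold too few surviving cells to count.

## Dose–response fitting

`FourPLModel.fit()` minimizes squared error of the 4PL on log₁₀ dose under
bounds 0 ≤ bottom ≤ top ≤ 120 (slight stimulation allowed), hill ∈ (0, 10],
log₁₀ IC50 within one decade beyond the dose range. The zero-dose control
anchors the top plateau and is placed 3 decades below the lowest nonzero
dose (sensitivity of the fitted IC50 to moving that anchor to 4 decades is
under 0.5 %, tested). Initialization: top/bottom from the response extremes,
IC50 at the dose bracketing the half-maximal response, hill = 1; five
multistarts jitter log₁₀ IC50 by ±1 decade; lowest residual SS wins, ties
to the lower hill. Data whose response range is under 10 percentage points
are flagged non-converged with no IC50 — there is no signal to fit. Standard
errors come from the Gauss–Newton covariance s²(JᵀJ)⁻¹, the IC50 SE by the
delta method from log₁₀ IC50. IC50s outside [min nonzero dose/100, max
dose×100] are flagged extrapolated. A fixed-slope (h = 1) option exists.

The default ladder is the vehicle control plus nine decade-spaced doses,
1 pM–100 µM — ten concentrations.

Selectivity: IC50ER = IC50(hepatocyte)/IC50(HCC), defined only for two
converged fits. Condition comparison reports the pooled-fit IC50 fold shift
and a two-sample Student's t-test on per-replicate log₁₀ IC50s (skipped
below 3 replicates; the shift is still reported). One calibration fact
matters when interpreting single experiments: at decade dose spacing with
3 % viability noise and triplicates, the fold-shift estimate carries ~12 %
sampling CV (it is unbiased). Recovery checks therefore average over
repeated simulated experiments rather than trusting one draw.

## Mode-of-action readouts

- **Lysosomal puncta**: Laplacian-of-Gaussian blob detection (radius range
  1–4 px, configurable intensity floor) on the background-subtracted
  LysoTracker channel; background is the per-image median outside all
  footprints. A punctum belongs to the footprint containing its centroid;
  orphans are dropped and logged. Counts are non-decreasing as the floor is
  lowered.
- **Cathepsin-B translocation index**: 1 − (background-subtracted signal
  inside the puncta mask)/(signal over the footprint), clipped to [0,1];
  0 is fully lysosomal, 1 fully cytosolic. Invariant under positive
  rescaling of the channel. Cells with no signal above background are
  excluded and logged, not imputed.
- **Nuclear channels**: γ-H2AX is quantified as mean nuclear intensity
  (it presents diffusely in this system, so focus counting would measure
  noise); EdU positivity by an Otsu cut on per-cell means; ROS/TMRM over
  the whole footprint (they are cytosolic/mitochondrial).
- **Caspase-3/7**: fold = mean(treated)/mean(control) of plate-reader
  readings after optional per-lysate protein normalization, with a
  two-sample t-test (≥3 readings per arm).
- **Spheroids**: stacks of ≥3 slices; the analysis takes slice
  floor(n/2), segments nuclei, measures cleaved-caspase-3 over
  nucleus+ring footprints, and calls positives by an Otsu cut. When the
  per-cell distribution is effectively unimodal (max/min < 3) Otsu would
  split noise, so cells are compared against an absolute floor (default
  3× the image background) — this is what makes the all-negative and
  all-positive spheroids return exactly 0 and 1.

## Assay-design module

Doubling times are fitted by least squares of log₂(count) on time
(slope = 1/T_d; SE by the delta method; scale-invariant in counts; a
non-positive slope is an error, not a number). Endpoint composition follows
the growth law; the seeding design inverts it in closed form (divide target
fractions by each population's growth factor and renormalize), and the
forward/inverse pair round-trips to numerical precision. The pilot seeding
densities 1500:800 are treated as the authoritative design; the inverse
solver is a tool, not a reconstruction of how they were chosen.

## Problem sizes used in validation

Validation runs were sized to be decisive yet quick: single fields of
120–300 cells for detection; one full 102-well, 43-compound plate
(4 fields/well, 512×512) for the end-to-end hit-calling check; 100 seeded
curves for fitter recovery; 220 cells per arm for puncta statistics; 10
simulated experiment pairs for the fold-shift check; 21–50-slice spheroids
with ~180 mid-plane cells.

## Known limitations

- The generator's simplifications above bound what green tests mean for
  real Operetta data; the segmentation operators are standard but untuned
  for real-image artifacts.
- The hit rule and Z′ are computed per plate; no B-score or cross-plate
  normalization exists (single-plate pilot design).
- IC50 uncertainty is frequentist-asymptotic (no bootstrap/Bayesian CI);
  replicate-level t-tests are the only inferential comparison.
- The translocation index conflates puncta-mask misses with genuine
  cytosolic signal if puncta detection under-segments; using the detected
  mask (not truth) in validation keeps this honest.
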