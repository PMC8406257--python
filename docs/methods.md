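# Methods

## Overview

`trenchph` implements a single-cell ratiometric pH phenotyping assay as a
closed loop: a generative model of the experiment (cohorts of mother-cell
lineages in mother-machine trenches, rendered through a simple optical
model) and an analysis pipeline that recovers per-cell pH trajectories
and end-point phenotype calls from the rendered data alone. Because the
generator's parameters are known exactly, every stage of the analysis can
be validated against ground truth, and population statistics recovered by
the full chain can be compared with the published values the presets
encode.

## The measurement model

Each cell expresses a pH-sensitive green reporter (FITC channel) fused to
a pH-insensitive red reporter (TRITC channel). Within a cell the expected
per-pixel intensities are

    TRITC(x) = B_T + E · c · ψ(x)
    FITC(x)  = B_F + R(pH) · E · c · ψ(x)

where `E` is the cell's expression level (copy-number proxy), `c` an
intensity scale (600 counts per unit expression by default), `ψ(x)` the
cell's footprint convolved with a Gaussian PSF, `B` the background, and

    R(pH) = (pH − b*) / a*

the ground-truth ratio map, by default the line `pH = 5R + 4` so that the
four calibration standards {6.5, 7.0, 7.5, 8.0} map to ratios
{0.5, 0.6, 0.7, 0.8} and hand computations stay exact. Because FITC is
proportional to TRITC pixel by pixel, the background-subtracted mean
ratio over any mask equals `R(pH)` exactly in the absence of noise — this
is the common-mode cancellation the ratio exists for, and it holds
through PSF blur. The analysis regresses pH on ratio (the direction the
pipeline applies) on per-standard mean ratios, and flags estimates
outside the reporter's linear regime [6.5, 8.0] as invalid; invalid
values are excluded from means and histograms but retained in the tables.

## The synthetic cohort generator

One mother cell per trench at t = 0 (canonical mother-machine loading);
the imaging schedule is hourly from 0 to 6 h plus a final frame at 24 h.
The treatment timeline is 3 h of ampicillin at 25× MIC followed by 21 h
of fresh medium; propidium iodide (PI) flows through at 24 h and one
extra TRITC frame is acquired.

Per strain preset:

- **Fates** are i.i.d. draws from `(P_persister, P_vbnc, P_susceptible)`.
  Susceptible lineages lyse with probability 0.9 (`susceptible_lysed`),
  at a time uniform in 3.5–10 h; the rest survive membrane-compromised
  (`susceptible_not_lysed`). The shipped presets encode the published
  compositions: parental 0.01/0.04/0.95; the tryptophanase knockout
  3.5× the parental persister fraction with VBNC unchanged; the
  0.5 mM-indole-supplemented knockout 0.001 persisters, VBNC unchanged.
- **t = 0 pH** comes from a per-fate mixture of ≤ 2 normal components.
  Parental VBNC and susceptible cells are bimodal with peaks at 7.0 and
  7.6 (component SD 0.15) and weights chosen so the mixture means equal
  the published 7.26 and 7.28 exactly; parental persisters are a single
  tighter peak with mean 7.04. The knockout starts unimodal near 7.5,
  the indole-supplemented knockout near 7.6.
- **Trajectories** are piecewise-linear interpolations of per-fate
  anchors at the scheduled times — the simplest model consistent with
  the reported means (parental persisters flat at 7.04 through
  treatment, rising to 7.3 at 24 h; VBNC/susceptible dropping to a 7.0
  minimum at 3 h and 6.8 at 24 h) — plus i.i.d. Gaussian frame noise.
  The per-cell trajectory SD is not published (only means ± SEM of large
  samples); it is a free parameter, default 0.1 pH units. Frames after
  t = 0 do not carry the t = 0 draw forward, which reproduces the
  observed collapse of the 7.6 peak during treatment.
- **Expression** is log-normal with arithmetic mean 1.0 and CV 0.25 —
  deliberately large enough that un-normalized single-channel intensity
  would be useless, so the tests genuinely exercise the ratio. Viable
  cells (persister, VBNC) double their expression by 24 h (continued
  synthesis in fresh medium); dead non-lysed cells decay to 0.2× as
  their fluorophores degrade. This separation is what the published
  images show (VBNC cells visibly brighter than susceptible-not-lysed at
  24 h) and is what makes a percentile-based low-expression cutoff
  clean.
- **PI response** multiplies a surviving cell's TRITC by a per-fate fold:
  3.0 for susceptible-not-lysed (membrane-compromised, stain enters),
  1.0 for persister and VBNC.
- **Division** (persisters only): first division uniform in 4–8 h, a
  possible second 3–10 h later (capped at 23 h), at most 3 cells per
  trench. Mothers elongate toward 2× their birth length before dividing
  and the daughters tile the elongated footprint, so frame-to-frame
  pixel overlap identifies divisions unambiguously at hourly sampling.

Geometry: trenches 20 µm × 1.6 µm at 6 µm pitch, 12 per field of view,
6 px/µm, PSF σ 0.15 µm; cells are capsules (rods with hemispherical
caps) 2.5–3.5 µm long, 1.0–1.2 µm wide, stacked from the closed end with
0.5 µm gaps and a 0.8 µm stand-off from the closed end. Backgrounds are
100 counts inside trenches (medium autofluorescence) and 60 outside
(PDMS), identical in both channels. Noise is Poisson shot noise on
expected counts plus Gaussian read noise (SD 2 counts), quantized to
16 bits; noiseless renders stay float and unquantized so exactness tests
are meaningful. Trace mode emits the background-free expected per-cell
intensities directly and is statistically equivalent to image-mode
photometry (tested), at ~100× the speed.

### What the generator does not emulate

No bright-field contrast, no cell motion or crowding-driven geometry
beyond the 3-cell cap, no photobleaching, no channel bleed-through or
FRET (the real assay acquires the two fluorophores serially to avoid
it), no focus drift, and no indole chemistry — indole conditions exist
only as alternative presets. Passing tests therefore demonstrate that
the analysis chain is unbiased under this controlled model, not that it
is robust to every artifact of real microscopy.

## Analysis pipeline

**Trench detection.** Trenches appear as periodic column bands whose
interior background steps above the outside level. Profiles use a robust
low quantile (25th percentile along the trench axis) so bright cells
cannot shift the band edges; the trench orientation is chosen by the
size of that background step (with the long-and-narrow aspect of the
candidate rectangles as fallback when backgrounds are equal), which
makes detection invariant to transposition. A frame with no significant
structure yields an empty map and a warning, not an error.

**Segmentation.** Per trench, Otsu thresholding on the TRITC channel
(constitutively bright), connected components, a 0.5 µm² minimum-size
filter, and a watershed split on the distance transform for components
longer than 2× the median cell length (division doublets). Labels run
from the closed end down. Saturated rasters raise an error advising a
bit-depth check rather than returning silently biased intensities.

**Tracking.** Greedy overlap-maximizing assignment between consecutive
frames (ties by centroid displacement, then label — deterministic and
order-invariant); a parent with two overlapping successors is a
division, none is a disappearance. Single-frame detection gaps are
bridged; two consecutive missing frames confirm disappearance. Unmatched
new masks near the open end are flagged washed-in and excluded; an
unmatched new mask deeper in the trench is attached to the trench's
single living lineage as regrowth. Because no frames exist between 6 and
24 h, a net increase in the trench's connected cell count at 24 h counts
as division evidence — without this rule a persister that first divides
after 6 h would be unclassifiable. Only lineages present at t = 0 enter
downstream analysis.

**Photometry.** The background is the mean of in-trench pixels outside
all (slightly dilated) masks, excluding a 3 px border ring where the
optical blur of the trench walls mixes in the darker outside level; with
the ring excluded, the noiseless ratio is exact to ≲ 10⁻³ and the
round-trip pH error stays below 0.01 units. A full trench falls back to
a caller-provided frame-level background. A non-positive TRITC signal
yields an undefined ratio with a QC flag (not an exception); TRITC below
5× the read-noise SD is flagged low-signal.

**Calibration.** OLS of pH on per-standard mean ratio (equal weight per
standard, as a 4-point standard curve implies), with n, residual SD and
R² as diagnostics; the inverse is applied directly. Out-of-range
estimates are flagged and excluded, never clamped — clamping would bias
the distribution tails.

**Phenotyping.** Decision order: absent at 24 h → susceptible_lysed;
divided after 3 h → persister; PI fold ≥ 2 or 24 h TRITC below the 10th
percentile of the t = 0 population → susceptible_not_lysed; otherwise
VBNC. The published analysis reports only statistical significance for
the PI response; the fixed fold-change threshold (2.0) keeps per-cell
calls deterministic. The percentile cutoff operationalizes "visibly
lower expression" and is a stand-in, not a published quantity. Surviving
non-dividers with no PI frame are labeled indeterminate and excluded
with a warning.

**Population statistics.** Phenotype fractions with binomial SEs
(susceptible = lysed + not lysed); per-phenotype histograms on a 0.1-pH
grid over [6.4, 8.1] with mean ± SEM (sample SD/√n; SEM 0 by convention
at n = 1); mode detection by Gaussian KDE with Silverman's-rule
bandwidth and a prominence floor of 10 % of peak density (the published
peaks were identified visually; the floor makes the call reproducible);
and the unpaired Welch t test, computed from the closed-form statistic
and a normalized Welch–Satterthwaite df that is immune to variance
underflow, with p from the t distribution. The hand computation is
cross-checked against an independent implementation to 10⁻¹⁰ in the
tests.

## Problem sizes and numerical choices

The acceptance recomputation uses trace-mode cohorts of 3 000 (parental
composition), 10 000 (indole-supplemented knockout, whose persister
fraction is 0.001) and 8 000 lineages (trajectory landmarks; ≥ 50
persisters at P = 0.01), and image-mode cohorts of 60/110/520 fate-pure
lineages for the t = 0 means — sizes chosen so each target's sampling
error is several times smaller than its comparison tolerance while the
whole recomputation stays around a minute on one CPU. Seeds are threaded
explicitly everywhere (`numpy.random.default_rng`); identical resolved
configurations give byte-identical outputs.

## Known limitations

- The trench-orientation heuristic can misjudge a frame whose inside and
  outside backgrounds are identical *and* whose cells all sit at the same
  height; default optics never produce this.
- Division assignment relies on parent/daughter pixel overlap, which the
  generator's elongate-then-split geometry guarantees; sparser sampling
  or fast-moving cells would need a motion model.
- The PI fold threshold and expression-percentile cutoff are operational
  stand-ins for judgments made by eye in the original assay; their
  defaults are documented, configurable, and validated only against the
  generator's model of those observables.
- Trace mode carries no measurement noise (it represents ideal
  photometry); measurement-noise robustness is exercised only by
  image-mode tests.
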