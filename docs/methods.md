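# Methods

## Measurement model

A NanoSIMS acquisition of one field is modeled as a set of per-ion count
images over `n_planes` consecutive raster passes. Pixel counts are
independent Poisson draws whose expectation field is constant within a cell
for each ion and equal to a small background fraction outside. Between
planes the whole field translates rigidly by an integer number of pixels
(stage/beam drift); there is no rotation, no scan distortion, and no
subpixel component in the model. These assumptions match the scale of the
instrument data the pipeline targets: ~0.02–0.16 μm pixels (5–41 μm rasters
at 256×256), drift of a few pixels over six planes, and count-limited
images where preserving integer Poisson statistics matters more than
subpixel registration.

Isotopic composition enters through the rare-channel expectation: a cell
with ¹³C atom fraction F has E[¹³C⁻]/E[¹²C⁻] = F/(1−F) exactly, and
likewise for ¹²C¹⁵N⁻/¹²C¹⁴N⁻ with the ¹⁵N fraction. The natural-abundance
baselines are count ratios R₁₃ = 0.0112 and R₁₅ = 0.0037 (overridable);
atom fraction and atom percent enrichment are deterministic transforms
F = R/(1+R), APE = 100·(F − F_nat).

## Drift correction and accumulation

Each plane's offset relative to plane 0 of a reference ion (default
¹²C¹⁴N⁻, the channel with the strongest biological contrast) is the integer
(dy, dx) within ±`max_shift` (default 10 px) maximizing the Pearson
correlation between the overlapping regions of the candidate-aligned plane
and plane 0. The search is exhaustive over the (2·max_shift+1)² grid, so
the estimate is exact on noise-free inputs by construction. Ties are broken
deterministically: smallest shift magnitude first, then row-major (dy, dx)
order; a candidate whose overlap has zero variance scores −∞. One trace is
estimated per stack and applied to all ions, which are acquired in
parallel and therefore share the drift.

Accumulation back-shifts every plane by its estimated offset and sums.
Pixels not covered by *every* shifted plane form the complement of a
validity mask; they are zeroed and excluded from all downstream statistics
rather than being zero-padded into them. At zero drift the accumulated
image is exactly the plane-wise sum, conserving total counts. Sums rather
than per-plane averages are used so the accumulated image remains an
integer count image; every downstream ratio is invariant to this choice.

## Segmentation and quantification

Automatic segmentation (a stand-in for manual ROI outlining) Otsu-
thresholds the reference ion inside the validity mask, fills holes, labels
8-connected components, and discards components below `min_area_px`
(default 50 px). Because Otsu always produces *some* split, a contrast
guard rejects the segmentation wholesale when the foreground class mean is
less than `contrast_min` (default 3×) the background class mean — on a
background-only Poisson field the split separates counting noise, not
cells, and the correct answer is "no ROIs". Cells in the images this
pipeline addresses are hundreds of times brighter than background, so the
guard is far from the operating point.

Per-cell ratios pool counts before dividing: R = Σ(rare)/Σ(abundant) over
the ROI∩validity pixels. The ratio-of-sums estimator is standard for
count-limited SIMS data; its relative bias is ≈ 1/Σ(abundant), i.e. below
10⁻⁴ at the ≥10⁴ denominator counts typical here (verified by Monte Carlo
in the test suite). The ¹⁵N/¹⁴N ratio is taken as exactly the
¹²C¹⁵N⁻/¹²C¹⁴N⁻ sum ratio with no correction factor. Both raw ratios and
APE are reported; downstream statistics default to ratios, with APE
available as a variable switch.

Rod morphometrics project the ROI pixel centers onto the principal axes of
their second central moment matrix; each extent is (max − min projection)
+ 1 px, so a single-pixel mask measures one pixel rather than zero, scaled
by the pixel pitch. The pair is ordered so length ≥ width. Rotating a mask
changes either extent by at most about one pixel (rasterization error).

Magnetosome crystal tables (length = longest axis, width ⟂ to it, both nm)
are summarized with fixed [0,10), [10,20), … nm histograms, mean ± SD,
mean shape factor (width/length), and an OLS regression of width on
length; the regression is NaN for degenerate all-equal lengths.

## Statistical layer

**Normality gate.** Shapiro–Wilk with "normal" declared at p > 0.05; a
constant sample is reported non-normal with p = 0 and a warning (the
statistic is undefined). Pairs of time points are compared with an
unpaired two-sided Student *t* (pooled variance) when both groups pass the
gate, otherwise a two-sided Mann–Whitney *U*; significance at p < 0.05,
with no multiple-testing correction by default; `pairwise_matrix` can
optionally fill a Holm-adjusted p-value column (`holm_adjust=True`)
without changing the raw significance calls.

**Subsample-median polynomial fit.** Per repetition, each time point
contributes the median of ⌈0.7·n⌉ cells drawn *without* replacement (the
scheme resamples a 70% subset; classical with-replacement resampling is a
config switch). The subsample size ⌈·⌉ guarantees non-empty groups down to
n = 1, and the median of an even-sized sample is the midpoint of the two
central order statistics. A degree-2 polynomial is least-squares fitted to
the (time, median) pairs — implemented as one Vandermonde pseudoinverse
applied to all repetitions at once. After `n_reps` (default 10,000)
repetitions, each coefficient is reported as the center of the most
populated bin of its 1-D Freedman–Diaconis histogram (ties → lowest bin;
degenerate all-equal repetitions → that exact value). The per-coefficient
marginal mode is the default because it is stable at 10⁴ repetitions; a
joint 3-D mode is available behind a flag. RSS is computed for the modal
polynomial against the *full-data* per-time-point medians (the fit's
actual targets), not against every cell.

Two properties pin the implementation down: with fraction 1 and one
repetition the procedure reduces exactly to a single least-squares fit of
the full-data medians, and noiseless polynomial data yield the exact
coefficients with RSS 0. Note the subsampling distribution is *not* a
confidence distribution for the coefficients: a 70% without-replacement
subsample understates full sampling variance by (1−f)/f ≈ 0.43, so its
central 95% interval covers the true coefficient only ~85–90% of the time.
Recovery tests therefore measure the modal coefficient's distance to truth
in units of that interval's width.

**Heterogeneity.** Per time point: IQR, IQR/|median| (robust CV, NaN at
zero median), and n (groups under 3 cells are flagged, never silently
dropped); the trend summary is the Spearman rank correlation of IQR
against time, reported as 0 with a `trend_defined=False` flag when
constant dispersion makes it undefined.

## Synthetic scenes

The generator emulates exactly the features the analysis depends on: rod
cells (rectangles with semicircular caps) placed without overlap and with
a ≥3 px clearance at random positions/orientations, lengths 3.5–6.5 μm and
widths 0.8–1.2 μm by default (the target organism is a ~5 × 1 μm rod);
per-ion in-cell expectations (defaults ¹²C⁻ 200, ¹²C¹⁴N⁻ 150, ¹⁶O⁻ 80
counts/px/plane — chosen for statistical power, as the study's own count
magnitudes are not published); ³²S⁻ tied to ¹²C¹⁴N⁻ (×0.8) to encode their
observed colocalization; a 1-px axial ¹⁶O stripe (×3) standing in for the
magnetosome chain; background at 1% of in-cell rates at natural abundance;
per-plane integer drift uniform in ±`drift_max_px` (default 3); and
per-cell atom fractions drawn normally (hence median-preserving) around a
quadratic trajectory in time with an SD that grows linearly in time,
clipped to [0, 1). One root seed spawns independent child streams per
(time point, replicate), so any scene is reproducible in isolation.

What the generator does **not** emulate — and what passing tests therefore
do not demonstrate about instrument data: detector dead time and
quasi-simultaneous-arrival effects, topography and matrix effects,
sub-pixel or rotational drift, intra-cell enrichment structure (real
enrichment is not uniform within a cell), cell division or movement during
acquisition, and manual-outlining subjectivity. The morphometric ground
truth is the *sampled* rod geometry; segmentation-based estimates carry an
extra ~1 px of threshold-dependent dilation.

## Problem sizes and numerical choices

The test suite and the reproduction script run at desk scale by design:
96–256 px fields, 2–5 cells per scene, 10–25 scenes per experiment,
10,000 bootstrap repetitions, 1000–2000 Monte-Carlo replicates for
calibration checks. Baseline-ratio recovery uses 50 cells across 10 seeded
256 px scenes — enough for the pooled-count standard error of the mean
ratio (~0.3%) to sit well inside the ±2% acceptance band. Floating-point
round-trips through CSV use 12 significant digits (re-parse agreement at
10⁻⁹ relative). All randomized procedures take explicit seeds;
`numpy.random.Generator` streams are never shared across unrelated
components.

## Known limitations

- Integer-pixel registration cannot correct genuine sub-pixel drift; at
  these rasters that error is below one pixel per plane and is absorbed
  into the ~1 px morphometric uncertainty.
- Otsu segmentation merges cells closer than ~2 px and is not a substitute
  for expert outlining on crowded fields; manual label masks can be
  imported instead.
- The modal-bin-center rule makes the reported coefficients depend weakly
  on the histogram binning; Freedman–Diaconis widths at 10⁴ repetitions
  keep that dependence below the subsampling spread itself.
- The descriptive quadratic is not a kinetic model; its coefficients
  summarize the median trajectory and nothing more.
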