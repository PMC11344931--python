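# nanosip

Single-cell stable-isotope-probing (SIP) analysis for NanoSIMS secondary-ion
image stacks.

NanoSIMS rasters a Cs⁺ beam over a field of cells and counts sputtered
secondary ions per pixel, producing one count image per ion species
(here ¹²C⁻, ¹³C⁻, ¹²C¹⁴N⁻, ¹²C¹⁵N⁻, ¹⁶O⁻, ³²S⁻) per raster pass ("plane").
After incubating environmental bacteria — rod-shaped magnetotactic cells —
with ¹³C-bicarbonate and ¹⁵N-nitrate, the enrichment of each single cell
above the natural-abundance baselines reveals its CO₂-fixation and nitrate
uptake activity, and the cell-to-cell scatter reveals metabolic
heterogeneity over incubation time.

`nanosip` implements the computational side of that experiment:

- **Drift correction and accumulation** — consecutive planes drift by a few
  pixels; each plane's integer offset relative to plane 0 is estimated by
  maximizing normalized cross-correlation over a bounded shift grid, planes
  are back-shifted and summed, and a validity mask excludes pixels not
  covered by every plane.
- **Per-cell quantification** — for each cell ROI (auto-segmented by Otsu
  thresholding, or imported manual label masks), isotope ratios are
  *ratios of pooled sums*, R₁₃ = Σ¹³C⁻/Σ¹²C⁻ and
  R₁₅ = Σ¹²C¹⁵N⁻/Σ¹²C¹⁴N⁻ (the ¹⁵N/¹⁴N proxy), with atom fraction
  F = R/(1+R) and atom percent enrichment APE = 100·(F − F_nat) against the
  natural baselines R₁₃ ≈ 0.0112, R₁₅ ≈ 0.0037. Rod length and width come
  from principal-axis extents of the ROI mask.
- **Trend statistics** — per-variable time-course fitting by a subsample
  bootstrap: at each time point 70% of the cells are drawn without
  replacement, their median is taken, a second-order polynomial is fitted
  to the (time, median) series, and after 10,000 repetitions each
  coefficient is reported as the mode of its empirical histogram, plus the
  RSS of that modal polynomial against the full-data medians. Pairwise
  time-point comparisons use a Shapiro–Wilk normality gate (p > 0.05)
  routing to an unpaired Student *t* or Mann–Whitney *U* test; a
  heterogeneity profile tracks per-time-point IQR and its Spearman trend
  against time.
- **Crystal morphometrics** — magnetosome crystal populations (length,
  width, shape factor = width/length) summarized with 10-nm histograms,
  moments, and width-vs-length regression.
- **Synthetic scenes** — the raw study images are not public, so a fully
  seeded generator produces rod-cell scenes with per-ion Poisson counts,
  per-plane drift, a ¹⁶O-boosted magnetosome-chain stripe, and per-cell
  enrichment following a quadratic median trajectory with time-growing
  spread — with complete ground truth for recovery testing.

## Worked example

```python
import numpy as np
from nanosip import (SceneConfig, generate_scene, estimate_drift, accumulate,
                     segment_cells, measure_cell)

cfg = SceneConfig(n_cells=3, seed=42)           # 256 px field, 20 um raster
stack, truth = generate_scene(cfg, timepoint_h=0.0)

trace = estimate_drift(stack, max_shift=5)      # align planes to plane 0
print("true drift:", truth.shifts)
print("estimated: ", list(trace))

acc = accumulate(stack, trace)
for roi in segment_cells(acc):
    m = measure_cell(acc, roi)
    print(f"cell {m.cell_id}: R13={m.r13:.5f}  R15={m.r15:.5f}  "
          f"APE13={m.ape13:+.4f}  length={m.length_um:.2f} um  width={m.width_um:.2f} um")
```

prints

```
true drift: [(0, 0), (1, -1), (-3, 3), (0, 3), (1, 2), (2, -2)]
estimated:  [(0, 0), (1, -1), (-3, 3), (0, 3), (1, 2), (2, -2)]
cell 1: R13=0.01116  R15=0.00380  APE13=-0.0035  length=6.49 um  width=1.18 um
cell 2: R13=0.01117  R15=0.00360  APE13=-0.0027  length=5.83 um  width=1.05 um
cell 3: R13=0.01114  R15=0.00364  APE13=-0.0056  length=4.64 um  width=1.25 um
```

Every injected plane drift is recovered exactly, and the unlabeled cells
measure at the natural-abundance baselines (R13 ≈ 0.0112, R15 ≈ 0.0037)
with near-zero atom percent enrichment — the Poisson counting scatter on
pooled sums of ~10⁶ ¹²C⁻ counts per cell is below 1%. Cell lengths and
widths land on the generated rod dimensions (~4–6.5 μm × ~1 μm).

## Command line

The same stages run as a pipeline with full config/seed stamping:

```sh
nanosip all --config config.yaml --seed 1 --outdir run/
nanosip stats --outdir run/ --variable R13 --use-replacement   # re-run one stage
```

Subcommands `simulate`, `process`, `segment` (accepts `--roi-masks` for
manual label images), `measure`, and `stats` each re-run one stage from the
previous stage's serialized outputs (per-ion multi-page TIFFs + JSON
sidecars, 16-bit label masks, a measurement CSV, and a JSON stats report).

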