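# Methods

This note documents the models, parameter choices and numerical decisions
behind `ocuscreen`, and what the synthetic-data tests do and do not
demonstrate about real microscopy data.

## The screening model

A micropatterned chip partitions a corneal epithelial monolayer into an
array of circular 80 µm adhesive islands, each holding a small colony.
Because each colony yields an independent binary outcome per assay, a single
chip produces hundreds of observations — enough to support logistic
regression, which bulk-well assays (one analog value per well) cannot.

Two mechanisms are read out per colony:

1. **Apoptosis.** After 24 h exposure, caspase-3/7 intensity is measured per
   cell (mean over the nucleus mask dilated by 2 px, capturing perinuclear
   stain). Each chip carries its own vehicle-control well; a cell is
   apoptotic when its relative excess over the pooled control-cell mean is
   strictly above 20 %. The 20 % rule is implemented as relative excess
   `(I − mean_ctrl)/mean_ctrl > 0.20` — the only reading under which "20 %"
   is unit-free; it is also the only scale-invariant choice (multiplying all
   intensities by k > 0 changes no outcome, a property the tests enforce).
2. **TRPV1 activation.** Fluo-4 is imaged at 5 frames/s for 5 min with
   compound induction after ~1 min of baseline. Per-cell traces are
   baseline-subtracted at the first frame (resting Ca²⁺ is highly
   heterogeneous across cells), and the integrated peak area is the
   rectangular-rule sum over frames `induction+1 … induction+20` (~4 s).
   Only the sign is used downstream, so rectangular vs. trapezoid
   integration is immaterial; frame units avoid a silent ×0.2 s rescale.
   A strictly positive area scores 1; zero scores 0 (a response must be
   positive, and an exactly-zero area carries no evidence of influx).

A micropattern scores 1 when **≥ 50 %** of its cells score 1. The strict
(> 50 %) variant is available via `rule=">"`; at exactly half the cells
positive the default scores 1. Patterns that end up with no segmented cells
are excluded with a logged exclusion record, never silently dropped.

## Image quantification

* **Auto-threshold**: Otsu on the intensity histogram, foreground strictly
  above threshold (bright nuclei, dark background). Otsu is the standard
  bimodal default and closely matches ImageJ's IsoData family on data of
  this kind. A constant image yields an empty mask plus a warning.
* **ROI-grid registration**: plate placement varies by a rigid shift, so one
  global integer offset is fitted. Candidates are the origin (always
  evaluated first) plus offsets sampled uniformly **without replacement**
  from the ±`max_shift_px` integer lattice (default ±10 px, 441 offsets);
  the score is total foreground area inside all ROI discs, ties keep the
  first-encountered maximum. With the default 500 iterations the candidate
  set covers the lattice, making the search exhaustive and its agreement
  with a brute-force enumeration deterministic. Note the score can plateau:
  when every nucleus lies strictly inside its ROI at several offsets, those
  offsets tie, and the returned offset is one of the tied optima — the
  downstream segmentation is identical at any of them.
* **Segmentation**: connected components (8-connectivity) of the binarized
  DAPI channel; components below `min_area_px` (default 20 px at the default
  1 µm/px scale — rejects specks without losing real nuclei) are discarded;
  each component is assigned to the ROI disc containing its centroid, giving
  a deterministic single assignment for boundary-straddling cells. Touching
  nuclei are not split: the 80 µm pattern size is chosen precisely so
  colonies are not over-clustered, and a watershed would add failure modes
  the assay design already avoids.
* **Coordinates**: 0-based pixels, (x, y) = (column, row), origin top-left;
  ROIs are closed discs.

## Dose-response fitting

The fitting unit is the **micropattern** (one binary record each), with
concentration C in nM on the linear scale — the natural scale for the
per-nM slope of the logistic law (a log₁₀ predictor can be applied by the
caller transforming C upstream). The maximum-likelihood fit is Newton/IRLS
with the predictor internally rescaled to C/max(C) (the raw design matrix
spans ~7 orders of magnitude and is numerically hostile); coefficients and
the inverse-observed-information covariance are mapped back to per-nM units.
Convergence requires the Newton step to fall below `tol` (default 1e-8,
relative); separation is declared when a rescaled coefficient exceeds 10³
logit units or the information matrix becomes numerically singular, and
all-identical outcomes raise immediately with an explanatory message.
The implementation agrees with an independent GLM fit (statsmodels) to
~1e-6 relative and with a dense log-likelihood grid search in the tests.

IC50 is −β₀/β₁, defined only for β₁ > 0 — a flat model (the mild-irritant
case prints a "+0.0·C" equation) has no IC50 and raising an error is the
honest behavior. Confidence bands are pointwise Wald intervals on the
linear predictor mapped through the logistic function: cheap, guaranteed to
bracket the point estimate, and coverage-testable (a 500-replicate
Monte-Carlo study in the suite checks ~95 % nominal coverage at mid-range
concentration). Profile-likelihood bands were deliberately not implemented;
the upstream software whose output this mirrors reports generic regression
bands.

The combined irritation probability uses the union rule for
non-mutually-exclusive events with the intersection modelled as the
**independence product** P_A·P_B. Independence reproduces both published
combined values (0.86 for the mild irritant, ~0.63 for the surfactant below
its cytotoxic range); a user-supplied intersection rule is accepted and
validated against the Fréchet bounds. Assays with concentration-independent
response (slope-zero fits) may be passed as a constant probability — a
non-identifiable slope is expected and legitimate there.

## Synthetic data: what it emulates and what it does not

The generator's defaults are the study conditions:

| parameter | default | rationale |
| --- | --- | --- |
| cells per pattern | rounded N(4.5, 2²), min 1 | printed colony statistics; the distribution shape is unstated, so a rounded truncated normal (matching the printed moments, never empty) is the package's stand-in |
| pattern diameter | 80 µm (80 px at 1 µm/px) | assay's chosen pattern size |
| grid pitch | 1.5 × diameter | keeps ROIs disjoint with registration headroom |
| nucleus radius | 5 px | ~10 µm nuclei at the default scale |
| apoptotic intensity | 1.5 × control level (≥ 1.2× enforced) | the 20 % threshold separates classes by construction; rendering noise (sd 2 on levels 100/150) makes misclassification rare but nonzero |
| time-lapse | 1500 frames at 5 Hz, induction at frame 300 | 5 min at 5 frames/s, induction after 1 min |
| sharp peak | exponential decay, 2-frame time constant | agonist-like transient gone within ~5 frames |
| broad peak | gamma-shaped (shape 2, scale 12.5 frames) | irritant-like transient decaying over ~50 frames |
| baseline CV | 0.2 across cells | heterogeneous resting Ca²⁺ |

Nuclei are rendered as non-overlapping Gaussian-profile discs (σ = 2 r, so
in-disc intensity stays within ~12 % of peak) placed by rejection sampling
with bounded retries (100 per cell, 100 whole-pattern restarts); an
impossible packing raises an error naming the pattern. The caspase/Fluo-4
stain footprint is painted on exactly the 2 px morphological dilation of the
rasterized nucleus, so noiseless measured means equal the painted levels to
machine precision — that is what makes the exact round-trip tests possible.
Trace noise is injected into the per-cell trace and painted uniformly per
frame, so re-measuring the rendered stack over ground-truth masks reproduces
the traces exactly (float32 rounding aside).

What passing these tests shows: the ROI registration, segmentation,
measurement, digitization and fitting chain is internally consistent and
recovers known ground truth under the assay's stated geometry and
statistics. What it does not show: robustness to uneven illumination,
focus drift, photobleaching, cell motion, cytoplasmic stain overlap between
touching cells, or non-bimodal intensity histograms — none of which the
generator emulates (deliberately: they are out of scope).

## Problem sizes and reproducibility

Every stochastic operation is driven by an explicit integer seed and is
bit-reproducible; the pipeline manifest records the config echo, all derived
per-chip seeds and the package version, and rerunning a config yields
byte-identical CSVs. The acceptance script evaluates the published models in
closed form, segments 4 × 256 = 1024 noiseless micropatterns for the mean
colony size, and refits 500 simulated pattern outcomes per concentration
over each compound's tested range — sizes chosen to put Monte-Carlo error
well inside the quantities' own uncertainty while keeping a laptop run in
seconds.

## Known limitations

* The per-cell apoptosis threshold and the ≥ 50 % rule are hard cutoffs; no
  fuzzy or multi-threshold scoring is offered.
* One global rigid offset registers the grid; per-ROI or affine drift is not
  modelled.
* The necrosis (EthD) channel of the bulk assay is not digitized.
* Chips are treated as exchangeable; no chip-level random effects.
* The independence intersection is an assumption, not an estimate — with
  only marginal probabilities observed, the intersection is not
  identifiable; the Fréchet bounds delimit the possible range.
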