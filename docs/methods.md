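# Methods

This note documents the models, parameter defaults and numerical choices
behind `cytoprofile`, and what the synthetic-data tests do and do not show
about real screens.

## Screen design

The default synthetic design mirrors a natural-product fractionation screen:
3 plants x 28 solid-phase-extraction fractions = 84 samples, a dose ladder
of (0, 1.56, 3.12, 6.25, 12.5, 25, 50) ug/ml, 4 replicate wells per
(sample, dose), and 4 staining panels, laid out column-major on 16x24
(384-well) plates whose first 16 wells are untreated medium-only controls.
Every count is configurable (`ScreenConfig`); one timepoint (24 h) is
simulated by default, with the timepoint set a config tuple.

## Generative model (synthdata)

Each sample is assigned a phenotype signature — one of ten bundled
mechanism classes (or inert) — and every well is simulated independently
from a per-well seed derived by hashing (master seed, plate, well), so any
well can be regenerated in isolation.

* **Cell count** ~ Poisson(baseline x survival), with the Hill kill curve
  survival(D) = 1 / (1 + (D / EC50_kill)^h). Baseline defaults to 2,000
  cells per well (the seeding density; imaged counts per well are not
  knowable from seeding density alone, so the baseline is config-exposed).
* **Dose -> effect strength** uses the same Hill family with its own
  midpoint: w(D) = 1 / (1 + (EC50_eff / D)^h), defaults EC50_eff = 5 ug/ml,
  h = 2. One parametric family keeps the knob count low.
* **Cell cycle / DNA content**: each cell draws a phase from the mixture
  (1 - w)·control + w·target, where the control mixture is
  (low 0.02, G0/G1 0.60, S 0.20, G2/M 0.16, high 0.02). DNA content in
  genome-copy units: Gaussian peaks at 2N and 4N (sd 0.16N), sub-2N cells at
  1.2N, super-4N at 5.5N, and S-phase cells uniform on the band between the
  G0/G1 and G2/M classification windows (2 + tau, 4 - tau). Drawing S on
  the open band rather than all of (2N, 4N) makes the phase mixture exactly
  recoverable by the DNA-content classifier, which is what the phase-
  recovery tests verify; real S-phase populations overlap the 2N/4N windows
  and would blur the recovered fractions.
* **Marker intensities**: control mean x (1 + w(D) x effect) per channel,
  with unit-mean lognormal per-cell noise (CV 0.25). Endpoint-assay
  inductions (MitoSOX, permeability, caspase-9, p53, gH2AX) are expressed as
  fold-change-at-saturation and folded into the same channel-effect model.
* **Nuclear area** scales as (N/2)^(2/3) (volume-like growth through the
  cycle) around an 80 px baseline, CV 0.15.
* **Rendered images** (optional): nuclei are flat-top radial spots
  (super-Gaussian exp(-(d/rho)^8)) whose integral equals DNA content x gain,
  cytoplasm a dimmer Gaussian halo, over a flat background with Poisson
  noise, written as 16-bit TIFF. A flat-top profile keeps integrated
  intensity nearly threshold-independent, which real stained nuclei
  approximate and pure Gaussians do not. Optics (PSF tails, illumination
  gradients) and plate-edge effects are deliberately not modelled.

## Imaging

Background is corrected per image by subtracting the median of sub-Otsu
pixels (robust, parameter-free), clipping at zero. Nuclei are segmented by
Otsu threshold, hole filling and distance-transform watershed
(`min_distance` 7 px); objects outside [25, 4000] px or touching the border
are invalid. The nuclear compartment grows the segmented object by 2 px to
recover the blurred rim a global threshold cuts off — without this, the
integrated DNA intensity of bright nuclei is biased upward relative to dim
ones; the cytoplasmic ring extends 4 px further, with `expand_labels`
guaranteeing neighbouring cells never share pixels. Wells need >= 500 valid
objects (config) to enter profiling.

## Profiling

Replicate wells are averaged first, then the in-plate control mean is
subtracted (per plate), then deltas are normalized per feature. Two
normalizations:

* **screen-max** (default): delta / max over all samples of |delta|,
  clipped to [-1, 1]. Parameter-free and reproduces the [-1, 1] score range
  exactly: per feature the strongest sample scores exactly +/-1. Its
  drawback — sensitivity of the scale to the single strongest sample — is
  why a bounded alternative exists.
* **robust-z-tanh**: tanh(z/3) with z = delta / (1.4826 x MAD of control
  wells). Bounded without clipping; scale meaningfull when many controls
  are present.

Normalization is per screen by default (per plate selectable). Samples
missing more than 25% of their features (QC exclusions) are dropped from
clustering. Profiles for clustering are taken at the mid-ladder dose
(12.5 ug/ml by default): at the top doses the strongest cytotoxic classes
fall below the valid-object QC gate, which is also why the real choice in
such screens is a sub-cytotoxic dose. If the configured dose is not on the
ladder the nearest positive dose is used.

## MoA assignment

Pearson distance d = 1 - r (centered, pairwise-complete over missing
features; pairs sharing < 3 features are an error, not NaN). d violates the
triangle inequality; average linkage does not require metricity. Linkage is
UPGMA by default (complete/single selectable); the displayed leaf order puts
the tighter (lower-height) subtree first at every node, ties broken by
smallest leaf index. The tree is cut at height 0.3, i.e. clusters cohere at
r >= 0.7 ("closely matching" profiles); fractions inherit the majority
reference class of their cluster, ties resolved by the nearest tied
reference, reference-free clusters labelled `unassigned`. Newick export is
ultrametric with node elevation = merge height / 2.

In the end-to-end pipeline, reference-library class signatures are expressed
in the same score space as the screen: the expected raw feature deltas of
each builtin mechanism class are divided by the same per-feature
normalization denominators the fractions were scored with. This mirrors the
real workflow, where reference compounds are screened and normalized
identically to the fractions; correlating raw effect directions against
screen-max scores instead systematically underestimates similarity.

## Endpoints

* `percent_of_control = OD_treated / OD_control x 100` is implemented
  exactly as printed in screening practice; because that quantity is the
  *surviving* percentage, the companion `cell_loss_pct = 100 - percent_of_control`
  is provided under an unambiguous name. The OD proxy in table mode is the
  well's integrated nuclear DNA stain.
* DNA scale calibration: the 2N anchor is the mode of a Gaussian-KDE over
  control DNA contents (1024-point grid to the 99.5th percentile); with
  multiple major modes (>= 50% of the peak density) the lowest is used, as
  G0/G1 dominates untreated populations. Scale = anchor / 2.
* Phase windows with tolerance tau = 0.5N (config): low < 2 - tau,
  G0/G1 = [2 - tau, 2 + tau], S = (2 + tau, 4 - tau), G2/M = [4 - tau, 4 + tau],
  high > 4 + tau. The five intervals partition [0, inf) for any tau in (0, 1);
  window edges are inclusive toward the peaks.
* Fold changes are well-mean ratios against in-plate controls.
* Tests are classical pooled-variance Student's t (two-tailed, alpha 0.05
  default) because that is the named test in the screening literature this
  models; Welch's form is available as `welch_t`. Degenerate zero-variance
  groups: equal means give (t, p) = (0, 1), unequal means raise. No
  multiple-testing correction is applied by default (per-comparison p values
  with star tiers * <= 0.05, ** <= 0.01, *** <= 0.001, **** <= 0.0001);
  Benjamini-Hochberg can be layered on the output table if desired.

## Problem sizes in tests and scripts

Unit and property tests run on screens of 1-2 plants x 3-6 fractions with
40-150 cells per well, sized so replicate averages are stable while the
whole suite stays fast. The screen-level summary script simulates the full
default design (84 samples, 7 doses, 4 replicates, 4 panels) at five seeds
with 120 imaged cells per well and a proportionally scaled valid-object
threshold (30); the score bound it reports is a property of the
normalization and does not depend on the per-well cell count. Large-sample
checks (phase-fraction recovery, type-I error rate) use 50,000 cells and
2,000 simulated tests respectively.

## Known limitations

* The simulator plants class phenotypes as clean mean shifts with
  independent lognormal noise; real fractions are mixtures of compounds,
  and real feature noise is correlated across markers. Passing recovery
  tests therefore demonstrates correctness of the pipeline's inference, not
  expected field performance on real extracts.
* No plate-position (row/column drift) normalization, B-scores, or
  illumination correction; the generator does not produce such artifacts.
* Texture and shape features beyond area are not implemented; the feature
  panel is an editable table, so they can be added without touching the
  scoring code.
* No IC50 / 4-parameter-logistic fitting: endpoints are per-dose
  comparisons, matching how such screens are usually reported.
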