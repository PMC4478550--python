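# Methods

This note records the models, parameter choices, and numerical
conventions behind `ensloc`, and what the synthetic phantoms do and do
not establish about real data.

## Phantom model

The generator emulates spinning-disc confocal fields of log-phase budding
yeast expressing a cytoplasmic red marker and one GFP-tagged protein.

**Geometry.** Mother cells are ellipses with full axes 18–30 px (typical
yeast pixel scale at high-content magnification); buds are ellipses
covering 25–75% of the mother area, attached with deep overlap so the
mother–bud pair segments as one object with a wide neck. Cycle stage is
defined from the bud/mother area ratio: < 0.4 is small-budded, otherwise
large/medium-budded. The nucleus is a disc of 0.32 of the minor semi-axis,
offset toward the bud neck in budded cells (mitotic geometry); the vacuole
is a disc of 0.55 of the minor semi-axis on the opposite side, so the
vacuolar rim stays clear of the neck. Both choices matter for classifier
separability: before the vacuole was enlarged and given its faint lumen
haze, the nuclear-envelope ring and the vacuolar rim were nearly the same
size and were confused by every ring-sensitive classifier.

**Patterns.** Each of the 16 localization classes renders a unit-amplitude
density confined to its defining region (interior minus nucleus, nuclear
disc, perinuclear crescent, rings, puncta with class-specific count and
size priors, branched threads, neck band, cortical dot, 1–2 bright dots),
multiplied by the cell's expression level and blurred by a fixed 0.6 px
point-spread sigma. Pattern parameters live in one table
(`phantom.PATTERN_PARAMS`) so classes can be made deliberately confusable
(e.g. endosome vs Golgi puncta sizes) for stress tests. Per-cell
expression is log-normal (mean 100 intensity units, CV 0.3) on a 0–4095
range.

**Artifacts and noise.** Dead cells are small, speckled, bright red blobs
with no coherent green signal; ghosts are dim smooth red blobs containing
no cell. The camera model is Poisson shot noise plus additive Gaussian
read noise (sd 2). Cells are placed by rejection sampling with no mask
overlap; an unplaceable specification fails with diagnostics rather than
degrading silently.

**What phantoms do not show.** No z-dimension, photobleaching, uneven
illumination, optical crowding, or biological heterogeneity beyond the
expression distribution; patterns are canonical stand-ins, not
reconstructions of real training cells. Passing tests demonstrate that
the pipeline's machinery is correct and well calibrated under its own
generative model, not that the specific accuracy numbers transfer to real
micrographs.

## Segmentation

Otsu threshold on a Gaussian-smoothed (sigma 2) red image, hole filling,
area filter (min 100 px), then a distance-transform watershed seeded at
h-maxima (h = 3 px). Seed markers whose centroids lie within 12 px are
merged: h-maxima marks peak pixels only, so a flat ridge inside one cell
can emit several splinter markers, while genuinely touching cells have
seeds a cell diameter apart. Border-clipped objects are kept — artifact
removal is the quality-control classifiers' job, not the segmenter's.
Object ids are assigned in raster order of centroid; coordinates are
(x, y) = (column, row), 0-based.

## Feature vector

The registry fixes 430 features in stable order; its SHA-256 hash travels
with every vector and model, and mismatched hashes are rejected. The
composition is area-shape 46, Zernike 49 (orders 0–12, GFP), intensity 60
per channel x 2, Haralick texture 13 statistics x 4 offsets x 2 distances
x 2 channels = 208, and location 7.

Conventions worth noting:

* Zernike moments are computed on the masked GFP crop mapped to the unit
  disc about the mask centroid and normalized by total mass — magnitudes
  are rotation- and contrast-invariant.
* Texture uses a masked co-occurrence matrix (only pixel pairs with both
  ends inside the mask), quantized to 16 levels over the cell's own
  intensity range, hence scale-invariant.
* Radial intensity-distribution features are taken about the signal's
  intensity-weighted centroid, not the mask centroid, so a ring's radius
  is measured about the structure itself wherever it sits in the cell.
* Every entry declares its homogeneity degree under uniform intensity
  scaling (0 or 1), which is enforced by test.
* Degenerate masks (< 9 px) yield a zero vector flagged unextractable;
  non-finite values are mapped to 0.

Position features (centroid, distance to border) are intentionally part
of the vector, so whole-vector translation invariance holds only outside
the location family.

## Classifier training

Each binary classifier is a 25-bag bootstrap ensemble; each bag draws 500
positives and 500 negatives with replacement, ranks features by a
chi-square test of independence on 4 equal-frequency bins (values equal
to a bin edge fall in the lower bin; zero-expected cells are dropped from
the sum; ties in the ranking break toward the lower index), keeps the top
50, z-scores them, and fits a linear SVM (C = 1) solved as the exact dual
QP. The ensemble's call is a strict plurality (>= 13 of 25; for a
user-set even bag count the threshold is floor(n/2)+1, so ties are
negative — conservative calls reduce spurious multi-localization).
Selection runs per bag, making each bag a complete learner; global
selection is available as an option. All randomness flows from one master
seed via per-bag counter seeds recorded in the model file.

Cross-validation is stratified 10-fold with the entire pipeline
(selection + bagging) retrained inside every fold; recall and precision
are pooled over held-out folds, and undefined ratios are reported as
absent rather than zero.

## Ensemble graph

The default configuration ships as a human-editable TSV of 60 nodes:
2 quality-control, 3 cell-cycle, and 55 localization nodes in 20
subgroups. Execution is level-ordered: DEAD then GHOST (a positive call
short-circuits), then cycle staging ("budded" means positive in either
budded classifier; when several stage classifiers fire, the larger
morphology wins; all-negative is "undetermined"), then the gated
subgroups. Within a subgroup, membership is the conjunction of the
primary and discriminator nodes; classes with cycle-specific variants
(cortical patches, cell periphery, spindle pole) take the disjunction
over the variants applicable to the stage; undetermined cells pass only
through ungated subgroups. Refinement nodes (cytoplasm-not-nuclear,
nuclei-not-cytoplasm, vacuole-vs-membrane) annotate positive cells and
never veto membership. The 16-element membership vector is independent
booleans: several classes, or none, may be true.

**Phantom training of the graph.** Every node gets positives rendered
from its own class recipe (with stage and pattern-parameter constraints
for variant nodes) and negatives per its role: discriminators train
against their named confuser class; primaries train against a mix of all
other classes refined by one round of hard-negative mining — a
provisional 7-bag classifier is scored against each negative class's
pool and the final negative set re-weights classes by their leak-through
rate. This mirrors per-classifier curation of negative sets and is what
keeps between-class false-positive rates at the sub-percent level the
relocalization analysis needs; with naive balanced negatives,
ring-like classes retained 3–20% mutual false positives.

## Scoring

LOC-scores divide per-class cell counts by the number of *classifiable*
cells (assigned to at least one class); dead/ghost cells are excluded
first. Profiles from fewer than 20 classifiable cells are flagged
low-confidence (configurable). `I_g` is the arithmetic mean over cells of
integrated GFP divided by segmented area; `dPL` is the ratio of `I_g`
between condition and control, undefined (and flagged) for a zero
control.

The z-LOC statistic is the pooled two-proportion z; a pooled proportion
of exactly 0 or 1 carries no evidence of difference and yields z = 0.

The mixture model is w·Uniform(lo, hi) + (1−w)·Normal(mu, sigma) with
(lo, hi) fixed at the data range. EM initialization is deterministic: mu
and sigma from the interquartile-trimmed sample (sd corrected by the
trimmed-normal factor 0.4857), w = 0.05. Convergence is a relative
log-likelihood change below 1e-8; the log-likelihood trajectory is stored
and is non-decreasing by construction. Cutoffs solve
(1−w)·N(z; mu, sigma) = w/(hi−lo), the posterior-0.5 crossing on each
side of mu; when the outlier density dominates everywhere the cutoffs
collapse to mu. Fewer than 50 values, or an all-identical sample, is
rejected. One mixture is fitted per screen comparison. Note that uniform
outliers drawn near the background mean are inherently undetectable, so
flagging performance is meaningful only for outliers beyond the
background's ~2-sigma band.

## Problem sizes

The acceptance computations use 200 cells per class for the eight-class
cross-validation, 150 crops per pool for training the full 60-node graph,
7 fields of 75 cells per screen (~500 classifiable cells per arm) for the
relocalization comparison, 10 fields of 64 cells per arm (~640 cells) for
the fold-change recovery — a power choice: with per-cell expression CV
0.3, the dPL estimator's sampling CV at that size is ~1.7%, small against
the 5% recovery check — 10^4 replicates for the type-I-error and mixture
simulations, and 10^3–10^4 random instances per oracle check. Sizes are
chosen so the whole stack exercises end to end on a single CPU at desk
scale.

## Known limitations

* The 430-feature composition is this package's own registry; the
  original instrument pipeline's exact feature list is not recoverable,
  so numeric feature values are not comparable across implementations.
* Phantom-trained classifiers are only as hard as the phantom patterns;
  the deliberately confusable parameterizations are available for stress
  testing but are not the defaults.
* No illumination correction or batch normalization is applied; intensity
  features are raw.
* The budsite pattern (a single cortical dot) is nearly indistinguishable
  from the one-dot spindle-pole pattern by design of the vocabulary;
  their mutual confusion is visible in full-graph evaluations and is a
  property of the pattern definitions, not the ensemble machinery.
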