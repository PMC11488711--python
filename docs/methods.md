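# Methods

`numobat` implements a numeric morphology-based alpha-taxonomy (NUMOBAT)
workflow for delimiting and identifying species of the *Temnothorax
corsicus* group — Palearctic ants that parasitize the colonies of other
*Temnothorax* species. The workflow has an exploratory arm (clustering
of nest samples, size-corrected ordination), a confirmatory arm
(cross-validated discriminant analysis), and an identification arm (the
published discriminant functions and dichotomous keys). A hierarchical
synthetic-data generator, parameterized by the published per-species
summary tables, makes every stage testable without the original
specimen-level measurement file.

## Data model and units

A trait table holds one row per specimen: specimen id, nest-sample id,
caste (worker or gyne), optional species label, and continuous linear
measurements in μm (CL, CW, CWb, ELmax, ELmin, FRS, ML, MW, PEH, PEW,
PHL, PnHL, POC, PPH, PPW, SL, SPBA, SPH, SPML, SPST, SPTI, SPWI).
Micrometres are canonical everywhere: the published discriminant
functions only reproduce their printed score ranges with μm inputs, so
the reader converts millimetre files (×1000) on ingestion and the
scorers refuse inputs whose magnitudes look like millimetres. Unit
auto-detection uses the median cephalic length: values in [0.3, 3] are
read as mm, values in [300, 3000] as μm, anything else is an error
rather than a guess.

Derived conventions: CS (cephalic size) is the arithmetic mean of CL
and CWb; FR in the published functions is read as FRS (the only
frontal-carina distance defined); EYE is the mean of ELmax and ELmin.
EYE and the PLST summary row have no formal definition in the published
trait list; EYE is computed as above and PLST is carried as an opaque
extra column when present. HPL in the text is treated as PHL. Missing
values propagate; multivariate operations take complete cases for the
traits they use and report exclusion counts.

Ratio summaries divide each trait by CS per individual (CL/CWb, POC/CL
and SL/CL by their own denominators), using the sample (n−1) SD. The
published table caption says "divided by cephalic size (CWb)" while the
row labels say "/CS"; the row labels and the formal CS definition win,
and the caption reading is noted here as unresolved in the source.

## Exploratory arm: nest-centroid clustering with recursive thresholding

Nest samples, not individuals, are the clustering unit: averaging the
individuals of a colony suppresses within-colony measurement and
developmental noise. The display dendrogram is UPGMA (average linkage)
on Euclidean distances of z-standardized nest centroids, exported as
Newick; its cophenetic matrix is ultrametric by construction, which the
tests verify.

The number of clusters is estimated by recursive thresholding (PART,
protocol defaults b = 1000 bootstrap references and minimum cluster
size 5): at each node the gap statistic compares the log pooled
within-cluster dispersion of the node's rows against B reference
datasets drawn uniformly over the PCA-aligned bounding box (the
rotation-respecting reference variant). k = 1 terminates the node;
k > 1 splits it by the engine — a Ward-linkage tree cut or k-means
(best inertia over 25 seeded restarts) — and recurses. Terminal groups
below the minimum size become outliers (label 0), mirroring the
published observation that a three-nest species cannot be recognized
when the minimum recognizable cluster is five. A partition is accepted
as a prior species hypothesis only when both engines reach the same
conclusion; strict mode demands identical partitions up to label
permutation over jointly non-outlier samples, relaxed mode demands
equal k and adjusted Rand index at or above a threshold (default 0.95).

Numerical choices that matter:

* **Gap decision rule.** The original one-standard-error rule (smallest
  k with gap(k) ≥ gap(k+1) − s(k+1)) is implemented (`criterion=
  "firstSE"`), but the default is `"globalSEmax"`: the smallest k whose
  gap reaches the global maximum minus one standard error. With several
  adjacent clusters the gap curve dips at k = 2 before climbing to its
  real peak, and the first-SE rule then stops at k = 1 — a documented
  underestimation mode. Both rules pass the canonical sanity cases (two
  well-separated clusters → k = 2; one Gaussian cloud → k = 1;
  degenerate data → k = 1); only globalSEmax also recovers the
  six-species structure the recursive procedure is used for here.
* **Symmetric treatment in the gap.** The observed data and every
  reference dataset are clustered by the same batched Lloyd procedure
  (identical restart count); an asymmetry (stronger optimization on the
  data side) biases the gap toward oversplitting.
* **Split engine linkage.** Inside the recursion the hierarchical
  engine cuts a Ward tree, not an average-linkage tree: average linkage
  chains and sheds singletons on touching clusters of equal size,
  which cost both k accuracy and assignment accuracy in the recovery
  benchmark. The UPGMA dendrogram remains the display and cophenetic
  reference.
* **Boundary consolidation.** Recursive splitting fixes each sample at
  the level where its branch separated, stranding boundary samples.
  After recursion, the partition is polished at fixed k: several
  candidate assignments (the recursion labels, a fresh engine cut, and
  a few seeded k-means starts) are each iterated to a fixed point of
  nearest-Gaussian reassignment — per-cluster diagonal variances shrunk
  halfway toward the pooled within-cluster variance, so a diffuse
  cluster keeps its tails against a tight neighbour — and the best
  partition under that same Gaussian score wins. k and outlier labels
  never change during consolidation.
* **Determinism.** Every stochastic step draws from an explicit seed;
  pipeline stages derive independent substreams from one top-level seed.
  UPGMA merge ties follow scipy's deterministic ordering, so dendrograms
  are reproducible for a fixed input.

For delimitation the clustering operates on nest means of shape ratios
(trait/CS and the named length ratios) rather than raw μm traits:
dividing by cephalic size removes the shared body-size axis exactly,
which otherwise dominates the standardized Euclidean geometry and masks
the shape differences that separate species. Clustering raw centroids
(the unstandardized and standardized modes) remains available.
Allometric residual correction — OLS of every trait on CL, pooled
across rows, residuals kept, orthogonality |r| < 1e-8 enforced by test
— is the analogous size correction for the PCA ordination arm, which
also projects held-out specimens (type material) into a reference
morphospace and flags peripheral positions by Mahalanobis distance in
score space.

## Confirmatory arm: LOOCV-LDA

Linear discriminant analysis with equal class priors (a taxonomic
convention: species hypotheses are equiprobable; proportional priors
are a config switch) and a pooled within-class covariance with n − g
denominator. Prediction is the class minimizing pooled Mahalanobis
distance, verified in tests against both a brute-force oracle and an
independent reference implementation. Leave-one-out cross-validation
refits the covariance in every fold (no downdating shortcuts); the
confusion matrix carries the overall accuracy with a Clopper–Pearson
exact binomial 95% interval. Entering the published gyne confusion
table reproduces its printed accuracy (369/380 = 0.971 → 0.97) and CI
(0.95, 0.99). The published worker table gives 335/349 = 0.960 by the
same arithmetic, not the 0.97 stated alongside it; the package reports
the computed value and leaves the discrepancy to the source.

Two-group discriminant functions are built in the published style: the
Fisher axis w ∝ S⁻¹(μ₁ − μ₂) scaled to unit pooled within-group score
SD, intercept placed so the group score means are exactly +d and −d
(the printed functions show the same symmetry: ±1.699, ±1.882, ±1.673).
Classification is by score sign. Because the trait subsets behind the
published functions are not explained in the source, a greedy forward
selection maximizing LOOCV sign success is provided as an explicit
stand-in, with a deterministic trait-name tie-break and a logged
trajectory.

## Identification arm

The three published discriminant functions are shipped verbatim — D5a
(gynes, *T. adlerzi* vs *T. ravouxi*), D3 (gynes, *T. algerianus* vs
*T. ravouxi*), D5b (workers, *T. algerianus* vs *T. ravouxi*) — with
their printed group means, score ranges and sample sizes as metadata;
they are never re-fit. Scores outside the printed group range are
annotated, not rejected.

The dichotomous keys are encoded couplet by couplet for both castes.
Threshold couplets are strict (>140 μm gyne petiole hair, >125 μm
worker); exact equality routes to the "else" branch with a borderline
warning, since the printed couplets use strict inequalities in both
directions. Geographic couplets take coarse region tokens supplied by
the user — geography is a heuristic and silent geocoding would
overstate confidence. A missing character explores both branches and
the result lists every reachable species; the *adlerzi*/*ravouxi* and
*algerianus*/*ravouxi* leaves invoke the matching discriminant function
when the traits allow. Published petiole-hair envelopes (e.g. kraussei
workers [125, 147] μm, algerianus workers [85, 130] μm, ravouxi workers
[88, 124] μm) annotate calls whose hair length falls outside them.

## Synthetic data generator

Each species is an envelope: CS mean ± SD (μm) plus ratio mean ± SD for
every summary row, transcribed from the published worker (6
multi-sample species + one singleton) and gyne (9 species) tables into
reviewed CSV fixtures. Generation draws, per nest, a nest effect per
ratio ~ N(0, (τ·SD)²); per individual, CS ~ N(CS_mean, CS_SD) and
ratio = mean + nest effect + N(0, (σ·SD)²), with τ² + σ² = 1 so the
marginal ratio SD matches the printed value. Default τ = 0.5 — the real
nest-level variance fraction is not derivable from the published
summaries, so it is an explicit, exposed parameter. Traits are
ratio × denominator (CL and CWb from CS and the CL/CWb ratio; POC and
SL on CL; the rest on CS), which induces size-driven trait correlation
without inventing trait-trait covariances the tables do not publish.
Negative draws are resampled, not truncated, keeping means unbiased.
Two conventions fill gaps the tables leave: the EYE row splits into
ELmax/ELmin with an individually jittered ellipticity (±15% ± 2%), and
CW sits above CWb by a jittered fraction of the eye bulge — the jitter
exists because exactly collinear traits would make covariances singular
in a way no measured dataset shows. Defaults are 10 nests × 3
individuals per multi-sample species.

What the generator does **not** emulate: trait-trait shape covariance
within species beyond the shared size factor, geographic or clinal
structure within species, measurement error correlated across traits of
one specimen, asymmetric or heavy-tailed trait distributions, and any
qualitative character other than optional petiole-hair lengths drawn
uniformly from the published envelopes. Recovery results on synthetic
data therefore demonstrate internal consistency of the pipeline under
the published first- and second-moment structure, not performance on
real measurement data.

## Benchmarks, problem sizes and known limitations

The package's benchmark experiments (also run by the acceptance script)
use B = 100 gap references per node and 50 seeds for the worker
recovery study, and a single draw (9 species × 10 nests × 3
individuals) for the gyne LOOCV study — sizes chosen so the full suite
runs comfortably on one CPU while keeping the Monte-Carlo error of a
50-seed fraction near ±0.07.

On gyne-preset data, LOOCV-LDA accuracy is ≈ 0.99. Refitting the
published trait combinations on synthetic look-alike pairs reproduces
the printed structure closely (group means ±1.65 / ±1.87 / ±1.75
against printed ±1.699 / ±1.882 / ±1.673; sign success 94–96% against
printed 94.5 / 97.3 / 96.3%).

In the worker recovery benchmark both engines find k = 6 with ARI ≥
0.95 against the generating labels in about nine draws out of ten. The
residual failures share one cause: the *bernardi* envelope (published
from only ten individuals) is diffuse, and its nests border *ravouxi*
in shape space. With true generator parameters a Bayes classifier
assigns essentially every nest correctly, so the information is
present; but an unsupervised procedure must estimate the metric, and on
some draws both the gap curve at the merged node and the estimated
Gaussian likelihood genuinely prefer a configuration that splits
*bernardi* or merges part of it into *ravouxi*. In those draws no
amount of restarts recovers the generating labels — a small-sample
identifiability limit of the envelope itself, visible in the per-seed
benchmark records rather than hidden by them.

Other limitations: the exact internals of the original recursive
partitioning implementation are specified only by citation in the
source; this package follows the published description of the method
(gap statistic, recursion, minimum cluster size, two engines) and
documents its own choices above where the description is silent. No
likelihood-based or molecular delimitation is attempted; the keys cover
the ten *corsicus*-group species only, with no male-based couplets.
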