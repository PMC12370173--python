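# Methods

## Study design and data model

The pipeline analyzes wide marker tables: one row per (cell line,
microenvironment, replicate), 16 marker columns, with metadata
identifying one of 12 microenvironments.  The condition grid crosses
four alginate/gelatin hydrogel classes — So-L (1.8 kPa), So-H
(2.4 kPa), St-L (6.1 kPa), St-H (10.1 kPa) — with three culture modes
per gel: pH 7.4 static, pH 6.5 static, pH 7.4 dynamic (perfused).
Acidic *and* perfused never co-occur; that cell of the factorial is not
part of the design.  Environments are encoded numerically as (Young's
modulus kPa, gelatin % w/v, alginate % w/v, pH, perfusion 0/1).  Note
alginate content is collinear with stiffness in this grid (soft gels
1.5 %, stiff gels 3 %), so marker-alginate and marker-stiffness
correlations are not separable; both are still reported.

Proliferation readings are normalized per record by the day-1
intensity, which makes the day-1 column identically 1.  The column is
kept so the schema stays the printed 16-marker panel; downstream it is
harmless by construction (z-scoring maps constant columns to zeros,
the MI of a constant feature is 0, and its correlations are reported
as an explicit undefined sentinel rather than 0 — "no variation" is
not "no relation").

Missing marker values reject the row (with a logged diagnostic) rather
than being imputed: the sample sizes are small enough that silent
imputation would visibly distort MI estimates, and no imputation rule
is part of the method.

## Synthetic data generator

The generator is the package's study stand-in: it emulates the
*structure* the analysis assumes, not any real dataset's numbers.

Latent model, per (cell line, environment, marker, replicate):

    latent = env_response(marker, env)
           + direction(marker) * effect(tier(marker), env) * [invasive]
           + Normal(0, noise_sd)

* **Tiers and effects** (standardized latent separation between cell
  lines): high = 4.0 in every environment (Vimentin MFI/%, CD44 MFI,
  CD44+%, CD44v6 MFI/%); moderate = 2.5, active only in stress
  environments, i.e. pH 6.5 or dynamic perfusion (CD24 MFI/%,
  CD44+/CD24-%, E-cadherin MFI/%); low = 0 (proliferation, ALDH+%).
  `noise_sd` defaults to 1.0 per marker; 3 replicates per cell
  (the usual triplicate-experiment convention).
* **Direction**: effects are applied with sign -1 for CD24 and
  E-cadherin (epithelial markers depressed in invasive cells), +1
  elsewhere.  Sign is irrelevant to clustering and MI; it only makes
  the tables read biologically.
* **Environment response** (shared by both lines): stress environments
  shift proliferation day 4/7/14 by -3 and ALDH+% and CD44+/CD24-% by
  +3 latent SD — a single stress-response axis (growth down, stress
  markers up) that plants exactly two environment regimes within each
  cell line (8 stress vs 4 baseline environments).  A single axis is
  deliberate: separate acidic and perfusion responses would plant
  three regimes and change the intended two-behavior geometry.
* **Links**: percent markers are 100·logistic(0.5·latent) and
  MFI/proliferation markers are scale·exp(0.25·latent).  The
  steepnesses are a realism choice: with unit latent noise they give
  replicate-level MFI coefficients of variation near 25 % and
  percent-positive replicate SDs of roughly 5-12 points, which is what
  isotype-normalized medians and gated fractions actually look like.
  (A steepness of 1.0 would give MFI CVs above 100 % and heavy
  within-class tails that no replicate-level flow summary shows.)
  Links are monotone, so the kNN MI of a marker is governed by the
  latent separation, not the link.
* **Seeding**: each record's stream derives from (master seed, cell
  line index, env id, replicate), so raising `replicates` extends a
  table without reshuffling existing rows.

What the generator does *not* emulate: raw fluorescence distributions,
gating, between-experiment batch effects, marker-marker correlations
beyond those induced by the shared regime structure, or any real
study's numeric values.  Passing tests therefore demonstrate that the
pipeline recovers planted structure under realistic noise at this
design's sample sizes — not that it would recover any particular
laboratory dataset's structure.

`planted_truth` reports, per condition level, the markers whose
planted effect is positive in *every* environment of that level — the
uniformly recoverable set.  (At the pH 7.4 level, which includes
dynamic environments, the moderate tier is active in only a third of
the subset and is deliberately not listed.)

## Clustering

k-means is implemented from its defining recursion (nearest-centroid
assignment with ties to the lowest cluster index; mean update;
convergence = unchanged assignments; `max_iter` 300 as a safety bound).
Initialization is a distance-weighted (++-style) draw from the data
points, 20 restarts by default, best SSE wins.  An emptied cluster is
re-seeded at the point farthest from its centroid.  After each
restart's convergence an exact single-point (Hartigan-style)
refinement runs: moving x from cluster a to b changes the SSE by
n_b/(n_b+1)·||x-mu_b||² - n_a/(n_a-1)·||x-mu_a||², which can be
negative even for Lloyd-stable configurations; refinement alternates
with Lloyd re-descent until neither changes anything.  This closes the
small but real gap between restarted Lloyd and the global optimum on
small instances (verified against an exhaustive-bipartition oracle);
the returned result is still a fixed point of the assignment/update
recursion.  SSE is asserted non-increasing at every iteration.

Columns are z-scored (using the rows being clustered) before any
distance computation: MFI and percent markers differ by orders of
magnitude and raw Euclidean distance would be dominated by MFI scale.
Raw-scale clustering remains available by passing an unstandardized
matrix.

The silhouette uses the standard per-sample score with the singleton
convention s = 0.  The headline number is the global mean over all
samples; per-cluster means are also reported for users who want the
per-cluster normalization instead.

**Cluster-count selection (least-drop rule)**: evaluate k = 2..6 and
return the smallest k whose global silhouette is within epsilon = 0.01
of the maximum.  Epsilon is configurable; 0.01 treats scores differing
in the third decimal as "comparable".  If even the best silhouette is
below 0.25 the selection is flagged low-confidence: on a flat profile
the minimal-k preference, not data structure, is what chose k.

**Backward elimination**: greedy removal of the single feature whose
removal most increases the silhouette, stopping when no removal
increases it.  Ties prefer the earliest feature index.  Users should
know silhouette mildly favors lower dimensionality (intra-cluster
distances grow faster than separation as redundant axes accumulate),
so elimination tends to prune aggressively; for duplicated features
the score is exactly scale-invariant and elimination stops
immediately.

## Mutual information and retention

MI between a marker and the binary phenotype label is reported in
nats.  Default estimator: the k-nearest-neighbour estimator for a
continuous feature against a discrete label (3 neighbours, seeded
tie-breaking jitter), via scikit-learn; robust at N of a few dozen and
invariant under monotone transforms.  An equal-frequency binned
plug-in estimator (4 bins) is kept as an independent cross-check;
estimates are clipped at 0.

The retention threshold tau = 0.65 is compared strictly (score > tau).
In nats this sits just below the ln 2 ≈ 0.693 ceiling for balanced
binary labels, so retention means "nearly perfectly discriminative at
this sample size".  Two consequences worth knowing: a marker with a
4-SD latent separation has a true MI of ≈ 0.633 nats — *below* tau —
and is retained only because the kNN estimator's small-sample
distribution at N = 18–48 scatters around that value, crossing tau
roughly 60–75 % of the time.  Retention of any individual marker near
the threshold is therefore noisy by design; what is stable is that
several high-tier markers clear tau at every level while moderate and
low tiers rarely or never do, and that the *post-reduction clustering*
on the union of retained markers separates the phenotypes essentially
without error (misassignment probability scales like
Phi(-2·sqrt(#retained))).  An empty retained set is a reportable
outcome (flagged profile), not an error.

## Profiling pipeline

Per condition level the feature matrix contains the 16 markers only —
residual environment variation inside the subset is deliberately not
given to the clusterer, so the separation must come from the markers.
Cluster-to-label alignment evaluates both mappings of two clusters
onto the two classes and keeps the accuracy-maximizing one (ties
prefer identity), guaranteeing aligned accuracy >= 0.5; confusion
matrices are reported with invasive as the positive class.
Aggregation across levels sums MI scores (exactly-rounded summation,
so profile order cannot change the result); the mean score and the
retained-level count are reported alongside so a different aggregation
convention can be reconstructed from the same table.  Stage and level
seeds derive from the master seed by a CRC-32 of (seed, stage, level),
keeping every derived seed below 2^31 and independent of stage
ordering.

## Problem sizes

Defaults everywhere reflect the 2 x 12 x 3 = 72-record design.
Stochastic claims in the test suite are checked over 15–100 generator
seeds depending on the per-seed cost of the stage under test; the
acceptance script uses 50 seeds for the cluster-count mode and 15 for
the zero-error profiling mode.

## Known limitations

* Retention is threshold-based with a fixed manual tau; no automated
  threshold selection is attempted.
* The MI estimator choice (kNN, nats) is a convention; thresholds in
  bits, or plug-in estimators, would shift retained-set sizes.
* Hydrogel identity and the two composition axes overlap as
  stratification variables; levels are profiled independently and no
  multiplicity correction across levels is applied.
* The correlation stage reports coefficients only (no significance
  testing), matching its role as an exploratory map.
* No PCA/UMAP embedding and no supervised classifier: the design
  philosophy is unsupervised clustering audited post hoc against
  labels, keeping every reported quantity attributable to named
  markers.
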