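# mpsprofiler

Unsupervised profiling of breast-cancer invasiveness from
microphysiological-system (MPS) marker panels.

## The problem

Engineered breast MPS models culture tumor cells under controlled
microenvironment conditions — hydrogel stiffness and composition,
extracellular pH, interstitial perfusion — and read out a panel of
phenotype markers per condition.  With 12 microenvironments, two cell
lines spanning the invasive-potential spectrum (highly invasive
MDA-MB-231-like vs non-invasive MCF-7-like) and 16 marker readouts
(proliferation time course; CD44/CD24/CD44v6/ALDH cancer-stem-cell
markers; Vimentin/E-cadherin EMT markers, as MFI or percent-positive),
the resulting tables are too high-dimensional to audit by eye but far
too small for deep models.  `mpsprofiler` implements a transparent,
fully seeded pipeline for this regime, aimed at bioengineers designing
MPS experiments who want to know *which* markers and *which* culture
conditions actually discriminate invasive from non-invasive phenotypes
— plus a synthetic-data generator so the whole pipeline runs and is
tested without access to any lab data.

## The method

For records $x_i \in \mathbb{R}^{16}$ with binary phenotype labels:

1. **Correlation maps.** Per cell line, sample Pearson coefficients
   $\rho_{j,h}$ between every marker pair and between each marker and
   each numeric environment feature (stiffness kPa, gelatin %,
   alginate %, pH, perfusion 0/1).
2. **Intraphenotype behavior count.** Within one cell line, k-means
   (Lloyd recursion: nearest-centroid assignment, mean update, stop
   when assignments repeat; 20 seeded restarts plus an exact
   single-point refinement) on z-scored markers for $k = 2..6$; the
   silhouette index $s_i = (b_i - a_i)/\max(a_i, b_i)$ (singletons
   score 0; global score = mean over samples) guides the *least-drop*
   rule: pick the smallest $k$ whose silhouette is within
   $\varepsilon = 0.01$ of the best.
3. **Condition-stratified profiling.** Fixing one condition level at a
   time (pH 7.4/6.5, static/dynamic, four hydrogels, gelatin and
   alginate content — 12 levels), pool both cell lines, cluster at
   $K = 2$, and align clusters to labels by accuracy (confusion
   matrix, invasive = positive).  Rank markers by mutual information
   with the true label (k-nearest-neighbour estimator, nats), retain
   those with $I > \tau = 0.65$ — just below the $\ln 2 \approx 0.693$
   ceiling for balanced binary labels, i.e. near-perfect
   discriminators — then re-cluster on the retained panel and
   re-evaluate.
4. **Aggregation.** Sum each marker's MI score over all 12 levels into
   a combined importance ranking.

The synthetic generator plants a three-tier effect structure on a
latent Gaussian scale (high tier: Vimentin/CD44-family, separated in
every environment; moderate tier: CD24-type/E-cadherin, separated only
under acidic or perfused stress conditions; low tier:
proliferation/ALDH, no phenotype effect) plus a shared two-regime
environment response, then maps to observation scales through
exponential (MFI) and logistic (percent) links.

## Worked example

```
$ mps-profile simulate --seed 1 --out data
wrote 72 records to data/markers.csv

$ mps-profile profile --input data/markers.csv --seed 1 --out run
report -> run/report.json
top aggregated markers: CD44+%, CD44v6 MFI, Vimentin MFI
```

`run/aggregate_importance.csv` then begins

```
marker,combined_score,mean_score,times_retained
CD44+%,8.463791394642055,0.7053159495535045,12
CD44v6 MFI,8.42711260275493,0.7022593835629108,11
Vimentin MFI,8.417940023790683,0.7014950019825569,11
```

meaning CD44+% accumulated 8.46 nats of mutual information with the
phenotype label across the 12 condition levels and cleared the 0.65-nat
retention threshold in all of them — the CD44-family and mesenchymal
markers dominate, while the proliferation time points and ALDH+% end
the ranking near zero.  In the same run every one of the 12
post-reduction confusion matrices has zero false positives and zero
false negatives, and the within-line cluster-count selection picks
$k^* = 2$ behaviors for both cell lines, separating stress (pH 6.5 or
dynamic) from baseline environments.

The numbered scripts under `analysis/` run the same stages as a
narrative (simulate, correlate, count behaviors, profile conditions,
aggregate) and write tables under `results/`.

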