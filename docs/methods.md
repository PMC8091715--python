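# Methods

`ecoassembly` infers how microbial communities are assembled — how much of
the variation among samples is due to deterministic niche processes
(selection) versus stochastic ones (dispersal and drift) — and analyses the
co-occurrence structure of the resulting communities.  Everything operates
on a rarefied OTU count table (samples × OTUs), optionally with sample
metadata (region / site / vegetation zone), a rooted phylogeny of the OTUs,
and a taxonomy table for labelling.

## Rarefaction and the descriptive layer

Rarefaction draws, for each sample independently, a multivariate
hypergeometric subsample (without replacement) to a common depth, so every
sample contributes the same number of reads to downstream statistics.  A
single fixed-seed draw is used rather than an average over draws: averaging
produces non-integer tables that break occupancy and the null models, and
with the depths involved the between-draw variance of every statistic we
compute is negligible.  All-zero OTU columns are dropped by default (they
cannot influence any downstream quantity); a flag retains them.

Richness and the Shannon–Wiener index use natural logarithms (the common
ecology default; a switch provides log2).  OTUs are classified into six
abundance categories from their per-sample relative abundances, with "rare"
strictly below 0.1% and "abundant" inclusive at 1%: always abundant (AAT),
always rare (ART), moderate (MT), conditionally rare (CRT), conditionally
abundant (CAT), and conditionally rare-and-abundant (CRAT).  The six
classes partition the OTUs by construction.

Sampling completeness is estimated by fitting a truncated Preston
log-normal to the species-abundance distribution in doubling (log2
abundance) octaves, with boundary abundances (exact powers of two) split
half-and-half between adjacent octaves — the convention matched against the
standard community-ecology octave builder.  Two approximations are exposed:
a Poisson GLM with log link and a quadratic in the octave index (exactly
the Gaussian octave curve ``S(R) = S0·exp(−(R−R0)²/2σ²)``), and a maximum-
likelihood fit of a left-truncated normal to the individual log2
abundances.  In both, octaves left of the veil line (below the smallest
observed abundance) are treated as unobservable, not as empty, which is
what lets the fitted curve extend beyond the data.  Extrapolated richness
is the Gaussian integral ``S0·σ·√(2π)`` (or observed/S-fraction-seen for the
MLE variant) and coverage is observed/extrapolated.  Group comparisons use
Tukey's HSD on untransformed values via the studentized-range distribution.

## Sloan neutral community model

The neutral model predicts an OTU's occupancy (fraction of samples where
it is detected) from its mean relative abundance ``p``:

    freq(p) = 1 − BetaCDF(d; I·p, I·(1−p))

with detection limit ``d = 1/N`` and ``N`` the per-sample read depth of the
rarefied table.  ``I`` is the dispersal number — the concentration of the
beta distribution of local relative abundances — and is the single free
parameter, fitted by bounded nonlinear least squares on a log scale with
multistart (I₀ ∈ {10, 100, 1000}) to avoid local minima.  ``R²`` is
``1 − SSE/SStot`` on occupancy; the 95% CI on the migration rate comes from
1000 bootstrap resamples of OTUs.  OTUs with ``p < d`` are excluded (the
prediction is degenerate below detection).

**Reporting scale for m.**  The classical composite writes the beta
parameters as ``N·m`` and reports ``m = I/N``.  That identification is an
approximation valid only for small m: for a Moran (one death, one
replacement) local community the exact stationary distribution is
beta-binomial with dispersal number ``I = m(N−1)/(1−m)``, so ``I/N``
overshoots badly once m is large (it passes 1 near m ≈ 0.5).  This package
therefore reports the migration rate on the per-death immigration
probability scale, ``m = I/(N−1+I)`` — the exact inversion, always in
(0, 1), and the same quantity the neutral simulator takes as ground truth —
and exposes the classical composite as ``m_sloan`` for comparability with
other software.  With this convention the simulator's m is recovered within
±0.05–0.1 across m ∈ {0.2, 0.5, 0.8} in the test suite.

Per-OTU neutrality uses a Wilson score 95% interval around the predicted
occupancy with n = number of samples; observed occupancy above/below the
band labels the OTU above/below the neutral expectation, with a 1e-9
floating-point guard at the band edges (OTUs with predicted and observed
occupancy both exactly 1 are neutral, not "above").

## βNTI / RC_Bray process partition

Phylogenetic turnover between two samples is the abundance-weighted β mean
nearest taxon distance (βMNTD): each taxon contributes its relative
abundance times the patristic distance to its closest relative in the other
sample (zero if it is present in both).  A presence/absence variant is
available by flag.  The null model is the taxa shuffle: each of the
``n_null`` (default 999; tests use 199) randomizations draws one
permutation of the OTU identities over the tree tips and recomputes βMNTD
for all pairs at once.  βNTI is the z-score of the observed value against
this null; pairs with zero null SD (e.g. identical samples) are reported
missing and excluded from the partition with a logged count.

Taxonomic turnover uses Bray–Curtis Raup–Crick: each randomization
assembles one null community per sample, preserving its observed richness
and total abundance — membership drawn without replacement with probability
proportional to occupancy across all samples, one individual per member,
and the remaining individuals distributed multinomially in proportion to
regional relative abundance.  RC rescales the rank of the observed
dissimilarity within the null distribution to [−1, 1] (ties counted half).

Pairs are partitioned as: βNTI > 2 → variable selection; βNTI < −2 →
homogeneous selection; otherwise RC > 0.95 → dispersal limitation,
RC < −0.95 → homogenizing dispersal, |RC| ≤ 0.95 → undominated (commonly
read as drift plus weak selection/dispersal and diversification).  Ties at
exactly ±2 fall to the stochastic side.  Determinism is the sum of the two
selection fractions; stochasticity the remaining three.

## Levins niche breadth

``B_j = 1/Σ_i P_ij²`` where ``P_ij`` is OTU j's proportion *of its own
total* found in sample i (OTU-margin normalisation, so Σ_i P_ij = 1).  Only
this margin bounds B by the number of communities and matches the inverse-
Simpson reading of niche width; the sample-margin alternative does not.
``Bcom`` is the plain mean of B over the taxa present in a sample, computed
per sample (zone summaries then describe the distribution of per-sample
values, which is what box-plot comparisons need).

## Co-occurrence networks

OTUs occurring in fewer than 50% of the analysis samples are removed, then
the 300 most abundant survivors are kept (ties at the cutoff broken by OTU
identifier, so filtering is deterministic).  Spearman rank correlations
(midrank ties) are computed over all retained OTU pairs, two-sided p-values
are BH/FDR-corrected over the full upper triangle of each network
separately, and an edge is kept when |ρ| > 0.6 and q < 0.01.  The sign of ρ
is stored as edge metadata; all topology metrics treat the graph as simple,
undirected and unweighted.  Constant OTU profiles (undefined correlation)
are dropped with a log entry.

Global topology: average degree 2E/N and density 2E/(N(N−1)) (exact
identities), mean local clustering (degree < 2 contributes 0), average path
length and diameter over connected node pairs only, Louvain modularity
(best of 10 seeded restarts), and a power-law fit to the degree histogram —
OLS of log10 frequency on log10 degree over non-empty bins, reporting R²,
plus the continuous maximum-likelihood exponent.  Node topology: degree,
betweenness normalized by (N−1)(N−2)/2, closeness per component as
(reachable−1)/Σdistances, and eigenvector centrality as the principal
adjacency eigenvector scaled to maximum 1.

Zi–Pi roles: Zi is the within-module degree z-score, Pi the participation
coefficient ``1 − Σ_s (k_is/k_i)²``.  Thresholds 2.5 / 0.62 define network
hubs (both high), module hubs (high Zi), connectors (high Pi) and
peripherals; hubs and connectors are flagged keystone taxa.  Modules whose
within-degrees have no spread give their members Zi = 0 (logged).

Random baselines are 1000 uniform Erdős–Rényi G(n, m) graphs with the
empirical node and edge counts, summarised as mean ± SD of clustering, path
length and modularity.  Graphs are sampled by drawing m distinct pair
indices with numpy (seeded) and metrics are computed with igraph for speed;
ensemble modularity uses igraph's multilevel detector — the same Louvain
family as the empirical detector.

Robustness is natural connectivity, ``ln((1/N)Σ exp(λ_i))`` over the
eigenvalues of the unweighted adjacency matrix, evaluated via log-sum-exp
(an edgeless graph scores exactly 0).  Curves remove growing node fractions
(default grid 0–0.8 in steps of 0.05) either uniformly at random (100
replicates, mean ± SD) or by descending degree (deterministic, ties by node
id), recomputing natural connectivity on the induced subgraph.

## Synthetic communities

The generator produces the ground truth every estimator is tested against,
at a desk scale that mirrors a typical amplicon survey: 48 samples (12 per
vegetation zone in the default metadata), a few hundred OTUs, and ~1000
individuals (reads) per sample.

* **Phylogeny and trait.**  A Yule (pure-birth) tree grown to n tips with a
  final exponential stretch, and a Brownian trait accumulated along
  branches (rate 1).  Close relatives therefore have similar traits — the
  phylogenetic conservatism that makes selection visible as phylogenetic
  turnover.  Trees are built directly on numpy so a single integer seed
  fixes topology, branch lengths and traits.
* **Metacommunity.**  Log-normal relative abundances (default σ = 2), the
  canonical species-abundance shape.
* **Neutral regime.**  Each sample is an independent Moran process: at each
  of 10·N death events a uniformly chosen individual is replaced by an
  immigrant drawn from the metacommunity (probability m) or by the copy of
  a uniformly chosen local individual.  The process starts at the
  stationary mean (a multinomial draw from the pool), so 10 sweeps suffice
  for quasi-stationarity; the realised across-sample variance matches the
  beta prediction in the test suite.
* **Niche regime.**  Gaussian filtering of the pool by a trait optimum per
  sample, ``w_i ∝ meta_i·exp(−(trait_i−E_s)²/2σ_sel²)``, with demographic
  drift on top: the realised weights are a ``Dirichlet(θ·w)`` draw per
  sample (default θ = 100, i.e. the community descends from ~100 founding
  lineages).  The drift term matters: without it, replicate samples under
  one environment are near carbon copies, and taxa shared by two samples
  contribute zero to βMNTD under any tip shuffle, erasing the very signal
  homogeneous selection is supposed to leave.  θ = None gives the pure
  deterministic filter.
* **Dispersal-limited regime.**  Each region's source pool is a
  ``Dirichlet(0.2·n_otus·p)`` perturbation of the shared metacommunity —
  a founder effect of a few dozen effective colonists per region — and
  samples are multinomial draws from their region's pool.  The perturbation
  is phylogenetically random, so it raises Raup–Crick between regions
  without generating a selection signal.

What the generator does **not** emulate: sequencing error and chimeras,
compositional biases of PCR, temporal dynamics, species interactions
(co-occurrence edges in neutral data are pure false positives, and the test
suite asserts there are almost none), and spatially explicit dispersal.
Passing tests therefore demonstrate that the estimators recover known
regimes from clean community matrices of realistic shape — not that any
particular field data set is free of those complications.

## Scenario scales used by the tests

Neutral-model recovery uses 500 OTUs × 48 samples × 1000 reads (fits for
m ∈ {0.2, 0.5, 0.8}).  Null-model calibration and the variable-selection
and dispersal-limitation recoveries use 150 OTUs × 24 samples with 199
randomizations; the homogeneous-selection recovery uses a 600-OTU pool —
with fewer taxa the tip-shuffle null is too coarse for |z| > 2 however
strong the filter, because the z-score tightens with the number of taxa
averaged per sample.  Random-graph baselines use the full 1000-replicate
ensembles.  These sizes are the package's test defaults; all replicate
counts are arguments.

## Known limitations

* The beta-CDF detection approximation slightly overstates occupancy
  differences at the rare end (an OTU's detection is really beta-binomial);
  the fitted m inherits a small upward bias at low m and downward at high m
  (within ±0.05 at the test scales).
* RC_Bray on strongly immigrating neutral communities tends toward −1
  (observed pairs are more similar than occupancy-random nulls), so the
  "homogenizing dispersal" class absorbs much of what is conceptually
  drift; the partition's stochastic total is unaffected.
* Louvain is stochastic; module identities (and thus Zi–Pi roles near the
  thresholds) can differ between seeds even though Q is stable.  The
  10-restart max-Q convention and fixed seeds make runs reproducible, not
  unique.
* The power-law R² is a descriptive statistic of the binned log-log
  histogram, kept for comparability; the ML exponent is the better
  estimator and is reported alongside.
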