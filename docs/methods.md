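# Methods

`proteostrat` re-implements, as a tested library, the statistical
workflow behind proteome-based stratification of chronic lymphocytic
leukemia (CLL): simulation of multi-omics cohorts with planted subgroup
structure, consensus clustering of the proteome, characterization of a
poor-outcome "ASB"-like subgroup (Altered Spliceosome, low B-cell
receptor signaling), differential splicing statistics with a
permutation null, cross-platform subtype classifiers, survival models,
and a protein co-expression network.  The real cohorts such a study
uses are restricted-access; every stage here is therefore exercised on
synthetic cohorts whose statistical structure matches the study's
published summary statistics.

## The synthetic cohort generator

`simulate.CohortConfig` / `simulate.simulate_cohort` define the study
conditions.  A cohort of `n_samples` (default 68) patients is drawn
from six subgroups — Tris12M (13%), Tris12U (12%), M (26%), U (25%),
TP53 (6%), ASB (18%) — matching the discovery-cohort composition, with
genetic lesions assigned consistently (both Tris12 groups carry
trisomy 12; the TP53 group is TP53-mutated with 85% probability; ASB
carries no trisomy 12 and mixed IGHV status; SF3B1 mutations occur at
15% independently of subgroup).

**Protein abundances** are `baseline + shift + latent + noise` on the
log2 scale:

- Baselines are Normal(20, 2), a typical MS intensity range.  They are
  drawn from a *cohort-independent* generator (`universe_seed`): the
  relative abundance of two proteins is a property of the biology, not
  of a cohort draw, and rank-based classifiers transfer between
  cohorts only because of this stability.
- Planted shifts: +0.585 (log2 3/2) on 100 chromosome-12 features in
  trisomy-12 carriers plus +0.6 on 70 off-chromosome trisomy-responsive
  features (so ~64% of trisomy-responsive proteins lie off chromosome
  12); ±0.8 on 80 IGHV-responsive features; +0.6 on 50 SF3B1-responsive
  features; +0.9 on a 50-feature TP53-group signature; and the ASB
  program +0.7 / −0.7 / −0.4 / +0.4 on the spliceosome (100), B-cell
  receptor (60), proteasome (30) and BCAA (20) sets.  The IGHV-driven
  program is damped to 25% inside ASB samples — the subgroup's low BcR
  signaling is independent of IGHV status, and without damping the ASB
  group splits in two along IGHV in clustering.
- Six co-expression modules (N1–N6, 12 features each) share a
  per-sample latent factor (variance 0.36, within-module Pearson
  r ≈ 0.7), giving the correlation-network stage real structure.
- Residual noise SD is 0.35 per feature; 5% of protein entries are
  missing completely at random (as in DIA/TMT matrices).

**mRNA** shares the latent signal (shifts + class latent + module
factors) and adds class-specific noise whose SD is solved in closed
form so that the per-class Spearman correlation between protein and
mRNA hits the published targets: 0.69 for trisomy-12-responsive, 0.86
for IGHV-responsive, 0.29 for SF3B1-responsive features, and a
background level placing the overall median near 0.243.  For protein
P = c + e_p and mRNA R = c + e_r, Pearson r = Var(c) /
sqrt((Var(c)+σ_p²)(Var(c)+σ_r²)); the Spearman target ρ is converted
with r = 2 sin(πρ/6) (exact for bivariate normal data) and σ_r solved
per feature.  Realized class medians land within ±0.01 of target
(averaged over 10 seeds).

**Splice events.**  2000 exon-skipping (SE) events plus 300 each of
A3SS/A5SS/RI/MXE.  Per-event totals are negative binomial (mean 60,
dispersion 0.3); 15% of events are drawn at mean 10 so the >20-mean-
inclusion coverage filter genuinely removes events.  Inclusion counts
are binomial with the length-normalized inclusion probability implied
by the event PSI (effective lengths 2/1, junction-read convention).
150 SE and 80+80 A3SS/A5SS events get a +0.65 logit shift in ASB
samples — ASB includes *more* exons and uses more alternative splice
sites, and its elevated spliceosome abundance correlates positively
with mean PSI, matching the reported directions.  The logit shift
realizes a mean |ΔPSI| of ≈0.15.  Baseline PSI values come from the
universe generator for the same transferability reason as baselines.

**Clinical layers.**  Survival times are exponential with per-subgroup
log hazard ratios (TTNT: ASB +1.1, TP53 +0.8, M −0.8, …; OS baseline
median 1800 days) and independent uniform censoring (~30–50% censored
depending on endpoint).  Lymphocyte counts grow exponentially with the
fastest rates in ASB; one sample in ten has only three time points to
exercise the <4-point exclusion.  The drug screen produces per-well
cell counts with DMSO solvent controls and plants TP53-group
resistance to DNA-damage drugs and Tris12 sensitivity to BcR
inhibitors.

Identical (config, seed) pairs give bit-identical bundles.  All counts
of features, events and effect magnitudes above are package defaults
chosen to make structure recovery non-trivial but achievable at n=68;
where the emulated study published a value (proportions, coupling
targets, dosage log2FC, |ΔPSI|, filters) that value is the default.

### What the generator does not emulate

No batch/TMT-set structure, no peptide-level quantification noise, no
clonal evolution, no correlated missingness (missingness is MCAR, not
intensity-dependent as in real DIA), no linkage between the splicing
layer and specific genes, and Gaussian log-intensities without heavy
tails.  Passing recovery tests therefore shows the *statistics* are
implemented correctly and well-calibrated at realistic effect sizes —
not that real cohorts would separate this cleanly.

## Differential abundance

`differential.moderated_fit` fits per-feature least squares for an
arbitrary full-rank design (built from annotation columns with a small
`a + b + a:b` formula syntax), with casewise deletion of missing
values; features with residual df < 1 are dropped with a warning.
Variances are moderated with an empirical-Bayes scaled
inverse-chi-square prior fitted by method of moments on log s² (with a
Newton trigamma inverse); the posterior variance is
(d0·s0² + d·s²)/(d0 + d) and the moderated t has d0 + d degrees of
freedom.  Two deliberate details: when the observed variances are
underdispersed (no detectable heterogeneity) the prior collapses onto
the geometric mean of s², so identical variances give s2_post = s²
exactly; and d0 can be forced (d0=0 reproduces the ordinary t) for
limit checks.  The implementation is cross-checked against
Bioconductor limma on a shared fixture in the test suite.  PSM-count-
dependent variance models are intentionally out of scope — the
synthetic data carry no spectral counts.

Hits use adjusted p < 0.001 and |log2FC| > 0.5 (the stringent cut the
emulated analysis used for proteins).  Dosage profiles are per-sample
LOWESS curves of feature-median-centred abundance against genomic
position (span 0.3 — the smoothing parameter is not published;
exposed as `frac`); no additional per-sample centring is applied since
matrices arrive normalized.  Trisomy-12 inference flags the top
ceil(0.2·n) samples by mean chromosome-12 abundance with a
deterministic sample-id tie-break.

## Consensus clustering

`consensus.consensus_cluster` is a Monti-style resampler: subsample
80% of samples per iteration, cluster with k-means (10 restarts, on
the 2000 highest-variance features) or average-linkage hierarchical on
1 − Pearson, and tally co-clustering over co-sampling.  Cluster-number
selection uses the relative change in area under the consensus CDF:
the smallest k whose gain at k+1 drops below 0.1.  The conventional
0.05 cut systematically over-segments with a resampled k-means inner
loop (the gain plateaus near 0.06 past the true k on clean planted
data), hence the looser default; an explicit `override` — recorded in
provenance — mirrors the workflow of choosing k partly on biology.
Final labels cut an average-linkage tree of 1 − consensus.  Genotype
enrichment tests each (group, lesion) 2×2 table two-sided (enrichment
and depletion both reported) with BH at FDR 10%.

## Splicing

PSI = (I/lI) / (I/lI + S/lS), missing iff I+S = 0.  Differential exon
skipping between a group and the rest uses a two-sided Wilcoxon
rank-sum test on per-sample PSI (tie-corrected normal approximation,
re-implemented in vectorized form for the permutation loop and exact
against scipy), BH across events, and three filters: adjusted p < 1%,
|ΔPSI| > 0.1 on groupwise means of per-sample PSI, and mean raw
inclusion counts strictly greater than 20.  The hierarchical
count-model alternative is deliberately replaced by this rank test:
downstream logic consumes only the significant-event set and effect
sizes, and the rank test is exactly specifiable and testable.  The
permutation null redraws the group of interest uniformly without
replacement (group size preserved), reruns the full pipeline, and
reports p = (1 + #{null ≥ observed})/(n_perm + 1); 57 permutations
reproduce the published p < 0.0172 bound, 200 is the default for
stability.  Peptide/exon-level relative usage subtracts the per-sample
gene mean from each exon and feeds the deviations to the moderated-t
machinery; the "quantified in more than two TMT sets" presence rule
generalizes to an optional per-sample batch label (without labels,
each sample counts as a batch).

## Classifiers

The k-TSP classifier scores ordered feature pairs by
Δ(i,j) = |P(Xi<Xj | ASB) − P(Xi<Xj | rest)| with a mean-rank-difference
secondary score, selects disjoint pairs greedily (ties: secondary
score, then lexicographic), and tunes the pair count by repeated
Monte-Carlo cross-validation (100 stratified 25% holdouts by default;
balanced accuracy, robust to the ~1:4 class imbalance; smallest k on
ties).  The vote threshold is ⌈k/2⌉; at prediction, a pair with a
missing feature is dropped and the threshold lowered by one (floor 1),
the documented rule for applying the classifier to a platform lacking
one pair.  Votes at exactly the threshold call the positive class.

PLS-DA centers and scales its predictors (the significant
exon-skipping events' PSI values), fits components by NIPALS with the
class coded {0,1}, picks the component count by leave-one-out AUROC
(rank-statistic AUROC, ties half-credit), and thresholds the fitted
score at the midpoint of class means.  The NIPALS fit is cross-checked
against scikit-learn's PLSRegression in the tests.

## Survival and phenotypes

Endpoint construction follows the cohort conventions: TTNT from sample
collection to treatment initiation with untreated patients (including
those who die untreated) censored at last contact; TTFT from
diagnosis; OS from collection to death; records with no follow-up are
excluded and counted.  Kaplan-Meier curves come from lifelines with
the median defined as the earliest time with S ≤ 0.5.  The log-rank
test is the standard O−E statistic (lifelines).  Cox models are fitted
here by Newton-Raphson on the partial likelihood with Efron (default)
or Breslow ties — Efron because the day-granularity synthetic data
produce ties; the Breslow score test at β = 0 equals the two-group
log-rank statistic, an identity asserted in the tests, and the full
fit is cross-checked against lifelines.  Monotone likelihood (perfect
separation) is flagged, not hidden.  Lymphocyte growth is the OLS
slope of log10 counts against days, requiring ≥4 time points.  Drug
wells are normalized to 100 × (%alive / mean %alive of the sample's
DMSO controls).  Nuclear-area classification calls a cell alive when
its area strictly exceeds 23.8 µm² — the threshold direction is not
published; condensed (small) nuclei mark dead/apoptotic cells, so
alive-above was chosen and is exposed as a parameter.

## Protein network

Top-SD features are connected where Pearson r ≥ r_edge (default 0.6;
the original edge rule is unpublished, so the threshold is exposed and
logged), negative correlations excluded, pruned to the 3-core, and
partitioned by Louvain modularity at resolution 0.8.  The graph is
canonicalized (sorted node order) before Louvain so module labels are
invariant to input order at a fixed seed.  Module expansion pulls in
any feature of the full matrix correlating strictly above 0.7 with a
module member; module×group summaries average member abundances per
patient group.

## Pipeline and reproducibility

`pipeline.run_discovery` chains simulate → cluster (k override 6) →
differential characterization of the recovered ASB cluster → splicing
(N_e + permutation p) → survival (TTNT log-rank across groups, OS Cox
with the TP53 interaction) → network, writing TSV tables and a JSON
report; `run_validation` trains k-TSP (proteome panel) and PLS-DA
(splicing signature) on a discovery cohort and applies them to an
independent cohort.  Per-stage seeds derive from the single global
seed via `numpy.random.SeedSequence(seed).generate_state` in a fixed
stage order, so a stage can be re-run in isolation and whole runs are
byte-reproducible (reports contain no timestamps).  Default problem
sizes (200 consensus iterations, 57 permutations, 50 MCCV splits,
n=165 validation) keep a full discovery+validation run around two
minutes on one CPU.

## Numerical choices and degenerate inputs

BH adjustment delegates to statsmodels and is property-tested against
the stepwise definition.  Rank tests use the exact null for ≤10
observations per group without ties, the tie-corrected normal
approximation otherwise.  Spearman correlations use average ranks;
genes with fewer than 3 complete pairs are skipped with a warning.
Consensus matrices are symmetrized and unit-diagonal by construction
and asserted on every run.  k-core output is asserted to satisfy the
degree invariant.  Zero-variance features are dropped (PLS-DA) or
flagged (top-variable event selection ties).  All-missing samples
yield missing labels rather than guesses.

## Known limitations

The rank-sum splicing test loses power against the hierarchical
count-model alternative when coverage is very low; the permutation
null inherits the exchangeability assumption (no batch structure); the
Cox implementation supports neither time-varying covariates nor
competing risks; PLS-DA assumes the 0/1 coding's linear score is
monotone in class probability; and all calibration statements above
are statements about the generator's Gaussian world, not about real
cohorts (see the generator's non-goals).
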