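# Methods

`subcovnet` implements a group-level structural covariance network
analysis of subcortical volumes for a four-group cohort design: normal
controls (NC), subjective cognitive decline split by spatial-navigation
performance into good (G-SCD) and bad (B-SCD) navigators, and mild
cognitive impairment (MCI). This note documents the statistical model,
the conventions and tunable parameters, what the synthetic cohort
generator does and does not emulate, and the numerical choices made
where the design was open.

## Subject-level statistics

**Composite scores.** Each raw cognitive test score is standardized to a
z-score over the full analyzed sample (SD with n−1 denominator),
sign-flipped where a higher score means worse performance (the trail
making tests, which are completion times), and averaged within its
domain (memory: the five auditory verbal learning measures; executive:
TMT-A, TMT-B, SDMT, CDT; language: animal fluency and Boston naming).
The navigation composite is the standardized mean distance error over
all 16 trials (8 egocentric + 8 allocentric) and is *not* sign-flipped:
a higher value means worse navigation. Standardizing over the whole
sample rather than the control group is a choice; it reproduces the
expected sign pattern (controls positive, MCI negative) and is exposed
through the domain-map argument for users who prefer an NC reference.

**Navigation subgrouping.** SCD subjects are ranked by mean distance
error and split symmetrically: the better half is labeled G-SCD, the
worse half B-SCD. Boundary ties are resolved by stable input order with
a logged warning; an odd SCD count requires an explicit rule
(`extra_good`/`extra_bad`). Alternative grouping scores (the memory,
language or executive composites, higher = better) reproduce the
sensitivity re-analysis in which subgroups are formed by cognition
instead of navigation.

**Group comparisons.** Continuous demographics use one-way ANOVA; sex
and scanner use Pearson chi-square *without* continuity correction
(this convention reproduces the published statistics exactly). Regional
volumes use one-way ANCOVA — least-squares fit of volume on group
dummies plus covariates (sex, age, education years, total intracranial
volume), F computed from the residual sums of squares of the full and
reduced models — followed by least-significant-difference (LSD)
pairwise t-tests on the covariate-adjusted means using the full-model
MSE. LSD p-values are by definition unadjusted across pairs;
Benjamini–Hochberg FDR is instead applied across each ROI family (the
15 nuclei, the 5 basal-forebrain subfields, the 12 hippocampal
subfields, and the volume-by-domain correlation grid). Volume–cognition
associations use partial correlation: Pearson correlation of the
residuals of both variables after regression on the covariates, with
p from t = r·sqrt((n−2−k)/(1−r²)).

**Follow-up.** Conversion to MCI between the two SCD subgroups is a 2×2
Fisher exact test, two-tailed by the "sum of small p" rule: the p-value
sums the hypergeometric probabilities of all tables with the observed
margins whose probability does not exceed that of the observed table
(relative tolerance 1e−7 on the comparison). The doubling rule (twice
the smaller tail) is available as an option. The sum-of-small-p rule is
what reproduces the published p = 0.047 for 0/20 vs 4/15 converters.

## Covariance networks

Nodes are the 5 basal-forebrain subfields (Ch4p, Ch4a-i, Ch3, NSP,
Ch1/2) and the 12 right-hippocampal subfields (17 nodes). Edges are
Pearson correlations of node volumes across the subjects of one group;
negative correlations are set to zero. No covariate residualization is
applied before correlating by default (covariate adjustment is part of
the volumetric analyses, not the network definition); residualization
and Spearman correlation are available for sensitivity analyses.

Binarization keeps the k = floor(s·N(N−1)/2) strongest positive edges
at sparsity s, over the grid 0.18 to 0.50 in steps of 0.01 (33 points,
computed with exact decimal handling). Ties at the cutoff are broken by
lexicographic node-pair order via a stable sort, which makes edge sets
nested across the grid. Zero-weight edges are never retained; the
achieved edge count is recorded and a warning logged when it falls
short of the target. The floor rule guarantees the realized sparsity
never exceeds the nominal fraction. The lower grid bound is taken as
given; a diagnostic reports the smallest grid sparsity at which each
group's graph becomes connected.

## Graph metrics

On each binary graph: clustering coefficient Cp (mean over all nodes of
edges-among-neighbours ÷ d(d−1)/2, zero for degree < 2), characteristic
path length Lp (mean shortest path over *finite* ordered pairs, with
the number of unreachable pairs reported and logged; a
largest-component variant is available), global efficiency (mean 1/d
with 1/∞ = 0), local efficiency (mean over nodes of the global
efficiency of the neighbour-induced subgraph), and the nodal metrics
nodal efficiency, betweenness centrality (Brandes algorithm, normalized
by (N−1)(N−2)/2), and degree.

Gamma = Cp/⟨Cp_random⟩ and Lambda = Lp/⟨Lp_random⟩ normalize against
the *mean* of an ensemble of degree-preserving random networks
generated by Maslov–Sneppen double-edge swaps (default 100 networks,
successful-swap budget 10× the edge count, attempt cap 3× the budget
with the achieved count logged). Sigma = Gamma/Lambda; Sigma > 1
indicates small-world organization. All ensemble seeds derive
deterministically from the master seed.

## AUC and permutation inference

Each metric curve over the sparsity grid is summarised by its area
under the curve (trapezoidal rule by default; a values-times-step rule
is provided as a toolbox-compatibility switch). Two groups are compared
on the AUC difference by a label permutation test (default 1000
permutations): subjects are pooled, reassigned preserving group sizes,
and the entire chain — correlation, zeroing, binarization, metrics,
random-network normalization, AUC — is recomputed per relabeling, with
fresh deterministically-derived random-network streams each time.
The two-tailed p is (1 + #{|Δπ| ≥ |Δobs|})/(1 + n_perm), never below
1/(n_perm + 1). Nodal metrics are tested per node with BH adjustment
across the 17 nodes.

**Null-ensemble scheme inside curves.** Because the binarized graphs
are nested across the grid, the rewired null networks are, by default,
carried up the grid: at each new sparsity the edges newly added to the
real graph are added to each null graph (with a degree-matched repair
when an edge already exists) followed by 10×(new edges) further
successful swaps, keeping the cumulative swap budget at 10×E at every
level. This is about 5× cheaper than independently re-randomizing at
all 33 sparsities and leaves the permutation test exact, since the
statistic is computed identically for every relabeling. Independent
per-sparsity rewiring is available (`ensemble_scheme="independent"`),
and the two schemes agree on Gamma/Lambda curves within ensemble noise
(tested). Single-graph normalization (`normalized_metrics`) always uses
independent full rewiring.

The metric engine is implemented twice on purpose: a plain
numpy/scipy route (readable, used for single graphs) and compiled
bitset kernels (one adjacency word per node; used for curves and
permutations, where ~10⁵ graphs per test and ~10⁷ per calibration study
are evaluated). The two routes are asserted equal across the whole grid
in the test suite, and both are checked against networkx and
brute-force shortest-path/path-enumeration oracles.

## Synthetic cohort generator

The generator draws, per group: multivariate-normal regional volumes on
the mm³ scale for 32 regions (15 subcortical nuclei, 5 basal-forebrain
subfields, 12 right-hippocampal subfields) with means and SDs
calibrated to the observed four-group cohort; age, education, sex,
scanner, standardized TIV and image-quality ratings from the observed
group distributions; raw cognitive test scores driven by a latent
per-domain ability (group means/SDs on the z scale equal to the
observed composite summaries, test-specific noise SD 0.5, time-scored
tests negated); per-trial navigation errors as a subject-level latent
error (group means/SDs matching the observed standardized summaries)
plus trial noise (SD 0.3); and follow-up for a fixed-size random subset
(20/40 good and 19/40 bad navigators) with Bernoulli conversion at the
observed rates (0 and 4/19) and intervals of roughly 1.5 years.
Subjects with a non-positive sampled volume are redrawn, up to 100
attempts (defaults put means ≥ 6 SDs above zero, so truncation bias is
negligible).

Assumptions worth knowing:

* **Inter-ROI correlation is not reported for the real data.** The
  default is exchangeable: 0.4 among the 17 network nodes, 0.2
  elsewhere. A per-group scalar (`covariance_strength`) multiplies the
  off-diagonals (result checked for positive semidefiniteness), and a
  modular alternative (`modular_base_correlation`: within-module 0.65,
  between 0.08, mean 0.40) is provided. Two consequences: (i) an
  exchangeable structure has no clustering excess, so synthetic
  covariance networks are *not* small-world (Sigma ≈ 0.95) — unlike
  real brain networks; (ii) because binarization is rank-based,
  *uniform* changes in correlation level barely change topology, so
  covariance-strength contrasts are only detectable against a
  structured (e.g. modular) base. The power analyses therefore realize
  "mean node correlation 0.6 vs 0.2" as strengths 1.5 vs 0.5 on the
  modular base. The sharp within/between contrast matters specifically
  for path-length metrics: under label permutation the pseudo-groups
  are mixtures of the two populations, and with a diffuse modular
  contrast the relabeling variability of Lp/Lambda AUCs swamps the
  group effect (measured effect-to-null-SD ratio ~1), while the sharp
  contrast stabilizes the binarized topology and makes the same mean
  correlation levels detectable (ratio ~3.8).
* **Aggregate regions are their own coordinates.** "Basal forebrain"
  and the whole hippocampi are drawn as separate correlated variables
  with the observed aggregate means/SDs; they are not constrained to
  equal the sum of their subfields (the observed aggregate SD is not
  the subfield-sum SD, and FreeSurfer whole-structure volumes are not
  subfield sums either).
* **Not modeled:** volume–covariate dependence (so ANCOVA covariates
  are calibration-neutral nuisance terms), volume–cognition
  correlation, scanner effects on volumes, segmentation error, and
  longitudinal trajectories. Passing tests therefore demonstrate
  statistical correctness of the machinery under the stated
  distributional assumptions, not fidelity of any particular real-data
  effect size.

## Problem sizes used in validation

Type-I calibration of the permutation tests uses 200 null cohorts
(n = 40/group, 17 nodes) at 500 permutations with 10 random networks
per sparsity for aLambda, extended to 600 null cohorts for aCp (which
needs no random-network normalization, so replicates are cheap and the
binomial noise of the rate estimate can be brought well under the width
of the acceptance band); power uses 30 replicates of the modular
1.5×/0.5× contrast at the same settings; ANCOVA calibration uses 1000
null and 200 deficit cohorts. Brute-force oracle sweeps cover 500 random graphs
on up to 7 nodes and all 5,550 2×2 tables with margins ≤ 12. The
acceptance script runs the full chain on one 180-subject cohort with
1000 permutations and 10 random networks per sparsity.

## Known limitations

* Graphs are capped at 32 nodes (one machine word per adjacency row);
  the design target is the 17-node subfield network.
* With a 10×E swap budget, rewired ensembles of *extremely* clustered
  graphs (ring lattices) retain slight residual clustering; for
  correlation-derived graphs at the default densities the effect is
  negligible, and the budget and attempt caps are configurable.
* Lp on disconnected graphs averages finite distances only, which can
  make Lp *drop* when a graph fragments; unreachable-pair counts are
  logged and should be inspected whenever the sparsity floor leaves a
  group's graph disconnected.
* The chi-square statistic is computed without continuity correction
  by design; for the small printed tables a corrected or exact variant
  would give different (larger) p-values.
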