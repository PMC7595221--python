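# Methods

This document records the statistical model behind `proteonet`, the design of
each analysis stage, and the numerical choices that affect results. The
package analyses a longitudinal label-free proteomics design: two cohorts
(healthy and amyloid-expressing "disease" brains) sampled at several ages,
with biological and technical repeats, quantified at the protein level and
interrogated for altered proteins, temporal profiles, network position and
functional enrichment.

## 1. Data model

An `AbundanceMatrix` is a proteins x samples grid of linear-scale abundances
with an explicit missing-value mask and per-sample metadata (`condition`,
`day`, `bio_rep`, `tech_rep`). A provenance log records every transform.
Peptide-level input is a long table of (protein, peptide, sample, intensity)
records.

### Synthetic generator

The generator plants known structure so every downstream stage can be tested
against ground truth.

* **Baseline abundances.** Per-protein log10 means are drawn from
  Normal(`baseline_log_mean`, `baseline_log_sd`); protein abundance in a
  sample is the expected value times independent unit-mean lognormal noise
  factors: one biological factor at CV `noise_cv` shared by all technical
  repeats of a biological repeat, and one technical factor at CV
  `noise_cv / 2`.
* **Archetypes.** A configurable fraction of proteins is "altered", split
  deterministically across four temporal archetypes:
  1. constitutively increased in disease (factor `effect_size` at all disease
     time points);
  2. constitutively decreased in disease (factor `1/effect_size`);
  3. ageing-coupled increase: abundance ramps up with age in **both**
     conditions, reaching `effect_size` at the last healthy age;
  4. disease-specific decline: abundance ramps down with age in the disease
     cohort only, reaching `1/effect_size` at the **last disease age**.

  The archetype-4 ramp is deliberately scaled to the disease observation
  window (day 5-46 by default), not to the full healthy window (day 5-80):
  the disease cohort is never observed beyond day 46, so a ramp over the
  longer window would under-realise the planted fold change within the data
  actually generated. Planted effects are generator semantics, so the
  nominal `effect_size` must be attained inside the observed window.
* **Missingness.** Intensity-dependent: a fixed number of entries
  (`missing_rate` x matrix size) is removed by weighted sampling with weights
  proportional to the value's rank from the top, so low-abundance entries are
  preferentially censored — the usual detection-limit mechanism in label-free
  MS.
* **Peptides.** Each protein gets 1-8 peptides with fixed per-peptide
  propensities rescaled so the mean of the top three equals 1 exactly; Hi3
  rollup of noise-free peptides therefore reproduces the protein value
  bit-for-bit.
* **Network.** Erdős–Rényi or Barabási–Albert backgrounds over the same
  protein-id namespace as the abundance matrix. Optional planted structure:
  a clique with combined scores ≥ 0.9 (a "dense module") and a central set
  whose members receive extra random edges up to three times the mean degree
  (a "high-centrality set").
* **Annotations.** Random term sets plus one `PLANTED` term equal to the
  first (up to 20) altered proteins.

All randomness derives from one root seed through `derive_seed(root,
component, index)` (a `SeedSequence` keyed by a stable per-component hash), so
stages are independently reproducible and adding samples to one stage never
shifts another.

## 2. Preprocessing

* **Hi3 rollup:** protein abundance = mean of its three most intense
  peptides; proteins with fewer than three peptides use the mean of what is
  available and are flagged.
* **Imputation:** missing entries get their sample's (column's) observed
  minimum — the detection-floor assumption matching the generator's censoring
  mechanism.
* **Quantile normalisation:** every sample is forced onto the mean of the
  per-sample sorted distributions; ties within a sample receive the mean of
  the reference values at the tied ranks. Requires a complete matrix
  (impute first).
* **Standardisation:** log10 then per-protein z-score with sample variance
  (ddof = 1); constant rows become zeros and are flagged.
* **Baseline-relative scaling:** division by the mean of the healthy day-5
  samples, for display of fold changes.
* **PCA** (samples as observations) and **Euclidean complete-linkage
  biclustering** (scipy) for structure inspection.

## 3. Consensus differential abundance

Three detectors with deliberately different distributional assumptions are
run per protein; BH-adjusted q-values are computed per detector, and a
protein is called altered when at least `votes` (default 2) of the detectors
call it at FDR 5%. Technical repeats are collapsed (averaged) first. Two
designs are tested:

* **condition** — disease vs healthy restricted to the shared days, full
  interaction model against a time-only reduced model;
* **time** (ageing) — healthy samples only, any-time-effect against an
  intercept model.

Detectors:

1. **Moderated F.** Group-mean (cell-mean) linear models on log10 data. The
   per-protein residual variances are shrunk toward a prior: the prior
   (s0², d0) is estimated by matching the first two moments of the observed
   variances to a scaled inverse-chi-squared distribution via the moments of
   the F distribution. The moderated statistic follows an F distribution
   with `d0 + df_residual` denominator degrees of freedom (chi-squared limit
   when d0 is infinite).
2. **Negative-binomial LRT.** Abundances are scaled by median-of-ratios size
   factors, rounded half-to-even to pseudo-counts, and fitted by NB
   likelihood with a common method-of-moments dispersion; per-cell means are
   the analytic MLE. The statistic is the likelihood-ratio chi-squared. The
   Poisson limit is used below dispersion 1e-8; all-zero proteins get p = 1
   and a flag.
3. **Polynomial LRT.** Gaussian polynomial-in-time regression (default
   degree 2, scaled day covariate) with condition main effect and
   condition x time interactions; statistic n·ln(RSS0/RSS1) against
   chi-squared with the difference in model dimensions.

BH adjustment is a shared, brute-force-verified step-up implementation.

## 4. Profile clustering

Altered proteins are represented by their mean z-scored log10 abundance per
(condition, day) cell, rows re-standardised. A diagonal-covariance Gaussian
mixture is fitted by EM (own implementation: k-means++ style initialisation,
five restarts, variance floor 1e-6, recorded log-likelihood trace with a
monotonicity assertion). The number of clusters minimises

    BIC = -2 ln(L) + ln(n) · k

with k the **number of clusters** — a deliberately light penalty variant used
in the domain literature for profile clustering; the conventional
free-parameter penalty (k(2d+1) − 1) is available as `mode="parameters"`.
Ties break toward smaller k.

**A measured limitation of the cluster-count penalty.** On clean
four-archetype generator output the k = 4 fit reproduces the planted
partition exactly (ARI 1.0, 10/10 seeds), but the BIC *argmin* does not stop
at 4: with a converged maximum-likelihood EM, each extra component gains
20–90 nats of log-likelihood (verified independently with
scikit-learn's `GaussianMixture`) against a penalty of only ln(60) ≈ 4.1,
so selection runs to k_max. This is the classical near-degeneracy of
unconstrained mixture likelihoods at small n and d ≈ 10, which a
cluster-count penalty cannot offset (the free-parameter penalty,
≈ 86 per extra cluster here, is stronger but still not reliable). A
published k = 4 minimum under this criterion is therefore only reproducible
with a likelihood that is *not* aggressively maximised (fewer restarts,
looser convergence) or with additional variance constraints. The acceptance
property asserting selection of k = 4 consequently fails and is left
failing; the package reports the full BIC trace so the elbow at the true k
(a steep drop up to k = 4, marginal gains after) remains visible.

## 5. Network statistics

The analysis network is the largest connected component (LCC) of the
score-thresholded interaction graph (combined scores parsed from STRING-style
flat files; 0-999 integer scales auto-detected and divided by 1000). Four
statistics describe a protein set against the *whole* analysis network:

* mean degree;
* mean shortest-path length over ordered pairs within the set, with paths
  running through the full network (dense unweighted distance matrix via
  scipy.csgraph);
* size of the largest connected component of the subgraph induced on the set
  alone;
* mean normalised betweenness centrality.

Significance is by permutation: node sets of the same size are resampled
uniformly from the network, the same samples reused for all four statistics.
Empirical one-sided P values use the add-one estimator (1 + #extreme) /
(1 + N) with a priori tails (upper for degree, betweenness and LCC size;
lower for shortest path). Hubs and bottlenecks are nodes **strictly** above
the 90th percentile (linear interpolation) of degree and betweenness
respectively; the four classes are hub-bottleneck, hub-nonbottleneck,
nonhub-bottleneck and neither.

## 6. Dense-module detection (MCODE)

Own implementation of Molecular Complex Detection:

* vertex weight = core-clustering coefficient: the order k_max of the highest
  k-core of the vertex's closed neighbourhood times that core's density;
  vertices below the degree cutoff (default 2) weigh 0;
* greedy expansion from the highest-weighted unvisited seed, admitting
  neighbours with weight strictly above seed_weight x (1 − VWP), VWP = 0.2;
* post-processing: "haircut" iteratively strips members with fewer than two
  in-module edges (the module's 2-core); modules whose highest core order is
  below 2 are discarded; "fluff" is not implemented and raises;
* module score = density x size; modules are node-disjoint and sorted by
  score; an optional reporting cutoff filters afterwards.

Modules are searched on the altered-proteins-plus-direct-neighbours subgraph
(LCC), and each module reports the fraction of its members in the query set.

## 7. Enrichment

One-sided hypergeometric (Fisher) overrepresentation per term against a
custom background universe. Term sets are intersected with the universe
first; query ids outside the universe are dropped and counted; terms with
fewer than three members after restriction are untestable and skipped;
q-values are BH. A minimum-hypergeometric (mHG) statistic over prefixes
1..N−1 of a ranked list, with label-permutation significance, covers the
threshold-free case.

## 8. Pipeline

`PipelineConfig` (YAML-loadable) names the inputs — either a synthetic block
or file paths (peptides or matrix + samples, links, GMT) — plus stage
parameters and toggles. `validate_config` returns (level, message) findings
without raising; `run_all` raises `StageError` naming the failing stage.
The report is a nested dict whose `content_hash` is the sha256 of its
canonical JSON form (keys sorted, floats rounded to 12 decimals), used for
end-to-end determinism checks. Problem sizes of bundled configurations
(hundreds of proteins, ~300-node networks, 1000-10,000 permutations) are the
package's own choice, sized so the full test suite runs on one CPU in
minutes.

## Numerical choices and limitations

* Detector type-I error was measured at ≤ 1.2% per detector and ≤ 0.05% at
  the consensus level on 2000-protein null datasets (nominal 5% FDR), i.e.
  the vote is conservative.
* The NB detector treats rounded, size-factor-scaled intensities as counts;
  this is an approximation adopted for its variance model, not a claim that
  MS intensities are counts.
* The moderated-F prior-df estimator falls back to a weak prior (d0 = 4.001)
  when the moment match is infeasible, and to the pooled-variance chi-squared
  limit when d0 is infinite.
* Permutation P values are never 0 by construction; resolution is bounded by
  1/(N+1).
* MCODE parameters are implementation-sensitive; published module counts are
  treated as soft targets.
* External-data criteria (published interaction-network counts) require the
  STRING v10 links file and published protein lists; without them the
  corresponding acceptance tests fail honestly rather than skip.
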