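# proteonet

Longitudinal label-free proteome analysis with protein-interaction-network
statistics.

`proteonet` implements an end-to-end analysis for a two-cohort time-course
proteomics design — healthy brains versus amyloid-expressing ("disease")
brains sampled across adult life — from quantitative tables to biological
readouts:

1. **Preprocessing** — Hi3 peptide-to-protein rollup, detection-floor
   imputation, quantile normalisation, log10 + z standardisation, PCA and
   hierarchical biclustering.
2. **Consensus differential abundance** — three statistically distinct
   detectors (moderated F, negative-binomial LRT, polynomial Gaussian LRT);
   a protein is called altered when at least 2 detectors agree at BH FDR 5%.
   Run under the disease-vs-healthy design and the healthy-ageing (time-only)
   design, with an AD-only / ageing-only / shared set comparison.
3. **Profile clustering** — diagonal-covariance Gaussian mixture (own EM with
   an asserted monotone log-likelihood trace), cluster count by the
   cluster-count BIC variant −2 ln(L) + ln(n)·k.
4. **Network statistics** — degree, shortest path, induced-LCC size and
   betweenness of a protein set against a STRING-style interaction network,
   with uniform-resampling permutation P values and > 90th-percentile
   hub/bottleneck classification.
5. **Dense modules** — an MCODE reimplementation (core-clustering-coefficient
   vertex weights, greedy expansion, haircut).
6. **Enrichment** — one-sided hypergeometric overrepresentation with BH,
   plus a ranked minimum-hypergeometric (mHG) statistic.
7. **Synthetic data** — a generator that plants the four temporal archetypes
   (constitutively up / constitutively down / ageing-coupled increase /
   disease-specific decline), intensity-dependent missingness, peptide
   tables, networks with planted cliques and high-centrality sets, and
   annotations — all with ground truth for recovery testing.
8. **Pipeline** — one YAML config drives everything; the run report carries a
   sha256 content hash so identical seeds give identical results.

See `docs/methods.md` for the statistical details and the measured
limitations (notably of the cluster-count BIC penalty).

## Quick start (Python)

```python
from proteonet import synthetic, preprocess, differential

cfg = synthetic.SyntheticConfig(n_proteins=200, n_altered=40, effect_size=4, seed=1)
matrix, truth = synthetic.generate_abundance_dataset(cfg)

norm = preprocess.quantile_normalise(preprocess.impute_missing(matrix))
consensus, detectors = differential.run_consensus(norm)   # disease vs healthy
recovered = consensus.significant_ids & truth.altered_ids
print(len(consensus.significant_ids), "called;", len(recovered), "of",
      len(truth.altered_ids), "planted alterations recovered")
```

## Quick start (pipeline)

```yaml
# config.yaml
synthetic:
  n_proteins: 500
  n_altered: 60
  n_nodes: 500
  edge_param: 0.02
  planted_clique: 10
  seed: 7
permutations: 10000
seed: 7
```

```bash
proteonet run --config config.yaml --outdir results/
```

`results/report.json` contains per-stage summaries (counts of altered
proteins, set comparison, BIC trace, network P values, modules, enriched
terms) and a `content_hash` that is identical across reruns with the same
config. Individual stages are also exposed as subcommands (`simulate`,
`preprocess`, `diff`, `cluster`, `network`, `modules`, `enrich`); see
`proteonet --help`.

## Testing

```bash
python -m pytest -q tests/
```

The suite contains unit and property tests per module plus
`tests/test_acceptance.py` with one test per acceptance criterion. Three of
those criteria reproduce published interaction-network counts and need
external inputs (a STRING v10 links file and published protein lists placed
under `data/external/`, see the docstring in `tests/test_acceptance.py`);
without them those tests **fail** — deliberately, rather than skipping. One
sub-property of the property-suite criterion (BIC argmin at the true cluster
count) also fails by design of the method; the analysis is in
`docs/methods.md` §4.

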