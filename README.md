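# grntopo

Topological analysis of gene regulatory networks (GRNs): which node-level
graph features separate **regulators** (transcription factors) from their
**target genes**, and how gene duplication reshapes the key feature — the
average nearest neighbor degree.

## The problem

A GRN is a set of directed regulator→target interactions. Modeled as an
undirected graph, regulators tend to be hubs and targets tend to be
low-degree leaves, so a handful of topological attributes should suffice to
tell them apart. This package implements that analysis end to end:

1. **Parse & filter** regulator→target edge lists (optional evidence-label
   filtering), assemble an undirected simple graph, and label every gene
   `regulator`, `target`, or `both`.
2. **Topology.** Compute 13 per-gene attributes — degree *k(i)*, average
   nearest neighbor degree
   *K*<sub>nn</sub>(i) = (1/k(i)) Σ<sub>j∈N(i)</sub> k(j),
   PageRank, eccentricity, eigenvector centrality, betweenness, closeness,
   strength, hub score, coreness, subgraph centrality, Burt's constraint,
   and local transitivity — and check scale-freeness by an OLS fit of
   P<sub>deg</sub>(k) ∝ k<sup>−γ</sup> on log-log axes (reporting γ and R²).
3. **Discretize** each attribute per network into six σ-bins
   A ≤ x̄−2σ < B ≤ x̄−σ < C ≤ x̄ < D ≤ x̄+σ < E ≤ x̄+2σ < F.
4. **Datasets.** Hold out 10% of regulators plus as many targets as a
   balanced test set; undersample the remaining targets into disjoint
   regulator-sized chunks, each joined with all regulators, to form balanced
   training sets; build label-shuffled random controls.
5. **Select features** by correlation-based feature selection (CFS: best-first
   search over subset merit k·r̄<sub>cf</sub>/√(k + k(k−1)·r̄<sub>ff</sub>)
   with symmetrical-uncertainty correlations), supported by an
   information-gain ranking.
6. **Learn** one gain-ratio (C4.5-style, 20 objects per leaf) decision tree
   per balanced set with stratified ten-fold cross-validation, combine them
   by probability averaging into a consensus model, classify the held-out
   set, and compare normal vs shuffled-label performance (Shapiro–Wilk, then
   Mann–Whitney U). A majority-rule merged consensus tree summarizes the
   rules and routes every gene to a leaf annotated with the feature leading
   to it.
7. **Simulate** how a regulator's K_nn evolves under target duplication
   (smooth decay toward 1), regulator duplication (exactly +1 per event),
   and pervasive transcription, starting from a 10-node/9-edge two-hub
   network.

A built-in **duplication–divergence generator** produces labeled synthetic
GRNs (scale-free, hub regulators, ~5% dual-role genes) so every stage is
testable without downloading any database.

## Worked example

```python
from grntopo import (PipelineConfig, SyntheticGRNConfig, run_pipeline)

cfg = PipelineConfig(seed=1, synthetic=SyntheticGRNConfig(seed=1))
res = run_pipeline(cfg)
print(res.selected_attributes)      # ['eccentricity', 'knn', 'page_rank']
print(round(res.power_law.r_squared, 3))   # 0.848  (scale-free check)
print(round(res.test_report.cci, 1))       # 84.6   (% held-out instances correct)
print(round(res.random_test_report.cci, 1))# 44.9   (shuffled-label control)
print(res.comparison["p_value"])           # 0.00216 (Mann–Whitney, normal vs random)
```

On this synthetic network (2319 genes) the CFS subset contains K_nn and
PageRank, the consensus model classifies 84.6% of held-out instances
correctly while the random control sits at chance, and the difference is
significant — the synthetic analogue of the regulator-vs-target separation
seen on curated species GRNs.

The simulator's laws are exact:

```python
from grntopo.knn_evolution import knn_trajectory
knn_trajectory("target_dup:100").knn_series[-1]   # 1.0381  (decays toward 1)
knn_trajectory("regulator_dup:10").knn_series[-1] # 11.8    (+1 per duplication)
```

## Command line

```bash
grntopo simulate --seed 1 --out syn        # synthetic GRN edge + role TSVs
grntopo features syn.edges.tsv             # 13-attribute CSV
grntopo powerlaw syn.edges.tsv             # {"gamma": ..., "r_squared": ...}
grntopo evolve --events target_dup:100     # K_nn trajectory CSV
grntopo run --seed 1 --out run_dir         # full pipeline + manifest.json
```

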