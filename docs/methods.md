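# Methods

This note documents the models, conventions and numerical choices behind
`grntopo`, in the order the pipeline runs them.

## Network model

Interaction lists are directed (regulator → target), but all topology is
computed on the **undirected** simple graph: direction is consumed once, to
assign each gene a role (`regulator` if it only regulates, `target` if it is
only regulated, `both` otherwise), then discarded. Reciprocal pairs collapse
to one edge and both endpoints become `both`. Self-loops are recorded and
excluded from the edge set — a loop would inflate its own node's degree and
contaminate neighbor-degree statistics such as K_nn. Identifiers are
whitespace-stripped and case-folded by default (`casefold=False` disables
this); genome-version name conversion is out of scope. When an evidence
keep-list is supplied, a gene pair survives if *any* of its rows passes the
filter.

## Topological attributes

Thirteen per-gene attributes are computed with networkx (Burt's constraint
via a vectorized sparse-matrix formulation, cross-checked against
`networkx.constraint` in the tests):

| attribute | convention |
|---|---|
| degree, strength | equal on unweighted graphs; both kept for fidelity to the classical feature list |
| K_nn | (1/k)·Σ neighbor degrees, implemented directly from the definition; missing for isolated nodes |
| page_rank | damping 0.85 (the cited graph library's default), configurable |
| eccentricity, closeness | per connected component; closeness unscaled (`wf_improved=False`); missing for isolated nodes |
| eigenvector, hub score | principal eigenvector per component (absolute values); hub score rescaled so the maximum is 1 — on undirected graphs the two coincide up to scaling but both are emitted |
| betweenness | unnormalized |
| coreness | k-core number |
| subgraph centrality | spectral (dense eigendecomposition) |
| burt_constraint | proportional tie strengths p_ij = A_ij/k_i; missing for isolated nodes |
| transitivity_local | local clustering coefficient; missing for degree < 2 |

Undefined values are stored as missing (NaN), never ±inf, so downstream
learning can treat them as "missing information".

Scale-freeness: ordinary least squares of log P_deg(k) on log k over the
non-empty degree classes (probability mass per distinct non-zero degree, no
log-binning); γ is the negated slope, and R² the coefficient of
determination. At least 3 distinct non-zero degree classes are required;
maximum-likelihood fitting with KS tests is deliberately not used — the
quantity of interest here is the R² of the fitted line.

## σ-discretization

Per attribute **and per network** (never pooled across networks), mean x̄ and
standard deviation σ of the non-missing values define five cut points; bins
are A ≤ x̄−2σ < B ≤ x̄−σ < C ≤ x̄ < D ≤ x̄+σ < E ≤ x̄+2σ < F, upper bounds
inclusive, so the mean itself maps to C and the four interior bins have
width exactly σ. Sample SD (n−1) is the default (`ddof` configurable) —
the classical description does not fix this choice. Constant or nearly
empty attributes are degenerate and excluded with a warning. Binning
depends only on z-scores, hence is invariant to affine rescaling.

## Instances and datasets

An *instance* is a (gene, role) pair: dual-role genes contribute one
regulator row and one target row. The test set takes ⌊0.10·#regulators⌋
regulators plus the same number of targets, uniformly at random, so it is
exactly class-balanced. Training targets are shuffled and chunked into
groups of size R (the regulator count); each full chunk joins all R
regulators. The final short chunk of r targets joins a random subsample of
r regulators, preserving exact balance (`drop_remainder=True` discards it
instead) — balance, not set count, is the purpose of the undersampling.
Rows within each set are shuffled before training. Random controls shuffle
only the class column, preserving the label histogram and every feature
cell.

## Feature selection

Entropies are in bits, and missing cells are treated as their own category
everywhere (consistent with how the learner consumes missing values).
Information gain I(attribute; class) ranks attributes (ties broken
lexicographically). CFS scores a subset S of size k by
M_S = k·r̄_cf / √(k + k(k−1)·r̄_ff) with symmetrical uncertainty
SU = 2·I/(H+H) as the correlation; the search is forward best-first with
backtracking via a priority queue, stopping after 5 consecutive
non-improving expansions (configurable). On small attribute counts the
result is verified in tests against exhaustive enumeration. Selection runs
on the whole instance matrix (training plus test) by default, matching the
classical workflow; `select_on="train"` restricts it.

## Tree learning

Trees are C4.5-style: multiway splits on the categorical bins, chosen by
gain ratio (information gain ÷ split information), with a split admissible
only when at least two branches hold ≥ `min_leaf` (default 20) instances
and gain is positive. Pruning is pessimistic-error subtree replacement at
confidence 0.25, using the classical normal-approximation upper confidence
bound on the leaf error rate. Two deliberate simplifications of the
original J48 mechanics, chosen for determinism and documented rather than
hidden: missing values are routed down the majority child (not split into
fractional instances), and no subtree raising is performed.

Leaf probabilities are Laplace-smoothed; prediction ties resolve to
"regulator". The consensus model averages member-tree probabilities.
Performance metrics: CCI (% correct), TPR, 1−FPR, MCC, ROC area
(trapezoidal) and PRC area (trapezoidal over the precision–recall curve),
with stratified k-fold cross-validation (fold count capped by the minority
class size). Normal-vs-random comparison applies Shapiro–Wilk per group and
a two-sided Mann–Whitney U test; the pipeline compares per-set
cross-validated CCIs because the synthetic held-out set is small and
per-tree test scores are heavily tied, which would starve the U test of
resolution.

The consensus *rule tree* merges member trees top-down: at each context,
member trees vote with the attribute they test there (trees already
resolved through assigned values); the modal attribute wins if it reaches
the majority fraction (default 0.5), otherwise the node collapses to a leaf
with the pooled class counts. Every path tests an attribute at most once.
Instances routed to leaves are grouped by (leading feature × class).

## K_nn evolution simulator

The start state is a 10-node/9-edge network: two degree-5 hubs joined by an
edge, each with four degree-1 neighbors; the focal regulator's
K_nn = (4·1+5)/5 = 1.8. Events: target duplication (and pervasive
transcription, modeled identically) adds a degree-1 neighbor to the focal
node, so (k,S) → (k+1, S+1) and K_nn decays strictly toward 1 whenever
S > k; regulator duplication copies the focal node's links, incrementing
every neighbor's degree, so K_nn increases by exactly +1; duplicating a
different hub raises the focal K_nn through the shared edge. The duplicate
is **not** linked to the focal node by default (the drawn topology is
ambiguous; the no-link choice yields the clean +1 law) — `link_duplicate=True`
adds the edge and is covered by tests. Incremental (k, S) bookkeeping is
re-verified against brute-force recomputation from the graph at every step.

## Synthetic GRN generator

Growth is duplication–divergence, not plain preferential attachment,
because duplication with partial inheritance of ancestral interactions is
the evolutionary process the analysis itself studies. From a small
bipartite seed motif, each step duplicates a random target
(p = 0.65; the copy inherits each regulator link with retention ρ,
at least one kept), duplicates a random regulator (p = 0.10), or adds a
fresh regulator→target edge (p = 0.25). Afterwards 5% of targets are
promoted to dual-role genes (one outgoing regulation each), echoing the
~4% dual-role share of curated data. Defaults: 5 regulators + 10 targets
seed, 3000 growth steps, ρ = 0.5. ρ was fixed during generator calibration
at the value giving ~3.5 edges per node — the density order of curated
species GRNs — with power-law R² ≈ 0.83–0.86 and regulator mean degree an
order of magnitude above target mean degree. Typical networks have ~2300
genes, ~390 regulator-role genes and ~8200 edges; the full pipeline on one
runs in well under a minute on one CPU.

**What the generator does not emulate:** evidence-label noise, false
positive/negative interactions, species-specific degree-distribution
shapes, autoregulation, or modular/GO structure. Passing tests therefore
show that the pipeline recovers a planted hub-regulator signal of realistic
scale — not that any particular organism's network will classify at the
same accuracy.

## Degenerate inputs and tie-breaks

Empty networks, all-missing or constant attributes, fewer than 3 degree
classes, and stratification-impossible fold counts raise explicit errors.
Ties: attribute ranking and split selection break lexicographically by
name; prediction ties go to "regulator"; the consensus-root vote breaks by
(count, name). Identical constant score groups make the U test undefined
and are reported as such rather than forced to a number.

## Known limitations

* The tree learner is a faithful re-implementation of the gain-ratio/
  pessimistic-pruning family, not a bit-for-bit port of any toolkit;
  absolute leaf counts can differ from other implementations.
* The Mann–Whitney comparison has limited power when the undersampling
  yields few balanced sets (small regulator pools).
* GO-term retrieval and enrichment of leaf gene sets are out of scope; leaf
  gene lists are exported for external tools.
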