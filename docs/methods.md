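# Methods

## Statistical model

### Normalization

All cohorts are reduced to a common log2 scale before testing. Counts are
transformed as log2(count + 0.5); the 0.5 offset keeps zeros finite and
matches the usual precision-weighting convention for logged counts.
Intensity matrices are assumed log-scaled already unless their maximum
exceeds 30, in which case log2(x + 1) is applied first — a heuristic for
linear-scale microarray exports, since mixed-platform inputs arrive in
unknown scale. Quantile normalization then forces every sample column onto
the vector of row-rank means. Ties within a column are assigned by stable
row order rather than tie-averaging: this keeps the transform exactly
idempotent and deterministic, at the cost of an arbitrary (but fixed)
allocation among tied entries.

### Moderated t-test

The two-group test shrinks per-gene variances towards a prior fitted
across all genes of the cohort. With pooled within-group variance s²_g on
d_g = n₁ + n₂ − 2 degrees of freedom, the prior (d₀, s₀²) is obtained by
matching the first two moments of log s²_g against the scaled-F model
s²_g ~ s₀²·F(d_g, d₀): the excess of var(log s²_g) over trigamma(d_g/2)
determines d₀ through a Newton inversion of the trigamma function, and
the mean determines s₀² with the chi-square log-bias correction
exp(log(d/2) − digamma(d/2)). Degenerate inputs are handled explicitly:
if the observed variances carry no excess spread, d₀ = +∞ and the test
uses the fully pooled variance (a notice is logged); non-positive
variances are excluded from the fit; a gene with zero residual variance
and zero effect gets t = 0, p = 1 by definition. Setting the prior
degrees of freedom to 0 recovers the ordinary pooled two-sample t exactly,
which the tests exploit as a limiting-case oracle.

DEG calls use strict inequalities p < 0.05 and BH-FDR < 0.1, with no
fold-change cutoff. BH adjustment is delegated to
`statsmodels.stats.multitest.multipletests`; the test suite checks it
against a brute-force step-up oracle on short p-vectors.

### Consensus

The consensus universe is the intersection of tested gene sets across all
cohorts after ortholog mapping: a gene absent from any cohort cannot be
consistently regulated in all comparisons, so it is excluded rather than
imputed. Ortholog mapping keeps only strict 1:1 pairs (a gene mapping to
several targets, or sharing a target, is dropped); this conservative rule
keeps the cross-cohort intersection well defined. Consensus-up genes are
the all-up rows of the direction matrix, consensus-down the all-down rows;
any `none` or sign conflict excludes the gene. Because cohorts are
independent, the probability of a gene passing in all of them by chance is
the product of the per-cohort probabilities — the intersection is the
meta-analysis; no p-value combination is performed.

### PIEA (protein-interaction enrichment analysis)

Each gene with strictly more than `min_degree` (default 5) in-background
interactants is scored by treating its one-step neighborhood (proper
neighbors, the focal gene excluded) as a gene signature and testing its
overlap with a DEG set via the hypergeometric upper tail
P(X ≥ k | N, K, n), BH-corrected across all tested hubs. The background is
the consensus universe intersected with the network's nodes, which keeps
the sampling null coherent with the genes that could have been called.
A master regulator must additionally be a member of the consensus set
whose regulation it is supposed to drive — enrichment of a hub's
neighborhood alone is not sufficient. The regulator FDR cut defaults to
0.05 and is configurable.

### Signature enrichment

Signatures are restricted to the explicit background universe before
sizing (members outside the background are ignored, so the expected count
e = nK/N and O/E = k/e are always well defined); signatures with no
background member are not tested. The multiple-testing family is the full
supplied collection. Reported signatures must pass FDR < 0.01 **and**
O/E > 1.5, both strict; the unfiltered table is always emitted alongside.
The background is an input, never a hard-coded genome size. The
hypergeometric tail is computed through `scipy.stats.hypergeom.sf`, which
works in log-space and remains accurate for backgrounds well beyond 1e5
genes; the test suite pins it against exact rational enumeration for all
parameters with N ≤ 25.

### MCODE

Vertex weight = k × density of the highest k-core of the closed
neighborhood; complexes grow greedily from the highest-weight unused seed,
absorbing neighbors whose weight exceeds seed_weight × (1 − vwp)
(vwp = 0.2 by default), with no node reuse. The haircut step keeps the
2-core of each complex (if the 2-core disconnects, the seed's component is
kept). Complexes smaller than 3 nodes are discarded; fluff is not
implemented. Scores are density × size. All tie-breaks (equal-weight
seeds, equal-score complexes, neighbor iteration) are lexicographic on
gene id, making the output independent of node insertion order.

### Overlap validation

Consensus sets are matched against an external cohort's up/down DEG lists
over the shared tested universe; only direction-concordant overlaps count
as matches (discordant overlaps are reported informationally). Each
direction gets a hypergeometric overlap p with the shared universe as
background.

## Synthetic-data generator

The generator emulates a five-cohort diploid/polyploid study: per-cohort
platforms alternate intensity (microarray-like) and counts (RNA-seq-like),
two cohorts are "mouse" and reach the shared namespace only through an
emitted ortholog table (95% strict 1:1; the remainder one-to-many to
exercise the dropping rule, always chosen among unplanted genes so the
planted signal survives mapping).

* **Counts model**: gene abundance log2-mean ~ N(8, 1.5) (median ≈ 256
  counts, an ordinary bulk-library depth), negative binomial with
  dispersion 0.05 + 2/mean — a 1/mean trend approaching a floor of 0.05,
  the shape assumed by variance-trend moderation.
* **Intensity model**: Gaussian on the log2 scale, gene baseline ~ N(7,
  1.5), per-gene residual sd ≈ 0.15–0.6 so the variance prior has spread
  to shrink.
* **Planted signal**: 50 up + 50 down genes shifted by ±2.0 log2 units in
  the polyploid group of every cohort; 30 cohort-private noise DEGs per
  cohort with random sign, disjoint from the planted sets.
* **Network**: preferential attachment (m = 3) over all genes; 10 planted
  hubs are rewired to neighborhoods of 20 genes, 80% drawn from the hub's
  own planted direction set. Hubs are excluded from each other's
  neighborhoods so later rewiring cannot sever an earlier hub.
* **Signatures**: 100 sets of size 20–60; 10 are planted-enriched (half
  towards planted-up, half planted-down, 50% of members from the planted
  set), the rest uniform draws.

One integer seed fans out through `numpy.random.SeedSequence` children
with fixed indices per component, so cohorts, network, signatures and
ortholog map are each reproducible in isolation and all emitted files are
byte-identical across runs. An extra held-out validation cohort (human,
counts) carrying the same planted signal feeds the overlap stage.

What the generator does **not** emulate: library-size variation and
batch effects within a cohort, correlated gene-gene expression, realistic
pathway topology (complex detection on synthetic consensus sets typically
finds 0–2 small complexes, since no dense planted modules exist), probe-
level microarray artefacts, or single-cell sparsity. Passing recovery
tests therefore demonstrates the statistical machinery is correct under
the stated models, not that any particular real cohort would behave this
way.

## Calibration checks and discreteness

Hypergeometric p-values are discrete and therefore sub-uniform under the
null: P(p < α) ≤ α, with equality only when the overlap distribution is
fine-grained. The calibration tests account for this honestly:

* **Enrichment null**: the empirical rejection rate over random queries is
  compared with the *exactly computed* null rejection probability
  Σ_sig P(p_sig < α) (within 3 standard errors), plus the validity bound
  rate ≤ α. Measured at α = 0.05 the exact null rate is ≈ 0.03 for the
  default signature sizes.
* **PIEA null**: under degree-preserving edge rewiring, raw p-values have
  a large point mass at 1 (most neighborhoods miss the DEG set entirely),
  so uniformity is checked on the randomized p-value
  u = P(X > k) + U·P(X = k), which is exactly Uniform(0,1) under a
  calibrated null. The KS bound (0.12) was frozen from a 20-seed null run
  (mean 0.062, max 0.084); the excess over iid KS sampling noise reflects
  dependence between overlapping neighborhoods.
* **Moderated-t null**: with zero planted effect the mean fraction of
  genes at p < 0.05 across seeds is 0.05 ± 0.01 (measured ≈ 0.051 for
  both platform models).

## Problem sizes

Default study design: 5 cohorts × 2000 genes × 12 samples; network of
2000 nodes / ~6000 edges; 100 signatures. A full pipeline run takes a few
seconds on one CPU; the complete test suite (including the exhaustive
N ≤ 25 oracle sweep and 1000-seed BH comparison) runs in well under a
minute. These sizes give the recovery and calibration tests adequate
power while keeping runs interactive.

## Known limitations

* Quantile normalization's stable-tie rule differs from tie-averaging
  implementations in the low-information case of exactly tied values.
* The unlogged-intensity heuristic (max > 30) misclassifies genuinely
  log-scale data with extreme dynamic range, and linear data whose maximum
  happens to be below 30.
* PIEA treats neighborhoods as independent signatures; overlapping
  neighborhoods make the BH correction slightly conservative-to-anticonservative
  depending on topology.
* The MCODE haircut/expansion follows the published greedy scheme; it is
  not an optimal densest-subgraph decomposition, and fluff is not offered.
* The ortholog rule discards all non-1:1 homology, which is conservative;
  many-to-many families are simply invisible to the consensus.
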