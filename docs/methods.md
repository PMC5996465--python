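# Methods

This note documents the models, estimators, parameter choices and known
limitations behind `cdrenet`, in the order the pipeline runs.

## Expression preprocessing

Input matrices are nonnegative abundance tables (features × samples), one
per feature class (miR / gene) and condition. The miR and gene matrices of
a condition are intersected on sample IDs (canonical order: the miR
matrix's column order; a minimum of 10 shared samples, configurable) and
log2-transformed with a pseudocount (default 1.0, the usual choice for
nonnegative abundances). No further normalization is applied: the MI
estimator bins each profile by rank, so it is invariant to any monotone
per-feature transform, and cross-sample normalization of real data is
deliberately left to upstream tooling.

Per-feature log2 fold change, `LFC(f) = log2((mean_B + c)/(mean_A + c))`,
is a deliberately simple mean-ratio substitute for a full differential
expression model. It is carried as a node annotation only (for coloring
network exports); nothing in edge retention or Commodore classification
depends on it.

## Mutual-information network

* **Estimator.** Equal-frequency (quantile) binning with
  `n_bins = ceil(sqrt(n_samples))` capped at 20 (15 bins at the default
  200 samples), followed by the plug-in estimate
  `MI = H(x) + H(y) − H(x,y)` on the empirical histograms, in bits. Ties
  receive the bin of their lowest rank, so binning is deterministic and a
  constant profile maps to a single bin — which makes MI of any
  zero-variance feature exactly 0 (flagged in the log, never an error).
  No bias correction is applied: the plug-in bias
  `≈ (n_bins−1)²/(2·n·ln 2)` is common to every pair at fixed `n` and bin
  count, and the edge filter only *ranks* pairs, so the bias cancels where
  it matters. Entropy terms sum sorted probabilities, making
  `MI(x,y) = MI(y,x)` bitwise exact and `MI(x,x)` exactly the binned
  entropy.
* **Edge filter.** The retention quantile `q` (default 0.99741) keeps the
  top `floor((1−q)·N)` pairs of the all-pairs MI distribution, with ties at
  the cutoff all retained. The alternative literal reading — keeping
  99.741 % of pairs — would retain nearly every pair and produce networks
  whose edge counts are wildly inconsistent with the reference
  node/degree figures, so the percentile reading is the default; `q` is a
  parameter, so either reading can be run. The quantile is computed per
  condition (per network), not pooled across conditions.
* **Graph representation.** Edges are semantically directed miR → gene,
  but every topology metric used is undirected, so the graph is stored as
  an undirected bipartite `networkx.Graph`; the direction is recorded as an
  edge attribute in GML exports (MI as `value`, rounded to 6 decimals).
  Nodes enter the graph only as endpoints of retained edges.

## Bipartite topology metrics

Degree distributions are computed per node class (`P(k) = n_k/n` over that
class), since the two layers' connectivities differ by construction.

The bipartite clustering coefficient of `u` is the mean Jaccard overlap
between `N(u)` and `N(v)` over all second neighbors `v ∈ N(N(u))`, with
`u` itself excluded from `N(N(u))` (the standard convention; the sum uses
`math.fsum`, so the value is independent of iteration order). Nodes with
no second neighbors have *undefined* clustering.

The redundancy coefficient of `u` is the fraction of its
`k(k−1)/2` neighbor pairs co-covered by at least one other node;
it is undefined for degree < 2. Undefined values propagate as NaN and are
**excluded** from class means (not coerced to 0); this choice affects
reported averages and is therefore stated here and in the summary layer.
Connected components are counted on the bipartite graph as a whole.

Both coefficients are validated in the test suite against (a) literal
brute-force enumeration of their set definitions and (b) the independent
`networkx` implementations (`latapy_clustering(mode="dot")`,
`node_redundancy`).

## Commodore classification

miRs are partitioned by a degree threshold (default 100) and a redundancy
threshold (default 0.5). Comparisons are strict (`k > 100`, `rc < 0.5`) —
the inclusive variant is exposed as a flag, since the convention at the
exact boundary is not fixed by the method itself. miRs with undefined
redundancy are labeled `excluded` and can never be Commodores. Raising the
redundancy threshold or lowering the degree threshold is monotone: it can
only add Commodores. Neighborhoods are first gene neighbors; pairwise
neighborhood intersections are reported with counts and percentages of
each parent neighborhood.

## Over-representation analysis

Exact hypergeometric upper tail `P(X ≥ k)` (`scipy.stats.hypergeom.sf`)
for a query of `n` genes against a category of `K` genes in a universe of
`N`; BH adjustment (`statsmodels`) across all tested categories; category
sizes restricted to [5, 2000] after universe restriction; results ordered
by adjusted then raw p. The universe is the annotation catalog's gene set
intersected with the measured genes — the catalog-side choice, since the
"true" background of any external ORA service is unknowable. Intersection
enrichment (every Commodore pair's shared gene set) is a first-class step,
because a process can be jointly controlled by two Commodores without
being enriched in either neighborhood alone. No ontology-graph
propagation or redundancy reduction is applied.

## Synthetic data generator

The generator emulates the *structure* the analysis assumes, not any
particular dataset's marginals:

* miR profiles are log-normal (latent standard Gaussian, exponentiated).
* A **Commodore** regulon couples each of its target genes to its
  regulator on the log scale: `g = sign·c·m + σ·ε` with coupling `c`
  (default 0.8), noise sd `σ` (default 0.5) and `sign = −1` by default
  (canonical miR repression; configurable). Target blocks are exclusive —
  no other planted regulator touches them.
* A **redundant group** (default triplets) shares one latent factor;
  members are `factor + 0.3·jitter` and targets couple to the factor. Each
  member–target pair therefore carries essentially full coupling strength,
  which is what makes every member individually dispensable (redundancy
  ≈ 1). Coupling targets to the *mean* of independent members would
  dilute per-member dependence by `1/group_size` and the group edges would
  not survive a top-0.259 % filter; the shared-factor design is also the
  more biologically natural model of a co-expressed miR family.
* Condition A expresses only the redundant groups; condition B
  additionally activates the Commodores. Unregulated genes are pure noise.

Default dimensions are 100 miRs × 3500 genes × 200 samples per condition,
with 3 Commodores (150 targets each) and 2 redundant triplets (60 shared
targets each). The dimensioning is deliberate: 350,000 pairs at the
default quantile retain ~906 edges, commensurate with the ~810 planted
pairs, so the planted structure is recoverable at the pipeline's default
filter setting and Commodore degrees (~150) clear the degree-100 threshold
with margin. All randomness flows from one seed through spawned
substreams; identical configs give bit-identical matrices.

What the generator does **not** emulate: count noise (negative binomial
dispersion), library-size and batch effects, correlated background
structure, or realistic effect-size distributions. Passing the synthetic
benchmark therefore demonstrates that the pipeline recovers the structure
it is designed for under clean, well-separated signal — not that it would
achieve the same precision on real tumor data, where coupling strengths
are weaker and confounding is pervasive.

## Numerical and degenerate-input conventions

* Quantile filter cutoff index uses `floor((1−q)·N)` with a 1e-9 epsilon
  so float rounding cannot drop the last edge of an exact-real count; with
  all-tied MI values the tie rule retains everything.
* Empty networks summarize to zero counts with NaN means; empty node
  classes and empty value lists are domain errors.
* ORA of an empty (post-universe) query is a domain error; categories
  outside the size window are silently excluded (logged).
* All tabular outputs use fixed float formats, and iteration orders are
  sorted, so pipeline bundles are byte-identical across reruns of the same
  config.

## Problem sizes used in the packaged checks

The test suite exercises small instances (≤ 15 nodes per class for the
brute-force metric oracles; 12 × 120 features for generator properties)
plus the full default synthetic conditions for recovery checks (10 seeds
in the acceptance checks, 2 seeds for the redundancy-separation property).
The acceptance script runs 10 full-scale synthetic seeds and a 10⁶-pair
filter calibration; these sizes were chosen to make every stochastic claim
reproducible in minutes on a single core.

## Known limitations

* The MI estimator is the binned plug-in; kernel or k-NN estimators may
  rank borderline pairs differently. Bin count and estimator parameters
  are configurable but only the plug-in is implemented.
* The percentile filter's quantile is a free parameter with a large
  effect on network size; the default encodes the top-0.259 % reading
  discussed above.
* Averages over clustering/redundancy exclude undefined nodes; analyses
  that coerce undefined values to 0 will report different class means.
* LFC is a mean ratio, not a shrunken model-based estimate; it is
  annotation-only by design.
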