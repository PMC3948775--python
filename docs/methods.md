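# Methods

## Model and procedure

The unit of analysis is an *edge*: an unordered gene pair connected in a
prior interaction network, annotated with the pathways in which the
interaction occurs. Given a gene × sample read-count matrix with a
two-group design (labels written LA/HA throughout; any pair of labels
works and is mapped onto these positions in reverse-alphabetical order),
the pipeline proceeds:

1. **Trim.** The network is restricted to genes present in the expression
   data (induced subgraph). Reading the network TSV deduplicates repeated
   and reversed pairs by pathway-set union and drops self-loops; both the
   raw row count and the deduplicated edge count are reported, since
   interaction databases routinely list one relation under several
   pathways.
2. **Normalize.** Counts become log2 counts-per-million,
   `log2((c + 0.5)/(L + 1)·10⁶)` with L the sample's library size (column
   sum). This is the log transform used by limma's voom. Observation
   weights from the voom mean–variance trend (lowess of √sd against mean
   log-count, weight = trend⁻⁴) are computed on request for diagnostics
   only: the downstream statistic is a plain Pearson correlation, and
   nothing in the procedure consumes weights, so results are invariant to
   the lowess span (default 0.5).
3. **Edge statistics.** Within each group, the Pearson correlation r of
   the edge's two genes; Fisher z = arctanh(r); the difference
   `z_diff = z_LA − z_HA`. Orientation is a convention — all inference
   uses |z_diff|. With five samples per group |r| = 1 occurs; r is clamped
   at 1 − 10⁻⁷ so z stays finite and perfect correlations rank above all
   others. A zero-variance gene in a group makes the edge's correlation
   undefined; such edges are flagged invalid and excluded rather than
   imputed (imputing r = 0 would fabricate a large difference).
4. **Permutation null.** Sample-to-group labels are reshuffled without
   replacement, preserving group sizes, N times (default 10,000) on the
   fixed normalized matrix — normalization is not redone per permutation,
   since library sizes do not depend on labels. Every edge receives its
   own null sample of z_diff values and of pseudo-group correlations.
   Empirical p-values are two-sided counts `#{|null| ≥ |obs|}/N`
   (`count_over_N`); an `add_one` mode `(1+count)/(N+1)` is available when
   exact zeros are unwanted. An edge is significant iff (i) p(|z_diff|) <
   α and (ii) at least one group correlation has p < α against the pooled
   permuted correlations of that edge (the two pseudo-groups are
   exchangeable under reshuffling, so pooling both doubles the null
   sample). α defaults to 0.05.
5. **Classification.** The significant group's correlation defines the
   driver; the label is `<driver>_<sign>` with suffix `_significance`
   when the other group's correlation agrees in sign (dashed line in the
   visual convention) and no suffix when it opposes (solid line). Colors:
   HA-positive red, HA-negative light green, LA-positive green,
   LA-negative orange. When both groups pass criterion (ii) the driver is
   the one with the smaller correlation p-value (ties: larger |r|, then
   HA); a driver r of exactly 0 counts as positive and a non-driver r of
   0 as sign-agreeing — both degenerate cases are logged.
6. **Enrichment.** For each pathway, the upper tail
   P(X ≥ k), X ~ Hypergeometric(M, K, n), where M = annotated edges in
   the trimmed network, K = those in the pathway, n = annotated
   significant edges, k = significant edges in the pathway; multi-pathway
   edges count toward every pathway they carry. BH correction across
   pathways, enrichment at p-adj < 0.05, and each record reports the
   LA-/HA-driven split of its k edges. A `paper_compat` tail mode computes
   1 − P(X ≤ k) = P(X > k) instead, reproducing the off-by-one that the
   one-minus-lower-tail idiom applied to R's `phyper` produces; the
   standard tail is the default because P(X ≥ k) is the correct
   over-representation probability.
7. **Export.** Significant network and enriched-pathway subnetwork as
   GraphML and Cytoscape-compatible XGMML, with per-edge attributes
   (correlations, p-values, type, color, line style, pathway ids, raw
   counts) serialized as strings at 15 significant digits so files
   round-trip exactly; a JSON manifest carries all summary counts and the
   resolved configuration.

## Synthetic data

The generator emulates the target study design: two groups of five
samples, a pathway-annotated network of hundreds to ~16,000 edges
(`paper_scale_spec()` gives 2,871 genes / 15,960 edges / 197 pathways),
and counts that are marginally negative binomial with library-size
variation.

Counts are drawn through a Gaussian copula: per group, latent gene
vectors ~ MVN(0, C) where C embeds the planted per-edge correlations
(identity elsewhere); each latent value maps through the standard normal
CDF and the inverse CDF of NB(μ_g·s_j, φ), with gene base means μ_g
log-normal (meanlog 4, sdlog 1.5 — median ≈ 55 counts with the heavy
right tail of bulk RNA-seq), dispersion φ = 0.1 (biological CV ≈ 0.32,
typical for tissue replicates), and per-sample factors s_j set so column
sums track library sizes drawn uniformly from [0.8, 1.2]·10⁶. When
planted edges share genes, C is repaired by eigenvalue clipping to the
nearest usable correlation matrix; the Frobenius repair delta is checked
and a distortion above 0.5 is an error rather than a silent change of
truth.

The planted correlation is specified on the *latent* scale. The
attenuation to count-scale (and log-CPM-scale) Pearson correlation is a
property of the copula that the tests measure rather than assume: at
ρ = 0.9 with 1,000 samples per group, the observed log-CPM correlation
lands within 0.9 ± 0.06.

What the generator does **not** emulate: gene-length and GC effects,
count outliers, batch structure, mean–variance trends beyond the single
global φ, and correlation induced through shared pathway membership
rather than planted edges. Passing tests therefore demonstrate that the
statistics, filters and bookkeeping behave as specified under a clean NB
model — not that the pipeline's error rates transfer to any particular
real dataset.

## Calibration and error rates

With both groups drawn from one correlation structure, the z-difference
test rejects at its nominal rate (measured 0.03–0.06 at α = 0.05 across
seeds; the test suite checks one fixed seed at 200 edges and 1,000
permutations).

The two-criterion filter controls the per-edge false-positive rate, **not
the FDR**. With 20 truly rewired edges among 200 at α = 0.05, ~8 of the
180 null edges pass criterion (i) by construction while power on strongly
planted edges approaches 1, so the expected FDR of the detected set sits
near 0.3. Criterion (ii) barely filters at 20 samples per group: any edge
with a permutation-significant |z_diff| necessarily shows at least one
|r| ≈ 0.35+, which at that sample size (null r sd ≈ 0.23) is itself
significant. At five samples per group (null r sd ≈ 0.5) criterion (ii)
is a real filter of weak–opposite correlation pairs, which is the design
it was written for. Users who need FDR control across edges should treat
the empirical p-values with a BH step; the pipeline deliberately reports
raw empirical p at the edge level, matching its inferential design.

## Numerical and design choices

- **z_diff orientation** is first-minus-second group (LA − HA under the
  default label ordering); the sign is never used for inference.
- **Group-label swap invariance**: permutations are drawn on the pooled
  sample columns in canonical matrix order, so with equal group sizes
  relabeling the groups reproduces the identical null and significant set
  bit for bit; with unequal sizes the invariance is distributional only.
- **Determinism**: every stochastic step derives from one seeded
  `numpy.random.Generator`; the permutation assignment matrix is
  precomputed, so chunking across workers (threads) cannot change
  results. Identical config + seed yields byte-identical bundles.
- **p = 0** is possible in `count_over_N` mode (the formula divides the
  exceedance count by N); `add_one` is offered for downstream consumers
  that cannot accept zero.
- **Edges vs genes** as the enrichment unit: the question asked is
  "which pathways concentrate rewired *interactions*", so M, K, n, k all
  count edges; unannotated edges are outside the universe and excluded
  from n.
- **Normalization scope**: the two groups are normalized jointly (one
  library-size scale), the standard usage; per-group normalization would
  make correlations incomparable across groups.
- **Default problem sizes in tests** (50–300 genes, 200–1,000
  permutations) are chosen so the full suite exercises every stage,
  including a complete 2,871-gene / 15,960-edge run at 100 permutations,
  in seconds; production runs use the 10,000-permutation default.

## Known limitations

- Pearson correlation at n = 5 is extremely noisy; the permutation
  framework makes the p-values honest but cannot create power that the
  sample size does not contain.
- Correlations are marginal, not partial: an edge can rewire because a
  shared neighbor rewired.
- The hypergeometric universe treats edges as exchangeable draws,
  ignoring network topology (hub edges are not down-weighted).
- KEGG relation directionality is discarded (the statistic is symmetric
  in the pair).
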