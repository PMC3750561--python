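# Methods

## The model

`pathscape` profiles pathway-level aberrations of individual tumour
samples from gene expression log ratios measured against a common
reference. The method makes one deliberately weak assumption: if a
pathway is functionally altered in a sample, its member genes tend to sit
unusually high (enrichment) or unusually low (depletion) in that sample's
ranked gene list. Nothing else about the pathway — topology, direction of
individual edges, magnitude of individual fold changes — is used.

### The rank-walk AUC statistic

For one sample, all `n` measured genes are ordered from most up- to most
down-regulated (exact ties broken by ascending gene symbol so the order is
total and deterministic; missing values drop the gene from that sample's
list). Walking down the list, member genes of a pathway of effective size
`m` are labelled 1 and non-members 0; plotting the running fraction of 1's
against the fraction of 0's gives a step curve whose area is

    AUC = (1 / (m·(n − m))) · Σ_{members i} #{non-members ranked below i},

the normalized Mann–Whitney concordance between members and non-members.
AUC = 1 iff all members precede all non-members; walking the reversed list
yields the depletion AUC, and because the order is strict,
`AUC_enr + AUC_dep = 1`. Internally an AUC is represented by the integer
sum of member ranks, so all observed-vs-null comparisons are exact integer
comparisons with no floating-point tie ambiguity.

### Permutation confidence

Significance is empirical. The null redraws the `m` member positions
uniformly from the `n` ranks (equivalent to permuting the gene list, but
cheaper) `B` times, and

    p = (1 + #{null AUC ≥ observed AUC}) / (B + 1).

The add-one estimator keeps `p` in `[1/(B+1), 1]`, so `log2 p` is always
defined. `B = 1000` by default: the resolution of the resulting score is
about `0.001`, adequate for a call threshold of 0.05, and scoring stays
cheap. No multiple-testing correction is applied anywhere in scoring or in
the association scans — an intentional choice for an exploratory profiling
method; Benjamini–Hochberg columns are emitted alongside scan outputs as a
supplementary aid only.

The null distribution of the AUC depends only on `(n, m)`. The scorer
therefore derives one RNG stream per `(n, m)` pair (seeded from the user
seed plus `(n, m)`) and caches the sorted null rank sums for the whole
cohort pass. This is distributionally identical to redrawing per sample
and pathway, makes the output exactly invariant to sample column order and
to any strictly monotone per-sample transform of the expression values,
and reduces the cost of scoring a cohort to one null draw per distinct
effective set size. The standalone `permutation_pvalue` draws fresh nulls
on every call; the calibration checks use it with an independent seed per
simulated pair, because p-values sharing one cached null sample are
conditionally dependent and a uniformity test would otherwise measure the
null sample's own Monte-Carlo error rather than calibration.

### Combined signed profiles and calls

Per (sample, pathway) the smaller of the enrichment and depletion
confidences is kept and mapped to `log2 p` for enrichment and `−log2 p`
for depletion (ties to enrichment). Strongly negative values mean
enriched, strongly positive depleted; with `B = 1000` the extremes are
`∓ log2(1001) ≈ ∓9.97`. Discrete calls at threshold `alpha` (default
0.05): ENRICHED iff `p_enr < alpha` and `p_enr ≤ p_dep`; DEPLETED iff
`p_dep < alpha` and `p_dep < p_enr`; otherwise NEUTRAL.

Because the statistic is competitive (members are compared against all
other genes of the same sample), a strong genuine enrichment of one gene
set slightly depresses the ranks of every other gene: with 50 of 2000
genes shifted by +1 sd, unrelated sets show a mildly inflated depletion
call rate (≈0.06–0.08 at alpha 0.05) while their enrichment call rate
drops below alpha. This is a property of competitive single-sample
statistics generally, not of the permutation scheme, and is why the
planted-signal checks measure false calls of the planted direction.

## Gene-set handling

GMT collections are uppercased, deduplicated within sets, optionally
mapped through an alias table to a common symbol namespace, restricted to
the measured-gene universe, and filtered to effective sizes in
`[10, 1000]`. Sizes are counted after universe intersection because the
null depends only on members actually present in the ranked list. Set
topology is ignored throughout.

## Quality control

Quantile normalization (each column mapped onto the mean of order
statistics; ties receive the mean of the reference values at their tied
ranks) and PCA screening operate on a copy of the matrix used only for QC:
the scoring engine ranks each sample internally, so cross-sample
normalization cannot change scores, and it consumes the raw log ratios.
Duplicate handling keeps the lexicographically first sample per patient
id, removes blacklisted patients unconditionally, and reports — but does
not remove — cross-patient pairs with Pearson correlation ≥ 0.99.
Missing values are excluded from ranked lists (scoring) and mean-imputed
per gene (PCA only). One caveat: the stated tie rule makes quantile
normalization exactly idempotent only on tie-free columns; a tied column
collapses to a shared mean that a second pass cannot undo.

## Subgroup discovery

Samples are clustered on their combined signed profiles with Euclidean
distance and Ward linkage (scipy's implementation; merge heights are in
scipy's Ward distance units). Branch extraction descends from the root
splitting any cluster larger than `max_size` (default 30) and then merges
clusters smaller than `min_size` (default 20) into the nearest remaining
cluster by centroid distance; `k_override` replaces this with the standard
k-cluster cut when a fixed subgroup count is wanted. Cohorts are compared
by clustering mean profiles; subgroups across cohorts by clustering
feature vectors made of per-pathway enrichment frequencies concatenated
with depletion frequencies.

## Clinical association

Subgroup-vs-rest survival uses Kaplan–Meier estimators and the unweighted
Mantel-Cox log-rank test (lifelines), with `event = False` meaning right
censoring at `time`; subgroups with fewer than two usable records are
skipped. Label enrichment uses the two-sided Fisher exact test
(probability-mass ordering) and differential expression the two-sided
Wilcoxon rank-sum test, exact when both groups have ≤ 12 untied values
and normal-approximated with tie correction otherwise. All scans report
uncorrected p at `alpha = 0.05`.

## The synthetic cohort generator

The generator emulates the structure the pipeline assumes: per-gene log
ratios against a common reference; multiple cancer types with distinct
sparse baselines (10% of genes shifted ±1, enough for PCA to separate
cancers); planted subgroups whose designated pathways' member genes are
coherently shifted by `+δ` (enrichment) or `−δ` (depletion); Gaussian
noise of sd `σ` on the log-ratio scale; near-duplicate samples (noise
σ/10) sharing a patient id; exponential survival with subgroup-dependent
hazard and uniform censoring calibrated to a target censored fraction.
All generators are bit-reproducible given their seed.

The canonical study design used by the validation suite and the
acceptance script is: 3 cancers × 100 samples, 2000 genes, 200 disjoint
gene sets of 20–100 genes, 3 subgroups per cancer (34/33/33), 8 planted
pathway aberrations per subgroup (alternating enrichment/depletion),
`δ = 1.0`, `σ = 1.0`, two injected duplicates, one hazard-ratio-3 subgroup
per cancer, 20% censoring. Scoring uses `B = 200` end-to-end and
`B = 1000` for the single-pathway detection checks. These sizes keep a
full validation run in well under a minute while leaving the per-test
statistics (KS bands, binomial bands, Monte-Carlo standard errors) sharp
enough to detect real defects.

What the generator does **not** emulate: probe-level array artifacts,
Lowess normalization residuals, batch effects, correlated gene-gene noise
within pathways, heavy-tailed expression noise (a config switch away from
Gaussian is deliberately not provided), or realistic overlap structure
between gene sets. Passing tests therefore demonstrate the statistical
machinery — calibration of the null, recovery of coherent shifts,
correctness of the clustering and survival plumbing — not performance on
real tumour cohorts, where correlated noise typically inflates single-
sample enrichment calls relative to the independent-gene null.

## Numerical choices and degenerate inputs

- AUC comparisons are integer rank-sum comparisons; the permutation p of
  an arbitrary (off-support) observed AUC uses a half-ulp guard when
  mapping it to the rank-sum grid.
- `m = 0` or `m = n` makes the statistic undefined and is an error, as is
  a single-sample quantile normalization or an empty group in frequency
  computation.
- Ranked-list ties break by ascending gene symbol; cluster-height ties
  follow scipy's deterministic merge order; duplicate resolution keeps the
  lexicographically first sample id.
- Zero-variance PCA inputs report explained-variance 0 rather than NaN.
- Survival times are clamped to a strictly positive floor (1e-9 days) so
  degenerate draws cannot violate the positive-time invariant.

## Known limitations

- The independence null ignores gene-gene correlation; on real data the
  empirical confidences are optimistic.
- The branch-extraction size band (20–30) reflects the subgroup scale the
  method was designed around; very small cohorts return a single subgroup
  rather than forcing splits.
- The competitive-ranking side effect described above means aberration
  frequencies of unrelated pathways are not exactly `alpha` in samples
  carrying strong true signals.
- Cross-patient high-correlation duplicates are reported, not removed:
  distinguishing technical replicates from true biological similarity
  needs metadata the matrix alone cannot provide.
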