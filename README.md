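# pathscape

Single-sample pathway aberration profiling for tumour expression cohorts.

Most pathway enrichment tools compare two phenotype groups. `pathscape`
instead asks, for **each individual sample**, which pathways' genes sit
coherently among that sample's most up-regulated (enriched) or most
down-regulated (depleted) genes — turning a genes × samples log-ratio
matrix into a pathways × samples *aberration profile* that can be
clustered into molecular subgroups and tested against survival and prior
subtype labels. It is aimed at researchers analysing heterogeneous
multi-cancer expression collections who want pathway-level descriptions
of single tumours without pooling samples first.

## The statistic

For a sample with `n` measured genes ranked from most up- to most
down-regulated, and a pathway with `m` of its members in the list, label
members 1 and non-members 0 while walking down the list. The area under
the curve of fraction-of-1's versus fraction-of-0's is the normalized
Mann–Whitney concordance

    AUC = (1 / (m(n − m))) Σ_{members i} #{non-members ranked below i},

with AUC = 1 when the whole pathway tops the list. Walking the reversed
list gives the depletion AUC. Significance is an empirical confidence from
`B` random redraws of the member positions,

    p = (1 + #{null AUC ≥ observed}) / (B + 1),

and the two confidences are combined into one signed value per
(sample, pathway): `log2 p_enr` if enrichment is the stronger trend
(negative), `−log2 p_dep` if depletion is (positive). Calls at
`alpha = 0.05` are uncorrected by design — this is an exploratory
profiling method. See `docs/methods.md` for assumptions, parameter
defaults, and limitations.

## Worked example

```python
import pathscape as ps

# a synthetic 3-cancer cohort with known planted structure
design, collection = ps.default_design(seed=1)
cohort, truth = ps.generate_cohort(design, collection)

profiles = ps.score_cohort(cohort, collection, B=200, seed=1)
calls = ps.call_aberrations(profiles, alpha=0.05)

sample = cohort.sample_ids[0]                      # 'CAN1-0001'
planted = [p for (s, p) in truth.aberrations if s == sample]
print(profiles.combined[sample].loc[planted].round(2))
print(calls[sample].loc[planted].tolist())
```

prints

```
SET0001    -7.65
SET0002     7.65
SET0003    -7.65
SET0004     7.65
SET0005    -7.65
SET0006     7.65
SET0007    -7.65
SET0008     7.65
Name: CAN1-0001, dtype: float64
['E', 'D', 'E', 'D', 'E', 'D', 'E', 'D']
```

All eight pathways planted in this sample's subgroup hit the confidence
floor `1/(B+1) = 1/201` (`|log2 1/201| ≈ 7.65`): the four enriched ones
come out strongly negative and called `E`, the four depleted ones
positive and called `D`. Clustering the combined profiles recovers the
planted subgroups:

```python
ids = cohort.metadata.index[cohort.metadata.cancer_label == "CAN1"].tolist()
feats = profiles.combined[ids].T
tree = ps.hierarchical_cluster(feats)
assignment = ps.extract_subgroups(tree, k_override=3, features=feats)

from sklearn.metrics import adjusted_rand_score
print(adjusted_rand_score(truth.subgroup[ids], assignment.labels[ids]))  # 1.0
```

and `ps.survival_scan(assignment, survival_table)` tests each subgroup
against the rest of its cohort with the Mantel-Cox log-rank test.

scikit-learn users can drop the scorer and subgrouper into pipelines:
`PathwayAberrationScorer(collection, B=1000).fit_transform(X)` takes a
samples × genes matrix and returns samples × pathways signed scores;
`PathwaySubgrouper(min_size=20, max_size=30).fit_predict(scores)` returns
subgroup labels.

A command-line interface mirrors the library:
`pathscape simulate --seed 17 --out sim/`, then `pathscape run --config
cfg.yaml` for the full load → QC → score → call → subgroup → associate
pipeline with a checksummed manifest.

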