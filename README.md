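# oralgut

Shared-ASV analysis of paired oral/gut 16S rRNA amplicon cohorts.

The oral cavity and the gut are anatomically continuous, yet their bacterial
communities are vastly different. A direct way to look for oral–gut bacterial
translocation in healthy people is to ask, for every amplicon sequence
variant (ASV) in a cohort where each participant contributed both a saliva
and a stool sample: is this exact sequence detected in *both* habitats of the
*same* individual? `oralgut` implements that question as a tested pipeline,
for microbiome researchers working with QIIME-2-style ASV feature tables.

## What it computes

Given a features × samples count table, per-sample metadata (individual,
habitat, age, sex, BMI category) and a taxonomy, the pipeline derives:

* **Habitat accounting** — the sets of ASVs detected in gut samples (G), in
  oral samples (O), their intersection G ∩ O (cross-habitat shared), and the
  habitat-exclusive complements;
* **Within-individual sharing** — the subset of G ∩ O co-detected in the
  saliva *and* stool of at least one single participant, with the set of
  co-detecting participants per ASV and the participant prevalence of sharing;
* **Directionality** — for each within-individual shared ASV, whether its
  mean relative abundance is higher oral-side or gut-side (oral-dominant
  sharing is the signature of oral→gut translocation);
* **Age persistence** — a child-only / adult-only / both-ages partition of the
  shared set (detection in both age groups suggests persistent colonization
  initiated in childhood);
* **Diversity statistics** — Shannon index H = −Σ pᵢ ln pᵢ per sample,
  zero-adjusted Bray–Curtis similarity S = 100·(1 − Σ|xᵢⱼ−xᵢₖ|/Σ(xᵢⱼ+xᵢₖ))
  on square-root-transformed percentages with a dummy feature, ANOSIM
  R = (r̄_between − r̄_within)/(M/2) with permutation p-values, PCO and NMDS
  ordinations, and STAMP-style Welch's t post-hoc genus comparisons with
  inverted-statistic confidence intervals.

A synthetic paired-cohort generator (`oralgut.synthetic_data`) plants
habitat-exclusive ASV pools, a known shared set with a controlled
oral-dominant fraction and age mixture, and multinomial sequencing noise, so
every stage of the pipeline can be scored against ground truth.

## Worked example

Simulate the default cohort (39 children + 97 adults, 61 planted shared ASVs,
38 of them oral-dominant, an age mixture of 15 child-only / 20 adult-only /
26 both, 50,000 reads per sample) and analyze it:

```bash
oralgut simulate --seed 17 -o demo/cohort
oralgut analyze --table demo/cohort/feature_table.tsv \
                --metadata demo/cohort/metadata.tsv \
                --taxonomy demo/cohort/taxonomy.tsv \
                -o demo/results --seed 17
oralgut report demo/results
```

prints (abridged):

```
=== Oral-gut shared-ASV summary ===
ASVs detected: 3801 total (2423 gut, 1438 oral)
Habitat-exclusive: 2363 gut-only, 1378 oral-only; 60 in both habitats
Within-individual shared: 59 (1.6% of all ASVs)
Directionality: 37 oral-dominant (63%), 22 gut-dominant (37%), 0 tied
Age partition: 15 child-only, 19 adult-only, 25 in both ages (42% of shared, 0.7% of all ASVs)
Participants with >=1 shared ASV: 136/136 (100%)
```

59 of the 61 planted shared ASVs survive sequencing noise at this depth (the
two misses are depth-limited dropout of rare variants), the recovered
oral-dominant fraction (37/59 ≈ 0.63) is within 0.01 of the planted 38/61,
and the age partition is recovered almost exactly. The habitat ANOSIM on the
same run gives R = 1.0, p = 0.0002 (4,999 permutations) — complete oral/gut
community separation, as expected from disjoint habitat pools.

The same machinery is available as a library:

```python
from oralgut import paper_shaped_spec, generate_cohort, build_report

table, metadata, taxonomy, truth = generate_cohort(paper_shaped_spec(seed=17))
report = build_report(table, metadata, taxonomy)
print(report.summary.n_within_individual_shared,
      report.summary.pct_oral_dominant)   # 59  63
```

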