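# Methods

## Presence and the shared-ASV definitions

An ASV is *present* in a sample when its read count is ≥ `min_count`
(default 1). Feature tables are assumed to be denoised upstream (DADA2-style
ASV inference), so a single read is treated as evidence; `min_count` is
exposed for sensitivity analysis. For percent-state tables (the generator's
noise-free expected compositions) presence is strict positivity.

Habitat sets are cohort-wide: `gut_set` contains every ASV present in at
least one gut sample of anyone. The *within-individual shared* set is
stricter: an ASV qualifies only if some single participant has it in both
their own saliva and stool samples. The distinction matters — an ASV can be
in G ∩ O through two different people without ever being co-resident. Sharing
prevalence is the fraction of participants who co-detect at least one shared
ASV, reported to the nearest integer percent.

Individuals lacking one habitat's sample are excluded from co-detection (with
a warning) but still contribute to the habitat sets; an individual with two
samples of the same habitat violates the pairing invariant and is a hard
error.

## Directionality

For each shared ASV we compare its mean relative abundance over *all* oral
samples against the mean over *all* gut samples, zeros included
(`oral_dominant` if the oral mean exceeds the gut mean by more than
`tie_tol`, default 1e-12, a pure floating-point guard). Averaging over
detected samples only is available via `detected_only=True`; habitat-wide
means are the default because they answer "where does this organism carry
more of the community?" rather than "how abundant is it where it happens to
appear?". A `tied` class exists so the three classes always partition the
shared set for any tie tolerance.

## Count summary conventions

Derived figures follow fixed rounding rules: percentages of the total
detected ASV pool to one decimal, percentages of the shared subset and
participant prevalence to the nearest integer. `summarize_counts` validates
the closure identities (exclusive = detected − both-environments; the
directionality and age partitions each sum to the shared count;
within-individual shared ≤ cross-habitat shared) and names the violated
identity on error.

## Transform chain and resemblance

Counts are converted to per-sample percentages (removing depth variability),
then square-root transformed (damping dominant taxa), enforced as a one-way
state machine `counts → percent → sqrt_percent` so no table can be normalized
twice. All-zero samples are kept in the table (dropping would mask upstream
failures) but excluded from resemblance analyses, with a warning.

Bray–Curtis similarities (0–100 scale) are computed on the sqrt-percent
matrix after appending a constant dummy feature of 1 to every sample —
the zero-adjusted variant, which renders sparse or empty sample pairs
well-defined (two empty samples are 100% similar) without materially
affecting dense pairs. The dummy magnitude of 1 on the sqrt-percent scale
(i.e. 0.01% before the square root) is the conventional choice.

## ANOSIM

R = (r̄_between − r̄_within)/(M/2), where ranks are taken over the
M = n(n−1)/2 pairwise dissimilarities with ties mid-ranked. Significance is
by label permutation, 4,999 permutations by default, with the add-one
convention p = (1 + #{R* ≥ R}) / (1 + n_permutations) so p can never be zero.
When the number of distinct label rearrangements is at most the requested
permutation count, the full enumeration is used instead and p is exact.
A numerical tolerance of 1e-12 guards the R* ≥ R comparison against
floating-point ties. Seeds are explicit in the API; the pipeline derives
stage seeds from one root seed by hashing the stage name, so single stages
re-run reproducibly in isolation.

## Ordination

PCO (classical metric scaling): dissimilarities d = (100 − S)/100, Gower
double-centering of −d²/2, symmetric eigendecomposition; coordinates are
eigenvectors scaled by √λ for λ > 1e-9, axes in descending-λ order. Negative
eigenvalues (non-Euclidean inputs) are counted and reported, not silently
corrected; a Lingoes correction is available behind `correction="lingoes"`.

NMDS minimizes Kruskal stress-1 via SMACOF with monotone (isotonic)
regression; restart 0 is initialized from the PCO configuration and the
remaining restarts (default 20 in the API, 8 in the pipeline) are random,
keeping the best stress. Non-convergence within `max_iter` returns the result
with a `converged=False` flag and a warning rather than failing. Strongly
clustered data can legitimately reach stress ≈ 0 in the non-metric sense
(any monotone map separating the clusters is perfect).

## Welch post-hoc comparisons

Genus-level abundance contrasts use Welch's two-sided t-test with
Welch–Satterthwaite degrees of freedom; the CI of the mean difference is the
inversion of the Welch statistic at the configured level (default 95%).
Aggregation to genus happens on the percent scale before testing. Raw
p-values are reported without multiplicity correction by default, matching
the post-hoc reporting style this pipeline mirrors; `fdr=True` adds
Benjamini–Hochberg q-values and logs loudly. Zero variance in both groups
with equal means is the degenerate t = 0, p = 1 case, not an error.

## Synthetic cohort model

The generator emulates a paired two-age-group cohort:

* **Pools.** `n_gut_pool` and `n_oral_pool` strictly habitat-exclusive ASVs
  plus `n_shared` cross-habitat ASVs. Rank abundance is log-normal
  (σ = 1.5 by default), chosen over a Dirichlet for its realistic long tail.
* **Occupancy.** Each pool ASV is present in each individual with
  probability 0.3; per-individual abundance noise is log-normal (σ = 0.7).
  These two values were fixed once as representative of the sparsity and
  person-to-person variation of 16S cohorts.
* **Shared ASVs.** Each is assigned a directionality (exactly
  `round(n_shared · oral_dominant_fraction)` oral-dominant) and an age
  partition drawn from `age_exclusive_fractions`. Carriers are sampled from
  the age-compatible individuals (probability 0.3); every ASV gets at least
  one carrier per required age group, and every individual at least one
  age-compatible shared ASV, so prevalence is 100% by construction. A
  carrier's shared ASV appears in **both** their samples with a single
  shared noise factor, the dominant habitat at the base abundance and the
  other habitat scaled by `transfer_factor` (default 0.1). Tying the noise
  across habitats makes the planted directionality exact in the expected
  compositions: per-sample normalization can only flip a comparison if one
  habitat's community total exceeds the other's by more than
  1/transfer_factor, which non-empty pools rule out.
* **Sequencing.** Per-sample depth is gamma–Poisson (negative binomial) with
  mean `read_depth` and dispersion 0.3; counts are multinomial given the
  expected composition, so rare variants genuinely drop out.
  `read_depth=None` disables sampling and emits the expected percentages
  directly (a percent-state table), giving exact-recovery ground truth.
* **Defaults.** `paper_shaped_spec()` is the documented study-shaped
  condition: 39 children + 97 adults, pools of 2,363 gut and 1,377 oral ASVs
  (sized so detected totals land near 2.4k/1.4k at 50,000 reads/sample),
  61 shared ASVs with oral-dominant fraction 38/61 and age mixture
  (15, 20, 26)/61. Taxonomy assigns the shared ASVs to an 18-genus list of
  known oral–gut commuters (*Actinomyces*, *Rothia*, *Bacteroides*, …) and
  filler genera to the pools, with habitat-weighted phylum draws.

What the generator does **not** emulate: compositional correlation between
taxa, strain-level variation within an ASV, chimeras or contamination,
batch/extraction effects, and any mechanistic model of gastric-barrier
survival (`transfer_factor` is phenomenological). Passing recovery tests
therefore demonstrates correctness of the set logic, classification and
calibration of the statistics under multinomial noise — not robustness to
real-data artifacts.

## Problem sizes used in the checks

The statistical calibration checks use 500 label-randomized 14-sample
datasets at 999 permutations (ANOSIM size), 2,000 null replicates of n = 20
groups (Welch CI coverage), and 10 seeded study-shaped cohorts at 50,000
reads/sample (recovery of the planted 61-ASV shared set within ±10% and the
oral-dominant fraction within ±0.05). Exact recovery is asserted with
sampling disabled.

## Known limitations

* Directionality compares habitat-wide means of relative abundance; it does
  not model compositional coupling between ASVs, and "dominance" is not a
  claim about the direction of transfer for any individual organism.
* The pipeline treats the feature table as final: no denoising, taxonomy
  classification, rarefaction, or prevalence filtering is applied (and none
  is assumed upstream beyond denoising).
* ANOSIM permutations are unrestricted (single-factor); no stratified or
  nested designs.
* NMDS relies on SMACOF local optimization; with few restarts on large
  matrices the stress may be a local optimum (the `converged` flag and
  stress value are reported for inspection).
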