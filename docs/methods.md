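# Methods

## The anchored IBS statistic

Raw IBS between two individuals is the mean over co-called loci of a
three-valued score: 1 for identical genotypes (including het×het), 0.5 for
one shared allele (het vs hom), 0 for opposite homozygotes; on dosages this
is `1 − |d₁ − d₂| / 2`. Loci where either sample is missing are excluded
(pairwise-complete), and pairs with fewer than `min_overlap` co-called loci
(default 500) are reported missing rather than unstable.

The anchored normalization `(IBS − av.min) / (1 − av.min)` rescales the
matrix so 1 = identical and 0 = the average IBS between the two most
genetically distinct groups in the dataset. The anchor unit is the nest
when nest labels exist, otherwise the population; among all group pairs the
one with the minimum mean cross-group IBS is chosen (ties broken to the
lexicographically smallest pair). No small-denominator regularization is
applied; `av.min ≥ 1` is rejected. Entries below the anchor go negative,
which is expected when the anchor lies within one population and a pair
spans divergent populations.

### Exact calibration

For HWE founders at allele frequency `p` (`q = 1 − p`):

| IBD state | E[IBS] |
|---|---|
| 0 | `1 − 2pq(1 − pq)` |
| 1 | `1 − pq` |
| 2 | `1` |

A relationship with IBD probabilities `(k₀, k₁, k₂)` therefore has excess
`k₂·2pq(1−pq) + k₁·pq(1−2pq)` over unrelated pairs. These formulas are
verified in-module by brute-force enumeration over the 9×9 genotype-pair
table per IBD state (`enumerate_expected_ibs`), and
`expected_normalized_ibs` integrates the ratio-of-averages over a MAF
spectrum. Two consequences worth stating plainly:

* Mean IBS is **not linear in kinship**. With MAF ~ U(0.05, 0.5) and a
  same-population unrelated anchor, the exact expectations are **0.4365**
  for full sibs, **0.1865** for half sibs and **0.3731** for
  parent–offspring — full sibs and parent–offspring pairs do *not* share an
  expectation under this scoring, and both sit below the first-order
  guesses of 1/2 and 1/4 (those drop O(pq²) terms). Empirical field values
  around 0.49/0.30 are consistent with a rarer-variant-skewed site
  frequency spectrum, a cross-population "most distinct nests" anchor
  (both raise the statistic), and inbreeding.
* Classification thresholds (defaults: ≥0.90 duplicate, ≥0.40
  full-sib-or-parent-offspring, ≥0.18 half-sib) are interval midpoints for
  panels of a few thousand SNPs, all configurable. The full-sib category is
  named `full_sib_or_parent_offspring` because with hatchling-only sampling
  the parent–offspring case does not arise; for mixed-age data the
  categories should be disambiguated with metadata.

## mtDNA repeat region

Amplicon length is affine in the repeat copy number:
`length = flank_bp + 8·copies` with `flank_bp = 89` calibrated from the
13-copy ↔ 193 bp endpoint of the observed 193–297 bp range; the constant is
exposed for other primer pairs. Band patterns drop fractions below a
detection threshold (default 0.05) and renormalize; dominant-band ties
break toward the higher copy number. Profile similarity is
1 − Bray–Curtis on thresholded fraction vectors, i.e. the shared mass
`Σ min(aᶜ, bᶜ)`.

Maternal lineages are single-linkage clusters at similarity ≥ 0.5 with
same-nest samples pre-linked (one mother per nest). Single linkage is
deliberate: bottleneck drift makes sibling profiles chain-like. Labels are
canonicalized by smallest member ID, so assignment is input-order
invariant. Sequence-level motif variation inside the repeat is not modeled;
haplotypes are reduced to copy-number patterns. That reduction caps
resolution: with ~14 plausible dominant-band states, unrelated females
collide into shared labels at a few percent per pair, so lineage labels are
treated as evidence that can only *veto* maternity, never confirm it
(haplotype sharing among unrelated females is expected), and the clustering
guarantees in practice that a true family is never split, while merges do
occur.

## Transmission model (generator)

Offspring mtDNA pools are multinomial samples of `bottleneck_n` units
(default N = 20) from the mother's pool; each unit slips ±1 copy with
probability µ (default 0.01) per transmission. N is a free parameter — the
real germline bottleneck size for this species is unknown; the default
reproduces visible sibling-to-sibling band variation without losing the
dominant band. Founder pools have 1–3 bands (dominant fraction 0.6–0.9,
minors within ±2 copies) over the observed 13–26 copy range.

The nuclear side: ancestral MAFs uniform on a configurable range,
Balding–Nichols Beta divergence calibrated so the among-population variance
equals `target_fst` (the F = 0 case is handled as the exact point-mass
limit); HWE founders; Mendelian transmission with no linkage; MCAR
missingness per genotype call; negative-binomial read depths (mean 65,
sd 16, matching RADseq-like coverage). A single root seed feeds per-stage
child streams, so changing the locus count does not perturb the pedigree,
and identical configs yield byte-identical VCFs.

Mating model: each mother's clutches draw fathers excluding her previous
mates, except that with probability `p_sperm_storage` a later clutch
re-uses a stored father — so with `p_sperm_storage = 0` no father ever
spans two clutches of one mother, giving a clean null for the storage
detector. With probability `p_multiple_paternity` a nest gets a second
father and each father sires at least one sampled offspring. The event
registry (multiple-paternity nests, storage events, repeat clutches) is
derived from the realized pedigree, not from the intended draws.

Default scale (20 mothers, 15 fathers, 30 nests of 4 sampled hatchlings,
3000 SNPs, one population) is a scaled-down analogue of a five-year
river-population study (44 females / 36 males / 51 sampled nests), chosen
so the full pipeline runs in seconds while keeping nests-per-mother and
fathers-per-nest ratios comparable.

What the generator does *not* emulate: linkage disequilibrium between loci
(LD pruning is exercised on constructed correlated fixtures instead),
genotyping error beyond missingness, relatedness among founders,
sequence-level mtDNA variation, and non-random sampling of nests. Passing
calibrations here therefore establish correctness of the estimators under
the stated models, not field performance on a specific dataset.

## Breeder inference

Maternal families are connected components over full-sib edges, half-sib
edges and same-nest co-membership, with mtDNA as a veto: a cross-nest
half-sib edge is maternal only when the samples share a lineage label *and*
the two nests' consensus profiles (clutch-averaged band fractions) agree at
Bray–Curtis ≥ 0.75. The consensus gate exists because label collisions
between unrelated females would otherwise convert shared fathers into false
maternal merges; a clutch pins down its mother's pool far more precisely
than one hatchling. Full-sib edges are accepted as same-mother links under
the hatchling-only assumption (disable with `hatchlings_only=False`).

Within a family, connected components of full-sib edges partition offspring
by father. Cross-lineage, cross-nest half-sib edges — which cannot be
maternal — are exactly the signature of paternal half sibs, and are used to
merge father identities across maternal families (never to merge mothers).
Events: a nest spanning ≥2 paternal groups is a multiple-paternity nest
(single-offspring nests are reported separately, not counted); one father's
full sibs spanning two clutches of one mother laid ≥ `min_gap_days` apart
(default 7, separating storage from same-event re-nesting) is a
sperm-storage event; a family with ≥2 nests in one calendar year is a
repeat-clutch event. Storage detection requires an actual cross-nest
full-sib edge, which keeps its false-positive rate at zero even when
maternal families are imperfect.

With noise-free calls the procedure reproduces the generator's registry
exactly (tested). At the default study scale with default thresholds,
measured performance across seeds: mother count within 0 to −3 of truth
(merges only, driven by residual mtDNA collisions), father count within
±1, maternal-partition Rand index ≥ 0.98, multiple-paternity recall 1.0,
zero sperm-storage false positives under the storage-free null. Known
limitation: two mothers with near-identical repeat pools who also share a
father are genuinely indistinguishable in this data model.

## Population structure

* **Filters** apply in a fixed order — per-genotype depth masking, site
  mean depth bounds (mean over genotypes called in the input), site
  missingness, MAF (computed after masking) — because the criteria
  themselves don't determine an order and order changes counts; each
  removed site is charged to the first rule it fails. Presets match the
  source workflow (full panel: depth 10–130×, missingness ≤ 10 %,
  MAF ≥ 0.02; single-site panel: 10–190×, ≤ 5 %, ≥ 0.05).
* **LD pruning** is the greedy 50-SNP window / step 5 / r² > 0.2 scheme,
  removing the later locus of an offending pair; deterministic and
  idempotent. Missing dosages are mean-imputed for the correlation only.
* **PCA** standardizes dosages by `2p̂` and `√(2p̂(1−p̂))`, mean-imputes
  missing values, drops monomorphic loci, and eigendecomposes the
  relationship matrix; coordinates are eigenvector × √eigenvalue, so
  duplicated samples land on coincident points.
* **Fst** is the Weir–Cockerham (1984) multi-locus ratio-of-averages θ.
  θ estimates the among-deme variance parameter (the Balding–Nichols F) and
  is *not* the frequency-level Wright/Nei `1 − Hs/Ht`, which is exposed
  separately as `wright_fst`; for two demes the two differ materially
  (e.g. frequencies 0.2/0.8 give 0.36 vs θ → 0.53). GenAlEx-style matrices
  computed on real data may also differ slightly from θ for the same
  reason.
* **AMOVA** is the three-level allele-based partition (among populations /
  among individuals within populations / within individuals) with
  Φ-statistics; per-locus variance components are summed across loci, and
  negative totals are clamped to zero for the percentage table (flagged).
  **ΦPT** is the distance-based two-level AMOVA on individual dosage
  vectors (squared Euclidean, pairwise-complete rescaled), which absorbs
  genotypic as well as allele-frequency differentiation and therefore runs
  above Fst on the same panels (≈ 2F/(1+F) under HWE divergence).
* **Permutation tests** reassign whole individuals to populations, with the
  add-one rule `p = (1 + #{perm ≥ obs}) / (B + 1)` (default B = 999);
  p-values are verified uniform under the null by a KS check.

## Problem sizes used in the test suite

Calibration runs use 64 relationship pairs at 2000 SNPs; estimator-recovery
runs use 5000 SNPs × 100 diploids (Fst/AMOVA) and 500 replicate permutation
tests of 16 diploids × 100 loci (uniformity); the pipeline check is the
default 120-hatchling × 3000-SNP design. These sizes put every simulated
standard error well inside the asserted tolerances while keeping the whole
suite under a minute of compute.
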