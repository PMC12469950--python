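# shellkin

Kinship, mtDNA heteroplasmy haplotyping and population structure for
nest-based sampling of freshwater turtles.

Small, fragmented turtle populations are hard to census directly: adults are
cryptic and aquatic, and field sampling is often limited to hatchlings left
in hatched nests. `shellkin` implements a genomic monitoring workflow built
for that setting — as used for the critically endangered Mediterranean
Nile soft-shelled turtle (*Trionyx triunguis*) — which reconstructs who is
breeding from the hatchlings alone:

* **Anchored normalized IBS kinship.** Pairwise identity-by-state over all
  SNPs with the 1 / 0.5 / 0 genotype scoring (same genotype / one shared
  allele / opposite homozygotes), rescaled as

  `nIBS = (IBS − av.min) / (1 − av.min)`

  where `av.min` is the mean IBS between the two most genetically distinct
  nests (or populations) in the dataset. 1 means identical samples, 0 means
  "as similar as the two most distinct groups"; values below the anchor go
  negative. Under Hardy–Weinberg founders the per-locus expectations are
  `E[IBS | IBD=0] = 1 − 2pq(1 − pq)` and `E[IBS | IBD=1] = 1 − pq`, from
  which the package derives (and verifies by brute-force enumeration over
  the 9×9 genotype-pair table) exact expectations for full sibs, half sibs
  and parent–offspring pairs under any MAF spectrum.
* **mtDNA repeat haplotyping.** The 3′ D-loop carries a tandem 8-bp repeat
  ("TATATATC", 13–26 copies, amplicons 193–297 bp); individuals are
  heteroplasmic and transmission passes a germline bottleneck, so band
  profiles mark maternal lineages. The package models amplicon arithmetic,
  profile similarity (Bray–Curtis), and single-linkage lineage assignment
  with a one-mother-per-nest constraint.
* **Breeder inference.** Full/half-sib calls, lineage labels and lay dates
  combine into maternal families, paternal groups, and reproductive events:
  multiple paternity, sperm storage across clutches, repeat clutches within
  a season.
* **Population structure.** Depth/missingness/MAF site filters, sliding
  window LD pruning (50/5/0.2), PCA of the variance-standardized
  relationship matrix, Weir–Cockerham Fst, ΦPT and three-level AMOVA with
  permutation tests.
* **Synthetic data.** A generator producing the full data structure the
  analysis assumes — Balding–Nichols population divergence at a target Fst,
  nested full/half-sib pedigrees with multiple paternity and father re-use,
  MCAR missingness, read depths, and bottlenecked heteroplasmic mtDNA
  pools — with ground truth for scoring every inference.

## Worked example

```python
import shellkin as sk

cfg = sk.SimulationConfig(rng_seed=7)        # 20 mothers, 15 fathers, 30 nests,
geno, dp, meta, profiles, ped = sk.simulate_dataset(cfg)   # 4 hatchlings/nest, 3000 SNPs
result = sk.run_kinship_pipeline(geno, meta, profiles)
print(result.anchor_groups, round(result.normalized.anchor_value, 4))
print(result.estimate.summary())
print(sk.score_inference(result.estimate, ped))
```

prints (abridged):

```
('N08', 'N28') 0.7349
{'n_mothers': 18, 'n_fathers': 13, 'n_multiple_paternity_nests': 6,
 'n_sperm_storage_events': 1, 'n_repeat_clutch_events': 8}
mother_count_error=-2  father_count_error=0  maternal_rand_index=0.984
```

Reading this: the normalization anchored on nests N08/N28 (mean raw IBS
0.7349 between them, mapped to 0). The pipeline inferred 18 breeding
females and 13 males from the 120 hatchlings; the generator's truth was 20
mothers (two pairs shared indistinguishable mtDNA profiles and a father, so
they merged) and exactly 13 participating fathers. All 6 true
multiple-paternity nests were flagged. Full-sib calls on this run averaged
nIBS 0.469 and half-sib calls 0.236.

The same workflow runs from the shell:

```sh
shellkin simulate --out data/
shellkin kinship --vcf data/genotypes.vcf --metadata data/metadata.tsv \
         --profiles data/profiles.tsv --out results/
shellkin popgen  --vcf data/genotypes.vcf --metadata data/metadata.tsv --out results/
```

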