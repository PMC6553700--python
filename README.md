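# famseg

Family-based rare-variant prioritization for multi-incident disease
pedigrees under an **autosomal dominant model with reduced penetrance**.

The package is aimed at statistical/medical geneticists working with
multi-incident families (several affected relatives across 3–4 generations)
where a single rare variant of major effect is suspected. It implements the
full desk workflow around whole-exome candidate variants:

- **Rare-variant filtering** — keep autosomal, heterozygous,
  missense/nonsense variants with minor allele frequency (MAF) strictly
  below 1% in every configured frequency database (a variant absent from a
  database counts as "not present", i.e. frequency 0).
- **Sharing among sequenced affected relatives** — variants carried by all
  sequenced affected members; when none survives, an all-but-one (n−1 of n)
  rescue pass.
- **Pedigree genotype inference** — under the assumptions of a single
  founder introduction and no de novo events, infer genotypes that are
  forced by the observed calls, and identify **obligate carriers**:
  unaffected individuals who must carry the variant (classically the
  unaffected parent of an affected carrier).
- **Co-segregation criterion** — a variant segregates with disease in a
  family when carried by at least **75%** of affected blood relatives with
  an observed or inferred genotype (inclusive, so 3/4 passes) **and** by no
  more than **one** unaffected family member, not counting obligate
  carriers. The two slack terms absorb phenocopies and reduced penetrance
  respectively.
- **Cohort mining** — rare missense/nonsense variants in a gene of interest
  present in cases and absent from all controls, pushed back into each
  carrier's family for follow-up segregation evaluation.
- **Case/control statistics** — carrier-based MAF (carriers / 2·individuals,
  heterozygous-carrier assumption) and odds ratios from the carrier 2×2
  table with a Woolf 95% confidence interval,
  `exp(ln OR ± 1.96·√(1/a + 1/b + 1/c + 1/d))`, with the Haldane–Anscombe
  +0.5 correction when a cell is zero.
- **Haplotype sharing** — CEPH-normalized microsatellite allele sizes on the
  variant-bearing chromosome decide whether variant-sharing families
  descend from one founder event or from recurrent mutation.
- **A seeded simulator** (`famseg.synthetic_data`) that generates
  multi-incident families (dominant founder variant, configurable
  penetrance, phenocopy rate and genotype missingness, married-in
  non-carriers), case/control cohorts, and complete fixture bundles
  (PED + VCF + frequency/marker TSVs), so every stage is testable without
  access to patient data.

## Worked example

Simulate two three-generation families segregating a dominant variant with
penetrance 0.7 and 2% phenocopies, then run discovery:

```sh
famseg simulate --outdir demo --n-families 2 --seed 11
famseg discover --ped demo/families.ped \
    --vcf FAM1=demo/FAM1.vcf --vcf FAM2=demo/FAM2.vcf \
    --freq demo/frequencies.tsv --outdir demo/out
```

```text
"FAM1": { "attrition": {"loaded": 26, "rare": 12, "shared": 0,
          "share_mode": "all_but_one", "segregating": 0},
          "nominations": [], "status": "unresolved" }
"FAM2": { "attrition": {"loaded": 26, "rare": 14, "shared": 2,
          "share_mode": "full", "segregating": 2},
          "nominations": ["7:5000123:C:T", "12:24977898:A:G"],
          "status": "resolved" }
```

Each family's variants are counted through the attrition stages
(loaded → rare → shared by affected → segregating). FAM1 is *unresolved*:
under reduced penetrance the planted variant missed the 75% rule — the
expected behaviour that leaves a fraction of real families without a
nomination. FAM2 nominates the planted variant `7:5000123:C:T` (4/4
affected carriers, 0 counted unaffected carriers, one obligate carrier
II-3) plus one background variant that co-segregates by chance; the
candidate table (`demo/out/candidates.tsv`) carries the per-family tallies.

Association from carrier counts (5 carriers among 6,252 cases vs 1 among
3,877 controls):

```sh
famseg assoc --counts counts.tsv
```

```text
label        maf_cases  maf_controls  or_ci95            correction_applied
NCOA3_R485C  0.04%      0.01%         3.10 (0.36–26.56)  False
```

i.e. carriers have a 3.1-fold increased odds of disease, with a 95%
confidence interval spanning 1 (0.36–26.56) as expected at these tiny
carrier counts.

Other subcommands: `evaluate` (one variant × one family), `mine` (cohort
mining), `haplotype` (pairwise founder-sharing verdicts), `vs-reference`
(odds ratio against a reference-population allele frequency).

## Layout

- `src/famseg/pedigree.py` — PED I/O, relationship queries, forced-genotype
  and obligate-carrier inference
- `src/famseg/variant_filter.py` — VCF I/O, frequency tables, the candidate
  filter, sharing among affected
- `src/famseg/segregation.py` — the co-segregation criterion, candidate
  nomination, cohort mining
- `src/famseg/association.py` — carrier MAFs, Woolf odds-ratio intervals
- `src/famseg/haplotype.py` — microsatellite haplotype phasing/comparison
- `src/famseg/synthetic_data.py` — family/cohort simulators and fixture
  bundles
- `src/famseg/report.py`, `src/famseg/cli.py` — orchestration and the
  `famseg` command
- `docs/methods.md` — model assumptions, parameter choices, limitations
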