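# Methods

## Disease model and scope

All inference assumes an **autosomal dominant model with reduced
penetrance**: a single rare heterozygous variant of major effect introduced
into each family by exactly one founder, transmitted as an independent fair
coin per meiosis, with no de novo events and no bilineal entry (married-in
spouses are assumed non-carriers; the simulator can relax this). Carriers
develop disease with probability equal to the penetrance; non-carriers with
probability equal to the phenocopy rate. Homozygous-alternate genotypes are
collapsed to "carrier" with a warning — under a dominant model dosage does
not change case status, and rare-variant homozygotes are overwhelmingly
genotyping artefacts at these frequencies. Consanguinity, X linkage and
polygenic models are out of scope.

## The co-segregation criterion

A variant co-segregates with disease in a family when

1. `affected_fraction = n_affected_carriers / n_affected_informative ≥ 0.75`
   (inclusive, so 3 of 4 passes), and
2. at most **one** unaffected family member carries it, excluding obligate
   carriers.

Counting rules, all configurable:

- The denominator contains affected **blood relatives** of the proband with
  an **observed or inferred** genotype. Wholly untyped affected members drop
  out rather than being assumed wild-type: treating missing DNA as wild-type
  would penalize exactly the families this analysis targets (multi-
  generation pedigrees with deceased members).
- Individuals with a "possible" (unconfirmed) diagnosis and unknown
  affection are excluded from both tallies by default
  (`include_possible=True` counts possibles as affected). Married-in members
  (no blood path to the proband) never count.
- The unaffected-carrier count excludes (a) unaffected parents of affected
  individuals — under a dominant model one parent had to transmit — and
  (b) with `extended_obligate=True` (default) every individual returned by
  the path-based obligate-carrier inference below, which extends the parent
  rule to forced carriers in deeper generations (e.g. a transmitting
  grandparent whose spouse is observed wild-type).
- A variant carried in several families must satisfy the criterion in
  *every* carrier family to survive (`mine_cohort` reports one result per
  family); an aggregate fraction above threshold does not rescue a variant
  that fails within individual families.

The 75% and ≤1 slack terms are the model's allowance for phenocopies and
reduced penetrance respectively; both thresholds are plain parameters of
`evaluate_segregation`.

## Genotype inference on the pedigree graph

The pedigree is a parent→child DAG (networkx). Under the single-founder /
no-de-novo assumptions, any Mendelian-consistent carrier configuration is a
union of descent paths from one introducing founder, avoiding observed
wild-type individuals. Two dual queries drive all inference:

- **Forced carrier**: for a fixed feasible founder *f*, an individual is
  forced exactly when it is *f* itself or its removal disconnects some
  observed carrier from *f* in the wild-type-pruned descent graph; an
  individual is forced overall when this holds for **every** feasible
  founder. Feasible founders are those from which every observed carrier is
  reachable (an observed-carrier founder must itself be the introduction).
- **Possible carrier**: reachable from at least one feasible founder.

`infer_genotypes` adds `origin=inferred` carrier calls for forced
individuals and inferred wild-type calls only for impossible carriers
(e.g. both parents observed wild-type); everything else stays missing, so a
second pass adds nothing (idempotence). `infer_obligate_carriers` applies
the forced-carrier test to every non-affected individual *with their own
genotype call withheld*, so an unaffected genotyped carrier parent is
recognized as obligate by pedigree position alone, while an unaffected
carrier sibling (a 50% event) is not. An observed wild-type individual is
never returned. When both grandparents of a carrier-connecting lineage are
untyped, neither is obligate — either could have introduced the variant —
and only the linking parents are forced; a grandparent becomes obligate
once its spouse is observed wild-type.

Both operations are validated in the test suite against an independent
brute-force oracle that enumerates all 2^k genotype assignments of untyped
members and keeps the Mendelian-consistent ones; on simulated families every
inferred call equals the simulator's hidden truth whenever an inference is
made (soundness over 1,000 seeded families).

Observed calls that are jointly impossible (a carrier child of two observed
wild-type parents) raise a consistency error naming the trio; carriers that
cannot descend from any single founder raise a model-violation warning and
inference abstains rather than guessing.

**A note on monotonicity.** Adding a *new* affected carrier to a family can
never break a segregating verdict, and adding a new unaffected non-obligate
carrier can never rescue a failed one (both are property-tested under
randomized inputs). The same is *not* true of revealing the genotype of an
existing untyped member: a newly observed unaffected carrier can force an
untyped affected parent to an inferred carrier, legitimately raising the
affected fraction. This information coupling is a feature of
pedigree-aware counting, not a defect, but it means verdicts should be
re-evaluated whenever follow-up genotyping lands.

## Variant filtering

`FilterCriteria` defaults: MAF threshold 0.01 with a **strict** comparison
(a variant at exactly 1% is removed — the literal reading of "below 1%");
consequences {missense, nonsense}; autosomes 1–22 with "chr" prefixes
normalized; heterozygous model. A record must be below the threshold in
*every* database attached to it; absence from a database counts as 0,
matching the treatment of novel variants that simply are not in reference
catalogues. Multiallelic VCF rows are split into biallelic records keyed
`chrom:pos:ref:alt`; consequence annotation is consumed (never computed)
from either a minimal `GENE|class` INFO tag or an ANN-style field, first
transcript winning. Sharing among sequenced affected members prefers the
full-sharing pass and falls back to all-but-one only when the full pass is
empty, mirroring discovery practice for families with one likely phenocopy
among the sequenced cases.

## Association statistics

MAF is computed as carriers / (2·individuals) under the heterozygous-carrier
assumption; percent strings round half-away-from-zero to two decimals
(0.2598% → "0.26%"). The odds ratio is computed from the 2×2 table of
**carrier vs non-carrier individuals** (a = case carriers, b = cases − a,
c = control carriers, d = controls − c) with the Woolf log-normal interval
at z = 1.96. This construction reproduces the published worked example —
5/6,252 vs 1/3,877 → OR 3.10, CI (0.36, 26.56) — to the printed precision,
which an allele-count table does not (it yields an upper bound of 26.55);
for rare heterozygous variants the two differ only in the second decimal.
The Haldane–Anscombe +0.5 correction is applied only when a cell is zero
and is always flagged (`correction_applied`), so silent correction can
never masquerade as data. `frequency_vs_reference`, which compares a
carrier count against a population reported only as an allele frequency,
builds both margins on allele counts instead, rounding the reference
carrier alleles to the nearest integer.

Exact (Fisher) tests, trend tests and meta-analysis are out of scope; at
the carrier counts this workflow handles (1–13 carriers), the Woolf
interval's width is the message, not the p-value.

## Haplotype comparison

The variant-bearing haplotype per family is phased by transmission: at each
microsatellite, the allele size consistent with every informative
carrier-parent → carrier-child meiosis (at least two, agreeing) is taken as
linked. Two families are called `shared_founder` only if allele sizes match
exactly at every co-genotyped marker (CEPH normalization makes integer
sizes comparable across runs; a ±1 bp stutter tolerance is available but
off by default); any mismatch yields `independent_origin`; fewer than
`min_shared=3` overlapping markers raises an inconclusive error rather than
returning a verdict. Statistical phasing and mutation-age dating are out of
scope.

## Synthetic data

The family generator emulates the ascertainment that produces
multi-incident families: 3 generations by default, mean sibship 3,
marriage probability 0.7, a dominant founder variant, penetrance 0.7
(mid-range of a plausible 0.5–0.8 band for a reduced-penetrance dominant
trait — no published point estimate exists, so this is an exploration
default, not a claim), phenocopy rate 0.02 (of the order of the lifetime
risk in first-degree relatives of patients, so that a typical family
contains at most one phenocopy), genotype missingness 0.15 (deceased or
unavailable members), and rejection sampling until the family has at least
4 affected blood relatives, ≥2 of them genotyped. The ascertainment
condition matters: it enriches affected carriers, so parameter-recovery
checks (e.g. Monte-Carlo recovery of the penetrance from carrier outcomes)
must disable it (`min_affected=0`), and the test suite does. Background
variants within a family each enter through one random founder and drop
through the pedigree by honest Mendelian transmission, so a fraction of
them co-segregate by chance — which is exactly the false-positive structure
the 75%-rule has to contend with. The cohort generator draws per-sample
carrier status binomially at the configured group frequencies
(heterozygote probability 2·maf·(1−maf)) with a background panel spanning
the 1% threshold.

All sampling flows through one `numpy` generator per configured seed;
identical config + seed yields byte-identical fixture bundles. What the
simulator does **not** model: linkage disequilibrium and coalescent
realism, genotyping error, age-dependent penetrance, variable age structure
— so passing tests demonstrate the logic of the pipeline, not its
performance on real cohort noise.

## Problem sizes and numerical choices

The packaged validation runs use 500 simulated families for the
full-penetrance sensitivity measurement, 1,000 for inference soundness, 60
families capped at 14 members / 9 untyped for the exhaustive-oracle
comparison (the 2^k enumeration is the oracle's cost, not the method's:
path-based inference is polynomial), and 1,000 random 2×2 tables at 1e−9
relative tolerance for the Woolf interval. Candidate ordering is
deterministic: affected fraction descending, then CADD descending, then
variant key; CADD is consumed as an input annotation and never computed.

## Known limitations

- Obligate-carrier and genotype inference are only as good as the single-
  introduction assumption; in a true bilineal family the model-violation
  warning fires and inference abstains.
- The criterion has no age censoring: a young unaffected carrier counts
  against a variant exactly like an elderly one (the field often reasons
  about this narratively; here it is deliberately structural and the
  threshold parameters are the only dials).
- Carrier-based MAFs understate allele counts if true homozygotes exist.
- `frequency_vs_reference` inherits whatever case/reference ascertainment
  mismatch exists between the cohorts being compared; it quantifies, but
  cannot correct, that bias.
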