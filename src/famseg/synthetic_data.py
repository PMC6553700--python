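"""Synthetic multi-incident families and case/control cohorts.

The family generator emulates the ascertainment of the analysis: three to
four generation pedigrees segregating a dominant founder variant with
reduced penetrance, phenocopies among non-carriers, married-in spouses who
never carry (rare-variant assumption), and a minimum number of affected
blood relatives (multi-incident ascertainment, default 4). Each meiosis is
an independent fair coin; affection is sampled as carrier → affected with
probability ``penetrance``, non-carrier → affected with probability
``phenocopy_rate``. The hidden carrier truth is retained next to a masked
observation set so that inference can be scored against it.

The cohort generator emulates genotyping summary structure: per-sample
binomial carrier sampling at configured case/control frequencies plus a
background of variants spanning the rarity threshold.

All sampling flows through one seeded generator; identical config + seed
gives byte-identical fixture bundles.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .pedigree import (
    Affection,
    Call,
    GenotypeCall,
    Individual,
    Origin,
    Pedigree,
    Sex,
    write_ped,
)
from .variant_filter import MISSENSE, NONSENSE, OTHER, VariantRecord, write_vcf

_ROMAN = ["I", "II", "III", "IV", "V", "VI"]

#: the planted disease variant shared by all simulations
CAUSAL_CHROM, CAUSAL_POS, CAUSAL_REF, CAUSAL_ALT = "7", 5000123, "C", "T"
CAUSAL_GENE = "CAND1"
CAUSAL_KEY = f"{CAUSAL_CHROM}:{CAUSAL_POS}:{CAUSAL_REF}:{CAUSAL_ALT}"


@dataclass(frozen=True)
class FamilySimConfig:
    family_id: str = "FAM1"
    n_generations: int = 3
    sibship_size_mean: float = 3.0
    marriage_prob: float = 0.7
    penetrance: float = 0.7
    phenocopy_rate: float = 0.02
    genotype_missingness: float = 0.15
    founder_carrier: bool = True
    min_affected: int = 4
    allow_bilineal: bool = False  # married-in spouses may carry when True
    seed: int = 0
    max_attempts: int = 10_000

    def __post_init__(self):
        if not 0 < self.penetrance <= 1:
            raise ValueError("penetrance must be in (0, 1]")
        if not 0 <= self.phenocopy_rate < 1:
            raise ValueError("phenocopy_rate must be in [0, 1)")
        if not 0 <= self.genotype_missingness < 1:
            raise ValueError("genotype_missingness must be in [0, 1)")
        if self.n_generations < 1:
            raise ValueError("need at least one generation")


@dataclass
class SimulatedFamily:
    pedigree: Pedigree
    truth: dict[str, bool]  # individual -> carries the planted variant
    observed_calls: list[GenotypeCall]
    married_in: set[str]
    config: FamilySimConfig
    causal_key: str = CAUSAL_KEY

    def truth_calls(self) -> list[GenotypeCall]:
        return [
            GenotypeCall(
                i,
                self.causal_key,
                Call.CARRIER if carrier else Call.WILDTYPE,
                Origin.OBSERVED,
            )
            for i, carrier in self.truth.items()
        ]

    def causal_record(self) -> VariantRecord:
        observed = {c.individual_id: c.call for c in self.observed_calls}
        genotypes = {
            i: observed.get(i, Call.MISSING) for i in self.truth
        }
        return VariantRecord(
            chrom=CAUSAL_CHROM,
            pos=CAUSAL_POS,
            ref=CAUSAL_REF,
            alt=CAUSAL_ALT,
            gene=CAUSAL_GENE,
            consequence=MISSENSE,
            cadd_phred=25.0,
            db_frequencies={},
            genotypes=genotypes,
        )


def _sample_family_once(
    cfg: FamilySimConfig, rng: np.random.Generator
) -> SimulatedFamily:
    members: list[Individual] = []
    truth: dict[str, bool] = {}
    married_in: set[str] = set()
    counters = [0] * cfg.n_generations

    def new_id(gen: int) -> str:
        counters[gen] += 1
        return f"{_ROMAN[gen]}-{counters[gen]}"

    def add(gen, father, mother, sex, carrier) -> str:
        iid = new_id(gen)
        affected = (
            rng.random() < (cfg.penetrance if carrier else cfg.phenocopy_rate)
        )
        onset = float(np.round(rng.normal(31, 8))) if affected else None
        members.append(
            Individual(
                individual_id=iid,
                family_id=cfg.family_id,
                father_id=father,
                mother_id=mother,
                sex=sex,
                affection=Affection.AFFECTED if affected else Affection.UNAFFECTED,
                age_at_onset=onset,
            )
        )
        truth[iid] = carrier
        return iid

    f0 = add(0, None, None, Sex.MALE, cfg.founder_carrier)
    m0 = add(0, None, None, Sex.FEMALE, False)
    couples = [(f0, m0)]
    for gen in range(1, cfg.n_generations):
        next_couples = []
        for father, mother in couples:
            parent_carrier = truth[father] or truth[mother]
            n_children = max(1, int(rng.poisson(cfg.sibship_size_mean)))
            for _ in range(n_children):
                carrier = bool(parent_carrier and rng.random() < 0.5)
                sex = Sex.MALE if rng.random() < 0.5 else Sex.FEMALE
                child = add(gen, father, mother, sex, carrier)
                if gen < cfg.n_generations - 1 and rng.random() < cfg.marriage_prob:
                    spouse_sex = Sex.FEMALE if sex is Sex.MALE else Sex.MALE
                    spouse_carrier = bool(
                        cfg.allow_bilineal and rng.random() < 0.01
                    )
                    spouse = add(gen, None, None, spouse_sex, spouse_carrier)
                    married_in.add(spouse)
                    pair = (child, spouse) if sex is Sex.MALE else (spouse, child)
                    next_couples.append(pair)
        couples = next_couples
    observed = [
        GenotypeCall(
            i,
            CAUSAL_KEY,
            Call.CARRIER if truth[i] else Call.WILDTYPE,
            Origin.OBSERVED,
        )
        for i in truth
        if rng.random() >= cfg.genotype_missingness
    ]
    ped = Pedigree(cfg.family_id, members)
    return SimulatedFamily(ped, truth, observed, married_in, cfg)


def simulate_family(cfg: FamilySimConfig = FamilySimConfig()) -> SimulatedFamily:
    """Draw one multi-incident family; resamples until the ascertainment
    condition holds (at least ``min_affected`` affected blood relatives and,
    when genotypes are masked, at least two affected members with an
    observed call)."""
    rng = np.random.default_rng(cfg.seed)
    for _ in range(cfg.max_attempts):
        sim = _sample_family_once(cfg, rng)
        blood = set(sim.truth) - sim.married_in
        affected = {
            i
            for i in blood
            if sim.pedigree[i].affection is Affection.AFFECTED
        }
        observed_ids = {c.individual_id for c in sim.observed_calls}
        need_observed = min(2, cfg.min_affected)
        if (
            len(affected) >= cfg.min_affected
            and len(affected & observed_ids) >= need_observed
        ):
            return sim
    raise RuntimeError(
        f"could not ascertain a family matching {cfg} in {cfg.max_attempts} attempts"
    )


# -- background variants within a family --------------------------------------


def family_background_records(
    sim: SimulatedFamily,
    n_background: int = 25,
    rng: np.random.Generator | None = None,
) -> list[VariantRecord]:
    """Non-causal variants for a family VCF: each enters through one random
    founder and is dropped through the pedigree by Mendelian transmission,
    with a mix of consequence classes and database frequencies spanning the
    rarity threshold."""
    if rng is None:
        rng = np.random.default_rng(sim.config.seed + 1)
    ped = sim.pedigree
    founders = sorted(ped.founders)
    order = [m.individual_id for m in ped.members]
    records = []
    for k in range(n_background):
        intro = founders[int(rng.integers(len(founders)))]
        carrier: dict[str, bool] = {}
        for iid in order:  # input order is topological (parents precede children)
            par = ped.parents(iid)
            if not par:
                carrier[iid] = iid == intro
            else:
                carrier[iid] = any(carrier.get(p, False) for p in par) and bool(
                    rng.random() < 0.5
                )
        cls = [MISSENSE, NONSENSE, OTHER][int(rng.integers(3))] if k else MISSENSE
        chrom = str(int(rng.integers(1, 23)))
        pos = int(rng.integers(1_000_000, 90_000_000))
        rare = rng.random() < 0.7
        freqs = {}
        if rng.random() < 0.8:  # the rest are "novel" (absent from databases)
            freqs["refdb"] = (
                float(rng.uniform(1e-5, 0.008)) if rare else float(rng.uniform(0.012, 0.2))
            )
        genotypes = {
            i: (Call.CARRIER if carrier[i] else Call.WILDTYPE)
            for i in sim.truth
            if rng.random() >= sim.config.genotype_missingness
        }
        genotypes = {i: genotypes.get(i, Call.MISSING) for i in sim.truth}
        records.append(
            VariantRecord(
                chrom=chrom,
                pos=pos,
                ref="A",
                alt="G",
                gene=f"BG{k:03d}",
                consequence=cls,
                cadd_phred=float(np.round(rng.uniform(0, 35), 1)),
                db_frequencies=freqs,
                genotypes=genotypes,
            )
        )
    return records


# -- case/control cohort -------------------------------------------------------


@dataclass(frozen=True)
class CohortSimConfig:
    n_cases: int = 500
    n_controls: int = 300
    causal_maf_cases: float = 0.0026
    causal_maf_controls: float = 0.0
    n_background_variants: int = 20
    background_maf_low: float = 1e-4
    background_maf_high: float = 0.05
    seed: int = 0

    def __post_init__(self):
        for f in (self.causal_maf_cases, self.causal_maf_controls):
            if not 0 <= f <= 0.5:
                raise ValueError("allele frequencies must be in [0, 0.5]")


@dataclass
class SimulatedCohort:
    case_records: list[VariantRecord]
    control_records: list[VariantRecord]
    frequency_table: dict[str, dict[str, float]]
    config: CohortSimConfig
    causal_key: str = CAUSAL_KEY


def _carrier_prob(maf: float) -> float:
    return 2 * maf * (1 - maf)  # heterozygote frequency under HWE


def simulate_cohort(cfg: CohortSimConfig = CohortSimConfig()) -> SimulatedCohort:
    rng = np.random.default_rng(cfg.seed)
    cases = [f"CASE{i:05d}" for i in range(1, cfg.n_cases + 1)]
    controls = [f"CTRL{i:05d}" for i in range(1, cfg.n_controls + 1)]

    # variant panel: the planted causal variant plus a rarity-spanning background
    panel: list[tuple[str, int, str, float, float, float | None]] = [
        (
            CAUSAL_CHROM,
            CAUSAL_POS,
            CAUSAL_GENE,
            cfg.causal_maf_cases,
            cfg.causal_maf_controls,
            None,  # novel: absent from the reference database
        )
    ]
    for k in range(cfg.n_background_variants):
        maf = float(
            np.exp(
                rng.uniform(
                    np.log(cfg.background_maf_low), np.log(cfg.background_maf_high)
                )
            )
        )
        chrom = str(int(rng.integers(1, 23)))
        pos = int(rng.integers(1_000_000, 90_000_000))
        panel.append((chrom, pos, f"BG{k:03d}", maf, maf, maf))

    freq_table: dict[str, dict[str, float]] = {}
    case_records, control_records = [], []
    for j, (chrom, pos, gene, maf_case, maf_ctrl, db_maf) in enumerate(panel):
        ref, alt = ("C", "T") if gene == CAUSAL_GENE else ("A", "G")
        cls = MISSENSE if j % 3 != 2 or gene == CAUSAL_GENE else NONSENSE
        key = f"{chrom}:{pos}:{ref}:{alt}"
        if db_maf is not None:
            freq_table[key] = {"refdb": db_maf}
        for samples, maf, bucket in (
            (cases, maf_case, case_records),
            (controls, maf_ctrl, control_records),
        ):
            hits = rng.random(len(samples)) < _carrier_prob(maf)
            genotypes = {
                s: (Call.CARRIER if h else Call.WILDTYPE)
                for s, h in zip(samples, hits)
            }
            bucket.append(
                VariantRecord(
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    gene=gene,
                    consequence=cls,
                    cadd_phred=float(np.round(rng.uniform(0, 35), 1)),
                    db_frequencies=dict(freq_table.get(key, {})),
                    genotypes=genotypes,
                )
            )
    return SimulatedCohort(case_records, control_records, freq_table, cfg)


# -- microsatellite markers ----------------------------------------------------

_MARKER_OFFSETS = {"MS1": -800_000, "MS2": -150_000, "MS3": 120_000, "MS4": 600_000}
_SIZE_POOL = list(range(150, 191, 2))


def simulate_markers(
    sims: Sequence[SimulatedFamily], rng: np.random.Generator | None = None
) -> list[dict]:
    """Microsatellite genotypes flanking the planted locus, one founder
    haplotype per family tightly linked to the variant (no recombination in
    the window). Returns TSV-ready row dicts."""
    if rng is None:
        rng = np.random.default_rng(sims[0].config.seed + 2 if sims else 2)
    rows = []
    for sim in sims:
        linked = {
            mid: int(_SIZE_POOL[int(rng.integers(len(_SIZE_POOL)))])
            for mid in _MARKER_OFFSETS
        }
        for iid, carrier in sim.truth.items():
            for mid, off in _MARKER_OFFSETS.items():
                other = int(_SIZE_POOL[int(rng.integers(len(_SIZE_POOL)))])
                a1 = linked[mid] if carrier else int(
                    _SIZE_POOL[int(rng.integers(len(_SIZE_POOL)))]
                )
                rows.append(
                    {
                        "family_id": sim.pedigree.family_id,
                        "individual_id": iid,
                        "marker_id": mid,
                        "physical_pos": CAUSAL_POS + off,
                        "allele1_bp": min(a1, other),
                        "allele2_bp": max(a1, other),
                    }
                )
    return rows


# -- fixture bundle ------------------------------------------------------------


def write_fixture_bundle(
    families: Sequence[SimulatedFamily],
    cohort: SimulatedCohort | None,
    outdir: str | Path,
    n_background: int = 25,
) -> dict:
    """Write PED, per-family VCFs, cohort VCF pair, frequency TSV, marker TSV
    and a JSON manifest; the bundle is sufficient to run the full pipeline."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"families": [], "causal_key": CAUSAL_KEY, "files": {}}

    freq_rows: list[tuple[str, str, float]] = []
    if families:
        write_ped([s.pedigree for s in families], outdir / "families.ped")
        manifest["files"]["ped"] = "families.ped"
        for sim in families:
            rng = np.random.default_rng(sim.config.seed + 1)
            records = [sim.causal_record()] + family_background_records(
                sim, n_background, rng
            )
            name = f"{sim.pedigree.family_id}.vcf"
            write_vcf(records, outdir / name, samples=sorted(sim.truth))
            for r in records:
                for db, f in r.db_frequencies.items():
                    freq_rows.append((r.variant_key, db, f))
            manifest["families"].append(
                {
                    "family_id": sim.pedigree.family_id,
                    "config": asdict(sim.config),
                    "vcf": name,
                    "truth_carriers": sorted(i for i, c in sim.truth.items() if c),
                }
            )
        marker_rows = simulate_markers(families)
        with (outdir / "markers.tsv").open("w") as fh:
            cols = [
                "family_id",
                "individual_id",
                "marker_id",
                "physical_pos",
                "allele1_bp",
                "allele2_bp",
            ]
            fh.write("\t".join(cols) + "\n")
            for row in marker_rows:
                fh.write("\t".join(str(row[c]) for c in cols) + "\n")
        manifest["files"]["markers"] = "markers.tsv"

    if cohort is not None:
        write_vcf(cohort.case_records, outdir / "cases.vcf")
        write_vcf(cohort.control_records, outdir / "controls.vcf")
        manifest["files"]["cases"] = "cases.vcf"
        manifest["files"]["controls"] = "controls.vcf"
        manifest["cohort_config"] = asdict(cohort.config)
        for key, dbs in cohort.frequency_table.items():
            for db, f in dbs.items():
                freq_rows.append((key, db, f))

    seen = set()
    with (outdir / "frequencies.tsv").open("w") as fh:
        fh.write("variant_key\tdatabase\tallele_fraction\n")
        for key, db, f in freq_rows:
            if (key, db) in seen:
                continue
            seen.add((key, db))
            fh.write(f"{key}\t{db}\t{f:.10g}\n")
    manifest["files"]["frequencies"] = "frequencies.tsv"

    with (outdir / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest["files"]["manifest"] = "manifest.json"
    return manifest
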