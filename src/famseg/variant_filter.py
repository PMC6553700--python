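"""Candidate-variant filtering: autosomal, heterozygous, missense/nonsense,
rare in every configured frequency database.

The consequence annotation is consumed from the VCF, not computed: the loader
accepts either a minimal ``GENE|consequence`` INFO tag or an ANN/SnpEff-style
field (first transcript wins). A variant absent from a frequency database
counts as frequency 0 ("not present"), and "below 1%" is a strict
inequality, so a variant at exactly the threshold is removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import pandas as pd
from cyvcf2 import VCF

from .exceptions import AnnotationError, HomozygousGenotypeWarning, InsufficientDataError
from .pedigree import Affection, Call, GenotypeCall, Origin, Pedigree

MISSENSE = "missense"
NONSENSE = "nonsense"
OTHER = "other"

AUTOSOMES = {str(i) for i in range(1, 23)}

_NONSENSE_TERMS = ("stop_gained", "nonsense", "stop-gained")
_MISSENSE_TERMS = ("missense",)


def normalize_chrom(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


@dataclass
class VariantRecord:
    """One biallelic site with its annotation and per-sample calls."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: str
    cadd_phred: float | None = None
    db_frequencies: dict[str, float] = field(default_factory=dict)
    genotypes: dict[str, Call] = field(default_factory=dict)

    @property
    def variant_key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def is_autosomal(self) -> bool:
        return self.chrom in AUTOSOMES

    def carriers(self) -> set[str]:
        return {s for s, c in self.genotypes.items() if c is Call.CARRIER}

    def calls(self) -> list[GenotypeCall]:
        return [
            GenotypeCall(s, self.variant_key, c, Origin.OBSERVED)
            for s, c in self.genotypes.items()
            if c is not Call.MISSING
        ]


@dataclass(frozen=True)
class FilterCriteria:
    maf_threshold: float = 0.01  # strict less-than
    consequences: frozenset = frozenset({MISSENSE, NONSENSE})
    autosomes_only: bool = True
    heterozygous_only: bool = True

    def __post_init__(self):
        if not 0 < self.maf_threshold <= 1:
            raise ValueError(f"maf_threshold must be in (0, 1], got {self.maf_threshold}")


def _parse_annotation(raw: str) -> tuple[str, str]:
    """Return (gene, consequence-class) from a minimal ``GENE|consequence``
    value or an ANN-style ``Allele|term|impact|Gene|...`` entry."""
    first = raw.split(",")[0]
    fields = first.split("|")
    if len(fields) >= 4:  # ANN dialect
        gene, term = fields[3], fields[1]
    elif len(fields) == 2:
        gene, term = fields[0], fields[1]
    else:
        raise AnnotationError(f"unparseable consequence annotation {raw!r}")
    term_l = term.lower()
    if any(t in term_l for t in _NONSENSE_TERMS):
        cls = NONSENSE
    elif any(t in term_l for t in _MISSENSE_TERMS):
        cls = MISSENSE
    else:
        cls = OTHER
    return gene, cls


def load_variants(vcf_path: str | Path, consequence_tag: str = "GENECONS") -> list[VariantRecord]:
    """Read a VCF into :class:`VariantRecord` objects, splitting multiallelic
    sites into one record per alternate allele.

    Genotype mapping per split allele: any heterozygous genotype containing
    the allele → carrier; homozygous-alternate → carrier with a warning (the
    dominant model does not distinguish dosage); ``./.`` → missing;
    everything else → wildtype for that allele.
    """
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    records: list[VariantRecord] = []
    for var in vcf:
        raw = var.INFO.get(consequence_tag)
        if raw is None:
            raise AnnotationError(
                f"record {var.CHROM}:{var.POS} lacks INFO tag {consequence_tag!r}"
            )
        gene, cls = _parse_annotation(str(raw))
        cadd = var.INFO.get("CADD")
        # htslib stores INFO floats single-precision; trim the excess digits
        cadd = float(f"{float(cadd):g}") if cadd is not None else None
        gts = var.genotypes  # [allele1, allele2, phased] per sample
        for alt_index, alt in enumerate(var.ALT, start=1):
            genotypes: dict[str, Call] = {}
            for sample, gt in zip(samples, gts):
                a, b = gt[0], gt[1]
                if a < 0 or b < 0:
                    genotypes[sample] = Call.MISSING
                elif a == alt_index and b == alt_index:
                    warnings.warn(
                        f"{sample} homozygous for {var.CHROM}:{var.POS}:{alt}; "
                        "collapsed to carrier",
                        HomozygousGenotypeWarning,
                        stacklevel=2,
                    )
                    genotypes[sample] = Call.CARRIER
                elif a == alt_index or b == alt_index:
                    genotypes[sample] = Call.CARRIER
                else:
                    genotypes[sample] = Call.WILDTYPE
            records.append(
                VariantRecord(
                    chrom=normalize_chrom(var.CHROM),
                    pos=var.POS,
                    ref=var.REF,
                    alt=alt,
                    gene=gene,
                    consequence=cls,
                    cadd_phred=cadd,
                    genotypes=genotypes,
                )
            )
    return records


def write_vcf(
    records: Sequence[VariantRecord],
    path: str | Path,
    samples: Sequence[str] | None = None,
    consequence_tag: str = "GENECONS",
) -> None:
    """Write records as a VCF 4.2 file in the dialect :func:`load_variants`
    reads back identically (biallelic rows, GT only, het carriers)."""
    if samples is None:
        seen: dict[str, None] = {}
        for r in records:
            for s in r.genotypes:
                seen.setdefault(s)
        samples = list(seen)
    gt_of = {Call.CARRIER: "0/1", Call.WILDTYPE: "0/0", Call.MISSING: "./."}
    with Path(path).open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            f'##INFO=<ID={consequence_tag},Number=1,Type=String,'
            'Description="Gene|consequence-class annotation">\n'
        )
        fh.write(
            '##INFO=<ID=CADD,Number=1,Type=Float,Description="CADD phred score">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = sorted({r.chrom for r in records}, key=lambda c: (len(c), c))
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for r in sorted(records, key=lambda r: ((len(r.chrom), r.chrom), r.pos, r.alt)):
            info = f"{consequence_tag}={r.gene}|{r.consequence}"
            if r.cadd_phred is not None:
                info += f";CADD={r.cadd_phred:g}"
            gts = "\t".join(gt_of[r.genotypes.get(s, Call.MISSING)] for s in samples)
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t{info}\tGT\t{gts}\n"
            )


# -- frequency databases ------------------------------------------------------


def load_frequency_table(path: str | Path) -> dict[str, dict[str, float]]:
    """TSV of (variant_key, database, allele_fraction) →
    {variant_key: {database: fraction}}."""
    df = pd.read_csv(path, sep="\t", dtype={"variant_key": str, "database": str})
    out: dict[str, dict[str, float]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.variant_key, {})[row.database] = float(row.allele_fraction)
    return out


def attach_frequencies(
    records: Iterable[VariantRecord],
    tables: dict[str, dict[str, float]] | Sequence[dict[str, dict[str, float]]],
) -> list[VariantRecord]:
    """Merge database frequencies onto records (returns new records; absent
    entries are simply absent and count as 0 at filter time)."""
    if isinstance(tables, dict):
        tables = [tables]
    out = []
    for r in records:
        freqs = dict(r.db_frequencies)
        for t in tables:
            freqs.update(t.get(r.variant_key, {}))
        out.append(replace(r, db_frequencies=freqs))
    return out


def load_filter_criteria(path: str | Path) -> FilterCriteria:
    """Build :class:`FilterCriteria` from a YAML key-value file; keys are the
    dataclass fields, ``consequences`` as a list."""
    import yaml

    with Path(path).open() as fh:
        raw = yaml.safe_load(fh) or {}
    if "consequences" in raw:
        raw["consequences"] = frozenset(raw["consequences"])
    return FilterCriteria(**raw)


# -- the candidate filter -----------------------------------------------------


def apply_filter(
    records: Iterable[VariantRecord], crit: FilterCriteria = FilterCriteria()
) -> list[VariantRecord]:
    """Retain autosomal variants of an allowed consequence class whose
    frequency is below the threshold in *every* configured database.
    Ordering is preserved and the input is untouched."""
    out = []
    for r in records:
        if crit.autosomes_only and not r.is_autosomal:
            continue
        if r.consequence not in crit.consequences:
            continue
        if any(f >= crit.maf_threshold for f in r.db_frequencies.values()):
            continue
        out.append(r)
    return out


class SharedVariants(NamedTuple):
    records: list[VariantRecord]
    mode: str  # "full" | "all_but_one"


def shared_by_affected(
    records: Iterable[VariantRecord],
    ped: Pedigree,
    min_affected_fraction: float | None = None,
) -> SharedVariants:
    """Variants carried by the sequenced affected members of a family.

    The discovery pass requires all sequenced affected members to carry the
    variant (mode ``full``). When no variant survives, the fallback accepts
    variants carried by all but one of them (mode ``all_but_one``) — the
    rescue used when a fully shared variant cannot be found. An explicit
    ``min_affected_fraction`` replaces the two-stage rule with a single
    carrier-fraction cutoff.
    """
    records = list(records)
    sequenced: set[str] = set()
    for r in records:
        for s, c in r.genotypes.items():
            if c is not Call.MISSING and s in ped:
                if ped[s].affection is Affection.AFFECTED:
                    sequenced.add(s)
    n = len(sequenced)
    if n < 2:
        raise InsufficientDataError(
            f"family {ped.family_id!r}: {n} sequenced affected member(s); "
            "need at least 2 for sharing analysis"
        )

    def n_carrying(r: VariantRecord) -> int:
        return sum(1 for s in sequenced if r.genotypes.get(s) is Call.CARRIER)

    if min_affected_fraction is not None:
        need = min_affected_fraction * n
        kept = [r for r in records if n_carrying(r) >= need]
        mode = "full" if min_affected_fraction >= 1 else "all_but_one"
        return SharedVariants(kept, mode)
    full = [r for r in records if n_carrying(r) == n]
    if full:
        return SharedVariants(full, "full")
    fallback = [r for r in records if n_carrying(r) >= n - 1]
    return SharedVariants(fallback, "all_but_one")
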