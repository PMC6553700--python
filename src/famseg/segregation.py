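"""Per-family co-segregation evaluation and the discovery workflow.

A variant is deemed to co-segregate with disease in a family when at least
75% of the affected blood relatives with an observed or inferred genotype
carry it, and no more than one unaffected family member carries it —
excluding obligate carriers, i.e. unaffected parents of affected individuals
and untyped individuals forced to carry under the single-founder dominant
model. The 75% threshold is inclusive (3 of 4 passes), which accommodates
both phenocopies (an affected non-carrier) and reduced penetrance (an
unaffected carrier).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

from .exceptions import InsufficientDataError
from .pedigree import (
    Affection,
    Call,
    GenotypeCall,
    Pedigree,
    call_map,
    infer_genotypes,
    infer_obligate_carriers,
)
from .variant_filter import (
    MISSENSE,
    NONSENSE,
    SharedVariants,
    VariantRecord,
    attach_frequencies,
)

FULL = "full"
ALL_BUT_ONE = "all_but_one"
GENOTYPED_FOLLOWUP = "genotyped_followup"

SEGREGATING = "segregating"
NOT_SEGREGATING = "not_segregating"


@dataclass
class SegregationResult:
    family_id: str
    variant_key: str
    n_affected_informative: int
    n_affected_carriers: int
    obligate_carriers: set[str]
    n_unaffected_carriers_counted: int
    verdict: str
    mode: str = GENOTYPED_FOLLOWUP

    def __post_init__(self):
        if self.n_affected_carriers > self.n_affected_informative:
            raise ValueError("more affected carriers than informative affected")

    @property
    def affected_fraction(self) -> float:
        return self.n_affected_carriers / self.n_affected_informative


def evaluate_segregation(
    ped: Pedigree,
    calls: Iterable[GenotypeCall],
    variant_key: str,
    *,
    affected_fraction_threshold: float = 0.75,
    max_unaffected_carriers: int = 1,
    include_possible: bool = False,
    extended_obligate: bool = True,
    mode: str = GENOTYPED_FOLLOWUP,
) -> SegregationResult:
    """Apply the co-segregation criterion to one variant in one family.

    Tallies use observed plus inferred calls; individuals with "possible" or
    unknown affection are excluded from both numerator and denominator (set
    ``include_possible`` to count possible diagnoses as affected), as are
    married-in members. ``extended_obligate=False`` restricts the obligate
    exclusion to the literal rule — unaffected parents of affected
    individuals — dropping the path-based extension to more distant forced
    carriers.
    """
    calls = list(calls)
    observed_carriers = any(
        c.call is Call.CARRIER
        and c.variant_key == variant_key
        and c.individual_id in ped
        for c in calls
    )
    obligate: set[str] = set()
    if observed_carriers:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # single-origin violations: count observed only
            merged = infer_genotypes(ped, calls, variant_key)
            if extended_obligate:
                obligate = infer_obligate_carriers(ped, calls, variant_key)
    else:
        merged = calls
    cmap = call_map(ped, merged, variant_key)

    blood = ped.blood_members()
    affected_statuses = {Affection.AFFECTED}
    if include_possible:
        affected_statuses.add(Affection.POSSIBLE)
    affected = [i for i in blood if ped[i].affection in affected_statuses]
    informative = [i for i in affected if i in cmap]
    if not informative:
        raise InsufficientDataError(
            f"family {ped.family_id!r}: no informative affected member "
            f"for {variant_key}"
        )
    n_car = sum(1 for i in informative if cmap[i].call is Call.CARRIER)

    # unaffected parents of affected individuals are never counted against
    # the variant: under a dominant model one of them had to transmit it
    excluded = set(obligate)
    for a in affected:
        for p in ped.parents(a):
            if ped[p].affection is Affection.UNAFFECTED:
                excluded.add(p)
    unaffected_counted = [
        i
        for i in blood
        if ped[i].affection is Affection.UNAFFECTED
        and i not in excluded
        and cmap.get(i) is not None
        and cmap[i].call is Call.CARRIER
    ]
    # report only members who can actually be carriers as obligate
    obligate_out = {
        x for x in excluded if cmap.get(x) is None or cmap[x].call is Call.CARRIER
    }

    fraction = n_car / len(informative)
    verdict = (
        SEGREGATING
        if fraction >= affected_fraction_threshold
        and len(unaffected_counted) <= max_unaffected_carriers
        else NOT_SEGREGATING
    )
    return SegregationResult(
        family_id=ped.family_id,
        variant_key=variant_key,
        n_affected_informative=len(informative),
        n_affected_carriers=n_car,
        obligate_carriers=obligate_out,
        n_unaffected_carriers_counted=len(unaffected_counted),
        verdict=verdict,
        mode=mode,
    )


def _merge_record_calls(
    rec: VariantRecord, ped: Pedigree, extra_calls: Iterable[GenotypeCall] | None
) -> list[GenotypeCall]:
    calls = [c for c in rec.calls() if c.individual_id in ped]
    have = {c.individual_id for c in calls}
    for c in extra_calls or ():
        if (
            c.variant_key == rec.variant_key
            and c.individual_id in ped
            and c.individual_id not in have
        ):
            calls.append(c)
    return calls


def nominate_candidates(
    ped: Pedigree,
    shared: SharedVariants | Sequence[VariantRecord],
    calls: Iterable[GenotypeCall] | None = None,
) -> list[SegregationResult]:
    """Evaluate each shared candidate in the family and return the
    segregating ones, ordered by affected fraction (desc), CADD (desc), then
    variant key. ``calls`` supplies follow-up genotypes for family members
    not in the VCF. An empty list means the family is unresolved."""
    if isinstance(shared, SharedVariants):
        records, mode = shared.records, shared.mode
    else:
        records, mode = list(shared), FULL
    calls = list(calls or ())
    keyed: dict[str, tuple[SegregationResult, VariantRecord]] = {}
    for rec in records:
        try:
            res = evaluate_segregation(
                ped, _merge_record_calls(rec, ped, calls), rec.variant_key, mode=mode
            )
        except InsufficientDataError:
            continue
        if res.verdict == SEGREGATING:
            keyed[rec.variant_key] = (res, rec)
    ordered = sorted(
        keyed.values(),
        key=lambda pair: (
            -pair[0].affected_fraction,
            -(pair[1].cadd_phred if pair[1].cadd_phred is not None else float("-inf")),
            pair[0].variant_key,
        ),
    )
    return [res for res, _ in ordered]


class MiningReport(NamedTuple):
    results: list[SegregationResult]
    excluded: list[tuple[str, str]]  # (variant_key, reason)


def mine_cohort(
    gene: str,
    case_records: Sequence[VariantRecord],
    control_records: Sequence[VariantRecord],
    freq_tables: dict[str, dict[str, float]] | Sequence[dict] | None,
    peds: Sequence[Pedigree],
    calls: Iterable[GenotypeCall] | None = None,
    *,
    maf_threshold: float = 0.01,
) -> MiningReport:
    """Mine cohort sequencing data for additional rare variants in a gene of
    interest: missense/nonsense variants present in at least one case,
    absent from every control, and rare in every frequency database are
    evaluated for segregation in each carrier's family
    (mode ``genotyped_followup``). Variants failing the exclusivity or
    frequency rule are reported as excluded with a machine-readable reason.
    """
    calls = list(calls or ())
    cands = [r for r in case_records if r.gene == gene]
    if not cands:
        warnings.warn(f"gene {gene!r} absent from case annotations", stacklevel=2)
        return MiningReport([], [])
    if freq_tables:
        cands = attach_frequencies(cands, freq_tables)
    control_carriers = {
        r.variant_key for r in control_records if r.carriers()
    }
    by_member = {m.individual_id: p for p in peds for m in p.members}
    results: list[SegregationResult] = []
    excluded: list[tuple[str, str]] = []
    for rec in cands:
        vk = rec.variant_key
        if rec.consequence not in (MISSENSE, NONSENSE):
            excluded.append((vk, "consequence_not_missense_or_nonsense"))
            continue
        if not rec.carriers():
            excluded.append((vk, "no_case_carriers"))
            continue
        if vk in control_carriers:
            excluded.append((vk, "present_in_controls"))
            continue
        if any(f >= maf_threshold for f in rec.db_frequencies.values()):
            excluded.append((vk, "database_maf_at_or_above_threshold"))
            continue
        fams = {
            by_member[s].family_id: by_member[s]
            for s in sorted(rec.carriers())
            if s in by_member
        }
        if not fams:
            excluded.append((vk, "no_family_data_for_carriers"))
            continue
        for ped in fams.values():
            try:
                results.append(
                    evaluate_segregation(
                        ped,
                        _merge_record_calls(rec, ped, calls),
                        vk,
                        mode=GENOTYPED_FOLLOWUP,
                    )
                )
            except InsufficientDataError:
                continue
    return MiningReport(results, excluded)
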