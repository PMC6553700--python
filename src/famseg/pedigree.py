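"""Pedigree parsing, relationship queries, and dominant-model genotype inference.

A pedigree is a directed acyclic graph with parent→child edges. Genotype
inference assumes the disease variant entered the family through exactly one
founder and that there are no de novo events, so the carrier set in any
Mendelian-consistent configuration is a set of descent paths rooted at that
founder. Under these assumptions an individual is an *obligate carrier* when
every consistent configuration makes them a carrier: classically the
unaffected parent through whom an affected child must have received the
variant, and any untyped individual sitting on every transmission path
between observed carriers and the introducing founder.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .exceptions import (
    DuplicateIndividualError,
    InsufficientDataError,
    MendelianInconsistencyError,
    PedigreeStructureError,
    SingleOriginViolationWarning,
    UnknownIndividualError,
)

MISSING = "0"


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"

    @classmethod
    def from_ped(cls, code: str) -> "Sex":
        return {"1": cls.MALE, "2": cls.FEMALE}.get(code, cls.UNKNOWN)

    def to_ped(self) -> str:
        return {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}[self]


class Affection(str, Enum):
    """Affection status. ``POSSIBLE`` is a PED extension (code 3) for
    individuals with an unconfirmed diagnosis; they are excluded from
    segregation tallies by default."""

    UNAFFECTED = "unaffected"
    AFFECTED = "affected"
    POSSIBLE = "possible"
    UNKNOWN = "unknown"

    @classmethod
    def from_ped(cls, code: str) -> "Affection":
        return {
            "1": cls.UNAFFECTED,
            "2": cls.AFFECTED,
            "3": cls.POSSIBLE,
        }.get(code, cls.UNKNOWN)

    def to_ped(self) -> str:
        return {
            Affection.UNAFFECTED: "1",
            Affection.AFFECTED: "2",
            Affection.POSSIBLE: "3",
            Affection.UNKNOWN: "0",
        }[self]


class Call(str, Enum):
    CARRIER = "carrier"
    WILDTYPE = "wildtype"
    MISSING = "missing"


class Origin(str, Enum):
    OBSERVED = "observed"
    INFERRED = "inferred"


@dataclass
class Individual:
    individual_id: str
    family_id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: Sex = Sex.UNKNOWN
    affection: Affection = Affection.UNKNOWN
    age_at_onset: float | None = None
    age_at_exam: float | None = None
    placeholder: bool = False


@dataclass(frozen=True)
class GenotypeCall:
    individual_id: str
    variant_key: str
    call: Call
    origin: Origin = Origin.OBSERVED


class Pedigree:
    """One family as a parent→child DAG.

    Every non-founder has exactly two recorded parents: rows listing a
    single parent are padded with a placeholder founder so that path logic
    never needs to special-case half-specified parentage.
    """

    def __init__(
        self,
        family_id: str,
        members: Iterable[Individual],
        proband_id: str | None = None,
    ):
        self.family_id = family_id
        self._members: dict[str, Individual] = {}
        for ind in members:
            if ind.individual_id in self._members:
                raise DuplicateIndividualError(
                    f"duplicate individual id {ind.individual_id!r} "
                    f"in family {family_id!r}"
                )
            self._members[ind.individual_id] = ind
        self._pad_placeholders()
        self.graph = nx.DiGraph()
        self.graph.add_nodes_from(self._members)
        for ind in self._members.values():
            for pid, role in ((ind.father_id, "father"), (ind.mother_id, "mother")):
                if pid is None:
                    continue
                if pid not in self._members:
                    raise PedigreeStructureError(
                        f"{role} {pid!r} of {ind.individual_id!r} is not a member "
                        f"of family {family_id!r}"
                    )
                self.graph.add_edge(pid, ind.individual_id)
        self._validate()
        self._proband_id = proband_id

    # -- construction helpers -------------------------------------------------

    def _pad_placeholders(self) -> None:
        pads: dict[tuple[str, str], str] = {}
        for ind in list(self._members.values()):
            pair = (ind.father_id, ind.mother_id)
            if (pair[0] is None) == (pair[1] is None):
                continue  # founder or fully specified
            known = pair[0] or pair[1]
            side = "mother" if pair[0] else "father"
            key = (known, side)
            if key not in pads:
                pid = f"{known}.spouse"
                n = 1
                while pid in self._members:
                    n += 1
                    pid = f"{known}.spouse{n}"
                sex = Sex.FEMALE if side == "mother" else Sex.MALE
                self._members[pid] = Individual(
                    pid, self.family_id, sex=sex, placeholder=True
                )
                pads[key] = pid
            if side == "mother":
                ind.mother_id = pads[key]
            else:
                ind.father_id = pads[key]

    def _validate(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            cyc = nx.find_cycle(self.graph)
            raise PedigreeStructureError(
                f"individual {cyc[0][0]!r} in family {self.family_id!r} "
                f"is its own ancestor (cycle {[e[0] for e in cyc]})"
            )
        for ind in self._members.values():
            f = self._members.get(ind.father_id) if ind.father_id else None
            m = self._members.get(ind.mother_id) if ind.mother_id else None
            if f is not None and f.sex is Sex.FEMALE:
                raise PedigreeStructureError(
                    f"father {f.individual_id!r} of {ind.individual_id!r} is female"
                )
            if m is not None and m.sex is Sex.MALE:
                raise PedigreeStructureError(
                    f"mother {m.individual_id!r} of {ind.individual_id!r} is male"
                )

    # -- basic queries --------------------------------------------------------

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self._members

    def __len__(self) -> int:
        return len(self._members)

    def __iter__(self):
        return iter(self._members)

    def __getitem__(self, individual_id: str) -> Individual:
        try:
            return self._members[individual_id]
        except KeyError:
            raise UnknownIndividualError(
                f"{individual_id!r} not in family {self.family_id!r}"
            ) from None

    @property
    def members(self) -> list[Individual]:
        return list(self._members.values())

    @property
    def founders(self) -> set[str]:
        return {i for i in self._members if self.graph.in_degree(i) == 0}

    def parents(self, individual_id: str) -> set[str]:
        self[individual_id]
        return set(self.graph.predecessors(individual_id))

    def children(self, individual_id: str) -> set[str]:
        self[individual_id]
        return set(self.graph.successors(individual_id))

    def ancestors(self, individual_id: str) -> set[str]:
        self[individual_id]
        return set(nx.ancestors(self.graph, individual_id))

    def affected(self, include_possible: bool = False) -> list[str]:
        keep = {Affection.AFFECTED}
        if include_possible:
            keep.add(Affection.POSSIBLE)
        return [i for i, m in self._members.items() if m.affection in keep]

    @property
    def proband(self) -> str:
        """The first affected member in input order (or the first member)."""
        if self._proband_id is not None:
            return self._proband_id
        aff = self.affected()
        return aff[0] if aff else next(iter(self._members))

    def blood_relatives(self, individual_id: str) -> set[str]:
        """All members sharing at least one common ancestor with
        ``individual_id`` (counting an individual as its own ancestor, so
        direct ancestors and descendants are included). Married-in members
        are excluded by construction."""
        anc_a = self.ancestors(individual_id) | {individual_id}
        out = set()
        for other in self._members:
            if other == individual_id:
                continue
            if anc_a & (self.ancestors(other) | {other}):
                out.add(other)
        return out

    def blood_members(self) -> set[str]:
        """Blood relatives of the proband, proband included."""
        p = self.proband
        return self.blood_relatives(p) | {p}


# -- PED I/O ------------------------------------------------------------------


def _parse_age(token: str) -> float | None:
    if token in ("0", "-9", "", "."):
        return None
    return float(token)


def parse_ped(path: str | Path) -> list[Pedigree]:
    """Parse a whitespace-delimited PED file into one :class:`Pedigree` per
    family.

    Mandatory columns: FID IID PAT MAT SEX PHENO. Optional columns 7-8 carry
    age at onset and age at examination (0 = missing). Affection codes:
    1 unaffected, 2 affected, 3 possible, 0/-9 unknown.
    """
    path = Path(path)
    fams: dict[str, list[Individual]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tok = line.split()
            if len(tok) < 6:
                raise PedigreeStructureError(
                    f"{path}:{lineno}: expected >=6 columns, got {len(tok)}"
                )
            fid, iid, pat, mat, sex, pheno = tok[:6]
            ind = Individual(
                individual_id=iid,
                family_id=fid,
                father_id=None if pat == MISSING else pat,
                mother_id=None if mat == MISSING else mat,
                sex=Sex.from_ped(sex),
                affection=Affection.from_ped(pheno),
                age_at_onset=_parse_age(tok[6]) if len(tok) > 6 else None,
                age_at_exam=_parse_age(tok[7]) if len(tok) > 7 else None,
            )
            fams.setdefault(fid, []).append(ind)
    return [Pedigree(fid, members) for fid, members in fams.items()]


def write_ped(pedigrees: Sequence[Pedigree] | Pedigree, path: str | Path) -> None:
    """Write pedigrees in the same dialect :func:`parse_ped` reads.

    Placeholder founders synthesized during parsing are written as ordinary
    rows, so a write/parse round trip is lossless.
    """
    if isinstance(pedigrees, Pedigree):
        pedigrees = [pedigrees]
    with_ages = any(
        m.age_at_onset is not None or m.age_at_exam is not None
        for p in pedigrees
        for m in p.members
    )

    def fmt_age(a: float | None) -> str:
        if a is None:
            return "0"
        return f"{a:g}"

    with Path(path).open("w") as fh:
        for ped in pedigrees:
            for m in ped.members:
                row = [
                    ped.family_id,
                    m.individual_id,
                    m.father_id or MISSING,
                    m.mother_id or MISSING,
                    m.sex.to_ped(),
                    m.affection.to_ped(),
                ]
                if with_ages:
                    row += [fmt_age(m.age_at_onset), fmt_age(m.age_at_exam)]
                fh.write("\t".join(row) + "\n")


# -- single-founder dominant-model inference ----------------------------------


def _observed_sets(
    ped: Pedigree, calls: Iterable[GenotypeCall], variant_key: str
) -> tuple[set[str], set[str]]:
    carriers, wildtypes = set(), set()
    for c in calls:
        if c.variant_key != variant_key or c.individual_id not in ped:
            continue
        if c.call is Call.CARRIER:
            carriers.add(c.individual_id)
        elif c.call is Call.WILDTYPE:
            wildtypes.add(c.individual_id)
    if carriers & wildtypes:
        both = sorted(carriers & wildtypes)
        raise MendelianInconsistencyError(
            f"conflicting carrier/wildtype calls for {both} at {variant_key}"
        )
    return carriers, wildtypes


def _descent_graph(ped: Pedigree, blocked: set[str]) -> nx.DiGraph:
    return ped.graph.subgraph(set(ped.graph) - blocked)


def _feasible_founders(
    ped: Pedigree, carriers: set[str], wildtypes: set[str]
) -> set[str]:
    """Founders that could be the single introduction: every observed carrier
    must be reachable from the founder through a descent chain avoiding
    observed wild-type individuals. A founder observed as a carrier must be
    the introduction itself; two carrier founders violate the model."""
    founders = ped.founders
    carrier_founders = carriers & founders
    if len(carrier_founders) > 1:
        return set()
    G = _descent_graph(ped, wildtypes - carriers)
    candidates = carrier_founders if carrier_founders else founders - wildtypes
    feasible = set()
    for f in candidates:
        if all(
            c == f or (c in G and f in G and nx.has_path(G, f, c)) for c in carriers
        ):
            feasible.add(f)
    return feasible


def _forced_carrier(
    ped: Pedigree, carriers: set[str], wildtypes: set[str], target: str
) -> bool:
    """True iff ``target`` carries the variant in every Mendelian-consistent
    configuration compatible with ``carriers``/``wildtypes`` (single founder
    introduction, no de novo).

    Path rule: for a fixed introducing founder f, a node is forced exactly
    when it is the founder itself or when removing it disconnects some
    observed carrier from f (every transmission path runs through it). The
    node is an obligate overall when that holds for every feasible founder.
    """
    if target in wildtypes:
        return False
    feasible = _feasible_founders(ped, carriers, wildtypes)
    if not feasible or not carriers:
        return False
    G = _descent_graph(ped, wildtypes)
    for f in feasible:
        if f == target:
            continue  # the introducing founder is a carrier by definition
        G2 = G.subgraph(set(G) - {target})
        cut = any(
            c != f and (c not in G2 or f not in G2 or not nx.has_path(G2, f, c))
            for c in carriers
            if c != target
        )
        if not cut:
            return False
    return True


def _can_carry(
    ped: Pedigree, carriers: set[str], wildtypes: set[str], target: str
) -> bool:
    """True iff some Mendelian-consistent configuration makes ``target`` a
    carrier (used to force wild-type calls when False)."""
    if target in wildtypes:
        return False
    feasible = _feasible_founders(ped, carriers, wildtypes)
    G = _descent_graph(ped, wildtypes)
    for f in feasible:
        if f == target:
            return True
        if target in G and f in G and nx.has_path(G, f, target):
            return True
    return False


def _check_trios(
    ped: Pedigree, carriers: set[str], wildtypes: set[str]
) -> None:
    for child in carriers:
        par = ped.parents(child)
        if len(par) == 2 and par <= wildtypes:
            f, m = sorted(par)
            raise MendelianInconsistencyError(
                f"carrier {child!r} has two observed wild-type parents "
                f"({f!r}, {m!r}): impossible without a de novo event"
            )


def infer_obligate_carriers(
    ped: Pedigree,
    calls: Iterable[GenotypeCall],
    variant_key: str,
) -> set[str]:
    """Individuals who must carry the variant but are not themselves affected.

    Includes (a) unaffected parents of affected carriers through whom
    transmission is forced (the co-parent observed wild-type or outside the
    carrier-connecting lineage), and (b) untyped individuals lying on every
    transmission path connecting the observed carriers to the introducing
    founder. Equivalently: every non-affected individual who is a carrier in
    each Mendelian-consistent genotype configuration, judged without using
    their own genotype call. Never returns an observed wild-type individual.
    """
    calls = list(calls)
    carriers, wildtypes = _observed_sets(ped, calls, variant_key)
    if not carriers:
        raise InsufficientDataError(
            f"no observed carriers of {variant_key} in family {ped.family_id!r}"
        )
    if not _feasible_founders(ped, carriers, wildtypes):
        warnings.warn(
            f"family {ped.family_id!r}: observed carriers of {variant_key} "
            "cannot descend from a single founder introduction",
            SingleOriginViolationWarning,
            stacklevel=2,
        )
        return set()
    obligate = set()
    for ind in ped.members:
        x = ind.individual_id
        if ind.affection is Affection.AFFECTED or x in wildtypes:
            continue
        # judge x without its own call: an observed carrier is obligate only
        # when pedigree position alone forces the carrier state
        if _forced_carrier(ped, carriers - {x}, wildtypes, x):
            obligate.add(x)
    return obligate


def infer_genotypes(
    ped: Pedigree,
    calls: Iterable[GenotypeCall],
    variant_key: str,
) -> list[GenotypeCall]:
    """Add ``origin=inferred`` calls for untyped individuals whose genotype is
    forced under the single-founder dominant model.

    Carrier is inferred when every consistent configuration carries; wild-type
    only when no configuration can (e.g. both parents wild-type). Everything
    else stays missing, so the operation is idempotent.
    """
    calls = list(calls)
    carriers, wildtypes = _observed_sets(ped, calls, variant_key)
    if not carriers:
        raise InsufficientDataError(
            f"no observed carriers of {variant_key} in family {ped.family_id!r}"
        )
    _check_trios(ped, carriers, wildtypes)
    if not _feasible_founders(ped, carriers, wildtypes):
        warnings.warn(
            f"family {ped.family_id!r}: observed carriers of {variant_key} "
            "cannot descend from a single founder introduction",
            SingleOriginViolationWarning,
            stacklevel=2,
        )
        return calls
    typed = carriers | wildtypes
    out = list(calls)
    for ind in ped.members:
        x = ind.individual_id
        if x in typed:
            continue
        if _forced_carrier(ped, carriers, wildtypes, x):
            out.append(GenotypeCall(x, variant_key, Call.CARRIER, Origin.INFERRED))
        elif not _can_carry(ped, carriers, wildtypes, x):
            out.append(GenotypeCall(x, variant_key, Call.WILDTYPE, Origin.INFERRED))
    return out


def call_map(
    ped: Pedigree, calls: Iterable[GenotypeCall], variant_key: str
) -> dict[str, GenotypeCall]:
    """Best call per member for one variant; observed calls win over inferred."""
    out: dict[str, GenotypeCall] = {}
    for c in calls:
        if c.variant_key != variant_key or c.individual_id not in ped:
            continue
        if c.call is Call.MISSING:
            continue
        prev = out.get(c.individual_id)
        if prev is None or (
            prev.origin is Origin.INFERRED and c.origin is Origin.OBSERVED
        ):
            out[c.individual_id] = c
    return out
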