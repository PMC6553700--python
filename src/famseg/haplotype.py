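"""Microsatellite-haplotype comparison between variant-sharing families.

Families carrying the same rare variant may descend from one founder event
or from recurrent mutation at a hotspot. The check compares CEPH-normalized
microsatellite allele sizes on the variant-bearing chromosome: identical
sizes at every co-genotyped marker in the window support a shared founder,
any mismatch indicates independent origin, and too few overlapping markers
is inconclusive (an error, not a verdict).

Phasing of the variant-bearing haplotype is by pedigree transmission: at
each marker the allele co-transmitted with the variant across at least two
informative carrier-to-carrier meioses is taken as the linked allele.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .exceptions import InconclusiveHaplotypeError
from .pedigree import Call, GenotypeCall, Pedigree, call_map

SHARED_FOUNDER = "shared_founder"
INDEPENDENT_ORIGIN = "independent_origin"


@dataclass(frozen=True)
class Marker:
    marker_id: str
    physical_pos: int  # bp
    allele_size: int  # bp, CEPH-normalized


@dataclass
class MarkerHaplotype:
    family_id: str
    locus: str
    markers: list[Marker]

    def __post_init__(self):
        self.markers = sorted(self.markers, key=lambda m: m.physical_pos)

    def sizes(self) -> dict[str, int]:
        return {m.marker_id: m.allele_size for m in self.markers}


def compare_haplotypes(
    h1: MarkerHaplotype,
    h2: MarkerHaplotype,
    min_shared: int = 3,
    size_tolerance: int = 0,
) -> str:
    """``shared_founder`` iff allele sizes agree at every co-genotyped marker;
    any mismatch → ``independent_origin``. Fewer than ``min_shared``
    overlapping markers raises :class:`InconclusiveHaplotypeError`.
    ``size_tolerance`` (bp) relaxes the exact-match rule for stutter."""
    if h1.locus != h2.locus:
        raise ValueError(f"locus mismatch: {h1.locus!r} vs {h2.locus!r}")
    s1, s2 = h1.sizes(), h2.sizes()
    common = sorted(set(s1) & set(s2))
    if len(common) < min_shared:
        raise InconclusiveHaplotypeError(
            f"{h1.family_id} vs {h2.family_id} at {h1.locus}: only "
            f"{len(common)} co-genotyped marker(s), need {min_shared}"
        )
    for m in common:
        if abs(s1[m] - s2[m]) > size_tolerance:
            return INDEPENDENT_ORIGIN
    return SHARED_FOUNDER


def read_marker_table(path: str | Path) -> pd.DataFrame:
    """TSV of per-individual marker genotypes with columns: family_id,
    individual_id, marker_id, physical_pos, allele1_bp, allele2_bp."""
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"family_id": str, "individual_id": str, "marker_id": str},
    )
    required = {
        "family_id",
        "individual_id",
        "marker_id",
        "physical_pos",
        "allele1_bp",
        "allele2_bp",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"marker table missing columns: {sorted(missing)}")
    return df


def phase_variant_haplotype(
    ped: Pedigree,
    calls: Iterable[GenotypeCall],
    marker_df: pd.DataFrame,
    variant_key: str,
    locus: str,
    min_meioses: int = 2,
) -> MarkerHaplotype:
    """Reconstruct the variant-bearing haplotype of one family.

    For every informative meiosis (carrier parent → carrier child, both
    genotyped at the marker) the transmitted allele must lie in the
    intersection of the two genotypes; a marker enters the haplotype when at
    least ``min_meioses`` meioses agree on a single allele size.
    """
    cmap = call_map(ped, calls, variant_key)
    carriers = {i for i, c in cmap.items() if c.call is Call.CARRIER}
    fam = marker_df[marker_df["family_id"] == ped.family_id]
    geno: dict[tuple[str, str], set[int]] = {}
    pos: dict[str, int] = {}
    for row in fam.itertuples(index=False):
        geno[(row.individual_id, row.marker_id)] = {
            int(row.allele1_bp),
            int(row.allele2_bp),
        }
        pos[row.marker_id] = int(row.physical_pos)
    markers: list[Marker] = []
    for mid, p in pos.items():
        votes: list[int] = []
        for child in carriers:
            for parent in ped.parents(child) & carriers:
                g_p = geno.get((parent, mid))
                g_c = geno.get((child, mid))
                if g_p is None or g_c is None:
                    continue
                shared = g_p & g_c
                if len(shared) == 1:
                    votes.append(next(iter(shared)))
        if len(votes) >= min_meioses and len(set(votes)) == 1:
            markers.append(Marker(mid, p, votes[0]))
    return MarkerHaplotype(family_id=ped.family_id, locus=locus, markers=markers)
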