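"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the package's path-based inference: genotype
configurations are enumerated exhaustively and checked against the model
constraints, so agreement is a genuine cross-validation.
"""

from __future__ import annotations

import itertools
import math

from famseg.pedigree import Affection, Call, GenotypeCall, Pedigree


def consistent_assignments(
    ped: Pedigree, calls, variant_key: str
) -> list[dict[str, bool]]:
    """All carrier/non-carrier configurations consistent with the observed
    calls under: exactly one founder introduction, no de novo events, every
    carrier non-founder has a carrier parent."""
    observed: dict[str, bool] = {}
    for c in calls:
        if c.variant_key != variant_key or c.call is Call.MISSING:
            continue
        if c.individual_id in ped:
            observed[c.individual_id] = c.call is Call.CARRIER
    members = [m.individual_id for m in ped.members]
    free = [i for i in members if i not in observed]
    founders = ped.founders
    out = []
    for bits in itertools.product((False, True), repeat=len(free)):
        asg = dict(observed)
        asg.update(zip(free, bits))
        any_carrier = any(asg.values())
        n_carrier_founders = sum(asg[f] for f in founders)
        if any_carrier and n_carrier_founders != 1:
            continue
        if not any_carrier and n_carrier_founders != 0:
            continue
        ok = True
        for i in members:
            if asg[i] and i not in founders:
                if not any(asg[p] for p in ped.parents(i)):
                    ok = False
                    break
        if ok:
            out.append(asg)
    return out


def forced_carriers(ped: Pedigree, calls, variant_key: str) -> set[str]:
    """Individuals that carry in every consistent configuration."""
    asgs = consistent_assignments(ped, calls, variant_key)
    if not asgs:
        return set()
    members = [m.individual_id for m in ped.members]
    return {i for i in members if all(a[i] for a in asgs)}


def forced_wildtype(ped: Pedigree, calls, variant_key: str) -> set[str]:
    asgs = consistent_assignments(ped, calls, variant_key)
    if not asgs:
        return set()
    members = [m.individual_id for m in ped.members]
    return {i for i in members if not any(a[i] for a in asgs)}


def obligate_oracle(ped: Pedigree, calls, variant_key: str) -> set[str]:
    """Definitional form: a non-affected individual is obligate when it
    carries in every configuration consistent with everyone *else's* calls."""
    out = set()
    for m in ped.members:
        if m.affection is Affection.AFFECTED:
            continue
        others = [c for c in calls if c.individual_id != m.individual_id]
        asgs = consistent_assignments(ped, others, variant_key)
        if asgs and all(a[m.individual_id] for a in asgs):
            # never call an observed wild-type individual obligate
            if not any(
                c.individual_id == m.individual_id and c.call is Call.WILDTYPE
                for c in calls
                if c.variant_key == variant_key
            ):
                out.add(m.individual_id)
    return out


def blood_relatives_oracle(ped: Pedigree, iid: str) -> set[str]:
    """Brute-force common-ancestor enumeration."""

    def anc(x):
        out, stack = {x}, [x]
        while stack:
            cur = stack.pop()
            for p in ped.parents(cur):
                if p not in out:
                    out.add(p)
                    stack.append(p)
        return out

    a = anc(iid)
    return {o for o in (m.individual_id for m in ped.members) if o != iid and a & anc(o)}


def segregation_tally_oracle(ped: Pedigree, cmap, excluded: set[str]):
    """Recompute the segregation tallies by plain member enumeration.

    ``cmap``: individual -> Call for observed+inferred calls;
    ``excluded``: individuals never counted against the variant.
    """
    blood = ped.blood_members()
    n_inf = n_car = n_unaff = 0
    for i in blood:
        aff = ped[i].affection
        call = cmap.get(i)
        if aff is Affection.AFFECTED and call in (Call.CARRIER, Call.WILDTYPE):
            n_inf += 1
            if call is Call.CARRIER:
                n_car += 1
        if aff is Affection.UNAFFECTED and call is Call.CARRIER and i not in excluded:
            n_unaff += 1
    return n_inf, n_car, n_unaff


def woolf_oracle(a, b, c, d, z=1.96):
    """Direct-formula log-odds interval (with Haldane correction on zeros)."""
    if 0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_or = math.log(a) + math.log(d) - math.log(b) - math.log(c)
    var = 1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d
    half = z * math.sqrt(var)
    return (
        math.exp(log_or),
        math.exp(log_or - half),
        math.exp(log_or + half),
    )
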