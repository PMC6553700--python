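import numpy as np
import pytest

from famseg.exceptions import InsufficientDataError
from famseg.pedigree import (
    Affection,
    Call,
    GenotypeCall,
    Pedigree,
    call_map,
    infer_genotypes,
    infer_obligate_carriers,
)
from famseg.segregation import (
    NOT_SEGREGATING,
    SEGREGATING,
    evaluate_segregation,
    mine_cohort,
    nominate_candidates,
)
from famseg.synthetic_data import FamilySimConfig, simulate_family
from famseg.variant_filter import MISSENSE, SharedVariants, shared_by_affected

from .conftest import gc, ind, with_new_child
from .oracles import segregation_tally_oracle
from .test_variant_filter import rec


class TestEvaluateSegregation:
    def test_four_of_five_with_one_counted_unaffected_carrier(self, plau_like_family):
        ped, calls, vk = plau_like_family
        res = evaluate_segregation(ped, calls, vk)
        assert res.verdict == SEGREGATING
        assert (res.n_affected_carriers, res.n_affected_informative) == (4, 5)
        assert res.affected_fraction == pytest.approx(0.8)
        assert res.n_unaffected_carriers_counted == 1  # II-7; father is obligate
        assert "I-1" in res.obligate_carriers

    def test_sporadic_proband_with_three_carrier_sibs_fails(
        self, sporadic_family_with_carrier_sibs
    ):
        ped, calls, vk = sporadic_family_with_carrier_sibs
        res = evaluate_segregation(ped, calls, vk)
        assert res.verdict == NOT_SEGREGATING
        assert res.affected_fraction == 1.0
        assert res.n_unaffected_carriers_counted == 3

    def test_six_of_seven_no_unaffected_carriers(self, seven_affected_family):
        ped, calls, vk = seven_affected_family
        res = evaluate_segregation(ped, calls, vk)
        assert res.verdict == SEGREGATING
        assert (res.n_affected_carriers, res.n_affected_informative) == (6, 7)

    def test_three_of_four_boundary_is_inclusive(self):
        members = [
            ind("F", sex="male"), ind("M", sex="female"),
            *[ind(f"A{i}", father="F", mother="M", aff=Affection.AFFECTED)
              for i in range(1, 5)],
        ]
        ped = Pedigree("B", members)
        calls = [gc(f"A{i}", Call.CARRIER) for i in (1, 2, 3)] + [
            gc("A4", Call.WILDTYPE)
        ]
        res = evaluate_segregation(ped, calls, "1:100:A:G")
        assert res.affected_fraction == pytest.approx(0.75)
        assert res.verdict == SEGREGATING

    def test_possible_diagnosis_excluded_by_default(self):
        members = [
            ind("F", sex="male"), ind("M", sex="female"),
            ind("A1", father="F", mother="M", aff=Affection.AFFECTED),
            ind("A2", father="F", mother="M", aff=Affection.AFFECTED),
            ind("P1", father="F", mother="M", aff=Affection.POSSIBLE),
        ]
        ped = Pedigree("P", members)
        calls = [gc("A1", Call.CARRIER), gc("A2", Call.CARRIER), gc("P1", Call.WILDTYPE)]
        res = evaluate_segregation(ped, calls, "1:100:A:G")
        assert res.n_affected_informative == 2
        res2 = evaluate_segregation(ped, calls, "1:100:A:G", include_possible=True)
        assert res2.n_affected_informative == 3

    def test_untyped_affected_excluded_from_denominator(self, plau_like_family):
        ped, calls, vk = plau_like_family
        calls = [c for c in calls if c.individual_id != "II-5"]
        res = evaluate_segregation(ped, calls, vk)
        # II-5 is untyped and not forced: drops out of the denominator
        assert (res.n_affected_carriers, res.n_affected_informative) == (4, 4)

    def test_no_informative_affected_raises(self):
        # the only affected member is untyped and nothing forces a call
        members = [ind("A", aff=Affection.AFFECTED), ind("B", aff=Affection.UNAFFECTED)]
        ped = Pedigree("E", members)
        with pytest.raises(InsufficientDataError):
            evaluate_segregation(ped, [gc("B", Call.WILDTYPE)], "1:100:A:G")

    def test_verdict_invariant_to_relabeling(self, plau_like_family):
        ped, calls, vk = plau_like_family
        mapping = {m.individual_id: f"X{j}" for j, m in enumerate(ped.members)}
        from famseg.pedigree import Individual

        relabeled = [
            Individual(
                mapping[m.individual_id],
                "R",
                mapping.get(m.father_id),
                mapping.get(m.mother_id),
                m.sex,
                m.affection,
            )
            for m in ped.members
        ]
        ped2 = Pedigree("R", relabeled)
        calls2 = [
            GenotypeCall(mapping[c.individual_id], c.variant_key, c.call, c.origin)
            for c in calls
        ]
        r1 = evaluate_segregation(ped, calls, vk)
        r2 = evaluate_segregation(ped2, calls2, vk)
        assert (
            r1.verdict,
            r1.n_affected_carriers,
            r1.n_affected_informative,
            r1.n_unaffected_carriers_counted,
        ) == (
            r2.verdict,
            r2.n_affected_carriers,
            r2.n_affected_informative,
            r2.n_unaffected_carriers_counted,
        )

    def test_tallies_agree_with_enumeration_oracle(self):
        for seed in range(60):
            sim = simulate_family(FamilySimConfig(seed=seed, genotype_missingness=0.25))
            ped, vk = sim.pedigree, sim.causal_key
            if not any(c.call is Call.CARRIER for c in sim.observed_calls):
                continue
            res = evaluate_segregation(ped, sim.observed_calls, vk)
            merged = infer_genotypes(ped, sim.observed_calls, vk)
            cmap = {i: c.call for i, c in call_map(ped, merged, vk).items()}
            excluded = set(infer_obligate_carriers(ped, sim.observed_calls, vk))
            for a in ped.affected():
                for p in ped.parents(a):
                    if ped[p].affection is Affection.UNAFFECTED:
                        excluded.add(p)
            n_inf, n_car, n_unaff = segregation_tally_oracle(ped, cmap, excluded)
            assert (
                res.n_affected_informative,
                res.n_affected_carriers,
                res.n_unaffected_carriers_counted,
            ) == (n_inf, n_car, n_unaff), seed


class TestMonotonicity:
    """Adding a new carrier individual to the family moves the verdict in one
    direction only. (Note this is about adding members, not about revealing
    hidden genotypes of existing members: a newly revealed genotype can force
    inferred calls elsewhere in the pedigree and legitimately move the
    affected fraction either way.)"""

    @staticmethod
    def _families(n):
        for seed in range(n):
            sim = simulate_family(FamilySimConfig(seed=seed, genotype_missingness=0.3))
            if any(c.call is Call.CARRIER for c in sim.observed_calls):
                yield sim

    @staticmethod
    def _an_observed_carrier(sim):
        observed_carriers = sorted(
            c.individual_id for c in sim.observed_calls if c.call is Call.CARRIER
        )
        blood = sim.pedigree.blood_members()
        return next(i for i in observed_carriers if i in blood)

    def test_adding_affected_carrier_never_breaks_segregation(self):
        checked = 0
        for sim in self._families(80):
            ped, vk = sim.pedigree, sim.causal_key
            base = evaluate_segregation(ped, sim.observed_calls, vk)
            if base.verdict != SEGREGATING:
                continue
            ped2, child = with_new_child(
                ped, self._an_observed_carrier(sim), Affection.AFFECTED
            )
            more = evaluate_segregation(
                ped2, sim.observed_calls + [gc(child, Call.CARRIER, vk)], vk
            )
            assert more.verdict == SEGREGATING, sim.config.seed
            assert more.n_affected_carriers == base.n_affected_carriers + 1
            checked += 1
        assert checked >= 20

    def test_adding_unaffected_carrier_never_rescues(self):
        checked = 0
        for sim in self._families(80):
            ped, vk = sim.pedigree, sim.causal_key
            base = evaluate_segregation(ped, sim.observed_calls, vk)
            if base.verdict != NOT_SEGREGATING:
                continue
            ped2, child = with_new_child(
                ped, self._an_observed_carrier(sim), Affection.UNAFFECTED
            )
            more = evaluate_segregation(
                ped2, sim.observed_calls + [gc(child, Call.CARRIER, vk)], vk
            )
            assert more.verdict == NOT_SEGREGATING, sim.config.seed
            checked += 1
        assert checked >= 10


class TestNominateCandidates:
    @staticmethod
    def nuclear(n_affected=4, fid="N"):
        members = [
            ind("F", fid, sex="male"), ind("M", fid, sex="female"),
            *[ind(f"A{i}", fid, father="F", mother="M", aff=Affection.AFFECTED)
              for i in range(1, n_affected + 1)],
        ]
        return Pedigree(fid, members)

    def geno(self, carriers, n=4):
        g = {f"A{i}": (Call.CARRIER if f"A{i}" in carriers else Call.WILDTYPE)
             for i in range(1, n + 1)}
        g["F"], g["M"] = Call.MISSING, Call.MISSING
        return g

    def test_single_segregating_nomination(self):
        ped = self.nuclear()
        all4 = {"A1", "A2", "A3", "A4"}
        records = [
            rec("1:10:A:G", gene="GOOD", genotypes=self.geno(all4), cadd=25.0),
            rec("1:20:A:G", gene="HALF", genotypes=self.geno({"A1", "A2"}), cadd=30.0),
        ]
        shared = shared_by_affected(records, ped)
        out = nominate_candidates(ped, shared)
        assert [r.variant_key for r in out] == ["1:10:A:G"]
        assert out[0].mode == "full"

    def test_unresolved_family_returns_empty(self):
        ped = self.nuclear()
        records = [rec("1:20:A:G", genotypes=self.geno({"A1", "A2"}))]
        shared = SharedVariants(records, "all_but_one")
        assert nominate_candidates(ped, shared) == []

    def test_tied_candidates_ordered_by_cadd_then_key(self):
        ped = self.nuclear()
        all4 = {"A1", "A2", "A3", "A4"}
        records = [
            rec("1:30:A:G", gene="LOW", genotypes=self.geno(all4), cadd=10.0),
            rec("1:10:A:G", gene="HIGH", genotypes=self.geno(all4), cadd=30.0),
            rec("1:20:A:G", gene="ALSO30", genotypes=self.geno(all4), cadd=30.0),
        ]
        out = nominate_candidates(ped, SharedVariants(records, "full"))
        assert [r.variant_key for r in out] == ["1:10:A:G", "1:20:A:G", "1:30:A:G"]


class TestMineCohort:
    def setup_method(self):
        self.ped = Pedigree(
            "MF",
            [
                ind("F", "MF", sex="male"), ind("M", "MF", sex="female"),
                ind("A1", "MF", father="F", mother="M", aff=Affection.AFFECTED),
                ind("A2", "MF", father="F", mother="M", aff=Affection.AFFECTED),
            ],
        )

    def test_case_exclusive_rare_variant_is_mined(self):
        case = rec("10:75672744:A:G", gene="PLAU",
                   freqs={"exac": 0.00004},
                   genotypes={"A1": Call.CARRIER})
        report = mine_cohort(
            "PLAU", [case], [], None, [self.ped],
            calls=[gc("A2", Call.CARRIER, "10:75672744:A:G")],
        )
        (res,) = report.results
        assert res.family_id == "MF" and res.mode == "genotyped_followup"
        assert report.excluded == []

    def test_variant_in_controls_excluded_with_reason(self):
        key = "19:54313859:G:A"
        case = rec(key, gene="NLRP12", genotypes={"A1": Call.CARRIER})
        control = rec(key, gene="NLRP12", genotypes={"C1": Call.CARRIER})
        report = mine_cohort("NLRP12", [case], [control], None, [self.ped])
        assert report.results == []
        assert report.excluded == [(key, "present_in_controls")]

    def test_absent_gene_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="absent"):
            report = mine_cohort("NOPE", [], [], None, [self.ped])
        assert report == ([], [])
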