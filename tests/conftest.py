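import pytest

from famseg.pedigree import (
    Affection,
    Call,
    GenotypeCall,
    Individual,
    Pedigree,
    Sex,
)

AFF = Affection.AFFECTED
UNAFF = Affection.UNAFFECTED


def ind(iid, fid="FAM", father=None, mother=None, sex=Sex.UNKNOWN, aff=Affection.UNKNOWN):
    return Individual(iid, fid, father, mother, Sex(sex), Affection(aff))


def gc(iid, call, vk="1:100:A:G"):
    return GenotypeCall(iid, vk, call)


def with_new_child(ped, parent_id, affection):
    """Rebuild ``ped`` with one extra child of ``parent_id`` (and a new
    married-in spouse); returns (new_ped, child_id)."""
    parent = ped[parent_id]
    spouse_id, child_id = f"{parent_id}.newsp", f"{parent_id}.newkid"
    spouse_sex = Sex.FEMALE if parent.sex is Sex.MALE else Sex.MALE
    father, mother = (
        (parent_id, spouse_id) if spouse_sex is Sex.FEMALE else (spouse_id, parent_id)
    )
    members = [Individual(**dict(m.__dict__)) for m in ped.members] + [
        Individual(spouse_id, ped.family_id, sex=spouse_sex,
                   affection=Affection.UNAFFECTED),
        Individual(child_id, ped.family_id, father, mother, Sex.UNKNOWN, affection),
    ]
    return Pedigree(ped.family_id, members), child_id


@pytest.fixture
def plau_like_family():
    """Nuclear family modelled on the urokinase discovery family: five
    affected siblings (four carriers, one wild-type), an unaffected carrier
    father (obligate), a wild-type mother and an unaffected carrier sister."""
    members = [
        ind("I-1", sex=Sex.MALE, aff=UNAFF),
        ind("I-2", sex=Sex.FEMALE, aff=UNAFF),
        *[ind(f"II-{i}", father="I-1", mother="I-2", aff=AFF) for i in range(1, 6)],
        ind("II-7", father="I-1", mother="I-2", aff=UNAFF),
    ]
    ped = Pedigree("FAM", members)
    vk = "10:75673131:G:T"
    calls = [
        GenotypeCall("I-1", vk, Call.CARRIER),
        GenotypeCall("I-2", vk, Call.WILDTYPE),
        *[GenotypeCall(f"II-{i}", vk, Call.CARRIER) for i in (1, 2, 3, 4)],
        GenotypeCall("II-5", vk, Call.WILDTYPE),
        GenotypeCall("II-7", vk, Call.CARRIER),
    ]
    return ped, calls, vk


@pytest.fixture
def sporadic_family_with_carrier_sibs():
    """Sporadic proband carrying the variant plus three unaffected carrier
    siblings: fails the no-more-than-one-unaffected-carrier rule."""
    members = [
        ind("I-1", sex=Sex.MALE),
        ind("I-2", sex=Sex.FEMALE),
        ind("II-1", father="I-1", mother="I-2", aff=AFF),
        *[ind(f"II-{i}", father="I-1", mother="I-2", aff=UNAFF) for i in (2, 3, 4)],
    ]
    ped = Pedigree("SPOR", members)
    vk = "17:78319114:A:G"
    calls = [GenotypeCall(f"II-{i}", vk, Call.CARRIER) for i in (1, 2, 3, 4)]
    return ped, calls, vk


@pytest.fixture
def seven_affected_family():
    """Seven affected siblings, six carriers and one non-carrier, no
    unaffected carriers: passes at 6/7."""
    members = [
        ind("I-1", sex=Sex.MALE, aff=UNAFF),
        ind("I-2", sex=Sex.FEMALE, aff=UNAFF),
        *[ind(f"II-{i}", father="I-1", mother="I-2", aff=AFF) for i in range(1, 8)],
        ind("II-8", father="I-1", mother="I-2", aff=UNAFF),
    ]
    ped = Pedigree("KC", members)
    vk = "16:84255962:C:T"
    calls = [
        *[GenotypeCall(f"II-{i}", vk, Call.CARRIER) for i in range(1, 7)],
        GenotypeCall("II-7", vk, Call.WILDTYPE),
        GenotypeCall("II-8", vk, Call.WILDTYPE),
        GenotypeCall("I-2", vk, Call.WILDTYPE),
    ]
    return ped, calls, vk


@pytest.fixture
def cousin_family():
    """Two affected carrier first cousins; the linking parents are forced
    carriers, the untyped grandparents are ambiguous (either could have
    introduced the variant)."""
    members = [
        ind("gf", fid="CZ", sex=Sex.MALE),
        ind("gm", fid="CZ", sex=Sex.FEMALE),
        ind("p1", fid="CZ", father="gf", mother="gm", sex=Sex.MALE, aff=UNAFF),
        ind("p2", fid="CZ", father="gf", mother="gm", sex=Sex.MALE, aff=UNAFF),
        ind("s1", fid="CZ", sex=Sex.FEMALE),
        ind("s2", fid="CZ", sex=Sex.FEMALE),
        ind("c1", fid="CZ", father="p1", mother="s1", aff=AFF),
        ind("c2", fid="CZ", father="p2", mother="s2", aff=AFF),
    ]
    for m in members:
        m.family_id = "CZ"
    ped = Pedigree("CZ", members)
    vk = "2:555:C:G"
    calls = [GenotypeCall("c1", vk, Call.CARRIER), GenotypeCall("c2", vk, Call.CARRIER)]
    return ped, calls, vk
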