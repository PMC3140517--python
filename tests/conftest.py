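import pytest

from pedlink.types import (DiseaseModel, GenotypeMatrix, Individual, Locus,
                           Pedigree)


def make_trio(affection=("affected", "unknown", "affected")) -> Pedigree:
    fa, ma, ca = affection
    return Pedigree("T", {
        "f": Individual("f", sex="male", affection=fa),
        "m": Individual("m", sex="female", affection=ma),
        "c": Individual("c", "f", "m", sex="male", affection=ca)})


def make_nuclear(n_children: int, affected_children=()) -> Pedigree:
    members = {
        "f": Individual("f", sex="male", affection="affected"),
        "m": Individual("m", sex="female")}
    for i in range(n_children):
        aff = "affected" if i in affected_children else "unknown"
        members[f"c{i}"] = Individual(f"c{i}", "f", "m",
                                      sex="male" if i % 2 == 0 else "female",
                                      affection=aff)
    return Pedigree("N", members)


def make_three_gen(n_kids: int, kid_affection=None) -> Pedigree:
    """Grandparental couple, one affected child married in, n grandkids."""
    members = {
        "gp": Individual("gp", sex="male", affection="affected"),
        "gm": Individual("gm", sex="female"),
        "par": Individual("par", "gp", "gm", sex="male",
                          affection="affected"),
        "sp": Individual("sp", sex="female")}
    for i in range(n_kids):
        aff = "affected" if kid_affection is None or i in kid_affection \
            else "unknown"
        members[f"k{i}"] = Individual(f"k{i}", "par", "sp",
                                      sex="male" if i % 2 == 0 else "female",
                                      affection=aff)
    return Pedigree("G", members)


@pytest.fixture
def trio() -> Pedigree:
    return make_trio()


@pytest.fixture
def dominant_model() -> DiseaseModel:
    return DiseaseModel()          # freq 2e-5, phenocopy 1e-6, penetrance 1


@pytest.fixture
def ideal_model() -> DiseaseModel:
    """Vanishing allele frequency and phenocopy: carrier-prior corrections
    are negligible, so textbook closed-form LODs hold to ~1e-5."""
    return DiseaseModel(disease_allele_freq=1e-8, phenocopy=0.0)


def phase_known_family(n_kids: int, recombinant_kids=()):
    """Fully informative three-generation family in which the affected
    parent's phase (risk allele with marker allele 1) is forced by the
    grandparental genotypes; each affected grandchild is a scored meiosis,
    nonrecombinant with marker 1, recombinant with marker 3."""
    ped = make_three_gen(n_kids)
    gm = GenotypeMatrix()
    gm.set("gp", "M1", (1, 2))
    gm.set("gm", "M1", (3, 3))
    gm.set("par", "M1", (1, 3))
    gm.set("sp", "M1", (5, 5))
    for i in range(n_kids):
        gm.set(f"k{i}", "M1", (3, 5) if i in recombinant_kids else (1, 5))
    locus = Locus("M1", "1", 0.0, (0.2,) * 5)
    return ped, gm, locus
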