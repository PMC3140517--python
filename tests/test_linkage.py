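"""Linkage engines checked against closed forms and exhaustive enumeration."""

import math

import numpy as np
import pytest

from pedlink.linkage import (BitCapError, MultipointEngine,
                             haldane_theta, max_lod, multipoint_lod,
                             reconstruct_haplotypes, sensitivity_analysis,
                             single_locus_likelihood, twopoint_lod)
from pedlink.simulate import (SimScenario, build_marker_map, gene_drop,
                              simulate_linked_study)
from pedlink.types import (DiseaseModel, GenotypeMatrix, Locus, MarkerMap,
                           Pedigree)

from .conftest import (make_nuclear, make_three_gen, make_trio,
                       phase_known_family)
from .oracles import (brute_multipoint_lod, brute_single_locus_loglik)


class TestHaldane:
    def test_zero_distance(self):
        assert haldane_theta(0.0).theta == 0.0

    def test_asymptote(self):
        assert haldane_theta(1e6).theta == pytest.approx(0.5)

    def test_closed_form_at_10cM(self):
        assert haldane_theta(10.0).theta == pytest.approx(
            0.5 * (1 - math.exp(-0.2)))

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            haldane_theta(-1.0)


class TestSingleLocusLikelihood:
    @pytest.mark.parametrize("theta", [0.0, 0.1, 0.3, 0.5])
    @pytest.mark.parametrize("shape,genos", [
        ("trio", {"f": (1, 2), "m": (2, 2), "c": (1, 2)}),
        ("trio", {"f": (1, 1), "c": (1, 2)}),
        ("nuclear", {"f": (1, 2), "m": (1, 2), "c0": (1, 1), "c1": (2, 2)}),
    ])
    def test_matches_exhaustive_enumeration(self, theta, shape, genos):
        ped = make_trio() if shape == "trio" \
            else make_nuclear(2, affected_children=(0,))
        locus = Locus("M1", "1", 0.0, (0.6, 0.4))
        gm = GenotypeMatrix()
        for iid, g in genos.items():
            gm.set(iid, "M1", g)
        model = DiseaseModel(0.01, 0.001, 0.9, 0.95)
        assert single_locus_likelihood(ped, gm, locus, model, theta) == \
            pytest.approx(
                brute_single_locus_loglik(ped, gm, locus, model, theta),
                abs=1e-10)

    def test_no_data_family_is_theta_independent(self):
        ped = make_trio(affection=("unknown", "unknown", "unknown"))
        locus = Locus("M1", "1", 0.0, (0.5, 0.5))
        gm = GenotypeMatrix()
        model = DiseaseModel()
        lls = [single_locus_likelihood(ped, gm, locus, model, th)
               for th in (0.0, 0.2, 0.5)]
        assert max(lls) - min(lls) < 1e-12

    def test_consanguineous_loop_is_handled(self):
        # first cousins marrying: a loop no peeling order can avoid
        from pedlink.types import Individual
        members = {
            "g1": Individual("g1", sex="male", affection="affected"),
            "g2": Individual("g2", sex="female"),
            "a": Individual("a", "g1", "g2", sex="male"),
            "b": Individual("b", "g1", "g2", sex="female"),
            "sa": Individual("sa", sex="female"),
            "sb": Individual("sb", sex="male"),
            "ca": Individual("ca", "a", "sa", sex="male"),
            "cb": Individual("cb", "sb", "b", sex="female"),
            "x": Individual("x", "ca", "cb", sex="male",
                            affection="affected")}
        ped = Pedigree("LOOP", members)
        locus = Locus("M1", "1", 0.0, (0.5, 0.5))
        gm = GenotypeMatrix()
        gm.set("x", "M1", (1, 1))
        ll = single_locus_likelihood(ped, gm, locus, DiseaseModel(), 0.1)
        assert math.isfinite(ll)


class TestTwoPoint:
    def test_lod_zero_at_free_recombination(self, ideal_model):
        ped, gm, locus = phase_known_family(4)
        res = twopoint_lod([ped], gm, locus, ideal_model, [0.5])
        assert res[0].lod == pytest.approx(0.0, abs=1e-12)

    def test_ten_nonrecombinant_meioses_reach_lod_three(self, ideal_model):
        ped, gm, locus = phase_known_family(10)
        res = twopoint_lod([ped], gm, locus, ideal_model, [0.0])
        assert res[0].lod == pytest.approx(10 * math.log10(2), abs=1e-4)

    def test_one_recombinant_in_ten_closed_form(self, ideal_model):
        ped, gm, locus = phase_known_family(10, recombinant_kids=(9,))
        res = twopoint_lod([ped], gm, locus, ideal_model, [0.1])
        expected = math.log10(0.1 * 0.9 ** 9 / 0.5 ** 10)
        assert res[0].lod == pytest.approx(expected, abs=1e-4)

    def test_additive_over_families(self, ideal_model):
        ped_a, gm, locus = phase_known_family(3)
        res = twopoint_lod([ped_a], gm, locus, ideal_model, [0.05])
        assert res[0].lod == pytest.approx(
            sum(res[0].per_family_lods.values()))


def _small_pedigrees():
    return [
        ("trio", make_trio()),
        ("nuclear2", make_nuclear(2, affected_children=(0, 1))),
        ("nuclear3", make_nuclear(3, affected_children=(0, 2))),
        ("threegen1", make_three_gen(1)),
    ]


class TestMultipointAgainstExhaustiveOracle:
    """Multipoint LOD equals dense exhaustive enumeration on every pedigree
    with <= 6 meiosis bits and maps of <= 3 markers."""

    @pytest.mark.parametrize("name,ped", _small_pedigrees())
    @pytest.mark.parametrize("n_markers", [1, 2, 3])
    def test_agrees_with_dense_enumeration(self, name, ped, n_markers):
        rng = np.random.default_rng(hash((name, n_markers)) % 2 ** 31)
        freqs = (0.5, 0.3, 0.2)
        loci = [Locus(f"M{i}", "1", 10.0 * i, freqs)
                for i in range(n_markers)]
        mm = MarkerMap(loci)
        model = DiseaseModel(0.01, 0.001, 0.9, 0.95)
        drop = gene_drop(ped, mm, model, None, rng)
        positions = [5.0, 0.0, 10.0 * (n_markers - 1) + 7.5]
        for cM in positions:
            got = multipoint_lod([ped], drop.gm, mm, model,
                                 positions=[("1", cM)])[0].lod
            want = brute_multipoint_lod(ped, drop.gm, loci, model, cM)
            assert got == pytest.approx(want, abs=1e-6)

    def test_single_marker_agrees_with_twopoint(self, ideal_model):
        ped, gm, locus = phase_known_family(4)
        locus = Locus("M1", "1", 20.0, locus.allele_freqs)
        mm = MarkerMap([locus])
        for d in (0.0, 5.0, 15.0):
            theta = haldane_theta(d).theta
            tp = twopoint_lod([ped], gm, locus, ideal_model, [theta])[0].lod
            mp = multipoint_lod([ped], gm, mm, ideal_model,
                                positions=[("1", 20.0 - d)])[0].lod
            assert mp == pytest.approx(tp, abs=1e-6)

    def test_uninformative_markers_give_zero_everywhere(self, ideal_model):
        ped = make_nuclear(2, affected_children=(0, 1))
        mm = MarkerMap([Locus("M0", "1", 0.0, (0.5, 0.5)),
                        Locus("M1", "1", 20.0, (0.5, 0.5))])
        gm = GenotypeMatrix()     # nobody typed
        res = multipoint_lod([ped], gm, mm, ideal_model, grid_cM=5.0)
        assert all(abs(r.lod) < 1e-9 for r in res)

    def test_phenocopy_equal_penetrance_flattens_lod(self):
        ped, gm, locus = phase_known_family(6)
        mm = MarkerMap([locus])
        flat = DiseaseModel(0.01, 0.8, 0.8, 0.8)
        res = multipoint_lod([ped], gm, mm, flat,
                             positions=[("1", 0.0), ("1", 10.0)])
        assert all(abs(r.lod) < 1e-9 for r in res)

    def test_bit_cap_enforced_with_family_name(self):
        ped = make_nuclear(9)
        mm = MarkerMap([Locus("M0", "1", 0.0, (0.5, 0.5))])
        with pytest.raises(BitCapError, match="N"):
            multipoint_lod([ped], GenotypeMatrix(), mm, DiseaseModel(),
                           bit_cap=16)


class TestPosteriorInvariants:
    def test_inheritance_posterior_normalized_everywhere(self, ideal_model):
        ped, gm, _ = phase_known_family(4)
        loci = [Locus("M1", "1", 0.0, (0.2,) * 5),
                Locus("M2", "1", 12.0, (0.2,) * 5)]
        gm.set("par", "M2", (2, 4))
        gm.set("sp", "M2", (1, 1))
        mm = MarkerMap(loci)
        eng = MultipointEngine([ped], gm, mm)
        chain = eng.chains[("G", "1")]
        for cM in (0.0, 3.0, 6.0, 12.0, 25.0):
            assert chain.posterior_at(cM).sum() == pytest.approx(1.0)


class TestHaplotypeReconstruction:
    def test_codominant_trio_phase_is_forced(self):
        ped = make_trio()
        mm = MarkerMap([Locus("M1", "1", 0.0, (0.25,) * 4)])
        gm = GenotypeMatrix()
        gm.set("f", "M1", (1, 2))
        gm.set("m", "M1", (3, 4))
        gm.set("c", "M1", (1, 3))
        rec = reconstruct_haplotypes(ped, gm, mm, "1")
        assert rec.haplotypes["c"][0] == (1, 3)   # paternal 1, maternal 3

    def test_gene_drop_truth_recovered_at_informative_markers(self):
        ped = make_nuclear(3, affected_children=(0, 1, 2))
        mm = build_marker_map(n_chromosomes=1, chrom_length_cM=40,
                              spacing_cM=10, n_alleles=8)
        model = DiseaseModel()
        drop = gene_drop(ped, mm, model, None, np.random.default_rng(4))
        rec = reconstruct_haplotypes(ped, drop.gm, mm, "1")
        for li, lid in enumerate(rec.loci):
            for iid in ("c0", "c1", "c2"):
                got = rec.haplotypes[iid][li]
                truth = drop.gm.get(iid, lid)
                if got[0] is not None and got[1] is not None:
                    assert tuple(sorted(got)) == truth

    def test_uninformative_meiosis_stays_unresolved(self):
        ped = make_trio()
        mm = MarkerMap([Locus("M1", "1", 0.0, (0.5, 0.5))])
        gm = GenotypeMatrix()
        gm.set("f", "M1", (1, 2))
        gm.set("m", "M1", (1, 2))
        gm.set("c", "M1", (1, 2))   # unphasable: everyone heterozygous
        rec = reconstruct_haplotypes(ped, gm, mm, "1")
        assert rec.haplotypes["c"][0] == (None, None)
        assert not rec.resolved(0, 0) and not rec.resolved(0, 1)


@pytest.fixture(scope="module")
def small_linked_study():
    mm = build_marker_map(n_chromosomes=1, chrom_length_cM=60,
                          spacing_cM=10, n_alleles=4)
    from pedlink.simulate import PedigreeTemplate
    scen = SimScenario(
        n_families=3, template=PedigreeTemplate(1, 2),
        disease_chromosome="1", disease_cM=30.0, min_affected=3,
        seed=11)
    return simulate_linked_study(scen, marker_map=mm), scen


class TestSensitivity:
    def test_identical_frequency_gives_zero_change(self, small_linked_study):
        study, scen = small_linked_study
        rows = sensitivity_analysis(study.pedigrees, study.gm,
                                    study.marker_map, scen.model,
                                    [scen.model.disease_allele_freq])
        assert rows[0]["relative_change"] == pytest.approx(0.0, abs=1e-12)

    def test_max_lod_at_true_locus(self, small_linked_study):
        study, scen = small_linked_study
        res = multipoint_lod(study.pedigrees, study.gm, study.marker_map,
                             scen.model)
        assert max_lod(res).position == ("1", 30.0)
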