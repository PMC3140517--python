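"""Generator contracts: determinism, transmission physics, planted truth."""

import numpy as np
import pytest
from scipy import stats

from pedlink.linkage import max_lod, multipoint_lod
from pedlink.simulate import (CaseControlSpec, ExomeSpec, PedigreeTemplate,
                              SimScenario, build_marker_map, build_pedigree,
                              gene_drop, simulate_case_control,
                              simulate_exome_tables, simulate_family,
                              simulate_linked_study)
from pedlink.types import DiseaseModel, Locus, MarkerMap, validate_pedigree

from .conftest import make_nuclear


class TestPedigreeTemplates:
    def test_built_pedigrees_are_valid_three_generation(self):
        ped = build_pedigree("F", PedigreeTemplate(2, 2))
        assert validate_pedigree(ped) == []
        assert len(ped.founders) == 4 and len(ped.nonfounders) == 6

    def test_map_builder_shapes(self):
        mm = build_marker_map(2, 40, 10, 4)
        assert [l.position_cM for l in mm.chromosome_loci("1")] == \
            [0.0, 10.0, 20.0, 30.0, 40.0]
        assert all(f == 0.25 for l in mm.loci for f in l.allele_freqs)


class TestGeneDrop:
    def test_deterministic_given_seed(self):
        ped = make_nuclear(2)
        mm = build_marker_map(1, 30, 10, 4)
        a = gene_drop(ped, mm, DiseaseModel(), ("1", 15.0), 42, "f")
        b = gene_drop(ped, mm, DiseaseModel(), ("1", 15.0), 42, "f")
        assert list(a.gm.items()) == list(b.gm.items())
        assert a.affection == b.affection

    def test_zero_distance_loci_cotransmitted(self):
        ped = make_nuclear(4)
        mm = MarkerMap([Locus("A", "1", 10.0, (0.5, 0.5)),
                        Locus("B", "1", 10.0, (0.5, 0.5))])
        rng = np.random.default_rng(0)
        for _ in range(30):
            drop = gene_drop(ped, mm, DiseaseModel(), None, rng)
            for (child, side), by_chrom in drop.origins.items():
                bits = by_chrom["1"]
                assert bits[0] == bits[1]   # theta(0) = 0

    def test_unlinked_disease_independent_of_marker_transmission(self):
        # ~2,400 meioses; carrier status and marker grand-origin independent
        ped = make_nuclear(10)
        mm = MarkerMap([Locus("A", "1", 0.0, (0.5, 0.5))])
        model = DiseaseModel(penetrance_het=1.0, phenocopy=0.0)
        rng = np.random.default_rng(9)
        table = np.zeros((2, 2))
        for _ in range(120):
            drop = gene_drop(ped, mm, model, None, rng, "f")
            for i in range(10):
                child = f"c{i}"
                carrier = drop.risk_copies[child] > 0
                bit = drop.origins[(child, "pat")]["1"][0]
                table[int(carrier), int(bit)] += 1
        _, p, _, _ = stats.chi2_contingency(table)
        assert p > 0.001

    def test_full_penetrance_affected_iff_carrier(self):
        ped = make_nuclear(6)
        mm = build_marker_map(1, 20, 10, 2)
        model = DiseaseModel(penetrance_het=1.0, penetrance_hom=1.0,
                             phenocopy=0.0)
        drop = gene_drop(ped, mm, model, ("1", 10.0), 3, "f")
        for iid, dose in drop.risk_copies.items():
            assert (drop.affection[iid] == "affected") == (dose > 0)

    def test_founder_allele_frequencies_recovered(self):
        ped = make_nuclear(1)
        locus = Locus("A", "1", 0.0, (0.7, 0.3))
        mm = MarkerMap([locus])
        rng = np.random.default_rng(5)
        n, ones = 0, 0
        for _ in range(400):
            drop = gene_drop(ped, mm, DiseaseModel(), None, rng)
            for f in ("f", "m"):
                a, b = drop.gm.get(f, "A")
                ones += (a == 1) + (b == 1)
                n += 2
        se = np.sqrt(0.7 * 0.3 / n)
        assert ones / n == pytest.approx(0.7, abs=4 * se)

    def test_absent_disease_chromosome_rejected(self):
        ped = make_nuclear(1)
        mm = build_marker_map(1, 20, 10, 2)
        with pytest.raises(ValueError, match="chromosome"):
            gene_drop(ped, mm, DiseaseModel(), ("7", 5.0), 0)

    def test_ascertainment_reaches_min_affected(self):
        ped = build_pedigree("F", PedigreeTemplate(2, 2))
        mm = build_marker_map(1, 40, 10, 4)
        ped2, drop = simulate_family(ped, mm, DiseaseModel(), ("1", 20.0),
                                     7, f"F_gf", min_affected=4)
        assert len(ped2.affected_ids()) >= 4


class TestLinkageRecovery:
    def test_max_lod_localizes_at_true_position_most_often(self):
        # 100 replicate small studies; the mode of the argmax position
        # must be the simulated disease locus
        mm = build_marker_map(1, 40, 10, 4)
        hits: dict[float, int] = {}
        for rep in range(100):
            scen = SimScenario(n_families=2,
                               template=PedigreeTemplate(1, 2),
                               disease_chromosome="1", disease_cM=20.0,
                               min_affected=3, seed=1000 + rep)
            study = simulate_linked_study(scen, marker_map=mm)
            res = multipoint_lod(study.pedigrees, study.gm, mm, scen.model)
            pos = max_lod(res).position[1]
            hits[pos] = hits.get(pos, 0) + 1
        top = max(hits, key=hits.get)
        assert top == 20.0
        assert all(hits[20.0] > v for k, v in hits.items() if k != 20.0)


@pytest.fixture(scope="module")
def small_exome():
    spec = ExomeSpec(n_cases=4, background_per_case=400,
                     synonymous_per_case=200, n_genes=2000,
                     planted_cases=3)
    return spec, simulate_exome_tables(spec, 8)


class TestExomeTables:
    def test_planted_variant_in_requested_cases_only(self, small_exome):
        spec, sim = small_exome
        assert len(sim.planted_case_ids) == 3
        for cid, recs in sim.cases.items():
            has = any(r.key == sim.planted_key for r in recs)
            assert has == (cid in sim.planted_case_ids)

    def test_planted_gene_inside_locus(self, small_exome):
        spec, sim = small_exome
        assert sim.gene_regions[sim.planted_gene].overlaps(spec.locus)

    def test_known_fraction_of_functional_background(self, small_exome):
        spec, sim = small_exome
        for recs in sim.cases.values():
            functional = [r for r in recs
                          if r.effect_class != "other"
                          and r.key != sim.planted_key]
            known = sum(bool(r.known_ids) for r in functional)
            frac = known / len(functional)
            # binomial tolerance around the requested fraction
            assert frac == pytest.approx(spec.fraction_known, abs=0.05)

    def test_quality_failures_near_requested_rate(self, small_exome):
        spec, sim = small_exome
        fails = total = 0
        for recs in sim.cases.values():
            for r in recs:
                if r.key == sim.planted_key:
                    continue
                total += 1
                fails += not (r.depth > 8 and r.consensus_quality > 30
                              and r.mapping_quality > 20)
        assert fails / total == pytest.approx(spec.fraction_quality_fail,
                                              abs=0.01)

    def test_excess_planted_cases_rejected(self):
        with pytest.raises(ValueError):
            ExomeSpec(n_cases=4, planted_cases=5)


class TestCaseControl:
    def test_counts_sum_to_sample_sizes(self):
        spec = CaseControlSpec(n_cases=100, n_controls=200)
        t = simulate_case_control(spec, 0)
        assert t.n_cases == 100 and t.n_controls == 200

    def test_control_het_count_matches_hwe_expectation(self):
        # E[het] = 2 p (1-p) n ~ 10.6 at p=0.014, n=384
        spec = CaseControlSpec(n_cases=10, n_controls=384,
                               control_risk_allele_freq=0.014)
        rng = np.random.default_rng(2)
        hets = [simulate_case_control(spec, rng).control_Dd
                for _ in range(60)]
        expected = 2 * 0.014 * 0.986 * 384
        se = np.sqrt(expected / 60)   # ~Poisson spread of the mean
        assert np.mean(hets) == pytest.approx(expected, abs=4 * se)

    def test_null_odds_ratio_equalizes_mafs(self):
        spec = CaseControlSpec(n_cases=3000, n_controls=3000,
                               control_risk_allele_freq=0.2,
                               carrier_odds_ratio=1.0)
        rng = np.random.default_rng(3)
        diffs = []
        for _ in range(10):
            t = simulate_case_control(spec, rng)
            maf_ca = (2 * t.case_DD + t.case_Dd) / (2 * t.n_cases)
            maf_co = (2 * t.control_DD + t.control_Dd) / (2 * t.n_controls)
            diffs.append(maf_ca - maf_co)
        se = np.sqrt(2 * 0.2 * 0.8 / (2 * 3000))
        assert abs(np.mean(diffs)) < 3 * se / np.sqrt(10)

    def test_invalid_odds_ratio_rejected(self):
        with pytest.raises(ValueError):
            CaseControlSpec(carrier_odds_ratio=0.0)

    def test_deterministic_given_seed(self):
        spec = CaseControlSpec()
        assert simulate_case_control(spec, 17) == \
            simulate_case_control(spec, 17)
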