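"""Synthetic-data generation for every pipeline stage.

The generator emulates the three data modalities of a dominant-disease
gene-mapping study, so the whole pipeline can be exercised end-to-end with
known ground truth:

* **Gene dropping** — founder marker haplotypes drawn from population
  allele frequencies are transmitted down a fixed pedigree, with meiotic
  recombination between adjacent loci at the Haldane fraction of their cM
  distance (no interference — the same map function the likelihood engines
  assume, which is what makes parameter-recovery tests meaningful). A
  disease locus can be planted on the map (linked) or dropped
  independently ("unlinked"); affection is sampled from penetrance given
  the carried dose, and multiplex families are ascertained by rejection
  sampling (resimulate until the minimum-affected rule is met).

* **Exome variant tables** — per-case background variants drawn from a
  shared pool of catalog-known common sites plus private unknown sites (a
  stated fraction also present in the control exomes), with quality fields
  drawn above/below the filter thresholds at a stated rate, and one causal
  variant planted in a configurable k of n cases inside the linkage locus.

* **Case-control genotype counts** — control genotypes drawn under
  Hardy-Weinberg equilibrium at a stated risk-allele frequency; case
  genotypes from a carrier-odds-ratio model (carrier odds in cases =
  OR x carrier odds in controls; carriers split into het/hom by the
  control conditional proportions).

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .linkage import haldane_theta
from .types import (DiseaseModel, GenomicRegion, GenotypeCountTable,
                    GenotypeMatrix, Individual, Locus, MarkerMap, Pedigree,
                    VariantRecord)

__all__ = [
    "PedigreeTemplate", "ExomeSpec", "CaseControlSpec", "SimScenario",
    "build_pedigree", "build_marker_map", "gene_drop", "GeneDropResult",
    "simulate_family", "simulate_linked_study", "simulate_exome_tables",
    "ExomeSimResult", "simulate_case_control",
]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Scenario specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PedigreeTemplate:
    """Three-generation family shape: a founder couple, ``n_couples`` of
    their children each married to an unrelated spouse, and
    ``children_per_couple`` grandchildren per couple."""

    n_couples: int = 2
    children_per_couple: int = 2


@dataclass(frozen=True)
class ExomeSpec:
    """Shape of the synthetic exome tables.

    Background levels mirror a typical early exome study: ~6,600 functional
    (MS/NS/SS/Indel) calls per case, ~85% of them in the known-variant
    catalog, ~40% of the remainder also seen in a small panel of control
    exomes run on the same platform, and ~5% of raw calls failing the
    depth/quality thresholds.
    """

    n_cases: int = 8
    background_per_case: int = 6600
    synonymous_per_case: int = 3300
    fraction_known: float = 0.85
    fraction_in_controls: float = 0.40
    fraction_quality_fail: float = 0.05
    n_genes: int = 18000
    genes_in_locus: int = 21
    locus: GenomicRegion = GenomicRegion("17", 78_000_000, 79_500_000)
    planted_gene: str = "LOCUS_G11"
    planted_cases: int = 8
    n_controls: int = 5

    def __post_init__(self) -> None:
        if not 1 <= self.planted_cases <= self.n_cases:
            raise ValueError(
                f"planted_cases {self.planted_cases} must lie in "
                f"1..{self.n_cases}")


@dataclass(frozen=True)
class CaseControlSpec:
    stratum: str = "Synthetic"
    n_cases: int = 161
    n_controls: int = 384
    control_risk_allele_freq: float = 0.014
    carrier_odds_ratio: float = 100.0

    def __post_init__(self) -> None:
        if self.carrier_odds_ratio <= 0:
            raise ValueError("carrier odds ratio must be > 0")
        if not 0.0 <= self.control_risk_allele_freq <= 1.0:
            raise ValueError("control risk-allele frequency not in [0, 1]")


@dataclass(frozen=True)
class SimScenario:
    """Full study design: defaults emulate an eight-family, three-generation
    genome scan with a rare (freq 2e-5) fully penetrant dominant allele,
    phenocopy rate 1e-6, and 10-cM marker spacing on 22 autosomes with
    equifrequent marker alleles."""

    n_families: int = 8
    template: PedigreeTemplate = PedigreeTemplate()
    model: DiseaseModel = DiseaseModel()
    n_chromosomes: int = 22
    chrom_length_cM: float = 160.0
    marker_spacing_cM: float = 10.0
    n_alleles: int = 4
    disease_chromosome: str = "17"
    disease_cM: float = 50.0
    min_affected: int = 4
    exome: ExomeSpec = ExomeSpec()
    case_control: CaseControlSpec = CaseControlSpec()
    seed: int = 0


# ---------------------------------------------------------------------------
# Pedigrees and maps
# ---------------------------------------------------------------------------

def build_pedigree(family_id: str,
                   template: PedigreeTemplate = PedigreeTemplate(),
                   ) -> Pedigree:
    members: dict[str, Individual] = {}
    gp, gm_ = f"{family_id}_gf", f"{family_id}_gm"
    members[gp] = Individual(gp, sex="male")
    members[gm_] = Individual(gm_, sex="female")
    for c in range(template.n_couples):
        child = f"{family_id}_c{c}"
        spouse = f"{family_id}_s{c}"
        child_sex = "male" if c % 2 == 0 else "female"
        members[child] = Individual(child, gp, gm_, sex=child_sex)
        members[spouse] = Individual(
            spouse, sex="female" if child_sex == "male" else "male")
        father = child if child_sex == "male" else spouse
        mother = spouse if child_sex == "male" else child
        for k in range(template.children_per_couple):
            kid = f"{family_id}_k{c}{k}"
            members[kid] = Individual(kid, father, mother,
                                      sex="male" if k % 2 == 0 else "female")
    return Pedigree(family_id, members)


def build_marker_map(n_chromosomes: int = 22, chrom_length_cM: float = 160.0,
                     spacing_cM: float = 10.0, n_alleles: int = 4,
                     ) -> MarkerMap:
    """Evenly spaced markers with equifrequent alleles; chromosome names
    '1'..'22'."""
    freqs = tuple([1.0 / n_alleles] * n_alleles)
    loci = []
    for c in range(1, n_chromosomes + 1):
        pos = 0.0
        i = 0
        while pos <= chrom_length_cM + 1e-9:
            loci.append(Locus(f"M{c}_{i}", str(c), round(pos, 6), freqs))
            pos += spacing_cM
            i += 1
    return MarkerMap(loci)


# ---------------------------------------------------------------------------
# Gene dropping
# ---------------------------------------------------------------------------

@dataclass
class GeneDropResult:
    """Simulated genotypes plus the ground truth oracle tests need."""

    gm: GenotypeMatrix
    affection: dict[str, str]               # iid -> affected/unknown
    risk_copies: dict[str, int]             # iid -> disease-allele dose
    origins: dict[tuple[str, str], dict[str, np.ndarray]]
    # (child_id, 'pat'|'mat') -> chrom -> grand-origin bit per locus
    founder_haplotypes: dict[str, dict[str, np.ndarray]]
    # founder id -> chrom -> (2, n_loci) allele array (1-based)


def gene_drop(ped: Pedigree, marker_map: MarkerMap, model: DiseaseModel,
              disease_position: tuple[str, float] | None,
              seed, carrier_founder: str | None = None) -> GeneDropResult:
    """Drop founder haplotypes through one pedigree.

    ``disease_position`` is (chromosome, cM) to link the disease locus to
    the map, or None for an unlinked locus (transmitted independently of
    every marker). ``carrier_founder`` plants exactly one disease allele on
    that founder's first haplotype — the standard construct for an
    ascertained multiplex family, where drawing carriers at the population
    frequency would essentially never yield one; when None, founder disease
    alleles are drawn at ``model.disease_allele_freq``.
    """
    rng = _rng(seed)
    if disease_position is not None:
        chrom, cM = disease_position
        if chrom not in marker_map.chromosomes:
            raise ValueError(
                f"disease chromosome {chrom!r} absent from the marker map")

    order = ped.topological_order()
    chroms = marker_map.chromosomes
    loci_by_chrom = {c: marker_map.chromosome_loci(c) for c in chroms}
    # insert the disease locus into its chromosome's position sequence
    seqs: dict[str, list[tuple[float, Locus | None]]] = {}
    for c in chroms:
        seq = [(loc.position_cM, loc) for loc in loci_by_chrom[c]]
        if disease_position is not None and c == disease_position[0]:
            seq.append((disease_position[1], None))  # None marks disease
            seq.sort(key=lambda t: (t[0], t[1] is None))
        seqs[c] = seq

    # founder haplotypes
    haps: dict[str, dict[str, np.ndarray]] = {}
    disease_hap: dict[str, np.ndarray] = {}  # iid -> (2,) disease alleles
    founders = [ind for ind in order if ind.is_founder]
    for ind in founders:
        haps[ind.id] = {}
        for c in chroms:
            loci = loci_by_chrom[c]
            arr = np.empty((2, len(loci)), dtype=np.int16)
            for j, loc in enumerate(loci):
                arr[:, j] = rng.choice(
                    np.arange(1, loc.n_alleles + 1), size=2,
                    p=loc.allele_freqs)
            haps[ind.id][c] = arr
        if carrier_founder is not None:
            d = np.zeros(2, dtype=np.int8)
            if ind.id == carrier_founder:
                d[0] = 1
        else:
            d = (rng.random(2) < model.disease_allele_freq).astype(np.int8)
        disease_hap[ind.id] = d
    if carrier_founder is not None and carrier_founder not in haps:
        raise ValueError(f"carrier founder {carrier_founder!r} is not a "
                         "founder of this family")

    origins: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    dis_origin: dict[tuple[str, str], int] = {}

    def meiosis(parent_id: str, child_id: str, side: str
                ) -> tuple[dict[str, np.ndarray], np.ndarray]:
        """One gamete: per-chromosome transmitted alleles + disease allele."""
        gamete: dict[str, np.ndarray] = {}
        origins[(child_id, side)] = {}
        d_allele = 0
        linked_chrom = disease_position[0] if disease_position else None
        for c in chroms:
            seq = seqs[c]
            bits = np.empty(len(seq), dtype=np.int8)
            bit = int(rng.integers(2))
            prev_pos = None
            for j, (pos, loc) in enumerate(seq):
                if prev_pos is not None:
                    th = haldane_theta(pos - prev_pos).theta
                    if rng.random() < th:
                        bit ^= 1
                bits[j] = bit
                prev_pos = pos
            marker_bits = np.array(
                [b for b, (_, loc) in zip(bits, seq) if loc is not None],
                dtype=np.int8)
            gamete[c] = np.array([
                haps[parent_id][c][b, jj]
                for jj, b in enumerate(marker_bits)], dtype=np.int16)
            origins[(child_id, side)][c] = marker_bits
            if c == linked_chrom:
                d_bit = int(bits[[loc is None
                                  for _, loc in seq].index(True)])
                d_allele = int(disease_hap[parent_id][d_bit])
                dis_origin[(child_id, side)] = d_bit
        if disease_position is None:
            d_bit = int(rng.integers(2))
            d_allele = int(disease_hap[parent_id][d_bit])
            dis_origin[(child_id, side)] = d_bit
        return gamete, np.int8(d_allele)

    for ind in order:
        if ind.is_founder:
            continue
        pat, d_pat = meiosis(ind.father_id, ind.id, "pat")
        mat, d_mat = meiosis(ind.mother_id, ind.id, "mat")
        haps[ind.id] = {c: np.stack([pat[c], mat[c]]) for c in chroms}
        disease_hap[ind.id] = np.array([d_pat, d_mat], dtype=np.int8)

    gm = GenotypeMatrix()
    risk_copies: dict[str, int] = {}
    affection: dict[str, str] = {}
    for ind in order:
        for c in chroms:
            for j, loc in enumerate(loci_by_chrom[c]):
                gm.set(ind.id, loc.id,
                       (int(haps[ind.id][c][0, j]),
                        int(haps[ind.id][c][1, j])))
        dose = int(disease_hap[ind.id].sum())
        risk_copies[ind.id] = dose
        affection[ind.id] = ("affected"
                             if rng.random() < model.penetrance(dose)
                             else "unknown")
    founder_haps = {ind.id: haps[ind.id] for ind in founders}
    return GeneDropResult(gm, affection, risk_copies, origins, founder_haps)


def apply_affection(ped: Pedigree, affection: dict[str, str]) -> Pedigree:
    """A copy of the pedigree with simulated affection statuses applied."""
    members = {iid: replace(ind, affection=affection[iid])
               for iid, ind in ped.members.items()}
    return Pedigree(ped.family_id, members, list(ped.loop_breakers))


def simulate_family(ped: Pedigree, marker_map: MarkerMap,
                    model: DiseaseModel,
                    disease_position: tuple[str, float] | None,
                    seed, carrier_founder: str | None,
                    min_affected: int = 1, max_tries: int = 1000,
                    ) -> tuple[Pedigree, GeneDropResult]:
    """Gene-drop with ascertainment: resimulate until at least
    ``min_affected`` members are affected (multiplex-family collection)."""
    rng = _rng(seed)
    for _ in range(max_tries):
        res = gene_drop(ped, marker_map, model, disease_position, rng,
                        carrier_founder)
        if sum(a == "affected" for a in res.affection.values()) \
                >= min_affected:
            return apply_affection(ped, res.affection), res
    raise RuntimeError(
        f"ascertainment failed after {max_tries} tries for "
        f"{ped.family_id}: min_affected={min_affected} never reached")


@dataclass
class LinkedStudy:
    pedigrees: list[Pedigree]
    gm: GenotypeMatrix
    marker_map: MarkerMap
    truths: dict[str, GeneDropResult]
    disease_position: tuple[str, float]


def simulate_linked_study(scenario: SimScenario,
                          marker_map: MarkerMap | None = None,
                          ) -> LinkedStudy:
    """The full multiplex-family linkage dataset: ``n_families`` ascertained
    three-generation families, each segregating one founder copy of the
    disease allele at the scenario's disease position."""
    rng = _rng(scenario.seed)
    if marker_map is None:
        marker_map = build_marker_map(
            scenario.n_chromosomes, scenario.chrom_length_cM,
            scenario.marker_spacing_cM, scenario.n_alleles)
    pos = (scenario.disease_chromosome, scenario.disease_cM)
    gm = GenotypeMatrix()
    peds, truths = [], {}
    for i in range(scenario.n_families):
        fid = f"fam{i + 1}"
        ped = build_pedigree(fid, scenario.template)
        carrier = f"{fid}_gf"
        ped2, res = simulate_family(ped, marker_map, scenario.model, pos,
                                    rng, carrier, scenario.min_affected)
        peds.append(ped2)
        truths[fid] = res
        for (iid, locus), g in res.gm.items():
            gm.set(iid, locus, g)
    return LinkedStudy(peds, gm, marker_map, truths, pos)


# ---------------------------------------------------------------------------
# Exome tables
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


@dataclass
class ExomeSimResult:
    cases: dict[str, list[VariantRecord]]
    controls: list[VariantRecord]          # merged control-panel variants
    gene_regions: dict[str, GenomicRegion]
    planted_gene: str
    planted_key: tuple[str, int, str, str]
    planted_case_ids: list[str]


def simulate_exome_tables(spec: ExomeSpec, seed) -> ExomeSimResult:
    """Per-case annotated variant tables with one planted causal variant.

    Known (catalog) sites form a shared common pool; unknown background
    sites are private per case, a stated fraction of them also present in
    the control panel. The planted variant sits in ``planted_gene`` inside
    the locus region, passes all quality thresholds, is absent from the
    catalog and the controls, and appears in ``planted_cases`` of the
    cases.
    """
    rng = _rng(seed)
    genes: dict[str, GenomicRegion] = {}
    loc = spec.locus
    width = (loc.length_bp - 1) // max(spec.genes_in_locus, 1)
    for g in range(spec.genes_in_locus):
        start = loc.start_bp + g * width
        genes[f"LOCUS_G{g}"] = GenomicRegion(
            loc.chromosome, start, min(start + width - 1, loc.end_bp))
    n_bg_genes = spec.n_genes - spec.genes_in_locus
    for g in range(n_bg_genes):
        chrom = str(1 + g % 16)
        start = 1_000_000 + (g // 16) * 60_000
        genes[f"BG_G{g}"] = GenomicRegion(chrom, start, start + 29_999)
    if spec.planted_gene not in genes:
        raise ValueError(f"planted gene {spec.planted_gene!r} does not lie "
                         "in the locus gene set")
    gene_ids = np.array(sorted(genes))

    n_known_per_case = round(spec.background_per_case * spec.fraction_known)
    n_unknown = spec.background_per_case - n_known_per_case
    # shared known-site pool: each site present in each case w.p. q
    q = 0.8
    pool_size = int(n_known_per_case / q)
    pool_genes = rng.choice(gene_ids, size=pool_size)
    pool_pos = np.empty(pool_size, dtype=np.int64)
    for i, g in enumerate(pool_genes):
        r = genes[g]
        pool_pos[i] = rng.integers(r.start_bp, r.end_bp + 1)

    def draw_quality(force_pass: bool = False):
        if not force_pass and rng.random() < spec.fraction_quality_fail:
            which = rng.integers(3)
            depth = int(rng.integers(0, 9)) if which == 0 \
                else int(rng.integers(9, 200))
            cq = float(rng.uniform(0, 30)) if which == 1 \
                else float(rng.uniform(31, 90))
            mq = float(rng.uniform(0, 20)) if which == 2 \
                else float(rng.uniform(21, 60))
        else:
            depth = int(rng.integers(9, 200))
            cq = float(rng.uniform(31, 90))
            mq = float(rng.uniform(21, 60))
        return depth, cq, mq

    def effect_class():
        return str(rng.choice(["MS", "NS", "SS", "Indel"],
                              p=[0.85, 0.03, 0.04, 0.08]))

    case_ids = [f"case{i + 1}" for i in range(spec.n_cases)]
    planted_cases = case_ids[:spec.planted_cases]
    pg = genes[spec.planted_gene]
    planted_pos = int((pg.start_bp + pg.end_bp) // 2)
    planted = dict(chromosome=pg.chromosome, position_bp=planted_pos,
                   ref="G", alt="A", gene=spec.planted_gene,
                   effect_class="MS")

    cases: dict[str, list[VariantRecord]] = {}
    controls: list[VariantRecord] = []
    uid = 0

    def new_record(cid_tag, chrom, pos, ref, alt, gene, eff, known,
                   force_pass=False) -> VariantRecord:
        nonlocal uid
        uid += 1
        depth, cq, mq = draw_quality(force_pass)
        return VariantRecord(
            f"v{uid}_{cid_tag}", chrom, pos, ref, alt, gene, eff,
            depth, cq, mq,
            frozenset({"dbSNP131"}) if known else frozenset(),
            "het")

    for ci, cid in enumerate(case_ids):
        recs: list[VariantRecord] = []
        present = rng.random(pool_size) < q
        for i in np.nonzero(present)[0]:
            g = str(pool_genes[i])
            ref, alt = _random_snv(rng)
            recs.append(new_record(cid, genes[g].chromosome,
                                   int(pool_pos[i]), ref, alt, g,
                                   effect_class(), known=True))
        for _ in range(n_unknown):
            g = str(rng.choice(gene_ids))
            r = genes[g]
            pos = int(rng.integers(r.start_bp, r.end_bp + 1))
            ref, alt = _random_snv(rng)
            rec = new_record(cid, r.chromosome, pos, ref, alt, g,
                             effect_class(), known=False)
            recs.append(rec)
            if rng.random() < spec.fraction_in_controls:
                controls.append(VariantRecord(
                    f"ctl_{rec.variant_id}", rec.chromosome,
                    rec.position_bp, rec.ref, rec.alt, g,
                    rec.effect_class, 50, 60.0, 40.0, rec.known_ids, "het"))
        for _ in range(spec.synonymous_per_case):
            g = str(rng.choice(gene_ids))
            r = genes[g]
            pos = int(rng.integers(r.start_bp, r.end_bp + 1))
            ref, alt = _random_snv(rng)
            recs.append(new_record(cid, r.chromosome, pos, ref, alt, g,
                                   "other", known=bool(rng.random() < 0.9)))
        if cid in planted_cases:
            recs.append(new_record(cid, planted["chromosome"],
                                   planted["position_bp"], planted["ref"],
                                   planted["alt"], planted["gene"],
                                   planted["effect_class"], known=False,
                                   force_pass=True))
        cases[cid] = recs

    planted_key = (planted["chromosome"], planted["position_bp"],
                   planted["ref"], planted["alt"])
    return ExomeSimResult(cases, controls, genes, spec.planted_gene,
                          planted_key, planted_cases)


def _random_snv(rng) -> tuple[str, str]:
    i = int(rng.integers(4))
    j = (i + 1 + int(rng.integers(3))) % 4
    return str(_BASES[i]), str(_BASES[j])


# ---------------------------------------------------------------------------
# Case-control counts
# ---------------------------------------------------------------------------

def simulate_case_control(spec: CaseControlSpec, seed) -> GenotypeCountTable:
    """Genotype counts under HWE controls and a carrier-odds-ratio case
    model (dominant effect of the risk allele)."""
    rng = _rng(seed)
    p = spec.control_risk_allele_freq
    hwe = np.array([p * p, 2 * p * (1 - p), (1 - p) ** 2])  # DD, Dd, dd
    ctl = rng.multinomial(spec.n_controls, hwe)
    carrier = p * p + 2 * p * (1 - p)
    if carrier in (0.0, 1.0):
        case_carrier = carrier
    else:
        odds = spec.carrier_odds_ratio * carrier / (1 - carrier)
        case_carrier = odds / (1 + odds)
    w_DD = p * p / carrier if carrier > 0 else 0.0
    case_probs = np.array([case_carrier * w_DD,
                           case_carrier * (1 - w_DD),
                           1 - case_carrier])
    cas = rng.multinomial(spec.n_cases, case_probs)
    return GenotypeCountTable(spec.stratum, int(cas[0]), int(cas[1]),
                              int(cas[2]), int(ctl[0]), int(ctl[1]),
                              int(ctl[2]))
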