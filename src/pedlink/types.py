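"""Core data model shared by every pipeline stage.

The pipeline studies autosomal-dominant disease families: a pedigree of
individuals with affection status, a parametric disease model (allele
frequency, phenocopy rate, carrier penetrance), a genetic marker map with
centimorgan positions and population allele frequencies, and the downstream
substrates — per-case annotated variant tables, genomic regions, and
case/control genotype-count tables.

Affection is deliberately two-valued (``affected`` / ``unknown``): with
incomplete, age-dependent penetrance an unaffected relative carries almost
no phenotype information, so unaffecteds are scored as phenotype-unknown.
An ``unaffected`` code is accepted on input but coerced to ``unknown`` with
a logged notice.

Coordinates are 1-based closed intervals throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

logger = logging.getLogger("pedlink")

SEXES = frozenset({"male", "female", "unknown"})
AFFECTIONS = frozenset({"affected", "unknown"})
EFFECT_CLASSES = frozenset({"MS", "NS", "SS", "Indel", "other"})
GENOTYPE_CALLS = frozenset({"het", "hom_alt"})
ASSOC_MODELS = ("allelic", "additive", "dominant", "recessive")


def _check_prob(value: float, name: str) -> float:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")
    return float(value)


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Individual:
    """One pedigree member.

    Founders have both parent ids absent; non-founders have both present.
    """

    id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: str = "unknown"
    affection: str = "unknown"

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"bad sex {self.sex!r} for {self.id}")
        if self.affection == "unaffected":
            logger.info(
                "individual %s coded 'unaffected'; scored as phenotype "
                "unknown (affected-only analysis)", self.id)
            object.__setattr__(self, "affection", "unknown")
        if self.affection not in AFFECTIONS:
            raise ValueError(f"bad affection {self.affection!r} for {self.id}")

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


@dataclass
class Pedigree:
    """A single family: members keyed by id, parent links forming a DAG."""

    family_id: str
    members: dict[str, Individual]
    loop_breakers: list[str] = field(default_factory=list)

    @property
    def founders(self) -> list[Individual]:
        return [m for m in self.members.values() if m.is_founder]

    @property
    def nonfounders(self) -> list[Individual]:
        return [m for m in self.members.values() if not m.is_founder]

    def topological_order(self) -> list[Individual]:
        """Members ordered parents-before-children (founders first)."""
        placed: dict[str, Individual] = {}
        order: list[Individual] = []
        pending = dict(self.members)
        while pending:
            progressed = False
            for iid, ind in list(pending.items()):
                ok = ind.is_founder or (
                    ind.father_id in placed and ind.mother_id in placed)
                if ok:
                    placed[iid] = ind
                    order.append(ind)
                    del pending[iid]
                    progressed = True
            if not progressed:
                raise ValueError(
                    f"pedigree {self.family_id}: parent links are cyclic or "
                    f"unresolvable for {sorted(pending)}")
        return order

    def affected_ids(self) -> list[str]:
        return [m.id for m in self.members.values()
                if m.affection == "affected"]


def validate_pedigree(ped: Pedigree) -> list[str]:
    """Return human-readable invariant violations (empty list = valid).

    Never raises: intended as a gatekeeper on freshly parsed input.
    """
    violations: list[str] = []
    for ind in ped.members.values():
        has_f, has_m = ind.father_id is not None, ind.mother_id is not None
        if has_f != has_m:
            which = "mother_id" if has_f else "father_id"
            violations.append(
                f"{ind.id}: non-founder missing {which} (parents must be "
                f"both present or both absent)")
        for role, pid in (("father", ind.father_id), ("mother", ind.mother_id)):
            if pid is not None and pid not in ped.members:
                violations.append(
                    f"{ind.id}: {role} {pid!r} not a member of family "
                    f"{ped.family_id}")
    if not any(m.is_founder for m in ped.members.values()):
        violations.append(f"family {ped.family_id}: no founder")
    # ancestry cycles (an individual its own ancestor), robust to bad links
    for start in ped.members.values():
        stack, seen = [start.id], set()
        while stack:
            iid = stack.pop()
            ind = ped.members.get(iid)
            if ind is None:
                continue
            for pid in (ind.father_id, ind.mother_id):
                if pid == start.id:
                    violations.append(f"{start.id}: is its own ancestor")
                    stack = []
                    break
                if pid is not None and pid not in seen:
                    seen.add(pid)
                    stack.append(pid)
    return violations


# ---------------------------------------------------------------------------
# Disease model and marker map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiseaseModel:
    """Parametric autosomal-dominant disease model.

    disease_allele_freq : population frequency of the risk allele D.
    phenocopy : P(affected | dd), the phenocopy rate.
    penetrance_het / penetrance_hom : P(affected | Dd) and P(affected | DD).
      Default 1.0 (fully penetrant dominant); configurable because
      published analyses often take penetrance from prior reports.
    """

    disease_allele_freq: float = 0.00002
    phenocopy: float = 0.000001
    penetrance_het: float = 1.0
    penetrance_hom: float = 1.0
    inheritance: str = "autosomal_dominant"

    def __post_init__(self) -> None:
        _check_prob(self.disease_allele_freq, "disease_allele_freq")
        _check_prob(self.phenocopy, "phenocopy")
        _check_prob(self.penetrance_het, "penetrance_het")
        _check_prob(self.penetrance_hom, "penetrance_hom")
        if not (self.phenocopy <= self.penetrance_het <= self.penetrance_hom):
            raise ValueError(
                "require phenocopy <= penetrance_het <= penetrance_hom")
        if self.inheritance != "autosomal_dominant":
            raise ValueError("only autosomal_dominant inheritance supported")

    def penetrance(self, n_risk_alleles: int) -> float:
        """P(affected | number of copies of the risk allele)."""
        return (self.phenocopy, self.penetrance_het,
                self.penetrance_hom)[n_risk_alleles]


@dataclass(frozen=True)
class Locus:
    id: str
    chromosome: str
    position_cM: float
    allele_freqs: tuple[float, ...]
    position_bp: int | None = None

    def __post_init__(self) -> None:
        if abs(sum(self.allele_freqs) - 1.0) > 1e-9:
            raise ValueError(
                f"locus {self.id}: allele frequencies sum to "
                f"{sum(self.allele_freqs)}, not 1")
        for f in self.allele_freqs:
            _check_prob(f, f"allele frequency at {self.id}")

    @property
    def n_alleles(self) -> int:
        return len(self.allele_freqs)


@dataclass
class MarkerMap:
    """Ordered marker loci with cM positions and allele frequencies."""

    loci: list[Locus]

    def __post_init__(self) -> None:
        by_chrom: dict[str, float] = {}
        for loc in self.loci:
            prev = by_chrom.get(loc.chromosome)
            if prev is not None and loc.position_cM < prev:
                raise ValueError(
                    f"locus {loc.id}: cM positions must be nondecreasing "
                    f"within chromosome {loc.chromosome}")
            by_chrom[loc.chromosome] = loc.position_cM
        self._index = {loc.id: loc for loc in self.loci}
        if len(self._index) != len(self.loci):
            raise ValueError("duplicate locus ids in map")

    def __getitem__(self, locus_id: str) -> Locus:
        return self._index[locus_id]

    def __contains__(self, locus_id: str) -> bool:
        return locus_id in self._index

    @property
    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for loc in self.loci:
            seen.setdefault(loc.chromosome, None)
        return list(seen)

    def chromosome_loci(self, chromosome: str) -> list[Locus]:
        return [l for l in self.loci if l.chromosome == chromosome]


class GenotypeMatrix:
    """(individual, locus) -> unordered allele pair (1-based ints) or missing."""

    def __init__(self) -> None:
        self._entries: dict[tuple[str, str], tuple[int, int]] = {}
        self.loci: set[str] = set()
        self.individuals: set[str] = set()

    def set(self, individual_id: str, locus_id: str,
            genotype: tuple[int, int] | None) -> None:
        self.individuals.add(individual_id)
        self.loci.add(locus_id)
        if genotype is None:
            self._entries.pop((individual_id, locus_id), None)
        else:
            a, b = genotype
            self._entries[(individual_id, locus_id)] = (min(a, b), max(a, b))

    def get(self, individual_id: str, locus_id: str) -> tuple[int, int] | None:
        return self._entries.get((individual_id, locus_id))

    def items(self):
        """Iterate ((individual_id, locus_id), (a1, a2)) pairs."""
        return self._entries.items()

    def __len__(self) -> int:
        return len(self._entries)


def mendelian_check(ped: Pedigree, gm: GenotypeMatrix,
                    locus_id: str) -> list[str]:
    """Ids of typed non-founders whose genotype violates Mendelian
    transmission from their (possibly untyped) parents.

    An untyped parent is a wildcard: it can transmit any allele, so it never
    falsifies a child.
    """
    if locus_id not in gm.loci:
        raise KeyError(f"locus {locus_id!r} has no genotypes")
    bad: list[str] = []
    for ind in ped.nonfounders:
        g = gm.get(ind.id, locus_id)
        if g is None:
            continue
        fg = gm.get(ind.father_id, locus_id)
        mg = gm.get(ind.mother_id, locus_id)
        fa = set(fg) if fg is not None else None  # None = wildcard
        mo = set(mg) if mg is not None else None
        a, b = g
        ok = False
        for x, y in ((a, b), (b, a)):
            if (fa is None or x in fa) and (mo is None or y in mo):
                ok = True
                break
        if not ok:
            bad.append(ind.id)
    return bad


# ---------------------------------------------------------------------------
# Linkage results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecombinationFraction:
    theta: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta <= 0.5:
            raise ValueError(f"theta must lie in [0, 0.5], got {self.theta}")


@dataclass(frozen=True)
class LodResult:
    """LOD score at one map position, with its per-family decomposition."""

    position: tuple[str, float]  # (chromosome, cM)
    lod: float
    per_family_lods: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.per_family_lods.values())
        if abs(total - self.lod) > 1e-9:
            raise ValueError(
                f"LOD {self.lod} != sum of per-family LODs {total}")


# ---------------------------------------------------------------------------
# Variants and regions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantRecord:
    """One annotated variant call in one case exome."""

    variant_id: str
    chromosome: str
    position_bp: int
    ref: str
    alt: str
    gene: str
    effect_class: str
    depth: int
    consensus_quality: float
    mapping_quality: float
    known_ids: frozenset[str] = frozenset()
    genotype: str = "het"

    def __post_init__(self) -> None:
        if self.effect_class not in EFFECT_CLASSES:
            raise ValueError(f"bad effect_class {self.effect_class!r}")
        if self.genotype not in GENOTYPE_CALLS:
            raise ValueError(f"bad genotype {self.genotype!r}")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.consensus_quality < 0 or self.mapping_quality < 0:
            raise ValueError("qualities must be >= 0")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Identity across cases: left-normalized (chrom, pos, ref, alt)."""
        return normalize_variant(self.chromosome, self.position_bp,
                                 self.ref, self.alt)


def normalize_variant(chromosome: str, position_bp: int, ref: str,
                      alt: str) -> tuple[str, int, str, str]:
    """Left-normalize an allele pair: trim shared suffix, then shared
    prefix (shifting the position), keeping at least one base each."""
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        position_bp += 1
    return (chromosome, position_bp, ref, alt)


@dataclass(frozen=True)
class GenomicRegion:
    """1-based closed interval on one chromosome."""

    chromosome: str
    start_bp: int
    end_bp: int

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError(
                f"start_bp {self.start_bp} > end_bp {self.end_bp}")

    def overlaps(self, other: "GenomicRegion") -> bool:
        """>= 1 bp of closed-interval overlap."""
        return (self.chromosome == other.chromosome
                and self.start_bp <= other.end_bp
                and other.start_bp <= self.end_bp)

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


# ---------------------------------------------------------------------------
# Association
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenotypeCountTable:
    """Case/control genotype counts for one stratum; D = minor/risk allele."""

    stratum: str
    case_DD: int
    case_Dd: int
    case_dd: int
    control_DD: int
    control_Dd: int
    control_dd: int

    def __post_init__(self) -> None:
        for name in ("case_DD", "case_Dd", "case_dd",
                     "control_DD", "control_Dd", "control_dd"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer")

    @property
    def n_cases(self) -> int:
        return self.case_DD + self.case_Dd + self.case_dd

    @property
    def n_controls(self) -> int:
        return self.control_DD + self.control_Dd + self.control_dd

    def pooled_with(self, other: "GenotypeCountTable",
                    stratum: str = "Total") -> "GenotypeCountTable":
        return GenotypeCountTable(
            stratum,
            self.case_DD + other.case_DD, self.case_Dd + other.case_Dd,
            self.case_dd + other.case_dd,
            self.control_DD + other.control_DD,
            self.control_Dd + other.control_Dd,
            self.control_dd + other.control_dd)


@dataclass(frozen=True)
class TwoByTwo:
    """2x2 table: (cases exposed, cases unexposed, controls exposed,
    controls unexposed)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0:
                raise ValueError("2x2 cells must be nonnegative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class AssociationResult:
    model: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    chi2: float
    neglog10_p: float
    maf_cases: float
    maf_controls: float
    hwe_p_cases: float
    hwe_p_controls: float
    corrected: bool = False  # Haldane-Anscombe +0.5 applied (zero cell)

    def __post_init__(self) -> None:
        if self.model not in ASSOC_MODELS:
            raise ValueError(f"bad model {self.model!r}")
        if self.neglog10_p < 0:
            raise ValueError("neglog10_p must be >= 0")


@dataclass(frozen=True)
class ParInput:
    """K = total cases; y = cases without the risk allele (phenocopies)."""

    K: int
    y: int

    def __post_init__(self) -> None:
        if not 0 <= self.y <= self.K:
            raise ValueError("require 0 <= y <= K")


# ---------------------------------------------------------------------------
# Haplotypes and filter accounting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HaplotypeClass:
    """One risk-haplotype class over the tracked rare-variant panel.

    Class 1 is the collective non-risk label (all-absent vector); risk
    classes carry at least one tracked variant.
    """

    class_id: int
    carried_variants: tuple[bool, ...]
    n_families: int

    def __post_init__(self) -> None:
        if self.class_id != 1 and not any(self.carried_variants):
            raise ValueError("risk class must carry >= 1 tracked variant")
        if self.class_id == 1 and any(self.carried_variants):
            raise ValueError("class 1 is the non-risk (all-absent) label")


@dataclass
class FilterStageCounts:
    """Ordered accounting of the filter cascade: per-case survivor counts
    and the shared-across-cases count at each stage."""

    stages: list[tuple[str, dict[str, int], int]] = field(default_factory=list)

    def add(self, label: str, per_case: dict[str, int], shared: int) -> None:
        self.stages.append((label, dict(per_case), shared))

    def labels(self) -> list[str]:
        return [s[0] for s in self.stages]
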