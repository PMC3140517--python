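"""Founder-haplotype analysis across apparently unrelated families.

When the same rare variant is found in many multiplex families, the
question is whether it arose once (a founder event) or recurrently. This
module phases the risk haplotype transmitted with disease in each family
over a panel of tracked rare variants, merges identical presence/absence
patterns into haplotype classes, infers the shared core region surviving
historical recombination, checks segregation of a candidate variant with
affection, and computes the probability that a multi-rare-variant
haplotype assembles by chance:

    P(chance) = 2^m * p1 * p2 * ... * pm

for m rare variants of population frequencies p_i — each variant can arrive
on either parental chromosome, hence the 2^m. A tiny value argues that the
most prevalent haplotype is ancestral (a founder haplotype) rather than a
coincidental stack of independent rare alleles.
"""

from __future__ import annotations

from dataclasses import dataclass

from .types import (GenomicRegion, GenotypeMatrix, HaplotypeClass, Pedigree,
                    logger, mendelian_check)

__all__ = [
    "PanelVariant", "RareVariantPanel", "chance_probability",
    "TransmissionPhase", "phase_by_transmission", "classify_haplotypes",
    "core_region", "SegregationReport", "check_segregation",
]


@dataclass(frozen=True)
class PanelVariant:
    id: str
    chromosome: str
    position_bp: int
    control_minor_count: int
    control_chromosome_count: int

    def __post_init__(self) -> None:
        if not 0 <= self.control_minor_count <= self.control_chromosome_count:
            raise ValueError(
                f"{self.id}: minor count exceeds chromosome count")

    @property
    def frequency(self) -> float:
        return self.control_minor_count / self.control_chromosome_count


@dataclass(frozen=True)
class RareVariantPanel:
    """Ordered rare variants tracked across families (map order)."""

    variants: tuple[PanelVariant, ...]

    def __post_init__(self) -> None:
        pos = [v.position_bp for v in self.variants]
        if pos != sorted(pos):
            raise ValueError("panel variants must be in position order")

    @property
    def frequencies(self) -> tuple[float, ...]:
        return tuple(v.frequency for v in self.variants)

    def chance_probability(self, rounded_to: int | None = None) -> float:
        """2^m x product of panel frequencies; ``rounded_to`` first rounds
        each frequency to that many decimals (to reproduce calculations
        quoted from rounded published frequencies)."""
        freqs = self.frequencies
        if rounded_to is not None:
            freqs = tuple(round(f, rounded_to) for f in freqs)
        return chance_probability(freqs)


def chance_probability(frequencies, m: int | None = None) -> float:
    """Probability that an m-variant haplotype assembles by chance:
    2^m x prod(p_i). ``m`` defaults to len(frequencies) and must match it
    when given."""
    freqs = tuple(float(f) for f in frequencies)
    if m is None:
        m = len(freqs)
    if m != len(freqs):
        raise ValueError(f"m={m} does not match {len(freqs)} frequencies")
    for f in freqs:
        if not 0.0 < f <= 0.5:
            raise ValueError(f"panel frequency {f} outside (0, 0.5]")
    out = float(2 ** m)
    for f in freqs:
        out *= f
    return out


# ---------------------------------------------------------------------------
# Transmission phasing
# ---------------------------------------------------------------------------

@dataclass
class TransmissionPhase:
    """Rule-based phase for one family over ordered biallelic loci
    (allele 2 = the tracked rare/minor allele).

    ``phased[iid][l]`` is the (from-father, from-mother) ordered pair where
    Mendelian transmission forces it, else None (e.g. both parents and the
    child heterozygous). ``risk_vector[l]`` marks the loci whose rare
    allele rides on the haplotype co-transmitted with affection.
    """

    family_id: str
    loci: list[str]
    phased: dict[str, list[tuple[int, int] | None]]
    risk_vector: tuple[bool, ...]


def phase_by_transmission(ped: Pedigree, gm: GenotypeMatrix,
                          loci: list[str]) -> TransmissionPhase:
    """Phase child genotypes by parental origin where forced, and extract
    the family's risk haplotype over the panel.

    A position is phased when exactly one ordered (paternal, maternal)
    assignment of the child's alleles is compatible with the parents'
    genotypes; untyped parents are wildcards. The risk haplotype carries a
    panel variant when every affected, typed member carries its rare
    allele — for variants this rare, joint carriage across all affecteds
    identifies the co-segregating haplotype content; ambiguous positions
    are scored non-carrying (conservative) and logged.

    Raises on Mendelian inconsistency, listing the offending members.
    """
    bad: dict[str, list[str]] = {}
    for locus in loci:
        if locus not in gm.loci:
            continue
        inconsistent = mendelian_check(ped, gm, locus)
        for iid in inconsistent:
            bad.setdefault(locus, []).append(iid)
    if bad:
        msgs = "; ".join(f"{locus}: {ids}" for locus, ids in bad.items())
        raise ValueError(
            f"family {ped.family_id}: Mendelian inconsistencies ({msgs})")

    phased: dict[str, list[tuple[int, int] | None]] = {}
    for ind in ped.members.values():
        row: list[tuple[int, int] | None] = []
        for locus in loci:
            g = gm.get(ind.id, locus)
            if g is None or ind.is_founder:
                row.append(None)
                continue
            fg = gm.get(ind.father_id, locus)
            mg = gm.get(ind.mother_id, locus)
            fa = set(fg) if fg is not None else None
            mo = set(mg) if mg is not None else None
            a, b = g
            options = {(x, y) for x, y in ((a, b), (b, a))
                       if (fa is None or x in fa)
                       and (mo is None or y in mo)}
            row.append(options.pop() if len(options) == 1 else None)
        phased[ind.id] = row

    affected = [iid for iid in ped.members
                if ped.members[iid].affection == "affected"]
    risk = []
    for l, locus in enumerate(loci):
        typed = [gm.get(iid, locus) for iid in affected
                 if gm.get(iid, locus) is not None]
        carried = bool(typed) and all(2 in g for g in typed)
        if carried and any(gm.get(iid, locus) is None for iid in affected):
            logger.info("family %s, locus %s: some affecteds untyped; "
                        "risk carriage based on typed members only",
                        ped.family_id, locus)
        risk.append(carried)
    return TransmissionPhase(ped.family_id, list(loci), phased, tuple(risk))


# ---------------------------------------------------------------------------
# Haplotype classes, core region, segregation
# ---------------------------------------------------------------------------

def classify_haplotypes(risk_vectors: dict[str, tuple[bool, ...]]
                        ) -> list[HaplotypeClass]:
    """Merge identical risk-haplotype vectors into classes.

    Families carrying no panel variant collapse into class 1 (the
    collective non-risk label); risk classes are numbered 2, 3, ... in
    descending family count (ties broken by vector, most variants first).
    """
    if not risk_vectors:
        return []
    n_loci = len(next(iter(risk_vectors.values())))
    groups: dict[tuple[bool, ...], int] = {}
    for fid, vec in risk_vectors.items():
        if len(vec) != n_loci:
            raise ValueError(f"family {fid}: vector length mismatch")
        groups[tuple(vec)] = groups.get(tuple(vec), 0) + 1
    nonrisk = tuple([False] * n_loci)
    classes = []
    n_nonrisk = groups.pop(nonrisk, 0)
    ordered = sorted(groups.items(),
                     key=lambda kv: (-kv[1], -sum(kv[0]), kv[0]))
    if n_nonrisk:
        classes.append(HaplotypeClass(1, nonrisk, n_nonrisk))
    for i, (vec, count) in enumerate(ordered):
        classes.append(HaplotypeClass(i + 2, vec, count))
    return classes


def core_region(classes: list[HaplotypeClass],
                positions: list[tuple[str, int]]) -> GenomicRegion | None:
    """Maximal interval over which every risk class carries the founder
    alleles: the intersection of each class's carried span, in panel
    coordinates ((chromosome, bp) per panel variant).

    Returns None when the intersection is empty — a meaningful outcome
    (no shared core survives the observed historical recombinations).
    """
    risk = [c for c in classes if c.class_id != 1]
    if not risk:
        raise ValueError("no risk classes")
    lo, hi = 0, len(positions) - 1
    for c in risk:
        idx = [i for i, carried in enumerate(c.carried_variants) if carried]
        lo = max(lo, min(idx))
        hi = min(hi, max(idx))
    if lo > hi:
        return None
    chrom = positions[lo][0]
    if positions[hi][0] != chrom:
        raise ValueError("panel spans multiple chromosomes")
    return GenomicRegion(chrom, positions[lo][1], positions[hi][1])


@dataclass
class SegregationReport:
    segregating_families: list[str]
    failing_families: dict[str, list[str]]  # fid -> affected non-carriers
    unaffected_carriers: dict[str, list[str]]

    @property
    def fully_segregating(self) -> bool:
        return not self.failing_families


def check_segregation(peds: list[Pedigree],
                      risk_copies: dict[str, int]) -> SegregationReport:
    """Does every affected member of every family carry >= 1 risk allele?

    ``risk_copies`` maps individual id to risk-allele dose (members absent
    from it are treated as untyped and skipped). Unaffected carriers are
    reported as reduced-penetrance evidence, never as failures.
    """
    seg, fail, unaff = [], {}, {}
    for ped in peds:
        bad = [iid for iid in ped.affected_ids()
               if iid in risk_copies and risk_copies[iid] == 0]
        carriers = [iid for iid, ind in ped.members.items()
                    if ind.affection != "affected"
                    and risk_copies.get(iid, 0) > 0]
        if bad:
            fail[ped.family_id] = bad
        else:
            seg.append(ped.family_id)
        if carriers:
            unaff[ped.family_id] = carriers
    return SegregationReport(seg, fail, unaff)
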