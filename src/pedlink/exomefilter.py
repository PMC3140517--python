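"""Exome rare-variant filter cascade with k-of-n case sharing.

A modified discrete-filtering strategy for dominant disease genes under
possible genetic heterogeneity. Per-case variant tables pass through, in
order:

1. quality filter   — depth > 8, consensus quality > 30, mapping quality
                      > 20 (strict inequalities);
2. class filter     — keep missense / nonsense / splice-site / indel;
3. known-catalog exclusion (e.g. a dbSNP build);
4. control-exome exclusion (variants seen in a same-platform control panel);
5. gene collapse    — a gene counts for a case if any surviving variant of
                      that case hits it (tolerating allelic heterogeneity);
6. subset sharing   — genes with a qualifying variant in >= k of n cases,
                      with the full k-sweep reported;
7. locus intersection — genes overlapping the linkage locus (1-based
                      closed intervals, >= 1 bp overlap).

Variant identity across cases and catalogs is the left-normalized
(chromosome, position, ref, alt) key.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .types import (FilterStageCounts, GenomicRegion, VariantRecord, logger)

__all__ = [
    "CascadeConfig", "quality_filter", "class_filter", "exclude_known",
    "exclude_controls", "genes_per_case", "subset_sharing",
    "locus_intersect", "run_cascade", "CascadeResult",
]

VariantKey = tuple[str, int, str, str]


@dataclass(frozen=True)
class CascadeConfig:
    depth_min: int = 8                    # exclusive
    consensus_quality_min: float = 30.0   # exclusive
    mapping_quality_min: float = 20.0     # exclusive
    effect_classes: frozenset[str] = frozenset({"MS", "NS", "SS", "Indel"})
    known_catalogs: frozenset[str] = frozenset({"dbSNP131"})
    k: int = 8
    locus: GenomicRegion | None = None

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("sharing parameter k must be >= 1")


def quality_filter(records: list[VariantRecord],
                   config: CascadeConfig = CascadeConfig(),
                   ) -> list[VariantRecord]:
    """Keep records strictly above all three quality thresholds."""
    return [r for r in records
            if r.depth > config.depth_min
            and r.consensus_quality > config.consensus_quality_min
            and r.mapping_quality > config.mapping_quality_min]


def class_filter(records: list[VariantRecord],
                 keep: frozenset[str] = frozenset({"MS", "NS", "SS",
                                                   "Indel"}),
                 ) -> list[VariantRecord]:
    return [r for r in records if r.effect_class in keep]


def exclude_known(records: list[VariantRecord],
                  catalog_names: frozenset[str] | set[str],
                  site_catalogs: dict[str, set[VariantKey]] | None = None,
                  ) -> list[VariantRecord]:
    """Remove records present in any named catalog, matched either by the
    record's own catalog-membership flags (ids) or by site key."""
    names = frozenset(catalog_names)
    sites: set[VariantKey] = set()
    for name, keys in (site_catalogs or {}).items():
        if name in names or not names:
            sites.update(keys)
    out = []
    for r in records:
        if r.known_ids & names:
            continue
        if sites and r.key in sites:
            continue
        out.append(r)
    return out


def exclude_controls(records: list[VariantRecord],
                     control_records: list[VariantRecord],
                     ) -> list[VariantRecord]:
    """Remove records whose site key is present in the control panel."""
    seen = {c.key for c in control_records}
    return [r for r in records if r.key not in seen]


def genes_per_case(per_case: dict[str, list[VariantRecord]]
                   ) -> dict[str, set[str]]:
    return {cid: {r.gene for r in recs} for cid, recs in per_case.items()}


def subset_sharing(per_case_gene_sets: dict[str, set[str]], k: int
                   ) -> tuple[set[str], dict[int, set[str]]]:
    """Genes present in >= k of the n cases, plus the full k-sweep.

    Returns ``(headline_set, {k: gene_set for k in 1..n})``; the candidate
    set is nonincreasing in k by construction.
    """
    n = len(per_case_gene_sets)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range 1..{n}")
    counts: dict[str, int] = {}
    for genes in per_case_gene_sets.values():
        for g in genes:
            counts[g] = counts.get(g, 0) + 1
    sweep = {kk: {g for g, c in counts.items() if c >= kk}
             for kk in range(1, n + 1)}
    return sweep[k], sweep


def locus_intersect(genes: set[str],
                    gene_regions: dict[str, GenomicRegion],
                    locus: GenomicRegion) -> set[str]:
    """Genes whose region overlaps the locus by >= 1 bp (closed
    intervals). Genes without a known region are dropped with a warning."""
    out = set()
    for g in genes:
        region = gene_regions.get(g)
        if region is None:
            logger.warning("gene %s has no region annotation; dropped from "
                           "locus intersection", g)
            continue
        if region.overlaps(locus):
            out.add(g)
    return out


@dataclass
class CascadeResult:
    counts: FilterStageCounts
    candidate_genes: set[str]
    sweep: dict[int, set[str]] = field(default_factory=dict)
    per_case_final: dict[str, list[VariantRecord]] = field(
        default_factory=dict)


def _shared_keys(per_case: dict[str, list[VariantRecord]], k: int) -> int:
    counts: dict[VariantKey, int] = {}
    for recs in per_case.values():
        for key in {r.key for r in recs}:
            counts[key] = counts.get(key, 0) + 1
    return sum(1 for c in counts.values() if c >= k)


def run_cascade(per_case: dict[str, list[VariantRecord]],
                config: CascadeConfig,
                control_records: list[VariantRecord] | None = None,
                gene_regions: dict[str, GenomicRegion] | None = None,
                site_catalogs: dict[str, set[VariantKey]] | None = None,
                ) -> CascadeResult:
    """Apply the full cascade and record the stage-by-stage accounting
    (per-case survivor counts and the >= k-shared count at each stage)."""
    counts = FilterStageCounts()
    cur = {cid: list(recs) for cid, recs in per_case.items()}
    if not cur:
        return CascadeResult(counts, set())
    k = config.k

    def record(label: str) -> None:
        counts.add(label, {cid: len(recs) for cid, recs in cur.items()},
                   _shared_keys(cur, k))

    record("input")
    cur = {cid: quality_filter(recs, config) for cid, recs in cur.items()}
    record("quality (>8 depth, >30 CQ, >20 MQ)")
    cur = {cid: class_filter(recs, config.effect_classes)
           for cid, recs in cur.items()}
    record("MS/NS/SS/Indel")
    cur = {cid: exclude_known(recs, config.known_catalogs, site_catalogs)
           for cid, recs in cur.items()}
    record("not in known catalogs")
    if control_records is not None:
        cur = {cid: exclude_controls(recs, control_records)
               for cid, recs in cur.items()}
        record("not in control exomes")
    gene_sets = genes_per_case(cur)
    counts.add("genes per case",
               {cid: len(g) for cid, g in gene_sets.items()},
               len(subset_sharing(gene_sets, k)[0]))
    headline, sweep = subset_sharing(gene_sets, k)
    shared_per_case = {cid: len(gene_sets[cid] & headline)
                       for cid in gene_sets}
    counts.add(f"shared by >={k} of {len(gene_sets)}", shared_per_case,
               len(headline))
    candidates = headline
    if config.locus is not None and gene_regions is not None:
        candidates = locus_intersect(headline, gene_regions, config.locus)
        counts.add("in linkage locus",
                   {cid: len(gene_sets[cid] & candidates)
                    for cid in gene_sets},
                   len(candidates))
    final = {cid: [r for r in recs if r.gene in candidates]
             for cid, recs in cur.items()}
    return CascadeResult(counts, candidates, sweep, final)
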