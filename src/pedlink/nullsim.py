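"""Simulation-based genome-wide significance for a multipoint linkage peak.

The null hypothesis keeps the observed affection pattern of every family
fixed and re-drops marker genotypes down the pedigrees unlinked to disease
(gene dropping). Each replicate records the genome-wide maximum multipoint
LOD; the observed peak is then referred to the empirical distribution of
those maxima. The empirical p-value uses the +1 correction,

    p = (1 + #{replicate max >= observed}) / (n_reps + 1),

so it is never zero, and the null distribution is summarized by its median,
2.5/97.5 percentiles and overall maximum.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .linkage import FamilyHMM, _Chain
from .simulate import gene_drop
from .types import DiseaseModel, MarkerMap, Pedigree

__all__ = ["NullScanSummary", "null_scan"]


@dataclass(frozen=True)
class NullScanSummary:
    n_reps: int
    max_of_maxima: float
    median: float
    percentile_2_5: float
    percentile_97_5: float
    observed_lod: float | None
    empirical_p: float | None
    seed: int | None

    def __post_init__(self) -> None:
        if not (self.percentile_2_5 <= self.median
                <= self.percentile_97_5 <= self.max_of_maxima + 1e-12):
            raise ValueError("percentile summary is not monotone")
        if self.empirical_p is not None and not \
                (1.0 / (self.n_reps + 1) - 1e-12 <= self.empirical_p
                 <= 1.0 + 1e-12):
            raise ValueError("empirical p outside [1/(n+1), 1]")


def _scan_max(hmms: dict[str, FamilyHMM], dis: dict[str, np.ndarray],
              marker_map: MarkerMap, gm, positions) -> float:
    """Genome-wide maximum LOD for one genotype replicate."""
    chains = {}
    for chrom in marker_map.chromosomes:
        loci = marker_map.chromosome_loci(chrom)
        for fid, hmm in hmms.items():
            chains[(fid, chrom)] = _Chain(hmm, loci, gm)
    best = -math.inf
    for chrom, cM in positions:
        total = 0.0
        for fid, hmm in hmms.items():
            D = dis[fid]
            den = D.mean()
            if den <= 0:
                continue
            gamma = chains[(fid, chrom)].posterior_at(cM)
            num = float(gamma @ D)
            total += math.log10(num / den) if num > 0 else -math.inf
        best = max(best, total)
    return best


def null_scan(peds: list[Pedigree], marker_map: MarkerMap,
              model: DiseaseModel, n_reps: int, seed,
              observed_lod: float | None = None,
              positions: list[tuple[str, float]] | None = None,
              grid_cM: float | None = None, bit_cap: int = 16,
              ) -> tuple[NullScanSummary, np.ndarray]:
    """Null distribution of the genome-wide maximum multipoint LOD.

    Affection statuses are those of ``peds`` (held fixed); marker genotypes
    are re-dropped from the map's allele frequencies each replicate with
    the disease locus unlinked. Returns the summary and the raw maxima.
    """
    if n_reps < 100:
        warnings.warn(
            f"n_reps={n_reps} < 100: empirical percentiles (and any "
            "empirical p) will be unstable", stacklevel=2)
    rng = np.random.default_rng(seed)
    hmms = {p.family_id: FamilyHMM(p, bit_cap) for p in peds}
    dis = {fid: hmm.disease_emission(model) for fid, hmm in hmms.items()}
    if positions is None:
        pos_list = []
        for chrom in marker_map.chromosomes:
            loci = marker_map.chromosome_loci(chrom)
            pts = sorted({loc.position_cM for loc in loci})
            if grid_cM:
                lo, hi = pts[0], pts[-1]
                g = lo
                while g <= hi + 1e-9:
                    pts.append(round(g, 6))
                    g += grid_cM
                pts = sorted(set(pts))
            pos_list.extend((chrom, p) for p in pts)
        positions = pos_list

    maxima = np.empty(n_reps)
    for r in range(n_reps):
        from .types import GenotypeMatrix
        gm = GenotypeMatrix()
        for p in peds:
            res = gene_drop(p, marker_map, model, None, rng)
            for (iid, locus), g in res.gm.items():
                gm.set(iid, locus, g)
        maxima[r] = _scan_max(hmms, dis, marker_map, gm, positions)

    emp_p = None
    if observed_lod is not None:
        emp_p = (1 + int((maxima >= observed_lod - 1e-12).sum())) \
            / (n_reps + 1)
    summary = NullScanSummary(
        n_reps=n_reps,
        max_of_maxima=float(maxima.max()),
        median=float(np.median(maxima)),
        percentile_2_5=float(np.percentile(maxima, 2.5)),
        percentile_97_5=float(np.percentile(maxima, 97.5)),
        observed_lod=observed_lod,
        empirical_p=emp_p,
        seed=seed if isinstance(seed, int) else None)
    return summary, maxima
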