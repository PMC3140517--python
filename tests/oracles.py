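"""Independent brute-force oracles for the likelihood engines.

These deliberately avoid the production code paths: emissions are computed
by itertools enumeration of founder-allele configurations, transitions as
dense Hamming-distance matrices, and the chain sum as plain matrix
products — no per-bit factorization, no scaling, no deduplication.
"""

import itertools
import math

import numpy as np

from pedlink.types import DiseaseModel, GenotypeMatrix, Locus, Pedigree


def _descent_slots(ped: Pedigree):
    """Per-state founder-slot assignment, by plain recursion."""
    order = ped.topological_order()
    founders = [i for i in order if i.is_founder]
    nonf = [i for i in order if not i.is_founder]
    B = 2 * len(nonf)
    slot = {f.id: (2 * j, 2 * j + 1) for j, f in enumerate(founders)}
    bit = {}
    for j, nf in enumerate(nonf):
        bit[(nf.id, 0)] = 2 * j
        bit[(nf.id, 1)] = 2 * j + 1
    states = []
    for v in range(1 << B):
        s = dict(slot)
        for nf in nonf:
            pb = (v >> bit[(nf.id, 0)]) & 1
            mb = (v >> bit[(nf.id, 1)]) & 1
            s[nf.id] = (s[nf.father_id][pb], s[nf.mother_id][mb])
        states.append(s)
    return order, founders, B, states


def brute_marker_emission(ped: Pedigree, gm: GenotypeMatrix,
                          locus: Locus) -> np.ndarray:
    order, founders, B, states = _descent_slots(ped)
    k = locus.n_alleles
    out = np.zeros(1 << B)
    for v, slots in enumerate(states):
        total = 0.0
        for alleles in itertools.product(range(1, k + 1),
                                         repeat=2 * len(founders)):
            w = 1.0
            ok = True
            for a in alleles:
                w *= locus.allele_freqs[a - 1]
            for ind in order:
                g = gm.get(ind.id, locus.id)
                if g is None:
                    continue
                s1, s2 = slots[ind.id]
                pair = tuple(sorted((alleles[s1], alleles[s2])))
                if pair != g:
                    ok = False
                    break
            if ok:
                total += w
        out[v] = total
    return out


def brute_disease_emission(ped: Pedigree, model: DiseaseModel) -> np.ndarray:
    order, founders, B, states = _descent_slots(ped)
    pen = [model.phenocopy, model.penetrance_het, model.penetrance_hom]
    p = model.disease_allele_freq
    out = np.zeros(1 << B)
    for v, slots in enumerate(states):
        total = 0.0
        for dis in itertools.product((0, 1), repeat=2 * len(founders)):
            w = 1.0
            for d in dis:
                w *= p if d else 1 - p
            for ind in order:
                if ind.affection == "affected":
                    s1, s2 = slots[ind.id]
                    w *= pen[dis[s1] + dis[s2]]
            total += w
        out[v] = total
    return out


def _dense_transition(B: int, theta: float) -> np.ndarray:
    n = 1 << B
    T = np.empty((n, n))
    for a in range(n):
        for b in range(n):
            h = bin(a ^ b).count("1")
            T[a, b] = theta ** h * (1 - theta) ** (B - h)
    return T


def brute_multipoint_lod(ped: Pedigree, gm: GenotypeMatrix,
                         loci: list[Locus], model: DiseaseModel,
                         position_cM: float) -> float:
    """Exhaustive multipoint LOD at one position on one chromosome."""
    _, _, B, _ = _descent_slots(ped)
    n = 1 << B
    E = [brute_marker_emission(ped, gm, loc) for loc in loci]
    D = brute_disease_emission(ped, model)

    def theta(d):
        return 0.5 * (1 - math.exp(-0.02 * abs(d)))

    # chain with the disease position spliced into the locus sequence
    seq = sorted([(loc.position_cM, i) for i, loc in enumerate(loci)]
                 + [(position_cM, None)], key=lambda t: (t[0], t[1] is None))

    def chain(with_disease: bool) -> float:
        v = np.full(n, 1.0 / n)
        prev_pos = None
        for pos, idx in seq:
            if prev_pos is not None:
                v = v @ _dense_transition(B, theta(pos - prev_pos))
            if idx is None:
                if with_disease:
                    v = v * D
            else:
                v = v * E[idx]
            prev_pos = pos
        return float(v.sum())

    num = chain(True)
    den = chain(False) * float(D.mean())
    return math.log10(num / den)


def brute_single_locus_loglik(ped: Pedigree, gm: GenotypeMatrix,
                              locus: Locus, model: DiseaseModel,
                              theta: float) -> float:
    """Exhaustive joint disease-marker likelihood: enumerate founder
    haplotypes and per-meiosis grand-origin choices for both loci."""
    k = locus.n_alleles
    order = ped.topological_order()
    founders = [i for i in order if i.is_founder]
    nonf = [i for i in order if not i.is_founder]
    pen = [model.phenocopy, model.penetrance_het, model.penetrance_hom]
    p = model.disease_allele_freq
    hap_space = [(d, a) for d in (0, 1) for a in range(1, k + 1)]
    total = 0.0
    for f_haps in itertools.product(hap_space, repeat=2 * len(founders)):
        prior = 1.0
        hap = {}
        for j, f in enumerate(founders):
            hp, hm = f_haps[2 * j], f_haps[2 * j + 1]
            hap[f.id] = (hp, hm)
            for (d, a) in (hp, hm):
                prior *= (p if d else 1 - p) * locus.allele_freqs[a - 1]
        if prior == 0.0:
            continue
        for choices in itertools.product(range(4), repeat=2 * len(nonf)):
            w = prior
            hh = dict(hap)
            ok = True
            for j, nfi in enumerate(nonf):
                out = []
                for side, par in ((0, nfi.father_id), (1, nfi.mother_id)):
                    c = choices[2 * j + side]
                    gd, ga = c >> 1, c & 1
                    w *= (1 - theta) / 2 if gd == ga else theta / 2
                    ph, pm = hh[par]
                    out.append(((ph if gd == 0 else pm)[0],
                                (ph if ga == 0 else pm)[1]))
                hh[nfi.id] = tuple(out)
            for ind in order:
                (dp, ap), (dm, am) = hh[ind.id]
                if ind.affection == "affected":
                    w *= pen[dp + dm]
                    if w == 0.0:
                        ok = False
                        break
                g = gm.get(ind.id, locus.id)
                if g is not None and tuple(sorted((ap, am))) != g:
                    ok = False
                    break
            if ok:
                total += w
    return math.log(total)
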