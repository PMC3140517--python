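"""Parametric LOD-score linkage analysis on pedigrees.

Two exact engines are provided and cross-validated against each other:

* :func:`single_locus_likelihood` — the classic pedigree likelihood for one
  marker jointly with the disease locus at recombination fraction theta.
  It is computed by sum-product variable elimination over per-individual
  *haplotype* variables (paternal and maternal (disease allele, marker
  allele) pairs). Eliminating haplotypes rather than whole genotypes keeps
  every factor at most (2k)^3 for a k-allele marker, and the elimination
  view generalizes pedigree peeling to looped (consanguineous) pedigrees
  without explicit loop breakers.

* :class:`MultipointEngine` — the inheritance-vector hidden Markov model.
  The hidden state at each locus is the inheritance vector: one bit per
  non-founder meiosis recording which grandparental allele was transmitted.
  Between adjacent loci each bit flips independently with the Haldane
  recombination fraction of the intervening distance (no interference), so
  the transition operator factorizes per bit and is applied in
  O(bits · 2^bits). Marker emissions sum founder-allele assignments
  consistent with the observed genotypes; the disease emission applies
  penetrance to affected members only (phenotype-unknown members contribute
  a factor of 1 — affected-only analysis).

At a queried position x the LOD is

    LOD(x) = log10 [ sum_v P(v_x = v | markers) P(aff | v)
                     / ( 2^-B sum_v P(aff | v) ) ]

summed over families. The full 2^B state space is used up to a configurable
bit cap (default 16); larger sibships should be split.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .types import (DiseaseModel, GenotypeMatrix, Locus, LodResult,
                    MarkerMap, Pedigree, RecombinationFraction)

__all__ = [
    "haldane_theta", "single_locus_likelihood", "twopoint_lod",
    "TwoPointResult", "multipoint_lod", "MultipointEngine", "FamilyHMM",
    "BitCapError", "reconstruct_haplotypes", "HaplotypeReconstruction",
    "sensitivity_analysis",
]


def haldane_theta(d_cM: float) -> RecombinationFraction:
    """Haldane map function: theta = (1 - exp(-2d/100))/2, d in cM."""
    if d_cM < 0:
        raise ValueError(f"map distance must be >= 0, got {d_cM}")
    return RecombinationFraction(0.5 * (1.0 - math.exp(-0.02 * d_cM)))


def _theta(d_cM: float) -> float:
    return haldane_theta(d_cM).theta


class BitCapError(ValueError):
    """Pedigree exceeds the inheritance-vector bit cap."""


# ---------------------------------------------------------------------------
# Inheritance-vector HMM per family
# ---------------------------------------------------------------------------

class FamilyHMM:
    """Inheritance-vector machinery for one pedigree.

    Bit 2j is the paternal, bit 2j+1 the maternal meiosis of the j-th
    non-founder (in topological order); bit value 0 transmits the parent's
    own paternal (grandpaternal) allele, 1 the maternal one. Founder f owns
    allele slots 2f and 2f+1.
    """

    def __init__(self, ped: Pedigree, bit_cap: int = 16) -> None:
        self.ped = ped
        order = ped.topological_order()
        self.individuals = [ind.id for ind in order]
        self._idx = {iid: i for i, iid in enumerate(self.individuals)}
        founders = [ind for ind in order if ind.is_founder]
        nonfounders = [ind for ind in order if not ind.is_founder]
        self.n_founders = len(founders)
        self.n_slots = 2 * self.n_founders
        self.B = 2 * len(nonfounders)
        if self.B > bit_cap:
            raise BitCapError(
                f"family {ped.family_id}: {self.B} meiosis bits exceed the "
                f"cap of {bit_cap}; split the pedigree or raise bit_cap")
        self.n_states = 1 << self.B
        self.bit_names: list[tuple[str, str]] = []
        for nf in nonfounders:
            self.bit_names.append((nf.id, "pat"))
            self.bit_names.append((nf.id, "mat"))

        states = np.arange(self.n_states, dtype=np.int64)
        bits = ((states[:, None] >> np.arange(self.B)[None, :]) & 1
                ).astype(np.int8)
        n_ind = len(order)
        self.S_pat = np.empty((self.n_states, n_ind), dtype=np.int16)
        self.S_mat = np.empty((self.n_states, n_ind), dtype=np.int16)
        founder_slot = {ind.id: 2 * j for j, ind in enumerate(founders)}
        bit_of = {}
        for j, nf in enumerate(nonfounders):
            bit_of[(nf.id, "pat")] = 2 * j
            bit_of[(nf.id, "mat")] = 2 * j + 1
        for i, ind in enumerate(order):
            if ind.is_founder:
                self.S_pat[:, i] = founder_slot[ind.id]
                self.S_mat[:, i] = founder_slot[ind.id] + 1
            else:
                fi = self._idx[ind.father_id]
                mi = self._idx[ind.mother_id]
                bp = bits[:, bit_of[(ind.id, "pat")]]
                bm = bits[:, bit_of[(ind.id, "mat")]]
                self.S_pat[:, i] = np.where(bp == 0, self.S_pat[:, fi],
                                            self.S_mat[:, fi])
                self.S_mat[:, i] = np.where(bm == 0, self.S_pat[:, mi],
                                            self.S_mat[:, mi])

    # -- emissions ---------------------------------------------------------

    def marker_emission(self, genotypes: dict[str, tuple[int, int] | None],
                        allele_freqs: tuple[float, ...]) -> np.ndarray:
        """P(observed genotypes at one locus | inheritance vector), for
        every state. Sums founder-allele assignments consistent with the
        descent pattern; untyped founders marginalize to 1."""
        typed = [i for i, iid in enumerate(self.individuals)
                 if genotypes.get(iid) is not None]
        if not typed:
            return np.ones(self.n_states)
        genos = [genotypes[self.individuals[i]] for i in typed]
        sig = np.concatenate([self.S_pat[:, typed], self.S_mat[:, typed]],
                             axis=1)
        uniq, inv = np.unique(sig, axis=0, return_inverse=True)
        t = len(typed)
        probs = np.array([
            self._descent_prob(row[:t], row[t:], genos, allele_freqs)
            for row in uniq])
        return probs[inv]

    @staticmethod
    def _descent_prob(pat_slots, mat_slots, genos, freqs) -> float:
        """Sum over founder-allele assignments consistent with the typed
        genotypes under one descent pattern (backtracking with pruning)."""
        assign: dict[int, int] = {}

        def rec(i: int) -> float:
            if i == len(genos):
                return 1.0
            s1, s2 = int(pat_slots[i]), int(mat_slots[i])
            a, b = genos[i]
            total = 0.0
            for x, y in ((a, b),) if a == b else ((a, b), (b, a)):
                undo = []
                ok, w = True, 1.0
                for s, al in ((s1, x), (s2, y)):
                    cur = assign.get(s)
                    if cur is None:
                        assign[s] = al
                        undo.append(s)
                        w *= freqs[al - 1]
                    elif cur != al:
                        ok = False
                        break
                if ok:
                    total += w * rec(i + 1)
                for s in undo:
                    del assign[s]
            return total

        return rec(0)

    def forced_alleles(self, state: int,
                       genotypes: dict[str, tuple[int, int] | None],
                       ) -> dict[str, tuple[int | None, int | None]]:
        """Per-individual (paternal, maternal) alleles forced by one
        inheritance vector: an allele is reported only when it is identical
        across every founder-assignment consistent with the genotypes."""
        typed = [i for i, iid in enumerate(self.individuals)
                 if genotypes.get(iid) is not None]
        solutions: list[dict[int, int]] = []
        genos = [genotypes[self.individuals[i]] for i in typed]
        pat = self.S_pat[state]
        mat = self.S_mat[state]
        assign: dict[int, int] = {}

        def rec(i: int) -> None:
            if i == len(genos):
                solutions.append(dict(assign))
                return
            s1, s2 = int(pat[typed[i]]), int(mat[typed[i]])
            a, b = genos[i]
            for x, y in ((a, b),) if a == b else ((a, b), (b, a)):
                undo = []
                ok = True
                for s, al in ((s1, x), (s2, y)):
                    cur = assign.get(s)
                    if cur is None:
                        assign[s] = al
                        undo.append(s)
                    elif cur != al:
                        ok = False
                        break
                if ok:
                    rec(i + 1)
                for s in undo:
                    del assign[s]

        rec(0)
        slot_value: dict[int, int | None] = {}
        for sol in solutions:
            for s, al in sol.items():
                if s not in slot_value:
                    slot_value[s] = al
                elif slot_value[s] != al:
                    slot_value[s] = None
        # a slot missing from some solution is unconstrained there -> unforced
        for s in list(slot_value):
            if any(s not in sol for sol in solutions):
                slot_value[s] = None
        out: dict[str, tuple[int | None, int | None]] = {}
        for i, iid in enumerate(self.individuals):
            out[iid] = (slot_value.get(int(pat[i])),
                        slot_value.get(int(mat[i])))
        return out

    def disease_emission(self, model: DiseaseModel,
                         affected_ids: list[str] | None = None,
                         ) -> np.ndarray:
        """P(affection pattern | inheritance vector) under the disease
        model, marginalized over founder disease alleles. Only affected
        members contribute penetrance factors (affected-only analysis)."""
        if affected_ids is None:
            affected_ids = self.ped.affected_ids()
        aff = [self._idx[iid] for iid in affected_ids]
        if not aff:
            return np.ones(self.n_states)
        ns = self.n_slots
        cfg = ((np.arange(1 << ns)[:, None] >> np.arange(ns)[None, :]) & 1
               ).astype(np.int8)
        p = model.disease_allele_freq
        prior = np.prod(np.where(cfg == 1, p, 1.0 - p), axis=1)
        pen = np.array([model.phenocopy, model.penetrance_het,
                        model.penetrance_hom])
        out = np.empty(self.n_states)
        chunk = max(1, (1 << 22) // (1 << ns))
        for lo in range(0, self.n_states, chunk):
            sl = slice(lo, min(lo + chunk, self.n_states))
            acc = np.ones((cfg.shape[0], sl.stop - sl.start))
            for i in aff:
                carriers = (cfg[:, self.S_pat[sl, i]]
                            + cfg[:, self.S_mat[sl, i]])
                acc *= pen[carriers]
            out[sl] = prior @ acc
        return out

    # -- transitions -------------------------------------------------------

    def mix(self, f: np.ndarray, theta: float) -> np.ndarray:
        """Apply the inter-locus transition operator: each meiosis bit flips
        independently with probability theta. Symmetric, so it serves both
        forward and backward passes."""
        if theta <= 0.0:
            return f.copy()
        v = f.copy()
        for b in range(self.B):
            w = v.reshape(-1, 2, 1 << b)
            v = ((1.0 - theta) * w + theta * w[:, ::-1, :]).reshape(-1)
        return v

    def mix_max(self, f: np.ndarray, theta: float
                ) -> tuple[np.ndarray, np.ndarray]:
        """Max-product analogue of :meth:`mix`, with argmax predecessors."""
        val = f.copy()
        idx = np.arange(self.n_states)
        if theta <= 0.0:
            return val, idx
        for b in range(self.B):
            shape = (-1, 2, 1 << b)
            w = val.reshape(shape)
            wi = idx.reshape(shape)
            stay = (1.0 - theta) * w
            move = theta * w[:, ::-1, :]
            take_stay = stay >= move
            val = np.where(take_stay, stay, move).reshape(-1)
            idx = np.where(take_stay, wi, wi[:, ::-1, :]).reshape(-1)
        return val, idx


# ---------------------------------------------------------------------------
# Forward-backward chain for one family on one chromosome
# ---------------------------------------------------------------------------

class _Chain:
    """Scaled forward-backward quantities for one family on one chromosome."""

    def __init__(self, hmm: FamilyHMM, loci: list[Locus],
                 gm: GenotypeMatrix) -> None:
        self.hmm = hmm
        self.loci = loci
        self.positions = [loc.position_cM for loc in loci]
        self.E = []
        for loc in loci:
            genos = {iid: gm.get(iid, loc.id) for iid in hmm.individuals}
            e = hmm.marker_emission(genos, loc.allele_freqs)
            if e.max() <= 0.0:
                raise ValueError(
                    f"family {hmm.ped.family_id}, locus {loc.id}: observed "
                    "genotypes are impossible on this pedigree "
                    "(run mendelian_check)")
            self.E.append(e)
        n = hmm.n_states
        L = len(loci)
        self.alpha = np.empty((L, n))
        self.beta = np.empty((L, n))
        a = self.E[0] / n
        self.alpha[0] = a / a.sum()
        for l in range(1, L):
            th = _theta(self.positions[l] - self.positions[l - 1])
            a = hmm.mix(self.alpha[l - 1], th) * self.E[l]
            self.alpha[l] = a / a.sum()
        b = np.ones(n)
        self.beta[L - 1] = b
        for l in range(L - 2, -1, -1):
            th = _theta(self.positions[l + 1] - self.positions[l])
            b = hmm.mix(self.beta[l + 1] * self.E[l + 1], th)
            self.beta[l] = b / b.sum()

    def posterior_at(self, cM: float) -> np.ndarray:
        """P(inheritance vector at map position cM | all markers)."""
        hmm, pos = self.hmm, self.positions
        if cM <= pos[0]:
            g = hmm.mix(self.E[0] * self.beta[0], _theta(pos[0] - cM))
        elif cM >= pos[-1]:
            g = hmm.mix(self.alpha[-1], _theta(cM - pos[-1]))
        else:
            r = next(i for i, p in enumerate(pos) if p >= cM)
            if pos[r] == cM:
                g = self.alpha[r] * self.beta[r]
            else:
                l = r - 1
                left = hmm.mix(self.alpha[l], _theta(cM - pos[l]))
                right = hmm.mix(self.E[r] * self.beta[r],
                                _theta(pos[r] - cM))
                g = left * right
        s = g.sum()
        if s <= 0:
            raise ValueError("degenerate posterior (zero likelihood)")
        return g / s

    def viterbi(self) -> np.ndarray:
        """Most probable inheritance-vector path (ties to the lowest-index
        vector via first-argmax and prefer-stay tie-breaks)."""
        hmm = self.hmm
        L = len(self.loci)
        n = hmm.n_states
        delta = self.E[0] / n
        back = np.empty((L, n), dtype=np.int64)
        back[0] = np.arange(n)
        for l in range(1, L):
            th = _theta(self.positions[l] - self.positions[l - 1])
            val, idx = hmm.mix_max(delta, th)
            delta = val * self.E[l]
            m = delta.max()
            if m > 0:
                delta = delta / m
            back[l] = idx
        path = np.empty(L, dtype=np.int64)
        path[L - 1] = int(np.argmax(delta))
        for l in range(L - 2, -1, -1):
            path[l] = back[l + 1][path[l + 1]]
        return path


# ---------------------------------------------------------------------------
# Single-locus likelihood by variable elimination (pedigree peeling)
# ---------------------------------------------------------------------------

@dataclass
class _Factor:
    vars: tuple
    table: np.ndarray  # one axis per variable, in `vars` order


def _multiply_sum_out(factors: list[_Factor], var) -> _Factor:
    all_vars: list = []
    for f in factors:
        for v in f.vars:
            if v not in all_vars:
                all_vars.append(v)
    shape = {}
    for f in factors:
        for v, s in zip(f.vars, f.table.shape):
            shape[v] = s
    acc = np.ones([shape[v] for v in all_vars])
    for f in factors:
        ax = [all_vars.index(v) for v in f.vars]
        expand = f.table
        # move factor axes into position, broadcasting over the rest
        full = np.ones_like(acc)
        idx = [None] * len(all_vars)
        t = f.table
        order = sorted(range(len(f.vars)), key=lambda i: ax[i])
        t = np.transpose(t, order)
        slicer = [np.newaxis] * len(all_vars)
        for i in sorted(ax):
            slicer[i] = slice(None)
        acc = acc * t[tuple(slicer)]
    k = all_vars.index(var)
    summed = acc.sum(axis=k)
    all_vars.pop(k)
    return _Factor(tuple(all_vars), summed)


def _eliminate_all(factors: list[_Factor]) -> float:
    factors = list(factors)
    while True:
        vars_left: list = []
        for f in factors:
            for v in f.vars:
                if v not in vars_left:
                    vars_left.append(v)
        if not vars_left:
            break
        # greedy: eliminate the variable whose product factor is smallest
        def cost(v):
            dims = {}
            for f in factors:
                if v in f.vars:
                    for u, s in zip(f.vars, f.table.shape):
                        dims[u] = s
            size = 1
            for s in dims.values():
                size *= s
            return size
        v = min(vars_left, key=cost)
        involved = [f for f in factors if v in f.vars]
        rest = [f for f in factors if v not in f.vars]
        factors = rest + [_multiply_sum_out(involved, v)]
    result = 1.0
    for f in factors:
        result *= float(f.table)
    return result


def single_locus_likelihood(ped: Pedigree, gm: GenotypeMatrix, locus: Locus,
                            model: DiseaseModel, theta: float) -> float:
    """Natural-log likelihood of one family's marker genotypes and
    affection pattern, with the disease locus at recombination fraction
    ``theta`` from the marker.

    Exact sum over all joint disease-marker haplotype configurations by
    variable elimination; penetrance applies to affected members only.
    Handles looped pedigrees (elimination cost grows with loop complexity).
    """
    if not 0.0 <= theta <= 0.5:
        raise ValueError("theta must lie in [0, 0.5]")
    k = locus.n_alleles
    nh = 2 * k  # haplotype = disease allele (0/1) * k + marker allele index
    freqs = np.asarray(locus.allele_freqs)
    p = model.disease_allele_freq
    hap_prior = np.empty(nh)
    for d in (0, 1):
        hap_prior[d * k:(d + 1) * k] = (p if d else 1 - p) * freqs

    # transmission tensor T[child_hap, par_pat_hap, par_mat_hap]
    T = np.zeros((nh, nh, nh))
    d_of = np.repeat(np.arange(2), k)
    a_of = np.tile(np.arange(k), 2)
    hp = np.arange(nh)
    for gd in (0, 1):          # grand-origin of the disease allele
        for ga in (0, 1):      # grand-origin of the marker allele
            w = (1.0 - theta) / 2.0 if gd == ga else theta / 2.0
            for h_p in range(nh):
                for h_m in range(nh):
                    d_c = d_of[h_p] if gd == 0 else d_of[h_m]
                    a_c = a_of[h_p] if ga == 0 else a_of[h_m]
                    T[d_c * k + a_c, h_p, h_m] += w

    pen = np.array([model.phenocopy, model.penetrance_het,
                    model.penetrance_hom])
    factors: list[_Factor] = []
    for ind in ped.members.values():
        vp, vm = ("p", ind.id), ("m", ind.id)
        if ind.is_founder:
            factors.append(_Factor((vp,), hap_prior.copy()))
            factors.append(_Factor((vm,), hap_prior.copy()))
        else:
            factors.append(_Factor(
                (vp, ("p", ind.father_id), ("m", ind.father_id)), T))
            factors.append(_Factor(
                (vm, ("p", ind.mother_id), ("m", ind.mother_id)), T))
        if ind.affection == "affected":
            tab = pen[d_of[:, None] + d_of[None, :]]
            factors.append(_Factor((vp, vm), tab))
        g = gm.get(ind.id, locus.id)
        if g is not None:
            a, b = g[0] - 1, g[1] - 1
            obs = np.zeros((nh, nh))
            ap = a_of[:, None]
            am = a_of[None, :]
            obs[((ap == a) & (am == b)) | ((ap == b) & (am == a))] = 1.0
            factors.append(_Factor((vp, vm), obs))
    like = _eliminate_all(factors)
    if like <= 0.0:
        raise ValueError(
            f"family {ped.family_id}: zero likelihood at locus {locus.id} "
            "(Mendelian inconsistency?)")
    return math.log(like)


@dataclass(frozen=True)
class TwoPointResult:
    theta: float
    lod: float
    per_family_lods: dict[str, float]


def twopoint_lod(peds: list[Pedigree], gm: GenotypeMatrix, locus: Locus,
                 model: DiseaseModel,
                 theta_grid: list[float]) -> list[TwoPointResult]:
    """Two-point LOD(theta) = sum over families of
    log10 L(theta) - log10 L(1/2)."""
    base = {p.family_id: single_locus_likelihood(p, gm, locus, model, 0.5)
            for p in peds}
    out = []
    for th in theta_grid:
        per = {}
        for p in peds:
            ll = single_locus_likelihood(p, gm, locus, model, th)
            per[p.family_id] = (ll - base[p.family_id]) / math.log(10.0)
        out.append(TwoPointResult(th, sum(per.values()), per))
    return out


# ---------------------------------------------------------------------------
# Multipoint engine
# ---------------------------------------------------------------------------

class MultipointEngine:
    """Precomputes per-family, per-chromosome forward-backward quantities
    once, so repeated LOD scans under different disease models (e.g. the
    allele-frequency sensitivity sweep) reuse the marker posteriors."""

    def __init__(self, peds: list[Pedigree], gm: GenotypeMatrix,
                 marker_map: MarkerMap, bit_cap: int = 16) -> None:
        self.peds = list(peds)
        self.marker_map = marker_map
        self.hmms = {p.family_id: FamilyHMM(p, bit_cap) for p in self.peds}
        self.chains: dict[tuple[str, str], _Chain] = {}
        for chrom in marker_map.chromosomes:
            loci = marker_map.chromosome_loci(chrom)
            for p in self.peds:
                self.chains[(p.family_id, chrom)] = _Chain(
                    self.hmms[p.family_id], loci, gm)
        self._post_cache: dict[tuple[str, str, float], np.ndarray] = {}

    def default_positions(self, grid_cM: float | None = None
                          ) -> list[tuple[str, float]]:
        """Marker positions, optionally augmented with a uniform grid."""
        out: list[tuple[str, float]] = []
        for chrom in self.marker_map.chromosomes:
            loci = self.marker_map.chromosome_loci(chrom)
            pos = sorted({loc.position_cM for loc in loci})
            if grid_cM:
                lo, hi = pos[0], pos[-1]
                g = lo
                extra = []
                while g <= hi + 1e-9:
                    extra.append(round(g, 6))
                    g += grid_cM
                pos = sorted(set(pos) | set(extra))
            out.extend((chrom, p) for p in pos)
        return out

    def _posterior(self, fid: str, chrom: str, cM: float) -> np.ndarray:
        key = (fid, chrom, cM)
        if key not in self._post_cache:
            self._post_cache[key] = self.chains[(fid, chrom)].posterior_at(cM)
        return self._post_cache[key]

    def lod(self, model: DiseaseModel,
            positions: list[tuple[str, float]] | None = None,
            grid_cM: float | None = None) -> list[LodResult]:
        if positions is None:
            positions = self.default_positions(grid_cM)
        dis = {p.family_id: self.hmms[p.family_id].disease_emission(model)
               for p in self.peds}
        results = []
        for chrom, cM in positions:
            per: dict[str, float] = {}
            for p in self.peds:
                D = dis[p.family_id]
                den = D.mean()
                if den <= 0.0:
                    per[p.family_id] = 0.0
                    continue
                gamma = self._posterior(p.family_id, chrom, cM)
                num = float(gamma @ D)
                per[p.family_id] = math.log10(num / den) if num > 0 else -math.inf
            results.append(LodResult((chrom, cM), sum(per.values()), per))
        return results


def multipoint_lod(peds: list[Pedigree], gm: GenotypeMatrix,
                   marker_map: MarkerMap, model: DiseaseModel,
                   positions: list[tuple[str, float]] | None = None,
                   grid_cM: float | None = None,
                   bit_cap: int = 16) -> list[LodResult]:
    """Multipoint parametric LOD scores at the requested map positions
    (default: all marker positions, optionally plus a uniform grid)."""
    eng = MultipointEngine(peds, gm, marker_map, bit_cap=bit_cap)
    return eng.lod(model, positions, grid_cM)


def max_lod(results: list[LodResult]) -> LodResult:
    """The maximum-LOD result; ties broken to the leftmost position."""
    best = results[0]
    for r in results[1:]:
        if r.lod > best.lod + 1e-12:
            best = r
    return best


# ---------------------------------------------------------------------------
# Haplotype reconstruction
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeReconstruction:
    """Viterbi-phased haplotypes for one family on one chromosome.

    haplotypes[iid][l] is the (paternal, maternal) allele pair at locus l;
    an entry is None when the chosen inheritance path does not force it.
    bit_posteriors[l, b] = P(meiosis bit b flipped | markers); a meiosis is
    ``resolved`` at a locus when its posterior is farther than
    ``resolve_threshold`` from 1/2.
    """

    loci: list[str]
    haplotypes: dict[str, list[tuple[int | None, int | None]]]
    inheritance_path: np.ndarray
    bit_names: list[tuple[str, str]]
    bit_posteriors: np.ndarray
    resolve_threshold: float = 0.95

    def resolved(self, locus_index: int, bit: int) -> bool:
        p = self.bit_posteriors[locus_index, bit]
        return max(p, 1.0 - p) >= self.resolve_threshold


def reconstruct_haplotypes(ped: Pedigree, gm: GenotypeMatrix,
                           marker_map: MarkerMap, chromosome: str,
                           bit_cap: int = 16) -> HaplotypeReconstruction:
    """Phase one family along one chromosome by the maximum-probability
    inheritance-vector path (Viterbi over the multipoint HMM). Alleles are
    imputed only where the chosen path forces them; uninformative meioses
    stay unresolved rather than being guessed."""
    hmm = FamilyHMM(ped, bit_cap)
    loci = marker_map.chromosome_loci(chromosome)
    chain = _Chain(hmm, loci, gm)
    path = chain.viterbi()
    haplotypes: dict[str, list[tuple[int | None, int | None]]] = {
        iid: [] for iid in hmm.individuals}
    bit_post = np.empty((len(loci), hmm.B))
    bits = ((np.arange(hmm.n_states)[:, None]
             >> np.arange(hmm.B)[None, :]) & 1)
    for l, loc in enumerate(loci):
        genos = {iid: gm.get(iid, loc.id) for iid in hmm.individuals}
        forced = hmm.forced_alleles(int(path[l]), genos)
        for iid in hmm.individuals:
            haplotypes[iid].append(forced[iid])
        gamma = chain.posterior_at(loc.position_cM)
        bit_post[l] = gamma @ bits
    return HaplotypeReconstruction([loc.id for loc in loci], haplotypes,
                                   path, hmm.bit_names, bit_post)


# ---------------------------------------------------------------------------
# Sensitivity analysis
# ---------------------------------------------------------------------------

def sensitivity_analysis(peds: list[Pedigree], gm: GenotypeMatrix,
                         marker_map: MarkerMap, model: DiseaseModel,
                         freq_list: list[float],
                         positions: list[tuple[str, float]] | None = None,
                         grid_cM: float | None = None,
                         bit_cap: int = 16) -> list[dict]:
    """Max LOD as a function of the assumed disease allele frequency.

    One scan per frequency; marker posteriors are computed once and reused.
    Returns rows with the frequency, max LOD, its position, and the
    relative change versus the baseline model's own frequency.
    """
    eng = MultipointEngine(peds, gm, marker_map, bit_cap=bit_cap)
    if positions is None:
        positions = eng.default_positions(grid_cM)
    base = max_lod(eng.lod(model, positions))
    rows = []
    for f in freq_list:
        m = DiseaseModel(disease_allele_freq=f, phenocopy=model.phenocopy,
                         penetrance_het=model.penetrance_het,
                         penetrance_hom=model.penetrance_hom)
        best = max_lod(eng.lod(m, positions))
        rel = (abs(best.lod - base.lod) / abs(base.lod)
               if base.lod != 0 else 0.0)
        rows.append({"disease_allele_freq": f, "max_lod": best.lod,
                     "position": best.position,
                     "relative_change": rel,
                     "baseline_max_lod": base.lod})
    return rows
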