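"""Case-control association under standard genetic models.

Given genotype counts (DD / Dd / dd in cases and controls, D the minor or
risk allele) this module computes, per stratum and pooled:

* odds ratios with Woolf confidence intervals
  (``exp(ln OR ± 1.96·sqrt(1/a + 1/b + 1/c + 1/d))``),
* Pearson chi-square tests with the tail p-value computed in log space, so
  ``-log10 p`` stays accurate far beyond float underflow (association
  studies of near-monogenic variants routinely reach p ~ 1e-120),
* Hardy-Weinberg goodness-of-fit p-values, minor allele frequencies,
* the Cochran-Armitage trend test and a logistic per-allele odds ratio for
  the additive model,
* population-attributable risk, and the power to detect a rare variant in a
  control chromosome panel.

Zero-cell odds ratios fall back to the Haldane-Anscombe +0.5 correction and
are flagged ``corrected``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special, stats

from .types import (AssociationResult, GenotypeCountTable, ParInput,
                    TwoByTwo)

LN10 = math.log(10.0)

__all__ = [
    "collapse", "odds_ratio", "chi2_2x2", "neglog10_sf_chi2_1df", "hwe_chi2",
    "maf", "armitage_trend", "logistic_additive_or", "par",
    "power_rare_variant", "analyze_stratum", "association_report",
    "LogisticFit",
]


def collapse(counts: GenotypeCountTable, model: str) -> TwoByTwo:
    """Collapse genotype counts to the 2x2 table of a genetic model.

    allelic   : allele counts, (2·DD + Dd) vs (Dd + 2·dd)
    dominant  : carriers (DD + Dd) vs dd
    recessive : DD vs (Dd + dd)

    The additive model is not a 2x2 collapse; use :func:`armitage_trend` or
    :func:`logistic_additive_or`.
    """
    if model == "allelic":
        return TwoByTwo(2 * counts.case_DD + counts.case_Dd,
                        counts.case_Dd + 2 * counts.case_dd,
                        2 * counts.control_DD + counts.control_Dd,
                        counts.control_Dd + 2 * counts.control_dd)
    if model == "dominant":
        return TwoByTwo(counts.case_DD + counts.case_Dd, counts.case_dd,
                        counts.control_DD + counts.control_Dd,
                        counts.control_dd)
    if model == "recessive":
        return TwoByTwo(counts.case_DD, counts.case_Dd + counts.case_dd,
                        counts.control_DD,
                        counts.control_Dd + counts.control_dd)
    if model == "additive":
        raise ValueError(
            "additive model has no 2x2 collapse; use armitage_trend or "
            "logistic_additive_or")
    raise ValueError(f"unknown model {model!r}")


def odds_ratio(t: TwoByTwo) -> tuple[float, float, float, bool]:
    """OR = ad/(bc) with the 95% Woolf interval.

    Returns ``(or, ci_low, ci_high, corrected)``; with any zero cell the
    Haldane-Anscombe +0.5 correction is applied to all four cells and
    ``corrected`` is True.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    orr = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    half = 1.959963984540054 * se
    return (orr, orr * math.exp(-half), orr * math.exp(half), corrected)


def neglog10_sf_chi2_1df(x: float) -> float:
    """-log10 of the upper tail of chi-square with 1 df, in log space.

    Uses ``sf(x) = erfc(sqrt(x/2)) = erfcx(z)·exp(-z²)`` with z = sqrt(x/2);
    ``erfcx`` is the scaled complementary error function, stable for large z,
    so the result is exact to ~1e-10 relative even when p underflows.
    """
    if x <= 0:
        return 0.0
    z = math.sqrt(x / 2.0)
    return -(math.log(special.erfcx(z)) - z * z) / LN10


def chi2_2x2(t: TwoByTwo) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) and -log10 p.

    Degenerate margins (an empty row or column) give (0, 0).
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    n = t.n
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if n == 0 or 0 in (r1, r2, c1, c2):
        return (0.0, 0.0)
    x = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return (x, neglog10_sf_chi2_1df(x))


def hwe_chi2(n_DD: int, n_Dd: int, n_dd: int) -> float:
    """Hardy-Weinberg goodness-of-fit p (Pearson, 1 df, no correction).

    Monomorphic samples return p = 1 (nothing to test).
    """
    n = n_DD + n_Dd + n_dd
    if n == 0:
        raise ValueError("empty sample")
    p = (2 * n_DD + n_Dd) / (2 * n)
    if p == 0.0 or p == 1.0:
        return 1.0
    exp = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) ** 2])
    obs = np.array([n_DD, n_Dd, n_dd], dtype=float)
    x = float(((obs - exp) ** 2 / exp).sum())
    return float(stats.chi2.sf(x, 1))


def maf(n_DD: int, n_Dd: int, n_dd: int) -> float:
    """Frequency of the D allele, (2·DD + Dd)/(2·N).

    The caller is responsible for D actually being the minor allele; a
    result above 0.5 is returned as computed.
    """
    n = n_DD + n_Dd + n_dd
    if n == 0:
        raise ValueError("empty sample")
    return (2 * n_DD + n_Dd) / (2 * n)


def armitage_trend(counts: GenotypeCountTable) -> tuple[float, float]:
    """Cochran-Armitage trend chi-square with scores (0, 1, 2) on
    (dd, Dd, DD), and its -log10 p (1 df)."""
    cases = np.array([counts.case_dd, counts.case_Dd, counts.case_DD],
                     dtype=float)
    ctrls = np.array([counts.control_dd, counts.control_Dd,
                      counts.control_DD], dtype=float)
    scores = np.array([0.0, 1.0, 2.0])
    tot = cases + ctrls
    n = tot.sum()
    r = cases.sum()
    if n == 0 or r == 0 or r == n or tot @ scores == 0:
        return (0.0, 0.0)
    # T = sum s_i (case_i * n_ctrl - ctrl_i * n_case); var under H0
    s = ctrls.sum()
    T = float(scores @ (cases * s - ctrls * r))
    var = (r * s / n) * float(
        n * (scores ** 2 @ tot) - (scores @ tot) ** 2)
    if var == 0:
        return (0.0, 0.0)
    x = T * T / var
    return (x, neglog10_sf_chi2_1df(x))


@dataclass(frozen=True)
class LogisticFit:
    or_per_allele: float
    ci_low: float
    ci_high: float
    corrected: bool
    n_iter: int


def logistic_additive_or(counts: GenotypeCountTable,
                         max_iter: int = 100,
                         tol: float = 1e-10) -> LogisticFit:
    """Per-allele odds ratio by maximum-likelihood logistic regression of
    case status on risk-allele dose (0/1/2), with the Wald 95% CI.

    Newton-Raphson on the aggregated 3x2 table; iterated until the gradient
    norm falls below ``tol``. Complete separation (a dose level observed in
    only one phenotype at the table edge making the MLE infinite) is
    detected by divergence of the slope; the fit is then redone with +0.5
    added to every cell and flagged ``corrected``.
    """
    dose = np.array([0.0, 1.0, 2.0])
    cases = np.array([counts.case_dd, counts.case_Dd, counts.case_DD],
                     dtype=float)
    ctrls = np.array([counts.control_dd, counts.control_Dd,
                      counts.control_DD], dtype=float)

    def loglik(beta, y1, ntot, X):
        eta = X @ beta
        # log(1+e^eta) computed stably
        return float(y1 @ eta - ntot @ np.logaddexp(0.0, eta))

    def newton(y1: np.ndarray, y0: np.ndarray):
        ntot = y1 + y0
        beta = np.zeros(2)  # intercept, slope
        X = np.column_stack([np.ones(3), dose])
        for it in range(1, max_iter + 1):
            eta = X @ beta
            mu = 1.0 / (1.0 + np.exp(-eta))
            grad = X.T @ (y1 - ntot * mu)
            W = ntot * mu * (1 - mu)
            H = X.T @ (X * W[:, None])
            if np.linalg.norm(grad) < tol:
                # a "converged" fit at an absurd slope is separation whose
                # gradient underflowed before the divergence guard fired
                if abs(beta[1]) > 15:
                    return beta, None, it, True
                return beta, np.linalg.inv(H), it, False
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                return beta, None, it, True
            # damped update: halve the step until the likelihood improves
            base = loglik(beta, y1, ntot, X)
            scale = 1.0
            for _ in range(40):
                cand = beta + scale * step
                if loglik(cand, y1, ntot, X) >= base - 1e-12:
                    break
                scale *= 0.5
            beta = beta + scale * step
            if abs(beta[1]) > 30:  # OR beyond e^30: separated
                return beta, None, it, True
        # no convergence within max_iter: treat as separation
        return beta, None, max_iter, True

    beta, cov, n_iter, separated = newton(cases, ctrls)
    corrected = False
    if separated or cov is None:
        corrected = True
        beta, cov, n_iter, separated = newton(cases + 0.5, ctrls + 0.5)
        if separated or cov is None:
            raise RuntimeError("logistic fit failed even after +0.5 correction")
    se = math.sqrt(cov[1, 1])
    orr = math.exp(beta[1])
    half = 1.959963984540054 * se
    return LogisticFit(orr, orr * math.exp(-half), orr * math.exp(half),
                       corrected, n_iter)


def par(inp: ParInput) -> float:
    """Population-attributable risk, percent: 100·(K − y)/K with K the case
    count and y the cases not carrying the risk allele."""
    if inp.K == 0:
        raise ValueError("K must be positive")
    return 100.0 * (inp.K - inp.y) / inp.K


def power_rare_variant(n_chromosomes: int, maf: float) -> float:
    """Probability of observing >= 1 copy of an allele of frequency ``maf``
    among ``n_chromosomes`` sampled chromosomes: 1 − (1 − maf)^n."""
    if n_chromosomes < 1:
        raise ValueError("need at least one chromosome")
    if not 0.0 <= maf <= 1.0:
        raise ValueError("maf must lie in [0, 1]")
    return 1.0 - (1.0 - maf) ** n_chromosomes


def analyze_stratum(counts: GenotypeCountTable,
                    model: str) -> AssociationResult:
    """Full association result for one stratum under one model."""
    maf_ca = maf(counts.case_DD, counts.case_Dd, counts.case_dd)
    maf_co = maf(counts.control_DD, counts.control_Dd, counts.control_dd)
    hwe_ca = hwe_chi2(counts.case_DD, counts.case_Dd, counts.case_dd)
    hwe_co = hwe_chi2(counts.control_DD, counts.control_Dd, counts.control_dd)
    if model == "additive":
        x, nlp = armitage_trend(counts)
        fit = logistic_additive_or(counts)
        return AssociationResult(model, fit.or_per_allele, fit.ci_low,
                                 fit.ci_high, x, nlp, maf_ca, maf_co,
                                 hwe_ca, hwe_co, corrected=fit.corrected)
    t = collapse(counts, model)
    orr, lo, hi, corrected = odds_ratio(t)
    x, nlp = chi2_2x2(t)
    return AssociationResult(model, orr, lo, hi, x, nlp, maf_ca, maf_co,
                             hwe_ca, hwe_co, corrected=corrected)


def association_report(tables: list[GenotypeCountTable],
                       models: tuple[str, ...] = ("allelic", "additive",
                                                  "dominant", "recessive"),
                       ) -> dict[str, dict[str, AssociationResult]]:
    """Per-stratum results plus a pooled ``Total`` stratum (sum of counts),
    for each requested model.

    Returns ``{stratum: {model: AssociationResult}}`` in input order, the
    Total last (only added when more than one stratum is given).
    """
    tables = list(tables)
    if not tables:
        raise ValueError("no count tables given")
    if len(tables) > 1:
        total = tables[0]
        for t in tables[1:]:
            total = total.pooled_with(t)
        tables = tables + [total]
    out: dict[str, dict[str, AssociationResult]] = {}
    for t in tables:
        out[t.stratum] = {m: analyze_stratum(t, m) for m in models}
    return out
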