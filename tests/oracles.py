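"""Independent brute-force oracles used to validate the package's statistics.

Every oracle here deliberately avoids the code path (and, where possible,
the library routine) it is used to check: explicit loops, exact rational
enumeration, quadrature of density formulas, and Monte Carlo.
"""
from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb, factorial, gamma, pi, sqrt

import numpy as np
from scipy.integrate import quad


def loop_predict(dosages, weights) -> dict[tuple[str, str], float]:
    """Triple-loop weighted-sum expression prediction: {(sample, gene): E}."""
    col = {v: j for j, v in enumerate(dosages.variants["variant_id"])}
    out = {}
    for i, s in enumerate(dosages.samples):
        for row in weights.weights.itertuples():
            if row.variant_id not in col:
                continue
            key = (s, row.gene)
            out[key] = out.get(key, 0.0) + row.weight * dosages.dosages[i, col[row.variant_id]]
    return out


def hwe_enum(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact HWE p by full rational enumeration over heterozygote counts."""
    n = n_hom_ref + n_het + n_hom_alt
    n_alt = 2 * n_hom_alt + n_het
    rare = min(n_alt, 2 * n - n_alt)
    probs: dict[int, Fraction] = {}
    for h in range(rare % 2, rare + 1, 2):
        hom_rare = (rare - h) // 2
        hom_common = n - h - hom_rare
        probs[h] = Fraction(
            factorial(n) * 2**h,
            factorial(hom_rare) * factorial(h) * factorial(hom_common),
        )
    total = sum(probs.values())
    p_obs = probs[n_het]
    return float(sum(p for p in probs.values() if p <= p_obs) / total)


def mendel_possible(child: int, mother: int, father: int) -> bool:
    """Enumerate parental gametes; is the child genotype attainable?"""
    gametes = {0: {0}, 1: {0, 1}, 2: {1}}
    return child in {a + b for a in gametes[mother] for b in gametes[father]}


def fisher_enum(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact hypergeometric summation (min-likelihood)."""
    r1, r2, c1, n = a + b, c + d, a + c, a + b + c + d
    def pr(k: int) -> Fraction:
        return Fraction(comb(r1, k) * comb(r2, c1 - k), comb(n, c1))
    p_obs = pr(a)
    eps = Fraction(10**9 + 1, 10**9)  # guard against spurious rational ties only
    total = Fraction(0)
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        if pr(k) <= p_obs * eps:
            total += pr(k)
    return float(min(Fraction(1), total))


def irls_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 200):
    """From-scratch Newton-Raphson logistic fit: (beta, se, wald_p)."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    beta = np.zeros(X.shape[1])
    H = np.eye(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        grad = X.T @ (y - mu)
        H = X.T @ (X * w[:, None])
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-13:
            break
    se = np.sqrt(np.diag(np.linalg.inv(H)))
    z = beta / se
    p = np.array([2 * normal_sf(abs(v)) for v in z])
    return beta, se, p


def normal_sf(x: float) -> float:
    """Standard normal survival function via erfc (no scipy.stats)."""
    from math import erfc
    return 0.5 * erfc(x / sqrt(2.0))


def t_sf_quadrature(t: float, df: int) -> float:
    """Student-t survival function by numerical integration of the pdf."""
    c = gamma((df + 1) / 2) / (sqrt(df * pi) * gamma(df / 2))
    val, _ = quad(lambda x: c * (1 + x * x / df) ** (-(df + 1) / 2), t, np.inf)
    return val


def mannwhitney_enum_p_less(cases, controls) -> float:
    """Exact one-sided (cases lower) Mann-Whitney p by full enumeration.

    Enumerates every assignment of the pooled values to the case group and
    counts assignments whose U statistic is at most the observed one.
    Requires untied values.
    """
    cases = list(map(float, cases))
    controls = list(map(float, controls))
    pooled = cases + controls

    def u_stat(cs, ks):
        return sum(1 for x in cs for y in ks if x > y)

    u_obs = u_stat(cases, controls)
    n_le = n_tot = 0
    for combo in itertools.combinations(range(len(pooled)), len(cases)):
        cs = [pooled[i] for i in combo]
        ks = [pooled[i] for i in range(len(pooled)) if i not in combo]
        n_tot += 1
        if u_stat(cs, ks) <= u_obs:
            n_le += 1
    return n_le / n_tot


def mc_paired_power(
    d: float, n: int, alpha: float, reps: int, rng: np.random.Generator
) -> float:
    """Monte-Carlo power of the one-sided paired t-test at Cohen's d."""
    from scipy.stats import t as tdist

    x = rng.normal(d, 1.0, size=(reps, n))
    tstat = x.mean(axis=1) / (x.std(axis=1, ddof=1) / sqrt(n))
    return float((tstat > tdist.ppf(1 - alpha, n - 1)).mean())
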