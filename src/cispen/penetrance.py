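"""Penetrance-modification tests and paired-t power analysis.

The central hypothesis: for a rare damaging variant in a loss-of-function
gene, penetrance depends on the cis-regulatory background — an unaffected
transmitting parent should be protected by HIGHER predicted expression of
the wild-type haplotype than their affected child.  Two tests target this:

* ``family_paired_test`` — a one-sided paired t-test on per-family
  differences d_i = parent expression - child expression (H1: mean > 0).
  The within-family design controls for population stratification and for
  the shared variant-carrying haplotype.
* ``percentile_ranks`` + ``rank_wilcoxon`` — a case/control alternative:
  per gene, expression values of variant-carrying probands and controls are
  converted to percentile ranks of the pooled distribution; ranks are
  aggregated across genes and compared with a one-sided Wilcoxon
  (Mann-Whitney) test, H1: carriers rank lower.  The percentile convention
  100*(rank - 0.5)/N (mean rank for ties) makes the complete-control mean
  exactly 50 and is invariant to monotone transforms of expression.

``paired_t_power`` / ``paired_t_sample_size`` give the exact noncentral-t
power of the paired test at Cohen's d = mean(d_i)/sd(d_i), matching R's
``pwr::pwr.t.test(type="paired")``.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, DegenerateDataError

log = logging.getLogger(__name__)


@dataclass
class PairedTestResult:
    n: int
    mean_diff: float
    sd_diff: float
    t: float
    df: int
    p_one_sided: float   # H1: parent > child (mean difference > 0)
    p_two_sided: float
    ci_low: float        # two-sided 95% CI on the mean difference
    ci_high: float


def family_paired_test(
    parent_expr: np.ndarray, child_expr: np.ndarray, ci_level: float = 0.95
) -> PairedTestResult:
    """One-sided paired t-test of parent-minus-child predicted expression.

    H1: transmitting parents have higher predicted expression than their
    affected children (mean difference > 0).  The two-sided p and a
    two-sided 95% t-interval are reported alongside for reversed effects.
    """
    parent = np.asarray(parent_expr, dtype=float)
    child = np.asarray(child_expr, dtype=float)
    if parent.shape != child.shape:
        raise ConfigurationError("parent and child expression vectors must be aligned")
    d = parent - child
    n = d.size
    if n < 2:
        raise DegenerateDataError(f"paired test needs n >= 2 pairs, got {n}")
    mean, sd = float(d.mean()), float(d.std(ddof=1))
    if sd == 0:
        raise DegenerateDataError("all paired differences are identical (sd = 0)")
    se = sd / np.sqrt(n)
    t = mean / se
    df = n - 1
    p_one = float(stats.t.sf(t, df))
    p_two = float(2 * stats.t.sf(abs(t), df))
    tcrit = stats.t.ppf(0.5 + ci_level / 2, df)
    return PairedTestResult(
        n=n, mean_diff=mean, sd_diff=sd, t=float(t), df=df,
        p_one_sided=p_one, p_two_sided=p_two,
        ci_low=mean - tcrit * se, ci_high=mean + tcrit * se,
    )


def percentile_ranks(values: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Percentile ranks on a 0-100 scale: 100*(rank - 0.5)/N, mean-rank ties.

    Computed over the pooled input vector (carriers + controls for one
    gene).  With this convention the mean of a complete untied set is
    exactly 50.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ConfigurationError("percentile ranks need at least 2 values")
    ranks = stats.rankdata(arr, method="average")
    pct = 100.0 * (ranks - 0.5) / arr.size
    if isinstance(values, pd.Series):
        return pd.Series(pct, index=values.index, name="percentile")
    return pct


@dataclass
class RankTestResult:
    u: float
    p_one_sided: float   # H1: case ranks stochastically lower
    n_cases: int
    n_controls: int
    method: str          # "exact" or "normal"


def rank_wilcoxon(
    case_ranks: np.ndarray, control_ranks: np.ndarray, exact_max_n: int = 20
) -> RankTestResult:
    """One-sided Mann-Whitney test that case percentile ranks are lower.

    Exact enumeration when the pooled size is <= ``exact_max_n`` with no
    ties; otherwise the tie-corrected normal approximation with continuity
    correction.  The method used is recorded in the result.
    """
    cases = np.asarray(case_ranks, dtype=float)
    controls = np.asarray(control_ranks, dtype=float)
    if cases.size == 0 or controls.size == 0:
        raise ConfigurationError("both groups must be non-empty")
    pooled = np.concatenate([cases, controls])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= exact_max_n and no_ties) else "normal"
    res = stats.mannwhitneyu(
        cases,
        controls,
        alternative="less",
        method="exact" if method == "exact" else "asymptotic",
        use_continuity=True,
    )
    return RankTestResult(
        u=float(res.statistic),
        p_one_sided=float(res.pvalue),
        n_cases=cases.size,
        n_controls=controls.size,
        method=method,
    )


def pooled_rank_test(
    carrier_expr: dict[str, np.ndarray], control_expr: dict[str, np.ndarray]
) -> tuple[RankTestResult, pd.DataFrame]:
    """Per-gene percentile ranks pooled across genes, then the rank test.

    ``carrier_expr[gene]`` holds variant-carrying probands' predicted
    expression for that gene; ``control_expr[gene]`` the controls'.  For
    every gene, carriers and controls are ranked together; each control
    contributes one rank per gene, so the pooled sample size is
    n_carriers + n_genes * n_controls.  Returns the test result and the
    pooled long-format rank table with gene provenance.
    """
    rows = []
    for gene, cases in carrier_expr.items():
        if gene not in control_expr:
            raise ConfigurationError(f"no control expression for gene {gene}")
        controls = np.asarray(control_expr[gene], dtype=float)
        cases = np.asarray(cases, dtype=float)
        pooled = np.concatenate([cases, controls])
        pct = percentile_ranks(pooled)
        for k, v in enumerate(pct[: cases.size]):
            rows.append({"gene": gene, "group": "case", "percentile": v})
        for v in pct[cases.size:]:
            rows.append({"gene": gene, "group": "control", "percentile": v})
    table = pd.DataFrame(rows)
    res = rank_wilcoxon(
        table.loc[table["group"] == "case", "percentile"].to_numpy(),
        table.loc[table["group"] == "control", "percentile"].to_numpy(),
    )
    return res, table


def paired_t_power(
    d: float, n: int, alpha: float = 0.05, sidedness: str = "one"
) -> float:
    """Power of the paired t-test at Cohen's d with n pairs.

    One-sided: P(T' > t_{1-alpha, n-1}) for T' noncentral t with
    noncentrality d*sqrt(n).  Two-sided sums both rejection tails.
    """
    if n < 2:
        raise ConfigurationError("power needs n >= 2 pairs")
    if not (0 < alpha < 1):
        raise ConfigurationError("alpha must lie in (0, 1)")
    df = n - 1
    nc = d * np.sqrt(n)
    if sidedness == "one":
        tcrit = stats.t.ppf(1 - alpha, df)
        return float(stats.nct.sf(tcrit, df, nc))
    if sidedness == "two":
        tcrit = stats.t.ppf(1 - alpha / 2, df)
        return float(stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))
    raise ConfigurationError("sidedness must be 'one' or 'two'")


def paired_t_sample_size(
    d: float, alpha: float = 0.05, target_power: float = 0.8, sidedness: str = "one"
) -> int:
    """Smallest n with paired_t_power(d, n) >= target_power (bracketed search)."""
    if d == 0:
        raise ConfigurationError("d = 0 has no finite sample size")
    if not (alpha < target_power < 1):
        raise ConfigurationError("target_power must lie in (alpha, 1)")
    d = abs(d)
    lo, hi = 2, 2
    while paired_t_power(d, hi, alpha, sidedness) < target_power:
        lo, hi = hi, hi * 2
        if hi > 10_000_000:
            raise ConfigurationError("no attainable sample size below 1e7 pairs")
    while lo < hi:
        mid = (lo + hi) // 2
        if paired_t_power(d, mid, alpha, sidedness) >= target_power:
            hi = mid
        else:
            lo = mid + 1
    return int(hi)
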