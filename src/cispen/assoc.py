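"""Case/control association on genetically-predicted expression.

Two complementary scans over a cohort of cases and controls:

* ``twas_scan`` — per gene, a maximum-likelihood logistic regression of case
  status on predicted expression plus a covariate matrix (genotype PCs in a
  real cohort; 10 columns by default), with a Wald test on the expression
  coefficient and Bonferroni control across genes.
* ``outlier_enrichment`` — per gene, flags individuals whose predicted
  expression is more than k standard deviations (default 3) from the
  CONTROL mean, and tests case-vs-control outlier counts with a two-sided
  Fisher's exact test.  This targets the tails the mean-shift TWAS misses:
  probands with an unusual cis-regulatory configuration driving extreme
  predicted expression.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import fisher_exact

from .exceptions import ConfigurationError
from .expression import ExpressionMatrix

log = logging.getLogger(__name__)


@dataclass
class TWASResult:
    gene: str
    tissue: str
    beta: float
    se: float
    z: float
    p: float
    n_cases: int
    n_controls: int
    converged: bool


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ConfigurationError("n_tests must be >= 1")
    if not (0 < alpha < 1):
        raise ConfigurationError("alpha must lie in (0, 1)")
    return alpha / n_tests


def twas_scan(
    expr: ExpressionMatrix,
    status: np.ndarray,
    covariates: np.ndarray | None = None,
    tissue: str | None = None,
    use_lrt: bool = False,
) -> pd.DataFrame:
    """Per-gene logistic regression of case status on predicted expression.

    Returns a summary-statistics frame (gene, tissue, beta, se, z, p,
    n_cases, n_controls, converged).  The p value is a Wald test on the
    expression coefficient by default (``use_lrt`` switches to a likelihood-
    ratio test).  Genes with constant expression, separation or
    non-convergence are flagged ``converged=False`` with p absent.
    """
    status = np.asarray(status, dtype=float)
    n = len(status)
    if expr.values.shape[0] != n:
        raise ConfigurationError("expression rows and status vector are misaligned")
    if covariates is None:
        covariates = np.empty((n, 0))
    covariates = np.asarray(covariates, dtype=float)
    if covariates.shape[0] != n:
        raise ConfigurationError("covariate rows and status vector are misaligned")
    classes = np.unique(status)
    if not np.array_equal(classes, [0.0, 1.0]):
        raise ConfigurationError("status must contain both cases (1) and controls (0)")
    n_cases, n_controls = int(status.sum()), int(n - status.sum())
    tissue = tissue or "NA"

    rows = []
    base = np.column_stack([np.ones(n), covariates])
    for gene in expr.genes:
        e = expr.values[gene].to_numpy(dtype=float)
        result = TWASResult(gene, tissue, np.nan, np.nan, np.nan, np.nan,
                            n_cases, n_controls, False)
        if np.ptp(e) == 0:
            log.warning("gene %s has constant predicted expression; skipped", gene)
            rows.append(result)
            continue
        X = np.column_stack([base[:, :1], e, base[:, 1:]])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(status, X).fit(disp=0, maxiter=100)
            if not fit.mle_retvals.get("converged", False):
                raise RuntimeError("no convergence")
            beta, se = fit.params[1], fit.bse[1]
            if not np.isfinite(se) or se <= 0 or se > 1e4:
                raise RuntimeError("unstable standard error (separation)")
            z = beta / se
            if use_lrt:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    null = sm.Logit(status, base).fit(disp=0, maxiter=100)
                from scipy.stats import chi2

                p = float(chi2.sf(2 * (fit.llf - null.llf), df=1))
            else:
                p = float(fit.pvalues[1])
            result = TWASResult(gene, tissue, float(beta), float(se), float(z), p,
                                n_cases, n_controls, True)
        except Exception as exc:  # separation / convergence failures
            log.warning("gene %s: logistic fit failed (%s)", gene, exc)
        rows.append(result)
    return pd.DataFrame([r.__dict__ for r in rows])


@dataclass
class OutlierTestResult:
    gene: str
    control_mean: float
    control_sd: float
    n_case_outliers: int
    n_case_total: int
    n_control_outliers: int
    n_control_total: int
    fisher_p: float


def outlier_enrichment(
    expr: ExpressionMatrix,
    case_ids: list[str],
    control_ids: list[str],
    k_sd: float = 3.0,
    gene_list: list[str] | None = None,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, float]:
    """Per-gene Fisher test of extreme predicted expression in cases.

    Moments are computed on CONTROLS ONLY; an individual is an outlier iff
    |E - control mean| > k_sd * control sd (strict).  Returns the per-gene
    table and the Bonferroni threshold alpha / (genes tested).
    """
    if not control_ids:
        raise ConfigurationError("control set must be non-empty")
    genes = [g for g in (gene_list or expr.genes) if g in expr.values.columns]
    rows = []
    case_vals = expr.values.loc[case_ids]
    ctrl_vals = expr.values.loc[control_ids]
    for gene in genes:
        c = ctrl_vals[gene].to_numpy(dtype=float)
        mean, sd = float(c.mean()), float(c.std(ddof=1))
        if sd == 0:
            log.warning("gene %s: zero control sd; skipped", gene)
            continue
        e = case_vals[gene].to_numpy(dtype=float)
        case_out = int((np.abs(e - mean) > k_sd * sd).sum())
        ctrl_out = int((np.abs(c - mean) > k_sd * sd).sum())
        table = [
            [case_out, len(e) - case_out],
            [ctrl_out, len(c) - ctrl_out],
        ]
        p = float(fisher_exact(table, alternative="two-sided")[1])
        rows.append(
            OutlierTestResult(
                gene, mean, sd, case_out, len(e), ctrl_out, len(c), p
            )
        )
    table_df = pd.DataFrame([r.__dict__ for r in rows])
    threshold = bonferroni_threshold(alpha, max(len(rows), 1))
    return table_df, threshold
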