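"""Negative-binomial differential expression: common dispersion, exact test,
BH-FDR, fold changes and the DEG filter (FC > 2 or < 0.5, CPM > 4, FDR < 0.01).

The exact test is the count analogue of Fisher's test: with equalized
library sizes, group sums Y1 ~ NB(n1*mu, phi/n1) and Y2 ~ NB(n2*mu, phi/n2)
are compared conditionally on their total, and the two-sided p-value sums
the conditional probabilities of all outcomes no more likely than the
observed one.  The common dispersion maximizes the conditional (given
per-group totals) NB log-likelihood summed over genes.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp
from scipy.stats import binom


@dataclass(frozen=True)
class DegThresholds:
    fc_hi: float = 2.0
    fc_lo: float = 0.5
    cpm_min: float = 4.0
    fdr_max: float = 0.01


@dataclass
class DispersionFit:
    dispersion: float
    bracket_log10: tuple[float, float]
    loglik: float
    loglik_at_bracket: tuple[float, float]


def _cond_loglik(counts: np.ndarray, groups: np.ndarray, r: float) -> float:
    """Conditional NB log-likelihood at size r = 1/phi (equal library sizes).

    For each gene and group with counts y_1..y_n summing to z:
    sum_i lgamma(y_i + r) - n*lgamma(r) + lgamma(n*r) - lgamma(z + n*r).
    """
    total = 0.0
    for g in np.unique(groups):
        y = counts[:, groups == g]
        n = y.shape[1]
        z = y.sum(axis=1)
        total += float(np.sum(gammaln(y + r)) - y.shape[0] * n * gammaln(r)
                       + y.shape[0] * gammaln(n * r) - np.sum(gammaln(z + n * r)))
    return total


def estimate_common_dispersion(
    counts: pd.DataFrame,
    groups: pd.Series,
    bracket_log10: tuple[float, float] = (-4.0, 1.0),
) -> DispersionFit:
    """Maximize the conditional log-likelihood over log10(phi) in *bracket*.

    Counts are expected to be library-size equalized (see
    :func:`equalize_library_sizes`); a CV of column sums above 10% draws a
    warning.  Requires replication in at least one group.
    """
    groups = groups.loc[counts.columns]
    sizes = groups.value_counts()
    if (sizes < 2).all():
        raise ValueError("no group has replicates; dispersion cannot be estimated")
    libs = counts.sum(axis=0).to_numpy(dtype=float)
    cv = libs.std() / libs.mean()
    if cv > 0.10:
        warnings.warn(f"library sizes differ by CV={cv:.2f} (>10%); "
                      "equalize counts before estimating dispersion")
    y = counts.to_numpy(dtype=float)
    garr = groups.to_numpy()

    def neg(l10):
        return -_cond_loglik(y, garr, 1.0 / (10.0 ** l10))

    res = minimize_scalar(neg, bounds=bracket_log10, method="bounded",
                          options={"xatol": 1e-4})
    phi = float(10.0 ** res.x)
    return DispersionFit(
        dispersion=phi,
        bracket_log10=bracket_log10,
        loglik=-float(res.fun),
        loglik_at_bracket=(-neg(bracket_log10[0]), -neg(bracket_log10[1])),
    )


def _nb_logpmf(y: np.ndarray, mean: float, phi: float) -> np.ndarray:
    r = 1.0 / phi
    logp = np.log(r / (r + mean))
    log1mp = np.log(mean / (r + mean))
    return gammaln(y + r) - gammaln(r) - gammaln(y + 1) + r * logp + y * log1mp


_TIE_TOL = 1e-8  # log-scale slack so that exact probability ties are kept


def nb_exact_test(y1_sum: int, y2_sum: int, n1: int, n2: int, phi: float) -> float:
    """Two-sided conditional exact p-value for NB group sums.

    ``y1_sum``/``y2_sum`` are group totals over ``n1``/``n2`` samples with
    equal library sizes; ``phi`` is the common per-sample dispersion.  With
    ``phi == 0`` this reduces to the conditional binomial test.
    """
    if phi < 0:
        raise ValueError("phi must be >= 0")
    t = int(y1_sum + y2_sum)
    if t == 0:
        return 1.0
    y = np.arange(t + 1)
    if phi == 0.0:
        logw = binom.logpmf(y, t, n1 / (n1 + n2))
    else:
        mu = t / (n1 + n2)
        logw = (_nb_logpmf(y, n1 * mu, phi / n1)
                + _nb_logpmf(y[::-1], n2 * mu, phi / n2))
        logw = logw - logsumexp(logw)
    obs = logw[int(y1_sum)]
    p = float(np.exp(logsumexp(logw[logw <= obs + _TIE_TOL])))
    return min(p, 1.0)


def exact_test_pvalues(counts: pd.DataFrame, groups: pd.Series,
                       phi: float) -> pd.Series:
    """Per-gene exact-test p-values for a two-group comparison."""
    groups = groups.loc[counts.columns]
    levels = list(pd.unique(groups))
    if len(levels) != 2:
        raise ValueError(f"exact test needs exactly two groups, got {levels}")
    g1, g2 = levels
    y1 = counts.loc[:, groups == g1].sum(axis=1).round().astype(np.int64)
    y2 = counts.loc[:, groups == g2].sum(axis=1).round().astype(np.int64)
    n1 = int((groups == g1).sum())
    n2 = int((groups == g2).sum())
    p = np.array([nb_exact_test(a, b, n1, n2, phi) for a, b in zip(y1, y2)])
    return pd.Series(p, index=counts.index)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p, dtype=float)
    if np.isnan(p).any():
        raise ValueError("NaN p-values cannot be adjusted")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def equalize_library_sizes(counts: pd.DataFrame,
                           norm_factors: pd.Series | None = None) -> pd.DataFrame:
    """Scale columns to a common effective library size (geometric mean).

    The effective library size is the column sum times its normalization
    factor (1 if None, e.g. after stratified adjustment whose factors are
    already folded into the counts)."""
    libs = counts.sum(axis=0).astype(float)
    if norm_factors is not None:
        libs = libs * norm_factors.loc[counts.columns].astype(float)
    target = float(np.exp(np.log(libs).mean()))
    return counts * (target / libs)


def log2fc_and_cpm(counts: pd.DataFrame, groups: pd.Series,
                   contrast: tuple[str, str], prior: float = 0.5
                   ) -> tuple[pd.Series, pd.Series]:
    """Per-gene (log2 fold change treated-vs-control, average CPM).

    logFC = log2((meanCPM_trt + prior) / (meanCPM_ctl + prior)); the prior
    bounds fold changes at zero counts."""
    trt, ctl = contrast
    groups = groups.loc[counts.columns]
    c = cpm_of(counts)
    m_trt = c.loc[:, groups == trt].mean(axis=1)
    m_ctl = c.loc[:, groups == ctl].mean(axis=1)
    logfc = np.log2((m_trt + prior) / (m_ctl + prior))
    ave_cpm = c.mean(axis=1)
    return logfc, ave_cpm


def cpm_of(counts: pd.DataFrame) -> pd.DataFrame:
    from .quantify import cpm
    return cpm(counts)


def deg_filter(table: pd.DataFrame,
               thresholds: DegThresholds = DegThresholds()) -> pd.DataFrame:
    """Apply the DEG thresholds with strict inequalities.

    Adds ``passed`` and ``direction`` (up/down/none) columns; up means
    FC > fc_hi, down means FC < fc_lo."""
    fc = 2.0 ** table["logFC"]
    up = fc > thresholds.fc_hi
    down = fc < thresholds.fc_lo
    ok = (table["aveCPM"] > thresholds.cpm_min) & (table["FDR"] < thresholds.fdr_max)
    out = table.copy()
    out["passed"] = (up | down) & ok
    out["direction"] = np.where(out["passed"] & up, "up",
                                np.where(out["passed"] & down, "down", "none"))
    return out


def de_test(
    counts: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    contrast: tuple[str, str],
    norm_factors: pd.Series | None = None,
    phi: float | None = None,
    thresholds: DegThresholds = DegThresholds(),
    prior: float = 0.5,
) -> tuple[pd.DataFrame, DispersionFit | None]:
    """Full DE analysis of one two-condition contrast.

    *counts* should already be normalization-adjusted (naive mode passes
    global TMM factors via *norm_factors* instead).  Columns are equalized
    to a common library size and rounded half-to-even before the
    count-based test.  Returns the DE table and the dispersion fit (None if
    *phi* was supplied)."""
    ss = sample_sheet.set_index("sample_id") if "sample_id" in sample_sheet.columns \
        else sample_sheet
    trt, ctl = contrast
    keep = ss.index[ss["condition"].isin([trt, ctl])]
    keep = [s for s in counts.columns if s in set(keep)]
    sub = counts[keep]
    groups = ss.loc[keep, "condition"]

    eq = equalize_library_sizes(sub, norm_factors)
    eq_int = pd.DataFrame(np.rint(eq.to_numpy()).astype(np.int64),
                          index=eq.index, columns=eq.columns)
    fit = None
    if phi is None:
        fit = estimate_common_dispersion(eq_int, groups)
        phi = fit.dispersion
    # order groups as (control, treated) internally; p is symmetric
    p = exact_test_pvalues(eq_int, groups, phi)
    logfc, ave_cpm = log2fc_and_cpm(eq, groups, contrast, prior)
    table = pd.DataFrame({
        "gene_id": counts.index,
        "logFC": logfc.values,
        "aveCPM": ave_cpm.values,
        "p": p.values,
        "FDR": bh_adjust(p.values),
    }).set_index("gene_id")
    return deg_filter(table, thresholds), fit
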