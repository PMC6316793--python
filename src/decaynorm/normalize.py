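"""TMM normalization, global and stratified by transcript length / CPM.

The stratified variant targets the residual length dependence of fold
changes between samples of unequal RNA integrity: genes are split into
quantile bins (by average transcript length, then by average CPM) and a
TMM scaling factor is computed within each bin, so systematic count-ratio
shifts that track the stratifier are removed instead of being averaged into
one global factor.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .quantify import cpm

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TmmParams:
    """Trimmed-mean-of-M-values parameters (two-sided trim fractions)."""

    m_trim: float = 0.30
    a_trim: float = 0.05
    min_genes: int = 10

    def __post_init__(self):
        if not (0 <= self.m_trim < 0.5 and 0 <= self.a_trim < 0.5):
            raise ValueError("trim fractions must lie in [0, 0.5)")


def choose_reference(counts: pd.DataFrame) -> str:
    """Sample whose 75th-percentile CPM is closest to the across-sample mean
    of that quantile (all-zero samples excluded; ties broken by column order)."""
    if counts.shape[1] < 2:
        raise ValueError("need at least two samples")
    libs = counts.sum(axis=0)
    candidates = [s for s in counts.columns if libs[s] > 0]
    if not candidates:
        raise ValueError("all samples are empty")
    uq = {s: float(np.quantile(counts[s].to_numpy() / libs[s] * 1e6, 0.75))
          for s in candidates}
    target = float(np.mean(list(uq.values())))
    return min(candidates, key=lambda s: (abs(uq[s] - target), counts.columns.get_loc(s)))


def tmm_factor(
    obs: np.ndarray | pd.Series,
    ref: np.ndarray | pd.Series,
    params: TmmParams = TmmParams(),
    lib_obs: float | None = None,
    lib_ref: float | None = None,
) -> float:
    """TMM scaling factor of *obs* relative to *ref*.

    M (log ratio) and A (log abundance) are computed on library-size-scaled
    counts over genes nonzero in both columns; genes outside the central
    (1 - 2*m_trim) M-range and (1 - 2*a_trim) A-range (average ranks, so
    ties trim symmetrically) are discarded; the factor is 2 to the
    precision-weighted mean of the surviving M values, with inverse
    delta-method variances as weights.
    """
    y_o = np.asarray(obs, dtype=float)
    y_r = np.asarray(ref, dtype=float)
    if y_o.shape != y_r.shape:
        raise ValueError("obs and ref must have the same gene order/length")
    N_o = float(y_o.sum()) if lib_obs is None else float(lib_obs)
    N_r = float(y_r.sum()) if lib_ref is None else float(lib_ref)
    keep = (y_o > 0) & (y_r > 0)
    y_o, y_r = y_o[keep], y_r[keep]
    n = y_o.size
    if n == 0:
        warnings.warn("no genes usable for TMM; returning factor 1")
        return 1.0
    p_o, p_r = y_o / N_o, y_r / N_r
    M = np.log2(p_o / p_r)
    A = 0.5 * np.log2(p_o * p_r)
    rM = rankdata(M)
    rA = rankdata(A)
    lo_m = math.floor(n * params.m_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = math.floor(n * params.a_trim) + 1
    hi_a = n + 1 - lo_a
    keep2 = (rM >= lo_m) & (rM <= hi_m) & (rA >= lo_a) & (rA <= hi_a)
    if keep2.sum() < params.min_genes:
        warnings.warn(f"only {int(keep2.sum())} genes survive TMM trimming; "
                      "returning factor 1")
        return 1.0
    w = 1.0 / ((N_o - y_o) / (N_o * y_o) + (N_r - y_r) / (N_r * y_r))
    log2f = float(np.sum(w[keep2] * M[keep2]) / np.sum(w[keep2]))
    return 2.0 ** log2f


def tmm_factors(counts: pd.DataFrame, params: TmmParams = TmmParams(),
                reference: str | None = None) -> pd.Series:
    """Global per-sample TMM factors, re-centered to geometric mean 1."""
    ref = choose_reference(counts) if reference is None else reference
    libs = counts.sum(axis=0).astype(float)
    f = pd.Series({
        s: tmm_factor(counts[s], counts[ref], params,
                      lib_obs=libs[s], lib_ref=libs[ref])
        for s in counts.columns
    })
    return f / np.exp(np.log(f).mean())


def quantile_bins(values: pd.Series, n_bins: int = 10) -> pd.Series:
    """Rank genes by *values* (stable, ties broken by gene id) and cut into
    *n_bins* contiguous groups whose sizes differ by at most 1."""
    n = len(values)
    if n < n_bins:
        raise ValueError(f"cannot split {n} genes into {n_bins} bins")
    order = values.to_frame("v").assign(g=values.index.astype(str)) \
        .sort_values(["v", "g"], kind="mergesort").index
    base, extra = divmod(n, n_bins)
    sizes = [base + 1] * extra + [base] * (n_bins - extra)
    labels = np.repeat(np.arange(n_bins), sizes)
    return pd.Series(labels, index=order).reindex(values.index)


@dataclass
class StratifiedNormResult:
    stratifier: str
    bins: pd.Series                      # gene -> bin label
    factors: pd.DataFrame                # bins x samples, geometric mean 1 per bin
    adjusted: pd.DataFrame               # counts / factor (float)
    reference: str
    params: TmmParams = field(default_factory=TmmParams)

    @property
    def adjusted_int(self) -> pd.DataFrame:
        """Adjusted counts rounded half-to-even, for count-based tests."""
        return pd.DataFrame(np.rint(self.adjusted.to_numpy()).astype(np.int64),
                            index=self.adjusted.index, columns=self.adjusted.columns)


def _merge_small_bins(bins: pd.Series, min_genes: int) -> pd.Series:
    """Merge bins holding fewer than *min_genes* genes into the adjacent bin
    (the smaller neighbor, lower index on ties), then relabel 0..k-1."""
    bins = bins.copy()
    while True:
        sizes = bins.value_counts().sort_index()
        if len(sizes) == 1 or (sizes >= min_genes).all():
            break
        b = int(sizes[sizes < min_genes].index[0])
        labels = list(sizes.index)
        pos = labels.index(b)
        neighbors = [labels[i] for i in (pos - 1, pos + 1) if 0 <= i < len(labels)]
        tgt = min(neighbors, key=lambda x: (sizes[x], x))
        log.info("merging stratification bin %d (%d genes) into bin %d",
                 b, sizes[b], tgt)
        bins[bins == b] = tgt
    relabel = {old: new for new, old in enumerate(sorted(bins.unique()))}
    return bins.map(relabel)


def stratified_tmm(
    counts: pd.DataFrame,
    strat_values: pd.Series,
    n_bins: int = 10,
    params: TmmParams = TmmParams(),
    min_bin_genes: int = 50,
    stratifier: str = "custom",
    reference: str | None = None,
) -> StratifiedNormResult:
    """Bin genes by *strat_values* and compute within-bin TMM factors.

    The reference sample is global; within each bin the observed and
    reference sub-columns are compared with whole-column library sizes.
    Factors are re-centered to geometric mean 1 across samples per bin, and
    adjusted counts are ``raw / factor`` (zeros are preserved).
    """
    strat_values = strat_values.loc[counts.index]
    ref = choose_reference(counts) if reference is None else reference
    bins = _merge_small_bins(quantile_bins(strat_values, n_bins), min_bin_genes)
    libs = counts.sum(axis=0).astype(float)
    rows = {}
    for b in sorted(bins.unique()):
        genes_b = bins.index[bins == b]
        fb = np.array([
            tmm_factor(counts.loc[genes_b, s], counts.loc[genes_b, ref], params,
                       lib_obs=libs[s], lib_ref=libs[ref])
            for s in counts.columns
        ])
        fb = fb / np.exp(np.log(fb).mean())
        rows[b] = fb
    factors = pd.DataFrame.from_dict(rows, orient="index", columns=counts.columns)
    gene_factors = factors.to_numpy()[bins.to_numpy(), :]
    adjusted = pd.DataFrame(counts.to_numpy(dtype=float) / gene_factors,
                            index=counts.index, columns=counts.columns)
    return StratifiedNormResult(stratifier, bins, factors, adjusted, ref, params)


@dataclass
class TwoStageNormResult:
    stage_length: StratifiedNormResult
    stage_cpm: StratifiedNormResult

    @property
    def adjusted(self) -> pd.DataFrame:
        return self.stage_cpm.adjusted

    @property
    def adjusted_int(self) -> pd.DataFrame:
        return self.stage_cpm.adjusted_int


def adjust_counts(
    counts: pd.DataFrame,
    bin_lengths: pd.Series,
    n_bins: int = 10,
    params: TmmParams = TmmParams(),
    min_bin_genes: int = 50,
) -> TwoStageNormResult:
    """Two-stage stratified TMM adjustment.

    Stage 1 stratifies by average transcript length; stage 2 stratifies by
    per-gene mean CPM computed from the stage-1 output, removing any
    remaining dependence of fold change on absolute expression level.
    """
    missing = counts.index.difference(bin_lengths.index)
    if len(missing):
        raise ValueError(f"missing binning lengths for genes: {list(missing[:5])}")
    s1 = stratified_tmm(counts, bin_lengths, n_bins, params, min_bin_genes,
                        stratifier="transcript_length")
    mean_cpm = cpm(s1.adjusted).mean(axis=1)
    s2 = stratified_tmm(s1.adjusted, mean_cpm, n_bins, params, min_bin_genes,
                        stratifier="cpm")
    return TwoStageNormResult(s1, s2)
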