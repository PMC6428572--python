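"""Trait-polarized Singleton Density Score (tSDS) analysis.

SDS measures recent allele-frequency change at a SNP from the spacing of
singletons around its two alleles, polarized to the derived allele.  Signing
it by the trait-increasing ("tall") allele instead gives tSDS:

    tSDS = +SDS  if the derived allele increases the trait,
           -SDS  otherwise.

A genome-wide excess of positive tSDS among trait-associated SNPs is the
signature of recent directional selection on the trait.  This module
standardizes SDS within 5% minor-allele-frequency bins, polarizes it,
computes the binned tSDS-versus-significance curve, and assesses the
SDS-significance correlation with a delete-one-block jackknife that is robust
to local LD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from ._jackknife import block_offsets, jackknife_se
from .containers import GwasSummary, SdsTable
from .exceptions import (
    AlignmentError,
    DegenerateInputError,
    ParameterError,
    UndefinedStatisticError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "standardize_sds",
    "polarize_tsds",
    "binned_tsds_curve",
    "jackknife_spearman",
    "mean_tsds_test",
    "JackknifeResult",
    "MeanTsdsResult",
]

MAF_FILTER = 0.05


def _maf_bin_index(maf: np.ndarray, bin_width: float) -> np.ndarray:
    """Half-open MAF bins [k w, (k+1) w); the top bin closes at 0.5 inclusive."""
    last = int(np.floor((0.5 - 1e-12) / bin_width))
    idx = np.floor(maf / bin_width).astype(int)
    return np.minimum(idx, last)


def standardize_sds(sds: SdsTable, bin_width: float = 0.05) -> SdsTable:
    """Standardize raw SDS to mean 0, SD 1 within minor-allele-frequency bins.

    SNPs with MAF below 5% are removed first (SDS is unreliable for rare
    alleles and the published scores are filtered the same way); the retained
    SNPs are binned by MAF in ``bin_width`` increments and z-scored within
    each bin.  The result carries the standardized values in ``sds_std``.

    Raises
    ------
    DegenerateInputError
        If a bin holds fewer than 2 SNPs or has zero variance.
    """
    if not 0 < bin_width <= 0.5:
        raise ParameterError("bin_width must lie in (0, 0.5]")
    df = sds.df
    maf = sds.maf
    keep = maf >= MAF_FILTER
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("standardize_sds: dropped %d SNP(s) with MAF < %.2f", n_dropped, MAF_FILTER)
    df = df.loc[keep].reset_index(drop=True)
    if df.empty:
        raise DegenerateInputError("no SNPs remain after the MAF filter")
    maf = maf[keep]
    idx = _maf_bin_index(maf, bin_width)
    values = df["sds"].to_numpy(float)
    out = np.empty_like(values)
    for k in np.unique(idx):
        sel = idx == k
        label = f"[{k * bin_width:.2f}, {(k + 1) * bin_width:.2f})"
        if sel.sum() < 2:
            raise DegenerateInputError(f"MAF bin {label} holds fewer than 2 SNPs")
        sd = values[sel].std(ddof=1)
        if sd == 0:
            raise DegenerateInputError(f"MAF bin {label} has zero SDS variance")
        out[sel] = (values[sel] - values[sel].mean()) / sd
    df = df.copy()
    df["sds_std"] = out
    return SdsTable(df=df)


def polarize_tsds(sds: SdsTable, gwas: GwasSummary) -> pd.DataFrame:
    """Polarize SDS by the trait-increasing allele of each matched SNP.

    SNPs are matched on id; the SDS allele pair {ancestral, derived} must
    equal the GWAS allele pair {effect, other}.  The trait-increasing allele
    is the effect allele when ``beta > 0`` and the other allele when
    ``beta < 0``; SNPs with ``beta == 0`` have no defined tall allele and are
    excluded with a log entry.

    Returns a table with columns ``chrom, pos, snp, tsds, beta, p`` in the
    SDS table's row order, using standardized SDS when available.
    """
    sdf = sds.df
    score_col = "sds_std" if "sds_std" in sdf.columns else "sds"
    gdf = gwas.df
    merged = sdf.merge(
        gdf[["snp", "a1", "a2", "beta", "p"]], on="snp", how="inner", validate="1:1"
    )
    bad = ~(
        ((merged["aa"] == merged["a1"]) & (merged["da"] == merged["a2"]))
        | ((merged["aa"] == merged["a2"]) & (merged["da"] == merged["a1"]))
    )
    if bad.any():
        snp = merged.loc[bad, "snp"].iloc[0]
        raise AlignmentError(f"allele sets disagree between SDS and GWAS at {snp!r}")
    zero = merged["beta"] == 0
    if zero.any():
        logger.info("polarize_tsds: excluded %d SNP(s) with zero effect", int(zero.sum()))
        merged = merged.loc[~zero]
    tall = np.where(merged["beta"] > 0, merged["a1"], merged["a2"])
    sign = np.where(merged["da"].to_numpy() == tall, 1.0, -1.0)
    out = merged[["chrom", "pos", "snp", "beta", "p"]].copy()
    out.insert(3, "tsds", sign * merged[score_col].to_numpy(float))
    return out.reset_index(drop=True)


def binned_tsds_curve(tsds: pd.DataFrame, bin_size: int = 1000) -> pd.DataFrame:
    """Average tSDS in consecutive significance-ordered SNP bins.

    SNPs are sorted by ascending GWAS p-value (most significant first; ties
    broken by chromosome then position for determinism) and averaged in
    consecutive runs of ``bin_size``.  A final partial bin is retained and
    flagged.

    Parameters
    ----------
    tsds
        Output of :func:`polarize_tsds` (columns ``chrom, pos, snp, tsds, p``).
    bin_size
        SNPs per bin.

    Returns
    -------
    DataFrame with columns ``bin, n, mean_tsds, mean_neglog10_p, partial``.
    """
    if bin_size < 1:
        raise ParameterError("bin_size must be positive")
    if len(tsds) < bin_size:
        raise ParameterError("fewer SNPs than one bin")
    df = tsds.sort_values(["p", "chrom", "pos"], kind="mergesort").reset_index(drop=True)
    values = df["tsds"].to_numpy(float)
    neglogp = -np.log10(df["p"].to_numpy(float))
    edges = np.arange(0, len(df) + bin_size, bin_size)
    edges[-1] = len(df)
    rows = []
    for i, (s, e) in enumerate(zip(edges[:-1], edges[1:])):
        rows.append(
            {
                "bin": i,
                "n": int(e - s),
                "mean_tsds": float(values[s:e].mean()),
                "mean_neglog10_p": float(neglogp[s:e].mean()),
                "partial": bool(e - s < bin_size),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class JackknifeResult:
    """Spearman correlation with a delete-one-block jackknife standard error."""

    point_estimate: float
    block_estimates: np.ndarray
    jackknife_mean: float
    se: float
    p_value: float
    n_blocks: int
    n_obs: int
    degenerate: bool = False

    def summary(self) -> str:
        tag = " [degenerate variance]" if self.degenerate else ""
        return (
            f"Spearman rho = {self.point_estimate:.4g}, jackknife SE = {self.se:.4g} "
            f"({self.n_blocks} blocks, n = {self.n_obs}), p = {self.p_value:.4g}{tag}"
        )


def _loo_spearman_naive(x, y, offsets):
    out = np.empty(len(offsets) - 1)
    for i, (s, e) in enumerate(zip(offsets[:-1], offsets[1:])):
        xi = np.concatenate([x[:s], x[e:]])
        yi = np.concatenate([y[:s], y[e:]])
        out[i] = stats.spearmanr(xi, yi).statistic
    return out


def _block_counts_below(values, block_of, n_blocks):
    # C[i, j] = number of block-i members with value strictly below values[j]
    # (tie-free input assumed): one-hot block membership in sorted order,
    # exclusive cumulative sum, mapped back to original positions.  Stored
    # (blocks, n) so the cumulative sum runs along the contiguous axis.
    n = values.size
    order = np.argsort(values, kind="mergesort")
    # cumulative counts are bounded by the largest block size
    dtype = np.int16 if n // n_blocks + 1 < np.iinfo(np.int16).max else np.int64
    onehot = np.zeros((n_blocks, n), dtype=dtype)
    onehot[block_of[order], np.arange(n)] = 1
    cum = np.cumsum(onehot, axis=1, dtype=dtype)
    cum -= onehot  # exclusive
    out = np.empty_like(cum)
    out[:, order] = cum
    return out


def _loo_spearman_fast(x, y, offsets):
    # Tie-free case: leave-block-out ranks are the full-sample ranks minus the
    # count of deleted values below each point, so each delete-one-block
    # Spearman reduces to one cross-product of corrected ranks.  The rank
    # margins of the reduced sample are exactly 1..n', giving closed-form
    # mean (n'+1)/2 and variance (n'^2-1)/12.  All blocks are handled at once
    # through per-block below-count matrices C_x, C_y (integers, exact in
    # float64):
    #   S_i = sum_{j not in i} (rx_j - Cx_ji)(ry_j - Cy_ji)
    #       = rx.ry - rx'Cy_i - ry'Cx_i + Cx_i.Cy_i - own-block terms.
    n = x.size
    b = len(offsets) - 1
    sizes = np.diff(offsets)
    block_of = np.repeat(np.arange(b), sizes)
    rx = np.empty(n)
    rx[np.argsort(x, kind="mergesort")] = np.arange(1, n + 1)
    ry = np.empty(n)
    ry[np.argsort(y, kind="mergesort")] = np.arange(1, n + 1)
    cx = _block_counts_below(x, block_of, b).astype(np.float64)
    cy = _block_counts_below(y, block_of, b).astype(np.float64)
    g = float(rx @ ry)
    t1 = cy @ rx
    t2 = cx @ ry
    t3 = np.einsum("bj,bj->b", cx, cy)
    rows = np.arange(n)
    own = (rx - cx[block_of, rows]) * (ry - cy[block_of, rows])
    ex = np.add.reduceat(own, offsets[:-1])
    cross = g - t1 - t2 + t3 - ex
    nprime = n - sizes
    mean = (nprime + 1) / 2.0
    var = (nprime.astype(float) ** 2 - 1.0) / 12.0
    return (cross / nprime - mean**2) / var


def jackknife_spearman(
    x: np.ndarray, y: np.ndarray, n_blocks: int = 200
) -> JackknifeResult:
    """Spearman correlation with block-jackknife inference.

    ``x`` and ``y`` must be aligned and sorted in concatenated genomic order;
    the ``n_blocks`` contiguous blocks then respect genomic contiguity, so the
    jackknife standard error is robust to correlation between nearby SNPs.
    The p-value treats the point estimate as N(0, se^2) under the null of no
    correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be aligned 1-D arrays")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise UndefinedStatisticError("Spearman correlation of a constant is undefined")
    offsets = block_offsets(x.size, n_blocks)
    rho = float(stats.spearmanr(x, y).statistic)
    tie_free = np.unique(x).size == x.size and np.unique(y).size == y.size
    loo = (_loo_spearman_fast if tie_free else _loo_spearman_naive)(x, y, offsets)
    se, loo_mean = jackknife_se(loo)
    if se == 0.0:
        p = 1.0 if rho == 0.0 else 0.0
        return JackknifeResult(rho, loo, loo_mean, 0.0, p, n_blocks, x.size, degenerate=True)
    p = float(2.0 * stats.norm.sf(abs(rho) / se))
    return JackknifeResult(rho, loo, loo_mean, se, p, n_blocks, x.size)


@dataclass(frozen=True)
class MeanTsdsResult:
    """One-sample t-test of mean tSDS against zero."""

    mean: float
    t_statistic: float
    p_value: float
    n: int
    degenerate: bool = False

    def summary(self) -> str:
        tag = " [degenerate variance]" if self.degenerate else ""
        return (
            f"mean tSDS = {self.mean:.4g} (n = {self.n}), "
            f"t = {self.t_statistic:.4g}, p = {self.p_value:.4g}{tag}"
        )


def mean_tsds_test(values: np.ndarray) -> MeanTsdsResult:
    """Two-sided one-sample t-test of the mean tSDS at ascertained SNPs."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ParameterError("need at least 2 SNPs")
    mean = float(values.mean())
    if values.std(ddof=1) == 0.0:
        # all values identical: t undefined; report exactly-zero mean as null
        if mean == 0.0:
            return MeanTsdsResult(0.0, 0.0, 1.0, values.size, degenerate=True)
        return MeanTsdsResult(mean, np.inf if mean > 0 else -np.inf, 0.0, values.size, degenerate=True)
    res = stats.ttest_1samp(values, 0.0)
    return MeanTsdsResult(mean, float(res.statistic), float(res.pvalue), values.size)
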