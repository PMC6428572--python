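"""Minimal LD Score regression engine.

Under a polygenic architecture the expected squared (or product of)
association statistics of a SNP grows linearly with its LD Score — the sum of
squared LD with neighbouring SNPs — while confounding that hits all SNPs
equally moves the intercept but not the slope.  This module implements the
pieces of that machinery the audit pipeline needs:

* within-MAF-bin normalization of per-SNP statistics;
* normalized population frequency contrasts (e.g. a north-south axis);
* a two-step univariate regression (intercept from SNPs below a chi-square
  cutoff, slope with the intercept fixed) and a single-step bivariate
  regression of products, both with delete-one-block jackknife errors;
* genetic correlation between two GWAS;
* second-moment-versus-LD-Score regressions with display bins.

Weights default to ``1 / max(l, 1)``, the dominant heteroskedasticity term of
the standard estimator; the full iteratively-reweighted scheme is deliberately
out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._jackknife import block_offsets, block_sums, jackknife_se
from .containers import FrequencyMatrix, GwasSummary, LdBlockSet, LdScoreTable
from .exceptions import (
    DegenerateInputError,
    ParameterError,
    UndefinedStatisticError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "normalize_by_maf_bins",
    "frequency_contrast",
    "LdScoreRegression",
    "LdscFit",
    "univariate_ldsc",
    "bivariate_ldsc",
    "genetic_correlation",
    "genetic_correlation_from_arrays",
    "RgResult",
    "moment_vs_ldscore",
    "default_exclusion_regions",
    "bed_mask",
]


def normalize_by_maf_bins(
    values: np.ndarray, ref_maf: np.ndarray, bin_width: float = 0.01
) -> np.ndarray:
    """Z-score ``values`` within reference minor-allele-frequency bins.

    Removes the mechanical dependence of effect sizes, SDS and frequency
    contrasts on allele frequency before they enter LD Score regressions.
    Bins are half-open multiples of ``bin_width`` on MAF; the top bin closes
    at 0.5.
    """
    values = np.asarray(values, dtype=float)
    maf = np.asarray(ref_maf, dtype=float)
    if values.shape != maf.shape:
        raise ParameterError("values and ref_maf must be aligned")
    if ((maf < 0) | (maf > 0.5)).any():
        raise ParameterError("reference MAF must lie in [0, 0.5]")
    last = int(np.floor((0.5 - 1e-12) / bin_width))
    idx = np.minimum(np.floor(maf / bin_width).astype(int), last)
    out = np.empty_like(values)
    for k in np.unique(idx):
        sel = idx == k
        label = f"[{k * bin_width:.2f}, {(k + 1) * bin_width:.2f})"
        if sel.sum() < 2:
            raise DegenerateInputError(f"MAF bin {label} holds fewer than 2 SNPs")
        sd = values[sel].std(ddof=1)
        if sd == 0:
            raise DegenerateInputError(f"MAF bin {label} has zero variance")
        out[sel] = (values[sel] - values[sel].mean()) / sd
    return out


def frequency_contrast(
    freqs: FrequencyMatrix,
    pop_a: str,
    pop_b: str,
    ref_maf: np.ndarray | None = None,
    bin_width: float = 0.01,
) -> tuple[np.ndarray, bool]:
    """Normalized per-SNP allele-frequency contrast between two populations.

    The raw difference ``freq[pop_a] - freq[pop_b]`` on the counted allele is
    z-scored within ``bin_width`` average-MAF bins.  Returns ``(values,
    degenerate)``; when the two populations have identical frequencies at
    every SNP the contrast is identically zero and is returned as such with
    ``degenerate=True`` instead of failing inside the normalization.
    """
    for pop in (pop_a, pop_b):
        if pop not in freqs.populations:
            raise ParameterError(f"population {pop!r} not in frequency matrix")
    pa = freqs.freq[freqs.populations.index(pop_a)]
    pb = freqs.freq[freqs.populations.index(pop_b)]
    raw = pa - pb
    if not raw.any():
        logger.warning("frequency_contrast: %s and %s have identical frequencies", pop_a, pop_b)
        return np.zeros_like(raw), True
    if ref_maf is None:
        mean_p = (pa + pb) / 2.0
        ref_maf = np.minimum(mean_p, 1.0 - mean_p)
    return normalize_by_maf_bins(raw, ref_maf, bin_width=bin_width), False


@dataclass(frozen=True)
class LdscFit:
    """Results of an LD Score regression fit."""

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    p_slope: float
    p_intercept: float
    n_snps: int
    n_blocks: int
    method: str  # "univariate" | "bivariate" | "moment"
    delete_block: np.ndarray | None = None  # (b, 2): intercept, slope per loo fit
    n_samples: float | None = None

    def summary(self) -> str:
        return (
            f"LD Score regression ({self.method}, {self.n_snps} SNPs, "
            f"{self.n_blocks} blocks)\n"
            f"  slope     = {self.slope: .6g}  (SE {self.slope_se:.3g}, "
            f"p = {self.p_slope:.3g})\n"
            f"  intercept = {self.intercept: .6g}  (SE {self.intercept_se:.3g}, "
            f"p = {self.p_intercept:.3g})"
        )

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "slope": self.slope,
            "intercept": self.intercept,
            "slope_se": self.slope_se,
            "intercept_se": self.intercept_se,
            "p_slope": self.p_slope,
            "p_intercept": self.p_intercept,
            "n_snps": self.n_snps,
            "n_blocks": self.n_blocks,
        }


def _as_l2(ld) -> np.ndarray:
    if isinstance(ld, LdScoreTable):
        return ld.l2
    return np.asarray(ld, dtype=float)


class LdScoreRegression:
    """Weighted regression of a per-SNP statistic on LD Score.

    Parameters
    ----------
    y
        Per-SNP statistic (chi-square, squared normalized statistic, or a
        product of two normalized statistics), in genomic order.
    ld_scores
        Per-SNP LD Scores aligned with ``y`` (array or LdScoreTable).
    chi2_cutoff
        Two-step estimation threshold: the intercept is estimated on SNPs
        with ``y < chi2_cutoff`` (step 1), then the slope on all SNPs with
        that intercept fixed (step 2).  ``None`` disables the two-step scheme
        and fits slope and intercept jointly on all SNPs.
    n_blocks
        Number of contiguous jackknife blocks.
    weights
        Optional regression weights; defaults to ``1 / max(l, 1)``.
    method
        Label stored on the fit ("univariate", "bivariate", "moment").

    Notes
    -----
    Standard errors come from a delete-one-block jackknife in which the full
    (two-step) estimator is recomputed with each block removed; leave-one-out
    fits are obtained from per-block sufficient statistics, so the jackknife
    costs O(blocks) after one pass over the data.
    """

    def __init__(
        self,
        y: np.ndarray,
        ld_scores,
        *,
        chi2_cutoff: float | None = 30.0,
        n_blocks: int = 200,
        weights: np.ndarray | None = None,
        method: str = "univariate",
        n_samples: float | None = None,
    ) -> None:
        self.y = np.asarray(y, dtype=float)
        self.l2 = _as_l2(ld_scores)
        if self.y.shape != self.l2.shape or self.y.ndim != 1:
            raise ParameterError("y and ld_scores must be aligned 1-D arrays")
        if len(self.y) < n_blocks:
            raise ParameterError(
                f"{len(self.y)} SNPs cannot support {n_blocks} jackknife blocks"
            )
        self.chi2_cutoff = chi2_cutoff
        self.n_blocks = int(n_blocks)
        self.method = method
        self.n_samples = n_samples
        if weights is None:
            weights = 1.0 / np.maximum(self.l2, 1.0)
        self.weights = np.asarray(weights, dtype=float)
        if self.weights.shape != self.y.shape:
            raise ParameterError("weights must be aligned with y")

    # -- sufficient statistics -------------------------------------------------
    @staticmethod
    def _suff(w, x, y):
        return np.array([w.sum(), (w * x).sum(), (w * y).sum(), (w * x * x).sum(), (w * x * y).sum()])

    @staticmethod
    def _joint(s):
        """Weighted LS (intercept, slope) from sums [Sw, Swx, Swy, Swxx, Swxy]."""
        sw, swx, swy, swxx, swxy = s
        d = sw * swxx - swx * swx
        if d <= 0:
            raise DegenerateInputError("degenerate design in LD Score regression")
        slope = (sw * swxy - swx * swy) / d
        intercept = (swy * swxx - swx * swxy) / d
        return intercept, slope

    def _estimate(self, s_step1, s_all):
        if self.chi2_cutoff is None:
            return self._joint(s_all)
        intercept, _ = self._joint(s_step1)
        sw, swx, swy, swxx, swxy = s_all
        slope = (swxy - intercept * swx) / swxx
        return intercept, slope

    def fit(self) -> LdscFit:
        w, x, y = self.weights, self.l2, self.y
        offsets = block_offsets(len(y), self.n_blocks)
        if self.chi2_cutoff is not None:
            m = (y < self.chi2_cutoff).astype(float)
            wm = w * m
        else:
            wm = w
        per_block_1 = np.stack(
            [
                block_sums(wm, offsets),
                block_sums(wm * x, offsets),
                block_sums(wm * y, offsets),
                block_sums(wm * x * x, offsets),
                block_sums(wm * x * y, offsets),
            ]
        )
        per_block_all = np.stack(
            [
                block_sums(w, offsets),
                block_sums(w * x, offsets),
                block_sums(w * y, offsets),
                block_sums(w * x * x, offsets),
                block_sums(w * x * y, offsets),
            ]
        )
        tot1 = per_block_1.sum(axis=1)
        tot_all = per_block_all.sum(axis=1)
        intercept, slope = self._estimate(tot1, tot_all)
        loo = np.empty((self.n_blocks, 2))
        for i in range(self.n_blocks):
            loo[i] = self._estimate(tot1 - per_block_1[:, i], tot_all - per_block_all[:, i])
        int_se, _ = jackknife_se(loo[:, 0])
        slope_se, _ = jackknife_se(loo[:, 1])
        p_slope = float(2 * stats.norm.sf(abs(slope) / slope_se)) if slope_se > 0 else (1.0 if slope == 0 else 0.0)
        p_int = float(2 * stats.norm.sf(abs(intercept) / int_se)) if int_se > 0 else (1.0 if intercept == 0 else 0.0)
        return LdscFit(
            slope=float(slope),
            intercept=float(intercept),
            slope_se=float(slope_se),
            intercept_se=float(int_se),
            p_slope=p_slope,
            p_intercept=p_int,
            n_snps=len(y),
            n_blocks=self.n_blocks,
            method=self.method,
            delete_block=loo,
            n_samples=self.n_samples,
        )


def univariate_ldsc(
    chi2: np.ndarray,
    ld_scores,
    n_samples: float | None = None,
    chi2_cutoff: float | None = 30.0,
    n_blocks: int = 200,
) -> LdscFit:
    """Two-step univariate LD Score regression of a chi-square-like statistic."""
    return LdScoreRegression(
        chi2,
        ld_scores,
        chi2_cutoff=chi2_cutoff,
        n_blocks=n_blocks,
        method="univariate",
        n_samples=n_samples,
    ).fit()


def bivariate_ldsc(products: np.ndarray, ld_scores, n_blocks: int = 200) -> LdscFit:
    """Regression of products of two normalized statistics on LD Score.

    The intercept absorbs any LD-Score-independent shared component (sample
    overlap or shared stratification), while the slope carries the genetic
    covariance signal.  The intercept is never constrained.
    """
    return LdScoreRegression(
        products, ld_scores, chi2_cutoff=None, n_blocks=n_blocks, method="bivariate"
    ).fit()


@dataclass(frozen=True)
class RgResult:
    """Genetic correlation between two GWAS with jackknife inference."""

    rg: float
    se: float
    p_value: float
    n_snps: int
    n_blocks: int
    fit_biv: LdscFit
    fit_uni1: LdscFit
    fit_uni2: LdscFit

    def summary(self) -> str:
        return (
            f"genetic correlation rg = {self.rg:.4f} (jackknife SE {self.se:.4f}, "
            f"p = {self.p_value:.3g}; {self.n_snps} SNPs, {self.n_blocks} blocks)"
        )


def genetic_correlation_from_arrays(
    z1: np.ndarray, z2: np.ndarray, ld_scores, n_blocks: int = 200
) -> RgResult:
    """Genetic correlation from aligned per-SNP z-scores.

    ``rg = slope(z1 z2) / sqrt(slope(z1^2) slope(z2^2))``.  All three
    regressions use one matched single-step estimator on identical blocks so
    the delete-one-block rg values are internally consistent (and the
    self-correlation is exactly 1).
    """
    l2 = _as_l2(ld_scores)
    fits = [
        LdScoreRegression(v, l2, chi2_cutoff=None, n_blocks=n_blocks, method=m).fit()
        for v, m in ((z1 * z2, "bivariate"), (z1**2, "univariate"), (z2**2, "univariate"))
    ]
    biv, uni1, uni2 = fits
    if uni1.slope <= 0 or uni2.slope <= 0:
        raise UndefinedStatisticError(
            "non-positive heritability slope; genetic correlation undefined"
        )
    rg = biv.slope / np.sqrt(uni1.slope * uni2.slope)
    denom = uni1.delete_block[:, 1] * uni2.delete_block[:, 1]
    valid = denom > 0
    if valid.sum() < 2:
        raise UndefinedStatisticError("jackknife heritability slopes are non-positive")
    loo_rg = biv.delete_block[valid, 1] / np.sqrt(denom[valid])
    se, _ = jackknife_se(loo_rg)
    p = float(2 * stats.norm.sf(abs(rg) / se)) if se > 0 else (1.0 if rg == 0 else 0.0)
    return RgResult(
        rg=float(rg),
        se=float(se),
        p_value=p,
        n_snps=len(l2),
        n_blocks=n_blocks,
        fit_biv=biv,
        fit_uni1=uni1,
        fit_uni2=uni2,
    )


def genetic_correlation(
    gwas1: GwasSummary,
    gwas2: GwasSummary,
    ld: LdScoreTable,
    n_blocks: int = 200,
) -> RgResult:
    """Genetic correlation between two harmonized GWAS via LD Score regression.

    Tables are joined on SNP id with the LD Score table; z-scores are
    ``beta / se``.  The two GWAS must already be harmonized to the same
    effect allele per SNP.
    """
    merged = (
        gwas1.df[["snp", "a1", "beta", "se"]]
        .merge(gwas2.df[["snp", "a1", "beta", "se"]], on="snp", suffixes=("_1", "_2"))
        .merge(ld.df[["snp", "l2"]], on="snp")
    )
    if (merged["a1_1"] != merged["a1_2"]).any():
        raise ParameterError("GWAS tables are not harmonized to the same effect allele")
    if len(merged) < n_blocks:
        raise ParameterError("fewer overlapping SNPs than jackknife blocks")
    z1 = (merged["beta_1"] / merged["se_1"]).to_numpy(float)
    z2 = (merged["beta_2"] / merged["se_2"]).to_numpy(float)
    return genetic_correlation_from_arrays(z1, z2, merged["l2"].to_numpy(float), n_blocks)


def moment_vs_ldscore(
    y: np.ndarray, ld_scores, n_bins: int = 20, n_blocks: int = 200
) -> tuple[LdscFit, pd.DataFrame]:
    """Regression of a squared normalized statistic on LD Score, with bins.

    Returns the single-step fit plus equal-count bin means (columns
    ``bin, n, mean_l2, mean_y``) for plotting the moment-versus-LD-Score
    relationship.
    """
    l2 = _as_l2(ld_scores)
    fit = LdScoreRegression(
        y, l2, chi2_cutoff=None, n_blocks=n_blocks, method="moment"
    ).fit()
    order = np.argsort(l2, kind="mergesort")
    offsets = block_offsets(len(l2), n_bins)
    rows = []
    for i, (s, e) in enumerate(zip(offsets[:-1], offsets[1:])):
        sel = order[s:e]
        rows.append(
            {
                "bin": i,
                "n": int(e - s),
                "mean_l2": float(l2[sel].mean()),
                "mean_y": float(np.asarray(y, dtype=float)[sel].mean()),
            }
        )
    return fit, pd.DataFrame(rows)


def default_exclusion_regions() -> LdBlockSet:
    """Default regions masked from LD Score regressions.

    Long-range LD and strong-selection loci whose outlier behaviour can
    dominate genome-wide regressions: the HLA region, the LCT locus and the
    chromosome 8 inversion (GRCh37 coordinates).
    """
    return LdBlockSet(
        pd.DataFrame(
            {
                "chrom": ["2", "6", "8"],
                "start": [134_000_000, 25_000_000, 8_000_000],
                "end": [138_000_000, 34_000_000, 12_000_000],
            }
        )
    )


def bed_mask(chrom: np.ndarray, pos: np.ndarray, regions: LdBlockSet) -> np.ndarray:
    """Boolean mask of SNPs falling OUTSIDE the given regions (keep-mask)."""
    chrom = np.asarray(chrom).astype(str)
    pos = np.asarray(pos, dtype=np.int64)
    inside = np.zeros(chrom.shape, dtype=bool)
    for _, row in regions.df.iterrows():
        inside |= (chrom == str(row["chrom"])) & (pos >= row["start"]) & (pos < row["end"])
    return ~inside
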