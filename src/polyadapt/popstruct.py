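"""Polygenic scores, standardized frequencies and the co-ancestry matrix.

Under neutral drift, population allele frequencies at SNP ``l`` scatter around
their across-population mean ``eps_l`` with covariance ``eps_l (1 - eps_l) F``,
where ``F`` is the population co-ancestry matrix.  This module computes the
standardized frequency matrix ``X`` (each column ``(p - eps) / sqrt(eps (1 -
eps))``), the method-of-moments estimate ``F = X X' / (L - 1)``, and population
polygenic scores with the moments of their multivariate-normal neutral null:

    Z_m = 2 * sum_l beta_l p_{m,l}
    mu  = 2 * sum_l beta_l eps_l
    VA  = 2 * sum_l beta_l^2 eps_l (1 - eps_l)

so that ``Z ~ MVN(mu 1, 2 VA F)`` under neutrality.
"""

from __future__ import annotations

import logging

import numpy as np

from .containers import CoancestryMatrix, FrequencyMatrix, GwasSummary, PolygenicScoreSet
from .exceptions import AlignmentError, DegenerateInputError

logger = logging.getLogger(__name__)


def standardize_frequencies(
    freqs: FrequencyMatrix, return_mask: bool = False
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Standardize frequencies SNP-wise by their drift scale.

    Column ``l`` of the result is ``(p_l - eps_l) / sqrt(eps_l (1 - eps_l))``.
    SNPs monomorphic across all populations (``eps`` of exactly 0 or 1) carry
    no information about drift and are dropped with a log entry.

    Parameters
    ----------
    freqs
        Population frequency matrix.
    return_mask
        If true, also return the boolean mask of retained SNPs.

    Returns
    -------
    X : ndarray of shape (n_pops, n_kept)
        Standardized frequencies; each column sums to zero by construction.
    """
    eps = freqs.eps
    keep = (eps > 0.0) & (eps < 1.0)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "standardize_frequencies: dropped %d monomorphic SNP(s) of %d",
            n_dropped,
            freqs.n_snps,
        )
    if not keep.any():
        raise DegenerateInputError("all SNPs are monomorphic across populations")
    eps_kept = eps[keep]
    x = (freqs.freq[:, keep] - eps_kept) / np.sqrt(eps_kept * (1.0 - eps_kept))
    if return_mask:
        return x, keep
    return x


def estimate_coancestry(freqs: FrequencyMatrix) -> CoancestryMatrix:
    """Estimate the co-ancestry matrix ``F = X X' / (L - 1)``.

    Computed from the same SNP set used for the polygenic scores, which is a
    conservative choice: any selected divergence at the scored SNPs also
    inflates the null covariance.  Because each column of ``X`` is centered,
    the estimate has rank at most ``n_pops - 1`` (rows sum to ~0).
    """
    x = standardize_frequencies(freqs)
    n_used = x.shape[1]
    if n_used < 2:
        raise DegenerateInputError(
            f"need at least 2 polymorphic SNPs to estimate F, found {n_used}"
        )
    F = (x @ x.T) / (n_used - 1)
    F = (F + F.T) / 2.0  # enforce exact symmetry against float round-off
    return CoancestryMatrix(F=F, populations=freqs.populations, n_snps_used=n_used)


def polygenic_scores(effects: GwasSummary, freqs: FrequencyMatrix) -> PolygenicScoreSet:
    """Population polygenic scores and their neutral-null moments.

    The two tables must already be harmonized: matched on SNP id with the
    GWAS effect allele equal to the frequency matrix's counted allele.

    Raises
    ------
    AlignmentError
        If a SNP is missing from the frequency panel or its counted allele
        disagrees with the GWAS effect allele.
    """
    gdf = effects.df
    sdf = freqs.snps
    if len(gdf) != len(sdf) or not (gdf["snp"].to_numpy() == sdf["snp"].to_numpy()).all():
        pos = sdf.set_index("snp").index
        missing = [s for s in gdf["snp"] if s not in pos]
        if missing:
            raise AlignmentError(f"SNP {missing[0]!r} absent from frequency panel")
        raise AlignmentError("GWAS and frequency tables are not in the same SNP order")
    mismatched = gdf["a1"].to_numpy() != sdf["a1"].to_numpy()
    if mismatched.any():
        snp = gdf["snp"].to_numpy()[mismatched][0]
        raise AlignmentError(
            f"counted allele mismatch at SNP {snp!r}; harmonize the tables first"
        )
    beta = gdf["beta"].to_numpy(float)
    eps = freqs.eps
    z = 2.0 * freqs.freq @ beta
    mu = 2.0 * float(beta @ eps)
    va = 2.0 * float((beta**2) @ (eps * (1.0 - eps)))
    return PolygenicScoreSet(
        z=z, populations=freqs.populations, mu=mu, va=va, snp_count=len(gdf)
    )
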