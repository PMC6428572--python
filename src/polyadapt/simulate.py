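"""Synthetic inputs for the audit pipeline, with known ground truth.

The generator emulates the statistical structure of the pipeline's real-world
inputs without any download:

* population allele frequencies diverging from a shared ancestral frequency
  by multivariate-normal drift under a co-ancestry matrix F;
* GWAS summary statistics whose estimated effects are contaminated by a bias
  proportional to a population-structure axis (the in-silico analogue of an
  imperfectly corrected, stratified GWAS);
* SDS-like scores sharing that structure axis, with drift variance inflated
  in high-LD regions the way background selection inflates it;
* right-skewed LD Scores;
* sibling-pair designs in which within-family regression is immune to
  between-group environmental offsets while pooled regression is not.

All operations take an integer seed (or a numpy Generator); fixed seeds give
bit-identical output.  Named substreams derived from one master seed let the
pieces of a pipeline run be regenerated independently.
"""

from __future__ import annotations

import io as _io
import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Phylo
from scipy import stats

from .containers import (
    CoancestryMatrix,
    FrequencyMatrix,
    GwasSummary,
    LdScoreTable,
    SdsTable,
)
from .exceptions import AlignmentError, DegenerateInputError, ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticTruth",
    "make_truth",
    "structure_axis",
    "substream",
    "simulate_coancestry",
    "coancestry_from_newick",
    "simulate_frequencies",
    "simulate_gwas",
    "simulate_sds",
    "simulate_ld_scores",
    "simulate_bgs_divergence",
    "simulate_sib_pairs",
    "sib_regression",
    "pooled_regression",
    "SibPairData",
]

# ordered non-palindromic allele pairs (counted, other): strand-safe by default
_ALLELE_PAIRS = [
    ("A", "G"), ("G", "A"), ("A", "C"), ("C", "A"),
    ("T", "G"), ("G", "T"), ("T", "C"), ("C", "T"),
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def substream(master_seed: int, name: str) -> np.random.Generator:
    """Derive a named, reproducible RNG substream from one master seed."""
    return np.random.default_rng(
        np.random.SeedSequence((int(master_seed), zlib.crc32(name.encode()) & 0x7FFFFFFF))
    )


# --------------------------------------------------------------------------
# ground truth
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class SyntheticTruth:
    """Generative quantities behind a synthetic GWAS.

    ``true_effects`` are per-SNP additive effects on the trait (trait units
    per counted allele); ``stratification_strength`` is the coefficient b
    coupling effect-size bias to ``structure_axis`` (the standardized
    frequency contrast between two designated populations, mean 0 and unit
    variance across SNPs); ``bgs_inflation`` multiplies per-SNP drift
    variance (>= 1, as background selection only accelerates drift).
    """

    true_effects: np.ndarray
    stratification_strength: float
    structure_axis: np.ndarray
    bgs_inflation: np.ndarray
    heritability: float
    seed: int

    def __post_init__(self) -> None:
        for name in ("true_effects", "structure_axis", "bgs_inflation"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        L = self.true_effects.size
        if self.structure_axis.shape != (L,) or self.bgs_inflation.shape != (L,):
            raise ParameterError("truth arrays must share one entry per SNP")
        if (self.bgs_inflation < 1.0).any():
            raise ParameterError("bgs_inflation must be >= 1 for every SNP")
        if not 0.0 <= self.heritability <= 1.0:
            raise ParameterError("heritability must lie in [0, 1]")
        if L > 1:
            ax = self.structure_axis
            if abs(ax.mean()) > 1e-8 or abs(ax.std() - 1.0) > 1e-8:
                raise ParameterError("structure_axis must be standardized over SNPs")

    @property
    def n_snps(self) -> int:
        return self.true_effects.size


def structure_axis(
    freqs: FrequencyMatrix, pop_a: str | None = None, pop_b: str | None = None
) -> np.ndarray:
    """Standardized per-SNP frequency contrast between two populations.

    Defaults to first versus last population — the synthetic analogue of a
    north-south contrast.  The raw drift-scaled contrast is re-standardized
    to mean 0, variance 1 across SNPs.
    """
    pops = freqs.populations
    pop_a = pop_a or pops[0]
    pop_b = pop_b or pops[-1]
    pa = freqs.freq[pops.index(pop_a)]
    pb = freqs.freq[pops.index(pop_b)]
    eps = freqs.eps
    raw = (pa - pb) / np.sqrt(eps * (1.0 - eps))
    sd = raw.std()
    if sd == 0:
        raise DegenerateInputError("populations have identical frequencies at all SNPs")
    return (raw - raw.mean()) / sd


def make_truth(
    freqs: FrequencyMatrix,
    heritability: float = 0.5,
    stratification_strength: float = 0.0,
    bgs_inflation: np.ndarray | None = None,
    axis_populations: tuple[str, str] | None = None,
    seed: int = 0,
) -> SyntheticTruth:
    """Draw ground-truth effects and the structure axis for a frequency panel.

    Effects are Gaussian with per-SNP variance ``h^2 / (2 L eps (1 - eps))``
    so the L SNPs jointly contribute heritability ``h^2`` to a unit-variance
    trait.
    """
    rng = _rng(seed)
    eps = freqs.eps
    L = freqs.n_snps
    if ((eps <= 0) | (eps >= 1)).any():
        raise DegenerateInputError("truth requires polymorphic SNPs")
    sd = np.sqrt(heritability / (2.0 * L * eps * (1.0 - eps)))
    effects = rng.normal(0.0, sd)
    axis = structure_axis(freqs, *(axis_populations or (None, None)))
    if bgs_inflation is None:
        bgs_inflation = np.ones(L)
    return SyntheticTruth(
        true_effects=effects,
        stratification_strength=float(stratification_strength),
        structure_axis=axis,
        bgs_inflation=bgs_inflation,
        heritability=float(heritability),
        seed=int(seed) if not isinstance(seed, np.random.Generator) else -1,
    )


# --------------------------------------------------------------------------
# co-ancestry
# --------------------------------------------------------------------------
def simulate_coancestry(
    n_pops: int,
    model: str = "gradient",
    depth: float = 0.005,
    seed: int = 0,
    decay: float = 0.5,
) -> CoancestryMatrix:
    """Simulate a population co-ancestry matrix.

    ``gradient`` places populations on a south-to-north line with co-ancestry
    ``depth * decay**|i - j|`` (a positive-definite exponential-decay
    kernel); ``tree`` draws a random bifurcating population tree with
    exponential branch lengths of mean ``depth`` and returns the shared
    branch-length covariance.  Populations carry evenly spaced latitudes and
    longitudes along the line.
    """
    if n_pops < 2:
        raise ParameterError("need at least 2 populations")
    if depth <= 0:
        raise ParameterError("depth must be positive")
    rng = _rng(seed)
    pops = tuple(f"POP{i + 1}" for i in range(n_pops))
    lat = np.linspace(36.0, 62.0, n_pops)
    lon = np.linspace(-9.0, 26.0, n_pops)
    if model == "gradient":
        idx = np.arange(n_pops)
        F = depth * decay ** np.abs(idx[:, None] - idx[None, :])
    elif model == "tree":
        F = np.zeros((n_pops, n_pops))

        def split(leaves: np.ndarray) -> None:
            if leaves.size == 1:
                F[leaves[0], leaves[0]] += rng.exponential(depth)
                return
            k = int(rng.integers(1, leaves.size))
            left, right = leaves[:k], leaves[k:]
            for part in (left, right):
                F[np.ix_(part, part)] += rng.exponential(depth)
                if part.size > 1:
                    split(part)

        order = rng.permutation(n_pops)
        split(order)
    else:
        raise ParameterError(f"unknown co-ancestry model {model!r}")
    return CoancestryMatrix(
        F=F, populations=pops, n_snps_used=0, latitude=lat, longitude=lon
    )


def coancestry_from_newick(newick: str, populations=None) -> CoancestryMatrix:
    """Co-ancestry matrix implied by a population tree in newick format.

    ``F[i, j]`` is the summed branch length shared by the root-to-tip paths
    of populations i and j (drift accumulated before their split).
    """
    tree = Phylo.read(_io.StringIO(newick), "newick")
    leaves = tree.get_terminals()
    names = [leaf.name for leaf in leaves]
    index = {name: i for i, name in enumerate(names)}
    n = len(names)
    F = np.zeros((n, n))

    def walk(clade, inherited: float) -> None:
        length = clade.branch_length or 0.0
        total = inherited + length
        under = [index[t.name] for t in clade.get_terminals()]
        if length:
            F[np.ix_(under, under)] += length
        for child in clade.clades:
            walk(child, total)

    for child in tree.root.clades:
        walk(child, 0.0)
    if populations is not None:
        order = [names.index(p) for p in populations]
        F = F[np.ix_(order, order)]
        names = list(populations)
    return CoancestryMatrix(F=F, populations=tuple(names), n_snps_used=0)


# --------------------------------------------------------------------------
# frequencies
# --------------------------------------------------------------------------
def _snp_metadata(n_snps: int, rng: np.random.Generator) -> pd.DataFrame:
    per_chrom = int(np.ceil(n_snps / 22))
    idx = np.arange(n_snps)
    chrom = (idx // per_chrom + 1).astype(str)
    pos = (idx % per_chrom + 1) * 10_000
    pairs = rng.integers(0, len(_ALLELE_PAIRS), size=n_snps)
    a1 = np.array([_ALLELE_PAIRS[k][0] for k in pairs])
    a2 = np.array([_ALLELE_PAIRS[k][1] for k in pairs])
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "snp": [f"rs{i + 1:06d}" for i in idx],
            "a1": a1,
            "a2": a2,
            "a1_ancestral": rng.random(n_snps) < 0.5,
        }
    )


def _draw_divergence(
    eps: np.ndarray, F_sqrt: np.ndarray, scale: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    z = rng.standard_normal((F_sqrt.shape[0], eps.size))
    p = eps + scale * (F_sqrt @ z)
    return np.clip(p, 0.0, 1.0)


def _matrix_sqrt(F: np.ndarray) -> np.ndarray:
    eigvals, eigvecs = np.linalg.eigh(F)
    eigvals = np.clip(eigvals, 0.0, None)
    return eigvecs * np.sqrt(eigvals)


def simulate_frequencies(
    F: CoancestryMatrix,
    n_snps: int,
    ancestral_maf_range: tuple[float, float] = (0.10, 0.49),
    seed: int = 0,
    max_retries: int = 10,
) -> FrequencyMatrix:
    """Draw population frequencies under multivariate-normal drift.

    For each SNP, an ancestral frequency ``eps`` is drawn uniformly in
    ``ancestral_maf_range`` and population frequencies follow
    ``MVN(eps 1, eps (1 - eps) F)``, clamped to [0, 1].  SNPs that end up
    fixed in every population are redrawn up to ``max_retries`` times, then
    dropped with a log record.
    """
    lo, hi = ancestral_maf_range
    if not (0.0 < lo < 0.5 and 0.0 < hi < 0.5 and lo <= hi):
        raise ParameterError("ancestral MAF bounds must satisfy 0 < lo <= hi < 0.5")
    if n_snps < 1:
        raise ParameterError("n_snps must be positive")
    rng = _rng(seed)
    eps = rng.uniform(lo, hi, size=n_snps)
    F_sqrt = _matrix_sqrt(F.F)
    p = _draw_divergence(eps, F_sqrt, np.sqrt(eps * (1.0 - eps)), rng)
    for _ in range(max_retries):
        fixed = np.nonzero((p == 0.0).all(axis=0) | (p == 1.0).all(axis=0))[0]
        if fixed.size == 0:
            break
        eps_f = eps[fixed]
        p[:, fixed] = _draw_divergence(eps_f, F_sqrt, np.sqrt(eps_f * (1.0 - eps_f)), rng)
    fixed = (p == 0.0).all(axis=0) | (p == 1.0).all(axis=0)
    snps = _snp_metadata(n_snps, rng)
    if fixed.any():
        logger.info(
            "simulate_frequencies: dropped %d SNP(s) still fixed after %d redraws",
            int(fixed.sum()),
            max_retries,
        )
        p = p[:, ~fixed]
        eps = eps[~fixed]
        snps = snps.loc[~fixed].reset_index(drop=True)
    if p.shape[1] == 0:
        raise DegenerateInputError("no polymorphic SNPs produced; increase drift or MAF range")
    return FrequencyMatrix(
        freq=p,
        populations=F.populations,
        snps=snps,
        latitude=F.latitude,
        longitude=F.longitude,
    )


def simulate_bgs_divergence(
    freqs: FrequencyMatrix,
    F: CoancestryMatrix,
    ld_scores: LdScoreTable,
    inflation_fn,
    seed: int = 0,
    max_retries: int = 10,
) -> FrequencyMatrix:
    """Redraw divergence with LD-Score-dependent drift inflation.

    Background selection purges linked neutral diversity, which acts like a
    locally increased rate of drift in high-LD regions.  Here the per-SNP
    drift variance is multiplied by ``inflation_fn(l2) >= 1`` while the
    ancestral frequencies and SNP metadata of ``freqs`` are kept.
    """
    if len(ld_scores) != freqs.n_snps:
        raise AlignmentError("LD Score table not aligned with frequency matrix")
    infl = np.asarray(inflation_fn(ld_scores.l2), dtype=float)
    if infl.shape != (freqs.n_snps,):
        raise ParameterError("inflation_fn must return one value per SNP")
    if (infl < 1.0).any():
        raise ParameterError("inflation_fn must be >= 1 everywhere")
    rng = _rng(seed)
    eps = freqs.eps
    F_sqrt = _matrix_sqrt(F.F)
    scale = np.sqrt(eps * (1.0 - eps) * infl)
    p = _draw_divergence(eps, F_sqrt, scale, rng)
    for _ in range(max_retries):
        fixed = np.nonzero((p == 0.0).all(axis=0) | (p == 1.0).all(axis=0))[0]
        if fixed.size == 0:
            break
        p[:, fixed] = _draw_divergence(eps[fixed], F_sqrt, scale[fixed], rng)
    fixed = (p == 0.0).all(axis=0) | (p == 1.0).all(axis=0)
    snps = freqs.snps
    if fixed.any():
        logger.info(
            "simulate_bgs_divergence: dropped %d SNP(s) fixed after %d redraws",
            int(fixed.sum()),
            max_retries,
        )
        p = p[:, ~fixed]
        snps = snps.loc[~fixed].reset_index(drop=True)
    return FrequencyMatrix(
        freq=p,
        populations=freqs.populations,
        snps=snps,
        latitude=freqs.latitude,
        longitude=freqs.longitude,
    )


# --------------------------------------------------------------------------
# GWAS and SDS
# --------------------------------------------------------------------------
def simulate_gwas(
    truth: SyntheticTruth,
    freqs: FrequencyMatrix,
    n_samples: int,
    seed: int = 0,
) -> GwasSummary:
    """Simulate GWAS summary statistics with structure-correlated bias.

    The estimated effect is ``beta = true + b * a + e`` with ``b`` the
    stratification strength, ``a`` the structure axis, and sampling noise
    ``e ~ N(0, 1 / (2 N p (1 - p)))`` — the standard approximation for the
    variance of a marginal GWAS estimate at mean frequency ``p``.
    """
    if n_samples <= 0:
        raise ParameterError("n_samples must be positive")
    if truth.n_snps != freqs.n_snps:
        raise AlignmentError("truth and frequency matrix do not share a SNP set")
    rng = _rng(seed)
    eps = freqs.eps
    se = 1.0 / np.sqrt(2.0 * n_samples * eps * (1.0 - eps))
    beta = (
        truth.true_effects
        + truth.stratification_strength * truth.structure_axis
        + rng.normal(0.0, se)
    )
    pvals = np.maximum(2.0 * stats.norm.sf(np.abs(beta) / se), np.finfo(float).tiny)
    df = freqs.snps[["snp", "chrom", "pos", "a1", "a2"]].copy()
    df["beta"] = beta
    df["se"] = se
    df["p"] = pvals
    df["n"] = int(n_samples)
    return GwasSummary(df=df.reset_index(drop=True))


def simulate_sds(
    freqs: FrequencyMatrix,
    truth: SyntheticTruth,
    ld_scores: LdScoreTable,
    axis_coupling: float = 0.0,
    seed: int = 0,
) -> SdsTable:
    """Simulate raw SDS-like scores sharing the GWAS structure axis.

    On the counted-allele scale the score is ``axis_coupling * a + e`` with
    ``Var(e) = bgs_inflation``: recent frequency change shares the structure
    axis with strength ``axis_coupling`` and its drift component grows with
    the strength of background selection.  Scores are then re-signed to the
    derived allele (the convention of published SDS) and are NOT
    standardized — that is the tSDS module's job.
    """
    if truth.n_snps != freqs.n_snps or len(ld_scores) != freqs.n_snps:
        raise AlignmentError("freqs, truth and ld_scores must share a SNP set")
    rng = _rng(seed)
    raw_counted = axis_coupling * truth.structure_axis + rng.normal(
        0.0, np.sqrt(truth.bgs_inflation)
    )
    snps = freqs.snps
    a1_anc = snps["a1_ancestral"].to_numpy(bool)
    aa = np.where(a1_anc, snps["a1"], snps["a2"])
    da = np.where(a1_anc, snps["a2"], snps["a1"])
    # counted allele is ancestral => derived is the other allele => flip sign
    sds = np.where(a1_anc, -raw_counted, raw_counted)
    eps = freqs.eps
    daf = np.where(a1_anc, 1.0 - eps, eps)
    return SdsTable(
        df=pd.DataFrame(
            {
                "chrom": snps["chrom"],
                "pos": snps["pos"],
                "snp": snps["snp"],
                "aa": aa,
                "da": da,
                "daf": daf,
                "sds": sds,
            }
        ).reset_index(drop=True)
    )


def simulate_ld_scores(
    n_snps: int | None = None,
    shape: float = 2.0,
    scale: float = 50.0,
    seed: int = 0,
    freqs: FrequencyMatrix | None = None,
) -> LdScoreTable:
    """Simulate positive, right-skewed LD Scores: ``l2 = 1 + Gamma(shape, scale)``.

    With the defaults the mean is ``1 + shape * scale = 101``, matching the
    scale of genome-wide human LD Scores.  If a frequency matrix is supplied
    its SNP metadata (and mean-frequency MAF) are reused so the table aligns
    with the rest of a simulated dataset.
    """
    rng = _rng(seed)
    if freqs is not None:
        n_snps = freqs.n_snps
    if n_snps is None or n_snps < 1:
        raise ParameterError("n_snps must be positive (or pass freqs)")
    l2 = 1.0 + rng.gamma(shape, scale, size=n_snps)
    if freqs is not None:
        eps = freqs.eps
        df = pd.DataFrame(
            {
                "chrom": freqs.snps["chrom"],
                "snp": freqs.snps["snp"],
                "pos": freqs.snps["pos"],
                "l2": l2,
                "maf": np.minimum(eps, 1.0 - eps),
            }
        )
    else:
        meta = _snp_metadata(n_snps, rng)
        df = pd.DataFrame(
            {"chrom": meta["chrom"], "snp": meta["snp"], "pos": meta["pos"], "l2": l2}
        )
    return LdScoreTable(df=df.reset_index(drop=True))


# --------------------------------------------------------------------------
# sibling pairs
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class SibPairData:
    """Genotypes and phenotypes for sibling pairs from labeled subpopulations."""

    geno_sib1: np.ndarray  # (n_families, n_snps) allele counts
    geno_sib2: np.ndarray
    pheno_sib1: np.ndarray
    pheno_sib2: np.ndarray
    geno_mother: np.ndarray
    geno_father: np.ndarray
    group: np.ndarray  # 0/1 subpopulation label per family
    group_offsets: np.ndarray  # per-group environmental phenotype offset

    @property
    def n_families(self) -> int:
        return self.geno_sib1.shape[0]

    @property
    def n_snps(self) -> int:
        return self.geno_sib1.shape[1]


def simulate_sib_pairs(
    n_families: int,
    truth: SyntheticTruth,
    env_strat: float = 0.0,
    group_freq_contrast: float = 0.2,
    group_freqs: np.ndarray | None = None,
    residual_sd: float = 1.0,
    seed: int = 0,
) -> SibPairData:
    """Simulate sibling pairs under Mendelian transmission with group offsets.

    Families are split evenly between two subpopulations whose allele
    frequencies differ by ``group_freq_contrast`` (or explicit ``group_freqs``
    of shape ``(2, n_snps)``).  Each sib inherits one allele from each parent;
    phenotype = genotype . true_effects + group offset + noise, where the two
    group offsets are ``-env_strat / 2`` and ``+env_strat / 2``.
    """
    if n_families < 2:
        raise ParameterError("need at least 2 families")
    rng = _rng(seed)
    L = truth.n_snps
    if group_freqs is None:
        base = 0.5
        group_freqs = np.vstack(
            [
                np.full(L, base - group_freq_contrast / 2.0),
                np.full(L, base + group_freq_contrast / 2.0),
            ]
        )
    group_freqs = np.asarray(group_freqs, dtype=float)
    if group_freqs.shape != (2, L):
        raise ParameterError("group_freqs must have shape (2, n_snps)")
    group = (np.arange(n_families) % 2).astype(int)
    p = group_freqs[group]  # (n_families, L)
    mother = rng.binomial(2, p)
    father = rng.binomial(2, p)

    def transmit(parent):
        return rng.binomial(1, parent / 2.0)

    sib1 = transmit(mother) + transmit(father)
    sib2 = transmit(mother) + transmit(father)
    offsets = np.array([-env_strat / 2.0, env_strat / 2.0])
    mean1 = sib1 @ truth.true_effects + offsets[group]
    mean2 = sib2 @ truth.true_effects + offsets[group]
    pheno1 = mean1 + rng.normal(0.0, residual_sd, size=n_families)
    pheno2 = mean2 + rng.normal(0.0, residual_sd, size=n_families)
    return SibPairData(
        geno_sib1=sib1,
        geno_sib2=sib2,
        pheno_sib1=pheno1,
        pheno_sib2=pheno2,
        geno_mother=mother,
        geno_father=father,
        group=group,
        group_offsets=offsets,
    )


def sib_regression(sib: SibPairData) -> pd.DataFrame:
    """Within-pair regression: phenotype difference on allele-count difference.

    Immune to any between-family (e.g. group-level environmental)
    confounding because differencing removes everything shared by the pair.
    Returns per-SNP ``beta, se, p, n_informative``; SNPs with no
    within-family genotype variance are flagged missing (NaN estimates).
    """
    dg = (sib.geno_sib1 - sib.geno_sib2).astype(float)
    dy = sib.pheno_sib1 - sib.pheno_sib2
    n = sib.n_families
    sxx = (dg**2).sum(axis=0)
    sxy = dg.T @ dy
    informative = sxx > 0
    beta = np.full(sib.n_snps, np.nan)
    se = np.full(sib.n_snps, np.nan)
    pvals = np.full(sib.n_snps, np.nan)
    beta[informative] = sxy[informative] / sxx[informative]
    resid_ss = (dy**2).sum() - beta[informative] ** 2 * sxx[informative]
    dof = max(n - 1, 1)
    sigma2 = np.maximum(resid_ss, 0.0) / dof
    se[informative] = np.sqrt(sigma2 / sxx[informative])
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta[informative] / se[informative]
    pvals[informative] = 2.0 * stats.t.sf(np.abs(tvals), dof)
    n_info = informative * (dg != 0).sum(axis=0)
    return pd.DataFrame(
        {
            "beta": beta,
            "se": se,
            "p": pvals,
            "n_informative": n_info,
            "missing": ~informative,
        }
    )


def pooled_regression(sib: SibPairData) -> pd.DataFrame:
    """Naive pooled per-SNP OLS over all individuals, ignoring family and group.

    The stratification-vulnerable comparator for :func:`sib_regression`:
    any correlation between group allele frequencies and group phenotype
    offsets biases these estimates.
    """
    g = np.vstack([sib.geno_sib1, sib.geno_sib2]).astype(float)
    y = np.concatenate([sib.pheno_sib1, sib.pheno_sib2])
    n = y.size
    gc = g - g.mean(axis=0)
    yc = y - y.mean()
    sxx = (gc**2).sum(axis=0)
    valid = sxx > 0
    beta = np.full(sib.n_snps, np.nan)
    beta[valid] = (gc.T @ yc)[valid] / sxx[valid]
    resid_ss = (yc**2).sum() - beta[valid] ** 2 * sxx[valid]
    sigma2 = np.maximum(resid_ss, 0.0) / max(n - 2, 1)
    se = np.full(sib.n_snps, np.nan)
    se[valid] = np.sqrt(sigma2 / sxx[valid])
    pvals = np.full(sib.n_snps, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta[valid] / se[valid]
    pvals[valid] = 2.0 * stats.t.sf(np.abs(tvals), max(n - 2, 1))
    return pd.DataFrame({"beta": beta, "se": se, "p": pvals, "missing": ~valid})
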