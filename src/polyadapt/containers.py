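"""Core data containers.

Tabular inputs (GWAS summary statistics, SDS tables, LD Scores, LD blocks) are
thin validated wrappers around :class:`pandas.DataFrame` with fixed column
names; matrix-shaped objects (population frequencies, co-ancestry) carry numpy
arrays plus ordered population labels.  All containers validate their
invariants at construction time and are treated as immutable by convention:
operations return new containers rather than mutating in place.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, FormatError, ParameterError

#: canonical column order for GWAS summary statistics
GWAS_COLUMNS = ["snp", "chrom", "pos", "a1", "a2", "beta", "se", "p", "n"]
#: canonical column order for SDS tables (a1-free: polarity is ancestral/derived)
SDS_COLUMNS = ["chrom", "pos", "snp", "aa", "da", "daf", "sds"]
#: canonical column order for LD Score tables (`.l2.ldscore` layout + optional MAF)
LDSCORE_COLUMNS = ["chrom", "snp", "pos", "l2"]


def _require_columns(df: pd.DataFrame, columns: Sequence[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{what} is missing required column(s): {', '.join(missing)}")


@dataclass(frozen=True)
class GwasSummary:
    """Per-SNP GWAS effect estimates.

    ``a1`` is the effect (counted) allele: ``beta`` is the estimated additive
    effect, in trait units, per copy of ``a1``.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        _require_columns(self.df, GWAS_COLUMNS, "GWAS summary table")
        df = self.df
        if df["snp"].duplicated().any():
            dup = df.loc[df["snp"].duplicated(), "snp"].iloc[0]
            raise FormatError(f"duplicate SNP identifier in GWAS table: {dup!r}")
        if ((df["p"] <= 0) | (df["p"] > 1)).any():
            raise FormatError("GWAS p-values must lie in (0, 1]")
        if (df["se"] <= 0).any():
            raise FormatError("GWAS standard errors must be positive")
        if (df["a1"] == df["a2"]).any():
            raise FormatError("effect and other allele must differ")

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "GwasSummary":
        return cls(df.reset_index(drop=True)[GWAS_COLUMNS].copy())

    def indexed(self) -> pd.DataFrame:
        return self.df.set_index("snp", drop=False)


@dataclass(frozen=True)
class SdsTable:
    """Per-SNP Singleton Density Scores with ancestral/derived polarity.

    ``sds`` is polarized to the derived allele (``da``).  ``daf`` is the
    derived-allele frequency in the reference sample.  The optional
    ``sds_std`` column is filled by within-MAF-bin standardization.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        _require_columns(self.df, SDS_COLUMNS, "SDS table")
        df = self.df
        if (df["aa"] == df["da"]).any():
            raise FormatError("ancestral and derived allele must differ")
        if ((df["daf"] < 0) | (df["daf"] > 1)).any():
            raise FormatError("derived-allele frequencies must lie in [0, 1]")
        if df["snp"].duplicated().any():
            raise FormatError("duplicate SNP identifier in SDS table")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def maf(self) -> np.ndarray:
        """Minor-allele frequency implied by the derived-allele frequency."""
        daf = self.df["daf"].to_numpy(float)
        return np.minimum(daf, 1.0 - daf)


@dataclass(frozen=True)
class LdScoreTable:
    """Per-SNP LD Scores, optionally with a reference minor-allele frequency."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        _require_columns(self.df, LDSCORE_COLUMNS, "LD Score table")
        if (self.df["l2"] < 0).any():
            raise FormatError("LD Scores must be non-negative")
        if self.df["snp"].duplicated().any():
            raise FormatError("duplicate SNP identifier in LD Score table")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def l2(self) -> np.ndarray:
        return self.df["l2"].to_numpy(float)


@dataclass(frozen=True)
class LdBlockSet:
    """Ordered, non-overlapping genomic intervals (0-based, half-open)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        _require_columns(self.df, ["chrom", "start", "end"], "LD block set")
        df = self.df
        if (df["start"] >= df["end"]).any():
            raise FormatError("LD blocks must satisfy start < end")
        for chrom, grp in df.groupby("chrom", sort=False):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            if not (np.diff(starts) > 0).all():
                raise FormatError(f"LD blocks on {chrom} are not sorted")
            if (starts[1:] < ends[:-1]).any():
                raise FormatError(f"LD blocks on {chrom} overlap")

    def __len__(self) -> int:
        return len(self.df)


@dataclass(frozen=True)
class FrequencyMatrix:
    """Allele frequencies of the counted allele across populations.

    Parameters
    ----------
    freq
        Array of shape ``(n_pops, n_snps)``; entry ``(m, l)`` is the frequency
        of the counted allele ``a1`` of SNP ``l`` in population ``m``.
    populations
        Ordered population labels.
    snps
        Per-SNP metadata with columns ``chrom, pos, snp, a1, a2`` and an
        optional boolean ``a1_ancestral`` flag.
    latitude, longitude
        Optional per-population coordinates in degrees.
    """

    freq: np.ndarray
    populations: tuple[str, ...]
    snps: pd.DataFrame
    latitude: np.ndarray | None = None
    longitude: np.ndarray | None = None

    def __post_init__(self) -> None:
        freq = np.asarray(self.freq, dtype=float)
        object.__setattr__(self, "freq", freq)
        object.__setattr__(self, "populations", tuple(self.populations))
        if freq.ndim != 2:
            raise ParameterError("freq must be a 2-D (populations x SNPs) array")
        if freq.shape[0] != len(self.populations):
            raise ParameterError("freq row count must match number of populations")
        if freq.shape[1] != len(self.snps):
            raise ParameterError("freq column count must match SNP table length")
        if ((freq < 0) | (freq > 1)).any():
            raise ParameterError("allele frequencies must lie in [0, 1]")
        _require_columns(self.snps, ["chrom", "pos", "snp", "a1", "a2"], "SNP table")
        if self.snps["snp"].duplicated().any():
            raise FormatError("duplicate SNP identifiers in frequency matrix")
        for coord in ("latitude", "longitude"):
            val = getattr(self, coord)
            if val is not None:
                val = np.asarray(val, dtype=float)
                if val.shape != (len(self.populations),):
                    raise ParameterError(f"{coord} must have one value per population")
                object.__setattr__(self, coord, val)

    @property
    def n_pops(self) -> int:
        return self.freq.shape[0]

    @property
    def n_snps(self) -> int:
        return self.freq.shape[1]

    @property
    def eps(self) -> np.ndarray:
        """Per-SNP mean frequency across populations (unweighted)."""
        return self.freq.mean(axis=0)

    def subset(self, mask: np.ndarray) -> "FrequencyMatrix":
        """Restrict to the SNPs selected by a boolean mask or integer index."""
        mask = np.asarray(mask)
        return replace(
            self,
            freq=self.freq[:, mask],
            snps=self.snps.iloc[mask].reset_index(drop=True)
            if mask.dtype != bool
            else self.snps.loc[mask].reset_index(drop=True),
        )

    def flip_alleles(self, mask: np.ndarray) -> "FrequencyMatrix":
        """Swap counted and other allele for the masked SNPs (p -> 1 - p)."""
        mask = np.asarray(mask, dtype=bool)
        freq = self.freq.copy()
        freq[:, mask] = 1.0 - freq[:, mask]
        snps = self.snps.copy()
        a1 = snps["a1"].copy()
        snps.loc[mask, "a1"] = snps.loc[mask, "a2"]
        snps.loc[mask, "a2"] = a1[mask]
        if "a1_ancestral" in snps.columns:
            snps.loc[mask, "a1_ancestral"] = ~snps.loc[mask, "a1_ancestral"].astype(bool)
        return replace(self, freq=freq, snps=snps)

    def maf(self, population: str) -> np.ndarray:
        """Minor-allele frequency within one population."""
        if population not in self.populations:
            raise ParameterError(f"unknown population {population!r}")
        p = self.freq[self.populations.index(population)]
        return np.minimum(p, 1.0 - p)


@dataclass(frozen=True)
class CoancestryMatrix:
    """Population co-ancestry matrix F (covariance of standardized frequencies).

    Simulated matrices may carry per-population coordinates so downstream
    frequency draws inherit a geography for the cline tests.
    """

    F: np.ndarray
    populations: tuple[str, ...]
    n_snps_used: int = 0
    latitude: np.ndarray | None = None
    longitude: np.ndarray | None = None

    #: eigenvalues above -PSD_TOL are accepted as numerically non-negative
    PSD_TOL = 1e-8

    def __post_init__(self) -> None:
        F = np.asarray(self.F, dtype=float)
        object.__setattr__(self, "F", F)
        object.__setattr__(self, "populations", tuple(self.populations))
        if F.ndim != 2 or F.shape[0] != F.shape[1]:
            raise ParameterError("F must be a square matrix")
        if F.shape[0] != len(self.populations):
            raise ParameterError("F dimension must match number of populations")
        if not np.allclose(F, F.T, atol=1e-10, rtol=0):
            raise ParameterError("F must be symmetric")
        eigvals = np.linalg.eigvalsh(F)
        if eigvals.size and eigvals[0] < -self.PSD_TOL * max(1.0, eigvals[-1]):
            raise ParameterError("F must be positive semi-definite")
        for coord in ("latitude", "longitude"):
            val = getattr(self, coord)
            if val is not None:
                val = np.asarray(val, dtype=float)
                if val.shape != (len(self.populations),):
                    raise ParameterError(f"{coord} must have one value per population")
                object.__setattr__(self, coord, val)

    @property
    def n_pops(self) -> int:
        return self.F.shape[0]


@dataclass(frozen=True)
class PolygenicScoreSet:
    """Population polygenic scores with their neutral-model moments.

    ``z[m] = 2 * sum_l beta_l * p[m, l]`` (trait units), ``mu`` its expectation
    under the null and ``va`` the additive-variance scale entering the null
    covariance ``2 * va * F``.
    """

    z: np.ndarray
    populations: tuple[str, ...]
    mu: float
    va: float
    snp_count: int

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "populations", tuple(self.populations))
        if z.shape != (len(self.populations),):
            raise ParameterError("one score per population required")
        if self.va < 0:
            raise ParameterError("VA must be non-negative")

    @property
    def n_pops(self) -> int:
        return self.z.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"population": self.populations, "score": self.z})


def check_aligned(ids_a: pd.Series, ids_b: pd.Series, what: str) -> None:
    """Raise :class:`AlignmentError` unless both id sequences are identical."""
    if len(ids_a) != len(ids_b) or not (ids_a.to_numpy() == ids_b.to_numpy()).all():
        raise AlignmentError(f"{what}: SNP sets are not aligned")
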