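"""Readers, writers and table-reconciliation utilities.

File formats (all plain text):

* GWAS summary statistics — tab-delimited with header
  ``SNP CHR POS A1 A2 BETA SE P N`` (``A1`` is the effect allele); other
  layouts are mapped through a ``dialect`` dict.
* Frequency table — tab-delimited ``CHR POS SNP A1 A2`` plus one column per
  population; population latitude/longitude live in a side YAML file.
* SDS table — tab-delimited ``CHR POS ID AA DA DAF SDS`` (the published SDS
  layout).
* LD Scores — whitespace-delimited ``CHR SNP BP L2`` with optional ``MAF``
  (the ``.l2.ldscore`` layout).
* LD blocks and masks — BED3, 0-based half-open.

Coordinates are kept 0-based half-open internally; VCF positions are
converted on read.  Every filtering step logs how many rows entered, how
many left, and why.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import (
    FrequencyMatrix,
    GwasSummary,
    LdBlockSet,
    LdScoreTable,
    SdsTable,
)
from .exceptions import DegenerateInputError, FormatError, ParameterError

logger = logging.getLogger(__name__)

GWAS_FILE_COLUMNS = {
    "snp": "SNP",
    "chrom": "CHR",
    "pos": "POS",
    "a1": "A1",
    "a2": "A2",
    "beta": "BETA",
    "se": "SE",
    "p": "P",
    "n": "N",
}

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


# --------------------------------------------------------------------------
# GWAS summary statistics
# --------------------------------------------------------------------------
def read_summary_stats(path, dialect: dict | None = None) -> GwasSummary:
    """Read a GWAS summary-statistic TSV.

    ``dialect`` maps canonical field names (``snp, chrom, pos, a1, a2, beta,
    se, p, n``) to the file's column headers; unspecified fields use the
    default layout.  Malformed rows (missing values, p outside (0, 1],
    non-positive SE, identical alleles) are dropped with a logged count.
    """
    colmap = dict(GWAS_FILE_COLUMNS)
    if dialect:
        colmap.update(dialect)
    try:
        raw = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty summary-statistic file") from None
    missing = [v for v in colmap.values() if v not in raw.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {', '.join(missing)}")
    df = pd.DataFrame({k: raw[v] for k, v in colmap.items()})
    n_in = len(df)
    for col in ("pos", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("beta", "se", "p"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    ok = (
        df[["snp", "chrom", "a1", "a2"]].notna().all(axis=1)
        & df[["pos", "beta", "se", "p", "n"]].notna().all(axis=1)
        & (df["p"] > 0)
        & (df["p"] <= 1)
        & (df["se"] > 0)
        & (df["a1"] != df["a2"])
    )
    if (~ok).any():
        logger.info(
            "read_summary_stats: dropped %d malformed row(s) of %d", int((~ok).sum()), n_in
        )
    df = df.loc[ok].reset_index(drop=True)
    if df.empty:
        raise FormatError(f"{path}: no valid rows")
    df["pos"] = df["pos"].astype(np.int64)
    df["n"] = df["n"].astype(np.int64)
    return GwasSummary.from_dataframe(df)


def write_summary_stats(gwas: GwasSummary, path) -> None:
    out = gwas.df.rename(columns=GWAS_FILE_COLUMNS)
    out.to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# frequency tables
# --------------------------------------------------------------------------
def read_frequency_table(path, metadata_path=None) -> FrequencyMatrix:
    """Read a population frequency TSV (+ optional population metadata YAML)."""
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str})
    fixed = ["CHR", "POS", "SNP", "A1", "A2"]
    missing = [c for c in fixed if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    pops = [c for c in df.columns if c not in fixed]
    if not pops:
        raise FormatError(f"{path}: no population columns")
    snps = df[fixed].rename(
        columns={"CHR": "chrom", "POS": "pos", "SNP": "snp", "A1": "a1", "A2": "a2"}
    )
    lat = lon = None
    if metadata_path is not None:
        meta = yaml.safe_load(Path(metadata_path).read_text())
        popmeta = meta.get("populations", {})
        lat = np.array([popmeta.get(p, {}).get("latitude", np.nan) for p in pops])
        lon = np.array([popmeta.get(p, {}).get("longitude", np.nan) for p in pops])
    return FrequencyMatrix(
        freq=df[pops].to_numpy(float).T,
        populations=tuple(pops),
        snps=snps.reset_index(drop=True),
        latitude=lat,
        longitude=lon,
    )


def write_frequency_table(freqs: FrequencyMatrix, path, metadata_path=None) -> None:
    out = freqs.snps[["chrom", "pos", "snp", "a1", "a2"]].rename(
        columns={"chrom": "CHR", "pos": "POS", "snp": "SNP", "a1": "A1", "a2": "A2"}
    )
    for i, pop in enumerate(freqs.populations):
        out[pop] = freqs.freq[i]
    out.to_csv(path, sep="\t", index=False)
    if metadata_path is not None:
        meta = {"populations": {}}
        for i, pop in enumerate(freqs.populations):
            entry = {}
            if freqs.latitude is not None:
                entry["latitude"] = float(freqs.latitude[i])
            if freqs.longitude is not None:
                entry["longitude"] = float(freqs.longitude[i])
            meta["populations"][pop] = entry
        Path(metadata_path).write_text(yaml.safe_dump(meta))


# --------------------------------------------------------------------------
# SDS / LD Score / BED
# --------------------------------------------------------------------------
def read_sds_table(path) -> SdsTable:
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str})
    cols = ["CHR", "POS", "ID", "AA", "DA", "DAF", "SDS"]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    out = df[cols].rename(
        columns={
            "CHR": "chrom", "POS": "pos", "ID": "snp",
            "AA": "aa", "DA": "da", "DAF": "daf", "SDS": "sds",
        }
    )
    return SdsTable(df=out.reset_index(drop=True))


def write_sds_table(sds: SdsTable, path) -> None:
    out = sds.df[["chrom", "pos", "snp", "aa", "da", "daf", "sds"]].rename(
        columns={
            "chrom": "CHR", "pos": "POS", "snp": "ID",
            "aa": "AA", "da": "DA", "daf": "DAF", "sds": "SDS",
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_ld_scores(path) -> LdScoreTable:
    df = pd.read_csv(path, sep=r"\s+", dtype={"CHR": str})
    cols = ["CHR", "SNP", "BP", "L2"]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    out = df[cols].rename(columns={"CHR": "chrom", "SNP": "snp", "BP": "pos", "L2": "l2"})
    if "MAF" in df.columns:
        out["maf"] = df["MAF"]
    return LdScoreTable(df=out.reset_index(drop=True))


def write_ld_scores(ld: LdScoreTable, path) -> None:
    out = ld.df.rename(
        columns={"chrom": "CHR", "snp": "SNP", "pos": "BP", "l2": "L2", "maf": "MAF"}
    )
    out.to_csv(path, sep="\t", index=False)


def read_bed(path) -> LdBlockSet:
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2], names=["chrom", "start", "end"],
        dtype={"chrom": str},
    )
    df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    return LdBlockSet(df=df)


def write_bed(blocks: LdBlockSet, path) -> None:
    blocks.df.to_csv(path, sep="\t", header=False, index=False)


# --------------------------------------------------------------------------
# VCF frequencies
# --------------------------------------------------------------------------
def read_frequencies_vcf(path, sample_to_population: dict) -> FrequencyMatrix:
    """Population ALT-allele frequencies from a VCF's GT fields.

    The counted allele (``a1``) is the ALT allele; per population,
    frequency = ALT allele count / (2 x non-missing diploids).  Non-biallelic
    or non-SNP records are skipped with a log entry, as are sites with no
    genotyped sample in some population.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = vcf.samples
    pops: list[str] = []
    for s in samples:
        pop = sample_to_population.get(s)
        if pop is not None and pop not in pops:
            pops.append(pop)
    if not pops:
        raise ParameterError("no VCF sample maps to a population")
    pop_masks = {
        p: np.array([sample_to_population.get(s) == p for s in samples]) for p in pops
    }
    if any(not m.any() for m in pop_masks.values()):
        empty = [p for p, m in pop_masks.items() if not m.any()]
        raise DegenerateInputError(f"population(s) with no samples: {', '.join(empty)}")
    rows, freqs = [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        gts = np.asarray(var.gt_types)  # 0=hom-ref, 1=het, 2=hom-alt, 3=missing
        per_pop = []
        usable = True
        for p in pops:
            g = gts[pop_masks[p]]
            called = g != 3
            if not called.any():
                usable = False
                break
            per_pop.append(g[called].sum() / (2.0 * called.sum()))
        if not usable:
            n_skipped += 1
            continue
        rows.append(
            {
                "chrom": str(var.CHROM),
                "pos": int(var.POS) - 1,  # to 0-based
                "snp": var.ID or f"{var.CHROM}:{var.POS}",
                "a1": var.ALT[0],
                "a2": var.REF,
            }
        )
        freqs.append(per_pop)
    if n_skipped:
        logger.info("read_frequencies_vcf: skipped %d unusable site(s)", n_skipped)
    if not rows:
        raise DegenerateInputError(f"{path}: no usable biallelic SNPs")
    return FrequencyMatrix(
        freq=np.array(freqs, dtype=float).T,
        populations=tuple(pops),
        snps=pd.DataFrame(rows),
    )


# --------------------------------------------------------------------------
# harmonization
# --------------------------------------------------------------------------
def _is_palindromic(a1, a2):
    return a2 == np.vectorize(_COMPLEMENT.get)(a1)


def harmonize(
    gwas: GwasSummary,
    other: pd.DataFrame,
    ambiguity_policy: str = "palindromic",
    flip_cols: tuple[str, ...] = ("beta",),
) -> pd.DataFrame:
    """Join a second allele-keyed table onto a GWAS, reconciling alleles.

    Rows are joined on SNP id.  Where the other table's allele labels are
    swapped relative to the GWAS effect/other alleles, its signed columns
    (``flip_cols``) are negated; irreconcilable allele pairs are dropped and
    logged.  ``ambiguity_policy`` removes strand-ambiguous SNPs first:

    * ``"palindromic"`` (default) — drop A/T and C/G pairs, the standard
      strand-safety rule;
    * ``"paper-literal"`` — drop A/G and C/T pairs instead;
    * ``"keep"`` — drop nothing.

    Other-table columns are suffixed ``_other`` where names collide.
    """
    if ambiguity_policy not in {"palindromic", "paper-literal", "keep"}:
        raise ParameterError(f"unknown ambiguity policy {ambiguity_policy!r}")
    gdf = gwas.df
    n_in = len(gdf)
    if ambiguity_policy == "palindromic":
        ambiguous = _is_palindromic(gdf["a1"].to_numpy(), gdf["a2"].to_numpy())
    elif ambiguity_policy == "paper-literal":
        pair = gdf["a1"] + gdf["a2"]
        ambiguous = pair.isin(["AG", "GA", "CT", "TC"]).to_numpy()
    else:
        ambiguous = np.zeros(n_in, dtype=bool)
    if ambiguous.any():
        logger.info(
            "harmonize: removed %d strand-ambiguous SNP(s) under policy %s",
            int(ambiguous.sum()),
            ambiguity_policy,
        )
    gdf = gdf.loc[~ambiguous]
    merged = gdf.merge(other, on="snp", how="inner", suffixes=("", "_other"))
    a1o = merged["a1_other"].to_numpy()
    a2o = merged["a2_other"].to_numpy()
    same = (merged["a1"].to_numpy() == a1o) & (merged["a2"].to_numpy() == a2o)
    swapped = (merged["a1"].to_numpy() == a2o) & (merged["a2"].to_numpy() == a1o)
    bad = ~(same | swapped)
    if bad.any():
        logger.info("harmonize: dropped %d SNP(s) with irreconcilable alleles", int(bad.sum()))
    merged = merged.loc[~bad].reset_index(drop=True)
    flip = swapped[~bad]
    for col in flip_cols:
        name = col if col in other.columns else None
        target = f"{col}_other" if f"{col}_other" in merged.columns else name
        if target is None or target not in merged.columns:
            continue
        merged.loc[flip, target] = -merged.loc[flip, target]
    merged.loc[flip, ["a1_other", "a2_other"]] = merged.loc[flip, ["a2_other", "a1_other"]].to_numpy()
    logger.info("harmonize: %d SNP(s) in, %d out (%d allele-flipped)", n_in, len(merged), int(flip.sum()))
    return merged


# --------------------------------------------------------------------------
# lead-SNP ascertainment
# --------------------------------------------------------------------------
def ascertain_lead_snps(
    gwas: GwasSummary,
    blocks: LdBlockSet,
    freqs: FrequencyMatrix,
    maf_min: float = 0.05,
    maf_population: str | None = None,
) -> GwasSummary:
    """Select the most significant SNP per approximately independent LD block.

    Within each block, among SNPs exceeding ``maf_min`` minor-allele
    frequency in the designated population, the SNP with the smallest GWAS
    p-value is chosen (p ties broken by chromosome then position).  Blocks
    with no qualifying SNP contribute nothing; SNPs falling in no block are
    excluded and counted.
    """
    maf_population = maf_population or freqs.populations[0]
    maf = pd.Series(freqs.maf(maf_population), index=freqs.snps["snp"].to_numpy())
    df = gwas.df.copy()
    df["maf"] = df["snp"].map(maf)
    n_in = len(df)
    missing = df["maf"].isna()
    if missing.any():
        logger.info(
            "ascertain_lead_snps: %d SNP(s) absent from the frequency panel", int(missing.sum())
        )
    df = df.loc[~missing]
    # assign blocks per chromosome with interval search on sorted starts
    df["block"] = -1
    bdf = blocks.df.reset_index()
    for chrom, grp in bdf.groupby("chrom", sort=False):
        sel = df["chrom"].astype(str) == str(chrom)
        if not sel.any():
            continue
        pos = df.loc[sel, "pos"].to_numpy()
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        k = np.searchsorted(starts, pos, side="right") - 1
        ok = (k >= 0) & (pos < ends[np.clip(k, 0, None)])
        ids = np.where(ok, grp["index"].to_numpy()[np.clip(k, 0, None)], -1)
        df.loc[sel, "block"] = ids
    unblocked = (df["block"] < 0).sum()
    if unblocked:
        logger.info("ascertain_lead_snps: %d SNP(s) outside all blocks", int(unblocked))
    df = df.loc[df["block"] >= 0]
    if df.empty:
        raise DegenerateInputError("no GWAS SNP overlaps any LD block")
    df = df.loc[df["maf"] > maf_min]
    if df.empty:
        raise DegenerateInputError("no SNP passes the MAF filter in any block")
    df = df.sort_values(["p", "chrom", "pos"], kind="mergesort")
    lead = df.groupby("block", sort=True).head(1)
    lead = lead.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    logger.info(
        "ascertain_lead_snps: %d SNP(s) in, %d lead SNP(s) from %d block(s)",
        n_in, len(lead), lead["block"].nunique(),
    )
    return GwasSummary.from_dataframe(lead.drop(columns=["maf", "block"]))


# --------------------------------------------------------------------------
# effect-size comparison
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class EffectSizeComparison:
    """Concordance diagnostics between two harmonized GWAS."""

    r2_effects: float
    r2_diff_vs_contrast: float | None
    n_snps: int
    n_positive_a: int
    n_positive_b: int
    n_sign_concordant: int
    degenerate: bool = False

    def summary(self) -> str:
        r2d = "undefined" if self.r2_diff_vs_contrast is None else f"{self.r2_diff_vs_contrast:.4f}"
        return (
            f"effect-size comparison over {self.n_snps} SNPs: r^2(effects) = "
            f"{self.r2_effects:.4f}; r^2(effect difference vs contrast) = {r2d}; "
            f"{self.n_positive_a}/{self.n_snps} positive in A, "
            f"{self.n_positive_b}/{self.n_snps} positive in B, "
            f"{self.n_sign_concordant} sign-concordant"
        )


def compare_effect_sizes(
    gwas_a: GwasSummary,
    gwas_b: GwasSummary,
    contrast: np.ndarray | None = None,
) -> EffectSizeComparison:
    """Compare two harmonized GWAS and relate their differences to structure.

    The two tables must be aligned (same SNPs, same order, same effect
    allele).  Reports the squared Pearson correlation of the effect vectors,
    the squared correlation of the per-SNP effect difference with a
    normalized frequency contrast (the structure-confounding diagnostic), and
    sign counts.  When the two GWAS are identical, the difference is
    identically zero and the contrast correlation is undefined (flagged).
    """
    from .containers import check_aligned

    check_aligned(gwas_a.df["snp"], gwas_b.df["snp"], "compare_effect_sizes")
    if (gwas_a.df["a1"].to_numpy() != gwas_b.df["a1"].to_numpy()).any():
        raise ParameterError("GWAS tables are not harmonized to the same effect allele")
    ba = gwas_a.df["beta"].to_numpy(float)
    bb = gwas_b.df["beta"].to_numpy(float)
    r2_effects = float(np.corrcoef(ba, bb)[0, 1] ** 2)
    diff = ba - bb
    r2_diff = None
    degenerate = False
    if contrast is not None:
        contrast = np.asarray(contrast, dtype=float)
        if contrast.shape != ba.shape:
            raise ParameterError("contrast must align with the shared SNP set")
        if diff.std() == 0 or contrast.std() == 0:
            degenerate = True
        else:
            r2_diff = float(np.corrcoef(diff, contrast)[0, 1] ** 2)
    return EffectSizeComparison(
        r2_effects=r2_effects,
        r2_diff_vs_contrast=r2_diff,
        n_snps=ba.size,
        n_positive_a=int((ba > 0).sum()),
        n_positive_b=int((bb > 0).sum()),
        n_sign_concordant=int((np.sign(ba) == np.sign(bb)).sum()),
        degenerate=degenerate,
    )
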