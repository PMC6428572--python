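"""Regenerate the frozen synthetic test fixture under tests/data/fixture/.

The fixture is fully synthetic (written by the package's own generator under
a pinned seed) and ships with the recorded statistics the pipeline must
reproduce bit-identically when re-run on the files.
"""

import json
from pathlib import Path

import numpy as np

from polyadapt import (
    axis_test,
    binned_tsds_curve,
    estimate_coancestry,
    jackknife_spearman,
    polarize_tsds,
    polygenic_scores,
    qx_test,
    standardize_sds,
    univariate_ldsc,
)
from polyadapt import io, simulate as sim

SEED = 20260922
N_POPS = 5
N_SNPS = 250
N_SAMPLES = 50_000
LDSC_BLOCKS = 50
TSDS_BIN = 50


def build(out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    F = sim.simulate_coancestry(N_POPS, depth=0.005, seed=sim.substream(SEED, "coancestry"))
    freqs = sim.simulate_frequencies(F, N_SNPS, seed=sim.substream(SEED, "frequencies"))
    ld = sim.simulate_ld_scores(freqs=freqs, seed=sim.substream(SEED, "ldscores"))
    truth = sim.make_truth(
        freqs,
        heritability=0.5,
        stratification_strength=0.01,
        seed=sim.substream(SEED, "truth"),
    )
    gwas = sim.simulate_gwas(truth, freqs, N_SAMPLES, seed=sim.substream(SEED, "gwas"))
    sds = sim.simulate_sds(freqs, truth, ld, axis_coupling=0.1, seed=sim.substream(SEED, "sds"))

    io.write_frequency_table(freqs, out_dir / "frequencies.tsv", out_dir / "populations.yaml")
    io.write_summary_stats(gwas, out_dir / "gwas.tsv")
    io.write_sds_table(sds, out_dir / "sds.tsv")
    io.write_ld_scores(ld, out_dir / "ldscores.tsv")

    # expected statistics, recomputed from the written files via the real I/O path
    freqs2 = io.read_frequency_table(out_dir / "frequencies.tsv", out_dir / "populations.yaml")
    gwas2 = io.read_summary_stats(out_dir / "gwas.tsv")
    sds2 = io.read_sds_table(out_dir / "sds.tsv")
    ld2 = io.read_ld_scores(out_dir / "ldscores.tsv")

    scores = polygenic_scores(gwas2, freqs2)
    Fe = estimate_coancestry(freqs2)
    qx = qx_test(scores, Fe)
    ax = axis_test(scores, Fe, freqs2.latitude, axis_label="latitude")
    table = polarize_tsds(standardize_sds(sds2), gwas2)
    curve = binned_tsds_curve(table, bin_size=TSDS_BIN)
    ordered = table.sort_values(["chrom", "pos"], kind="mergesort")
    jk = jackknife_spearman(
        -np.log10(ordered["p"].to_numpy(float)),
        ordered["tsds"].to_numpy(float),
        n_blocks=20,
    )
    merged = gwas2.df.merge(ld2.df[["snp", "l2"]], on="snp")
    chi2 = (merged["beta"] / merged["se"]).to_numpy(float) ** 2
    fit = univariate_ldsc(chi2, merged["l2"].to_numpy(float), n_blocks=LDSC_BLOCKS)

    expected = {
        "seed": SEED,
        "qx": {"statistic": qx.statistic, "df": qx.df, "p_value": qx.p_value},
        "axis_latitude": {"statistic": ax.statistic, "df": ax.df, "p_value": ax.p_value},
        "tsds_curve_means": curve["mean_tsds"].tolist(),
        "tsds_jackknife": {"rho": jk.point_estimate, "se": jk.se, "p_value": jk.p_value},
        "ldsc": {
            "slope": fit.slope,
            "intercept": fit.intercept,
            "slope_se": fit.slope_se,
            "intercept_se": fit.intercept_se,
        },
    }
    (out_dir / "expected.json").write_text(json.dumps(expected, indent=2) + "\n")
    print(f"fixture written to {out_dir}")
    print(json.dumps(expected, indent=2)[:400])


if __name__ == "__main__":
    build(Path(__file__).resolve().parent.parent / "tests" / "data" / "fixture")
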