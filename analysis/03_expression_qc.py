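#!/usr/bin/env python
"""Expression-level QC of the lncRNA matrix: FPKM, median-of-ratios size
factors, PCA of samples, and the all-pairs Pearson correlation heatmap
table. Writes tables plus simple PCA/correlation figures."""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from cernapipe import io, qc

DATA = Path(__file__).resolve().parent.parent / "results" / "data"
OUT = DATA.parent


def main() -> None:
    counts = io.read_counts(DATA / "lnc_counts.tsv")
    sheet = io.read_samplesheet(DATA / "samples.tsv")
    io.validate_samples(counts, sheet)
    lengths = io.read_lengths(DATA / "lengths_lncRNA.tsv")

    fpkm = qc.fpkm(counts, lengths)
    io.write_fpkm(fpkm, OUT / "lnc_fpkm.tsv")
    factors = qc.size_factors(counts)
    factors.to_csv(OUT / "size_factors.tsv", sep="\t", index_label="sample_id")
    coords, varfrac = qc.pca_coordinates(fpkm)
    coords.to_csv(OUT / "pca.tsv", sep="\t", index_label="sample_id")
    corr = qc.sample_correlation(fpkm)
    corr.to_csv(OUT / "sample_correlation.tsv", sep="\t",
                index_label="sample_id")

    stage_of = sheet.set_index("sample_id")["stage"]
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for stage in dict.fromkeys(stage_of):
        sub = coords.loc[stage_of[coords.index] == stage]
        axes[0].scatter(sub["PC1"], sub["PC2"], label=stage)
    axes[0].set_xlabel(f"PC1 ({100 * varfrac[0]:.0f}%)")
    axes[0].set_ylabel(f"PC2 ({100 * varfrac[1]:.0f}%)")
    axes[0].legend(fontsize=7)
    axes[0].set_title("PCA of samples")
    im = axes[1].imshow(corr, vmin=corr.to_numpy().min(), vmax=1, cmap="viridis")
    axes[1].set_title("sample Pearson correlation")
    fig.colorbar(im, ax=axes[1])
    fig.tight_layout()
    fig.savefig(OUT / "qc_overview.png", dpi=120)

    print(f"size factors: min {factors.min():.3f}, max {factors.max():.3f}")
    print(f"PC1/PC2 variance fractions: {varfrac[0]:.2f} / {varfrac[1]:.2f}")
    print(f"sample correlations: median {float(corr.stack().median()):.3f}")


if __name__ == "__main__":
    main()
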