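#!/usr/bin/env python
"""Fixed-dispersion NB exact-test differential expression for all six
pairwise stage comparisons, separately for the lncRNA, mRNA and miRNA
matrices, with BH-FDR, the FDR<0.05 & |log2FC|>1 significance rule, and the
multi-comparison membership matrix behind the Venn counts."""

from pathlib import Path

from cernapipe import diffexpr, io

DATA = Path(__file__).resolve().parent.parent / "results" / "data"
OUT = DATA.parent

PHI = 0.01
ALPHA = 0.05
LFC = 1.0


def main() -> None:
    sheet = io.read_samplesheet(DATA / "samples.tsv")
    for kind, fname in [("lncRNA", "lnc_counts.tsv"),
                        ("mRNA", "mrna_counts.tsv"),
                        ("miRNA", "mirna_counts.tsv")]:
        counts = io.read_counts(DATA / fname)
        io.validate_samples(counts, sheet)
        tables = diffexpr.call_de(counts, sheet, phi=PHI, alpha=ALPHA,
                                  lfc_min=LFC)
        print(f"{kind} (n={len(counts)} features):")
        for comp, df in tables.items():
            df.to_csv(OUT / f"de_{kind}_{comp}.tsv", sep="\t", index=False)
            up = int((df["status"] == "up").sum())
            down = int((df["status"] == "down").sum())
            print(f"  {comp:<16} {up:>3} up, {down:>3} down")
        membership = diffexpr.de_set_ops(tables)
        membership.to_csv(OUT / f"de_{kind}_membership.tsv", sep="\t")
        print(f"  union of significant features: {len(membership)}")


if __name__ == "__main__":
    main()
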