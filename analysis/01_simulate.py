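#!/usr/bin/env python
"""Generate the synthetic study: annotation, verdicts, count matrices with
planted ceRNA triplets, target predictions, and ground-truth tables.

Everything downstream (02-06) reads the files written here, so the whole
analysis exercises the on-disk interfaces, not just in-memory objects.
"""

from pathlib import Path

import pandas as pd

from cernapipe import io, simulate
from cernapipe.config import SimulationConfig

OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimulationConfig(seed=42)

    anno = simulate.simulate_annotation(cfg)
    io.write_gtf(anno.coding, OUT / "coding.gtf")
    io.write_gtf(anno.novel, OUT / "novel.gtf")
    anno.verdicts.to_csv(OUT / "verdicts.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"transcript_id": list(anno.true_class),
         "true_class": list(anno.true_class.values())}
    ).to_csv(OUT / "truth_classes.tsv", sep="\t", index=False)

    expr = simulate.simulate_expression(cfg)
    io.write_counts(expr.lnc_counts, OUT / "lnc_counts.tsv")
    io.write_counts(expr.mrna_counts, OUT / "mrna_counts.tsv")
    io.write_counts(expr.mirna_counts, OUT / "mirna_counts.tsv")
    io.write_samplesheet(expr.samplesheet, OUT / "samples.tsv")
    for kind, lengths in expr.lengths.items():
        io.write_lengths(lengths, OUT / f"lengths_{kind}.tsv")
    truth = expr.ground_truth
    pd.DataFrame(truth.planted_triplets,
                 columns=["lncRNA", "miRNA", "mRNA"]).to_csv(
        OUT / "truth_triplets.tsv", sep="\t", index=False)
    pd.DataFrame(truth.decoy_pairs, columns=["rna_a", "rna_b"]).to_csv(
        OUT / "truth_decoys.tsv", sep="\t", index=False)

    targets = simulate.simulate_targets(cfg, truth)
    io.write_targets(targets, OUT / "targets.tsv")

    print(f"wrote synthetic study to {OUT}")
    print(f"  coding transcripts : {len(anno.coding)}")
    print(f"  novel transcripts  : {len(anno.novel)}")
    print(f"  samples            : {len(expr.samplesheet)} "
          f"({len(cfg.stages)} stages x {cfg.replicates_per_stage} replicates)")
    print(f"  planted triplets   : {len(truth.planted_triplets)} "
          f"({len(truth.planted_pairs)} lncRNA-mRNA pairs)")
    print(f"  decoy pairs        : {len(truth.decoy_pairs)}")
    print(f"  target records     : {len(targets)}")


if __name__ == "__main__":
    main()
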