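#!/usr/bin/env python
"""Filter novel lncRNA candidates (>=200 bp, >=2 exons, non-coding by all
three predictors) and classify the retained set into the five positional
classes, then compare against the generator's ground truth."""

from pathlib import Path

import pandas as pd

from cernapipe import annotation, io

DATA = Path(__file__).resolve().parent.parent / "results" / "data"
OUT = DATA.parent


def main() -> None:
    novel = io.read_gtf(DATA / "novel.gtf")
    coding = io.read_gtf(DATA / "coding.gtf")
    verdicts = pd.read_csv(DATA / "verdicts.tsv", sep="\t")

    retained = annotation.filter_novel_lncrnas(novel, verdicts)
    classes = annotation.classify_lncrnas(retained, coding)
    annotation.class_table(classes).to_csv(OUT / "lnc_classes.tsv", sep="\t",
                                           index=False)

    truth = pd.read_csv(DATA / "truth_classes.tsv", sep="\t").set_index(
        "transcript_id")["true_class"]
    agree = sum(classes[t] == truth[t] for t in classes) / len(classes)

    print(f"retained {len(retained)}/{len(novel)} novel transcripts")
    counts = pd.Series(list(classes.values())).value_counts()
    for cls, n in counts.items():
        print(f"  {cls:<18} {n:>4}  ({100 * n / len(classes):.1f}%)")
    print(f"agreement with generated classes: {100 * agree:.1f}%")


if __name__ == "__main__":
    main()
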