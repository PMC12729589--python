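"""Novel-lncRNA retention filtering and positional classification.

Retention keeps assembled transcripts that are >= 200 bp (summed exon
length), have >= 2 exons, and are called non-coding by all three
coding-potential predictors (intersection rule; the predictors themselves are
upstream of this package, only their boolean verdicts enter).

Classification assigns each retained lncRNA exactly one of five positional
classes relative to the protein-coding transcripts on its chromosome, in this
precedence order:

1. ``intronic`` — the lncRNA interval lies fully inside one intron of a coding
   transcript (either strand);
2. ``antisense`` — >= ``min_overlap`` bp of exonic overlap with a coding
   transcript on the opposite strand;
3. ``sense_overlapping`` — >= ``min_overlap`` bp of transcript-span overlap
   with a coding transcript on the same strand;
4. ``bidirectional`` — no span overlap with the coding transcript, opposite
   strand, TSSs within ``bidirectional_window`` bp, and divergent
   orientation (the two transcripts point away from each other);
5. ``lincRNA`` (intergenic) otherwise.

Containment-first precedence makes the five classes a partition.
"""

from __future__ import annotations

import pandas as pd

from .models import TranscriptModel, ValidationError

MIN_LNC_LENGTH = 200
MIN_LNC_EXONS = 2

VERDICT_COLUMNS = ("cpc_noncoding", "cnci_noncoding", "feelnc_noncoding")


def filter_novel_lncrnas(
    candidates: list[TranscriptModel], verdicts: pd.DataFrame
) -> list[TranscriptModel]:
    """Apply the length / exon-count / three-predictor retention rule.

    Parameters
    ----------
    candidates
        Assembled novel transcripts.
    verdicts
        One row per candidate with boolean columns ``cpc_noncoding``,
        ``cnci_noncoding`` and ``feelnc_noncoding``.
    """
    missing_cols = [c for c in VERDICT_COLUMNS if c not in verdicts.columns]
    if missing_cols:
        raise ValidationError(f"verdict table missing columns {missing_cols}")
    v = verdicts.set_index("transcript_id") if "transcript_id" in verdicts else verdicts
    retained = []
    for t in candidates:
        if t.transcript_id not in v.index:
            raise ValidationError(
                f"candidate {t.transcript_id} has no coding-potential verdict"
            )
        row = v.loc[t.transcript_id]
        noncoding = all(bool(row[c]) for c in VERDICT_COLUMNS)
        if t.length >= MIN_LNC_LENGTH and t.exon_count >= MIN_LNC_EXONS and noncoding:
            retained.append(t)
    return retained


def _span_overlap(a: TranscriptModel, b: TranscriptModel) -> int:
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def _exonic_overlap(a: TranscriptModel, b: TranscriptModel) -> int:
    total = 0
    for s1, e1 in a.exons:
        for s2, e2 in b.exons:
            total += max(0, min(e1, e2) - max(s1, s2))
    return total


def _inside_an_intron(lnc: TranscriptModel, coding: TranscriptModel) -> bool:
    return any(s <= lnc.start and lnc.end <= e for s, e in coding.introns())


def _divergent(lnc: TranscriptModel, coding: TranscriptModel) -> bool:
    # opposite strands assumed; the pair is divergent when each transcribes
    # away from the other's body
    if coding.strand == "+":
        return lnc.strand == "-" and lnc.tss <= coding.tss
    return lnc.strand == "+" and lnc.tss >= coding.tss


def classify_lncrnas(
    lncrnas: list[TranscriptModel],
    coding: list[TranscriptModel],
    bidirectional_window: int = 1000,
    min_overlap: int = 1,
) -> dict[str, str]:
    """Assign each lncRNA exactly one positional class (see module docstring)."""
    coding_ids = {t.transcript_id for t in coding}
    collisions = [t.transcript_id for t in lncrnas if t.transcript_id in coding_ids]
    if collisions:
        raise ValidationError(
            f"lncRNA ids collide with coding ids: {collisions[:5]}"
        )
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for t in coding:
        by_chrom.setdefault(t.chrom, []).append(t)

    classes: dict[str, str] = {}
    for lnc in lncrnas:
        neighbours = by_chrom.get(lnc.chrom, [])
        cls = "lincRNA"
        if any(_inside_an_intron(lnc, c) for c in neighbours):
            cls = "intronic"
        elif any(
            c.strand != lnc.strand and _exonic_overlap(lnc, c) >= min_overlap
            for c in neighbours
        ):
            cls = "antisense"
        elif any(
            c.strand == lnc.strand and _span_overlap(lnc, c) >= min_overlap
            for c in neighbours
        ):
            cls = "sense_overlapping"
        elif any(
            c.strand != lnc.strand
            and _span_overlap(lnc, c) == 0
            and abs(lnc.tss - c.tss) <= bidirectional_window
            and _divergent(lnc, c)
            for c in neighbours
        ):
            cls = "bidirectional"
        classes[lnc.transcript_id] = cls
    return classes


def class_table(classes: dict[str, str]) -> pd.DataFrame:
    return pd.DataFrame(
        {"transcript_id": list(classes), "lnc_class": list(classes.values())}
    )
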