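"""Core in-memory types shared across the pipeline.

Genomic coordinates are stored 0-based half-open throughout; GTF is the only
1-based surface and the conversion happens in :mod:`cernapipe.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import re

#: Allowed characters for feature/transcript identifiers (ids such as
#: "MSTRG.5182.1" contain dots, hence TSV rather than CSV on disk).
ID_PATTERN = re.compile(r"^[A-Za-z0-9._-]+$")

#: The five positional lncRNA classes relative to protein-coding genes.
LNC_CLASSES = (
    "lincRNA",
    "antisense",
    "sense_overlapping",
    "intronic",
    "bidirectional",
)


class ValidationError(ValueError):
    """Raised when an on-disk artifact or in-memory object violates a contract."""


@dataclass
class TranscriptModel:
    """Exon-resolved structure of one transcript.

    Exons are 0-based half-open ``(start, end)`` intervals, sorted by start and
    non-overlapping.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    biotype: str = "coding"  # "coding" | "novel"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"transcript {self.transcript_id}: unknown strand {self.strand!r}"
            )
        if not self.exons:
            raise ValidationError(f"transcript {self.transcript_id}: no exons")
        prev_end = None
        for start, end in self.exons:
            if end < start:
                raise ValidationError(
                    f"transcript {self.transcript_id}: exon end {end} < start {start}"
                )
            if prev_end is not None and start < prev_end:
                raise ValidationError(
                    f"transcript {self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = end
        if not ID_PATTERN.match(self.transcript_id):
            raise ValidationError(f"invalid transcript id {self.transcript_id!r}")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def length(self) -> int:
        """Transcript length = sum of exon lengths (bp)."""
        return sum(e - s for s, e in self.exons)

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def tss(self) -> int:
        """Transcription start site: leftmost base on '+', rightmost on '-'."""
        return self.start if self.strand == "+" else self.end

    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]


@dataclass
class CeRNAEdge:
    """A retained miRNA -> ceRNA targeting edge with its Spearman rho."""

    mirna_id: str
    cerna_id: str
    spearman_rho: float


@dataclass
class CeRNAPair:
    """A screened ceRNA pair with shared-miRNA evidence.

    ``k`` shared miRNAs out of target-set sizes ``K`` (rna_a) and ``n`` (rna_b)
    in a universe of ``N`` miRNAs; ``hyper_p`` is the survivor-function
    P(X >= k) of the hypergeometric draw.
    """

    rna_a: str
    rna_b: str
    shared_mirnas: frozenset[str]
    k: int
    K: int
    n: int
    N: int
    pearson_r: float
    hyper_p: float


@dataclass
class CeRNANetwork:
    """Bipartite miRNA-ceRNA graph plus ceRNA-ceRNA pair edges.

    ``connectivity`` of an RNA node is the number of distinct miRNAs with
    retained targeting edges to it; for a miRNA node it is the number of
    distinct RNAs it targets in the network.
    """

    node_types: dict[str, str]  # id -> "lncRNA" | "miRNA" | "mRNA"
    connectivity: dict[str, int]
    mirna_edges: list[CeRNAEdge] = field(default_factory=list)
    pair_edges: list[CeRNAPair] = field(default_factory=list)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CeRNANetwork):
            return NotImplemented

        def pair_key(p: CeRNAPair):
            return (p.rna_a, p.rna_b)

        def edge_key(e: CeRNAEdge):
            return (e.mirna_id, e.cerna_id)

        return (
            self.node_types == other.node_types
            and self.connectivity == other.connectivity
            and sorted(self.mirna_edges, key=edge_key)
            == sorted(other.mirna_edges, key=edge_key)
            and sorted(self.pair_edges, key=pair_key)
            == sorted(other.pair_edges, key=pair_key)
        )


@dataclass
class GroundTruth:
    """What the generator planted, kept separate from pipeline inputs."""

    planted_triplets: list[tuple[str, str, str]] = field(default_factory=list)
    true_class: dict[str, str] = field(default_factory=dict)
    decoy_pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def planted_pairs(self) -> list[tuple[str, str]]:
        """Distinct planted (lncRNA, mRNA) pairs, in planting order."""
        seen: dict[tuple[str, str], None] = {}
        for lnc, _mir, mrna in self.planted_triplets:
            seen.setdefault((lnc, mrna), None)
        return list(seen)
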