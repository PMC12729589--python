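"""Readers and writers for every on-disk artifact the pipeline touches.

Conventions
-----------
* GTF 2.2 is the only 1-based-inclusive surface; everything in memory is
  0-based half-open.
* Tables are TSV with a header row. Feature ids must match
  ``[A-Za-z0-9._-]+`` (dots occur in assembled-transcript ids).
* Readers reject rather than coerce: negative or fractional counts, duplicate
  ids and samplesheet/matrix mismatches are hard errors.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import networkx as nx
import pandas as pd

from .models import (
    ID_PATTERN,
    CeRNAEdge,
    CeRNANetwork,
    CeRNAPair,
    TranscriptModel,
    ValidationError,
)

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')

NETWORK_FORMATS = ("edge-tsv", "graphml", "json")


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Parse a GTF 2.2 file into transcript models.

    Only ``exon`` features are used to build exon chains; coordinates are
    converted from 1-based inclusive to 0-based half-open.
    """
    path = Path(path)
    exons: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValidationError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _src, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise ValidationError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from None
            if end1 < start1:
                raise ValidationError(f"{path}:{lineno}: end {end1} < start {start1}")
            if strand not in ("+", "-"):
                raise ValidationError(f"{path}:{lineno}: unknown strand {strand!r}")
            attr = dict(_ATTR_RE.findall(attrs))
            if "gene_id" not in attr or "transcript_id" not in attr:
                raise ValidationError(
                    f"{path}:{lineno}: malformed attributes "
                    "(gene_id/transcript_id required)"
                )
            tid = attr["transcript_id"]
            rec = exons.get(tid)
            if rec is None:
                rec = exons[tid] = {
                    "gene_id": attr["gene_id"],
                    "chrom": chrom,
                    "strand": strand,
                    "biotype": attr.get("transcript_biotype", "coding"),
                    "exons": [],
                }
                order.append(tid)
            rec["exons"].append((start1 - 1, end1))
    models = []
    for tid in order:
        rec = exons[tid]
        rec["exons"].sort()
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=rec["gene_id"],
                chrom=rec["chrom"],
                strand=rec["strand"],
                exons=rec["exons"],
                biotype=rec["biotype"],
            )
        )
    return models


def write_gtf(models: list[TranscriptModel], path: str | Path) -> None:
    """Write transcript + exon rows; coordinates converted back to 1-based."""
    with open(path, "w") as fh:
        for m in models:
            attrs = (
                f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}"; '
                f'transcript_biotype "{m.biotype}";'
            )
            fh.write(
                "\t".join(
                    [m.chrom, "cernapipe", "transcript", str(m.start + 1),
                     str(m.end), ".", m.strand, ".", attrs]
                )
                + "\n"
            )
            for s, e in m.exons:
                fh.write(
                    "\t".join(
                        [m.chrom, "cernapipe", "exon", str(s + 1), str(e),
                         ".", m.strand, ".", attrs]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# tabular artifacts
# ---------------------------------------------------------------------------

def _check_ids(ids, what: str) -> None:
    ids = list(ids)
    dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
    if dupes:
        raise ValidationError(f"duplicated {what}: {dupes}")
    bad = [i for i in ids if not ID_PATTERN.match(str(i))]
    if bad:
        raise ValidationError(f"invalid {what}: {bad[:5]}")


def read_counts(path: str | Path) -> pd.DataFrame:
    """Integer count matrix, features x samples, first column = feature id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    _check_ids(df.index, "feature ids")
    _check_ids(df.columns, "sample ids")
    if df.isna().any().any():
        raise ValidationError(f"{path}: missing cells in count matrix")
    if len(df) > 0:
        numeric = df.apply(pd.to_numeric, errors="coerce")
        if numeric.isna().any().any():
            raise ValidationError(f"{path}: non-numeric counts")
        if (numeric < 0).any().any():
            raise ValidationError(f"{path}: negative counts")
        if not (numeric == numeric.round()).all().all():
            raise ValidationError(f"{path}: non-integer counts")
        df = numeric.astype("int64")
    return df


def write_counts(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="feature_id")


def read_fpkm(path: str | Path) -> pd.DataFrame:
    """Real-valued expression matrix (distinct file type from counts)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    _check_ids(df.index, "feature ids")
    if df.isna().any().any():
        raise ValidationError(f"{path}: missing cells")
    return df.astype(float)


def write_fpkm(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="feature_id")


def read_samplesheet(path: str | Path) -> pd.DataFrame:
    """Sample sheet with columns sample_id, stage, replicate."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "stage", "replicate"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"{path}: samplesheet needs columns {sorted(required)}"
        )
    _check_ids(df["sample_id"], "sample ids")
    counts = df.groupby("stage")["sample_id"].count()
    thin = counts[counts < 2]
    if len(thin):
        raise ValidationError(
            f"{path}: stages with < 2 replicates: {thin.index.tolist()}"
        )
    return df


def write_samplesheet(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def validate_samples(counts: pd.DataFrame, samplesheet: pd.DataFrame) -> None:
    """Samplesheet and matrix columns must match exactly."""
    mat = set(counts.columns)
    sheet = set(samplesheet["sample_id"])
    extra = sorted(mat - sheet)
    missing = sorted(sheet - mat)
    if extra or missing:
        raise ValidationError(
            f"sample mismatch: columns not in samplesheet {extra}; "
            f"samplesheet rows not in matrix {missing}"
        )


def read_targets(path: str | Path) -> pd.DataFrame:
    """miRNA->target prediction table.

    Columns: mirna_id, target_id, targetscan_score, miranda_energy, source.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"mirna_id", "target_id", "targetscan_score", "miranda_energy",
                "source"}
    if not required.issubset(df.columns):
        raise ValidationError(f"{path}: target table needs {sorted(required)}")
    _check_ids(df["mirna_id"].unique(), "miRNA ids")
    _check_ids(df["target_id"].unique(), "target ids")
    return df


def write_targets(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_lengths(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if not {"feature_id", "length"}.issubset(df.columns):
        raise ValidationError(f"{path}: lengths table needs feature_id, length")
    s = df.set_index("feature_id")["length"]
    if (s <= 0).any():
        raise ValidationError(f"{path}: non-positive lengths")
    return s


def write_lengths(s: pd.Series, path: str | Path) -> None:
    s.rename("length").to_csv(path, sep="\t", index_label="feature_id")


# ---------------------------------------------------------------------------
# network serialization
# ---------------------------------------------------------------------------

def _network_frames(net: CeRNANetwork) -> tuple[pd.DataFrame, pd.DataFrame]:
    nodes = pd.DataFrame(
        {
            "node_id": list(net.node_types),
            "node_type": [net.node_types[n] for n in net.node_types],
            "connectivity": [net.connectivity.get(n, 0) for n in net.node_types],
        }
    )
    rows = []
    for e in net.mirna_edges:
        rows.append(
            {
                "source": e.mirna_id, "target": e.cerna_id,
                "edge_type": "mirna-cerna", "rho": e.spearman_rho,
                "r": "", "hyper_p": "", "shared": "",
            }
        )
    for p in net.pair_edges:
        rows.append(
            {
                "source": p.rna_a, "target": p.rna_b,
                "edge_type": "cerna-cerna", "rho": "",
                "r": p.pearson_r, "hyper_p": p.hyper_p, "shared": p.k,
            }
        )
    edges = pd.DataFrame(
        rows, columns=["source", "target", "edge_type", "rho", "r",
                       "hyper_p", "shared"]
    )
    return nodes, edges


def network_to_dict(net: CeRNANetwork) -> dict:
    return {
        "nodes": [
            {"id": n, "type": t, "connectivity": net.connectivity.get(n, 0)}
            for n, t in net.node_types.items()
        ],
        "mirna_edges": [
            {"mirna_id": e.mirna_id, "cerna_id": e.cerna_id,
             "spearman_rho": e.spearman_rho}
            for e in net.mirna_edges
        ],
        "pair_edges": [
            {
                "rna_a": p.rna_a, "rna_b": p.rna_b,
                "shared_mirnas": sorted(p.shared_mirnas),
                "k": p.k, "K": p.K, "n": p.n, "N": p.N,
                "pearson_r": p.pearson_r, "hyper_p": p.hyper_p,
            }
            for p in net.pair_edges
        ],
    }


def network_from_dict(d: dict) -> CeRNANetwork:
    return CeRNANetwork(
        node_types={n["id"]: n["type"] for n in d["nodes"]},
        connectivity={n["id"]: n["connectivity"] for n in d["nodes"]},
        mirna_edges=[
            CeRNAEdge(e["mirna_id"], e["cerna_id"], e["spearman_rho"])
            for e in d["mirna_edges"]
        ],
        pair_edges=[
            CeRNAPair(
                rna_a=p["rna_a"], rna_b=p["rna_b"],
                shared_mirnas=frozenset(p["shared_mirnas"]),
                k=p["k"], K=p["K"], n=p["n"], N=p["N"],
                pearson_r=p["pearson_r"], hyper_p=p["hyper_p"],
            )
            for p in d["pair_edges"]
        ],
    )


def network_to_networkx(net: CeRNANetwork) -> nx.Graph:
    g = nx.Graph()
    for n, t in net.node_types.items():
        g.add_node(n, node_type=t, connectivity=net.connectivity.get(n, 0))
    for e in net.mirna_edges:
        g.add_edge(e.mirna_id, e.cerna_id, edge_type="mirna-cerna",
                   rho=e.spearman_rho)
    for p in net.pair_edges:
        g.add_edge(p.rna_a, p.rna_b, edge_type="cerna-cerna",
                   r=p.pearson_r, hyper_p=p.hyper_p, shared=p.k)
    return g


def write_network(net: CeRNANetwork, path: str | Path, fmt: str = "edge-tsv") -> None:
    """Serialize a network as edge/node TSVs, GraphML XML, or JSON."""
    path = Path(path)
    if fmt == "edge-tsv":
        nodes, edges = _network_frames(net)
        edges.to_csv(path, sep="\t", index=False)
        nodes.to_csv(path.with_suffix(".nodes.tsv"), sep="\t", index=False)
    elif fmt == "graphml":
        nx.write_graphml(network_to_networkx(net), path)
    elif fmt == "json":
        with open(path, "w") as fh:
            json.dump(network_to_dict(net), fh, indent=1)
    else:
        raise ValidationError(
            f"unknown network format {fmt!r}; choose one of {NETWORK_FORMATS}"
        )


def read_network_json(path: str | Path) -> CeRNANetwork:
    with open(path) as fh:
        return network_from_dict(json.load(fh))
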