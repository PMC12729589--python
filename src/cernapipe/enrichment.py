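"""Generic hypergeometric over-representation analysis (ORA).

Tests a gene list against user-supplied term annotations (GO/KEGG-style
tables of term -> member genes); one-sided over-representation with BH
correction across tested terms. The term databases themselves are inputs,
never bundled.
"""

from __future__ import annotations

import pandas as pd
from scipy.stats import hypergeom

from .diffexpr import bh_fdr
from .models import ValidationError


def ora(
    gene_list,
    annotations: pd.DataFrame,
    universe=None,
) -> pd.DataFrame:
    """Over-representation of ``gene_list`` in each annotated term.

    Parameters
    ----------
    annotations
        TSV-shaped table with columns term_id, term_name, gene_id.
    universe
        Background gene set; defaults to all genes in ``annotations``.

    Returns a table (term_id, term_name, k, K, n, N, pvalue, fdr) sorted by
    p-value. p = P(X >= k) with X ~ Hypergeometric(N, K, n).
    """
    required = {"term_id", "term_name", "gene_id"}
    if not required.issubset(annotations.columns):
        raise ValidationError(f"annotation table needs columns {sorted(required)}")
    if universe is None:
        universe = set(annotations["gene_id"])
    else:
        universe = set(universe)
    if not universe:
        raise ValidationError("empty gene universe")
    hits = set(gene_list) & universe
    n = len(hits)
    N = len(universe)

    rows = []
    for (term_id, term_name), grp in annotations.groupby(
        ["term_id", "term_name"], sort=True
    ):
        members = set(grp["gene_id"]) & universe
        K = len(members)
        if K == 0:
            continue
        k = len(members & hits)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {"term_id": term_id, "term_name": term_name,
             "k": k, "K": K, "n": n, "N": N, "pvalue": min(p, 1.0)}
        )
    out = pd.DataFrame(
        rows, columns=["term_id", "term_name", "k", "K", "n", "N", "pvalue"]
    )
    if len(out) == 0 or n == 0:
        out["fdr"] = pd.Series(dtype=float)
        return out.iloc[0:0] if n == 0 else out
    out["fdr"] = bh_fdr(out["pvalue"].to_numpy())
    return out.sort_values(["pvalue", "term_id"], kind="mergesort").reset_index(
        drop=True
    )
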