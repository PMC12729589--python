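"""ceRNA network construction: the three-step screen and its graph.

Pipeline: predicted miRNA->RNA interactions are filtered on the two
prediction scores and the two-predictor intersection; each surviving
(miRNA, ceRNA) edge must be anti-correlated in expression (Spearman rho <=
-0.7 by default); ceRNA pairs sharing >= 1 retained miRNA must be positively
co-expressed (Pearson r >= 0.9) and share more miRNAs than expected under a
hypergeometric draw (survivor-function p < 0.05). Node connectivity is the
number of distinct miRNAs with retained targeting edges to an RNA.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import rankdata

from .models import CeRNAEdge, CeRNANetwork, CeRNAPair, ValidationError

logger = logging.getLogger(__name__)

UNIVERSE_MODES = ("filtered", "all_expressed", "all_predicted")


@dataclass
class FilteredTargetSet:
    """miRNA -> target map (and transpose) after score filtering + intersection."""

    mirna_to_targets: dict[str, set[str]] = field(default_factory=dict)

    @property
    def target_to_mirnas(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for mir, targets in self.mirna_to_targets.items():
            for t in targets:
                out.setdefault(t, set()).add(mir)
        return out

    @property
    def n_mirnas(self) -> int:
        return len(self.mirna_to_targets)

    def pairs(self) -> list[tuple[str, str]]:
        return sorted(
            (mir, t)
            for mir, targets in self.mirna_to_targets.items()
            for t in targets
        )


def filter_targets(
    records: pd.DataFrame, score_min: float = 50.0, energy_max: float = -10.0
) -> FilteredTargetSet:
    """Retain (miRNA, target) pairs predicted by BOTH tools and passing both
    thresholds: seed-match score >= ``score_min`` and binding energy <=
    ``energy_max``.

    The ``source`` column says which predictor produced a record
    ("targetscan", "miranda", or "both"); a pair counts as intersected when
    its records jointly cover both predictors.
    """
    out: dict[str, set[str]] = {}
    if len(records) == 0:
        return FilteredTargetSet(out)
    for (mir, target), grp in records.groupby(["mirna_id", "target_id"], sort=False):
        sources: set[str] = set()
        for s in grp["source"]:
            sources |= {"targetscan", "miranda"} if s == "both" else {s}
        if not {"targetscan", "miranda"} <= sources:
            continue
        if grp["targetscan_score"].max() < score_min:
            continue
        if grp["miranda_energy"].min() > energy_max:
            continue
        out.setdefault(mir, set()).add(target)
    return FilteredTargetSet(out)


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation: Pearson on mid-ranks (average ranks for ties).

    Returns NaN for constant vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rx = rankdata(x, method="average")
    ry = rankdata(y, method="average")
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return float("nan")
    return float(np.corrcoef(rx, ry)[0, 1])


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def spearman_edges(
    mirna_expr: pd.DataFrame,
    cerna_expr: pd.DataFrame,
    targets: FilteredTargetSet,
    rho_max: float = -0.7,
) -> list[CeRNAEdge]:
    """Retain predicted (miRNA, ceRNA) edges with Spearman rho <= rho_max.

    Expression matrices must share identical sample columns. Pairs with a
    constant expression vector have undefined rho and are skipped with a
    warning.
    """
    if list(mirna_expr.columns) != list(cerna_expr.columns):
        raise ValidationError("miRNA and ceRNA matrices must share sample columns")
    edges: list[CeRNAEdge] = []
    mir_index = set(mirna_expr.index)
    cer_index = set(cerna_expr.index)
    for mir, mir_targets in sorted(targets.mirna_to_targets.items()):
        if mir not in mir_index:
            continue
        mx = mirna_expr.loc[mir].to_numpy(dtype=float)
        for t in sorted(mir_targets):
            if t not in cer_index:
                continue
            rho = spearman_rho(mx, cerna_expr.loc[t].to_numpy(dtype=float))
            if np.isnan(rho):
                logger.warning(
                    "skipping (%s, %s): constant expression, rho undefined", mir, t
                )
                continue
            if rho <= rho_max:
                edges.append(CeRNAEdge(mir, t, rho))
    return edges


def hypergeom_shared(k: int, K: int, n: int, N: int) -> float:
    """Survivor-function P(X >= k), X ~ Hypergeometric(N, K, n), in log-space.

    N miRNAs in the universe, K targeting one RNA, n targeting the other,
    k shared.
    """
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise ValidationError(
            f"inconsistent hypergeometric arguments k={k} K={K} n={n} N={N}"
        )
    if k == 0:
        return 1.0
    lo = max(k, n + K - N)  # support lower bound: at least n+K-N overlaps forced
    if lo > min(K, n):
        return 0.0
    xs = np.arange(lo, min(K, n) + 1)
    log_pmf = (
        gammaln(K + 1) - gammaln(xs + 1) - gammaln(K - xs + 1)
        + gammaln(N - K + 1) - gammaln(n - xs + 1) - gammaln(N - K - n + xs + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )
    return float(min(1.0, np.exp(logsumexp(log_pmf))))


def screen_pairs(
    edges: list[CeRNAEdge],
    cerna_expr: pd.DataFrame,
    targets: FilteredTargetSet,
    feature_types: dict[str, str],
    r_min: float = 0.9,
    p_max: float = 0.05,
    universe_mode: str = "filtered",
    pair_types: frozenset[frozenset[str]] = frozenset({frozenset({"lncRNA", "mRNA"})}),
    all_shared: bool = False,
    pair_fdr: bool = False,
) -> list[CeRNAPair]:
    """The pair-level screen over retained miRNA-ceRNA edges.

    Candidates are unordered ceRNA pairs sharing >= 1 retained miRNA (with
    ``all_shared=True``, every predicted miRNA shared by the pair must have
    retained edges to both members). Survivors must have Pearson r >= r_min
    across samples and hypergeometric p < p_max, where K and n are the
    post-Spearman (correlation-filtered) target-set sizes and N follows
    ``universe_mode``:

    * ``filtered`` (default): distinct miRNAs with >= 1 retained edge;
    * ``all_expressed``: distinct miRNAs passed in via ``feature_types``;
    * ``all_predicted``: distinct miRNAs in the filtered target set.

    With ``pair_fdr=True``, BH-adjusted p replaces the raw p in the p_max cut.
    """
    if universe_mode not in UNIVERSE_MODES:
        raise ValidationError(f"unknown universe_mode {universe_mode!r}")
    # retained adjacency: RNA -> set of miRNAs with retained edges
    rna_mirnas: dict[str, set[str]] = {}
    mirna_rnas: dict[str, set[str]] = {}
    for e in edges:
        rna_mirnas.setdefault(e.cerna_id, set()).add(e.mirna_id)
        mirna_rnas.setdefault(e.mirna_id, set()).add(e.cerna_id)

    if universe_mode == "filtered":
        N = len(mirna_rnas)
    elif universe_mode == "all_expressed":
        N = sum(1 for _f, t in feature_types.items() if t == "miRNA")
    else:
        N = targets.n_mirnas
    if N == 0:
        return []

    candidates: set[tuple[str, str]] = set()
    for rnas in mirna_rnas.values():
        for a, b in itertools.combinations(sorted(rnas), 2):
            ta = feature_types.get(a, "mRNA")
            tb = feature_types.get(b, "mRNA")
            if frozenset({ta, tb}) in pair_types:
                candidates.add((a, b))

    prelim: list[CeRNAPair] = []
    predicted = targets.target_to_mirnas
    for a, b in sorted(candidates):
        shared = rna_mirnas[a] & rna_mirnas[b]
        if all_shared:
            # every predicted miRNA shared by the pair must survive the
            # Spearman filter for both members
            predicted_shared = predicted.get(a, set()) & predicted.get(b, set())
            if shared != predicted_shared:
                continue
        if not shared:
            continue
        r = pearson_r(
            cerna_expr.loc[a].to_numpy(dtype=float),
            cerna_expr.loc[b].to_numpy(dtype=float),
        )
        if np.isnan(r) or r < r_min:
            continue
        K, n = len(rna_mirnas[a]), len(rna_mirnas[b])
        p = hypergeom_shared(len(shared), K, n, N)
        prelim.append(
            CeRNAPair(
                rna_a=a, rna_b=b, shared_mirnas=frozenset(shared),
                k=len(shared), K=K, n=n, N=N, pearson_r=r, hyper_p=p,
            )
        )
    if pair_fdr and prelim:
        from .diffexpr import bh_fdr

        adj = bh_fdr([p.hyper_p for p in prelim])
        return [p for p, q in zip(prelim, adj) if q < p_max]
    return [p for p in prelim if p.hyper_p < p_max]


def build_network(
    pairs: list[CeRNAPair],
    edges: list[CeRNAEdge],
    feature_types: dict[str, str],
) -> CeRNANetwork:
    """Assemble the network around retained pairs.

    Includes every ceRNA participating in >= 1 retained pair, all retained
    miRNA edges incident to those ceRNAs, and the miRNAs of those edges.
    """
    cernas = {p.rna_a for p in pairs} | {p.rna_b for p in pairs}
    kept_edges = sorted(
        (e for e in edges if e.cerna_id in cernas),
        key=lambda e: (e.mirna_id, e.cerna_id),
    )
    node_types: dict[str, str] = {}
    connectivity: dict[str, int] = {}
    rna_mirnas: dict[str, set[str]] = {}
    mirna_rnas: dict[str, set[str]] = {}
    for e in kept_edges:
        rna_mirnas.setdefault(e.cerna_id, set()).add(e.mirna_id)
        mirna_rnas.setdefault(e.mirna_id, set()).add(e.cerna_id)
    for rna in sorted(cernas):
        node_types[rna] = feature_types.get(rna, "mRNA")
        connectivity[rna] = len(rna_mirnas.get(rna, set()))
    for mir in sorted(mirna_rnas):
        node_types[mir] = "miRNA"
        connectivity[mir] = len(mirna_rnas[mir])
    return CeRNANetwork(
        node_types=node_types,
        connectivity=connectivity,
        mirna_edges=kept_edges,
        pair_edges=sorted(pairs, key=lambda p: (p.rna_a, p.rna_b)),
    )


def connectivity_ranking(
    network: CeRNANetwork, top_lnc: int = 3, top_mrna: int = 6
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Rank RNA nodes by connectivity and emit Sankey (lnc, miRNA, mRNA) triples.

    Ties are broken lexicographically by id; Sankey triples cover every
    retained lncRNA-miRNA-mRNA path among the top-ranked nodes.
    """

    def ranked(node_type: str, top: int) -> pd.DataFrame:
        rows = [
            {"node_id": n, "connectivity": network.connectivity.get(n, 0)}
            for n, t in network.node_types.items()
            if t == node_type
        ]
        df = pd.DataFrame(rows, columns=["node_id", "connectivity"])
        df = df.sort_values(
            ["connectivity", "node_id"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
        return df.head(top)

    lnc_rank = ranked("lncRNA", top_lnc)
    mrna_rank = ranked("mRNA", top_mrna)
    top_l = set(lnc_rank["node_id"])
    top_m = set(mrna_rank["node_id"])
    adj: dict[str, set[str]] = {}
    for e in network.mirna_edges:
        adj.setdefault(e.cerna_id, set()).add(e.mirna_id)
    triples = []
    for p in network.pair_edges:
        a, b = p.rna_a, p.rna_b
        lnc, mrna = (a, b) if network.node_types.get(a) == "lncRNA" else (b, a)
        if lnc in top_l and mrna in top_m:
            for mir in sorted(p.shared_mirnas):
                triples.append({"lncRNA": lnc, "miRNA": mir, "mRNA": mrna})
    sankey = pd.DataFrame(triples, columns=["lncRNA", "miRNA", "mRNA"])
    return lnc_rank, mrna_rank, sankey
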