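"""Negative-binomial exact differential-expression test with fixed dispersion.

The test conditions on a gene's total count across both groups after
size-factor normalization. With replicate counts i.i.d. NB(mu, Var = mu +
phi*mu^2), a group of n replicates sums to NB(n*mu, dispersion phi/n); the
conditional distribution of the group-A sum given the total is the normalized
product of the two group-sum pmfs. The two-sided p-value sums the
probabilities of all outcomes no more probable than the observed one
(small-probability-mass rule), floored at the observed outcome's own mass.

One test serves every matrix (lncRNA, mRNA, miRNA); the dispersion is a fixed
configuration value (default 0.01), not estimated.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import nbinom

from .models import ValidationError
from .qc import size_factors as _size_factors

#: Relative tolerance when comparing outcome probabilities to the observed
#: one: outcomes tied with the observed mass must be included.
_TIE_REL_TOL = 1e-12


def nb_exact_test(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    phi: float = 0.01,
    size_factors_a: np.ndarray | None = None,
    size_factors_b: np.ndarray | None = None,
) -> float:
    """Two-sided conditional NB exact test for one gene.

    Counts are scaled to a common effective library (divided by their size
    factors, rounded) before conditioning. Returns p in (0, 1]; an all-zero
    gene returns 1.0 by convention.
    """
    if phi <= 0:
        raise ValidationError("dispersion phi must be > 0")
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("each group needs >= 1 replicate")
    if (a < 0).any() or (b < 0).any():
        raise ValidationError("counts must be non-negative")
    if size_factors_a is not None:
        a = a / np.asarray(size_factors_a, dtype=float)
    if size_factors_b is not None:
        b = b / np.asarray(size_factors_b, dtype=float)
    a = np.rint(a)
    b = np.rint(b)
    na, nb_ = a.size, b.size
    sa = int(a.sum())
    total = sa + int(b.sum())
    if total == 0:
        return 1.0
    mu = total / (na + nb_)

    s = np.arange(total + 1)
    ra = na / phi  # NB "number of successes" parameter for the group-A sum
    rb = nb_ / phi
    la = nbinom.logpmf(s, ra, ra / (ra + na * mu))
    lb = nbinom.logpmf(total - s, rb, rb / (rb + nb_ * mu))
    lw = la + lb
    lw -= logsumexp(lw)
    w = np.exp(lw)
    obs = w[sa]
    p = float(w[w <= obs * (1.0 + _TIE_REL_TOL)].sum())
    return min(1.0, max(p, float(obs)))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values.

    adjusted_i = min over j with p_(j) >= p_(i) of p_(j) * m / rank(j),
    capped at 1; monotone in p and order-equivariant.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def log2_fold_change(
    norm_mean_a: float, norm_mean_b: float, pseudocount: float = 1.0
) -> float:
    """log2 of (B + pc) / (A + pc) on size-factor-normalized group means."""
    return float(np.log2((norm_mean_b + pseudocount) / (norm_mean_a + pseudocount)))


def stage_comparisons(stages: list[str]) -> list[tuple[str, str]]:
    """All pairwise comparisons in stage order (4 stages -> 6 comparisons)."""
    return list(itertools.combinations(stages, 2))


def call_de(
    counts: pd.DataFrame,
    samplesheet: pd.DataFrame,
    phi: float = 0.01,
    alpha: float = 0.05,
    lfc_min: float = 1.0,
    factors: pd.Series | None = None,
) -> dict[str, pd.DataFrame]:
    """Exact-test DE for every pairwise stage comparison.

    Returns a mapping ``"A_vs_B" -> DataFrame`` with columns feature_id,
    log2FC (B relative to A), pvalue, fdr and status in {up, down, ns}.
    Empty matrices yield empty tables.
    """
    stages = list(dict.fromkeys(samplesheet["stage"]))
    sample_of = {
        st: samplesheet.loc[samplesheet["stage"] == st, "sample_id"].tolist()
        for st in stages
    }
    if factors is None:
        factors = (
            _size_factors(counts)
            if len(counts) > 0
            else pd.Series(1.0, index=counts.columns)
        )
    results: dict[str, pd.DataFrame] = {}
    x = counts.to_numpy(dtype=float)
    col_idx = {c: i for i, c in enumerate(counts.columns)}
    f = factors.to_numpy(dtype=float)
    for st_a, st_b in stage_comparisons(stages):
        ia = [col_idx[s] for s in sample_of[st_a]]
        ib = [col_idx[s] for s in sample_of[st_b]]
        pvals = np.ones(len(counts))
        lfc = np.zeros(len(counts))
        for g in range(len(counts)):
            pvals[g] = nb_exact_test(
                x[g, ia], x[g, ib], phi=phi,
                size_factors_a=f[ia], size_factors_b=f[ib],
            )
            mean_a = float((x[g, ia] / f[ia]).mean())
            mean_b = float((x[g, ib] / f[ib]).mean())
            lfc[g] = log2_fold_change(mean_a, mean_b)
        fdr = bh_fdr(pvals) if len(counts) else np.array([])
        status = np.where(
            (fdr < alpha) & (lfc > lfc_min), "up",
            np.where((fdr < alpha) & (lfc < -lfc_min), "down", "ns"),
        )
        results[f"{st_a}_vs_{st_b}"] = pd.DataFrame(
            {
                "feature_id": counts.index,
                "comparison": f"{st_a}_vs_{st_b}",
                "log2FC": lfc,
                "pvalue": pvals,
                "fdr": fdr,
                "status": status,
            }
        ).reset_index(drop=True)
    return results


def significant_features(tables: dict[str, pd.DataFrame]) -> set[str]:
    """Features called up or down in at least one comparison."""
    out: set[str] = set()
    for df in tables.values():
        out |= set(df.loc[df["status"] != "ns", "feature_id"])
    return out


def de_set_ops(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Membership matrix for Venn logic.

    Rows: features significant in >= 1 comparison; columns: comparisons;
    boolean entries. Union/intersection and all Venn region counts derive
    from it (see :func:`venn_region_counts`).
    """
    union = sorted(significant_features(tables))
    data = {}
    for comp, df in tables.items():
        sig = set(df.loc[df["status"] != "ns", "feature_id"])
        data[comp] = [f in sig for f in union]
    return pd.DataFrame(data, index=pd.Index(union, name="feature_id"))


def venn_region_counts(membership: pd.DataFrame) -> dict[tuple[bool, ...], int]:
    """Count features per Venn region (one region per membership pattern)."""
    counts: dict[tuple[bool, ...], int] = {}
    for _, row in membership.iterrows():
        key = tuple(bool(v) for v in row)
        counts[key] = counts.get(key, 0) + 1
    return counts
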