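"""Bench-validation statistics: 2^-ddCt qPCR, dual-luciferase ratios, ANOVA.

The luciferase helper is channel-role-agnostic: inputs name a ``reporter``
and a ``normalizer`` channel explicitly, because reporter constructs differ
in which luciferase (firefly vs Renilla) carries the cloned site.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import f_oneway

from .models import ValidationError

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def star_label(p: float) -> str:
    """Map a p-value to the conventional significance stars (else "ns")."""
    for cut, label in STAR_THRESHOLDS:
        if p < cut:
            return label
    return "ns"


def ddct(
    records: pd.DataFrame,
    reference_gene: str,
    calibrator_group: str,
    target_gene: str | None = None,
) -> pd.DataFrame:
    """Relative quantification by the 2^-ddCt method.

    ``records`` has columns sample_id, group, gene, ct (one row per technical
    replicate). Technical replicates are averaged at the Ct level; per sample
    dCt = mean Ct(target) - mean Ct(reference); ddCt subtracts the calibrator
    group's mean dCt; fold = 2^-ddCt. The calibrator group's geometric mean
    fold is exactly 1.
    """
    required = {"sample_id", "group", "gene", "ct"}
    if not required.issubset(records.columns):
        raise ValidationError(f"qPCR table needs columns {sorted(required)}")
    genes = set(records["gene"])
    if reference_gene not in genes:
        raise ValidationError(f"reference gene {reference_gene!r} absent")
    if target_gene is None:
        others = sorted(genes - {reference_gene})
        if len(others) != 1:
            raise ValidationError(
                f"target_gene must be given explicitly (found {others})"
            )
        target_gene = others[0]
    mean_ct = (
        records.groupby(["sample_id", "group", "gene"])["ct"].mean().reset_index()
    )
    wide = mean_ct.pivot_table(
        index=["sample_id", "group"], columns="gene", values="ct"
    ).reset_index()
    if wide[reference_gene].isna().any():
        bad = wide.loc[wide[reference_gene].isna(), "sample_id"].tolist()
        raise ValidationError(f"samples missing reference gene Ct: {bad}")
    if wide[target_gene].isna().any():
        bad = wide.loc[wide[target_gene].isna(), "sample_id"].tolist()
        raise ValidationError(f"samples missing target gene Ct: {bad}")
    wide["dct"] = wide[target_gene] - wide[reference_gene]
    calib = wide.loc[wide["group"] == calibrator_group, "dct"]
    if len(calib) == 0:
        raise ValidationError(f"calibrator group {calibrator_group!r} is empty")
    wide["ddct"] = wide["dct"] - calib.mean()
    wide["fold"] = 2.0 ** (-wide["ddct"])
    return wide[["sample_id", "group", "dct", "ddct", "fold"]]


def luciferase_relative(records: pd.DataFrame) -> pd.DataFrame:
    """Relative luciferase activity per construct.

    ``records`` has columns construct (WT/MUT), treatment (mimic/NC),
    reporter, normalizer, replicate. Per replicate activity =
    reporter / normalizer; per construct, relative activity =
    mean activity(mimic) / mean activity(NC). Per-replicate activities,
    normalized to the NC mean, are returned alongside for plotting/ANOVA.
    """
    required = {"construct", "treatment", "reporter", "normalizer"}
    if not required.issubset(records.columns):
        raise ValidationError(f"luciferase table needs columns {sorted(required)}")
    if (records["normalizer"] <= 0).any():
        raise ValidationError("non-positive normalizer channel reading")
    df = records.copy()
    df["activity"] = df["reporter"] / df["normalizer"]
    rows = []
    for construct, grp in df.groupby("construct", sort=True):
        mimic = grp.loc[grp["treatment"] == "mimic", "activity"]
        nc = grp.loc[grp["treatment"] == "NC", "activity"]
        if len(mimic) == 0 or len(nc) == 0:
            raise ValidationError(
                f"construct {construct!r} needs both mimic and NC replicates"
            )
        rows.append(
            {
                "construct": construct,
                "relative_activity": mimic.mean() / nc.mean(),
                "mimic_activities": (mimic / nc.mean()).tolist(),
                "nc_activities": (nc / nc.mean()).tolist(),
            }
        )
    return pd.DataFrame(rows)


def one_way_anova(groups: list[np.ndarray]) -> tuple[float, float, str]:
    """Classical one-way ANOVA F test with star labeling.

    Returns (F, p, stars). All-identical data (zero between- and within-group
    variance) returns F = 0, p = 1, "ns" by convention.
    """
    if len(groups) < 2:
        raise ValidationError("ANOVA needs >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValidationError("each group needs >= 2 values")
    allvals = np.concatenate(arrays)
    if np.ptp(allvals) == 0:
        return 0.0, 1.0, "ns"
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if ss_within == 0:
        # perfectly separated groups
        return float("inf"), 0.0, "***"
    f_stat, p = f_oneway(*arrays)
    return float(f_stat), float(p), star_label(float(p))
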