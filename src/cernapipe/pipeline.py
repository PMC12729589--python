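"""End-to-end orchestration: simulate -> classify -> qc -> de -> cerna -> validate.

:func:`run_screen` is the in-memory core (used by tests and the acceptance
script); :func:`run_all` drives a full configured run on disk and writes a
machine-readable JSON report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation as ann
from . import cerna, diffexpr, io, qc, simulate, wetlab
from .config import RunConfig
from .models import CeRNAEdge, CeRNANetwork, CeRNAPair, GroundTruth

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class ScreenResult:
    edges: list[CeRNAEdge]
    pairs: list[CeRNAPair]
    network: CeRNANetwork
    de_tables: dict[str, dict[str, pd.DataFrame]] = field(default_factory=dict)


def _normalize(counts: pd.DataFrame) -> pd.DataFrame:
    try:
        return qc.normalized_counts(counts)
    except Exception:
        return qc.normalized_counts(counts, qc.size_factors(counts, pseudo_reference=True))


def run_screen(
    expr: simulate.ExpressionResult,
    targets_df: pd.DataFrame,
    cfg: RunConfig,
    permute_rng: np.random.Generator | None = None,
    de_tables: dict[str, dict[str, pd.DataFrame]] | None = None,
) -> ScreenResult:
    """The full ceRNA screen on in-memory matrices.

    With ``permute_rng`` given, each expression matrix's sample columns are
    permuted independently first (label-shuffle null). Differential
    expression gating (on by default) restricts the screen to features
    significant in >= 1 stage comparison.
    """
    lnc = expr.lnc_counts
    mrna = expr.mrna_counts
    mirna = expr.mirna_counts
    if permute_rng is not None:
        lnc = simulate.permute_columns(lnc, permute_rng)
        mrna = simulate.permute_columns(mrna, permute_rng)
        mirna = simulate.permute_columns(mirna, permute_rng)

    if de_tables is None and cfg.de_gate:
        de_tables = {
            "lncRNA": diffexpr.call_de(
                lnc, expr.samplesheet, phi=cfg.dispersion,
                alpha=cfg.alpha, lfc_min=cfg.lfc_min,
            ),
            "mRNA": diffexpr.call_de(
                mrna, expr.samplesheet, phi=cfg.dispersion,
                alpha=cfg.alpha, lfc_min=cfg.lfc_min,
            ),
            "miRNA": diffexpr.call_de(
                mirna, expr.samplesheet, phi=cfg.dispersion,
                alpha=cfg.alpha, lfc_min=cfg.lfc_min,
            ),
        }
    de_tables = de_tables or {}

    targets = cerna.filter_targets(
        targets_df, score_min=cfg.score_min, energy_max=cfg.energy_max
    )
    if cfg.de_gate and de_tables:
        sig_mir = diffexpr.significant_features(de_tables.get("miRNA", {}))
        sig_cer = diffexpr.significant_features(
            de_tables.get("lncRNA", {})
        ) | diffexpr.significant_features(de_tables.get("mRNA", {}))
        targets = cerna.FilteredTargetSet(
            {
                mir: {t for t in ts if t in sig_cer}
                for mir, ts in targets.mirna_to_targets.items()
                if mir in sig_mir
            }
        )
        targets.mirna_to_targets = {
            m: ts for m, ts in targets.mirna_to_targets.items() if ts
        }

    mirna_norm = _normalize(mirna)
    cerna_norm = pd.concat([_normalize(lnc), _normalize(mrna)])
    edges = cerna.spearman_edges(mirna_norm, cerna_norm, targets, rho_max=cfg.rho_max)
    pairs = cerna.screen_pairs(
        edges,
        cerna_norm,
        targets,
        expr.feature_types,
        r_min=cfg.r_min,
        p_max=cfg.p_max,
        universe_mode=cfg.universe_mode,
        all_shared=cfg.all_shared,
        pair_fdr=cfg.pair_fdr,
    )
    network = cerna.build_network(pairs, edges, expr.feature_types)
    return ScreenResult(edges=edges, pairs=pairs, network=network,
                        de_tables=de_tables)


def pair_set(pairs: list[CeRNAPair]) -> set[frozenset[str]]:
    return {frozenset((p.rna_a, p.rna_b)) for p in pairs}


def planted_recovery(pairs: list[CeRNAPair], truth: GroundTruth) -> float:
    """Fraction of planted (lncRNA, mRNA) pairs present in the screened set."""
    planted = [frozenset(p) for p in truth.planted_pairs]
    if not planted:
        return float("nan")
    found = pair_set(pairs)
    return sum(1 for p in planted if p in found) / len(planted)


def decoy_passage(pairs: list[CeRNAPair], truth: GroundTruth) -> float:
    """Fraction of decoy pairs that survived the screen."""
    decoys = [frozenset(p) for p in truth.decoy_pairs]
    if not decoys:
        return float("nan")
    found = pair_set(pairs)
    return sum(1 for p in decoys if p in found) / len(decoys)


def run_all(cfg: RunConfig, outdir: str | Path) -> dict:
    """Full configured run on disk; returns (and writes) the JSON run report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = cfg.simulation
    report: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "thresholds": {
            "score_min": cfg.score_min, "energy_max": cfg.energy_max,
            "rho_max": cfg.rho_max, "r_min": cfg.r_min, "p_max": cfg.p_max,
            "alpha": cfg.alpha, "lfc_min": cfg.lfc_min,
            "dispersion": cfg.dispersion,
        },
        "stages": {},
    }

    # 1. simulate
    anno = simulate.simulate_annotation(sim)
    io.write_gtf(anno.coding, outdir / "coding.gtf")
    io.write_gtf(anno.novel, outdir / "novel.gtf")
    anno.verdicts.to_csv(outdir / "verdicts.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"transcript_id": list(anno.true_class),
         "true_class": list(anno.true_class.values())}
    ).to_csv(outdir / "truth_classes.tsv", sep="\t", index=False)

    expr = simulate.simulate_expression(sim)
    io.write_counts(expr.lnc_counts, outdir / "lnc_counts.tsv")
    io.write_counts(expr.mrna_counts, outdir / "mrna_counts.tsv")
    io.write_counts(expr.mirna_counts, outdir / "mirna_counts.tsv")
    io.write_samplesheet(expr.samplesheet, outdir / "samples.tsv")
    for kind, s in expr.lengths.items():
        io.write_lengths(s, outdir / f"lengths_{kind}.tsv")
    truth = expr.ground_truth
    pd.DataFrame(
        truth.planted_triplets, columns=["lncRNA", "miRNA", "mRNA"]
    ).to_csv(outdir / "truth_triplets.tsv", sep="\t", index=False)
    pd.DataFrame(
        truth.decoy_pairs, columns=["rna_a", "rna_b"]
    ).to_csv(outdir / "truth_decoys.tsv", sep="\t", index=False)

    targets_df = simulate.simulate_targets(sim, truth)
    io.write_targets(targets_df, outdir / "targets.tsv")
    report["stages"]["simulate"] = {
        "coding_transcripts": len(anno.coding),
        "novel_transcripts": len(anno.novel),
        "target_records": len(targets_df),
        "samples": len(expr.samplesheet),
    }

    # 2. classify
    retained = ann.filter_novel_lncrnas(anno.novel, anno.verdicts)
    classes = ann.classify_lncrnas(
        retained, anno.coding,
        bidirectional_window=cfg.bidirectional_window,
        min_overlap=cfg.min_overlap,
    )
    ann.class_table(classes).to_csv(outdir / "classes.tsv", sep="\t", index=False)
    report["stages"]["classify"] = {
        "retained": len(retained),
        "class_counts": pd.Series(list(classes.values())).value_counts().to_dict(),
    }

    # 3. qc
    fpkm_lnc = qc.fpkm(expr.lnc_counts, expr.lengths["lncRNA"])
    io.write_fpkm(fpkm_lnc, outdir / "lnc_fpkm.tsv")
    factors = qc.size_factors(expr.lnc_counts)
    factors.to_csv(outdir / "size_factors.tsv", sep="\t", index_label="sample_id")
    coords, varfrac = qc.pca_coordinates(fpkm_lnc)
    coords.to_csv(outdir / "pca.tsv", sep="\t", index_label="sample_id")
    qc.sample_correlation(fpkm_lnc).to_csv(
        outdir / "sample_correlation.tsv", sep="\t", index_label="sample_id"
    )
    report["stages"]["qc"] = {
        "pc_variance_fractions": [float(v) for v in varfrac],
    }

    # 4. de + 5. cerna
    screen = run_screen(expr, targets_df, cfg)
    de_counts = {}
    for kind, tables in screen.de_tables.items():
        for comp, df in tables.items():
            df.to_csv(outdir / f"de_{kind}_{comp}.tsv", sep="\t", index=False)
            de_counts[f"{kind}:{comp}"] = {
                "up": int((df["status"] == "up").sum()),
                "down": int((df["status"] == "down").sum()),
            }
        membership = diffexpr.de_set_ops(tables)
        membership.to_csv(outdir / f"de_{kind}_membership.tsv", sep="\t")
    report["stages"]["de"] = de_counts

    pairs_df = pd.DataFrame(
        [
            {
                "rna_a": p.rna_a, "rna_b": p.rna_b, "k": p.k, "K": p.K,
                "n": p.n, "N": p.N, "pearson_r": p.pearson_r,
                "hyper_p": p.hyper_p,
                "shared_mirnas": ",".join(sorted(p.shared_mirnas)),
            }
            for p in screen.pairs
        ]
    )
    pairs_df.to_csv(outdir / "cerna_pairs.tsv", sep="\t", index=False)
    io.write_network(screen.network, outdir / "network.tsv", "edge-tsv")
    io.write_network(screen.network, outdir / "network.json", "json")
    io.write_network(screen.network, outdir / "network.graphml", "graphml")
    lnc_rank, mrna_rank, sankey = cerna.connectivity_ranking(screen.network)
    lnc_rank.to_csv(outdir / "top_lncrnas.tsv", sep="\t", index=False)
    mrna_rank.to_csv(outdir / "top_mrnas.tsv", sep="\t", index=False)
    sankey.to_csv(outdir / "sankey.tsv", sep="\t", index=False)
    report["stages"]["cerna"] = {
        "retained_edges": len(screen.edges),
        "retained_pairs": len(screen.pairs),
        "planted_recovery": planted_recovery(screen.pairs, truth),
        "decoy_passage": decoy_passage(screen.pairs, truth),
    }

    # 6. wet-lab validation
    ct = simulate.simulate_qpcr(sim, noise_sd=0.1)
    ct.to_csv(outdir / "qpcr_ct.tsv", sep="\t", index=False)
    folds = wetlab.ddct(ct, reference_gene="ACTB",
                        calibrator_group=sim.stages[0])
    folds.to_csv(outdir / "qpcr_folds.tsv", sep="\t", index=False)
    groups = [g["fold"].to_numpy() for _st, g in folds.groupby("group", sort=False)]
    f_stat, p_anova, stars = wetlab.one_way_anova(groups)
    luc = simulate.simulate_luciferase(sim, noise_sd=0.05)
    luc.to_csv(outdir / "luciferase.tsv", sep="\t", index=False)
    rel = wetlab.luciferase_relative(luc)
    rel.drop(columns=["mimic_activities", "nc_activities"]).to_csv(
        outdir / "luciferase_relative.tsv", sep="\t", index=False
    )
    report["stages"]["wetlab"] = {
        "qpcr_anova": {"F": f_stat, "p": p_anova, "stars": stars},
        "relative_activity": {
            row["construct"]: float(row["relative_activity"])
            for _i, row in rel.iterrows()
        },
    }

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    return report
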