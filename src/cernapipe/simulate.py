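"""Synthetic-data generator: every input the pipeline consumes.

The generator emits (a) a GTF-style annotation whose novel transcripts
realize known positional classes by construction, with coding-potential
verdicts; (b) stage-structured negative-binomial count matrices for lncRNA,
mRNA and miRNA with planted ceRNA triplets; (c) miRNA->target prediction
tables with seed-match scores and binding energies; (d) qPCR Ct and
dual-luciferase readout tables. Ground truth is returned separately and is
never embedded in pipeline inputs.

Planted structure: each planted lncRNA-mRNA pair shares several miRNAs
(``mirnas_per_triplet``, one GroundTruth triplet row per miRNA). The miRNA
stage-mean trajectory is a strictly monotone geometric ramp over the four
stages and the lncRNA/mRNA trajectories are the reversed ramp, so at zero
noise the planted Spearman(miRNA, ceRNA) is exactly -1 and the planted
Pearson(lncRNA, mRNA) is exactly +1. Decoy features carry randomly permuted,
milder ramps: they pass the differential-expression gate but have no shared
correlation structure. Randomness is drawn from per-entity sub-streams
derived deterministically from the seed, so adding features does not
reshuffle existing ones.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .models import LNC_CLASSES, GroundTruth, TranscriptModel

# coding-gene template geometry (offsets from the gene start, bp):
# three exons separated by two introns; gene span 11 kb, one gene per
# 100 kb slot so neighbouring slots cannot interact positionally.
_GENE_EXONS = ((0, 2000), (5000, 6000), (9000, 11000))
_GENE_SPAN = 11_000
_SLOT = 100_000
_OFFSET = 20_000
_GENES_PER_CHROM = 200


def _rng(seed: int, domain: str, index: int = 0) -> np.random.Generator:
    """Deterministic per-entity sub-stream."""
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(domain.encode()), index])
    )


def _allocate(n: int, proportions: dict[str, float]) -> dict[str, int]:
    """Largest-remainder allocation of n items over the five classes."""
    keys = [c for c in LNC_CLASSES if c in proportions]
    exact = {c: n * proportions[c] for c in keys}
    counts = {c: int(np.floor(exact[c])) for c in keys}
    leftover = n - sum(counts.values())
    by_remainder = sorted(keys, key=lambda c: (-(exact[c] - counts[c]), c))
    for c in by_remainder[:leftover]:
        counts[c] += 1
    return counts


@dataclass
class AnnotationResult:
    coding: list[TranscriptModel]
    novel: list[TranscriptModel]
    true_class: dict[str, str]
    verdicts: pd.DataFrame


def simulate_annotation(config: SimulationConfig) -> AnnotationResult:
    """Coding genes plus novel transcripts with known positional classes.

    Each novel transcript is anchored to its own coding-gene slot and its
    geometry forces the assigned class under the classifier's rules. All
    novel transcripts have 2 exons and length >= 200 bp, and are marked
    non-coding by all three predictors unless ``contamination_fraction`` > 0.
    """
    rng = _rng(config.seed, "annotation")
    n_novel = config.n_novel_transcripts
    n_genes = max(config.n_coding_genes, n_novel)

    coding: list[TranscriptModel] = []
    gene_info: list[tuple[str, int, str]] = []  # (chrom, slot start, strand)
    for g in range(n_genes):
        chrom = f"chr{g // _GENES_PER_CHROM + 1}"
        s = _OFFSET + (g % _GENES_PER_CHROM) * _SLOT
        strand = "+" if rng.random() < 0.5 else "-"
        gene_info.append((chrom, s, strand))
        coding.append(
            TranscriptModel(
                transcript_id=f"CG.{g + 1}.t1",
                gene_id=f"CG.{g + 1}",
                chrom=chrom,
                strand=strand,
                exons=[(s + a, s + b) for a, b in _GENE_EXONS],
                biotype="coding",
            )
        )

    counts = _allocate(n_novel, config.class_proportions)
    labels = [c for c in LNC_CLASSES for _ in range(counts.get(c, 0))]
    labels = [labels[i] for i in rng.permutation(n_novel)]

    novel: list[TranscriptModel] = []
    true_class: dict[str, str] = {}
    for i, cls in enumerate(labels):
        chrom, s, gstrand = gene_info[i]
        anti = "-" if gstrand == "+" else "+"
        rand_strand = "+" if rng.random() < 0.5 else "-"
        if cls == "intronic":
            exons = [(s + 2500, s + 2700), (s + 2900, s + 3100)]
            strand = rand_strand
        elif cls == "antisense":
            exons = [(s + 500, s + 800), (s + 1200, s + 1500)]
            strand = anti
        elif cls == "sense_overlapping":
            exons = [(s - 3000, s - 2500), (s - 1000, s + 500)]
            strand = gstrand
        elif cls == "bidirectional":
            if gstrand == "+":
                exons = [(s - 900, s - 700), (s - 500, s - 300)]
            else:
                e = s + _GENE_SPAN
                exons = [(e + 300, e + 500), (e + 700, e + 900)]
            strand = anti
        else:  # lincRNA: mid-slot, far beyond the bidirectional window
            exons = [(s + 45_000, s + 45_400), (s + 46_000, s + 46_400)]
            strand = rand_strand
        tid = f"MSTRG.{i + 1}.1"
        novel.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=f"MSTRG.{i + 1}",
                chrom=chrom,
                strand=strand,
                exons=exons,
                biotype="novel",
            )
        )
        true_class[tid] = cls

    verdicts = pd.DataFrame(
        {
            "transcript_id": [t.transcript_id for t in novel],
            "cpc_noncoding": True,
            "cnci_noncoding": True,
            "feelnc_noncoding": True,
        }
    )
    n_contam = int(round(config.contamination_fraction * n_novel))
    if n_contam:
        rows = rng.choice(n_novel, size=n_contam, replace=False)
        cols = rng.choice(
            ["cpc_noncoding", "cnci_noncoding", "feelnc_noncoding"], size=n_contam
        )
        for r, c in zip(rows, cols):
            verdicts.loc[r, c] = False
    return AnnotationResult(coding, novel, true_class, verdicts)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def lnc_id(i: int) -> str:
    return f"MSTRG.{i + 1}.1"


def mrna_id(i: int) -> str:
    return f"GENE.{i + 1}"


def mirna_id(i: int) -> str:
    return f"miR-{i + 1}"


@dataclass
class ExpressionResult:
    lnc_counts: pd.DataFrame
    mrna_counts: pd.DataFrame
    mirna_counts: pd.DataFrame
    samplesheet: pd.DataFrame
    ground_truth: GroundTruth
    #: exact per-sample NB means for each matrix (noise-free reference)
    means: dict[str, pd.DataFrame] = field(default_factory=dict)
    lengths: dict[str, pd.Series] = field(default_factory=dict)

    @property
    def feature_types(self) -> dict[str, str]:
        out = {f: "lncRNA" for f in self.lnc_counts.index}
        out.update({f: "mRNA" for f in self.mrna_counts.index})
        out.update({f: "miRNA" for f in self.mirna_counts.index})
        return out


def _plan_structure(config: SimulationConfig):
    """Assign planted/decoy roles to feature indices.

    Returns (triplets, decoys) where ``triplets`` maps planted pair index ->
    list of miRNA indices and ``decoys`` maps decoy pair index -> miRNA index.
    Pair i uses lncRNA i and mRNA i; decoy pair d uses index
    n_planted_triplets + d in both matrices.
    """
    mir_cursor = 0
    triplets: dict[int, list[int]] = {}
    for i in range(config.n_planted_triplets):
        m = config.mirnas_per_triplet + (config.hub_extra_mirnas if i == 0 else 0)
        triplets[i] = list(range(mir_cursor, mir_cursor + m))
        mir_cursor += m
    decoys = {
        d: mir_cursor + d for d in range(config.n_decoy_pairs)
    }
    return triplets, decoys


def _sample_counts(
    rng: np.random.Generator,
    stage_means: np.ndarray,
    config: SimulationConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Replicate-level (counts, means) for one feature from its stage means."""
    reps = config.replicates_per_stage
    mu = np.repeat(stage_means, reps)
    if config.noise_sd > 0:
        mu = mu * rng.lognormal(0.0, config.noise_sd, size=mu.size)
    if config.dispersion == 0:
        return np.rint(mu).astype(np.int64), mu
    r = 1.0 / config.dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    return counts.astype(np.int64), mu


def simulate_expression(config: SimulationConfig) -> ExpressionResult:
    """Stage-structured NB count matrices with planted ceRNA triplets."""
    stages = list(config.stages)
    n_stage = len(stages)
    reps = config.replicates_per_stage
    sample_ids = [f"{st}_{r + 1}" for st in stages for r in range(reps)]
    samplesheet = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "stage": [st for st in stages for _ in range(reps)],
            "replicate": [r + 1 for _ in stages for r in range(reps)],
        }
    )

    triplets, decoys = _plan_structure(config)
    ramp = config.fold_span ** (np.arange(n_stage) / (n_stage - 1))
    decoy_ramp = config.decoy_fold_span ** (np.arange(n_stage) / (n_stage - 1))

    # per-pair direction of the planted miRNA trajectory
    directions = {
        i: bool(_rng(config.seed, "direction", i).random() < 0.5)
        for i in triplets
    }

    lnc_pattern: dict[int, np.ndarray] = {}
    mrna_pattern: dict[int, np.ndarray] = {}
    mirna_pattern: dict[int, np.ndarray] = {}
    for i, mirs in triplets.items():
        mir_traj = ramp if directions[i] else ramp[::-1]
        cer_traj = mir_traj[::-1]
        lnc_pattern[i] = cer_traj
        mrna_pattern[i] = cer_traj
        for m in mirs:
            mirna_pattern[m] = mir_traj
    for d, m in decoys.items():
        j = config.n_planted_triplets + d
        lnc_pattern[j] = _rng(config.seed, "decoy_lnc", d).permutation(decoy_ramp)
        mrna_pattern[j] = _rng(config.seed, "decoy_mrna", d).permutation(decoy_ramp)
        mirna_pattern[m] = _rng(config.seed, "decoy_mir", d).permutation(decoy_ramp)

    def build_matrix(kind: str, n: int, idfun, patterns) -> tuple[pd.DataFrame, pd.DataFrame]:
        lo, hi = config.baseline_mean_log_range
        counts = np.empty((n, len(sample_ids)), dtype=np.int64)
        means = np.empty((n, len(sample_ids)))
        for i in range(n):
            rng = _rng(config.seed, kind, i)
            base = float(np.exp(rng.uniform(lo, hi)))
            pattern = patterns.get(i, np.ones(n_stage))
            counts[i], means[i] = _sample_counts(rng, base * pattern, config)
        ids = [idfun(i) for i in range(n)]
        return (
            pd.DataFrame(counts, index=ids, columns=sample_ids),
            pd.DataFrame(means, index=ids, columns=sample_ids),
        )

    lnc_counts, lnc_means = build_matrix("lnc", config.n_lncRNA, lnc_id, lnc_pattern)
    mrna_counts, mrna_means = build_matrix("mrna", config.n_mRNA, mrna_id, mrna_pattern)
    mirna_counts, mirna_means = build_matrix(
        "mirna", config.n_miRNA, mirna_id, mirna_pattern
    )

    truth = GroundTruth(
        planted_triplets=[
            (lnc_id(i), mirna_id(m), mrna_id(i))
            for i in triplets
            for m in triplets[i]
        ],
        decoy_pairs=[
            (lnc_id(config.n_planted_triplets + d), mrna_id(config.n_planted_triplets + d))
            for d in decoys
        ],
    )

    len_rng = _rng(config.seed, "lengths")
    lengths = {
        "lncRNA": pd.Series(
            len_rng.integers(400, 3000, size=config.n_lncRNA),
            index=lnc_counts.index, name="length",
        ),
        "mRNA": pd.Series(
            len_rng.integers(1000, 5000, size=config.n_mRNA),
            index=mrna_counts.index, name="length",
        ),
        "miRNA": pd.Series(
            len_rng.integers(20, 25, size=config.n_miRNA),
            index=mirna_counts.index, name="length",
        ),
    }
    return ExpressionResult(
        lnc_counts=lnc_counts,
        mrna_counts=mrna_counts,
        mirna_counts=mirna_counts,
        samplesheet=samplesheet,
        ground_truth=truth,
        means={"lncRNA": lnc_means, "mRNA": mrna_means, "miRNA": mirna_means},
        lengths=lengths,
    )


# ---------------------------------------------------------------------------
# target predictions
# ---------------------------------------------------------------------------

def simulate_targets(config: SimulationConfig, truth: GroundTruth) -> pd.DataFrame:
    """miRNA->target records for planted triplets, decoy pairs, and failing decoys.

    Planted and decoy-pair interactions pass both thresholds in both
    predictors. A ``decoy_fail_fraction`` share of extra records fails
    exactly one threshold or appears in only one predictor's output, to
    exercise the intersection rule.
    """
    rng = _rng(config.seed, "targets")
    rows = []

    def good_record(mir: str, target: str, source: str = "both") -> dict:
        return {
            "mirna_id": mir,
            "target_id": target,
            "targetscan_score": float(rng.uniform(60, 95)),
            "miranda_energy": float(rng.uniform(-25, -12)),
            "source": source,
        }

    for lnc, mir, mrna in truth.planted_triplets:
        rows.append(good_record(mir, lnc))
        rows.append(good_record(mir, mrna))
    triplet_mirs = len({m for _l, m, _r in truth.planted_triplets})
    for d, (lnc, mrna) in enumerate(truth.decoy_pairs):
        mir = mirna_id(triplet_mirs + d)
        rows.append(good_record(mir, lnc))
        rows.append(good_record(mir, mrna))

    n_good = len(rows)
    n_bad = int(round(config.decoy_fail_fraction * n_good))
    bad_pool_start = config.n_planted_triplets + config.n_decoy_pairs
    modes = ("low_score", "weak_energy", "targetscan", "miranda")
    for j in range(n_bad):
        mir = mirna_id(triplet_mirs + (j % max(config.n_decoy_pairs, 1)))
        idx = bad_pool_start + j
        target = lnc_id(idx) if j % 2 == 0 else mrna_id(idx)
        mode = modes[j % 4]
        rec = good_record(mir, target)
        if mode == "low_score":
            rec["targetscan_score"] = float(rng.uniform(10, 49.5))
        elif mode == "weak_energy":
            rec["miranda_energy"] = float(rng.uniform(-9.5, -1))
        else:
            rec["source"] = mode
        rows.append(rec)
    return pd.DataFrame(
        rows,
        columns=["mirna_id", "target_id", "targetscan_score", "miranda_energy",
                 "source"],
    )


# ---------------------------------------------------------------------------
# wet-lab readouts
# ---------------------------------------------------------------------------

def simulate_qpcr(
    config: SimulationConfig,
    target_gene: str = "target",
    reference_gene: str = "ACTB",
    group_folds: dict[str, float] | None = None,
    noise_sd: float = 0.0,
    n_technical: int = 3,
    baseline_ct: float = 25.0,
    reference_ct: float = 18.0,
) -> pd.DataFrame:
    """Ct table: Ct = baseline - log2(fold) + Gaussian noise.

    One target and one reference gene per sample, ``n_technical`` technical
    replicates, ``replicates_per_stage`` biological replicates per group.
    Default planted folds follow the generator's geometric stage ramp, with
    the first stage as calibrator (fold 1).
    """
    stages = list(config.stages)
    if group_folds is None:
        ramp = config.fold_span ** (np.arange(len(stages)) / (len(stages) - 1))
        group_folds = dict(zip(stages, ramp))
    rng = _rng(config.seed, "qpcr")
    rows = []
    for st in stages:
        fold = group_folds[st]
        for b in range(config.replicates_per_stage):
            sample = f"{st}_{b + 1}"
            for gene, base in ((target_gene, baseline_ct - np.log2(fold)),
                               (reference_gene, reference_ct)):
                for _t in range(n_technical):
                    ct = base + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                    rows.append(
                        {"sample_id": sample, "group": st, "gene": gene,
                         "ct": float(ct)}
                    )
    return pd.DataFrame(rows)


def simulate_luciferase(
    config: SimulationConfig,
    wt_suppression: float = 0.5,
    mut_suppression: float = 1.0,
    n_replicates: int = 6,
    noise_sd: float = 0.0,
    reporter_base: float = 1000.0,
    normalizer_base: float = 800.0,
) -> pd.DataFrame:
    """WT/MUT x mimic/NC two-channel readouts.

    The mimic multiplies the WT reporter channel by ``wt_suppression``; the
    mutated binding site abolishes the effect (``mut_suppression`` = 1).
    """
    rng = _rng(config.seed, "luciferase")
    rows = []
    for construct, suppression in (("WT", wt_suppression), ("MUT", mut_suppression)):
        for treatment in ("mimic", "NC"):
            eff = suppression if treatment == "mimic" else 1.0
            for rep in range(n_replicates):
                noise_r = rng.lognormal(0.0, noise_sd) if noise_sd > 0 else 1.0
                noise_n = rng.lognormal(0.0, noise_sd) if noise_sd > 0 else 1.0
                rows.append(
                    {
                        "construct": construct,
                        "treatment": treatment,
                        "reporter": reporter_base * eff * noise_r,
                        "normalizer": normalizer_base * noise_n,
                        "replicate": rep + 1,
                    }
                )
    return pd.DataFrame(rows)


def permute_columns(matrix: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Shuffle sample columns while keeping the column labels in place.

    Used for label-permutation nulls: applying independent permutations to
    each expression matrix destroys cross-matrix correlation structure.
    """
    perm = rng.permutation(matrix.shape[1])
    out = matrix.iloc[:, perm].copy()
    out.columns = matrix.columns
    return out
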