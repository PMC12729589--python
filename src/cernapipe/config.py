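"""Simulation and run configuration objects with validation."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

from .models import LNC_CLASSES, ValidationError

#: Observed proportions of the five positional classes in goat muscle
#: lncRNA surveys (intergenic-dominated), renormalized to sum to 1.
_RAW_CLASS_WEIGHTS = {
    "lincRNA": 52.4,
    "antisense": 13.4,
    "sense_overlapping": 7.2,
    "intronic": 11.6,
    "bidirectional": 10.22,
}
_TOTAL = sum(_RAW_CLASS_WEIGHTS.values())
DEFAULT_CLASS_PROPORTIONS = {k: v / _TOTAL for k, v in _RAW_CLASS_WEIGHTS.items()}

#: Developmental stages in temporal order: 120 days post-gestation (fetal),
#: then 1, 3 and 10 months of age.
DEFAULT_STAGES = ("120dPG", "1mo", "3mo", "10mo")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    The negative binomial is parameterized as Var = mu + phi * mu**2, so the
    generator's ``dispersion`` and the exact test's fixed dispersion mean the
    same quantity.
    """

    seed: int = 0
    # annotation
    n_coding_genes: int = 50
    n_novel_transcripts: int = 300
    class_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )
    contamination_fraction: float = 0.0
    # expression
    n_lncRNA: int = 300
    n_mRNA: int = 500
    n_miRNA: int = 150
    n_planted_triplets: int = 20
    mirnas_per_triplet: int = 3
    hub_extra_mirnas: int = 2
    n_decoy_pairs: int = 40
    decoy_fail_fraction: float = 0.3
    stages: tuple[str, ...] = DEFAULT_STAGES
    replicates_per_stage: int = 3
    dispersion: float = 0.01
    baseline_mean_log_range: tuple[float, float] = (3.5, 6.0)
    fold_span: float = 6.0
    decoy_fold_span: float = 3.0
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if set(self.class_proportions) != set(LNC_CLASSES):
            raise ValidationError(
                "class_proportions must cover exactly the classes "
                f"{sorted(LNC_CLASSES)}"
            )
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"class_proportions must sum to 1 (got {total!r})"
            )
        if any(v < 0 for v in self.class_proportions.values()):
            raise ValidationError("class_proportions must be non-negative")
        if self.replicates_per_stage < 2:
            raise ValidationError("replicates_per_stage must be >= 2")
        for name in (
            "n_coding_genes",
            "n_novel_transcripts",
            "n_lncRNA",
            "n_mRNA",
            "n_miRNA",
        ):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if self.n_planted_triplets < 0 or self.n_decoy_pairs < 0:
            raise ValidationError("planted/decoy counts must be >= 0")
        if self.mirnas_per_triplet < 1:
            raise ValidationError("mirnas_per_triplet must be >= 1")
        if len(self.stages) < 2:
            raise ValidationError("need at least 2 stages")
        if len(set(self.stages)) != len(self.stages):
            raise ValidationError("stage labels must be unique")
        if self.dispersion < 0:
            raise ValidationError("dispersion must be >= 0")
        if self.fold_span <= 0 or self.decoy_fold_span <= 0:
            raise ValidationError("fold spans must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not 0 <= self.decoy_fail_fraction <= 1:
            raise ValidationError("decoy_fail_fraction must be in [0, 1]")
        if not 0 <= self.contamination_fraction <= 1:
            raise ValidationError("contamination_fraction must be in [0, 1]")
        lo, hi = self.baseline_mean_log_range
        if hi < lo:
            raise ValidationError("baseline_mean_log_range must be (lo, hi)")
        needed_mirnas = (
            self.n_planted_triplets * self.mirnas_per_triplet
            + (self.hub_extra_mirnas if self.n_planted_triplets else 0)
            + self.n_decoy_pairs
        )
        if needed_mirnas > self.n_miRNA:
            raise ValidationError(
                f"n_miRNA={self.n_miRNA} too small for planted+decoy structure "
                f"({needed_mirnas} needed)"
            )
        if self.n_planted_triplets + self.n_decoy_pairs > min(
            self.n_lncRNA, self.n_mRNA
        ):
            raise ValidationError(
                "n_lncRNA and n_mRNA must each exceed planted + decoy pair counts"
            )

    @property
    def n_samples(self) -> int:
        return len(self.stages) * self.replicates_per_stage


@dataclass
class RunConfig:
    """Thresholds and knobs of a full pipeline run.

    Defaults are the screen's reference operating point: target-prediction
    score >= 50 and binding energy <= -10 kcal/mol, miRNA-ceRNA Spearman rho
    <= -0.7, ceRNA-ceRNA Pearson r >= 0.9 and hypergeometric p < 0.05, with
    differential expression called at FDR < 0.05 and |log2FC| > 1 under a
    fixed NB dispersion of 0.01.
    """

    seed: int = 0
    score_min: float = 50.0
    energy_max: float = -10.0
    rho_max: float = -0.7
    r_min: float = 0.9
    p_max: float = 0.05
    alpha: float = 0.05
    lfc_min: float = 1.0
    dispersion: float = 0.01
    bidirectional_window: int = 1000
    min_overlap: int = 1
    universe_mode: str = "filtered"
    de_gate: bool = True
    pair_fdr: bool = False
    all_shared: bool = False
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1 or not 0 < self.p_max <= 1:
            raise ValidationError("alpha and p_max must lie in (0, 1]")
        if not -1 <= self.rho_max <= 1 or not -1 <= self.r_min <= 1:
            raise ValidationError("correlation thresholds must lie in [-1, 1]")
        if self.dispersion <= 0:
            raise ValidationError("dispersion must be > 0")
        if self.universe_mode not in ("filtered", "all_expressed", "all_predicted"):
            raise ValidationError(f"unknown universe_mode {self.universe_mode!r}")
        if self.lfc_min < 0:
            raise ValidationError("lfc_min must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)
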