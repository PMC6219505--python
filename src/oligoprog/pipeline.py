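"""End-to-end orchestration of the analysis stages.

simulate -> prepare -> train/rank (genetic-protein) -> train/rank
(transcriptional) -> GSEA -> density -> associations -> survival,
under one configuration with a global seed that expands into fixed
per-stage seeds.  Any stage failure halts its dependents; independent
stages still run.  The run produces tab-separated stage outputs plus a
machine-readable JSON report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import enrichment, histodensity, stats, survnet, synthetic

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "run_pipeline", "validate_inputs", "stage_seeds"]

STAGES = ("simulate", "train", "rank", "transcriptional", "gsea",
          "density", "assoc", "survive")


@dataclass
class RunConfig:
    """Configuration of a pipeline run (synthetic-cohort demo mode)."""

    out_dir: str = "oligoprog_run"
    seed: int = 0
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    # cohort
    n_samples: int = 169
    n_features: int = 20
    # transcriptional arm
    n_genes: int = 1000
    n_gene_sets: int = 50
    planted_set_size: int = 50
    set_effect: float = -0.5
    # training
    training: survnet.TrainingConfig = field(default_factory=survnet.TrainingConfig)
    n_splits: int = 20
    # GSEA
    n_perm: int = 1000
    min_set_size: int = 10
    # density
    n_density_samples: int = 20
    lambda_tumor: float = 0.01
    lambda_normal: float = 0.002
    field_size: float = 1000.0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        training = survnet.TrainingConfig(**raw.pop("training", {}))
        cfg = cls(**{k: v for k, v in raw.items() if k != "training"})
        cfg.training = training
        return cfg


@dataclass
class RunReport:
    """Per-stage status plus headline outputs, serialisable to JSON."""

    seed: int
    stage_status: dict = field(default_factory=dict)
    stage_seeds: dict = field(default_factory=dict)
    headline: dict = field(default_factory=dict)
    input_hashes: dict = field(default_factory=dict)
    version: str = ""

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(type(o))

        return json.dumps(asdict(self), indent=2, default=default, sort_keys=True)

    def write(self, path) -> None:
        Path(path).write_text(self.to_json())


def stage_seeds(global_seed: int) -> dict[str, int]:
    """Expand a global seed into fixed per-stage seeds (order is part of
    the contract: changing one stage's work never perturbs another's)."""
    state = np.random.SeedSequence(global_seed).generate_state(len(STAGES))
    return {s: int(v % (2 ** 31)) for s, v in zip(STAGES, state)}


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def validate_inputs(features: survnet.FeatureMatrix | None = None,
                    outcomes: survnet.SurvivalOutcome | None = None,
                    sample_ids: list[str] | None = None,
                    arm_cna: pd.DataFrame | None = None,
                    gmt: enrichment.GeneSetCollection | None = None) -> list[dict]:
    """Schema checks across pipeline inputs.

    Returns findings as dicts with 'level' ("error"/"warning") and
    'message'; an empty list means the inputs are clean.
    """
    findings: list[dict] = []
    if features is not None and outcomes is not None and \
            features.n_samples != len(outcomes):
        findings.append({"level": "error",
                         "message": "features and outcomes have different sample counts"})
    if features is not None and sample_ids is not None and \
            list(features.sample_ids) != list(sample_ids):
        findings.append({"level": "error",
                         "message": "sample ids differ between features and clinical table"})
    if arm_cna is not None:
        vals = arm_cna.to_numpy(float)
        if np.any(np.abs(vals) > 1):
            findings.append({"level": "error",
                             "message": "arm CNA fractions outside [-1, 1]"})
    if gmt is not None:
        for name, members in gmt.sets.items():
            if len(members) != len(set(members)):
                findings.append({"level": "warning",
                                 "message": f"gene set {name} has duplicates"})
    return findings


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the enabled stages on a synthetic demo cohort."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    fh = logging.FileHandler(out / "run.log")
    logging.getLogger().addHandler(fh)
    seeds = stage_seeds(config.seed)
    report = RunReport(seed=config.seed, stage_seeds=seeds, version="oligoprog 0.1.0")
    on = config.stages

    cohort = None
    if on.get("simulate", True):
        try:
            sim_cfg = synthetic.default_cohort_config(
                seed=seeds["simulate"], n_samples=config.n_samples,
                n_features=config.n_features)
            cohort = synthetic.generate_cohort(sim_cfg)
            cohort.write(out / "cohort")
            report.stage_status["simulate"] = "ok"
            report.input_hashes["features.tsv"] = _hash_file(out / "cohort" / "features.tsv")
        except Exception as exc:  # pragma: no cover - defensive
            logger.exception("simulate stage failed")
            report.stage_status["simulate"] = f"error: {exc}"

    cv = None
    if on.get("train", True) and cohort is not None:
        try:
            cv = survnet.monte_carlo_cv(cohort.features, cohort.outcomes,
                                        config.training, n_splits=config.n_splits,
                                        seed=seeds["train"])
            cv.to_frame().to_csv(out / "cv_cindex.tsv", sep="\t", index=False)
            report.stage_status["train"] = "ok"
            report.headline["cv_median_cindex"] = cv.median
            report.headline["cv_sd_cindex"] = cv.sd
        except Exception as exc:
            logger.exception("train stage failed")
            report.stage_status["train"] = f"error: {exc}"
    elif on.get("train", True):
        report.stage_status["train"] = "skipped: missing cohort"

    if on.get("rank", True) and cv is not None and cohort is not None:
        try:
            scores = survnet.prognostic_scores(cv, cohort.features)
            ranking = survnet.rank_features(scores)
            ranking.to_csv(out / "feature_ranking.tsv", sep="\t", index=False)
            scores.write_tsv(out / "prognostic_scores.tsv")
            report.stage_status["rank"] = "ok"
            report.headline["top_features"] = ranking["feature"].head(10).tolist()
        except Exception as exc:
            logger.exception("rank stage failed")
            report.stage_status["rank"] = f"error: {exc}"
    elif on.get("rank", True):
        report.stage_status["rank"] = "skipped: missing trained models"

    gene_scores = None
    planted_set_name = "PLANTED_PATHWAY"
    gene_sets = None
    if on.get("transcriptional", True):
        try:
            genes = [f"G{j + 1:04d}" for j in range(config.n_genes)]
            planted = genes[: config.planted_set_size]
            expr, expr_out, _truth = synthetic.generate_expression(
                config.n_samples, config.n_genes, planted, config.set_effect,
                seed=seeds["transcriptional"])
            tcfg = survnet.TrainingConfig.transcriptional(
                seed=seeds["transcriptional"],
                epochs=config.training.epochs,
                learning_rate=config.training.learning_rate,
                dropout_rate=config.training.dropout_rate)
            model = survnet.train(expr, expr_out, tcfg)
            sens = survnet.feature_sensitivity(model, expr)
            gene_scores = pd.Series(sens, index=genes)
            gene_scores.rename("score").to_csv(out / "transcript_scores.tsv", sep="\t",
                                               header=True)
            rng = np.random.default_rng(seeds["transcriptional"] + 1)
            sets = {planted_set_name: planted}
            for k in range(config.n_gene_sets - 1):
                size = int(rng.integers(config.min_set_size, 80))
                sets[f"RANDOM_SET_{k + 1:03d}"] = list(
                    rng.choice(genes, size=size, replace=False))
            gene_sets = enrichment.GeneSetCollection(sets, provenance="synthetic")
            enrichment.write_gmt(gene_sets, out / "gene_sets.gmt")
            report.stage_status["transcriptional"] = "ok"
        except Exception as exc:
            logger.exception("transcriptional stage failed")
            report.stage_status["transcriptional"] = f"error: {exc}"

    if on.get("gsea", True) and gene_scores is not None and gene_sets is not None:
        try:
            res = enrichment.preranked_gsea(gene_scores, gene_sets,
                                            n_perm=config.n_perm,
                                            min_size=config.min_set_size,
                                            seed=seeds["gsea"])
            res.write_tsv(out / "gsea.tsv")
            report.stage_status["gsea"] = "ok"
            split = enrichment.two_direction_report(res)
            report.headline["enriched_good_prognosis"] = \
                split["good_prognosis"]["set"].head(5).tolist()
            report.headline["enriched_poor_prognosis"] = \
                split["poor_prognosis"]["set"].head(5).tolist()
            planted_row = res.table[res.table["set"] == planted_set_name]
            if len(planted_row):
                report.headline["planted_set_p"] = float(planted_row["p_nominal"].iloc[0])
                report.headline["planted_set_es"] = float(planted_row["es"].iloc[0])
        except Exception as exc:
            logger.exception("gsea stage failed")
            report.stage_status["gsea"] = f"error: {exc}"
    elif on.get("gsea", True):
        report.stage_status["gsea"] = "skipped: missing transcript scores"

    density_class = None
    if on.get("density", True):
        try:
            rng = np.random.default_rng(seeds["density"])
            fits = {}
            for i in range(config.n_density_samples):
                lam_t = config.lambda_tumor * float(rng.uniform(0.5, 1.5))
                pat = synthetic.generate_point_pattern(
                    lam_t, config.lambda_normal, 0.5, config.field_size,
                    config.field_size, seed=int(rng.integers(2 ** 31)),
                    sample_id=f"S{i + 1:03d}")
                nn = histodensity.nearest_neighbor_distances(pat)
                fits[pat.sample_id] = histodensity.fit_poisson_mixture(
                    nn, seed=int(rng.integers(2 ** 31)))
            density_class = histodensity.classify_cohort(fits)
            density_class.to_frame().to_csv(out / "density.tsv", sep="\t", index=False)
            report.stage_status["density"] = "ok"
            counts = pd.Series(density_class.labels).value_counts().to_dict()
            report.headline["density_split"] = counts
        except Exception as exc:
            logger.exception("density stage failed")
            report.stage_status["density"] = f"error: {exc}"

    if on.get("assoc", True) and cohort is not None:
        try:
            screen = stats.association_screen(cohort.features, cohort.ce_labels)
            screen.to_csv(out / "ce_associations.tsv", sep="\t", index=False)
            report.stage_status["assoc"] = "ok"
            report.headline["top_ce_associations"] = screen.head(5).to_dict("records")
        except Exception as exc:
            logger.exception("assoc stage failed")
            report.stage_status["assoc"] = f"error: {exc}"
    elif on.get("assoc", True):
        report.stage_status["assoc"] = "skipped: missing cohort"

    if on.get("survive", True) and cohort is not None:
        try:
            ce = cohort.ce_labels
            lr = stats.logrank_test(cohort.outcomes, ce)
            _, med_pos = stats.km_estimate(cohort.outcomes.subset(np.where(ce == 1)[0]))
            _, med_neg = stats.km_estimate(cohort.outcomes.subset(np.where(ce == 0)[0]))
            cox = stats.cox_fit(pd.DataFrame({"ce": ce}), cohort.outcomes)
            report.stage_status["survive"] = "ok"
            report.headline["ce_logrank_p"] = lr.p_two_sided
            report.headline["km_median_ce_pos"] = med_pos
            report.headline["km_median_ce_neg"] = med_neg
            report.headline["ce_hr"] = float(cox.table.loc["ce", "hr"])
        except Exception as exc:
            logger.exception("survive stage failed")
            report.stage_status["survive"] = f"error: {exc}"
    elif on.get("survive", True):
        report.stage_status["survive"] = "skipped: missing cohort"

    report.write(out / "report.json")
    logging.getLogger().removeHandler(fh)
    fh.close()
    return report
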