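"""End-to-end orchestration of the molecular scoring workflow.

Stages: load-or-simulate -> labeling-kit correction -> activity classes ->
moderated-t landscape (volcano, top lists) -> both median-ensemble
classifiers (Mayo_Prob_1 without IBDU, Mayo_Prob_2 with) -> transcript-set
scores (MCalpro) -> overrepresentation analysis -> outcome-association
battery.  Every stage writes its CSV artifacts into the output directory
and the run ends with ``report.json`` carrying the key numbers.  Stages are
re-entrant: each reads its inputs from the output directory, so a single
stage can be re-run against cached upstream artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, de, enrichment, outcomes, setscores, synthetic
from .data import CohortBundle, define_activity_classes, apply_kit_correction, load_cohort

logger = logging.getLogger(__name__)

#: Table-7 default clinical model; the narrative variant swaps total for partial Mayo.
CLINICAL_MODEL = ["endoscopic_mayo", "total_mayo", "fecal_calprotectin"]
MOLECULAR_MODEL = ["Mayo_Prob_1", "Mayo_Prob_2", "MCalpro"]
IMPORTANCE_VARIABLES = [
    "MCalpro", "Mayo_Prob_1", "Mayo_Prob_2",
    "endoscopic_mayo", "partial_mayo", "total_mayo", "fecal_calprotectin",
]


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """One config drives every stage; exactly one input source.

    Either the three input paths are given, or ``simulate`` holds a
    :class:`~ucscore.synthetic.CohortConfig` and the cohort is generated.
    """

    outdir: str = "ucscore_out"
    matrix_path: str | None = None
    samples_path: str | None = None
    annotation_path: str | None = None
    simulate: synthetic.CohortConfig | None = None
    gmt_path: str | None = None
    transcript_sets_path: str | None = None
    k_folds: int = 10
    n_features: int = 20
    seed: int = 0
    top_n_enrichment: int = 150
    status_threshold: float = 1.0
    clinical_model: list[str] = field(default_factory=lambda: list(CLINICAL_MODEL))
    molecular_model: list[str] = field(default_factory=lambda: list(MOLECULAR_MODEL))
    importance_trees: int = 500
    importance_permutations: int = 50

    def __post_init__(self) -> None:
        has_paths = all(p is not None for p in
                        (self.matrix_path, self.samples_path, self.annotation_path))
        if has_paths == (self.simulate is not None):
            raise ValueError("config must carry exactly one of: input paths, simulate block")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        payload = json.loads(Path(path).read_text())
        if "simulate" in payload and payload["simulate"] is not None:
            sim = dict(payload["simulate"])
            if "mayo_distribution" in sim:
                sim["mayo_distribution"] = tuple(sim["mayo_distribution"])
            payload["simulate"] = synthetic.CohortConfig(**sim)
        return cls(**payload)

    def echo(self) -> dict:
        payload = dataclasses.asdict(self)
        return payload


def _outpath(config: PipelineConfig) -> Path:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    return out


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig) -> CohortBundle:
    if config.simulate is None:
        raise ValueError("config has no simulate block")
    out = _outpath(config)
    bundle, truth = synthetic.generate_cohort(config.simulate)
    synthetic.write_cohort_files(bundle, truth, out)
    synthetic.write_synthetic_gene_sets(truth, bundle.annotation, out / "gene_sets.gmt",
                                        seed=config.simulate.seed)
    return bundle


def _load_bundle(config: PipelineConfig) -> CohortBundle:
    out = _outpath(config)
    if config.simulate is not None:
        if not (out / "matrix.tsv").exists():
            return stage_simulate(config)
        return load_cohort(out / "matrix.tsv", out / "samples.csv", out / "annotation.csv")
    return load_cohort(config.matrix_path, config.samples_path, config.annotation_path)


def _corrected_bundle(config: PipelineConfig) -> CohortBundle:
    bundle = _load_bundle(config)
    matrix = apply_kit_correction(bundle.matrix, bundle.samples)
    return CohortBundle(matrix=matrix, samples=bundle.samples, annotation=bundle.annotation)


def stage_de(config: PipelineConfig, bundle: CohortBundle | None = None) -> de.DEResults:
    out = _outpath(config)
    bundle = bundle if bundle is not None else _corrected_bundle(config)
    classes = define_activity_classes(bundle.samples, include_ibdu=False)
    results = de.fit_moderated_t(bundle.matrix, classes, control_ids=bundle.control_ids,
                                 annotation=bundle.annotation)
    results.table.rename_axis("probe_id").to_csv(out / "de_table.csv")
    results.volcano(bundle.annotation).rename_axis("probe_id").to_csv(out / "volcano.csv")
    for direction in ("increased", "decreased"):
        top = results.top(direction, k=min(30, len(results.table)), collapse_to_genes=True)
        top.to_csv(out / f"top_{direction}.csv")
    logger.info("%s", results.summary())
    return results


def stage_classify(config: PipelineConfig,
                   bundle: CohortBundle | None = None) -> dict[str, classify.CVResults]:
    out = _outpath(config)
    bundle = bundle if bundle is not None else _corrected_bundle(config)
    results = {}
    for include_ibdu in (False, True):
        classes = define_activity_classes(bundle.samples, include_ibdu=include_ibdu)
        model = classify.ActivityClassifier(bundle.matrix, classes,
                                            n_features=config.n_features)
        cv = model.cross_validate(k=config.k_folds, seed=config.seed)
        results[classes.cohort_tag] = cv
        cv.scores.rename_axis("sample_id").to_csv(out / f"cv_scores_{cv.cohort_tag}.csv")
        feats = pd.DataFrame(
            [(fold, rank + 1, probe) for fold, probes in cv.fold_features.items()
             for rank, probe in enumerate(probes)],
            columns=["fold", "rank", "probe_id"],
        )
        feats.to_csv(out / f"cv_features_{cv.cohort_tag}.csv", index=False)
        logger.info("%s", cv.summary())
    return results


def stage_set_scores(config: PipelineConfig, bundle: CohortBundle | None = None) -> pd.DataFrame:
    out = _outpath(config)
    bundle = bundle if bundle is not None else _corrected_bundle(config)
    sets = [setscores.calprotectin_set(bundle.annotation)]
    if config.transcript_sets_path:
        sets += setscores.read_transcript_sets(config.transcript_sets_path)
    table = setscores.score_sets(bundle.matrix, bundle.control_ids, sets)
    table.rename_axis("sample_id").to_csv(out / "set_scores.csv")
    return table


def stage_enrich(config: PipelineConfig, bundle: CohortBundle | None = None,
                 de_results: de.DEResults | None = None) -> pd.DataFrame | None:
    out = _outpath(config)
    bundle = bundle if bundle is not None else _corrected_bundle(config)
    gmt = config.gmt_path
    if gmt is None and (out / "gene_sets.gmt").exists():
        gmt = out / "gene_sets.gmt"
    if gmt is None:
        logger.warning("no GMT collection configured; enrichment stage skipped")
        return None
    if de_results is None:
        de_results = stage_de(config, bundle)
    collection = enrichment.read_gene_sets(gmt, universe=enrichment.array_universe(bundle.annotation))
    genes = enrichment.select_enrichment_input(de_results.table, bundle.annotation,
                                               n=config.top_n_enrichment)
    table = enrichment.ora_test(genes, collection)
    table.to_csv(out / "enrichment.csv", index=False)
    return table


def stage_outcomes(config: PipelineConfig, bundle: CohortBundle,
                   cv_results: dict[str, classify.CVResults],
                   set_scores: pd.DataFrame) -> dict:
    out = _outpath(config)
    predictors = outcomes.build_predictor_table(
        bundle.samples,
        mayo_prob_1=cv_results["Mayo_Prob_1"].scores["ensemble"],
        mayo_prob_2=cv_results["Mayo_Prob_2"].scores["ensemble"],
        mcalpro=set_scores["MCalpro"],
        status_threshold=config.status_threshold,
    )
    correlations = outcomes.correlation_table(predictors)
    correlations.to_csv(out / "correlations.csv", index=False)

    group_tests = outcomes.group_test_table(predictors)
    group_tests.to_csv(out / "group_tests.csv", index=False)

    screen = outcomes.single_predictor_screen(predictors)
    screen.to_csv(out / "predictor_screen.csv", index=False)

    full_model = config.clinical_model + config.molecular_model
    comparisons = {
        "molecular_over_clinical": outcomes.likelihood_ratio_compare(
            predictors, config.clinical_model, full_model),
        "clinical_over_molecular": outcomes.likelihood_ratio_compare(
            predictors, config.molecular_model, full_model),
    }
    comp_table = pd.DataFrame([
        {"comparison": name, "reduced": "+".join(c.reduced), "full": "+".join(c.full),
         "lrt": c.lrt, "df": c.df, "p": c.p, "auc_reduced": c.auc_reduced,
         "auc_full": c.auc_full, "n": c.n}
        for name, c in comparisons.items()
    ])
    comp_table.to_csv(out / "model_comparison.csv", index=False)

    importance = outcomes.permutation_importance(
        predictors, variables=[v for v in IMPORTANCE_VARIABLES if v in predictors.columns],
        n_trees=config.importance_trees, n_permutations=config.importance_permutations,
        seed=config.seed,
    )
    importance.to_csv(out / "importance.csv", index=False)

    return {
        "correlations": correlations.to_dict(orient="records"),
        "group_tests": group_tests.to_dict(orient="records"),
        "lrt": {name: {"p": c.p, "lrt": c.lrt, "df": c.df,
                       "auc_reduced": c.auc_reduced, "auc_full": c.auc_full}
                for name, c in comparisons.items()},
        "importance_ranking": importance["variable"].tolist(),
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns (and writes) the summary report."""
    out = _outpath(config)

    def run(stage_name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - abort with the stage name
            raise StageError(stage_name, exc) from exc

    if config.simulate is not None:
        run("simulate", stage_simulate, config)
    bundle = run("load", _corrected_bundle, config)
    de_results = run("de", stage_de, config, bundle)
    cv_results = run("classify", stage_classify, config, bundle)
    set_scores = run("score-sets", stage_set_scores, config, bundle)
    enrich_table = run("enrich", stage_enrich, config, bundle, de_results)
    outcome_report = run("outcomes", stage_outcomes, config, bundle, cv_results, set_scores)

    report = {
        "seed": config.seed,
        "config": config.echo(),
        "n_samples": int(bundle.matrix.shape[1]),
        "n_probesets": int(bundle.matrix.shape[0]),
        "auc": {tag: cv.auc for tag, cv in cv_results.items()},
        "de_significant_fdr05": int((de_results.table["p_fdr"] < 0.05).sum()),
        "moderation": {"prior_df": float(de_results.params.prior_df),
                       "prior_var": float(de_results.params.prior_var)},
        "top_enrichment": (enrich_table.head(10).to_dict(orient="records")
                           if enrich_table is not None else None),
        **outcome_report,
    }
    (out / "report.json").write_text(json.dumps(report, indent=1, default=float))
    logger.info("pipeline complete; report at %s", out / "report.json")
    return report
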