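"""End-to-end orchestration: curate → features → splits → grid search →
holdout → importance → ordination → robustness → resilience.

Stages communicate through files, every artifact carries provenance (config
hash, seed, package version), and a given config + seed determines every
output deterministically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, curation, evaluate, features, forest, ordination
from . import robustness as rob
from . import synthdata
from .io_model import ValidationError, export_results, load_dataset

log = logging.getLogger("microtnt")


@dataclass
class PipelineConfig:
    """Validated, structured configuration of a full run."""

    seed: int = 0
    output_dir: str = "microtnt_out"
    # input: either the three table paths or a synthetic-data block
    community_path: str | None = None
    taxonomy_path: str | None = None
    samples_path: str | None = None
    synthetic: dict = field(default_factory=dict)
    # curation
    distance_threshold_m: float = 20.0
    imbalance_rule: int = 1
    detection_limit_pmol_g: float = curation.DETECTION_LIMIT_PMOL_G
    # features / grid
    thresholds: tuple = (0.08,)
    ranks: tuple = ("genus",)
    n_trees: tuple = (500,)
    mtry_factors: tuple = (5,)
    models_per_combo: int = 5
    # splits
    n_splits: int = 6
    holdout_fraction: float = 0.25
    # importance
    importance_models: int = 10
    importance_cutoff: float = 0.25
    p_cutoff: float = 0.01
    # feature filter referencing a prior importance artifact
    feature_filter: str | None = None  # "top" | "non_top" | None
    feature_filter_artifact: str | None = None
    # ordination
    envfit_permutations: int = 999
    # robustness
    consistency_models: int = 50
    consistency_trees: int = 500
    run_ann: bool = False
    ann_repeats: int = 10
    ann_folds: int = 3

    def __post_init__(self) -> None:
        have_paths = all(
            p is not None
            for p in (self.community_path, self.taxonomy_path, self.samples_path)
        )
        if not have_paths and self.synthetic is None:
            raise ValidationError("config must provide table paths or a synthetic block")
        if self.feature_filter not in (None, "top", "non_top"):
            raise ValidationError(f"unknown feature_filter {self.feature_filter!r}")
        self.thresholds = tuple(self.thresholds)
        self.ranks = tuple(self.ranks)
        self.n_trees = tuple(self.n_trees)
        self.mtry_factors = tuple(self.mtry_factors)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _provenance(config: PipelineConfig) -> dict:
    return {
        "config_hash": config.digest(),
        "seed": config.seed,
        "version": __version__,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the artifact bundle as a dict.

    Any stage failure aborts with the stage name; artifacts written before
    the failure are retained in the output directory.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    jsonl = (outdir / "run_log.jsonl").open("w")

    def record(stage: str, **info) -> None:
        log.info("stage %s: %s", stage, info)
        jsonl.write(json.dumps({"stage": stage, "time": time.time(), **info}) + "\n")
        jsonl.flush()

    bundle: dict = {"provenance": _provenance(config)}
    export_results(bundle["provenance"], outdir / "provenance.json", format="json")
    stage = "load"
    try:
        # -- load -----------------------------------------------------------
        if config.community_path:
            community, taxonomy, samples = load_dataset(
                config.community_path, config.taxonomy_path, config.samples_path
            )
        else:
            synth_cfg = synthdata.SynthConfig(
                **{"seed": config.seed, **config.synthetic}
            )
            dataset = synthdata.generate(synth_cfg)
            community, taxonomy, samples = (
                dataset.community,
                dataset.taxonomy,
                dataset.samples,
            )
            bundle["synthetic_truth"] = dataset
        record(stage, n_libraries=len(community.sample_ids))

        # -- curate ---------------------------------------------------------
        stage = "curate"
        averaged = curation.average_replicates(community, samples)
        sediment_meta = samples.data.groupby(samples.data["replicate_group"]).first()
        sediment_meta.index = sediment_meta.index.astype(str)
        sediments = type(samples)(
            sediment_meta,
            env_columns=samples.env_columns,
            metabolite_columns=samples.metabolite_columns,
        )
        response_all = curation.binarize_response(
            sediments, config.detection_limit_pmol_g
        )
        report = curation.apply_exclusion_guideline(
            sediments,
            response_all,
            curation.GuidelineParams(config.distance_threshold_m, config.imbalance_rule),
        )
        kept = report.kept_ids
        averaged = type(averaged)._unchecked(
            averaged.data.loc[kept], averaged.unit, averaged.rank
        )
        sediments = type(sediments)(
            sediments.data.loc[kept],
            env_columns=sediments.env_columns,
            metabolite_columns=sediments.metabolite_columns,
        )
        response = response_all.subset(kept)
        export_results(report, outdir / "curation_report.tsv")
        record(stage, kept=len(kept), removed=len(report.removed_ids))

        # -- splits ---------------------------------------------------------
        stage = "splits"
        splits = evaluate.make_splits(
            kept, config.holdout_fraction, config.n_splits, seed=config.seed
        )
        record(stage, k=len(splits))

        # -- grid search ----------------------------------------------------
        stage = "grid_search"
        grid = evaluate.GridSpec(
            config.thresholds, config.ranks, config.n_trees, config.mtry_factors
        )
        grid_result = evaluate.grid_search(
            averaged,
            taxonomy,
            response,
            splits,
            grid,
            models_per_combo=config.models_per_combo,
            seed=config.seed,
        )
        export_results(grid_result, outdir / "grid_result.tsv")
        best = (
            grid_result.mean_by_combination()
            .sort_values("mean", ascending=False)
            .iloc[0]
        )
        record(stage, best=best.to_dict())

        # -- holdout --------------------------------------------------------
        stage = "holdout"
        hp = forest.HyperParams(
            int(best["trees"]), int(best["mtry_factor"]), config.seed
        )
        fm = evaluate.build_input_features(
            averaged, taxonomy, float(best["threshold"]), str(best["rank"])
        )
        if config.feature_filter:
            prior = pd.read_csv(config.feature_filter_artifact, sep="\t", index_col=0)
            top = set(prior.index)
            chosen = (
                [f for f in fm.feature_ids if f in top]
                if config.feature_filter == "top"
                else [f for f in fm.feature_ids if f not in top]
            )
            fm = fm.subset_features(chosen)
        holdout = evaluate.evaluate_holdout(fm, response, hp, splits)
        export_results(holdout, outdir / "holdout_scores.tsv")
        record(stage, mean=holdout.mean, sd=holdout.sd)

        # -- importance / fingerprint ---------------------------------------
        stage = "importance"
        imp = forest.importance_corrected_janitza(
            fm, response, hp, m_models=config.importance_models
        )
        export_results(imp, outdir / "importance_janitza.tsv")
        top_features = forest.select_top_features(
            imp, config.importance_cutoff, config.p_cutoff
        )
        (outdir / "top_features.txt").write_text("\n".join(top_features) + "\n")
        record(stage, n_top=len(top_features))

        # -- ordination ------------------------------------------------------
        stage = "ordination"
        ord_features = fm.subset_features(top_features) if top_features else fm
        _, prox = forest.unsupervised_forest(
            ord_features, forest.HyperParams(config.consistency_trees, 1, config.seed)
        )
        ordn = ordination.ordinate_from_proximity(prox)
        export_results(ordn.scores, outdir / "ordination_scores.tsv")
        vectors = ordination.fit_environment_vectors(
            ordn, sediments.env(), n_perm=config.envfit_permutations, seed=config.seed
        )
        export_results(vectors, outdir / "envfit_vectors.tsv")
        record(stage, explained=ordn.explained.to_dict())

        # -- robustness ------------------------------------------------------
        stage = "robustness"
        cons = rob.consistency_analysis(
            fm,
            response,
            forest.HyperParams(config.consistency_trees, 1, config.seed),
            m_models=config.consistency_models,
        )
        export_results(cons, outdir / "consistency.tsv")
        ann_result = None
        if config.run_ann:
            scaled = features.encode_and_scale(fm)
            ann_result = rob.ann_cross_validate(
                scaled,
                response,
                repeats=config.ann_repeats,
                folds=config.ann_folds,
                seed=config.seed,
            )
            export_results(ann_result, outdir / "ann_rates.tsv")
        record(stage, n_models=cons.n_models)

        # -- resilience ------------------------------------------------------
        stage = "resilience"
        resilience = rob.false_positive_resilience(cons, sediments)
        export_results(resilience, outdir / "resilience_summary.tsv")
        record(stage, partitions=len(resilience.summary))

        bundle.update(
            curation_report=report,
            splits=splits,
            grid_result=grid_result,
            holdout=holdout,
            importance=imp,
            top_features=top_features,
            ordination=ordn,
            envfit=vectors,
            consistency=cons,
            ann=ann_result,
            resilience=resilience,
        )
        return bundle
    except Exception as exc:
        record(stage, error=str(exc))
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc
    finally:
        jsonl.close()
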