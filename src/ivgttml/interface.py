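"""End-to-end orchestration and command-line interface.

Stage order: synthetic cohort (or feature file) -> feature extraction ->
LOF outlier removal -> decision-tree feature selection -> 5-fold CV of the
three classifiers -> metrics / pairwise comparison / Venn counts / cohort
summary.  Every run writes its configuration verbatim into the output
directory and logs stage parameters and counts; reruns with the same
configuration are bit-identical for the deterministic stages.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import click
import pandas as pd
import yaml

from . import classify, cohort_stats, feature_table, synth_cohort
from .constants import DECONV_LAMBDA_DEFAULT, FIT_START_MIN

__all__ = ["RunConfig", "run_pipeline", "cli"]

logger = logging.getLogger("ivgttml")

# fixed per-stage seed offsets so stages can be rerun alone reproducibly
STAGE_SEED_OFFSETS = {"simulate": 0, "extract": 101, "classify": 211, "stats": 307}


@dataclass
class RunConfig:
    """Complete configuration of one pipeline run."""

    seed: int = 0
    out_dir: str = "ivgttml_run"
    features_path: str | None = None  #: skip simulation, read this CSV instead
    simulation: synth_cohort.SimulationConfig = field(
        default_factory=synth_cohort.SimulationConfig
    )
    deconv_lambda: float = DECONV_LAMBDA_DEFAULT
    fit_start: float = FIT_START_MIN
    lof_neighbors: int = 20
    lof_contamination: float = 0.04
    cv_folds: int = 5
    classifiers: tuple = ("tree", "naive_bayes", "logistic_l2")

    def stage_seed(self, stage: str) -> int:
        return self.seed + STAGE_SEED_OFFSETS[stage]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["classifiers"] = list(self.classifiers)
        d["simulation"]["schedule"] = list(self.simulation.schedule)
        d["simulation"]["group_params"] = {
            g: {k: list(v) for k, v in params.items()}
            for g, params in self.simulation.group_params.items()
        }
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.pop("simulation", {})
        sim.setdefault("seed", raw.get("seed", 0))
        config = cls(**{k: v for k, v in raw.items() if k != "simulation"})
        config.simulation = synth_cohort.SimulationConfig(**sim)
        return config


def _setup_logging(out_dir: Path) -> None:
    logger.setLevel(logging.INFO)
    if not logger.handlers:
        logger.addHandler(logging.StreamHandler())
    file_handler = logging.FileHandler(out_dir / "run.log", mode="w")
    file_handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(file_handler)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis and return the report directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out)
    (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict()))

    if config.features_path:
        logger.info("stage extract: reading features from %s", config.features_path)
        features = feature_table.read_feature_matrix(config.features_path)
    else:
        sim = dataclasses.replace(config.simulation, seed=config.stage_seed("simulate"))
        logger.info(
            "stage simulate: n_nonprog=%d n_prog=%d seed=%d",
            sim.n_nonprog, sim.n_prog, sim.seed,
        )
        truths = synth_cohort.sample_cohort(sim)
        records = synth_cohort.simulate_cohort(truths, sim)
        synth_cohort.write_cohort(out, records, truths)
        logger.info(
            "stage extract: fit_start=%g deconv_lambda=%g",
            config.fit_start, config.deconv_lambda,
        )
        features = feature_table.extract_feature_matrix(
            records, fit_start=config.fit_start, deconv_lambda=config.deconv_lambda
        )
        feature_table.write_feature_matrix(features, out / "features.csv")

    logger.info(
        "stage lof: neighbors=%d contamination=%g n=%d",
        config.lof_neighbors, config.lof_contamination, len(features),
    )
    retained, flagged = classify.lof_filter(
        features, neighbors=config.lof_neighbors,
        contamination=config.lof_contamination,
    )
    pd.Series(flagged, name="id").to_csv(out / "flagged_outliers.csv", index=False)
    logger.info("stage lof: removed %d cases, retained %d", len(flagged), len(retained))

    normalized = classify.normalize(retained)
    tree = classify.induce_tree(normalized)
    logger.info("stage selection: selected features %s", tree.selected_features)
    (out / "selected_features.json").write_text(
        json.dumps(tree.selected_features, indent=2)
    )

    selected = retained[["label", *tree.selected_features]] if tree.selected_features \
        else retained
    seed = config.stage_seed("classify")
    reports = {
        name: classify.crossvalidate(name, selected, k=config.cv_folds, seed=seed)
        for name in config.classifiers
    }
    metric_rows = []
    for name, report in reports.items():
        logger.info("stage cv: %s pooled confusion %s", name, report.pooled_confusion)
        metric_rows.append({"classifier": name, **report.metrics})
        report.predictions.to_csv(out / f"predictions_{name}.csv")
    pd.DataFrame(metric_rows).set_index("classifier").to_csv(out / "metrics.csv")

    comparison = classify.compare_classifiers(reports)
    pairwise = pd.concat(
        {m: t for m, t in comparison.pairwise.items()}, names=["measure", "classifier"]
    )
    pairwise.to_csv(out / "pairwise.csv")
    (out / "venn.json").write_text(
        json.dumps(
            {"correct": comparison.venn_correct,
             "misclassified": comparison.venn_misclassified},
            indent=2,
        )
    )

    summary = cohort_stats.summary_table(retained, seed=config.stage_seed("stats"))
    summary.table.to_csv(out / "summary.csv")
    logger.info("pipeline complete: %s", out)
    return out


# --- CLI ----------------------------------------------------------------------

@click.group()
def cli() -> None:
    """IM-IVGTT feature extraction and progression classification."""


@cli.command()
@click.option("--seed", type=int, required=True)
@click.option("--out", "out_dir", type=click.Path(), required=True)
@click.option("--n-nonprog", type=int, default=59, show_default=True)
@click.option("--n-prog", type=int, default=19, show_default=True)
def simulate(seed, out_dir, n_nonprog, n_prog):
    """Generate a synthetic cohort (subjects/timeseries/truth CSVs)."""
    config = synth_cohort.SimulationConfig(
        n_nonprog=n_nonprog, n_prog=n_prog, seed=seed
    )
    truths = synth_cohort.sample_cohort(config)
    records = synth_cohort.simulate_cohort(truths, config)
    synth_cohort.write_cohort(out_dir, records, truths)
    click.echo(f"wrote {len(records)} subjects to {out_dir}")


@cli.command()
@click.option("--cohort", type=click.Path(exists=True), required=True)
@click.option("--out", "out_path", type=click.Path(), required=True)
def extract(cohort, out_path):
    """Extract the 34-feature table from a cohort directory."""
    records = synth_cohort.read_cohort(cohort)
    features = feature_table.extract_feature_matrix(records)
    feature_table.write_feature_matrix(features, out_path)
    click.echo(f"wrote features for {len(features)} subjects to {out_path}")


@cli.command("classify")
@click.option("--features", "features_path", type=click.Path(exists=True), required=True)
@click.option("--seed", type=int, required=True)
@click.option("--out", "out_dir", type=click.Path(), required=True)
def classify_cmd(features_path, seed, out_dir):
    """Run LOF, feature selection, CV and comparisons on a feature table."""
    config = RunConfig(seed=seed, out_dir=out_dir, features_path=features_path)
    run_pipeline(config)


@cli.command()
@click.option("--features", "features_path", type=click.Path(exists=True), required=True)
@click.option("--out", "out_path", type=click.Path(), required=True)
@click.option("--seed", type=int, default=0, show_default=True)
def summarize(features_path, out_path, seed):
    """Write the per-feature group summary table."""
    features = feature_table.read_feature_matrix(features_path)
    summary = cohort_stats.summary_table(features, seed=seed)
    summary.table.to_csv(out_path)
    click.echo(f"wrote summary for {len(summary.table)} features to {out_path}")


@cli.command("run-all")
@click.option("--seed", type=int, required=True)
@click.option("--out", "out_dir", type=click.Path(), required=True)
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
def run_all(seed, out_dir, config_path):
    """Full pipeline: simulate, extract, classify, summarize."""
    if config_path:
        config = RunConfig.from_yaml(config_path)
        config.seed = seed
        config.out_dir = out_dir
    else:
        config = RunConfig(seed=seed, out_dir=out_dir)
    run_pipeline(config)
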