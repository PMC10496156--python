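"""End-to-end experiment runner and command-line interface.

The pipeline replays the screening protocol on a synthetic cohort:
simulate → extract features → rank candidate models by 10-fold CV →
GA feature selection over the top three → train on a stratified 90/10
split with training-side oversampling → evaluate on the held-out test set
with exact binomial intervals → ablation over feature sets.  Every stage
is seeded from a single run seed and the emitted report is byte-identical
across reruns of the same configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import click
import numpy as np
import pandas as pd
import yaml

from . import classify, evaluate, features, ga_select, landmark_io, synth_cohort
from .errors import FHPError, IncompleteLandmarksError

log = logging.getLogger("fhpdetect")

DEFAULT_STAGES = ["simulate", "extract", "rank", "select", "train", "evaluate", "ablate"]


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "fhp_run"
    stages: List[str] = field(default_factory=lambda: list(DEFAULT_STAGES))
    cohort: Dict = field(default_factory=dict)      # CohortParams overrides
    ga: Dict = field(default_factory=dict)          # GAConfig overrides
    conf_min: float = landmark_io.DEFAULT_CONF_MIN
    cv_folds: int = 10
    test_fraction: float = 0.10
    models: Optional[List[Dict]] = None             # candidate ModelSpec dicts
    oversample: str = "train_folds"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise FHPError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def canonical(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:16]


def default_candidates(seed: int, n_estimators: Optional[int] = None) -> List[classify.ModelSpec]:
    """The three tree-ensemble candidates, seed-pinned; hyperparameters are
    library defaults unless a tree count is given."""
    hp = {} if n_estimators is None else {"n_estimators": n_estimators}
    return [
        classify.ModelSpec.make("extremely_randomized_trees", seed, "ETC", **hp),
        classify.ModelSpec.make("gradient_boosting", seed, "GBC", **hp),
        classify.ModelSpec.make("extreme_gradient_boosting", seed, "XGB", **hp),
    ]


def _specs_from_config(config: RunConfig) -> List[classify.ModelSpec]:
    if not config.models:
        return default_candidates(config.seed)
    specs = []
    for m in config.models:
        specs.append(classify.ModelSpec.make(
            m["family"], m.get("seed", config.seed), m.get("name"),
            **m.get("hyperparams", {})))
    return specs


def extract_features_from_files(poses_dir, demographics_csv, conf_min: float) -> pd.DataFrame:
    """Read per-subject pose JSONs + a demographics table and assemble the
    feature table.  Subjects with missing anatomical points are skipped
    (logged), mirroring the quality filtering any landmark pipeline needs."""
    demo = pd.read_csv(demographics_csv).set_index("subject_id")
    vectors = []
    skipped = 0
    for path in sorted(Path(poses_dir).glob("*.json")):
        for rec in landmark_io.read_openpose_json(path):
            try:
                pts = landmark_io.extract_anatomical_points(rec, conf_min)
            except IncompleteLandmarksError as exc:
                log.warning("skipping %s: %s", rec.subject_id, exc)
                skipped += 1
                continue
            meta = None
            if rec.subject_id in demo.index:
                row = demo.loc[rec.subject_id]
                meta = landmark_io.SubjectMeta(
                    gender=row.get("gender"), age=row.get("age"),
                    height=row.get("height"), weight=row.get("weight"),
                    bmi=row.get("bmi"), label=row.get("label"),
                )
            vectors.append(features.compute_features(pts, meta, subject_id=rec.subject_id))
    if skipped:
        log.info("skipped %d subjects with incomplete landmarks", skipped)
    return features.feature_frame(vectors)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order; returns the (JSON-ready) report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config": json.loads(config.canonical()),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    stages = config.stages
    table: Optional[pd.DataFrame] = None
    features_csv = out / "features.csv"

    try:
        if "simulate" in stages:
            params = synth_cohort.CohortParams(seed=config.seed, **config.cohort)
            manifest = synth_cohort.generate_cohort(params, out / "cohort")
            report["stages"]["simulate"] = manifest
            log.info("simulated %d subjects (%d positive)",
                     manifest["n_subjects"], manifest["n_positive"])

        if "extract" in stages:
            cohort_dir = out / "cohort"
            table = extract_features_from_files(
                cohort_dir / "poses", cohort_dir / "demographics.csv", config.conf_min)
            features.write_feature_table(table, features_csv)
            report["stages"]["extract"] = {
                "n_rows": int(len(table)), "features_csv": str(features_csv)}

        if table is None and any(s in stages for s in ("rank", "select", "train", "evaluate", "ablate")):
            table = features.read_feature_table(features_csv)

        specs = _specs_from_config(config)
        top3 = [(s, None) for s in specs[:3]]
        if "rank" in stages:
            ranked = classify.rank_models(
                table, specs, k=config.cv_folds, seed=config.seed,
                oversample=config.oversample)
            top3 = ranked
            report["stages"]["rank"] = [
                {"model": s.name or s.family, "cv_accuracy": a} for s, a in ranked]

        selected_spec = top3[0][0]
        selected_cols = list(features.FEATURE_COLUMNS)
        if "select" in stages:
            ga_cfg = ga_select.GAConfig(seed=config.seed, **config.ga)
            selected_spec, mask, sel_report = ga_select.select_features_across_models(
                table, [s for s, _ in top3], ga_cfg)
            selected_cols = [c for c, b in zip(features.FEATURE_COLUMNS, mask) if b]
            with open(out / "ga_report.json", "w") as fh:
                json.dump(sel_report, fh, indent=1, sort_keys=True)
            report["stages"]["select"] = {
                "model": selected_spec.name or selected_spec.family,
                "selected_features": selected_cols,
                "comparison": sel_report["comparison"],
            }

        model = None
        test = None
        if "train" in stages or "evaluate" in stages:
            plan = classify.stratified_split(table, config.test_fraction, config.seed)
            train_df = table[table["subject_id"].isin(plan.train_ids)]
            test = table[table["subject_id"].isin(plan.test_ids)]
            model = classify.train_final(
                train_df, selected_spec, selected_cols, seed=config.seed)
            report["stages"]["train"] = {
                "model": selected_spec.name or selected_spec.family,
                "n_train": int(len(train_df)), "n_test": int(len(test)),
                "features": selected_cols,
            }

        if "evaluate" in stages:
            y_pred = classify.predict(model, test)
            cm = evaluate.ConfusionMatrix.from_labels(test["label"].to_numpy(), y_pred)
            report["stages"]["evaluate"] = {
                "confusion": {"TP": cm.TP, "FP": cm.FP, "TN": cm.TN, "FN": cm.FN},
                "metrics": evaluate.metrics_report(cm),
            }

        if "ablate" in stages:
            sets = {"selected": selected_cols,
                    "all_features": list(features.FEATURE_COLUMNS)}
            abl = evaluate.ablation_study(
                table, selected_spec, sets,
                test_fraction=config.test_fraction, seed=config.seed)
            abl.to_csv(out / "ablation.csv", index=False, float_format="%.10g")
            report["stages"]["ablate"] = abl.to_dict(orient="records")
    except FHPError as exc:
        stage = next((s for s in stages if s not in report["stages"]), "?")
        raise FHPError(f"stage {stage!r} failed: {exc}") from exc

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report


# ---------------------------------------------------------------- CLI ----

@click.group()
@click.option("-v", "--verbose", is_flag=True, help="debug logging to stderr")
def cli(verbose):
    """Non-contact forward-head-posture screening toolkit."""
    logging.basicConfig(
        stream=sys.stderr, format="%(levelname)s %(name)s: %(message)s",
        level=logging.DEBUG if verbose else logging.INFO)


@cli.command()
@click.option("--n", type=int, default=200, show_default=True)
@click.option("--seed", type=int, required=True)
@click.option("--out", type=click.Path(), required=True)
def simulate(n, seed, out):
    """Generate a synthetic labelled cohort (pose JSONs + CSVs)."""
    params = synth_cohort.CohortParams(n_subjects=n, seed=seed)
    manifest = synth_cohort.generate_cohort(params, out)
    click.echo(json.dumps(manifest, indent=1, sort_keys=True))


@cli.command()
@click.option("--poses", type=click.Path(exists=True), required=True)
@click.option("--demographics", type=click.Path(exists=True), required=True)
@click.option("--out", type=click.Path(), required=True)
@click.option("--conf-min", type=float, default=landmark_io.DEFAULT_CONF_MIN, show_default=True)
def extract(poses, demographics, out, conf_min):
    """Extract the 12-feature table from pose files."""
    table = extract_features_from_files(poses, demographics, conf_min)
    features.write_feature_table(table, out)
    click.echo(f"wrote {len(table)} rows to {out}")


@cli.command()
@click.option("--features", "features_csv", type=click.Path(exists=True), required=True)
@click.option("--seed", type=int, required=True)
@click.option("--out", type=click.Path(), required=True)
@click.option("--population", type=int, default=50, show_default=True)
@click.option("--generations", type=int, default=40, show_default=True)
def select(features_csv, seed, out, population, generations):
    """GA feature selection across the three candidate models."""
    table = features.read_feature_table(features_csv)
    cfg = ga_select.GAConfig(seed=seed, population_size=population, generations=generations)
    spec, mask, report = ga_select.select_features_across_models(
        table, default_candidates(seed), cfg)
    with open(out, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    click.echo(f"winner: {report['winner']}; features: "
               f"{[c for c, b in zip(features.FEATURE_COLUMNS, mask) if b]}")


@cli.command()
@click.option("--features", "features_csv", type=click.Path(exists=True), required=True)
@click.option("--model", "family", type=click.Choice(["etc", "gbc", "xgb"]), default="etc", show_default=True)
@click.option("--columns", default=None, help="comma-separated feature columns (default: all 12)")
@click.option("--seed", type=int, required=True)
@click.option("--out", type=click.Path(), required=True)
def train(features_csv, family, columns, seed, out):
    """Train a final model on a feature-table CSV and persist it."""
    import joblib

    fam = {"etc": "extremely_randomized_trees", "gbc": "gradient_boosting",
           "xgb": "extreme_gradient_boosting"}[family]
    table = features.read_feature_table(features_csv)
    cols = columns.split(",") if columns else list(features.FEATURE_COLUMNS)
    model = classify.train_final(table, classify.ModelSpec.make(fam, seed), cols, seed=seed)
    joblib.dump(model, out)
    click.echo(f"trained {fam} on {len(table)} rows; saved to {out}")


@cli.command()
@click.option("--features", "features_csv", type=click.Path(exists=True), required=True)
@click.option("--model", "model_path", type=click.Path(exists=True), required=True)
@click.option("--out", type=click.Path(), required=True)
def predict(features_csv, model_path, out):
    """Predict labels for a feature-table CSV with a saved model."""
    import joblib

    table = features.read_feature_table(features_csv)
    model = joblib.load(model_path)
    labels = classify.predict(model, table)
    pd.DataFrame({"subject_id": table["subject_id"], "predicted_label": labels}
                 ).to_csv(out, index=False)
    click.echo(f"wrote {len(labels)} predictions to {out}")


@cli.command("evaluate")
@click.option("--features", "features_csv", type=click.Path(exists=True), required=True)
@click.option("--model", "model_path", type=click.Path(exists=True), required=True)
@click.option("--out", type=click.Path(), required=True)
def evaluate_cmd(features_csv, model_path, out):
    """Confusion matrix + exact 95% CIs of a saved model on labelled data."""
    import joblib

    table = features.read_feature_table(features_csv)
    model = joblib.load(model_path)
    y_pred = classify.predict(model, table)
    cm = evaluate.ConfusionMatrix.from_labels(table["label"].to_numpy(), y_pred)
    doc = {"confusion": {"TP": cm.TP, "FP": cm.FP, "TN": cm.TN, "FN": cm.FN},
           "metrics": evaluate.metrics_report(cm)}
    with open(out, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
    click.echo(json.dumps(doc["metrics"], indent=1, sort_keys=True))


@cli.command()
@click.option("--features", "features_csv", type=click.Path(exists=True), required=True)
@click.option("--model", "family", type=click.Choice(["etc", "gbc", "xgb"]), default="etc", show_default=True)
@click.option("--sets", required=True,
              help="semicolon-separated named masks, e.g. 'angles=NAH,ENA,PAH,EAH;all=*'")
@click.option("--seed", type=int, required=True)
@click.option("--out", type=click.Path(), required=True)
def ablate(features_csv, family, sets, seed, out):
    """Ablation table over named feature sets on a shared split."""
    fam = {"etc": "extremely_randomized_trees", "gbc": "gradient_boosting",
           "xgb": "extreme_gradient_boosting"}[family]
    table = features.read_feature_table(features_csv)
    feature_sets = {}
    for part in sets.split(";"):
        name, cols = part.split("=", 1)
        feature_sets[name] = (list(features.FEATURE_COLUMNS) if cols.strip() == "*"
                              else cols.split(","))
    abl = evaluate.ablation_study(table, classify.ModelSpec.make(fam, seed),
                                  feature_sets, seed=seed)
    abl.to_csv(out, index=False, float_format="%.10g")
    click.echo(abl.to_string(index=False))


@cli.command()
@click.option("--config", "config_path", type=click.Path(exists=True), required=True)
@click.option("--seed", type=int, default=None, help="override the config seed")
def run(config_path, seed):
    """Run the full pipeline from a YAML config."""
    config = RunConfig.from_yaml(config_path)
    if seed is not None:
        config.seed = seed
    try:
        report = run_pipeline(config)
    except FHPError as exc:
        raise click.ClickException(str(exc))
    ev = report["stages"].get("evaluate", {})
    click.echo(json.dumps(ev, indent=1, sort_keys=True))


if __name__ == "__main__":  # pragma: no cover
    cli()
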