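"""End-to-end orchestration: simulate/load -> screen -> train -> score -> evaluate.

Each stage persists its outputs under the run directory with fixed file
names, so stages are independently re-runnable and a finished run is a
complete audit trail. A single global seed fans out to per-stage seeds
through :func:`stage_seed` (a documented SeedSequence derivation), and the
run manifest records the config hash, per-stage record counts, seeds and
wall-clock, making bit-reproducibility checkable by hashing the output
files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
import warnings
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluate as ev
from . import io as uio
from .model import UAIscoreModel, four_group_labels, score, train_uaiscore
from .screen import (
    interaction_screen,
    mad_filter,
    select_marker_genes,
    split_cohort,
    univariate_survival_screen,
)
from .simulate import SimulationConfig, SyntheticTrial, simulate_trial

logger = logging.getLogger("uaiscore")

__all__ = ["PipelineConfig", "RunManifest", "PipelineStageError", "run_pipeline", "stage_seed"]

#: stage order used by the seed derivation
STAGES = ("simulate", "split", "train", "evaluate")


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed from the global seed (stable, documented).

    ``SeedSequence([global_seed, index-of-stage])`` reduced mod 2^31, so each
    stage can be rerun in isolation with the same stream.
    """
    idx = STAGES.index(stage)
    return int(np.random.SeedSequence([int(global_seed), idx]).generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """One structured config for the whole run (YAML-serializable)."""

    seed: int = 0
    # exactly one of (expression_path & clinical_path) or simulation
    expression_path: str | None = None
    clinical_path: str | None = None
    simulation: SimulationConfig | None = None
    split_ratio: float = 0.65
    split_stratify: bool = True
    mad_keep_fraction: float = 0.5
    alpha_survival: float = 0.05
    alpha_interaction: float = 0.05
    n_trees: int = 1000
    min_node_size: int = 15
    max_features: str = "sqrt"
    landmark_time: float | None = None
    train_on_arm: str | None = "IO"
    eval_times: list[float] = field(default_factory=lambda: [6.0, 12.0, 18.0, 24.0, 30.0])
    n_bootstrap: int = 200

    def __post_init__(self) -> None:
        has_paths = self.expression_path is not None and self.clinical_path is not None
        has_sim = self.simulation is not None
        if has_paths == has_sim:
            raise ValueError(
                "config must provide exactly one of input paths or a simulation block"
            )

    @staticmethod
    def from_yaml(path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return PipelineConfig.from_dict(raw)

    @staticmethod
    def from_dict(raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        sim = raw.pop("simulation", None)
        if sim is not None:
            sim = SimulationConfig(**sim)
        known = {f.name for f in fields(PipelineConfig)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return PipelineConfig(simulation=sim, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stage_seeds: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    wall_clock: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    versions: dict = field(default_factory=dict)
    settings: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True, default=str)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name and the partial manifest."""

    def __init__(self, stage: str, manifest: RunManifest, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.manifest = manifest
        self.cause = cause


def _versions() -> dict:
    import lifelines
    import sklearn
    import sksurv

    from . import __version__

    return {
        "uaiscore": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "lifelines": lifelines.__version__,
        "scikit-survival": sksurv.__version__,
        "scikit-learn": sklearn.__version__,
    }


def load_or_simulate(config: PipelineConfig) -> SyntheticTrial | tuple:
    if config.simulation is not None:
        sim = SimulationConfig(**{**asdict(config.simulation), "seed": stage_seed(config.seed, "simulate")})
        return simulate_trial(sim)
    expr = uio.read_expression(config.expression_path)
    clin = uio.read_clinical(config.clinical_path)
    extra = set(expr.columns) ^ set(clin.index)
    if extra:
        raise ValueError(f"expression/clinical sample mismatch: {sorted(extra)[:5]}")
    return SyntheticTrial(expression=expr, clinical=clin, truth=None)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> RunManifest:
    """Execute every stage in order, persisting all intermediates.

    A rerun with the same config and seed reproduces every output file
    bit-identically. Any stage error raises :class:`PipelineStageError`
    naming the stage, after writing the partial manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=config.config_hash(),
        seed=config.seed,
        stage_seeds={s: stage_seed(config.seed, s) for s in STAGES},
        versions=_versions(),
        settings=config.to_dict(),
    )
    stage = "setup"
    caught: list[warnings.WarningMessage] = []
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")

            stage = "data"
            t0 = _time.perf_counter()
            trial = load_or_simulate(config)
            expr, clin = trial.expression, trial.clinical
            uio.write_expression(expr, out / "expression.tsv")
            uio.write_clinical(clin, out / "clinical.csv")
            if trial.truth is not None:
                trial.truth.to_frame().to_csv(out / "truth.csv")
            manifest.counts["genes_input"] = len(expr)
            manifest.counts["samples"] = expr.shape[1]
            manifest.wall_clock[stage] = round(_time.perf_counter() - t0, 3)

            stage = "mad_filter"
            t0 = _time.perf_counter()
            expr_f, removed = mad_filter(expr, config.mad_keep_fraction)
            manifest.counts["genes_removed_by_mad"] = len(removed)
            manifest.counts["genes_after_mad"] = len(expr_f)
            manifest.wall_clock[stage] = round(_time.perf_counter() - t0, 3)

            stage = "split"
            t0 = _time.perf_counter()
            strata = (
                clin["arm"].astype(str) + "/" + clin["dfs_event"].astype(str)
                if config.split_stratify
                else None
            )
            split = split_cohort(
                expr.columns, config.split_ratio, stage_seed(config.seed, "split"), strata
            )
            (out / "split.json").write_text(
                json.dumps(
                    {
                        "training_ids": split.training_ids,
                        "validation_ids": split.validation_ids,
                        "ratio": split.ratio,
                        "seed": split.seed,
                    },
                    indent=2,
                )
            )
            manifest.counts["n_training"] = len(split.training_ids)
            manifest.counts["n_validation"] = len(split.validation_ids)
            manifest.wall_clock[stage] = round(_time.perf_counter() - t0, 3)

            stage = "survival_screen"
            t0 = _time.perf_counter()
            scr_dfs = univariate_survival_screen(expr_f, clin, "DFS", split.training_ids)
            scr_os = univariate_survival_screen(expr_f, clin, "OS", split.training_ids)
            passed = (
                (scr_dfs["p"] < config.alpha_survival)
                & (scr_os["p"] < config.alpha_survival)
                & scr_dfs["converged"]
                & scr_os["converged"]
            )
            survivors = scr_dfs.index[passed].tolist()
            manifest.counts["genes_after_survival_screen"] = len(survivors)
            manifest.wall_clock[stage] = round(_time.perf_counter() - t0, 3)

            stage = "interaction_screen"
            t0 = _time.perf_counter()
            records = interaction_screen(
                expr_f, clin, survivors, split.training_ids, config.alpha_interaction
            )
            records = records.join(
                scr_dfs.rename(columns=lambda c: f"cox_{c}_dfs")
            ).join(scr_os.rename(columns=lambda c: f"cox_{c}_os"))
            records["passed_survival_screen"] = records.index.isin(survivors)
            records.to_csv(out / "gene_screen_records.csv")
            markers = select_marker_genes(
                records,
                config.alpha_interaction,
                provenance={
                    "split_seed": split.seed,
                    "alpha_survival": config.alpha_survival,
                    "alpha_interaction": config.alpha_interaction,
                    "mad_keep_fraction": config.mad_keep_fraction,
                },
            )
            pd.DataFrame(
                {
                    "gene_id": markers.genes,
                    "direction": ["protective"] * len(markers.protective_genes)
                    + ["risk"] * len(markers.risk_genes),
                }
            ).to_csv(out / "marker_genes.csv", index=False)
            manifest.counts["markers_protective"] = len(markers.protective_genes)
            manifest.counts["markers_risk"] = len(markers.risk_genes)
            manifest.counts["markers_total"] = len(markers)
            manifest.wall_clock[stage] = round(_time.perf_counter() - t0, 3)

            stage = "train"
            t0 = _time.perf_counter()
            model = train_uaiscore(
                expr_f,
                clin,
                markers,
                split.training_ids,
                train_on_arm=config.train_on_arm,
                n_trees=config.n_trees,
                min_node_size=config.min_node_size,
                max_features=config.max_features,
                landmark_time=config.landmark_time,
                seed=stage_seed(config.seed, "train"),
            )
            model.save(out / "model.joblib")
            manifest.counts["forest_trees"] = config.n_trees
            manifest.wall_clock[stage] = round(_time.perf_counter() - t0, 3)

            stage = "score"
            t0 = _time.perf_counter()
            scores = score(model, expr_f)
            labels = four_group_labels(scores, clin)
            scores = scores.assign(
                four_group=labels,
                cohort=np.where(
                    scores.index.isin(split.training_ids), "training", "validation"
                ),
            )
            scores.to_csv(out / "scores.csv", index=False)
            for grp, cnt in labels.value_counts().items():
                manifest.counts[f"group_{grp}"] = int(cnt)
            manifest.wall_clock[stage] = round(_time.perf_counter() - t0, 3)

            stage = "evaluate"
            t0 = _time.perf_counter()
            _evaluate(config, out, clin, scores, split, manifest)
            manifest.wall_clock[stage] = round(_time.perf_counter() - t0, 3)
    except Exception as exc:
        manifest.warnings = [str(w.message) for w in caught]
        manifest.write(out / "manifest.json")
        raise PipelineStageError(stage, manifest, exc) from exc

    manifest.warnings = [str(w.message) for w in caught]
    manifest.write(out / "manifest.json")
    logger.info("pipeline complete: %s", out / "manifest.json")
    return manifest


def _evaluate(config, out, clin, scores, split, manifest) -> None:
    endpoint = "dfs"
    times = clin[f"{endpoint}_time"]
    events = clin[f"{endpoint}_event"]

    analysis = ev.benefit_analysis(scores, clin, endpoint)
    rows = []
    km_frames = []
    for stratum, res in analysis["by_stratum"].items():
        s = res["cox"].summary
        rows.append(
            {
                "analysis": f"{stratum}-score stratum",
                "covariate": "IO vs Obs",
                "hr": s["hr"].iloc[0],
                "ci_low": s["ci_low"].iloc[0],
                "ci_high": s["ci_high"].iloc[0],
                "p": s["p"].iloc[0],
                "logrank_p": res["logrank_p"],
                "n": res["cox"].n,
                "n_events": res["cox"].n_events,
            }
        )
        km_frames.extend(k.to_frame() for k in res["km"].values())
    for arm, res in analysis["by_arm"].items():
        s = res["cox"].summary
        rows.append(
            {
                "analysis": f"{arm} arm",
                "covariate": "high vs low score",
                "hr": s["hr"].iloc[0],
                "ci_low": s["ci_low"].iloc[0],
                "ci_high": s["ci_high"].iloc[0],
                "p": s["p"].iloc[0],
                "logrank_p": res["logrank_p"],
                "n": res["cox"].n,
                "n_events": res["cox"].n_events,
            }
        )
    pd.DataFrame(rows).to_csv(out / "benefit_cox.csv", index=False)
    if km_frames:
        pd.concat(km_frames).to_csv(out / "km_curves.csv", index=False)

    # time-dependent AUC of the score and available biomarkers, IO validation arm
    val_io = [
        s
        for s in split.validation_ids
        if clin.loc[s, "arm"] == "IO"
    ] or [s for s in scores.index if clin.loc[s, "arm"] == "IO"]
    eval_seed = stage_seed(config.seed, "evaluate")
    curves = []
    # components over ALL samples (combination coefficients fit on training);
    # biomarker positivity is adverse, so negate to match score orientation
    components: dict[str, pd.Series] = {"uaiscore": scores["uaiscore"]}
    for bio in ("ctdna_c1d1", "ttmb", "pdl1"):
        if bio in clin.columns:
            ind = uio.biomarker_indicator(clin, bio)
            if ind.notna().any() and ind.nunique() > 1:
                components[bio] = -ind
    for name, vals in components.items():
        sub = vals.loc[[s for s in val_io if s in vals.index]].dropna()
        curves.append(
            ev.time_dependent_auc(
                -sub,  # AUC convention: higher value = higher risk
                times.loc[sub.index],
                events.loc[sub.index],
                config.eval_times,
                n_bootstrap=config.n_bootstrap,
                seed=eval_seed,
                marker=name,
                endpoint=endpoint,
            )
        )
    if len(components) > 1:
        combo = ev.combine_modalities(
            components,
            clin[f"{endpoint}_time"],
            clin[f"{endpoint}_event"],
            split.training_ids,
        )
        risk = combo.risk.loc[[s for s in val_io if s in combo.risk.index]].dropna()
        if len(risk) >= 20:
            curves.append(
                ev.time_dependent_auc(
                    risk,
                    times.loc[risk.index],
                    events.loc[risk.index],
                    config.eval_times,
                    n_bootstrap=config.n_bootstrap,
                    seed=eval_seed,
                    marker="+".join(components),
                    endpoint=endpoint,
                )
            )
    pd.concat([c.to_frame() for c in curves]).to_csv(out / "auc_curves.csv", index=False)
    manifest.counts["auc_markers"] = len(curves)
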