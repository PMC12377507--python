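"""Random-survival-forest benefit score (UAIscore).

A random survival forest is fit to disease-free survival of the
immunotherapy-arm training patients using the interaction-selected marker
genes as features. A sample's UAIscore is the forest-predicted survival
probability at a fixed landmark time, so higher score = better predicted
outcome under immunotherapy. Patients are stratified at the median score of
the full training set (both arms), and that cutoff is frozen in the model —
validation scoring never recomputes it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import warnings

import joblib
import numpy as np
import pandas as pd
from sksurv.ensemble import RandomSurvivalForest
from sksurv.util import Surv

from .screen import MarkerGeneSet

__all__ = ["UAIscoreModel", "train_uaiscore", "score", "four_group_labels"]

FOUR_GROUPS = ("high+IO", "high+Obs", "low+IO", "low+Obs")


@dataclass
class UAIscoreModel:
    """A trained scorer: forest + marker list + frozen cutoff + orientation."""

    marker_genes: list[str]
    directions: dict[str, str]  # gene -> protective / risk
    forest: RandomSurvivalForest
    training_cutoff: float
    landmark_time: float
    orientation: str = "higher_score_is_benefit"
    metadata: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path: str | Path) -> "UAIscoreModel":
        model = joblib.load(path)
        if not isinstance(model, UAIscoreModel):
            raise TypeError(f"{path} does not contain a UAIscoreModel")
        return model


def _marker_matrix(expr: pd.DataFrame, markers: list[str], samples) -> np.ndarray:
    missing = [g for g in markers if g not in expr.index]
    if missing:
        raise ValueError(
            f"expression matrix lacks {len(missing)} marker gene(s): {missing[:10]}"
        )
    return expr.loc[markers, samples].to_numpy().T


def train_uaiscore(
    expr: pd.DataFrame,
    clinical: pd.DataFrame,
    markers: MarkerGeneSet,
    training_ids,
    *,
    endpoint: str = "dfs",
    train_on_arm: str | None = "IO",
    n_trees: int = 1000,
    min_node_size: int = 15,
    max_features: str | float = "sqrt",
    landmark_time: float | None = None,
    min_events: int = 10,
    seed: int = 0,
) -> UAIscoreModel:
    """Fit the forest and freeze the stratification cutoff.

    Training uses the ``train_on_arm`` patients among ``training_ids``
    (default: the immunotherapy arm, whose outcomes the score is meant to
    predict; ``None`` trains on all). The stratification cutoff is the
    median score of *all* training patients regardless of arm.

    ``landmark_time`` defaults to the median observed follow-up time of the
    fitting samples; a landmark beyond the last observed time is clipped
    with a warning. Fixing the seed makes training deterministic.
    """
    if len(markers) == 0:
        raise ValueError("cannot train on an empty marker gene set")
    training_ids = list(training_ids)
    endpoint = endpoint.lower()
    sub = clinical.loc[training_ids]
    if train_on_arm is not None:
        fit_ids = sub.index[sub["arm"] == train_on_arm].tolist()
    else:
        fit_ids = training_ids
    fit_clin = clinical.loc[fit_ids]
    time = fit_clin[f"{endpoint}_time"].to_numpy(float)
    event = fit_clin[f"{endpoint}_event"].to_numpy(bool)
    if int(event.sum()) < min_events:
        raise ValueError(
            f"only {int(event.sum())} {endpoint.upper()} events in the fitting "
            f"samples; at least {min_events} required"
        )

    gene_list = markers.genes
    X = _marker_matrix(expr, gene_list, fit_ids)
    forest = RandomSurvivalForest(
        n_estimators=n_trees,
        min_samples_leaf=min_node_size,
        max_features=max_features,
        random_state=seed,
        n_jobs=1,
    ).fit(X, Surv.from_arrays(event, time))

    if landmark_time is None:
        landmark_time = float(np.median(time))
    last = float(forest.unique_times_[-1])
    if landmark_time > last:
        warnings.warn(
            f"landmark time {landmark_time:g} beyond last observed time {last:g}; "
            "clipped",
            UserWarning,
            stacklevel=2,
        )
        landmark_time = last

    directions = {g: "protective" for g in markers.protective_genes}
    directions.update({g: "risk" for g in markers.risk_genes})
    model = UAIscoreModel(
        marker_genes=gene_list,
        directions=directions,
        forest=forest,
        training_cutoff=float("nan"),
        landmark_time=float(landmark_time),
        metadata={
            "endpoint": endpoint,
            "train_on_arm": train_on_arm,
            "n_fitting_samples": len(fit_ids),
            "n_fitting_events": int(event.sum()),
            "training_ids": training_ids,
            "n_trees": n_trees,
            "min_node_size": min_node_size,
            "max_features": max_features,
            "seed": seed,
        },
    )
    # cutoff = median score over ALL training patients (both arms)
    model.training_cutoff = float(np.median(_raw_scores(model, expr, training_ids)))
    return model


def _raw_scores(model: UAIscoreModel, expr: pd.DataFrame, samples) -> np.ndarray:
    X = _marker_matrix(expr, model.marker_genes, samples)
    surv = model.forest.predict_survival_function(X, return_array=True)
    times = model.forest.unique_times_
    # step-function value at the landmark
    idx = int(np.searchsorted(times, model.landmark_time, side="right")) - 1
    if idx < 0:
        return np.ones(X.shape[0])
    return surv[:, idx]


def score(model: UAIscoreModel, expr: pd.DataFrame) -> pd.DataFrame:
    """Score every sample of ``expr``; side-effect free.

    Returns a frame indexed by sample with columns ``uaiscore`` (predicted
    survival probability at the model's landmark; higher = benefit) and
    ``group`` (``high`` iff uaiscore > frozen training cutoff).
    """
    samples = list(expr.columns)
    values = _raw_scores(model, expr, samples)
    group = np.where(values > model.training_cutoff, "high", "low")
    return pd.DataFrame(
        {"sample_id": samples, "uaiscore": values, "group": group}
    ).set_index("sample_id", drop=False)


def four_group_labels(scores: pd.DataFrame, clinical: pd.DataFrame) -> pd.Series:
    """Cross-classify score stratum x treatment arm.

    Labels are ``high+IO, high+Obs, low+IO, low+Obs``; both tables must
    cover exactly the same samples.
    """
    only_scores = scores.index.difference(clinical.index)
    only_clin = clinical.index.difference(scores.index)
    if len(only_scores) or len(only_clin):
        raise ValueError(
            f"sample mismatch: {len(only_scores)} only in scores "
            f"(e.g. {list(only_scores[:3])}), {len(only_clin)} only in clinical "
            f"(e.g. {list(only_clin[:3])})"
        )
    labels = scores["group"] + "+" + clinical.loc[scores.index, "arm"]
    return labels.rename("four_group")
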