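"""Survival evaluation layer.

Kaplan–Meier curves, log-rank (Mantel–Cox) tests and Cox
proportional-hazards fits are delegated to lifelines; this module adds the
pieces a treatment-benefit analysis needs on top of them:

* :func:`time_dependent_auc` — cumulative/dynamic AUC(t) with inverse
  probability of censoring weighting (IPCW) and percentile-bootstrap
  confidence bands, for comparing a continuous score against binary
  biomarkers at a range of horizons.
* :func:`combine_modalities` — a frozen-coefficient Cox combination of
  several biomarkers (e.g. score + ctDNA + tTMB + PD-L1) fit on training
  samples with complete components.
* :func:`benefit_analysis` — the four-group treatment-benefit readout:
  within each score stratum, the hazard ratio of immunotherapy vs
  observation (and the converse score effect within each arm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

__all__ = [
    "KMEstimate",
    "CoxResult",
    "TimeAUCCurve",
    "CombinedScore",
    "km_fit",
    "logrank_test",
    "cox_fit",
    "time_dependent_auc",
    "combine_modalities",
    "benefit_analysis",
]


@dataclass
class KMEstimate:
    label: str
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.label,
                "time": self.times,
                "survival": self.survival,
                "at_risk": self.at_risk,
            }
        )


@dataclass
class CoxResult:
    summary: pd.DataFrame  # per covariate: hr, ci_low, ci_high, p
    log_likelihood: float
    n: int
    n_events: int
    flagged: bool = False
    diagnostics: str = ""

    def hr(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hr"])


@dataclass
class TimeAUCCurve:
    marker: str
    endpoint: str
    times: np.ndarray
    auc: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker": self.marker,
                "endpoint": self.endpoint,
                "time": self.times,
                "auc": self.auc,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


@dataclass
class CombinedScore:
    components: list[str]
    coefficients: pd.Series
    risk: pd.Series  # linear predictor; higher = higher hazard
    benefit: pd.Series  # -risk, oriented like the forest score
    complete: pd.Series  # bool per sample: all components observed
    training_ids: list[str] = field(default_factory=list)
    n_training_complete: int = 0


def km_fit(times, events, group_labels) -> dict[str, KMEstimate]:
    """Product-limit survival estimate per group."""
    times = pd.Series(np.asarray(times, float))
    events = pd.Series(np.asarray(events, int))
    if len(times) == 0:
        raise ValueError("empty input: no samples to fit")
    if isinstance(group_labels, pd.Categorical) or isinstance(
        getattr(group_labels, "dtype", None), pd.CategoricalDtype
    ):
        cats = pd.Series(group_labels).cat
        unused = set(cats.categories) - set(pd.Series(group_labels).unique())
        if unused:
            raise ValueError(f"empty group: {sorted(unused)}")
    labels = pd.Series(np.asarray(group_labels, object))
    out: dict[str, KMEstimate] = {}
    for label in pd.unique(labels):
        mask = (labels == label).to_numpy()
        if mask.sum() == 0:
            raise ValueError(f"empty group: {label!r}")
        kmf = KaplanMeierFitter().fit(times[mask], events[mask])
        timeline = kmf.survival_function_.index.to_numpy(float)
        surv = kmf.survival_function_.iloc[:, 0].to_numpy(float)
        ev_table = kmf.event_table
        at_risk = ev_table["at_risk"].reindex(timeline).to_numpy(float)
        out[str(label)] = KMEstimate(
            label=str(label), times=timeline, survival=surv, at_risk=at_risk
        )
    return out


def logrank_test(times, events, group_labels) -> tuple[float, float]:
    """Mantel–Cox test across 2+ groups; returns (chi-squared, p)."""
    labels = pd.Series(np.asarray(group_labels, object))
    if labels.nunique() < 2:
        raise ValueError("log-rank test requires at least two groups")
    events = np.asarray(events, int)
    if events.sum() < 1:
        raise ValueError("log-rank test requires at least one event")
    res = multivariate_logrank_test(np.asarray(times, float), labels, events)
    return float(res.test_statistic), float(res.p_value)


def cox_fit(design: pd.DataFrame, times, events, alpha: float = 0.05) -> CoxResult:
    """Cox proportional-hazards fit (Efron ties) with Wald CIs per covariate.

    Constant covariates raise; rank-deficient (collinear) designs and
    non-convergence return a flagged result with diagnostics rather than
    crashing.
    """
    design = design.astype(float)
    const = design.columns[design.nunique() <= 1].tolist()
    if const:
        raise ValueError(f"constant covariate(s): {const}")
    n = len(design)
    events = np.asarray(events, int)
    df = design.copy()
    df["_time"] = np.asarray(times, float)
    df["_event"] = events

    centered = design - design.mean()
    rank = np.linalg.matrix_rank(centered.to_numpy())
    if rank < design.shape[1]:
        return CoxResult(
            summary=pd.DataFrame(
                np.nan,
                index=design.columns,
                columns=["hr", "ci_low", "ci_high", "p"],
            ),
            log_likelihood=float("nan"),
            n=n,
            n_events=int(events.sum()),
            flagged=True,
            diagnostics=f"design is rank deficient (rank {rank} < {design.shape[1]}); "
            "covariates are collinear",
        )

    cph = CoxPHFitter(alpha=alpha)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="_time", event_col="_event")
    except Exception as exc:  # lifelines ConvergenceError and kin
        return CoxResult(
            summary=pd.DataFrame(
                np.nan,
                index=design.columns,
                columns=["hr", "ci_low", "ci_high", "p"],
            ),
            log_likelihood=float("nan"),
            n=n,
            n_events=int(events.sum()),
            flagged=True,
            diagnostics=f"fit failed: {exc}",
        )
    s = cph.summary
    summary = pd.DataFrame(
        {
            "hr": s["exp(coef)"],
            "ci_low": s["exp(coef) lower 95%"],
            "ci_high": s["exp(coef) upper 95%"],
            "p": s["p"],
        }
    )
    return CoxResult(
        summary=summary,
        log_likelihood=float(cph.log_likelihood_),
        n=n,
        n_events=int(events.sum()),
    )


def _censoring_survival(times: np.ndarray, events: np.ndarray):
    """Left-continuous KM estimate of the censoring survival G(t-)."""
    kmf = KaplanMeierFitter().fit(times, 1 - events)
    grid = kmf.survival_function_.index.to_numpy(float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(float)

    def G_minus(t):
        t = np.asarray(t, float)
        idx = np.searchsorted(grid, t, side="left") - 1
        return np.where(idx >= 0, surv[np.clip(idx, 0, None)], 1.0)

    return G_minus


def _ipcw_auc_at(scores, times, events, t, G_minus) -> float:
    """Uno cumulative/dynamic AUC at horizon t (ties in score count 1/2)."""
    case = (times <= t) & (events == 1)
    control = times > t
    if case.sum() == 0 or control.sum() == 0:
        return np.nan
    w = np.zeros_like(times, dtype=float)
    G = G_minus(times[case])
    w[case] = np.where(G > 0, 1.0 / G, 0.0)
    sc, scon = scores[case], scores[control]
    wins = (sc[:, None] > scon[None, :]) + 0.5 * (sc[:, None] == scon[None, :])
    num = (w[case][:, None] * wins).sum()
    den = w[case].sum() * control.sum()
    return float(num / den) if den > 0 else np.nan


def time_dependent_auc(
    scores,
    times,
    events,
    eval_times,
    n_bootstrap: int = 200,
    seed: int = 0,
    marker: str = "score",
    endpoint: str = "dfs",
) -> TimeAUCCurve:
    """Cumulative-case / dynamic-control AUC(t) with IPCW.

    Cases at horizon t are events with T <= t, weighted 1/G(T-) where G is
    the Kaplan–Meier estimate of the censoring survival; controls are
    samples still at risk (T > t), unweighted. The estimator is rank-based:
    any strictly monotone transform of the score leaves the curve unchanged.
    Confidence bands are percentile bootstrap over samples. Evaluation times
    beyond the last observed event are dropped with a warning.
    """
    scores = np.asarray(scores, float)
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    eval_times = np.atleast_1d(np.asarray(eval_times, float))
    if n_bootstrap < 0:
        raise ValueError("n_bootstrap must be >= 0")

    last_event = times[events == 1].max() if events.any() else -np.inf
    keep = eval_times <= max(last_event, -np.inf)
    keep &= eval_times < times.max()
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} evaluation time(s) beyond the "
            "observed follow-up",
            UserWarning,
            stacklevel=2,
        )
    eval_times = eval_times[keep]

    G = _censoring_survival(times, events)
    auc = np.array([_ipcw_auc_at(scores, times, events, t, G) for t in eval_times])

    if n_bootstrap > 0 and eval_times.size:
        rng = np.random.default_rng(seed)
        n = len(times)
        boots = np.full((n_bootstrap, eval_times.size), np.nan)
        for b in range(n_bootstrap):
            idx = rng.integers(0, n, n)
            tb, eb, sb = times[idx], events[idx], scores[idx]
            if eb.sum() == 0:
                continue
            Gb = _censoring_survival(tb, eb)
            boots[b] = [_ipcw_auc_at(sb, tb, eb, t, Gb) for t in eval_times]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ci_low = np.nanpercentile(boots, 2.5, axis=0)
            ci_high = np.nanpercentile(boots, 97.5, axis=0)
    else:
        ci_low = np.full_like(auc, np.nan)
        ci_high = np.full_like(auc, np.nan)

    return TimeAUCCurve(
        marker=marker,
        endpoint=endpoint,
        times=eval_times,
        auc=auc,
        ci_low=ci_low,
        ci_high=ci_high,
    )


def combine_modalities(
    components: dict[str, pd.Series],
    times: pd.Series,
    events: pd.Series,
    training_ids,
    method: str = "cox",
    landmark_time: float | None = None,
) -> CombinedScore:
    """Frozen-coefficient combination of several biomarkers.

    Coefficients are fit on the training samples with every component
    observed (complete-case) and frozen; the combined risk value is the
    linear predictor for every complete-case sample (NaN otherwise).
    ``benefit`` is its negation, matching the orientation of the forest
    score (higher = better predicted outcome).

    ``method="cox"`` (default) fits a Cox proportional-hazards model;
    ``method="logistic_landmark"`` fits logistic regression on
    event-by-landmark status (samples censored before the landmark are
    excluded from fitting), for settings where proportional hazards is
    implausible. ``landmark_time`` defaults to the median training event
    time.
    """
    if not components:
        raise ValueError("at least one component required")
    if method not in ("cox", "logistic_landmark"):
        raise ValueError(f"unknown combination method: {method!r}")
    comp = pd.DataFrame({k: pd.Series(v, dtype=float) for k, v in components.items()})
    complete = comp.notna().all(axis=1)
    training_ids = [s for s in training_ids if s in comp.index]
    train_mask = comp.index.isin(training_ids) & complete
    if train_mask.sum() == 0:
        raise ValueError("no complete-component training samples")

    df = comp.loc[train_mask].copy()
    df["_time"] = pd.Series(times, dtype=float).loc[df.index]
    df["_event"] = pd.Series(events, dtype=int).loc[df.index]
    if method == "cox":
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="_time", event_col="_event")
        coef = cph.params_.rename("coefficient")
    else:
        from sklearn.linear_model import LogisticRegression

        if landmark_time is None:
            ev_times = df.loc[df["_event"] == 1, "_time"]
            if ev_times.empty:
                raise ValueError("no training events for the landmark fit")
            landmark_time = float(ev_times.median())
        # event-by-landmark outcome; censored-before-landmark is unknowable
        known = (df["_time"] >= landmark_time) | (df["_event"] == 1)
        fit_df = df.loc[known]
        y = ((fit_df["_time"] <= landmark_time) & (fit_df["_event"] == 1)).astype(int)
        if y.nunique() < 2:
            raise ValueError("landmark outcome is constant in the training samples")
        lr = LogisticRegression(penalty=None, max_iter=1000).fit(
            fit_df[comp.columns], y
        )
        coef = pd.Series(lr.coef_[0], index=comp.columns, name="coefficient")

    centered = comp - comp.loc[train_mask].mean()
    risk = centered.mul(coef, axis=1).sum(axis=1, min_count=len(coef))
    risk[~complete] = np.nan
    return CombinedScore(
        components=list(components),
        coefficients=coef,
        risk=risk.rename("combined_risk"),
        benefit=(-risk).rename("combined_benefit"),
        complete=complete,
        training_ids=training_ids,
        n_training_complete=int(train_mask.sum()),
    )


def benefit_analysis(
    scores: pd.DataFrame, clinical: pd.DataFrame, endpoint: str = "dfs"
) -> dict:
    """Treatment-benefit readout of a high/low score stratification.

    Within each score stratum: Cox HR of IO vs Obs (with CI and p) and the
    log-rank p — the direct "does this stratum benefit from treatment"
    question. Also the converse: the score-group effect within each arm.
    Strata missing an arm are skipped with a warning.
    """
    endpoint = endpoint.lower()
    clin = clinical.loc[scores.index]
    times = clin[f"{endpoint}_time"]
    events = clin[f"{endpoint}_event"]
    out: dict = {"endpoint": endpoint, "by_stratum": {}, "by_arm": {}}

    for stratum in ("high", "low"):
        mask = (scores["group"] == stratum).to_numpy()
        arms = clin.loc[mask, "arm"]
        if arms.nunique() < 2:
            warnings.warn(
                f"stratum {stratum!r} lacks one arm; skipped", UserWarning, stacklevel=2
            )
            continue
        design = pd.DataFrame({"io": (arms == "IO").astype(float)})
        cox = cox_fit(design, times[mask], events[mask])
        _, lr_p = logrank_test(times[mask], events[mask], arms)
        km = km_fit(times[mask], events[mask], arms + f" ({stratum})")
        out["by_stratum"][stratum] = {"cox": cox, "logrank_p": lr_p, "km": km}

    for arm in ("IO", "Obs"):
        mask = (clin["arm"] == arm).to_numpy()
        grp = scores.loc[mask, "group"]
        if grp.nunique() < 2:
            warnings.warn(f"arm {arm!r} lacks one stratum; skipped", UserWarning, stacklevel=2)
            continue
        design = pd.DataFrame({"high_score": (grp == "high").astype(float)})
        cox = cox_fit(design, times[mask], events[mask])
        _, lr_p = logrank_test(times[mask], events[mask], grp)
        out["by_arm"][arm] = {"cox": cox, "logrank_p": lr_p}
    return out
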