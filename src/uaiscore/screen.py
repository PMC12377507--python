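"""Marker-gene selection cascade.

Four stages, each shrinking the gene set:

1. :func:`mad_filter` — drop low-variation genes by median absolute
   deviation.
2. :func:`split_cohort` — seed-deterministic, optionally stratified
   training/validation split.
3. :func:`univariate_survival_screen` — per-gene univariate Cox on
   standardized expression, run per endpoint (DFS and OS) on the training
   samples; a gene survives only if associated with both endpoints.
4. :func:`interaction_screen` + :func:`select_marker_genes` — dichotomize
   each gene at its training-set mean, test survival separately within each
   treatment arm, keep genes significant in *exactly one* arm (the
   treatment-interaction signature that separates predictive from
   prognostic genes), and partition them at HR = 1 into protective and risk
   markers.

Raw p < alpha is used throughout the screens (no multiplicity correction at
this stage); Cox fits use the Efron tie approximation. Per-gene fits that
fail (constant gene, separation, degenerate follow-up) are flagged and
treated as non-significant so batch screening is total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._batchsurv import batch_two_group_logrank, batch_univariate_cox

__all__ = [
    "mad_filter",
    "split_cohort",
    "univariate_survival_screen",
    "interaction_screen",
    "select_marker_genes",
    "CohortSplit",
    "MarkerGeneSet",
]


@dataclass
class CohortSplit:
    training_ids: list[str]
    validation_ids: list[str]
    seed: int
    ratio: float

    def __post_init__(self) -> None:
        overlap = set(self.training_ids) & set(self.validation_ids)
        if overlap:
            raise ValueError(f"training/validation overlap: {sorted(overlap)[:5]}")


@dataclass
class MarkerGeneSet:
    """Interaction-screen survivors split at HR = 1."""

    protective_genes: list[str]  # HR < 1 in the significant arm
    risk_genes: list[str]  # HR > 1 in the significant arm
    alpha: float
    provenance: dict = field(default_factory=dict)

    @property
    def genes(self) -> list[str]:
        return list(self.protective_genes) + list(self.risk_genes)

    def __len__(self) -> int:
        return len(self.protective_genes) + len(self.risk_genes)


def mad_filter(
    expr: pd.DataFrame, keep_fraction: float = 0.5
) -> tuple[pd.DataFrame, list[str]]:
    """Remove genes whose MAD falls strictly below the (1 - keep_fraction)
    quantile of per-gene MADs.

    At the default ``keep_fraction = 0.5`` this is the strictly-below-median
    rule: a matrix of 24,443 genes with distinct MADs loses exactly 12,221.
    Ties at the threshold are kept (strict inequality) and reported.
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    values = expr.to_numpy()
    med = np.median(values, axis=1, keepdims=True)
    mads = np.median(np.abs(values - med), axis=1)
    cutoff = np.quantile(mads, 1.0 - keep_fraction)
    removed_mask = mads < cutoff
    n_tied = int((mads == cutoff).sum())
    if n_tied > 1:
        warnings.warn(
            f"{n_tied} genes tie at the MAD threshold {cutoff:.6g}; "
            "ties are kept (strict-below rule), so fewer genes than the "
            "nominal fraction may be removed",
            UserWarning,
            stacklevel=2,
        )
    removed = expr.index[removed_mask].tolist()
    return expr.loc[~removed_mask], removed


def split_cohort(
    sample_ids,
    ratio: float,
    seed: int,
    strata: pd.Series | None = None,
) -> CohortSplit:
    """Randomly partition samples into training/validation at ``ratio``.

    When ``strata`` is given (a label per sample), the ratio is applied
    within each stratum so that event rates and arm balance carry over to
    both halves. A stratum smaller than 2 goes wholly to training.
    """
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    ids = pd.Index(sample_ids)
    if strata is not None:
        missing = ids.difference(strata.index)
        if len(missing):
            raise ValueError(f"strata labels missing for {list(missing[:5])}")
        groups = [ids[strata.loc[ids] == lev] for lev in strata.loc[ids].unique()]
    else:
        groups = [ids]

    rng = np.random.default_rng(seed)
    train: list[str] = []
    valid: list[str] = []
    for grp in groups:
        if len(grp) < 2:
            if len(grp):
                warnings.warn(
                    f"stratum with {len(grp)} sample(s) assigned wholly to training",
                    UserWarning,
                    stacklevel=2,
                )
                train.extend(grp)
            continue
        n_train = int(round(ratio * len(grp)))
        n_train = min(max(n_train, 1), len(grp) - 1)
        perm = rng.permutation(len(grp))
        train.extend(grp[perm[:n_train]])
        valid.extend(grp[perm[n_train:]])
    return CohortSplit(training_ids=train, validation_ids=valid, seed=seed, ratio=ratio)


def _survival_arrays(clinical: pd.DataFrame, endpoint: str, samples) -> tuple:
    endpoint = endpoint.lower()
    if endpoint not in ("dfs", "os"):
        raise ValueError("endpoint must be 'DFS' or 'OS'")
    sub = clinical.loc[samples]
    return sub[f"{endpoint}_time"].to_numpy(), sub[f"{endpoint}_event"].to_numpy()


def univariate_survival_screen(
    expr: pd.DataFrame,
    clinical: pd.DataFrame,
    endpoint: str = "DFS",
    samples=None,
) -> pd.DataFrame:
    """Per-gene univariate Cox of ``endpoint`` on standardized expression.

    Returns a frame indexed by gene with columns ``p`` (Wald), ``hr``
    (per SD of expression), and ``converged``. Genes whose fit fails get
    ``p = 1`` and ``converged = False``.
    """
    samples = list(expr.columns) if samples is None else list(samples)
    time, event = _survival_arrays(clinical, endpoint, samples)
    if event.sum() == 0:
        raise ValueError(f"no events for endpoint {endpoint}: cannot screen")

    X = expr[samples].to_numpy().T  # samples x genes
    sd = X.std(axis=0)
    mean = X.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        Xz = (X - mean) / np.where(sd > 0, sd, np.nan)
    Xz = np.where(np.isfinite(Xz), Xz, 0.0)

    res = batch_univariate_cox(Xz, time, event)
    return pd.DataFrame(
        {"p": res.p, "hr": res.hr, "converged": res.converged},
        index=pd.Index(expr.index, name="gene_id"),
    )


def interaction_screen(
    expr: pd.DataFrame,
    clinical: pd.DataFrame,
    gene_ids,
    training_ids,
    alpha: float = 0.05,
    endpoint: str = "DFS",
) -> pd.DataFrame:
    """Arm-specific subgroup survival analysis at the mean-expression cutoff.

    For each gene: training samples are dichotomized at the gene's
    training-set mean; within each treatment arm separately, a log-rank test
    of high vs low and a Cox HR (high vs low) are computed. A gene is an
    interaction gene when exactly one arm is significant at ``alpha`` —
    prognostic genes tend to reach significance in both arms and are
    excluded; null genes in neither.

    Returns one row per gene: ``cutoff, logrank_p_io, logrank_p_obs, hr_io,
    hr_obs, interaction_arm`` ({IO, Obs, none, both}), ``direction``
    ({protective, risk, NA} — from the significant arm's HR), ``testable``.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    training_ids = list(training_ids)
    gene_ids = list(gene_ids)
    sub = clinical.loc[training_ids]
    arms = sub["arm"].to_numpy()
    if len(set(arms)) < 2:
        raise ValueError("both treatment arms must be present among training samples")

    E = expr.loc[gene_ids, training_ids].to_numpy()  # genes x samples
    cutoff = E.mean(axis=1)
    high = (E > cutoff[:, None]).T.astype(float)  # samples x genes

    out = pd.DataFrame(index=pd.Index(gene_ids, name="gene_id"))
    out["cutoff"] = cutoff
    stats_by_arm: dict[str, dict[str, np.ndarray]] = {}
    for arm_label in ("IO", "Obs"):
        mask = arms == arm_label
        time, event = _survival_arrays(clinical, endpoint, sub.index[mask])
        Ha = high[mask]
        _, lr_p = batch_two_group_logrank(Ha, time, event)
        cox = batch_univariate_cox(Ha, time, event)
        # a split with an empty side in this arm is untestable
        counts = Ha.sum(axis=0)
        testable = (counts > 0) & (counts < mask.sum())
        stats_by_arm[arm_label] = {
            "lr_p": np.where(testable, lr_p, 1.0),
            "hr": cox.hr,
            "testable": testable,
        }
        key = arm_label.lower()
        out[f"logrank_p_{key}"] = stats_by_arm[arm_label]["lr_p"]
        out[f"hr_{key}"] = cox.hr

    testable = stats_by_arm["IO"]["testable"] & stats_by_arm["Obs"]["testable"]
    sig_io = (stats_by_arm["IO"]["lr_p"] < alpha) & testable
    sig_obs = (stats_by_arm["Obs"]["lr_p"] < alpha) & testable
    arm_col = np.where(
        sig_io & sig_obs,
        "both",
        np.where(sig_io, "IO", np.where(sig_obs, "Obs", "none")),
    )
    hr_sig = np.where(
        arm_col == "IO",
        stats_by_arm["IO"]["hr"],
        np.where(arm_col == "Obs", stats_by_arm["Obs"]["hr"], np.nan),
    )
    direction = np.where(
        np.isin(arm_col, ["IO", "Obs"]),
        np.where(hr_sig < 1, "protective", "risk"),
        "NA",
    )
    out["interaction_arm"] = arm_col
    out["direction"] = direction
    out["testable"] = testable
    out["alpha"] = alpha
    return out


def select_marker_genes(
    records: pd.DataFrame, alpha: float = 0.05, provenance: dict | None = None
) -> MarkerGeneSet:
    """Partition interaction-screen survivors at HR = 1.

    Selected genes are those with ``interaction_arm`` in {IO, Obs};
    the significant arm's high-vs-low HR decides the side (HR < 1 →
    protective, HR > 1 → risk; an exact HR of 1 goes to risk with a
    warning). An empty selection is returned as-is with a warning —
    downstream training refuses it.
    """
    sel = records[records["interaction_arm"].isin(["IO", "Obs"])]
    hr = np.where(
        sel["interaction_arm"] == "IO", sel["hr_io"], sel["hr_obs"]
    )
    ties = hr == 1.0
    if ties.any():
        warnings.warn(
            f"{int(ties.sum())} gene(s) with HR exactly 1 assigned to the risk side",
            UserWarning,
            stacklevel=2,
        )
    protective = sel.index[hr < 1].tolist()
    risk = sel.index[hr >= 1].tolist()
    if not protective and not risk:
        warnings.warn(
            "interaction screen selected no genes; marker set is empty",
            UserWarning,
            stacklevel=2,
        )
    return MarkerGeneSet(
        protective_genes=protective,
        risk_genes=risk,
        alpha=alpha,
        provenance=provenance or {},
    )
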