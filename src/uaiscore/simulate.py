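"""Synthetic two-arm randomized-trial generator.

Emulates the statistical structure an adjuvant-immunotherapy biomarker
analysis assumes: a gene x sample log-scale expression matrix, 1:1
randomization to immunotherapy (IO) vs observation (Obs), proportional-
hazards disease-free survival (DFS) with three planted gene classes, an
overall-survival (OS) endpoint coupled to DFS, right censoring, and binary
biomarkers tied to the hazard.

Gene classes
------------
prognostic
    log-hazard ``beta_prognostic`` per SD of the class module score in
    *both* arms.
predictive_protective / predictive_risk
    log-hazard ``-/+ |beta_predictive|`` per SD of the module score in the
    *treatment arm only* — the treatment-effect-modifying signal the
    interaction screen targets.
null
    no effect; the remainder of the genome (half of it, by default,
    generated at a shrunken scale to emulate the low-variation genes a MAD
    filter removes).

Planted genes within a class form a co-expressed module: gene g in class c
is ``x_g = sqrt(rho) * F_c + sqrt(1-rho) * eps_g`` with a shared factor
``F_c`` and ``rho = module_correlation``, marginally standard normal per
gene. The DFS hazard for patient *i* is

    h_i(t) = h0 * exp( b_prog * S_prog,i + arm_i * (b_risk * S_risk,i
                       - b_prot * S_prot,i) + sum_b b_b z_bi )

where ``S_c`` is the standardized module mean. Driving the hazard through
module scores keeps each gene's marginal per-SD log-hazard close to its
class beta (exactly beta for a one-gene class) while the total hazard
heterogeneity stays bounded no matter how many genes are planted — as with
a real co-expressed signature, not ninety independent effects.

The baseline hazard is exponential (chosen so censoring fractions and
hazard ratios are analytically checkable), with exponential dropout
censoring and administrative censoring at a fixed horizon. OS is DFS's
latent event time plus an exponential lag (rate ``os_coupling``), censored
by the same mechanisms, so OS >= DFS holds sample-by-sample as it does when
death is a DFS event.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = ["SimulationConfig", "SimulationTruth", "SyntheticTrial", "simulate_trial"]

GENE_CLASSES = ("prognostic", "predictive_protective", "predictive_risk", "null")


def _default_prevalence() -> dict[str, float]:
    return {"ctdna_c1d1": 0.35, "ttmb": 0.40, "pdl1": 0.45}


def _default_biomarker_log_hr() -> dict[str, float]:
    return {"ctdna_c1d1": 0.7, "ttmb": -0.2, "pdl1": -0.2}


@dataclass
class SimulationConfig:
    """Generating parameters of one synthetic trial.

    Times are in months. Defaults describe a 728-patient, 2,000-gene trial
    with strong predictive effects (|beta| = 1.0 per SD), ~70% DFS events
    by the 36-month administrative horizon, and modest prognostic effects.
    Effect sizes are illustrative — the trial this emulates publishes no
    per-gene effect magnitudes.
    """

    n_patients: int = 728
    arm_ratio: float = 0.5
    n_genes_total: int = 2000
    n_prognostic: int = 30
    n_predictive_protective: int = 30
    n_predictive_risk: int = 30
    beta_prognostic: float = 0.5
    beta_predictive: float = 1.0
    baseline_hazard: float = 0.05
    admin_censor_time: float = 36.0
    dropout_censor_rate: float = 0.01
    os_coupling: float = 0.15
    biomarker_prevalence: dict[str, float] = field(default_factory=_default_prevalence)
    biomarker_log_hr: dict[str, float] = field(default_factory=_default_biomarker_log_hr)
    biomarker_benefit_corr: float = 0.0
    ctdna_clearance_prob: float = 0.35
    noise_sd: float = 0.3
    module_correlation: float = 0.9
    low_variation_fraction: float = 0.5
    low_variation_scale: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        numeric = {
            k: v
            for k, v in asdict(self).items()
            if isinstance(v, (int, float)) and not isinstance(v, bool)
        }
        for k, v in numeric.items():
            if not math.isfinite(v):
                raise ValueError(f"non-finite configuration value: {k}={v}")
        planted = self.n_prognostic + self.n_predictive_protective + self.n_predictive_risk
        if planted > self.n_genes_total:
            raise ValueError(
                f"planted genes ({planted}) exceed n_genes_total ({self.n_genes_total})"
            )
        if not 0 < self.arm_ratio < 1:
            raise ValueError("arm_ratio must be in (0, 1)")
        for name in ("baseline_hazard", "admin_censor_time", "os_coupling"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.dropout_censor_rate < 0 or self.noise_sd < 0:
            raise ValueError("dropout_censor_rate and noise_sd must be non-negative")
        for b, p in self.biomarker_prevalence.items():
            if not 0 < p < 1:
                raise ValueError(f"prevalence of {b} must be in (0, 1), got {p}")
        if not 0 <= self.low_variation_fraction < 1:
            raise ValueError("low_variation_fraction must be in [0, 1)")
        if not 0 < self.module_correlation <= 1:
            raise ValueError("module_correlation must be in (0, 1]")
        n_lowvar = int(round(self.low_variation_fraction * self.n_genes_total))
        if planted + n_lowvar > self.n_genes_total:
            raise ValueError(
                "not enough null genes to host the low-variation fraction: "
                f"{planted} planted + {n_lowvar} low-variation > {self.n_genes_total}"
            )


@dataclass
class SimulationTruth:
    """Ground-truth labels for every planted effect."""

    gene_class: pd.Series  # gene_id -> class label
    true_beta: pd.Series  # gene_id -> class log-hazard coefficient (0 for null)
    benefit: pd.Series  # per-sample latent benefit score (higher = more IO benefit)
    linear_predictor_io: pd.Series | None = None  # true log-hazard if assigned to IO
    linear_predictor_obs: pd.Series | None = None  # true log-hazard if assigned to Obs

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_class": self.gene_class, "true_beta": self.true_beta}
        ).rename_axis("gene_id")


@dataclass
class SyntheticTrial:
    expression: pd.DataFrame  # genes x samples
    clinical: pd.DataFrame  # indexed by sample_id
    truth: SimulationTruth


def simulate_trial(config: SimulationConfig) -> SyntheticTrial:
    """Draw one trial. Identical config + seed gives a bit-identical dataset."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, g = config.n_patients, config.n_genes_total

    sample_ids = [f"P{i:04d}" for i in range(n)]
    gene_ids = [f"G{i:05d}" for i in range(g)]

    # gene classes occupy a fixed prefix of the gene list; recovery tests
    # look classes up by id, so placement is immaterial
    classes = np.array(["null"] * g, dtype=object)
    a = 0
    for name, count in (
        ("prognostic", config.n_prognostic),
        ("predictive_protective", config.n_predictive_protective),
        ("predictive_risk", config.n_predictive_risk),
    ):
        classes[a : a + count] = name
        a += count

    class_beta = {
        "prognostic": config.beta_prognostic,
        "predictive_protective": -abs(config.beta_predictive),
        "predictive_risk": abs(config.beta_predictive),
    }
    beta = np.array([class_beta.get(c, 0.0) for c in classes])

    # planted classes are co-expressed modules sharing a per-class factor;
    # each gene stays marginally N(0, 1)
    rho = config.module_correlation
    latent = rng.standard_normal((g, n))
    module_score: dict[str, np.ndarray] = {}
    for name in ("prognostic", "predictive_protective", "predictive_risk"):
        idx = np.flatnonzero(classes == name)
        m = idx.size
        if m == 0:
            module_score[name] = np.zeros(n)
            continue
        factor = rng.standard_normal(n)
        latent[idx] = np.sqrt(rho) * factor + np.sqrt(1 - rho) * latent[idx]
        # standardized module mean: Var(mean of m equicorrelated genes)
        sd_mean = np.sqrt((1 + (m - 1) * rho) / m)
        module_score[name] = latent[idx].mean(axis=0) / sd_mean

    observed = latent + config.noise_sd * rng.standard_normal((g, n))

    # the trailing null genes are "low-variation": shrunken marginal scale,
    # emulating the weakly expressed half of a transcriptome that the MAD
    # filter exists to remove (they carry no hazard signal either way)
    n_lowvar = int(round(config.low_variation_fraction * g))
    if n_lowvar:
        observed[g - n_lowvar :] *= config.low_variation_scale

    arm = (rng.random(n) < config.arm_ratio).astype(int)  # 1 = IO

    lp_prog = config.beta_prognostic * module_score["prognostic"]
    lp_pred = abs(config.beta_predictive) * (
        module_score["predictive_risk"] - module_score["predictive_protective"]
    )
    benefit = -lp_pred  # higher = larger hazard reduction under IO

    lp_bio = np.zeros(n)
    biomarkers: dict[str, np.ndarray] = {}
    for name, prev in config.biomarker_prevalence.items():
        if config.biomarker_benefit_corr != 0 and benefit.std() > 0:
            z = (benefit - benefit.mean()) / benefit.std()
            logit = math.log(prev / (1 - prev)) + config.biomarker_benefit_corr * z
            prob = 1 / (1 + np.exp(-logit))
        else:
            prob = np.full(n, prev)
        pos = (rng.random(n) < prob).astype(int)
        biomarkers[name] = pos
        lp_bio += config.biomarker_log_hr.get(name, 0.0) * pos

    lp = lp_prog + arm * lp_pred + lp_bio
    rate = config.baseline_hazard * np.exp(np.clip(lp, -30, 30))
    t_event = rng.exponential(1.0 / rate)
    t_lag = rng.exponential(1.0 / config.os_coupling, size=n)
    t_death = t_event + t_lag

    if config.dropout_censor_rate > 0:
        t_drop = rng.exponential(1.0 / config.dropout_censor_rate, size=n)
    else:
        t_drop = np.full(n, np.inf)
    t_censor = np.minimum(t_drop, config.admin_censor_time)

    dfs_time = np.minimum(t_event, t_censor)
    dfs_event = (t_event <= t_censor).astype(int)
    os_time = np.minimum(t_death, t_censor)
    os_event = (t_death <= t_censor).astype(int)

    ctdna_c1d1 = biomarkers.get("ctdna_c1d1")
    if ctdna_c1d1 is not None:
        cleared = rng.random(n) < config.ctdna_clearance_prob
        ctdna_c3d1 = (ctdna_c1d1 == 1) & ~cleared
    else:
        ctdna_c1d1 = np.zeros(n, dtype=int)
        ctdna_c3d1 = np.zeros(n, dtype=bool)

    def _posneg(x):
        return np.where(np.asarray(x).astype(bool), "pos", "neg")

    clinical = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "arm": np.where(arm == 1, "IO", "Obs"),
            "dfs_time": dfs_time,
            "dfs_event": dfs_event,
            "os_time": os_time,
            "os_event": os_event,
            "ctdna_c1d1": _posneg(ctdna_c1d1),
            "ctdna_c3d1": _posneg(ctdna_c3d1),
            "ttmb": _posneg(biomarkers.get("ttmb", np.zeros(n, dtype=int))),
            "pdl1": np.where(
                biomarkers.get("pdl1", np.zeros(n, dtype=int)).astype(bool),
                "IC23",
                "IC01",
            ),
        }
    ).set_index("sample_id", drop=False)

    expression = pd.DataFrame(observed, index=gene_ids, columns=sample_ids)
    expression.index.name = "gene_id"
    truth = SimulationTruth(
        gene_class=pd.Series(classes, index=gene_ids, name="gene_class"),
        true_beta=pd.Series(beta, index=gene_ids, name="true_beta"),
        benefit=pd.Series(benefit, index=sample_ids, name="benefit"),
        linear_predictor_io=pd.Series(
            lp_prog + lp_pred + lp_bio, index=sample_ids, name="lp_io"
        ),
        linear_predictor_obs=pd.Series(
            lp_prog + lp_bio, index=sample_ids, name="lp_obs"
        ),
    )
    return SyntheticTrial(expression=expression, clinical=clinical, truth=truth)
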