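"""Compare the score against binary biomarkers with time-dependent AUC.

Computes the IPCW cumulative/dynamic AUC of the forest score, ctDNA
positivity, and their Cox combination on validation immunotherapy
patients, at several horizons, with bootstrap confidence bands; also
writes an AUC plot next to this script.
"""

from pathlib import Path

import tempfile

import pandas as pd

from uaiscore import PipelineConfig, SimulationConfig, run_pipeline
from uaiscore.evaluate import TimeAUCCurve
from uaiscore.plotting import plot_auc

config = PipelineConfig(
    simulation=SimulationConfig(), seed=7, n_trees=500, n_bootstrap=100,
    eval_times=[6.0, 12.0, 18.0, 24.0],
)
with tempfile.TemporaryDirectory() as out:
    run_pipeline(config, out)
    auc = pd.read_csv(f"{out}/auc_curves.csv")

curves = []
for marker, grp in auc.groupby("marker", sort=False):
    curves.append(TimeAUCCurve(
        marker=marker, endpoint="dfs", times=grp["time"].to_numpy(),
        auc=grp["auc"].to_numpy(), ci_low=grp["ci_low"].to_numpy(),
        ci_high=grp["ci_high"].to_numpy(),
    ))
    cells = "  ".join(
        f"t={t:.0f}mo {a:.2f} [{lo:.2f},{hi:.2f}]"
        for t, a, lo, hi in zip(grp["time"], grp["auc"], grp["ci_low"], grp["ci_high"])
    )
    print(f"{marker:32s} {cells}")

png = Path(__file__).with_name("time_dependent_auc.png")
plot_auc(curves, png, title="Validation IO arm, DFS")
print(f"\nplot written to {png}")
print("reading: the continuous score dominates each binary biomarker alone;")
print("adding ctDNA to the score can lift early-horizon discrimination.")
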