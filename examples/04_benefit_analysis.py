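"""The treatment-benefit readout: who gains from adjuvant immunotherapy?

Runs the full pipeline on the default simulated trial, then prints the
hazard ratio of immunotherapy vs observation within each score stratum.
A high-stratum HR well below 1 with a low-stratum HR above 1 is the
signature of a predictive (treatment-selecting) score, as opposed to a
merely prognostic one.
"""

import tempfile

import pandas as pd

from uaiscore import PipelineConfig, SimulationConfig, run_pipeline

config = PipelineConfig(
    simulation=SimulationConfig(), seed=7, n_trees=500, n_bootstrap=50,
    eval_times=[6.0, 12.0, 18.0, 24.0],
)
with tempfile.TemporaryDirectory() as out:
    manifest = run_pipeline(config, out)
    benefit = pd.read_csv(f"{out}/benefit_cox.csv")

print("screening cascade:",
      f"{manifest.counts['genes_input']} genes",
      f"-> {manifest.counts['genes_after_mad']} after MAD filter",
      f"-> {manifest.counts['genes_after_survival_screen']} after survival screen",
      f"-> {manifest.counts['markers_total']} markers")
print()
for _, row in benefit.iterrows():
    print(f"{row['analysis']:20s} {row['covariate']:18s} "
          f"HR {row['hr']:5.2f} (95% CI {row['ci_low']:.2f}-{row['ci_high']:.2f}) "
          f"log-rank p {row['logrank_p']:.2g}")
print()
print("reading: in the high-score stratum immunotherapy roughly halves the")
print("hazard (HR<1), while low-score patients fare no better (HR>1) -- the")
print("score separates who benefits from treatment, not merely who does well.")
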