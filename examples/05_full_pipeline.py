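"""The full pipeline on a synthetic cohort with a planted SW->NE gradient.

Runs filtering, relatedness, quantile classification, spatial clustering,
binary disperser clustering and life-history analytics in one call and
compares the per-cluster SHORT-range proportions with the planted truth.
"""

import numpy as np

import patchkin as pk

cfg = pk.PipelineConfig(seed=1, simulation=pk.SimulationConfig(seed=1))
report = pk.run_pipeline(cfg, outdir="pipeline_output")

cohort = report.cohorts["juvenile"]
print(f"cohort of {cohort.n}: spatial K = {cohort.clustering.n_clusters}, "
      f"{len(cohort.ratio_classification.locals_)} locals, "
      f"{len(cohort.ratio_classification.migrants)} recent migrants")
print("\nper-cluster category proportions (clusters ordered SW->NE):")
print(cohort.proportions.round(3).to_string(index=False))

planted = pk.generate(cfg.simulation).planted_proportions()
est = cohort.proportions["SHORT"].to_numpy()
pl = planted["SHORT"].to_numpy()
print("\nSHORT-range proportion, estimated vs planted:")
for k, (e, p) in enumerate(zip(est, pl), start=1):
    print(f"  cluster {k}: {e:.3f} vs {p:.3f}")
print(f"max absolute error: {np.abs(est - pl).max():.3f}")
print("the planted SW->NE increase in local recruitment is recovered;")
print("tables and model files were written to pipeline_output/.")
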