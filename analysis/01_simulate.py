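"""Generate the synthetic study: predictor rasters, truth surfaces, occurrences.

The scenario plays the role of the real study system: a stack of
standardized, spatially autocorrelated environmental predictors over a
tropical-extent grid, a known log-linear (linear + quadratic) intensity
surface, and presence points sampled proportional to that intensity. Because
the truth is known, every downstream stage has a recoverable target.
"""

import numpy as np

from common import study_run

run = study_run()
run.stage_data()

study = run.truth
print(f"grid: {study.stack.grid.n_rows} x {study.stack.grid.n_cols} cells "
      f"of {study.stack.grid.cell_size * 60:.1f} arc-minutes")
print(f"predictors: {study.stack.names}")
print(f"true coefficients: linear={study.scenario.beta_linear.tolist()} "
      f"quadratic={study.scenario.beta_quadratic.tolist()}")
print(f"occurrences sampled: {len(study.occurrences)}")
print(f"true raw intensity sums to {np.nansum(study.true_raw.values):.6f} "
      f"(range {np.nanmin(study.true_raw.values):.2e}"
      f"..{np.nanmax(study.true_raw.values):.2e})")
print(f"artifacts under {run.outdir}")
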