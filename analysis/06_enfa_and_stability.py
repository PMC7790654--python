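"""Niche ordination and multi-period stability mapping.

ENFA contrasts the occupied environment (all unthinned occurrences,
cell-weighted) with the available background: marginality M is the shift of
the niche centroid in background-SD units, specialization S the narrowness
of the occupied variance. The fitted model is then projected onto synthetic
past-period stacks (the first predictor shifted, three noisy circulation-
model variants per period), ensembled, thresholded at the same 10TP value,
and stacked with the current range into stability classes.
"""

import pandas as pd

from common import study_run

run = study_run()
run.stage_data()
run.stage_thin()
run.stage_select()
run.stage_tune()
run.stage_evaluate()
run.stage_range()
run.stage_enfa()
run.stage_paleo()

en = run.report["enfa"]
print(f"ENFA: M = {en['M']:.3f}, S = {en['S']:.3f}")
print(f"variance share per axis (%, marginality first): "
      f"{[round(v, 2) for v in en['variance_share']]}")
print(f"top marginality predictor: {en['top_marginality_predictor']}")
print(f"loadings table: {run.outdir / 'enfa_loadings.csv'}")
print(pd.read_csv(run.outdir / "enfa_loadings.csv", index_col=0)
      .round(3).to_string())

p = run.report["paleo"]
print("\nrange area by period (km^2):")
print(f"  current:      {p['current_area_km2']:,.0f}")
for period, area in p["period_area_km2"].items():
    print(f"  {period:<12} {area:,.0f}")
print(f"stability class cell counts: {p['stability_class_cells']}")
print(f"stability map: {run.outdir / 'stability.asc'}")
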