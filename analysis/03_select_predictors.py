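"""Collinearity screen: stepwise VIF, then pairwise Spearman, at presence cells.

Redundant predictors inflate each other's apparent importance; the screen
drops the worst VIF column while any VIF >= 10, then resolves remaining
pairs with |rho| > 0.7 by discarding the more globally redundant member.
The synthetic layers are generated near-independent, so typically everything
survives — the audit trail is the interesting output when layers are built
correlated (set cross_corr in the scenario to exercise it).
"""

from common import study_run

run = study_run()
run.stage_data()
run.stage_thin()
run.stage_select()

rep = run.report["predictors"]
print(f"candidate predictors: {rep['n_candidates']}")
print(f"retained:             {rep['retained']}")
print(f"points dropped on nodata during extraction: "
      f"{rep['n_dropped_nodata_points']}")
audit = run.outdir / "selection_audit.csv"
print(f"drop-by-drop audit written to {audit}")
for line in audit.read_text().splitlines()[1:]:
    print("  dropped:", line)
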