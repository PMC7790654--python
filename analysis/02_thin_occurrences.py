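"""Clean the raw occurrence records and thin them to a 4 km minimum spacing.

Thinning counters spatially aggregated sampling effort: clusters of records
inside the exclusion radius collapse to representatives, so no pair of
retained points lies closer than the target spacing (here a surrogate for
mean inter-nest distance).
"""

from ppmsdm.occurrences import is_feasible

from common import study_run

run = study_run()
run.stage_data()
run.stage_thin()

rep = run.report["occurrences"]
print(f"input records:            {rep['n_input']}")
print(f"dropped (no coords):      {rep['n_no_georeference']}")
print(f"dropped (invalid coords): {rep['n_invalid_coordinate']}")
print(f"dropped (duplicates):     {rep['n_duplicate']}")
print(f"cleaned records:          {rep['n_cleaned']}")
print(f"thinned at {rep['thin_km']} km:        {rep['n_thinned']}")
assert is_feasible(run.thinned, rep["thin_km"]), "thinning audit failed"
print("all-pairs distance audit passed: no pair closer than the minimum")
print(f"thinned set written to {run.outdir / 'occurrences_thinned.csv'}")
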