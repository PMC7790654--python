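# Bundled synthetic end-to-end configuration.
#
# ppmsdm run-all --config configs/synthetic.yaml --seed 42 --outdir out/
#
# Omitted keys keep the study defaults: 4 km thinning over 100 trials,
# VIF < 10 then |rho| <= 0.7 selection, 18 candidates (rm 1..5 step 0.5 x
# {L, LQ}), 10,000 background cells, checkerboard folds, 10TP threshold,
# pROC with E = 5% / 1,000 bootstraps / 50% resamples, CBI with 5 folds and
# 101 windows, ENFA on 100,000 background cells.
synthetic:
  n_rows: 100
  n_cols: 100
  n_layers: 3
  autocorr_length: 5.0
  n_presences: 500
  beta_linear: [1.0, 0.6, 0.0]
  beta_quadratic: [-0.8, 0.0, 0.0]
seed: 42
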