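# ppmsdm — presence-only point-process species distribution modelling

`ppmsdm` is a tested, seed-reproducible pipeline for estimating a species'
geographic range and environmental requirements from presence-only
occurrence records and gridded environmental predictors — the standard
workflow for data-poor, wide-ranging species (the motivating case is a
continental-scale tropical forest raptor). It covers:

- **occurrence handling** — cleaning (duplicates, missing/invalid
  coordinates) and distance-based spatial thinning (greedy
  maximum-neighbour removal with random restarts) to a minimum great-circle
  spacing;
- **predictor screening** — stepwise variance-inflation-factor elimination
  (VIF < 10) followed by pairwise Spearman screening (|ρ| ≤ 0.7) at
  presence cells, with a full audit trail;
- **the model** — a penalized inhomogeneous Poisson process (the maxent
  estimator) over linear + quadratic features, tuned across 18 candidates
  (regularization multiplier 1–5 × feature classes) by AICc, with
  checkerboard spatial cross-validation;
- **validation** — AUC, MTP/10TP omission rates, bootstrap partial-ROC
  ratios and the Continuous Boyce Index;
- **geography** — 10TP binary range maps, exact spherical cell-area sums
  (km²), minimum convex polygon / extent of occurrence;
- **ordination** — Ecological Niche Factor Analysis (marginality M,
  specialization S, factor loadings);
- **time projection** — projection onto other periods' predictor stacks,
  circulation-model ensembling, Schoener's D niche overlap and stability
  (refugium) classification;
- **synthetic data** — a generator of correlated, spatially autocorrelated
  predictor stacks with a *known* intensity surface, so every stage has a
  recoverable ground truth without any external download.

## The model

Occurrences are treated as a realization of an inhomogeneous Poisson point
process with log-linear intensity in scaled features
z<sub>k</sub>(x) ∈ [0, 1] (min–max scaled predictors and their squares).
The estimator minimizes the penalized IPP log-loss

    f(β) = −(1/n) Σ_presences η(x_i) + log Σ_background exp η(z_j) + Σ_k λ_k |β_k|

with per-feature penalties λ_k = rm · Λ_class(n) · √(var_k/n), where
Λ_class(n) is the maxent default schedule interpolated on the presence
sample size and *rm* is the tuned regularization multiplier. Relative
intensity is reported either raw (e^η normalized over the background) or as
the cloglog suitability index 1 − exp(−e^H · raw), H the entropy of the raw
surface. The same objective is the large-weight limit of weighted logistic
regression, which the test suite uses as an independent estimation route.

ENFA standardizes predictors over the background and contrasts the occupied
cells (weighted by occurrence counts): M = ‖m‖ is the norm of the weighted
mean shift, and the specialization factors maximize the available/occupied
variance ratio (u'R_g u)/(u'R_s u) subject to R_s-orthogonality, with
S = √(mean λ).

## Worked example

The `analysis/` scripts run the bundled synthetic study (100 × 100 grid of
2.5′ cells, three autocorrelated predictors, 500 presences sampled from a
known intensity surface, seed 42) through the full pipeline:

```bash
cd analysis
python 01_simulate.py
python 02_thin_occurrences.py
python 04_fit_and_tune.py
```

`02_thin_occurrences.py` reports 500 cleaned records thinned to **434** at
4 km (the all-pairs distance audit passes). `04_fit_and_tune.py` prints the
18-candidate table; on this realization the selected model is
`rm=1.5 classes=LQ K=5` with spatially cross-validated
AUC train/test = 0.748/0.729 and omission rates MTP = 0.003,
10TP = 0.104 — close to their theoretical expectations (0 and 0.10).
`05_evaluate_and_range.py` then reports

```
pROC ratio: 1.160 (SD 0.021, range 1.108-1.247, p=0.000)
mean CBI over 5 folds: 0.937
Spearman rho (fitted vs true intensity): 0.990
10TP threshold: 0.311
suitable range area: 128,321 km^2
MCP extent of occurrence: 197,272 km^2
```

i.e. the model is far from the random-model null (ratio 1 would be random),
well calibrated, and recovers the true intensity ordering almost perfectly
(ρ = 0.990). `06_enfa_and_stability.py` closes with the niche ordination
(M = 0.919, S = 1.296) and the paleo trajectory: range area shrinks from
128,321 km² (current) to 97,717 km² (mid-Holocene analogue) to 72,156 km²
(glacial-maximum analogue), matching the ordering imposed on the synthetic
past climates, and every unmasked cell receives exactly one stability class.

The same pipeline is scriptable via the CLI
(`ppmsdm run-all --seed 42 --outdir out/`, plus per-stage subcommands
`simulate`, `thin`, `select`, `fit`, `evaluate`, `range`, `enfa`, `project`,
`stability`) or with user-supplied data by pointing a YAML config at an
occurrence CSV, a predictor directory, and optional land-mask and
past-period rasters.

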