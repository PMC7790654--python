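"""Configuration-driven orchestration of the full modelling pipeline.

One :class:`RunConfig` (YAML-loadable) drives: data acquisition (bundled
synthetic scenario or user-supplied CSV + rasters) -> cleaning -> spatial
thinning -> collinearity selection -> candidate tuning -> validation ->
binary range + geometry -> ENFA -> paleoclimate projection and stability.
A single global seed is expanded deterministically into per-stage seeds, so
one number reproduces every artifact; the run report is path- and
timestamp-free, making identical configurations byte-identical.

Stages cache their primary artifacts under the output directory together
with a marker recording the config hash; a rerun with an unchanged config
resumes from the cached outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enfa as enfa_mod
from . import evaluation, geography, occurrences, paleo, ppm, predictors
from . import synthetic as synth
from .grid import GeoGrid, RasterStack

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Everything one pipeline run depends on."""

    # data: either a synthetic scenario (default) or user-supplied paths
    synthetic: dict = field(default_factory=dict)   # SyntheticScenario overrides
    occurrences_csv: str | None = None
    predictor_dir: str | None = None
    landmask: str | None = None
    past_period_dirs: dict = field(default_factory=dict)   # period -> [gcm dirs]

    # stage parameters (defaults are the study conditions)
    thin_km: float = 4.0
    thin_trials: int = 100
    vif_max: float = 10.0
    rho_max: float = 0.7
    rm_grid: list = field(default_factory=lambda: [1, 1.5, 2, 2.5, 3, 3.5, 4, 4.5, 5])
    class_grid: list = field(default_factory=lambda: [["linear"], ["linear", "quadratic"]])
    background_n: int = 10000
    enfa_background_n: int = 100000
    checkerboard_agg: list = field(default_factory=lambda: [10, 2])
    threshold_rule: str = "10tp"
    proc_e_rate: float = 0.05
    proc_n_boot: int = 1000
    proc_boot_prop: float = 0.5
    cbi_folds: int = 5
    cbi_windows: int = 101
    cbi_window_frac: float = 0.1
    fit_tol: float = 1e-5
    fit_max_iter: int = 5000
    # synthetic paleo scenario: period -> shift of the first predictor (SD units)
    paleo_shifts: dict = field(default_factory=lambda: {"midholocene": -0.4, "lgm": -0.8})
    paleo_n_gcms: int = 3
    paleo_gcm_noise: float = 0.05

    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]

    def stage_seeds(self) -> dict[str, int]:
        """Deterministic per-stage seeds (< 2^31) from the global seed."""
        names = ["simulate", "thin", "background", "tune", "evaluate",
                 "enfa", "paleo", "folds"]
        state = np.random.SeedSequence(self.seed).generate_state(len(names))
        return {n: int(s % (2 ** 31)) for n, s in zip(names, state)}


class PipelineRun:
    """Executes the configured stages in order, caching artifacts."""

    def __init__(self, config: RunConfig, outdir: str | Path):
        self.config = config
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.stage_dir = self.outdir / ".stages"
        self.stage_dir.mkdir(exist_ok=True)
        self.seeds = config.stage_seeds()
        self.report: dict = {
            "schema_version": REPORT_SCHEMA_VERSION,
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "stage_seeds": self.seeds,
        }

    # -- caching helpers ----------------------------------------------------
    def _fresh(self, stage: str) -> bool:
        marker = self.stage_dir / f"{stage}.json"
        if not marker.exists():
            return False
        return json.loads(marker.read_text()).get("config_hash") == self.config.config_hash()

    def _mark(self, stage: str) -> None:
        (self.stage_dir / f"{stage}.json").write_text(
            json.dumps({"config_hash": self.config.config_hash()}))

    # -- stages -------------------------------------------------------------
    def stage_data(self) -> None:
        cfg = self.config
        if cfg.occurrences_csv is not None and cfg.predictor_dir is not None:
            self.raw_records = pd.read_csv(cfg.occurrences_csv)
            self.stack = RasterStack.read_dir(cfg.predictor_dir)
            self.truth = None
        else:
            overrides = dict(cfg.synthetic)
            overrides.setdefault("seed", self.seeds["simulate"])
            scenario = synth.SyntheticScenario(**overrides)
            study = synth.realize(scenario)
            self.stack = study.stack
            self.truth = study
            self.raw_records = study.occurrences.data
            if not self._fresh("data"):
                self.stack.write_dir(self.outdir / "predictors")
                study.true_raw.write_ascii(self.outdir / "true_raw.asc")
                study.true_cloglog.write_ascii(self.outdir / "true_cloglog.asc")
                self.raw_records.to_csv(self.outdir / "occurrences_raw.csv", index=False)
                self._mark("data")
        self.landmask = GeoGrid.read_ascii(cfg.landmask) if cfg.landmask else None

    def stage_thin(self) -> None:
        self.cleaned = occurrences.clean(self.raw_records)
        path = self.outdir / "occurrences_thinned.csv"
        if self._fresh("thin") and path.exists():
            self.thinned = occurrences.OccurrenceSet(pd.read_csv(path),
                                                     report=self.cleaned.report)
        else:
            self.thinned = occurrences.thin(self.cleaned, self.config.thin_km,
                                            self.config.thin_trials,
                                            seed=self.seeds["thin"])
            self.thinned.to_csv(path)
            self._mark("thin")
        rep = self.cleaned.report.to_dict() if self.cleaned.report else {}
        self.report["occurrences"] = {
            **rep, "n_cleaned": len(self.cleaned), "n_thinned": len(self.thinned),
            "thin_km": self.config.thin_km,
        }

    def stage_select(self) -> None:
        extraction = predictors.extract(self.stack, self.thinned)
        retained, audit = predictors.select_uncorrelated(
            extraction.matrix, vif_max=self.config.vif_max, rho_max=self.config.rho_max)
        audit.to_frame().to_csv(self.outdir / "selection_audit.csv", index=False)
        self.retained = retained
        self.report["predictors"] = {
            "n_candidates": len(self.stack),
            "retained": retained,
            "n_dropped_nodata_points": extraction.n_dropped_nodata,
        }

    def stage_tune(self) -> None:
        cfg = self.config
        sub = RasterStack.from_mapping({n: self.stack[n] for n in self.retained})
        bg = ppm.sample_background(sub, n=cfg.background_n, seed=self.seeds["background"])
        self.bg_values = bg[self.retained]
        pres_ex = predictors.extract(sub, self.thinned)
        self.pres_values = pres_ex.matrix
        kept = pres_ex.kept_index
        lon = self.thinned.lon[kept]
        lat = self.thinned.lat[kept]
        folds = ppm.checkerboard_partition(lon, lat, sub.grid, *cfg.checkerboard_agg)
        _, _, grid_matrix = sub.cell_table()
        self.grid_values = pd.DataFrame(grid_matrix, columns=self.retained)

        model_path = self.outdir / "model.json"
        table_path = self.outdir / "candidates.csv"
        if self._fresh("tune") and model_path.exists() and table_path.exists():
            self.model = ppm.PPMModel.from_json(model_path)
            self.candidates = pd.read_csv(table_path, float_precision="round_trip")
            best = self.candidates["delta_aicc"].idxmin()
        else:
            result = ppm.tune(self.pres_values, self.bg_values, self.grid_values,
                              folds, rm_grid=cfg.rm_grid,
                              class_grid=[tuple(c) for c in cfg.class_grid],
                              tol=cfg.fit_tol, max_iter=cfg.fit_max_iter)
            self.model = result.best
            self.candidates = result.table
            self.candidates.to_csv(table_path, index=False, float_format="%.17g")
            self.model.to_json(model_path)
            self._mark("tune")
            best = result.best_index
        self.sub_stack = sub
        row = self.candidates.loc[best]
        self.report["model"] = {
            "n_candidates": len(self.candidates),
            "best_rm": float(row["rm"]),
            "best_classes": str(row["classes"]),
            "best_K": int(row["K"]),
            "best_aicc": float(row["aicc"]),
            "auc_train": float(row["auc_train"]),
            "auc_test": float(row["auc_test"]),
            "auc_diff": float(row["auc_diff"]),
            "or_mtp": float(row["or_mtp"]),
            "or_10tp": float(row["or_10tp"]),
            "converged": bool(self.model.converged),
        }

    def stage_evaluate(self) -> None:
        cfg = self.config
        suit = self.model.predict_grid(self.sub_stack, output="cloglog")
        suit.write_ascii(self.outdir / "suitability_cloglog.asc")
        self.suitability = suit
        pres_scores = self.model.predict(self.pres_values, output="cloglog")
        cell_scores = suit.unmasked_values()
        proc = evaluation.partial_roc(cell_scores, pres_scores, e_rate=cfg.proc_e_rate,
                                      n_boot=cfg.proc_n_boot, boot_prop=cfg.proc_boot_prop,
                                      seed=self.seeds["evaluate"])
        cbi_mean, cbi_folds = evaluation.cbi_cross_validated(
            pres_scores, cell_scores, n_folds=cfg.cbi_folds,
            seed=self.seeds["evaluate"], n_windows=cfg.cbi_windows,
            window_frac=cfg.cbi_window_frac)
        m = self.report["model"]
        self.eval_report = evaluation.EvaluationReport(
            auc_train=m["auc_train"], auc_test=m["auc_test"], auc_diff=m["auc_diff"],
            or_mtp=m["or_mtp"], or_10tp=m["or_10tp"],
            proc_mean=proc.mean_ratio, proc_sd=proc.sd, proc_range=proc.range,
            proc_p=proc.p_value, cbi_mean=cbi_mean, cbi_folds=cbi_folds)
        self.report["evaluation"] = self.eval_report.to_dict()
        (self.outdir / "evaluation.json").write_text(
            json.dumps(self.eval_report.to_dict(), indent=2, sort_keys=True))
        self.pres_scores = pres_scores
        # recovery diagnostic against ground truth when it exists
        if self.truth is not None:
            from scipy import stats as sstats
            pred_raw = self.model.predict_grid(self.sub_stack, output="raw")
            shared = pred_raw.mask & self.truth.true_raw.mask
            rho = sstats.spearmanr(pred_raw.values[shared],
                                   self.truth.true_raw.values[shared]).statistic
            self.report["evaluation"]["spearman_true_vs_fitted_raw"] = float(rho)

    def stage_range(self) -> None:
        thr = evaluation.threshold(self.pres_scores, self.config.threshold_rule)
        self.binary = geography.binarize(self.suitability, thr, source="best-model")
        self.binary.grid.write_ascii(self.outdir / "binary_range.asc")
        area = geography.area_km2(self.binary)
        hull = geography.mcp(self.thinned.lon, self.thinned.lat)
        eoo = geography.eoo_area_km2(hull, landmask=self.landmask)
        (self.outdir / "mcp.geojson").write_text(json.dumps(geography.to_geojson(hull)))
        self.report["range"] = {
            "threshold_rule": self.config.threshold_rule,
            "threshold": thr,
            "suitable_area_km2": area,
            "eoo_km2": eoo,
        }
        self.threshold = thr

    def stage_enfa(self) -> None:
        result = enfa_mod.enfa_fit(self.sub_stack, self.cleaned,
                                   n_background=self.config.enfa_background_n,
                                   seed=self.seeds["enfa"])
        result.loadings_table().to_csv(self.outdir / "enfa_loadings.csv")
        (self.outdir / "enfa.json").write_text(
            json.dumps(result.to_dict(), indent=2, sort_keys=True))
        enfa_mod.biplot(result, self.outdir / "enfa_biplot.svg")
        self.report["enfa"] = {
            "M": result.marginality,
            "S": result.specialization,
            "variance_share": result.variance_share.tolist(),
            "top_marginality_predictor":
                result.loadings_table().index[0],
        }

    def stage_paleo(self) -> None:
        cfg = self.config
        if cfg.past_period_dirs:
            period_stacks = {
                period: [RasterStack.read_dir(d, names=self.retained) for d in dirs]
                for period, dirs in cfg.past_period_dirs.items()}
        elif self.truth is not None:
            period_stacks = self._synthetic_past_stacks()
        else:
            self.report["paleo"] = {"skipped": "no past-period rasters configured"}
            return
        projections: dict[str, GeoGrid] = {}
        past_binaries = []
        overlaps = {}
        for period, stacks in period_stacks.items():
            per_gcm = [paleo.project(self.model, s, output="cloglog") for s in stacks]
            mean_grid = paleo.ensemble(per_gcm, method="mean")
            projections[period] = mean_grid
            named = {f"{period}_gcm{i + 1}": g for i, g in enumerate(per_gcm)}
            overlaps[period] = paleo.overlap_matrix(named).to_dict()
            past_binaries.append(geography.binarize(mean_grid, self.threshold,
                                                    source=period))
            mean_grid.write_ascii(self.outdir / f"suitability_{period}.asc")
        stab = paleo.stability(self.binary, past_binaries,
                               period_ids=list(period_stacks))
        stab.grid.write_ascii(self.outdir / "stability.asc")
        (self.outdir / "stability_codes.json").write_text(
            json.dumps(stab.code_book, indent=2, sort_keys=True))
        areas = {p: geography.area_km2(b) for p, b in
                 zip(period_stacks, past_binaries)}
        class_cells = {label: int(stab.class_mask(label).sum())
                       for label in stab.code_book}
        self.report["paleo"] = {
            "period_area_km2": areas,
            "current_area_km2": self.report["range"]["suitable_area_km2"],
            "stability_class_cells": class_cells,
            "gcm_overlap": overlaps,
        }

    def _synthetic_past_stacks(self) -> dict[str, list[RasterStack]]:
        """Past periods built by shifting the first retained predictor."""
        cfg = self.config
        rng = np.random.default_rng(self.seeds["paleo"])
        out: dict[str, list[RasterStack]] = {}
        first = self.retained[0]
        for period, shift in cfg.paleo_shifts.items():
            stacks = []
            for _ in range(cfg.paleo_n_gcms):
                layers = {}
                for name in self.retained:
                    g = self.sub_stack[name]
                    if name == first:
                        noise = rng.normal(0.0, cfg.paleo_gcm_noise)
                        layers[name] = g.with_values(g.values + shift + noise)
                    else:
                        layers[name] = g
                stacks.append(RasterStack.from_mapping(layers))
            out[period] = stacks
        return out

    # -- driver -------------------------------------------------------------
    def run(self) -> dict:
        self.stage_data()
        self.stage_thin()
        self.stage_select()
        self.stage_tune()
        self.stage_evaluate()
        self.stage_range()
        self.stage_enfa()
        self.stage_paleo()
        report_path = self.outdir / "report.json"
        report_path.write_text(json.dumps(self.report, indent=2, sort_keys=True))
        logger.info("pipeline complete: %s", report_path)
        return self.report


def run(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the full pipeline; returns the report dictionary."""
    return PipelineRun(config, outdir).run()
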