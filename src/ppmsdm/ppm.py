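"""Penalized inhomogeneous-Poisson-process (maxent) model fitting.

Presence-only occurrences are modelled as an inhomogeneous Poisson point
process whose log-intensity is linear in scaled features of the predictors
(here linear and quadratic transforms). The estimator minimizes the
L1-penalized IPP log-loss

    f(beta) = -(1/n) sum_presences eta(x_i) + log sum_background e^{eta(z_j)}
              + sum_k lambda_k |beta_k|

which is the same estimator maxent computes, and which "infinitely weighted"
logistic regression approaches as the background weight grows
(:func:`fit_iwlr` implements that second route; tests use it as a
cross-check, never as the estimator). Per-feature penalties follow the
maxent default schedule: lambda_k = rm * Lambda_class(n) * sqrt(var_k / n),
with the class tables interpolated on the presence sample size and the
regularization multiplier ``rm`` the single tuned knob.

Model selection fits a grid of candidates (rm x feature-class combinations),
scores each by AICc with K = number of nonzero coefficients and the
likelihood of grid-standardized raw suitability, and evaluates spatial
transferability by checkerboard cross-validation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp, softmax

from .grid import GeoGrid, RasterStack
from . import evaluation

FEATURE_CLASSES = ("linear", "quadratic")

# Maxent default per-feature-class regularization, interpolated on the
# presence sample size (transcribed from the reference open-source
# implementation's defaults).
_REG_SCHEDULE = {
    "linear": (np.array([0.0, 10.0, 30.0, 100.0]),
               np.array([1.0, 1.0, 0.2, 0.05])),
    "quadratic": (np.array([0.0, 10.0, 17.0, 30.0, 100.0]),
                  np.array([1.3, 1.3, 0.8, 0.5, 0.05])),
}


def default_regularization(feature_class: str, n_presences: int) -> float:
    """Base penalty Lambda_class(n) for one feature class at sample size n."""
    xs, ys = _REG_SCHEDULE[feature_class]
    return float(np.interp(n_presences, xs, ys))


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

@dataclass
class FeatureSpec:
    """Feature classes plus the calibration scaling bounds per predictor."""

    predictors: list[str]
    classes: tuple[str, ...] = ("linear", "quadratic")
    bounds: dict[str, dict[str, float]] = field(default_factory=dict)
    # bounds[name] = {lin_min, lin_max, sq_min, sq_max}

    def __post_init__(self) -> None:
        if not self.classes:
            raise ValueError("at least one feature class is required")
        for c in self.classes:
            if c not in FEATURE_CLASSES:
                raise ValueError(f"unknown feature class {c!r}")

    @classmethod
    def from_calibration(cls, values: pd.DataFrame,
                         classes: Sequence[str] = ("linear", "quadratic")) -> "FeatureSpec":
        bounds = {}
        for name in values.columns:
            x = values[name].to_numpy(dtype=float)
            sq = x * x
            b = {"lin_min": float(x.min()), "lin_max": float(x.max()),
                 "sq_min": float(sq.min()), "sq_max": float(sq.max())}
            if b["lin_max"] <= b["lin_min"]:
                raise ValueError(f"predictor {name!r} is constant on calibration data")
            bounds[name] = b
        return cls(predictors=list(values.columns), classes=tuple(classes), bounds=bounds)

    @property
    def feature_names(self) -> list[str]:
        names = []
        if "linear" in self.classes:
            names += [f"{p}" for p in self.predictors]
        if "quadratic" in self.classes:
            names += [f"{p}^2" for p in self.predictors]
        return names

    @property
    def feature_classes(self) -> list[str]:
        out = []
        if "linear" in self.classes:
            out += ["linear"] * len(self.predictors)
        if "quadratic" in self.classes:
            out += ["quadratic"] * len(self.predictors)
        return out


def build_features(values: pd.DataFrame, spec: FeatureSpec,
                   clamp: bool = True) -> tuple[np.ndarray, int]:
    """Scaled feature matrix (n x K) plus the count of clamped entries.

    Linear features are min-max scaled to [0,1] on the calibration bounds;
    quadratic features min-max scale x^2. Projection data outside the
    calibration range is clamped to [0,1].
    """
    missing = [p for p in spec.predictors if p not in values.columns]
    if missing:
        raise ValueError(f"missing predictor column(s): {missing}")
    cols = []
    for cls_name in spec.classes:
        for p in spec.predictors:
            x = values[p].to_numpy(dtype=float)
            b = spec.bounds[p]
            if cls_name == "linear":
                f = (x - b["lin_min"]) / (b["lin_max"] - b["lin_min"])
            else:
                denom = b["sq_max"] - b["sq_min"]
                f = (x * x - b["sq_min"]) / denom if denom > 0 else np.zeros_like(x)
            cols.append(f)
    feats = np.column_stack(cols)
    if not np.isfinite(feats).all():
        raise ValueError("non-finite feature values")
    n_clamped = int(((feats < 0) | (feats > 1)).sum())
    if clamp and n_clamped:
        feats = np.clip(feats, 0.0, 1.0)
    return feats, n_clamped


def penalty_vector(spec: FeatureSpec, pres_features: np.ndarray, rm: float,
                   penalty_n: int | None = None) -> np.ndarray:
    """Per-feature L1 weights: rm * Lambda_class(n) * sqrt(var_k / n).

    ``penalty_n`` overrides the sample size entering the schedule (useful
    when rows are deliberately replicated but the effective n is known).
    """
    n = penalty_n if penalty_n is not None else pres_features.shape[0]
    var = pres_features.var(axis=0)
    lam = np.empty(pres_features.shape[1])
    for k, cls_name in enumerate(spec.feature_classes):
        lam[k] = rm * default_regularization(cls_name, n) * np.sqrt(var[k] / n)
    return lam


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class PPMModel:
    """A fitted penalized IPP model with everything needed to predict."""

    coefficients: np.ndarray
    spec: FeatureSpec
    rm: float
    log_z: float                 # log sum_background e^eta over calibration bg
    entropy_h: float             # Shannon entropy of raw over calibration bg
    n_presences: int
    n_background: int
    converged: bool
    n_iter: int
    objective: float

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.coefficients))

    def eta(self, values: pd.DataFrame) -> np.ndarray:
        feats, _ = build_features(values, self.spec, clamp=True)
        return feats @ self.coefficients

    def predict(self, values: pd.DataFrame, output: str = "cloglog") -> np.ndarray:
        """Raw (background-normalized intensity) or cloglog suitability."""
        eta = self.eta(values)
        raw = np.exp(eta - self.log_z)
        if output == "raw":
            return raw
        if output == "cloglog":
            return 1.0 - np.exp(-np.exp(self.entropy_h) * raw)
        raise ValueError(f"unknown output {output!r}")

    def predict_grid(self, stack: RasterStack, output: str = "cloglog") -> GeoGrid:
        """Suitability over every shared unmasked cell of a stack."""
        rows, cols, matrix = stack.cell_table()
        values = pd.DataFrame(matrix, columns=stack.names)
        scores = self.predict(values[self.spec.predictors], output=output)
        out = np.full(stack.grid.values.shape, np.nan)
        out[rows, cols] = scores
        return stack.grid.with_values(out)

    # -- serialization ------------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "coefficients": self.coefficients.tolist(),
            "feature_names": self.spec.feature_names,
            "predictors": self.spec.predictors,
            "classes": list(self.spec.classes),
            "bounds": self.spec.bounds,
            "rm": self.rm,
            "log_z": self.log_z,
            "entropy_h": self.entropy_h,
            "n_presences": self.n_presences,
            "n_background": self.n_background,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "objective": self.objective,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PPMModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        spec = FeatureSpec(predictors=d["predictors"], classes=tuple(d["classes"]),
                           bounds=d["bounds"])
        return cls(coefficients=np.asarray(d["coefficients"]), spec=spec, rm=d["rm"],
                   log_z=d["log_z"], entropy_h=d["entropy_h"],
                   n_presences=d["n_presences"], n_background=d["n_background"],
                   converged=d["converged"], n_iter=d["n_iter"], objective=d["objective"])


def _ipp_objective(beta: np.ndarray, pres: np.ndarray, bg: np.ndarray,
                   lam: np.ndarray) -> float:
    eta_bg = bg @ beta
    return float(-(pres @ beta).mean() + logsumexp(eta_bg) + lam @ np.abs(beta))


def fit(pres_features: np.ndarray, bg_features: np.ndarray, spec: FeatureSpec,
        rm: float = 1.0, tol: float = 1e-5, max_iter: int = 5000,
        penalty_n: int | None = None) -> PPMModel:
    """Minimize the penalized IPP log-loss by FISTA with backtracking.

    Convergence is declared when the change in the penalized objective
    between successive iterations falls below ``tol``; the convergence flag
    and iteration count are recorded on the model. The intercept is
    unnecessary: it cancels exactly between the presence and normalizer
    terms of the IPP loss.
    """
    pres = np.asarray(pres_features, dtype=float)
    bg = np.asarray(bg_features, dtype=float)
    if pres.shape[0] < 2:
        raise ValueError("need at least 2 presences")
    if not (np.isfinite(pres).all() and np.isfinite(bg).all()):
        raise ValueError("non-finite feature values")
    if bg.shape[0] < pres.shape[0]:
        warnings.warn("background smaller than presence sample; normalizer will be noisy")
    lam = penalty_vector(spec, pres, rm, penalty_n=penalty_n)
    pres_mean = pres.mean(axis=0)

    def smooth(beta):
        return float(-(pres_mean @ beta) + logsumexp(bg @ beta))

    def grad(beta):
        w = softmax(bg @ beta)
        return -pres_mean + w @ bg

    k = pres.shape[1]
    beta = np.zeros(k)
    y = beta.copy()
    t = 1.0
    step = 1.0
    obj_prev = smooth(beta) + lam @ np.abs(beta)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        g_y = smooth(y)
        grad_y = grad(y)
        # backtracking on the smooth part
        while True:
            cand = np.sign(y - step * grad_y) * np.maximum(
                np.abs(y - step * grad_y) - step * lam, 0.0)
            diff = cand - y
            if smooth(cand) <= g_y + grad_y @ diff + (diff @ diff) / (2 * step) + 1e-12:
                break
            step *= 0.5
            if step < 1e-14:
                break
        beta_new = cand
        t_new = (1.0 + np.sqrt(1.0 + 4.0 * t * t)) / 2.0
        y = beta_new + ((t - 1.0) / t_new) * (beta_new - beta)
        beta, t = beta_new, t_new
        obj = smooth(beta) + lam @ np.abs(beta)
        if obj > obj_prev + tol:       # FISTA ripple: restart momentum
            y = beta.copy()
            t = 1.0
        if abs(obj_prev - obj) < tol:
            converged = True
            obj_prev = obj
            break
        obj_prev = obj
        step *= 1.2                    # allow the step to grow back

    eta_bg = bg @ beta
    log_z = float(logsumexp(eta_bg))
    p = softmax(eta_bg)
    entropy_h = float(-(p * np.log(np.clip(p, 1e-300, None))).sum())
    return PPMModel(coefficients=beta, spec=spec, rm=rm, log_z=log_z,
                    entropy_h=entropy_h, n_presences=pres.shape[0],
                    n_background=bg.shape[0], converged=converged,
                    n_iter=n_iter, objective=obj_prev)


def fit_iwlr(pres_features: np.ndarray, bg_features: np.ndarray, spec: FeatureSpec,
             rm: float = 1.0, bg_weight: float = 100.0, tol: float = 1e-12,
             max_iter: int = 20000) -> np.ndarray:
    """Weighted-logistic route to the same estimator (cross-check only).

    Penalized logistic regression with response 1 on presences (weight 1)
    and 0 on background (weight ``bg_weight``), free intercept, and the same
    per-feature L1 penalties as :func:`fit` (scaled per presence). As the
    background weight grows this converges to the IPP slopes; returns the
    slope vector (intercept dropped). Solved by the split-variable
    (beta = u - v, u, v >= 0) smooth reformulation with L-BFGS-B.
    """
    from scipy.optimize import minimize

    pres = np.asarray(pres_features, dtype=float)
    bg = np.asarray(bg_features, dtype=float)
    n, k = pres.shape
    lam = penalty_vector(spec, pres, rm)
    x_pres = np.column_stack([np.ones(n), pres])
    x_bg = np.column_stack([np.ones(bg.shape[0]), bg])
    kk = k + 1   # with intercept

    def unpack(z):
        alpha_u, alpha_v = z[0], z[kk]
        return (z[:kk] - z[kk:])

    def objective(z):
        b = unpack(z)
        eta_p = x_pres @ b
        eta_b = x_bg @ b
        nll = (np.logaddexp(0.0, -eta_p).sum()
               + bg_weight * np.logaddexp(0.0, eta_b).sum()) / n
        pen = lam @ (z[1:kk] + z[kk + 1:])
        # gradient of the smooth part w.r.t. beta
        gp = -(1.0 / (1.0 + np.exp(eta_p))) @ x_pres
        gb = bg_weight * (1.0 / (1.0 + np.exp(-eta_b))) @ x_bg
        g_beta = (gp + gb) / n
        g_pen = np.concatenate([[0.0], lam])
        grad = np.concatenate([g_beta + g_pen, -g_beta + g_pen])
        return nll + pen, grad

    z0 = np.zeros(2 * kk)
    z0[0] = 0.0
    # warm-start the intercept near its limiting value
    alpha0 = -np.log(bg_weight * bg.shape[0] / n)
    if alpha0 >= 0:
        z0[0] = alpha0
    else:
        z0[kk] = -alpha0
    res = minimize(objective, z0, jac=True, method="L-BFGS-B",
                   bounds=[(0, None)] * (2 * kk),
                   options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-12})
    b = res.x[:kk] - res.x[kk:]
    return b[1:]


# ---------------------------------------------------------------------------
# background sampling, AICc, cross-validation, tuning
# ---------------------------------------------------------------------------

def sample_background(stack: RasterStack, n: int = 10000,
                      seed: int | None = None) -> pd.DataFrame:
    """Uniform random unmasked cells (without replacement when possible)."""
    rows, cols, matrix = stack.cell_table()
    m = len(rows)
    rng = np.random.default_rng(seed)
    if m >= n:
        idx = rng.choice(m, size=n, replace=False)
    else:
        idx = np.arange(m)
    df = pd.DataFrame(matrix[idx], columns=stack.names)
    lon, lat = stack.grid.cell_center(rows[idx], cols[idx])
    df.insert(0, "lat", lat)
    df.insert(0, "lon", lon)
    return df


def aicc(model: PPMModel, pres_values: pd.DataFrame,
         grid_values: pd.DataFrame) -> float:
    """Small-sample AIC with grid-standardized likelihood.

    Raw suitability is re-standardized to sum to one over all supplied grid
    cells; logL is the presence log-likelihood under that surface; K counts
    nonzero coefficients. Returns NaN (candidate invalid) when n - K - 1 <= 0.
    """
    n = len(pres_values)
    k = model.n_nonzero
    if n - k - 1 <= 0:
        return float("nan")
    eta_grid = model.eta(grid_values)
    eta_pres = model.eta(pres_values)
    log_z_grid = logsumexp(eta_grid)
    log_l = float((eta_pres - log_z_grid).sum())
    return float(2 * k - 2 * log_l + 2 * k * (k + 1) / (n - k - 1))


def checkerboard_partition(lon: np.ndarray, lat: np.ndarray, grid: GeoGrid,
                           agg1: int = 2, agg2: int = 2) -> np.ndarray:
    """Four spatial folds from two nested checkerboard colorings.

    A fine checkerboard over blocks of ``agg1`` cells and a coarse one over
    blocks of ``agg1 * agg2`` cells combine into labels 1-4 per point.
    """
    if agg1 < 1 or agg2 < 1:
        raise ValueError("aggregation factors must be >= 1")
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)

    def coloring(block_cells: int) -> np.ndarray:
        size = grid.cell_size * block_cells
        bx = np.floor((lon - grid.origin_lon) / size).astype(int)
        by = np.floor((grid.origin_lat - lat) / size).astype(int)
        return (bx + by) % 2

    c1 = coloring(agg1)
    c2 = coloring(agg1 * agg2)
    folds = 1 + c1 + 2 * c2
    present = np.unique(folds)
    if len(present) < 4:
        warnings.warn(f"only folds {present.tolist()} are nonempty")
    return folds


@dataclass
class TuneResult:
    table: pd.DataFrame
    best: PPMModel
    best_index: int


def tune(pres_values: pd.DataFrame, bg_values: pd.DataFrame,
         grid_values: pd.DataFrame, pres_folds: np.ndarray,
         rm_grid: Sequence[float] = (1, 1.5, 2, 2.5, 3, 3.5, 4, 4.5, 5),
         class_grid: Sequence[tuple[str, ...]] = (("linear",), ("linear", "quadratic")),
         tol: float = 1e-5, max_iter: int = 5000) -> TuneResult:
    """Fit every (rm, feature-class) candidate and select by AICc.

    Each candidate is fitted on the full presence set for AICc and
    re-fitted per cross-validation fold (train on the other folds, all
    background) for test AUC and omission rates. Ties on AICc break toward
    fewer nonzero coefficients, then smaller rm.
    """
    if len(list(rm_grid)) == 0 or len(list(class_grid)) == 0:
        raise ValueError("rm_grid and class_grid must be nonempty")
    calib = pd.concat([pres_values, bg_values], ignore_index=True)
    rows = []
    models: list[PPMModel] = []
    fold_ids = np.unique(pres_folds)
    for classes in class_grid:
        spec = FeatureSpec.from_calibration(calib, classes=classes)
        pres_f, _ = build_features(pres_values, spec)
        bg_f, _ = build_features(bg_values, spec)
        for rm in rm_grid:
            model = fit(pres_f, bg_f, spec, rm=rm, tol=tol, max_iter=max_iter)
            a = aicc(model, pres_values, grid_values)
            eta_grid = model.eta(grid_values)
            log_l = float((model.eta(pres_values) - logsumexp(eta_grid)).sum())

            aucs_tr, aucs_te, or_mtp, or_10tp = [], [], [], []
            for f in fold_ids:
                train = pres_folds != f
                test = ~train
                if test.sum() == 0 or train.sum() < 2:
                    continue
                cv = fit(pres_f[train], bg_f, spec, rm=rm, tol=tol, max_iter=max_iter)
                s_train = cv.predict(pres_values.iloc[train], output="cloglog")
                s_test = cv.predict(pres_values.iloc[test], output="cloglog")
                s_bg = cv.predict(bg_values, output="cloglog")
                aucs_tr.append(evaluation.auc(s_train, s_bg))
                aucs_te.append(evaluation.auc(s_test, s_bg))
                or_mtp.append(evaluation.omission_rate(
                    s_test, evaluation.threshold(s_train, "mtp")))
                or_10tp.append(evaluation.omission_rate(
                    s_test, evaluation.threshold(s_train, "10tp")))
            auc_train = float(np.mean(aucs_tr)) if aucs_tr else float("nan")
            auc_test = float(np.mean(aucs_te)) if aucs_te else float("nan")
            rows.append({
                "rm": float(rm),
                "classes": "".join(c[0].upper() for c in classes),
                "K": model.n_nonzero,
                "logL": log_l,
                "aicc": a,
                "auc_train": auc_train,
                "auc_test": auc_test,
                "auc_diff": auc_train - auc_test,
                "or_mtp": float(np.mean(or_mtp)) if or_mtp else float("nan"),
                "or_10tp": float(np.mean(or_10tp)) if or_10tp else float("nan"),
            })
            models.append(model)
    table = pd.DataFrame(rows)
    valid = table["aicc"].notna()
    if not valid.any():
        raise ValueError("all candidates invalid (n - K - 1 <= 0 everywhere)")
    order = table[valid].sort_values(["aicc", "K", "rm"], kind="stable")
    best_index = int(order.index[0])
    table["delta_aicc"] = table["aicc"] - table.loc[best_index, "aicc"]
    return TuneResult(table=table, best=models[best_index], best_index=best_index)


# ---------------------------------------------------------------------------
# variable importance
# ---------------------------------------------------------------------------

def permutation_importance(model: PPMModel, pres_values: pd.DataFrame,
                           bg_values: pd.DataFrame, n_repeats: int = 5,
                           seed: int | None = None) -> pd.Series:
    """Drop in training AUC after permuting one predictor, normalized to 100%."""
    rng = np.random.default_rng(seed)
    s_pres = model.predict(pres_values, output="cloglog")
    s_bg = model.predict(bg_values, output="cloglog")
    base = evaluation.auc(s_pres, s_bg)
    n_pres = len(pres_values)
    combined = pd.concat([pres_values, bg_values], ignore_index=True)
    drops = {}
    for p in model.spec.predictors:
        deltas = []
        for _ in range(n_repeats):
            shuffled = combined.copy()
            shuffled[p] = rng.permutation(shuffled[p].to_numpy())
            sp = model.predict(shuffled.iloc[:n_pres], output="cloglog")
            sb = model.predict(shuffled.iloc[n_pres:], output="cloglog")
            deltas.append(base - evaluation.auc(sp, sb))
        drops[p] = max(float(np.mean(deltas)), 0.0)
    total = sum(drops.values())
    if total == 0:
        return pd.Series({p: 0.0 for p in drops})
    return pd.Series({p: 100.0 * v / total for p, v in drops.items()})


def jackknife_gain(pres_values: pd.DataFrame, bg_values: pd.DataFrame,
                   classes: tuple[str, ...] = ("linear", "quadratic"),
                   rm: float = 1.0, tol: float = 1e-5,
                   max_iter: int = 5000) -> pd.DataFrame:
    """Leave-one-predictor-out and only-one-predictor regularized training gain.

    Training gain is the decrease in penalized IPP log-loss relative to the
    null (all-zero) model; it starts at 0 and grows as the model concentrates
    intensity near presences.
    """
    def gain(cols: list[str]) -> float:
        calib = pd.concat([pres_values[cols], bg_values[cols]], ignore_index=True)
        spec = FeatureSpec.from_calibration(calib, classes=classes)
        pres_f, _ = build_features(pres_values[cols], spec)
        bg_f, _ = build_features(bg_values[cols], spec)
        model = fit(pres_f, bg_f, spec, rm=rm, tol=tol, max_iter=max_iter)
        lam = penalty_vector(spec, pres_f, rm)
        null_obj = _ipp_objective(np.zeros(pres_f.shape[1]), pres_f, bg_f, lam)
        return null_obj - model.objective

    predictors = list(pres_values.columns)
    rows = []
    full = gain(predictors)
    for p in predictors:
        others = [q for q in predictors if q != p]
        rows.append({"predictor": p,
                     "gain_without": gain(others) if others else 0.0,
                     "gain_only": gain([p]),
                     "gain_full": full})
    return pd.DataFrame(rows)
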