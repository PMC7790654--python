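"""Validation metrics for presence-only suitability predictions.

AUC (rank/Mann-Whitney form), threshold rules and omission rates, the
bootstrap partial-ROC ratio (which privileges omission over commission
error by restricting the ROC-like curve to the high-sensitivity region) and
the Continuous Boyce Index (Spearman correlation between the
predicted-to-expected presence ratio and suitability across moving windows
— a calibration measure independent of any threshold).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats


def auc(pos_scores, neg_scores) -> float:
    """P(pos > neg) + 0.5 * P(tie) via midranks (exact Mann-Whitney AUC)."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score sets must be nonempty")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def threshold(train_scores, rule: str = "10tp") -> float:
    """Binarization threshold from training presence scores.

    ``mtp`` is the minimum training presence score; ``10tp`` the empirical
    10th percentile (linear interpolation between order statistics).
    """
    s = np.asarray(train_scores, dtype=float)
    if s.size == 0:
        raise ValueError("scores must be nonempty")
    rule = rule.lower()
    if rule == "mtp":
        return float(s.min())
    if rule in ("10tp", "ttp10"):
        return float(np.quantile(s, 0.10, method="linear"))
    raise ValueError(f"unknown threshold rule {rule!r}")


def omission_rate(test_scores, thr: float) -> float:
    """Fraction of test scores strictly below the threshold."""
    s = np.asarray(test_scores, dtype=float)
    if s.size == 0:
        raise ValueError("scores must be nonempty")
    return float((s < thr).mean())


@dataclass
class PartialRocResult:
    mean_ratio: float
    sd: float
    range: tuple[float, float]
    p_value: float          # fraction of bootstrap ratios <= 1
    ratios: np.ndarray


def partial_roc(cell_scores, test_scores, e_rate: float = 0.05,
                n_boot: int = 1000, boot_prop: float = 0.5,
                seed: int | None = None) -> PartialRocResult:
    """Bootstrap partial-ROC ratio against the 1:1 null line.

    The curve plots, over thresholds t, the proportion of all cells scoring
    >= t (x) against the sensitivity of the test points (y), restricted to
    the region y >= 1 - E. The ratio is the trapezoidal area under the model
    curve divided by the area under the null line y = x on the same
    x-interval: 1 for a random model, approaching 2 for a perfect one.
    """
    cells = np.asarray(cell_scores, dtype=float)
    test = np.asarray(test_scores, dtype=float)
    if test.size == 0:
        raise ValueError("test scores must be nonempty")
    if not 0 < e_rate <= 1:
        raise ValueError("E must be in (0, 1]")
    if np.unique(cells).size < 2:
        raise ValueError("need at least 2 distinct cell scores")

    thresholds = np.unique(cells)
    if thresholds.size > 1000:        # cap the grid; quantile-spaced
        thresholds = np.quantile(cells, np.linspace(0, 1, 1001), method="lower")
        thresholds = np.unique(thresholds)
    # x: proportion of cells >= t (decreasing in t)
    x = 1.0 - np.searchsorted(np.sort(cells), thresholds, side="left") / cells.size

    rng = np.random.default_rng(seed)
    n_take = math.ceil(boot_prop * test.size)
    ratios = np.empty(n_boot)
    for b in range(n_boot):
        sample = rng.choice(test, size=n_take, replace=True)
        sens = 1.0 - np.searchsorted(np.sort(sample), thresholds, side="left") / n_take
        ratios[b] = _partial_area_ratio(x, sens, e_rate)
    finite = ratios[np.isfinite(ratios)]
    if finite.size == 0:
        raise ValueError("no bootstrap replicate produced a defined ratio")
    return PartialRocResult(
        mean_ratio=float(finite.mean()),
        sd=float(finite.std(ddof=1)) if finite.size > 1 else 0.0,
        range=(float(finite.min()), float(finite.max())),
        p_value=float((finite <= 1.0).mean()),
        ratios=ratios,
    )


def _partial_area_ratio(x: np.ndarray, sens: np.ndarray, e_rate: float) -> float:
    """Trapezoidal model/null partial-area ratio on the y >= 1-E region."""
    qual = sens >= 1.0 - e_rate
    if qual.sum() < 2:
        return np.nan
    xs = x[qual]
    ys = sens[qual]
    order = np.argsort(xs)
    xs, ys = xs[order], ys[order]
    if xs[-1] - xs[0] <= 0:
        return np.nan
    area_model = float(np.trapezoid(ys, xs))
    area_null = float((xs[-1] ** 2 - xs[0] ** 2) / 2.0)
    if area_null <= 0:
        return np.nan
    return area_model / area_null


@dataclass
class BoyceResult:
    cbi: float | None
    window_centers: np.ndarray
    pe_ratio: np.ndarray     # predicted/expected per usable window


def continuous_boyce(presence_scores, background_scores, n_windows: int = 101,
                     window_frac: float = 0.1) -> BoyceResult:
    """Continuous Boyce Index over a moving suitability window.

    Windows of width ``window_frac`` x the background score range slide so
    the ``n_windows`` windows together span [min, max] of the background
    scores. Per window, F = (share of presences inside) / (share of
    background inside); windows with no background mass are dropped. CBI is
    the Spearman correlation between F and the window center; it needs at
    least 3 usable windows, otherwise ``cbi`` is None (undefined).
    """
    pres = np.asarray(presence_scores, dtype=float)
    bg = np.asarray(background_scores, dtype=float)
    if pres.size == 0 or bg.size == 0:
        raise ValueError("both score sets must be nonempty")
    lo, hi = float(bg.min()), float(bg.max())
    if hi <= lo:
        return BoyceResult(cbi=None, window_centers=np.array([]), pe_ratio=np.array([]))
    w = window_frac * (hi - lo)
    centers = np.linspace(lo + w / 2.0, hi - w / 2.0, n_windows)
    p_share = np.empty(n_windows)
    e_share = np.empty(n_windows)
    for i, c in enumerate(centers):
        a, b = c - w / 2.0, c + w / 2.0
        p_share[i] = ((pres >= a) & (pres <= b)).mean()
        e_share[i] = ((bg >= a) & (bg <= b)).mean()
    usable = e_share > 0
    if usable.sum() < 3:
        return BoyceResult(cbi=None, window_centers=centers[usable],
                           pe_ratio=np.array([]))
    f = p_share[usable] / e_share[usable]
    rho = stats.spearmanr(f, centers[usable]).statistic
    return BoyceResult(cbi=float(rho), window_centers=centers[usable], pe_ratio=f)


def cbi_cross_validated(presence_scores, background_scores, n_folds: int = 5,
                        seed: int | None = None, n_windows: int = 101,
                        window_frac: float = 0.1) -> tuple[float, list[float]]:
    """Mean CBI over seeded random folds, each scored on its held-out share.

    With the default 5 folds each test split holds 20% of the presences.
    """
    pres = np.asarray(presence_scores, dtype=float)
    rng = np.random.default_rng(seed)
    folds = rng.permutation(len(pres)) % n_folds
    per_fold = []
    for f in range(n_folds):
        test = pres[folds == f]
        if test.size == 0:
            continue
        res = continuous_boyce(test, background_scores,
                               n_windows=n_windows, window_frac=window_frac)
        if res.cbi is not None:
            per_fold.append(res.cbi)
    mean = float(np.mean(per_fold)) if per_fold else float("nan")
    return mean, per_fold


@dataclass
class EvaluationReport:
    """The full validation bundle for one fitted model."""

    auc_train: float
    auc_test: float
    auc_diff: float
    or_mtp: float
    or_10tp: float
    proc_mean: float
    proc_sd: float
    proc_range: tuple[float, float]
    proc_p: float
    cbi_mean: float
    cbi_folds: list[float]

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["proc_range"] = list(self.proc_range)
        return d
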