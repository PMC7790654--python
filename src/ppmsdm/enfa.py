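"""Ecological Niche Factor Analysis: marginality and specialization.

ENFA contrasts the environment occupied by a species with the environment
available to it. After standardizing every predictor to zero mean / unit
variance over the background, the *marginality* vector m is the (occurrence-
weighted) mean of the occupied cells — how far the niche centroid sits from
the average available environment, in background standard deviations — and
M = ||m|| summarizes it. *Specialization* compares the variance available
(R_g, background covariance) with the variance occupied (R_s, weighted
covariance of the occupied cells): the first factor is the marginality axis
itself, and each subsequent factor maximizes the generalized Rayleigh
quotient (u' R_g u)/(u' R_s u) subject to R_s-orthogonality to the earlier
factors. Eigenvalues lambda_k > 1 mean the species occupies less variance
than is available along that axis; S = sqrt(mean lambda) summarizes niche
narrowness.

Cells are weighted by their occurrence counts, so duplicating every record
k times changes nothing, and all (unthinned) occurrences can — and should —
be used: ENFA measures conditions at presences directly, so spatial
autocorrelation is not the concern it is for the fitted model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .grid import RasterStack
from .occurrences import OccurrenceSet


@dataclass
class EnfaResult:
    predictors: list[str]
    marginality_vector: np.ndarray    # per predictor, background-SD units
    marginality: float                # M = ||m|| (modern unscaled convention)
    eigenvalues: np.ndarray           # lambda per axis, marginality axis first
    specialization: float             # S = sqrt(mean lambda)
    loadings: np.ndarray              # predictors x axes, unit-norm columns
    variance_share: np.ndarray        # % of total eigenvalue mass per axis

    def loadings_table(self) -> pd.DataFrame:
        """Loadings ordered by descending |marginality coefficient|."""
        axes = ["Marg"] + [f"Spec{i}" for i in range(1, len(self.predictors))]
        df = pd.DataFrame(self.loadings, index=self.predictors, columns=axes)
        order = np.argsort(-np.abs(self.marginality_vector), kind="stable")
        return df.iloc[order]

    def to_dict(self) -> dict:
        return {
            "predictors": self.predictors,
            "marginality_vector": self.marginality_vector.tolist(),
            "M": self.marginality,
            "eigenvalues": self.eigenvalues.tolist(),
            "S": self.specialization,
            "variance_share": self.variance_share.tolist(),
        }


def _weighted_cov(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    mu = w @ x / w.sum()
    xc = x - mu
    return (xc * w[:, None]).T @ xc / w.sum()


def enfa_fit(stack: RasterStack, occ: OccurrenceSet, n_background: int = 100000,
             seed: int | None = None, m_scaling: str = "unscaled",
             s_statistic: str = "mean") -> EnfaResult:
    """Fit ENFA from a predictor stack and (unthinned) occurrences.

    ``n_background`` random unmasked cells represent the available
    environment (all cells, logged via the returned sizes, when the grid is
    smaller). ``m_scaling='classical'`` divides M by 1.96; ``s_statistic``
    is ``'mean'`` (S = sqrt(mean lambda)) or ``'sum'``.
    """
    if len(stack) < 2:
        raise ValueError("ENFA needs at least 2 predictors")
    rows, cols, matrix = stack.cell_table()
    m_cells = len(rows)
    rng = np.random.default_rng(seed)
    if m_cells > n_background:
        idx = rng.choice(m_cells, size=n_background, replace=False)
    else:
        idx = np.arange(m_cells)
    bg = matrix[idx]

    mu = bg.mean(axis=0)
    sd = bg.std(axis=0)
    if (sd == 0).any():
        bad = [stack.names[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant predictor(s) over background: {bad}")
    z_bg = (bg - mu) / sd

    # occurrence cells, weighted by number of records per cell
    g = stack.grid
    prow, pcol = g.cell_index(occ.lon, occ.lat)
    on_grid = prow >= 0
    mask = stack.shared_mask()
    usable = on_grid.copy()
    usable[on_grid] = mask[prow[on_grid], pcol[on_grid]]
    if not usable.any():
        raise ValueError("no occurrence falls on a usable cell")
    cells = prow[usable] * g.n_cols + pcol[usable]
    uniq, counts = np.unique(cells, return_counts=True)
    urow, ucol = uniq // g.n_cols, uniq % g.n_cols
    z_occ = (stack.to_matrix(urow, ucol) - mu) / sd
    w = counts.astype(float)

    m = w @ z_occ / w.sum()
    big_m = float(np.linalg.norm(m))
    if m_scaling == "classical":
        big_m /= 1.96
    elif m_scaling != "unscaled":
        raise ValueError("m_scaling must be 'unscaled' or 'classical'")

    r_g = _weighted_cov(z_bg, np.ones(len(z_bg)))
    r_s = _weighted_cov(z_occ, w)
    cond = np.linalg.cond(r_s)
    if cond > 1e10:
        raise ValueError(f"singular occupied-niche covariance (condition number {cond:.3g})")

    p = len(stack)
    u1 = m / np.linalg.norm(m) if np.linalg.norm(m) > 0 else np.eye(p)[:, 0]
    lam1 = float(u1 @ r_g @ u1) / float(u1 @ r_s @ u1)

    # subsequent factors: maximize u'R_g u / u'R_s u, R_s-orthogonal to u1
    basis = linalg.null_space((r_s @ u1)[None, :])   # p x (p-1)
    a = basis.T @ r_g @ basis
    b = basis.T @ r_s @ basis
    eigvals, eigvecs = linalg.eigh(a, b)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    spec_axes = basis @ eigvecs[:, order]

    eigenvalues = np.concatenate([[lam1], eigvals])
    loadings = np.column_stack([u1, spec_axes])
    loadings = loadings / np.linalg.norm(loadings, axis=0, keepdims=True)

    if s_statistic == "mean":
        s = float(np.sqrt(eigenvalues.mean()))
    elif s_statistic == "sum":
        s = float(np.sqrt(eigenvalues.sum()))
    else:
        raise ValueError("s_statistic must be 'mean' or 'sum'")

    total = eigenvalues.sum()
    variance_share = 100.0 * eigenvalues / total if total > 0 else np.zeros(p)

    return EnfaResult(predictors=stack.names, marginality_vector=m,
                      marginality=big_m, eigenvalues=eigenvalues,
                      specialization=s, loadings=loadings,
                      variance_share=variance_share)


def enfa_fit_matrix(bg: np.ndarray, occ_values: np.ndarray,
                    weights: np.ndarray | None = None,
                    names: list[str] | None = None) -> EnfaResult:
    """ENFA from raw matrices (background x P, occupied x P) — no rasters.

    Convenience surface for simulation studies and tests; same algebra as
    :func:`enfa_fit`.
    """
    bg = np.asarray(bg, dtype=float)
    occ_values = np.asarray(occ_values, dtype=float)
    p = bg.shape[1]
    if weights is None:
        weights = np.ones(len(occ_values))
    names = names or [f"x{i + 1}" for i in range(p)]

    mu = bg.mean(axis=0)
    sd = bg.std(axis=0)
    z_bg = (bg - mu) / sd
    z_occ = (occ_values - mu) / sd
    w = np.asarray(weights, dtype=float)

    m = w @ z_occ / w.sum()
    r_g = _weighted_cov(z_bg, np.ones(len(z_bg)))
    r_s = _weighted_cov(z_occ, w)

    u1 = m / np.linalg.norm(m) if np.linalg.norm(m) > 0 else np.eye(p)[:, 0]
    lam1 = float(u1 @ r_g @ u1) / float(u1 @ r_s @ u1)
    basis = linalg.null_space((r_s @ u1)[None, :])
    eigvals, eigvecs = linalg.eigh(basis.T @ r_g @ basis, basis.T @ r_s @ basis)
    order = np.argsort(eigvals)[::-1]
    eigenvalues = np.concatenate([[lam1], eigvals[order]])
    spec_axes = basis @ eigvecs[:, order]
    loadings = np.column_stack([u1, spec_axes])
    loadings = loadings / np.linalg.norm(loadings, axis=0, keepdims=True)
    total = eigenvalues.sum()
    return EnfaResult(predictors=names, marginality_vector=m,
                      marginality=float(np.linalg.norm(m)),
                      eigenvalues=eigenvalues,
                      specialization=float(np.sqrt(eigenvalues.mean())),
                      loadings=loadings,
                      variance_share=100.0 * eigenvalues / total)


def biplot(result: EnfaResult, path=None):
    """Marginality x first-specialization-axis variable biplot (SVG/PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    marg = result.loadings[:, 0]
    spec1 = result.loadings[:, 1] if result.loadings.shape[1] > 1 else np.zeros_like(marg)
    for name, x, y in zip(result.predictors, marg, spec1):
        ax.annotate("", xy=(x, y), xytext=(0, 0),
                    arrowprops=dict(arrowstyle="->", color="tab:blue"))
        ax.annotate(name, xy=(x, y), fontsize=9)
    ax.axhline(0, color="0.8", lw=0.8)
    ax.axvline(0, color="0.8", lw=0.8)
    ax.set_xlabel("Marginality axis")
    ax.set_ylabel("Specialization axis 1")
    ax.set_title(f"ENFA (M = {result.marginality:.2f}, S = {result.specialization:.2f})")
    lim = 1.1 * max(1e-6, np.abs(np.column_stack([marg, spec1])).max())
    ax.set_xlim(-lim, lim)
    ax.set_ylim(-lim, lim)
    if path is not None:
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
    return fig
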