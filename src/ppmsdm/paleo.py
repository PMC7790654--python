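"""Projection to other time periods, ensembling, niche overlap, stability.

A fitted model carries its own feature bounds and normalizers, so projecting
onto a different period's predictor stack is just prediction with clamped
features (the clamp fraction is logged — heavy clamping flags extrapolation).
Several circulation models' projections are ensembled cell-wise; overlap
between any two suitability surfaces is Schoener's D on the normalized
surfaces; and the current binary range stacked with the past binary ranges
yields a stability map whose classes follow the standard refugium logic:
suitable in every period = stable refugium.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .geography import BinaryRangeMap
from .grid import GeoGrid, RasterStack
from .ppm import PPMModel, build_features

logger = logging.getLogger(__name__)

STABILITY_CODES = {
    "absence": -2.0,      # never suitable
    "colonizable": -0.5,  # currently suitable, not in every past period
    "stable": 1.0,        # suitable in every period
    "unstable": 2.0,      # suitable in some past period, not now
}


def project(model: PPMModel, stack: RasterStack, output: str = "cloglog") -> GeoGrid:
    """Model suitability over another period's stack (features clamped)."""
    missing = [p for p in model.spec.predictors if p not in stack.names]
    if missing:
        raise ValueError(f"projection stack is missing predictor layer(s): {missing}")
    rows, cols, matrix = stack.cell_table()
    import pandas as pd
    values = pd.DataFrame(matrix, columns=stack.names)[model.spec.predictors]
    feats, n_clamped = build_features(values, model.spec, clamp=True)
    if n_clamped:
        frac = n_clamped / feats.size
        logger.info("projection clamped %.2f%% of feature values", 100 * frac)
    eta = feats @ model.coefficients
    raw = np.exp(eta - model.log_z)
    scores = raw if output == "raw" else 1.0 - np.exp(-np.exp(model.entropy_h) * raw)
    out = np.full(stack.grid.values.shape, np.nan)
    out[rows, cols] = scores
    return stack.grid.with_values(out)


def ensemble(grids: list[GeoGrid], method: str = "mean") -> GeoGrid:
    """Cell-wise mean (default) or sum; nodata propagates from any member."""
    if not grids:
        raise ValueError("need at least one grid")
    ref = grids[0]
    for g in grids[1:]:
        if not g.same_geometry(ref):
            raise ValueError("ensemble members must share the grid geometry")
    stacked = np.stack([g.values for g in grids])
    if method == "mean":
        out = stacked.mean(axis=0)
    elif method == "sum":
        out = stacked.sum(axis=0)
    else:
        raise ValueError(f"unknown ensemble method {method!r}")
    return ref.with_values(out)


def schoeners_d(g1: GeoGrid, g2: GeoGrid) -> float | None:
    """Schoener's D = 1 - 0.5 * sum |p - q| over shared unmasked cells.

    Each surface is normalized to sum to one over the shared cells; 0 means
    no overlap, 1 identical surfaces. Returns None (undefined) when either
    surface is all zero.
    """
    if not g1.same_geometry(g2):
        raise ValueError("grids must share the geometry")
    shared = g1.mask & g2.mask
    if not shared.any():
        raise ValueError("no shared unmasked cells")
    p = g1.values[shared]
    q = g2.values[shared]
    sp, sq = p.sum(), q.sum()
    if sp <= 0 or sq <= 0:
        return None
    return float(1.0 - 0.5 * np.abs(p / sp - q / sq).sum())


@dataclass
class StabilityMap:
    """Coded class raster plus the class code book and raw (c, f) layers."""

    grid: GeoGrid                  # coded classes
    code_book: dict[str, float]
    current: GeoGrid               # c: current binary
    past_fraction: GeoGrid         # f: fraction of past periods suitable
    period_ids: list[str]

    def class_mask(self, label: str) -> np.ndarray:
        return self.grid.mask & (self.grid.values == self.code_book[label])


def stability(current: BinaryRangeMap, past: list[BinaryRangeMap],
              period_ids: list[str] | None = None) -> StabilityMap:
    """Stack current + past binary maps into a stability classification.

    With c the current binary value and f the fraction of past periods
    suitable: stable iff c = 1 and f = 1; colonizable iff c = 1 and f < 1;
    unstable iff c = 0 and f > 0; absence iff c = 0 and f = 0. The numeric
    codes (absence -2, colonizable -0.5, stable 1, unstable 2) follow the
    convention that the -2..1 range runs from never-suitable to
    always-suitable, with 2 flagging past-only suitability.
    """
    if not past:
        raise ValueError("need at least one past-period map")
    ref = current.grid
    for p in past:
        if not p.grid.same_geometry(ref):
            raise ValueError("stability maps must share the grid geometry")
    c = current.grid.values
    f = np.mean(np.stack([p.grid.values for p in past]), axis=0)
    mask = np.isfinite(c) & np.isfinite(f)

    out = np.full(c.shape, np.nan)
    cur = c > 0.5
    out[mask & cur & (f >= 1.0)] = STABILITY_CODES["stable"]
    out[mask & cur & (f < 1.0)] = STABILITY_CODES["colonizable"]
    out[mask & ~cur & (f > 0.0)] = STABILITY_CODES["unstable"]
    out[mask & ~cur & (f <= 0.0)] = STABILITY_CODES["absence"]

    return StabilityMap(grid=ref.with_values(out), code_book=dict(STABILITY_CODES),
                        current=ref.with_values(np.where(mask, c, np.nan)),
                        past_fraction=ref.with_values(np.where(mask, f, np.nan)),
                        period_ids=period_ids or [f"past{i + 1}" for i in range(len(past))])


def overlap_matrix(grids: dict[str, GeoGrid]):
    """Pairwise Schoener's D between named suitability surfaces."""
    import pandas as pd
    names = list(grids)
    out = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            d = schoeners_d(grids[a], grids[b])
            out.loc[a, b] = out.loc[b, a] = np.nan if d is None else d
    return out
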