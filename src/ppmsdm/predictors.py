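"""Value extraction at points and the two-stage collinearity screen.

Highly collinear predictors inflate the apparent biological relevance of
redundant variables, so before model fitting the candidate set is reduced
in two stages: (1) stepwise elimination by variance inflation factor,
dropping the worst column while any VIF exceeds the threshold, then
(2) pairwise Spearman screening, dropping from the most-correlated pair the
member that is on average more redundant with everything else. Both stages
leave a full audit trail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import RasterStack
from .occurrences import OccurrenceSet


@dataclass
class ExtractionResult:
    matrix: pd.DataFrame        # rows = points, columns = predictors
    n_dropped_nodata: int
    kept_index: np.ndarray      # positions of retained points in the input


def extract(stack: RasterStack, occ: OccurrenceSet) -> ExtractionResult:
    """Values of every layer at the cell containing each point.

    Points falling on nodata (in any layer) or off the grid are dropped and
    counted. Raises if no point lands on a usable cell.
    """
    g = stack.grid
    row, col = g.cell_index(occ.lon, occ.lat)
    inside = row >= 0
    mask = stack.shared_mask()
    usable = inside.copy()
    usable[inside] = mask[row[inside], col[inside]]
    if not usable.any():
        raise ValueError("no occurrence point falls on a usable grid cell")
    values = stack.to_matrix(row[usable], col[usable])
    matrix = pd.DataFrame(values, columns=stack.names)
    return ExtractionResult(matrix=matrix,
                            n_dropped_nodata=int((~usable).sum()),
                            kept_index=np.flatnonzero(usable))


def vif(matrix: pd.DataFrame, column: str) -> float:
    """Variance inflation factor 1/(1 - R^2) of one column on the others.

    R^2 comes from ordinary least squares of the column on all remaining
    columns plus an intercept. Perfect collinearity returns ``inf``.
    """
    if matrix.shape[1] < 2:
        raise ValueError("VIF needs at least two columns")
    if matrix.shape[0] <= matrix.shape[1]:
        raise ValueError("VIF needs more rows than columns")
    y = matrix[column].to_numpy(dtype=float)
    x = matrix.drop(columns=[column]).to_numpy(dtype=float)
    design = np.column_stack([np.ones(len(x)), x])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    sst = np.sum((y - y.mean()) ** 2)
    if sst == 0:
        return np.inf
    r2 = 1.0 - resid @ resid / sst
    if r2 >= 1.0 - 1e-12:
        return np.inf
    return float(1.0 / (1.0 - r2))


def spearman_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman rank correlations (average ranks on ties)."""
    return matrix.corr(method="spearman")


@dataclass
class SelectionAudit:
    """Every drop made by :func:`select_uncorrelated`, in order."""

    steps: list[dict] = field(default_factory=list)

    def record(self, stage: str, dropped: str, statistic: float, detail: str = "") -> None:
        self.steps.append({"stage": stage, "dropped": dropped,
                           "statistic": float(statistic), "detail": detail})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["stage", "dropped", "statistic", "detail"])


def select_uncorrelated(matrix: pd.DataFrame, vif_max: float = 10.0,
                        rho_max: float = 0.7) -> tuple[list[str], SelectionAudit]:
    """Two-stage collinearity screen; returns retained names + audit trail.

    Stage 1 repeatedly drops the column with the largest VIF while that VIF
    is >= ``vif_max`` (a column at exactly the threshold is dropped). Stage 2
    then, while any pair has \\|Spearman rho\\| > ``rho_max``, drops from the
    worst pair the member with the larger mean absolute correlation to all
    remaining columns. Ties keep the earlier column. Deterministic given
    column order.
    """
    audit = SelectionAudit()
    cols = list(matrix.columns)

    # stage 1: stepwise VIF
    while len(cols) >= 2:
        sub = matrix[cols]
        vifs = np.array([vif(sub, c) for c in cols])
        worst = int(np.flatnonzero(vifs == vifs.max())[-1])  # tie keeps the earlier col
        if not vifs[worst] >= vif_max:
            break
        audit.record("vif", cols[worst], vifs[worst],
                     f"max VIF among {len(cols)} columns")
        cols.pop(worst)

    # stage 2: pairwise Spearman
    while len(cols) >= 2:
        rho = spearman_matrix(matrix[cols]).to_numpy()
        np.fill_diagonal(rho, 0.0)
        abs_rho = np.abs(rho)
        i, j = np.unravel_index(np.argmax(abs_rho), abs_rho.shape)
        if not abs_rho[i, j] > rho_max:
            break
        if i > j:
            i, j = j, i
        mean_i = abs_rho[i].sum() / (len(cols) - 1)
        mean_j = abs_rho[j].sum() / (len(cols) - 1)
        drop = j if mean_j >= mean_i else i   # tie keeps the earlier column
        audit.record("spearman", cols[drop], rho[i, j],
                     f"|rho|={abs_rho[i, j]:.4f} pair=({cols[i]},{cols[j]}) "
                     f"mean|rho| dropped={max(mean_i, mean_j):.4f}")
        cols.pop(drop)

    return cols, audit
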