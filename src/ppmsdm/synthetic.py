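"""Synthetic raster stacks and occurrences with known ground truth.

Every downstream stage of the pipeline — thinning, collinearity screening,
point-process fitting, validation, range geometry, ordination — is exercised
on data generated here, where the true log-linear intensity surface and its
coefficients are known exactly and therefore recoverable.

The generator builds spatially autocorrelated, cross-correlated standardized
predictor fields (Gaussian-smoothed white noise mixed through a Cholesky
factor), derives a normalized intensity from linear + quadratic features of
those fields, and samples presence points cell-multinomially with uniform
within-cell jitter, so points live in continuous space rather than on cell
centers. Layers are abstract standardized predictors; no attempt is made to
mimic the units or semantics of real bioclimatic variables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import GeoGrid, RasterStack
from .occurrences import OccurrenceSet


@dataclass
class SyntheticScenario:
    """Full description of one synthetic study condition.

    Defaults describe the bundled desk-scale scenario: a 100 x 100 grid of
    2.5 arc-minute cells in the tropics, three moderately autocorrelated
    predictors, a smooth unimodal intensity surface and 500 expected
    presences (the order of magnitude of a thinned continental raptor
    occurrence set).
    """

    n_rows: int = 100
    n_cols: int = 100
    cell_size: float = 2.5 / 60.0          # degrees (2.5 arc-minutes)
    origin_lon: float = -70.0
    origin_lat: float = 2.0
    n_layers: int = 3
    autocorr_length: float = 5.0           # Gaussian-blur sigma, in cells
    cross_corr: np.ndarray | None = None   # defaults to identity
    beta_linear: Sequence[float] = (1.0, 0.6, 0.0)
    beta_quadratic: Sequence[float] = (-0.8, 0.0, 0.0)
    n_presences: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if self.n_presences < 1:
            raise ValueError("n_presences must be >= 1")
        if self.cross_corr is None:
            self.cross_corr = np.eye(self.n_layers)
        self.cross_corr = np.asarray(self.cross_corr, dtype=float)
        self.beta_linear = np.asarray(self.beta_linear, dtype=float)
        self.beta_quadratic = np.asarray(self.beta_quadratic, dtype=float)
        if self.cross_corr.shape != (self.n_layers, self.n_layers):
            raise ValueError("cross_corr must be n_layers x n_layers")
        if len(self.beta_linear) != self.n_layers or len(self.beta_quadratic) != self.n_layers:
            raise ValueError("coefficient vectors must match n_layers")
        _validate_correlation(self.cross_corr)

    @property
    def layer_names(self) -> list[str]:
        return [f"env{k + 1}" for k in range(self.n_layers)]


def _validate_correlation(c: np.ndarray) -> None:
    if not np.allclose(c, c.T, atol=1e-10):
        raise ValueError("cross_corr must be symmetric")
    if not np.allclose(np.diag(c), 1.0, atol=1e-10):
        raise ValueError("cross_corr must have unit diagonal")
    eigvals = np.linalg.eigvalsh(c)
    if eigvals.min() < -1e-10:
        raise ValueError(
            f"cross_corr is not positive semi-definite: smallest eigenvalue "
            f"{eigvals.min():.6g} < 0"
        )


def _standardize(values: np.ndarray) -> np.ndarray:
    mu = values.mean()
    sd = values.std()
    if sd == 0:
        raise ValueError("degenerate constant field cannot be standardized")
    return (values - mu) / sd


def generate_predictor_stack(scenario: SyntheticScenario) -> RasterStack:
    """Correlated, autocorrelated, standardized predictor layers.

    White noise fields are mixed through the Cholesky factor of
    ``cross_corr`` (imposing the between-layer correlation), Gaussian-blurred
    with sigma ``autocorr_length`` cells (imposing spatial autocorrelation —
    the blur is layer-wise and so preserves cross-correlation), then each
    layer is re-standardized to zero mean / unit variance.
    """
    rng = np.random.default_rng(scenario.seed)
    shape = (scenario.n_layers, scenario.n_rows, scenario.n_cols)
    white = rng.standard_normal(shape)
    # PSD-safe Cholesky: add a whisper of jitter only if strictly singular
    c = scenario.cross_corr
    try:
        chol = np.linalg.cholesky(c)
    except np.linalg.LinAlgError:
        chol = np.linalg.cholesky(c + 1e-10 * np.eye(len(c)))
    mixed = np.tensordot(chol, white, axes=(1, 0))
    stack = RasterStack()
    for k, name in enumerate(scenario.layer_names):
        fld = mixed[k]
        if scenario.autocorr_length > 0:
            fld = ndimage.gaussian_filter(fld, sigma=scenario.autocorr_length,
                                          mode="reflect")
        stack.add(name, GeoGrid(_standardize(fld), scenario.origin_lon,
                                scenario.origin_lat, scenario.cell_size))
    return stack


def true_suitability(stack: RasterStack, beta_linear: Sequence[float],
                     beta_quadratic: Sequence[float]) -> tuple[GeoGrid, GeoGrid]:
    """The ground-truth intensity and its cloglog suitability transform.

    eta = sum_k bL_k z_k + bQ_k z_k^2 per cell; ``raw`` is exp(eta)
    normalized to sum to one over unmasked cells (a point-process intensity
    as a probability surface); ``cloglog = 1 - exp(-e^H * raw)`` with H the
    Shannon entropy of raw, the standard 0-1 suitability index.
    """
    bl = np.asarray(beta_linear, dtype=float)
    bq = np.asarray(beta_quadratic, dtype=float)
    if len(bl) != len(stack) or len(bq) != len(stack):
        raise ValueError("coefficient vectors must match the number of layers")
    mask = stack.shared_mask()
    if not mask.any():
        raise ValueError("all cells are masked; no suitability surface exists")
    eta = np.zeros(mask.shape, dtype=float)
    for k, name in enumerate(stack.names):
        z = stack[name].values
        eta = eta + bl[k] * np.where(mask, z, 0.0) + bq[k] * np.where(mask, z * z, 0.0)
    eta = np.where(mask, eta, np.nan)

    finite_eta = eta[mask]
    shifted = np.exp(finite_eta - finite_eta.max())
    raw_vals = shifted / shifted.sum()
    raw = np.full(mask.shape, np.nan)
    raw[mask] = raw_vals

    h = -np.sum(raw_vals * np.log(raw_vals))
    cloglog = np.full(mask.shape, np.nan)
    cloglog[mask] = 1.0 - np.exp(-np.exp(h) * raw_vals)

    g = stack.grid
    return g.with_values(raw), g.with_values(cloglog)


def sample_presences(raw: GeoGrid, n_presences: int, seed: int | None = None) -> OccurrenceSet:
    """Sample presence points proportional to a normalized intensity.

    Cell membership is multinomial with probabilities ``raw``; the position
    within a cell is uniform, so no two points coincide and none sits on a
    cell center.
    """
    if n_presences <= 0:
        raise ValueError("n_presences must be positive")
    mask = raw.mask
    probs = raw.values[mask]
    if probs.min() < -1e-12:
        raise ValueError("raw intensity must be nonnegative")
    probs = np.clip(probs, 0.0, None)
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    rows, cols = np.nonzero(mask)
    counts = rng.multinomial(n_presences, probs)
    idx = np.repeat(np.arange(len(probs)), counts)
    jitter_lon = rng.uniform(0.0, 1.0, size=n_presences)
    jitter_lat = rng.uniform(0.0, 1.0, size=n_presences)
    lon = raw.origin_lon + (cols[idx] + jitter_lon) * raw.cell_size
    lat = raw.origin_lat - (rows[idx] + jitter_lat) * raw.cell_size
    df = pd.DataFrame({"lon": lon, "lat": lat})
    return OccurrenceSet(df)


@dataclass
class SyntheticStudy:
    """One fully realized scenario: stack, truth surfaces, occurrences."""

    scenario: SyntheticScenario
    stack: RasterStack
    true_raw: GeoGrid
    true_cloglog: GeoGrid
    occurrences: OccurrenceSet


def realize(scenario: SyntheticScenario) -> SyntheticStudy:
    """Generate the complete synthetic study for a scenario (seed-stable)."""
    stack = generate_predictor_stack(scenario)
    raw, cloglog = true_suitability(stack, scenario.beta_linear, scenario.beta_quadratic)
    occ = sample_presences(raw, scenario.n_presences, seed=scenario.seed + 1)
    return SyntheticStudy(scenario, stack, raw, cloglog, occ)
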