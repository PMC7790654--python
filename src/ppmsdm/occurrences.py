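"""Occurrence records: cleaning and distance-based spatial thinning.

Presence-only records compiled from heterogeneous sources carry duplicates,
missing coordinates and strong survey bias. Cleaning removes records that
cannot enter a model at all; spatial thinning then enforces a minimum
great-circle distance between retained points (a biological spacing, e.g. a
mean inter-nest distance) to dampen spatially aggregated sampling effort.

Thinning is the classic greedy scheme: repeatedly delete the record with the
most neighbours inside the exclusion radius (uniform among ties), restart
over many seeded trials, and keep a maximum-cardinality feasible solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import EARTH_RADIUS_KM


@dataclass
class CleaningReport:
    """Counts of records removed per reason during :func:`clean`."""

    n_input: int = 0
    n_no_georeference: int = 0
    n_invalid_coordinate: int = 0
    n_duplicate: int = 0
    n_retained: int = 0

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class OccurrenceSet:
    """Cleaned point records in continuous space (WGS84 decimal degrees)."""

    data: pd.DataFrame  # columns: lon, lat [, source, id]
    crs: str = "EPSG:4326"
    report: CleaningReport | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not {"lon", "lat"}.issubset(self.data.columns):
            raise ValueError("OccurrenceSet requires 'lon' and 'lat' columns")
        self.data = self.data.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def lon(self) -> np.ndarray:
        return self.data["lon"].to_numpy(dtype=float)

    @property
    def lat(self) -> np.ndarray:
        return self.data["lat"].to_numpy(dtype=float)

    def coords(self) -> np.ndarray:
        return np.column_stack([self.lon, self.lat])

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.data.to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "OccurrenceSet":
        return clean(pd.read_csv(path))


def clean(records: pd.DataFrame) -> OccurrenceSet:
    """Drop non-georeferenced and invalid records, collapse exact duplicates.

    Duplicate (lon, lat) pairs keep the first record in file order. Raises
    ``ValueError`` when nothing survives — there is nothing to model.
    """
    report = CleaningReport(n_input=len(records))
    df = records.copy()
    if not {"lon", "lat"}.issubset(df.columns):
        raise ValueError("records must have 'lon' and 'lat' columns")
    df["lon"] = pd.to_numeric(df["lon"], errors="coerce")
    df["lat"] = pd.to_numeric(df["lat"], errors="coerce")

    georef = df["lon"].notna() & df["lat"].notna()
    report.n_no_georeference = int((~georef).sum())
    df = df[georef]

    valid = df["lon"].between(-180, 180) & df["lat"].between(-90, 90)
    report.n_invalid_coordinate = int((~valid).sum())
    df = df[valid]

    deduped = df.drop_duplicates(subset=["lon", "lat"], keep="first")
    report.n_duplicate = len(df) - len(deduped)
    report.n_retained = len(deduped)
    if report.n_retained == 0:
        raise ValueError("no usable occurrence records after cleaning")
    return OccurrenceSet(deduped.reset_index(drop=True), report=report)


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray | float:
    """Great-circle distance in km on a sphere of radius 6,371 km."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def pairwise_distances_km(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    """Dense n x n great-circle distance matrix in km."""
    return haversine_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])


def thin(occ: OccurrenceSet, min_dist_km: float = 4.0, n_trials: int = 100,
         seed: int | None = None) -> OccurrenceSet:
    """Enforce a minimum pairwise distance, keeping as many records as possible.

    Per trial: while any pair lies closer than ``min_dist_km``, remove the
    record with the greatest number of too-close neighbours (uniform among
    ties). The best (largest) feasible subset over ``n_trials`` seeded trials
    is returned; earliest trial wins ties, so results are reproducible.
    """
    if not min_dist_km > 0:
        raise ValueError("min_dist_km must be positive")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    n = len(occ)
    if n <= 1:
        return occ
    dist = pairwise_distances_km(occ.lon, occ.lat)
    adj = dist < min_dist_km
    np.fill_diagonal(adj, False)
    if not adj.any():
        return occ

    rng = np.random.default_rng(seed)
    best_keep: np.ndarray | None = None
    for _ in range(n_trials):
        keep = np.ones(n, dtype=bool)
        counts = adj.sum(axis=1).astype(int)
        while True:
            active = counts > 0
            if not active.any():
                break
            candidates = np.flatnonzero(keep & (counts == counts[keep].max()))
            victim = candidates[rng.integers(len(candidates))]
            keep[victim] = False
            neigh = np.flatnonzero(adj[victim] & keep)
            counts[neigh] -= 1
            counts[victim] = 0
        if best_keep is None or keep.sum() > best_keep.sum():
            best_keep = keep
    assert best_keep is not None
    thinned = OccurrenceSet(occ.data.loc[best_keep].reset_index(drop=True),
                            report=occ.report)
    return thinned


def is_feasible(occ: OccurrenceSet, min_dist_km: float) -> bool:
    """All-pairs audit: does every pair satisfy the minimum distance?"""
    if len(occ) <= 1:
        return True
    dist = pairwise_distances_km(occ.lon, occ.lat)
    np.fill_diagonal(dist, np.inf)
    return bool((dist >= min_dist_km).all())
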