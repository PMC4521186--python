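"""Extraction of oceanographic covariates from 1° gridded climatologies.

Temperature (°C), salinity (PSU) and surface current speed (m/s) are sampled
at each occurrence point from the 1°x1° cell containing it; masked (land)
cells fall back to the nearest ocean cell within a bounded search radius.
Seasons are three-month calendar blocks; a point's hemisphere decides which
block a season label refers to (southern-hemisphere seasons are shifted six
months). Per-species summaries (mean, SD, min, max per variable x season,
plus annual pooled statistics and annual range) become the environmental
predictors of the range regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geodesy import great_circle_km

VARIABLES = ("temperature", "salinity", "current_speed")
SEASONS = ("winter", "spring", "summer", "autumn")
STATS = ("mean", "sd", "min", "max")

#: Conventions mapping northern-hemisphere season labels to month blocks.
#: "jfm" (default): winter = Jan-Mar ... matching quarter-aligned ocean
#: climatology fields; "djf": meteorological winter = Dec-Feb.
SEASON_CONVENTIONS = {
    "jfm": {"winter": (1, 2, 3), "spring": (4, 5, 6),
            "summer": (7, 8, 9), "autumn": (10, 11, 12)},
    "djf": {"winter": (12, 1, 2), "spring": (3, 4, 5),
            "summer": (6, 7, 8), "autumn": (9, 10, 11)},
}

#: Default bound on the nearest-ocean-cell fallback search (degrees of arc).
MAX_FALLBACK_DEG = 5.0
_DEG_KM = 2.0 * np.pi * 6371.0 / 360.0


def season_months(season: str, hemisphere: str, convention: str = "jfm") -> frozenset:
    """Months (1-12) covered by a season label in a given hemisphere.

    ``annual`` maps to all twelve months. Southern-hemisphere seasons are the
    northern blocks shifted by six months.
    """
    if convention not in SEASON_CONVENTIONS:
        raise ValueError(f"unknown season convention {convention!r}")
    if season == "annual":
        return frozenset(range(1, 13))
    table = SEASON_CONVENTIONS[convention]
    if season not in table:
        raise ValueError(f"unknown season {season!r}")
    if hemisphere not in ("N", "S"):
        raise ValueError(f"unknown hemisphere {hemisphere!r}")
    months = table[season]
    if hemisphere == "S":
        months = tuple((m + 5) % 12 + 1 for m in months)
    return frozenset(months)


@dataclass
class ClimatologyGrid:
    """One 1°-resolution field: a variable averaged over a block of months.

    ``values[i, j]`` is the cell between ``lat_edges[i:i+2]`` and
    ``lon_edges[j:j+2]``; NaN marks masked (land) cells. The month block is
    hemisphere-neutral — season labels resolve to months at query time.
    """

    variable: str
    months: frozenset
    lat_edges: np.ndarray
    lon_edges: np.ndarray
    values: np.ndarray
    _centers: tuple = field(init=False, repr=False, default=None)

    def __post_init__(self) -> None:
        self.lat_edges = np.asarray(self.lat_edges, dtype=float)
        self.lon_edges = np.asarray(self.lon_edges, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.months = frozenset(int(m) for m in self.months)
        if not (np.allclose(np.diff(self.lat_edges), 1.0)
                and np.allclose(np.diff(self.lon_edges), 1.0)):
            raise ValueError("grid resolution must be exactly 1 degree")
        if self.values.shape != (len(self.lat_edges) - 1, len(self.lon_edges) - 1):
            raise ValueError("values shape does not match edges")

    @property
    def cell_centers(self):
        if self._centers is None:
            la = (self.lat_edges[:-1] + self.lat_edges[1:]) / 2.0
            lo = (self.lon_edges[:-1] + self.lon_edges[1:]) / 2.0
            self._centers = (la, lo)
        return self._centers

    def to_frame(self) -> pd.DataFrame:
        la, lo = self.cell_centers
        lat_g, lon_g = np.meshgrid(la, lo, indexing="ij")
        return pd.DataFrame(
            {"lat": lat_g.ravel(), "lon": lon_g.ravel(),
             "value": self.values.ravel()}
        )

    def to_csv(self, path) -> None:
        """Dense CSV export (lat, lon, value); masked cells as empty values."""
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, variable: str, months) -> "ClimatologyGrid":
        lats = np.sort(df["lat"].unique())
        lons = np.sort(df["lon"].unique())
        lat_edges = np.concatenate([lats - 0.5, [lats[-1] + 0.5]])
        lon_edges = np.concatenate([lons - 0.5, [lons[-1] + 0.5]])
        values = np.full((len(lats), len(lons)), np.nan)
        i = np.searchsorted(lats, df["lat"].to_numpy())
        j = np.searchsorted(lons, df["lon"].to_numpy())
        values[i, j] = df["value"].to_numpy()
        return cls(variable, frozenset(months), lat_edges, lon_edges, values)

    @classmethod
    def read_csv(cls, path, variable: str, months) -> "ClimatologyGrid":
        return cls.from_frame(pd.read_csv(path), variable, months)


def sample_grid(
    grid: ClimatologyGrid,
    lat: float,
    lon: float,
    max_fallback_deg: float = MAX_FALLBACK_DEG,
) -> float:
    """Value of the cell containing the point; nearest ocean cell on land.

    If the containing cell is masked, the value of the nearest unmasked cell
    center (great-circle distance, ties broken by (lat, lon) lexicographic
    order on the centers) is used, provided it lies within
    ``max_fallback_deg`` degrees of arc; otherwise NaN (the point contributes
    missing data for this variable).
    """
    if np.all(np.isnan(grid.values)):
        raise ValueError("fully masked grid")
    i = int(np.searchsorted(grid.lat_edges, lat, side="right") - 1)
    j = int(np.searchsorted(grid.lon_edges, lon, side="right") - 1)
    ni, nj = grid.values.shape
    if 0 <= i < ni and 0 <= j < nj and not np.isnan(grid.values[i, j]):
        return float(grid.values[i, j])
    la, lo = grid.cell_centers
    ii, jj = np.nonzero(~np.isnan(grid.values))
    d = great_circle_km((lat, lon), (la[ii], lo[jj]))
    d = np.atleast_1d(d)
    dmin = d.min()
    if dmin > max_fallback_deg * _DEG_KM:
        return float("nan")
    cand = np.nonzero(d <= dmin + 1e-9)[0]
    # deterministic tie-break: smallest (lat, lon) cell center
    order = np.lexsort((lo[jj[cand]], la[ii[cand]]))
    k = cand[order[0]]
    return float(grid.values[ii[k], jj[k]])


class ClimatologySet:
    """Collection of grids keyed by (variable, month block)."""

    def __init__(self, grids, convention: str = "jfm"):
        self.convention = convention
        self._grids: dict[tuple[str, frozenset], ClimatologyGrid] = {}
        for g in grids:
            self._grids[(g.variable, g.months)] = g

    def grid_for(self, variable: str, season: str, hemisphere: str) -> ClimatologyGrid:
        months = season_months(season, hemisphere, self.convention)
        key = (variable, months)
        if key not in self._grids:
            raise KeyError(
                f"no grid for variable {variable!r} covering months {sorted(months)}"
            )
        return self._grids[key]

    @property
    def variables(self) -> list[str]:
        return sorted({v for v, _ in self._grids})


def _stat_block(values: np.ndarray) -> dict[str, float]:
    v = values[~np.isnan(values)]
    if v.size == 0:
        return {s: float("nan") for s in STATS}
    return {
        "mean": float(v.mean()),
        # sample SD (n-1 denominator); a single value has SD 0 by convention
        "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
        "min": float(v.min()),
        "max": float(v.max()),
    }


def summarize_species_env(
    points: pd.DataFrame,
    climatology: ClimatologySet,
    max_fallback_deg: float = MAX_FALLBACK_DEG,
) -> dict[str, float] | None:
    """Seasonal/annual environment statistics over a species' occurrences.

    Each point resolves season labels through its own hemisphere, so a
    species straddling the equator mixes the matching month blocks. Annual
    statistics pool the four seasonal values of every point, which makes the
    annual SD capture seasonal as well as spatial variability;
    ``annual_range`` (temperature and salinity) is max - min of that pool.
    Returns None for a species with no points.
    """
    if points.empty:
        return None
    lats = points["lat"].to_numpy(dtype=float)
    lons = points["lon"].to_numpy(dtype=float)
    hemis = np.where(lats >= 0.0, "N", "S")
    out: dict[str, float] = {}
    for var in climatology.variables:
        pooled = []
        for season in SEASONS:
            vals = np.array(
                [
                    sample_grid(
                        climatology.grid_for(var, season, h), la, lo,
                        max_fallback_deg,
                    )
                    for la, lo, h in zip(lats, lons, hemis)
                ]
            )
            pooled.append(vals)
            for stat, value in _stat_block(vals).items():
                out[f"{var}_{season}_{stat}"] = value
        pool = np.concatenate(pooled)
        for stat, value in _stat_block(pool).items():
            out[f"{var}_annual_{stat}"] = value
        if var in ("temperature", "salinity"):
            ok = pool[~np.isnan(pool)]
            out[f"{var}_annual_range"] = (
                float(ok.max() - ok.min()) if ok.size else float("nan")
            )
    return out


def summarize_all_species(
    occurrences: pd.DataFrame,
    climatology: ClimatologySet,
    max_fallback_deg: float = MAX_FALLBACK_DEG,
) -> pd.DataFrame:
    """One row of environment statistics per species in ``occurrences``."""
    rows = []
    for sp, grp in occurrences.groupby("species_id", sort=True):
        summary = summarize_species_env(grp, climatology, max_fallback_deg)
        if summary is not None:
            rows.append({"species_id": sp, **summary})
    return pd.DataFrame(rows)
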