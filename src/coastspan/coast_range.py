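"""Quantifying species ranges along coastlines.

A coastline is an ordered polyline on the sphere carrying a cumulative
along-coast arc length ``cum_s`` (km). Occurrence points are projected onto
the nearest coastline and a species' non-native range is then measured on
that 1-D axis with three rules, all expressed in km:

* a single isolated occurrence counts as 50 km (the measurement floor);
* consecutive occurrences more than 1500 km apart (along the coast) break the
  range into disjoint segments, each measured as the span of its points;
* occurrence clusters more than 1000 km from every continental coastline are
  treated as oceanic-archipelago distributions and measured as the straight
  (great-circle) line through the cluster.

Per-coast and archipelago segment lengths are summed into the species' total
range, the response variable of the downstream regression competition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .geodesy import (
    from_unit_vectors,
    great_circle_km,
    to_unit_vectors,
    unit_vector_distance_km,
)

# Rule constants (km); overridable per call, echoed into run configs.
ISOLATED_KM = 50.0
GAP_KM = 1500.0
ARCHIPELAGO_KM = 1000.0
OFFSHORE_TOL_KM = 100.0
LOCALE_STEP_KM = 200.0

OCCURRENCE_COLUMNS = ["species_id", "lat", "lon", "source"]

#: Darwin-Core-compatible column aliases accepted when reading occurrence CSVs.
_COLUMN_ALIASES = {
    "decimallatitude": "lat",
    "decimallongitude": "lon",
    "latitude": "lat",
    "longitude": "lon",
    "species": "species_id",
    "scientificname": "species_id",
}


@dataclass
class Coastline:
    """Directed coastline polyline with cumulative along-coast arc length.

    ``s`` increases from the first stored vertex; this orientation is a
    file-level convention of the coastline inputs.
    """

    id: str
    lats: np.ndarray
    lons: np.ndarray
    basin: str = ""
    hemisphere: str = "N"
    is_continental: bool = True
    cum_s: np.ndarray = field(init=False, repr=False)
    _uv: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.lats = np.asarray(self.lats, dtype=float)
        self.lons = np.asarray(self.lons, dtype=float)
        if self.lats.ndim != 1 or self.lats.shape != self.lons.shape:
            raise ValueError("lats and lons must be 1-D arrays of equal length")
        if self.lats.size < 2:
            raise ValueError(f"coastline {self.id!r} needs >= 2 vertices")
        if np.any(np.abs(self.lats) > 90.0):
            raise ValueError(f"coastline {self.id!r}: latitude out of [-90, 90]")
        if np.any((self.lons < -180.0) | (self.lons >= 180.0)):
            raise ValueError(f"coastline {self.id!r}: longitude out of [-180, 180)")
        steps = great_circle_km(
            (self.lats[:-1], self.lons[:-1]), (self.lats[1:], self.lons[1:])
        )
        steps = np.atleast_1d(steps)
        if np.any(steps <= 0.0):
            raise ValueError(f"coastline {self.id!r}: duplicate consecutive vertices")
        self.cum_s = np.concatenate([[0.0], np.cumsum(steps)])
        self._uv = to_unit_vectors(self.lats, self.lons)

    @property
    def length_km(self) -> float:
        return float(self.cum_s[-1])

    def __len__(self) -> int:
        return self.lats.size


@dataclass
class CoastAssignment:
    """Projection of one occurrence point onto a coastline."""

    species_id: str
    lat: float
    lon: float
    coastline_id: str
    s: float
    offshore_km: float
    is_archipelago: bool = False
    archipelago_id: str | None = None


@dataclass
class RangeSegment:
    """One disjoint piece of a species' range, on a coast or an archipelago."""

    coastline_id: str
    s_start: float
    s_end: float
    length_km: float
    n_points: int
    is_isolated: bool = False
    is_archipelago: bool = False


@dataclass
class RangeResult:
    """Per-species range: disjoint segments, their km total, and lat bands."""

    species_id: str
    segments: list[RangeSegment]
    total_km: float
    lat_band_per_coast: dict[str, tuple[float, float]]
    n_points: int

    @property
    def has_range(self) -> bool:
        return self.n_points > 0


# ---------------------------------------------------------------------------
# coastline I/O


def read_coastlines_geojson(path) -> list[Coastline]:
    """Read coastlines from a GeoJSON FeatureCollection of LineStrings.

    Feature properties: ``id``, ``basin``, ``hemisphere``, ``is_continental``.
    GeoJSON coordinates are (lon, lat).
    """
    with open(path) as fh:
        gj = json.load(fh)
    coasts = []
    for feat in gj["features"]:
        geom = feat["geometry"]
        if geom["type"] != "LineString":
            raise ValueError(f"unsupported geometry type {geom['type']!r}")
        coords = np.asarray(geom["coordinates"], dtype=float)
        props = feat.get("properties", {}) or {}
        coasts.append(
            Coastline(
                id=str(props.get("id", f"coast-{len(coasts)}")),
                lats=coords[:, 1],
                lons=coords[:, 0],
                basin=str(props.get("basin", "")),
                hemisphere=str(props.get("hemisphere", "N")),
                is_continental=bool(props.get("is_continental", True)),
            )
        )
    if not coasts:
        raise ValueError(f"no LineString features in {path}")
    return coasts


def write_coastlines_geojson(coastlines: Sequence[Coastline], path) -> None:
    feats = []
    for c in coastlines:
        feats.append(
            {
                "type": "Feature",
                "properties": {
                    "id": c.id,
                    "basin": c.basin,
                    "hemisphere": c.hemisphere,
                    "is_continental": c.is_continental,
                },
                "geometry": {
                    "type": "LineString",
                    "coordinates": [
                        [float(lon), float(lat)] for lat, lon in zip(c.lats, c.lons)
                    ],
                },
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def read_coastlines_csv(path) -> list[Coastline]:
    """Read coastlines from a vertex CSV with columns id, order, lat, lon."""
    df = pd.read_csv(path)
    coasts = []
    for cid, grp in df.groupby("id", sort=True):
        grp = grp.sort_values("order")
        coasts.append(Coastline(id=str(cid), lats=grp["lat"].to_numpy(),
                                lons=grp["lon"].to_numpy()))
    return coasts


def read_occurrences(path) -> pd.DataFrame:
    """Read an occurrence CSV, accepting Darwin-Core column names."""
    df = pd.read_csv(path)
    renames = {}
    for col in df.columns:
        key = col.strip().lower()
        if key in _COLUMN_ALIASES:
            renames[col] = _COLUMN_ALIASES[key]
    df = df.rename(columns=renames)
    missing = [c for c in ("species_id", "lat", "lon") if c not in df.columns]
    if missing:
        raise ValueError(f"occurrence file {path} lacks required columns: {missing}")
    if "source" not in df.columns:
        df["source"] = "gbif"
    return df[OCCURRENCE_COLUMNS].copy()


# ---------------------------------------------------------------------------
# projection onto coastlines


def project_many(lats, lons, coastline: Coastline) -> tuple[np.ndarray, np.ndarray]:
    """Project points onto a coastline polyline.

    Returns ``(s, d)``: along-coast positions (km, clamped to [0, length])
    and offshore great-circle distances (km). Nearest points are found per
    polyline segment with chord-parameterized interpolation of the vertex
    unit vectors; beyond the terminal vertices positions clamp to the
    terminus.
    """
    lats = np.atleast_1d(np.asarray(lats, dtype=float))
    lons = np.atleast_1d(np.asarray(lons, dtype=float))
    p = to_unit_vectors(lats, lons)  # (n, 3)
    a = coastline._uv[:-1]  # (m, 3)
    d_vec = coastline._uv[1:] - a  # (m, 3)
    dd = np.einsum("ij,ij->i", d_vec, d_vec)  # (m,)
    ad = np.einsum("ij,ij->i", a, d_vec)
    t = (p @ d_vec.T - ad[None, :]) / dd[None, :]  # (n, m)
    t = np.clip(t, 0.0, 1.0)
    q = a[None, :, :] + t[:, :, None] * d_vec[None, :, :]
    q /= np.linalg.norm(q, axis=-1, keepdims=True)
    dist = unit_vector_distance_km(p[:, None, :], q)  # (n, m)
    j = np.argmin(dist, axis=1)
    rows = np.arange(lats.size)
    seg_len = np.diff(coastline.cum_s)
    s = coastline.cum_s[j] + t[rows, j] * seg_len[j]
    return s, dist[rows, j]


def project_to_coast(point, coastline: Coastline) -> CoastAssignment:
    """Project a single point; ``point`` is (lat, lon) or a mapping/row."""
    if isinstance(point, (tuple, list, np.ndarray)):
        species_id, lat, lon = "", float(point[0]), float(point[1])
    else:
        species_id = str(point.get("species_id", ""))
        lat, lon = float(point["lat"]), float(point["lon"])
    s, d = project_many([lat], [lon], coastline)
    return CoastAssignment(
        species_id=species_id,
        lat=lat,
        lon=lon,
        coastline_id=coastline.id,
        s=float(s[0]),
        offshore_km=float(d[0]),
    )


def _distance_matrix(df: pd.DataFrame, coastlines: Sequence[Coastline]):
    """(s, d) arrays of shape (n_points, n_coasts)."""
    n = len(df)
    s = np.empty((n, len(coastlines)))
    d = np.empty((n, len(coastlines)))
    for k, coast in enumerate(coastlines):
        s[:, k], d[:, k] = project_many(
            df["lat"].to_numpy(), df["lon"].to_numpy(), coast
        )
    return s, d


def point_at_s(coastline: Coastline, s) -> tuple[np.ndarray, np.ndarray]:
    """Interpolate coordinates at along-coast position(s) ``s`` (km).

    The returned points reproject (via :func:`project_many`) onto the same
    ``s`` to machine precision, so discretize-then-measure round trips are
    exact. ``s`` is clamped to [0, length].
    """
    s = np.atleast_1d(np.asarray(s, dtype=float))
    s = np.clip(s, 0.0, coastline.length_km)
    cum = coastline.cum_s
    j = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(cum) - 2)
    frac = (s - cum[j]) / (cum[j + 1] - cum[j])
    a = coastline._uv[j]
    d_vec = coastline._uv[j + 1] - a
    dd = np.einsum("ij,ij->i", d_vec, d_vec)
    ad = np.einsum("ij,ij->i", a, d_vec)
    # invert the chord parameterization: find alpha whose normalized point
    # projects back to exactly `frac`; contraction converges in a few steps
    alpha = frac.copy()
    for _ in range(6):
        q = a + alpha[:, None] * d_vec
        q = q / np.linalg.norm(q, axis=-1, keepdims=True)
        t = (np.einsum("ij,ij->i", q, d_vec) - ad) / dd
        alpha = alpha + (frac - t)
    q = a + alpha[:, None] * d_vec
    return from_unit_vectors(q)


def locale_to_points(
    coastline: Coastline,
    s_start: float,
    s_end: float,
    step_km: float = LOCALE_STEP_KM,
    species_id: str = "",
) -> pd.DataFrame:
    """Discretize a reported locale [s_start, s_end] into coordinates.

    Emits a point every ``step_km`` starting at ``s_start``; the interval end
    is always included so the realized span equals the reported locale
    extent. Points carry source ``literature``.
    """
    if s_start > s_end:
        raise ValueError("inverted interval: s_start > s_end")
    if s_start < 0 or s_end > coastline.length_km + 1e-6:
        raise ValueError("interval outside coastline extent")
    n = int(np.floor((s_end - s_start) / step_km + 1e-9)) + 1
    s = s_start + step_km * np.arange(n)
    if s_end - s[-1] > 1e-9:
        s = np.append(s, s_end)
    lat, lon = point_at_s(coastline, s)
    return pd.DataFrame(
        {"species_id": species_id, "lat": lat, "lon": lon, "source": "literature"}
    )


# ---------------------------------------------------------------------------
# cleaning and assignment


def clean_occurrences(
    occurrences: pd.DataFrame,
    coastlines: Sequence[Coastline],
    offshore_tol_km: float = OFFSHORE_TOL_KM,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop implausible occurrence records; log every drop with a reason.

    Reason codes: ``bad-coords`` (outside valid lat/lon), ``zero-zero``
    (exact 0,0 — a standard georeferencing artifact), ``duplicate``
    (identical coordinates within a species) and ``off-coast`` (farther than
    ``offshore_tol_km`` from every coastline, i.e. inland or implausibly
    offshore). Returns (cleaned, drop_log).
    """
    df = occurrences.reset_index(drop=True).copy()
    reason = pd.Series("", index=df.index, dtype=object)

    bad = (df["lat"].abs() > 90) | (df["lon"] < -180) | (df["lon"] >= 180)
    bad |= df["lat"].isna() | df["lon"].isna()
    reason[bad] = "bad-coords"

    zz = (df["lat"] == 0.0) & (df["lon"] == 0.0) & ~bad
    reason[zz] = "zero-zero"

    ok = reason == ""
    dup = df.duplicated(subset=["species_id", "lat", "lon"]) & ok
    reason[dup] = "duplicate"

    ok = reason == ""
    if ok.any() and coastlines:
        _, d = _distance_matrix(df.loc[ok], list(coastlines))
        off = d.min(axis=1) > offshore_tol_km
        idx = df.index[ok][off]
        reason[idx] = "off-coast"

    kept = df[reason == ""].copy()
    log = df[reason != ""].copy()
    log["reason"] = reason[reason != ""]
    return kept.reset_index(drop=True), log.reset_index(drop=True)


def _single_linkage_clusters(lats, lons, radius_km: float) -> np.ndarray:
    """Single-linkage clustering labels on great-circle distances."""
    n = len(lats)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    uv = to_unit_vectors(lats, lons)
    dist = unit_vector_distance_km(uv[:, None, :], uv[None, :, :])
    for i in range(n):
        for j in range(i + 1, n):
            if dist[i, j] <= radius_km:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    roots = np.array([find(i) for i in range(n)])
    # relabel 0..k-1 in order of first appearance
    _, labels = np.unique(roots, return_inverse=True)
    return labels


def assign_points(
    occurrences: pd.DataFrame,
    coastlines: Sequence[Coastline],
    archipelago_km: float = ARCHIPELAGO_KM,
    linkage_km: float = ARCHIPELAGO_KM,
) -> pd.DataFrame:
    """Attach cleaned points to coastlines; flag and cluster archipelagos.

    Each point attaches to its nearest coastline. Points farther than
    ``archipelago_km`` from every *continental* coastline are flagged
    ``is_archipelago`` and grouped per species by single-linkage clustering
    with ``linkage_km`` radius.
    """
    coastlines = list(coastlines)
    if not coastlines:
        raise ValueError("no coastlines provided")
    df = occurrences.reset_index(drop=True).copy()
    s_mat, d_mat = _distance_matrix(df, coastlines)
    nearest = np.argmin(d_mat, axis=1)
    rows = np.arange(len(df))
    df["coastline_id"] = [coastlines[k].id for k in nearest]
    df["s"] = s_mat[rows, nearest]
    df["offshore_km"] = d_mat[rows, nearest]

    cont = [k for k, c in enumerate(coastlines) if c.is_continental]
    if cont:
        d_cont = d_mat[:, cont].min(axis=1)
    else:
        d_cont = np.full(len(df), np.inf)
    df["is_archipelago"] = d_cont > archipelago_km
    df["archipelago_id"] = None

    for sp, grp in df[df["is_archipelago"]].groupby("species_id", sort=True):
        labels = _single_linkage_clusters(
            grp["lat"].to_numpy(), grp["lon"].to_numpy(), linkage_km
        )
        ids = [f"{sp}/arch-{lab}" for lab in labels]
        df.loc[grp.index, "archipelago_id"] = ids
    return df


# ---------------------------------------------------------------------------
# range rules


def segment_coast_positions(
    s_values,
    gap_km: float = GAP_KM,
    isolated_km: float = ISOLATED_KM,
    coastline_id: str = "",
) -> list[RangeSegment]:
    """Split sorted along-coast positions into disjoint range segments.

    Consecutive positions strictly more than ``gap_km`` apart break the
    range. Multi-point groups measure as the span first-to-last, floored at
    ``isolated_km`` (the measurement resolution, so that ranges never fall
    below it and duplicate points cannot shrink a total); singleton groups
    are isolated points of fixed ``isolated_km`` length.
    """
    s = np.sort(np.asarray(list(s_values), dtype=float))
    if s.size == 0:
        return []
    breaks = np.nonzero(np.diff(s) > gap_km)[0]
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [s.size - 1]])
    segments = []
    for i0, i1 in zip(starts, ends):
        if i0 == i1:
            segments.append(
                RangeSegment(coastline_id, float(s[i0]), float(s[i1]),
                             isolated_km, 1, is_isolated=True)
            )
        else:
            segments.append(
                RangeSegment(coastline_id, float(s[i0]), float(s[i1]),
                             max(float(s[i1] - s[i0]), isolated_km),
                             int(i1 - i0 + 1))
            )
    return segments


def archipelago_range(
    lats, lons, isolated_km: float = ISOLATED_KM, archipelago_id: str = ""
) -> RangeSegment:
    """Measure an archipelago cluster as the line through its occurrences.

    The span is the great-circle distance between the two most separated
    cluster members; a singleton takes the isolated-point length.
    """
    lats = np.atleast_1d(np.asarray(lats, dtype=float))
    lons = np.atleast_1d(np.asarray(lons, dtype=float))
    if lats.size == 0:
        raise ValueError("empty archipelago cluster")
    if lats.size == 1:
        return RangeSegment(archipelago_id, np.nan, np.nan, isolated_km, 1,
                            is_isolated=True, is_archipelago=True)
    uv = to_unit_vectors(lats, lons)
    dist = unit_vector_distance_km(uv[:, None, :], uv[None, :, :])
    # floored at the measurement resolution, as for coastal segments
    return RangeSegment(archipelago_id, np.nan, np.nan,
                        max(float(dist.max()), isolated_km),
                        int(lats.size), is_archipelago=True)


def total_range(
    species_id: str,
    assignments: pd.DataFrame,
    gap_km: float = GAP_KM,
    isolated_km: float = ISOLATED_KM,
) -> RangeResult:
    """Sum per-coast segments and archipelago spans into a total range.

    ``assignments`` is the output of :func:`assign_points` filtered (or not)
    to one species. A species with no cleaned points yields an explicit
    no-range result (``total_km`` is NaN, ``has_range`` False), not 0 km.
    """
    df = assignments[assignments["species_id"] == species_id]
    if df.empty:
        return RangeResult(species_id, [], float("nan"), {}, 0)
    segments: list[RangeSegment] = []
    coastal = df[~df["is_archipelago"]]
    for cid, grp in coastal.groupby("coastline_id", sort=True):
        segments.extend(
            segment_coast_positions(grp["s"].to_numpy(), gap_km, isolated_km, cid)
        )
    for aid, grp in df[df["is_archipelago"]].groupby("archipelago_id", sort=True):
        segments.append(
            archipelago_range(grp["lat"].to_numpy(), grp["lon"].to_numpy(),
                              isolated_km, aid)
        )
    bands = {
        cid: (float(grp["lat"].min()), float(grp["lat"].max()))
        for cid, grp in coastal.groupby("coastline_id", sort=True)
    }
    total = float(sum(seg.length_km for seg in segments))
    return RangeResult(species_id, segments, total, bands, int(len(df)))


def measure_all_ranges(
    assignments: pd.DataFrame,
    gap_km: float = GAP_KM,
    isolated_km: float = ISOLATED_KM,
) -> dict[str, RangeResult]:
    """Total range for every species present in ``assignments``."""
    return {
        sp: total_range(sp, assignments, gap_km, isolated_km)
        for sp in sorted(assignments["species_id"].unique())
    }


def segments_frame(results: Iterable[RangeResult]) -> pd.DataFrame:
    """Long-format export: one row per range segment."""
    rows = []
    for res in results:
        for seg in res.segments:
            rows.append(
                {
                    "species_id": res.species_id,
                    "coastline_id": seg.coastline_id,
                    "s_start": seg.s_start,
                    "s_end": seg.s_end,
                    "length_km": seg.length_km,
                    "n_points": seg.n_points,
                    "is_isolated": seg.is_isolated,
                    "is_archipelago": seg.is_archipelago,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["species_id", "coastline_id", "s_start", "s_end", "length_km",
                 "n_points", "is_isolated", "is_archipelago"],
    ).sort_values(["species_id", "coastline_id", "s_start"]).reset_index(drop=True)


def totals_frame(results: Iterable[RangeResult]) -> pd.DataFrame:
    """Per-species total range export (species with no points excluded)."""
    rows = [
        {"species_id": r.species_id, "total_range_km": r.total_km,
         "n_points": r.n_points, "n_segments": len(r.segments)}
        for r in results
        if r.has_range
    ]
    return pd.DataFrame(
        rows, columns=["species_id", "total_range_km", "n_points", "n_segments"]
    ).sort_values("species_id").reset_index(drop=True)
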