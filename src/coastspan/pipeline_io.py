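"""Pipeline orchestration: configuration, stage functions, table assembly.

Chains the stages (occurrence cleaning → coastline assignment → range
measurement → climatology extraction → analysis-table join → model
competition) over files, with every threshold carried in a flat
:class:`RunConfig` that is echoed next to the outputs for provenance. All
output tables are deterministically ordered (species id, then coastline id).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import coast_range, env_climatology, model_competition
from .coast_range import Coastline, RangeResult
from .env_climatology import ClimatologyGrid, ClimatologySet
from .synthetic_world import MONTH_BLOCKS

#: the candidate predictor roster of the range regression
PREDICTORS = [
    "time_since_introduction",
    "habitat",
    "mobility",
    "max_body_size",
    "development_type",
    "current_speed_spring_mean",
    "current_variability_annual",
    "temperature_spring_mean",
    "temperature_annual_sd",
    "salinity_annual_mean",
    "salinity_annual_sd",
]

RESPONSE = "total_range_km"

#: 0/1 coding of the categorical traits. Signs in reports read against this
#: table: habitat 1 = epifaunal, mobility 1 = mobile, development 1 = planktonic.
TRAIT_CODING = {
    "habitat": {"epifaunal": 1, "infaunal": 0},
    "mobility": {"mobile": 1, "sessile": 0},
    "development_type": {"planktonic": 1, "non-planktonic": 0,
                         "nonplanktonic": 0},
}


@dataclass
class RunConfig:
    """All pipeline thresholds and conventions, with the field defaults."""

    analysis_year: int = 2012
    isolated_km: float = coast_range.ISOLATED_KM
    gap_km: float = coast_range.GAP_KM
    archipelago_km: float = coast_range.ARCHIPELAGO_KM
    linkage_km: float = coast_range.ARCHIPELAGO_KM
    offshore_tol_km: float = coast_range.OFFSHORE_TOL_KM
    step_km: float = coast_range.LOCALE_STEP_KM
    r_cluster: float = model_competition.DEFAULT_R_CLUSTER
    r_rep: float = model_competition.DEFAULT_R_REP
    top_k: int = model_competition.DEFAULT_TOP_K
    season_convention: str = "jfm"
    max_fallback_deg: float = env_climatology.MAX_FALLBACK_DEG
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Read a flat key = value text file; unknown keys are rejected."""
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        kwargs = {}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, 1):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key = value")
                key, value = (part.strip() for part in line.split("=", 1))
                if key not in fields:
                    raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
                typ = fields[key]
                if typ == "int":
                    kwargs[key] = int(value)
                elif typ == "float":
                    kwargs[key] = float(value)
                else:
                    kwargs[key] = value
        return cls(**kwargs)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                fh.write(f"{f.name} = {getattr(self, f.name)}\n")


# ---------------------------------------------------------------------------
# stages


def clean_and_assign(
    occurrences: pd.DataFrame,
    coastlines: list[Coastline],
    config: RunConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Clean occurrences and assign them to coastlines in one pass.

    Returns (assignments, drop_log). Equivalent to
    :func:`coast_range.clean_occurrences` followed by
    :func:`coast_range.assign_points` but projects each point onto each
    coastline only once.
    """
    cfg = config or RunConfig()
    if not coastlines:
        raise ValueError("no coastlines provided")
    df = occurrences.reset_index(drop=True).copy()
    reason = pd.Series("", index=df.index, dtype=object)
    bad = (df["lat"].abs() > 90) | (df["lon"] < -180) | (df["lon"] >= 180)
    bad |= df["lat"].isna() | df["lon"].isna()
    reason[bad] = "bad-coords"
    zz = (df["lat"] == 0.0) & (df["lon"] == 0.0) & ~bad
    reason[zz] = "zero-zero"
    dup = df.duplicated(subset=["species_id", "lat", "lon"]) & (reason == "")
    reason[dup] = "duplicate"

    ok_idx = df.index[reason == ""]
    sub = df.loc[ok_idx]
    s_mat, d_mat = coast_range._distance_matrix(sub, coastlines)
    off = d_mat.min(axis=1) > cfg.offshore_tol_km
    reason[ok_idx[off]] = "off-coast"

    keep_mask = ~off
    kept = sub.loc[ok_idx[keep_mask]].copy()
    s_keep = s_mat[keep_mask]
    d_keep = d_mat[keep_mask]
    nearest = np.argmin(d_keep, axis=1)
    rows = np.arange(len(kept))
    kept["coastline_id"] = [coastlines[k].id for k in nearest]
    kept["s"] = s_keep[rows, nearest]
    kept["offshore_km"] = d_keep[rows, nearest]
    cont = [k for k, c in enumerate(coastlines) if c.is_continental]
    d_cont = d_keep[:, cont].min(axis=1) if cont else np.full(len(kept), np.inf)
    kept["is_archipelago"] = d_cont > cfg.archipelago_km
    kept["archipelago_id"] = None
    for sp, grp in kept[kept["is_archipelago"]].groupby("species_id", sort=True):
        labels = coast_range._single_linkage_clusters(
            grp["lat"].to_numpy(), grp["lon"].to_numpy(), cfg.linkage_km
        )
        kept.loc[grp.index, "archipelago_id"] = [
            f"{sp}/arch-{lab}" for lab in labels
        ]

    log = df[reason != ""].copy()
    log["reason"] = reason[reason != ""]
    return kept.reset_index(drop=True), log.reset_index(drop=True)


def measure_ranges(
    occurrences: pd.DataFrame,
    coastlines: list[Coastline],
    config: RunConfig | None = None,
) -> tuple[dict[str, RangeResult], pd.DataFrame, pd.DataFrame]:
    """Full measurement stage: returns (results, assignments, drop_log)."""
    cfg = config or RunConfig()
    assignments, drop_log = clean_and_assign(occurrences, coastlines, cfg)
    results = coast_range.measure_all_ranges(
        assignments, gap_km=cfg.gap_km, isolated_km=cfg.isolated_km
    )
    return results, assignments, drop_log


def read_grids_dir(path) -> ClimatologySet:
    """Load ``<variable>_<block>.csv`` grids from a directory."""
    grids = []
    for f in sorted(Path(path).glob("*.csv")):
        stem = f.stem
        var, _, block = stem.rpartition("_")
        if block not in MONTH_BLOCKS or not var:
            raise ValueError(f"unrecognized grid file name {f.name!r}")
        grids.append(ClimatologyGrid.read_csv(f, var, MONTH_BLOCKS[block]))
    if not grids:
        raise ValueError(f"no grid CSVs found in {path}")
    return ClimatologySet(grids)


def extract_env(
    assignments: pd.DataFrame,
    climatology: ClimatologySet,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    cfg = config or RunConfig()
    climatology.convention = cfg.season_convention
    return env_climatology.summarize_all_species(
        assignments, climatology, cfg.max_fallback_deg
    )


def _encode_traits(traits: pd.DataFrame) -> pd.DataFrame:
    df = traits.copy()
    for col, coding in TRAIT_CODING.items():
        if col in df.columns and df[col].dtype == object:
            unknown = set(df[col].str.lower()) - set(coding)
            if unknown:
                raise ValueError(f"unknown {col} levels: {sorted(unknown)}")
            df[col] = df[col].str.lower().map(coding)
    return df


def build_analysis_table(
    totals: pd.DataFrame,
    traits: pd.DataFrame,
    env: pd.DataFrame,
    analysis_year: int = 2012,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join ranges, traits and environment into the analysis table.

    Inner join on species id; categorical traits are 0/1-encoded per
    :data:`TRAIT_CODING`; ``time_since_introduction`` is computed relative to
    ``analysis_year``. Rows missing any predictor or the response are
    dropped and logged. Returns (table, drop_log).
    """
    for name, df in (("ranges", totals), ("traits", traits), ("env", env)):
        if df["species_id"].duplicated().any():
            dups = df.loc[df["species_id"].duplicated(), "species_id"].tolist()
            raise ValueError(f"duplicate species ids in {name}: {dups[:5]}")
    traits = _encode_traits(traits)
    traits = traits.assign(
        time_since_introduction=analysis_year - traits["year"]
    )
    env = env.rename(
        columns={"current_speed_annual_sd": "current_variability_annual"}
    )
    merged = (
        totals[["species_id", RESPONSE] if RESPONSE in totals.columns
               else ["species_id", "total_range_km"]]
        .merge(traits, on="species_id", how="inner")
        .merge(env, on="species_id", how="inner")
    )
    cols = ["species_id", RESPONSE, "year"] + PREDICTORS
    merged = merged[[c for c in cols if c in merged.columns]]
    complete = merged.dropna(subset=[RESPONSE] + PREDICTORS)
    dropped = merged.loc[~merged.index.isin(complete.index)].copy()
    dropped["reason"] = "incomplete-case"
    table = complete.sort_values("species_id").reset_index(drop=True)
    return table, dropped.reset_index(drop=True)


def compete(
    table: pd.DataFrame,
    config: RunConfig | None = None,
    predictors: list[str] | None = None,
) -> model_competition.CompetitionResult:
    cfg = config or RunConfig()
    preds = predictors or [p for p in PREDICTORS if p in table.columns]
    return model_competition.run_competition(
        table, RESPONSE, preds, top_k=cfg.top_k
    )


def waterfall_export(
    results: dict[str, RangeResult],
    years: pd.Series,
    median_year: float | None = None,
) -> pd.DataFrame:
    """Per species x coast latitudinal bands with an Old/Young era flag.

    The split is the dataset median first-introduction year; a species first
    recorded exactly at the median counts as Young (the recent era is closed
    on the left).
    """
    if median_year is None:
        median_year = float(np.median(years.to_numpy(dtype=float)))
    rows = []
    for sp in sorted(results):
        res = results[sp]
        if sp not in years.index:
            continue
        year = float(years[sp])
        era = "Old" if year < median_year else "Young"
        for cid, (lo, hi) in sorted(res.lat_band_per_coast.items()):
            rows.append(
                {"species_id": sp, "coastline_id": cid, "lat_min": lo,
                 "lat_max": hi, "year": year, "era": era}
            )
    return pd.DataFrame(
        rows, columns=["species_id", "coastline_id", "lat_min", "lat_max",
                       "year", "era"]
    )


def headline_stats(
    table: pd.DataFrame,
    config: RunConfig | None = None,
    run_models: bool = True,
) -> dict[str, float]:
    """Headline quantities of an analysis table.

    Computes the raw-scale time-only regression (slope km/yr, intercept,
    R²), the median first-introduction year, the largest total range, and —
    when ``run_models`` — the full competition's best-model R², the null
    model's ΔAICc and the RVI of time since introduction.
    """
    cfg = config or RunConfig()
    fit = model_competition.simple_regression(
        table["time_since_introduction"], table[RESPONSE]
    )
    out = {
        "slope_time_km_per_yr": fit["slope"],
        "intercept_km": fit["intercept"],
        "r2_time_only": fit["r2"],
        "median_year": float(np.median(cfg.analysis_year
                                       - table["time_since_introduction"])),
        "max_range_km": float(table[RESPONSE].max()),
        "n_species": int(len(table)),
    }
    if run_models:
        comp = compete(table, cfg)
        null = next(f for f in comp.fits if f.k == 0)
        out["best_model_r2"] = comp.fits[0].r2
        out["null_delta_aicc"] = null.delta
        out["rvi_time"] = comp.rvi["time_since_introduction"]
    return out
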