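"""CSV codecs for the assessment's tabular inputs and outputs.

All tables are UTF-8 CSV with a header row; missing values are empty
fields. Validation errors report the 1-based file line number of the first
offending row (header is line 1).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


class TableFormatError(ValueError):
    """A table file violated its schema; message carries the line number."""


def _require_columns(df: pd.DataFrame, columns: list[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: header missing columns {missing}")


def _first_bad_line(mask: pd.Series) -> int:
    # +2: header is line 1, frame index 0 is line 2
    return int(mask.idxmax()) + 2


def _check(df: pd.DataFrame, mask: pd.Series, message: str, path) -> None:
    if mask.any():
        raise TableFormatError(f"{path}, line {_first_bad_line(mask)}: {message}")


def read_trade(path: str | Path) -> pd.DataFrame:
    """Trade flows: origin_region, dest_region, year, tonnes (tonnes >= 0)."""
    df = pd.read_csv(path)
    _require_columns(df, ["origin_region", "dest_region", "year", "tonnes"], path)
    df = df.reset_index(drop=True)
    _check(df, df["tonnes"] < 0, "negative tonnes", path)
    _check(df, df["year"].isna() | (df["year"] % 1 != 0), "year must be an integer", path)
    df["year"] = df["year"].astype(int)
    return df


def read_production(path: str | Path) -> pd.DataFrame:
    """Production records: region, commodity, year, quantity, unit."""
    df = pd.read_csv(path).reset_index(drop=True)
    _require_columns(df, ["region", "commodity", "year", "quantity", "unit"], path)
    _check(df, df["quantity"] < 0, "negative quantity", path)
    _check(df, ~df["commodity"].isin({"grape", "wine"}), "unknown commodity", path)
    _check(df, ~df["unit"].isin({"tonnes", "gallons"}), "unknown unit", path)
    _check(
        df,
        (df["commodity"] == "grape") & (df["unit"] == "gallons"),
        "grape production cannot be in gallons",
        path,
    )
    df["year"] = df["year"].astype(int)
    return df


def read_exports(path: str | Path) -> pd.DataFrame:
    """Export values: region, year, usd_value (usd_value >= 0)."""
    df = pd.read_csv(path).reset_index(drop=True)
    _require_columns(df, ["region", "year", "usd_value"], path)
    _check(df, df["usd_value"] < 0, "negative usd_value", path)
    df["year"] = df["year"].astype(int)
    return df


def read_regions(path: str | Path) -> pd.DataFrame:
    """Region set: region, level (state|country), invaded (true/false)."""
    df = pd.read_csv(path).reset_index(drop=True)
    _require_columns(df, ["region", "level", "invaded"], path)
    _check(df, ~df["level"].isin({"state", "country"}), "level must be state or country", path)
    dup = df.duplicated(subset=["region", "level"])
    _check(df, dup, "duplicate region within level", path)
    if df["invaded"].dtype == object:
        mapped = df["invaded"].astype(str).str.strip().str.lower().map(
            {"true": True, "false": False, "1": True, "0": False}
        )
        _check(df, mapped.isna(), "invaded must be boolean", path)
        df["invaded"] = mapped
    df["invaded"] = df["invaded"].astype(bool)
    return df


def read_establishment(path: str | Path) -> pd.DataFrame:
    """Precomputed per-region establishment potential: region, establishment in [0,1]."""
    df = pd.read_csv(path).reset_index(drop=True)
    _require_columns(df, ["region", "establishment"], path)
    bad = df["establishment"].notna() & (
        (df["establishment"] < 0) | (df["establishment"] > 1)
    )
    _check(df, bad, "establishment outside [0, 1]", path)
    return df


def read_occurrences(path: str | Path):
    """Occurrence CSV (species, lon, lat) -> OccurrenceSet."""
    from .establishment import OccurrenceSet

    df = pd.read_csv(path).reset_index(drop=True)
    _require_columns(df, ["species", "lon", "lat"], path)
    _check(df, df["lon"].abs() > 180, "lon outside [-180, 180]", path)
    _check(df, df["lat"].abs() > 90, "lat outside [-90, 90]", path)
    species = str(df["species"].iloc[0]) if len(df) else "unknown"
    return OccurrenceSet(species, df[["lon", "lat"]].to_numpy(float))


def write_occurrences(occ, path: str | Path) -> None:
    pd.DataFrame(
        {"species": occ.species, "lon": occ.points[:, 0], "lat": occ.points[:, 1]}
    ).to_csv(path, index=False)


def write_potentials(potentials: pd.DataFrame, path: str | Path) -> None:
    potentials.to_csv(path, index=False)


def read_potentials(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path).reset_index(drop=True)
    _require_columns(df, ["region"], path)
    return df


def read_region_grid(asc_path: str | Path, legend_path: str | Path):
    """Region zone raster: ESRI ASCII of integer codes + legend CSV (code, region)."""
    from .grids import RegionGrid, read_ascii_grid

    grid = read_ascii_grid(asc_path)
    legend = pd.read_csv(legend_path).reset_index(drop=True)
    _require_columns(legend, ["code", "region"], legend_path)
    lookup = dict(zip(legend["code"].astype(int), legend["region"].astype(str)))
    labels = np.full(grid.shape, None, dtype=object)
    valid = ~np.isnan(grid.values)
    codes = grid.values[valid].astype(int)
    unknown = set(codes) - set(lookup)
    if unknown:
        raise TableFormatError(f"{asc_path}: codes missing from legend: {sorted(unknown)}")
    labels[valid] = [lookup[c] for c in codes]
    return RegionGrid(labels, grid.origin, grid.cellsize)


def write_region_grid(zones, asc_path: str | Path, legend_path: str | Path) -> None:
    from .grids import Grid, write_ascii_grid

    regions = sorted({r for r in zones.labels.ravel() if r is not None})
    code_of = {r: i + 1 for i, r in enumerate(regions)}
    values = np.full(zones.shape, np.nan)
    for r, c in code_of.items():
        values[zones.labels == r] = c
    write_ascii_grid(Grid(values, zones.origin, zones.cellsize), asc_path)
    pd.DataFrame({"code": [code_of[r] for r in regions], "region": regions}).to_csv(
        legend_path, index=False
    )
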