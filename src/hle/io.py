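"""Reading and writing the delimited-text schemas the pipeline uses.

Two input schemas:

* mortality: one row per sex x age interval (x year), columns
  ``sex, age_start, deaths, population[, year]``;
* survey: one row per respondent, columns
  ``id, sex, age, weight, psu, srh, lim_g, lim_h, lim_i, lim_j``.

Validation is row-wise and exhaustive: every offending row is reported with
its line number before the reader fails.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import ValidationError
from .grids import AgeGrid
from .life_tables import MortalityInput
from .prevalence import BINARY_LEVELS, ITEM_COLUMNS, SRH_LEVELS, THREE_LEVELS

__all__ = [
    "read_mortality_csv",
    "write_mortality_csv",
    "read_survey_csv",
    "write_survey_csv",
    "RunConfig",
    "load_config",
]

MORTALITY_COLUMNS = ("sex", "age_start", "deaths", "population")
SURVEY_COLUMNS = ("id", "sex", "age", "weight", "psu", "srh") + ITEM_COLUMNS


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")


def _fail_if(errors: list[str], path) -> None:
    if errors:
        msg = "\n".join(f"  line {ln}: {m}" for ln, m in sorted(errors))
        raise ValidationError(f"{path}: {len(errors)} invalid row(s):\n{msg}")


def read_mortality_csv(path, grid: AgeGrid | None = None) -> dict:
    """Load a mortality registry extract.

    Returns ``{sex: [MortalityInput, ...]}`` with one entry per year (one
    entry total when no ``year`` column is present).  The grid is taken from
    the distinct ``age_start`` values unless supplied.
    """
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, MORTALITY_COLUMNS, path)
    errors: list[tuple[int, str]] = []
    for col in ("age_start", "deaths", "population"):
        vals = pd.to_numeric(df[col], errors="coerce")
        for pos in np.flatnonzero(vals.isna() & df[col].notna()):
            errors.append((pos + 2, f"unparsable {col} value {df[col].iloc[pos]!r}"))
        df[col] = vals
    for pos in np.flatnonzero((df["deaths"] < 0).to_numpy()):
        errors.append((pos + 2, f"negative deaths {df['deaths'].iloc[pos]}"))
    for pos in np.flatnonzero((df["population"] <= 0).to_numpy()):
        errors.append((pos + 2, f"non-positive population {df['population'].iloc[pos]}"))
    _fail_if(errors, path)

    if grid is None:
        grid = AgeGrid(sorted(df["age_start"].unique()))
    starts = list(grid.exact_ages)
    years = sorted(df["year"].unique()) if "year" in df.columns else [None]
    out: dict[str, list[MortalityInput]] = {}
    for sex, sex_df in df.groupby("sex", sort=True):
        out[str(sex)] = []
        for year in years:
            ydf = sex_df if year is None else sex_df[sex_df["year"] == year]
            ydf = ydf.set_index("age_start")
            missing = [s for s in starts if s not in ydf.index]
            if missing:
                raise ValidationError(
                    f"{path}: sex {sex!r}"
                    + (f", year {year}" if year is not None else "")
                    + f" lacks age_start value(s) {missing}"
                )
            out[str(sex)].append(
                MortalityInput(
                    grid=grid,
                    deaths=ydf.loc[starts, "deaths"].to_numpy(dtype=float),
                    population=ydf.loc[starts, "population"].to_numpy(dtype=float),
                    sex=str(sex),
                    period="" if year is None else str(year),
                )
            )
    return out


def write_mortality_csv(inputs, path) -> None:
    """Write ``{sex: [MortalityInput, ...]}`` (or a flat list) back to CSV."""
    if isinstance(inputs, dict):
        flat = [mi for lst in inputs.values() for mi in lst]
    elif isinstance(inputs, MortalityInput):
        flat = [inputs]
    else:
        flat = list(inputs)
    rows = []
    for mi in flat:
        for s, d, p in zip(mi.grid.starts, mi.deaths, mi.population):
            row = {"sex": mi.sex, "age_start": s, "deaths": d, "population": p}
            if mi.period:
                row["year"] = mi.period
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_survey_csv(path, item_scale: str = "binary") -> pd.DataFrame:
    """Load and validate survey microdata; missing srh/item cells stay NA."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, SURVEY_COLUMNS, path)
    errors: list[tuple[int, str]] = []
    for col in ("age", "weight"):
        vals = pd.to_numeric(df[col], errors="coerce")
        for pos in np.flatnonzero(vals.isna().to_numpy()):
            errors.append((pos + 2, f"unparsable or missing {col} value {df[col].iloc[pos]!r}"))
        df[col] = vals
    for pos in np.flatnonzero((df["weight"] <= 0).to_numpy()):
        errors.append((pos + 2, f"non-positive weight {df['weight'].iloc[pos]}"))
    valid_items = set(BINARY_LEVELS if item_scale == "binary" else THREE_LEVELS)
    for col in ITEM_COLUMNS + ("srh",):
        domain = set(SRH_LEVELS) if col == "srh" else valid_items
        s = df[col].astype("string").str.strip().str.lower().str.replace(" ", "_")
        for pos in np.flatnonzero((s.notna() & ~s.isin(domain)).to_numpy()):
            errors.append((pos + 2, f"out-of-domain {col} value {df[col].iloc[pos]!r}"))
        df[col] = s
    _fail_if(errors, path)
    return df


def write_survey_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


@dataclass
class RunConfig:
    """Configuration for a full pipeline run (YAML or JSON on disk)."""

    deaths: str | None = None
    survey: str | None = None
    output_dir: str = "hle_output"
    grid_starts: tuple = (60, 65, 70, 75, 80)
    a: float | None = None  # None -> n/2
    radix: float = 100_000.0
    variance_mode: str = "prevalence_only"
    prevalence_method: str = "taylor"
    deff0: float = 2.0
    z: float = 1.96
    seed: int = 0
    item_scale: str = "binary"
    indicators: tuple = ("poor_srh", "global", "mild_moderate", "severe")
    extra: dict = field(default_factory=dict)

    @property
    def grid(self) -> AgeGrid:
        return AgeGrid(self.grid_starts)


def load_config(path) -> RunConfig:
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    known = {f for f in RunConfig.__dataclass_fields__ if f != "extra"}
    kwargs = {k: v for k, v in data.items() if k in known}
    extra = {k: v for k, v in data.items() if k not in known}
    for key in ("grid_starts", "indicators"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    return RunConfig(**kwargs, extra=extra)
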