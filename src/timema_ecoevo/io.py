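"""Domain types and delimited-text I/O for the survey tables.

Three tidy input tables describe the field survey:

* plants — one row per host-plant patch: id, host species (``A`` =
  *Adenostoma fasciculatum*, ``C`` = *Ceanothus spinosus*), planar x/y
  coordinates in metres, length/width/height in metres, the year the size
  was measured (2013 or 2014), and foliar %C / %N by mass.
* arthropods — one row per collected non-*Timema* individual: plant id,
  morphospecies id, body length (mm), and wet mass (mg) where the
  individual was weighed.
* timema — per-plant tallies of the three colour-pattern morphs
  (striped, unstriped, melanic).

All tables are comma-delimited UTF-8 with a header row; missing values are
empty strings.  Validation is total: malformed rows raise located errors
(``SchemaError`` for missing columns, ``RowError`` carrying the offending
row number) rather than being silently dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "SchemaError",
    "RowError",
    "PlantPatch",
    "MorphCounts",
    "ArthropodIndividual",
    "CommunitySummary",
    "read_plants",
    "read_arthropods",
    "read_timema",
    "write_summary",
    "read_summary",
    "plants_to_frame",
    "summaries_to_frame",
]


class SchemaError(ValueError):
    """A required column is missing or the table-level contract is violated."""


class RowError(ValueError):
    """A single row failed validation; carries the 1-based data row number."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


@dataclass(frozen=True)
class PlantPatch:
    """One host-plant patch with geometry, location and foliar chemistry.

    Dimensions follow the field protocol: ``length_m`` is the longest
    horizontal extent, ``width_m`` perpendicular to it, ``height_m``
    vertical.  Any of the three may be missing (``None``) when the plant's
    size record is absent; such plants are flagged, not dropped.
    """

    plant_id: str
    host: str  # "A" or "C"
    x: float
    y: float
    length_m: float | None = None
    width_m: float | None = None
    height_m: float | None = None
    size_year: int | None = None  # 2013 or 2014
    pct_carbon: float | None = None
    pct_nitrogen: float | None = None

    def __post_init__(self):
        if self.host not in ("A", "C"):
            raise ValueError(f"host must be 'A' or 'C', got {self.host!r}")
        for name in ("length_m", "width_m", "height_m"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be > 0, got {v}")
        for name in ("pct_carbon", "pct_nitrogen"):
            v = getattr(self, name)
            if v is not None and not 0 < v < 100:
                raise ValueError(f"{name} must lie in (0, 100), got {v}")
        if self.size_year is not None and self.size_year not in (2013, 2014):
            raise ValueError(f"size_year must be 2013 or 2014, got {self.size_year}")

    @property
    def has_geometry(self) -> bool:
        return None not in (self.length_m, self.width_m, self.height_m)


@dataclass(frozen=True)
class MorphCounts:
    """Striped / unstriped / melanic tallies for one plant patch."""

    plant_id: str
    n_striped: int = 0
    n_unstriped: int = 0
    n_melanic: int = 0

    def __post_init__(self):
        for name in ("n_striped", "n_unstriped", "n_melanic"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")

    @property
    def total(self) -> int:
        return self.n_striped + self.n_unstriped + self.n_melanic


@dataclass(frozen=True)
class ArthropodIndividual:
    """One collected specimen with length and (measured or predicted) mass."""

    plant_id: str
    morphospecies_id: str
    length_mm: float
    wet_mass_mg: float | None = None
    mass_source: str = field(default="predicted")  # "measured" | "predicted"

    def __post_init__(self):
        if not self.length_mm > 0:
            raise ValueError(f"length_mm must be > 0, got {self.length_mm}")
        if self.wet_mass_mg is not None and not self.wet_mass_mg > 0:
            raise ValueError(f"wet_mass_mg must be > 0, got {self.wet_mass_mg}")
        if self.mass_source not in ("measured", "predicted"):
            raise ValueError(f"bad mass_source {self.mass_source!r}")


#: fixed column order of the per-plant summary table (see write_summary)
SUMMARY_COLUMNS = [
    "plant_id",
    "host",
    "timema_abundance",
    "arthropod_abundance_ge5",
    "richness_ge5",
    "maladaptation",
    "conn_timema",
    "conn_arthropod",
    "ln_volume",
    "cn_ratio",
    "mas_slope",
]


@dataclass(frozen=True)
class CommunitySummary:
    """Per-plant derived variables feeding the statistical model suites.

    ``maladaptation`` is missing (``None``) exactly when the plant holds no
    striped or unstriped *Timema*; ``mas_slope`` is missing when fewer than
    two biomass bins are occupied; ``ln_volume`` is missing when geometry is.
    """

    plant_id: str
    host: str
    timema_abundance: int
    arthropod_abundance_ge5: int
    richness_ge5: int
    maladaptation: float | None
    conn_timema: float
    conn_arthropod: float
    ln_volume: float | None
    cn_ratio: float | None
    mas_slope: float | None

    def __post_init__(self):
        for name in ("timema_abundance", "arthropod_abundance_ge5", "richness_ge5"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.maladaptation is not None and not 0 <= self.maladaptation <= 1:
            raise ValueError("maladaptation must lie in [0, 1]")


# ---------------------------------------------------------------------------
# readers


def _require_columns(df: pd.DataFrame, required: Sequence[str], table: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{table} table is missing column(s): {', '.join(missing)}")


def _opt_float(value, row: int, name: str) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise RowError(row, f"non-numeric value {value!r} in column {name}") from None


def read_plants(path: str | Path) -> list[PlantPatch]:
    """Read and validate the plant-patch table.

    Rows with missing geometry are kept (``has_geometry`` is False); rows
    with non-numeric coordinates or duplicate ids raise located errors.
    """
    df = pd.read_csv(path, dtype={"plant_id": str})
    _require_columns(df, ["plant_id", "host", "x", "y"], "plants")
    dup = df["plant_id"][df["plant_id"].duplicated()].unique()
    if len(dup):
        raise SchemaError(f"duplicate plant_id(s): {', '.join(map(str, dup))}")
    plants: list[PlantPatch] = []
    for i, rec in enumerate(df.to_dict("records"), start=1):
        x = _opt_float(rec.get("x"), i, "x")
        y = _opt_float(rec.get("y"), i, "y")
        if x is None or y is None:
            raise RowError(i, f"plant {rec['plant_id']}: missing coordinate")
        size_year = _opt_float(rec.get("size_year"), i, "size_year")
        try:
            plants.append(
                PlantPatch(
                    plant_id=str(rec["plant_id"]),
                    host=str(rec["host"]).strip(),
                    x=x,
                    y=y,
                    length_m=_opt_float(rec.get("length_m"), i, "length_m"),
                    width_m=_opt_float(rec.get("width_m"), i, "width_m"),
                    height_m=_opt_float(rec.get("height_m"), i, "height_m"),
                    size_year=int(size_year) if size_year is not None else None,
                    pct_carbon=_opt_float(rec.get("pct_carbon"), i, "pct_carbon"),
                    pct_nitrogen=_opt_float(rec.get("pct_nitrogen"), i, "pct_nitrogen"),
                )
            )
        except ValueError as e:
            raise RowError(i, str(e)) from None
    return plants


def read_arthropods(path: str | Path) -> list[ArthropodIndividual]:
    """Read the arthropod-individual table.

    ``mass_source`` is set to ``measured`` exactly when ``wet_mass_mg`` is
    present in the row, else ``predicted`` with mass left missing.
    """
    df = pd.read_csv(path, dtype={"plant_id": str, "morphospecies_id": str})
    _require_columns(df, ["plant_id", "morphospecies_id", "length_mm"], "arthropods")
    out: list[ArthropodIndividual] = []
    for i, rec in enumerate(df.to_dict("records"), start=1):
        length = _opt_float(rec.get("length_mm"), i, "length_mm")
        if length is None:
            raise RowError(i, "missing length_mm")
        mass = _opt_float(rec.get("wet_mass_mg"), i, "wet_mass_mg")
        try:
            out.append(
                ArthropodIndividual(
                    plant_id=str(rec["plant_id"]),
                    morphospecies_id=str(rec["morphospecies_id"]),
                    length_mm=length,
                    wet_mass_mg=mass,
                    mass_source="measured" if mass is not None else "predicted",
                )
            )
        except ValueError as e:
            raise RowError(i, str(e)) from None
    return out


def read_timema(path: str | Path) -> list[MorphCounts]:
    """Read per-plant morph tallies.

    Accepts either pre-tallied counts (columns ``n_striped``, ``n_unstriped``,
    ``n_melanic``) or one row per individual (column ``morph`` in
    {striped, unstriped, melanic}), which is tallied here.
    """
    df = pd.read_csv(path, dtype={"plant_id": str})
    if "morph" in df.columns:
        _require_columns(df, ["plant_id", "morph"], "timema")
        bad = set(df["morph"].unique()) - {"striped", "unstriped", "melanic"}
        if bad:
            raise SchemaError(f"unknown morph value(s): {', '.join(sorted(map(str, bad)))}")
        tallies = (
            df.groupby(["plant_id", "morph"]).size().unstack(fill_value=0)
        )
        out = []
        for pid, row in tallies.iterrows():
            out.append(
                MorphCounts(
                    plant_id=str(pid),
                    n_striped=int(row.get("striped", 0)),
                    n_unstriped=int(row.get("unstriped", 0)),
                    n_melanic=int(row.get("melanic", 0)),
                )
            )
        return out
    _require_columns(df, ["plant_id", "n_striped", "n_unstriped", "n_melanic"], "timema")
    out = []
    for i, rec in enumerate(df.to_dict("records"), start=1):
        try:
            out.append(
                MorphCounts(
                    plant_id=str(rec["plant_id"]),
                    n_striped=int(rec["n_striped"]),
                    n_unstriped=int(rec["n_unstriped"]),
                    n_melanic=int(rec["n_melanic"]),
                )
            )
        except (ValueError, TypeError) as e:
            raise RowError(i, str(e)) from None
    return out


# ---------------------------------------------------------------------------
# summary table round-trip


def summaries_to_frame(summaries: Iterable[CommunitySummary]) -> pd.DataFrame:
    rows = [{f.name: getattr(s, f.name) for f in fields(CommunitySummary)} for s in summaries]
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def write_summary(summaries: Sequence[CommunitySummary], path: str | Path) -> None:
    """Write the per-plant summary as CSV in the fixed column order.

    Missing values are written as empty fields (never ``0``), so the table
    round-trips losslessly through :func:`read_summary`.
    """
    summaries_to_frame(summaries).to_csv(path, index=False)


def read_summary(path: str | Path) -> list[CommunitySummary]:
    df = pd.read_csv(path, dtype={"plant_id": str})
    _require_columns(df, SUMMARY_COLUMNS, "summary")
    out = []
    for i, rec in enumerate(df.to_dict("records"), start=1):
        kw = {}
        for name in SUMMARY_COLUMNS:
            v = rec[name]
            if name in ("plant_id", "host"):
                kw[name] = str(v)
            elif name in ("timema_abundance", "arthropod_abundance_ge5", "richness_ge5"):
                kw[name] = int(v)
            else:
                kw[name] = _opt_float(v, i, name)
        try:
            out.append(CommunitySummary(**kw))
        except ValueError as e:
            raise RowError(i, str(e)) from None
    return out


def plants_to_frame(plants: Iterable[PlantPatch]) -> pd.DataFrame:
    rows = [{f.name: getattr(p, f.name) for f in fields(PlantPatch)} for p in plants]
    return pd.DataFrame(rows)
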