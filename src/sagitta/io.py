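"""CSV readers/writers, run configuration and the plain-text report.

All tabular interchange is RFC-4180 CSV (UTF-8, "." decimal).  Writers
prepend ``# key: value`` comment lines carrying provenance (parameters and
seeds); readers skip them, so write-then-read is lossless for the data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .electivity import CompositionTable
from .feeding import GutSurvey, Season, StationRecord, Zone

__all__ = [
    "RunConfig",
    "load_config",
    "read_table",
    "write_table",
    "read_metadata",
    "stations_to_frame",
    "read_station_table",
    "read_gut_table",
    "gut_surveys_by_station",
    "read_ctd_table",
    "ctd_profiles_by_station",
    "read_composition_table",
    "composition_pair",
    "build_report",
]

logger = logging.getLogger("sagitta")

STATION_COLUMNS = {
    "station_id": str,
    "season": str,
    "zone": str,
    "temp_c": float,
    "sal_psu": float,
    "chl_mg_m3": float,
    "bottom_depth_m": float,
    "dist_coast_km": float,
    "copepod_density_ind_m3": float,
    "chaetognath_density_ind_m3": float,
    "wind_speed_m_s": float,
}
STATION_REQUIRED = ("station_id", "season", "zone")
GUT_REQUIRED = ("predator_id", "station_id", "n_prey_in_gut")
CTD_REQUIRED = ("station_id", "depth_m", "temp_c")
COMPOSITION_COUNT_COLUMNS = ("taxon", "gut_count", "habitat_count")


@dataclass(frozen=True)
class RunConfig:
    """Model and statistics parameters for one pipeline run.

    Paths are optional; when given they must exist at load time.  Seeds are
    echoed into every output's metadata header so each artifact is a
    one-command reproduction.
    """

    stations_csv: Path | None = None
    guts_csv: Path | None = None
    ctd_csv: Path | None = None
    composition_csv: Path | None = None
    out_dir: Path = Path("sagitta_out")
    radius_m: float = 0.003
    prey_speed_m_s: float = 0.150
    predator_speed_m_s: float = 0.0
    w0_m_s: float = 0.0
    profile_mode: str = "exponential"
    decay_depth_m: float = 12.0
    dt_a_hours: float = 10.48
    dt_b_per_degc: float = 0.086
    integration_depth_m: float = 50.0
    n_perm: int = 9999
    n_sims: int = 10_000
    alpha: float = 0.05
    seed: int = 0
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("stations_csv", "guts_csv", "ctd_csv", "composition_csv"):
            p = getattr(self, name)
            if p is not None:
                p = Path(p)
                if not p.exists():
                    raise FileNotFoundError(f"{name}: {p} does not exist")
                object.__setattr__(self, name, p)
        object.__setattr__(self, "out_dir", Path(self.out_dir))


def load_config(path) -> RunConfig:
    """Load a YAML run configuration; unknown keys land in ``extras``."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a mapping")
    known = {k: v for k, v in raw.items() if k in RunConfig.__dataclass_fields__ and k != "extras"}
    extras = {k: v for k, v in raw.items() if k not in known}
    return RunConfig(**known, extras=extras)


def write_table(df: pd.DataFrame, path, metadata: dict | None = None) -> None:
    """Write a CSV with ``# key: value`` provenance header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table` (comment lines skipped)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, comment="#")
    if df.empty:
        raise ValueError(f"{path}: no data rows (empty input)")
    return df


def read_metadata(path) -> dict:
    """Provenance header of a CSV written by :func:`write_table`."""
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                k, v = line[1:].split(":", 1)
                meta[k.strip()] = v.strip()
    return meta


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def _numeric(df: pd.DataFrame, col: str, path) -> pd.Series:
    try:
        return pd.to_numeric(df[col])
    except (ValueError, TypeError):
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
        row = int(bad[0]) + 2 if len(bad) else "?"
        raise ValueError(f"{path}: non-numeric value in column {col!r} (file row {row})") from None


def stations_to_frame(stations) -> pd.DataFrame:
    """StationRecord list -> tidy DataFrame with the canonical columns."""
    return pd.DataFrame(
        {
            "station_id": [s.station_id for s in stations],
            "season": [s.season.value for s in stations],
            "zone": [s.zone.value for s in stations],
            "temp_c": [s.temperature for s in stations],
            "sal_psu": [s.salinity for s in stations],
            "chl_mg_m3": [s.chlorophyll for s in stations],
            "bottom_depth_m": [s.bottom_depth for s in stations],
            "dist_coast_km": [s.dist_coast for s in stations],
            "copepod_density_ind_m3": [s.copepod_density for s in stations],
            "chaetognath_density_ind_m3": [s.chaetognath_density for s in stations],
            "wind_speed_m_s": [s.wind_speed for s in stations],
        }
    )


def read_station_table(path) -> list[StationRecord]:
    """Validated station records from CSV.

    Requires station_id, season, zone; numeric columns are optional and may
    be blank.  Unknown season/zone values are rejected with the offending
    file row.
    """
    df = read_table(path).reset_index(drop=True)
    _require_columns(df, STATION_REQUIRED, path)
    numeric = {
        col: _numeric(df, col, path)
        for col in STATION_COLUMNS
        if col in df.columns and STATION_COLUMNS[col] is float
    }
    records = []
    for idx, row in df.iterrows():
        try:
            season = Season.parse(row["season"])
            zone = Zone.parse(row["zone"])
        except ValueError as exc:
            raise ValueError(f"{path}: row {int(idx) + 2}: {exc}") from None

        def opt(col):
            if col not in numeric:
                return None
            v = numeric[col].iloc[idx]
            return None if pd.isna(v) else float(v)

        records.append(
            StationRecord(
                station_id=str(row["station_id"]),
                season=season,
                zone=zone,
                temperature=opt("temp_c"),
                salinity=opt("sal_psu"),
                chlorophyll=opt("chl_mg_m3"),
                bottom_depth=opt("bottom_depth_m"),
                dist_coast=opt("dist_coast_km"),
                copepod_density=opt("copepod_density_ind_m3"),
                chaetognath_density=opt("chaetognath_density_ind_m3"),
                wind_speed=opt("wind_speed_m_s"),
            )
        )
    return records


def read_gut_table(path) -> pd.DataFrame:
    """Per-predator gut-content rows; excludes near-mouth-flagged prey rows
    upstream (the flag column is kept but counts with flag 1 are dropped with
    a log message)."""
    df = read_table(path)
    _require_columns(df, GUT_REQUIRED, path)
    df["n_prey_in_gut"] = _numeric(df, "n_prey_in_gut", path)
    if (df["n_prey_in_gut"] < 0).any():
        raise ValueError(f"{path}: negative gut counts")
    if "near_mouth_excluded" in df.columns:
        flagged = df["near_mouth_excluded"].astype(bool)
        if flagged.any():
            logger.info("dropping %d near-mouth-flagged predator rows", int(flagged.sum()))
            df = df.loc[~flagged].reset_index(drop=True)
    return df


def gut_surveys_by_station(guts: pd.DataFrame) -> dict[str, GutSurvey]:
    return {
        sid: GutSurvey(counts=grp["n_prey_in_gut"].to_numpy())
        for sid, grp in guts.groupby("station_id")
    }


def read_ctd_table(path) -> pd.DataFrame:
    df = read_table(path)
    _require_columns(df, CTD_REQUIRED, path)
    for col in df.columns:
        if col != "station_id":
            df[col] = _numeric(df, col, path)
    return df


def ctd_profiles_by_station(ctd: pd.DataFrame) -> dict[str, pd.DataFrame]:
    return {
        sid: grp.sort_values("depth_m").reset_index(drop=True)
        for sid, grp in ctd.groupby("station_id")
    }


def read_composition_table(path) -> pd.DataFrame:
    """Gut/habitat prey composition: either integer counts (taxon, gut_count,
    habitat_count) or printed percentages (taxon, gut_pct, habitat_pct plus
    gut_total, habitat_total), optionally per season."""
    df = read_table(path)
    if all(c in df.columns for c in COMPOSITION_COUNT_COLUMNS):
        return df
    pct_cols = ("taxon", "gut_pct", "habitat_pct", "gut_total", "habitat_total")
    if all(c in df.columns for c in pct_cols):
        return df
    raise ValueError(
        f"{path}: expected columns {COMPOSITION_COUNT_COLUMNS} or {pct_cols} "
        f"(got {list(df.columns)})"
    )


def composition_pair(block: pd.DataFrame) -> tuple[CompositionTable, CompositionTable]:
    """One composition block (single season) -> (gut, habitat) count tables.

    Percentage blocks are reconstructed to integer counts via the known
    totals; taxa absent from a compartment simply carry a zero count.
    """
    if "gut_count" in block.columns:
        gut = {r.taxon: int(r.gut_count) for r in block.itertuples() if r.gut_count > 0}
        hab = {r.taxon: int(r.habitat_count) for r in block.itertuples() if r.habitat_count > 0}
        return CompositionTable.from_counts(gut), CompositionTable.from_counts(hab)
    gut_total = int(block["gut_total"].iloc[0])
    hab_total = int(block["habitat_total"].iloc[0])
    gut_pct = {r.taxon: float(r.gut_pct) for r in block.itertuples() if r.gut_pct > 0}
    hab_pct = {r.taxon: float(r.habitat_pct) for r in block.itertuples() if r.habitat_pct > 0}
    return (
        CompositionTable.from_percentages(gut_pct, gut_total),
        CompositionTable.from_percentages(hab_pct, hab_total),
    )


# ---------------------------------------------------------------------------
# report

_REPORT_SECTIONS = (
    ("Stations", "stations.csv"),
    ("Encounter rates", "encounters.csv"),
    ("Feeding rates", "feeding.csv"),
    ("Feeding summary (season x zone)", "feeding_summary.csv"),
    ("Prey electivity", "electivity.csv"),
    ("PERMANOVA", "permanova.csv"),
    ("BIOENV", "bioenv.csv"),
)


def _fmt(df: pd.DataFrame) -> str:
    with pd.option_context("display.width", 200, "display.max_columns", 50,
                           "display.float_format", lambda v: f"{v:.4g}"):
        return df.to_string(index=False)


def build_report(out_dir) -> str:
    """Human-readable markdown summary of a run directory.

    Every number is re-read from the CSV artifacts (with their provenance
    headers echoed), so regenerating the report from the same directory is
    byte-identical; missing artifacts render as SKIPPED sections.
    """
    out_dir = Path(out_dir)
    lines = ["# Chaetognath-copepod interaction report", ""]
    for title, fname in _REPORT_SECTIONS:
        path = out_dir / fname
        lines.append(f"## {title}")
        lines.append("")
        if not path.exists():
            lines.append("SKIPPED (no artifact)")
            lines.append("")
            continue
        meta = read_metadata(path)
        if meta:
            lines.extend(f"- {k}: {v}" for k, v in sorted(meta.items()))
            lines.append("")
        df = pd.read_csv(path, comment="#")
        lines.append("```")
        lines.append(_fmt(df))
        lines.append("```")
        lines.append("")
    return "\n".join(lines)
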