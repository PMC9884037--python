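"""Tabular input/output, schema validation and pipeline configuration.

All files are comma-separated text with a header row.  Timestamps are naive
local time in ISO 8601 minute precision (``YYYY-MM-DDTHH:MM``); dates are
``YYYY-MM-DD``.  Operation-log date intervals are inclusive on both ends
("the camera ran on that day").
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

log = logging.getLogger(__name__)

TIMESTAMP_FMT = "%Y-%m-%dT%H:%M"
DATE_FMT = "%Y-%m-%d"

GUILDS = ("carnivore", "herbivore", "omnivore")


class ValidationError(ValueError):
    """Raised when an input table violates its schema."""


@dataclass(frozen=True)
class DetectionRecord:
    """One timestamped species observation (image sequence row) at a station."""

    station_id: str
    species: str
    timestamp: dt.datetime
    n_individuals: int = 1

    def __post_init__(self) -> None:
        if not self.station_id:
            raise ValidationError("station_id must be non-empty")
        if not self.species:
            raise ValidationError("species must be non-empty")
        if self.n_individuals < 0:
            raise ValidationError("n_individuals must be >= 0")


@dataclass
class StationOperationLog:
    """Closed date intervals of camera operation per station.

    Intervals are normalised on construction: sorted, and overlapping or
    adjacent intervals merged, so that per-station intervals are disjoint.
    """

    intervals: dict[str, list[tuple[dt.date, dt.date]]]

    def __post_init__(self) -> None:
        for sid, ivals in self.intervals.items():
            for start, end in ivals:
                if end < start:
                    raise ValidationError(
                        f"station {sid!r}: interval end {end} before start {start}"
                    )
            self.intervals[sid] = _merge_intervals(ivals)

    @property
    def station_ids(self) -> list[str]:
        return list(self.intervals)

    def is_operational(self, station_id: str, day: dt.date) -> bool:
        """A day counts as operational if the log covers any part of it."""
        return any(
            start <= day <= end for start, end in self.intervals.get(station_id, [])
        )


def _merge_intervals(
    ivals: Iterable[tuple[dt.date, dt.date]]
) -> list[tuple[dt.date, dt.date]]:
    merged: list[tuple[dt.date, dt.date]] = []
    for start, end in sorted(ivals):
        if merged and start <= merged[-1][1] + dt.timedelta(days=1):
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


@dataclass
class CovariateTable:
    """Per-station covariates with declared types.

    ``type_map`` assigns each column one of ``continuous``, ``categorical``
    or ``binary``.  Missing values are a hard error: covariates are recorded
    exhaustively at every station, so a gap signals a data problem rather
    than something to impute.
    """

    data: pd.DataFrame  # indexed by station_id
    type_map: dict[str, str]

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise ValidationError(f"duplicate station rows: {dupes}")
        unknown = set(self.type_map) - set(self.data.columns)
        if unknown:
            raise ValidationError(f"type_map names absent columns: {sorted(unknown)}")
        untyped = set(self.data.columns) - set(self.type_map)
        if untyped:
            raise ValidationError(f"columns without a declared type: {sorted(untyped)}")
        bad = {t for t in self.type_map.values()} - {"continuous", "categorical", "binary"}
        if bad:
            raise ValidationError(f"unknown covariate types: {sorted(bad)}")
        if self.data.isna().any().any():
            cols = self.data.columns[self.data.isna().any()].tolist()
            raise ValidationError(f"missing covariate values in columns: {cols}")

    @property
    def station_ids(self) -> list[str]:
        return list(self.data.index)

    def subset(self, station_ids: Sequence[str]) -> "CovariateTable":
        missing = set(station_ids) - set(self.data.index)
        if missing:
            raise ValidationError(f"stations absent from covariate table: {sorted(missing)}")
        return CovariateTable(self.data.loc[list(station_ids)].copy(), dict(self.type_map))


@dataclass(frozen=True)
class SpeciesTraits:
    """Mean adult body mass and trophic guild for one species.

    The analysis is restricted to terrestrial mammals above 0.5 kg, so a
    mass at or below that bound is rejected.
    """

    species: str
    body_mass_kg: float
    guild: str

    def __post_init__(self) -> None:
        if self.body_mass_kg <= 0.5:
            raise ValidationError(
                f"{self.species}: body mass must exceed 0.5 kg, got {self.body_mass_kg}"
            )
        if self.guild not in GUILDS:
            raise ValidationError(f"{self.species}: unknown guild {self.guild!r}")


@dataclass
class PipelineConfig:
    """Key/value configuration for the whole pipeline (read from YAML)."""

    survey_start: dt.date
    survey_end: dt.date
    event_interval_minutes: int = 60
    occasion_lengths: tuple[int, ...] = (5, 6, 7, 8, 9, 10, 11)
    operational_fraction: float = 0.80
    vif_threshold: float = 3.0
    n_bootstrap: int = 1000
    max_model_terms: int = 4
    species_list: tuple[str, ...] = ()
    species_blocklist: tuple[str, ...] = ()
    covariate_types: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.survey_end < self.survey_start:
            raise ValidationError("survey_end before survey_start")
        if self.event_interval_minutes < 1:
            raise ValidationError("event_interval_minutes must be >= 1")
        if not 0 < self.operational_fraction <= 1:
            raise ValidationError("operational_fraction must be in (0, 1]")

    @property
    def survey_window(self) -> tuple[dt.date, dt.date]:
        return (self.survey_start, self.survey_end)

    @property
    def survey_days(self) -> int:
        return (self.survey_end - self.survey_start).days + 1


def read_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for key in ("survey_start", "survey_end"):
        if key not in raw:
            raise ValidationError(f"config missing required key {key!r}")
        if not isinstance(raw[key], dt.date):
            raw[key] = dt.datetime.strptime(str(raw[key]), DATE_FMT).date()
    for key in ("occasion_lengths", "species_list", "species_blocklist"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return PipelineConfig(**raw)


def write_config(cfg: PipelineConfig, path: str | Path) -> None:
    raw = {
        "survey_start": cfg.survey_start.isoformat(),
        "survey_end": cfg.survey_end.isoformat(),
        "event_interval_minutes": cfg.event_interval_minutes,
        "occasion_lengths": list(cfg.occasion_lengths),
        "operational_fraction": cfg.operational_fraction,
        "vif_threshold": cfg.vif_threshold,
        "n_bootstrap": cfg.n_bootstrap,
        "max_model_terms": cfg.max_model_terms,
        "species_list": list(cfg.species_list),
        "species_blocklist": list(cfg.species_blocklist),
        "covariate_types": dict(cfg.covariate_types),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


def normalise_species(name: str) -> str:
    """Species names match case-insensitively after trimming."""
    return " ".join(name.strip().lower().split())


# ---------------------------------------------------------------------------
# detection records


def read_records(
    path: str | Path,
    log_: StationOperationLog | None = None,
    window: tuple[dt.date, dt.date] | None = None,
) -> list[DetectionRecord]:
    """Read detection records, validating each row.

    If an operation log is supplied, stations absent from it are rejected.
    If a survey window is supplied, timestamps outside it are rejected.
    """
    df = pd.read_csv(path, dtype=str)
    required = {"station_id", "species", "timestamp", "n_individuals"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"{path}: header must declare {sorted(required)}, got {list(df.columns)}"
        )
    records: list[DetectionRecord] = []
    known = set(log_.station_ids) if log_ is not None else None
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        try:
            ts = dt.datetime.strptime(row.timestamp, TIMESTAMP_FMT)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"{path} row {i}: bad timestamp {row.timestamp!r}") from exc
        if known is not None and row.station_id not in known:
            raise ValidationError(
                f"{path} row {i}: station {row.station_id!r} absent from operation log"
            )
        if window is not None and not (window[0] <= ts.date() <= window[1]):
            raise ValidationError(
                f"{path} row {i}: timestamp {row.timestamp} outside survey window"
            )
        records.append(
            DetectionRecord(
                station_id=row.station_id,
                species=normalise_species(row.species),
                timestamp=ts,
                n_individuals=int(row.n_individuals),
            )
        )
    return records


def write_records(records: Sequence[DetectionRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "station_id": [r.station_id for r in records],
            "species": [r.species for r in records],
            "timestamp": [r.timestamp.strftime(TIMESTAMP_FMT) for r in records],
            "n_individuals": [r.n_individuals for r in records],
        }
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# operation log


def read_operation_log(path: str | Path) -> StationOperationLog:
    df = pd.read_csv(path, dtype=str)
    required = {"station_id", "start_date", "end_date"}
    if not required.issubset(df.columns):
        raise ValidationError(f"{path}: header must declare {sorted(required)}")
    intervals: dict[str, list[tuple[dt.date, dt.date]]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            start = dt.datetime.strptime(row.start_date, DATE_FMT).date()
            end = dt.datetime.strptime(row.end_date, DATE_FMT).date()
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"{path} row {i}: bad date") from exc
        intervals.setdefault(row.station_id, []).append((start, end))
    return StationOperationLog(intervals)


def write_operation_log(log_: StationOperationLog, path: str | Path) -> None:
    rows = [
        {"station_id": sid, "start_date": s.isoformat(), "end_date": e.isoformat()}
        for sid, ivals in log_.intervals.items()
        for s, e in ivals
    ]
    pd.DataFrame(rows, columns=["station_id", "start_date", "end_date"]).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# covariates and traits


def read_covariates(path: str | Path, type_map: Mapping[str, str]) -> CovariateTable:
    df = pd.read_csv(path)
    if "station_id" not in df.columns:
        raise ValidationError(f"{path}: missing station_id column")
    df["station_id"] = df["station_id"].astype(str)
    df = df.set_index("station_id")
    for col, typ in type_map.items():
        if typ in ("continuous", "binary") and col in df.columns:
            df[col] = pd.to_numeric(df[col])
    return CovariateTable(df, dict(type_map))


def write_covariates(covs: CovariateTable, path: str | Path) -> None:
    covs.data.rename_axis("station_id").reset_index().to_csv(path, index=False)


def read_traits(path: str | Path) -> dict[str, SpeciesTraits]:
    df = pd.read_csv(path)
    required = {"species", "body_mass_kg", "guild"}
    if not required.issubset(df.columns):
        raise ValidationError(f"{path}: header must declare {sorted(required)}")
    out: dict[str, SpeciesTraits] = {}
    for row in df.itertuples(index=False):
        sp = normalise_species(str(row.species))
        out[sp] = SpeciesTraits(sp, float(row.body_mass_kg), str(row.guild))
    return out


def write_traits(traits: Mapping[str, SpeciesTraits], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"species": t.species, "body_mass_kg": t.body_mass_kg, "guild": t.guild}
            for t in traits.values()
        ]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# effort


def effort_days(
    log_: StationOperationLog, window: tuple[dt.date, dt.date]
) -> pd.Series:
    """Operational camera-trap days per station within a survey window.

    Returns a Series indexed by station_id; ``.sum()`` gives the total
    effort.  Both interval and window bounds are inclusive.
    """
    start_w, end_w = window
    if end_w < start_w:
        raise ValidationError("window end before start")
    if not log_.intervals:
        log.warning("empty operation log: total effort is 0")
    days: dict[str, int] = {}
    for sid, ivals in log_.intervals.items():
        n = 0
        for s, e in ivals:
            lo, hi = max(s, start_w), min(e, end_w)
            if lo <= hi:
                n += (hi - lo).days + 1
        days[sid] = n
    return pd.Series(days, dtype=int, name="effort_days")
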