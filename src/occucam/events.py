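"""Independent-event extraction and relative abundance indices (RAI).

An *event* is an image sequence of one species at one station separated
from the previous sequence of that species by at least the independence
interval (60 minutes by default).  The gap is measured from the most recent
image of the ongoing sequence, the standard camera-trap convention; a gap
exactly equal to the interval opens a new event.  RAI is events per 100
operational camera-trap days.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .data_io import DetectionRecord, ValidationError


@dataclass(frozen=True)
class Event:
    station_id: str
    species: str
    start_time: dt.datetime
    end_time: dt.datetime
    n_images: int
    max_individuals: int = 1

    def __post_init__(self) -> None:
        if self.end_time < self.start_time:
            raise ValidationError("event end_time before start_time")
        if self.n_images < 1:
            raise ValidationError("event must contain at least one image")


def deduplicate_events(
    records: Sequence[DetectionRecord], interval_minutes: int = 60
) -> list[Event]:
    """Collapse raw records into independent events.

    Records are processed per (station, species) in time order; a new event
    starts when the gap from the previous retained image is >= the interval.
    Streams at different stations never merge.  Duplicate timestamps fall
    into the ongoing event.
    """
    if interval_minutes < 1:
        raise ValidationError("interval_minutes must be >= 1")
    gap = dt.timedelta(minutes=interval_minutes)
    by_stream: dict[tuple[str, str], list[DetectionRecord]] = {}
    for r in records:
        by_stream.setdefault((r.station_id, r.species), []).append(r)

    events: list[Event] = []
    for (sid, sp), recs in sorted(by_stream.items()):
        recs = sorted(recs, key=lambda r: r.timestamp)
        current: list[DetectionRecord] = []
        for r in recs:
            if current and r.timestamp - current[-1].timestamp >= gap:
                events.append(_close(sid, sp, current))
                current = []
            current.append(r)
        if current:
            events.append(_close(sid, sp, current))
    return events


def _close(sid: str, sp: str, imgs: list[DetectionRecord]) -> Event:
    return Event(
        station_id=sid,
        species=sp,
        start_time=imgs[0].timestamp,
        end_time=imgs[-1].timestamp,
        n_images=len(imgs),
        max_individuals=max(r.n_individuals for r in imgs),
    )


def compute_rai(events: Sequence[Event], effort: pd.Series) -> pd.DataFrame:
    """Per-(species, station) and global event counts, effort and RAI.

    ``effort`` is operational trap-days per station.  The returned frame has
    columns (station, species, events, effort_days, rai); the global row per
    species uses station_id ``__all__`` with effort equal to total effort.
    RAI counts events, not individuals.
    """
    counts: dict[tuple[str, str], int] = {}
    for ev in events:
        if ev.station_id not in effort.index:
            raise ValidationError(f"event at station {ev.station_id!r} not in effort table")
        if effort[ev.station_id] == 0:
            raise ValidationError(
                f"station {ev.station_id!r} has zero effort but recorded events"
            )
        counts[(ev.station_id, ev.species)] = counts.get((ev.station_id, ev.species), 0) + 1

    species = sorted({sp for _, sp in counts})
    rows = []
    for sid in effort.index:
        for sp in species:
            n = counts.get((sid, sp), 0)
            eff = int(effort[sid])
            rai = 100.0 * n / eff if eff > 0 else float("nan")
            rows.append((sid, sp, n, eff, rai))
    total_eff = int(effort.sum())
    for sp in species:
        n = sum(v for (sid, s), v in counts.items() if s == sp)
        rai = 100.0 * n / total_eff if total_eff > 0 else float("nan")
        rows.append(("__all__", sp, n, total_eff, rai))
    return pd.DataFrame(rows, columns=["station_id", "species", "events", "effort_days", "rai"])


def global_rai(rai_table: pd.DataFrame) -> pd.Series:
    """Global per-species RAI values (events per 100 trap-days)."""
    glob = rai_table[rai_table["station_id"] == "__all__"]
    return glob.set_index("species")["rai"]


def station_rai_matrix(rai_table: pd.DataFrame) -> pd.DataFrame:
    """Species x station RAI matrix (global row excluded)."""
    per = rai_table[rai_table["station_id"] != "__all__"]
    return per.pivot(index="species", columns="station_id", values="rai")


def write_events(events: Sequence[Event], path) -> None:
    pd.DataFrame(
        {
            "station_id": [e.station_id for e in events],
            "species": [e.species for e in events],
            "start_time": [e.start_time.strftime("%Y-%m-%dT%H:%M") for e in events],
            "end_time": [e.end_time.strftime("%Y-%m-%dT%H:%M") for e in events],
            "n_images": [e.n_images for e in events],
            "max_individuals": [e.max_individuals for e in events],
        }
    ).to_csv(path, index=False)


def write_rai(rai_table: pd.DataFrame, path) -> None:
    out = rai_table.copy()
    out["rai"] = out["rai"].round(2)
    out.to_csv(path, index=False)
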