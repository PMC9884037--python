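"""Detection-history construction: daily matrices, occasion collapsing and
the station operationality filter.

A detection history is a site x occasion matrix over {0, 1, missing}: 1 if
the species was detected at least once during the occasion (at most one
detection is scored per 24-h period), 0 if the camera was operational but
recorded nothing, missing (NaN) if the camera was not operational at any
point of the occasion.  Occasion blocks are anchored at the survey start
date and the final partial block is kept as a shorter occasion.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import StationOperationLog, ValidationError
from .events import Event


@dataclass
class DetectionHistory:
    matrix: np.ndarray  # sites x occasions, values 0.0 / 1.0 / nan
    site_ids: list[str]
    occasion_length: int
    survey_window: tuple[dt.date, dt.date]

    def __post_init__(self) -> None:
        vals = self.matrix[~np.isnan(self.matrix)]
        if not np.isin(vals, (0.0, 1.0)).all():
            raise ValidationError("history entries must be 0, 1 or missing")
        if self.matrix.shape[0] != len(self.site_ids):
            raise ValidationError("site_ids length does not match matrix")

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.matrix.shape[1]

    @property
    def survey_days(self) -> int:
        return (self.survey_window[1] - self.survey_window[0]).days + 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix,
            index=pd.Index(self.site_ids, name="station_id"),
            columns=[f"occ{i + 1}" for i in range(self.n_occasions)],
        )


def daily_history(
    events: Sequence[Event],
    log_: StationOperationLog,
    species: str,
    window: tuple[dt.date, dt.date],
) -> DetectionHistory:
    """Daily detection/non-detection matrix for one species.

    Sites are the stations in the operation log.  An event on a day the log
    marks non-operational is a consistency error (record/log mismatch).
    """
    start, end = window
    if end < start:
        raise ValidationError("window end before start")
    n_days = (end - start).days + 1
    sites = list(log_.station_ids)
    site_index = {sid: i for i, sid in enumerate(sites)}

    mat = np.full((len(sites), n_days), np.nan)
    for i, sid in enumerate(sites):
        for s, e in log_.intervals[sid]:
            lo = max((s - start).days, 0)
            hi = min((e - start).days, n_days - 1)
            if lo <= hi:
                mat[i, lo : hi + 1] = 0.0

    for ev in events:
        if ev.species != species:
            continue
        if ev.station_id not in site_index:
            raise ValidationError(f"event at unknown station {ev.station_id!r}")
        day = (ev.start_time.date() - start).days
        if day < 0 or day >= n_days:
            raise ValidationError(
                f"event at {ev.station_id!r} on {ev.start_time.date()} outside window"
            )
        i = site_index[ev.station_id]
        if np.isnan(mat[i, day]):
            raise ValidationError(
                f"event at {ev.station_id!r} on {ev.start_time.date()} "
                "but station not operational that day"
            )
        mat[i, day] = 1.0

    return DetectionHistory(mat, sites, 1, window)


def collapse_occasions(daily: DetectionHistory, k: int) -> DetectionHistory:
    """Merge consecutive days into k-day sampling occasions.

    An occasion scores 1 if any constituent day scored 1, 0 if at least one
    day was operational with no detection, and missing if the camera was
    down for the whole block.
    """
    if daily.occasion_length != 1:
        raise ValidationError("collapse_occasions expects a daily history")
    if k < 1 or k > daily.survey_days:
        raise ValidationError(f"occasion length {k} outside [1, {daily.survey_days}]")
    n_occ = math.ceil(daily.n_occasions / k)
    out = np.full((daily.n_sites, n_occ), np.nan)
    for j in range(n_occ):
        block = daily.matrix[:, j * k : (j + 1) * k]
        any_obs = ~np.all(np.isnan(block), axis=1)
        detected = np.nansum(np.where(np.isnan(block), 0, block), axis=1) > 0
        out[any_obs, j] = 0.0
        out[detected & any_obs, j] = 1.0
    return DetectionHistory(out, list(daily.site_ids), k, daily.survey_window)


def filter_stations(
    h: DetectionHistory, min_operational_fraction: float = 0.80
) -> tuple[DetectionHistory, list[str]]:
    """Drop sites operational for fewer than the required fraction of occasions.

    The fraction is computed on the supplied (typically collapsed) history.
    Returns the filtered history and the list of excluded site ids.
    """
    if not 0 < min_operational_fraction <= 1:
        raise ValidationError("min_operational_fraction must be in (0, 1]")
    frac = 1.0 - np.isnan(h.matrix).mean(axis=1)
    keep = frac >= min_operational_fraction
    excluded = [sid for sid, k in zip(h.site_ids, keep) if not k]
    if not keep.any():
        raise ValidationError("all sites excluded by operationality filter")
    return (
        DetectionHistory(
            h.matrix[keep], [s for s, k in zip(h.site_ids, keep) if k],
            h.occasion_length, h.survey_window,
        ),
        excluded,
    )


def write_history(h: DetectionHistory, path) -> None:
    df = h.to_frame()
    df.to_csv(path, na_rep="NA")


def read_history(
    path, occasion_length: int, survey_window: tuple[dt.date, dt.date]
) -> DetectionHistory:
    df = pd.read_csv(path, index_col=0, na_values=["NA"])
    return DetectionHistory(
        df.to_numpy(dtype=float), [str(s) for s in df.index], occasion_length, survey_window
    )
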