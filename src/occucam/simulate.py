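"""Synthetic camera-trap surveys with known generating parameters.

The generator emulates the structure of a two-region leopard/prey survey:
stations carrying mixed continuous/categorical/binary covariates, species
whose occupancy and daily detection follow logit-linear models on those
covariates, within-day image timestamps (bursts that exercise the 60-minute
independence rule) and random mid-survey station failures.  Defaults mirror
the study design the pipeline targets: one region with 73 stations over 151
days and one with 64 stations over 132 days, with about 1 and 3 station
failures respectively.

Coefficients apply to internally standardised covariates (continuous
columns z-scored across stations, binaries as 0/1, categoricals dummy-coded
against their first level), so generating slopes live on the same scale as
the fitted ones.
"""

from __future__ import annotations

import datetime as dt
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .data_io import (
    CovariateTable,
    DetectionRecord,
    SpeciesTraits,
    StationOperationLog,
    ValidationError,
)

# covariate specification: ("continuous", mean, sd) | ("binary", p) |
# ("categorical", {level: prob})
DEFAULT_COVARIATES: dict[str, tuple] = {
    "altitude": ("continuous", 650.0, 250.0),
    "vegetation_type": ("categorical", {"fynbos": 0.5, "karoo": 0.3, "renosterveld": 0.2}),
    "vegetation_age_yr": ("continuous", 8.0, 4.0),
    "water_dist_km": ("continuous", 1.2, 0.8),
    "water_source": ("categorical", {"permanent": 0.4, "seasonal": 0.4, "none": 0.2}),
    "road_dist_km": ("continuous", 2.0, 1.5),
    "habitation_dist_km": ("continuous", 4.0, 2.5),
    "disturbance": ("binary", 0.3),
    "livestock": ("binary", 0.25),
    "hunting": ("binary", 0.15),
}


@dataclass
class SpeciesParams:
    """Generating parameters for one species.

    ``beta_psi`` and ``beta_p`` map covariate names to logit-scale slopes;
    the ``"(intercept)"`` entry is required.  ``p`` is the daily detection
    probability model.  ``extra_images_rate`` is the Poisson mean of extra
    images beyond the first on a detection day, placed inside a two-hour
    burst window so both sub-hour and super-hour gaps occur.
    """

    beta_psi: dict[str, float]
    beta_p: dict[str, float]
    extra_images_rate: float = 1.5
    body_mass_kg: float = 5.0
    guild: str = "herbivore"

    def __post_init__(self) -> None:
        for name, b in (("beta_psi", self.beta_psi), ("beta_p", self.beta_p)):
            if "(intercept)" not in b:
                raise ValidationError(f"{name} must contain an '(intercept)' entry")


@dataclass
class SyntheticSpec:
    """Full description of one synthetic survey."""

    n_stations: int = 73
    survey_days: int = 151
    survey_start: dt.date = dt.date(2017, 11, 1)
    covariates: dict[str, tuple] = field(default_factory=lambda: dict(DEFAULT_COVARIATES))
    species_params: dict[str, SpeciesParams] = field(default_factory=dict)
    failure_rate: float = 1.0 / 73.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_stations < 1 or self.survey_days < 1:
            raise ValidationError("n_stations and survey_days must be >= 1")
        if not 0 <= self.failure_rate <= 1:
            raise ValidationError("failure_rate must lie in [0, 1]")

    @property
    def survey_end(self) -> dt.date:
        return self.survey_start + dt.timedelta(days=self.survey_days - 1)

    @property
    def survey_window(self) -> tuple[dt.date, dt.date]:
        return (self.survey_start, self.survey_end)


def region_spec(region: str = "protected", seed: int = 0, **overrides) -> SyntheticSpec:
    """Survey specs mirroring the two study regions.

    ``"protected"``: 73 stations, 151 days, ~1 failure (a mostly protected
    mountain reserve); ``"farmland"``: 64 stations, 132 days, ~3 failures
    (an agriculturally transformed landscape).
    """
    presets = {
        "protected": dict(n_stations=73, survey_days=151, failure_rate=1 / 73,
                          survey_start=dt.date(2017, 11, 1)),
        "farmland": dict(n_stations=64, survey_days=132, failure_rate=3 / 64,
                         survey_start=dt.date(2019, 11, 1)),
    }
    if region not in presets:
        raise ValidationError(f"unknown region preset {region!r}")
    kwargs = {**presets[region], "seed": seed, **overrides}
    return SyntheticSpec(**kwargs)


# ---------------------------------------------------------------------------
# landscape


def generate_landscape(spec: SyntheticSpec) -> tuple[CovariateTable, StationOperationLog]:
    """Draw station covariates and operation intervals.

    Each station fails mid-survey with probability ``failure_rate``; a
    failed station operates from the survey start to a uniformly drawn day
    strictly before the end.
    """
    rng = np.random.default_rng(spec.seed)
    ids = [f"ST{i + 1:03d}" for i in range(spec.n_stations)]

    cols: dict[str, object] = {}
    type_map: dict[str, str] = {}
    for name, cov in spec.covariates.items():
        kind = cov[0]
        if kind == "continuous":
            _, mu, sd = cov
            if sd <= 0:
                raise ValidationError(f"covariate {name!r}: sd must be > 0")
            cols[name] = rng.normal(mu, sd, size=spec.n_stations)
            type_map[name] = "continuous"
        elif kind == "binary":
            _, p = cov
            if not 0 <= p <= 1:
                raise ValidationError(f"covariate {name!r}: probability outside [0, 1]")
            cols[name] = (rng.random(spec.n_stations) < p).astype(int)
            type_map[name] = "binary"
        elif kind == "categorical":
            _, level_probs = cov
            levels = list(level_probs)
            probs = np.array([level_probs[lv] for lv in levels], dtype=float)
            if abs(probs.sum() - 1.0) > 1e-9 or (probs < 0).any():
                raise ValidationError(f"covariate {name!r}: level probabilities must sum to 1")
            cols[name] = rng.choice(levels, size=spec.n_stations, p=probs)
            type_map[name] = "categorical"
        else:
            raise ValidationError(f"covariate {name!r}: unknown kind {kind!r}")

    covs = CovariateTable(pd.DataFrame(cols, index=pd.Index(ids, name="station_id")),
                          type_map)

    intervals: dict[str, list[tuple[dt.date, dt.date]]] = {}
    fails = rng.random(spec.n_stations) < spec.failure_rate
    for sid, failed in zip(ids, fails):
        if failed and spec.survey_days > 1:
            last = int(rng.integers(1, spec.survey_days))  # fails before the end
            end = spec.survey_start + dt.timedelta(days=last - 1)
        else:
            end = spec.survey_end
        intervals[sid] = [(spec.survey_start, end)]
    return covs, StationOperationLog(intervals)


def standardised_design(covs: CovariateTable) -> pd.DataFrame:
    """Internal design used by the generator: z-scored continuous columns,
    0/1 binaries and first-level-reference dummies for categoricals."""
    cols: dict[str, np.ndarray] = {}
    df = covs.data
    for name in df.columns:
        typ = covs.type_map[name]
        if typ == "continuous":
            x = df[name].to_numpy(dtype=float)
            sd = x.std(ddof=0)
            cols[name] = (x - x.mean()) / (sd if sd > 0 else 1.0)
        elif typ == "binary":
            cols[name] = df[name].to_numpy(dtype=float)
        else:
            levels = sorted(df[name].astype(str).unique())
            for lev in levels[1:]:
                cols[f"{name}[{lev}]"] = (df[name].astype(str) == lev).to_numpy(dtype=float)
    return pd.DataFrame(cols, index=df.index)


def _linear(design: pd.DataFrame, beta: Mapping[str, float]) -> np.ndarray:
    eta = np.full(len(design), beta["(intercept)"], dtype=float)
    for name, b in beta.items():
        if name == "(intercept)":
            continue
        if name not in design.columns:
            raise ValidationError(f"coefficient on unknown covariate {name!r}")
        eta += b * design[name].to_numpy(dtype=float)
    return eta


def true_probabilities(
    spec: SyntheticSpec, covs: CovariateTable, species: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-station generating (psi, daily p) for one species."""
    params = spec.species_params[species]
    design = standardised_design(covs)
    return expit(_linear(design, params.beta_psi)), expit(_linear(design, params.beta_p))


# ---------------------------------------------------------------------------
# detections


def generate_detections(
    spec: SyntheticSpec,
    covs: CovariateTable,
    log_: StationOperationLog,
    species: str,
    rng: np.random.Generator | None = None,
) -> list[DetectionRecord]:
    """Simulate image records for one species.

    Occupancy is drawn once per station; occupied stations yield a Bernoulli
    detection on each operational day.  A detection day receives one image
    plus a Poisson number of extra images at uniform offsets within a
    two-hour burst, so some gaps fall under and some over 60 minutes.
    """
    if species not in spec.species_params:
        raise ValidationError(f"no generating parameters for species {species!r}")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, _species_key(species)]))
    params = spec.species_params[species]
    psi, p_daily = true_probabilities(spec, covs, species)

    records: list[DetectionRecord] = []
    for i, sid in enumerate(covs.station_ids):
        if rng.random() >= psi[i]:
            continue
        for day in range(spec.survey_days):
            date = spec.survey_start + dt.timedelta(days=day)
            if not log_.is_operational(sid, date):
                continue
            if rng.random() >= p_daily[i]:
                continue
            base_min = int(rng.integers(0, 22 * 60))  # leave room for the burst
            n_extra = int(rng.poisson(params.extra_images_rate))
            offsets = [0.0] + list(rng.uniform(0.0, 120.0, size=n_extra))
            n_ind = 1 + int(rng.poisson(0.3))
            for off in sorted(offsets):
                ts = dt.datetime.combine(date, dt.time(0, 0)) + dt.timedelta(
                    minutes=base_min + off
                )
                records.append(
                    DetectionRecord(sid, species, ts.replace(second=0, microsecond=0), n_ind)
                )
    records.sort(key=lambda r: (r.station_id, r.timestamp))
    return records


def _species_key(species: str) -> int:
    # process-independent hash so identical spec+seed gives identical output
    return zlib.crc32(species.encode("utf8")) % (2**31)


# ---------------------------------------------------------------------------
# whole surveys and paired communities


@dataclass
class SyntheticSurvey:
    spec: SyntheticSpec
    covariates: CovariateTable
    operation_log: StationOperationLog
    records: list[DetectionRecord]
    traits: dict[str, SpeciesTraits]


def default_species_params(rng: np.random.Generator) -> SpeciesParams:
    """Moderate occupancy/detection parameters for background species."""
    psi0 = float(rng.uniform(-0.5, 1.5))
    p0 = float(rng.uniform(-4.0, -1.0))  # daily detection ~0.02-0.27
    mass = float(np.exp(rng.normal(1.5, 1.0)))
    guild = str(rng.choice(["carnivore", "herbivore", "omnivore"], p=[0.3, 0.5, 0.2]))
    return SpeciesParams(
        beta_psi={"(intercept)": psi0},
        beta_p={"(intercept)": p0},
        body_mass_kg=max(mass, 0.6),
        guild=guild,
    )


def generate_survey(spec: SyntheticSpec, ensure_detected: bool = False) -> SyntheticSurvey:
    """Generate a complete survey (landscape + all species' records).

    With ``ensure_detected`` every species in the pool is guaranteed at
    least one record (a forced detection at the first operational
    station-day), so incidence-based metrics see exactly the intended pool.
    """
    covs, log_ = generate_landscape(spec)
    records: list[DetectionRecord] = []
    traits: dict[str, SpeciesTraits] = {}
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2**20]))
    for species, params in spec.species_params.items():
        recs = generate_detections(spec, covs, log_, species)
        if ensure_detected and not recs:
            recs = [_forced_record(spec, log_, species, rng)]
        records.extend(recs)
        traits[species] = SpeciesTraits(species, params.body_mass_kg, params.guild)
    records.sort(key=lambda r: (r.station_id, r.timestamp))
    return SyntheticSurvey(spec, covs, log_, records, traits)


def _forced_record(
    spec: SyntheticSpec, log_: StationOperationLog, species: str,
    rng: np.random.Generator,
) -> DetectionRecord:
    for sid in log_.station_ids:
        for day in range(spec.survey_days):
            date = spec.survey_start + dt.timedelta(days=day)
            if log_.is_operational(sid, date):
                minute = int(rng.integers(0, 24 * 60))
                ts = dt.datetime.combine(date, dt.time(minute // 60, minute % 60))
                return DetectionRecord(sid, species, ts, 1)
    raise ValidationError("no operational station-day available for forced record")


def generate_two_communities(
    spec_a: SyntheticSpec,
    spec_b: SyntheticSpec,
    shared_species: Sequence[str],
    unique_a: Sequence[str],
    unique_b: Sequence[str],
) -> tuple[SyntheticSurvey, SyntheticSurvey]:
    """Paired surveys whose species pools overlap exactly as specified.

    Species parameters missing from a spec are drawn from
    ``default_species_params`` (seeded); every species in a community's pool
    is guaranteed at least one detection, so downstream similarity metrics
    see the intended shared/unique structure exactly.
    """
    shared, ua, ub = set(shared_species), set(unique_a), set(unique_b)
    if shared & ua or shared & ub or ua & ub:
        raise ValidationError("shared and unique species lists must be disjoint")

    for spec, pool in ((spec_a, shared | ua), (spec_b, shared | ub)):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2**21]))
        for species in sorted(pool):
            if species not in spec.species_params:
                spec.species_params[species] = default_species_params(rng)
        for species in list(spec.species_params):
            if species not in pool:
                del spec.species_params[species]

    # shared species keep identical traits across the two communities
    survey_a = generate_survey(spec_a, ensure_detected=True)
    for sp in shared:
        spec_b.species_params[sp].body_mass_kg = spec_a.species_params[sp].body_mass_kg
        spec_b.species_params[sp].guild = spec_a.species_params[sp].guild
    survey_b = generate_survey(spec_b, ensure_detected=True)
    return survey_a, survey_b
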