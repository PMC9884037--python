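"""Community richness, rarefaction, diversity and similarity metrics.

Richness is estimated from incidence (species x station presence) with the
first-order Jackknife; sample-based rarefaction is computed analytically
from the hypergeometric expectation.  Diversity uses global trap-rate (RAI)
proportions: Shannon-Wiener H' in nats and the Gini-Simpson index
1 - sum(p^2) (the inverse form 1/sum(p^2) is available as an option).
Between-community similarity is incidence-based Jaccard and Sorensen.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .data_io import SpeciesTraits, ValidationError
from .events import Event


@dataclass
class IncidenceMatrix:
    """Binary species x station detection matrix (>= 1 event = present)."""

    data: pd.DataFrame  # index species, columns station ids, values 0/1

    def __post_init__(self) -> None:
        vals = self.data.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValidationError("incidence entries must be 0 or 1")

    @property
    def n_stations(self) -> int:
        return self.data.shape[1]

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    def drop_undetected(self) -> "IncidenceMatrix":
        return IncidenceMatrix(self.data.loc[self.data.sum(axis=1) >= 1])


def incidence_from_events(
    events: Sequence[Event],
    station_ids: Iterable[str],
    exclude: Iterable[str] = (),
) -> IncidenceMatrix:
    stations = list(station_ids)
    blocked = set(exclude)
    species = sorted({e.species for e in events} - blocked)
    mat = pd.DataFrame(0, index=species, columns=stations, dtype=int)
    for e in events:
        if e.species in blocked:
            continue
        mat.loc[e.species, e.station_id] = 1
    return IncidenceMatrix(mat)


@dataclass
class CommunityMetrics:
    S_obs: int
    f1: int
    S_jack1: float
    H_shannon: float
    D_simpson: float
    rarefaction: pd.Series  # expected richness indexed by subsample size h


# ---------------------------------------------------------------------------
# richness


def jackknife1(inc: IncidenceMatrix) -> tuple[float, int, int]:
    """First-order Jackknife richness: S_obs + f1 * (n-1)/n.

    f1 counts species detected at exactly one station.  Returns
    (S_jack1, S_obs, f1).
    """
    if inc.data.empty or inc.n_stations < 1:
        raise ValidationError("empty incidence matrix")
    occ = inc.data.sum(axis=1)
    s_obs = int((occ >= 1).sum())
    f1 = int((occ == 1).sum())
    n = inc.n_stations
    return s_obs + f1 * (n - 1) / n, s_obs, f1


def rarefaction_curve(inc: IncidenceMatrix, sizes: Sequence[int] | None = None) -> pd.Series:
    """Analytic sample-based rarefaction.

    E[S_h] = sum_j (1 - C(n - n_j, h) / C(n, h)) where n_j is the number of
    stations at which species j was detected.  Computed with log-gamma for
    numerical stability; no resampling involved.
    """
    n = inc.n_stations
    if n < 1:
        raise ValidationError("need at least one station")
    occ = inc.data.sum(axis=1).to_numpy()
    occ = occ[occ >= 1]
    if sizes is None:
        sizes = range(1, n + 1)
    sizes = list(sizes)
    if any(h < 1 or h > n for h in sizes):
        raise ValidationError(f"subsample sizes must lie in [1, {n}]")

    def log_comb(a: np.ndarray, b: int) -> np.ndarray:
        out = np.full(a.shape, -np.inf)
        ok = a >= b
        out[ok] = gammaln(a[ok] + 1) - gammaln(b + 1) - gammaln(a[ok] - b + 1)
        return out

    vals = {}
    for h in sizes:
        log_ratio = log_comb(n - occ, h) - log_comb(np.array([n]), h)
        vals[h] = float(np.sum(1.0 - np.exp(log_ratio)))
    return pd.Series(vals, name="expected_richness")


def rarefaction_resampled(
    inc: IncidenceMatrix, h: int, n_perm: int, seed: int
) -> float:
    """Monte-Carlo rarefaction: mean richness over random station subsets."""
    rng = np.random.default_rng(seed)
    mat = inc.data.to_numpy()
    n = inc.n_stations
    richness = np.empty(n_perm)
    for i in range(n_perm):
        cols = rng.choice(n, size=h, replace=False)
        richness[i] = (mat[:, cols].sum(axis=1) >= 1).sum()
    return float(richness.mean())


# ---------------------------------------------------------------------------
# diversity


def diversity(weights: Mapping[str, float] | pd.Series, simpson: str = "gini") -> tuple[float, float]:
    """Shannon-Wiener H' (nats) and Simpson diversity from abundance weights.

    Weights (e.g. global RAI values) are normalised internally, so the
    result is invariant to a common scale factor.  ``simpson`` selects the
    Gini-Simpson form 1 - sum(p^2) (default) or ``"inverse"`` 1/sum(p^2).
    """
    w = pd.Series(weights, dtype=float)
    if (w < 0).any():
        raise ValidationError("abundance weights must be >= 0")
    total = w.sum()
    if total <= 0:
        raise ValidationError("all abundance weights are zero")
    p = (w / total).to_numpy()
    p = p[p > 0]
    h = float(-(p * np.log(p)).sum())
    sum_p2 = float((p**2).sum())
    d = 1.0 - sum_p2 if simpson == "gini" else 1.0 / sum_p2
    return h, d


# ---------------------------------------------------------------------------
# similarity


@dataclass(frozen=True)
class SimilarityResult:
    A: int  # shared species
    B: int  # unique to community 1
    C: int  # unique to community 2
    J: float  # Jaccard index A/(A+B+C)
    CC: float  # Sorensen coefficient 2A/(2A+B+C)
    D_CC: float  # Sorensen ecological distance 1 - CC


def similarity(species_1: Iterable[str], species_2: Iterable[str]) -> SimilarityResult:
    """Jaccard and Sorensen similarity between two species assemblages."""
    s1, s2 = set(species_1), set(species_2)
    if not s1 and not s2:
        raise ValidationError("similarity of two empty assemblages is undefined")
    a = len(s1 & s2)
    b = len(s1 - s2)
    c = len(s2 - s1)
    j = a / (a + b + c)
    cc = 2 * a / (2 * a + b + c)
    return SimilarityResult(A=a, B=b, C=c, J=j, CC=cc, D_CC=1.0 - cc)


# ---------------------------------------------------------------------------
# community summary


def community_metrics(
    inc: IncidenceMatrix, rai_global: pd.Series, simpson: str = "gini"
) -> CommunityMetrics:
    inc = inc.drop_undetected()
    s_jack, s_obs, f1 = jackknife1(inc)
    h, d = diversity(rai_global, simpson=simpson)
    return CommunityMetrics(
        S_obs=s_obs,
        f1=f1,
        S_jack1=s_jack,
        H_shannon=h,
        D_simpson=d,
        rarefaction=rarefaction_curve(inc),
    )


def community_structure_table(
    rai_global: pd.Series, traits: Mapping[str, SpeciesTraits]
) -> pd.DataFrame:
    """Per-species guild, body mass, global RAI and trap-rate share.

    A species is flagged dominant when it holds strictly more than 50% of
    the total trap rate.  Sorted by guild then body mass.
    """
    if len(rai_global) == 0:
        return pd.DataFrame(
            columns=["species", "guild", "body_mass_kg", "rai", "share", "dominant"]
        )
    missing = [sp for sp in rai_global.index if sp not in traits]
    if missing:
        raise ValidationError(f"species without traits: {missing}")
    total = float(rai_global.sum())
    rows = [
        {
            "species": sp,
            "guild": traits[sp].guild,
            "body_mass_kg": traits[sp].body_mass_kg,
            "rai": float(rai_global[sp]),
            "share": float(rai_global[sp]) / total if total > 0 else float("nan"),
        }
        for sp in rai_global.index
    ]
    df = pd.DataFrame(rows)
    df["dominant"] = df["share"] > 0.5
    return df.sort_values(["guild", "body_mass_kg"]).reset_index(drop=True)
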