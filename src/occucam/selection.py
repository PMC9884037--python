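"""Covariate screening, QAICc ranking and two-stage model selection.

Continuous covariates are standardised to z-scores and categorical ones
dummy-coded before collinearity screening with variance inflation factors
(VIF = 1/(1 - R^2) from regressing each column on the rest); columns are
removed greedily, largest VIF first, until all fall at or below the
threshold (3 by default).

Candidate models are ranked by the quasi-likelihood small-sample criterion

    QAICc = -2 logL / c-hat + 2K + 2K(K+1) / (n - K - 1)

with K counting one extra parameter for c-hat whenever c-hat > 1, and n the
number of sites.  Selection is two-stage: detection structure first with
constant occupancy, then occupancy structure on top of the best detection
model.  Models within 2 QAICc of the best and holding Akaike weight above
0.10 form the retained set; covariate evidence is tiered from the 95%
confidence interval of the coefficient (strong: CI excludes 0; medium: CI
overlaps 0 but the estimate sits more than one standard error from 0; weak:
otherwise).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data_io import CovariateTable, ValidationError
from .history import DetectionHistory
from .occupancy import ModelSpec, OccupancyModel, fit_occupancy

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# covariate screening


@dataclass
class CovariateScreenReport:
    scaling: dict[str, tuple[float, float]]  # continuous column -> (mean, sd)
    dummy_map: dict[str, tuple[str, list[str]]]  # categorical -> (reference, dummies)
    vif_trace: list[tuple[str, float, bool]]  # (column, vif, removed?)

    @property
    def removed(self) -> list[str]:
        return [c for c, _, rm in self.vif_trace if rm]

    @property
    def retained(self) -> list[str]:
        return [c for c, _, rm in self.vif_trace if not rm]


def _vif(design: np.ndarray, j: int) -> float:
    """VIF of column j: regress it (with intercept) on the other columns."""
    y = design[:, j]
    others = sm.add_constant(np.delete(design, j, axis=1), has_constant="add")
    r2 = sm.OLS(y, others).fit().rsquared
    if not np.isfinite(r2) or r2 >= 1.0 - 1e-12:
        return float("inf")
    return 1.0 / (1.0 - r2)


def screen_covariates(
    covs: CovariateTable,
    threshold: float = 3.0,
    reference_levels: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, CovariateScreenReport]:
    """Standardise, dummy-code and VIF-screen a covariate table.

    Returns the reduced numeric design table (indexed by station) and a
    report recording the scaling constants, the dummy coding and the VIF
    removal trace.  With perfectly collinear columns the later one (input
    order) is removed with an infinite-VIF note.
    """
    df = covs.data
    if df.shape[0] <= df.shape[1]:
        log.warning("fewer stations than covariates; VIFs may be unstable")
    reference_levels = dict(reference_levels or {})

    cols: dict[str, np.ndarray] = {}
    scaling: dict[str, tuple[float, float]] = {}
    dummy_map: dict[str, tuple[str, list[str]]] = {}
    for name in df.columns:
        typ = covs.type_map[name]
        if typ == "continuous":
            x = df[name].to_numpy(dtype=float)
            mu, sd = float(x.mean()), float(x.std(ddof=0))
            if sd == 0:
                raise ValidationError(f"continuous covariate {name!r} is constant")
            cols[name] = (x - mu) / sd
            scaling[name] = (mu, sd)
        elif typ == "binary":
            x = df[name].to_numpy(dtype=float)
            if not np.isin(x, (0.0, 1.0)).all():
                raise ValidationError(f"binary covariate {name!r} has non-0/1 values")
            cols[name] = x
        else:  # categorical
            levels = sorted(df[name].astype(str).unique())
            ref = reference_levels.get(name, levels[0])
            if ref not in levels:
                raise ValidationError(f"reference level {ref!r} absent from {name!r}")
            dummies = []
            for lev in levels:
                if lev == ref:
                    continue
                col = f"{name}[{lev}]"
                cols[col] = (df[name].astype(str) == lev).to_numpy(dtype=float)
                dummies.append(col)
            dummy_map[name] = (ref, dummies)

    design = pd.DataFrame(cols, index=df.index)
    order = {c: i for i, c in enumerate(design.columns)}
    trace: list[tuple[str, float, bool]] = []

    active = list(design.columns)
    while len(active) >= 2:
        mat = design[active].to_numpy(dtype=float)
        vifs = np.array([_vif(mat, j) for j in range(len(active))])
        worst = float(np.max(vifs))
        if worst <= threshold:
            break
        # among maximal VIFs (e.g. several infinities) drop the later column
        candidates = [active[j] for j in range(len(active)) if vifs[j] == worst]
        drop = max(candidates, key=lambda c: order[c])
        trace.append((drop, worst, True))
        active.remove(drop)

    if len(active) >= 2:
        mat = design[active].to_numpy(dtype=float)
        for j, c in enumerate(active):
            trace.append((c, _vif(mat, j), False))
    else:
        for c in active:
            trace.append((c, 1.0, False))

    report = CovariateScreenReport(scaling=scaling, dummy_map=dummy_map, vif_trace=trace)
    return design[active].copy(), report


# ---------------------------------------------------------------------------
# QAICc


def qaicc(logL: float, K: int, n: int, c_hat: float) -> float:
    """Quasi-likelihood small-sample information criterion.

    ``K`` must already include the extra parameter for c-hat where
    applicable and ``c_hat`` must be floored at 1.
    """
    if c_hat < 1.0:
        raise ValidationError("c_hat must be floored at 1 before computing QAICc")
    if n <= K + 1:
        raise ValidationError(f"small-sample correction undefined: n={n} <= K+1={K + 1}")
    return (-2.0 * logL) / c_hat + 2.0 * K + 2.0 * K * (K + 1) / (n - K - 1)


def effective_k(model_k: int, c_hat: float) -> int:
    """Parameter count for QAICc: +1 for c-hat when it is estimated > 1."""
    return model_k + (1 if c_hat > 1.0 else 0)


def rank_models(
    models: Sequence[OccupancyModel], c_hat: float, n: int
) -> pd.DataFrame:
    """QAICc rank table: logL, K, QAICc, delta and Akaike weights.

    The raw c-hat is floored at 1 (no underdispersion inflation).  Ties in
    QAICc are broken by smaller K, then input order.
    """
    if not models:
        raise ValidationError("no models to rank")
    c_eff = max(1.0, c_hat)
    rows = []
    for i, m in enumerate(models):
        k = effective_k(m.K, c_eff)
        rows.append(
            {
                "model": m.spec.label(),
                "logL": m.logL,
                "K": k,
                "QAICc": qaicc(m.logL, k, n, c_eff),
                "_order": i,
            }
        )
    df = pd.DataFrame(rows).sort_values(["QAICc", "K", "_order"]).reset_index(drop=True)
    df["delta_QAICc"] = df["QAICc"] - df["QAICc"].iloc[0]
    rel = np.exp(-df["delta_QAICc"].to_numpy() / 2.0)
    df["weight"] = rel / rel.sum()
    df["c_hat"] = c_eff
    df["n"] = n
    return df.drop(columns="_order")


# ---------------------------------------------------------------------------
# two-stage selection


@dataclass
class TwoStageResult:
    best_p_spec: ModelSpec
    p_table: pd.DataFrame
    psi_table: pd.DataFrame
    retained: pd.DataFrame  # psi-stage rows with delta < 2 and weight > 0.10
    models: dict[str, OccupancyModel]  # label -> fitted model (both stages)


def _subsets(pool: Sequence[str], max_terms: int):
    for size in range(0, min(len(pool), max_terms) + 1):
        yield from itertools.combinations(pool, size)


def two_stage_selection(
    h: DetectionHistory,
    design_table: pd.DataFrame,
    candidates_p: Sequence[str],
    candidates_psi: Sequence[str],
    c_hat: float,
    max_terms: int = 4,
    seed: int = 0,
    delta_threshold: float = 2.0,
    weight_threshold: float = 0.10,
) -> TwoStageResult:
    """Stepwise detection-then-occupancy model selection under QAICc.

    Stage 1 fits every additive subset of ``candidates_p`` (up to
    ``max_terms`` terms, plus the null) with constant occupancy and fixes
    the QAICc-best detection structure.  Stage 2 fits every additive
    occupancy subset on top of it.  Non-convergent candidates are excluded
    from ranking.
    """
    models: dict[str, OccupancyModel] = {}

    def fit_all(specs: list[ModelSpec]) -> list[OccupancyModel]:
        fitted = []
        for sp in specs:
            try:
                m = fit_occupancy(h, design_table, sp, seed=seed)
            except ValidationError as exc:
                log.warning("candidate %s failed: %s", sp.label(), exc)
                continue
            if m.converged:
                fitted.append(m)
                models[sp.label()] = m
            else:
                log.warning("candidate %s did not converge; excluded", sp.label())
        return fitted

    p_specs = [ModelSpec((), tuple(sub)) for sub in _subsets(candidates_p, max_terms)]
    p_models = fit_all(p_specs)
    if not p_models:
        raise ValidationError("no detection-stage candidate converged")
    p_table = rank_models(p_models, c_hat, h.n_sites)
    best_p = next(m.spec for m in p_models if m.spec.label() == p_table["model"].iloc[0])

    psi_specs = [
        ModelSpec(tuple(sub), best_p.p_covariates)
        for sub in _subsets(candidates_psi, max_terms)
    ]
    psi_models = fit_all(psi_specs)
    if not psi_models:
        raise ValidationError("no occupancy-stage candidate converged")
    psi_table = rank_models(psi_models, c_hat, h.n_sites)
    retained = psi_table[
        (psi_table["delta_QAICc"] < delta_threshold)
        & (psi_table["weight"] > weight_threshold)
    ].reset_index(drop=True)
    return TwoStageResult(best_p, p_table, psi_table, retained, models)


# ---------------------------------------------------------------------------
# evidence classification


def classify_evidence(beta: float, se: float, z_crit: float = 1.96) -> tuple[str, str]:
    """Strength tier and direction of a coefficient from its 95% CI.

    Strong: the CI excludes 0.  Medium: the CI overlaps 0 but the estimate
    is not centred on 0, operationalised as |beta|/se > 1.  Weak: otherwise.
    """
    if se <= 0:
        raise ValidationError("standard error must be positive")
    z = abs(beta) / se
    strength = "strong" if z > z_crit else ("medium" if z > 1.0 else "weak")
    direction = "+" if beta > 0 else ("-" if beta < 0 else "0")
    return strength, direction


def evidence_table(result: TwoStageResult) -> pd.DataFrame:
    """Per-covariate evidence summary over the retained model set.

    For each covariate appearing in a retained model the summed Akaike
    weight of the retained models containing it is reported, together with
    the direction and strength tier of its coefficient in the
    highest-weight retained model that contains it.
    """
    rows = []
    seen: set[tuple[str, str]] = set()
    for _, rank_row in result.retained.iterrows():
        model = result.models[rank_row["model"]]
        for param, names, betas, ses in (
            ("psi", model.spec.psi_covariates, model.beta_psi[1:], model.se_psi[1:]),
            ("p", model.spec.p_covariates, model.beta_p[1:], model.se_p[1:]),
        ):
            for name, beta, se in zip(names, betas, ses):
                key = (param, name)
                if key in seen:
                    continue
                seen.add(key)
                weight = sum(
                    r["weight"]
                    for _, r in result.retained.iterrows()
                    if name
                    in (
                        result.models[r["model"]].spec.psi_covariates
                        if param == "psi"
                        else result.models[r["model"]].spec.p_covariates
                    )
                )
                if np.isfinite(se) and se > 0:
                    strength, direction = classify_evidence(float(beta), float(se))
                else:
                    strength, direction = "unknown", "+" if beta > 0 else "-"
                rows.append(
                    {
                        "covariate": name,
                        "parameter": param,
                        "weight": weight,
                        "direction": direction,
                        "strength": strength,
                        "beta": float(beta),
                        "se": float(se),
                    }
                )
    return pd.DataFrame(
        rows, columns=["covariate", "parameter", "weight", "direction", "strength", "beta", "se"]
    )
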