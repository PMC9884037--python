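import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from occucam.data_io import CovariateTable, ValidationError
from occucam.occupancy import ModelSpec, fit_occupancy, simulate_history
from occucam.selection import (
    classify_evidence,
    effective_k,
    evidence_table,
    qaicc,
    rank_models,
    screen_covariates,
    two_stage_selection,
)

from conftest import make_history


def cov_table(df, type_map=None):
    if type_map is None:
        type_map = {c: "continuous" for c in df.columns}
    df = df.copy()
    df.index = [f"S{i + 1}" for i in range(len(df))]
    df.index.name = "station_id"
    return CovariateTable(df, type_map)


class TestScreenCovariates:
    def test_orthogonal_columns_all_kept(self):
        n = 8
        base = np.eye(n)
        covs = cov_table(pd.DataFrame({"a": base[:, 0], "b": base[:, 1], "c": base[:, 2]}))
        design, report = screen_covariates(covs)
        assert list(design.columns) == ["a", "b", "c"]
        assert not report.removed
        assert all(v <= 3 for _, v, rm in report.vif_trace if not rm)

    def test_zscore_invariants(self, rng):
        covs = cov_table(pd.DataFrame({"alt": rng.normal(600, 200, 30),
                                       "road": rng.exponential(2, 30)}))
        design, report = screen_covariates(covs)
        for col in design.columns:
            assert design[col].mean() == pytest.approx(0, abs=1e-9)
            assert design[col].std(ddof=0) == pytest.approx(1, abs=1e-9)
        assert set(report.scaling) == {"alt", "road"}

    def test_duplicated_column_removed_with_infinite_vif(self, rng):
        x = rng.normal(size=20)
        covs = cov_table(pd.DataFrame({"x": x, "y": rng.normal(size=20), "x2": x}))
        design, report = screen_covariates(covs)
        assert "x2" not in design.columns  # the later duplicate goes
        assert "x" in design.columns
        removed = {c: v for c, v, rm in report.vif_trace if rm}
        assert removed["x2"] == float("inf")

    def test_correlated_trio_ends_below_threshold(self, rng):
        z = rng.normal(size=40)
        covs = cov_table(
            pd.DataFrame(
                {
                    "a": z + rng.normal(0, 0.2, 40),
                    "b": z + rng.normal(0, 0.2, 40),
                    "c": z + rng.normal(0, 0.2, 40),
                }
            )
        )
        design, report = screen_covariates(covs, threshold=3)
        # brute force: every retained subset must satisfy the VIF bound
        final = design.to_numpy()
        for j in range(final.shape[1]):
            y = final[:, j]
            x = np.column_stack([np.ones(len(y)), np.delete(final, j, axis=1)])
            coef, *_ = np.linalg.lstsq(x, y, rcond=None)
            r2 = 1 - ((y - x @ coef) ** 2).sum() / ((y - y.mean()) ** 2).sum()
            assert 1 / (1 - r2) <= 3 + 1e-9

    def test_dummy_coding_with_reference(self, rng):
        covs = cov_table(
            pd.DataFrame({"veg": ["fynbos", "karoo", "karoo", "renoster"] * 5,
                          "alt": rng.normal(size=20)}),
            {"veg": "categorical", "alt": "continuous"},
        )
        design, report = screen_covariates(covs, reference_levels={"veg": "fynbos"})
        ref, dummies = report.dummy_map["veg"]
        assert ref == "fynbos"
        assert set(dummies) == {"veg[karoo]", "veg[renoster]"}
        assert set(design.columns) >= {"veg[karoo]", "veg[renoster]"}

    def test_constant_continuous_column_is_error(self):
        covs = cov_table(pd.DataFrame({"a": [1.0] * 10, "b": np.arange(10.0)}))
        with pytest.raises(ValidationError, match="constant"):
            screen_covariates(covs)


class TestQAICc:
    def test_known_values(self):
        assert qaicc(-100.0, 3, 50, 1.0) == pytest.approx(206.5217, abs=1e-4)
        assert qaicc(-100.0, 4, 50, 2.0) == pytest.approx(108.8889, abs=1e-4)

    def test_reduces_to_aicc_when_no_overdispersion(self):
        logL, k, n = -57.3, 4, 40
        aicc = -2 * logL + 2 * k + 2 * k * (k + 1) / (n - k - 1)
        assert qaicc(logL, k, n, 1.0) == pytest.approx(aicc)

    def test_validation(self):
        with pytest.raises(ValidationError):
            qaicc(-10, 3, 4, 1.0)  # n <= K+1
        with pytest.raises(ValidationError):
            qaicc(-10, 3, 50, 0.8)  # unfloored c-hat

    def test_effective_k_adds_one_for_estimated_overdispersion(self):
        assert effective_k(3, 1.0) == 3
        assert effective_k(3, 1.5) == 4


class TestRankModels:
    def fit_two_models(self, rng):
        n, t = 60, 8
        x = rng.normal(size=n)
        design = pd.DataFrame({"x": x}, index=[f"S{i + 1}" for i in range(n)])
        psi = 1 / (1 + np.exp(-(0.4 + 1.2 * x)))
        h = simulate_history(psi, np.full(n, 0.35), np.ones((n, t), bool), rng,
                             make_history(np.zeros((n, t))))
        m0 = fit_occupancy(h, design, ModelSpec(), seed=0)
        m1 = fit_occupancy(h, design, ModelSpec(("x",), ()), seed=0)
        return [m0, m1], h

    def test_weights_sum_to_one_and_sorted(self, rng):
        models, h = self.fit_two_models(rng)
        table = rank_models(models, c_hat=1.3, n=h.n_sites)
        assert table["weight"].sum() == pytest.approx(1.0, abs=1e-12)
        assert table["delta_QAICc"].iloc[0] == 0.0
        assert table["QAICc"].is_monotonic_increasing

    def test_nesting_monotonicity(self, rng):
        # the covariate model can only raise the log-likelihood, yet pays
        # a larger penalty
        models, h = self.fit_two_models(rng)
        m0, m1 = models
        assert m1.logL >= m0.logL - 1e-8
        table = rank_models(models, c_hat=1.0, n=h.n_sites).set_index("model")
        pen0 = table.loc[m0.spec.label(), "QAICc"] + 2 * m0.logL
        pen1 = table.loc[m1.spec.label(), "QAICc"] + 2 * m1.logL
        assert pen1 > pen0

    def test_c_hat_floored_at_one(self, rng):
        models, h = self.fit_two_models(rng)
        t1 = rank_models(models, c_hat=0.7, n=h.n_sites)
        t2 = rank_models(models, c_hat=1.0, n=h.n_sites)
        pd.testing.assert_frame_equal(t1, t2)


class TestClassifyEvidence:
    @pytest.mark.parametrize(
        "beta,se,strength,direction",
        [
            (0.5, 0.1, "strong", "+"),
            (0.5, 0.4, "medium", "+"),
            (0.1, 0.4, "weak", "+"),
            (-2.0, 0.5, "strong", "-"),
            (-0.3, 0.25, "medium", "-"),
        ],
    )
    def test_tiers(self, beta, se, strength, direction):
        assert classify_evidence(beta, se) == (strength, direction)

    def test_se_must_be_positive(self):
        with pytest.raises(ValidationError):
            classify_evidence(0.5, 0.0)

    @given(
        beta=st.floats(-5, 5, allow_nan=False),
        se=st.floats(0.01, 5),
        c=st.floats(0.01, 100),
    )
    @settings(max_examples=200, deadline=None)
    def test_scale_equivariance(self, beta, se, c):
        assert classify_evidence(beta, se) == classify_evidence(c * beta, c * se)


class TestTwoStageSelection:
    def simulated(self, rng, n=80, t=8):
        design = pd.DataFrame(
            {"x": rng.normal(size=n), "z": rng.normal(size=n)},
            index=[f"S{i + 1}" for i in range(n)],
        )
        psi = 1 / (1 + np.exp(-(0.5 + 1.5 * design["z"].to_numpy())))
        p = 1 / (1 + np.exp(-(-0.5 + 1.5 * design["x"].to_numpy())))
        h = simulate_history(psi, p, np.ones((n, t), bool), rng,
                             make_history(np.zeros((n, t)), site_ids=design.index))
        return h, design

    def test_empty_pools_give_null_model_only(self, rng):
        h, design = self.simulated(rng)
        res = two_stage_selection(h, design, (), (), c_hat=1.0, max_terms=4, seed=0)
        assert len(res.p_table) == 1 and len(res.psi_table) == 1
        assert res.retained["weight"].iloc[0] == pytest.approx(1.0)

    def test_single_covariate_pools_enumerate_two_models_each(self, rng):
        h, design = self.simulated(rng)
        res = two_stage_selection(h, design, ("x",), ("z",), c_hat=1.0,
                                  max_terms=4, seed=0)
        assert len(res.p_table) == 2
        assert len(res.psi_table) == 2

    def test_max_terms_caps_enumeration(self, rng):
        h, design = self.simulated(rng)
        res = two_stage_selection(h, design, ("x", "z"), (), c_hat=1.0,
                                  max_terms=1, seed=0)
        assert len(res.p_table) == 3  # null, x, z but not x+z

    def test_recovers_generating_structure(self, rng):
        h, design = self.simulated(rng, n=150, t=10)
        res = two_stage_selection(h, design, ("x", "z"), ("x", "z"), c_hat=1.0,
                                  max_terms=2, seed=0)
        assert "x" in res.best_p_spec.p_covariates
        best_psi = res.psi_table["model"].iloc[0]
        assert "psi" in best_psi and "z" in best_psi.split("p(")[0]

    def test_evidence_table_covers_retained_terms(self, rng):
        h, design = self.simulated(rng, n=120, t=10)
        res = two_stage_selection(h, design, ("x",), ("z",), c_hat=1.0,
                                  max_terms=2, seed=0)
        ev = evidence_table(res)
        assert set(ev.columns) >= {"covariate", "parameter", "weight", "direction", "strength"}
        if not ev.empty:
            assert ev["weight"].between(0, 1).all()
            sub = ev[(ev.covariate == "z") & (ev.parameter == "psi")]
            if not sub.empty:
                assert sub["direction"].iloc[0] == "+"
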