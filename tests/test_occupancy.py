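import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import logit

from occucam.data_io import ValidationError
from occucam.history import DetectionHistory
from occucam.occupancy import (
    ModelSpec,
    choose_occasion_length,
    fit_occupancy,
    history_probabilities,
    mb_gof,
    naive_occupancy,
    occupancy_negloglik,
    pearson_chi2,
    select_occasion_length,
    simulate_history,
)

from conftest import make_history


def intercept_params(psi, p):
    return np.array([logit(psi), logit(p)])


class TestNaiveOccupancy:
    def test_survey_scale_example(self):
        # 60 of 72 operational stations with at least one detection
        mat = np.zeros((72, 14))
        mat[:60, 0] = 1
        nv = naive_occupancy(make_history(mat, 11))
        assert nv.n_detected_sites == 60
        assert nv.psi_naive == pytest.approx(0.833, abs=5e-4)

    def test_extremes(self):
        assert naive_occupancy(make_history(np.zeros((5, 3)))).psi_naive == 0
        assert naive_occupancy(make_history(np.ones((5, 3)))).psi_naive == 1

    def test_missing_cells_do_not_count_as_detections(self):
        mat = np.array([[np.nan, 0.0], [1.0, np.nan]])
        assert naive_occupancy(make_history(mat)).psi_naive == 0.5


class TestNegLogLik:
    def test_detected_history_hand_value(self):
        h = make_history([[1, 0]])
        nll = occupancy_negloglik(intercept_params(0.5, 0.5), h, None, ModelSpec())
        assert nll == pytest.approx(math.log(8))  # psi*p*(1-p) = 1/8

    def test_all_zero_history_hand_value(self):
        h = make_history([[0, 0]])
        nll = occupancy_negloglik(intercept_params(0.5, 0.5), h, None, ModelSpec())
        assert nll == pytest.approx(-math.log(0.625))  # 0.5*0.25 + 0.5

    def test_certain_occupancy_reduces_to_bernoulli(self):
        h = make_history([[1, 0, 1], [0, 0, 0]])
        params = np.array([30.0, logit(0.3)])  # psi -> 1
        nll = occupancy_negloglik(params, h, None, ModelSpec())
        bern = -(2 * math.log(0.3) + 4 * math.log(0.7))
        assert nll == pytest.approx(bern, abs=1e-6)

    def test_missing_occasions_skipped(self):
        full = make_history([[1, 0]])
        padded = make_history([[1, np.nan, 0, np.nan]])
        params = intercept_params(0.4, 0.3)
        assert occupancy_negloglik(params, full, None, ModelSpec()) == pytest.approx(
            occupancy_negloglik(params, padded, None, ModelSpec())
        )

    @given(
        psi=st.floats(0.05, 0.95),
        p=st.floats(0.05, 0.95),
        t=st.integers(1, 4),
    )
    @settings(max_examples=150, deadline=None)
    def test_history_probabilities_normalise(self, psi, p, t):
        probs = history_probabilities(psi, p, t)
        assert len(probs) == 2**t
        assert sum(probs.values()) == pytest.approx(1.0, abs=1e-12)

    def test_negloglik_consistent_with_enumeration(self):
        # the per-site likelihood equals the enumeration probability
        psi, p = 0.37, 0.61
        for hist in [(1, 1, 0), (0, 0, 0), (1, 0, 1)]:
            h = make_history([list(hist)])
            nll = occupancy_negloglik(intercept_params(psi, p), h, None, ModelSpec())
            assert nll == pytest.approx(-math.log(history_probabilities(psi, p, 3)[hist]))


class TestFitOccupancy:
    def grid_oracle(self, h):
        d = np.nansum(np.where(np.isnan(h.matrix), 0, h.matrix), axis=1)
        t = (~np.isnan(h.matrix)).sum(axis=1)
        grid = np.arange(0.001, 1.0, 0.001)
        psi_g, p_g = np.meshgrid(grid, grid, indexing="ij")
        nll = np.zeros_like(psi_g)
        for di, ti in zip(d, t):
            if di > 0:
                nll -= np.log(psi_g) + di * np.log(p_g) + (ti - di) * np.log(1 - p_g)
            else:
                nll -= np.log(psi_g * (1 - p_g) ** ti + 1 - psi_g)
        i, j = np.unravel_index(np.argmin(nll), nll.shape)
        return grid[i], grid[j]

    def test_intercept_only_matches_grid_search(self):
        h = make_history([[1, 0, 0], [0, 1, 1], [0, 0, 0], [1, 1, 0], [0, 0, 0]])
        m = fit_occupancy(h, None, ModelSpec(), seed=0)
        psi_star, p_star = self.grid_oracle(h)
        psi_hat = 1 / (1 + math.exp(-m.beta_psi[0]))
        p_hat = 1 / (1 + math.exp(-m.beta_p[0]))
        assert psi_hat == pytest.approx(psi_star, abs=1e-3)
        assert p_hat == pytest.approx(p_star, abs=1e-3)
        assert m.converged

    def test_second_toy_matches_grid_search(self):
        h = make_history(
            [[1, 1, 1], [1, 0, 1], [0, 0, 0], [0, 0, 0], [0, 1, 0], [0, 0, 0]]
        )
        m = fit_occupancy(h, None, ModelSpec(), seed=1)
        psi_star, p_star = self.grid_oracle(h)
        assert 1 / (1 + math.exp(-m.beta_psi[0])) == pytest.approx(psi_star, abs=1e-3)
        assert 1 / (1 + math.exp(-m.beta_p[0])) == pytest.approx(p_star, abs=1e-3)

    def test_boundary_flagged_when_all_sites_saturated(self):
        h = make_history(np.ones((10, 6)))
        m = fit_occupancy(h, None, ModelSpec(), seed=0)
        assert m.boundary

    def test_psi_hat_at_least_naive(self, rng):
        window = (dt.date(2020, 1, 1), dt.date(2020, 1, 8))
        for _ in range(5):
            mat = (rng.random((40, 8)) < 0.25).astype(float)
            mat[rng.random(40) > 0.7] = 0.0  # unoccupied rows
            h = make_history(mat, window=window)
            if naive_occupancy(h).psi_naive in (0.0, 1.0):
                continue
            m = fit_occupancy(h, None, ModelSpec(), seed=3)
            psi_hat = 1 / (1 + math.exp(-m.beta_psi[0]))
            assert psi_hat >= naive_occupancy(h).psi_naive - 1e-6

    def test_covariate_design_and_rank_checks(self, rng):
        mat = (rng.random((30, 5)) < 0.3).astype(float)
        h = make_history(mat, window=(dt.date(2020, 1, 1), dt.date(2020, 1, 5)))
        design = pd.DataFrame(
            {"x": rng.normal(size=30), "x_copy": np.zeros(30)}, index=h.site_ids
        )
        design["x_copy"] = design["x"]
        with pytest.raises(ValidationError, match="rank-deficient"):
            fit_occupancy(h, design, ModelSpec(("x", "x_copy"), ()), seed=0)
        with pytest.raises(ValidationError, match="absent"):
            fit_occupancy(h, design, ModelSpec(("y",), ()), seed=0)

    def test_too_few_sites_is_error(self):
        with pytest.raises(ValidationError):
            fit_occupancy(make_history([[1, 0]]), None, ModelSpec(), seed=0)


class TestPearsonChi2:
    def test_matches_hand_enumeration_on_two_occasions(self):
        # all four possible histories observed: chi2 is the plain sum over cells
        rows = [[0, 0]] * 3 + [[0, 1]] * 2 + [[1, 0]] * 2 + [[1, 1]] * 1
        h = make_history(rows)
        psi, p = 0.7, 0.4
        n = len(rows)
        e = {
            (0, 0): n * (psi * 0.6**2 + 0.3),
            (0, 1): n * psi * 0.4 * 0.6,
            (1, 0): n * psi * 0.4 * 0.6,
            (1, 1): n * psi * 0.4**2,
        }
        o = {(0, 0): 3, (0, 1): 2, (1, 0): 2, (1, 1): 1}
        hand = sum((o[k] - e[k]) ** 2 / e[k] for k in e)
        got = pearson_chi2(h, np.full(n, psi), np.full(n, p))
        assert got == pytest.approx(hand, rel=1e-9)

    def test_cohorts_split_by_missingness(self):
        rows = np.array([[1.0, 0.0, np.nan], [0.0, 0.0, 0.0]])
        h = make_history(rows)
        # two singleton cohorts: statistic is finite and positive
        chi2 = pearson_chi2(h, np.array([0.5, 0.5]), np.array([0.5, 0.5]))
        assert np.isfinite(chi2) and chi2 > 0


class TestGoodnessOfFit:
    def fit_small(self, rng, n=40, t=6):
        mat = simulate_history(
            np.full(n, 0.6), np.full(n, 0.4), np.ones((n, t), bool), rng,
            make_history(np.zeros((n, t))),
        )
        return fit_occupancy(mat, None, ModelSpec(), seed=0), mat

    def test_seed_determinism(self, rng):
        m, h = self.fit_small(rng)
        g1 = mb_gof(m, h, None, n_boot=25, seed=11)
        g2 = mb_gof(m, h, None, n_boot=25, seed=11)
        assert g1.chi2_obs == g2.chi2_obs
        assert np.array_equal(g1.boot_chi2, g2.boot_chi2)
        assert g1.p_value == g2.p_value and g1.c_hat == g2.c_hat

    def test_nboot_validation(self, rng):
        m, h = self.fit_small(rng)
        with pytest.raises(ValidationError):
            mb_gof(m, h, None, n_boot=1, seed=0)

    def test_well_specified_model_fits(self, rng):
        m, h = self.fit_small(rng, n=60, t=8)
        g = mb_gof(m, h, None, n_boot=60, seed=5)
        assert 0 <= g.p_value <= 1
        assert 0.5 < g.c_hat < 2.0


class TestOccasionLengthRule:
    def table(self, ks, chats, ps):
        return pd.DataFrame({"k": ks, "c_hat": chats, "p_value": ps})

    def test_argmin_distance_to_one(self):
        t = self.table([5, 8, 11], [1.8, 1.1, 0.95], [0.3, 0.4, 0.5])
        assert choose_occasion_length(t) == 11

    def test_all_overdispersed_flags_species(self):
        t = self.table([5, 8, 11], [3.4, 4.0, 5.1], [0.3, 0.4, 0.5])
        assert choose_occasion_length(t) is None

    def test_tie_goes_to_smaller_k(self):
        t = self.table([5, 8], [1.1, 0.9], [0.5, 0.5])
        assert choose_occasion_length(t) == 5

    def test_low_p_value_disqualifies(self):
        t = self.table([5, 8], [1.0, 1.3], [0.01, 0.4])
        assert choose_occasion_length(t) == 8

    def test_underdispersion_bound(self):
        t = self.table([5, 8], [0.85, 1.6], [0.5, 0.5])
        assert choose_occasion_length(t) == 8

    def test_integration_on_simulated_daily_history(self, rng):
        n, days = 50, 60
        window = (dt.date(2020, 1, 1), dt.date(2020, 2, 29))
        daily = simulate_history(
            np.full(n, 0.7), np.full(n, 0.08), np.ones((n, days), bool), rng,
            make_history(np.zeros((n, days)), window=window),
        )
        k, table = select_occasion_length(
            daily, None, ModelSpec(), ks=(6, 10), n_boot=20, seed=2
        )
        assert set(table["k"]) == {6, 10}
        assert k in (None, 6, 10)
        assert table["converged"].all()
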