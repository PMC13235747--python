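"""Spline trend model: recovery oracles, extrapolation arithmetic, UIs."""

import numpy as np
import pytest

from u5m.b3 import (
    B3Config,
    B3SplineModel,
    PosteriorTrajectories,
    cap_imr_at_u5mr,
    compute_global_trend,
    extrapolate,
    fit_b3,
)
from u5m.synthetic import SeriesSpec, TrueTrajectory, generate_observations


def _log_linear_truth(level=120.0, arr=0.03, years=None):
    years = years if years is not None else np.arange(1995, 2021)
    u5 = level * np.exp(-arr * (years - years[0]))
    return TrueTrajectory("T", years, u5, 0.8 * u5, 0.5 * u5,
                          np.zeros(years.size))


class TestFit:
    def test_noise_free_single_series_recovers_truth_within_2pct(self):
        truth = _log_linear_truth()
        spec = SeriesSpec("T-VR", "VR", 0.0, 0.0, 0.0,
                          obs_years=[y + 0.5 for y in truth.years])
        obs = generate_observations(truth, spec, seed=0)
        traj = fit_b3(obs, B3Config(n_warmup=300, n_draws=300, seed=2))
        ti = np.searchsorted(truth.years, traj.years)
        assert np.all(np.abs(traj.median() / truth.u5mr[ti] - 1) < 0.02)
        assert traj.metadata["converged"]

    def test_biased_series_recovered_against_vr_anchor(self):
        truth = _log_linear_truth()
        anchor = SeriesSpec("T-VR", "VR", 0.0, 0.02, 0.0,
                            obs_years=[y + 0.5 for y in truth.years])
        biased = SeriesSpec("T-FBH", "survey_FBH", np.log(1.15), 0.03, 0.0,
                            obs_years=[y + 0.5 for y in truth.years[::2]])
        obs = (generate_observations(truth, anchor, seed=1)
               + generate_observations(truth, biased, seed=2))
        model = B3SplineModel(n_warmup=400, n_draws=400, seed=3).fit(obs)
        b = model.bias_["survey_FBH"]
        lo, hi = np.percentile(model.bias_draws_[:, 0], [5, 95])
        assert lo < np.log(1.15) < hi
        assert b == pytest.approx(np.log(1.15), abs=0.05)

    def test_no_observations_raises_instructively(self):
        with pytest.raises(ValueError, match="extrapolation-only"):
            fit_b3([], B3Config())

    def test_seed_reproducibility(self, small_world):
        c = small_world[1]
        cfg = B3Config(n_warmup=100, n_draws=100, seed=5)
        t1 = fit_b3(c.observations, cfg)
        t2 = fit_b3(c.observations, cfg)
        assert np.array_equal(t1.draws, t2.draws)

    def test_trajectories_positive_and_finite(self, fitted_country):
        _, traj = fitted_country
        assert np.all(traj.draws > 0)
        assert np.all(np.isfinite(np.log(traj.draws)))


class TestExtrapolate:
    def _traj(self, arr=0.04):
        years = np.arange(2000, 2015)
        draws = np.tile(100 * np.exp(-arr * (years - 2000)), (20, 1))
        return PosteriorTrajectories("X", "U5MR", years, draws)

    def test_equal_weighting_of_country_and_global_trend(self):
        ext = extrapolate(self._traj(0.04), 2014.5, 0.02,
                          window=10, reference_year=2020)
        slope = np.log(ext.draws[0, -2] / ext.draws[0, -1])
        assert slope == pytest.approx(0.03, abs=1e-9)
        assert not ext.fitted[-1]
        assert ext.fitted[:15].all()

    def test_country_equal_to_global_keeps_slope(self):
        ext = extrapolate(self._traj(0.02), 2014.5, 0.02,
                          window=10, reference_year=2020)
        slope = np.log(ext.draws[0, -2] / ext.draws[0, -1])
        assert slope == pytest.approx(0.02, abs=1e-9)

    def test_identity_when_data_reach_reference_year(self):
        traj = self._traj()
        assert extrapolate(traj, 2020.0, 0.02, reference_year=2020) is traj

    def test_missing_global_trend_rejected(self):
        with pytest.raises(ValueError, match="global"):
            extrapolate(self._traj(), 2014.5, None, reference_year=2020)

    def test_ui_widens_with_years_since_last_datum(self, fitted_country):
        """Extrapolation-period uncertainty grows away from the data."""
        _, traj = fitted_country
        ext = extrapolate(traj, traj.metadata["last_data_year"], 0.02,
                          reference_year=int(traj.years[-1]) + 8)
        lo, hi = ext.interval(0.90)
        rel_width = (hi - lo) / ext.median()
        tail = rel_width[-8:]
        assert tail[-1] > tail[0]


class TestGlobalTrend:
    def _make(self, cid, arr, level=100.0):
        years = np.arange(2005, 2020)
        draws = np.tile(level * np.exp(-arr * (years - 2005)), (10, 1))
        return PosteriorTrajectories(cid, "U5MR", years, draws)

    def test_single_country_equals_its_arr(self):
        import pandas as pd
        trajs = {"A": self._make("A", 0.03)}
        births = {"A": pd.Series(1000.0, index=np.arange(2005, 2020))}
        g = compute_global_trend(trajs, births, window=10)
        assert g["arr"] == pytest.approx(0.03, abs=1e-9)

    def test_identical_countries_share_common_arr(self):
        import pandas as pd
        trajs = {c: self._make(c, 0.025) for c in "ABC"}
        births = {c: pd.Series(500.0, index=np.arange(2005, 2020))
                  for c in "ABC"}
        g = compute_global_trend(trajs, births, window=10)
        assert g["arr"] == pytest.approx(0.025, abs=1e-9)

    def test_two_countries_arr_between_members(self):
        import pandas as pd
        trajs = {"A": self._make("A", 0.01), "B": self._make("B", 0.05)}
        births = {c: pd.Series(800.0, index=np.arange(2005, 2020))
                  for c in "AB"}
        g = compute_global_trend(trajs, births, window=10)
        assert 0.01 < g["arr"] < 0.05


def test_imr_capped_at_u5mr_per_draw():
    years = np.arange(2000, 2010)
    rng = np.random.default_rng(3)
    u5 = PosteriorTrajectories(
        "C", "U5MR", years, np.abs(rng.normal(40, 5, (50, 10))) + 1)
    imr = PosteriorTrajectories(
        "C", "IMR", years, np.abs(rng.normal(42, 5, (50, 10))) + 1)
    capped = cap_imr_at_u5mr(imr, u5)
    assert np.all(capped.draws <= u5.draws)
    assert capped.indicator == "IMR"
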