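"""Scenario engine: component algebra, target endpoints, floors, ordering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from types import SimpleNamespace

from u5m.projections import (
    COMPONENTS,
    ComponentRates,
    ScenarioSpec,
    components_from_trajectories,
    decompose,
    project,
    projected_deaths,
    recombine,
    scenario_arr,
)
from u5m.data_model import ConfigError


class TestDecomposeRecombine:
    def test_equal_nmr_imr_gives_zero_postneonatal(self):
        _, pnmr, _ = decompose(0.02, 0.02, 0.03)
        assert pnmr == 0.0

    def test_published_global_2024_components(self):
        n, p, c = decompose(0.0172, 0.0277, 0.0374)
        assert p == pytest.approx(0.01068, abs=5e-6)
        assert c == pytest.approx(0.00998, abs=5e-6)
        nmr, imr, u5 = recombine(n, p, c)
        assert u5 == pytest.approx(0.0374, abs=1e-12)

    def test_zero_components_collapse_rates(self):
        nmr, imr, u5 = recombine(0.02, 0.0, 0.0)
        assert imr == pytest.approx(0.02, abs=1e-15)
        assert u5 == pytest.approx(0.02, abs=1e-15)

    @given(st.floats(0.0005, 0.05), st.floats(0.0, 0.05), st.floats(0.0, 0.05))
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_round_trip_identity(self, n, p, c):
        nmr, imr, u5 = recombine(n, p, c)
        n2, p2, c2 = decompose(nmr, imr, u5)
        assert n2 == pytest.approx(n, abs=1e-12)
        assert p2 == pytest.approx(p, abs=1e-12)
        assert c2 == pytest.approx(c, abs=1e-12)

    def test_ordering_violation_rejected(self):
        with pytest.raises(ValueError):
            decompose(0.03, 0.02, 0.04)


def _component_traj(arr_values, level=0.02, n_draws=40, noise=0.0, seed=0):
    years = np.arange(2010, 2025)
    rng = np.random.default_rng(seed)
    out = {}
    for comp, a in zip(COMPONENTS, arr_values):
        path = level * np.exp(-a * (years - years[0]))
        draws = np.tile(path, (n_draws, 1))
        if noise:
            draws = draws * np.exp(rng.normal(0, noise, draws.shape))
        out[comp] = SimpleNamespace(years=years, draws=draws)
    return out


class TestScenarioArr:
    def test_constant_scenario_zero_arr(self):
        trajs = _component_traj((0.03, 0.02, 0.04))
        arrs = scenario_arr(trajs, ScenarioSpec(kind="constant"))
        assert all(v == 0.0 for v in arrs.values())

    def test_negative_arr_clamped_to_zero(self):
        trajs = _component_traj((-0.02, 0.02, 0.02))  # rising neonatal
        arrs = scenario_arr(trajs, ScenarioSpec(kind="current_trends"))
        assert arrs["nmr"] == 0.0
        assert arrs["pnmr"] > 0.0

    def test_ui_bound_scenarios_are_ordered(self):
        trajs = _component_traj((0.03, 0.03, 0.03), noise=0.05, seed=4)
        lo = scenario_arr(trajs, ScenarioSpec(kind="current_trends_lower"))
        md = scenario_arr(trajs, ScenarioSpec(kind="current_trends"))
        hi = scenario_arr(trajs, ScenarioSpec(kind="current_trends_upper"))
        for c in COMPONENTS:
            assert lo[c] <= md[c] <= hi[c]


def _base(nmr=0.020, pnmr=0.012, cmr=0.020):
    return ComponentRates("X", np.array([2024]), np.array([nmr]),
                          np.array([pnmr]), np.array([cmr]))


class TestProject:
    def test_constant_scenario_freezes_rates(self):
        proj = project(_base(), ScenarioSpec(kind="constant"),
                       {c: 0.0 for c in COMPONENTS})
        assert proj.at(2030) == proj.at(2024)

    def test_floor_is_absorbing(self):
        base = _base(nmr=0.0008)  # 0.8 per 1000, just above the 0.7 floor
        proj = project(base, ScenarioSpec(kind="current_trends"),
                       {"nmr": 0.10, "pnmr": 0.0, "cmr": 0.0})
        nmr_path = proj.nmr * 1000
        hit = np.nonzero(np.isclose(nmr_path, 0.7))[0]
        assert hit.size >= 2  # reaches the floor and stays
        assert np.allclose(nmr_path[hit[0]:], 0.7)

    def test_country_at_floor_stays_there(self):
        base = _base(nmr=0.0007)
        proj = project(base, ScenarioSpec(kind="current_trends"),
                       {"nmr": 0.05, "pnmr": 0.0, "cmr": 0.0})
        assert np.allclose(proj.nmr * 1000, 0.7)

    def test_sdg_scenario_hits_targets_exactly(self):
        base = _base(nmr=0.020, pnmr=0.012, cmr=0.020)  # far off track
        proj = project(base, ScenarioSpec(kind="sdg_target"),
                       {c: 0.01 for c in COMPONENTS})
        at30 = proj.at(2030)
        _, _, u5 = recombine(at30["nmr"], at30["pnmr"], at30["cmr"])
        assert u5 * 1000 == pytest.approx(25.0, rel=1e-9)
        assert at30["nmr"] * 1000 == pytest.approx(12.0, rel=1e-9)

    def test_high_income_scenario_hits_thresholds_exactly(self):
        proj = project(_base(), ScenarioSpec(kind="high_income"),
                       {c: 0.01 for c in COMPONENTS})
        at30 = proj.at(2030)
        _, _, u5 = recombine(at30["nmr"], at30["pnmr"], at30["cmr"])
        assert u5 * 1000 == pytest.approx(5.1, rel=1e-9)
        assert at30["nmr"] * 1000 == pytest.approx(2.8, rel=1e-9)

    def test_on_track_country_keeps_current_trends(self):
        base = _base(nmr=0.002, pnmr=0.001, cmr=0.001)  # well under targets
        ct = project(base, ScenarioSpec(kind="current_trends"),
                     {c: 0.02 for c in COMPONENTS})
        sdg = project(base, ScenarioSpec(kind="sdg_target"),
                      {c: 0.02 for c in COMPONENTS})
        assert np.allclose(ct.nmr, sdg.nmr)
        assert np.allclose(ct.cmr, sdg.cmr)

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ConfigError):
            ScenarioSpec(kind="wishful_thinking")


class TestProjectedDeaths:
    def _births(self):
        return pd.Series(100_000.0, index=np.arange(2020, 2031))

    def _lead(self, base):
        years = np.arange(2020, 2024)
        b = base.at(2024)
        return ComponentRates("X", years,
                              np.full(4, b["nmr"]), np.full(4, b["pnmr"]),
                              np.full(4, b["cmr"]))

    def test_zero_rates_zero_deaths(self):
        years = np.arange(2024, 2031)
        comp = ComponentRates("X", years, np.full(7, 1e-9), np.zeros(7),
                              np.zeros(7))
        lead = ComponentRates("X", np.arange(2020, 2024), np.full(4, 1e-9),
                              np.zeros(4), np.zeros(4))
        _, totals = projected_deaths(comp, self._births(), lead)
        assert totals["under5"] < 1.0

    def test_scenario_cumulative_ordering(self):
        base = _base(nmr=0.022, pnmr=0.013, cmr=0.018)
        arrs = {c: 0.02 for c in COMPONENTS}
        totals = {}
        for kind in ("constant", "current_trends", "sdg_target",
                     "high_income"):
            proj = project(base, ScenarioSpec(kind=kind),
                           arrs if kind != "constant"
                           else {c: 0.0 for c in COMPONENTS})
            _, t = projected_deaths(proj, self._births(), self._lead(base))
            totals[kind] = t["under5"]
        assert (totals["high_income"] <= totals["sdg_target"]
                <= totals["current_trends"] <= totals["constant"])

    def test_missing_births_rejected(self):
        base = _base()
        proj = project(base, ScenarioSpec(kind="constant"),
                       {c: 0.0 for c in COMPONENTS})
        short = pd.Series(1000.0, index=np.arange(2024, 2028))
        with pytest.raises(ValueError, match="births"):
            projected_deaths(proj, short)


def test_components_from_trajectories_consistency():
    years = np.arange(2020, 2025)
    nmr = np.full(5, 17.2)
    imr = np.full(5, 27.7)
    u5 = np.full(5, 37.4)
    comp = components_from_trajectories("W", years, nmr, imr, u5)
    n, i, u = recombine(comp.nmr, comp.pnmr, comp.cmr)
    assert np.allclose(u * 1000, 37.4)
    assert np.allclose(i * 1000, 27.7)
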