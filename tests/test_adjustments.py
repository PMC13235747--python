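"""Crisis and HIV adjustments: allocation arithmetic and additivity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from u5m.adjustments import (
    CrisisEvent,
    allocate_crisis_deaths,
    apply_crisis_adjustment,
    apply_hiv_adjustment,
    crisis_rate_additions,
)
from u5m.b3 import PosteriorTrajectories


def _traj(indicator, level, years=None, n_draws=20):
    years = years if years is not None else np.arange(2000, 2011)
    return PosteriorTrajectories("C", indicator, years,
                                 np.full((n_draws, years.size), level))


def _trio(nmr=15.0, imr=25.0, u5=40.0):
    return {"NMR": _traj("NMR", nmr), "IMR": _traj("IMR", imr),
            "U5MR": _traj("U5MR", u5)}


class TestAllocate:
    def test_fraction_arithmetic(self):
        ev = CrisisEvent("C", (2005,), 1000.0, (0.1, 0.1, 0.2, 0.6))
        counts = allocate_crisis_deaths(ev)
        assert counts == {"neonatal": 100.0, "postneonatal": 100.0,
                          "child": 200.0}

    def test_all_adult_pattern_gives_zero_child_deaths(self):
        ev = CrisisEvent("C", (2005,), 1000.0, (0.0, 0.0, 0.0, 1.0))
        assert sum(allocate_crisis_deaths(ev).values()) == 0.0

    def test_direct_vr_counts_override_pattern(self):
        ev = CrisisEvent("C", (2005,), 1000.0, (0.1, 0.1, 0.2, 0.6),
                         direct_counts=(7.0, 8.0, 9.0))
        assert allocate_crisis_deaths(ev) == {
            "neonatal": 7.0, "postneonatal": 8.0, "child": 9.0}

    def test_bad_pattern_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            CrisisEvent("C", (2005,), 10.0, (0.5, 0.1, 0.2, 0.1))


class TestCrisisAdjustment:
    def test_no_qualifying_events_is_identity(self):
        trajs = _trio()
        births = pd.Series(1000.0, index=np.arange(2000, 2011))
        ev = CrisisEvent("C", (2005,), 500.0, (0.1, 0.1, 0.2, 0.6),
                         meets_criteria=False)
        out = apply_crisis_adjustment(trajs, [ev], births)
        for ind in trajs:
            assert np.array_equal(out[ind].draws, trajs[ind].draws)

    def test_known_event_adds_exact_rate(self):
        trajs = _trio()
        births = pd.Series(10_000.0, index=np.arange(2000, 2011))
        # 50 under-5 deaths on 10 000 births = +5.0 per 1000 on U5MR
        ev = CrisisEvent("C", (2005,), 100.0, (0.1, 0.15, 0.25, 0.5))
        out = apply_crisis_adjustment(trajs, [ev], births)
        i = 5
        assert np.allclose(out["U5MR"].draws[:, i] - 40.0, 5.0)
        assert np.allclose(out["NMR"].draws[:, i] - 15.0, 1.0)
        assert np.allclose(out["IMR"].draws[:, i] - 25.0, 2.5)
        # other years untouched
        assert np.allclose(out["U5MR"].draws[:, 4], 40.0)
        assert out["U5MR"].crisis_adjusted

    def test_missing_births_year_rejected(self):
        births = pd.Series(1000.0, index=np.arange(2000, 2005))
        ev = CrisisEvent("C", (2009,), 100.0, (0.1, 0.15, 0.25, 0.5))
        with pytest.raises(ValueError, match="2009"):
            crisis_rate_additions([ev], births)

    @given(st.floats(0.0, 0.3), st.floats(0.0, 0.3), st.floats(0.0, 0.3),
           st.floats(10.0, 5000.0))
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_ordering_preserved_for_any_event(self, f1, f2, f3, total):
        rest = 1.0 - (f1 + f2 + f3)
        if rest < 0:
            return
        trajs = _trio()
        births = pd.Series(10_000.0, index=np.arange(2000, 2011))
        ev = CrisisEvent("C", (2003,), total, (f1, f2, f3, rest))
        out = apply_crisis_adjustment(trajs, [ev], births)
        assert np.all(out["NMR"].draws <= out["IMR"].draws + 1e-9)
        assert np.all(out["IMR"].draws <= out["U5MR"].draws + 1e-9)

    def test_adjustment_invertible_by_subtraction(self):
        trajs = _trio()
        births = pd.Series(10_000.0, index=np.arange(2000, 2011))
        events = [CrisisEvent("C", (2003,), 200.0, (0.1, 0.1, 0.1, 0.7)),
                  CrisisEvent("C", (2008,), 300.0, (0.2, 0.1, 0.1, 0.6))]
        out = apply_crisis_adjustment(trajs, events, births)
        adds = crisis_rate_additions(events, births)
        recovered = out["U5MR"].draws.copy()
        for year, row in adds.iterrows():
            i = np.nonzero(out["U5MR"].years == year)[0][0]
            recovered[:, i] -= row["U5MR"]
        assert np.allclose(recovered, trajs["U5MR"].draws)


class TestHivAdjustment:
    def test_empty_table_is_identity(self):
        trajs = _trio()
        out = apply_hiv_adjustment(trajs, None)
        assert out["U5MR"] is trajs["U5MR"]

    def test_exact_addition_in_named_year(self):
        trajs = _trio()
        tab = pd.DataFrame({"year": [2000], "u5mr_add": [2.0],
                            "nmr_add": [0.5]})
        out = apply_hiv_adjustment(trajs, tab)
        assert np.allclose(out["U5MR"].draws[:, 0] - 40.0, 2.0)
        assert np.allclose(out["NMR"].draws[:, 0] - 15.0, 0.5)
        assert np.allclose(out["U5MR"].draws[:, 1], 40.0)

    def test_multiple_years_accumulate_independently(self):
        trajs = _trio()
        tab = pd.DataFrame({"year": [2001, 2004], "u5mr_add": [1.0, 3.0],
                            "nmr_add": [0.2, 0.6]})
        out = apply_hiv_adjustment(trajs, tab)
        assert np.allclose(out["U5MR"].draws[:, 1] - 40.0, 1.0)
        assert np.allclose(out["U5MR"].draws[:, 4] - 40.0, 3.0)

    def test_negative_adjustment_rejected(self):
        tab = pd.DataFrame({"year": [2001], "u5mr_add": [-1.0],
                            "nmr_add": [0.0]})
        with pytest.raises(ValueError):
            apply_hiv_adjustment(_trio(), tab)


def test_disjoint_adjustments_commute():
    trajs = _trio()
    births = pd.Series(10_000.0, index=np.arange(2000, 2011))
    ev = [CrisisEvent("C", (2002,), 100.0, (0.1, 0.1, 0.1, 0.7))]
    hiv = pd.DataFrame({"year": [2007], "u5mr_add": [1.5], "nmr_add": [0.3]})
    ab = apply_hiv_adjustment(apply_crisis_adjustment(trajs, ev, births), hiv)
    ba = apply_crisis_adjustment(apply_hiv_adjustment(trajs, hiv), ev, births)
    for ind in trajs:
        assert np.allclose(ab[ind].draws, ba[ind].draws)
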