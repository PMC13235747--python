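"""Cohort deaths engine: identities, oracles and monotonicity."""

import numpy as np
import pandas as pd
import pytest

from u5m.deaths import (
    SEGMENT_BOUNDS,
    AgeSegmentHazards,
    compute_deaths,
    deaths_uncertainty,
    rates_to_hazards,
)


def _const_hazards(years, nmr, imr, u5):
    n = len(years)
    return rates_to_hazards(np.full(n, nmr), np.full(n, imr), np.full(n, u5),
                            years=years)


class TestRatesToHazards:
    def test_equal_rates_zero_later_hazards(self):
        hz = rates_to_hazards(20.0, 20.0, 20.0)
        assert hz.hazard[0, 1] == 0.0
        assert hz.hazard[0, 2] == 0.0

    def test_survival_product_reconstructs_u5mr(self):
        hz = rates_to_hazards(17.2, 27.7, 37.4)
        q = hz.q[0]
        surv = np.prod(1 - q)
        assert surv == pytest.approx(1 - 37.4 / 1000, abs=1e-15)

    def test_postneonatal_probability_at_published_global_rates(self):
        hz = rates_to_hazards(17.2, 27.7, 37.4)
        assert hz.q[0, 1] == pytest.approx(
            1 - (1 - 0.0277) / (1 - 0.0172), abs=1e-12)
        assert hz.q[0, 1] == pytest.approx(0.01068, abs=5e-5)

    def test_ordering_violation_rejected(self):
        with pytest.raises(ValueError):
            rates_to_hazards(30.0, 20.0, 40.0)


class TestComputeDeaths:
    def test_zero_hazards_zero_deaths(self):
        years = np.arange(2000, 2010)
        hz = AgeSegmentHazards(years=years,
                               hazard=np.zeros((10, 3)), q=np.zeros((10, 3)))
        t = compute_deaths(pd.Series(1000.0, index=years), hz)
        assert np.all(t.deaths == 0.0)

    def test_steady_state_identity(self):
        """Constant births B and rates: annual under-5 deaths = B x U5MR/1000."""
        years = np.arange(2000, 2021)
        hz = _const_hazards(years, 17.2, 27.7, 37.4)
        births = pd.Series(100_000.0, index=years)
        t = compute_deaths(births, hz)
        sel = t.years >= t.complete_from
        expected = 100_000 * 37.4 / 1000
        assert np.allclose(t.point("under5")[sel], expected, rtol=1e-3)
        assert np.allclose(t.point("neonatal")[sel], 100_000 * 17.2 / 1000,
                           rtol=1e-3)

    def test_conservation_of_cohort(self):
        """Deaths through age 5 plus survivors equal the cohort size."""
        years = np.arange(2000, 2011)
        hz = _const_hazards(years, 20.0, 30.0, 45.0)
        births = pd.Series(0.0, index=years)
        births.loc[2000] = 10_000.0  # single cohort
        t = compute_deaths(births, hz)
        total_deaths = t.point("under5").sum()
        assert total_deaths == pytest.approx(10_000 * 45.0 / 1000, rel=1e-12)

    def test_age_group_additivity(self, rng):
        years = np.arange(2000, 2012)
        rates = np.sort(rng.uniform(5, 80, (len(years), 3)), axis=1)
        hz = rates_to_hazards(rates[:, 0], rates[:, 1], rates[:, 2], years=years)
        t = compute_deaths(pd.Series(50_000.0, index=years), hz)
        assert np.allclose(t.group("under5"),
                           t.group("neonatal") + t.group("1-59m"), atol=1e-9)
        assert np.all(t.group("neonatal") <= t.group("infant") + 1e-9)
        assert np.all(t.group("infant") <= t.group("under5") + 1e-9)

    def test_monotone_response_to_hazards(self):
        years = np.arange(2000, 2012)
        hz_lo = _const_hazards(years, 15.0, 25.0, 35.0)
        hz_hi = _const_hazards(years, 15.0, 25.0, 35.0)
        hz_hi.hazard[8, :] *= 1.5  # raise one year's hazards
        births = pd.Series(20_000.0, index=years)
        lo = compute_deaths(births, hz_lo)
        hi = compute_deaths(births, hz_hi)
        i = np.nonzero(lo.years == years[8])[0][0]
        assert hi.point("under5")[i] > lo.point("under5")[i]

    def test_missing_hazard_year_named(self):
        years = np.arange(2000, 2010)
        hz = _const_hazards(years[:5], 10.0, 15.0, 20.0)
        with pytest.raises(ValueError, match="2005"):
            compute_deaths(pd.Series(1000.0, index=years), hz)


def _daily_oracle(births, rates):
    """Expected deaths by (year, segment) at daily resolution."""
    h = {y: rates_to_hazards(*rates[y]).hazard[0] for y in rates}
    out = {y: np.zeros(3) for y in rates}
    dt = 1 / 365.25
    for by, b in births.items():
        for wk in range(52):
            surv = b / 52
            age = 0.0
            while age < 5.0 - 1e-12:
                cal_year = int(np.floor(by + (wk + 0.5) / 52 + age + 1e-12))
                if cal_year not in h:
                    break
                seg = (0 if age < SEGMENT_BOUNDS[1]
                       else (1 if age < 1.0 else 2))
                step = min(dt, 5.0 - age)
                p = -np.expm1(-h[cal_year][seg] * step)
                out[cal_year][seg] += surv * p
                surv *= 1 - p
                age += step
    return out


def test_agreement_with_daily_resolution_microsimulation():
    """Within 0.5% of a brute-force daily-step simulation on a 3-year toy."""
    years = [2000, 2001, 2002]
    rates = {2000: (20.0, 30.0, 45.0), 2001: (18.0, 27.0, 40.0),
             2002: (15.0, 24.0, 34.0)}
    births = {y: 50_000.0 for y in years}
    oracle = _daily_oracle(births, rates)
    hz = rates_to_hazards(*np.array([rates[y] for y in years]).T,
                          years=np.array(years))
    t = compute_deaths(pd.Series(births), hz)
    for i, y in enumerate(years):
        orc = oracle[y]
        expected = np.array([orc[0], orc[0] + orc[1], orc[1] + orc[2],
                             orc.sum()])
        assert np.allclose(t.deaths[i, 0, :], expected, rtol=5e-3)


def test_late_cohort_neonatal_deaths_split_across_years():
    """A cohort born late in year t leaves some neonatal deaths to t+1."""
    years = np.arange(2000, 2006)
    hz = _const_hazards(years, 25.0, 30.0, 35.0)
    births = pd.Series(0.0, index=years)
    births.loc[2001] = 10_000.0
    t = compute_deaths(births, hz)
    i1 = np.nonzero(t.years == 2001)[0][0]
    i2 = np.nonzero(t.years == 2002)[0][0]
    neo1, neo2 = t.point("neonatal")[i1], t.point("neonatal")[i2]
    assert neo1 > neo2 > 0  # most in the birth year, some spill to the next
    assert neo1 + neo2 == pytest.approx(10_000 * 25.0 / 1000, rel=1e-9)


class TestDeathsUncertainty:
    def _table(self, draws):
        years = np.arange(2000, 2012)
        hz = AgeSegmentHazards(
            years=years, hazard=np.abs(draws), q=np.abs(draws))
        return compute_deaths(pd.Series(10_000.0, index=years), hz)

    def test_identical_draws_zero_width(self, rng):
        h = np.tile(rng.uniform(0.001, 0.01, (12, 1, 3)), (1, 20, 1))
        t = self._table(h)
        ui = deaths_uncertainty(t)
        assert np.allclose(ui["upper"] - ui["lower"], 0.0, atol=1e-9)

    def test_scaling_equivariance(self, rng):
        h = rng.uniform(0.001, 0.01, (12, 30, 3))
        t = self._table(h)
        t2 = self._table(h)
        t2.deaths = t2.deaths * 2.0
        ui1 = deaths_uncertainty(t)
        ui2 = deaths_uncertainty(t2)
        assert np.allclose(ui2["median"], 2 * ui1["median"])
        assert np.allclose(ui2["upper"], 2 * ui1["upper"])

    def test_matches_sort_based_oracle(self, rng):
        h = rng.uniform(0.001, 0.02, (12, 50, 3))
        t = self._table(h)
        ui = deaths_uncertainty(t)
        row = ui[(ui["year"] == 2005) & (ui["age_group"] == "under5")].iloc[0]
        gi = t.groups.index("under5")
        yi = np.nonzero(t.years == 2005)[0][0]
        draws = np.sort(t.deaths[yi, :, gi])
        assert row["lower"] == pytest.approx(np.percentile(draws, 5))
        assert row["median"] == pytest.approx(np.percentile(draws, 50))
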