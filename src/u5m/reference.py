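"""Published global and regional summary estimates used in worked examples.

Median estimates from the UN IGME 2025 estimation round (childmortality.org):
regional and world under-5 and neonatal mortality rates (deaths per 1000
live births) and death counts (thousands) for 1990, 2000, 2015 and 2024,
plus 2024 live-birth totals (millions).  These few headline numbers let the
pace-of-decline and share metrics be exercised and verified on real
published inputs without any access to the underlying observation database.
"""

from __future__ import annotations

import io

import pandas as pd

SUB_SAHARAN_REGIONS = ("West and Central Africa", "Eastern and Southern Africa")

_RATES_CSV = """\
region,year,u5mr,nmr
West and Central Africa,1990,194.9,47.5
West and Central Africa,2000,169.5,41.9
West and Central Africa,2015,102.6,32.3
West and Central Africa,2024,91.0,30.2
Eastern and Southern Africa,1990,163.0,42.4
Eastern and Southern Africa,2000,131.6,36.1
Eastern and Southern Africa,2015,65.7,25.8
Eastern and Southern Africa,2024,50.2,22.7
South Asia,1990,131.0,58.9
South Asia,2000,93.5,45.7
South Asia,2015,49.4,29.5
South Asia,2024,33.5,21.1
Middle East and North Africa,1990,69.0,28.2
Middle East and North Africa,2000,44.0,21.7
Middle East and North Africa,2015,25.1,13.8
Middle East and North Africa,2024,20.5,11.9
Latin America and Caribbean,1990,54.6,22.4
Latin America and Caribbean,2000,32.7,15.8
Latin America and Caribbean,2015,18.3,10.0
Latin America and Caribbean,2024,15.4,8.3
East Asia and Pacific,1990,56.4,27.6
East Asia and Pacific,2000,39.6,19.9
East Asia and Pacific,2015,16.6,8.3
East Asia and Pacific,2024,13.2,6.7
Eastern Europe and Central Asia,1990,46.5,20.3
Eastern Europe and Central Asia,2000,34.9,16.5
Eastern Europe and Central Asia,2015,13.8,7.2
Eastern Europe and Central Asia,2024,11.1,5.6
North America,1990,11.0,5.6
North America,2000,8.3,4.6
North America,2015,6.6,3.9
North America,2024,6.4,3.6
Western Europe,1990,10.4,5.5
Western Europe,2000,6.2,3.5
Western Europe,2015,4.0,2.4
Western Europe,2024,3.8,2.4
World,1990,93.5,36.6
World,2000,76.7,30.3
World,2015,42.9,19.4
World,2024,37.4,17.2
"""

_DEATHS_CSV = """\
region,year,under5_deaths_thousands,neonatal_deaths_thousands
West and Central Africa,1990,2062,529
West and Central Africa,2000,2275,595
West and Central Africa,2015,1963,635
West and Central Africa,2024,1918,656
Eastern and Southern Africa,1990,1869,510
Eastern and Southern Africa,2000,1818,519
Eastern and Southern Africa,2015,1160,466
Eastern and Southern Africa,2024,1014,468
South Asia,1990,4988,2283
South Asia,2000,3750,1868
South Asia,2015,1839,1100
South Asia,2024,1196,756
Middle East and North Africa,1990,590,244
Middle East and North Africa,2000,344,172
Middle East and North Africa,2015,267,148
Middle East and North Africa,2024,204,119
Latin America and Caribbean,1990,644,267
Latin America and Caribbean,2000,377,183
Latin America and Caribbean,2015,192,105
Latin America and Caribbean,2024,143,77
East Asia and Pacific,1990,2371,1186
East Asia and Pacific,2000,1250,635
East Asia and Pacific,2015,539,264
East Asia and Pacific,2024,283,141
Eastern Europe and Central Asia,1990,339,146
Eastern Europe and Central Asia,2000,184,86
Eastern Europe and Central Asia,2015,89,47
Eastern Europe and Central Asia,2024,58,29
North America,1990,49,26
North America,2000,35,20
North America,2015,29,17
North America,2024,26,15
Western Europe,1990,58,31
Western Europe,2000,31,17
Western Europe,2015,20,12
Western Europe,2024,16,10
World,1990,12970,5220
World,2000,10063,4095
World,2015,6096,2793
World,2024,4858,2271
"""

#: 2024 live births, millions
BIRTHS_2024_MILLIONS = {
    "Sub-Saharan Africa": 42.4,
    "South Asia": 35.9,
    "World": 132.4,
}


def summary_rates() -> pd.DataFrame:
    """Regional/world U5MR and NMR medians (per 1000), selected years."""
    return pd.read_csv(io.StringIO(_RATES_CSV))


def summary_deaths() -> pd.DataFrame:
    """Regional/world under-5 and neonatal deaths (thousands), selected years."""
    return pd.read_csv(io.StringIO(_DEATHS_CSV))


def world_rate(indicator: str, year: int) -> float:
    df = summary_rates()
    row = df[(df["region"] == "World") & (df["year"] == year)]
    return float(row["u5mr" if indicator == "U5MR" else "nmr"].iloc[0])


def region_rate(region: str, indicator: str, year: int) -> float:
    df = summary_rates()
    row = df[(df["region"] == region) & (df["year"] == year)]
    return float(row["u5mr" if indicator == "U5MR" else "nmr"].iloc[0])


def region_deaths(region: str, group: str, year: int) -> float:
    df = summary_deaths()
    row = df[(df["region"] == region) & (df["year"] == year)]
    col = ("under5_deaths_thousands" if group == "under5"
           else "neonatal_deaths_thousands")
    return float(row[col].iloc[0])
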