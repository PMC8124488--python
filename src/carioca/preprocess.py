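"""Bespoke data-construction rules for the areal hospitalization study.

Covers the correction of counts for a multi-year facility closure, the
population interpolation used for non-census years, crude hospitalization
ratios (period counts over period population, per 1000), the annual ratio
series behind the descriptive sequence charts, and the rank-based scoring
of traffic density and tunnel portals into ordinal covariates.

Corrected counts stay real-valued through the pipeline; rounding (half to
even) happens only if a corrected year feeds the Poisson outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "RoadRecord",
    "impute_closure_counts",
    "interpolate_population",
    "moving_average_population",
    "crude_ratio",
    "annual_ratio_series",
    "score_traffic",
    "score_tunnels",
    "rank_bins",
    "TUNNEL_FIXTURE_BINS",
]

#: Upper edges of the published tunnel-count categories
#: ({0}, 1-5, 6-15, 16-30, >30), mapped to ordinal scores 1-5.
TUNNEL_FIXTURE_BINS = (0, 5, 15, 30)


@dataclass
class RoadRecord:
    """One monitored road with its 24-h average vehicle counts.

    ``measurements`` holds one value per monitoring point; a road with no
    monitoring data has an empty list and ``has_data`` False.
    """

    road_id: str
    area_id: str
    measurements: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if any(m < 0 for m in self.measurements):
            raise ValueError(f"road {self.road_id}: negative traffic measurement")

    @property
    def has_data(self) -> bool:
        return len(self.measurements) > 0

    @property
    def density(self) -> float:
        """Arithmetic mean of the monitoring-point measurements."""
        if not self.has_data:
            raise ValueError(f"road {self.road_id} has no measurements")
        return float(np.mean(self.measurements))


def impute_closure_counts(
    series: Mapping[int, float],
    closure_months: Mapping[int, int],
    min_lookback: int = 2,
    max_lookback: int = 4,
) -> dict[int, float]:
    """Correct per-year counts of one area for a facility closure.

    Each closure year receives ``mean(corrected previous years) *
    months_closed / 12`` on top of its observed count.  The averaging
    window starts ``min_lookback`` years before the first closure year and
    grows with the cascade (capped at ``max_lookback`` years), so later
    closure years average over already-corrected earlier years — e.g. with
    closures in 2010 (2 mo), 2011 (12 mo), 2012 (6 mo): 2010 uses the mean
    of 2008-2009, 2011 the mean of 2008-2010, 2012 the mean of 2008-2011.
    """
    closure_years = sorted(y for y, m in closure_months.items() if m != 0)
    for y, m in closure_months.items():
        if not 0 <= m <= 12:
            raise ValueError(f"months closed in {y} must be in 0..12, got {m}")
    corrected = {y: float(v) for y, v in series.items()}
    if not closure_years:
        return corrected
    first = closure_years[0]
    for y in closure_years:
        start = max(y - max_lookback, first - min_lookback)
        window = [yy for yy in range(start, y) if yy in corrected]
        if len(window) < min_lookback:
            raise ValueError(
                f"closure year {y}: need at least {min_lookback} prior years, "
                f"have {len(window)}"
            )
        history_mean = float(np.mean([corrected[yy] for yy in window]))
        corrected[y] = corrected[y] + history_mean * closure_months[y] / 12.0
    return corrected


def interpolate_population(
    census: pd.DataFrame, city_totals: pd.DataFrame
) -> pd.DataFrame:
    """Spread per-year city totals across areas by census-year shares.

    ``census`` is a tidy population panel for the census year (columns
    ``area_id, year, stratum, population``); ``city_totals`` has columns
    ``year, stratum, population`` with the citywide total per year.  The
    output assigns each area ``share_census * city_total[year]`` per
    stratum, so per-year area populations sum to the city total exactly.
    """
    out_rows = []
    for stratum, grp in census.groupby("stratum"):
        if grp["area_id"].duplicated().any():
            raise ValueError(f"census has duplicate areas for stratum {stratum!r}")
        shares = grp.set_index("area_id")["population"]
        if (shares <= 0).any():
            raise ValueError("census populations must be positive")
        shares = shares / shares.sum()
        totals = city_totals.loc[city_totals["stratum"] == stratum]
        if totals.empty:
            raise ValueError(f"no city totals for stratum {stratum!r}")
        for _, row in totals.iterrows():
            for area_id, share in shares.items():
                out_rows.append(
                    (area_id, int(row["year"]), stratum, share * float(row["population"]))
                )
    return pd.DataFrame(out_rows, columns=["area_id", "year", "stratum", "population"])


def moving_average_population(
    panel: pd.DataFrame, target_years: Sequence[int]
) -> pd.DataFrame:
    """Impute missing years as the mean of the three preceding years.

    Applied recursively in chronological order, so the second imputed year
    averages over the first (age-specific populations for the last study
    years are produced this way).  Requires the three prior years to be
    present (observed or previously imputed) for every (area, stratum).
    """
    panel = panel.copy()
    for year in sorted(target_years):
        new_rows = []
        for (area_id, stratum), grp in panel.groupby(["area_id", "stratum"]):
            by_year = grp.set_index("year")["population"]
            prior = [year - 3, year - 2, year - 1]
            if any(y not in by_year.index for y in prior):
                raise ValueError(
                    f"{area_id}/{stratum}: need three years before {year} for the "
                    "moving average"
                )
            new_rows.append(
                (area_id, year, stratum, float(by_year.loc[prior].mean()))
            )
        panel = pd.concat(
            [
                panel,
                pd.DataFrame(
                    new_rows, columns=["area_id", "year", "stratum", "population"]
                ),
            ],
            ignore_index=True,
        )
    return panel


def _window_sums(
    counts: pd.DataFrame,
    pop: pd.DataFrame,
    years: Sequence[int],
    stratum: str,
) -> tuple[pd.Series, pd.Series]:
    c = counts[(counts["stratum"] == stratum) & counts["year"].isin(years)]
    p = pop[(pop["stratum"] == stratum) & pop["year"].isin(years)]
    c_years = set(c["year"].unique())
    p_years = set(p["year"].unique())
    missing = set(years) - (c_years & p_years)
    if missing:
        raise ValueError(f"window years {sorted(missing)} not covered by both panels")
    num = c.groupby("area_id")["count"].sum()
    den = p.groupby("area_id")["population"].sum()
    num, den = num.align(den, fill_value=np.nan)
    if den.isna().any() or (den <= 0).any():
        raise ValueError("zero or missing summed population in the window")
    return num.fillna(0.0), den


def crude_ratio(
    counts: pd.DataFrame,
    pop: pd.DataFrame,
    years: Sequence[int],
    stratum: str = "total",
    per: float = 1000.0,
) -> pd.Series:
    """Period hospitalization ratio per area: sum(counts)/sum(pop) x per.

    Pools numerator and denominator over the year window (default scale:
    per 1000 inhabitants), so the result is invariant to how the window is
    split into sub-windows.
    """
    num, den = _window_sums(counts, pop, years, stratum)
    return (num / den * per).rename("ratio")


def annual_ratio_series(
    counts: pd.DataFrame,
    pop: pd.DataFrame,
    years: Sequence[int],
    stratum: str = "total",
    per: float = 1000.0,
) -> pd.DataFrame:
    """Year-wise crude ratios: the table behind the descriptive sequence charts.

    Returns a DataFrame indexed by area with one column per year.
    """
    cols = {}
    for year in years:
        cols[year] = crude_ratio(counts, pop, [year], stratum=stratum, per=per)
    return pd.DataFrame(cols)


def rank_bins(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Rank-based equal-count binning into categories 1..n_bins.

    Ties share the lower category (tied values take their minimum rank).
    Invariant to relabeling and to monotone increasing rescaling.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n == 0:
        raise ValueError("cannot bin an empty value set")
    ranks = rankdata(values, method="min")  # 1..n, ties -> min rank
    return ((ranks - 1) * n_bins // n + 1).astype(int)


def score_traffic(
    roads: Sequence[RoadRecord],
) -> tuple[pd.Series, pd.Series]:
    """Ordinal 1-5 traffic-density score per area.

    Steps: (1) per-road density is the arithmetic mean over monitoring
    points; (2) roads with data are ranked into quartiles of density and
    weighted 1-4 (lowest quartile -> 1), roads without data weigh 0;
    (3) weights are summed within each area; (4) the per-area sums are
    stratified into quintiles, giving scores 1-5.

    Returns ``(scores, weight_sums)`` indexed by area_id.
    """
    if not roads:
        raise ValueError("need at least one road record")
    with_data = [r for r in roads if r.has_data]
    if not with_data:
        raise ValueError("need at least one road with traffic data")
    densities = np.array([r.density for r in with_data])
    quartile_weights = rank_bins(densities, 4)
    weight_of = {r.road_id: int(w) for r, w in zip(with_data, quartile_weights)}
    sums: dict[str, float] = {}
    for r in roads:
        sums.setdefault(r.area_id, 0.0)
        sums[r.area_id] += weight_of.get(r.road_id, 0)
    areas = sorted(sums)
    weight_sums = pd.Series([sums[a] for a in areas], index=areas, name="weight_sum")
    scores = pd.Series(
        rank_bins(weight_sums.to_numpy(), 5), index=areas, name="traffic_score"
    )
    return scores, weight_sums


def score_tunnels(
    counts: Mapping[str, int] | pd.Series,
    bins: Sequence[float] | None = None,
) -> pd.Series:
    """Ordinal 1-5 score of tunnel entrance/exit counts per area.

    With ``bins`` (upper category edges, e.g. the published
    ``TUNNEL_FIXTURE_BINS`` = (0, 5, 15, 30) for categories {0}, 1-5,
    6-15, 16-30, >30) the score is the 1-based category index; without,
    counts are stratified into rank-based quintiles.
    """
    counts = pd.Series(counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("tunnel counts must be nonnegative")
    if bins is not None:
        edges = np.asarray(bins, dtype=float)
        scores = np.searchsorted(edges, counts.to_numpy(), side="left") + 1
    else:
        scores = rank_bins(counts.to_numpy(), 5)
    return pd.Series(scores.astype(int), index=counts.index, name="tunnel_score")
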