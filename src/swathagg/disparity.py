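"""Population-weighted exposure statistics and disparity metrics by region.

The exposure unit is the per-polygon average column (10^15 molecules/cm^2)
produced by the oversampler; demographic weights come from a GEOID-keyed
table of group population counts.  For each region (a CBSA-like grouping
of polygons) we compute

* the population-weighted mean exposure of each demographic group,
* the relative disparity, 100 x (comparison - reference) / reference, with
  white non-Hispanic (racial/ethnic) and the high-income group (income) as
  references — positive values mean the minority / low-income group is
  more exposed,
* the same quantities restricted to the most polluted days (top fraction
  of days ranked by the regional daily mean), and the change in disparity
  between the two windows in percentage points.

Relative disparities are invariant to rescaling all exposures by a common
positive factor, so they are comparable across regions with different
absolute pollution levels.
"""

from __future__ import annotations

import datetime as _dt
import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

#: Racial/ethnic group columns; 'minority' pools the last four.
RACE_COLUMNS = ["white", "hispanic", "black", "asian", "native_american"]
MINORITY_COLUMNS = ["hispanic", "black", "asian", "native_american"]
#: Income-to-poverty-ratio tails; the middle band (1.24–1.5) belongs to neither.
INCOME_COLUMNS = ["income_below_1_24", "income_above_1_5"]


@dataclass(frozen=True)
class DemographicTable:
    """GEOID-indexed group population counts.

    ``table`` has one row per geoid and the columns in RACE_COLUMNS and
    INCOME_COLUMNS.  Counts must be non-negative.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in RACE_COLUMNS + INCOME_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"demographic table missing columns: {missing}")
        if (self.table[RACE_COLUMNS + INCOME_COLUMNS] < 0).any().any():
            raise ValidationError("negative population counts")

    def group_population(self, group: str) -> pd.Series:
        """Population per geoid for 'white', 'minority', 'low_income',
        'high_income', 'total', or any raw column."""
        t = self.table
        if group == "minority":
            return t[MINORITY_COLUMNS].sum(axis=1)
        if group == "low_income":
            return t["income_below_1_24"]
        if group == "high_income":
            return t["income_above_1_5"]
        if group == "total":
            return t[RACE_COLUMNS].sum(axis=1)
        return t[group]


def population_weighted_mean(
    values: Mapping[str, float] | pd.Series, populations: Mapping[str, float] | pd.Series
) -> float | None:
    """Sum(pop x value) / Sum(pop) over geoids with both present.

    Geoids with a missing (None/NaN) value are excluded from numerator and
    denominator alike.  Returns None when no population remains.
    """
    v = pd.Series(dict(values), dtype=float) if not isinstance(values, pd.Series) else values.astype(float)
    p = pd.Series(dict(populations), dtype=float) if not isinstance(populations, pd.Series) else populations.astype(float)
    joined = pd.concat([v.rename("v"), p.rename("p")], axis=1, join="inner").dropna()
    joined = joined[joined["p"] > 0]
    total = joined["p"].sum()
    if total <= 0:
        return None
    return float((joined["v"] * joined["p"]).sum() / total)


def relative_disparity(reference_mean: float | None, comparison_mean: float | None) -> float | None:
    """Percent difference of the comparison group from the reference group.

    Positive when the comparison group (minority / low-income) is more
    exposed.  Undefined (None) when the reference is missing or <= 0.
    """
    if reference_mean is None or comparison_mean is None or reference_mean <= 0:
        return None
    return 100.0 * (comparison_mean - reference_mean) / reference_mean


def regional_daily_means(
    daily_values: pd.DataFrame, min_coverage: float = 0.5
) -> pd.Series:
    """Unweighted regional mean per day, restricted to valid days.

    ``daily_values`` is a (date x geoid) frame of polygon means with NaN
    for missing polygons.  A day is valid iff at least ``min_coverage`` of
    the region's polygons are non-missing; invalid days are dropped so
    cloud-biased days cannot masquerade as clean ones.
    """
    coverage = daily_values.notna().mean(axis=1)
    valid = daily_values[coverage >= min_coverage]
    return valid.mean(axis=1)


def select_polluted_days(
    daily_means: Mapping[_dt.date, float] | pd.Series, fraction: float = 0.05
) -> list[_dt.date]:
    """Dates of the ceil(fraction x n) highest regional daily means.

    Ties at the selection boundary go to the earlier date.  Warns below 20
    valid days; returns an empty list for empty input.
    """
    s = pd.Series(dict(daily_means)) if not isinstance(daily_means, pd.Series) else daily_means
    s = s.dropna()
    if len(s) == 0:
        logger.warning("select_polluted_days: no valid days")
        return []
    if len(s) < 20:
        logger.warning("select_polluted_days: only %d valid days", len(s))
    k = math.ceil(fraction * len(s))
    # sort by (-value, date): highest means first, earlier date wins ties
    order = sorted(s.items(), key=lambda kv: (-kv[1], kv[0]))
    return [d for d, _ in order[:k]]


def normalized_gradient(values: Mapping[str, float] | pd.Series) -> pd.Series:
    """Each polygon's value divided by the regional maximum (in (0, 1]).

    A dimensionless map of within-region spatial gradients, comparable
    across regions regardless of absolute pollution level.
    """
    s = pd.Series(dict(values), dtype=float) if not isinstance(values, pd.Series) else values.astype(float)
    s = s.dropna()
    if len(s) == 0:
        return s
    vmax = s.max()
    if vmax <= 0:
        raise ValidationError("normalized_gradient needs a positive regional maximum")
    return s / vmax


@dataclass(frozen=True)
class DisparityResult:
    """Per-region disparity summary for one exposure window."""

    region_id: str
    window_label: str
    n_polygons: int
    mean_all: float | None
    mean_white: float | None
    mean_minority: float | None
    racial_disparity_pct: float | None
    mean_low_income: float | None
    mean_high_income: float | None
    income_disparity_pct: float | None


def _region_result(
    region_id: str,
    label: str,
    values: pd.Series,
    demo: DemographicTable,
) -> DisparityResult:
    means = {
        g: population_weighted_mean(values, demo.group_population(g).reindex(values.index))
        for g in ("total", "white", "minority", "low_income", "high_income")
    }
    return DisparityResult(
        region_id=region_id,
        window_label=label,
        n_polygons=int(values.notna().sum()),
        mean_all=means["total"],
        mean_white=means["white"],
        mean_minority=means["minority"],
        racial_disparity_pct=relative_disparity(means["white"], means["minority"]),
        mean_low_income=means["low_income"],
        mean_high_income=means["high_income"],
        income_disparity_pct=relative_disparity(means["high_income"], means["low_income"]),
    )


def disparity_report(
    exposure_by_window: Mapping[str, Mapping[str, float] | pd.Series],
    demographics: DemographicTable,
    region_map: Mapping[str, str] | pd.Series,
) -> pd.DataFrame:
    """Group means and disparities per region per exposure window.

    ``exposure_by_window`` maps a window label (e.g. 'full', 'top5') to a
    geoid -> mean-column mapping (NaN/None = missing polygon).  When both a
    'full' and another window are present, the report adds
    ``racial_disparity_change_pp`` / ``income_disparity_change_pp`` columns:
    that window's disparity minus the full-window disparity, in percentage
    points.  Regions with no demographic coverage are skipped with a log
    entry.
    """
    regions = pd.Series(dict(region_map)) if not isinstance(region_map, pd.Series) else region_map
    rows: list[DisparityResult] = []
    for label, exposure in exposure_by_window.items():
        values = pd.Series(dict(exposure), dtype=float) if not isinstance(exposure, pd.Series) else exposure.astype(float)
        for region_id in sorted(regions.unique()):
            geoids = regions[regions == region_id].index
            vals = values.reindex(geoids)
            demo_cov = demographics.table.index.intersection(geoids)
            if len(demo_cov) == 0:
                logger.info("region %s skipped: no demographic coverage", region_id)
                continue
            rows.append(_region_result(region_id, label, vals, demographics))
    df = pd.DataFrame([r.__dict__ for r in rows])
    if df.empty:
        return df
    if "full" in exposure_by_window and len(exposure_by_window) > 1:
        base = df[df.window_label == "full"].set_index("region_id")
        for metric in ("racial_disparity_pct", "income_disparity_pct"):
            change = df.apply(
                lambda r: (
                    r[metric] - base.loc[r.region_id, metric]
                    if r.window_label != "full"
                    and r.region_id in base.index
                    and pd.notna(r[metric])
                    and pd.notna(base.loc[r.region_id, metric])
                    else np.nan
                ),
                axis=1,
            )
            df[metric.replace("_pct", "_change_pp")] = change
    return df
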