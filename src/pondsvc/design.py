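"""Covariate construction: monthly climate -> seasonal windows -> design panel.

The survey flies in late May, so the covariates for survey year t are the
four preceding seasons: summer (Jun-Aug, t-1), fall (Sep-Nov, t-1), winter
(Dec t-1 + Jan-Feb t) and spring (Mar-May, t).  Precipitation is summed
within the window and entered as its log; temperature is the unweighted
mean of the monthly means of daily maxima and entered untransformed.  The
lag predictor is the log of the previous year's pond count and time is the
integer survey-year index.  Covariates are deliberately not standardized:
coefficients stay on the log-precipitation / degC scales.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import DesignPanel
from .simulate import SEASONS, ClimatePanel, PREDICTOR_NAMES, StrataGeometry

__all__ = [
    "MissingClimateError",
    "SEASON_MONTHS",
    "validate_monthly",
    "seasonal_aggregate",
    "seasonal_panel",
    "build_design",
    "monthly_from_seasonal",
]

#: (month, survey-year offset) pairs per season; offset -1 means the
#: calendar year before the survey year.
SEASON_MONTHS: dict[str, tuple[tuple[int, int], ...]] = {
    "summer": ((6, -1), (7, -1), (8, -1)),
    "fall": ((9, -1), (10, -1), (11, -1)),
    "winter": ((12, -1), (1, 0), (2, 0)),
    "spring": ((3, 0), (4, 0), (5, 0)),
}

MONTHLY_COLUMNS = ["stratum", "year", "month", "precip_mm", "tmax_c"]


class MissingClimateError(ValueError):
    """A required stratum-year-month climate record is absent."""


def validate_monthly(monthly: pd.DataFrame) -> pd.DataFrame:
    """Check the monthly climate table schema and uniqueness."""
    missing_cols = set(MONTHLY_COLUMNS) - set(monthly.columns)
    if missing_cols:
        raise ValueError(f"monthly climate table missing columns {sorted(missing_cols)}")
    dup = monthly.duplicated(subset=["stratum", "year", "month"])
    if dup.any():
        first = monthly.loc[dup.idxmax(), ["stratum", "year", "month"]]
        raise ValueError(
            f"duplicate monthly climate record for stratum {first['stratum']}, "
            f"year {int(first['year'])}, month {int(first['month'])}"
        )
    if (monthly["precip_mm"] < 0).any():
        raise ValueError("monthly precipitation must be nonnegative")
    if not monthly["month"].between(1, 12).all():
        raise ValueError("months must be in 1..12")
    return monthly


def seasonal_aggregate(monthly: pd.DataFrame, survey_year: int) -> pd.DataFrame:
    """Seasonal totals/means for one survey year, per stratum.

    Returns a frame indexed by stratum with columns ``precip_<season>``
    (mm, summed) and ``tmax_<season>`` (degC, unweighted monthly mean) in
    the fixed season order.  A missing month raises
    :class:`MissingClimateError` naming the stratum, calendar year and
    month.
    """
    validate_monthly(monthly)
    lut = monthly.set_index(["stratum", "year", "month"])
    strata = sorted(monthly["stratum"].unique())
    out: dict[str, list[float]] = {}
    for season in SEASONS:
        months = SEASON_MONTHS[season]
        precip_col, tmax_col = [], []
        for s in strata:
            p_total, t_vals = 0.0, []
            for month, offset in months:
                key = (s, survey_year + offset, month)
                try:
                    rec = lut.loc[key]
                except KeyError:
                    raise MissingClimateError(
                        f"missing climate record: stratum {s}, "
                        f"year {survey_year + offset}, month {month}"
                    ) from None
                p_total += float(rec["precip_mm"])
                t_vals.append(float(rec["tmax_c"]))
            precip_col.append(p_total)
            tmax_col.append(float(np.mean(t_vals)))
        out[f"precip_{season}"] = precip_col
        out[f"tmax_{season}"] = tmax_col
    return pd.DataFrame(out, index=pd.Index(strata, name="stratum"))


def seasonal_panel(
    monthly: pd.DataFrame, survey_years: np.ndarray
) -> ClimatePanel:
    """Seasonal climate for a run of survey years, as a ClimatePanel."""
    survey_years = np.asarray(survey_years)
    frames = [seasonal_aggregate(monthly, int(y)) for y in survey_years]
    S = len(frames[0])
    Y = len(frames)
    precip = np.empty((S, Y, 4))
    tmax = np.empty((S, Y, 4))
    for t, frame in enumerate(frames):
        for k, season in enumerate(SEASONS):
            precip[:, t, k] = frame[f"precip_{season}"].to_numpy()
            tmax[:, t, k] = frame[f"tmax_{season}"].to_numpy()
    if np.any(precip <= 0):
        raise ValueError(
            "a seasonal precipitation total of 0 mm was aggregated; "
            "stratum-scale seasonal totals of exactly zero indicate an "
            "upstream data failure and cannot be log-transformed"
        )
    return ClimatePanel(precip=precip, tmax=tmax, years=survey_years)


def build_design(
    ponds: np.ndarray,
    climate: ClimatePanel,
    geometry: StrataGeometry,
) -> DesignPanel:
    """Assemble the design panel from counts, seasonal climate and geometry.

    ``ponds`` is the (S, Y) panel of strictly positive counts aligned with
    ``climate.years``; the first year is retained only as the lag source.
    Predictor order: intercept, log lag, time, 4 log seasonal precipitation
    totals, 4 seasonal mean daily-maximum temperatures.  Zero or negative
    counts/precipitation are an error for the caller to resolve — no silent
    offsets are applied.
    """
    ponds = np.asarray(ponds, dtype=float)
    S, Y = ponds.shape
    if climate.precip.shape[:2] != (S, Y):
        raise ValueError(
            f"climate panel shape {climate.precip.shape[:2]} does not match "
            f"pond panel ({S}, {Y})"
        )
    if geometry.n_strata != S:
        raise ValueError("geometry stratum count does not match pond panel")
    if np.any(ponds <= 0):
        raise ValueError(
            "pond counts must be strictly positive (log transform); "
            "resolve zero/negative counts upstream"
        )
    if np.any(climate.precip <= 0):
        raise ValueError(
            "seasonal precipitation totals must be strictly positive "
            "(log transform); resolve zeros upstream"
        )
    X = np.empty((S, Y - 1, len(PREDICTOR_NAMES)))
    X[:, :, 0] = 1.0
    X[:, :, 1] = np.log(ponds[:, :-1])
    X[:, :, 2] = np.arange(1, Y)[None, :]
    X[:, :, 3:7] = np.log(climate.precip[:, 1:, :])
    X[:, :, 7:11] = climate.tmax[:, 1:, :]
    return DesignPanel(
        ponds=ponds,
        X=X,
        offset=geometry.offset,
        years=np.asarray(climate.years),
        predictor_names=list(PREDICTOR_NAMES),
    )


def monthly_from_seasonal(
    climate: ClimatePanel, strata_ids: tuple[str, ...]
) -> pd.DataFrame:
    """Expand a seasonal panel to a monthly table (uniform within-season split).

    Precipitation is divided equally across a season's three months and
    temperature repeated, so re-aggregating through
    :func:`seasonal_aggregate` reproduces the seasonal panel.  Used to
    exercise the monthly ingestion path on synthetic data.
    """
    records = []
    years = np.asarray(climate.years)
    for si, s in enumerate(strata_ids):
        for t, survey_year in enumerate(years):
            for k, season in enumerate(SEASONS):
                for month, offset in SEASON_MONTHS[season]:
                    records.append(
                        {
                            "stratum": s,
                            "year": int(survey_year) + offset,
                            "month": month,
                            "precip_mm": climate.precip[si, t, k] / 3.0,
                            "tmax_c": climate.tmax[si, t, k],
                        }
                    )
    # The four windows of consecutive survey years tile the calendar without
    # overlap (Jun t-1 .. May t), so no month is emitted twice.
    return pd.DataFrame.from_records(records)
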