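"""Photo-thermal product (PTP) accumulation from daily weather records.

The photo-thermal product is the running sum, over a window of the seed-growth
period, of daily photosynthetically active radiation (PAR) discounted by a
dimensionless thermal-effectiveness response::

    PTP = sum_i PAR_i * RTE_i          [MJ m^-2]

PAR is taken as half the measured global solar radiation.  RTE_i combines the
single-temperature response ``rte`` evaluated at the daily average, maximum and
minimum air temperatures with weights 0.5 / 0.25 / 0.25.  The temperature
response is a beta-type curve anchored at three cardinal temperatures for seed
development (base 15 degC, optimum 30 degC, ceiling 35 degC): zero at and
outside the base/ceiling, one at the optimum.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError, MissingDataError

logger = logging.getLogger(__name__)

#: Factor converting global solar radiation to photosynthetically active radiation.
PAR_FRACTION = 0.5

__all__ = [
    "PAR_FRACTION",
    "CardinalTemperatures",
    "PTPSeries",
    "par_from_solar",
    "rte",
    "daily_rte",
    "cumulative_ptp",
    "read_weather",
    "validate_weather",
]


@dataclass(frozen=True)
class CardinalTemperatures:
    """Base, optimum and ceiling air temperatures (degC) for seed development."""

    t_base: float = 15.0
    t_opt: float = 30.0
    t_ceil: float = 35.0

    def __post_init__(self) -> None:
        if not (self.t_base < self.t_opt < self.t_ceil):
            raise InvalidInputError(
                f"cardinal temperatures must satisfy t_base < t_opt < t_ceil, "
                f"got ({self.t_base}, {self.t_opt}, {self.t_ceil})"
            )


@dataclass
class PTPSeries:
    """Daily PAR, thermal effectiveness and photo-thermal product over a window.

    ``daily`` holds one row per day with columns ``date``, ``par``, ``rte`` and
    ``ptp_daily`` (MJ m^-2 d^-1); ``cumulative`` is their sum in MJ m^-2.
    """

    daily: pd.DataFrame
    cumulative: float = field(init=False)

    def __post_init__(self) -> None:
        self.cumulative = float(self.daily["ptp_daily"].sum())


def par_from_solar(srad):
    """Convert global solar radiation (MJ m^-2 d^-1) to PAR via the 0.5 factor."""
    arr = np.asarray(srad, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr < 0):
        raise InvalidInputError("solar radiation must be finite and non-negative")
    out = PAR_FRACTION * arr
    return float(out) if np.isscalar(srad) or arr.ndim == 0 else out


def rte(t: float, cardinals: CardinalTemperatures = CardinalTemperatures()) -> float:
    """Thermal effectiveness of a single temperature, in [0, 1].

    Piecewise beta-type response: with u = (T - Tb)/(To - Tb),
    v = (Tc - T)/(Tc - To) and q = (Tc - To)/(Tc - Tb),

    * ``Tb <= T <= To``:  u**(1 + (To - T)/(To - Tb)) * v**q
    * ``To <= T <= Tc``:  u * v**q
    * zero outside [Tb, Tc].

    The upper branch marginally exceeds 1 just above the optimum (max ~1.009
    at the defaults), so the result is clamped to 1: the response is a
    *relative* effectiveness with its maximum at the optimum temperature.
    """
    if not math.isfinite(t):
        raise InvalidInputError(f"temperature must be finite, got {t!r}")
    tb, to, tc = cardinals.t_base, cardinals.t_opt, cardinals.t_ceil
    if t <= tb or t >= tc:
        return 0.0
    u = (t - tb) / (to - tb)
    v = (tc - t) / (tc - to)
    q = (tc - to) / (tc - tb)
    if t <= to:
        val = u ** (1.0 + (to - t) / (to - tb)) * v**q
    else:
        val = u * v**q
    return min(val, 1.0)


def daily_rte(
    tavg: float,
    tmax: float,
    tmin: float,
    cardinals: CardinalTemperatures = CardinalTemperatures(),
) -> float:
    """Daily thermal effectiveness: 0.5*rte(Tavg) + 0.25*rte(Tmax) + 0.25*rte(Tmin)."""
    if not (tmin <= tavg <= tmax):
        raise InvalidInputError(
            f"temperatures must satisfy tmin <= tavg <= tmax, got "
            f"tavg={tavg}, tmax={tmax}, tmin={tmin}"
        )
    return (
        0.5 * rte(tavg, cardinals)
        + 0.25 * rte(tmax, cardinals)
        + 0.25 * rte(tmin, cardinals)
    )


def validate_weather(weather: pd.DataFrame) -> pd.DataFrame:
    """Validate a daily weather frame and impute a missing ``tavg`` column.

    Requires columns ``date``, ``srad``, ``tmax``, ``tmin`` (``tavg`` optional;
    missing values are imputed as the tmax/tmin midpoint with a logged warning).
    Dates must be strictly increasing; srad non-negative; tmin <= tavg <= tmax.
    """
    required = {"date", "srad", "tmax", "tmin"}
    missing = required - set(weather.columns)
    if missing:
        raise InvalidInputError(f"weather frame missing columns: {sorted(missing)}")
    w = weather.copy()
    w["date"] = pd.to_datetime(w["date"])
    if len(w) and not w["date"].is_monotonic_increasing or w["date"].duplicated().any():
        raise InvalidInputError("weather dates must be strictly increasing")
    if (w["srad"] < 0).any() or not np.isfinite(w["srad"]).all():
        raise InvalidInputError("srad must be finite and non-negative")
    if "tavg" not in w.columns:
        w["tavg"] = np.nan
    n_missing = int(w["tavg"].isna().sum())
    if n_missing:
        logger.warning(
            "imputing tavg = (tmax + tmin)/2 for %d day(s) with missing tavg",
            n_missing,
        )
        w.loc[w["tavg"].isna(), "tavg"] = (w["tmax"] + w["tmin"]) / 2.0
    bad = ~((w["tmin"] <= w["tavg"]) & (w["tavg"] <= w["tmax"]))
    if bad.any():
        raise InvalidInputError(
            f"tmin <= tavg <= tmax violated on {w.loc[bad, 'date'].iloc[0].date()}"
        )
    return w


def read_weather(path) -> pd.DataFrame:
    """Read a weather CSV with columns date, srad_mj_m2, tmax_c, tmin_c[, tavg_c]."""
    raw = pd.read_csv(path)
    rename = {"srad_mj_m2": "srad", "tmax_c": "tmax", "tmin_c": "tmin", "tavg_c": "tavg"}
    return validate_weather(raw.rename(columns=rename))


def cumulative_ptp(
    weather: pd.DataFrame,
    start,
    end,
    cardinals: CardinalTemperatures = CardinalTemperatures(),
) -> PTPSeries:
    """Accumulate the photo-thermal product over [start, end], endpoints inclusive.

    Every calendar day of the window must be present in ``weather``; a gap is an
    error (never silently skipped).  Daily PTP is PAR x daily RTE; the series
    is additive over adjacent windows by construction.
    """
    w = validate_weather(weather)
    start = pd.Timestamp(start)
    end = pd.Timestamp(end)
    if end < start:
        raise InvalidInputError(f"empty window: end {end.date()} < start {start.date()}")
    expected = pd.date_range(start, end, freq="D")
    sel = w.set_index("date").reindex(expected)
    gaps = expected[sel["srad"].isna()]
    if len(gaps):
        raise MissingDataError(
            f"weather series is missing {len(gaps)} day(s) in the window, "
            f"first gap at {gaps[0].date()}"
        )
    par = par_from_solar(sel["srad"].to_numpy())
    rte_day = np.array(
        [
            daily_rte(a, mx, mn, cardinals)
            for a, mx, mn in zip(sel["tavg"], sel["tmax"], sel["tmin"])
        ]
    )
    daily = pd.DataFrame(
        {
            "date": expected,
            "par": par,
            "rte": rte_day,
            "ptp_daily": par * rte_day,
        }
    )
    return PTPSeries(daily=daily)
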