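"""From raw egg-collection records to per-bird deviation series.

Pipeline: span-level average daily egg production (EP) -> removal of
birds with physiologically impossible spans (> 2 eggs/day) ->
aggregation into non-overlapping 1/2/3-week intervals anchored at 25
weeks of age -> expected EP per interval from either the batch average
or a per-bird 4th-order 0.7-quantile polynomial production curve ->
ordered deviation series (observed - expected) per life period.

Life periods: the 'traditional' laying period covers 25 to 83 weeks of
age; the late period runs from 83 weeks to death or censoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linprog

DAYS_PER_WEEK = 7
ANCHOR_DAY = 25 * DAYS_PER_WEEK  # intervals anchored at exactly 25 weeks of age
DAY_83 = 83 * DAYS_PER_WEEK

PERIODS = ("25-83", "83-end")
MIN_CURVE_POINTS = 9  # weekly points required for the individual quantile fit


class EggRecordError(ValueError):
    pass


def average_daily_ep(egglog: pd.DataFrame) -> pd.Series:
    """Average daily EP per collection span: eggs / span length in days."""
    ndays = egglog["end_day"] - egglog["start_day"] + 1
    if (ndays <= 0).any():
        raise EggRecordError("zero- or negative-length collection span")
    return egglog["eggs"] / ndays


def remove_super_biological(egglog: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """Drop birds with any span averaging strictly more than 2 eggs/day.

    Exactly 2.0 eggs/day is retained: a day-1 egg collected late plus a
    day-2 egg collected early is a real observation.
    """
    rate = average_daily_ep(egglog)
    bad = egglog.loc[rate > 2.0, "bird"].unique()
    kept = egglog[~egglog["bird"].isin(bad)].reset_index(drop=True)
    return kept, sorted(bad.tolist())


def aggregate_intervals(
    egglog: pd.DataFrame, interval_weeks: int, hens: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-bird interval series of average daily EP.

    Span egg counts are apportioned to intervals proportionally to days
    of overlap (equivalently: each day of a span carries eggs/ndays).
    Only days at or after the 25-week anchor contribute.  Returns a tidy
    frame (bird, interval, avg_daily_ep, days_covered, eggs) where
    ``interval`` counts intervals of ``interval_weeks`` weeks from the
    anchor; intervals with zero covered days are absent.
    """
    if interval_weeks not in (1, 2, 3):
        raise EggRecordError("interval length must be 1, 2 or 3 weeks")
    L = interval_weeks * DAYS_PER_WEEK
    logs = egglog[egglog["end_day"] >= ANCHOR_DAY]
    start = np.maximum(logs["start_day"].to_numpy(), ANCHOR_DAY)
    end = logs["end_day"].to_numpy()
    span_len = (logs["end_day"] - logs["start_day"] + 1).to_numpy()
    rate = logs["eggs"].to_numpy() / span_len
    bird = logs["bird"].to_numpy()

    # explode each (possibly clipped) span into the intervals it touches
    first_iv = (start - ANCHOR_DAY) // L
    last_iv = (end - ANCHOR_DAY) // L
    n_iv = (last_iv - first_iv + 1).astype(np.int64)
    rep = np.repeat(np.arange(len(logs)), n_iv)
    offs = np.concatenate([np.arange(k) for k in n_iv]) if len(n_iv) else np.array([], dtype=int)
    iv = first_iv[rep] + offs
    iv_start = ANCHOR_DAY + iv * L
    iv_end = iv_start + L - 1
    ov_start = np.maximum(start[rep], iv_start)
    ov_end = np.minimum(end[rep], iv_end)
    ov_days = ov_end - ov_start + 1
    out = pd.DataFrame(
        {
            "bird": bird[rep],
            "interval": iv,
            "days_covered": ov_days,
            "eggs": rate[rep] * ov_days,
        }
    )
    g = out.groupby(["bird", "interval"], as_index=False).sum()
    g["avg_daily_ep"] = g["eggs"] / g["days_covered"]
    return g[["bird", "interval", "avg_daily_ep", "days_covered", "eggs"]]


def split_periods(
    series: pd.DataFrame, interval_weeks: int, hens: pd.DataFrame,
    include_full_period: bool = False,
) -> dict[str, pd.DataFrame]:
    """Assign interval entries to the 25-83 and 83-end life periods.

    An interval belongs to 25-83 if it starts before day 83*7 and to
    83-end otherwise; partial trailing intervals (death mid-interval)
    are kept as long as at least one day is covered.  The whole-life
    25-end period is computable on request but off by default (it is
    nearly equivalent to 25-83 genetically and not normally reported).
    """
    L = interval_weeks * DAYS_PER_WEEK
    iv_start = ANCHOR_DAY + series["interval"] * L
    out = {
        "25-83": series[iv_start < DAY_83].reset_index(drop=True),
        "83-end": series[iv_start >= DAY_83].reset_index(drop=True),
    }
    if include_full_period:
        out["25-end"] = series.reset_index(drop=True)
    return out


def expected_batch_ep(series: pd.DataFrame, hens: pd.DataFrame) -> pd.DataFrame:
    """Unweighted batch mean of avg_daily_ep per interval (focal bird included)."""
    s = series.merge(hens[["bird", "batch"]], on="bird")
    m = (
        s.groupby(["batch", "interval"], as_index=False)["avg_daily_ep"]
        .mean()
        .rename(columns={"avg_daily_ep": "expected_ep"})
    )
    return m


@dataclass
class ExpectedCurve:
    """Per-bird 4th-order polynomial production curve at quantile tau.

    Coefficients apply to powers of the centered/scaled age axis
    ``x = (day - center)/scale`` in increasing order.
    """

    bird: object
    coef: np.ndarray
    center: float
    scale: float
    tau: float
    n_points: int
    objective: float

    def predict(self, days: np.ndarray) -> np.ndarray:
        x = (np.asarray(days, dtype=float) - self.center) / self.scale
        return np.polynomial.polynomial.polyval(x, self.coef)


def pinball_loss(y: np.ndarray, yhat: np.ndarray, tau: float) -> float:
    u = np.asarray(y, dtype=float) - np.asarray(yhat, dtype=float)
    return float(np.sum(u * (tau - (u < 0))))


def fit_quantile_polynomial(
    x_days: np.ndarray, y: np.ndarray, tau: float = 0.7, order: int = 4,
    bird=None,
) -> ExpectedCurve:
    """Quantile polynomial regression by exact linear programming.

    Minimizes the pinball loss sum_i rho_tau(y_i - p(x_i)) over
    polynomial coefficients via the standard LP formulation
    (y = Xb + u+ - u-, cost tau*u+ + (1-tau)*u-), solved with HiGHS.
    The age axis is centered and scaled to [-1, 1] before powers are
    formed, for conditioning.
    """
    x_days = np.asarray(x_days, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < order + 1:
        raise EggRecordError("too few points for the quantile polynomial fit")
    center = 0.5 * (x_days.max() + x_days.min())
    scale = max(0.5 * (x_days.max() - x_days.min()), 1.0)
    x = (x_days - center) / scale
    X = np.vander(x, order + 1, increasing=True)
    p = order + 1
    # variables: [b+ (p), b- (p), u+ (n), u- (n)]
    c = np.concatenate([np.zeros(2 * p), tau * np.ones(n), (1 - tau) * np.ones(n)])
    A_eq = np.hstack([X, -X, np.eye(n), -np.eye(n)])
    res = linprog(c, A_eq=A_eq, b_eq=y, bounds=(0, None), method="highs")
    if not res.success:
        raise EggRecordError(f"quantile LP failed: {res.message}")
    b = res.x[:p] - res.x[p:2 * p]
    yhat = X @ b
    return ExpectedCurve(
        bird=bird, coef=b, center=center, scale=scale, tau=tau,
        n_points=n, objective=pinball_loss(y, yhat, tau),
    )


def fit_individual_curves(
    weekly: pd.DataFrame, tau: float = 0.7, order: int = 4,
    min_points: int = MIN_CURVE_POINTS,
) -> dict:
    """Fit one production curve per bird to its 1-week-interval series.

    Birds with fewer than ``min_points`` weekly entries get no curve and
    are excluded from individual-reference indicators.
    """
    curves = {}
    for bird, sub in weekly.groupby("bird"):
        if len(sub) < min_points:
            continue
        mid = ANCHOR_DAY + sub["interval"].to_numpy() * DAYS_PER_WEEK + 3.0
        curves[bird] = fit_quantile_polynomial(
            mid, sub["avg_daily_ep"].to_numpy(), tau=tau, order=order, bird=bird
        )
    return curves


def deviations_batch(
    series: pd.DataFrame, hens: pd.DataFrame
) -> pd.DataFrame:
    """Deviation series against the average batch reference."""
    exp = expected_batch_ep(series, hens)
    s = series.merge(hens[["bird", "batch"]], on="bird").merge(
        exp, on=["batch", "interval"]
    )
    s["deviation"] = s["avg_daily_ep"] - s["expected_ep"]
    return s[["bird", "interval", "deviation"]].sort_values(
        ["bird", "interval"]
    ).reset_index(drop=True)


def deviations_individual(
    series: pd.DataFrame, curves: dict, interval_weeks: int = 1
) -> pd.DataFrame:
    """Deviation series against each bird's fitted production curve.

    Expectations are the curve evaluated at interval midpoints; birds
    without a curve are absent.
    """
    L = interval_weeks * DAYS_PER_WEEK
    parts = []
    for bird, sub in series.groupby("bird"):
        curve = curves.get(bird)
        if curve is None:
            continue
        mid = ANCHOR_DAY + sub["interval"].to_numpy() * L + L / 2.0 - 0.5
        dev = sub["avg_daily_ep"].to_numpy() - curve.predict(mid)
        parts.append(
            pd.DataFrame({"bird": bird, "interval": sub["interval"], "deviation": dev})
        )
    if not parts:
        return pd.DataFrame(columns=["bird", "interval", "deviation"])
    return pd.concat(parts, ignore_index=True).sort_values(
        ["bird", "interval"]
    ).reset_index(drop=True)
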