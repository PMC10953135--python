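"""Per-bird resilience statistics of production-deviation series.

Three indicators per bird, computed for each combination of life
period (25-83, 83-end), interval length (1/2/3 weeks) and expected-EP
reference (batch average, individual curve):

* ln(variance): natural log of the sample variance (denominator n-1) of
  the deviations; small values mean uniform production.
* skewness: moment skewness in the convention of R's e1071 default
  (type 3), b1 = g1 * ((n-1)/n)^{3/2} with g1 = m3 / m2^{3/2} and m_k
  the k-th central moment with denominator n.
* autocorrelation: lag-one autocorrelation where only pairs of
  consecutive interval indices are counted in the numerator (gaps in
  the series break pairs) and the denominator sums over all entries,
  which keeps the estimate in [-1, 1].

Eligibility: at least five interval observations in the period; per
trait-variant, values more than four population SDs from the population
mean are discarded in a single pass.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

MIN_INTERVALS = 5

STATS = ("ln_variance", "skewness", "autocorrelation")
BATCH_INTERVALS = (1, 2, 3)
INDIVIDUAL_INTERVALS = (1,)
PERIODS = ("25-83", "83-end")


def ln_variance(devs: np.ndarray) -> float:
    """ln of the sample variance (ddof=1); NaN when degenerate."""
    devs = np.asarray(devs, dtype=float)
    if len(devs) < MIN_INTERVALS:
        return np.nan
    v = np.var(devs, ddof=1)
    if v <= 0:
        return np.nan
    return float(np.log(v))


def skewness(devs: np.ndarray) -> float:
    """Moment skewness, e1071 type-3 convention; NaN when degenerate."""
    devs = np.asarray(devs, dtype=float)
    n = len(devs)
    if n < MIN_INTERVALS:
        return np.nan
    d = devs - devs.mean()
    m2 = np.mean(d**2)
    if m2 <= 0:
        return np.nan
    g1 = np.mean(d**3) / m2**1.5
    return float(g1 * ((n - 1) / n) ** 1.5)


def autocorr_lag1(devs: np.ndarray, intervals: np.ndarray | None = None) -> float:
    """Lag-one autocorrelation with gap-aware pairing.

    ``intervals`` gives the interval index of each deviation; only
    entries whose indices differ by exactly one form a numerator pair.
    Without indices, entries are assumed consecutive.
    """
    devs = np.asarray(devs, dtype=float)
    n = len(devs)
    if n < MIN_INTERVALS:
        return np.nan
    d = devs - devs.mean()
    den = np.sum(d**2)
    if den <= 0:
        return np.nan
    if intervals is None:
        pair = np.ones(n - 1, dtype=bool)
    else:
        intervals = np.asarray(intervals)
        pair = np.diff(intervals) == 1
    if not pair.any():
        return np.nan
    num = np.sum(d[:-1][pair] * d[1:][pair])
    return float(num / den)


def trim_outliers(values: pd.Series | np.ndarray, n_sd: float = 4.0):
    """Single-pass population trim: drop x with |x - mean| > n_sd * SD.

    Mean and SD (ddof=1) come from the untrimmed values.  Returns
    (trimmed values, boolean keep-mask aligned with the input).
    """
    v = pd.Series(values).astype(float)
    obs = v.dropna()
    if len(obs) < 2:
        return v, v.notna()
    mu, sd = obs.mean(), obs.std(ddof=1)
    keep = v.notna() & ((v - mu).abs() <= n_sd * sd) if sd > 0 else v.notna()
    return v[keep], keep


def assign_max_age_class(end_week: float) -> int:
    """Survival class: 1 for death before 30 weeks, then 4-week bins.

    Class 2 covers 30-34 weeks, class 3 covers 34-38 weeks, etc.; a bird
    censored at 105 weeks lands in class 20.
    """
    if end_week < 25:
        raise ValueError("bird leaves the data before 25 weeks of age")
    if end_week < 30:
        return 1
    return 2 + int((end_week - 30) // 4)


def max_age_classes(hens: pd.DataFrame) -> pd.Series:
    """Maximum age-class per bird from death/censoring day-of-age."""
    wk = hens["end_day"].to_numpy() / 7.0
    return pd.Series(
        [assign_max_age_class(w) for w in wk], index=hens["bird"], name="mac"
    )


def _series_stats(devs: pd.DataFrame) -> pd.DataFrame:
    """All three indicators per bird for one deviation set."""
    rows = []
    for bird, sub in devs.groupby("bird"):
        d = sub["deviation"].to_numpy()
        iv = sub["interval"].to_numpy()
        rows.append(
            (
                bird,
                ln_variance(d),
                skewness(d),
                autocorr_lag1(d, iv),
                len(d),
            )
        )
    return pd.DataFrame(
        rows, columns=["bird", "ln_variance", "skewness", "autocorrelation", "n_intervals"]
    )


def variant_name(stat: str, period: str, interval_weeks: int, reference: str) -> str:
    return f"{stat}|{period}|{interval_weeks}wk|{reference}"


def compute_indicator_table(
    deviation_sets: dict[tuple[str, int, str], pd.DataFrame],
    trim_sd: float = 4.0,
) -> pd.DataFrame:
    """Bird x variant table of trimmed resilience indicators.

    ``deviation_sets`` maps (period, interval_weeks, reference) to a
    deviation frame.  The standard grid of 18 batch-reference plus 6
    individual-reference variants is produced when all keys are present;
    the >= 5-interval rule and the four-SD trim are applied per variant
    independently.
    """
    columns = {}
    for (period, ivw, ref), devs in sorted(deviation_sets.items()):
        stats = _series_stats(devs).set_index("bird")
        for stat in STATS:
            col = stats[stat].where(stats["n_intervals"] >= MIN_INTERVALS)
            _, keep = trim_outliers(col, n_sd=trim_sd)
            columns[variant_name(stat, period, ivw, ref)] = col.where(keep)
    table = pd.DataFrame(columns)
    table.index.name = "bird"
    return table


def standard_variant_keys() -> list[tuple[str, int, str]]:
    """The (period, interval, reference) combinations of the full design."""
    keys = [
        (p, ivw, "batch") for p in PERIODS for ivw in BATCH_INTERVALS
    ] + [(p, ivw, "individual") for p in PERIODS for ivw in INDIVIDUAL_INTERVALS]
    return keys
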