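"""Recurrence intervals of threshold exceedances and their temporal structure.

The recurrence interval at threshold q is the waiting time between two
consecutive hours at which the adjusted series strictly exceeds q:
d_q = min{t - t' : x(t) > q, x(t') > q, t > t'}.  Consecutive exceedance
hours give intervals of 1 hour (extreme spells recur in clusters).

The spatially reviewed interval d^(ij) pairs each completed interval at
station i with the most recently completed interval at neighbour j (at the
same q); before j's first completed interval, j's whole-series mean interval
is used as an ad hoc fill.

Temporal-structure scans: the maximal significant lag of an AR(max_lag) fit
to the durations, and a DFA(1) Hurst exponent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, InsufficientDataError, ValidationError
from .timeseries import AdjustedSeries

__all__ = [
    "RecurrenceSeries",
    "SpatialReviewPair",
    "ExceedanceDiagnostic",
    "extract_recurrence",
    "exceedance_check",
    "spatially_reviewed",
    "ar_max_significant_lag",
    "hurst_exponent",
]


@dataclass
class RecurrenceSeries:
    """Exceedance event times and waiting times for one series at threshold q.

    ``event_times`` are the hour indices with x > q (strictly increasing);
    ``durations[s] = event_times[s+1] - event_times[s]`` — the first
    exceedance anchors the clock but contributes no duration.
    """

    q: float
    event_times: np.ndarray
    durations: np.ndarray
    n_hours: int
    station_id: str = ""
    pollutant: str = ""
    too_few: bool = field(default=False)

    def __post_init__(self) -> None:
        self.event_times = np.asarray(self.event_times, dtype=np.int64)
        self.durations = np.asarray(self.durations, dtype=np.int64)
        if len(self.event_times) >= 2:
            expected = np.diff(self.event_times)
            if not np.array_equal(expected, self.durations):
                raise ValidationError("durations must be consecutive differences")
        if (self.durations <= 0).any():
            raise ValidationError("durations must be positive")
        self.too_few = len(self.durations) == 0

    @property
    def mean_duration(self) -> float:
        """⟨d_q⟩, the arithmetic mean waiting time in hours."""
        if self.too_few:
            return float("nan")
        return float(self.durations.mean())

    def __len__(self) -> int:
        return len(self.durations)


@dataclass
class SpatialReviewPair:
    """Aligned own intervals d^(i) and spatially reviewed intervals d^(ij)."""

    base: RecurrenceSeries
    reviewed: np.ndarray
    fill_value: float
    n_filled: int = 0
    all_fill: bool = False

    def __post_init__(self) -> None:
        self.reviewed = np.asarray(self.reviewed, dtype=float)
        if len(self.reviewed) != len(self.base.durations):
            raise ValidationError("reviewed and base durations must align")
        if (self.reviewed <= 0).any():
            raise ValidationError("reviewed intervals must be positive")


@dataclass
class ExceedanceDiagnostic:
    """Both sides of the mean-interval/exceedance identity 1/⟨d_q⟩ = P(x > q)."""

    q: float
    p_exceed: float
    recip_mean_interval: float


def _values_of(x) -> np.ndarray:
    if isinstance(x, AdjustedSeries) or hasattr(x, "values") and isinstance(
        getattr(x, "values", None), pd.Series
    ):
        return x.values.to_numpy(dtype=float)
    return np.asarray(x, dtype=float)


def extract_recurrence(x, q: float, station_id: str = "", pollutant: str = "") -> RecurrenceSeries:
    """Event times and waiting times of strict exceedances x > q.

    Missing (NaN) hours can never be exceedances.  Fewer than two
    exceedances yields an empty, flagged duration series, not an error.
    """
    if q <= 0:
        raise ValidationError("threshold q must be positive")
    v = _values_of(x)
    with np.errstate(invalid="ignore"):
        events = np.flatnonzero(v > q)
    durations = np.diff(events) if len(events) >= 2 else np.empty(0, dtype=np.int64)
    return RecurrenceSeries(
        q=float(q),
        event_times=events,
        durations=durations,
        n_hours=len(v),
        station_id=station_id,
        pollutant=pollutant,
    )


def exceedance_check(x, q: float) -> ExceedanceDiagnostic:
    """Empirical exceedance probability vs reciprocal mean interval.

    For i.i.d. data the two agree: the mean waiting time between exceedances
    is the reciprocal of the exceedance probability.
    """
    v = _values_of(x)
    rec = extract_recurrence(v, q)
    if len(rec) < 1:
        raise InsufficientDataError("need at least 2 exceedances")
    n_present = int(np.sum(~np.isnan(v)))
    p_hat = len(rec.event_times) / n_present
    return ExceedanceDiagnostic(
        q=float(q), p_exceed=p_hat, recip_mean_interval=1.0 / rec.mean_duration
    )


def spatially_reviewed(
    base: RecurrenceSeries, neighbour: RecurrenceSeries
) -> SpatialReviewPair:
    """Pair each completed interval at i with j's most recent interval.

    For the interval of ``base`` ending at hour t_s, the reviewed value is
    the neighbour's duration most recently completed at an hour <= t_s
    (inclusive, so identical series review themselves exactly).  Before the
    neighbour's first completed interval, its whole-series mean duration is
    the fill; a neighbour with no completed interval at all gives an
    all-fill result (filled with the base's own mean) and is flagged.
    """
    if base.q != neighbour.q:
        raise ConfigurationError(
            f"threshold mismatch: base q={base.q}, neighbour q={neighbour.q}"
        )
    m = len(base.durations)
    if neighbour.too_few:
        fill = base.mean_duration if not base.too_few else 1.0
        return SpatialReviewPair(
            base=base,
            reviewed=np.full(m, fill),
            fill_value=fill,
            n_filled=m,
            all_fill=True,
        )
    fill = neighbour.mean_duration
    # neighbour's s-th duration completes at its (s+1)-th event hour
    completion = neighbour.event_times[1:]
    ends = base.event_times[1:]  # hour at which each base interval completes
    pos = np.searchsorted(completion, ends, side="right") - 1
    reviewed = np.where(pos >= 0, neighbour.durations[np.maximum(pos, 0)], fill)
    return SpatialReviewPair(
        base=base,
        reviewed=reviewed.astype(float),
        fill_value=fill,
        n_filled=int(np.sum(pos < 0)),
    )


def ar_max_significant_lag(
    d: RecurrenceSeries | np.ndarray, max_lag: int = 10, conf: float = 0.95
) -> int:
    """Largest significant lag of an AR(max_lag) fit to the durations.

    A single AR(max_lag) model (with constant) is fitted and each lag
    coefficient Wald-tested against the two-sided normal critical value at
    ``conf``; returns 0 when no lag is significant.
    """
    from statsmodels.tsa.ar_model import AutoReg

    y = d.durations if isinstance(d, RecurrenceSeries) else np.asarray(d, float)
    if len(y) <= max_lag + 10:
        raise InsufficientDataError(
            f"need more than max_lag + 10 = {max_lag + 10} durations, got {len(y)}"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = AutoReg(np.asarray(y, float), lags=max_lag, trend="c").fit()
    crit = stats.norm.ppf(0.5 + conf / 2)
    tvals = np.abs(res.params[1:] / res.bse[1:])  # skip the constant
    sig = np.flatnonzero(tvals > crit)
    return int(sig[-1] + 1) if len(sig) else 0


def hurst_exponent(series) -> tuple[float, float]:
    """Hurst exponent by first-order detrended fluctuation analysis.

    Windows are logarithmically spaced from 8 to length/4; within each
    non-overlapping window the cumulative profile is linearly detrended and
    the RMS fluctuation F(n) computed.  H is the slope of log F(n) against
    log n, returned with its regression standard error.  H = 0.5 for
    uncorrelated series; H > 0.5 signals persistence.
    """
    y = np.asarray(series, dtype=float)
    y = y[~np.isnan(y)]
    n = len(y)
    if n < 100:
        raise InsufficientDataError(f"need at least 100 observations, got {n}")
    profile = np.cumsum(y - y.mean())
    sizes = np.unique(
        np.floor(np.logspace(np.log10(8), np.log10(n // 4), 20)).astype(int)
    )
    flucts = []
    for s in sizes:
        n_seg = n // s
        segs = profile[: n_seg * s].reshape(n_seg, s)
        t = np.arange(s, dtype=float)
        t_c = t - t.mean()
        denom = np.sum(t_c**2)
        slope = segs @ t_c / denom
        resid = segs - segs.mean(axis=1, keepdims=True) - np.outer(slope, t_c)
        flucts.append(np.sqrt(np.mean(resid**2)))
    fit = stats.linregress(np.log(sizes), np.log(flucts))
    return float(fit.slope), float(fit.stderr)
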