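"""Rolling out-of-sample forecasting of the next recurrence interval.

The one-step forecast of the next waiting time is the fitted conditional
expectation: E[d_{s+1} | I_s] = psi_hat_{s+1} = omega_hat
+ sum alpha_hat d + sum beta_hat psi + sum gamma_hat d^(ij), i.e. the
model recursion rolled one step past the sample.  Multi-step forecasts
iterate the recursion substituting psi_hat for each unrealized duration
(valid because E[d | I] = psi); reviewed durations are held at their last
observed value.

Errors: AE = |psi_hat - d| in hours; RMSE over a 30-interval holdout; and
a table of breakpoint fractions p(AE < 1, 6, 12, 24, 48, 96 hours).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .acd import ModelOrder, SACDParams, conditional_path
from .estimation import FitResult, fit as _fit
from .exceptions import ConvergenceError, InsufficientDataError, StateError, ValidationError

__all__ = [
    "ForecastRecord",
    "ErrorSummary",
    "AE_BREAKPOINTS",
    "one_step_forecast",
    "forecast_from_state",
    "multi_step_forecast",
    "rolling_out_of_sample",
    "summarize_errors",
]

AE_BREAKPOINTS = (1, 6, 12, 24, 48, 96)


@dataclass
class ForecastRecord:
    """One out-of-sample forecast: origin, horizon, psi_hat vs realized."""

    s: int
    horizon: int
    psi_hat: float
    realized: float
    ae: float
    converged: bool = True


@dataclass
class ErrorSummary:
    """Holdout error summary: RMSE, average AE, breakpoint fractions."""

    rmse: float
    avg_ae: float
    p_ae: dict
    n_records: int
    n_failed: int = 0

    def to_row(self) -> dict:
        row = {f"p_ae_lt_{b}": self.p_ae[b] for b in AE_BREAKPOINTS}
        row["avg_ae"] = self.avg_ae
        row["rmse"] = self.rmse
        row["n_records"] = self.n_records
        row["n_failed"] = self.n_failed
        return row


def _forecast_path(
    params: SACDParams,
    order: ModelOrder,
    d: np.ndarray,
    d_review: np.ndarray | None,
    h: int,
) -> np.ndarray:
    """psi_hat for horizons 1..h past the end of ``d``.

    Runs the recursion over the sample, then iterates forward substituting
    psi_hat for unrealized durations; the reviewed durations stay at their
    last observed value.
    """
    d = np.asarray(d, float)
    n = len(d)
    path = conditional_path(params, order, d, d_review)
    dbar = d.mean()
    geff = params.effective_gamma() if order.L_j > 0 else None
    # extended sequences: observed history then forecasts
    d_ext = list(d)
    psi_ext = list(path.psi)
    out = np.empty(h)
    for step in range(1, h + 1):
        s = n + step - 1  # 0-based index of the value being forecast
        val = params.omega
        for u, a in enumerate(params.alpha, start=1):
            lag = s - u
            val += a * (d_ext[lag] if lag >= 0 else dbar)
        for v, b in enumerate(params.beta, start=1):
            lag = s - v
            val += b * (psi_ext[lag] if lag >= 0 else dbar)
        if order.L_j > 0:
            for j in range(order.n_neighbours):
                for kk in range(1, order.L_j + 1):
                    lag = s - kk
                    if lag >= n:  # unrealized: hold at last observed
                        rev = d_review[j, n - 1]
                    elif lag >= 0:
                        rev = d_review[j, lag]
                    else:
                        rev = dbar
                    val += geff[j, kk - 1] * rev
        out[step - 1] = val
        psi_ext.append(val)
        d_ext.append(val)  # E[d | I] = psi
    return out


def forecast_from_state(
    params: SACDParams,
    order: ModelOrder,
    last_d,
    last_psi,
    last_review=None,
) -> float:
    """One-step forecast from an explicit state.

    ``last_d`` / ``last_psi`` hold the most recent L_d durations and L_psi
    conditional durations (most recent last); ``last_review`` the most
    recent L_j reviewed durations per neighbour, shape (n_neighbours, L_j).
    """
    last_d = np.atleast_1d(np.asarray(last_d, float))
    last_psi = np.atleast_1d(np.asarray(last_psi, float))
    if len(last_d) < order.L_d or len(last_psi) < order.L_psi:
        raise StateError("state must cover all duration and psi lags")
    val = params.omega
    for u, a in enumerate(params.alpha, start=1):
        val += a * last_d[-u]
    for v, b in enumerate(params.beta, start=1):
        val += b * last_psi[-v]
    if order.L_j > 0:
        if last_review is None:
            raise StateError("spatial model requires reviewed state")
        rev = np.atleast_2d(np.asarray(last_review, float))
        if rev.shape[1] < order.L_j:
            raise StateError("reviewed state must cover all spatial lags")
        geff = params.effective_gamma()
        for j in range(order.n_neighbours):
            for kk in range(1, order.L_j + 1):
                val += geff[j, kk - 1] * rev[j, -kk]
    return float(val)


def one_step_forecast(
    fit_result: FitResult | SACDParams,
    d,
    d_review=None,
    order: ModelOrder | None = None,
) -> float:
    """Forecast of the next recurrence interval, psi_hat_{N+1}."""
    params, order = _unpack_fit(fit_result, order)
    d = np.asarray(d, float)
    if len(d) < 1:
        raise StateError("need at least one observed duration")
    if order.L_j > 0 and d_review is None:
        raise StateError("spatial model requires reviewed durations")
    val = _forecast_path(params, order, d, _as_review(d_review), 1)[0]
    return float(val)


def multi_step_forecast(
    fit_result: FitResult | SACDParams,
    d,
    h: int,
    d_review=None,
    order: ModelOrder | None = None,
) -> np.ndarray:
    """psi_hat for horizons 1..h; h = 1 equals one_step_forecast exactly."""
    if h < 1:
        raise ValidationError("horizon must be >= 1")
    params, order = _unpack_fit(fit_result, order)
    if order.L_j > 0 and d_review is None:
        raise StateError("spatial model requires reviewed durations")
    return _forecast_path(params, order, np.asarray(d, float), _as_review(d_review), h)


def _unpack_fit(fit_result, order):
    if isinstance(fit_result, FitResult):
        return fit_result.params, fit_result.order
    if order is None:
        raise ValidationError("order required when passing raw parameters")
    return fit_result, order


def _as_review(d_review):
    return None if d_review is None else np.atleast_2d(np.asarray(d_review, float))


def rolling_out_of_sample(
    d,
    d_review=None,
    order: ModelOrder = ModelOrder(1, 1, 0),
    family: str = "exponential",
    holdout: int = 30,
    mode: str = "refit",
    n_restarts: int = 4,
    seed: int = 20181102,
    **fit_kwargs,
) -> tuple[list[ForecastRecord], ErrorSummary]:
    """One-step out-of-sample test over the last ``holdout`` intervals.

    ``mode="refit"``: re-estimate on all data strictly before each holdout
    origin (expanding window).  ``mode="fixed"``: estimate once on the
    training part and roll only the state forward.  Non-convergent refits
    are flagged and excluded from the error averages.
    """
    d = np.asarray(d, float)
    n = len(d)
    if n <= holdout + 30:
        raise InsufficientDataError(
            f"need more than holdout + 30 = {holdout + 30} durations, got {n}"
        )
    d_review = _as_review(d_review)
    records: list[ForecastRecord] = []
    n_failed = 0

    fixed_fit = None
    if mode == "fixed":
        fixed_fit = _fit(
            d[: n - holdout],
            d_review[:, : n - holdout] if d_review is not None else None,
            order=order, family=family, n_restarts=n_restarts, seed=seed,
            **fit_kwargs,
        )
    elif mode != "refit":
        raise ValidationError(f"unknown mode {mode!r}")

    for t in range(n - holdout, n):
        train_d = d[:t]
        train_rev = d_review[:, :t] if d_review is not None else None
        try:
            if mode == "refit":
                f = _fit(
                    train_d, train_rev, order=order, family=family,
                    n_restarts=n_restarts, seed=seed, **fit_kwargs,
                )
            else:
                f = fixed_fit
            psi_hat = _forecast_path(f.params, order, train_d, train_rev, 1)[0]
        except ConvergenceError:
            n_failed += 1
            records.append(ForecastRecord(t, 1, np.nan, d[t], np.nan, converged=False))
            continue
        records.append(
            ForecastRecord(t, 1, float(psi_hat), float(d[t]), abs(float(psi_hat) - d[t]))
        )
    summary = summarize_errors(records)
    return records, summary


def summarize_errors(records) -> ErrorSummary:
    """Breakpoint fractions p(AE < 1, 6, 12, 24, 48, 96), average AE, RMSE.

    Accepts ForecastRecord lists or anything with ``ae``/``psi_hat``/
    ``realized`` fields; flagged (non-converged) records are excluded and
    counted.
    """
    recs = list(records)
    if not recs:
        raise ValidationError("need at least one forecast record")
    ok = [r for r in recs if getattr(r, "converged", True) and np.isfinite(r.ae)]
    n_failed = len(recs) - len(ok)
    if not ok:
        return ErrorSummary(np.nan, np.nan, {b: np.nan for b in AE_BREAKPOINTS},
                            0, n_failed)
    ae = np.array([r.ae for r in ok])
    err = np.array([r.realized - r.psi_hat for r in ok])
    p_ae = {b: float(np.mean(ae < b)) for b in AE_BREAKPOINTS}
    return ErrorSummary(
        rmse=float(np.sqrt(np.mean(err**2))),
        avg_ae=float(ae.mean()),
        p_ae=p_ae,
        n_records=len(ok),
        n_failed=n_failed,
    )


def records_to_frame(records, **meta) -> pd.DataFrame:
    """Tidy frame of forecast records (origin, horizon, psi_hat, realized, ae)."""
    df = pd.DataFrame(
        {
            "origin_s": [r.s for r in records],
            "horizon": [r.horizon for r in records],
            "psi_hat": [r.psi_hat for r in records],
            "realized": [r.realized for r in records],
            "ae": [r.ae for r in records],
            "converged": [r.converged for r in records],
        }
    )
    for k, v in meta.items():
        df[k] = v
    return df


__all__.append("records_to_frame")
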