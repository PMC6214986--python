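"""ACD / SACD model family: recursion, innovation laws, stationary moments.

The autoregressive conditional duration (ACD) model writes each waiting
time as d_s = psi_s * eps_s with eps i.i.d., positive, unit-mean, and

    psi_s = omega + sum_u alpha_u d_{s-u} + sum_v beta_v psi_{s-v},

the conditional expected duration given the past.  The spatial extension
(SACD) adds coupling to neighbours' spatially reviewed intervals:

    psi_s = omega + sum_u alpha_u d_{s-u} + sum_v beta_v psi_{s-v}
            + sum_j sum_k gamma_{jk} w_j d^(ij)_{s-k}.

All coefficients are non-negative (omega strictly positive) so psi stays
positive.  Innovations are exponential or Weibull with shape k in (0, 1]
and scale lambda = 1/Gamma(1 + 1/k), which forces E[eps] = 1; k = 1
recovers the exponential exactly.

Pre-sample convention: every lagged quantity with index <= 0 (durations,
psi, reviewed durations) is set to the sample mean of the duration series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.special import gammaln
from scipy.stats import expon, weibull_min

from .exceptions import NonstationarityError, ValidationError

__all__ = [
    "ModelOrder",
    "SACDParams",
    "ConditionalPath",
    "conditional_path",
    "stationary_mean",
    "coupled_stationary_means",
    "unit_weibull_scale",
    "innovation_density",
    "innovation_logpdf",
    "model_to_json",
    "model_from_json",
]


@dataclass(frozen=True)
class ModelOrder:
    """Model orders (L_d, L_psi, L_j) and the neighbour list N(i)."""

    L_d: int = 1
    L_psi: int = 1
    L_j: int = 0
    neighbours: tuple = ()

    def __post_init__(self) -> None:
        for name in ("L_d", "L_psi", "L_j"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValidationError(f"{name} must be a non-negative integer")
        if self.L_j > 0 and len(self.neighbours) == 0:
            raise ValidationError("L_j > 0 requires a non-empty neighbour list")

    @property
    def n_neighbours(self) -> int:
        return len(self.neighbours)


@dataclass
class SACDParams:
    """Parameter vector theta = (omega, alpha, beta, gamma, k) with weights.

    ``gamma`` has shape (n_neighbours, L_j).  ``weights`` (one per
    neighbour, default 1) implement the adjacency/deterrence factor w_ij.
    ``k`` is the Weibull shape, required iff family == "weibull".
    """

    omega: float
    alpha: np.ndarray = field(default_factory=lambda: np.empty(0))
    beta: np.ndarray = field(default_factory=lambda: np.empty(0))
    gamma: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))
    family: str = "exponential"
    k: float | None = None
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        self.gamma = np.atleast_2d(np.asarray(self.gamma, dtype=float))
        if self.gamma.size == 0:
            self.gamma = self.gamma.reshape(0, 0)
        if self.omega <= 0:
            raise ValidationError("omega must be strictly positive")
        if (self.alpha < 0).any() or (self.beta < 0).any() or (self.gamma < 0).any():
            raise ValidationError("alpha, beta, gamma must be non-negative")
        if self.family not in ("exponential", "weibull"):
            raise ValidationError(f"unknown family {self.family!r}")
        if self.family == "weibull":
            if self.k is None or not (0 < self.k <= 1):
                raise ValidationError("weibull shape k must lie in (0, 1]")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if (self.weights < 0).any():
                raise ValidationError("weights must be non-negative")

    def effective_gamma(self) -> np.ndarray:
        """gamma_{jk} * w_j, shape (n_neighbours, L_j)."""
        if self.gamma.size == 0:
            return self.gamma
        w = self.weights if self.weights is not None else np.ones(self.gamma.shape[0])
        return self.gamma * w[:, None]


@dataclass
class ConditionalPath:
    """psi path and implied innovations eps = d / psi."""

    psi: np.ndarray
    innovations: np.ndarray


def conditional_path(
    params: SACDParams,
    order: ModelOrder,
    d: np.ndarray,
    d_review: np.ndarray | None = None,
) -> ConditionalPath:
    """Evaluate the psi recursion over a duration series.

    ``d_review`` holds the reviewed durations, one row per neighbour in
    ``order.neighbours`` (shape (n_neighbours, N)); aligned with ``d``.
    Pre-sample lags use mean(d).  The AR-in-psi part runs through a linear
    filter for speed; a naive loop gives identical values.
    """
    d = np.asarray(d, dtype=float)
    if (d <= 0).any():
        raise ValidationError("durations must be strictly positive")
    n = len(d)
    dbar = d.mean()
    if len(params.alpha) != order.L_d or len(params.beta) != order.L_psi:
        raise ValidationError("parameter lengths must match model orders")
    if order.L_j > 0:
        if d_review is None:
            raise ValidationError("spatial order requires reviewed durations")
        d_review = np.atleast_2d(np.asarray(d_review, dtype=float))
        if d_review.shape != (order.n_neighbours, n):
            raise ValidationError(
                f"d_review must have shape ({order.n_neighbours}, {n})"
            )
        if (d_review <= 0).any():
            raise ValidationError("reviewed durations must be strictly positive")

    # z_s = omega + sum_u alpha_u d_{s-u} + sum_jk gamma_jk w_j d_rev[j, s-k]
    z = np.full(n, params.omega)
    for u, a in enumerate(params.alpha, start=1):
        lagged = np.empty(n)
        lagged[:u] = dbar
        lagged[u:] = d[:-u] if u < n else d[:0]
        if u >= n:
            lagged[:] = dbar
        z += a * lagged
    if order.L_j > 0:
        geff = params.effective_gamma()
        for j in range(order.n_neighbours):
            for kk in range(1, order.L_j + 1):
                lagged = np.empty(n)
                lagged[:kk] = dbar
                if kk < n:
                    lagged[kk:] = d_review[j, :-kk]
                z += geff[j, kk - 1] * lagged

    if order.L_psi == 0:
        psi = z
    else:
        a_poly = np.concatenate(([1.0], -params.beta))
        zi = signal.lfiltic([1.0], a_poly, y=[dbar] * order.L_psi)
        psi, _ = signal.lfilter([1.0], a_poly, z, zi=zi)
    if (psi <= 0).any():
        raise ValidationError("psi path left the positive domain")
    return ConditionalPath(psi=psi, innovations=d / psi)


def stationary_mean(params: SACDParams) -> float:
    """Long-run expected duration mu = omega / (1 - sum alpha - sum beta).

    Valid for the uncoupled model (all gamma zero); raises if the
    persistence sum reaches 1.
    """
    if params.gamma.size and params.effective_gamma().sum() > 0:
        raise ValidationError(
            "stationary_mean is for gamma = 0; use coupled_stationary_means"
        )
    persistence = params.alpha.sum() + params.beta.sum()
    if persistence >= 1:
        raise NonstationarityError(f"alpha + beta = {persistence:.4f} >= 1")
    return float(params.omega / (1.0 - persistence))


def coupled_stationary_means(
    params_i: SACDParams, params_j: SACDParams
) -> tuple[float, float]:
    """Stationary expected durations of two mutually coupled (1,1,1) stations.

    For mutual nearest neighbours, with a_i = 1 - alpha_i - beta_i,

        E[d_i] = (omega_j * gamma_i + omega_i * a_j) / (a_i a_j - gamma_i gamma_j)

    and symmetrically for j.  gamma_i = gamma_j = 0 reduces to
    omega/(1 - alpha - beta) per station; one-sided coupling gives
    mu_i + mu_j * gamma_i / a_i.
    """
    gi = float(params_i.effective_gamma().sum()) if params_i.gamma.size else 0.0
    gj = float(params_j.effective_gamma().sum()) if params_j.gamma.size else 0.0
    ai = 1.0 - params_i.alpha.sum() - params_i.beta.sum()
    aj = 1.0 - params_j.alpha.sum() - params_j.beta.sum()
    denom = ai * aj - gi * gj
    if denom <= 0:
        raise NonstationarityError(f"coupled stationarity denominator {denom:.4f} <= 0")
    mu_i = (params_j.omega * gi + params_i.omega * aj) / denom
    mu_j = (params_i.omega * gj + params_j.omega * ai) / denom
    return float(mu_i), float(mu_j)


def model_to_json(params: SACDParams, order: ModelOrder) -> str:
    """Serialize a model specification and parameter vector losslessly."""
    import json

    payload = {
        "family": params.family,
        "L_d": order.L_d,
        "L_psi": order.L_psi,
        "L_j": order.L_j,
        "neighbours": list(order.neighbours),
        "omega": params.omega,
        "alpha": params.alpha.tolist(),
        "beta": params.beta.tolist(),
        "gamma": params.gamma.tolist(),
        "k": params.k,
        "weights": None if params.weights is None else params.weights.tolist(),
    }
    return json.dumps(payload)


def model_from_json(s: str) -> tuple[SACDParams, ModelOrder]:
    """Inverse of :func:`model_to_json`."""
    import json

    p = json.loads(s)
    order = ModelOrder(p["L_d"], p["L_psi"], p["L_j"], tuple(p["neighbours"]))
    gamma = np.asarray(p["gamma"], dtype=float)
    if gamma.size == 0:
        gamma = np.empty((0, 0))
    params = SACDParams(
        omega=p["omega"],
        alpha=np.asarray(p["alpha"], dtype=float),
        beta=np.asarray(p["beta"], dtype=float),
        gamma=gamma,
        family=p["family"],
        k=p["k"],
        weights=None if p["weights"] is None else np.asarray(p["weights"], float),
    )
    return params, order


def unit_weibull_scale(k: float) -> float:
    """Scale lambda = 1/Gamma(1 + 1/k) making a Weibull(k, lambda) unit-mean."""
    if not (0 < k <= 1):
        raise ValidationError("weibull shape k must lie in (0, 1]")
    return float(np.exp(-gammaln(1.0 + 1.0 / k)))


def innovation_density(eps, family: str = "exponential", k: float | None = None):
    """Density of the unit-mean innovation law at eps > 0."""
    eps = np.asarray(eps, dtype=float)
    if (eps <= 0).any():
        raise ValidationError("innovation density defined for eps > 0 only")
    if family == "exponential":
        out = expon.pdf(eps)
    elif family == "weibull":
        lam = unit_weibull_scale(k)
        out = weibull_min.pdf(eps, k, scale=lam)
    else:
        raise ValidationError(f"unknown family {family!r}")
    return out if out.ndim else float(out)


def innovation_logpdf(eps, family: str = "exponential", k: float | None = None):
    """Log-density of the unit-mean innovation law (log-space, overflow-safe)."""
    eps = np.asarray(eps, dtype=float)
    if (eps <= 0).any():
        raise ValidationError("innovation log-density defined for eps > 0 only")
    if family == "exponential":
        out = -eps
    elif family == "weibull":
        lam = unit_weibull_scale(k)
        out = weibull_min.logpdf(eps, k, scale=lam)
    else:
        raise ValidationError(f"unknown family {family!r}")
    return out if np.ndim(out) else float(out)
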