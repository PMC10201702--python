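"""The trimmed log-t convergence regression with HAC inference.

Given the cross-sectional transition variance H_t of a panel (t = 1..T), the
log-t test regresses

    y_t = log(H_1 / H_t) - 2 log(log t)  on  {1, log t},   t = [rT]+1, ..., T

by OLS, discarding the first fraction r of the sample (r = 0.3 is the
convention for annual data).  Under convergence H_t decays like
t^{-2a} (log t)^{-2} and the slope estimates beta = 2a >= 0; the null of
convergence is rejected, one-sided at the 5% level, when the
autocorrelation-robust t-statistic falls below -1.65.

The standard error of the slope uses a Bartlett-kernel (Newey-West) long-run
variance with lag truncation floor(4 (T_reg/100)^{2/9}) by default.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .exceptions import InsufficientSampleError
from .panel import ZERO_H_TOL, Panel, transform_values, transition_from_matrix

__all__ = [
    "LogTResult",
    "logt_regression",
    "convergence_decision",
    "default_hac_bandwidth",
    "LogTTest",
]

#: one-sided 5% critical value of the convergence t-test
CRIT_5PCT = -1.65


def convergence_decision(t_stat: float, crit: float = CRIT_5PCT) -> bool:
    """True unless the t-statistic is strictly below the critical value.

    The null of convergence is rejected only when t < crit; a value exactly
    at the critical value does not reject.
    """
    return not (t_stat < crit)


def default_hac_bandwidth(n_obs: int) -> int:
    """Newey-West lag truncation floor(4 (n/100)^{2/9})."""
    return int(math.floor(4.0 * (n_obs / 100.0) ** (2.0 / 9.0)))


@dataclass(frozen=True)
class LogTResult:
    """Fitted log-t regression and the one-sided convergence decision.

    ``t_stat`` is ``beta_hat / se_beta``; it is the +inf sentinel (with NaN
    coefficients) when the retained H_t are exactly zero, i.e. the
    cross-section has already fully converged.
    """

    alpha_hat: float
    beta_hat: float
    se_beta: float
    t_stat: float
    trim_fraction: float
    n_years: int
    n_regression_obs: int
    converged: bool
    crit: float = CRIT_5PCT
    hac_bandwidth: Optional[int] = None
    n_units: Optional[int] = None

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "LogTResult":
        return cls(**d)


def logt_regression(
    H,
    trim_fraction: float = 0.3,
    *,
    crit: float = CRIT_5PCT,
    hac_bandwidth: Optional[int] = None,
    n_units: Optional[int] = None,
    zero_tol: float = ZERO_H_TOL,
) -> LogTResult:
    """Run the trimmed log-t regression on a cross-sectional variance series.

    Parameters
    ----------
    H : array-like, length T >= 10
        Cross-sectional transition variance at t = 1..T (H[0] is H_1).
    trim_fraction : float in (0, 0.5)
        Fraction r of early periods discarded; the regression runs over
        t = floor(rT)+1 .. T.
    hac_bandwidth : int, optional
        Bartlett-kernel lag truncation; default floor(4 (T_reg/100)^{2/9}).
    n_units : int, optional
        Cross-section size, echoed in the result for reporting.

    Returns
    -------
    LogTResult
        With the perfect-convergence sentinel (t = +inf, converged) when any
        retained H_t, or H_1, is exactly zero.
    """
    H = np.asarray(H, dtype=float)
    if H.ndim != 1:
        raise ValueError("H must be one-dimensional")
    T = int(H.size)
    if T < 10:
        raise InsufficientSampleError(f"need T >= 10 periods for the log-t test, got {T}")
    if not 0.0 < trim_fraction < 0.5:
        raise ValueError(f"trim_fraction must lie in (0, 0.5), got {trim_fraction}")
    if np.any(H < 0):
        raise ValueError("H must be non-negative")

    start = int(math.floor(trim_fraction * T)) + 1  # first retained t (1-based)
    if start < 2:
        raise ValueError(
            f"trim_fraction {trim_fraction} retains t = 1 where log(log t) is "
            "undefined; increase the trim or the sample length"
        )
    n_obs = T - (start - 1)
    if n_obs < 5:
        raise InsufficientSampleError(
            f"only {n_obs} observations remain after trimming; need at least 5"
        )
    bandwidth = default_hac_bandwidth(n_obs) if hac_bandwidth is None else int(hac_bandwidth)

    retained = H[start - 1 :]
    sentinel = None
    if np.any(retained <= zero_tol):
        # exact convergence: H has hit zero inside the window
        sentinel = math.inf
    elif H[0] <= zero_tol:
        # degenerate start: the cross-section coincided at t=1 but has
        # positive variance later, the strongest possible divergence signal
        sentinel = -math.inf
    if sentinel is not None:
        return LogTResult(
            alpha_hat=math.nan,
            beta_hat=math.nan,
            se_beta=math.nan,
            t_stat=sentinel,
            trim_fraction=trim_fraction,
            n_years=T,
            n_regression_obs=n_obs,
            converged=convergence_decision(sentinel, crit),
            crit=crit,
            hac_bandwidth=bandwidth,
            n_units=n_units,
        )

    t = np.arange(start, T + 1, dtype=float)
    y = np.log(H[0] / retained) - 2.0 * np.log(np.log(t))
    X = sm.add_constant(np.log(t))
    fit = sm.OLS(y, X).fit(
        cov_type="HAC", cov_kwds={"maxlags": bandwidth, "use_correction": False}
    )
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    t_stat = beta / se if se > 0 else math.copysign(math.inf, beta)
    return LogTResult(
        alpha_hat=float(fit.params[0]),
        beta_hat=beta,
        se_beta=se,
        t_stat=t_stat,
        trim_fraction=trim_fraction,
        n_years=T,
        n_regression_obs=n_obs,
        converged=convergence_decision(t_stat, crit),
        crit=crit,
        hac_bandwidth=bandwidth,
        n_units=n_units,
    )


class LogTTest(BaseEstimator):
    """Sklearn-style estimator running the full log-t convergence test.

    ``fit`` accepts either a :class:`~clubconv.panel.Panel` or a raw
    (n_units, n_years) array of positive densities, applies the configured
    transform and smoothing, computes the transition paths and runs the
    trimmed log-t regression.

    Parameters
    ----------
    transform : {"log", "levels"}, default "log"
        Whether the transition paths are computed from log densities.
    hp_lambda : float or None, default 400.0
        HP-smoothing weight applied per unit before the transition paths;
        None disables smoothing.
    trim_fraction : float, default 0.3
        Early-sample trim r of the regression.
    crit : float, default -1.65
        One-sided critical value of the convergence decision.
    hac_bandwidth : int or None
        Newey-West lag truncation; None uses floor(4 (T_reg/100)^{2/9}).

    Attributes
    ----------
    result_ : LogTResult
    h_ : ndarray of shape (n_units, n_years)
    H_ : ndarray of shape (n_years,)
    """

    def __init__(
        self,
        transform: str = "log",
        hp_lambda: Optional[float] = 400.0,
        trim_fraction: float = 0.3,
        crit: float = CRIT_5PCT,
        hac_bandwidth: Optional[int] = None,
    ):
        self.transform = transform
        self.hp_lambda = hp_lambda
        self.trim_fraction = trim_fraction
        self.crit = crit
        self.hac_bandwidth = hac_bandwidth

    def fit(self, X, y=None):
        values = X.values if isinstance(X, Panel) else np.asarray(X, dtype=float)
        if values.ndim != 2:
            raise ValueError("X must be a Panel or a 2-D (n_units, n_years) array")
        if np.any(values <= 0) or not np.all(np.isfinite(values)):
            raise ValueError("densities must be finite and strictly positive")
        xt = transform_values(values, self.transform, self.hp_lambda)
        self.h_, self.H_ = transition_from_matrix(xt)
        self.result_ = logt_regression(
            self.H_,
            self.trim_fraction,
            crit=self.crit,
            hac_bandwidth=self.hac_bandwidth,
            n_units=values.shape[0],
        )
        return self

    @property
    def converged_(self) -> bool:
        return self.result_.converged

    @property
    def t_stat_(self) -> float:
        return self.result_.t_stat

    @property
    def beta_(self) -> float:
        return self.result_.beta_hat
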