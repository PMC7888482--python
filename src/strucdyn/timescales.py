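"""Autocorrelation-based intrinsic-timescale estimators.

Two classic summaries of how quickly a signal decorrelates:

* :func:`decay_timescale` -- nonlinear least-squares fit of
  ``acf(k) ~ A (exp(-k dt / tau) + B)`` to the sample autocorrelation
  function, returning the decay constant ``tau`` in seconds.  For an AR(1)
  process with coefficient phi the ACF is exactly exponential with
  ``tau = -dt / ln(phi)``, which the fit recovers.
* :func:`acf_area_to_zero` -- the area under the ACF before its first
  non-positive value (a rectangular sum times the sampling period).

Both operate on an :class:`AcfCurve` produced by :func:`acf`, which uses the
biased (nonnegative-definite) estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit
from statsmodels.tsa.stattools import acf as _sm_acf

__all__ = [
    "AcfCurve",
    "TimescaleEstimate",
    "acf",
    "first_zero_lag",
    "decay_timescale",
    "acf_area_to_zero",
]


@dataclass
class AcfCurve:
    """Sample autocorrelation values at lags 0..L with the sampling period."""

    values: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("AcfCurve needs a 1-D array of >= 2 lags")
        if abs(self.values[0] - 1.0) > 1e-9:
            raise ValueError("values[0] must be 1")
        if np.any(np.abs(self.values) > 1 + 1e-9):
            raise ValueError("autocorrelations must lie in [-1, 1]")
        if not self.tr > 0:
            raise ValueError("tr must be positive")

    @property
    def lags(self) -> np.ndarray:
        return np.arange(self.values.size)

    @property
    def max_lag(self) -> int:
        return self.values.size - 1


@dataclass
class TimescaleEstimate:
    """A timescale in seconds plus fit diagnostics.

    ``value`` is None when the estimator failed to converge; ``flags``
    carries qualitative diagnostics such as ``"no_crossing"``.
    """

    value: float | None
    kind: str
    converged: bool
    resid_norm: float | None = None
    flags: tuple[str, ...] = field(default_factory=tuple)
    params: dict = field(default_factory=dict)


def acf(ts: np.ndarray, max_lag: int, tr: float = 1.0) -> AcfCurve:
    """Biased sample autocorrelation function up to ``max_lag``.

    values[k] = sum_t (x_t - xbar)(x_{t+k} - xbar) / sum_t (x_t - xbar)^2.
    The biased estimator guarantees a nonnegative-definite sequence.
    """
    x = np.asarray(ts, dtype=float)
    if max_lag >= x.size / 2:
        raise ValueError("max_lag must be below half the series length")
    if x.std() == 0:
        raise ValueError("cannot compute the ACF of a constant series")
    vals = _sm_acf(x, nlags=max_lag, fft=True, adjusted=False)
    return AcfCurve(vals, tr=tr)


def first_zero_lag(curve: AcfCurve) -> int | None:
    """Smallest lag k >= 1 with acf(k) <= 0, or None if no crossing."""
    below = np.nonzero(curve.values[1:] <= 0)[0]
    return int(below[0]) + 1 if below.size else None


def _decay_model(k: np.ndarray, amp: float, tau: float, offset: float) -> np.ndarray:
    # exponent clipped so wayward optimizer steps (tau -> 0-) cannot overflow
    return amp * (np.exp(np.clip(-k / tau, -700.0, 50.0)) + offset)


def decay_timescale(curve: AcfCurve, max_fit_lag: int = 50) -> TimescaleEstimate:
    """Fit ``A (exp(-k tr / tau) + B)`` to the ACF; return tau in seconds.

    The fit uses lags 1..min(L, first_zero - 1, max_fit_lag): lag 0 is
    excluded (dominated by noise variance) and so is everything at or beyond
    the first zero crossing.  tau is constrained to the fitted lag window --
    a decay constant longer than the window is not identifiable from it, and
    unbounded fits on near-white series can otherwise return arbitrarily
    large extrapolations; a fit pinned at the window bound is flagged
    ``"window_limited"``.  Several starting values of tau are tried and the
    converged fit with the smallest residual norm wins; an honest
    ``converged`` flag is returned when all starts fail.
    """
    if curve.max_lag < 10:
        raise ValueError("decay_timescale needs an ACF with >= 10 lags")
    zero = first_zero_lag(curve)
    upper = min(curve.max_lag, max_fit_lag, (zero - 1) if zero is not None else curve.max_lag)
    lags = np.arange(1, upper + 1, dtype=float)
    if lags.size < 3:
        return TimescaleEstimate(
            None, kind="decay", converged=False, flags=("too_few_lags",)
        )
    y = curve.values[1 : upper + 1]

    # tau here is in lag units; converted to seconds on return
    tau_hi = float(lags.size)
    starts = [1.0, 5.0, 20.0]
    v1 = curve.values[1]
    if 0 < v1 < 1:
        starts.insert(0, -1.0 / np.log(v1))
    bounds = ([0.0, 1e-2, -1.0], [2.0, tau_hi, 1.0])
    best = None
    for tau0 in starts:
        tau0 = float(np.clip(tau0, 2e-2, tau_hi * 0.99))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", OptimizeWarning)
                popt, _ = curve_fit(
                    _decay_model,
                    lags,
                    y,
                    p0=[float(np.clip(v1, 0.1, 2.0)), tau0, 0.0],
                    bounds=bounds,
                    maxfev=5000,
                )
        except RuntimeError:
            continue
        if not np.isfinite(popt).all() or popt[1] <= 0:
            continue
        resid = float(np.linalg.norm(y - _decay_model(lags, *popt)))
        if best is None or resid < best[1]:
            best = (popt, resid)
    if best is None:
        return TimescaleEstimate(
            None, kind="decay", converged=False, flags=("no_convergence",)
        )
    popt, resid = best
    flags = ("window_limited",) if popt[1] > 0.99 * tau_hi else ()
    return TimescaleEstimate(
        float(popt[1] * curve.tr),
        kind="decay",
        converged=True,
        resid_norm=resid,
        flags=flags,
        params={"A": float(popt[0]), "B": float(popt[2]), "fit_lags": int(lags.size)},
    )


def acf_area_to_zero(curve: AcfCurve) -> TimescaleEstimate:
    """Area under the ACF before it first passes zero, in seconds.

    Rectangular sum: tr * sum of values[0..z-1], where z is the first lag
    with acf <= 0.  If the ACF never crosses within the available lags the
    full sum is returned with a ``"no_crossing"`` flag.
    """
    zero = first_zero_lag(curve)
    if zero is None:
        area = curve.tr * float(curve.values.sum())
        return TimescaleEstimate(
            area, kind="area", converged=True, flags=("no_crossing",)
        )
    area = curve.tr * float(curve.values[:zero].sum())
    return TimescaleEstimate(
        area, kind="area", converged=True, params={"first_zero_lag": zero}
    )
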