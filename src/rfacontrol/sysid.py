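"""ARX system identification of the voltage→impedance roll-off dynamics.

The tissue-impedance trace recorded during radiofrequency ablation is
modelled as an ARX (autoregressive with exogenous input) process

    A(z⁻¹)·y(k) = B(z⁻¹)·u(k) + ξ(k),
    A(z⁻¹) = 1 + a₁z⁻¹ + … + a_na·z⁻ⁿᵃ,   B(z⁻¹) = b₁z⁻¹ + … + b_nb·z⁻ⁿᵇ,

with u the applied RMS voltage, y the tissue impedance and ξ the equation
error.  The coefficients are estimated by linear least squares on the
one-step-ahead regression, goodness of fit is reported as the NRMSE-based
FIT percentage and the coefficient of determination R², and the estimated
model is refined into a low-order rational transfer function by iterative
prefiltering (Steiglitz–McBride).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from sklearn.base import BaseEstimator, RegressorMixin

from .lti import RationalTF, d2c_convert

__all__ = [
    "TimeSeries",
    "ARXModel",
    "FitReport",
    "ResidualDiagnostics",
    "ARXRegressor",
    "TransferFunctionEstimator",
    "resample_uniform",
    "build_regression",
    "fit_arx",
    "predict_one_step",
    "simulate_free_run",
    "fit_percent",
    "r_squared",
    "residual_correlations",
    "estimate_tf_from_series",
]


@dataclass
class TimeSeries:
    """Paired input/output samples: times (s), voltage u (V RMS), impedance y (Ω)."""

    times: np.ndarray
    input_u: np.ndarray
    output_y: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.input_u = np.asarray(self.input_u, dtype=float)
        self.output_y = np.asarray(self.output_y, dtype=float)
        if not (self.times.size == self.input_u.size == self.output_y.size):
            raise ValueError("times, input and output must have equal length")
        if self.times.size >= 2 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    @property
    def uniform(self) -> bool:
        if len(self) < 3:
            return True
        d = np.diff(self.times)
        return bool(np.allclose(d, d[0], rtol=1e-9, atol=1e-12))

    @property
    def rate(self) -> float:
        """Sampling rate in Hz (uniform series only)."""
        if not self.uniform:
            raise ValueError("rate is only defined for uniform series")
        return 1.0 / float(self.times[1] - self.times[0])


@dataclass
class ARXModel:
    """Estimated ARX polynomial coefficients (sign convention A = 1 + Σaᵢz⁻ⁱ)."""

    na: int
    nb: int
    a_coeffs: np.ndarray
    b_coeffs: np.ndarray

    def __post_init__(self) -> None:
        self.a_coeffs = np.asarray(self.a_coeffs, dtype=float)
        self.b_coeffs = np.asarray(self.b_coeffs, dtype=float)
        if self.a_coeffs.size != self.na or self.b_coeffs.size != self.nb:
            raise ValueError("coefficient counts must match the model orders")
        if self.na < 1 or self.nb < 1:
            raise ValueError("model orders must be >= 1")

    @property
    def p(self) -> int:
        """Regression start index, 1 + max(na, nb) (1-based, as in the model)."""
        return 1 + max(self.na, self.nb)


@dataclass
class FitReport:
    fit_percent: float
    r_squared: float
    residuals: np.ndarray


@dataclass
class ResidualDiagnostics:
    """Whiteness diagnostics of the one-step residuals ξ(k).

    Linear panels: normalized autocorrelation of ξ and cross-correlation of
    ξ with the input, over lags −max_lag…max_lag.  Nonlinear panels repeat
    both for the squared (mean-removed) residuals.  The 95% whiteness bound
    is ±1.96/√N.
    """

    lags: np.ndarray
    autocorrelation: np.ndarray
    cross_correlation_with_input: np.ndarray
    confidence_bound: float
    autocorrelation_squared: np.ndarray = field(default=None)
    cross_correlation_squared: np.ndarray = field(default=None)


# ---------------------------------------------------------------------------
# resampling and regression construction
# ---------------------------------------------------------------------------


def resample_uniform(ts: TimeSeries, rate: float = 1.0) -> TimeSeries:
    """Linear-interpolation resampling onto a uniform grid at ``rate`` Hz.

    The grid runs from the first to the last timestamp; a record spanning
    0–316 s therefore yields 317 samples at 1 Hz.
    """
    if len(ts) < 2:
        raise ValueError("need at least two samples to resample")
    if rate <= 0:
        raise ValueError("rate must be positive")
    t0, t1 = ts.times[0], ts.times[-1]
    n = int(np.floor((t1 - t0) * rate + 1e-9)) + 1
    grid = t0 + np.arange(n) / rate
    return TimeSeries(
        times=grid,
        input_u=np.interp(grid, ts.times, ts.input_u),
        output_y=np.interp(grid, ts.times, ts.output_y),
    )


def build_regression(
    ts: TimeSeries, na: int, nb: int
) -> tuple[np.ndarray, np.ndarray]:
    """Regression matrix φ and target vector for the ARX least-squares problem.

    Row k (k = p…N, 1-based, p = 1 + max(na, nb)) is
    ``[-y(k-1) … -y(k-na), u(k-1) … u(k-nb)]``; φ has shape
    ``(N - p + 1, na + nb)``.
    """
    if not ts.uniform:
        raise ValueError("ARX regression requires a uniformly sampled series")
    u, y = ts.input_u, ts.output_y
    N = len(ts)
    p = 1 + max(na, nb)
    if N <= p:
        raise ValueError(f"series too short: need more than {p} samples, got {N}")
    rows = N - p + 1
    phi = np.empty((rows, na + nb))
    for i in range(1, na + 1):
        phi[:, i - 1] = -y[p - 1 - i : N - i]
    for j in range(1, nb + 1):
        phi[:, na + j - 1] = u[p - 1 - j : N - j]
    return phi, y[p - 1 : N].copy()


def fit_arx(ts: TimeSeries, na: int, nb: int) -> ARXModel:
    """Least-squares ARX estimate θ̂ = argmin ‖y − φθ‖²."""
    phi, target = build_regression(ts, na, nb)
    theta, _, rank, _ = np.linalg.lstsq(phi, target, rcond=None)
    if rank < phi.shape[1]:
        warnings.warn(
            f"rank-deficient regression matrix (rank {rank} < {phi.shape[1]}); "
            "returning the minimum-norm least-squares solution",
            stacklevel=2,
        )
    return ARXModel(na=na, nb=nb, a_coeffs=theta[:na], b_coeffs=theta[na:])


def predict_one_step(model: ARXModel, ts: TimeSeries) -> np.ndarray:
    """One-step-ahead prediction ŷ(k) for k = p…N, using measured past outputs."""
    if not ts.uniform:
        raise ValueError("prediction requires a uniformly sampled series")
    if len(ts) < model.p:
        raise ValueError("series shorter than the regression start index")
    phi, _ = build_regression(ts, model.na, model.nb)
    theta = np.concatenate([model.a_coeffs, model.b_coeffs])
    return phi @ theta


def simulate_free_run(model: ARXModel, ts: TimeSeries) -> np.ndarray:
    """Free-run simulation: past *predicted* outputs feed the recursion.

    Diagnostic companion to :func:`predict_one_step`; the first p−1 samples
    are initialized from the measured outputs.
    """
    u, y = ts.input_u, ts.output_y
    N = len(ts)
    p = model.p
    yhat = np.empty(N)
    yhat[: p - 1] = y[: p - 1]
    for k in range(p - 1, N):
        acc = 0.0
        for i in range(1, model.na + 1):
            acc -= model.a_coeffs[i - 1] * yhat[k - i]
        for j in range(1, model.nb + 1):
            acc += model.b_coeffs[j - 1] * u[k - j]
        yhat[k] = acc
    return yhat[p - 1 :]


# ---------------------------------------------------------------------------
# goodness of fit
# ---------------------------------------------------------------------------


def _check_pair(y, yhat):
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.size != yhat.size or y.size < 2:
        raise ValueError("need equal-length arrays with at least two samples")
    sst = np.sum((y - y.mean()) ** 2)
    if sst == 0.0:
        raise ValueError("constant reference signal: fit metrics undefined")
    return y, yhat, sst


def fit_percent(y, yhat, convention: str = "nrmse") -> float:
    """FIT index in percent.

    ``"nrmse"`` (default) is the normalized-root-mean-square-error fit
    ``100·(1 − ‖y−ŷ‖/‖y−ȳ‖)`` used by standard identification toolchains;
    a perfect model scores 100, predicting the mean scores 0.  ``"ratio"``
    exposes the plain percentage ratio ``100·Σξ²/Σ(y−ȳ)²`` for comparison.
    """
    y, yhat, sst = _check_pair(y, yhat)
    sse = np.sum((y - yhat) ** 2)
    if convention == "nrmse":
        return float(100.0 * (1.0 - np.sqrt(sse) / np.sqrt(sst)))
    if convention == "ratio":
        return float(100.0 * sse / sst)
    raise ValueError(f"unknown convention {convention!r}")


def r_squared(y, yhat) -> float:
    """Coefficient of determination R² = 1 − Σξ²/Σ(y−ȳ)²."""
    y, yhat, sst = _check_pair(y, yhat)
    return float(1.0 - np.sum((y - yhat) ** 2) / sst)


def residual_correlations(
    residuals, input_u, max_lag: int = 20
) -> ResidualDiagnostics:
    """Normalized residual auto/cross-correlations with a ±1.96/√N bound."""
    xi = np.asarray(residuals, dtype=float)
    u = np.asarray(input_u, dtype=float)
    if xi.size != u.size:
        raise ValueError("residuals and input must have equal length")
    n = xi.size
    if n < max_lag + 1:
        raise ValueError("series shorter than max_lag + 1")
    if np.std(xi) == 0.0:
        raise ValueError("zero-variance residuals")
    lags = np.arange(-max_lag, max_lag + 1)

    def _norm_xcorr(a, b):
        a = a - a.mean()
        b = b - b.mean()
        denom = n * a.std() * b.std()
        if denom == 0.0:
            return np.zeros(lags.size)
        full = np.correlate(a, b, mode="full")  # lag k at index n-1+k
        return full[n - 1 - max_lag : n + max_lag] / denom

    xi2 = xi**2
    return ResidualDiagnostics(
        lags=lags,
        autocorrelation=_norm_xcorr(xi, xi),
        cross_correlation_with_input=_norm_xcorr(xi, u),
        confidence_bound=1.96 / np.sqrt(n),
        autocorrelation_squared=_norm_xcorr(xi2, xi2),
        cross_correlation_squared=_norm_xcorr(xi2, u),
    )


# ---------------------------------------------------------------------------
# transfer-function estimation (Steiglitz–McBride iterative prefiltering)
# ---------------------------------------------------------------------------


def _sm_regression(uf, yf, n_poles, n_terms, delay):
    rows = uf.size - n_poles
    phi = np.empty((rows, n_poles + n_terms))
    for i in range(1, n_poles + 1):
        phi[:, i - 1] = -yf[n_poles - i : uf.size - i]
    for j in range(n_terms):
        lag = delay + j
        phi[:, n_poles + j] = uf[n_poles - lag : uf.size - lag]
    return phi, yf[n_poles:]


def estimate_tf_from_series(
    ts: TimeSeries,
    n_poles: int,
    n_zeros: int,
    max_iter: int = 50,
    tol: float = 1e-8,
    continuous: bool = False,
    d2c_method: str = "zoh",
) -> RationalTF:
    """Estimate a rational transfer function from input/output data.

    A discrete equation-error least-squares fit is refined by iterative
    prefiltering à la Steiglitz–McBride: both signals are filtered by the
    reciprocal of the current denominator estimate before each re-fit, which
    removes the equation-error bias.  Iteration stops when the coefficient
    vector changes by less than ``tol`` (infinity norm) or after
    ``max_iter`` rounds; non-convergence issues a warning and returns the
    last iterate.  With ``continuous=True`` the result is converted to the
    s-domain via :func:`rfacontrol.lti.d2c_convert`.
    """
    if not ts.uniform:
        raise ValueError("transfer-function estimation requires uniform sampling")
    if n_zeros >= n_poles + 1:
        raise ValueError("need n_zeros <= n_poles for a proper discrete model")
    dt = 1.0 / ts.rate
    u, y = ts.input_u, ts.output_y
    delay = n_poles - n_zeros  # relative degree; numerator starts at z^-delay
    n_terms = n_zeros + 1

    a_prev = None
    den_zinv = np.ones(1)
    for _ in range(max_iter):
        if den_zinv.size > 1:
            uf = signal.lfilter([1.0], den_zinv, u)
            yf = signal.lfilter([1.0], den_zinv, y)
        else:
            uf, yf = u, y
        phi, target = _sm_regression(uf, yf, n_poles, n_terms, delay)
        theta, *_ = np.linalg.lstsq(phi, target, rcond=None)
        den_zinv = np.concatenate([[1.0], theta[:n_poles]])
        if a_prev is not None and np.max(np.abs(theta - a_prev)) < tol:
            a_prev = theta
            break
        a_prev = theta
    else:
        warnings.warn(
            "Steiglitz-McBride iteration did not converge; returning last iterate",
            stacklevel=2,
        )

    b = theta[n_poles:]
    num_zinv = np.concatenate([np.zeros(delay), b])
    tf = RationalTF.from_zinv(num_zinv, den_zinv, dt=dt)
    if continuous:
        tf = d2c_convert(tf, method=d2c_method)
    return tf


# ---------------------------------------------------------------------------
# scikit-learn style estimators
# ---------------------------------------------------------------------------


class ARXRegressor(RegressorMixin, BaseEstimator):
    """ARX identification as a scikit-learn estimator.

    Parameters
    ----------
    na, nb : int
        Orders of the output and input polynomials.  The canonical order
        for the ablation roll-off data is na = nb = 20.

    Attributes
    ----------
    model_ : ARXModel
        The estimated coefficients.
    fit_percent_, r_squared_ : float
        One-step-ahead goodness of fit on the training series.
    residuals_ : ndarray
        One-step-ahead residuals on the training series.
    """

    def __init__(self, na: int = 20, nb: int = 20):
        self.na = na
        self.nb = nb

    def fit(self, ts: TimeSeries, y=None) -> "ARXRegressor":
        self.model_ = fit_arx(ts, self.na, self.nb)
        yhat = predict_one_step(self.model_, ts)
        ref = ts.output_y[self.model_.p - 1 :]
        self.residuals_ = ref - yhat
        self.fit_percent_ = fit_percent(ref, yhat)
        self.r_squared_ = r_squared(ref, yhat)
        return self

    def predict(self, ts: TimeSeries) -> np.ndarray:
        return predict_one_step(self.model_, ts)

    def score(self, ts: TimeSeries, y=None) -> float:
        """R² of the one-step-ahead prediction on ``ts``."""
        yhat = self.predict(ts)
        return r_squared(ts.output_y[self.model_.p - 1 :], yhat)

    def report(self, ts: TimeSeries) -> FitReport:
        yhat = self.predict(ts)
        ref = ts.output_y[self.model_.p - 1 :]
        return FitReport(
            fit_percent=fit_percent(ref, yhat),
            r_squared=r_squared(ref, yhat),
            residuals=ref - yhat,
        )

    def diagnostics(self, ts: TimeSeries, max_lag: int = 20) -> ResidualDiagnostics:
        rep = self.report(ts)
        return residual_correlations(
            rep.residuals, ts.input_u[self.model_.p - 1 :], max_lag=max_lag
        )


class TransferFunctionEstimator(BaseEstimator):
    """Rational transfer-function estimation as a scikit-learn estimator.

    Fits a discrete n_poles/n_zeros model by Steiglitz–McBride iterative
    prefiltering; ``continuous=True`` converts the result to the s-domain.
    The headline configuration of the roll-off study is 9 poles / 8 zeros.
    """

    def __init__(
        self,
        n_poles: int = 9,
        n_zeros: int = 8,
        continuous: bool = False,
        max_iter: int = 50,
        tol: float = 1e-8,
        d2c_method: str = "zoh",
    ):
        self.n_poles = n_poles
        self.n_zeros = n_zeros
        self.continuous = continuous
        self.max_iter = max_iter
        self.tol = tol
        self.d2c_method = d2c_method

    def fit(self, ts: TimeSeries, y=None) -> "TransferFunctionEstimator":
        self.tf_ = estimate_tf_from_series(
            ts,
            self.n_poles,
            self.n_zeros,
            max_iter=self.max_iter,
            tol=self.tol,
            continuous=self.continuous,
            d2c_method=self.d2c_method,
        )
        return self

    def predict(self, ts: TimeSeries) -> np.ndarray:
        """Simulated response of the fitted model to ``ts.input_u``."""
        tf = self.tf_
        if tf.domain == "s":
            from .synthetic import _simulate_lti  # lazy: avoids module cycle

            return _simulate_lti(tf, ts.input_u, 1.0 / ts.rate)
        num, den = tf.to_zinv()
        return signal.lfilter(num, den, ts.input_u)

    def score(self, ts: TimeSeries, y=None) -> float:
        return r_squared(ts.output_y, self.predict(ts))
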