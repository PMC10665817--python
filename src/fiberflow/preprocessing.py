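"""zdF/F correction chain for dual-channel fiber photometry.

The activity measure is a standardized, reference-corrected fluorescence
signal: both the calcium-dependent signal and the calcium-independent
reference are smoothed, flattened with an airPLS baseline (adaptive
iteratively reweighted penalized least squares), standardized to zero mean
and unit variance, the standardized reference is fitted to the
standardized signal with a non-negative L1-regularized (Lasso) regression,
and the fitted reference is subtracted:

    zdF/F(t) = z_signal(t) - (a * z_reference(t) + b),   a >= 0

Motion artifacts and residual drift are shared between the channels, so
the subtraction cancels them while calcium transients — present only in
the signal channel — survive.

The numerical steps are exposed both as plain functions and as
scikit-learn estimators (:class:`MovingAverageSmoother`, :class:`AirPLS`,
:class:`ReferenceRegressor`, :class:`ZdFF`) so the chain composes with
sklearn pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve
from scipy.signal import butter, filtfilt
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin
from sklearn.linear_model import Lasso, LinearRegression

from .datatypes import AlignmentError, DataError, PhotometryTrace

__all__ = ["PreprocessParams", "FitResult", "smooth", "airpls_baseline",
           "whittaker_smooth", "standardize", "fit_reference", "compute_zdff",
           "MovingAverageSmoother", "AirPLS", "ReferenceRegressor", "ZdFF"]


@dataclass
class PreprocessParams:
    """Tunable parameters of the correction chain.

    Exactly one of ``smooth_window_s`` (centered moving average width) and
    ``lowpass_cutoff_hz`` (zero-phase Butterworth low-pass) must be set.
    """

    smooth_window_s: float | None = 1.0
    lowpass_cutoff_hz: float | None = None
    airpls_lambda: float = 1e8
    airpls_max_iter: int = 50
    airpls_tol: float = 1e-3
    l1_alpha: float = 1e-4
    sd_floor: float = 1e-8

    def __post_init__(self) -> None:
        if (self.smooth_window_s is None) == (self.lowpass_cutoff_hz is None):
            raise ValueError(
                "set exactly one of smooth_window_s and lowpass_cutoff_hz")
        if not self.airpls_lambda > 0:
            raise ValueError("airpls_lambda must be > 0")
        if self.airpls_max_iter < 1:
            raise ValueError("airpls_max_iter must be >= 1")
        if self.l1_alpha < 0:
            raise ValueError("l1_alpha must be >= 0")
        if not self.sd_floor > 0:
            raise ValueError("sd_floor must be > 0")


@dataclass
class FitResult:
    """Non-negative Lasso fit of the standardized reference to the signal."""

    slope_a: float
    intercept_b: float
    fitted_reference: np.ndarray


def _estimate_rate(trace: PhotometryTrace) -> float:
    if trace.nominal_rate_hz:
        return trace.nominal_rate_hz
    return 1.0 / float(np.median(np.diff(trace.timestamp_s)))


def _moving_average(y: np.ndarray, width: int) -> np.ndarray:
    # odd symmetric kernel with reflect padding: zero phase, DC preserved
    if width % 2 == 0:
        width += 1
    if width <= 1:
        return y.copy()
    if len(y) <= width:
        raise DataError(f"trace length {len(y)} <= smoothing width {width}")
    half = width // 2
    padded = np.pad(y, half, mode="reflect")
    kernel = np.full(width, 1.0 / width)
    return np.convolve(padded, kernel, mode="valid")


def smooth(trace: PhotometryTrace, params: PreprocessParams) -> PhotometryTrace:
    """Zero-phase smoothing (moving average or Butterworth low-pass)."""
    rate = _estimate_rate(trace)
    if params.smooth_window_s is not None:
        width = max(int(round(params.smooth_window_s * rate)), 1)
        out = _moving_average(trace.value, width)
    else:
        nyq = rate / 2.0
        if not 0 < params.lowpass_cutoff_hz < nyq:
            raise DataError("lowpass_cutoff_hz must lie in (0, Nyquist)")
        b, a = butter(2, params.lowpass_cutoff_hz / nyq)
        pad = min(3 * max(len(b), len(a)), len(trace) - 1)
        out = filtfilt(b, a, trace.value, padlen=pad)
    return trace.with_values(out)


def whittaker_smooth(y: np.ndarray, w: np.ndarray, lam: float) -> np.ndarray:
    """Solve the weighted Whittaker system (W + lam*D'D) z = W y.

    Second-order difference penalty; this is the inner solve of airPLS and,
    with uniform weights, the classical Whittaker smoother.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    D = sp.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n), format="csc")
    W = sp.diags(w, 0, format="csc")
    A = (W + lam * (D.T @ D)).tocsc()
    return spsolve(A, w * y)


def airpls_baseline(y, lam: float = 1e8, max_iter: int = 50,
                    tol: float = 1e-3, return_info: bool = False):
    """Adaptive iteratively reweighted penalized least-squares baseline.

    Points above the running baseline (peaks) get zero weight; points below
    get exponentially increasing weight in the magnitude of their residual,
    so the baseline sinks under the peaks while tracking the slow floor.
    Iteration stops once the summed magnitude of negative residuals falls
    below ``tol`` times the total absolute signal, or at ``max_iter``.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or len(y) < 3:
        raise DataError("airPLS needs a 1-D input of length >= 3")
    if not np.all(np.isfinite(y)):
        raise DataError("airPLS input contains non-finite values")
    n = len(y)
    w = np.ones(n)
    total = np.abs(y).sum()
    z = y.copy()
    history = []
    for it in range(1, max_iter + 1):
        z = whittaker_smooth(y, w, lam)
        d = y - z
        neg = d[d < 0]
        dssn = float(np.abs(neg.sum()))
        history.append(dssn)
        if dssn < tol * total:
            break
        w[d >= 0] = 0.0
        w[d < 0] = np.exp(it * np.abs(neg) / dssn)
    if return_info:
        return z, {"n_iter": len(history), "neg_residual_history": history}
    return z


def standardize(y, sd_floor: float = 1e-8):
    """Standardize to mean 0, sd 1 (population sd).

    Returns ``(z, degenerate)``; a trace whose sd is below ``sd_floor`` is
    returned as centered zeros with ``degenerate=True``.
    """
    y = np.asarray(y, dtype=float)
    if len(y) < 2:
        raise DataError("standardize needs length >= 2")
    sd = float(np.std(y))
    if sd < sd_floor:
        return np.zeros_like(y), True
    return (y - y.mean()) / sd, False


def fit_reference(reference_std: np.ndarray, signal_std: np.ndarray,
                  l1_alpha: float = 1e-4) -> FitResult:
    """Fit the standardized reference to the standardized signal.

    Non-negative L1-regularized least squares: slope constrained >= 0 so
    the reference can only be subtracted, never sign-flipped into a fake
    signal. ``l1_alpha = 0`` falls back to constrained ordinary least
    squares.
    """
    x = np.asarray(reference_std, dtype=float)
    y = np.asarray(signal_std, dtype=float)
    if x.shape != y.shape:
        raise DataError(f"length mismatch: reference {x.shape}, signal {y.shape}")
    if len(x) < 2:
        raise DataError("fit_reference needs length >= 2")
    if l1_alpha > 0:
        model = Lasso(alpha=l1_alpha, positive=True, fit_intercept=True,
                      max_iter=50_000)
    else:
        model = LinearRegression(positive=True)
    model.fit(x[:, None], y)
    a = float(model.coef_[0])
    b = float(model.intercept_)
    return FitResult(a, b, a * x + b)


def compute_zdff(signal: PhotometryTrace, reference: PhotometryTrace,
                 params: PreprocessParams | None = None,
                 return_fit: bool = False):
    """Full correction chain: smooth, detrend, standardize, fit, subtract.

    The reference is linearly interpolated onto the signal's timestamps
    (the two channels live on offset grids by construction of LED
    interleaving) before the fit. Returns the zdF/F trace on the signal's
    grid, plus the :class:`FitResult` when ``return_fit`` is true.
    """
    params = params or PreprocessParams()
    lo = max(signal.timestamp_s[0], reference.timestamp_s[0])
    hi = min(signal.timestamp_s[-1], reference.timestamp_s[-1])
    if hi <= lo:
        raise AlignmentError("signal and reference have no overlapping time support")

    def _prep(trace: PhotometryTrace) -> np.ndarray:
        y = smooth(trace, params).value
        y = y - airpls_baseline(y, params.airpls_lambda, params.airpls_max_iter,
                                params.airpls_tol)
        z, _ = standardize(y, params.sd_floor)
        return z

    z_sig = _prep(signal)
    z_ref = _prep(reference)
    z_ref_on_sig = np.interp(signal.timestamp_s, reference.timestamp_s, z_ref)
    fit = fit_reference(z_ref_on_sig, z_sig, params.l1_alpha)
    out = signal.with_values(z_sig - fit.fitted_reference)
    out.channel_label = f"zdff({signal.channel_label})"
    return (out, fit) if return_fit else out


# ---------------------------------------------------------------------------
# scikit-learn estimator facade


def _columns(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2:
        raise DataError("expected a 1-D or 2-D array (samples x traces)")
    return X


class MovingAverageSmoother(TransformerMixin, BaseEstimator):
    """Centered moving-average smoother; columns are independent traces."""

    def __init__(self, window_s: float = 1.0, rate_hz: float = 10.0):
        self.window_s = window_s
        self.rate_hz = rate_hz

    def fit(self, X, y=None):
        _columns(X)
        self.n_features_in_ = _columns(X).shape[1]
        return self

    def transform(self, X):
        X = _columns(X)
        width = max(int(round(self.window_s * self.rate_hz)), 1)
        return np.column_stack([_moving_average(X[:, j], width)
                                for j in range(X.shape[1])])


class AirPLS(TransformerMixin, BaseEstimator):
    """airPLS detrender: fit estimates ``baseline_``, transform subtracts it."""

    def __init__(self, lam: float = 1e8, max_iter: int = 50, tol: float = 1e-3):
        self.lam = lam
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y=None):
        X = _columns(X)
        cols, infos = [], []
        for j in range(X.shape[1]):
            z, info = airpls_baseline(X[:, j], self.lam, self.max_iter,
                                      self.tol, return_info=True)
            cols.append(z)
            infos.append(info)
        self.baseline_ = np.column_stack(cols)
        self.info_ = infos
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = _columns(X)
        if X.shape != self.baseline_.shape:
            raise DataError("transform input shape differs from fitted shape")
        return X - self.baseline_

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)


class ReferenceRegressor(RegressorMixin, BaseEstimator):
    """Non-negative Lasso of a reference channel onto a signal channel."""

    def __init__(self, alpha: float = 1e-4):
        self.alpha = alpha

    def fit(self, X, y):
        X = _columns(X)
        fit = fit_reference(X[:, 0], np.asarray(y, dtype=float), self.alpha)
        self.coef_ = np.array([fit.slope_a])
        self.intercept_ = fit.intercept_b
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        X = _columns(X)
        return self.coef_[0] * X[:, 0] + self.intercept_


class ZdFF(BaseEstimator):
    """High-level estimator for the whole correction chain.

    ``fit(signal, reference)`` runs the chain and exposes ``slope_a_``,
    ``intercept_b_`` and the corrected trace ``zdff_``; ``transform()``
    returns the corrected values.
    """

    def __init__(self, smooth_window_s: float | None = 1.0,
                 lowpass_cutoff_hz: float | None = None,
                 airpls_lambda: float = 1e8, airpls_max_iter: int = 50,
                 airpls_tol: float = 1e-3, l1_alpha: float = 1e-4,
                 sd_floor: float = 1e-8):
        self.smooth_window_s = smooth_window_s
        self.lowpass_cutoff_hz = lowpass_cutoff_hz
        self.airpls_lambda = airpls_lambda
        self.airpls_max_iter = airpls_max_iter
        self.airpls_tol = airpls_tol
        self.l1_alpha = l1_alpha
        self.sd_floor = sd_floor

    def _params(self) -> PreprocessParams:
        return PreprocessParams(
            smooth_window_s=self.smooth_window_s,
            lowpass_cutoff_hz=self.lowpass_cutoff_hz,
            airpls_lambda=self.airpls_lambda,
            airpls_max_iter=self.airpls_max_iter,
            airpls_tol=self.airpls_tol,
            l1_alpha=self.l1_alpha,
            sd_floor=self.sd_floor,
        )

    def fit(self, signal: PhotometryTrace, reference: PhotometryTrace):
        trace, fit = compute_zdff(signal, reference, self._params(),
                                  return_fit=True)
        self.zdff_ = trace
        self.slope_a_ = fit.slope_a
        self.intercept_b_ = fit.intercept_b
        return self

    def transform(self, signal=None, reference=None) -> np.ndarray:
        if signal is not None and reference is not None:
            return compute_zdff(signal, reference, self._params()).value
        return self.zdff_.value

    def fit_transform(self, signal: PhotometryTrace,
                      reference: PhotometryTrace) -> np.ndarray:
        return self.fit(signal, reference).transform()
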