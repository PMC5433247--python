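"""Causal FIR prediction of one ROI timeseries from another.

The target series ``x_tgt`` is predicted from the source ``x_src`` through a
causal finite-impulse-response filter,

.. math::

    \\hat{x}[n] = \\sum_{m=0}^{N_h - 1} h[m] \\, x_{src}[n - m],

with ``x_src[n] = 0`` for ``n < 0`` (zero-padding), so the prediction and
its least-squares cost are defined over the same ``N_x`` samples for every
candidate filter length.  Coefficients minimize the residual sum of squares
either unconstrained (ordinary least squares, minimum-norm when singular) or
under elementwise nonnegativity (NNLS), the latter encoding prior knowledge
that interactions are positive.

The filter length ``N_h`` (the memory duration, in samples) is selected by
minimizing an Akaike information criterion over ``N_h = 1..max_taps``:

.. math::

    \\mathrm{AIC} = N_x \\log\\left(\\frac{2\\pi J}{N_x - N_h}\\right)
                  + N_x + N_h,

with the small-sample (AICc) correction ``+ 2 N_h (N_h + 1)/(N_x - N_h - 1)``
added when ``N_x / N_h < 40``.  With ``N_h = 1`` the model uses only the
current source value and the method reduces to standard correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .errors import InputError

__all__ = [
    "FirFit",
    "lagged_design",
    "predict",
    "least_squares_cost",
    "fit_fir",
    "aic",
    "select_order",
    "max_taps_from_seconds",
]


@dataclass(frozen=True)
class FirFit:
    """Estimated impulse response for one ordered (source, target) pair."""

    coefficients: np.ndarray  # h[0..n_taps-1]
    n_taps: int
    cost: float  # residual sum of squares J
    aic_value: float
    constrained: bool

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "coefficients", np.asarray(self.coefficients, dtype=float)
        )
        if self.coefficients.shape != (self.n_taps,):
            raise InputError("coefficients length must equal n_taps")
        if self.cost < 0:
            raise InputError("cost must be nonnegative")
        if self.constrained and np.any(self.coefficients < 0):
            raise InputError("constrained fit has negative coefficients")


def lagged_design(x_src: np.ndarray, n_taps: int) -> np.ndarray:
    """Design matrix with column ``m`` holding ``x_src`` delayed by ``m``
    samples, zero-padded at the start."""
    x_src = np.asarray(x_src, dtype=float)
    n = x_src.size
    if n == 0:
        raise InputError("empty series")
    if not 1 <= n_taps <= n:
        raise InputError(f"n_taps must be in [1, {n}], got {n_taps}")
    X = np.zeros((n, n_taps))
    for m in range(n_taps):
        X[m:, m] = x_src[: n - m]
    return X


def predict(x_src: np.ndarray, fit: FirFit | np.ndarray) -> np.ndarray:
    """Apply the causal filter to ``x_src`` (zero initial conditions).

    Output has the same length as the input.
    """
    h = fit.coefficients if isinstance(fit, FirFit) else np.asarray(fit, dtype=float)
    x_src = np.asarray(x_src, dtype=float)
    if x_src.size == 0:
        raise InputError("empty series")
    if x_src.size < h.size:
        raise InputError("series shorter than the filter")
    return np.convolve(x_src, h)[: x_src.size]


def least_squares_cost(x_tgt: np.ndarray, x_hat: np.ndarray) -> float:
    """Residual sum of squares J between a series and its prediction."""
    x_tgt = np.asarray(x_tgt, dtype=float)
    x_hat = np.asarray(x_hat, dtype=float)
    if x_tgt.shape != x_hat.shape:
        raise InputError("series and prediction must have equal length")
    return float(np.sum((x_tgt - x_hat) ** 2))


def fit_fir(
    x_src: np.ndarray, x_tgt: np.ndarray, n_taps: int, constrained: bool
) -> FirFit:
    """Least-squares FIR coefficients for a fixed filter length.

    Unconstrained fits use the minimum-norm least-squares solution;
    constrained fits solve the same problem under ``h[m] >= 0`` via the
    Lawson-Hanson active-set algorithm (KKT-exact).  A constant-zero source
    legitimately yields the all-zero filter.
    """
    x_src = np.asarray(x_src, dtype=float)
    x_tgt = np.asarray(x_tgt, dtype=float)
    if x_src.shape != x_tgt.shape:
        raise InputError("source and target must have equal length")
    n = x_src.size
    if not 1 <= n_taps <= n:
        raise InputError(f"n_taps must be in [1, {n}], got {n_taps}")
    X = lagged_design(x_src, n_taps)
    if constrained:
        h, _ = nnls(X, x_tgt)
    else:
        h, *_ = np.linalg.lstsq(X, x_tgt, rcond=None)
    cost = least_squares_cost(x_tgt, X @ h)
    return FirFit(
        coefficients=h,
        n_taps=n_taps,
        cost=cost,
        aic_value=aic(cost, n, n_taps),
        constrained=constrained,
    )


def aic(cost: float, n_samples: int, n_taps: int) -> float:
    """Akaike information criterion for an ``n_taps``-parameter FIR fit.

    Uses the large-sample form when ``n_samples / n_taps >= 40`` and adds
    the AICc small-sample correction otherwise.  A perfect fit (J = 0) has
    an unbounded log-likelihood and returns ``-inf`` so that the smallest
    perfect-fit order wins the selection.
    """
    if n_samples <= n_taps + 1:
        raise InputError("n_samples must exceed n_taps + 1")
    if cost < 0:
        raise InputError("cost must be nonnegative")
    if cost == 0:
        return -np.inf
    value = (
        n_samples * np.log(2.0 * np.pi * cost / (n_samples - n_taps))
        + n_samples
        + n_taps
    )
    if n_samples / n_taps < 40:
        value += 2.0 * n_taps * (n_taps + 1) / (n_samples - n_taps - 1)
    return float(value)


def select_order(
    x_src: np.ndarray, x_tgt: np.ndarray, max_taps: int, constrained: bool
) -> FirFit:
    """Fit every filter length in ``1..max_taps`` and keep the AIC minimum.

    Ties are broken toward the shorter filter (parsimony).
    """
    n = np.asarray(x_src).size
    if not 1 <= max_taps < n / 2:
        raise InputError(f"max_taps must be in [1, N_x/2), got {max_taps} for N_x={n}")
    best: FirFit | None = None
    for n_taps in range(1, max_taps + 1):
        fit = fit_fir(x_src, x_tgt, n_taps, constrained)
        if best is None or fit.aic_value < best.aic_value:
            best = fit
    assert best is not None
    return best


def max_taps_from_seconds(window_seconds: float, tr_seconds: float) -> int:
    """Convert a seconds-denominated search window to a tap count.

    ``floor(window / TR)`` clamped to at least one tap (the zero-lag term).
    """
    if window_seconds <= 0 or tr_seconds <= 0:
        raise InputError("window_seconds and tr_seconds must be positive")
    return max(1, int(np.floor(window_seconds / tr_seconds)))
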