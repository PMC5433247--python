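"""p-correlation: correlation between a series and its causal prediction.

For an ordered ROI pair (source i, target j), the p-correlation
``rho_{j|i}`` is the Pearson correlation between the target series and its
AIC-order-selected causal FIR prediction from the source.  Unlike plain
correlation it is asymmetric — the system predicting j from i is distinct
from the one predicting i from j — so the full matrix is a directed
connectivity estimate.  With a single tap and a nonnegative coefficient it
reduces exactly to (sign-clipped) standard correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError
from .fir import FirFit, lagged_design, predict, select_order
from .simulate import TimeseriesSet

__all__ = ["ConnectivityMatrix", "PairResult", "pcorr_pair", "pcorr_pairs",
           "pcorr_matrix", "corr_matrix"]


@dataclass
class ConnectivityMatrix:
    """Directed n_rois x n_rois matrix; ``values[j, i]`` quantifies the
    influence of source ROI ``i`` on target ROI ``j``.  Diagonal entries are
    uninformative and stored as 0."""

    values: np.ndarray
    roi_labels: list[str] = field(default_factory=list)
    method_tag: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise InputError("connectivity matrix must be square")
        if not self.roi_labels:
            self.roi_labels = [f"ROI{r + 1}" for r in range(self.values.shape[0])]
        if len(self.roi_labels) != self.values.shape[0]:
            raise InputError("roi_labels length must match matrix size")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    def replace(self, values: np.ndarray, method_tag: str) -> "ConnectivityMatrix":
        return ConnectivityMatrix(
            values=values, roi_labels=list(self.roi_labels), method_tag=method_tag
        )


@dataclass
class PairResult:
    """One ordered pair's p-correlation with its fit diagnostics.

    ``lagged_cov[m]`` is the covariance of the target with the source
    delayed by ``m`` samples (zero-padded, n-1 normalization), and
    ``prediction_cov`` the covariance of the target with its prediction;
    the two satisfy ``prediction_cov = sum_m lagged_cov[m] * h[m]``.
    """

    rho: float
    fit: FirFit
    lagged_cov: np.ndarray
    prediction_cov: float
    degenerate: bool = False


def _center(x: np.ndarray) -> np.ndarray:
    return x - x.mean()


def pcorr_pair(
    x_src: np.ndarray,
    x_tgt: np.ndarray,
    max_taps: int,
    constrained: bool,
    center: bool = True,
) -> PairResult:
    """p-correlation of one ordered pair.

    Degenerate cases (constant target, or an all-zero constrained filter
    whose prediction is constant) return ``rho = 0`` with the flag set —
    NNLS legitimately produces the zero filter for negatively related pairs
    and downstream thresholding expects finite values.
    """
    x_src = np.asarray(x_src, dtype=float)
    x_tgt = np.asarray(x_tgt, dtype=float)
    if x_src.shape != x_tgt.shape:
        raise InputError("source and target must have equal length")
    if x_src.size < 4:
        raise InputError("series must have length >= 4")
    if center:
        x_src, x_tgt = _center(x_src), _center(x_tgt)

    fit = select_order(x_src, x_tgt, max_taps, constrained)
    x_hat = predict(x_src, fit)

    n = x_tgt.size
    X = lagged_design(x_src, fit.n_taps)
    tgt_dev = x_tgt - x_tgt.mean()
    lagged_cov = tgt_dev @ X / (n - 1)
    prediction_cov = float(tgt_dev @ x_hat / (n - 1))

    degenerate = bool(np.ptp(x_tgt) == 0 or np.ptp(x_hat) == 0)
    if degenerate:
        rho = 0.0
    else:
        rho = float(np.corrcoef(x_tgt, x_hat)[0, 1])
        rho = float(np.clip(rho, -1.0, 1.0))
    return PairResult(
        rho=rho,
        fit=fit,
        lagged_cov=lagged_cov,
        prediction_cov=prediction_cov,
        degenerate=degenerate,
    )


def pcorr_pairs(
    ts: TimeseriesSet, max_taps: int, constrained: bool, center: bool = True
) -> dict[tuple[int, int], PairResult]:
    """All ordered-pair results keyed by (target j, source i), i != j.

    Pairs are mutually independent; any evaluation order yields identical
    results.
    """
    if ts.n_rois < 2:
        raise InputError("connectivity requires at least 2 ROIs")
    out: dict[tuple[int, int], PairResult] = {}
    for j in range(ts.n_rois):
        for i in range(ts.n_rois):
            if i == j:
                continue
            out[(j, i)] = pcorr_pair(
                ts.values[:, i], ts.values[:, j], max_taps, constrained, center
            )
    return out


def pcorr_matrix(
    ts: TimeseriesSet, max_taps: int, constrained: bool, center: bool = True
) -> ConnectivityMatrix:
    """Full asymmetric p-correlation matrix; entry (j, i) = rho_{j|i}."""
    pairs = pcorr_pairs(ts, max_taps, constrained, center)
    values = np.zeros((ts.n_rois, ts.n_rois))
    for (j, i), res in pairs.items():
        values[j, i] = res.rho
    tag = "pcorr_constrained" if constrained else "pcorr_unconstrained"
    return ConnectivityMatrix(values=values, roi_labels=list(ts.roi_labels),
                              method_tag=tag)


def corr_matrix(ts: TimeseriesSet) -> ConnectivityMatrix:
    """Standard (symmetric) Pearson correlation matrix, diagonal stored 0.

    Constant columns have undefined correlations; their entries are 0.
    """
    if ts.n_rois < 2:
        raise InputError("connectivity requires at least 2 ROIs")
    values = ts.values
    constant = np.ptp(values, axis=0) == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(values, rowvar=False)
    C = np.nan_to_num(C, nan=0.0)
    C[constant, :] = 0.0
    C[:, constant] = 0.0
    np.fill_diagonal(C, 0.0)
    return ConnectivityMatrix(values=C, roi_labels=list(ts.roi_labels),
                              method_tag="correlation")
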