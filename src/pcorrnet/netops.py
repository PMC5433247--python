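"""Network post-processing: thresholding, averaging, accuracy, pipeline.

Three thresholding operators turn a raw connectivity matrix into a directed
network estimate:

* ``clip_negative`` — zero all negative entries (nonnegativity prior);
* ``percentile_threshold`` — keep only the top ``s`` percent of all stored
  entries (the sparsity threshold used in functional-connectivity work);
* ``unidirectional`` — for each node pair, zero the weaker of the two
  directed weights (prior knowledge that connections are one-way).

When a ground-truth network is available, ``s`` is derived from it as the
fraction of *connections of interest* (COIs): every ordered pair between
ROIs incident to a true connection, including the absent reverse direction
of a unidirectional edge, over all ``n_rois**2`` possible connections.

Directionality accuracy is the fraction of true directed connections whose
entry in the thresholded estimate is strictly positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import InputError
from .pcorrelation import ConnectivityMatrix

__all__ = [
    "GroundTruthNetwork",
    "AccuracyResult",
    "CohortComparison",
    "clip_negative",
    "percentile_threshold",
    "unidirectional",
    "coi_threshold_s",
    "average_matrices",
    "accuracy",
    "simulated_data_pipeline",
    "cohort_split_regression",
]


@dataclass
class GroundTruthNetwork:
    """Binary directed adjacency; ``adjacency[j, i] = 1`` iff a true
    connection i -> j exists."""

    adjacency: np.ndarray
    roi_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency)
        if self.adjacency.ndim != 2 or self.adjacency.shape[0] != self.adjacency.shape[1]:
            raise InputError("adjacency must be square")
        if not np.isin(self.adjacency, (0, 1)).all():
            raise InputError("adjacency must be binary (0/1)")
        if np.any(np.diag(self.adjacency) != 0):
            raise InputError("adjacency diagonal must be zero (no self-loops)")
        self.adjacency = self.adjacency.astype(int)
        if not self.roi_labels:
            self.roi_labels = [f"ROI{r + 1}" for r in range(self.adjacency.shape[0])]

    @classmethod
    def from_edges(
        cls, n_rois: int, edges: list[tuple[int, int]] | tuple, **kwargs
    ) -> "GroundTruthNetwork":
        """Build from (source, target) index pairs (0-based)."""
        adj = np.zeros((n_rois, n_rois), dtype=int)
        for src, tgt in edges:
            adj[tgt, src] = 1
        return cls(adjacency=adj, **kwargs)

    @property
    def n_rois(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_connections(self) -> int:
        return int(self.adjacency.sum())


@dataclass(frozen=True)
class AccuracyResult:
    """Directionality accuracy A = n_hit / n_true."""

    accuracy: float
    n_true: int
    n_hit: int


@dataclass(frozen=True)
class CohortComparison:
    """Least-squares line predicting cohort-2 mean positive strengths from
    cohort-1's, over coordinates where at least one cohort is nonzero."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    degenerate: bool = False


def clip_negative(M: ConnectivityMatrix) -> ConnectivityMatrix:
    """Replace all negative entries by zero."""
    return M.replace(np.maximum(M.values, 0.0), "thresholded")


def percentile_threshold(
    M: ConnectivityMatrix, s_percent: float, *, include_diagonal: bool = True
) -> ConnectivityMatrix:
    """Keep the top ``s_percent`` of entries, zero the rest.

    The retained count is ``ceil(s/100 * n_rois**2)`` over all stored
    entries — by default including the zero diagonal, which is how the COI
    ratio ``s`` is denominated.  The cutoff is the nearest-rank value from
    above; ties at the cutoff are all kept.  ``include_diagonal=False``
    restricts the universe to off-diagonal entries (sensitivity option).
    """
    if s_percent <= 0 or s_percent > 100:
        raise InputError(f"s_percent must be in (0, 100], got {s_percent}")
    values = M.values
    if include_diagonal:
        universe = values.ravel()
    else:
        universe = values[~np.eye(M.n_rois, dtype=bool)]
    k = math.ceil(s_percent / 100.0 * universe.size)
    gamma = np.sort(universe)[::-1][k - 1]
    return M.replace(np.where(values >= gamma, values, 0.0), "thresholded")


def unidirectional(M: ConnectivityMatrix) -> ConnectivityMatrix:
    """For each ordered pair keep the entry only if it is >= its transpose.

    Equal weights are both kept, so a symmetric matrix passes unchanged.
    """
    out = np.where(M.values >= M.values.T, M.values, 0.0)
    return M.replace(out, "thresholded")


def coi_threshold_s(gt: GroundTruthNetwork) -> float:
    """Percentile threshold ``s`` implied by a ground-truth network.

    Every unordered ROI pair carrying at least one true directed connection
    contributes both of its directions to the COI count; ``s`` is 100 x
    COI / n_rois**2.  Returned exact (never rounded).
    """
    if gt.n_connections == 0:
        raise InputError("ground truth has no connections; threshold undefined")
    either = (gt.adjacency + gt.adjacency.T) > 0
    n_pairs = int(np.triu(either, k=1).sum())
    coi = 2 * n_pairs
    return 100.0 * coi / gt.n_rois**2


def average_matrices(matrices: list[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Elementwise mean across subjects (SNR-improving group average)."""
    if not matrices:
        raise InputError("cannot average an empty list of matrices")
    first = matrices[0]
    for M in matrices[1:]:
        if M.values.shape != first.values.shape or M.roi_labels != first.roi_labels:
            raise InputError("matrices must share shape and ROI labels")
    mean = np.mean([M.values for M in matrices], axis=0)
    return first.replace(mean, "averaged")


def accuracy(gt: GroundTruthNetwork, d: ConnectivityMatrix) -> AccuracyResult:
    """Fraction of true directed connections with a strictly positive
    estimate: A = sum 1{a_ji > 0} 1{d_ji > 0} / sum 1{a_ji > 0}."""
    if gt.adjacency.shape != d.values.shape:
        raise InputError("ground truth and estimate shapes differ")
    true_mask = gt.adjacency > 0
    n_true = int(true_mask.sum())
    if n_true == 0:
        raise InputError("ground truth has no connections; accuracy undefined")
    n_hit = int(np.sum(true_mask & (d.values > 0)))
    return AccuracyResult(accuracy=n_hit / n_true, n_true=n_true, n_hit=n_hit)


def simulated_data_pipeline(
    ts,
    gt: GroundTruthNetwork,
    max_taps: int,
    constrained: bool,
    center: bool = True,
) -> ConnectivityMatrix:
    """Estimate the directed network d for one subject.

    Composes p-correlation -> negative clipping -> COI percentile threshold
    (s from the ground truth) -> unidirectional projection, in that fixed
    order.
    """
    from .pcorrelation import pcorr_matrix

    rho = pcorr_matrix(ts, max_taps, constrained, center)
    c = percentile_threshold(clip_negative(rho), coi_threshold_s(gt))
    return unidirectional(c)


def cohort_split_regression(
    per_subject: list[ConnectivityMatrix], split_seed: int
) -> CohortComparison:
    """Split-half robustness of group-mean positive connection strengths.

    Subjects are shuffled with ``split_seed`` and divided into two equal
    cohorts (the extra subject of an odd count joins cohort 1).  Each
    cohort's matrices are clipped at zero and averaged elementwise;
    coordinates where both cohorts are zero are dropped, and cohort-2
    values are regressed on cohort-1's.
    """
    if len(per_subject) < 2:
        raise InputError("need at least 2 subjects to split")
    rng = np.random.default_rng(split_seed)
    order = rng.permutation(len(per_subject))
    half = (len(per_subject) + 1) // 2
    cohort1 = [per_subject[k] for k in order[:half]]
    cohort2 = [per_subject[k] for k in order[half:]]
    m1 = average_matrices([clip_negative(M) for M in cohort1]).values
    m2 = average_matrices([clip_negative(M) for M in cohort2]).values
    mask = ~((m1 == 0) & (m2 == 0))
    x, y = m1[mask], m2[mask]
    if x.size < 2 or np.ptp(x) == 0:
        return CohortComparison(np.nan, np.nan, np.nan, int(x.size), degenerate=True)
    fit = stats.linregress(x, y)
    return CohortComparison(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n_points=int(x.size),
    )
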