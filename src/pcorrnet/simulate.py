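"""Synthetic multivariate timeseries from stationary linear AR(1) networks.

The central generator is the three-ROI *common driver* system

.. math::

    x_1[n+1] &= a_1 x_1[n] + b_1 w_1[n] \\
    x_2[n+1] &= a_2 x_2[n] + a_{21} x_1[n] + b_2 w_2[n] \\
    x_3[n+1] &= a_3 x_3[n] + a_{31} x_1[n] + b_3 w_3[n]

with i.i.d. standard-normal innovations ``w``.  ROI 1 drives ROIs 2 and 3,
which never interact directly — the classic confound in which undirected
correlation reports a spurious 2-3 link.  Four driving regimes are studied:

=====  ======  ======
case    a21     a31
=====  ======  ======
1       0.0     0.0    (no driving)
2       0.1     0.1    (weak)
3       0.4     0.4    (strong)
4       0.4     0.1    (asymmetric strong)
=====  ======  ======

All simulations start in the exact stationary state: the initial vector is
drawn from N(0, P) where P solves the discrete Lyapunov equation
``P = A P A^T + B B^T``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_discrete_lyapunov

from .errors import InputError, StationarityError

__all__ = [
    "CommonDriverSpec",
    "TimeseriesSet",
    "COMMON_DRIVER_CASES",
    "steady_state_covariance",
    "simulate_common_driver",
    "simulate_linear_network",
    "common_driver_ground_truth_edges",
]

#: (a21, a31) driving coefficients for the four study regimes.
COMMON_DRIVER_CASES: dict[int, tuple[float, float]] = {
    1: (0.0, 0.0),
    2: (0.1, 0.1),
    3: (0.4, 0.4),
    4: (0.4, 0.1),
}

#: True directed edges (source, target) of the common-driver network, 0-based.
common_driver_ground_truth_edges: tuple[tuple[int, int], ...] = ((0, 1), (0, 2))


@dataclass(frozen=True)
class CommonDriverSpec:
    """Parameters of the three-ROI common-driver AR(1) network.

    ``a1..a3`` are the self-coupling (memory) coefficients, ``b1..b3`` the
    innovation gains, and ``a21``/``a31`` the strengths with which ROI 1
    drives ROIs 2 and 3.  All coefficients are dimensionless.
    """

    a1: float = 0.8
    a2: float = 0.8
    a3: float = 0.8
    b1: float = 0.2
    b2: float = 0.2
    b3: float = 0.2
    a21: float = 0.0
    a31: float = 0.0
    n_samples: int = 1000
    n_subjects: int = 50
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise InputError(f"n_samples must be >= 2, got {self.n_samples}")
        if self.n_subjects < 1:
            raise InputError(f"n_subjects must be >= 1, got {self.n_subjects}")
        if max(abs(self.a1), abs(self.a2), abs(self.a3)) >= 1:
            raise StationarityError(
                "self-coupling coefficients must satisfy |a| < 1 for a "
                f"stationary system, got a1={self.a1}, a2={self.a2}, a3={self.a3}"
            )

    @classmethod
    def from_case(cls, case: int, **kwargs) -> "CommonDriverSpec":
        """Spec for one of the four driving regimes (see COMMON_DRIVER_CASES)."""
        try:
            a21, a31 = COMMON_DRIVER_CASES[case]
        except KeyError:
            raise InputError(f"case must be in {{1,2,3,4}}, got {case}") from None
        return cls(a21=a21, a31=a31, **kwargs)

    @property
    def state_matrix(self) -> np.ndarray:
        """Lower-triangular AR(1) state matrix A."""
        return np.array(
            [
                [self.a1, 0.0, 0.0],
                [self.a21, self.a2, 0.0],
                [self.a31, 0.0, self.a3],
            ]
        )

    @property
    def noise_gains(self) -> np.ndarray:
        return np.array([self.b1, self.b2, self.b3])


@dataclass
class TimeseriesSet:
    """One subject's multivariate timeseries: ``values[n, r]`` is ROI ``r``
    at sample ``n``.  ``tr_seconds`` is the sampling interval (TR)."""

    values: np.ndarray
    tr_seconds: float = 1.0
    roi_labels: list[str] = field(default_factory=list)
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InputError("values must be a 2-D samples x ROIs matrix")
        if self.values.shape[1] < 1:
            raise InputError("at least one ROI is required")
        if not np.all(np.isfinite(self.values)):
            raise InputError("timeseries contain non-finite values")
        if self.tr_seconds <= 0:
            raise InputError("tr_seconds must be positive")
        if not self.roi_labels:
            self.roi_labels = [f"ROI{r + 1}" for r in range(self.values.shape[1])]
        if len(self.roi_labels) != self.values.shape[1]:
            raise InputError("roi_labels length must match number of columns")
        # constant columns are allowed but flagged: correlations with them
        # are degenerate and reported as 0 downstream
        self.constant_columns = np.ptp(self.values, axis=0) == 0

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]


def _check_stationary(state_matrix: np.ndarray) -> None:
    radius = np.max(np.abs(np.linalg.eigvals(state_matrix)))
    if radius >= 1:
        raise StationarityError(
            f"state matrix has spectral radius {radius:.4f} >= 1; "
            "the system has no stationary distribution"
        )


def steady_state_covariance(spec: CommonDriverSpec) -> np.ndarray:
    """Stationary covariance P of the common-driver system.

    Solves the discrete Lyapunov equation ``P = A P A^T + B B^T`` with
    ``A = spec.state_matrix`` and ``B = diag(b1, b2, b3)``.
    """
    return linear_network_steady_state(spec.state_matrix, spec.noise_gains)


def linear_network_steady_state(
    state_matrix: np.ndarray, noise_gains: np.ndarray
) -> np.ndarray:
    """Stationary covariance of ``x[n+1] = A x[n] + diag(b) w[n]``."""
    A = np.asarray(state_matrix, dtype=float)
    b = np.asarray(noise_gains, dtype=float)
    _check_stationary(A)
    Q = np.diag(b**2)
    P = solve_discrete_lyapunov(A, Q)
    return (P + P.T) / 2.0  # symmetrize away round-off


def _subject_rng(base_seed: int, subject_index: int) -> np.random.Generator:
    # counter-based scheme: independent, reproducible streams per subject
    return np.random.default_rng(np.random.SeedSequence([int(base_seed), int(subject_index)]))


def simulate_linear_network(
    state_matrix: np.ndarray,
    noise_gains: np.ndarray,
    n_samples: int,
    seed: int | tuple[int, int] | np.random.Generator,
    *,
    initial_state: np.ndarray | None = None,
    roi_labels: list[str] | None = None,
    subject_id: str = "",
) -> TimeseriesSet:
    """Simulate ``x[n+1] = A x[n] + diag(b) w[n]`` for ``n_samples`` steps.

    By default the initial state is drawn from the exact stationary Gaussian
    N(0, P); pass ``initial_state`` to start deterministically instead.
    ``seed`` may be an integer, a ``(base_seed, subject_index)`` pair, or a
    ready ``numpy`` Generator.
    """
    A = np.asarray(state_matrix, dtype=float)
    b = np.asarray(noise_gains, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise InputError("state_matrix must be square")
    if b.shape != (A.shape[0],):
        raise InputError("noise_gains must have one entry per ROI")
    if n_samples < 2:
        raise InputError("n_samples must be >= 2")
    _check_stationary(A)

    if isinstance(seed, np.random.Generator):
        rng = seed
    elif isinstance(seed, (tuple, list)):
        rng = _subject_rng(*seed)
    else:
        rng = np.random.default_rng(int(seed))

    dim = A.shape[0]
    x = np.empty((n_samples, dim))
    if initial_state is None:
        P = solve_discrete_lyapunov(A, np.diag(b**2))
        x[0] = rng.multivariate_normal(np.zeros(dim), (P + P.T) / 2.0, method="svd")
    else:
        x[0] = np.asarray(initial_state, dtype=float)
    innovations = rng.standard_normal((n_samples - 1, dim))
    for n in range(n_samples - 1):
        x[n + 1] = A @ x[n] + b * innovations[n]
    return TimeseriesSet(
        values=x, tr_seconds=1.0, roi_labels=roi_labels or [], subject_id=subject_id
    )


def simulate_common_driver(spec: CommonDriverSpec, subject_index: int) -> TimeseriesSet:
    """One subject of the common-driver system, steady-state initialized.

    Seeding is derived from ``(spec.base_seed, subject_index)`` so re-runs
    are bit-identical and subjects are statistically independent.
    """
    if not 0 <= subject_index < spec.n_subjects:
        raise InputError(
            f"subject_index {subject_index} outside [0, {spec.n_subjects})"
        )
    return simulate_linear_network(
        spec.state_matrix,
        spec.noise_gains,
        spec.n_samples,
        _subject_rng(spec.base_seed, subject_index),
        subject_id=f"subject{subject_index:03d}",
    )
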