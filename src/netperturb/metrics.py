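"""Ensemble-similarity metrics.

Two families of comparisons are provided:

* **Subspace geometry** — the root-mean-square inner product (RMSIP) and the
  covariance overlap (CO) between two sets of principal-component eigenpairs.
  RMSIP scores the alignment of the spans alone; CO additionally weights each
  pairwise overlap by the variances carried along the two directions, so that
  agreement along high-variance modes dominates.  Both live in [0, 1].

* **Sampled distributions** — the sliced Wasserstein distance (SWD) between
  the weighted point clouds obtained by projecting two ensembles into a common
  essential subspace.  The order-gamma 1-D Wasserstein distance is computed
  exactly for weighted empirical distributions via the quantile-function
  formulation, and the SWD averages WD^gamma over random unit directions
  ("slices") drawn uniformly from the sphere.  Unlike RMSIP/CO, the SWD is a
  genuine metric on distributions and is sensitive to how the subspace is
  populated, not just to which directions are explored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .ensembles import ProjectedEnsemble

__all__ = [
    "SubspacePair",
    "SliceSet",
    "rmsip",
    "covariance_overlap",
    "wasserstein_1d",
    "sample_slices",
    "sliced_wasserstein",
]

logger = logging.getLogger(__name__)

_ORTHO_TOL = 1e-6
DEFAULT_GAMMA = 3.0
DEFAULT_N_SLICES = 1000


@dataclass
class SubspacePair:
    """Two subspaces over the same ambient 3B space, with their eigenvalues."""

    eigenvectors_a: np.ndarray  # (3B, n)
    eigenvectors_b: np.ndarray  # (3B, n)
    eigenvalues_a: np.ndarray  # (n,)
    eigenvalues_b: np.ndarray  # (n,)

    def __post_init__(self) -> None:
        self.eigenvectors_a = np.asarray(self.eigenvectors_a, dtype=float)
        self.eigenvectors_b = np.asarray(self.eigenvectors_b, dtype=float)
        self.eigenvalues_a = np.asarray(self.eigenvalues_a, dtype=float)
        self.eigenvalues_b = np.asarray(self.eigenvalues_b, dtype=float)
        if self.eigenvectors_a.shape != self.eigenvectors_b.shape:
            raise ValueError("subspaces must share ambient dimension and size n")
        n = self.n_components
        if self.eigenvalues_a.shape != (n,) or self.eigenvalues_b.shape != (n,):
            raise ValueError("eigenvalue vectors must have length n")
        if np.any(self.eigenvalues_a < 0) or np.any(self.eigenvalues_b < 0):
            raise ValueError("eigenvalues must be non-negative")
        for name, V in (("a", self.eigenvectors_a), ("b", self.eigenvectors_b)):
            gram = V.T @ V
            if not np.allclose(gram, np.eye(n), atol=_ORTHO_TOL):
                raise ValueError(f"eigenvectors_{name} are not orthonormal")

    @classmethod
    def from_subspaces(cls, sub_a, sub_b) -> "SubspacePair":
        n = min(sub_a.n_components, sub_b.n_components)
        return cls(
            eigenvectors_a=sub_a.eigenvectors[:, :n],
            eigenvectors_b=sub_b.eigenvectors[:, :n],
            eigenvalues_a=sub_a.eigenvalues[:n],
            eigenvalues_b=sub_b.eigenvalues[:n],
        )

    @property
    def n_components(self) -> int:
        return self.eigenvectors_a.shape[1]

    def overlap_matrix(self) -> np.ndarray:
        """Squared inner products (v_p . w_q)^2, shape (n, n)."""
        return (self.eigenvectors_a.T @ self.eigenvectors_b) ** 2


def rmsip(pair: SubspacePair) -> float:
    """Root-mean-square inner product between the two n-dimensional subspaces.

    sqrt( (1/n) sum_{p,q} (v_p . w_q)^2 ); 1 for identical spans, 0 for
    mutually orthogonal ones.  Invariant under orthonormal re-basis within
    each span.
    """
    n = pair.n_components
    value = float(np.sqrt(pair.overlap_matrix().sum() / n))
    return min(value, 1.0)


def covariance_overlap(pair: SubspacePair) -> float:
    """Variance-weighted subspace overlap in [0, 1].

    sum_{p,q} mu_p nu_q (v_p . w_q)^2 / (||mu|| ||nu||), with ||.|| the
    Euclidean norm of the eigenvalue vector.  Equals 1 when both eigenvectors
    and eigenvalues coincide and 0 for orthogonal subspaces; directions
    carrying little variance contribute little.  The raw value is clamped to
    [0, 1] (and logged) to guard against rounding excursions.
    """
    mu = pair.eigenvalues_a
    nu = pair.eigenvalues_b
    norm = np.linalg.norm(mu) * np.linalg.norm(nu)
    if norm == 0.0:
        raise ValueError("covariance overlap undefined: all-zero eigenvalues")
    raw = float(mu @ pair.overlap_matrix() @ nu / norm)
    if raw < 0.0 or raw > 1.0:
        logger.debug("covariance overlap raw value %.3e clamped to [0, 1]", raw)
    return float(np.clip(raw, 0.0, 1.0))


def _weighted_quantile_integral(a, wa, b, wb, gamma):
    """integral_0^1 |Qa(u) - Qb(u)|^gamma du for step quantile functions."""
    ia = np.argsort(a, kind="stable")
    ib = np.argsort(b, kind="stable")
    a_sorted, wa_sorted = a[ia], wa[ia]
    b_sorted, wb_sorted = b[ib], wb[ib]
    ca = np.cumsum(wa_sorted)
    cb = np.cumsum(wb_sorted)
    ca /= ca[-1]
    cb /= cb[-1]
    # merged breakpoints of the two step CDFs
    u = np.concatenate([ca, cb])
    u.sort(kind="stable")
    u = u[u > 0.0]
    du = np.diff(np.concatenate([[0.0], u]))
    # quantile value on each (u_{k-1}, u_k] interval: first sample whose cum-weight >= u_k
    mid = u - du / 2.0
    qa = a_sorted[np.searchsorted(ca, mid, side="left").clip(max=len(a_sorted) - 1)]
    qb = b_sorted[np.searchsorted(cb, mid, side="left").clip(max=len(b_sorted) - 1)]
    return float(np.sum(du * np.abs(qa - qb) ** gamma))


def wasserstein_1d(samples_a, weights_a=None, samples_b=None, weights_b=None, gamma: float = DEFAULT_GAMMA) -> float:
    """Order-gamma Wasserstein distance between two weighted 1-D empirical laws.

    Computed exactly through the quantile-function formulation
    ``( int_0^1 |Qa(u) - Qb(u)|^gamma du )^(1/gamma)``, integrating over the
    merged breakpoints of the two step CDFs (no resampling).
    """
    if gamma < 1:
        raise ValueError("gamma must be >= 1")
    a = np.asarray(samples_a, dtype=float).ravel()
    b = np.asarray(samples_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample set")
    wa = np.ones_like(a) if weights_a is None else np.asarray(weights_a, dtype=float).ravel()
    wb = np.ones_like(b) if weights_b is None else np.asarray(weights_b, dtype=float).ravel()
    if wa.shape != a.shape or wb.shape != b.shape:
        raise ValueError("weights must match samples in length")
    if np.any(wa < 0) or np.any(wb < 0):
        raise ValueError("weights must be non-negative")
    if wa.sum() <= 0 or wb.sum() <= 0:
        raise ValueError("zero total weight")
    integral = _weighted_quantile_integral(a, wa, b, wb, gamma)
    return float(integral ** (1.0 / gamma))


@dataclass
class SliceSet:
    """Random unit directions used to slice d-dimensional distributions."""

    directions: np.ndarray  # (S, d), unit rows
    seed: int

    def __post_init__(self) -> None:
        self.directions = np.asarray(self.directions, dtype=float)
        norms = np.linalg.norm(self.directions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-10):
            raise ValueError("slice directions must have unit norm (tol 1e-10)")


def sample_slices(n_slices: int, dim: int, seed: int) -> SliceSet:
    """Quasi-uniform directions on S^{d-1} via normalized Gaussian draws."""
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    rng = np.random.default_rng(seed)
    if dim == 1:
        # degenerate sphere {-1, +1}
        directions = rng.choice([-1.0, 1.0], size=(n_slices, 1))
    else:
        directions = rng.standard_normal((n_slices, dim))
        directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    return SliceSet(directions=directions, seed=seed)


def _as_points_weights(obj):
    if isinstance(obj, ProjectedEnsemble):
        return obj.points, obj.normalized_weights()
    pts = np.atleast_2d(np.asarray(obj, dtype=float))
    return pts, np.full(pts.shape[0], 1.0 / pts.shape[0])


def sliced_wasserstein(
    proj_a,
    proj_b,
    gamma: float = DEFAULT_GAMMA,
    n_slices: int = DEFAULT_N_SLICES,
    seed: int = 0,
    slices: SliceSet | None = None,
) -> float:
    """Sliced Wasserstein distance between two weighted point clouds.

    ``( mean over slices of WD_gamma(f_theta, g_theta)^gamma )^(1/gamma)``
    with directions theta drawn uniformly on the unit sphere from ``seed``.
    Accepts :class:`ProjectedEnsemble` objects (weights respected) or plain
    (F, d) arrays (uniform weights).
    """
    pts_a, wa = _as_points_weights(proj_a)
    pts_b, wb = _as_points_weights(proj_b)
    if pts_a.shape[1] != pts_b.shape[1]:
        raise ValueError(
            f"projection dimension mismatch: {pts_a.shape[1]} vs {pts_b.shape[1]}"
        )
    dim = pts_a.shape[1]
    if slices is None:
        slices = sample_slices(n_slices, dim, seed)
    elif slices.directions.shape[1] != dim:
        raise ValueError("slice dimension does not match the point clouds")
    acc = 0.0
    for theta in slices.directions:
        xa = pts_a @ theta
        xb = pts_b @ theta
        acc += _weighted_quantile_integral(xa, wa, xb, wb, gamma)
    return float((acc / len(slices.directions)) ** (1.0 / gamma))
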