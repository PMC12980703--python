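"""Second-order perturbation estimator for contact-strength changes.

Write the model potential as a sum of pairwise terms and collect, for every
frame of a sampled ensemble, the M selected contact energies into a row vector
L (in units of k_B T).  Rescaling contact k by a factor ``(1 + lambda_k)``
adds ``lambda_k L_k`` to the potential, so the Boltzmann distribution of the
perturbed model is a reweighting of the sampled one with per-frame log-weight
``-lambda . L`` (up to normalization).  For small ``lambda`` the normalizer —
the cumulant-generating function ``psi(lambda) = ln < exp(lambda . L) >`` — is
expanded to second order in the mean ``<L>`` and covariance ``C`` of the
contact energies, giving the analytic log density ratio

    ln(rho_lambda / rho)  ~  -lambda.(L - <L>) - 1/2 lambda.C.lambda .

Because C is positive semidefinite it factors as ``C = U Omega U^T``; in the
eigenbasis ``xi = U^T lambda`` the ratio becomes the numerically convenient
``sum_k (B_k xi_k - 1/2 omega_k^2 xi_k^2)`` with ``B = U^T (L - <L>)``
(evaluated at the matching sign of xi).  This estimator predicts how a
candidate strength update shifts the conformational distribution *without
re-sampling*, which is what makes a swarm search over lambda affordable.

Sign convention, used consistently package-wide: ``lambda_k > 0`` strengthens
contact k (the well deepens / the spring stiffens), matching
:func:`netperturb.networks.apply_perturbation`.

All energies are handled in k_B T with k_B = 0.00831446 kJ/mol/K.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .ensembles import BeadEnsemble, ProjectedEnsemble
from .networks import ENM_HARMONIC, GO_LJ, InteractionNetwork

__all__ = [
    "KB_KJ_PER_MOL_K",
    "DEFAULT_TEMPERATURE_K",
    "DEFAULT_LAMBDA_BOUND",
    "TermMatrix",
    "PerturbationBasis",
    "evaluate_terms",
    "build_basis",
    "log_density_ratio",
    "reweight_frames",
    "kish_ess",
    "psi_second_order",
    "save_basis",
    "load_basis",
]

logger = logging.getLogger(__name__)

KB_KJ_PER_MOL_K = 0.00831446
DEFAULT_TEMPERATURE_K = 300.0
DEFAULT_LAMBDA_BOUND = 0.3  # per-component trust region |lambda_k| <= bound
ESS_WARN_FRACTION = 0.05

_BASIS_SCHEMA_VERSION = 1


@dataclass
class TermMatrix:
    """Per-frame, per-contact energies in k_B T units, shape (F, M)."""

    values: np.ndarray
    temperature_K: float
    kBT_kJmol: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("term matrix must be 2-D (frames x contacts)")
        if not np.all(np.isfinite(self.values)):
            f, k = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(f"non-finite contact energy at frame {f}, contact {k}")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_terms(self) -> int:
        return self.values.shape[1]


@dataclass
class PerturbationBasis:
    """Mean/covariance of the contact energies and the covariance eigenbasis."""

    mean: np.ndarray  # (M,)
    covariance: np.ndarray  # (M, M)
    eigenvectors: np.ndarray  # (M, M), orthonormal columns U
    eigenvalues: np.ndarray  # (M,) omega_k^2 >= 0
    centered_eigenprojections: np.ndarray  # (F, M), rows B_f = U^T (L_f - <L>)
    frame_weights: np.ndarray  # (F,) normalized

    @property
    def n_terms(self) -> int:
        return self.mean.shape[0]

    @property
    def n_frames(self) -> int:
        return self.centered_eigenprojections.shape[0]


def evaluate_terms(
    ensemble: BeadEnsemble,
    network: InteractionNetwork,
    temperature_K: float = DEFAULT_TEMPERATURE_K,
) -> TermMatrix:
    """Evaluate every contact's energy in every frame, in k_B T.

    Entry (f, k) is the LJ or harmonic energy of contact k at frame f divided
    by k_B T.  Overlapping beads that produce non-finite LJ energies raise
    with the offending frame/contact index.
    """
    if network.n_beads > ensemble.n_beads:
        raise ValueError("network references more beads than the ensemble has")
    kBT = KB_KJ_PER_MOL_K * temperature_K
    pairs = network.pairs()
    diffs = ensemble.coords[:, pairs[:, 0], :] - ensemble.coords[:, pairs[:, 1], :]
    r = np.linalg.norm(diffs, axis=2)  # (F, M)
    strengths = network.strengths()
    geometry = network.geometries()
    if network.kind == GO_LJ:
        if np.any(r <= 0):
            f, k = np.argwhere(r <= 0)[0]
            raise ValueError(f"overlapping beads (r=0) at frame {f}, contact {k}")
        sr6 = (geometry / r) ** 6
        energies = 4.0 * strengths * (sr6 * sr6 - sr6)
    elif network.kind == ENM_HARMONIC:
        energies = 0.5 * strengths * (r - geometry) ** 2
    else:  # pragma: no cover - kinds validated upstream
        raise ValueError(f"unknown network kind {network.kind!r}")
    return TermMatrix(values=energies / kBT, temperature_K=temperature_K, kBT_kJmol=kBT)


def build_basis(term_matrix: TermMatrix, frame_weights=None) -> PerturbationBasis:
    """Weighted mean/covariance of the contact-energy rows plus its eigenbasis.

    The covariance uses the population normalization (weights summing to one,
    no Bessel correction); numerically negative eigenvalues down to -1e-10 are
    clamped to zero.
    """
    L = term_matrix.values
    F = term_matrix.n_frames
    if F < 2:
        raise ValueError("need at least 2 frames to estimate a covariance")
    if frame_weights is None:
        w = np.full(F, 1.0 / F)
    else:
        w = np.asarray(frame_weights, dtype=float)
        if w.shape != (F,):
            raise ValueError("frame_weights must have one entry per frame")
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("frame_weights must be non-negative with positive sum")
        w = w / w.sum()
    mean = w @ L
    centered = L - mean
    cov = (centered * w[:, None]).T @ centered
    cov = 0.5 * (cov + cov.T)
    evals, evecs = np.linalg.eigh(cov)
    if evals.min() < -1e-10 * max(1.0, abs(evals.max())):
        logger.warning("covariance eigenvalue %.3e clamped to 0", evals.min())
    evals = np.clip(evals, 0.0, None)
    return PerturbationBasis(
        mean=mean,
        covariance=cov,
        eigenvectors=evecs,
        eigenvalues=evals,
        centered_eigenprojections=centered @ evecs,
        frame_weights=w,
    )


def _check_lambda(basis: PerturbationBasis, lam, lambda_bound) -> np.ndarray:
    lam = np.asarray(lam, dtype=float)
    if lam.shape != (basis.n_terms,):
        raise ValueError(f"lambda must have length M={basis.n_terms}")
    if not np.all(np.isfinite(lam)):
        raise ValueError("lambda must be finite")
    if lambda_bound is not None and np.max(np.abs(lam)) > lambda_bound:
        logger.warning(
            "lambda max |component| %.3g exceeds trust region %.3g; "
            "second-order estimate may be inaccurate",
            np.max(np.abs(lam)), lambda_bound,
        )
    return lam


def log_density_ratio(
    basis: PerturbationBasis,
    lam,
    form: str = "eigen",
    lambda_bound: float | None = DEFAULT_LAMBDA_BOUND,
) -> np.ndarray:
    """Per-frame second-order log density ratio for a perturbation ``lam``.

    Evaluates ``lam.(L_f - <L>) - 1/2 lam.C.lam`` — in the covariance
    eigenbasis by default (``sum_k B_{f,k} xi_k - 1/2 omega_k^2 xi_k^2`` with
    ``xi = U^T lam``), or directly from C with ``form="direct"``; the two
    agree to machine precision.  A ``lam`` outside the trust region triggers a
    warning but is still evaluated.

    Note the sign of ``lam`` here is the raw exponent coefficient of Eq-style
    reweighting; :func:`reweight_frames` negates it to express the package's
    "positive lambda strengthens" convention.
    """
    lam = _check_lambda(basis, lam, lambda_bound)
    if form == "eigen":
        xi = basis.eigenvectors.T @ lam
        return basis.centered_eigenprojections @ xi - 0.5 * float(
            basis.eigenvalues @ xi**2
        )
    if form == "direct":
        centered = basis.centered_eigenprojections @ basis.eigenvectors.T
        return centered @ lam - 0.5 * float(lam @ basis.covariance @ lam)
    raise ValueError("form must be 'eigen' or 'direct'")


def kish_ess(weights) -> float:
    """Kish effective sample size of a weight vector."""
    w = np.asarray(weights, dtype=float)
    return float(w.sum() ** 2 / np.sum(w**2))


def reweight_frames(
    ensemble_or_projection,
    basis: PerturbationBasis,
    lam,
    lambda_bound: float | None = DEFAULT_LAMBDA_BOUND,
):
    """Frame weights representing the ensemble with strengths scaled by (1+lam).

    Each frame's weight is multiplied by ``exp(-lam.(L_f - <L>) - 1/2
    lam.C.lam)`` (strengthening a contact, lam_k > 0, favours frames where
    that contact sits low in its well) and renormalized to sum one.  Returns
    the same container type with updated weights; the Kish effective sample
    size is logged and a warning is emitted when it drops below
    ``ESS_WARN_FRACTION`` of the frame count.
    """
    obj = ensemble_or_projection
    if not isinstance(obj, (BeadEnsemble, ProjectedEnsemble)):
        raise TypeError("expected a BeadEnsemble or ProjectedEnsemble")
    if obj.n_frames != basis.n_frames:
        raise ValueError("frame count differs between object and basis")
    lam = _check_lambda(basis, lam, lambda_bound)
    log_ratio = log_density_ratio(basis, -lam, lambda_bound=None)
    log_w = np.log(obj.frame_weights, where=obj.frame_weights > 0,
                   out=np.full(obj.n_frames, -np.inf)) + log_ratio
    log_w -= log_w.max()
    w = np.exp(log_w)
    total = w.sum()
    if not np.isfinite(total) or total <= 0:
        raise FloatingPointError(
            "all reweighting factors underflowed; use a smaller trust region"
        )
    w /= total
    ess = kish_ess(w)
    logger.debug("reweight_frames: ESS %.1f of %d frames", ess, obj.n_frames)
    if ess < ESS_WARN_FRACTION * obj.n_frames:
        logger.warning(
            "effective sample size %.1f below %.0f%% of %d frames; "
            "reweighted estimates are unreliable",
            ess, 100 * ESS_WARN_FRACTION, obj.n_frames,
        )
    return obj.with_weights(w)


def psi_second_order(basis: PerturbationBasis, lam) -> float:
    """Second-order cumulant expansion of psi(lam) = ln < exp(lam . L) >.

    ``lam.<L> + 1/2 lam.C.lam``; exact for Gaussian contact-energy statistics,
    with an O(||lam||^3) remainder otherwise.
    """
    lam = _check_lambda(basis, lam, None)
    return float(lam @ basis.mean + 0.5 * lam @ basis.covariance @ lam)


def save_basis(basis: PerturbationBasis, path) -> None:
    """Persist a basis to an HDF5 container with shape metadata."""
    import h5py

    with h5py.File(path, "w") as h5:
        h5.attrs["schema_version"] = _BASIS_SCHEMA_VERSION
        h5.attrs["n_terms"] = basis.n_terms
        h5.attrs["n_frames"] = basis.n_frames
        for name in ("mean", "covariance", "eigenvectors", "eigenvalues",
                     "centered_eigenprojections", "frame_weights"):
            h5.create_dataset(name, data=getattr(basis, name))


def load_basis(path) -> PerturbationBasis:
    import h5py

    with h5py.File(path, "r") as h5:
        version = int(h5.attrs.get("schema_version", -1))
        if version != _BASIS_SCHEMA_VERSION:
            raise ValueError(f"unsupported basis schema version {version}")
        fields = {
            name: np.asarray(h5[name])
            for name in ("mean", "covariance", "eigenvectors", "eigenvalues",
                         "centered_eigenprojections", "frame_weights")
        }
    return PerturbationBasis(**fields)
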