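"""Bead-resolution ensemble handling: I/O, superposition, PCA and fluctuations.

A conformational ensemble is stored as an ``(F, B, 3)`` coordinate block in
nanometres together with per-frame statistical weights.  Weights default to
uniform but are carried through every statistical operation (mean, covariance,
PCA, projection, RMSF) so that reweighted ensembles — frames whose weights were
updated to represent a perturbed Boltzmann distribution — can be analysed with
the same code paths as plainly sampled ones.

The *essential subspace* of an ensemble is the span of the leading principal
components of the Cartesian covariance of the aligned trajectory.  It is the
reference frame in which ensembles are compared and in which the contact-network
optimizer operates: the subspace is derived once from the target ensemble and
held fixed, and every other ensemble is rigid-body fitted to the target mean
before being projected into it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "BeadEnsemble",
    "EssentialSubspace",
    "ProjectedEnsemble",
    "load_ensemble",
    "write_gro",
    "write_xtc",
    "superpose",
    "compute_pca",
    "variance_fraction",
    "project",
    "rmsf",
    "rmsf_aue",
]

_NM_PER_ANGSTROM = 0.1


@dataclass
class BeadEnsemble:
    """Trajectory of B beads over F frames, coordinates in nm.

    ``frame_weights`` are relative statistical weights (any positive scale);
    use :meth:`normalized_weights` for weights summing to one.
    """

    coords: np.ndarray  # (F, B, 3) nm
    bead_ids: list[str] | None = None
    frame_weights: np.ndarray | None = None
    box: np.ndarray | None = None  # optional 3-vector, nm
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (F, B, 3)")
        if self.n_beads < 2:
            raise ValueError("an ensemble needs at least 2 beads")
        if self.bead_ids is None:
            self.bead_ids = [f"B{i}" for i in range(self.n_beads)]
        if len(self.bead_ids) != self.n_beads:
            raise ValueError("bead_ids length does not match bead count")
        if self.frame_weights is None:
            self.frame_weights = np.ones(self.n_frames)
        self.frame_weights = np.asarray(self.frame_weights, dtype=float)
        if self.frame_weights.shape != (self.n_frames,):
            raise ValueError("frame_weights must have one entry per frame")
        if np.any(self.frame_weights < 0):
            raise ValueError("frame_weights must be non-negative")
        if self.frame_weights.sum() <= 0:
            raise ValueError("frame_weights must have positive sum")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_beads(self) -> int:
        return self.coords.shape[1]

    def normalized_weights(self) -> np.ndarray:
        w = self.frame_weights
        return w / w.sum()

    def with_weights(self, weights: np.ndarray) -> "BeadEnsemble":
        """Copy of the ensemble with new frame weights (coords shared)."""
        return BeadEnsemble(
            coords=self.coords,
            bead_ids=list(self.bead_ids),
            frame_weights=np.asarray(weights, dtype=float),
            box=self.box,
            meta=dict(self.meta),
        )

    def mean_structure(self) -> np.ndarray:
        """Weighted mean frame, (B, 3) nm."""
        w = self.normalized_weights()
        return np.einsum("f,fbc->bc", w, self.coords)


@dataclass
class EssentialSubspace:
    """Fixed reference subspace: mean structure plus leading PCA eigenpairs.

    ``eigenvectors`` has shape ``(3B, n)`` with orthonormal columns; the
    eigenvalues are coordinate variances in nm^2, sorted descending.
    ``total_variance`` is the trace of the full covariance, stored at
    construction so variance fractions remain exact after truncation.
    """

    mean_structure: np.ndarray  # (B, 3) nm
    eigenvectors: np.ndarray  # (3B, n)
    eigenvalues: np.ndarray  # (n,) nm^2, descending
    total_variance: float
    label: str = "subspace"

    def __post_init__(self) -> None:
        self.mean_structure = np.asarray(self.mean_structure, dtype=float)
        self.eigenvectors = np.asarray(self.eigenvectors, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        gram = self.eigenvectors.T @ self.eigenvectors
        if not np.allclose(gram, np.eye(self.n_components), atol=1e-8):
            raise ValueError("eigenvector columns must be orthonormal (tol 1e-8)")
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise ValueError("eigenvalues must be sorted descending")
        if np.any(self.eigenvalues < -1e-12):
            raise ValueError("eigenvalues must be non-negative")
        self.eigenvalues = np.clip(self.eigenvalues, 0.0, None)

    @property
    def n_components(self) -> int:
        return self.eigenvectors.shape[1]

    @property
    def n_beads(self) -> int:
        return self.mean_structure.shape[0]


@dataclass
class ProjectedEnsemble:
    """Frames projected into an essential subspace: (F, n) points in nm."""

    points: np.ndarray
    frame_weights: np.ndarray | None = None
    subspace_ref: str = "subspace"

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.frame_weights is None:
            self.frame_weights = np.ones(self.n_frames)
        self.frame_weights = np.asarray(self.frame_weights, dtype=float)
        if self.frame_weights.shape != (self.n_frames,):
            raise ValueError("frame_weights must have one entry per frame")
        if np.any(self.frame_weights < 0) or self.frame_weights.sum() <= 0:
            raise ValueError("frame_weights must be non-negative with positive sum")

    @property
    def n_frames(self) -> int:
        return self.points.shape[0]

    @property
    def dim(self) -> int:
        return self.points.shape[1]

    def normalized_weights(self) -> np.ndarray:
        return self.frame_weights / self.frame_weights.sum()

    def with_weights(self, weights: np.ndarray) -> "ProjectedEnsemble":
        return ProjectedEnsemble(self.points, np.asarray(weights, float), self.subspace_ref)


def _resolve_selection(universe, bead_selection):
    """Turn a selection spec into an MDAnalysis AtomGroup.

    Accepted forms: ``None`` (all atoms), a list of atom names, or an
    ``(start, stop)`` 0-based half-open index range.
    """
    if bead_selection is None:
        return universe.atoms
    if isinstance(bead_selection, tuple) and len(bead_selection) == 2:
        start, stop = bead_selection
        return universe.atoms[int(start):int(stop)]
    if isinstance(bead_selection, str):
        return universe.select_atoms(bead_selection)
    names = list(bead_selection)
    sel = " or ".join(f"name {n}" for n in names)
    return universe.select_atoms(sel)


def _read_multiframe_gro(path):
    """Concatenated GRO frames (title/natoms/atoms/box blocks back to back).

    GRO is a single-frame format; GROMACS tools emit multi-frame trajectories
    as plain concatenation, which trajectory readers do not handle, so the
    blocks are split here (fixed-width columns, coordinates natively in nm).
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    frames, names, box = [], None, None
    pos = 0
    while pos + 2 < len(lines):
        try:
            n_atoms = int(lines[pos + 1].strip())
        except ValueError as exc:
            raise IOError(f"{path}: malformed GRO atom count at line {pos + 2}") from exc
        block = lines[pos + 2:pos + 2 + n_atoms]
        if len(block) < n_atoms:
            raise IOError(f"{path}: truncated GRO frame at line {pos + 1}")
        coords = np.array(
            [[float(l[20:28]), float(l[28:36]), float(l[36:44])] for l in block]
        )
        if names is None:
            names = [l[10:15].strip() for l in block]
        elif len(block) != len(names):
            raise IOError(f"{path}: inconsistent atom counts across GRO frames")
        frames.append(coords)
        box_fields = lines[pos + 2 + n_atoms].split()
        box = np.array([float(x) for x in box_fields[:3]])
        pos += n_atoms + 3
    if not frames:
        raise IOError(f"{path}: no frames found")
    return names, np.stack(frames), box


def load_ensemble(trajectory_path, topology_path=None, bead_selection=None) -> BeadEnsemble:
    """Read a trajectory (PDB/GRO multi-frame, or XTC/TRR plus a topology).

    Coordinates are converted from the Angstrom convention of the readers to
    nm.  Frames are kept in file order with uniform weights.
    """
    import MDAnalysis as mda

    if str(trajectory_path).endswith(".gro") and topology_path is None:
        names, coords, box = _read_multiframe_gro(trajectory_path)
        universe = mda.Universe.empty(len(names), trajectory=True)
        universe.add_TopologyAttr("names", names)
        group = _resolve_selection(universe, bead_selection)
        if len(group) == 0:
            raise ValueError("bead selection matched no atoms")
        if len(group) < 2:
            raise ValueError("bead selection must match at least 2 beads")
        idx = group.indices
        return BeadEnsemble(
            coords=coords[:, idx, :],
            bead_ids=[names[i] for i in idx],
            box=box,
        )

    try:
        if topology_path is None:
            universe = mda.Universe(str(trajectory_path))
        else:
            universe = mda.Universe(str(topology_path), str(trajectory_path))
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot read trajectory {trajectory_path!r}: {exc}") from exc

    group = _resolve_selection(universe, bead_selection)
    if len(group) == 0:
        raise ValueError("bead selection matched no atoms")
    if len(group) < 2:
        raise ValueError("bead selection must match at least 2 beads")

    frames = []
    box = None
    for ts in universe.trajectory:
        frames.append(group.positions.astype(float) * _NM_PER_ANGSTROM)
        if ts.dimensions is not None and box is None:
            box = np.asarray(ts.dimensions[:3], dtype=float) * _NM_PER_ANGSTROM
    coords = np.stack(frames, axis=0)
    names = [str(n) for n in group.names] if hasattr(group, "names") else None
    return BeadEnsemble(coords=coords, bead_ids=names, box=box)


def _make_universe(ensemble: BeadEnsemble):
    import MDAnalysis as mda

    B = ensemble.n_beads
    u = mda.Universe.empty(B, n_residues=B, atom_resindex=np.arange(B), trajectory=True)
    u.add_TopologyAttr("names", [bid[:4] if bid else "BB" for bid in ensemble.bead_ids])
    u.add_TopologyAttr("resnames", ["BEA"] * B)
    u.add_TopologyAttr("resids", np.arange(1, B + 1))
    return u

def write_gro(ensemble: BeadEnsemble, path) -> None:
    """Write all frames as a concatenated multi-frame GRO file.

    Standard GROMACS fixed-width format at its native 0.001 nm coordinate
    precision; frames are emitted back to back the way trjconv concatenates
    them (single-frame writers cannot produce this).
    """
    box = ensemble.box if ensemble.box is not None else np.array([50.0, 50.0, 50.0])
    with open(path, "w") as fh:
        for f, frame in enumerate(ensemble.coords):
            fh.write(f"bead ensemble frame {f}\n")
            fh.write(f"{ensemble.n_beads:5d}\n")
            for b, (x, y, z) in enumerate(frame):
                name = (ensemble.bead_ids[b] or "BB")[:5]
                fh.write(
                    f"{b + 1:5d}{'BEA':<5s}{name:>5s}{(b + 1) % 100000:5d}"
                    f"{x:8.3f}{y:8.3f}{z:8.3f}\n"
                )
            fh.write(f"{box[0]:10.5f}{box[1]:10.5f}{box[2]:10.5f}\n")

def write_xtc(ensemble: BeadEnsemble, path) -> None:
    """Write the ensemble as an XTC trajectory (pair with a one-frame GRO topology)."""
    import MDAnalysis as mda

    u = _make_universe(ensemble)
    box = ensemble.box if ensemble.box is not None else np.array([50.0, 50.0, 50.0])
    with mda.Writer(str(path), n_atoms=ensemble.n_beads) as writer:
        for frame in ensemble.coords:
            u.atoms.positions = frame / _NM_PER_ANGSTROM
            u.dimensions = [*(box / _NM_PER_ANGSTROM), 90.0, 90.0, 90.0]
            writer.write(u.atoms)


def _kabsch(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Optimal rotation (Kabsch) aligning centred ``mobile`` onto centred ``reference``."""
    H = mobile.T @ reference
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    return U @ D @ Vt


def superpose(ensemble: BeadEnsemble, reference_structure: np.ndarray) -> BeadEnsemble:
    """Rigid-body least-squares fit of every frame onto a reference structure.

    Mass-unweighted over all beads: per frame the translation and proper
    rotation minimizing the RMSD to the reference are applied (no scaling).
    A geometrically degenerate reference (collinear or coincident beads) is
    flagged with a warning; the fit is still returned but the rotation about
    the degenerate axis is arbitrary.
    """
    reference = np.asarray(reference_structure, dtype=float)
    if reference.shape != (ensemble.n_beads, 3):
        raise ValueError(
            f"reference has {reference.shape[0]} beads, ensemble has {ensemble.n_beads}"
        )
    ref_centered = reference - reference.mean(axis=0)
    if np.linalg.matrix_rank(ref_centered, tol=1e-10) < 2:
        warnings.warn(
            "reference structure is degenerate (collinear or coincident beads); "
            "superposition is not unique", stacklevel=2,
        )
    fitted = np.empty_like(ensemble.coords)
    for f in range(ensemble.n_frames):
        frame = ensemble.coords[f]
        frame_centered = frame - frame.mean(axis=0)
        R = _kabsch(frame_centered, ref_centered)
        fitted[f] = frame_centered @ R + reference.mean(axis=0)
    return BeadEnsemble(
        coords=fitted,
        bead_ids=list(ensemble.bead_ids),
        frame_weights=ensemble.frame_weights.copy(),
        box=ensemble.box,
        meta=dict(ensemble.meta),
    )


def compute_pca(ensemble: BeadEnsemble, n_components: int, label: str = "subspace") -> EssentialSubspace:
    """Cartesian PCA of the (weighted) flattened 3B coordinates.

    The ensemble must already be superposed; the covariance uses the
    population normalization (weights summing to one).
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if ensemble.n_frames <= n_components:
        raise ValueError(
            f"need more frames ({ensemble.n_frames}) than components ({n_components})"
        )
    w = ensemble.normalized_weights()
    flat = ensemble.coords.reshape(ensemble.n_frames, -1)
    mean = w @ flat
    centered = flat - mean
    cov = (centered * w[:, None]).T @ centered
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    total = float(np.trace(cov))
    return EssentialSubspace(
        mean_structure=mean.reshape(-1, 3),
        eigenvectors=evecs[:, :n_components],
        eigenvalues=evals[:n_components],
        total_variance=total,
        label=label,
    )


def variance_fraction(subspace: EssentialSubspace, k: int) -> float:
    """Fraction of total coordinate variance carried by the first k components."""
    if not 1 <= k <= subspace.n_components:
        raise ValueError(f"k={k} out of range [1, {subspace.n_components}]")
    if subspace.total_variance <= 0:
        return 0.0
    return float(subspace.eigenvalues[:k].sum() / subspace.total_variance)


def project(ensemble: BeadEnsemble, subspace: EssentialSubspace) -> ProjectedEnsemble:
    """Project frames into the subspace: V^T (q - q_mean) per flattened frame.

    The ensemble should already be superposed onto ``subspace.mean_structure``.
    """
    if ensemble.n_beads != subspace.n_beads:
        raise ValueError("bead count mismatch between ensemble and subspace")
    flat = ensemble.coords.reshape(ensemble.n_frames, -1)
    centered = flat - subspace.mean_structure.reshape(-1)
    points = centered @ subspace.eigenvectors
    return ProjectedEnsemble(
        points=points,
        frame_weights=ensemble.frame_weights.copy(),
        subspace_ref=subspace.label,
    )


def rmsf(ensemble: BeadEnsemble) -> np.ndarray:
    """Per-bead root-mean-square fluctuation about the weighted mean, in nm.

    Assumes the ensemble is superposed; rigid-body motion left in the frames
    will inflate the profile.
    """
    if ensemble.n_frames == 1:
        warnings.warn("single-frame ensemble: RMSF is identically zero", stacklevel=2)
        return np.zeros(ensemble.n_beads)
    w = ensemble.normalized_weights()
    mean = np.einsum("f,fbc->bc", w, ensemble.coords)
    sq_dev = ((ensemble.coords - mean) ** 2).sum(axis=2)  # (F, B)
    return np.sqrt(np.einsum("f,fb->b", w, sq_dev))


def rmsf_aue(profile_a: Sequence[float], profile_b: Sequence[float]) -> float:
    """Average unsigned error between two per-bead fluctuation profiles."""
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"profile length mismatch: {a.shape} vs {b.shape}")
    return float(np.mean(np.abs(a - b)))
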