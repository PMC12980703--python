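"""Structure-based interaction networks and their comparison statistics.

A network is a list of pairwise contacts between beads, either Lennard-Jones
Go-type contacts (breakable, strength = well depth epsilon in kJ/mol, geometry
= sigma in nm) or harmonic elastic-network springs (unbreakable, strength =
force constant kappa in kJ/mol/nm^2, geometry = equilibrium length r0 in nm).
The network topology is fixed; the optimizer only rescales strengths.

Default construction parameters follow common structure-based Martini
practice: Go contacts between beads 0.3-1.1 nm apart with uniform
epsilon = 9.4 kJ/mol, elastic springs for pairs closer than 0.9 nm with
kappa = 500 kJ/mol/nm^2.  For Go contacts the LJ minimum is placed at the
observed pair distance, i.e. sigma = r / 2^(1/6).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "Contact",
    "InteractionNetwork",
    "GO_LJ",
    "ENM_HARMONIC",
    "DEFAULT_GO_EPSILON",
    "DEFAULT_ENM_KAPPA",
    "DEFAULT_GO_CUTOFFS",
    "DEFAULT_ENM_CUTOFFS",
    "lj_energy",
    "enm_energy",
    "build_uniform_network",
    "set_equilibrium_from_ensemble",
    "apply_perturbation",
    "network_pearson",
    "laplacian_spectrum_distance",
    "network_to_tsv",
    "network_from_tsv",
]

logger = logging.getLogger(__name__)

GO_LJ = "go_lj"
ENM_HARMONIC = "enm_harmonic"

DEFAULT_GO_EPSILON = 9.4  # kJ/mol
DEFAULT_ENM_KAPPA = 500.0  # kJ/mol/nm^2
DEFAULT_GO_CUTOFFS = (0.3, 1.1)  # nm
DEFAULT_ENM_CUTOFFS = (0.0, 0.9)  # nm
DEFAULT_GO_MIN_SEQ_SEP = 3
DEFAULT_ENM_MIN_SEQ_SEP = 1

# floors keeping perturbed bonds physical
DEFAULT_STRENGTH_FLOOR = {GO_LJ: 0.5, ENM_HARMONIC: 10.0}

_RMIN_FACTOR = 2.0 ** (1.0 / 6.0)


@dataclass(frozen=True)
class Contact:
    """One pairwise term: bead indices i < j, kind, strength and geometry."""

    i: int
    j: int
    kind: str
    strength: float
    geometry: float

    def __post_init__(self):
        if self.i == self.j:
            raise ValueError("a contact needs two distinct beads")
        if self.i > self.j:
            raise ValueError("contact indices must satisfy i < j")
        if self.kind not in (GO_LJ, ENM_HARMONIC):
            raise ValueError(f"unknown contact kind {self.kind!r}")
        if self.strength <= 0:
            raise ValueError("contact strength must be positive")
        if self.geometry <= 0:
            raise ValueError("contact geometry must be positive")


@dataclass
class InteractionNetwork:
    """Homogeneous list of contacts over B beads; the object being optimized."""

    contacts: list[Contact]
    n_beads: int
    kind: str

    def __post_init__(self):
        if self.kind not in (GO_LJ, ENM_HARMONIC):
            raise ValueError(f"unknown network kind {self.kind!r}")
        seen = set()
        for c in self.contacts:
            if c.kind != self.kind:
                raise ValueError("network kind must be homogeneous")
            if not (0 <= c.i < self.n_beads and 0 <= c.j < self.n_beads):
                raise ValueError(f"contact ({c.i},{c.j}) outside bead range")
            if (c.i, c.j) in seen:
                raise ValueError(f"duplicate contact pair ({c.i},{c.j})")
            seen.add((c.i, c.j))

    @property
    def n_contacts(self) -> int:
        return len(self.contacts)

    def pairs(self) -> np.ndarray:
        return np.array([(c.i, c.j) for c in self.contacts], dtype=int).reshape(-1, 2)

    def strengths(self) -> np.ndarray:
        return np.array([c.strength for c in self.contacts], dtype=float)

    def geometries(self) -> np.ndarray:
        return np.array([c.geometry for c in self.contacts], dtype=float)

    def with_strengths(self, strengths) -> "InteractionNetwork":
        strengths = np.asarray(strengths, dtype=float)
        if strengths.shape != (self.n_contacts,):
            raise ValueError("one strength per contact required")
        contacts = [replace(c, strength=float(s)) for c, s in zip(self.contacts, strengths)]
        return InteractionNetwork(contacts, self.n_beads, self.kind)


def lj_energy(epsilon, sigma, r):
    """12-6 Lennard-Jones energy 4 eps [(sigma/r)^12 - (sigma/r)^6], kJ/mol.

    Minimum of depth -epsilon at r = 2^(1/6) sigma; zero crossing at r = sigma.
    Accepts scalars or arrays (broadcast).
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("lj_energy requires r > 0")
    sr6 = (sigma / r) ** 6
    out = 4.0 * epsilon * (sr6 * sr6 - sr6)
    return float(out) if out.ndim == 0 else out


def enm_energy(kappa, r0, r):
    """Harmonic spring energy 1/2 kappa (r - r0)^2, kJ/mol."""
    r = np.asarray(r, dtype=float)
    out = 0.5 * kappa * (r - r0) ** 2
    return float(out) if out.ndim == 0 else out


def build_uniform_network(
    structure,
    kind: str = GO_LJ,
    cutoff_lo: float | None = None,
    cutoff_hi: float | None = None,
    strength: float | None = None,
    min_seq_sep: int | None = None,
) -> InteractionNetwork:
    """Distance-cutoff network from a reference bead structure, uniform strength.

    A contact is created for every pair with sequence separation
    ``|i - j| >= min_seq_sep`` whose reference distance lies in
    ``[cutoff_lo, cutoff_hi]``.  Go contacts get sigma = r / 2^(1/6) so the LJ
    minimum sits at the observed distance; springs get r0 = r.
    """
    structure = np.asarray(structure, dtype=float)
    if structure.ndim != 2 or structure.shape[1] != 3:
        raise ValueError("structure must be a (B, 3) bead frame")
    defaults_cut = DEFAULT_GO_CUTOFFS if kind == GO_LJ else DEFAULT_ENM_CUTOFFS
    cutoff_lo = defaults_cut[0] if cutoff_lo is None else cutoff_lo
    cutoff_hi = defaults_cut[1] if cutoff_hi is None else cutoff_hi
    if cutoff_lo >= cutoff_hi:
        raise ValueError("cutoff_lo must be smaller than cutoff_hi")
    if strength is None:
        strength = DEFAULT_GO_EPSILON if kind == GO_LJ else DEFAULT_ENM_KAPPA
    if min_seq_sep is None:
        min_seq_sep = DEFAULT_GO_MIN_SEQ_SEP if kind == GO_LJ else DEFAULT_ENM_MIN_SEQ_SEP

    B = structure.shape[0]
    contacts = []
    for i in range(B):
        for j in range(i + min_seq_sep, B):
            r = float(np.linalg.norm(structure[j] - structure[i]))
            if cutoff_lo <= r <= cutoff_hi:
                geometry = r / _RMIN_FACTOR if kind == GO_LJ else r
                contacts.append(Contact(i, j, kind, float(strength), geometry))
    if not contacts:
        raise ValueError(
            "no bead pair falls inside the cutoff window: empty network "
            "(nothing to optimize)"
        )
    return InteractionNetwork(contacts, B, kind)


def set_equilibrium_from_ensemble(network: InteractionNetwork, ensemble) -> InteractionNetwork:
    """Refit each contact's equilibrium geometry to the ensemble-mean distance.

    For every contact the weighted mean pair distance r_ij over frames is
    computed; Go contacts get sigma = r_ij / 2^(1/6) (LJ minimum moved to
    r_ij), springs get r0 = r_ij.  Strengths are untouched; idempotent for a
    fixed ensemble.
    """
    if ensemble.n_beads <= max(max(c.i, c.j) for c in network.contacts):
        raise ValueError("ensemble has fewer beads than the network references")
    w = ensemble.normalized_weights()
    pairs = network.pairs()
    diffs = ensemble.coords[:, pairs[:, 0], :] - ensemble.coords[:, pairs[:, 1], :]
    dists = np.linalg.norm(diffs, axis=2)  # (F, M)
    mean_r = w @ dists
    contacts = []
    for c, r in zip(network.contacts, mean_r):
        geometry = float(r / _RMIN_FACTOR) if c.kind == GO_LJ else float(r)
        contacts.append(replace(c, geometry=geometry))
    return InteractionNetwork(contacts, network.n_beads, network.kind)


def apply_perturbation(
    network: InteractionNetwork,
    lambda_vector,
    strength_floor: float | None = None,
) -> InteractionNetwork:
    """Rescale contact strengths by (1 + lambda_k), floored at a physical minimum.

    Positive lambda_k strengthens (deepens/stiffens) contact k, negative
    weakens it; lambda_k <= -1 would invert the interaction and is clamped to
    the floor with a logged warning.  Contact count, order and geometry are
    preserved.
    """
    lam = np.asarray(lambda_vector, dtype=float)
    if lam.shape != (network.n_contacts,):
        raise ValueError(
            f"lambda has length {lam.size}, network has {network.n_contacts} contacts"
        )
    if strength_floor is None:
        strength_floor = DEFAULT_STRENGTH_FLOOR[network.kind]
    if strength_floor <= 0:
        raise ValueError("strength_floor must be positive")
    new = network.strengths() * (1.0 + lam)
    n_clamped = int(np.sum(new < strength_floor))
    if n_clamped:
        logger.warning(
            "apply_perturbation clamped %d/%d strengths at floor %g",
            n_clamped, network.n_contacts, strength_floor,
        )
    return network.with_strengths(np.maximum(new, strength_floor))


def _check_same_pairs(net_a: InteractionNetwork, net_b: InteractionNetwork) -> None:
    if net_a.n_contacts != net_b.n_contacts or not np.array_equal(net_a.pairs(), net_b.pairs()):
        raise ValueError("networks have different contact pair lists")


def network_pearson(net_a: InteractionNetwork, net_b: InteractionNetwork) -> float:
    """Pearson correlation of the two strength vectors over identical pair lists.

    Raises ``ValueError`` when either side has zero variance (e.g. a uniform
    starting network), since the correlation is undefined there.
    """
    _check_same_pairs(net_a, net_b)
    a = net_a.strengths()
    b = net_b.strengths()
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError(
            "Pearson correlation undefined: a strength vector has zero variance "
            "(uniform network)"
        )
    return float(np.corrcoef(a, b)[0, 1])


def _laplacian(network: InteractionNetwork, scale: float = 1.0) -> np.ndarray:
    B = network.n_beads
    A = np.zeros((B, B))
    for c in network.contacts:
        w = c.strength / scale
        A[c.i, c.j] = w
        A[c.j, c.i] = w
    return np.diag(A.sum(axis=1)) - A


def laplacian_spectrum_distance(
    net_a: InteractionNetwork,
    net_b: InteractionNetwork,
    normalize: bool = False,
) -> float:
    """L2 distance between the sorted weighted-Laplacian eigenvalue spectra.

    Each network defines a weighted graph (edge weight = contact strength);
    the distance is the Euclidean norm of the difference of the
    ascending-sorted eigenvalue vectors of L = D - A (dense eigensolve).
    With ``normalize=True`` strengths are first divided by the joint mean of
    both networks, making the distance scale-free.
    """
    if net_a.n_beads != net_b.n_beads:
        raise ValueError("networks must share the bead count")
    if net_a.n_contacts == 0 or net_b.n_contacts == 0:
        raise ValueError("both networks must be nonempty")
    scale = 1.0
    if normalize:
        scale = float(np.concatenate([net_a.strengths(), net_b.strengths()]).mean())
    ev_a = np.sort(np.linalg.eigvalsh(_laplacian(net_a, scale)))
    ev_b = np.sort(np.linalg.eigvalsh(_laplacian(net_b, scale)))
    return float(np.linalg.norm(ev_a - ev_b))


def network_to_tsv(network: InteractionNetwork, path) -> None:
    """Plain TSV dump (i, j, kind, strength, geometry) for inspection/plotting."""
    with open(path, "w") as fh:
        fh.write(f"# n_beads={network.n_beads}\tkind={network.kind}\n")
        fh.write("i\tj\tkind\tstrength\tgeometry\n")
        for c in network.contacts:
            fh.write(f"{c.i}\t{c.j}\t{c.kind}\t{c.strength:.10g}\t{c.geometry:.10g}\n")


def network_from_tsv(path) -> InteractionNetwork:
    """Read a network written by :func:`network_to_tsv`."""
    contacts = []
    n_beads = None
    kind = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                for tok in line[1:].split():
                    key, _, val = tok.partition("=")
                    if key == "n_beads":
                        n_beads = int(val)
                    elif key == "kind":
                        kind = val
                continue
            if not line or line.startswith("i\t"):
                continue
            i, j, ckind, strength, geometry = line.split("\t")
            contacts.append(Contact(int(i), int(j), ckind, float(strength), float(geometry)))
    if n_beads is None or kind is None:
        raise ValueError("TSV header missing n_beads/kind metadata")
    return InteractionNetwork(contacts, n_beads, kind)
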