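"""Optimal-superposition RMSD and greedy neighbour-count (Daura) clustering.

The clustering procedure is the "gromos" method: repeatedly find the
unassigned conformer with the most unassigned neighbours within the RMSD
cutoff, make it the centre of a new cluster containing it and those
neighbours, remove them, and iterate until every conformer is assigned.
Cluster extraction order is therefore by neighbourhood size, so the first
cluster is always the most populated.

RMSD between two models is computed after least-squares rigid superposition
(Kabsch, proper rotations only).  Coordinates are Angstrom internally;
RMSDs are reported in nanometres to match the conventional 0.2 nm cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .synthetic_ensemble import Ensemble3D

__all__ = [
    "AtomSelection",
    "BACKBONE",
    "RMSDMatrix",
    "Cluster",
    "ClusterResult",
    "kabsch_superpose",
    "pairwise_rmsd",
    "daura_cluster",
]

ANGSTROM_PER_NM = 10.0


@dataclass(frozen=True)
class AtomSelection:
    """Atom filter by name and (optionally) residue index."""

    atom_names: frozenset[str] = frozenset({"N", "CA", "C", "O"})
    res_ids: frozenset[int] | None = None

    def mask(self, ensemble: Ensemble3D) -> np.ndarray:
        m = ensemble.select(
            atom_names=self.atom_names,
            res_ids=self.res_ids,
        )
        if m.sum() < 3:
            raise ValueError(
                f"selection keeps only {int(m.sum())} atoms; need at least 3"
            )
        return m


#: Default selection: backbone heavy atoms of the peptide residues.
BACKBONE = AtomSelection()


def _kabsch_batch(p: np.ndarray, q: np.ndarray):
    """Optimal proper rotations aligning q onto p, batched over axis 0.

    ``p``, ``q``: (..., n_atoms, 3), already centred.  Returns (rotations
    (..., 3, 3), rmsd (...)) where rmsd is in the input length unit.
    """
    h = np.einsum("...ni,...nj->...ij", q, p)
    u, s, vt = np.linalg.svd(h)
    det = np.linalg.det(np.einsum("...ij,...jk->...ik", u, vt))
    # flip the smallest singular vector where the rotation would be improper
    flip = np.ones_like(s)
    flip[..., -1] = np.sign(det)
    rot = np.einsum("...ij,...j,...jk->...ki", u, flip, vt)
    q_rot = np.einsum("...ij,...nj->...ni", rot, q)
    rmsd = np.sqrt(np.mean(np.sum((p - q_rot) ** 2, axis=-1), axis=-1))
    return rot, rmsd


def kabsch_superpose(
    model_a: np.ndarray, model_b: np.ndarray, selection_mask: np.ndarray | None = None
):
    """Least-squares rigid superposition of model_b onto model_a.

    Inputs are (n_atoms, 3) coordinate arrays in Angstrom.  Returns
    ``(rotation, translation, rmsd_nm)`` such that
    ``rotation @ b + translation`` best fits ``a``; the rotation is proper
    (determinant +1) and the RMSD is minimal over all rigid transforms.
    A degenerate selection (fewer than 3 atoms, or all collinear) is an error.
    """
    a = np.asarray(model_a, dtype=float)
    b = np.asarray(model_b, dtype=float)
    if selection_mask is not None:
        a = a[selection_mask]
        b = b[selection_mask]
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("models must be (n_atoms, 3) arrays of equal shape")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 atoms for superposition")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    ac, bc = a - ca, b - cb
    if np.linalg.matrix_rank(ac, tol=1e-8) < 2 or np.linalg.matrix_rank(bc, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) atom selection")
    rot, rmsd = _kabsch_batch(ac[None], bc[None])
    rotation = rot[0]
    translation = ca - rotation @ cb
    return rotation, translation, float(rmsd[0]) / ANGSTROM_PER_NM


@dataclass
class RMSDMatrix:
    """Symmetric pairwise RMSD matrix in nanometres, zero diagonal."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("RMSD matrix must be square")
        if not np.allclose(v, v.T):
            raise ValueError("RMSD matrix must be symmetric")
        if np.any(v < 0) or np.any(np.diag(v) != 0):
            raise ValueError("RMSD matrix must be non-negative with zero diagonal")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def pairwise_rmsd(
    ensemble: Ensemble3D, selection: AtomSelection = BACKBONE
) -> RMSDMatrix:
    """All-pairs Kabsch RMSD over the selected atoms, in nm.

    Superpositions for all n(n-1)/2 pairs are solved in one batched SVD.
    """
    if ensemble.n_models < 2:
        raise ValueError("need at least 2 models")
    mask = selection.mask(ensemble)
    x = ensemble.coords[:, mask]
    x = x - x.mean(axis=1, keepdims=True)
    n = x.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    _, rmsd = _kabsch_batch(x[iu], x[ju])
    mat = np.zeros((n, n))
    mat[iu, ju] = rmsd / ANGSTROM_PER_NM
    mat[ju, iu] = mat[iu, ju]
    return RMSDMatrix(mat)


@dataclass
class Cluster:
    center: int
    members: tuple[int, ...]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ClusterResult:
    """Clusters in extraction order (sizes non-increasing); cutoff in nm."""

    clusters: list[Cluster]
    cutoff: float

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def labels(self, n_frames: int | None = None) -> np.ndarray:
        """Per-frame cluster id (0 = largest cluster)."""
        if n_frames is None:
            n_frames = sum(c.size for c in self.clusters)
        lab = np.full(n_frames, -1, dtype=int)
        for cid, cl in enumerate(self.clusters):
            lab[list(cl.members)] = cid
        return lab


def daura_cluster(matrix: RMSDMatrix, cutoff: float) -> ClusterResult:
    """Greedy neighbour-count clustering at the given RMSD cutoff (nm).

    At each round the unassigned frame with the most unassigned neighbours
    (RMSD <= cutoff) becomes a cluster centre; ties go to the lowest frame
    index.  The centre and its unassigned neighbours form the cluster and
    are removed.  The result partitions all frames.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    adj = matrix.values <= cutoff
    np.fill_diagonal(adj, True)  # a frame neighbours itself
    unassigned = np.ones(matrix.n, dtype=bool)
    clusters: list[Cluster] = []
    while unassigned.any():
        counts = (adj & unassigned).sum(axis=1)
        counts[~unassigned] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.flatnonzero(adj[center] & unassigned)
        clusters.append(Cluster(center=center, members=tuple(int(m) for m in members)))
        unassigned[members] = False
    return ClusterResult(clusters=clusters, cutoff=cutoff)
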