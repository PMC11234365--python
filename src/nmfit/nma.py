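"""Elastic-network normal modes with rotation-translation-block reduction.

The network connects every atom pair within a cutoff by a harmonic spring
whose constant decays with the pair distance (default k(r) = C r^-6, the
distance-weighted law of all-atom elastic network models, calibrated so
that k(5 Å) = 1 kcal/mol/Å²). The Hessian is mass-weighted and either
diagonalised in full or first projected onto per-residue rigid-body motions
(RTB, one residue per block: 6 degrees of freedom per block, 3 for
single-atom blocks). Eigenvectors are returned in Cartesian space with
mass-weighted orthonormality q_i^T M q_j = delta_ij; the six rigid-body
modes of a connected network are detected and removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

__all__ = ["ENMParams", "ModeSet", "build_hessian", "full_modes",
           "rtb_modes", "mode_overlap", "DisconnectedNetworkWarning"]


class DisconnectedNetworkWarning(UserWarning):
    pass


@dataclass
class ENMParams:
    """Elastic network parameters.

    ``force_constant`` may be any callable k(r) in kcal/mol/Å²; the default
    power law is C r^-6 with C = prefactor * r_ref^6.
    """

    cutoff: float = 10.0
    prefactor: float = 1.0   # kcal/mol/Å² at r = r_ref
    r_ref: float = 5.0
    power: float = 6.0
    force_constant: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self):
        if self.cutoff <= 0 or self.prefactor <= 0:
            raise ValueError("cutoff and prefactor must be positive")

    def k(self, r):
        if self.force_constant is not None:
            return self.force_constant(r)
        return self.prefactor * (self.r_ref / np.asarray(r)) ** self.power


@dataclass
class ModeSet:
    """Low-frequency normal modes of a structure.

    ``modes[k]`` is an (N, 3) Cartesian eigenvector with mass-weighted
    orthonormality; ``eigenvalues`` are ascending, in kcal/mol/Å²/amu
    (mass-weighted Hessian units). ``block_keys`` records the RTB block
    definition used (None for a full all-atom solve).
    """

    eigenvalues: np.ndarray      # (K,)
    modes: np.ndarray            # (K, N, 3)
    masses: np.ndarray           # (N,)
    block_keys: list | None = None

    def __post_init__(self):
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.modes = np.asarray(self.modes, dtype=float)
        if np.any(np.diff(self.eigenvalues) < -1e-10):
            raise ValueError("eigenvalues must be ascending")

    @property
    def n_modes(self) -> int:
        return self.eigenvalues.size


def build_hessian(s, p: ENMParams) -> sparse.csr_matrix:
    """Sparse 3N x 3N Cartesian Hessian of the elastic network (not
    mass-weighted). Warns if the contact network is disconnected."""
    n = s.n_atoms
    if n < 3:
        raise ValueError("need at least 3 atoms")
    tree = cKDTree(s.coords)
    pairs = np.array(sorted(tree.query_pairs(p.cutoff)), dtype=int)
    if pairs.size == 0:
        raise ValueError("no pairs within cutoff: empty network")

    adj = sparse.coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    ncomp, labels = connected_components(adj, directed=False)
    if ncomp > 1:
        sizes = np.bincount(labels)
        warnings.warn(
            f"elastic network has {ncomp} connected components "
            f"(sizes {sizes.tolist()}); expect more than 6 zero modes",
            DisconnectedNetworkWarning)

    d = s.coords[pairs[:, 1]] - s.coords[pairs[:, 0]]
    r = np.linalg.norm(d, axis=1)
    u = d / r[:, None]
    k = p.k(r)
    blocks = k[:, None, None] * (u[:, :, None] * u[:, None, :])  # (P,3,3)

    rows, cols, vals = [], [], []
    ii, jj = pairs[:, 0], pairs[:, 1]
    for a in range(3):
        for b in range(3):
            v = blocks[:, a, b]
            rows += [3 * ii + a, 3 * jj + a, 3 * ii + a, 3 * jj + a]
            cols += [3 * jj + b, 3 * ii + b, 3 * ii + b, 3 * jj + b]
            vals += [-v, -v, v, v]
    H = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(3 * n, 3 * n)).tocsr()
    return H


def _strip_rigid(evals, evecs, tol_factor=1e-8):
    """Drop the rigid-body modes; return (evals, evecs, n_zero).

    A connected network has exactly six zero eigenvalues (machine-level);
    soft internal modes can approach the 1e-8*lam_max near-zero threshold
    on distorted structures, so only modes that are both below the
    threshold and among the six smallest are treated as rigid-body.
    ``n_zero`` reports the raw below-threshold count for diagnostics.
    """
    lam_max = max(evals.max(), 1e-30)
    near = np.abs(evals) < tol_factor * lam_max
    drop = np.zeros_like(near)
    drop[np.argsort(np.abs(evals))[:min(6, evals.size)]] = True
    drop &= near
    return evals[~drop], evecs[:, ~drop], int(drop.sum())


def _finish(s, evals, evecs_mw, n_modes, block_keys):
    """Strip rigid modes, convert to Cartesian, package as ModeSet."""
    lam, vec, n_zero = _strip_rigid(evals, evecs_mw)
    if n_zero != 6:
        warnings.warn(f"detected {n_zero} near-zero modes (expected 6)",
                      DisconnectedNetworkWarning)
    if n_modes > lam.size:
        raise ValueError(f"requested {n_modes} modes, only {lam.size} available")
    lam = lam[:n_modes]
    vec = vec[:, :n_modes]
    inv_sqrt_m = 1.0 / np.sqrt(np.repeat(s.masses, 3))
    cart = (vec * inv_sqrt_m[:, None]).T.reshape(n_modes, s.n_atoms, 3)
    return ModeSet(lam, cart, s.masses.copy(), block_keys=block_keys)


def full_modes(s, p: ENMParams, n_modes: int) -> ModeSet:
    """Normal modes of the full (unreduced) mass-weighted elastic Hessian.

    Dense solve below 3N = 1500, sparse shift-invert above.
    """
    H = build_hessian(s, p)
    n3 = H.shape[0]
    inv_sqrt_m = 1.0 / np.sqrt(np.repeat(s.masses, 3))
    D = sparse.diags(inv_sqrt_m)
    Hmw = D @ H @ D
    if n3 < 1500:
        evals, evecs = np.linalg.eigh(Hmw.toarray())
    else:
        k = min(n_modes + 20, n3 - 2)
        evals, evecs = sparse.linalg.eigsh(Hmw.tocsc(), k=k, sigma=0,
                                           which="LM")
        order = np.argsort(evals)
        evals, evecs = evals[order], evecs[:, order]
    return _finish(s, evals, evecs, n_modes, block_keys=None)


def _rtb_projection(s) -> tuple[sparse.csr_matrix, list]:
    """Orthonormal (in mass-weighted metric) basis of per-residue rigid
    translations and rotations, as a sparse (3N, n_dof) matrix."""
    keys = s.residue_keys()
    uniq = []
    index = {}
    for k in keys:
        if k not in index:
            index[k] = len(uniq)
            uniq.append(k)
    members = [[] for _ in uniq]
    for i, k in enumerate(keys):
        members[index[k]].append(i)

    cols, col_rows, col_vals = 0, [], []
    for atoms in members:
        atoms = np.array(atoms, dtype=int)
        m = s.masses[atoms]
        x = s.coords[atoms]
        com = np.average(x, axis=0, weights=m)
        dx = x - com
        sq = np.sqrt(m)
        basis = []
        for ax in range(3):  # translations
            v = np.zeros((atoms.size, 3))
            v[:, ax] = sq
            basis.append(v)
        if atoms.size > 1:
            for ax in range(3):  # rotations about the block centre of mass
                e = np.zeros(3)
                e[ax] = 1.0
                v = sq[:, None] * np.cross(e, dx)
                basis.append(v)
        # orthonormalise within the block (drops degenerate rotations,
        # e.g. about the axis of a collinear block)
        B = np.stack([b.ravel() for b in basis], axis=1)
        q, r = np.linalg.qr(B)
        keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())
        q = q[:, keep]
        rows3 = (3 * atoms[:, None] + np.arange(3)[None, :]).ravel()
        for j in range(q.shape[1]):
            col_rows.append(rows3)
            col_vals.append(q[:, j])
            cols += 1
    rows = np.concatenate(col_rows)
    vals = np.concatenate(col_vals)
    colidx = np.concatenate([np.full(r.size, j) for j, r in enumerate(col_rows)])
    P = sparse.coo_matrix((vals, (rows, colidx)),
                          shape=(3 * s.n_atoms, cols)).tocsr()
    return P, uniq


def rtb_modes(s, p: ENMParams, n_modes: int) -> ModeSet:
    """Normal modes under the rotation-translation-block approximation,
    one residue per block. Eigenvectors are expanded back to all-atom
    Cartesian space and are mass-weighted-orthonormal."""
    H = build_hessian(s, p)
    inv_sqrt_m = 1.0 / np.sqrt(np.repeat(s.masses, 3))
    D = sparse.diags(inv_sqrt_m)
    Hmw = (D @ H @ D).tocsr()
    P, uniq = _rtb_projection(s)
    Hred = np.asarray((P.T @ Hmw @ P).toarray()
                      if sparse.issparse(P.T @ Hmw @ P)
                      else P.T @ Hmw @ P)
    Hred = 0.5 * (Hred + Hred.T)
    evals, evecs = np.linalg.eigh(Hred)
    # expansion of orthonormal reduced eigenvectors through the orthonormal
    # block basis stays orthonormal; renormalise columns against round-off
    full = np.asarray(P @ evecs)
    full /= np.linalg.norm(full, axis=0)
    return _finish(s, evals, full, n_modes, block_keys=uniq)


def mode_overlap(ms: ModeSet, displacement: np.ndarray) -> np.ndarray:
    """Mass-weighted inner products q_i^T M d of each mode with a Cartesian
    displacement (3N or (N,3)). With the modes M-orthonormal, the squared
    overlaps sum to at most the squared M-norm of the displacement."""
    d = np.asarray(displacement, dtype=float).reshape(-1)
    if d.size != ms.modes.shape[1] * 3:
        raise ValueError("displacement dimension mismatch")
    w = np.repeat(ms.masses, 3)
    flat = ms.modes.reshape(ms.n_modes, -1)
    return flat @ (w * d)
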