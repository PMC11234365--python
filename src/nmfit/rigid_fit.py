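"""Rigid-body docking of a structure into a target map.

The pose search maximises the cross-correlation between the structure's
synthetic map and the target: centre-of-mass alignment to the density
centroid, principal-axes alignment (four proper axis-sign hypotheses),
then derivative-free Nelder-Mead refinement over the 6 rigid degrees of
freedom (rotation vector + translation) from each hypothesis and from a
set of random restarts. Deterministic for a given seed, and the returned
pose never scores below the input pose.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize
from scipy.spatial.transform import Rotation

from .density import DensityMap, cc_structure
from .model_io import RigidTransform, Structure

__all__ = ["rigid_body_fit"]


def _map_moments(tm: DensityMap):
    """Density-weighted centroid and second-moment (covariance) matrix."""
    w = np.clip(tm.data, 0.0, None)
    total = w.sum()
    if total <= 0:
        raise ValueError("empty map: no positive density")
    idx = np.indices(tm.shape, dtype=float)
    pos = np.stack([tm.origin[a] + tm.voxel[a] * idx[a] for a in range(3)])
    centroid = np.array([(w * pos[a]).sum() / total for a in range(3)])
    d = pos - centroid[:, None, None, None]
    cov = np.einsum("aijk,bijk->ab", d * w, d) / total
    return centroid, cov


def _structure_moments(s: Structure):
    w = s.masses
    com = np.average(s.coords, axis=0, weights=w)
    d = s.coords - com
    cov = (d * w[:, None]).T @ d / w.sum()
    return com, cov


def _axis_hypotheses(cov_s, cov_m):
    """Proper rotations aligning structure principal axes to map axes;
    4 sign combinations keep det = +1."""
    _, vs = np.linalg.eigh(cov_s)
    _, vm = np.linalg.eigh(cov_m)
    if np.linalg.det(vs) < 0:
        vs[:, 0] *= -1
    if np.linalg.det(vm) < 0:
        vm[:, 0] *= -1
    rots = []
    for sx, sy in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
        S = np.diag([sx, sy, sx * sy])
        rots.append(vm @ S @ vs.T)
    return rots


def _apply_pose(s: Structure, x, pivot):
    rot = Rotation.from_rotvec(x[:3]).as_matrix()
    return s.with_coords((s.coords - pivot) @ rot.T + pivot + x[3:])


def rigid_body_fit(s: Structure, tm: DensityMap, resolution: float,
                   restarts: int = 8, seed: int = 0,
                   maxiter: int = 200, mode: str = "global"):
    """Dock ``s`` rigidly into ``tm``; returns ``(fitted Structure, cc)``.

    ``mode="global"`` seeds the refinement from centre-of-mass +
    principal-axes hypotheses (four proper sign choices) as well as the
    input pose; ``mode="local"`` refines from the input pose only,
    matching the common practice of locally optimising a user-placed
    structure. ``restarts`` adds random perturbations (rotations up to
    0.5 rad, translations up to 5 Å) around the best base pose. The output
    correlation never falls below the input pose's.
    """
    if restarts < 0:
        raise ValueError("restarts must be >= 0")
    if mode not in ("global", "local"):
        raise ValueError("mode must be 'global' or 'local'")
    rng = np.random.default_rng(seed)
    cc_in = cc_structure(s, tm, resolution)
    centroid, cov_m = _map_moments(tm)
    com, cov_s = _structure_moments(s)

    candidates = [(np.eye(3), np.zeros(3))]
    if mode == "global":
        for R in _axis_hypotheses(cov_s, cov_m):
            candidates.append((R, centroid - R @ com))
    # encode pose as rotation about the structure COM plus net COM shift
    starts = []
    for R, t in candidates:
        rv = Rotation.from_matrix(R).as_rotvec()
        shift = R @ com + t - com  # net COM displacement
        starts.append(np.concatenate([rv, shift]))
    base = max(starts, key=lambda x: cc_structure(
        _apply_pose(s, x, com), tm, resolution))
    for _ in range(restarts):
        pert = np.concatenate([rng.uniform(-0.5, 0.5, 3),
                               rng.uniform(-5.0, 5.0, 3)])
        starts.append(base + pert)

    def neg_cc(x):
        return -cc_structure(_apply_pose(s, x, com), tm, resolution)

    best_x, best_cc = None, -np.inf
    for x0 in starts:
        res = optimize.minimize(neg_cc, x0, method="Nelder-Mead",
                                options={"maxiter": maxiter,
                                         "xatol": 1e-3, "fatol": 1e-6})
        if -res.fun > best_cc:
            best_cc, best_x = -res.fun, res.x
    if best_cc <= cc_in:
        return s.copy(), cc_in
    return _apply_pose(s, best_x, com), float(best_cc)
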