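"""Programmatic toy systems for exercising the fitting machinery.

The central fixture is a two-domain "hinge" protein: two compact
pseudo-helical domains joined by a short coil linker, with a closed form
generated from the open one by a rigid rotation of the second domain about
a hinge axis through the linker. It stands in for the classic
open/closed-domain benchmark pairs: the open form is the start, a map
simulated from the closed form is the target, and the known closed
structure provides the ground-truth RMSD. Atoms are Cα-only pseudo-atoms
(mass 12 amu) by default; a 3-atoms-per-residue variant exercises the
rotation-translation-block reduction non-trivially.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .density import DensityMap, simulate_map, write_map
from .dynamics import build_forcefield, total_forces
from .model_io import Structure, rmsd, select_ca, write_structure
from .nma import ENMParams, DisconnectedNetworkWarning, full_modes
from .rigid_fit import rigid_body_fit

__all__ = ["make_two_domain_toy", "make_benchmark_case", "make_noise_map"]

_HELIX_RADIUS = 1.8     # Å, pseudo-helix backbone radius
_HELIX_RISE = 2.2       # Å per residue along the strand axis
_HELIX_TWIST = 1.745    # rad per residue (~100 deg)
_STRAND_SEP = 7.5       # Å between the two strand axes of a hairpin
_JITTER = 0.1           # Å seeded jitter breaking the analytic symmetry
_D2_OFFSET = np.array([16.0, 1.5, -8.5])   # domain-2 placement
_MIN_CLEARANCE = 3.15   # Å smallest allowed non-bonded contact


def _hairpin(n_res: int, phase: float = 0.0) -> np.ndarray:
    """Cα trace of a compact antiparallel two-helix hairpin: strand up,
    turn residue, strand down, cross-braced at ~4-8 Å."""
    na = n_res // 2
    nb = n_res - na - 1
    t = np.arange(na)
    A = np.stack([_HELIX_RADIUS * np.cos(_HELIX_TWIST * t + phase),
                  _HELIX_RADIUS * np.sin(_HELIX_TWIST * t + phase),
                  _HELIX_RISE * t], axis=1)
    top = A[-1]
    t2 = np.arange(nb)
    B = np.stack([_STRAND_SEP + _HELIX_RADIUS * np.cos(_HELIX_TWIST * t2 + 2.6 + phase),
                  _HELIX_RADIUS * np.sin(_HELIX_TWIST * t2 + 2.6 + phase),
                  top[2] - _HELIX_RISE * t2], axis=1)
    turn = 0.5 * (top + B[0]) + np.array([0.0, 0.8, 0.3])
    return np.concatenate([A, [turn], B])


def _arc(p0: np.ndarray, p1: np.ndarray, step: float = 3.6,
         n_mid: int = 3, bulge=np.array([0.0, -1.0, 0.0])) -> np.ndarray:
    """n_mid linker points on a circular arc from p0 to p1 with ~equal
    Cα-Cα steps, bulging sideways when the chord is shorter than the arc."""
    chord = p1 - p0
    L = np.linalg.norm(chord)
    ns = n_mid + 1
    arc_len = ns * step
    if arc_len <= L * 1.01:
        return np.stack([p0 + chord * (k / ns) for k in range(1, ns)])
    from scipy.optimize import brentq
    half = brentq(lambda x: np.sin(x) / x - L / arc_len, 1e-6, np.pi - 1e-9)
    theta, R = 2 * half, arc_len / (2 * half)
    u = chord / L
    b = bulge - u * (bulge @ u)
    b /= np.linalg.norm(b)
    centre = 0.5 * (p0 + p1) + b * (R * np.cos(theta / 2))
    angles = [-theta / 2 + theta * k / ns for k in range(1, ns)]
    return np.stack([centre - b * (R * np.cos(a)) + u * (R * np.sin(a))
                     for a in angles])


def _assemble(n_res_per_domain: int, seed: int, atoms_per_residue: int,
              open_deg: float, closed_deg: float):
    """Build the jittered scaffold and return (open Structure,
    closed Structure) related by a rigid rotation of domain 2 (plus
    linker) about the hinge axis (y through the last domain-1 residue).

    The jitter draw is redrawn (deterministically, sub-seeded) until both
    poses are free of non-bonded contacts below ~3.1 Å.
    """
    n = n_res_per_domain
    d1 = _hairpin(n)
    d2 = _hairpin(n, phase=np.pi) + _D2_OFFSET
    link = _arc(d1[-1], d2[0])
    ca0 = np.concatenate([d1, link, d2])
    from scipy.spatial import cKDTree

    def bend_coords(ca, deg, hp):
        R = Rotation.from_euler("y", deg, degrees=True).as_matrix()
        c = ca.copy()
        c[n:] = (c[n:] - hp) @ R.T + hp
        return c

    for sub in range(100):
        ca = ca0 + np.random.default_rng([seed, sub]).normal(
            0.0, _JITTER, ca0.shape)
        hp = ca[n - 1].copy()
        clean = all(
            not any(j - i > 1 for i, j in
                    cKDTree(bend_coords(ca, deg, hp)).query_pairs(_MIN_CLEARANCE))
            for deg in (open_deg, closed_deg))
        if clean:
            break
    ca_open = bend_coords(ca, open_deg, hp)
    ca_closed = bend_coords(ca, closed_deg, hp)

    ss = np.array(["H"] * n + ["C"] * 3 + ["H"] * n)
    return (_to_structure(ca_open, ss, atoms_per_residue),
            _to_structure(ca_closed, ss, atoms_per_residue))


def _to_structure(ca: np.ndarray, ss: np.ndarray,
                  atoms_per_residue: int) -> Structure:
    n_res = ca.shape[0]
    if atoms_per_residue == 1:
        coords, names, resids, codes = ca, ["CA"] * n_res, \
            list(range(1, n_res + 1)), list(ss)
    elif atoms_per_residue == 3:
        coords, names, resids, codes = [], [], [], []
        for i in range(n_res):
            nxt = ca[min(i + 1, n_res - 1)] - ca[max(i - 1, 0)]
            nxt = nxt / max(np.linalg.norm(nxt), 1e-9)
            perp = np.cross(nxt, [0.0, 0.0, 1.0])
            if np.linalg.norm(perp) < 1e-6:
                perp = np.cross(nxt, [0.0, 1.0, 0.0])
            perp /= np.linalg.norm(perp)
            for name, off in (("N", -0.75 * nxt + 0.5 * perp),
                              ("CA", np.zeros(3)),
                              ("C", 0.75 * nxt + 0.5 * perp)):
                coords.append(ca[i] + off)
                names.append(name)
                resids.append(i + 1)
                codes.append(ss[i])
        coords = np.array(coords)
    else:
        raise ValueError("atoms_per_residue must be 1 or 3")

    n_atoms = len(names)
    return Structure(
        names=np.array(names), elements=np.array(["C"] * n_atoms),
        res_names=np.array(["ALA"] * n_atoms),
        res_ids=np.array(resids, dtype=int),
        chain_ids=np.array(["A"] * n_atoms), coords=np.asarray(coords),
        masses=np.full(n_atoms, 12.0), ss=np.array(codes))


def _self_validate(s: Structure) -> None:
    """Fixture sanity: connected elastic network with exactly 6 zero modes,
    finite surrogate energy at the reference geometry."""
    with warnings.catch_warnings():
        warnings.simplefilter("error", DisconnectedNetworkWarning)
        full_modes(s, ENMParams(), min(6, 3 * s.n_atoms - 6))
    ff = build_forcefield(s)
    _, bd = total_forces(s, ff)
    if not np.isfinite(bd["total"]):
        raise AssertionError("fixture has non-finite reference energy")


def make_two_domain_toy(n_res_per_domain: int = 15,
                        hinge_angle_open: float = 60.0,
                        hinge_angle_closed: float = 10.0,
                        seed: int = 0, atoms_per_residue: int = 1):
    """Two-domain hinge toy; returns ``(open, closed, ca_rmsd)``.

    Both forms come from one jittered scaffold: the closed form differs
    from the open form by a rigid rotation of domain 2 (with the linker)
    about the hinge axis through the last domain-1 residue. The reported
    Cα RMSD is measured in the shared generation frame (domain 1 is
    identical in both forms, so no superposition is involved).
    Deterministic given the seed.
    """
    if n_res_per_domain < 5:
        raise ValueError("need at least 5 residues per domain")
    s_open, s_closed = _assemble(n_res_per_domain, seed, atoms_per_residue,
                                 hinge_angle_open, hinge_angle_closed)
    if hinge_angle_open == hinge_angle_closed:
        warnings.warn("hinge angles equal: degenerate (identical) pair")
    _self_validate(s_open)
    _self_validate(s_closed)
    ca_rmsd = rmsd(s_open, s_closed, select_ca(s_open), select_ca(s_closed),
                   superpose=False)
    return s_open, s_closed, ca_rmsd


def make_benchmark_case(toy_pair, resolution: float = 5.0, voxel: float = 1.0,
                        out_dir=None, seed: int = 0):
    """Fitting benchmark from a (open, closed) pair: the target map is
    simulated from the closed form, and the start is the open form
    rigid-body docked into that map. Returns
    ``(start, target_map, target_structure)``; with ``out_dir`` the bundle
    (PDBs, MRC map, manifest JSON) is written to disk."""
    s_open, s_closed = toy_pair[0], toy_pair[1]
    tm = simulate_map(s_closed, resolution, voxel=voxel)
    # local refinement from the generation pose: the open and closed forms
    # share a frame, mirroring the usual practice of locally refining a
    # roughly pre-placed structure in the map
    start, cc0 = rigid_body_fit(s_open, tm, resolution, seed=seed,
                                mode="local", restarts=2)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_structure(start, out / "start.pdb")
        write_structure(s_closed, out / "target.pdb")
        write_map(tm, out / "target.mrc")
        manifest = {
            "seed": seed, "resolution": resolution, "voxel": voxel,
            "start_cc": cc0,
            "start_rmsd": rmsd(start, s_closed, select_ca(start),
                               select_ca(s_closed), superpose=False),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return start, tm, s_closed


def make_noise_map(m: DensityMap, snr: float, seed: int = 0) -> DensityMap:
    """Additive Gaussian voxel noise with SNR = RMS(signal)/RMS(noise)."""
    if snr <= 0:
        raise ValueError("snr must be positive")
    rng = np.random.default_rng(seed)
    signal_rms = float(np.sqrt(np.mean(m.data ** 2)))
    sigma = signal_rms / snr
    noisy = m.data + rng.normal(0.0, sigma, size=m.shape)
    return DensityMap(noisy, m.voxel.copy(), m.origin.copy(), m.resolution)
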