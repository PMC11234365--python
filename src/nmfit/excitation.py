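"""Stochastic mode selection, combination, correlation-gated trial moves,
and kinetic excitation of velocities.

Each fitting cycle draws k modes from the low-frequency pool with
probability favouring softer modes (default p_i ∝ 1/λ_i), combines them
with uniform random coefficients α ∈ [-0.5, 0.5], mass-normalises the
combination Q (QᵀMQ = 1), and keeps it only if displacing the structure
along Q (either sign) raises the cross-correlation with the target map.
An accepted Q is then injected into the atomic velocities carrying exactly
Ek kcal/mol of kinetic energy: λ_exc = sqrt(2 Ek / QᵀMQ) in internal units,
v_tot = v_curr + λ_exc Q.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .density import cc_structure
from .units import KCAL_PER_AMU_A2_FS2

__all__ = ["ModeCombination", "mode_probabilities", "select_modes",
           "combine_modes", "trial_test", "excite_velocities"]

@dataclass
class ModeCombination:
    """A mass-normalised linear combination of selected modes, with the
    velocity vector that injects Ek kcal/mol of kinetic energy along it."""

    indices: np.ndarray
    alphas: np.ndarray
    Q: np.ndarray                # (N,3), QᵀMQ = 1
    lambda_exc: float | None = None
    Q_exct: np.ndarray | None = None  # (N,3) Å/fs
    Ek: float | None = None


def mode_probabilities(eigenvalues, law: str = "inverse") -> np.ndarray:
    """Selection probabilities over a candidate pool of eigenvalues.

    Default law p_i ∝ 1/λ_i: softer (lower-frequency) modes are favoured.
    Alternatives: 'inverse_sqrt' (p ∝ 1/sqrt(λ)), 'uniform'.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("all eigenvalues must be positive")
    if law == "inverse":
        w = 1.0 / lam
    elif law == "inverse_sqrt":
        w = 1.0 / np.sqrt(lam)
    elif law == "uniform":
        w = np.ones_like(lam)
    else:
        raise ValueError(f"unknown selection law {law!r}")
    return w / w.sum()


def select_modes(ms, k: int, pool_fraction: float, rng: np.random.Generator,
                 law: str = "inverse") -> np.ndarray:
    """Sample k distinct mode indices from the low-frequency pool.

    The pool is the bottom max(k, ceil(pool_fraction * K)) modes of the
    spectrum; sampling is without replacement with probabilities from
    ``mode_probabilities`` restricted to the pool.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    pool = max(k, int(np.ceil(pool_fraction * ms.n_modes)))
    pool = min(pool, ms.n_modes)
    if k > pool:
        raise ValueError("k exceeds the mode pool")
    p = mode_probabilities(ms.eigenvalues[:pool], law=law)
    return np.sort(rng.choice(pool, size=k, replace=False, p=p))


def _mass_normalize(Q: np.ndarray, masses: np.ndarray) -> np.ndarray:
    norm2 = float(np.sum(masses[:, None] * Q * Q))
    if norm2 <= 0:
        raise ValueError("zero combination cannot be normalised")
    return Q / np.sqrt(norm2)


def combine_modes(ms, indices, alphas=None, rng: np.random.Generator | None = None,
                  max_resample: int = 100) -> ModeCombination:
    """Linearly combine the selected modes with coefficients α ∈ [-0.5, 0.5]
    (drawn uniformly when not supplied) and mass-normalise: QᵀMQ = 1."""
    indices = np.asarray(indices, dtype=int)
    if alphas is None:
        if rng is None:
            raise ValueError("need an rng to draw alphas")
        for _ in range(max_resample):
            alphas = rng.uniform(-0.5, 0.5, size=indices.size)
            if np.any(alphas != 0.0):
                break
    alphas = np.asarray(alphas, dtype=float)
    if alphas.shape != indices.shape:
        raise ValueError("indices/alphas length mismatch")
    if np.all(alphas == 0.0):
        raise ValueError("all-zero coefficients")
    if np.any(np.abs(alphas) > 0.5):
        raise ValueError("coefficients must lie in [-0.5, 0.5]")
    Q = np.tensordot(alphas, ms.modes[indices], axes=(0, 0))
    Q = _mass_normalize(Q, ms.masses)
    return ModeCombination(indices=indices, alphas=alphas, Q=Q)


def trial_test(s, Q: np.ndarray, amplitude: float, tm, resolution: float,
               cc_ref: float, threshold: float = 0.0,
               convention: str = "fwhm"):
    """Correlation gate on a candidate displacement direction.

    The structure is displaced along Q so that the mass-weighted RMS
    displacement equals ``amplitude`` Å, and the move is accepted iff the
    cross-correlation with the target map improves (Δc.c > 0). Both signs
    of Q are tried (the coefficient sign is arbitrary); on acceptance the
    productive signed Q is returned.

    Returns ``(accept, dcc, trial_structure, Q_signed)``.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    scale = amplitude * np.sqrt(s.masses.sum())  # QᵀMQ=1 ⇒ mwRMS = scale/√M
    best = (False, 0.0, s, Q)
    for sign in (1.0, -1.0):
        trial = s.with_coords(s.coords + sign * scale * Q)
        dcc = cc_structure(trial, tm, resolution, threshold=threshold,
                           convention=convention) - cc_ref
        if dcc > best[1]:
            best = (True, dcc, trial, sign * Q)
    return best


def excite_velocities(Q: np.ndarray, masses: np.ndarray, Ek: float,
                      v_curr: np.ndarray):
    """Scale Q so it carries exactly Ek kcal/mol of kinetic energy and add
    it to the current velocities.

    λ_exc = sqrt(2 Ek / (c QᵀMQ)) with c the amu·Å²/fs² → kcal/mol
    conversion; returns ``(combination-updated λ_exc, Q_exct, v_tot)``.
    """
    if Ek <= 0:
        raise ValueError("excitation energy must be positive")
    Q = np.asarray(Q, dtype=float)
    masses = np.asarray(masses, dtype=float)
    qmq = float(np.sum(masses[:, None] * Q * Q))
    if not np.isfinite(qmq) or qmq <= 0:
        raise ValueError("Q must have positive mass-weighted norm")
    lam = np.sqrt(2.0 * Ek / (KCAL_PER_AMU_A2_FS2 * qmq))
    Q_exct = lam * Q
    v_tot = np.asarray(v_curr, dtype=float) + Q_exct
    return lam, Q_exct, v_tot
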