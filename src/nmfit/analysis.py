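"""Ensemble and convergence analysis.

Covers the evaluation toolkit used around the fitting runs: principal
component analysis of conformational ensembles (covariance of Cα
displacements from the ensemble mean after iterative superposition),
projection of trajectories onto those components, an exact binomial
(Clopper-Pearson) success-rate comparison between two methods, and
per-cycle convergence summaries across replicas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model_io import _kabsch, select_ca

__all__ = ["EnsemblePCA", "pca_ensemble", "project", "success_test",
           "convergence_report"]


@dataclass
class EnsemblePCA:
    """PCA of an aligned conformational ensemble.

    ``components[k]`` is a (3n,) unit eigenvector of the positional
    covariance matrix C_ij = <Δr_i Δr_j>; eigenvalues are in Å² and sorted
    descending. ``mean`` is the aligned ensemble average (n, 3) used as
    the projection reference frame.
    """

    mean: np.ndarray
    components: np.ndarray       # (K, 3n)
    eigenvalues: np.ndarray      # (K,)
    variance_fraction: np.ndarray
    selection: np.ndarray

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


def _superpose_onto(coords: np.ndarray, ref: np.ndarray) -> np.ndarray:
    R, t = _kabsch(coords, ref)
    return coords @ R.T + t


def pca_ensemble(structures, sel=None, n_components: int | None = None
                 ) -> EnsemblePCA:
    """Principal components of an ensemble of conformations.

    All members are superposed onto the first, then twice onto the running
    mean (two-pass mean-structure alignment, deterministic), before the
    covariance of the selected coordinates (default: Cα) is diagonalised.
    """
    if len(structures) < 3:
        raise ValueError("need at least 3 structures for PCA")
    if sel is None:
        sel = select_ca(structures[0])
    sel = np.asarray(sel, dtype=int)
    X = np.stack([np.asarray(s.coords, dtype=float)[sel]
                  if hasattr(s, "coords") else np.asarray(s)[sel]
                  for s in structures])
    X = np.stack([_superpose_onto(x, X[0]) for x in X])
    for _ in range(2):
        mean = X.mean(axis=0)
        X = np.stack([_superpose_onto(x, mean) for x in X])
    mean = X.mean(axis=0)
    D = (X - mean).reshape(len(X), -1)
    C = D.T @ D / len(X)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.maximum(evals[order], 0.0), evecs[:, order]
    total = evals.sum()
    frac = evals / total if total > 0 else np.zeros_like(evals)
    if n_components is not None:
        evals = evals[:n_components]
        evecs = evecs[:, :n_components]
        frac = frac[:n_components]
    return EnsemblePCA(mean=mean, components=evecs.T, eigenvalues=evals,
                       variance_fraction=frac, selection=sel)


def project(pca: EnsemblePCA, structures, sel=None) -> np.ndarray:
    """Project conformations onto the principal components.

    Each structure is superposed onto the PCA mean frame first, so the
    scores are invariant to rigid motion of the inputs. Returns an
    (n_structures, n_components) array in Å.
    """
    sel = pca.selection if sel is None else np.asarray(sel, dtype=int)
    out = []
    for s in structures:
        coords = (s.coords if hasattr(s, "coords") else np.asarray(s))[sel]
        aligned = _superpose_onto(coords, pca.mean)
        out.append(pca.components @ (aligned - pca.mean).ravel())
    return np.asarray(out)


def success_test(final_rmsds_a, final_rmsds_b, threshold: float = 5.0) -> dict:
    """Success-rate comparison between two sets of replica outcomes.

    A run succeeds when its final RMSD is below ``threshold`` Å. Reports
    per-method success counts, proportions, exact (Clopper-Pearson) 95%
    confidence intervals, a two-sided Fisher exact p-value for the 2x2
    table, and per-method one-sample binomial tests against p = 0.5.
    """
    a = np.asarray(final_rmsds_a, dtype=float)
    b = np.asarray(final_rmsds_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both replica sets must be non-empty")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    ka, kb = int((a < threshold).sum()), int((b < threshold).sum())
    na, nb = a.size, b.size
    ci_a = _clopper_pearson(ka, na)
    ci_b = _clopper_pearson(kb, nb)
    _, fisher_p = stats.fisher_exact([[ka, na - ka], [kb, nb - kb]],
                                     alternative="two-sided")
    return {
        "n": (na, nb), "successes": (ka, kb),
        "proportions": (ka / na, kb / nb),
        "ci95": (ci_a, ci_b),
        "fisher_p": float(fisher_p),
        "binom_p": (float(stats.binomtest(ka, na, 0.5).pvalue),
                    float(stats.binomtest(kb, nb, 0.5).pvalue)),
    }


def _clopper_pearson(k: int, n: int, alpha: float = 0.05):
    """Exact binomial confidence interval via beta quantiles."""
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return (lo, hi)


def convergence_report(trajectories, pad: bool = False) -> pd.DataFrame:
    """Per-cycle mean ± SD of RMSD and c.c across replicas.

    Replicas of unequal length are truncated to the shortest by default;
    with ``pad=True`` shorter replicas are padded by their last row
    (documented flag, mirrors how converged runs hold their final state).
    """
    frames = [t.to_dataframe() if hasattr(t, "to_dataframe") else t
              for t in trajectories]
    if not frames:
        raise ValueError("no trajectories given")
    lengths = [len(f) for f in frames]
    n = max(lengths) if pad else min(lengths)
    cols = {}
    for key in ("cc_ref", "rmsd_target"):
        mat = []
        for f in frames:
            v = f[key].to_numpy(dtype=float)
            if pad and v.size < n:
                v = np.concatenate([v, np.full(n - v.size, v[-1])])
            mat.append(v[:n])
        mat = np.stack(mat)
        cols[f"{key}_mean"] = mat.mean(axis=0)
        cols[f"{key}_sd"] = mat.std(axis=0, ddof=0)
    out = pd.DataFrame({"cycle": np.arange(1, n + 1), **cols})
    out.attrs["cycles_to_convergence"] = lengths
    return out
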