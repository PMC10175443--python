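"""Rarefaction, alpha diversity, Bray-Curtis dissimilarity and PCoA.

Alpha metrics follow the usual ecological definitions: Shannon entropy in
natural log, the bias-corrected Chao1 richness estimator
``S_obs + F1*(F1-1) / (2*(F2+1))`` (well-defined even without doubletons),
and the observed-feature count.  Beta diversity is Bray-Curtis,
``sum |x_i - y_i| / sum (x_i + y_i)``.  Ordination is classical principal
coordinates: Gower-center ``-D**2 / 2``, eigendecompose, scale eigenvectors
by sqrt(eigenvalue).  Negative eigenvalues (non-Euclidean input) are dropped
from the reported axes and excluded from the proportion-explained
denominator; the signed squared distances they carry are still used by the
dispersion test, which imports the full embedding from here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix

_EIG_TOL = 1e-10


class DiversityError(ValueError):
    pass


# --------------------------------------------------------------------------
# rarefaction
# --------------------------------------------------------------------------

def rarefy(
    counts: pd.DataFrame, depth: int | None = None, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Subsample every sample column to a common depth without replacement.

    ``depth`` defaults to the smallest sample total.  Deterministic given the
    generator's seed.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise DiversityError("rarefaction needs integer counts")
        arr = np.round(arr).astype(np.int64)
    totals = arr.sum(axis=0)
    if depth is None:
        depth = int(totals.min())
    if depth <= 0:
        raise DiversityError("rarefaction depth must be > 0")
    short = np.flatnonzero(totals < depth)
    if short.size:
        bad = counts.columns[short[0]]
        raise DiversityError(
            f"sample {bad!r} has {totals[short[0]]} counts, fewer than depth {depth}"
        )
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        out[:, j] = rng.multivariate_hypergeometric(arr[:, j], depth)
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


# --------------------------------------------------------------------------
# alpha diversity
# --------------------------------------------------------------------------

def alpha_diversity(vector, metric: str, base: float | None = None) -> float:
    """One alpha-diversity value for one sample.

    metric: ``shannon`` (natural log by default; pass ``base=2`` for log2),
    ``chao1`` (bias-corrected) or ``observed``.
    """
    x = np.asarray(vector, dtype=float)
    if (x < 0).any():
        raise DiversityError("negative abundances")
    if x.sum() == 0:
        raise DiversityError("all-zero vector has no diversity")
    if metric == "shannon":
        p = x / x.sum()
        p = p[p > 0]
        h = float(-(p * np.log(p)).sum())
        return h / np.log(base) if base else h
    if metric == "chao1":
        obs = int((x > 0).sum())
        f1 = int((x == 1).sum())
        f2 = int((x == 2).sum())
        return obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    if metric == "observed":
        return float((x > 0).sum())
    raise DiversityError(f"unknown alpha metric {metric!r}")


def alpha_diversity_frame(
    counts: pd.DataFrame, metrics=("shannon", "chao1", "observed")
) -> pd.DataFrame:
    """Samples x metrics table of alpha diversities from a count table."""
    return pd.DataFrame(
        {m: {s: alpha_diversity(counts[s], m) for s in counts.columns} for m in metrics}
    )


# --------------------------------------------------------------------------
# Bray-Curtis
# --------------------------------------------------------------------------

def bray_curtis_matrix(table: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Bray-Curtis between sample columns of an abundance table."""
    X = table.to_numpy(dtype=float).T
    if (X < 0).any():
        raise DiversityError("negative abundances")
    zero = X.sum(axis=1) == 0
    if zero.sum() >= 2:
        bad = list(table.columns[zero])
        raise DiversityError(f"Bray-Curtis undefined between all-zero samples: {bad}")
    # explicit formula keeps the all-zero-vs-nonzero pair defined (distance 1)
    num = np.abs(X[:, None, :] - X[None, :, :]).sum(axis=2)
    den = (X[:, None, :] + X[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=[str(c) for c in table.columns])


# --------------------------------------------------------------------------
# PCoA
# --------------------------------------------------------------------------

@dataclass
class PcoaResult:
    """Principal-coordinates embedding on the positive-eigenvalue axes."""

    coordinates: pd.DataFrame      # samples x PC1..PCk
    eigenvalues: np.ndarray        # positive eigenvalues, descending
    proportion_explained: np.ndarray


def _gower_eig(D: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of the Gower-centered matrix, descending order."""
    A = -0.5 * D.astype(float) ** 2
    n = A.shape[0]
    row = A.mean(axis=1, keepdims=True)
    col = A.mean(axis=0, keepdims=True)
    G = A - row - col + A.mean()
    vals, vecs = np.linalg.eigh(G)
    order = np.argsort(vals)[::-1]
    return vals[order], vecs[:, order]


def full_embedding(D: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(pos_coords, pos_eigvals, neg_coords, neg_eigvals) of a distance matrix.

    Coordinates are eigenvectors scaled by sqrt(|eigenvalue|); the negative
    axes are the imaginary part of the embedding of a non-Euclidean matrix
    and are needed for Anderson-corrected dispersion distances.
    """
    vals, vecs = _gower_eig(D)
    scale = max(1.0, float(np.abs(vals).max(initial=1.0)))
    pos = vals > _EIG_TOL * scale
    neg = vals < -_EIG_TOL * scale
    pos_coords = vecs[:, pos] * np.sqrt(vals[pos])
    neg_coords = vecs[:, neg] * np.sqrt(-vals[neg])
    return pos_coords, vals[pos], neg_coords, -vals[neg]


def pcoa(D: DistanceMatrix | np.ndarray, n_axes: int | None = None) -> PcoaResult:
    """Classical PCoA keeping only positive-eigenvalue axes.

    Proportion explained is eigenvalue / sum of positive eigenvalues.  On a
    matrix of Euclidean distances the pairwise distances among the returned
    coordinates reproduce the input.
    """
    if isinstance(D, DistanceMatrix):
        ids = list(D.ids)
        mat = D.data
    else:
        mat = np.asarray(D, dtype=float)
        if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
            raise DiversityError("distance matrix must be square")
        if not np.allclose(mat, mat.T):
            raise DiversityError("distance matrix must be symmetric")
        ids = [f"s{i}" for i in range(mat.shape[0])]
    coords, vals, _, _ = full_embedding(mat)
    if n_axes is not None:
        coords = coords[:, :n_axes]
        vals_kept = vals[:n_axes]
    else:
        vals_kept = vals
    total = vals.sum()
    props = vals_kept / total if total > 0 else np.zeros_like(vals_kept)
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return PcoaResult(
        coordinates=pd.DataFrame(coords, index=ids, columns=cols),
        eigenvalues=vals_kept,
        proportion_explained=props,
    )
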