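"""PCA-initialized batch-learning self-organizing map (BLSOM).

A BLSOM is an order-independent variant of Kohonen's SOM.  Weights are laid
out on a rectangular I x J lattice inside the plane spanned by the first two
principal axes of the data:

    w_ij = x_av + (5 sigma1 / I) * [ b1 (i - I/2) + b2 (j - J/2) ]

where x_av is the mean input vector, b1/b2 the first two (orthonormal)
principal eigenvectors and sigma1 the SD of PC1 scores, so the lattice's
first dimension spans about five SDs of the widest axis of the data cloud.
Training is fully batch: each epoch assigns every vector to its
best-matching node (minimal Euclidean distance) and replaces each node
weight by the mean of all vectors assigned within a square (Chebyshev)
neighborhood whose integer radius shrinks linearly to 1.  No step depends
on the order of the input rows.

Bitwise order-independence
--------------------------
Floating-point summation is not associative, so naive batch updates would
differ in the last bits under row permutation.  All reductions here (mean,
covariance, per-node batch sums) are therefore computed over an internal
canonical ordering of the rows (lexicographic sort), which depends only on
the *multiset* of input vectors: permuting the rows yields a bit-identical
trained map.  Eigenvector signs are fixed by forcing the largest-magnitude
component positive, so maps are reproducible across runs.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist


def size_grid(n_sequences: int, avg_per_node: int, sigma1: float, sigma2: float):
    """Lattice dimensions (I, J) for a target node budget.

    The node budget is B = round(n_sequences / avg_per_node); I is chosen so
    that I*J is close to B with the aspect ratio J/I = sigma2/sigma1, i.e.
    I = round(sqrt(B * sigma1/sigma2)), and J is the nearest integer greater
    than (sigma2/sigma1) * I.  Both are clipped to >= 2.
    """
    if not (n_sequences >= avg_per_node >= 1):
        raise ValueError("need n_sequences >= avg_per_node >= 1")
    B = max(1, round(n_sequences / avg_per_node))
    if sigma2 <= 0 or not np.isfinite(sigma2):
        warnings.warn("sigma2 is degenerate (<= 0); forcing J = 2")
        J = 2
        I = max(2, math.ceil(B / J))
        return I, J
    ratio = sigma2 / sigma1
    I = max(2, round(math.sqrt(B / ratio)))
    J = max(2, math.ceil(ratio * I))
    return I, J


def default_schedule(I: int, J: int, min_epochs: int = 8) -> list:
    """Linearly shrinking integer radii, max(I,J)/2 down to 1.

    One epoch per radius value; small grids are padded to ``min_epochs``
    epochs so the learning-rate schedule has room to anneal.
    """
    r0 = max(1, round(max(I, J) / 2))
    n = max(r0, min_epochs)
    return [int(r) for r in np.rint(np.linspace(r0, 1, n))] + [1, 1]


@dataclass
class BLSOMGrid:
    """A trained or initialized I x J lattice of weight vectors."""

    I: int
    J: int
    weights: np.ndarray  # (I*J, D), node (i, j) at row i*J + j
    group_labels: list
    x_av: np.ndarray
    b1: np.ndarray
    b2: np.ndarray
    sigma1: float
    sigma2: float
    radius_schedule: list
    epochs_trained: int = 0
    qe_history: list = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.I * self.J

    def node_index(self, i: int, j: int) -> int:
        return i * self.J + j

    def weights_lattice(self) -> np.ndarray:
        """Weights reshaped to (I, J, D)."""
        return self.weights.reshape(self.I, self.J, -1)


@dataclass
class NodeAssignment:
    """Best-matching-node assignment of every window to a lattice node.

    ``frame`` carries one row per window with at least the columns
    window_id, record_id, species, i, j.
    """

    I: int
    J: int
    frame: pd.DataFrame

    def species_counts(self) -> pd.DataFrame:
        """Per-node species tallies, indexed by all (i, j) incl. empty nodes."""
        tab = self.frame.groupby(["i", "j", "species"]).size().unstack(fill_value=0)
        full = pd.MultiIndex.from_product(
            [range(self.I), range(self.J)], names=["i", "j"]
        )
        return tab.reindex(full, fill_value=0)

    def members(self, i: int, j: int) -> pd.DataFrame:
        return self.frame[(self.frame["i"] == i) & (self.frame["j"] == j)]


def _check_data(X: np.ndarray) -> np.ndarray:
    X = np.ascontiguousarray(np.asarray(X, dtype=np.float64))
    if X.ndim != 2:
        raise ValueError("data must be a 2-D matrix (windows x groups)")
    if np.isnan(X).any():
        raise ValueError("data contains NaN")
    return X

def _canonical_order(X: np.ndarray) -> np.ndarray:
    # lexsort: last key is primary -> make column 0 the primary key
    return np.lexsort(X.T[::-1])


def _fix_sign(v: np.ndarray) -> np.ndarray:
    return -v if v[np.argmax(np.abs(v))] < 0 else v


def pca_init(
    X,
    group_labels=None,
    avg_per_node: int = 10,
    I: int | None = None,
    J: int | None = None,
) -> BLSOMGrid:
    """Initialize a lattice on the PC1/PC2 plane of the data.

    PCA is computed on the covariance matrix of the input frequency matrix.
    If I, J are not given they are derived from :func:`size_grid` with the
    target of ``avg_per_node`` sequences per node.
    """
    X = _check_data(X)
    if np.unique(X, axis=0).shape[0] < 3:
        raise ValueError("need at least 3 distinct data vectors for PCA initialization")
    Xs = X[_canonical_order(X)]
    x_av = Xs.mean(axis=0)
    C = np.cov(Xs, rowvar=False)
    evals, evecs = np.linalg.eigh(C)
    lam1, lam2 = float(evals[-1]), float(evals[-2])
    if lam1 <= 0:
        raise ValueError("rank-deficient data: no principal axis")
    b1 = _fix_sign(evecs[:, -1].copy())
    b2 = _fix_sign(evecs[:, -2].copy())
    sigma1 = math.sqrt(max(lam1, 0.0))
    sigma2 = math.sqrt(max(lam2, 0.0))
    if I is None or J is None:
        I, J = size_grid(X.shape[0], avg_per_node, sigma1, sigma2)
    ii, jj = np.meshgrid(np.arange(I), np.arange(J), indexing="ij")
    scale = 5.0 * sigma1 / I
    offsets = (
        np.multiply.outer((ii - I / 2.0), b1) + np.multiply.outer((jj - J / 2.0), b2)
    )
    weights = (x_av + scale * offsets).reshape(I * J, -1)
    if group_labels is None:
        group_labels = [f"g{d}" for d in range(X.shape[1])]
    return BLSOMGrid(
        I=I, J=J, weights=weights, group_labels=list(group_labels),
        x_av=x_av, b1=b1, b2=b2, sigma1=sigma1, sigma2=sigma2,
        radius_schedule=default_schedule(I, J),
    )


def _box_sum(A: np.ndarray, r: int) -> np.ndarray:
    """Sum of A over the (2r+1)-square Chebyshev ball, clipped at edges."""
    I, J = A.shape[:2]
    P = np.zeros((I + 1, J + 1) + A.shape[2:], dtype=A.dtype)
    P[1:, 1:] = A.cumsum(axis=0).cumsum(axis=1)
    i0 = np.clip(np.arange(I) - r, 0, None)
    i1 = np.clip(np.arange(I) + r + 1, None, I)
    j0 = np.clip(np.arange(J) - r, 0, None)
    j1 = np.clip(np.arange(J) + r + 1, None, J)
    return (
        P[np.ix_(i1, j1)] - P[np.ix_(i0, j1)] - P[np.ix_(i1, j0)] + P[np.ix_(i0, j0)]
    )


def _bmu(weights: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Row-major argmin distance; ties break to the smallest (i, then j)."""
    d2 = cdist(X, weights, metric="sqeuclidean")
    return d2.argmin(axis=1)


def train(grid: BLSOMGrid, X, epochs: int | None = None) -> BLSOMGrid:
    """Batch-train a grid; returns a new grid, the input is untouched.

    Per epoch: (1) every vector is assigned to its best-matching node;
    (2) each node weight moves toward the mean of all vectors assigned
    within the epoch's Chebyshev radius,

        w <- w + alpha_r * (neighborhood mean - w),

    with alpha_r = 0.5 while the radius exceeds 1 and alpha_r = 1 (full
    mean replacement) at radius 1; nodes with an empty neighborhood keep
    their previous weight.  Blending during the wide-radius phase keeps the
    PCA scaffold alive, so tightly clustered data spread over a lattice
    region instead of collapsing onto a single node of an exactly-constant
    weight plateau; replacement at radius 1 is the usual batch-SOM endgame
    and lets nodes settle onto the local data.  Both are order-independent
    since the neighborhood mean is a batch quantity.  With ``epochs=None``
    the grid's radius schedule is used as-is (one epoch per radius);
    otherwise the schedule is resampled linearly onto ``epochs`` epochs
    (plus two radius-1 refinements).  ``epochs=0`` is the identity.
    """
    X = _check_data(X)
    if X.shape[1] != grid.weights.shape[1]:
        raise ValueError(
            f"dimension mismatch: data has {X.shape[1]} groups, "
            f"grid has {grid.weights.shape[1]}"
        )
    if epochs is None:
        radii = list(grid.radius_schedule)
    elif epochs == 0:
        return replace(grid, weights=grid.weights.copy(),
                       qe_history=list(grid.qe_history))
    else:
        r0 = grid.radius_schedule[0] if grid.radius_schedule else 1
        radii = [int(r) for r in np.rint(np.linspace(r0, 1, epochs))] + [1, 1]

    Xs = X[_canonical_order(X)]
    I, J, D = grid.I, grid.J, X.shape[1]
    W = grid.weights.copy()
    qe = list(grid.qe_history)
    for r in radii:
        alpha = 0.5
        d2 = cdist(Xs, W, metric="sqeuclidean")
        bmu = d2.argmin(axis=1)
        qe.append(float(np.sqrt(d2[np.arange(len(Xs)), bmu]).mean()))
        counts = np.bincount(bmu, minlength=I * J).astype(np.float64)
        sums = np.zeros((I * J, D))
        order = np.argsort(bmu, kind="stable")
        sb = bmu[order]
        starts = np.flatnonzero(np.r_[True, sb[1:] != sb[:-1]])
        sums[sb[starts]] = np.add.reduceat(Xs[order], starts, axis=0)
        box_s = _box_sum(sums.reshape(I, J, D), int(r))
        box_c = _box_sum(counts.reshape(I, J), int(r))
        newW = W.reshape(I, J, D).copy()
        occupied = box_c > 0
        target = box_s[occupied] / box_c[occupied, None]
        newW[occupied] += alpha * (target - newW[occupied])
        W = newW.reshape(I * J, D)
    return replace(
        grid, weights=W, epochs_trained=grid.epochs_trained + len(radii),
        qe_history=qe,
    )


def assign(grid: BLSOMGrid, X, meta: pd.DataFrame | None = None) -> NodeAssignment:
    """Map every vector to its best-matching node.

    ``meta`` rows (window_id, record_id, species, ...) are carried through
    in the caller's order; ties break to the smallest (i, then j).
    """
    X = _check_data(X)
    if X.shape[1] != grid.weights.shape[1]:
        raise ValueError("dimension mismatch between data and grid weights")
    bmu = _bmu(grid.weights, X)
    if meta is None:
        meta = pd.DataFrame({
            "window_id": [f"w{n}" for n in range(len(X))],
            "record_id": "?", "species": "?",
        })
    frame = meta.reset_index(drop=True).copy()
    frame["i"] = bmu // grid.J
    frame["j"] = bmu % grid.J
    return NodeAssignment(I=grid.I, J=grid.J, frame=frame)


def quantization_error(grid: BLSOMGrid, X) -> float:
    """Mean Euclidean distance of vectors to their best-matching node."""
    X = _check_data(X)
    d2 = cdist(X, grid.weights, metric="sqeuclidean")
    return float(np.sqrt(d2.min(axis=1)).mean())


def save_grid(grid: BLSOMGrid, path) -> None:
    """Serialize a grid to a single JSON bundle (text, documented keys)."""
    payload = {
        "I": grid.I,
        "J": grid.J,
        "group_labels": list(grid.group_labels),
        "x_av": grid.x_av.tolist(),
        "b1": grid.b1.tolist(),
        "b2": grid.b2.tolist(),
        "sigma1": grid.sigma1,
        "sigma2": grid.sigma2,
        "radius_schedule": list(map(int, grid.radius_schedule)),
        "epochs_trained": grid.epochs_trained,
        "qe_history": grid.qe_history,
        "weights": grid.weights.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_grid(path) -> BLSOMGrid:
    with open(path) as fh:
        p = json.load(fh)
    return BLSOMGrid(
        I=p["I"], J=p["J"], weights=np.asarray(p["weights"], dtype=np.float64),
        group_labels=p["group_labels"], x_av=np.asarray(p["x_av"]),
        b1=np.asarray(p["b1"]), b2=np.asarray(p["b2"]),
        sigma1=p["sigma1"], sigma2=p["sigma2"],
        radius_schedule=p["radius_schedule"],
        epochs_trained=p["epochs_trained"], qe_history=p["qe_history"],
    )
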