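"""Mean-centered PCA and non-negative matrix factorization of unfolded spectra.

PCA is the standard mean-centered singular-value decomposition (delegated to
scikit-learn); NNMF factorizes the non-negative matrix X (samples x RD) into
non-negative scores W (S x k) and loadings H (k x RD) minimizing the
root-mean-square residual

    D = sqrt(mean((X - W H)^2)),

by alternating exact non-negative least squares from several seeded random
initializations; the restart with the lowest residual wins (ties broken by
the earliest restart).  Because each half-step solves its subproblem exactly,
the residual is non-increasing over iterations.

Each NNLS half-step shares one small design matrix (k columns, k <= ~12)
across tens of thousands of right-hand sides, so it is solved by enumerating
all non-empty active sets: for every support the normal equations are solved
batched over columns, and among the feasible (non-negative) candidates the
one with the lowest residual is exact NNLS.

Loadings rows refold onto the retention x drift grid ("back-projection"),
giving a pseudo-spectrum characteristic of one sample group.  Unseen samples
are projected onto a fitted model: linearly for PCA, by per-row NNLS against
the fixed H for NNMF (the factorization's scores are only defined up to a
per-component scale, so all component comparisons should use cosine
similarity).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.decomposition import PCA as _SKPCA

from .preprocess import AxisMap, UnfoldedMatrix, refold

__all__ = [
    "PCAModel",
    "NNMFModel",
    "pca_fit",
    "pca_project",
    "nnmf_fit",
    "nnmf_project",
    "backproject_component",
    "nnls_multi",
    "match_components",
    "component_class_assignment",
]


def _values(X) -> np.ndarray:
    if isinstance(X, UnfoldedMatrix):
        return X.values
    return np.asarray(X, dtype=float)


@dataclass
class PCAModel:
    """Mean-centered PCA result."""

    mean_vector: np.ndarray
    components: np.ndarray  # n x (R*D), orthonormal rows
    scores: np.ndarray      # S x n
    explained_variance_pct: np.ndarray

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


@dataclass
class NNMFModel:
    """Non-negative factorization X ~ W H with RMS residual D."""

    k: int
    W: np.ndarray
    H: np.ndarray
    residual: float
    seed: int
    n_iterations: int


def pca_fit(X, n_components: int) -> PCAModel:
    """Fit a mean-centered PCA with the leading ``n_components`` directions."""
    values = _values(X)
    s = values.shape[0]
    if s < 2:
        raise ValueError("PCA requires at least 2 samples")
    if n_components > min(s - 1, values.shape[1]):
        raise ValueError(
            f"n_components {n_components} exceeds min(S-1, R*D) = "
            f"{min(s - 1, values.shape[1])}"
        )
    pca = _SKPCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(values)
    return PCAModel(
        mean_vector=pca.mean_,
        components=pca.components_,
        scores=scores,
        explained_variance_pct=100.0 * pca.explained_variance_ratio_,
    )


def pca_project(model: PCAModel, X_new) -> np.ndarray:
    """Scores of unseen rows: (X_new - mean) @ components.T."""
    values = np.atleast_2d(_values(X_new))
    if values.shape[1] != model.mean_vector.size:
        raise ValueError(
            f"column count {values.shape[1]} does not match the model's "
            f"{model.mean_vector.size}"
        )
    return (values - model.mean_vector) @ model.components.T


def nnls_multi(
    A: np.ndarray, B: np.ndarray, X0: np.ndarray | None = None
) -> np.ndarray:
    """Exact NNLS ``min ||A x - b||, x >= 0`` for every column b of B.

    A is m x k with small k; B is m x n.  All 2^k - 1 non-empty supports are
    enumerated; for each, the normal equations are solved batched over all
    columns, every feasible (non-negative) candidate's quadratic objective
    ``0.5 x'A'Ax - x'A'b`` is evaluated explicitly, and the lowest wins (the
    zero solution is the always-feasible baseline).  Exact in exact
    arithmetic because the NNLS optimum solves the normal equations
    restricted to its own active set; evaluating the objective rather than
    trusting the solve keeps ill-conditioned supports honest.  ``X0``
    (k x n), if given, seeds the incumbent — the result is then never worse
    than ``X0``, which makes alternating minimization structurally monotone.
    """
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    k = A.shape[1]
    if k > 12:
        raise ValueError("active-set enumeration is limited to k <= 12")
    n = B.shape[1]
    ata = A.T @ A
    atb = A.T @ B  # k x n

    def objective(X: np.ndarray) -> np.ndarray:
        return 0.5 * np.einsum("ij,ij->j", X, ata @ X) - np.einsum(
            "ij,ij->j", X, atb
        )

    if X0 is not None:
        best_x = np.clip(np.asarray(X0, float), 0.0, None).copy()
        best_f = np.minimum(objective(best_x), 0.0)
        best_x[:, best_f == 0.0] = 0.0
    else:
        best_x = np.zeros((k, n))
        best_f = np.zeros(n)
    feas_tol = -1e-10
    for size in range(1, k + 1):
        for support in itertools.combinations(range(k), size):
            idx = list(support)
            sub = ata[np.ix_(idx, idx)]
            rhs = atb[idx, :]
            try:
                xs = np.linalg.solve(sub, rhs)
            except np.linalg.LinAlgError:
                xs = np.linalg.lstsq(sub, rhs, rcond=None)[0]
            feasible = (xs >= feas_tol).all(axis=0)
            if not feasible.any():
                continue
            f = 0.5 * np.einsum(
                "ij,ij->j", xs, sub @ xs
            ) - np.einsum("ij,ij->j", xs, rhs)
            better = feasible & (f < best_f)
            if better.any():
                best_f[better] = f[better]
                best_x[:, better] = 0.0
                best_x[np.ix_(idx, np.flatnonzero(better))] = xs[:, better]
    return np.clip(best_x, 0.0, None)


def _rms_residual(X: np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
    return float(np.sqrt(np.mean((X - W @ H) ** 2)))


def nnmf_fit(
    X,
    k: int,
    seed: int = 0,
    n_restarts: int = 5,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> NNMFModel:
    """Alternating exact-NNLS factorization, best of ``n_restarts`` restarts.

    W0 and H0 are seeded uniform random non-negative matrices scaled to the
    data magnitude.  Iterations stop when the relative residual change drops
    below ``tol``; the restart with the minimal RMS residual D is returned
    (ties: earliest restart).
    """
    values = _values(X)
    if (values < 0).any():
        raise ValueError("NNMF input must be non-negative")
    s, m = values.shape
    if not 1 <= k <= min(s, m):
        raise ValueError(f"k must satisfy 1 <= k <= min(S, R*D) = {min(s, m)}")
    scale = np.sqrt(max(values.mean(), np.finfo(float).tiny) / k)
    # roundoff floor for the monotonicity check: exact factorizations reach
    # residuals ~ eps * |X| where iteration-to-iteration noise dominates
    rms_floor = 1e-12 * float(np.sqrt(np.mean(values**2)) + 1.0)
    best: NNMFModel | None = None
    seeds = np.random.SeedSequence(seed).generate_state(n_restarts) % (2**31)
    for restart, restart_seed in enumerate(seeds):
        rng = np.random.default_rng(int(restart_seed))
        W = rng.uniform(0.0, 1.0, size=(s, k)) * scale
        H = rng.uniform(0.0, 1.0, size=(k, m)) * scale
        prev = _rms_residual(values, W, H)
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            H = nnls_multi(W, values, X0=H)
            W = nnls_multi(H.T, values.T, X0=W.T).T
            cur = _rms_residual(values, W, H)
            if cur > prev * (1.0 + 1e-9) + rms_floor:
                raise AssertionError(
                    "NNMF residual increased: alternating NNLS must be "
                    "monotone"
                )
            if prev - cur < tol * max(prev, np.finfo(float).tiny):
                prev = cur
                break
            prev = cur
        candidate = NNMFModel(
            k=k, W=W, H=H, residual=prev, seed=int(restart_seed),
            n_iterations=n_iter,
        )
        if best is None or candidate.residual < best.residual:
            best = candidate
    assert best is not None
    return best


def nnmf_project(model: NNMFModel, X_new) -> np.ndarray:
    """Non-negative scores of unseen rows: per-row NNLS against fixed H."""
    values = np.atleast_2d(_values(X_new))
    if values.shape[1] != model.H.shape[1]:
        raise ValueError(
            f"column count {values.shape[1]} does not match the model's "
            f"{model.H.shape[1]}"
        )
    return nnls_multi(model.H.T, values.T).T


def backproject_component(
    model: NNMFModel, j: int, axis_map: AxisMap
) -> np.ndarray:
    """Refold loading row ``j`` (0-based) into an R x D component spectrum."""
    if not 0 <= j < model.k:
        raise IndexError(f"component index {j} out of range 0..{model.k - 1}")
    return refold(model.H[j], axis_map)


def _cosine_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    an = A / np.maximum(np.linalg.norm(A, axis=1, keepdims=True), 1e-300)
    bn = B / np.maximum(np.linalg.norm(B, axis=1, keepdims=True), 1e-300)
    return an @ bn.T


def match_components(
    H: np.ndarray, patterns: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Best one-to-one assignment of components to reference patterns.

    Hungarian matching on cosine similarity between loading rows and
    (unfolded) reference patterns; returns (pattern index per component,
    cosine per component).  Cosine is used because NNMF components carry an
    arbitrary scale.
    """
    sim = _cosine_matrix(np.atleast_2d(H), np.atleast_2d(patterns))
    rows, cols = linear_sum_assignment(-sim)
    order = np.argsort(rows)
    return cols[order], sim[rows, cols][order]


def component_class_assignment(
    W: np.ndarray, labels: list[str]
) -> dict[str, int]:
    """Map each class label to the component with the highest mean score.

    One-to-one (Hungarian) on the class-mean score matrix; requires at least
    as many components as classes.
    """
    classes = sorted(set(labels))
    labels_arr = np.asarray(labels)
    means = np.stack(
        [W[labels_arr == c].mean(axis=0) for c in classes]
    )  # n_classes x k
    if W.shape[1] < len(classes):
        raise ValueError("need at least one component per class")
    rows, cols = linear_sum_assignment(-means)
    return {classes[r]: int(c) for r, c in zip(rows, cols)}
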