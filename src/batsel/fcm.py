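"""Fuzzy C-means clustering of gene expression profiles.

Each gene profile g_i (a row of the expression matrix) receives a graded
membership mu_ij in every cluster j, governed by the fuzzifier m > 1.  The
algorithm alternates the two stationarity conditions of the weighted
within-cluster sum of squares

    J_m(U, P) = sum_j sum_i mu_ij^m * ||g_i - p_j||_A^2

until the objective change falls below a tolerance.  With A = I (the
default, plain Euclidean norm) these are the classical updates

    mu_ij = 1 / sum_k (d_ij / d_ik)^(2/(m-1)),
    p_j   = sum_i mu_ij^m g_i / sum_i mu_ij^m.

As m -> 1+ memberships harden to 0/1; large m drives them toward 1/c.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ExpressionMatrix

__all__ = [
    "FuzzyPartition",
    "membership_update",
    "prototype_update",
    "fcm_objective",
    "fcm_fit",
]


def _as_profiles(X) -> np.ndarray:
    """Gene profiles as an (N, d) array: rows are data items."""
    if isinstance(X, ExpressionMatrix):
        if X.missing_mask.any():
            raise ValueError("expression matrix has missing values; impute first")
        return X.values
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X


def _sq_dists(G: np.ndarray, P: np.ndarray, A: np.ndarray | None) -> np.ndarray:
    """Squared A-norm distances, shape (c, N)."""
    diffs = P[:, None, :] - G[None, :, :]  # (c, N, d)
    if A is None:
        return np.einsum("cnd,cnd->cn", diffs, diffs)
    return np.einsum("cnd,de,cne->cn", diffs, A, diffs)


@dataclass
class FuzzyPartition:
    """Result of a fuzzy C-means fit.

    U is the clusters x genes membership matrix (columns sum to 1), P the
    cluster prototypes, J_trace the objective value after each iteration.
    """

    U: np.ndarray
    P: np.ndarray
    c: int
    N: int
    m: float
    J_trace: list[float] = field(default_factory=list)
    gene_ids: list[str] | None = None
    seed: int | None = None

    @property
    def hard_labels(self) -> np.ndarray:
        """Hard assignment per gene: argmax membership (ties -> lowest cluster)."""
        return self.U.argmax(axis=0)

    def to_tsv(self, path) -> None:
        ids = self.gene_ids or [f"g{i}" for i in range(self.N)]
        hard = self.hard_labels
        with open(path, "w", encoding="utf-8") as fh:
            head = "\t".join(f"mu_{j}" for j in range(self.c))
            fh.write(f"gene_id\t{head}\thard_label\n")
            for i, gid in enumerate(ids):
                mus = "\t".join(repr(float(v)) for v in self.U[:, i])
                fh.write(f"{gid}\t{mus}\t{hard[i]}\n")


def membership_update(
    X, P: np.ndarray, m: float = 2.0, A: np.ndarray | None = None
) -> np.ndarray:
    """Memberships given prototypes: the FCM stationarity condition.

    Genes coinciding with one or more prototypes get membership split
    equally among the coincident prototypes (the zero-distance
    singularity).
    """
    if m <= 1:
        raise ValueError(f"fuzzifier m must be > 1, got {m}")
    G = _as_profiles(X)
    P = np.atleast_2d(np.asarray(P, dtype=float))
    d2 = _sq_dists(G, P, A)  # (c, N)
    U = np.zeros_like(d2)
    zero = d2 <= 0
    has_zero = zero.any(axis=0)
    cols = ~has_zero
    # log-domain weights keep the update stable for m close to 1, where
    # d2 ** (-1/(m-1)) overflows
    with np.errstate(divide="ignore"):
        logw = -np.log(d2[:, cols]) / (m - 1.0)
    logw -= logw.max(axis=0, keepdims=True)
    w = np.exp(logw)
    U[:, cols] = w / w.sum(axis=0, keepdims=True)
    for j in np.flatnonzero(has_zero):
        hits = zero[:, j]
        U[hits, j] = 1.0 / hits.sum()
    return U


def prototype_update(X, U: np.ndarray, m: float = 2.0) -> np.ndarray:
    """Prototypes given memberships: the mu^m-weighted means."""
    if m <= 1:
        raise ValueError(f"fuzzifier m must be > 1, got {m}")
    G = _as_profiles(X)
    W = np.asarray(U, dtype=float) ** m  # (c, N)
    totals = W.sum(axis=1)
    if (totals <= 0).any():
        bad = int(np.flatnonzero(totals <= 0)[0])
        raise ValueError(f"cluster {bad} has zero total membership")
    return (W @ G) / totals[:, None]


def fcm_objective(X, U: np.ndarray, P: np.ndarray, m: float = 2.0,
                  A: np.ndarray | None = None) -> float:
    """Weighted within-cluster sum of squared A-norm errors."""
    G = _as_profiles(X)
    P = np.atleast_2d(np.asarray(P, dtype=float))
    d2 = _sq_dists(G, P, A)
    return float((np.asarray(U, dtype=float) ** m * d2).sum())


def fcm_fit(
    X,
    c: int,
    m: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 300,
    seed: int = 0,
    A: np.ndarray | None = None,
) -> FuzzyPartition:
    """Alternate membership/prototype updates from a seeded random start.

    Initial memberships are uniform random columns normalised to 1.  Stops
    when the objective change drops below ``tol`` or after ``max_iter``
    iterations; the recorded J_trace is non-increasing.
    """
    if m <= 1:
        raise ValueError(f"fuzzifier m must be > 1, got {m}")
    if tol <= 0:
        raise ValueError("tol must be positive")
    G = _as_profiles(X)
    N = G.shape[0]
    if not 2 <= c < N:
        raise ValueError(f"need 2 <= c < n_genes, got c={c}, n_genes={N}")
    rng = np.random.default_rng(seed)
    U = rng.random((c, N))
    U /= U.sum(axis=0, keepdims=True)

    trace: list[float] = []
    prev = np.inf
    for _ in range(max_iter):
        P = prototype_update(G, U, m)
        U = membership_update(G, P, m, A)
        J = fcm_objective(G, U, P, m, A)
        trace.append(J)
        if abs(prev - J) < tol:
            break
        prev = J

    gene_ids = X.gene_ids if isinstance(X, ExpressionMatrix) else None
    return FuzzyPartition(U=U, P=P, c=c, N=N, m=m, J_trace=trace,
                          gene_ids=gene_ids, seed=seed)
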