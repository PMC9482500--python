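"""Coexpression-module detection: dendrogram cuts refined by PAM.

The dissimilarity between genes is 1 - |r| (or 1 - r in signed mode) from
the Pearson correlation matrix.  An agglomerative dendrogram is cut at a
fixed height to obtain initial clusters; each cluster is then
re-dendrogramed, and whenever its own fixed-height cut still separates it,
partitioning-around-medoids (PAM) splits it.  The loop repeats until no
cluster splits further; undersized clusters are merged into the module
with the nearest medoid, and a final PAM pass seeded with the resulting
medoids restores the nearest-medoid property exactly.

PAM here is the classical swap algorithm: starting from seeded random
medoids, evaluate for every (medoid m, non-medoid x) pair the switching
cost S = total assignment cost after swapping m and x minus the current
cost, perform the most negative swap, and repeat until no swap has S < 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import cophenet, fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "Dendrogram",
    "ModuleAssignment",
    "dissimilarity",
    "hierarchical_dendrogram",
    "fixed_height_cut",
    "pam",
    "pam_dtc",
]


def dissimilarity(R: np.ndarray, mode: str = "absolute") -> np.ndarray:
    """Distance matrix from correlations: 1 - |r| (absolute) or 1 - r (signed)."""
    R = np.asarray(R, dtype=float)
    if np.isnan(R).any():
        i, j = np.argwhere(np.isnan(R))[0]
        raise ValueError(
            f"undefined correlation at gene indices ({i}, {j}); "
            "remove zero-variance genes first"
        )
    if mode == "absolute":
        D = 1.0 - np.abs(R)
    elif mode == "signed":
        D = 1.0 - R
    else:
        raise ValueError(f"mode must be 'absolute' or 'signed', got {mode!r}")
    np.fill_diagonal(D, 0.0)
    return np.clip(D, 0.0, None)


@dataclass
class Dendrogram:
    """Agglomerative merge tree over gene leaves (scipy linkage encoding)."""

    Z: np.ndarray  # (n-1, 4) scipy linkage matrix
    leaf_ids: list[str]
    method: str

    @property
    def root_height(self) -> float:
        return float(self.Z[-1, 2]) if len(self.Z) else 0.0

    @property
    def merge_heights(self) -> np.ndarray:
        return self.Z[:, 2]

    def cophenetic_matrix(self) -> np.ndarray:
        return squareform(cophenet(self.Z))

    def to_newick(self) -> str:
        """Newick string; branch lengths are merge-height differences."""
        n = len(self.leaf_ids)
        heights = {i: 0.0 for i in range(n)}
        labels = {i: self.leaf_ids[i] for i in range(n)}
        for k, (a, b, h, _) in enumerate(self.Z):
            a, b = int(a), int(b)
            la = f"{labels[a]}:{h - heights[a]:.6g}"
            lb = f"{labels[b]}:{h - heights[b]:.6g}"
            labels[n + k] = f"({la},{lb})"
            heights[n + k] = h
        return labels[n + len(self.Z) - 1] + ";"


def hierarchical_dendrogram(
    D: np.ndarray, leaf_ids: list[str], method: str = "average"
) -> Dendrogram:
    """Agglomerative clustering of a dissimilarity matrix.

    ``method`` is one of average, complete, single.
    """
    D = np.asarray(D, dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T):
        raise ValueError("distance matrix must be square and symmetric")
    if len(leaf_ids) != D.shape[0]:
        raise ValueError("leaf_ids length must match matrix size")
    if method not in ("average", "complete", "single"):
        raise ValueError(f"unsupported linkage {method!r}")
    if D.shape[0] < 2:
        raise ValueError("need at least 2 leaves")
    Z = linkage(squareform(D, checks=False), method=method)
    return Dendrogram(Z=Z, leaf_ids=list(leaf_ids), method=method)


def fixed_height_cut(dend: Dendrogram, h: float) -> list[list[str]]:
    """Clusters after removing all merges at height strictly above h.

    Returns the leaf groups, each sorted by gene identifier, ordered by
    their first identifier.
    """
    if h < 0:
        raise ValueError("cut height must be >= 0")
    flat = fcluster(dend.Z, t=h, criterion="distance")
    groups: dict[int, list[str]] = {}
    for leaf, cl in zip(dend.leaf_ids, flat):
        groups.setdefault(int(cl), []).append(leaf)
    clusters = [sorted(g) for g in groups.values()]
    clusters.sort(key=lambda g: g[0])
    return clusters


@dataclass
class ModuleAssignment:
    """Gene -> module map with the medoid gene representing each module."""

    assignment: dict[str, int]
    medoids: dict[int, str]
    total_cost: float
    n_iter: int

    @property
    def n_modules(self) -> int:
        return len(self.medoids)

    def members(self, module_id: int) -> list[str]:
        return sorted(g for g, m in self.assignment.items() if m == module_id)

    def to_tsv(self, path) -> None:
        medoid_genes = set(self.medoids.values())
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("gene_id\tmodule_id\tis_medoid\n")
            for g in sorted(self.assignment):
                fh.write(f"{g}\t{self.assignment[g]}\t{int(g in medoid_genes)}\n")


def _assignment_cost(D: np.ndarray, medoids: list[int]) -> float:
    return float(D[:, medoids].min(axis=1).sum())


def _nearest_medoid(D: np.ndarray, medoids: list[int], gene_ids: list[str]) -> np.ndarray:
    """Index of each gene's nearest medoid; ties -> lowest medoid gene id."""
    order = sorted(medoids, key=lambda m: gene_ids[m])
    sub = D[:, order]
    choice = sub.argmin(axis=1)  # argmin takes the first = lowest id on ties
    return np.asarray([order[c] for c in choice])


def pam(
    D: np.ndarray,
    gene_ids: list[str],
    k: int,
    seed: int = 0,
    init_medoids: list[str] | None = None,
    max_swaps: int = 10_000,
) -> ModuleAssignment:
    """Partitioning around medoids with the classical swap phase.

    The build phase draws k medoids at random (seeded) unless
    ``init_medoids`` is given.  Swaps strictly decrease the total
    assignment cost, guaranteeing termination; ties between equally good
    swaps resolve to the lexicographically lowest (medoid, candidate)
    gene-id pair.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if len(gene_ids) != n:
        raise ValueError("gene_ids length must match matrix size")
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= {n}, got k={k}")
    if init_medoids is not None:
        idx = {g: i for i, g in enumerate(gene_ids)}
        medoids = sorted((idx[g] for g in init_medoids), key=lambda i: gene_ids[i])
        if len(medoids) != k:
            raise ValueError("init_medoids length must equal k")
    else:
        rng = np.random.default_rng(seed)
        medoids = sorted(rng.choice(n, size=k, replace=False).tolist(),
                         key=lambda i: gene_ids[i])

    cost = _assignment_cost(D, medoids)
    n_swaps = 0
    while n_swaps < max_swaps:
        best = None  # (S, medoid_gid, cand_gid, m, x)
        medoid_set = set(medoids)
        for m in medoids:
            for x in range(n):
                if x in medoid_set:
                    continue
                trial = [x if mm == m else mm for mm in medoids]
                S = _assignment_cost(D, trial) - cost
                if S < 0:
                    key = (S, gene_ids[m], gene_ids[x])
                    if best is None or key < best[:3]:
                        best = (S, gene_ids[m], gene_ids[x], m, x)
        if best is None:
            break
        _, _, _, m, x = best
        medoids = sorted((x if mm == m else mm for mm in medoids),
                         key=lambda i: gene_ids[i])
        cost = _assignment_cost(D, medoids)
        n_swaps += 1

    nearest = _nearest_medoid(D, medoids, gene_ids)
    module_of_medoid = {m: j for j, m in enumerate(
        sorted(medoids, key=lambda i: gene_ids[i]))}
    assignment = {gene_ids[i]: module_of_medoid[nearest[i]] for i in range(n)}
    medoid_map = {j: gene_ids[m] for m, j in module_of_medoid.items()}
    return ModuleAssignment(assignment=assignment, medoids=medoid_map,
                            total_cost=cost, n_iter=n_swaps)


def _cluster_medoid(D: np.ndarray, members: list[int], gene_ids: list[str]) -> int:
    """Member minimising total within-cluster distance; ties -> lowest id."""
    sub = D[np.ix_(members, members)]
    totals = sub.sum(axis=1)
    best = min(range(len(members)),
               key=lambda i: (totals[i], gene_ids[members[i]]))
    return members[best]


def pam_dtc(
    D: np.ndarray,
    gene_ids: list[str],
    cut_height: float | None = None,
    min_module_size: int = 5,
    k_split: int = 2,
    linkage_method: str = "average",
    seed: int = 0,
    max_outer_iter: int = 100,
) -> ModuleAssignment:
    """Fixed-height dendrogram cut iteratively refined by PAM.

    ``cut_height`` defaults to 0.99 x the root height of the full
    dendrogram.  Clusters whose own sub-dendrogram still reaches above the
    cut height are split by PAM (k = ``k_split``); the loop runs until an
    iteration creates no new cluster.  Modules smaller than
    ``min_module_size`` merge into the module with the nearest medoid
    (``min_module_size=1`` disables merging).
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if len(gene_ids) != n:
        raise ValueError("gene_ids length must match matrix size")
    if n < 2:
        raise ValueError("need at least 2 genes")
    idx_of = {g: i for i, g in enumerate(gene_ids)}

    dend = hierarchical_dendrogram(D, gene_ids, linkage_method)
    h = 0.99 * dend.root_height if cut_height is None else float(cut_height)
    clusters = [[idx_of[g] for g in cl] for cl in fixed_height_cut(dend, h)]

    outer = 0
    changed = True
    while changed and outer < max_outer_iter:
        changed = False
        outer += 1
        next_clusters: list[list[int]] = []
        for ci, cl in enumerate(clusters):
            if len(cl) <= k_split:
                next_clusters.append(cl)
                continue
            sub_ids = [gene_ids[i] for i in cl]
            subD = D[np.ix_(cl, cl)]
            sub_dend = hierarchical_dendrogram(subD, sub_ids, linkage_method)
            if sub_dend.root_height <= h:
                next_clusters.append(cl)
                continue
            if len(fixed_height_cut(sub_dend, h)) <= 1:
                next_clusters.append(cl)
                continue
            res = pam(subD, sub_ids, k=min(k_split, len(cl)), seed=seed + ci)
            parts = [
                [idx_of[g] for g in res.members(j)] for j in res.medoids
            ]
            parts = [p for p in parts if p]
            if len(parts) <= 1:
                next_clusters.append(cl)
            else:
                next_clusters.extend(parts)
                changed = True
        clusters = next_clusters

    # merge undersized clusters into the module with the nearest medoid
    if min_module_size > 1 and len(clusters) > 1:
        while len(clusters) > 1:
            sizes = [len(c) for c in clusters]
            small = [i for i, s in enumerate(sizes) if s < min_module_size]
            if not small:
                break
            i = min(small, key=lambda i: (sizes[i], gene_ids[min(clusters[i])]))
            med_i = _cluster_medoid(D, clusters[i], gene_ids)
            others = [j for j in range(len(clusters)) if j != i]
            j = min(
                others,
                key=lambda j: (
                    D[med_i, _cluster_medoid(D, clusters[j], gene_ids)],
                    gene_ids[_cluster_medoid(D, clusters[j], gene_ids)],
                ),
            )
            clusters[j] = sorted(clusters[j] + clusters[i])
            del clusters[i]

    medoid_genes = sorted(
        (gene_ids[_cluster_medoid(D, cl, gene_ids)] for cl in clusters)
    )
    result = pam(D, gene_ids, k=len(medoid_genes), seed=seed,
                 init_medoids=medoid_genes)
    return ModuleAssignment(
        assignment=result.assignment,
        medoids=result.medoids,
        total_cost=result.total_cost,
        n_iter=outer,
    )
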