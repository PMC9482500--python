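"""HSIC-guided gene selection with a binary bat-swarm optimizer.

The fitness of a candidate gene subset is the empirical Hilbert-Schmidt
independence criterion between the subset's sample-level kernel K and the
label kernel B,

    HSIC(K, B) = tr(HKHB) / (n - 1)^2,     H = I - (1/n) 1 1^T,

which is zero when expression and labels are independent (characteristic
kernels) and grows with dependence.  A swarm of "bats" searches the
subset space: each bat carries a continuous position (one coordinate per
candidate gene), a velocity and a random frequency; positions are pulled
relative to the best position found so far (Gbest), occasionally replaced
by a local walk around Gbest, and binarized to a mask by keeping the k
largest coordinates.  Loudness and pulse rate follow the canonical
schedules A <- alpha*A and r_t = r0*(1 - exp(-gamma*t)).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .io import ExpressionMatrix

__all__ = [
    "BatSwarm",
    "SelectionResult",
    "empirical_hsic",
    "projection_hsic",
    "subset_hsic",
    "delta_kernel",
    "linear_label_kernel",
    "rbf_median_kernel",
    "bat_step",
    "ibo_select",
]


# ---------------------------------------------------------------------------
# kernels and the HSIC statistic


def _center(K: np.ndarray) -> np.ndarray:
    """HKH without forming H: subtract row/column/grand means."""
    row = K.mean(axis=0, keepdims=True)
    col = K.mean(axis=1, keepdims=True)
    return K - row - col + K.mean()


def empirical_hsic(K: np.ndarray, B: np.ndarray) -> float:
    """tr(HKHB) / (n-1)^2 for two n x n symmetric kernel matrices."""
    K = np.asarray(K, dtype=float)
    B = np.asarray(B, dtype=float)
    if K.shape != B.shape or K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError(f"kernel shapes must match and be square, "
                         f"got {K.shape} and {B.shape}")
    n = K.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    return float((_center(K) * B).sum()) / (n - 1) ** 2


def delta_kernel(y: np.ndarray) -> np.ndarray:
    """B_ij = 1 iff y_i = y_j (class-indicator kernel)."""
    y = np.asarray(y)
    return (y[:, None] == y[None, :]).astype(float)


def linear_label_kernel(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    return np.outer(y, y)


def rbf_median_kernel(S: np.ndarray) -> np.ndarray:
    """RBF kernel over sample rows with the median-heuristic bandwidth."""
    S = np.asarray(S, dtype=float)
    sq = ((S[:, None, :] - S[None, :, :]) ** 2).sum(axis=-1)
    off = sq[np.triu_indices_from(sq, k=1)]
    med = np.median(off[off > 0]) if (off > 0).any() else 1.0
    return np.exp(-sq / med)


def _label_kernel(y: np.ndarray, kind: str) -> np.ndarray:
    if kind == "delta":
        return delta_kernel(y)
    if kind == "linear":
        return linear_label_kernel(y)
    raise ValueError(f"unknown label kernel {kind!r}")


def projection_hsic(X, u: np.ndarray, B: np.ndarray) -> float:
    """HSIC of the u-weighted gene projection: K = (X^T u)(X^T u)^T."""
    G = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=float)
    u = np.asarray(u, dtype=float)
    if not np.any(u):
        raise ValueError("weight vector u is all-zero")
    z = G.T @ u  # (n_samples,)
    return empirical_hsic(np.outer(z, z), B)


def subset_hsic(
    X,
    mask: np.ndarray,
    y: np.ndarray,
    label_kernel: str = "delta",
    gene_kernel: str = "linear",
) -> float:
    """HSIC between the masked genes' sample kernel and the label kernel."""
    G = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (G.shape[0],):
        raise ValueError("mask must have one entry per gene")
    if not mask.any():
        raise ValueError("mask selects no genes")
    S = G[mask].T  # samples x selected genes
    if gene_kernel == "linear":
        K = S @ S.T
    elif gene_kernel == "rbf_median":
        K = rbf_median_kernel(S)
    else:
        raise ValueError(f"unknown gene kernel {gene_kernel!r}")
    return empirical_hsic(K, _label_kernel(np.asarray(y), label_kernel))


# ---------------------------------------------------------------------------
# bat swarm


@dataclass
class BatSwarm:
    """State of the bat swarm over p candidate-gene coordinates."""

    positions: np.ndarray     # (n_bats, p)
    velocities: np.ndarray    # (n_bats, p)
    loudness: np.ndarray      # (n_bats,)
    pulse_rate: np.ndarray    # (n_bats,)
    fitness: np.ndarray       # (n_bats,) fitness of each bat's position
    gbest_position: np.ndarray
    gbest_mask: np.ndarray
    gbest_fitness: float
    t: int = 0
    fr_min: float = 0.0
    fr_max: float = 2.0
    alpha: float = 0.9
    gamma: float = 0.9
    r0: float = 0.5
    bounds: tuple[float, float] | None = (0.0, 1.0)


def _top_k_mask(position: np.ndarray, k: int, gene_ids: list[str]) -> np.ndarray:
    """Boolean mask of the k largest coordinates; ties -> lowest gene id."""
    order = sorted(range(len(position)),
                   key=lambda i: (-position[i], gene_ids[i]))
    mask = np.zeros(len(position), dtype=bool)
    mask[order[:k]] = True
    return mask


def bat_step(swarm: BatSwarm, fitness_fn, rng: np.random.Generator,
             k: int, gene_ids: list[str]) -> BatSwarm:
    """One synchronous swarm update (bats processed in fixed order).

    Per bat: draw a frequency, update velocity and position relative to
    Gbest, possibly replace the move by a local walk around Gbest scaled
    by the mean loudness, binarize to a top-k mask, and accept the
    candidate when it improves the bat's fitness and a loudness-gated coin
    flip passes.  Gbest is elitist: it records the best mask ever
    evaluated, accepted or not.

    Positions are clamped to ``swarm.bounds`` (the unit box by default).
    The clamp matters: accepted walk steps otherwise push coordinates
    ever further above the box until no coordinate outside the incumbent
    mask can reach the top k any more and the search freezes.
    """
    swarm.t += 1
    n_bats, p = swarm.positions.shape
    for i in range(n_bats):
        beta = rng.random()
        fr = swarm.fr_min + (swarm.fr_max - swarm.fr_min) * beta
        swarm.velocities[i] += (swarm.positions[i] - swarm.gbest_position) * fr
        candidate = swarm.positions[i] + swarm.velocities[i]
        if rng.random() > swarm.pulse_rate[i]:
            eps = rng.uniform(-1.0, 1.0, size=p)
            candidate = swarm.gbest_position + eps * swarm.loudness.mean()
        if swarm.bounds is not None:
            candidate = np.clip(candidate, *swarm.bounds)
        mask = _top_k_mask(candidate, k, gene_ids)
        f = fitness_fn(mask)
        if f > swarm.fitness[i] and rng.random() < swarm.loudness[i]:
            swarm.positions[i] = candidate
            swarm.fitness[i] = f
            swarm.loudness[i] *= swarm.alpha
            swarm.pulse_rate[i] = swarm.r0 * (1.0 - np.exp(-swarm.gamma * swarm.t))
        if f > swarm.gbest_fitness:
            swarm.gbest_fitness = f
            swarm.gbest_position = candidate.copy()
            swarm.gbest_mask = mask
    return swarm


@dataclass
class SelectionResult:
    """Outcome of a gene-selection run."""

    gene_ids: list[str]
    mask: np.ndarray
    u: np.ndarray
    hsic_score: float
    trajectory: list[float]
    seed: int
    iterations: int
    params: dict = field(default_factory=dict)

    @property
    def selected_genes(self) -> list[str]:
        return [g for g, m in zip(self.gene_ids, self.mask) if m]

    def to_tsv(self, path, final_positions: np.ndarray | None = None) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("gene_id\tselected\tweight\n")
            for i, g in enumerate(self.gene_ids):
                w = self.u[i] if final_positions is None else final_positions[i]
                fh.write(f"{g}\t{int(self.mask[i])}\t{w!r}\n")

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "iterations": self.iterations,
            "hsic_score": self.hsic_score,
            "selected_genes": self.selected_genes,
            "trajectory": self.trajectory,
            "params": self.params,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")


def ibo_select(
    X,
    y: np.ndarray,
    k: int,
    gene_ids: list[str] | None = None,
    n_bats: int = 30,
    n_iter: int = 100,
    seed: int = 0,
    fr_min: float = 0.0,
    fr_max: float = 2.0,
    alpha: float = 0.9,
    gamma: float = 0.9,
    loudness0: float = 1.0,
    r0: float = 0.5,
    label_kernel: str = "delta",
    gene_kernel: str = "linear",
    bounds: tuple[float, float] | None = (0.0, 1.0),
) -> SelectionResult:
    """Select k genes maximising subset HSIC with the bat swarm.

    The returned mask is the best ever evaluated (elitist), u is the mask
    normalised to unit length, and the trajectory records the best-so-far
    fitness after each iteration (non-decreasing by construction).  Fully
    reproducible from ``seed``.
    """
    G = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=float)
    if gene_ids is None:
        gene_ids = (X.gene_ids if isinstance(X, ExpressionMatrix)
                    else [f"g{i:04d}" for i in range(G.shape[0])])
    p = G.shape[0]
    if not 1 <= k <= p:
        raise ValueError(f"need 1 <= k <= {p}, got k={k}")
    y = np.asarray(y)
    B = _label_kernel(y, label_kernel)
    n = G.shape[1]

    if gene_kernel == "linear":
        # tr(HKHB) is additive over genes for the linear kernel:
        # per-gene contributions q_g = x_g^T (HBH) x_g are precomputed.
        M = _center(B)
        q = np.einsum("gs,st,gt->g", G, M, G) / (n - 1) ** 2

        def fitness_fn(mask: np.ndarray) -> float:
            return float(q[mask].sum())
    else:
        def fitness_fn(mask: np.ndarray) -> float:
            return subset_hsic(G, mask, y, label_kernel, gene_kernel)

    rng = np.random.default_rng(seed)
    positions = rng.random((n_bats, p))
    velocities = np.zeros((n_bats, p))
    fitness = np.empty(n_bats)
    masks = [_top_k_mask(positions[i], k, gene_ids) for i in range(n_bats)]
    for i in range(n_bats):
        fitness[i] = fitness_fn(masks[i])
    best = int(fitness.argmax())
    swarm = BatSwarm(
        positions=positions,
        velocities=velocities,
        loudness=np.full(n_bats, loudness0),
        pulse_rate=np.full(n_bats, r0),
        fitness=fitness,
        gbest_position=positions[best].copy(),
        gbest_mask=masks[best],
        gbest_fitness=float(fitness[best]),
        fr_min=fr_min, fr_max=fr_max, alpha=alpha, gamma=gamma, r0=r0,
        bounds=bounds,
    )
    trajectory = [swarm.gbest_fitness]
    for _ in range(n_iter):
        bat_step(swarm, fitness_fn, rng, k, gene_ids)
        trajectory.append(swarm.gbest_fitness)

    mask = swarm.gbest_mask
    u = mask.astype(float) / np.sqrt(k)
    return SelectionResult(
        gene_ids=list(gene_ids),
        mask=mask,
        u=u,
        hsic_score=swarm.gbest_fitness,
        trajectory=trajectory,
        seed=seed,
        iterations=n_iter,
        params={
            "k": k, "n_bats": n_bats, "fr_min": fr_min, "fr_max": fr_max,
            "alpha": alpha, "gamma": gamma, "loudness0": loudness0, "r0": r0,
            "label_kernel": label_kernel, "gene_kernel": gene_kernel,
        },
    )
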