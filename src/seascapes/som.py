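"""Batch self-organizing map on a hexagonal lattice with link-distance
neighborhoods.

The map is an X x Y lattice of neurons, each carrying a weight vector in
(range-standardized) feature space. Batch training alternates two exact
steps: every data row is assigned to its best-matching unit (BMU, nearest
weight by Euclidean distance, ties to the lowest neuron index), then every
neuron's weight is replaced by the mean of all rows whose BMU lies within
link distance r(t) of it on the lattice. The neighborhood radius decays
linearly from its initial value (default 3) to 1 over the first 90% of the
training steps (ordering phase), then drops to 0 for the final 10%
(convergence phase), during which the update is exactly Lloyd's k-means
iteration and the final labeling is a Voronoi partition of the data by the
neuron weights.

A 1 x k lattice degenerates to a path — the "linear topology" of the
scenario scan.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .features import FeatureTable

__all__ = [
    "Lattice",
    "TrainConfig",
    "SOMModel",
    "HexSOM",
    "build_hex_lattice",
    "link_distance_matrix",
    "init_weights",
    "train_batch",
    "assign_labels",
    "neighbor_weight_distances",
    "input_weight_planes",
]


# ---------------------------------------------------------------------------
# Lattice
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Lattice:
    """Hexagonal neuron lattice in odd-row-offset layout.

    ``positions`` are 2-D plot coordinates (odd rows shifted half a cell
    right, rows sqrt(3)/2 apart); ``edges`` is the symmetric adjacency as a
    sorted list of index pairs (i < j). Neuron index = row * Y + col.
    """

    X: int
    Y: int
    positions: np.ndarray
    edges: tuple[tuple[int, int], ...]

    @property
    def k(self) -> int:
        return self.X * self.Y


def build_hex_lattice(X: int, Y: int) -> Lattice:
    """Odd-r offset hexagonal lattice with X rows and Y columns.

    Interior neurons have exactly 6 neighbors; a single-row (1 x k) lattice
    degenerates to a path.
    """
    if X < 1 or Y < 1:
        raise ValueError("lattice dimensions must be positive")
    idx = lambda r, c: r * Y + c
    pos = np.empty((X * Y, 2))
    edges: set[tuple[int, int]] = set()
    for r in range(X):
        for c in range(Y):
            pos[idx(r, c)] = (c + 0.5 * (r % 2), r * np.sqrt(3) / 2)
            # even rows pair with (c-1, c) above/below; odd rows with (c, c+1)
            shift = 0 if r % 2 else -1
            nbrs = [(r, c - 1), (r, c + 1),
                    (r - 1, c + shift), (r - 1, c + shift + 1),
                    (r + 1, c + shift), (r + 1, c + shift + 1)]
            for rr, cc in nbrs:
                if 0 <= rr < X and 0 <= cc < Y:
                    i, j = idx(r, c), idx(rr, cc)
                    edges.add((min(i, j), max(i, j)))
    return Lattice(X=X, Y=Y, positions=pos, edges=tuple(sorted(edges)))


def link_distance_matrix(lattice: Lattice) -> np.ndarray:
    """All-pairs minimum hop count over the lattice adjacency (k x k int)."""
    k = lattice.k
    if k == 1:
        return np.zeros((1, 1), dtype=int)
    rows, cols = zip(*[(i, j) for i, j in lattice.edges] +
                     [(j, i) for i, j in lattice.edges])
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(k, k))
    d = shortest_path(adj, method="D", unweighted=True, directed=False)
    if np.isinf(d).any():
        raise ValueError("lattice is disconnected")
    return d.astype(int)


# ---------------------------------------------------------------------------
# Configuration / model containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    """Batch-training schedule.

    steps: total batch iterations (default 1000).
    init_radius: initial link-distance neighborhood radius (default 3); the
        radius decays linearly to 1 over the first ``ordering_frac`` of the
        steps and is 0 afterwards. init_radius 0 keeps the radius at 0
        throughout (pure k-means iteration).
    init: "pca_plane" (deterministic), "random", or "sample_d2"
        (squared-distance-weighted seeding from data rows).
    tol: convergence-phase early stop on the max absolute weight change.
    """

    steps: int = 1000
    init_radius: int = 3
    ordering_frac: float = 0.9
    init: str = "pca_plane"
    seed: int = 0
    tol: float = 1e-9

    def __post_init__(self) -> None:
        if self.steps < 1:
            raise ValueError("steps >= 1 required")
        if self.init_radius < 0:
            raise ValueError("init_radius >= 0 required")
        if self.init not in ("pca_plane", "random", "sample_d2"):
            raise ValueError("init must be 'pca_plane', 'random' or 'sample_d2'")

    def radius_at(self, t: int) -> float:
        """Neighborhood radius for 0-based step t."""
        if self.init_radius == 0:
            return 0.0
        n_order = int(np.ceil(self.ordering_frac * self.steps))
        if t >= n_order:
            return 0.0
        if n_order == 1:
            return float(self.init_radius)
        return self.init_radius - (self.init_radius - 1) * t / (n_order - 1)


@dataclass
class SOMModel:
    """Trained map: lattice + weights + link distances + config snapshot."""

    lattice: Lattice
    weights: np.ndarray      # k x d, standardized feature space
    link_dist: np.ndarray    # k x k int
    config: TrainConfig
    n_iter: int = 0          # batch updates actually evaluated

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"X": self.lattice.X, "Y": self.lattice.Y,
                       "config": asdict(self.config),
                       "n_iter": self.n_iter,
                       "weights": self.weights.tolist()}, fh)

    @classmethod
    def from_json(cls, path) -> "SOMModel":
        with open(path) as fh:
            d = json.load(fh)
        lat = build_hex_lattice(d["X"], d["Y"])
        return cls(lattice=lat, weights=np.array(d["weights"]),
                   link_dist=link_distance_matrix(lat),
                   config=TrainConfig(**d["config"]), n_iter=d["n_iter"])


# ---------------------------------------------------------------------------
# Initialization and training
# ---------------------------------------------------------------------------

def _as_matrix(table) -> np.ndarray:
    if isinstance(table, FeatureTable):
        return table.values
    return np.asarray(table, float)


def init_weights(table, lattice: Lattice, method: str = "pca_plane",
                 seed: int = 0) -> np.ndarray:
    """Initial k x d weights.

    pca_plane lays the lattice out on the plane of the first two principal
    directions of the data, spanning mean +/- 2 SD along each (first
    direction only for a single-row or single-column lattice); fully
    deterministic. random draws uniformly within each column's data range.
    sample_d2 seeds weights at data rows drawn with probability
    proportional to the squared distance from the nearest already-chosen
    seed, so the initial weights spread across the occupied regions of
    feature space.
    """
    X = _as_matrix(table)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows to initialize")
    k, d = lattice.k, X.shape[1]
    if method == "random":
        rng = np.random.default_rng(seed)
        return rng.uniform(X.min(axis=0), X.max(axis=0), size=(k, d))
    if method == "sample_d2":
        rng = np.random.default_rng(seed)
        chosen = [int(rng.integers(X.shape[0]))]
        d2 = ((X - X[chosen[0]]) ** 2).sum(axis=1)
        for _ in range(k - 1):
            total = d2.sum()
            if total <= 0:  # all remaining rows coincide with a seed
                chosen.append(int(rng.integers(X.shape[0])))
            else:
                chosen.append(int(rng.choice(X.shape[0], p=d2 / total)))
            d2 = np.minimum(d2, ((X - X[chosen[-1]]) ** 2).sum(axis=1))
        return X[np.array(chosen)].copy()
    if method != "pca_plane":
        raise ValueError(f"unknown init method {method!r}")
    mean = X.mean(axis=0)
    C = X - mean
    _, s, Vt = np.linalg.svd(C, full_matrices=False)
    sd = s / np.sqrt(max(X.shape[0] - 1, 1))
    # deterministic sign: largest-|loading| component of each axis positive
    axes = []
    for comp in range(min(2, Vt.shape[0])):
        v = Vt[comp]
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        axes.append((v, sd[comp]))

    def ramp(n, j):  # lattice coordinate in [-1, 1] along axis j (rows/cols)
        if n == 1:
            return np.zeros(n)
        return np.linspace(-1.0, 1.0, n)

    rowpos = np.repeat(ramp(lattice.X, 0), lattice.Y)
    colpos = np.tile(ramp(lattice.Y, 1), lattice.X)
    # the longer lattice axis carries the first principal direction
    primary, secondary = (colpos, rowpos) if lattice.Y >= lattice.X else (rowpos, colpos)
    W = np.tile(mean, (k, 1))
    v, sdev = axes[0]
    W += 2.0 * sdev * primary[:, None] * v[None, :]
    if len(axes) > 1 and lattice.X > 1 and lattice.Y > 1:
        v2, sdev2 = axes[1]
        W += 2.0 * sdev2 * secondary[:, None] * v2[None, :]
    return W


def _bmu(X: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Best-matching unit per row; ties resolve to the lowest neuron index."""
    d2 = ((X[:, None, :] - W[None, :, :]) ** 2).sum(axis=2) if X.shape[0] * W.shape[0] < 2_000_000 \
        else (X ** 2).sum(1)[:, None] - 2 * X @ W.T + (W ** 2).sum(1)[None, :]
    return np.argmin(d2, axis=1)


def _batch_update(X: np.ndarray, W: np.ndarray, neigh: np.ndarray) -> np.ndarray:
    """One batch step: neuron j <- mean of rows whose BMU is within the
    neighborhood of j; neurons capturing no rows keep their weight."""
    k, d = W.shape
    bmu = _bmu(X, W)
    counts = np.bincount(bmu, minlength=k).astype(float)
    sums = np.zeros((k, d))
    np.add.at(sums, bmu, X)
    num = neigh @ sums
    den = neigh @ counts
    out = W.copy()
    hit = den > 0
    out[hit] = num[hit] / den[hit, None]
    return out


def train_batch(table, lattice: Lattice, config: TrainConfig) -> SOMModel:
    """Batch-train a SOM on the (standardized) feature table.

    The batch update is a deterministic map of the weight state at fixed
    effective radius, so within a stretch of steps sharing one radius the
    trajectory is eventually periodic (a fixed point or a short limit
    cycle). The loop detects the first revisited state and jumps ahead by
    the remaining step count modulo the cycle length — exactly equivalent
    to evaluating every step of the stretch. In the final radius-0 phase
    the loop additionally stops early once the maximum absolute weight
    change falls below ``config.tol``.
    """
    X = _as_matrix(table)
    if X.shape[0] == 0:
        raise ValueError("empty feature table")
    k = lattice.k
    if X.shape[0] < k:
        import warnings
        warnings.warn(f"fewer rows ({X.shape[0]}) than neurons ({k})", stacklevel=2)
    link = link_distance_matrix(lattice)
    W = init_weights(table, lattice, method=config.init, seed=config.seed)

    radii = np.array([config.radius_at(t) for t in range(config.steps)])
    eff = np.floor(radii).astype(int)  # integer link distances: floor(r) acts
    # A hard-indicator neighborhood spanning the whole lattice would pull
    # every neuron to the global mean and the map could never de-collapse
    # (identical weights tie-break all rows to neuron 0); cap the radius so
    # at least the most distant neuron pair updates independently.
    eff = np.minimum(eff, max(int(link.max()) - 1, 0))
    n_evaluated = 0
    t = 0
    stop = False
    while t < config.steps and not stop:
        run_end = t
        while run_end < config.steps and eff[run_end] == eff[t]:
            run_end += 1
        neigh = (link <= eff[t])
        final_phase = eff[t] == 0
        seen: dict[bytes, int] = {W.tobytes(): t}
        jumped = False
        while t < run_end:
            Wn = _batch_update(X, W, neigh)
            n_evaluated += 1
            t += 1
            delta = np.max(np.abs(Wn - W))
            W = Wn
            if final_phase and delta < config.tol:
                stop = True
                break
            key = W.tobytes()
            if not jumped:
                if key in seen:
                    cycle = t - seen[key]
                    t = run_end - (run_end - t) % cycle
                    jumped = True  # replay the remainder of the cycle only
                else:
                    seen[key] = t
    return SOMModel(lattice=lattice, weights=W, link_dist=link,
                    config=config, n_iter=n_evaluated)


def assign_labels(model: SOMModel, table) -> np.ndarray:
    """BMU index (0..k-1) per row; ties to the lowest neuron index."""
    X = _as_matrix(table)
    if X.shape[1] != model.weights.shape[1]:
        raise ValueError("feature-space dimension mismatch with the model")
    return _bmu(X, model.weights)


def neighbor_weight_distances(model: SOMModel) -> list[tuple[int, int, float]]:
    """Euclidean weight distance per lattice edge (the U-matrix content)."""
    W = model.weights
    return [(i, j, float(np.linalg.norm(W[i] - W[j])))
            for i, j in model.lattice.edges]


def input_weight_planes(model: SOMModel,
                        columns: tuple[str, ...] | None = None) -> dict[str, np.ndarray]:
    """Per-variable slices of the weight matrix (component planes)."""
    d = model.weights.shape[1]
    if columns is None:
        from .synthetic import VARIABLES
        columns = VARIABLES if d == len(VARIABLES) else tuple(f"var{j}" for j in range(d))
    if len(columns) != d:
        raise ValueError("one column name per weight dimension required")
    return {c: model.weights[:, j].copy() for j, c in enumerate(columns)}


# ---------------------------------------------------------------------------
# Estimator surface
# ---------------------------------------------------------------------------

class HexSOM(ClusterMixin, BaseEstimator):
    """Scikit-learn-style clusterer wrapping the batch hexagonal SOM.

    Parameters
    ----------
    x, y : lattice rows and columns (x*y neurons).
    steps : total batch iterations.
    radius : initial link-distance neighborhood radius.
    init : "pca_plane" or "random" weight initialization.
    random_state : seed for the random initialization.

    Attributes (after ``fit``)
    --------------------------
    model_ : the trained :class:`SOMModel`.
    weights_ : (x*y, n_features) neuron weights.
    labels_ : BMU index per training row (0-based).
    n_iter_ : batch updates actually evaluated.
    """

    def __init__(self, x: int = 1, y: int = 9, steps: int = 1000,
                 radius: int = 3, init: str = "pca_plane",
                 random_state: int = 0):
        self.x = x
        self.y = y
        self.steps = steps
        self.radius = radius
        self.init = init
        self.random_state = random_state

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=2)
        lattice = build_hex_lattice(self.x, self.y)
        config = TrainConfig(steps=self.steps, init_radius=self.radius,
                             init=self.init, seed=int(self.random_state or 0))
        self.model_ = train_batch(X, lattice, config)
        self.weights_ = self.model_.weights
        self.labels_ = assign_labels(self.model_, X)
        self.n_iter_ = self.model_.n_iter
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        X = check_array(X)
        return assign_labels(self.model_, X)

    def transform(self, X):
        """Distances from each sample to every neuron weight."""
        check_is_fitted(self, "model_")
        X = check_array(X)
        d2 = (X ** 2).sum(1)[:, None] - 2 * X @ self.weights_.T + (self.weights_ ** 2).sum(1)[None, :]
        return np.sqrt(np.maximum(d2, 0.0))
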