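"""Scenario scan and silhouette-based selection of the best partition.

Candidate maps are all unordered bi-dimensional lattice topologies {X, Y}
with X*Y neurons for every neuron count in the scan range (default 4..25,
which yields exactly 43 scenarios, 1 x k "linear" topologies included).
Each trained map's partition is scored by the mean silhouette index

    SI_i = (b_i - a_i) / max(a_i, b_i),

where a_i is the average distance from point i to the other points of its
cluster and b_i the minimum over other clusters of the average distance to
that cluster's points; the scenario with the highest mean SI wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .features import FeatureTable
from .som import HexSOM, SOMModel, TrainConfig, assign_labels, build_hex_lattice, train_batch

__all__ = [
    "Scenario",
    "ScenarioResult",
    "enumerate_scenarios",
    "silhouette",
    "run_scan",
    "select_best",
    "TopologyScan",
]

DEFAULT_K_MIN = 4
DEFAULT_K_MAX = 25
DEFAULT_SI_SAMPLE = 10_000


@dataclass(frozen=True)
class Scenario:
    """One lattice topology in canonical unordered form (X <= Y)."""

    X: int
    Y: int

    def __post_init__(self) -> None:
        if self.X < 1 or self.Y < 1 or self.X > self.Y:
            raise ValueError("scenario requires 1 <= X <= Y")

    @property
    def k(self) -> int:
        return self.X * self.Y


@dataclass
class ScenarioResult:
    scenario: Scenario
    model: SOMModel | None
    labels: np.ndarray | None
    mean_si: float
    si: np.ndarray | None          # per evaluated point
    si_rows: np.ndarray | None     # table rows the SI was evaluated on
    n_nonempty: int
    valid: bool = True


def enumerate_scenarios(k_min: int = DEFAULT_K_MIN,
                        k_max: int = DEFAULT_K_MAX) -> list[Scenario]:
    """All unordered factor pairs {X, Y} with X*Y in [k_min, k_max].

    Includes the 1 x k linear topologies; sorted by neuron count then X.
    The default 4..25 range contains exactly 43 scenarios.
    """
    if not 1 <= k_min <= k_max:
        raise ValueError("require 1 <= k_min <= k_max")
    out = []
    for k in range(k_min, k_max + 1):
        for x in range(1, int(np.sqrt(k)) + 1):
            if k % x == 0:
                out.append(Scenario(X=x, Y=k // x))
    return out


# ---------------------------------------------------------------------------
# Silhouette index
# ---------------------------------------------------------------------------

def _silhouette_full(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-point silhouette by cluster-mean distance aggregation (O(n^2))."""
    n = len(X)
    uniq, inv = np.unique(labels, return_inverse=True)
    counts = np.bincount(inv).astype(float)
    d2 = (X ** 2).sum(1)[:, None] - 2 * X @ X.T + (X ** 2).sum(1)[None, :]
    np.fill_diagonal(d2, 0.0)
    D = np.sqrt(np.maximum(d2, 0.0))
    # mean distance from each point to each cluster
    onehot = np.zeros((n, len(uniq)))
    onehot[np.arange(n), inv] = 1.0
    sums = D @ onehot
    mean_to = sums / counts[None, :]
    si = np.zeros(n)
    own = counts[inv]
    singleton = own <= 1
    a = np.where(singleton, 0.0, sums[np.arange(n), inv] / np.maximum(own - 1, 1))
    other = mean_to.copy()
    other[np.arange(n), inv] = np.inf
    b = other.min(axis=1)
    denom = np.maximum(a, b)
    good = ~singleton & (denom > 0)
    si[good] = (b[good] - a[good]) / denom[good]
    return si


def silhouette(table, labels: np.ndarray,
               sample_size: int | None = DEFAULT_SI_SAMPLE,
               seed: int = 0) -> tuple[float, np.ndarray, np.ndarray]:
    """Mean and per-point silhouette in standardized feature space.

    For large inputs the index is evaluated on a seeded uniform subsample
    (distances taken within the subsample); pass ``sample_size=None`` for
    the full computation. Singleton points score 0. Returns
    (mean_SI, per-point SI, evaluated row indices).
    """
    X = table.values if isinstance(table, FeatureTable) else np.asarray(table, float)
    labels = np.asarray(labels)
    if len(labels) != len(X):
        raise ValueError("labels not aligned with rows")
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette requires at least 2 non-empty clusters")
    n = len(X)
    if sample_size is not None and n > sample_size:
        rng = np.random.default_rng(seed)
        rows = np.sort(rng.choice(n, size=sample_size, replace=False))
        Xs, ls = X[rows], labels[rows]
        if len(np.unique(ls)) < 2:  # degenerate subsample; fall back to full
            rows, Xs, ls = np.arange(n), X, labels
    else:
        rows, Xs, ls = np.arange(n), X, labels
    si = _silhouette_full(Xs, ls)
    return float(si.mean()), si, rows


# ---------------------------------------------------------------------------
# Scan and selection
# ---------------------------------------------------------------------------

DEFAULT_REFINE_RESTARTS = 2


def run_scan(table, scenarios: list[Scenario] | None = None,
             train_config: TrainConfig | None = None,
             sample_size: int | None = DEFAULT_SI_SAMPLE,
             seed: int = 0,
             refine_restarts: int = DEFAULT_REFINE_RESTARTS,
             progress=None) -> list[ScenarioResult]:
    """Train and score every scenario; never aborts mid-scan.

    Deterministic topology-ordered training can land in poor partitions of
    well-separated data, so in addition to the neighborhood-trained map
    each scenario considers ``refine_restarts`` convergence-phase-only
    candidates (radius 0 throughout) started from squared-distance-weighted
    data seeding; all candidates are scored by the same silhouette and the
    best one represents the scenario (ties keep the neighborhood-trained
    map). One silhouette subsample (seeded) is shared across scenarios so
    scores are directly comparable. A scenario whose best map leaves fewer
    than 2 non-empty clusters is recorded with mean SI = -1 and flagged
    invalid.
    """
    scenarios = scenarios if scenarios is not None else enumerate_scenarios()
    base = train_config or TrainConfig()
    X = table.values if isinstance(table, FeatureTable) else np.asarray(table, float)
    results = []
    for i, sc in enumerate(scenarios):
        lattice = build_hex_lattice(sc.X, sc.Y)
        configs = [base]
        for r in range(refine_restarts):
            child = int(np.random.SeedSequence([seed, i, r]).generate_state(1)[0]
                        % (2**31))
            configs.append(replace(base, init="sample_d2", init_radius=0, seed=child))
        best = None
        for cfg in configs:
            model = train_batch(X, lattice, cfg)
            labels = assign_labels(model, X)
            n_nonempty = len(np.unique(labels))
            if n_nonempty < 2:
                cand = ScenarioResult(scenario=sc, model=model, labels=labels,
                                      mean_si=-1.0, si=None, si_rows=None,
                                      n_nonempty=n_nonempty, valid=False)
            else:
                mean_si, si, rows = silhouette(X, labels, sample_size=sample_size,
                                               seed=seed)
                cand = ScenarioResult(scenario=sc, model=model, labels=labels,
                                      mean_si=mean_si, si=si, si_rows=rows,
                                      n_nonempty=n_nonempty)
            if best is None or cand.mean_si > best.mean_si:
                best = cand
        results.append(best)
        if progress is not None:
            progress(best)
    return results


def select_best(results: list[ScenarioResult]) -> ScenarioResult:
    """Maximal mean SI; ties -> smaller neuron count, then smaller X."""
    valid = [r for r in results if r.valid]
    if not valid:
        raise ValueError("no valid scenarios to select from")
    return min(valid, key=lambda r: (-r.mean_si, r.scenario.k, r.scenario.X))


def scan_table(results: list[ScenarioResult]) -> pd.DataFrame:
    """Tabular scan summary (one row per scenario)."""
    return pd.DataFrame([
        {"X": r.scenario.X, "Y": r.scenario.Y, "k": r.scenario.k,
         "mean_si": r.mean_si, "n_nonempty": r.n_nonempty, "valid": r.valid}
        for r in results])


__all__.append("scan_table")


class TopologyScan(ClusterMixin, BaseEstimator):
    """Scan all lattice topologies in a neuron-count range, keep the best.

    Fitting trains one :class:`HexSOM` per scenario, scores each partition
    by mean silhouette, and exposes the winning scenario's model and labels.

    Attributes (after ``fit``)
    --------------------------
    results_ : list of ScenarioResult for every scenario scanned.
    best_ : the winning ScenarioResult.
    best_scenario_ : (X, Y) of the winner.
    labels_ : winner's labels for the training rows (0-based neuron index).
    """

    def __init__(self, k_min: int = DEFAULT_K_MIN, k_max: int = DEFAULT_K_MAX,
                 steps: int = 1000, radius: int = 3, init: str = "pca_plane",
                 si_sample: int | None = DEFAULT_SI_SAMPLE,
                 refine_restarts: int = DEFAULT_REFINE_RESTARTS,
                 random_state: int = 0):
        self.k_min = k_min
        self.k_max = k_max
        self.steps = steps
        self.radius = radius
        self.init = init
        self.si_sample = si_sample
        self.refine_restarts = refine_restarts
        self.random_state = random_state

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=2)
        cfg = TrainConfig(steps=self.steps, init_radius=self.radius,
                          init=self.init, seed=int(self.random_state or 0))
        self.results_ = run_scan(X, enumerate_scenarios(self.k_min, self.k_max),
                                 train_config=cfg, sample_size=self.si_sample,
                                 seed=int(self.random_state or 0),
                                 refine_restarts=self.refine_restarts)
        self.best_ = select_best(self.results_)
        self.best_scenario_ = (self.best_.scenario.X, self.best_.scenario.Y)
        self.labels_ = self.best_.labels
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "best_")
        X = check_array(X)
        return assign_labels(self.best_.model, X)
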