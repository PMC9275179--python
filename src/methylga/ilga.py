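"""Inner-layer genetic algorithm: grouping-GA clustering of samples.

The chromosome is a permutation of sample indices cut into contiguous
logical clusters (a "grouping" encoding): the cluster count and sizes are
free and evolve with the population.  Fitness is the Calinski-Harabasz
index built from Ward-style dispersion terms:

* ``alpha`` — between-cluster weighted sum of squared distances of cluster
  centroids to the overall centroid,
* ``gamma`` — within-cluster dispersion in its pairwise form,
  ``sum_h (1/(2 S_h)) sum_{i,j in C_h} d(i,j)^2``, which equals the
  familiar sum of squared distances to cluster centroids,
* ``F_CH = (alpha/gamma) * (n_samples - n_clusters)/(n_clusters - 1)``;
  higher is better.

Operators: a modified maximal-preservation crossover (MPX) that transplants
a substring of the cluster nearest the overall centroid between parents, a
split/merge mutation whose probability ramps linearly up to a cap as the
run converges, roulette-wheel selection on min-shifted fitness, and
elitism.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .methyl_data import BetaMatrix

__all__ = [
    "ClusterPartition",
    "FitnessRecord",
    "IlgaConfig",
    "IlgaResult",
    "PartitionScorer",
    "init_partition",
    "compute_alpha",
    "compute_gamma",
    "ch_fitness",
    "mpx_crossover",
    "split_merge_mutation",
    "roulette_select",
    "run_ilga",
]

#: fitness assigned to degenerate (zero within-cluster dispersion)
#: partitions; kept finite so downstream arithmetic stays well defined,
#: but such records are flagged and never treated as elite.
DEGENERATE_SENTINEL = float(np.finfo(np.float64).max)


@dataclass
class ClusterPartition:
    """An ordered arrangement of sample indices cut into contiguous clusters.

    ``arrangement`` is a permutation of ``0..n-1``; ``boundaries`` are
    strictly increasing cut positions in ``1..n-1``.  Cluster ``h`` holds
    ``arrangement[boundaries[h-1]:boundaries[h]]`` (with implicit 0 and n
    at the ends), so every cluster is non-empty by construction.
    """

    arrangement: np.ndarray
    boundaries: np.ndarray

    def __post_init__(self) -> None:
        self.arrangement = np.asarray(self.arrangement, dtype=np.intp)
        self.boundaries = np.asarray(self.boundaries, dtype=np.intp)
        n = self.arrangement.size
        if n == 0:
            raise ValueError("empty partition")
        if not np.array_equal(np.sort(self.arrangement), np.arange(n)):
            raise ValueError("arrangement must be a permutation of 0..n-1")
        if self.boundaries.size:
            if (np.diff(self.boundaries) <= 0).any():
                raise ValueError("boundaries must be strictly increasing")
            if self.boundaries[0] < 1 or self.boundaries[-1] > n - 1:
                raise ValueError("boundaries must lie in 1..n-1")

    @property
    def n_samples(self) -> int:
        return int(self.arrangement.size)

    @property
    def n_clusters(self) -> int:
        return int(self.boundaries.size) + 1

    def cluster_sizes(self) -> np.ndarray:
        return np.diff(self.boundaries, prepend=0,
                       append=self.arrangement.size)

    def clusters(self) -> list[np.ndarray]:
        return np.split(self.arrangement, self.boundaries)

    def labels(self) -> np.ndarray:
        """Cluster id per sample index (inverse of the grouping encoding)."""
        out = np.empty(self.n_samples, dtype=np.intp)
        out[self.arrangement] = np.repeat(np.arange(self.n_clusters),
                                          self.cluster_sizes())
        return out

    def copy(self) -> "ClusterPartition":
        return _fast_partition(self.arrangement.copy(), self.boundaries.copy())

    def write(self, path: str | Path, sample_ids: Sequence[str] | None = None) -> None:
        with open(path, "w") as fh:
            for members in self.clusters():
                names = (str(i) if sample_ids is None else sample_ids[i]
                         for i in members)
                fh.write("\t".join(names) + "\n")


def _fast_partition(arrangement: np.ndarray,
                    boundaries: np.ndarray) -> ClusterPartition:
    """Internal constructor skipping invariant validation (hot paths only;
    operators are property-tested to emit valid partitions)."""
    out = object.__new__(ClusterPartition)
    out.arrangement = arrangement
    out.boundaries = boundaries
    return out


@dataclass
class FitnessRecord:
    """Dispersion terms and Calinski-Harabasz fitness of one partition."""

    alpha_c: float
    gamma_c: float
    f_ch: float
    n_clusters: int
    n_samples: int
    degenerate: bool = False


@dataclass(frozen=True)
class IlgaConfig:
    population_size: int = 30
    generations: int = 200
    crossover_probability: float = 0.30
    mutation_probability_max: float = 0.10
    elite_count: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.crossover_probability <= 1.0:
            raise ValueError("crossover_probability must be in [0, 1]")
        if not 0.0 <= self.mutation_probability_max <= 1.0:
            raise ValueError("mutation_probability_max must be in [0, 1]")
        if not 1 <= self.elite_count < self.population_size:
            raise ValueError("need 1 <= elite_count < population_size")


def _as_array(data: BetaMatrix | np.ndarray) -> np.ndarray:
    X = data.values if isinstance(data, BetaMatrix) else np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise ValueError("data must be a 2-D samples x features array")
    if np.isnan(X).any():
        raise ValueError("data must be fully observed (impute first)")
    return X


def init_partition(n_samples: int, rng: np.random.Generator) -> ClusterPartition:
    """Random partition: uniform permutation, cluster count uniform in
    ``2..ceil(sqrt(n_samples))`` (at least 2)."""
    if n_samples < 2:
        raise ValueError("need at least 2 samples to partition")
    hi = max(2, int(np.ceil(np.sqrt(n_samples))))
    k = int(rng.integers(2, hi + 1))
    arrangement = rng.permutation(n_samples)
    boundaries = np.sort(rng.choice(np.arange(1, n_samples), size=k - 1,
                                    replace=False))
    return ClusterPartition(arrangement, boundaries)


def compute_alpha(partition: ClusterPartition,
                  data: BetaMatrix | np.ndarray) -> float:
    """Between-cluster dispersion: sum of squared centroid-to-centre
    distances weighted by cluster size."""
    X = _as_array(data)
    centre = X.mean(axis=0)
    total = 0.0
    for members in partition.clusters():
        if members.size == 0:
            raise ValueError("empty cluster")
        centroid = X[members].mean(axis=0)
        total += float(((centroid - centre) ** 2).sum()) * members.size
    return total


def compute_gamma(partition: ClusterPartition,
                  data: BetaMatrix | np.ndarray) -> float:
    """Within-cluster dispersion in the pairwise form:
    ``sum_h (1/(2 S_h)) sum_{i,j in C_h} d(i,j)^2``."""
    X = _as_array(data)
    total = 0.0
    for members in partition.clusters():
        if members.size == 0:
            raise ValueError("empty cluster")
        if members.size == 1:
            continue
        sub = X[members]
        total += float(cdist(sub, sub, "sqeuclidean").sum()) / (2.0 * members.size)
    return total


def ch_fitness(partition: ClusterPartition,
               data: BetaMatrix | np.ndarray) -> FitnessRecord:
    """Calinski-Harabasz fitness of a partition on the given data.

    A partition with zero within-cluster dispersion (e.g. all singletons)
    is flagged degenerate and given a sentinel fitness; callers must not
    treat it as elite.
    """
    X = _as_array(data)
    alpha = compute_alpha(partition, X)
    gamma = compute_gamma(partition, X)
    n, k = partition.n_samples, partition.n_clusters
    if gamma <= 0.0 or k < 2:
        return FitnessRecord(alpha, gamma, DEGENERATE_SENTINEL, k, n,
                             degenerate=True)
    f = (alpha / gamma) * (n - k) / (k - 1)
    return FitnessRecord(alpha, gamma, f, k, n)


class PartitionScorer:
    """Fast repeated fitness evaluation on one fixed data matrix.

    Precomputes the full pairwise squared-distance matrix once; each
    partition is then scored in O(n^2) index sums using the total-variance
    decomposition ``alpha = total SSD - gamma``.  Numerically equivalent
    to :func:`ch_fitness` (asserted in the test suite).
    """

    def __init__(self, data: BetaMatrix | np.ndarray):
        self.X = _as_array(data)
        self.n = self.X.shape[0]
        self.D = cdist(self.X, self.X, "sqeuclidean")
        self.total_ssd = float(self.D.sum()) / (2.0 * self.n)
        self.centre = self.X.mean(axis=0)
        centred = self.X - self.centre
        # Gram matrix of centred data: lets centroid-to-centre distances be
        # read off cluster indicator products without touching features
        self.G = centred @ centred.T

    @property
    def degenerate_data(self) -> bool:
        return self.total_ssd <= 0.0

    def _onehot(self, partition: ClusterPartition) -> tuple[np.ndarray, np.ndarray]:
        labels = partition.labels()
        k = partition.n_clusters
        onehot = np.zeros((k, self.n))
        onehot[labels, np.arange(self.n)] = 1.0
        return onehot, onehot.sum(axis=1)

    def score(self, partition: ClusterPartition) -> FitnessRecord:
        onehot, sizes = self._onehot(partition)
        pair_sums = ((onehot @ self.D) * onehot).sum(axis=1)
        gamma = float((pair_sums / (2.0 * sizes)).sum())
        alpha = max(self.total_ssd - gamma, 0.0)
        n, k = partition.n_samples, partition.n_clusters
        if gamma <= 0.0 or k < 2:
            return FitnessRecord(alpha, gamma, DEGENERATE_SENTINEL, k, n,
                                 degenerate=True)
        f = (alpha / gamma) * (n - k) / (k - 1)
        return FitnessRecord(alpha, gamma, f, k, n)

    def principal_scores(self) -> np.ndarray:
        """Sample scores on the data's first principal axis (cached)."""
        if not hasattr(self, "_pc1"):
            centred = self.X - self.centre
            if min(centred.shape) == 0 or not centred.any():
                self._pc1 = np.zeros(self.n)
            else:
                _, _, vt = np.linalg.svd(centred, full_matrices=False)
                self._pc1 = centred @ vt[0]
        return self._pc1

    def canonicalize(self, partition: ClusterPartition) -> ClusterPartition:
        """Reorder the arrangement -- without changing the grouping, hence
        the fitness -- so that items within each cluster are sorted by
        their first-principal-axis score and clusters follow their mean
        score.  Split and neighbour-merge moves then act on spatially
        coherent segments, which speeds convergence dramatically."""
        scores = self.principal_scores()
        labels = partition.labels()
        k = partition.n_clusters
        sizes = np.bincount(labels, minlength=k)
        means = np.bincount(labels, weights=scores, minlength=k) / sizes
        cluster_order = np.argsort(means, kind="stable")
        rank = np.empty(k, dtype=np.intp)
        rank[cluster_order] = np.arange(k)
        order = np.lexsort((scores, rank[labels]))
        boundaries = np.cumsum(sizes[cluster_order])[:-1]
        return _fast_partition(order.astype(np.intp), boundaries)

    def nearest_cluster_to_centre(self, partition: ClusterPartition) -> int:
        """Index of the cluster whose centroid is closest to the overall
        centroid -- the MPX transplant target."""
        onehot, sizes = self._onehot(partition)
        d = ((onehot @ self.G) * onehot).sum(axis=1) / sizes**2
        return int(np.argmin(d))


def _remove_items(partition: ClusterPartition,
                  removed: set[int]) -> tuple[list[int], list[int]]:
    """Drop ``removed`` items from a partition, preserving order and the
    surviving cluster structure.  Returns (arrangement, cluster sizes)."""
    arrangement: list[int] = []
    sizes: list[int] = []
    for members in partition.clusters():
        kept = [int(i) for i in members if int(i) not in removed]
        if kept:
            arrangement.extend(kept)
            sizes.append(len(kept))
    return arrangement, sizes


def _mpx_child(p_main: ClusterPartition, p_other: ClusterPartition,
               scorer: PartitionScorer, rng: np.random.Generator) -> ClusterPartition:
    """One MPX offspring.

    A substring of p_main's centre-nearest cluster (the least distinctive
    one) is removed; its items re-enter in p_other's relative order,
    sequentially added to the tail of p_main's remainder -- they extend
    the final surviving cluster rather than opening new ones, and the
    split mutation can carve them off again later.  This keeps the
    operator a strong merger, countering the objective's known bias
    toward fragmenting clusters.
    """
    target = scorer.nearest_cluster_to_centre(p_main)
    cluster = p_main.clusters()[target]
    size = int(rng.integers(1, cluster.size + 1))
    cut = int(rng.integers(0, cluster.size))
    substring = {int(i) for i in cluster[cut:cut + size]}
    if len(substring) == p_main.n_samples:  # whole sample set: child = p_other
        return p_other.copy()

    remainder, sizes = _remove_items(p_main, substring)
    appended = [int(i) for i in p_other.arrangement if int(i) in substring]
    sizes[-1] += len(appended)

    arrangement = np.array(remainder + appended, dtype=np.intp)
    boundaries = np.cumsum(sizes)[:-1]
    return _fast_partition(arrangement, np.asarray(boundaries, dtype=np.intp))


def mpx_crossover(parent1: ClusterPartition, parent2: ClusterPartition,
                  data: BetaMatrix | np.ndarray | PartitionScorer,
                  rng: np.random.Generator) -> ClusterPartition:
    """Modified MPX: build one offspring from each parent and keep the
    fitter of the two."""
    if parent1.n_samples != parent2.n_samples:
        raise ValueError("parents must partition the same sample set")
    scorer = data if isinstance(data, PartitionScorer) else PartitionScorer(data)
    child_a = _mpx_child(parent1, parent2, scorer, rng)
    child_b = _mpx_child(parent2, parent1, scorer, rng)
    rec_a, rec_b = scorer.score(child_a), scorer.score(child_b)
    # a degenerate child never wins against a non-degenerate one
    if rec_a.degenerate != rec_b.degenerate:
        return child_b if rec_a.degenerate else child_a
    return child_a if rec_a.f_ch >= rec_b.f_ch else child_b


def split_merge_mutation(partition: ClusterPartition, probability: float,
                         rng: np.random.Generator) -> ClusterPartition:
    """With the given probability, split one cluster at a random interior
    point or merge two neighbouring clusters (uniform over the feasible
    move types); otherwise return the partition unchanged."""
    if not 0.0 <= probability <= 1.0:
        raise ValueError("probability must be in [0, 1]")
    if probability == 0.0 or rng.random() >= probability:
        return partition.copy()
    n = partition.n_samples
    cuts = set(int(b) for b in partition.boundaries)
    can_split = len(cuts) < n - 1
    can_merge = len(cuts) >= 1
    moves = [m for m, ok in (("split", can_split), ("merge", can_merge)) if ok]
    if not moves:  # n == 1 cannot occur (init requires n >= 2)
        return partition.copy()
    move = moves[int(rng.integers(len(moves)))]
    if move == "split":
        candidates = np.setdiff1d(np.arange(1, n), np.array(sorted(cuts), dtype=int))
        cuts.add(int(rng.choice(candidates)))
    else:
        cuts.remove(int(rng.choice(np.array(sorted(cuts), dtype=int))))
    return _fast_partition(partition.arrangement.copy(),
                           np.array(sorted(cuts), dtype=np.intp))


def roulette_select(population: Sequence, fitnesses: Sequence[float],
                    rng: np.random.Generator):
    """Roulette-wheel selection on min-shifted fitness.

    Fitness values are shifted so the minimum maps to zero (plus a tiny
    epsilon floor so a uniform population stays selectable); selection
    probability is proportional to the shifted value.
    """
    if len(population) == 0:
        raise ValueError("empty population")
    f = np.asarray(fitnesses, dtype=float)
    if not np.isfinite(f).all():
        raise ValueError("fitnesses must be finite")
    shifted = f - f.min()
    total = shifted.sum()
    if total <= 0.0:
        return population[int(rng.integers(f.size))]
    wheel = np.cumsum(shifted)
    idx = int(np.searchsorted(wheel, rng.random() * total, side="right"))
    return population[min(idx, f.size - 1)]


@dataclass
class IlgaResult:
    best_partition: ClusterPartition
    best_record: FitnessRecord
    history: pd.DataFrame  # columns: generation, best, mean


def _selection_fitness(records: list[FitnessRecord]) -> np.ndarray:
    """Finite fitness vector for roulette: degenerate records get the
    population minimum (no selection advantage)."""
    f = np.array([r.f_ch for r in records])
    ok = ~np.array([r.degenerate for r in records])
    floor = f[ok].min() if ok.any() else 0.0
    f[~ok] = floor
    return f


def _best_index(records: list[FitnessRecord]) -> int:
    """Index of the fittest non-degenerate record (falls back to 0 when
    every record is degenerate)."""
    best, best_f = None, -np.inf
    for i, r in enumerate(records):
        if not r.degenerate and r.f_ch > best_f:
            best, best_f = i, r.f_ch
    return 0 if best is None else best


def run_ilga(data: BetaMatrix | np.ndarray, config: IlgaConfig,
             scorer: PartitionScorer | None = None) -> IlgaResult:
    """Evolve sample partitions on (masked) data; returns the best
    partition, its fitness record and the per-generation history.

    Elitism copies the ``elite_count`` fittest non-degenerate individuals
    unchanged, so the best-fitness trajectory is non-decreasing.  The
    split/merge mutation probability ramps linearly from 0 to the cap over
    the configured generations.  Fully deterministic for a fixed seed.
    """
    if scorer is None:
        scorer = PartitionScorer(data)
    n = scorer.n
    if n < 2:
        raise ValueError("need at least 2 samples")
    rng = np.random.default_rng(config.seed)

    if scorer.degenerate_data:
        part = init_partition(n, rng)
        rec = replace(scorer.score(part), degenerate=True)
        history = pd.DataFrame({"generation": [0], "best": [np.nan],
                                "mean": [np.nan]})
        return IlgaResult(part, rec, history)

    population = [scorer.canonicalize(init_partition(n, rng))
                  for _ in range(config.population_size)]
    records = [scorer.score(p) for p in population]
    rows = []

    def log(gen: int) -> None:
        finite = [r.f_ch for r in records if not r.degenerate]
        rows.append((gen, max(finite) if finite else np.nan,
                     float(np.mean(finite)) if finite else np.nan))

    log(0)
    for gen in range(1, config.generations + 1):
        order = np.argsort([-r.f_ch if not r.degenerate else np.inf
                            for r in records], kind="stable")
        elites = [population[i].copy() for i in order[: config.elite_count]]
        sel_f = _selection_fitness(records)
        p_mut = config.mutation_probability_max * gen / config.generations

        new_pop = elites
        while len(new_pop) < config.population_size:
            if rng.random() < config.crossover_probability:
                p1 = roulette_select(population, sel_f, rng)
                p2 = roulette_select(population, sel_f, rng)
                child = mpx_crossover(p1, p2, scorer, rng)
            else:
                child = roulette_select(population, sel_f, rng).copy()
            child = split_merge_mutation(scorer.canonicalize(child), p_mut, rng)
            new_pop.append(child)
        population = new_pop
        records = [scorer.score(p) for p in population]
        log(gen)

    best = _best_index(records)
    history = pd.DataFrame(rows, columns=["generation", "best", "mean"])
    return IlgaResult(population[best].copy(), records[best], history)
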