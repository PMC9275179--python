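"""Outer-layer genetic algorithm: unsupervised CpG feature selection.

Each chromosome is a binary mask over the platform's loci.  A mask has no
fitness of its own: it is scored by restricting the cohort to the selected
loci and running the inner clustering GA (:mod:`methylga.ilga`) to
convergence -- the converged Calinski-Harabasz fitness of the best
partition on the masked data is the mask's fitness.  Better cluster
separability on a locus subset is taken as evidence that the subset
carries the cohort's structure and the rest is noise.

Operators: single-point crossover, roulette selection, elitism, and an
adaptive bit-flip mutation whose per-bit rate rises toward a 5% cap as the
population converges (average fitness approaching the best).

Masks selected per cancer type are intersected across types to obtain the
common pan-cancer locus set consumed by the classification stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .ilga import FitnessRecord, IlgaConfig, run_ilga
from .methyl_data import BetaMatrix
from .platforms import Platform

__all__ = [
    "FeatureMask",
    "OlgaConfig",
    "OlgaResult",
    "single_point_crossover",
    "adaptive_bitflip_mutation",
    "evaluate_mask",
    "run_olga",
    "reduction_report",
    "common_features",
    "chromosome_seed",
]


@dataclass
class FeatureMask:
    """Binary selection vector over a platform's CpG loci."""

    bits: np.ndarray
    platform: Platform

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=bool)
        if self.bits.shape != (self.platform.n_loci,):
            raise ValueError(
                f"mask length {self.bits.size} != platform locus count "
                f"{self.platform.n_loci}")

    @property
    def n_selected(self) -> int:
        return int(self.bits.sum())

    def copy(self) -> "FeatureMask":
        return FeatureMask(self.bits.copy(), self.platform)

    def selected_locus_ids(self, locus_ids: Sequence[str]) -> list[str]:
        return [l for l, b in zip(locus_ids, self.bits) if b]

    def write_locus_ids(self, path: str | Path, locus_ids: Sequence[str]) -> None:
        with open(path, "w") as fh:
            for locus in self.selected_locus_ids(locus_ids):
                fh.write(locus + "\n")

    def write_bits_csv(self, path: str | Path, locus_ids: Sequence[str]) -> None:
        pd.Series(self.bits.astype(int), index=list(locus_ids),
                  name="selected").to_csv(path, index_label="locus_id")

    @classmethod
    def read_locus_ids(cls, path: str | Path, locus_ids: Sequence[str],
                       platform: Platform) -> "FeatureMask":
        selected = {line.strip() for line in open(path) if line.strip()}
        bits = np.array([l in selected for l in locus_ids])
        return cls(bits, platform)


@dataclass(frozen=True)
class OlgaConfig:
    population_size: int = 30
    generations: int = 100
    mutation_probability_max: float = 0.05
    elite_count: int = 1
    ilga_config: IlgaConfig = field(default_factory=IlgaConfig)
    seed: int = 0
    n_jobs: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.mutation_probability_max <= 1.0:
            raise ValueError("mutation_probability_max must be in [0, 1]")
        if not 1 <= self.elite_count < self.population_size:
            raise ValueError("need 1 <= elite_count < population_size")


def single_point_crossover(p1: FeatureMask, p2: FeatureMask,
                           rng: np.random.Generator) -> tuple[FeatureMask, FeatureMask]:
    """Swap the tails of two masks after one uniform cut point."""
    if p1.bits.size != p2.bits.size:
        raise ValueError("mask length mismatch")
    cut = int(rng.integers(1, p1.bits.size))
    a = np.concatenate([p1.bits[:cut], p2.bits[cut:]])
    b = np.concatenate([p2.bits[:cut], p1.bits[cut:]])
    return FeatureMask(a, p1.platform), FeatureMask(b, p2.platform)


def adaptive_bitflip_mutation(mask: FeatureMask, f_best: float, f_avg: float,
                              rng: np.random.Generator,
                              p_max: float = 0.05) -> FeatureMask:
    """Flip each bit independently with probability ``p_max * f_avg/f_best``.

    ``f_best``/``f_avg`` are the shifted (non-negative) best and average
    fitness of the latest generation, so the rate approaches the cap as
    the population converges and stays low while fitness is still spread
    out.  ``f_best = 0`` disables mutation.
    """
    if f_avg < 0 or f_best < f_avg:
        raise ValueError("need f_best >= f_avg >= 0 (shifted fitness)")
    p = 0.0 if f_best == 0 else min(p_max * (f_avg / f_best), p_max)
    out = mask.copy()
    if p > 0:
        flips = rng.random(out.bits.size) < p
        out.bits[flips] = ~out.bits[flips]
    return out


def evaluate_mask(mask: FeatureMask, data: BetaMatrix,
                  ilga_config: IlgaConfig) -> FitnessRecord:
    """Fitness of a mask: converged inner-GA fitness on the masked cohort.

    The mask multiplies the feature space -- unselected loci are dropped
    before clustering -- and the best partition's Calinski-Harabasz record
    after the inner GA converges is returned as the mask's fitness.
    """
    if mask.n_selected < 2:
        raise ValueError("mask must select at least 2 loci to be evaluable")
    X = data.values[:, mask.bits]
    if np.isnan(X).any():
        raise ValueError("data must be fully observed (impute first)")
    return run_ilga(X, ilga_config).best_record


def chromosome_seed(master_seed: int, generation: int, index: int) -> int:
    """Stable per-chromosome seed so concurrent evaluation reproduces the
    sequential result bit for bit."""
    ss = np.random.SeedSequence(entropy=master_seed,
                                spawn_key=(generation, index))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class OlgaResult:
    best_mask: FeatureMask
    best_record: FitnessRecord
    history: pd.DataFrame  # columns: generation, best_fitness, n_selected


def run_olga(data: BetaMatrix, config: OlgaConfig) -> OlgaResult:
    """Evolve feature masks on a single-cancer-type cohort.

    Each chromosome's inner-GA evaluation is independent (fresh inner run,
    per-chromosome derived seed) and may execute concurrently
    (``config.n_jobs > 1``); results are combined in chromosome order, so
    parallel and sequential runs are identical.
    """
    if data.n_samples < 4:
        raise ValueError("cohort too small for feature selection (< 4 samples)")
    if np.isnan(data.values).any():
        raise ValueError("data must be fully observed (impute first)")
    n_loci = data.n_loci
    rng = np.random.default_rng(config.seed)

    population = []
    for _ in range(config.population_size):
        bits = rng.random(n_loci) < 0.5
        if bits.sum() < 2:  # guarantee evaluable masks
            bits[rng.choice(n_loci, size=2, replace=False)] = True
        population.append(FeatureMask(bits, data.platform))

    def evaluate_many(masks: list[FeatureMask], gen: int,
                      indices: list[int]) -> list[FitnessRecord]:
        def one(mask: FeatureMask, index: int) -> FitnessRecord:
            cfg = replace(config.ilga_config,
                          seed=chromosome_seed(config.seed, gen, index))
            return evaluate_mask(mask, data, cfg)

        if config.n_jobs == 1 or len(masks) <= 1:
            return [one(m, i) for m, i in zip(masks, indices)]
        results = Parallel(n_jobs=config.n_jobs, prefer="threads")(
            delayed(one)(m, i) for m, i in zip(masks, indices))
        return list(results)

    def _best_index(recs: list[FitnessRecord]) -> int:
        best, best_f = 0, -np.inf
        for i, r in enumerate(recs):
            if not r.degenerate and r.f_ch > best_f:
                best, best_f = i, r.f_ch
        return best

    def finite_fitness(recs: list[FitnessRecord]) -> np.ndarray:
        f = np.array([r.f_ch for r in recs])
        deg = np.array([r.degenerate for r in recs])
        floor = f[~deg].min() if (~deg).any() else 0.0
        f[deg] = floor
        return f

    records = evaluate_many(population, 0, list(range(len(population))))
    rows = []

    def log(gen: int) -> None:
        i = _best_index(records)
        rows.append((gen, records[i].f_ch if not records[i].degenerate else np.nan,
                     population[i].n_selected))

    log(0)
    for gen in range(1, config.generations + 1):
        sel_f = finite_fitness(records)
        shifted = sel_f - sel_f.min()
        f_best, f_avg = float(shifted.max()), float(shifted.mean())
        order = np.argsort(-sel_f, kind="stable")
        # elites are copied together with their fitness records: the inner
        # GA is not re-run for an unchanged chromosome, so the elite
        # trajectory is monotone
        elites = [population[i].copy() for i in order[: config.elite_count]]
        elite_records = [records[i] for i in order[: config.elite_count]]

        probs = shifted / shifted.sum() if shifted.sum() > 0 else \
            np.full(len(population), 1.0 / len(population))

        children: list[FeatureMask] = []
        n_children = config.population_size - config.elite_count
        while len(children) < n_children:
            i1 = int(rng.choice(len(population), p=probs))
            i2 = int(rng.choice(len(population), p=probs))
            c1, c2 = single_point_crossover(population[i1], population[i2], rng)
            for child in (c1, c2):
                if len(children) >= n_children:
                    break
                child = adaptive_bitflip_mutation(
                    child, f_best, f_avg, rng,
                    p_max=config.mutation_probability_max)
                if child.n_selected < 2:
                    child.bits[rng.choice(n_loci, size=2, replace=False)] = True
                children.append(child)
        child_records = evaluate_many(
            children, gen,
            list(range(config.elite_count, config.population_size)))
        population = elites + children
        records = elite_records + child_records
        log(gen)

    best = _best_index(records)
    history = pd.DataFrame(rows, columns=["generation", "best_fitness",
                                          "n_selected"])
    return OlgaResult(population[best].copy(), records[best], history)


def reduction_report(mask: FeatureMask) -> tuple[int, float]:
    """Selected-locus count and percent dimensionality reduction."""
    n = mask.n_selected
    return n, 100.0 * (1.0 - n / mask.bits.size)


def common_features(masks: Sequence[FeatureMask]) -> FeatureMask:
    """Bitwise intersection of per-cancer masks: the common pan-cancer loci."""
    if not masks:
        raise ValueError("need at least one mask")
    platform = masks[0].platform
    for m in masks[1:]:
        if m.platform.n_loci != platform.n_loci:
            raise ValueError("platform mismatch across masks")
    bits = np.logical_and.reduce([m.bits for m in masks])
    if not bits.any():
        warnings.warn("common-feature intersection is empty", stacklevel=2)
    return FeatureMask(bits, platform)
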