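"""Synthetic methylation cohorts with known informative loci.

Real Illumina beta values are strongly bimodal: most probes sit near the
unmethylated (beta ~ 0.1-0.2) or methylated (beta ~ 0.8-0.9) mode.  The
generator emulates that shape with Beta-distributed draws around
class-specific modes.  Informative loci get class-conditional modes
``0.5 +/- separation/2`` (a hypo/hyper-methylated contrast between
classes); noise loci get one mode shared by every class.  Platform-style
missingness is injected cell-wise at a configurable rate.

The generator emits the same containers and CSV dialect as
:mod:`methylga.methyl_data`, plus a :class:`CohortTruth` naming the
informative loci so downstream feature selection can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .methyl_data import BetaMatrix
from .platforms import Platform, custom

__all__ = ["CohortSpec", "CohortTruth", "generate_cohort", "inject_missing"]


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters for one synthetic cohort.

    Defaults describe the desk-scale condition used throughout the test
    suite: a 500-probe custom platform with 50 label-informative loci,
    three cancer types of 20 samples each, and a between-class mode
    separation of 0.6 beta units.
    """

    n_samples_per_class: int = 20
    class_labels: tuple[tuple[str, bool], ...] = (
        ("BRCA", True), ("OV", True), ("STAD", True))
    n_informative_loci: int = 50
    n_noise_loci: int = 450
    informative_separation: float = 0.6
    noise_concentration: float = 30.0
    missing_rate: float = 0.0
    platform: Platform | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples_per_class < 2:
            raise ValueError("need at least 2 samples per class")
        if not 0.0 < self.informative_separation <= 1.0:
            raise ValueError("informative_separation must be in (0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.noise_concentration <= 0:
            raise ValueError("noise_concentration must be positive")
        total = self.n_informative_loci + self.n_noise_loci
        if self.platform is not None and self.platform.n_loci != total:
            raise ValueError(
                f"locus budget {total} does not match platform "
                f"{self.platform.n_loci} loci")

    @property
    def resolved_platform(self) -> Platform:
        return self.platform or custom(self.n_informative_loci + self.n_noise_loci)


@dataclass
class CohortTruth:
    """Ground truth for a generated cohort."""

    informative_locus_ids: set[str]
    class_of_sample: dict[str, str]

    def write_locus_ids(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for locus in sorted(self.informative_locus_ids):
                fh.write(locus + "\n")


def _beta_draw(rng: np.random.Generator, mode: float, concentration: float,
               size: int) -> np.ndarray:
    """Draw from a Beta distribution with the given mean and concentration."""
    mode = float(np.clip(mode, 0.02, 0.98))
    a = mode * concentration
    b = (1.0 - mode) * concentration
    return rng.beta(a, b, size=size)


def generate_cohort(spec: CohortSpec) -> tuple[BetaMatrix, CohortTruth]:
    """Generate a labelled beta matrix plus its ground truth, reproducibly.

    Informative loci: each class is assigned, per locus, either the hypo
    mode ``0.5 - separation/2`` or the hyper mode ``0.5 + separation/2``
    (random, but never the same mode for all classes at one locus).  Noise
    loci: a single random bimodal mode shared across classes.
    """
    rng = np.random.default_rng(spec.seed)
    platform = spec.resolved_platform
    n_classes = len(spec.class_labels)
    n_total = spec.n_samples_per_class * n_classes
    n_loci = spec.n_informative_loci + spec.n_noise_loci

    lo = 0.5 - spec.informative_separation / 2.0
    hi = 0.5 + spec.informative_separation / 2.0

    # per (class, informative locus) mode assignment; re-draw any locus on
    # which every class landed in the same mode, so each informative locus
    # really separates at least one pair of classes
    assign = rng.integers(0, 2, size=(n_classes, spec.n_informative_loci))
    degenerate = np.flatnonzero(assign.min(0) == assign.max(0))
    for j in degenerate:
        flip = rng.integers(0, n_classes)
        assign[flip, j] ^= 1
    info_modes = np.where(assign == 1, hi, lo)  # (n_classes, n_informative)

    noise_modes = rng.choice([lo, hi], size=spec.n_noise_loci)

    values = np.empty((n_total, n_loci))
    sample_ids: list[str] = []
    cancer_types: list[str] = []
    malignant: list[bool] = []
    for c, (cancer_type, is_malignant) in enumerate(spec.class_labels):
        rows = slice(c * spec.n_samples_per_class, (c + 1) * spec.n_samples_per_class)
        for j in range(spec.n_informative_loci):
            values[rows, j] = _beta_draw(rng, info_modes[c, j],
                                         spec.noise_concentration,
                                         spec.n_samples_per_class)
        for i in range(spec.n_samples_per_class):
            sid = f"{cancer_type}-{'t' if is_malignant else 'n'}{i:03d}"
            sample_ids.append(sid)
            cancer_types.append(cancer_type)
            malignant.append(is_malignant)
    # noise loci: identical distribution for all classes
    for j in range(spec.n_noise_loci):
        values[:, spec.n_informative_loci + j] = _beta_draw(
            rng, noise_modes[j], spec.noise_concentration, n_total)

    locus_ids = [f"cg{j:08d}" for j in range(n_loci)]
    labels = pd.DataFrame({"cancer_type": cancer_types, "malignant": malignant},
                          index=pd.Index(sample_ids, name="sample_id"))
    matrix = BetaMatrix(sample_ids, locus_ids, values, platform, labels)
    if spec.missing_rate > 0:
        matrix = inject_missing(matrix, spec.missing_rate,
                                seed=int(rng.integers(2**31)))
    truth = CohortTruth(
        informative_locus_ids=set(locus_ids[: spec.n_informative_loci]),
        class_of_sample=dict(zip(sample_ids, cancer_types)))
    return matrix, truth


def inject_missing(matrix: BetaMatrix, rate: float, seed: int) -> BetaMatrix:
    """Set each cell missing independently with probability ``rate``."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    out = matrix.copy()
    if rate == 0.0:
        return out
    rng = np.random.default_rng(seed)
    mask = rng.random(out.values.shape) < rate
    out.values[mask] = np.nan
    return out
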