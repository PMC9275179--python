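"""Beta-value matrices: computation, validation, preprocessing and I/O.

The central container is :class:`BetaMatrix`: a samples x CpG-loci matrix of
methylation beta values in ``[0, 1]`` with ``NaN`` marking missing probes,
plus per-sample labels (cancer type, malignant flag).

Preprocessing follows the standard array pipeline: samples with too many
missing probes are rejected (strictly more than 10% on 27k arrays, 20% on
450k arrays), then remaining gaps are filled by per-sample linear
regression on locus index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .platforms import Platform, custom

__all__ = [
    "MethylationSignal",
    "BetaMatrix",
    "FilterResult",
    "compute_beta",
    "missing_fraction",
    "filter_samples",
    "impute_missing",
    "assemble_matrix",
    "read_beta_csv",
    "write_beta_csv",
    "read_labels_csv",
    "write_labels_csv",
]


@dataclass(frozen=True)
class MethylationSignal:
    """Raw fluorescence intensities for one CpG probe.

    ``methylated_intensity`` (M) and ``unmethylated_intensity`` (U) are in
    arbitrary fluorescence units; ``offset`` is the calibration constant
    added to the denominator (Illumina default 100) that stabilises the
    ratio when both intensities are near zero.
    """

    methylated_intensity: float
    unmethylated_intensity: float
    offset: float = 100.0

    def __post_init__(self) -> None:
        if self.offset <= 0:
            raise ValueError("offset must be positive")


def compute_beta(
    signal: MethylationSignal | None = None,
    *,
    methylated: float | None = None,
    unmethylated: float | None = None,
    offset: float = 100.0,
) -> float:
    """Beta value of one probe: ``max(M,0) / (max(M,0) + max(U,0) + offset)``.

    Negative intensities are clamped to zero, so the result lies in
    ``[0, 1)`` and equals 0 exactly when no methylated signal was detected.
    """
    if signal is None:
        if methylated is None or unmethylated is None:
            raise TypeError("provide a MethylationSignal or M/U keyword intensities")
        signal = MethylationSignal(methylated, unmethylated, offset)
    m = max(signal.methylated_intensity, 0.0)
    u = max(signal.unmethylated_intensity, 0.0)
    return m / (m + u + signal.offset)


@dataclass
class BetaMatrix:
    """Samples x loci matrix of beta values with labels.

    ``values`` is float with ``NaN`` for missing probes; every non-missing
    entry lies in ``[0, 1]``.  ``labels`` maps each sample id to a
    ``(cancer_type, malignant)`` pair and may be empty for unlabeled data.
    """

    sample_ids: list[str]
    locus_ids: list[str]
    values: np.ndarray
    platform: Platform
    labels: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["cancer_type", "malignant"]))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.locus_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.locus_ids)} loci")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample ids must be unique")
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise ValueError("locus ids must be unique")
        finite = self.values[~np.isnan(self.values)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            raise ValueError("beta values must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample {sample_id!r}") from None

    def select_samples(self, indices: Sequence[int]) -> "BetaMatrix":
        ids = [self.sample_ids[i] for i in indices]
        labels = self.labels.loc[self.labels.index.intersection(ids)].reindex(
            [i for i in ids if i in self.labels.index])
        return BetaMatrix(ids, list(self.locus_ids),
                          self.values[list(indices)].copy(),
                          self.platform, labels)

    def select_loci(self, mask: np.ndarray) -> "BetaMatrix":
        """Restrict columns to ``mask`` (boolean over loci); platform becomes custom."""
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (self.n_loci,):
            raise ValueError("locus mask length mismatch")
        loci = [l for l, keep in zip(self.locus_ids, mask) if keep]
        return BetaMatrix(list(self.sample_ids), loci,
                          self.values[:, mask].copy(),
                          custom(len(loci)), self.labels.copy())

    def copy(self) -> "BetaMatrix":
        return BetaMatrix(list(self.sample_ids), list(self.locus_ids),
                          self.values.copy(), self.platform, self.labels.copy())


def missing_fraction(matrix: BetaMatrix, sample_id: str) -> float:
    """Fraction of a sample's loci that are missing."""
    row = matrix.values[matrix.sample_index(sample_id)]
    return float(np.isnan(row).mean())


@dataclass
class FilterResult:
    """Outcome of sample rejection: the retained matrix plus a log of
    ``(sample_id, missing_fraction)`` pairs for every rejected sample."""

    matrix: BetaMatrix
    rejected: list[tuple[str, float]]

    def write_log(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for sid, frac in self.rejected:
                fh.write(f"{sid}\t{frac:.6g}\n")


def filter_samples(matrix: BetaMatrix, threshold: float | None = None) -> FilterResult:
    """Reject samples whose missing fraction strictly exceeds the threshold.

    The threshold comes from the platform (10% for 27k, 20% for 450k) unless
    given explicitly; custom platforms require an explicit value.  Samples at
    exactly the threshold are retained.  The input matrix is not modified.
    """
    if threshold is None:
        threshold = matrix.platform.rejection_threshold
        if threshold is None:
            raise ValueError(
                "custom platform: an explicit rejection threshold is required")
    fractions = np.isnan(matrix.values).mean(axis=1)
    keep = fractions <= threshold
    rejected = [(sid, float(frac))
                for sid, frac, k in zip(matrix.sample_ids, fractions, keep) if not k]
    if not keep.any():
        raise ValueError("empty cohort: every sample exceeded the missingness threshold")
    kept = matrix.select_samples(np.flatnonzero(keep))
    return FilterResult(kept, rejected)


def _impute_row(row: np.ndarray, k: int = 4) -> np.ndarray:
    """Fill NaNs in one sample by linear regression of beta on locus index.

    Interior gaps reduce to linear interpolation between the flanking
    observed loci; gaps at either edge are extrapolated from the straight
    line fitted to the k nearest observed loci.  Results are clamped to
    [0, 1].
    """
    missing = np.isnan(row)
    if not missing.any():
        return row
    obs = np.flatnonzero(~missing)
    if obs.size == 0:
        raise ValueError("cannot impute a sample with no observed loci")
    out = row.copy()
    idx = np.arange(row.size)
    # interior gaps: piecewise-linear between flanking neighbours
    out[missing] = np.interp(idx[missing], obs, row[obs])
    # edges: least-squares line through the k nearest observed loci
    lead = np.flatnonzero(missing & (idx < obs[0]))
    trail = np.flatnonzero(missing & (idx > obs[-1]))
    for gap, nearest in ((lead, obs[:k]), (trail, obs[-k:])):
        if gap.size == 0:
            continue
        if nearest.size == 1:
            out[gap] = row[nearest[0]]
            continue
        slope, intercept = np.polyfit(nearest, row[nearest], 1)
        out[gap] = slope * gap + intercept
    return np.clip(out, 0.0, 1.0)


def impute_missing(matrix: BetaMatrix, k_neighbors: int = 4) -> BetaMatrix:
    """Return a fully observed copy; non-missing values are untouched."""
    values = matrix.values.copy()
    for i in range(matrix.n_samples):
        if np.isnan(values[i]).any():
            try:
                values[i] = _impute_row(values[i], k=k_neighbors)
            except ValueError as exc:
                raise ValueError(
                    f"sample {matrix.sample_ids[i]!r}: {exc}") from None
    return BetaMatrix(list(matrix.sample_ids), list(matrix.locus_ids),
                      values, matrix.platform, matrix.labels.copy())


def assemble_matrix(
    per_sample: Iterable[tuple[str, Mapping[str, float]]],
    labels: pd.DataFrame | None,
    locus_universe: Sequence[str],
    platform: Platform | None = None,
) -> BetaMatrix:
    """Assemble per-sample ``locus -> beta`` maps into one matrix.

    Row order follows input sample order; column order follows
    ``locus_universe``.  Loci absent from a sample's map are set missing.
    A locus outside the universe is a schema error; duplicate sample ids
    are rejected.
    """
    locus_universe = list(locus_universe)
    universe = {l: j for j, l in enumerate(locus_universe)}
    sample_ids: list[str] = []
    rows: list[np.ndarray] = []
    for sid, mapping in per_sample:
        if sid in sample_ids:
            raise ValueError(f"duplicate sample id {sid!r}")
        row = np.full(len(locus_universe), np.nan)
        for locus, beta in mapping.items():
            j = universe.get(locus)
            if j is None:
                raise ValueError(f"locus {locus!r} not in platform universe")
            row[j] = beta
        sample_ids.append(sid)
        rows.append(row)
    if platform is None:
        platform = custom(len(locus_universe))
    if labels is None:
        labels = pd.DataFrame(columns=["cancer_type", "malignant"])
    return BetaMatrix(sample_ids, locus_universe,
                      np.vstack(rows) if rows else np.empty((0, len(locus_universe))),
                      platform, labels)


# ---------------------------------------------------------------------------
# CSV dialect: first row = locus ids, first column = sample id, empty cell =
# missing, UTF-8, comma separated.  Labels: sample_id,cancer_type,malignant.
# ---------------------------------------------------------------------------

def write_beta_csv(matrix: BetaMatrix, path: str | Path) -> None:
    df = pd.DataFrame(matrix.values, index=matrix.sample_ids,
                      columns=matrix.locus_ids)
    df.index.name = "sample_id"
    df.to_csv(path, float_format="%.10g", na_rep="")


def read_beta_csv(path: str | Path, platform: Platform | None = None,
                  labels: pd.DataFrame | None = None) -> BetaMatrix:
    df = pd.read_csv(path, index_col=0)
    if platform is None:
        platform = custom(df.shape[1])
    if labels is None:
        labels = pd.DataFrame(columns=["cancer_type", "malignant"])
    return BetaMatrix([str(s) for s in df.index],
                      [str(l) for l in df.columns],
                      df.to_numpy(dtype=float), platform, labels)


def write_labels_csv(labels: pd.DataFrame, path: str | Path) -> None:
    out = labels.copy()
    out["malignant"] = out["malignant"].astype(int)
    out.index.name = "sample_id"
    out.to_csv(path)


def read_labels_csv(path: str | Path) -> pd.DataFrame:
    labels = pd.read_csv(path, index_col=0)
    required = {"cancer_type", "malignant"}
    if not required.issubset(labels.columns):
        missing = ", ".join(sorted(required - set(labels.columns)))
        raise ValueError(f"labels file {path}: missing column(s) {missing}")
    mapping = {0: False, 1: True, "0": False, "1": True,
               False: False, True: True, "False": False, "True": True}
    flags = labels["malignant"].map(mapping)
    if flags.isna().any():
        line = int(np.flatnonzero(flags.isna().to_numpy())[0]) + 2  # header = line 1
        raise ValueError(f"labels file {path}: line {line}: malignant must be 0 or 1")
    labels.index = labels.index.astype(str)
    labels["malignant"] = flags.astype(bool)
    return labels
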